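"""Bill-corolla trait matching: morphometric ratios and their PCA reduction.

Matching is quantified as ratios of bird to floral linear morphometrics
(e.g. bill length / total corolla length).  A ratio of 1 means the two
structures have the same size; <1 the flower is larger, >1 the bill is
larger.  The ratios plus tarsus length (a body-size proxy) are reduced
by a centred-and-scaled (correlation-matrix) PCA, run separately for
pollen-donor and pollen-receiver flowers because anther distances exist
only on donor flowers and stigma distances only on receivers.  Models
downstream use the absolute value of the PC scores: 0 is the closest
bill-corolla match, larger magnitudes mean more mismatch in either
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "MatchingError",
    "PCResult",
    "compute_ratios",
    "matching_table",
    "run_pca",
    "abs_scores",
    "DONOR_VARIABLES",
    "RECEIVER_VARIABLES",
]

# ratio name -> (bird column, floral column)
_RATIO_DEFS = {
    "BL_TCL": ("bill_length", "TCL"),
    "BL_ECL": ("bill_length", "ECL"),
    "BW_CW": ("bill_width", "CW"),
    "BL_ACO": ("bill_length", "ACO"),
    "BL_AN": ("bill_length", "AN"),
    "BL_SCO": ("bill_length", "SCO"),
    "BL_SN": ("bill_length", "SN"),
}

DONOR_VARIABLES = ["BL_TCL", "BL_ECL", "BW_CW", "BL_ACO", "BL_AN", "tarsus"]
RECEIVER_VARIABLES = ["BL_TCL", "BL_ECL", "BW_CW", "BL_SCO", "BL_SN", "tarsus"]


class MatchingError(ValueError):
    """Invalid or missing measurement for a matching computation."""


def compute_ratios(bird, flower) -> dict[str, float]:
    """Bill-corolla matching ratios for one bird x flower interaction.

    ``bird`` and ``flower`` are mappings (e.g. DataFrame rows).  Only the
    ratios whose floral measurement is present for the flower's role are
    returned; tarsus length is copied through to account for body size.
    """
    out: dict[str, float] = {}
    for name, (bcol, fcol) in _RATIO_DEFS.items():
        denom = flower.get(fcol) if hasattr(flower, "get") else getattr(flower, fcol, None)
        if denom is None or (isinstance(denom, float) and np.isnan(denom)):
            continue
        if denom <= 0:
            raise MatchingError(f"floral measurement {fcol} must be positive, got {denom}")
        num = bird[bcol] if not hasattr(bird, "get") else bird.get(bcol)
        if num is None or num <= 0:
            raise MatchingError(f"bird measurement {bcol} must be positive, got {num}")
        out[name] = float(num) / float(denom)
    if not out:
        raise MatchingError("no floral measurements present; cannot compute any ratio")
    out["tarsus"] = float(bird["tarsus"])
    return out


def matching_table(birds: pd.DataFrame, flowers: pd.DataFrame,
                   trials: pd.DataFrame, role: str) -> pd.DataFrame:
    """One row of matching ratios per trial for the requested flower role.

    Pools all bird x flower pairs across trials (one row per trial-flower
    interaction).  Returns identifying columns plus the role's ratio set.
    """
    if role not in ("donor", "receiver"):
        raise MatchingError(f"role must be 'donor' or 'receiver', got {role!r}")
    flower_col = f"{role}_flower_id"
    fl = flowers.set_index("flower_id")
    bd = birds.set_index("bird_id")
    rows = []
    for _, tr in trials.iterrows():
        bird = bd.loc[tr.bird_id]
        flower = fl.loc[tr[flower_col]]
        ratios = compute_ratios(bird, flower)
        rows.append({"bird_id": tr.bird_id, "species": tr.species,
                     "trial_number": tr.trial_number, "flower_id": tr[flower_col],
                     "role": role, **ratios})
    return pd.DataFrame(rows)


@dataclass
class PCResult:
    """PCA of the correlation matrix of matching variables.

    ``scores`` reproduce ``(X - center) / scale @ loadings``; loading
    columns are orthonormal; variance fractions sum to 1.  The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """

    loadings: np.ndarray          # variables x components
    scores: np.ndarray            # observations x components
    variance_fraction: np.ndarray
    variable_names: list[str]
    center_vector: np.ndarray
    scale_vector: np.ndarray

    def score_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, columns=cols)


def run_pca(table: pd.DataFrame, variables: list[str] | None = None) -> PCResult:
    """Centred-and-scaled PCA of a ratios+tarsus table.

    Columns are centred and divided by their sample (n−1) standard
    deviation, so the decomposition is that of the correlation matrix.
    Components are ordered by decreasing variance fraction.
    """
    if variables is None:
        variables = [c for c in table.columns if c in _RATIO_DEFS or c == "tarsus"]
    data = table[variables]
    if data.shape[0] < 2:
        raise MatchingError("PCA needs at least 2 observations")
    if data.isna().any().any():
        bad = [c for c in variables if data[c].isna().any()]
        raise MatchingError(f"missing cells in PCA input columns: {bad}")
    X = data.to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = [v for v, s in zip(variables, scale) if s == 0]
        raise MatchingError(f"zero-variance columns cannot be scaled: {bad}")
    Z = (X - center) / scale

    pca = PCA(n_components=min(Z.shape), svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # variables x components, orthonormal columns
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    frac = pca.explained_variance_ratio_
    return PCResult(loadings=loadings, scores=scores,
                    variance_fraction=frac, variable_names=list(variables),
                    center_vector=center, scale_vector=scale)


def abs_scores(pc: PCResult, components: list[int]) -> pd.DataFrame:
    """Absolute PC scores for the requested 1-based components.

    Zero is the closest bill-corolla match; the further from zero, the
    more mismatched bill and corolla are (in either direction).
    """
    n_comp = pc.scores.shape[1]
    for c in components:
        if not 1 <= c <= n_comp:
            raise MatchingError(f"component {c} not in 1..{n_comp}")
    cols = {f"abs_PC{c}": np.abs(pc.scores[:, c - 1]) for c in components}
    return pd.DataFrame(cols)
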