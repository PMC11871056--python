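"""Permutation scaling of per-flower pollen deposition to the landscape.

Camera traps record which species visited a plant and how many flowers
it probed, but not how much pollen each visit deposited.  The estimator
assigns each recorded visit a per-flower deposition value drawn
uniformly, with replacement, from that species' experimentally measured
stigma counts, multiplies it by the flowers probed in the visit, and
aggregates: the per-species mean over visits is the per-plant estimate,
the per-species sum is the landscape total.  Repeating the assignment R
times (default 100) yields a sampling distribution for each quantity;
species are then compared by one-way type-III ANOVA with Tukey-adjusted
pairwise contrasts and Cohen's d on the runs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .glmm import cohens_d
from .synthetic import stage_rng

__all__ = [
    "LandscapeError",
    "deposition_pools",
    "run_permutations",
    "closed_form_expectation",
    "enumerate_expectation",
    "compare_species",
    "summarize",
    "SpeciesComparison",
]


class LandscapeError(ValueError):
    """Invalid permutation input."""


def deposition_pools(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-species pools of measured per-flower stigma pollen counts.

    Zero-deposition trials are retained: they are measured outcomes, and
    dropping them would bias the scaled totals upward.
    """
    return {sp: grp["stigma_pollen_count"].to_numpy(dtype=float)
            for sp, grp in trials.groupby("species")}


def _check_inputs(visits: pd.DataFrame, pools: dict[str, np.ndarray]) -> list[str]:
    if np.any(visits["flowers_probed"].to_numpy() < 1):
        raise LandscapeError("flowers_probed must be >= 1 for every visit")
    species = sorted(visits["species"].unique())
    missing = [sp for sp in species if sp not in pools or len(pools[sp]) == 0]
    if missing:
        raise LandscapeError(f"species with visits but empty deposition pool: {missing}")
    return species


def run_permutations(visits: pd.DataFrame, pools: dict[str, np.ndarray],
                     R: int = 100, seed: int = 0,
                     per_flower: bool = False) -> pd.DataFrame:
    """Run R permutation assignments of deposition values onto visits.

    Returns a long table with one row per run x species holding
    ``mean_per_plant`` (mean over that species' visits of deposition x
    flowers probed) and ``landscape_total`` (the sum).  Draws are
    independent across visits and runs.  With ``per_flower=True`` each
    probed flower within a visit draws its own value (same expectation,
    smaller variance than the default per-visit assignment).
    """
    if R < 1:
        raise LandscapeError("R must be >= 1")
    species = _check_inputs(visits, pools)
    rng = stage_rng(seed, "permutation")
    rows = []
    for run in range(1, R + 1):
        for sp in species:
            probed = visits.loc[visits["species"] == sp, "flowers_probed"].to_numpy(dtype=float)
            pool = pools[sp]
            if per_flower:
                totals = np.array([
                    rng.choice(pool, size=int(f), replace=True).sum() for f in probed])
            else:
                totals = rng.choice(pool, size=len(probed), replace=True) * probed
            rows.append({"run": run, "species": sp,
                         "mean_per_plant": float(totals.mean()),
                         "landscape_total": float(totals.sum())})
    return pd.DataFrame(rows)


def closed_form_expectation(visits: pd.DataFrame, pools: dict[str, np.ndarray],
                            per_flower: bool = False) -> pd.DataFrame:
    """Exact expectation and variance of both permutation metrics.

    Under uniform-with-replacement sampling, the assigned deposition is
    independent of the visit, so per species::

        E[mean_per_plant] = mean(pool) * mean(flowers_probed)
        E[landscape_total] = mean(pool) * sum(flowers_probed)

    Variances use the population (uniform over pool) variance: a
    per-visit draw scales by flowers_probed, so ``Var[total] =
    var(pool) * sum(f_i^2)``; per-flower draws give ``var(pool) * sum(f_i)``.
    """
    species = _check_inputs(visits, pools)
    rows = []
    for sp in species:
        probed = visits.loc[visits["species"] == sp, "flowers_probed"].to_numpy(dtype=float)
        pool = np.asarray(pools[sp], dtype=float)
        m, v = pool.mean(), pool.var(ddof=0)
        n = len(probed)
        var_total = v * (probed.sum() if per_flower else np.sum(probed ** 2))
        rows.append({
            "species": sp, "n_visits": n,
            "expected_mean_per_plant": m * probed.mean(),
            "expected_landscape_total": m * probed.sum(),
            "var_mean_per_plant": var_total / n ** 2,
            "var_landscape_total": var_total,
        })
    return pd.DataFrame(rows)


def enumerate_expectation(visits: pd.DataFrame, pools: dict[str, np.ndarray]) -> pd.DataFrame:
    """Brute-force expectation over all pool-to-visit assignments.

    Exhaustive enumeration of the |pool|^n equally likely assignments;
    only feasible for tiny instances, used as an independent oracle for
    :func:`closed_form_expectation`.
    """
    species = _check_inputs(visits, pools)
    rows = []
    for sp in species:
        probed = visits.loc[visits["species"] == sp, "flowers_probed"].to_numpy(dtype=float)
        pool = np.asarray(pools[sp], dtype=float)
        n = len(probed)
        if len(pool) ** n > 200_000:
            raise LandscapeError("instance too large for exhaustive enumeration")
        totals, means = [], []
        for combo in itertools.product(pool, repeat=n):
            per_visit = np.asarray(combo) * probed
            totals.append(per_visit.sum())
            means.append(per_visit.mean())
        totals, means = np.asarray(totals), np.asarray(means)
        rows.append({
            "species": sp, "n_visits": n,
            "expected_mean_per_plant": means.mean(),
            "expected_landscape_total": totals.mean(),
            "var_mean_per_plant": means.var(ddof=0),
            "var_landscape_total": totals.var(ddof=0),
        })
    return pd.DataFrame(rows)


@dataclass
class SpeciesComparison:
    """One-way ANOVA + Tukey pairwise results across species."""

    metric: str
    anova_f: float
    anova_p: float
    contrasts: pd.DataFrame  # pair, estimate, p_adjusted, cohens_d


def compare_species(runs: pd.DataFrame, metric: str,
                    visits: pd.DataFrame | None = None) -> SpeciesComparison:
    """Interspecific comparison of a permutation metric or of raw visits.

    For ``mean_per_plant`` / ``landscape_total`` each permutation run
    contributes one observation per species (runs treated as i.i.d., as
    the estimator's sampling distribution); for ``flowers_probed`` the
    raw camera-trap visit records are the observations and ``visits``
    must be supplied.  A single factor makes the type-III ANOVA equal the
    ordinary one-way ANOVA.
    """
    if metric == "flowers_probed":
        if visits is None:
            raise LandscapeError("metric 'flowers_probed' needs the visits table")
        data = visits.rename(columns={"flowers_probed": "value"})[["species", "value"]]
    elif metric in ("mean_per_plant", "landscape_total"):
        if runs is None or runs["run"].nunique() < 2:
            raise LandscapeError("need >= 2 permutation runs to compare species")
        data = runs.rename(columns={metric: "value"})[["species", "value"]]
    else:
        raise LandscapeError(f"unknown metric {metric!r}")
    species = sorted(data["species"].unique())
    if len(species) < 2:
        raise LandscapeError("need >= 2 species to compare")

    groups = [data.loc[data["species"] == sp, "value"].to_numpy(dtype=float)
              for sp in species]
    f_stat, p = map(float, stats.f_oneway(*groups))

    tuk = pairwise_tukeyhsd(data["value"].to_numpy(dtype=float),
                            data["species"].to_numpy(), alpha=0.05)
    tuk_df = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    rows = []
    for _, r in tuk_df.iterrows():
        a, b = str(r["group1"]), str(r["group2"])
        d = cohens_d(data, "value", a, b, group_col="species")
        rows.append({"pair": (a, b), "estimate": float(r["meandiff"]),
                     "p_adjusted": float(r["p-adj"]), "cohens_d": d})
    return SpeciesComparison(metric=metric, anova_f=f_stat, anova_p=p,
                             contrasts=pd.DataFrame(rows))


def summarize(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean ± SE over permutation runs for both metrics.

    SE is the SD over runs divided by sqrt(R), matching how permutation
    distributions are summarised.
    """
    R = runs["run"].nunique()
    if R < 2:
        raise LandscapeError("need >= 2 runs for an SE")
    rows = []
    for sp, grp in runs.groupby("species", sort=True):
        row = {"species": sp, "R": R}
        for metric in ("mean_per_plant", "landscape_total"):
            vals = grp[metric].to_numpy(dtype=float)
            row[f"{metric}_mean"] = vals.mean()
            row[f"{metric}_se"] = vals.std(ddof=1) / math.sqrt(len(vals))
        rows.append(row)
    return pd.DataFrame(rows)
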