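"""End-to-end orchestration: configuration, table I/O, and the full run.

The pipeline chains simulate -> match -> metrics -> trial-effect check ->
models -> landscape, exchanging plain CSV (RFC 4180, UTF-8, "." decimal)
with a provenance comment line, and finishes with a machine-readable run
manifest (version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glmm import ModelSpec, fit_glmm, pairwise_contrasts, r2_nakagawa, trial_effect_check, type3_test
from .landscape import compare_species, deposition_pools, run_permutations, summarize
from .matching import abs_scores, matching_table, run_pca, DONOR_VARIABLES, RECEIVER_VARIABLES
from .metrics import compute_metrics
from .synthetic import (FloralParams, SpeciesParams, default_floral_params,
                        default_species_params, generate_dataset)

__all__ = ["RunConfig", "SchemaError", "read_table", "write_table",
           "run_pipeline", "SCHEMAS", "MODEL_SPECS"]

logger = logging.getLogger("pollscape")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class SchemaError(ValueError):
    """A table does not match its documented schema."""


# column name -> dtype kind: "str", "int", "float", "float?" (may be missing)
SCHEMAS: dict[str, dict[str, str]] = {
    "birds": {"bird_id": "str", "species": "str", "mass": "float",
              "wing_chord": "float", "tarsus": "float", "bill_length": "float",
              "bill_width": "float", "bill_depth": "float"},
    "flowers": {"flower_id": "str", "plant_id": "str", "role": "str",
                "TCL": "float", "ECL": "float", "CW": "float",
                "ACO": "float?", "AN": "float?", "SCO": "float?", "SN": "float?"},
    "trials": {"bird_id": "str", "species": "str", "trial_number": "int",
               "donor_flower_id": "str", "receiver_flower_id": "str",
               "anther_contact_frames": "int", "feeding_frames_donor": "int",
               "feeding_frames_receiver": "int", "lick_count": "int",
               "patch_polygon": "str?", "image_scale": "float",
               "stigma_pollen_count": "int", "nectar_volume": "float"},
    "visits": {"visit_id": "str", "species": "str", "site_id": "str",
               "flowers_probed": "int"},
}


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                config_hash: str = "") -> None:
    """Write a CSV with a provenance comment line (version, seed, hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# pollscape v{__version__} seed={seed} config_hash={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path, schema: str | dict[str, str]) -> pd.DataFrame:
    """Read and validate a CSV against a documented schema.

    Missing or extra *required* columns raise a :class:`SchemaError`
    listing the offenders; unparsable cells raise naming the row and
    column.  An empty-but-headered file yields an empty table.
    """
    if isinstance(schema, str):
        if schema not in SCHEMAS:
            raise SchemaError(f"unknown schema {schema!r}")
        schema = SCHEMAS[schema]
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    required = {c for c, kind in schema.items() if not kind.endswith("?")}
    missing = sorted(required - set(df.columns))
    extra = sorted(set(df.columns) - set(schema))
    if missing or extra:
        raise SchemaError(f"{path}: schema mismatch; missing columns {missing}, "
                          f"unexpected columns {extra}")
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        optional = kind.endswith("?")
        kind = kind.rstrip("?")
        if col not in df.columns:
            continue
        raw = df[col]
        if kind == "str":
            out[col] = raw
            continue
        vals = raw.replace("", np.nan)
        conv = pd.to_numeric(vals, errors="coerce")
        bad = conv.isna() & vals.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"{path}: cannot parse {kind} in column {col!r}, "
                              f"row {row + 1}: {raw.iloc[row]!r}")
        if conv.isna().any() and not optional:
            row = int(conv.isna().idxmax())
            raise SchemaError(f"{path}: missing required {kind} in column {col!r}, row {row + 1}")
        if kind == "int":
            nonint = conv.notna() & (conv != conv.round())
            if nonint.any():
                row = int(nonint.idxmax())
                raise SchemaError(f"{path}: non-integer value in column {col!r}, "
                                  f"row {row + 1}: {raw.iloc[row]!r}")
            out[col] = conv.astype("Int64").astype(object).where(conv.notna(), np.nan)
            if not conv.isna().any():
                out[col] = conv.astype(int)
        else:
            out[col] = conv.astype(float)
    logger.info("read %s: %d rows", path, len(out))
    return out


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    output_dir: str = "pollscape_out"
    n_trials: int = 5
    permutation_runs: int = 100
    per_flower: bool = False
    feeding_source: str = "receiver"
    models: list[str] = field(default_factory=lambda: [f"mod{i}" for i in range(1, 9)])
    species_params: list[SpeciesParams] | None = None
    floral_params: FloralParams | None = None
    inputs: dict[str, str] = field(default_factory=dict)  # optional CSV paths
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.species_params is not None and len(self.species_params) == 0:
            raise SchemaError("species list must not be empty")
        if self.permutation_runs < 1:
            raise SchemaError("permutation_runs must be >= 1")
        if self.n_trials < 1:
            raise SchemaError("n_trials must be >= 1")
        unknown = [m for m in self.models if m not in MODEL_SPECS]
        if unknown:
            raise SchemaError(f"unknown models {unknown}; available: {list(MODEL_SPECS)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulation", {})
        land = raw.get("landscape", {})
        species = None
        if "species" in sim:
            if not sim["species"]:
                raise SchemaError("species list must not be empty")
            species = [SpeciesParams(**{**sp,
                                        "morphometric_means": np.asarray(sp["morphometric_means"]),
                                        "morphometric_cov": np.asarray(sp["morphometric_cov"])})
                       for sp in sim["species"]]
        floral = FloralParams(**sim["floral"]) if "floral" in sim else None
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "pollscape_out")),
            n_trials=int(sim.get("n_trials", 5)),
            permutation_runs=int(land.get("runs", 100)),
            per_flower=bool(land.get("per_flower", False)),
            feeding_source=str(raw.get("metrics", {}).get("feeding_source", "receiver")),
            models=list(raw.get("models", [f"mod{i}" for i in range(1, 9)])),
            species_params=species,
            floral_params=floral,
            inputs=dict(raw.get("inputs", {})),
            verbosity=str(raw.get("verbosity", "INFO")),
        )

    def hash(self) -> str:
        blob = json.dumps({
            "seed": self.seed, "n_trials": self.n_trials,
            "permutation_runs": self.permutation_runs, "per_flower": self.per_flower,
            "feeding_source": self.feeding_source, "models": self.models,
            "inputs": self.inputs,
            "n_species": len(self.species_params) if self.species_params else "default",
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# the eight models of the study
# --------------------------------------------------------------------------

MODEL_SPECS: dict[str, ModelSpec] = {
    "mod1": ModelSpec("stigma_pollen_count", "negative_binomial", ["species"],
                      random_effects="bird_id", name="mod1"),
    "mod2": ModelSpec("anther_contact_s", "tweedie", ["species"],
                      random_effects="bird_id", zero_inflation="species", name="mod2"),
    "mod3": ModelSpec("patch_area_mm2", "tweedie", ["species"],
                      random_effects="bird_id", zero_inflation="species", name="mod3"),
    "mod4": ModelSpec("feeding_duration_s", "gamma", ["species"],
                      random_effects="bird_id", name="mod4"),
    "mod5": ModelSpec("feeding_efficiency_ul_s", "gamma", ["species"],
                      random_effects="bird_id", name="mod5"),
    "mod6": ModelSpec("patch_area_mm2", "tweedie", ["abs_PC1_donor", "abs_PC2_donor"],
                      random_effects="bird_id_in_species", name="mod6"),
    "mod7": ModelSpec("stigma_pollen_count", "negative_binomial",
                      ["patch_area_mm2", "abs_PC1_receiver", "abs_PC2_receiver"],
                      random_effects="bird_id_in_species", name="mod7"),
    "mod8": ModelSpec("feeding_efficiency_ul_s", "gamma", ["abs_PC1", "abs_PC2"],
                      random_effects="bird_id_in_species", name="mod8"),
}


def _matching_with_scores(birds, flowers, trials, role: str):
    """Ratio table + PCA + absolute scores for one flower role."""
    table = matching_table(birds, flowers, trials, role)
    variables = DONOR_VARIABLES if role == "donor" else RECEIVER_VARIABLES
    pc = run_pca(table, variables)
    table["PC1"] = pc.scores[:, 0]
    table["PC2"] = pc.scores[:, 1]
    ab = abs_scores(pc, [1, 2])
    table["abs_PC1"] = ab["abs_PC1"].to_numpy()
    table["abs_PC2"] = ab["abs_PC2"].to_numpy()
    return table, pc


def build_model_data(metrics: pd.DataFrame, donor_match: pd.DataFrame,
                     recv_match: pd.DataFrame, trials: pd.DataFrame,
                     fps: float = 800.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge metrics and matching scores into the modeling tables.

    Returns ``(per_trial, per_visit)``: the per-trial table carries both
    roles' absolute PC scores (mod1-mod7); the per-visit table stacks
    donor and receiver feeding bouts with role-matched scores (mod8).
    """
    keys = ["bird_id", "trial_number"]
    dm = donor_match.set_index(keys)[["abs_PC1", "abs_PC2"]].rename(
        columns={"abs_PC1": "abs_PC1_donor", "abs_PC2": "abs_PC2_donor"})
    rm = recv_match.set_index(keys)[["abs_PC1", "abs_PC2"]].rename(
        columns={"abs_PC1": "abs_PC1_receiver", "abs_PC2": "abs_PC2_receiver"})
    per_trial = metrics.set_index(keys).join(dm).join(rm).reset_index()

    tr = trials.set_index(keys)
    rows = []
    for (bird, t), match, col in (
            [((b, t), "donor", "feeding_frames_donor") for b, t in tr.index]
            + [((b, t), "receiver", "feeding_frames_receiver") for b, t in tr.index]):
        rec = tr.loc[(bird, t)]
        src = dm if match == "donor" else rm
        sc = src.loc[(bird, t)]
        dur = rec[col] / fps
        nectar = rec.get("nectar_volume", 30.0) or 30.0
        rows.append({"bird_id": bird, "trial_number": t, "species": rec["species"],
                     "visit_role": match, "feeding_duration_s": dur,
                     "feeding_efficiency_ul_s": nectar / dur if dur > 0 else np.nan,
                     "abs_PC1": float(sc.iloc[0]), "abs_PC2": float(sc.iloc[1])})
    per_visit = pd.DataFrame(rows).dropna(subset=["feeding_efficiency_ul_s"])
    return per_trial, per_visit


def fit_models(model_names: list[str], per_trial: pd.DataFrame,
               per_visit: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Fit the requested models; return the Table-1/2-shaped rows and fits."""
    rows, fits = [], {}
    for name in model_names:
        spec = MODEL_SPECS[name]
        data = per_visit if name == "mod8" else per_trial
        t0 = time.perf_counter()
        fit = fit_glmm(spec, data)
        fits[name] = fit
        r2 = r2_nakagawa(fit)
        for term in spec.fixed_effects:
            p = type3_test(fit, term)
            idx = fit.term_columns[term]
            coef = float(fit.coefficients_link.iloc[idx[0]]) if len(idx) == 1 else np.nan
            rows.append({"model": name, "response": spec.response, "term": term,
                         "pair": "", "coef_link": coef,
                         "coef_response": float(np.exp(coef)) if np.isfinite(coef) else np.nan,
                         "p_type3": p, "p_tukey": np.nan, "cohens_d": np.nan,
                         "r2_marginal": r2.marginal, "r2_conditional": r2.conditional,
                         "converged": fit.converged})
            if term == "species":
                for ct in pairwise_contrasts(fit, "species"):
                    rows.append({"model": name, "response": spec.response,
                                 "term": "species", "pair": f"{ct.pair[0]} - {ct.pair[1]}",
                                 "coef_link": ct.estimate_link,
                                 "coef_response": float(np.exp(ct.estimate_link)),
                                 "p_type3": np.nan, "p_tukey": ct.p_adjusted,
                                 "cohens_d": ct.cohens_d,
                                 "r2_marginal": r2.marginal, "r2_conditional": r2.conditional,
                                 "converged": fit.converged})
        logger.info("stage=models model=%s elapsed=%.2fs converged=%s",
                    name, time.perf_counter() - t0, fit.converged)
    return pd.DataFrame(rows), fits


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest dictionary.

    Stages: simulate (or load) -> trait matching (donor + receiver PCAs)
    -> transfer metrics -> trial-effect pre-check -> GLMMs -> landscape
    permutation.  Every CSV written carries a provenance header; the
    manifest records version, seed, and config hash, so a run can be
    reproduced byte-identically.
    """
    logger.setLevel(config.verbosity)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config_hash": chash, "stages": []}

    def timed(stage):
        t0 = time.perf_counter()

        def done():
            manifest["stages"].append(stage)
            logger.info("stage=%s elapsed=%.2fs", stage, time.perf_counter() - t0)
        return done

    try:
        done = timed("simulate")
        if config.inputs:
            tables = {name: read_table(path, name) for name, path in config.inputs.items()}
            needed = {"birds", "flowers", "trials", "visits"} - set(tables)
            if needed:
                raise SchemaError(f"inputs missing tables: {sorted(needed)}")
        else:
            tables = generate_dataset(config.species_params, config.floral_params,
                                      n_trials=config.n_trials, seed=config.seed)
        for name in ("birds", "flowers", "trials", "visits"):
            write_table(tables[name], out / f"{name}.csv", config.seed, chash)
        done()

        done = timed("match")
        donor_match, donor_pc = _matching_with_scores(
            tables["birds"], tables["flowers"], tables["trials"], "donor")
        recv_match, recv_pc = _matching_with_scores(
            tables["birds"], tables["flowers"], tables["trials"], "receiver")
        write_table(pd.concat([donor_match, recv_match], ignore_index=True),
                    out / "matching.csv", config.seed, chash)
        manifest["pca"] = {
            "donor_variance_fraction": [round(float(v), 6) for v in donor_pc.variance_fraction],
            "receiver_variance_fraction": [round(float(v), 6) for v in recv_pc.variance_fraction],
        }
        done()

        done = timed("metrics")
        metrics = compute_metrics(tables["trials"], feeding_source=config.feeding_source)
        write_table(metrics, out / "metrics.csv", config.seed, chash)
        done()

        done = timed("trial_effect_check")
        manifest["trial_effect_check"] = trial_effect_check(metrics)
        done()

        done = timed("models")
        per_trial, per_visit = build_model_data(metrics, donor_match, recv_match,
                                                tables["trials"])
        models_df, _fits = fit_models(config.models, per_trial, per_visit)
        write_table(models_df, out / "models.csv", config.seed, chash)
        done()

        done = timed("landscape")
        pools = deposition_pools(tables["trials"])
        runs = run_permutations(tables["visits"], pools, R=config.permutation_runs,
                                seed=config.seed, per_flower=config.per_flower)
        write_table(runs, out / "permutations.csv", config.seed, chash)
        write_table(summarize(runs), out / "landscape_summary.csv", config.seed, chash)
        manifest["landscape_comparisons"] = {}
        for metric in ("mean_per_plant", "landscape_total", "flowers_probed"):
            cmp_res = compare_species(runs, metric, visits=tables["visits"])
            manifest["landscape_comparisons"][metric] = {
                "anova_f": cmp_res.anova_f, "anova_p": cmp_res.anova_p,
                "pairs": [{"pair": list(r["pair"]), "estimate": r["estimate"],
                           "p_adjusted": r["p_adjusted"], "cohens_d": r["cohens_d"]}
                          for _, r in cmp_res.contrasts.iterrows()],
            }
        done()
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        logger.error("pipeline halted after stage=%s: %s", stage, exc)
        manifest["failed"] = True
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=float)
        raise

    manifest["permutation_runs"] = config.permutation_runs
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
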