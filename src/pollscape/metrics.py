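"""Convert raw video-derived trial measurements to response variables.

Frame counts from 800-fps high-speed video become durations (s); the
digitised pollen-patch polygon (pixel coordinates plus a px/mm image
scale) becomes an area in mm²; the standardised 30 µL nectar load
divided by feeding-bout duration gives feeding efficiency (µL/s); lick
counts over the bout give licking rate (licks/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "MetricsError",
    "EfficiencyMetrics",
    "frames_to_seconds",
    "parse_polygon",
    "polygon_area",
    "feeding_metrics",
    "compute_metrics",
    "species_summary",
    "DEFAULT_FPS",
    "DEFAULT_NECTAR_UL",
]

DEFAULT_FPS = 800.0
DEFAULT_NECTAR_UL = 30.0


class MetricsError(ValueError):
    """Invalid raw measurement."""


def frames_to_seconds(frames: int | float | np.ndarray, fps: float = DEFAULT_FPS):
    """Convert a frame count to seconds at the given frame rate."""
    if fps <= 0:
        raise MetricsError(f"fps must be positive, got {fps}")
    frames = np.asarray(frames, dtype=float)
    if np.any(frames < 0):
        raise MetricsError("frame counts must be nonnegative")
    out = frames / fps
    return float(out) if out.ndim == 0 else out


def parse_polygon(text: str) -> np.ndarray:
    """Parse a ``"x1 y1;x2 y2;..."`` vertex string into an (n, 2) array."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or str(text).strip() == "":
        return np.empty((0, 2))
    try:
        pts = [tuple(float(v) for v in pair.split()) for pair in str(text).split(";") if pair.strip()]
        arr = np.asarray(pts, dtype=float)
    except ValueError as exc:
        raise MetricsError(f"malformed polygon string: {text!r}") from exc
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise MetricsError(f"polygon vertices must be x-y pairs: {text!r}")
    return arr


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_area(vertices: np.ndarray | str, scale: float) -> float:
    """Area (mm²) of a digitised polygon given the image scale in px/mm.

    Orientation-independent; an empty or degenerate (<3 vertex) polygon
    has zero area.  A self-intersecting polygon raises a warning and the
    magnitude of its signed (shoelace) area is returned.
    """
    if scale <= 0:
        raise MetricsError(f"image scale must be positive px/mm, got {scale}")
    if isinstance(vertices, str):
        vertices = parse_polygon(vertices)
    vertices = np.asarray(vertices, dtype=float)
    if len(vertices) < 3:
        return 0.0
    poly = Polygon(vertices)
    if not poly.is_valid:
        warnings.warn("WARN self-intersecting pollen-patch polygon; "
                      "returning signed-area magnitude", stacklevel=2)
        area_px = _shoelace(vertices)
    else:
        area_px = poly.area
    return area_px / scale ** 2


@dataclass
class EfficiencyMetrics:
    """Per-trial pollen-transfer and feeding responses."""

    anther_contact_s: float
    patch_area: float           # mm²
    feeding_duration_s: float
    feeding_efficiency: float   # µL/s
    licking_rate: float         # licks/s


def feeding_metrics(record, fps: float = DEFAULT_FPS,
                    feeding_source: str = "receiver") -> EfficiencyMetrics:
    """Derive all response variables for one trial record.

    ``feeding_source`` selects which visit's film provides the feeding
    bout: ``"receiver"`` (default), ``"donor"``, or ``"pooled"`` (the two
    bouts summed).  Feeding efficiency is the standardised nectar volume
    (30 µL unless the record says otherwise) divided by bout duration.
    """
    frames = {"receiver": record["feeding_frames_receiver"],
              "donor": record["feeding_frames_donor"]}
    if feeding_source == "pooled":
        feed_frames = frames["receiver"] + frames["donor"]
    elif feeding_source in frames:
        feed_frames = frames[feeding_source]
    else:
        raise MetricsError(f"feeding_source must be receiver|donor|pooled, got {feeding_source!r}")

    duration = frames_to_seconds(feed_frames, fps)
    licks = int(record["lick_count"])
    if duration == 0 and licks > 0:
        raise MetricsError(f"zero feeding duration with {licks} licks in trial "
                           f"{record.get('bird_id', '?')}/{record.get('trial_number', '?')}")
    nectar = float(record.get("nectar_volume", DEFAULT_NECTAR_UL) or DEFAULT_NECTAR_UL)
    efficiency = nectar / duration if duration > 0 else 0.0
    licking_rate = licks / duration if duration > 0 else 0.0
    return EfficiencyMetrics(
        anther_contact_s=frames_to_seconds(record["anther_contact_frames"], fps),
        patch_area=polygon_area(record["patch_polygon"], record["image_scale"]),
        feeding_duration_s=duration,
        feeding_efficiency=efficiency,
        licking_rate=licking_rate,
    )


def compute_metrics(trials: pd.DataFrame, fps: float = DEFAULT_FPS,
                    feeding_source: str = "receiver") -> pd.DataFrame:
    """Response-variable table, one row per trial."""
    rows = []
    for _, rec in trials.iterrows():
        m = feeding_metrics(rec, fps=fps, feeding_source=feeding_source)
        rows.append({
            "bird_id": rec.bird_id, "species": rec.species,
            "trial_number": rec.trial_number,
            "stigma_pollen_count": rec.stigma_pollen_count,
            "anther_contact_s": m.anther_contact_s,
            "patch_area_mm2": m.patch_area,
            "feeding_duration_s": m.feeding_duration_s,
            "feeding_efficiency_ul_s": m.feeding_efficiency,
            "licking_rate_s": m.licking_rate,
        })
    return pd.DataFrame(rows)


_SUMMARY_VARS = ["stigma_pollen_count", "anther_contact_s", "patch_area_mm2",
                 "feeding_duration_s", "feeding_efficiency_ul_s", "licking_rate_s"]


def species_summary(metrics: pd.DataFrame, per_bird: bool = False) -> pd.DataFrame:
    """Per-species mean ± SE of every response variable.

    SE is SD/√n with n the number of trials (matching trial-level violin
    plots); with ``per_bird=True`` trials are first averaged within bird
    and n becomes the number of birds.
    """
    data = metrics
    if per_bird:
        data = metrics.groupby(["species", "bird_id"], as_index=False)[_SUMMARY_VARS].mean()
    rows = []
    for species, grp in data.groupby("species", sort=True):
        for var in _SUMMARY_VARS:
            vals = grp[var].to_numpy(dtype=float)
            n = len(vals)
            se = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            rows.append({"species": species, "variable": var, "n": n,
                         "mean": vals.mean(), "se": se})
    return pd.DataFrame(rows)
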