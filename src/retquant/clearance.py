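"""Photoreceptor-outer-segment (POS) clearance from RPE flat-mount records.

The RPE phagocytoses the outer-segment tips photoreceptors shed at light
onset; clearance competence is read out as the density of rhodopsin-positive
dots per RPE cell at 11 am (3 h after the shedding peak) relative to 8 am.

The statistic follows the field's counting protocol: dots are kept only if
their diameter exceeds 2 μm (strictly), ten square areas of 40,000 μm² are
sampled at random within a 1.5 mm radius of the mount center, dots-per-cell
is averaged over the ten fields per mount, and the result is the percentage
100 x (11 am mean) / (8 am mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FieldSample",
    "ClearanceResult",
    "filter_dots",
    "sample_fields",
    "dots_per_cell",
    "clearance_percent",
    "DIAMETER_THRESHOLD_UM",
    "FIELD_AREA_UM2",
    "SAMPLING_RADIUS_UM",
]

DIAMETER_THRESHOLD_UM = 2.0
FIELD_AREA_UM2 = 40_000.0
SAMPLING_RADIUS_UM = 1_500.0
DEFAULT_N_FIELDS = 10


@dataclass(frozen=True)
class FieldSample:
    field_id: int
    center: tuple[float, float]  # μm
    side: float  # μm
    dot_count: int = 0
    cell_count: int = 0

    @property
    def dots_per_cell(self) -> float:
        return self.dot_count / self.cell_count


@dataclass(frozen=True)
class ClearanceResult:
    mount_pair_id: str
    mean_dots_per_cell_8am: float
    mean_dots_per_cell_11am: float

    @property
    def percent_remaining(self) -> float:
        return 100.0 * self.mean_dots_per_cell_11am / self.mean_dots_per_cell_8am


def filter_dots(dots: pd.DataFrame, threshold: float = DIAMETER_THRESHOLD_UM) -> pd.DataFrame:
    """Keep exactly the dots with diameter strictly greater than 2 μm."""
    return dots[dots["diameter_um"] > threshold].reset_index(drop=True)


def sample_fields(
    n_fields: int = DEFAULT_N_FIELDS,
    seed: int | np.random.Generator = 0,
    mount_radius: float | None = None,
    field_area: float = FIELD_AREA_UM2,
    sampling_radius: float = SAMPLING_RADIUS_UM,
    max_attempts: int = 10_000,
) -> list[FieldSample]:
    """Randomly place non-overlapping square sampling fields.

    Field centers are uniform in the disk of ``sampling_radius`` around the
    mount center; overlapping candidates are rejected.  When
    ``mount_radius`` is given it must contain every field entirely
    (radius >= sampling radius + half field diagonal).
    """
    side = float(np.sqrt(field_area))
    if mount_radius is not None and mount_radius < sampling_radius + side * np.sqrt(2) / 2:
        raise ValueError(
            f"mount radius {mount_radius:.0f} μm cannot contain "
            f"{side:.0f} μm fields sampled within {sampling_radius:.0f} μm"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_fields:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_fields} non-overlapping fields in "
                f"{max_attempts} attempts"
            )
        attempts += 1
        theta = rng.uniform(0, 2 * np.pi)
        rad = sampling_radius * np.sqrt(rng.uniform())
        cx, cy = rad * np.cos(theta), rad * np.sin(theta)
        if any(abs(cx - x) < side and abs(cy - y) < side for x, y in centers):
            continue
        centers.append((cx, cy))
    return [FieldSample(i, c, side) for i, c in enumerate(centers)]


def _in_field(x: np.ndarray, y: np.ndarray, f: FieldSample) -> np.ndarray:
    half = f.side / 2.0
    return (np.abs(x - f.center[0]) <= half) & (np.abs(y - f.center[1]) <= half)


def dots_per_cell(
    cells: pd.DataFrame,
    dots: pd.DataFrame,
    fields: list[FieldSample],
) -> tuple[float, list[FieldSample]]:
    """Average dots-per-cell over the sampled fields of one mount.

    Cells belong to a field when their centroid lies inside it; dots by
    their center point.  ``dots`` should already be diameter-filtered.
    """
    cx = cells["centroid_x_um"].to_numpy()
    cy = cells["centroid_y_um"].to_numpy()
    dx = dots["x_um"].to_numpy()
    dy = dots["y_um"].to_numpy()
    counted = []
    for f in fields:
        n_cells = int(_in_field(cx, cy, f).sum())
        n_dots = int(_in_field(dx, dy, f).sum())
        if n_cells == 0:
            raise ValueError(f"field {f.field_id} at {f.center} contains no cell centroid")
        counted.append(
            FieldSample(f.field_id, f.center, f.side, dot_count=n_dots, cell_count=n_cells)
        )
    return float(np.mean([f.dots_per_cell for f in counted])), counted


def clearance_percent(
    cells: pd.DataFrame,
    dots: pd.DataFrame,
    n_fields: int = DEFAULT_N_FIELDS,
    seed: int = 0,
    mount_pair_id: str = "",
) -> ClearanceResult:
    """Full clearance statistic for one mount pair.

    ``dots`` must carry a ``time_label`` column with both '8am' and '11am'
    records on the shared cell geometry.  Fields are sampled independently
    for the two clock times (separate mounts in the real protocol), dots
    are diameter-filtered, and the result is the 11 am / 8 am percentage of
    field-averaged dots-per-cell.
    """
    kept = filter_dots(dots)
    rng = np.random.default_rng(seed)
    means = {}
    for label in ("8am", "11am"):
        sub = kept[kept["time_label"] == label]
        fields = sample_fields(n_fields, seed=rng)
        means[label], _ = dots_per_cell(cells, sub, fields)
    if means["8am"] == 0:
        raise ZeroDivisionError(
            "no dots per cell at 8 am; the clearance percentage is undefined"
        )
    return ClearanceResult(mount_pair_id, means["8am"], means["11am"])
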