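"""Drusen morphometry on segmented OCT boundary surfaces.

The measurement chain mirrors how drusen are quantified from layer
segmentations in the clinic:

1. :func:`compute_thickness` — thickness is the distance between the
   Choroid/Bruch's-membrane (BrM) boundary and the RPE/photoreceptor-outer-
   segment (RPE/POS) boundary, evaluated pointwise on the B-scan x A-scan
   grid.
2. :func:`detect_drusen` — drusen are localized elevations of the thickness
   map above a per-B-scan running-median reference; footprints are
   4-connected components of the excess map.
3. :func:`flanking_baseline` — the drusen-free thickness for a druse is the
   average thickness of the two adjacent sections (first B-scan before the
   footprint and first after it).
4. :func:`measure_druse` — a druse's height in each section is the mean
   thickness over its footprint minus the flanking baseline (clipped at 0);
   its average height is the mean of the per-section heights over all
   sections in which it appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "BoundaryVolume",
    "ThicknessMap",
    "DetectionParams",
    "DruseMeasurement",
    "compute_thickness",
    "detect_drusen",
    "flanking_baseline",
    "measure_druse",
    "measure_volume",
]

#: 4-connectivity structuring element for footprint labeling
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class BoundaryVolume:
    """Two segmented boundary surfaces of one eye at one visit.

    Depths increase posteriorly (μm); in healthy geometry the BrM depth is
    at least the RPE/POS depth.  The grid must be complete — missing rows
    in the input table are an error, never imputed.
    """

    eye_id: str
    arm: str
    timepoint: float
    rpe_pos_depth: np.ndarray  # (n_bscans, n_ascans) μm
    brm_depth: np.ndarray  # (n_bscans, n_ascans) μm
    bscan_spacing: float = 109.0  # μm
    ascan_spacing: float = 17.0  # μm

    def __post_init__(self) -> None:
        self.rpe_pos_depth = np.asarray(self.rpe_pos_depth, dtype=float)
        self.brm_depth = np.asarray(self.brm_depth, dtype=float)
        if self.rpe_pos_depth.shape != self.brm_depth.shape:
            raise ValueError("boundary grids must have identical shape")
        if self.rpe_pos_depth.ndim != 2:
            raise ValueError("boundary grids must be 2-D (bscan, ascan)")
        for name, arr in (("rpe_pos_depth", self.rpe_pos_depth), ("brm_depth", self.brm_depth)):
            if np.isnan(arr).any():
                b, a = np.argwhere(np.isnan(arr))[0]
                raise ValueError(f"missing {name} sample at (bscan={b}, ascan={a})")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        bscan_spacing: float = 109.0,
        ascan_spacing: float = 17.0,
    ) -> "BoundaryVolume":
        """Build one volume from `boundaries.csv` rows of a single eye+visit."""
        for col in ("eye_id", "arm", "timepoint_months"):
            if df[col].nunique() != 1:
                raise ValueError(f"from_dataframe expects a single {col}")
        eye_id = df["eye_id"].iloc[0]
        arm = df["arm"].iloc[0]
        timepoint = float(df["timepoint_months"].iloc[0])
        n_b = int(df["bscan_index"].max()) + 1
        n_a = int(df["ascan_index"].max()) + 1
        if len(df) != n_b * n_a or df.duplicated(["bscan_index", "ascan_index"]).any():
            missing = n_b * n_a - len(df.drop_duplicates(["bscan_index", "ascan_index"]))
            raise ValueError(
                f"incomplete boundary grid for eye {eye_id} at {timepoint} months: "
                f"{missing} of {n_b * n_a} grid points missing"
            )
        rpe = np.full((n_b, n_a), np.nan)
        brm = np.full((n_b, n_a), np.nan)
        bi = df["bscan_index"].to_numpy(int)
        ai = df["ascan_index"].to_numpy(int)
        rpe[bi, ai] = df["rpe_pos_depth_um"].to_numpy(float)
        brm[bi, ai] = df["brm_depth_um"].to_numpy(float)
        return cls(eye_id, arm, timepoint, rpe, brm, bscan_spacing, ascan_spacing)


@dataclass
class ThicknessMap:
    """Pointwise BrM-to-RPE/POS thickness (μm) on the scan grid."""

    thickness: np.ndarray  # (n_bscans, n_ascans) μm
    bscan_spacing: float = 109.0
    ascan_spacing: float = 17.0
    #: grid points flagged as implausibly negative (< -3 x axial noise sd)
    negative_flags: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.thickness.shape


@dataclass(frozen=True)
class DetectionParams:
    """Operationalization of the 'clear visible druse' criterion.

    A candidate elevation becomes a counted druse only if its peak excess
    reaches ``min_peak_height`` and its footprint spans at least
    ``min_sections`` B-scans and ``min_footprint_ascans`` A-scans in its
    widest section.

    ``baseline_smoothing_window`` must exceed roughly twice a druse's
    lateral extent in A-scans for the running median to reject it; the
    default (61 samples ≈ 1 mm at 17 μm pitch) covers drusen up to ~500 μm
    across.
    """

    min_peak_height: float = 10.0  # μm
    min_sections: int = 2
    min_footprint_ascans: int = 3
    baseline_smoothing_window: int = 61  # A-scans, odd

    def __post_init__(self) -> None:
        if self.min_peak_height <= 0 or self.min_sections <= 0 or self.min_footprint_ascans <= 0:
            raise ValueError("detection thresholds must be positive")
        if self.baseline_smoothing_window <= 0 or self.baseline_smoothing_window % 2 == 0:
            raise ValueError("baseline_smoothing_window must be a positive odd count")


@dataclass
class DruseMeasurement:
    """One druse's footprint and (once measured) its heights."""

    druse_id: str
    footprint: np.ndarray  # (k, 2) array of (bscan, ascan) indices
    sections: list[int] = field(default_factory=list)
    per_section_height: dict[int, float] = field(default_factory=dict)
    average_height: float = float("nan")
    peak_height: float = float("nan")
    visible: bool = False
    edge: bool = False
    centroid: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def ascan_span(self) -> tuple[int, int]:
        a = self.footprint[:, 1]
        return int(a.min()), int(a.max())


def compute_thickness(volume: BoundaryVolume, axial_noise_sd: float | None = None) -> ThicknessMap:
    """Pointwise thickness: BrM depth minus RPE/POS depth, μm.

    Thickness may be transiently negative under noise; points below
    ``-3 x axial_noise_sd`` are flagged when the noise level is given.
    """
    t = volume.brm_depth - volume.rpe_pos_depth
    flags = None
    if axial_noise_sd is not None:
        flags = t < -3.0 * axial_noise_sd
    return ThicknessMap(t, volume.bscan_spacing, volume.ascan_spacing, flags)


def excess_map(tmap: ThicknessMap, params: DetectionParams) -> np.ndarray:
    """Thickness excess over a per-B-scan running-median reference.

    The running median (window ``baseline_smoothing_window`` A-scans,
    mirrored at the volume edge) estimates the drusen-free thickness profile of each
    B-scan; drusen, being narrower than the window, survive as positive
    excess.  The median is iterated: samples elevated above the current
    reference are replaced by it before re-filtering, so a druse whose
    width is comparable to half the window cannot inflate its own
    baseline.  Iteration stops when the reference is stable (or after 8
    passes).
    """
    w = params.baseline_smoothing_window
    if w > tmap.shape[1]:
        raise ValueError(
            f"baseline_smoothing_window ({w}) exceeds A-scan count ({tmap.shape[1]})"
        )
    t = tmap.thickness
    reference = ndimage.median_filter(t, size=(1, w), mode="reflect")
    for _ in range(8):
        elevated = (t - reference) > params.min_peak_height / 2.0
        new_ref = ndimage.median_filter(
            np.where(elevated, reference, t), size=(1, w), mode="reflect"
        )
        if np.allclose(new_ref, reference, atol=1e-3):
            reference = new_ref
            break
        reference = new_ref
    return t - reference


def detection_mask(excess: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Candidate-druse mask: excess at or above half the peak threshold."""
    return excess >= params.min_peak_height / 2.0


def detect_drusen(tmap: ThicknessMap, params: DetectionParams | None = None) -> list[DruseMeasurement]:
    """Detect drusen footprints; heights are left unfilled.

    Footprints are 4-connected components of ``excess >= min_peak_height/2``
    whose peak excess reaches ``min_peak_height``.  ``visible`` encodes the
    clear-visible-druse counting criterion.  Components are ordered by
    (centroid B-scan, centroid A-scan).
    """
    params = params or DetectionParams()
    excess = excess_map(tmap, params)
    mask = detection_mask(excess, params)
    labels, n = ndimage.label(mask, structure=_CROSS)
    found: list[DruseMeasurement] = []
    for lab in range(1, n + 1):
        fp = np.argwhere(labels == lab)
        peak = float(excess[fp[:, 0], fp[:, 1]].max())
        if peak < params.min_peak_height:
            continue
        sections = sorted(set(int(b) for b in fp[:, 0]))
        widest = max(np.sum(fp[:, 0] == b) for b in sections)
        visible = len(sections) >= params.min_sections and widest >= params.min_footprint_ascans
        centroid = (float(fp[:, 0].mean()), float(fp[:, 1].mean()))
        found.append(
            DruseMeasurement(
                druse_id="",
                footprint=fp,
                sections=sections,
                visible=visible,
                centroid=centroid,
            )
        )
    found.sort(key=lambda d: d.centroid)
    for i, d in enumerate(found):
        d.druse_id = f"d{i:03d}"
    return found


def flanking_baseline(
    tmap: ThicknessMap,
    footprint: np.ndarray,
    ascan_span: tuple[int, int] | None = None,
) -> tuple[float, bool]:
    """Drusen-free reference thickness from the two adjacent sections.

    The baseline is the thickness averaged over the druse's A-scan span in
    the first B-scan before the footprint and the first after it, averaged
    across those two sections.  The same pair serves every section of the
    druse.  When the footprint touches the first or last B-scan only the
    available side is used and the measurement is flagged (``edge=True``).
    """
    footprint = np.asarray(footprint)
    if footprint.size == 0:
        raise ValueError("footprint is empty")
    if ascan_span is None:
        ascan_span = (int(footprint[:, 1].min()), int(footprint[:, 1].max()))
    a0, a1 = ascan_span
    b_before = int(footprint[:, 0].min()) - 1
    b_after = int(footprint[:, 0].max()) + 1
    flank_means = []
    edge = False
    for b in (b_before, b_after):
        if 0 <= b < tmap.shape[0]:
            flank_means.append(float(tmap.thickness[b, a0 : a1 + 1].mean()))
        else:
            edge = True
    if not flank_means:
        raise ValueError("footprint spans every B-scan; no flanking section exists")
    return float(np.mean(flank_means)), edge


def measure_druse(
    tmap: ThicknessMap,
    footprint: np.ndarray,
    baseline: float,
    stat: str = "mean",
) -> DruseMeasurement:
    """Fill per-section and average heights for one footprint.

    Per section, height is the ``stat`` ("mean" or "peak") of thickness over
    the footprint's A-scans in that section, minus the baseline, clipped at
    0.  The average height is the arithmetic mean of the per-section heights
    over every section in which the druse appears.
    """
    footprint = np.asarray(footprint)
    if footprint.size == 0:
        raise ValueError("footprint is empty")
    if stat not in ("mean", "peak"):
        raise ValueError("stat must be 'mean' or 'peak'")
    sections = sorted(set(int(b) for b in footprint[:, 0]))
    per_section: dict[int, float] = {}
    for b in sections:
        cols = footprint[footprint[:, 0] == b, 1]
        vals = tmap.thickness[b, cols]
        raw = float(vals.mean() if stat == "mean" else vals.max())
        per_section[b] = max(raw - baseline, 0.0)
    avg = float(np.mean(list(per_section.values())))
    peak = float(max(per_section.values()))
    centroid = (float(footprint[:, 0].mean()), float(footprint[:, 1].mean()))
    return DruseMeasurement(
        druse_id="",
        footprint=footprint,
        sections=sections,
        per_section_height=per_section,
        average_height=avg,
        peak_height=peak,
        centroid=centroid,
    )


def measure_volume(
    volume: BoundaryVolume,
    params: DetectionParams | None = None,
    stat: str = "mean",
) -> list[DruseMeasurement]:
    """Full chain for one volume: thickness -> detection -> heights."""
    params = params or DetectionParams()
    tmap = compute_thickness(volume)
    out = []
    for det in detect_drusen(tmap, params):
        baseline, edge = flanking_baseline(tmap, det.footprint)
        m = measure_druse(tmap, det.footprint, baseline, stat=stat)
        m.druse_id = det.druse_id
        m.visible = det.visible
        m.edge = edge
        out.append(m)
    return out


def measurements_table(
    volumes: list[BoundaryVolume],
    params: DetectionParams | None = None,
) -> pd.DataFrame:
    """Run :func:`measure_volume` over volumes into a `measurements.csv` table."""
    rows = []
    for v in volumes:
        for m in measure_volume(v, params):
            rows.append(
                {
                    "eye_id": v.eye_id,
                    "arm": v.arm,
                    "timepoint_months": v.timepoint,
                    "druse_id": f"{v.eye_id}_{m.druse_id}",
                    "n_sections": len(m.sections),
                    "centroid_bscan": m.centroid[0],
                    "centroid_ascan": m.centroid[1],
                    "avg_height_um": m.average_height,
                    "peak_height_um": m.peak_height,
                    "visible": int(m.visible),
                    "edge": int(m.edge),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "eye_id",
            "arm",
            "timepoint_months",
            "druse_id",
            "n_sections",
            "centroid_bscan",
            "centroid_ascan",
            "avg_height_um",
            "peak_height_um",
            "visible",
            "edge",
        ],
    )
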