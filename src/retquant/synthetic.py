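"""Seeded synthetic fixtures for the quantification pipeline.

Three generators emulate the inputs the analysis stages consume:

* :func:`generate_oct_series` — segmented OCT boundary volumes (Choroid/BrM
  and RPE/POS surfaces on a regular B-scan x A-scan grid) for a longitudinal
  two-arm study in which drusen appear, grow, shrink and disappear.  Drusen
  are anisotropic Gaussian elevations of the RPE/POS boundary toward the
  vitreous, so every ground-truth height is analytically evaluable.
* :func:`generate_flatmount` — an RPE flat mount as a centroidal Voronoi
  tessellation of a disk, with rhodopsin-positive dot records at 8 am and
  11 am whose per-cell rates encode a known clearance fraction.
* :func:`generate_lipid_panel` — per-sample phospholipid species responses
  whose class sums follow prescribed baseline fractions times group effects.

All generators are deterministic given their spec (which carries the seed):
identical spec -> byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon

__all__ = [
    "OctStudySpec",
    "DruseSeed",
    "FlatMountSpec",
    "LipidPanelSpec",
    "FlatMount",
    "generate_oct_series",
    "generate_flatmount",
    "generate_lipid_panel",
    "generate_two_arm_study",
    "DEFAULT_EYES",
]

DEFAULT_TIMEPOINTS = (0, 3, 6, 9, 12)

#: Two animals, each contributing one injected (OS) and one uninjected (OD)
#: eye; counts are pooled across the two eyes of an arm downstream.
DEFAULT_EYES: Mapping[str, str] = {
    "A_OS": "injected",
    "B_OS": "injected",
    "A_OD": "uninjected",
    "B_OD": "uninjected",
}


@dataclass(frozen=True)
class OctStudySpec:
    """Geometry and noise model of a longitudinal OCT boundary study.

    Defaults follow the acquisition protocol of the study this package
    quantifies: 61 B-scans separated by 109 μm.  ``nominal_thickness`` is the
    drusen-free Choroid/BrM to RPE/POS distance; ``undulation_*`` describe a
    smooth surface warp shared by both boundaries (it changes depths but not
    thickness), while ``axial_noise_sd`` is i.i.d. Gaussian noise added to
    each boundary sample independently.
    """

    n_bscans: int = 61
    bscan_spacing: float = 109.0  # μm
    n_ascans: int = 512
    ascan_spacing: float = 17.0  # μm
    nominal_thickness: float = 30.0  # μm
    axial_noise_sd: float = 2.0  # μm
    undulation_amplitude: float = 5.0  # μm
    undulation_wavelength: float = 2500.0  # μm
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    arms: tuple[str, ...] = ("injected", "uninjected")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bscans < 3:
            raise ValueError("n_bscans must be >= 3")
        for name in ("bscan_spacing", "ascan_spacing", "nominal_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("axial_noise_sd", "undulation_amplitude", "undulation_wavelength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        tps = tuple(self.timepoints)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")


@dataclass(frozen=True)
class DruseSeed:
    """Ground-truth encoding of one druse across the study timeline.

    ``amplitude_by_timepoint`` maps month label -> peak elevation in μm;
    an amplitude of 0 means the druse is absent at that visit, which is how
    appearance and disappearance are encoded.
    """

    druse_id: str
    center_bscan: int
    center_ascan: int
    sigma_bscan: float  # μm, Gaussian sigma across B-scans
    sigma_ascan: float  # μm, Gaussian sigma along a B-scan
    amplitude_by_timepoint: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma_bscan <= 0 or self.sigma_ascan <= 0:
            raise ValueError("sigmas must be > 0")
        amps = dict(self.amplitude_by_timepoint)
        if any(a < 0 for a in amps.values()):
            raise ValueError("amplitudes must be >= 0")
        if not any(a > 0 for a in amps.values()):
            raise ValueError("a druse seed needs at least one timepoint with amplitude > 0")


def _bump(seed: DruseSeed, amplitude: float, spec: OctStudySpec) -> np.ndarray:
    """Evaluate the druse's Gaussian elevation on the full (bscan, ascan) grid."""
    db = (np.arange(spec.n_bscans) - seed.center_bscan) * spec.bscan_spacing
    da = (np.arange(spec.n_ascans) - seed.center_ascan) * spec.ascan_spacing
    return amplitude * np.exp(
        -0.5 * (db[:, None] / seed.sigma_bscan) ** 2
        - 0.5 * (da[None, :] / seed.sigma_ascan) ** 2
    )


def generate_oct_series(
    spec: OctStudySpec,
    seeds: Mapping[str, Sequence[DruseSeed]],
    arms_by_eye: Mapping[str, str] | None = None,
    base_depth: float = 300.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate boundary tables for every eye at every timepoint.

    Parameters
    ----------
    spec
        Study geometry and noise.
    seeds
        Mapping eye_id -> druse seeds for that eye.
    arms_by_eye
        Mapping eye_id -> arm label; defaults to :data:`DEFAULT_EYES`
        restricted to the eyes present in ``seeds``.
    base_depth
        Mean depth of the Choroid/BrM boundary, μm (posterior-positive).

    Returns
    -------
    boundaries, truth
        ``boundaries`` has columns eye_id, arm, timepoint_months,
        bscan_index, ascan_index, rpe_pos_depth_um, brm_depth_um.
        ``truth`` catalogs, per druse per timepoint, the analytic peak
        amplitude and geometry (druse_id, eye_id, timepoint_months,
        center_bscan, center_ascan, sigma_bscan_um, sigma_ascan_um,
        amplitude_um).
    """
    if arms_by_eye is None:
        arms_by_eye = {e: DEFAULT_EYES[e] for e in seeds if e in DEFAULT_EYES}
    unknown = set(seeds) - set(arms_by_eye)
    if unknown:
        raise ValueError(f"no arm label for eyes: {sorted(unknown)}")
    for eye_id, eye_seeds in seeds.items():
        for s in eye_seeds:
            if not (0 <= s.center_bscan < spec.n_bscans and 0 <= s.center_ascan < spec.n_ascans):
                raise ValueError(
                    f"druse seed {s.druse_id!r} (eye {eye_id}) lies outside the "
                    f"{spec.n_bscans}x{spec.n_ascans} grid"
                )

    rng = np.random.default_rng(spec.rng_seed)
    x_b = np.arange(spec.n_bscans)[:, None] * spec.bscan_spacing
    x_a = np.arange(spec.n_ascans)[None, :] * spec.ascan_spacing

    bidx, aidx = np.meshgrid(
        np.arange(spec.n_bscans), np.arange(spec.n_ascans), indexing="ij"
    )
    boundary_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for eye_id in sorted(seeds):
        arm = arms_by_eye[eye_id]
        # per-eye random undulation phase, fixed across the eye's visits
        phase_b, phase_a = rng.uniform(0, 2 * np.pi, size=2)
        k = 2 * np.pi / spec.undulation_wavelength if spec.undulation_wavelength > 0 else 0.0
        undulation = spec.undulation_amplitude * (
            np.sin(k * x_b + phase_b) + np.sin(k * x_a + phase_a)
        ) / 2.0
        smooth_brm = base_depth + undulation
        for t in spec.timepoints:
            shape = (spec.n_bscans, spec.n_ascans)
            brm = smooth_brm + rng.normal(0.0, spec.axial_noise_sd, size=shape)
            elevation = np.zeros(shape)
            for s in seeds[eye_id]:
                amp = float(dict(s.amplitude_by_timepoint).get(t, 0.0))
                truth_rows.append(
                    {
                        "druse_id": s.druse_id,
                        "eye_id": eye_id,
                        "timepoint_months": t,
                        "center_bscan": s.center_bscan,
                        "center_ascan": s.center_ascan,
                        "sigma_bscan_um": s.sigma_bscan,
                        "sigma_ascan_um": s.sigma_ascan,
                        "amplitude_um": amp,
                    }
                )
                if amp > 0:
                    elevation += _bump(s, amp, spec)
            # both boundaries share the smooth surface but carry independent
            # axial noise, so thickness noise has sd sqrt(2)*axial_noise_sd
            rpe = (
                smooth_brm
                - spec.nominal_thickness
                - elevation
                + rng.normal(0.0, spec.axial_noise_sd, size=shape)
            )
            boundary_rows.append(
                pd.DataFrame(
                    {
                        "eye_id": eye_id,
                        "arm": arm,
                        "timepoint_months": t,
                        "bscan_index": bidx.ravel(),
                        "ascan_index": aidx.ravel(),
                        "rpe_pos_depth_um": rpe.ravel(),
                        "brm_depth_um": brm.ravel(),
                    }
                )
            )
    boundaries = pd.concat(boundary_rows, ignore_index=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "druse_id",
            "eye_id",
            "timepoint_months",
            "center_bscan",
            "center_ascan",
            "sigma_bscan_um",
            "sigma_ascan_um",
            "amplitude_um",
        ],
    )
    return boundaries, truth


def generate_two_arm_study(
    spec: OctStudySpec,
    n_drusen_per_arm: int = 20,
    growth_multipliers: Mapping[str, float] | None = None,
    amplitude_range: tuple[float, float] = (15.0, 60.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random two-arm longitudinal study with arm-specific growth.

    Each druse starts at a baseline amplitude drawn uniformly from
    ``amplitude_range`` and is scaled by its arm's growth multiplier per
    3-month interval, so a multiplier < 1 encodes treated shrinkage and
    > 1 untreated growth.  Drusen are split evenly across the two eyes of
    each arm and placed away from volume edges with a minimum spacing that
    keeps footprints resolvable.
    """
    if growth_multipliers is None:
        growth_multipliers = {"injected": 0.9, "uninjected": 1.1}
    rng = np.random.default_rng(seed)
    eyes_by_arm: dict[str, list[str]] = {}
    for eye, arm in DEFAULT_EYES.items():
        eyes_by_arm.setdefault(arm, []).append(eye)
    seeds: dict[str, list[DruseSeed]] = {e: [] for e in DEFAULT_EYES}
    counter = 0
    for arm in spec.arms:
        g = growth_multipliers[arm]
        eyes = eyes_by_arm[arm]
        for i in range(n_drusen_per_arm):
            eye = eyes[i % len(eyes)]
            # keep a margin so footprints stay off the volume edge
            cb = int(rng.integers(6, spec.n_bscans - 6))
            ca = int(rng.integers(30, spec.n_ascans - 30))
            # avoid overlapping footprints within an eye
            taken = [(s.center_bscan, s.center_ascan) for s in seeds[eye]]
            tries = 0
            while any(
                abs(cb - b0) * spec.bscan_spacing < 700
                and abs(ca - a0) * spec.ascan_spacing < 700
                for b0, a0 in taken
            ):
                cb = int(rng.integers(6, spec.n_bscans - 6))
                ca = int(rng.integers(30, spec.n_ascans - 30))
                tries += 1
                if tries > 500:
                    raise RuntimeError("could not place non-overlapping drusen")
            a0 = rng.uniform(*amplitude_range)
            amps = {
                t: a0 * g ** (t / 3.0) for t in spec.timepoints
            }
            seeds[eye].append(
                DruseSeed(
                    druse_id=f"{arm[:3]}{counter:03d}",
                    center_bscan=cb,
                    center_ascan=ca,
                    sigma_bscan=150.0,
                    sigma_ascan=100.0,
                    amplitude_by_timepoint=amps,
                )
            )
            counter += 1
    return generate_oct_series(spec, seeds)


# ---------------------------------------------------------------------------
# RPE flat mounts


@dataclass(frozen=True)
class FlatMountSpec:
    """Parameters of one synthetic RPE flat-mount pair (8 am and 11 am).

    ``clearance_fraction_11am`` is the expected ratio of dots remaining at
    11 am to dots present at 8 am; 1.0 means no clearance.  Dot diameters
    are drawn from a normal distribution truncated at 0.2 μm so that a
    known mass falls below the 2 μm counting threshold.
    """

    mount_radius: float = 1700.0  # μm
    mean_cell_area: float = 400.0  # μm²
    dots_per_cell_8am: float = 10.0
    clearance_fraction_11am: float = 0.5
    dot_diameter_distribution: tuple[float, float] = (3.0, 1.0)  # (mean, sd) μm
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mount_radius < 1500.0:
            raise ValueError("mount_radius must be >= 1500 μm to contain the sampling disk")
        if self.mean_cell_area <= 0:
            raise ValueError("mean_cell_area must be > 0")
        if self.dots_per_cell_8am < 0:
            raise ValueError("dots_per_cell_8am must be >= 0")
        if not 0.0 <= self.clearance_fraction_11am <= 1.0:
            raise ValueError("clearance_fraction_11am must lie in [0, 1]")


@dataclass
class FlatMount:
    """Cell tessellation plus dot records for a mount pair.

    ``cells`` columns: cell_id, centroid_x_um, centroid_y_um, area_um2, wkt.
    ``dots`` columns: dot_id, time_label (8am/11am), x_um, y_um,
    diameter_um, cell_id.
    """

    spec: FlatMountSpec
    cells: pd.DataFrame
    dots: pd.DataFrame
    #: shapely polygons aligned with ``cells`` rows
    polygons: list[Polygon]

    @property
    def ground_truth_clearance(self) -> float:
        return self.spec.clearance_fraction_11am


def _voronoi_cells(rng: np.random.Generator, spec: FlatMountSpec, lloyd_iters: int = 1):
    """Centroidal-ish random tessellation of the mount disk."""
    r = spec.mount_radius
    n_cells = max(4, int(round(np.pi * r * r / spec.mean_cell_area)))
    # uniform points in the disk
    theta = rng.uniform(0, 2 * np.pi, n_cells)
    rad = r * np.sqrt(rng.uniform(0, 1, n_cells))
    pts = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
    # guard ring so every interior region is finite
    n_ring = 256
    ang = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    ring = 1.3 * r * np.column_stack([np.cos(ang), np.sin(ang)])
    disk = Point(0, 0).buffer(r, quad_segs=128)
    for it in range(lloyd_iters + 1):
        vor = Voronoi(np.vstack([pts, ring]))
        vert_radius = np.hypot(vor.vertices[:, 0], vor.vertices[:, 1])
        polys = []
        for i in range(n_cells):
            region = vor.regions[vor.point_region[i]]
            poly = Polygon(vor.vertices[region])
            # only boundary cells (with a vertex outside the disk) need clipping
            if vert_radius[region].max() > r:
                poly = poly.intersection(disk)
            polys.append(poly)
        if it < lloyd_iters:
            pts = shapely.get_coordinates(shapely.centroid(np.asarray(polys, dtype=object)))
    return polys


def generate_flatmount(spec: FlatMountSpec) -> FlatMount:
    """Generate a flat-mount pair: one tessellation, dots at both clock times.

    8 am dot counts per cell are Poisson with rate ``dots_per_cell_8am``;
    11 am counts are an independent redraw at rate
    ``dots_per_cell_8am * clearance_fraction_11am``, emulating POS clearance
    between the shedding peak and 3 h later.  Each dot is placed uniformly
    inside its cell, so every dot belongs to exactly one cell region.
    """
    rng = np.random.default_rng(spec.rng_seed)
    polys = _voronoi_cells(rng, spec)
    n_cells = len(polys)
    geoms = np.asarray(polys, dtype=object)
    cent = shapely.get_coordinates(shapely.centroid(geoms))
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "centroid_x_um": cent[:, 0],
            "centroid_y_um": cent[:, 1],
            "area_um2": shapely.area(geoms),
            "wkt": shapely.to_wkt(geoms, rounding_precision=3),
        }
    )

    mu, sd = spec.dot_diameter_distribution
    dot_frames = []
    next_id = 0
    for label, rate in (
        ("8am", spec.dots_per_cell_8am),
        ("11am", spec.dots_per_cell_8am * spec.clearance_fraction_11am),
    ):
        counts = rng.poisson(rate, size=n_cells)
        cell_idx = np.repeat(np.arange(n_cells), counts)
        n_dots = cell_idx.size
        xs = np.empty(n_dots)
        ys = np.empty(n_dots)
        pending = np.arange(n_dots)
        geoms = np.asarray(polys, dtype=object)
        bounds = np.array([p.bounds for p in polys])  # minx,miny,maxx,maxy
        while pending.size:
            ci = cell_idx[pending]
            bx0, by0, bx1, by1 = bounds[ci].T
            cx = rng.uniform(bx0, bx1)
            cy = rng.uniform(by0, by1)
            inside = shapely.contains_xy(geoms[ci], cx, cy)
            hit = pending[inside]
            xs[hit] = cx[inside]
            ys[hit] = cy[inside]
            pending = pending[~inside]
        diam = rng.normal(mu, sd, size=n_dots)
        diam = np.clip(diam, 0.2, None)
        dot_frames.append(
            pd.DataFrame(
                {
                    "dot_id": next_id + np.arange(n_dots),
                    "time_label": label,
                    "x_um": xs,
                    "y_um": ys,
                    "diameter_um": diam,
                    "cell_id": cell_idx,
                }
            )
        )
        next_id += n_dots
    dots = pd.concat(dot_frames, ignore_index=True)
    return FlatMount(spec=spec, cells=cells, dots=dots, polygons=polys)


# ---------------------------------------------------------------------------
# Lipid panels


@dataclass(frozen=True)
class LipidPanelSpec:
    """Structure of a synthetic phospholipid panel.

    ``baseline_class_fractions`` give the expected share of total response
    per class (they must sum to 1); ``group_effects`` maps
    (group, class) -> multiplicative shift applied before renormalisation.
    Noise is multiplicative log-normal with coefficient of variation
    ``noise_cv``.
    """

    classes: tuple[str, ...] = ("PE", "PC", "PS", "PI", "PG", "BMP")
    species_per_class: int = 5
    baseline_class_fractions: Mapping[str, float] | None = None
    group_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    groups: tuple[str, ...] = ("control", "treated")
    noise_cv: float = 0.15
    n_samples_per_group: int = 6
    rng_seed: int = 0

    def resolved_fractions(self) -> dict[str, float]:
        if self.baseline_class_fractions is None:
            # retina-like composition: PC and PE dominate
            defaults = {"PE": 0.35, "PC": 0.45, "PS": 0.08, "PI": 0.07, "PG": 0.03, "BMP": 0.02}
            if set(self.classes) == set(defaults):
                return defaults
            return {c: 1.0 / len(self.classes) for c in self.classes}
        return dict(self.baseline_class_fractions)

    def __post_init__(self) -> None:
        fr = self.resolved_fractions()
        if set(fr) != set(self.classes):
            raise ValueError("baseline fractions must cover exactly the declared classes")
        if not np.isclose(sum(fr.values()), 1.0):
            raise ValueError("baseline class fractions must sum to 1")
        if any(v <= 0 for v in self.group_effects.values()):
            raise ValueError("group effects must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def generate_lipid_panel(spec: LipidPanelSpec, total_response: float = 1e6) -> pd.DataFrame:
    """Per-sample species responses with class structure and group effects.

    Returns a long table (sample_id, group, class, species, response) whose
    expected class sums equal ``baseline_fraction x group_effect`` (up to the
    common total), with multiplicative log-normal noise of the stated CV.
    """
    rng = np.random.default_rng(spec.rng_seed)
    fractions = spec.resolved_fractions()
    sigma = float(np.sqrt(np.log(1.0 + spec.noise_cv**2)))
    rows = []
    for group in spec.groups:
        for i in range(spec.n_samples_per_group):
            sample_id = f"{group}_{i + 1}"
            for cls in spec.classes:
                shift = float(spec.group_effects.get((group, cls), 1.0))
                class_total = total_response * fractions[cls] * shift
                per_species = class_total / spec.species_per_class
                for j in range(spec.species_per_class):
                    noise = (
                        np.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
                    )
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "group": group,
                            "class": cls,
                            "species": f"{cls}({j + 1})",
                            "response": per_species * noise,
                        }
                    )
    return pd.DataFrame(rows)
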