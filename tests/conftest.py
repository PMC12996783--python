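import numpy as np
import pytest

from retquant import longitudinal as lng
from retquant import morphometry as mm
from retquant import synthetic as syn


@pytest.fixture
def noiseless_spec() -> syn.OctStudySpec:
    """Study geometry with no axial noise and no surface undulation."""
    return syn.OctStudySpec(axial_noise_sd=0.0, undulation_amplitude=0.0)


def make_volume(thickness: np.ndarray, **kw) -> mm.BoundaryVolume:
    """Boundary volume with a prescribed thickness field (BrM flat at 300 μm)."""
    thickness = np.asarray(thickness, dtype=float)
    brm = np.full_like(thickness, 300.0)
    return mm.BoundaryVolume(
        eye_id=kw.pop("eye_id", "E"),
        arm=kw.pop("arm", "injected"),
        timepoint=kw.pop("timepoint", 0.0),
        rpe_pos_depth=brm - thickness,
        brm_depth=brm,
        **kw,
    )


@pytest.fixture(scope="session")
def ten_seed_studies():
    """Ten independently seeded two-arm studies with opposite growth.

    The treated arm shrinks (multiplier 0.85 per 3 months) and the control
    arm grows (1.15); 20 drusen per arm, axial noise sd 2 μm.  Tracks are
    computed once and shared by effect-direction and permutation checks.
    """
    studies = []
    for seed in range(10):
        boundaries, _ = syn.generate_two_arm_study(
            syn.OctStudySpec(),
            n_drusen_per_arm=20,
            growth_multipliers={"injected": 0.85, "uninjected": 1.15},
            seed=seed,
        )
        volumes = [
            mm.BoundaryVolume.from_dataframe(sub)
            for _, sub in boundaries.groupby(["eye_id", "timepoint_months"])
        ]
        studies.append(lng.track_study(volumes))
    return studies
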