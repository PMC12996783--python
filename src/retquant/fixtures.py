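"""Named synthetic fixture configurations used in examples and validation.

The flat-mount catalog encodes the two POS-clearance study conditions the
pipeline is validated against: a "diseased" condition in which the RPE
clears outer segments slowly (80% of dots remaining at 11 am) and a
"rescued" condition with restored clearance (40% remaining).  All fixtures
are synthetic; their ground truth is the generator parameter itself.
"""

from __future__ import annotations

from .synthetic import FlatMountSpec

__all__ = ["FLATMOUNT_CATALOG", "flatmount_spec"]

#: name -> expected fraction of dots remaining at 11 am
FLATMOUNT_CATALOG: dict[str, float] = {
    "rescued": 0.40,
    "diseased": 0.80,
}


def flatmount_spec(name: str, seed: int = 0) -> FlatMountSpec:
    """Spec for a cataloged flat-mount pair, reseeded per replicate."""
    try:
        fraction = FLATMOUNT_CATALOG[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FLATMOUNT_CATALOG)}"
        ) from None
    return FlatMountSpec(clearance_fraction_11am=fraction, rng_seed=seed)
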