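"""Mutation parameter sets and regional conductance profiles.

The three atrial-fibrillation mutations studied here (KCNH2 T895M, KCNH2 T436M
and KCNE3-V17M) are represented as multiplicative/additive modifiers of the
Hodgkin-Huxley rate constants and conductances of the rapid delayed-rectifier
current I_Kr (nine parameters ``p0r``..``p8r``) and of the transient-outward
current I_to (seven parameters ``p0t``..``p6t``).  The wild type is the
identity: every scale and slope factor is 1 and every voltage shift is 0 mV.

Regional electrical heterogeneity (right atrium, left atrium, pulmonary vein)
is encoded as per-current conductance multipliers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "MutationParameterSet",
    "RegionProfile",
    "MUTATIONS",
    "REGIONS",
    "PARAM_NAMES",
    "SCALE_PARAMS",
    "SHIFT_PARAMS",
    "get_mutation",
    "get_region",
    "save_parameter_set",
    "load_parameter_set",
]

#: canonical ordering used by the numeric kernels
PARAM_NAMES = (
    "p0r", "p1r", "p2r", "p3r", "p4r", "p5r", "p6r", "p7r", "p8r",
    "p0t", "p1t", "p2t", "p3t", "p4t", "p5t", "p6t",
)

#: scale and slope factors: strictly positive, identity = 1
SCALE_PARAMS = frozenset(
    {"p0r", "p2r", "p3r", "p5r", "p6r", "p8r", "p0t", "p2t", "p3t", "p5t", "p6t"}
)
#: additive voltage shifts in mV, identity = 0
SHIFT_PARAMS = frozenset({"p1r", "p4r", "p7r", "p1t", "p4t"})


class InvalidParameterError(ValueError):
    """A scale/slope factor is non-positive or a shift is non-finite."""


@dataclass(frozen=True)
class MutationParameterSet:
    """The 16 modifiers injected into the I_Kr / I_to formulations.

    ``p0r,p3r`` scale the forward/backward rates of the xr activation gate,
    ``p1r,p4r`` shift their voltage dependence, ``p2r,p5r`` change the slopes,
    ``p6r`` scales g_Kr, and ``p7r,p8r`` shift/reslope the instantaneous
    rectification of I_Kr.  ``p0t..p5t`` act analogously on the oi
    inactivation gate of I_to and ``p6t`` scales g_to.
    """

    p0r: float = 1.0
    p1r: float = 0.0
    p2r: float = 1.0
    p3r: float = 1.0
    p4r: float = 0.0
    p5r: float = 1.0
    p6r: float = 1.0
    p7r: float = 0.0
    p8r: float = 1.0
    p0t: float = 1.0
    p1t: float = 0.0
    p2t: float = 1.0
    p3t: float = 1.0
    p4t: float = 0.0
    p5t: float = 1.0
    p6t: float = 1.0
    label: str = "WT"

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise InvalidParameterError(f"{name} must be finite, got {value}")
            if name in SCALE_PARAMS and value <= 0:
                raise InvalidParameterError(
                    f"{name} is a scale/slope factor and must be > 0, got {value}"
                )

    def as_array(self) -> np.ndarray:
        """Parameters in canonical kernel order (float64, length 16)."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=np.float64)

    def replace(self, **changes) -> "MutationParameterSet":
        return dataclasses.replace(self, **changes)

    @property
    def is_identity(self) -> bool:
        return all(
            getattr(self, n) == (0.0 if n in SHIFT_PARAMS else 1.0)
            for n in PARAM_NAMES
        )

    @classmethod
    def from_dict(cls, d: dict) -> "MutationParameterSet":
        return cls(**d)

    def to_dict(self) -> dict:
        d = {n: float(getattr(self, n)) for n in PARAM_NAMES}
        d["label"] = self.label
        return d


@dataclass(frozen=True)
class RegionProfile:
    """Per-region conductance multipliers for six currents.

    The right atrium (RA) is the reference tissue (all multipliers 1); the
    left atrium (LA) and pulmonary vein (PV) profiles encode the published
    regional remodelling of I_CaL, I_Kr, I_KACh, I_to, I_K1 and I_Ks.
    """

    region: str
    i_cal: float = 1.0
    i_kr: float = 1.0
    i_kach: float = 1.0
    i_to: float = 1.0
    i_k1: float = 1.0
    i_ks: float = 1.0

    def __post_init__(self) -> None:
        for f in ("i_cal", "i_kr", "i_kach", "i_to", "i_k1", "i_ks"):
            if getattr(self, f) <= 0:
                raise InvalidParameterError(f"region multiplier {f} must be > 0")

    def as_array(self) -> np.ndarray:
        """Multipliers in kernel order [CaL, Kr, KACh, to, K1, Ks]."""
        return np.array(
            [self.i_cal, self.i_kr, self.i_kach, self.i_to, self.i_k1, self.i_ks],
            dtype=np.float64,
        )


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

MUTATIONS: dict[str, MutationParameterSet] = {
    "WT": MutationParameterSet(label="WT"),
    # KCNH2 T895M: altered I_Kr deactivation kinetics and conductance
    "KCNH2-T895M": MutationParameterSet(
        p3r=2.134, p4r=51.14, p5r=3.49, p6r=1.99, label="KCNH2-T895M"
    ),
    # KCNH2 T436M
    "KCNH2-T436M": MutationParameterSet(
        p3r=1.08, p4r=46.96, p5r=4.64, p6r=1.41, label="KCNH2-T436M"
    ),
    # KCNE3-V17M impairs both Kv11.1 (I_Kr) and Kv4.3 (I_to); the two fitted
    # columns are applied simultaneously.
    "KCNE3-V17M": MutationParameterSet(
        p3r=0.51, p6r=6.18, p8r=0.71,
        p0t=2.0, p2t=1.87, p3t=8.14, p5t=0.68, p6t=12.56,
        label="KCNE3-V17M",
    ),
}

REGIONS: dict[str, RegionProfile] = {
    "RA": RegionProfile(region="RA"),
    "LA": RegionProfile(region="LA", i_cal=0.9, i_kr=2.0, i_kach=1.0,
                        i_to=1.0, i_k1=1.0, i_ks=1.0),
    "PV": RegionProfile(region="PV", i_cal=0.8, i_kr=2.5, i_kach=1.0,
                        i_to=0.9, i_k1=0.9, i_ks=1.9),
}

MUTATION_ALIASES = {
    "WT": "WT",
    "T895M": "KCNH2-T895M",
    "T436M": "KCNH2-T436M",
    "V17M": "KCNE3-V17M",
    "KCNH2-T895M": "KCNH2-T895M",
    "KCNH2-T436M": "KCNH2-T436M",
    "KCNE3-V17M": "KCNE3-V17M",
}


def get_mutation(name: str) -> MutationParameterSet:
    key = MUTATION_ALIASES.get(name.strip())
    if key is None:
        raise KeyError(
            f"unknown mutation {name!r}; known: {sorted(MUTATION_ALIASES)}"
        )
    return MUTATIONS[key]


def get_region(name: str) -> RegionProfile:
    try:
        return REGIONS[name.strip().upper()]
    except KeyError:
        raise KeyError(f"unknown region {name!r}; known: RA, LA, PV") from None


def save_parameter_set(params: MutationParameterSet, path) -> None:
    """Write a parameter set as a human-editable YAML mapping."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_parameter_set(path) -> MutationParameterSet:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return MutationParameterSet.from_dict(d)
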