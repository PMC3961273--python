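"""Model geometry and growth parameters.

Single source of truth for the null-model geometry of the polytene nucleus:
a spherical nucleus of radius ``nucleus_radius`` containing a chromocenter
bead anchored at the north pole and five freely-jointed bead--cylinder chains
(arms X, 2L, 2R, 3L, 3R) grown simultaneously as self-avoiding walks.

All lengths are in microns.  The bond length equals the Kuhn length of the
polytene chromosome fiber (3.1 um), so consecutive bead directions are
uncorrelated and each bond is one statistical segment.  The default nucleus
radius is not a stored constant: it is derived at construction time by
solving ``chromatin_volume_ratio(R) = 0.30`` for the default chain geometry,
pinning the model to the experimentally measured chromosome-to-nucleus
volume ratio.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, fields, replace
from itertools import permutations
from pathlib import Path
from typing import Mapping

import yaml
from scipy.optimize import brentq

__all__ = [
    "ARM_IDS",
    "DEFAULT_ARM_BEAD_COUNTS",
    "TARGET_VOLUME_RATIO",
    "ModelParams",
    "ParamError",
    "arrangement_ids",
    "chromatin_volume_ratio",
    "default_params",
    "load_params",
    "params_digest",
    "solve_nucleus_radius",
]

#: Order of the five major polytene arms; fixed throughout the package.
ARM_IDS = ("X", "2L", "2R", "3L", "3R")

#: Per-arm bead counts.  Proportions follow the relative polytene arm
#: lengths (3R is the longest arm); the total is 248 beads.
DEFAULT_ARM_BEAD_COUNTS = {"X": 45, "2L": 49, "2R": 47, "3L": 48, "3R": 59}

#: Chromosome-to-nucleus volume ratio the default geometry is pinned to.
TARGET_VOLUME_RATIO = 0.30


class ParamError(ValueError):
    """Raised when a parameter value fails validation; names the field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"parameter '{field_name}': {message}")


def arrangement_ids() -> tuple[str, ...]:
    """Distinct circular orderings of the five arms around the chromocenter.

    Two orderings are identified when related by rotation or reflection of
    the circle, giving (5-1)!/2 = 12 classes.  Each id is the canonical
    member written ``"X-..-.."`` with arm X first.
    """
    seen = set()
    out = []
    for perm in permutations(ARM_IDS[1:]):
        order = (ARM_IDS[0],) + perm
        mirrored = (order[0],) + tuple(reversed(order[1:]))
        key = min(order, mirrored)
        if key not in seen:
            seen.add(key)
            out.append("-".join(key))
    return tuple(sorted(out))


def _sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


def _chain_volume(
    bead_radius: float,
    cylinder_radius: float,
    bond_length: float,
    total_beads: int,
    n_bonds: int,
) -> float:
    """Total excluded volume of the chains: bead spheres plus the exposed
    (surface-to-surface) cylindrical connectors, counted once per intra-arm
    bond.  The chromocenter is excluded."""
    gap = max(0.0, bond_length - 2.0 * bead_radius)
    return total_beads * _sphere_volume(bead_radius) + n_bonds * math.pi * cylinder_radius**2 * gap


def solve_nucleus_radius(
    bead_radius: float = 1.0,
    cylinder_radius: float = 1.0,
    bond_length: float = 3.1,
    total_beads: int = 248,
    n_bonds: int = 243,
    target_ratio: float = TARGET_VOLUME_RATIO,
) -> float:
    """Nucleus radius at which the chain/nucleus volume ratio equals
    ``target_ratio``, found numerically by bracketing root search."""
    v_chain = _chain_volume(bead_radius, cylinder_radius, bond_length, total_beads, n_bonds)

    def f(radius: float) -> float:
        return v_chain / _sphere_volume(radius) - target_ratio

    lo, hi = bead_radius * 1.001, 1e4
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def _default_arrangement_weights() -> dict[str, float]:
    # The experimental arrangement tallies are not machine-readable here;
    # default to a uniform prior over the 12 circular classes.
    return {a: 1.0 for a in arrangement_ids()}


@dataclass(frozen=True)
class ModelParams:
    """All geometric and growth parameters of the null model.

    Lengths in microns; probabilities dimensionless.  Instances are
    validated on construction and immutable afterwards.
    """

    nucleus_radius: float | None = None  # derived from volume ratio if None
    bead_radius: float = 1.0
    cylinder_radius: float = 1.0
    bond_length: float = 3.1  # Kuhn length
    chromocenter_radius: float = 1.0
    arm_bead_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ARM_BEAD_COUNTS)
    )
    bt1: int = 2000  # failed additions before a single-bead backtrack
    bt2: int = 6000  # failed additions before a five-bead backtrack
    chirality_right_accept: float = 1.0
    chirality_left_accept: float = 0.5
    ne_contact_distance: float = 1.0
    locus_contact_distance: float = 2.0
    nuclei_per_experiment: int = 24
    n_replicate_experiments: int = 96
    rabl_target_fraction: float = 0.80
    sigma_multiplier: float = 2.0
    arrangement_weights: Mapping[str, float] = field(
        default_factory=_default_arrangement_weights
    )
    nucleolus_enabled: bool = False
    nucleolus_radius: float = 2.0
    nucleolus_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0
    # growth bookkeeping knobs (see saw module)
    growth_mode: str = "lockstep"  # "lockstep" | "independent" | "joint"
    reset_counters_on_accept: bool = True
    count_failures_per_candidate: bool = False
    cylinder_collision: str = "center"  # "center" | "surface" | "none"
    proposal_cap: int = 2_000_000

    def __post_init__(self):
        # scalar geometry must be sane before the radius can be derived
        for name in ("bead_radius", "cylinder_radius", "bond_length"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ParamError(name, f"must be a positive finite length, got {v!r}")
        if self.nucleus_radius is None:
            object.__setattr__(
                self,
                "nucleus_radius",
                solve_nucleus_radius(
                    self.bead_radius,
                    self.cylinder_radius,
                    self.bond_length,
                    self.total_beads,
                    self.n_bonds,
                ),
            )
        self._validate()

    # -- derived quantities -------------------------------------------------

    @property
    def total_beads(self) -> int:
        return int(sum(self.arm_bead_counts.values()))

    @property
    def n_bonds(self) -> int:
        """Intra-arm bonds: each arm of n beads contributes n - 1."""
        return self.total_beads - len(self.arm_bead_counts)

    @property
    def chromocenter_position(self) -> tuple[float, float, float]:
        """Chromocenter bead center: touching the NE at the north pole."""
        return (0.0, 0.0, self.nucleus_radius - self.chromocenter_radius)

    def arm_count(self, arm_id: str) -> int:
        return int(self.arm_bead_counts[arm_id])

    @property
    def cylinder_clearance(self) -> float:
        """Required bead-center-to-connector-axis distance.

        Under the default center-exclusion rule the cylinder volume of
        radius ``cylinder_radius`` around each bond excludes bead centers;
        under the stricter surface-exclusion rule the bead sphere may not
        overlap the exposed connector cylinder at all.  Zero disables the
        cylinder collision checks.
        """
        if self.cylinder_collision == "center":
            return self.cylinder_radius
        if self.cylinder_collision == "surface":
            if self.bond_length <= 2.0 * self.bead_radius:
                return 0.0  # no exposed connector between overlapping beads
            return self.bead_radius + self.cylinder_radius
        return 0.0

    @property
    def cylinder_segment_shrink(self) -> float:
        """Fraction of the bond trimmed from each end of the collision
        segment: the surface-exclusion rule applies to the exposed
        (surface-to-surface) part of the bond only."""
        if self.cylinder_collision == "surface" and self.bond_length > 2.0 * self.bead_radius:
            return self.bead_radius / self.bond_length
        return 0.0

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        positive_lengths = (
            "nucleus_radius",
            "bead_radius",
            "cylinder_radius",
            "bond_length",
            "chromocenter_radius",
            "ne_contact_distance",
            "locus_contact_distance",
            "nucleolus_radius",
        )
        for name in positive_lengths:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ParamError(name, f"must be a positive finite length, got {v!r}")
        if self.bead_radius >= self.nucleus_radius:
            raise ParamError("bead_radius", "must be smaller than nucleus_radius")
        if self.chromocenter_radius >= self.nucleus_radius:
            raise ParamError("chromocenter_radius", "must be smaller than nucleus_radius")
        if set(self.arm_bead_counts) != set(ARM_IDS):
            raise ParamError(
                "arm_bead_counts", f"must map exactly the arms {ARM_IDS}"
            )
        for arm, n in self.arm_bead_counts.items():
            if not (isinstance(n, int) and n >= 1):
                raise ParamError("arm_bead_counts", f"count for {arm} must be a positive integer")
        if not (isinstance(self.bt1, int) and self.bt1 > 0):
            raise ParamError("bt1", "must be a positive integer")
        if not (isinstance(self.bt2, int) and self.bt2 > self.bt1):
            raise ParamError("bt2", "must be an integer greater than bt1")
        for name in (
            "chirality_right_accept",
            "chirality_left_accept",
            "rabl_target_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParamError(name, f"must be a probability in (0, 1], got {v!r}")
        if self.sigma_multiplier <= 0:
            raise ParamError("sigma_multiplier", "must be positive")
        for name in ("nuclei_per_experiment", "n_replicate_experiments"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ParamError(name, "must be a positive integer")
        valid_arr = set(arrangement_ids())
        if not set(self.arrangement_weights) <= valid_arr:
            bad = set(self.arrangement_weights) - valid_arr
            raise ParamError("arrangement_weights", f"unknown arrangement ids {sorted(bad)}")
        w = list(self.arrangement_weights.values())
        if any(x < 0 for x in w):
            raise ParamError("arrangement_weights", "weights must be nonnegative")
        if not any(x > 0 for x in w):
            raise ParamError("arrangement_weights", "weights must not all be zero")
        if len(self.nucleolus_position) != 3:
            raise ParamError("nucleolus_position", "must be a 3D point")
        if not (isinstance(self.proposal_cap, int) and self.proposal_cap > 0):
            raise ParamError("proposal_cap", "must be a positive integer")
        if self.cylinder_collision not in ("center", "surface", "none"):
            raise ParamError("cylinder_collision", "must be 'center', 'surface' or 'none'")
        if self.growth_mode not in ("lockstep", "independent", "joint"):
            raise ParamError("growth_mode", "must be 'lockstep', 'independent' or 'joint'")

    def with_updates(self, **kwargs) -> "ModelParams":
        """Copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


def default_params(**overrides) -> ModelParams:
    """The default parameter set, optionally with fields overridden."""
    return ModelParams(**overrides)


def load_params(config_source=None) -> ModelParams:
    """Build validated :class:`ModelParams` from a config source.

    ``config_source`` may be None (all defaults), a mapping, or a path to a
    flat YAML/JSON key-value document.  Unknown keys are rejected.
    """
    if config_source is None:
        data: dict = {}
    elif isinstance(config_source, Mapping):
        data = dict(config_source)
    else:
        path = Path(config_source)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParamError("<config>", f"{path} does not contain a key-value mapping")

    known = {f.name for f in fields(ModelParams)}
    unknown = set(data) - known
    if unknown:
        raise ParamError(sorted(unknown)[0], "unknown configuration key")
    if "nucleolus_position" in data:
        data["nucleolus_position"] = tuple(float(x) for x in data["nucleolus_position"])
    return ModelParams(**data)


def chromatin_volume_ratio(params: ModelParams) -> float:
    """Chain-to-nucleus volume ratio.

    Sum of bead sphere volumes plus inter-bead connector cylinder volumes
    (one per intra-arm bond, length equal to the surface-to-surface gap
    ``max(0, bond_length - 2 bead_radius)``), divided by the nucleus sphere
    volume.  The chromocenter is excluded.
    """
    v_chain = _chain_volume(
        params.bead_radius,
        params.cylinder_radius,
        params.bond_length,
        params.total_beads,
        params.n_bonds,
    )
    return v_chain / _sphere_volume(params.nucleus_radius)


def params_digest(params: ModelParams) -> str:
    """Short stable identifier for a parameter set."""
    payload = {}
    for f in fields(ModelParams):
        v = getattr(params, f.name)
        if isinstance(v, Mapping):
            v = dict(sorted(v.items()))
        payload[f.name] = v
    blob = json.dumps(payload, sort_keys=True, default=float).encode()
    return hashlib.sha1(blob).hexdigest()[:12]
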