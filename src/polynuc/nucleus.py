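"""Containers for a single generated model nucleus."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .params import ARM_IDS

__all__ = ["NucleusModel", "GrowthError", "GeometryError"]


class GrowthError(RuntimeError):
    """Chain growth failed to complete (proposal cap exceeded)."""


class GeometryError(ValueError):
    """Requested geometry is infeasible (e.g. initial beads cannot fit)."""


@dataclass
class NucleusModel:
    """One model nucleus: chromocenter bead plus five ordered bead chains.

    ``chains`` maps arm id to an ``(n_arm, 3)`` array of bead centers in
    microns; bead 0 of each arm touches the chromocenter and the nuclear
    envelope.  Consecutive centers are exactly one bond length apart.
    """

    params_digest: str
    chromocenter: np.ndarray  # (3,) center of the chromocenter bead
    arrangement_id: str
    chains: Mapping[str, np.ndarray]
    rng_seed: int
    nucleus_id: str = ""

    @property
    def total_beads(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def all_beads(self) -> np.ndarray:
        """All chain bead centers stacked in canonical arm order, (N, 3)."""
        return np.concatenate([self.chains[a] for a in ARM_IDS])

    def bead_arm_index(self) -> np.ndarray:
        """Arm index (position in ARM_IDS) of each row of :meth:`all_beads`."""
        return np.concatenate(
            [np.full(len(self.chains[a]), i, dtype=np.int64) for i, a in enumerate(ARM_IDS)]
        )

    def telomeres(self) -> np.ndarray:
        """Terminal bead center of each arm, (5, 3)."""
        return np.stack([self.chains[a][-1] for a in ARM_IDS])

    def segments(self, arm_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Connector segment endpoints (starts, ends) for one arm."""
        c = self.chains[arm_id]
        return c[:-1], c[1:]
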