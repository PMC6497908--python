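"""Indexing conventions for multi-muscle activity vectors.

A muscle-activity pattern for one stride is a flat vector indexed by
``(leg, muscle, phase)``: the slow-leg block first, then the fast-leg
block, muscle-major / phase-minor within each block.  With the default
15 muscles per leg and 12 gait phases this gives 360 components, each in
units of % of that muscle's maximum baseline activity.  The mirroring
operation (exchange the two leg blocks) and all serialization depend on
this ordering, so it is centralized here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recorded muscles (distal to proximal), abbreviations as used in the field.
MUSCLES: tuple[str, ...] = (
    "TA", "PER", "MG", "LG", "SOL",
    "BF", "SMT", "SMB", "RF", "VL",
    "VM", "HIP", "ADM", "GLU", "TFL",
)

#: The 12 gait-phase bins of one leg's cycle, in temporal order starting at
#: ipsilateral heel-strike: first double support split in halves, single
#: stance in quarters, second double support in halves, swing in quarters.
PHASE_LABELS: tuple[str, ...] = (
    "DS1a", "DS1b",
    "SINGLE1", "SINGLE2", "SINGLE3", "SINGLE4",
    "DS2a", "DS2b",
    "SWING1", "SWING2", "SWING3", "SWING4",
)

LEGS: tuple[str, str] = ("slow", "fast")


@dataclass(frozen=True)
class ActivityIndex:
    """Component ordering of an activity vector.

    Parameters
    ----------
    muscles
        Muscle labels shared by the two legs.
    phases
        Phase-bin labels of one gait cycle.
    """

    muscles: tuple[str, ...] = MUSCLES
    phases: tuple[str, ...] = PHASE_LABELS
    legs: tuple[str, str] = LEGS

    @property
    def n_components(self) -> int:
        return len(self.legs) * len(self.muscles) * len(self.phases)

    @property
    def block_size(self) -> int:
        """Number of components in one leg's block."""
        return len(self.muscles) * len(self.phases)

    def labels(self) -> list[str]:
        """Flat component labels, e.g. ``slow_TA_DS1a``."""
        return [
            f"{leg}_{m}_{ph}"
            for leg in self.legs
            for m in self.muscles
            for ph in self.phases
        ]

    def position(self, leg: str, muscle: str, phase: str) -> int:
        li = self.legs.index(leg)
        mi = self.muscles.index(muscle)
        pi = self.phases.index(phase)
        return (li * len(self.muscles) + mi) * len(self.phases) + pi

    def mirror_permutation(self) -> np.ndarray:
        """Permutation that exchanges the two leg blocks.

        Within-block (muscle, phase) order is preserved; applying the
        permutation twice is the identity.
        """
        b = self.block_size
        return np.concatenate([np.arange(b, 2 * b), np.arange(0, b)])

    def mirror(self, values: np.ndarray) -> np.ndarray:
        """Leg-transpose ``values`` along its last axis."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_components:
            raise ValueError(
                f"expected {self.n_components} components, got {values.shape[-1]}"
            )
        return values[..., self.mirror_permutation()]


DEFAULT_INDEX = ActivityIndex()
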