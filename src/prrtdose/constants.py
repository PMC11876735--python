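"""Physical constants for the radionuclide under study.

The default values describe :sup:`177`Lu: a physical half-life of 6.647 days
(159.53 h) and the fixed conversion of 3.6e9 nuclear transformations per
MBq·h of time-integrated activity.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhysicalConstants", "LU177", "substream"]


@dataclass(frozen=True)
class PhysicalConstants:
    """Decay data for one radionuclide.

    Parameters
    ----------
    physical_half_life:
        Physical half-life in hours (default: 159.53 h for Lu-177).
    decays_per_MBq_hour:
        Nuclear transformations per MBq·h (1e6 /s x 3600 s = 3.6e9).
    """

    physical_half_life: float = 159.53
    decays_per_MBq_hour: float = 3.6e9

    def __post_init__(self) -> None:
        if self.physical_half_life <= 0:
            raise ValueError("physical_half_life must be positive")
        if self.decays_per_MBq_hour <= 0:
            raise ValueError("decays_per_MBq_hour must be positive")

    @property
    def decay_constant(self) -> float:
        """Physical decay constant lambda = ln2 / T_half [1/h]."""
        return math.log(2.0) / self.physical_half_life


#: Default constants for Lu-177.
LU177 = PhysicalConstants()


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one global seed.

    Every stochastic artifact (planar images, blood samples, lesion courses,
    cohort draws) pulls its own generator keyed by a stable name, so adding a
    new artifact never perturbs the draws of an existing one.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )
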