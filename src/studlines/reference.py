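"""Reference coordinate frame for the equine mtDNA control region.

All coordinates in this package are 1-based inclusive nucleotide
positions ("np") on the reference mitogenome numbering, the convention
used throughout the equine mtDNA literature.  The D-loop control region
spans np 15445-16660 and is split into an upstream hypervariable
segment (UP, np 15445-16153, ending at the first bases of the 8-bp
repeat array) and a downstream segment (DOWN, np 16154-16660).

The repeat array itself is excluded from variant calling and haplotype
identity: its copy number is subject to length heteroplasmy and is not
reproducible between sequencing runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Interval = tuple[int, int]

DLOOP_INTERVAL: Interval = (15445, 16660)
UP_INTERVAL: Interval = (15445, 16153)
DOWN_INTERVAL: Interval = (16154, 16660)
#: default bounds of the 8-bp repeat array adjacent to the UP/DOWN boundary
REPEAT_INTERVAL: Interval = (16129, 16153)


@dataclass(frozen=True)
class ReferenceMap:
    """A reference sequence plus the control-region interval layout.

    Parameters
    ----------
    reference_id:
        Accession-style identifier of the coordinate frame.
    sequence:
        Upper-case DNA string; ``sequence[p - 1]`` is the base at np ``p``.
    dloop_interval, up_interval, down_interval:
        1-based inclusive bounds.  UP and DOWN must be disjoint, adjacent
        and tile the D-loop exactly.
    repeat_interval:
        Optional bounds of the repeat array masked from variant calling.
    """

    reference_id: str
    sequence: str
    dloop_interval: Interval = DLOOP_INTERVAL
    up_interval: Interval = UP_INTERVAL
    down_interval: Interval = DOWN_INTERVAL
    repeat_interval: Interval | None = REPEAT_INTERVAL

    def __post_init__(self) -> None:
        lo, hi = self.dloop_interval
        u0, u1 = self.up_interval
        d0, d1 = self.down_interval
        if not (u0 == lo and d1 == hi and u1 + 1 == d0):
            raise ValueError(
                "UP and DOWN intervals must be adjacent, disjoint and tile "
                f"the D-loop: UP={self.up_interval} DOWN={self.down_interval} "
                f"D-loop={self.dloop_interval}"
            )
        intervals = [self.dloop_interval, self.up_interval, self.down_interval]
        if self.repeat_interval is not None:
            intervals.append(self.repeat_interval)
        for a, b in intervals:
            if not (1 <= a <= b <= len(self.sequence)):
                raise ValueError(f"interval ({a}, {b}) outside reference of length {len(self.sequence)}")

    def base(self, position: int) -> str:
        """Reference base at 1-based ``position``."""
        return self.sequence[position - 1]

    def slice(self, interval: Interval) -> str:
        """Reference subsequence over a 1-based inclusive interval."""
        a, b = interval
        return self.sequence[a - 1 : b]

    def repeat_positions(self) -> frozenset[int]:
        if self.repeat_interval is None:
            return frozenset()
        a, b = self.repeat_interval
        return frozenset(range(a, b + 1))

    def dloop_positions(self) -> frozenset[int]:
        a, b = self.dloop_interval
        return frozenset(range(a, b + 1))


# Internal constant: the synthetic frame must be identical across runs
# and is therefore never derived from a user-supplied seed.
_SYNTHETIC_FRAME_SEED = 398377


def synthetic_dloop_reference(length: int = 16660) -> ReferenceMap:
    """Deterministic synthetic reference on the equine mtDNA coordinate frame.

    The true reference mitogenome cannot be redistributed with the
    package, so tests and simulations run on a synthetic stand-in: a
    fixed pseudo-random sequence long enough to carry the published
    control-region interval layout (np 15445-16660).  Every analysis in
    the package is coordinate-frame relative, so nothing downstream
    depends on the actual base composition.
    """
    rng = np.random.default_rng(_SYNTHETIC_FRAME_SEED)
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=length))
    return ReferenceMap(reference_id="SYNTH_DLOOP_FRAME", sequence=seq)
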