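"""Per-position allele counts (pileup) from ungapped alignments.

The pileup is the bridge between mapping and the mutation-load statistics:
for every reference position it records how many aligned reads observed A,
C, G and T (reference orientation; reverse-strand reads were already
complemented at alignment time).  No base- or mapping-quality filtering is
applied — every aligned base counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mapping import Alignment
from .reference import CircularReference


@dataclass
class PileupMatrix:
    """Observed A/C/G/T counts per position against a designated reference.

    ``counts[p, c]`` is the number of aligned bases with code ``c`` at
    position ``p`` (original coordinates); ``ref_codes[p]`` is the reference
    base.  ``excluded_bases`` counts aligned bases outside {A,C,G,T} (only
    possible for imported alignments; the simulator never emits them).
    """

    ref_codes: np.ndarray  # (L,) uint8
    counts: np.ndarray  # (L, 4) int64
    provenance: str = "original"
    excluded_bases: int = 0

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.ref_codes), 4):
            raise ValueError("counts must have shape (L, 4)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def length(self) -> int:
        return len(self.ref_codes)

    @property
    def depth(self) -> np.ndarray:
        """Per-position depth: the row sums of the count matrix."""
        return self.counts.sum(axis=1)

    @property
    def total_bases(self) -> int:
        return int(self.counts.sum())


def build_pileup(
    alignments: Sequence[Alignment],
    ref: CircularReference,
    ref_version: str = "original",
) -> PileupMatrix:
    """Count every aligned base per reference position.

    Alignments made on the rotated linearisation are back-translated to
    original coordinates, so downstream consumers always see one frame.
    Observed codes above 3 (ambiguous bases from imported SAM) are excluded
    and tallied in ``excluded_bases``.
    """
    L = ref.length
    counts = np.zeros((L, 4), dtype=np.int64)
    excluded = 0
    if alignments:
        for a in alignments:
            if a.ref_version != ref_version:
                raise ValueError(
                    f"alignment on {a.ref_version!r}, expected {ref_version!r}"
                )
        # one vectorised bincount per read length (lengths are uniform for
        # simulated data; imported SAM may mix)
        by_len: dict[int, list[Alignment]] = {}
        for a in alignments:
            by_len.setdefault(len(a.observed), []).append(a)
        for rl, group in by_len.items():
            starts = np.fromiter(
                (a.start for a in group), dtype=np.int64, count=len(group)
            )
            obs = np.stack([a.observed for a in group])
            pos = starts[:, None] + np.arange(rl)[None, :]
            pos, obs = pos.ravel(), obs.ravel().astype(np.int64)
            valid = obs < 4
            excluded += int((~valid).sum())
            flat = pos[valid] * 4 + obs[valid]
            counts += np.bincount(flat, minlength=L * 4).reshape(L, 4)
    if ref_version == "rotated":
        counts = np.roll(counts, ref.rotation_offset(), axis=0)
    return PileupMatrix(
        ref_codes=ref.codes,
        counts=counts,
        provenance=ref_version,
        excluded_bases=excluded,
    )
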