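"""Ungapped read mapping by exact k-mer seeding and Hamming verification.

Simulated reads carry substitutions only, so gapped alignment is
unnecessary: a read is placed by looking up an exact k-mer seed (from the
5' end, falling back to the 3' end) in a reference index, then verifying
every candidate position by full-length Hamming comparison on the linear
reference.  Both strands are tried; the unique best placement with at most
``max_mismatches`` mismatches wins, and a tie between equally good
placements leaves the read unmapped.

Reads whose template wraps the linearisation origin have no full-length
placement on the original reference and come back unmapped here — they are
recovered by mapping against the rotated reference (see
:mod:`mtload.coverage`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import COMPLEMENT_CODE, CircularReference
from .simulate import ReadSet

DEFAULT_MAX_MISMATCHES = 5
DEFAULT_SEED_KMER = 31


@dataclass
class Alignment:
    """One ungapped read placement on a linear reference version.

    ``observed`` holds the read's bases in reference orientation (reverse
    strand reads are stored reverse-complemented), so pileup construction is
    a straight overlay.
    """

    read_id: str
    read_index: int
    ref_version: str  # "original" or "rotated"
    start: int  # 0-based on the linear sequence of that version
    is_reverse: bool
    n_mismatches: int
    observed: np.ndarray  # (read_length,) uint8, reference orientation


class KmerIndex:
    """Exact k-mer -> positions lookup over a linear reference string."""

    def __init__(self, ref: CircularReference, k: int = DEFAULT_SEED_KMER):
        if k < 1 or k > ref.length:
            raise ValueError("seed k-mer length out of range")
        self.k = k
        self.length = ref.length
        raw = ref.codes.tobytes()
        index: dict[bytes, list[int]] = {}
        for p in range(ref.length - k + 1):
            index.setdefault(raw[p : p + k], []).append(p)
        self._index = index

    def lookup(self, kmer: bytes) -> list[int]:
        return self._index.get(kmer, [])


def map_reads(
    reads: ReadSet,
    ref: CircularReference,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    seed_kmer_length: int = DEFAULT_SEED_KMER,
    ref_version: str = "original",
) -> list[Alignment]:
    """Map every read; returns alignments for the mappable subset.

    Candidate positions are gathered from both strands (5' seed first, 3'
    seed if the 5' seed finds nothing), then verified in one vectorised
    Hamming pass.  Placement rules: fewest mismatches wins; more than one
    placement at the best score, or best score above ``max_mismatches``,
    leaves the read unmapped.
    """
    rl = reads.read_length
    k = seed_kmer_length
    if rl < k:
        raise ValueError("read_length must be >= seed_kmer_length")
    if len(set(reads.ids)) != len(reads.ids):
        raise ValueError("duplicate read ids in input")
    index = KmerIndex(ref, k)
    L = ref.length

    fwd = reads.codes
    rev = COMPLEMENT_CODE[fwd][:, ::-1]

    cand_read: list[int] = []
    cand_start: list[int] = []
    cand_rev: list[bool] = []
    for i in range(len(reads)):
        for oriented, is_rev in ((fwd[i], False), (rev[i], True)):
            raw = oriented.tobytes()
            hits = index.lookup(raw[:k])
            offset = 0
            if not hits:
                hits = index.lookup(raw[rl - k :])
                offset = rl - k
            for p in hits:
                start = p - offset
                if 0 <= start and start + rl <= L:
                    cand_read.append(i)
                    cand_rev.append(is_rev)
                    cand_start.append(start)

    if not cand_read:
        return []
    cr = np.asarray(cand_read)
    cs = np.asarray(cand_start)
    cv = np.asarray(cand_rev)

    # Vectorised full-length Hamming verification of all candidates.
    window = ref.codes[cs[:, None] + np.arange(rl)[None, :]]
    oriented = np.where(cv[:, None], rev[cr], fwd[cr])
    mism = (window != oriented).sum(axis=1)

    alignments: list[Alignment] = []
    order = np.lexsort((mism, cr))
    n_cand = len(order)
    pos = 0
    while pos < n_cand:
        j = order[pos]
        i = cr[j]
        end = pos
        while end < n_cand and cr[order[end]] == i:
            end += 1
        best = mism[j]
        if best <= max_mismatches:
            # tie at the best score -> ambiguous -> unmapped
            if not (end > pos + 1 and mism[order[pos + 1]] == best):
                alignments.append(
                    Alignment(
                        read_id=reads.ids[i],
                        read_index=int(i),
                        ref_version=ref_version,
                        start=int(cs[j]),
                        is_reverse=bool(cv[j]),
                        n_mismatches=int(best),
                        observed=oriented[j],
                    )
                )
        pos = end
    return alignments
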