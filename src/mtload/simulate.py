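"""Short-read simulation on a circular genome with a full truth record.

The simulator emulates an amplicon-free MiSeq-style shotgun experiment on
mtDNA: fragments start uniformly around the circle (optionally thinned inside
the non-coding region to reproduce the coverage trough seen there), paired
reads are taken from the fragment ends, heteroplasmic alternate alleles are
placed per read at their site frequency, and each emitted base is substituted
with a per-base error probability.  Everything injected is recorded in a
:class:`TruthTable` so downstream estimators can be checked against exact
ground truth.

All randomness flows from a single integer seed; identical parameters and
seed give byte-identical reads and truth output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import (
    BASES,
    CircularReference,
    decode_bases,
    reverse_complement_codes,
)


@dataclass
class Heteroplasmy:
    """A single heteroplasmic site: alternate allele at a site frequency."""

    position: int
    alt: str
    frequency: float

    def __post_init__(self) -> None:
        if self.alt not in BASES:
            raise ValueError(f"alternate allele must be one of {BASES}")
        if not 0.0 < self.frequency < 1.0:
            raise ValueError("heteroplasmy frequency must be in (0, 1)")


@dataclass
class ReadSimParams:
    """Parameters of one simulated sequencing run.

    ``error_rate * run_multiplier`` is the realised per-base substitution
    probability; ``run_multiplier`` models run-level batch effects (the same
    library re-sequenced on a noisier run shows uniformly elevated error
    rates).  ``coverage_bias`` <= 1 thins fragments whose midpoint falls in
    the reference's non-coding region, producing the characteristic trough.
    """

    seed: int = 0
    read_length: int = 100
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 20.0
    mean_depth: float = 100.0
    error_rate: float = 0.0
    run_multiplier: float = 1.0
    heteroplasmies: list[Heteroplasmy] = field(default_factory=list)
    coverage_bias: float = 1.0
    paired: bool = True

    def __post_init__(self) -> None:
        self.heteroplasmies = [
            h if isinstance(h, Heteroplasmy) else Heteroplasmy(*h)
            for h in self.heteroplasmies
        ]
        eff = self.error_rate * self.run_multiplier
        if not 0.0 <= eff < 0.01:
            raise ValueError("effective error rate must lie in [0, 0.01)")
        if not 0.0 < self.coverage_bias <= 1.0:
            raise ValueError("coverage_bias must lie in (0, 1]")
        if self.read_length < 1 or self.mean_depth <= 0:
            raise ValueError("read_length and mean_depth must be positive")

    @property
    def effective_error_rate(self) -> float:
        return self.error_rate * self.run_multiplier


@dataclass
class ReadSet:
    """Simulated reads: ids plus base-code matrix in read orientation."""

    ids: list[str]
    codes: np.ndarray  # (n_reads, read_length) uint8
    read_length: int

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def total_bases(self) -> int:
        return int(self.codes.size)

    def sequence(self, i: int) -> str:
        return decode_bases(self.codes[i])


@dataclass
class TruthTable:
    """Exact record of what the simulator injected.

    ``start`` / ``strand`` are per-read template origins on the circle
    (0-based; the read covers ``[start, start + read_length)`` mod L).
    ``error_counts`` counts injected sequencing errors per reference
    position; ``alt_counts`` stratifies the injected errors by the
    substituted-in allele in reference orientation, so the realised total
    always equals the sum of the four per-allele counts.
    """

    start: np.ndarray  # (n_reads,) int64, position on the circle
    strand: np.ndarray  # (n_reads,) '+'/'-' stored as bool is_reverse
    mate: np.ndarray  # (n_reads,) uint8, 1 or 2 (0 for unpaired)
    error_counts: np.ndarray  # (L,) int64 injected errors per position
    alt_counts: np.ndarray  # (4,) int64 injected errors per substituted allele
    het_counts: np.ndarray  # (L,) int64 heteroplasmic alternates placed

    @property
    def total_errors(self) -> int:
        return int(self.error_counts.sum())

    @property
    def total_het_placements(self) -> int:
        return int(self.het_counts.sum())


def _fragment_starts(
    rng: np.random.Generator, n: int, ref: CircularReference, params: ReadSimParams
) -> tuple[np.ndarray, np.ndarray]:
    """Draw fragment (start, length) pairs, thinning inside the NCR."""
    starts = rng.integers(0, ref.length, size=n)
    lengths = rng.normal(params.fragment_length_mean, params.fragment_length_sd, size=n)
    lengths = np.maximum(np.rint(lengths).astype(np.int64), params.read_length)
    if params.coverage_bias < 1.0:
        mid = (starts + lengths // 2) % ref.length
        s, e = ref.ncr_span
        in_ncr = (mid >= s) & (mid < e)
        keep = ~in_ncr | (rng.random(n) < params.coverage_bias)
        starts, lengths = starts[keep], lengths[keep]
    return starts, lengths


def simulate_reads(
    ref: CircularReference, params: ReadSimParams
) -> tuple[ReadSet, TruthTable]:
    """Simulate a read set and its exact truth record.

    The number of fragments is chosen so the expected emitted base count is
    ``mean_depth * L`` (before NCR thinning).  Fragments may wrap the origin;
    the corresponding reads then span position 0 on the circle and have no
    full-length placement on the original linearisation — the case the
    rotated-reference rescue exists for.
    """
    L = ref.length
    rl = params.read_length
    if rl > L:
        raise ValueError("read_length exceeds reference length")
    rng = np.random.default_rng(params.seed)

    bases_per_fragment = 2 * rl if params.paired else rl
    n_fragments = int(round(params.mean_depth * L / bases_per_fragment))
    frag_start, frag_len = _fragment_starts(rng, n_fragments, ref, params)
    n_frag = len(frag_start)

    # Fragment orientation: which physical strand the fragment was sequenced
    # from.  Read 1 starts at the fragment 5' end on that strand; for paired
    # mode read 2 is the opposite end, opposite strand.
    frag_reverse = rng.random(n_frag) < 0.5
    if params.paired:
        # read 1 forward template window [start, start+rl); read 2 reverse
        # template window [start+len-rl, start+len).  Swapping orientation
        # exchanges which mate is reverse-complemented.
        start1 = frag_start
        start2 = (frag_start + frag_len - rl) % L
        starts = np.concatenate([start1, start2])
        is_reverse = np.concatenate([frag_reverse, ~frag_reverse])
        mate = np.concatenate(
            [np.ones(n_frag, np.uint8), np.full(n_frag, 2, np.uint8)]
        )
        frag_index = np.concatenate([np.arange(n_frag), np.arange(n_frag)])
    else:
        starts = frag_start
        is_reverse = frag_reverse
        mate = np.zeros(n_frag, np.uint8)
        frag_index = np.arange(n_frag)
    n_reads = len(starts)

    # Template windows in forward (reference) orientation.
    offsets = np.arange(rl)
    pos = (starts[:, None] + offsets[None, :]) % L  # (n_reads, rl)
    window = ref.codes[pos].copy()

    # Heteroplasmies: per-read Bernoulli at the site frequency, independent
    # across reads (no linkage).
    het_counts = np.zeros(L, dtype=np.int64)
    for het in params.heteroplasmies:
        off = (het.position - starts) % L
        covers = off < rl
        place = covers & (rng.random(n_reads) < het.frequency)
        idx = np.flatnonzero(place)
        alt_code = BASES.index(het.alt)
        window[idx, off[idx]] = alt_code
        het_counts[het.position] += len(idx)

    # Sequencing errors: substitute to a uniformly chosen different base.
    # Applied in reference orientation (equivalent under strand symmetry of
    # the uniform substitution model) so the truth record is reference-frame.
    error_counts = np.zeros(L, dtype=np.int64)
    alt_counts = np.zeros(4, dtype=np.int64)
    e = params.effective_error_rate
    if e > 0:
        err_mask = rng.random(window.shape) < e
        r_idx, c_idx = np.nonzero(err_mask)
        shift = rng.integers(1, 4, size=len(r_idx)).astype(np.uint8)
        new_codes = (window[r_idx, c_idx] + shift) % 4
        window[r_idx, c_idx] = new_codes
        np.add.at(error_counts, pos[r_idx, c_idx], 1)
        np.add.at(alt_counts, new_codes, 1)

    # Emit in read orientation.
    out = window.copy()
    rev = np.flatnonzero(is_reverse)
    for i in rev:
        out[i] = reverse_complement_codes(window[i])

    ids = [
        f"frag{frag_index[i]}/{mate[i]}" if params.paired else f"read{i}"
        for i in range(n_reads)
    ]
    reads = ReadSet(ids=ids, codes=out, read_length=rl)
    truth = TruthTable(
        start=starts.astype(np.int64),
        strand=is_reverse,
        mate=mate,
        error_counts=error_counts,
        alt_counts=alt_counts,
        het_counts=het_counts,
    )
    return reads, truth
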