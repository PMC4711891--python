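"""Coverage profiles, rotated-reference merging and sliding-window smoothing.

The rescue workflow for a circular genome is: map once against the original
linearisation and once against the half-rotated copy, express both coverage
profiles (and pileups) in original coordinates, then take forward, base by
base, whichever alignment version has the higher coverage.  Near the
linearisation origin the rotated version wins (origin-spanning reads map
only there); in the interior the original version wins; the merged profile
is trough-free up to sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .mapping import Alignment
from .pileup import PileupMatrix
from .reference import CircularReference

DEFAULT_WINDOW = 2000


@dataclass
class CoverageProfile:
    """Per-position read depth in original coordinates."""

    depth: np.ndarray  # (L,) int64
    provenance: str  # "original" | "rotated" | "merged"

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depths")

    @property
    def length(self) -> int:
        return len(self.depth)

    @property
    def total_bases(self) -> int:
        return int(self.depth.sum())


@dataclass
class WindowedProfile:
    """Sliding-window coverage divided by its maximum."""

    values: np.ndarray  # (L,) float, in [0, 1], max exactly 1
    window: int
    norm_constant: float  # maximum of the smoothed profile


def coverage(
    alignments: Sequence[Alignment],
    ref: CircularReference,
    ref_version: str = "original",
) -> CoverageProfile:
    """Per-position depth of aligned bases, in original coordinates.

    ``ref_version`` names the linear sequence the alignments were made on;
    a rotated-version profile is back-translated through
    ``p_original = (p_rotated + floor(L/2)) mod L``.
    """
    L = ref.length
    delta = np.zeros(L + 1, dtype=np.int64)
    for aln in alignments:
        if aln.ref_version != ref_version:
            raise ValueError(
                f"alignment on {aln.ref_version!r}, expected {ref_version!r}"
            )
        rl = len(aln.observed)
        delta[aln.start] += 1
        delta[aln.start + rl] -= 1
    depth = np.cumsum(delta[:L])
    if ref_version == "rotated":
        depth = np.roll(depth, ref.rotation_offset())
    return CoverageProfile(depth=depth, provenance=ref_version)


def merge_highest_coverage(
    profile_orig: CoverageProfile,
    profile_rot: CoverageProfile,
    pileup_orig: PileupMatrix,
    pileup_rot: PileupMatrix,
) -> tuple[CoverageProfile, PileupMatrix]:
    """Per base, take forward the alignment version with the higher coverage.

    Both inputs must already be in original coordinates.  The rotated column
    is used only where its depth is strictly higher; ties keep the original
    version, so the merge is deterministic.
    """
    if profile_orig.length != profile_rot.length:
        raise ValueError("profile length mismatch")
    d_orig, d_rot = profile_orig.depth, profile_rot.depth
    use_rot = d_rot > d_orig
    merged_depth = np.where(use_rot, d_rot, d_orig)
    counts = np.where(use_rot[:, None], pileup_rot.counts, pileup_orig.counts)
    merged_pileup = PileupMatrix(
        ref_codes=pileup_orig.ref_codes,
        counts=counts,
        provenance="merged",
        excluded_bases=pileup_orig.excluded_bases + pileup_rot.excluded_bases,
    )
    return CoverageProfile(depth=merged_depth, provenance="merged"), merged_pileup


def sliding_window(
    profile: CoverageProfile, window: int = DEFAULT_WINDOW
) -> WindowedProfile:
    """Circular centred moving average, normalised to its maximum.

    The average wraps around the origin (the genome is a circle).  For even
    window sizes the centre is taken half a position to the left, the
    convention of ``scipy.ndimage.uniform_filter1d``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > profile.length:
        raise ValueError("window exceeds genome length")
    smoothed = uniform_filter1d(
        profile.depth.astype(float), size=window, mode="wrap"
    )
    peak = float(smoothed.max())
    if peak <= 0:
        raise ValueError("all-zero coverage cannot be normalised")
    return WindowedProfile(values=smoothed / peak, window=window, norm_constant=peak)
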