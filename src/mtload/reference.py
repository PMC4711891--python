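"""Circular reference genomes: generation, rotation and coordinate mapping.

Mitochondrial genomes are circular, but short-read mappers place reads on a
linear string, so reads whose template spans the arbitrary linearisation
origin have no full-length placement.  The standard rescue is to cut the
assembly in half, splice the two halves in swapped order (juxtaposing the
original start and end), and map again on that rotated copy.  This module
owns the rotation and the coordinate translation between the two frames.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed code order used everywhere a base is stored as an integer.
BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
#: A<->T, C<->G under the 0..3 encoding.
COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)

#: Length of the mouse mitochondrial genome (bp); default stand-in length.
DEFAULT_LENGTH = 16_299
#: Default stand-in span for the major non-coding region (control region),
#: placed at the end of the genome as in the mouse assembly.
DEFAULT_NCR_SPAN = (15_422, 16_299)


def encode_bases(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array with the package base order."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return codes


def decode_bases(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_bases`."""
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT_CODE[codes][::-1]


@dataclass
class CircularReference:
    """A circular genome sequence with rotation support.

    Parameters
    ----------
    name
        Sequence identifier (FASTA header).
    sequence
        The genome as an ACGT string; its length defines ``L``.
    ncr_span
        Half-open ``(start, end)`` interval of the major non-coding region,
        used by the read simulator to place the coverage trough.
    """

    name: str
    sequence: str
    ncr_span: tuple[int, int]
    codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("empty reference sequence")
        self.codes = encode_bases(self.sequence)
        s, e = self.ncr_span
        if not (0 <= s < e <= self.length):
            raise ValueError(
                f"ncr_span {self.ncr_span} outside [0, {self.length})"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def rotation_offset(self) -> int:
        """Offset used by :func:`rotate_reference`: ``floor(L / 2)``."""
        return self.length // 2

    def to_original(self, rotated_pos: np.ndarray | int) -> np.ndarray | int:
        """Map a position on the rotated linear sequence back to the original.

        ``p_original = (p_rotated + floor(L/2)) mod L``.
        """
        return (rotated_pos + self.rotation_offset()) % self.length

    def to_rotated(self, original_pos: np.ndarray | int) -> np.ndarray | int:
        return (original_pos - self.rotation_offset()) % self.length


def generate_reference(
    length: int = DEFAULT_LENGTH,
    ncr_span: tuple[int, int] | None = None,
    seed: int = 0,
    name: str = "synthetic_mt",
) -> CircularReference:
    """Generate a random circular reference of the given length.

    The sequence is i.i.d. uniform over A/C/G/T — a structural stand-in for a
    real mitochondrial assembly, adequate for exercising mapping and pileup
    statistics.  When ``ncr_span`` is omitted, the last ~5.4% of the genome is
    designated as the non-coding region, mirroring the position of the mouse
    control region at the end of the assembly.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000 bp")
    if ncr_span is None:
        ncr_span = (int(round(length * (1 - 877 / 16_299))), length)
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return CircularReference(name=name, sequence=decode_bases(codes), ncr_span=ncr_span)


def rotate_reference(ref: CircularReference) -> CircularReference:
    """Cut the genome in half and splice so start and end are juxtaposed.

    Returns the sequence rotated left by ``floor(L/2)``; positions map back
    through :meth:`CircularReference.to_original`.  For even L, rotating twice
    is the identity.
    """
    if ref.length < 2:
        raise ValueError("cannot rotate a length-1 reference")
    h = ref.rotation_offset()
    rotated = ref.sequence[h:] + ref.sequence[:h]
    return CircularReference(
        name=f"{ref.name}|rot{h}", sequence=rotated, ncr_span=ref.ncr_span
    )
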