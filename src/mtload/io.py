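"""Readers and writers for the standard formats the pipeline touches.

FASTA and FASTQ go through Bio.SeqIO, SAM through pysam; the tabular
formats (truth table, Ct table, dNTP panel, pileup, coverage) are single-
header-row TSVs handled with pandas.  SAM positions are 1-based on disk and
0-based in memory; the conversion happens here and nowhere else.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assays import CT_COLUMNS, DNTP_COLUMNS, TIMECOURSE_COLUMNS, validate_ct_table
from .mapping import Alignment
from .pileup import PileupMatrix
from .reference import CircularReference, decode_bases, encode_bases
from .simulate import ReadSet, TruthTable

PLACEHOLDER_QUALITY = 30  # constant Q30; base quality is not modelled


# -- FASTA ------------------------------------------------------------------

def write_fasta(ref: CircularReference, path: str | Path) -> None:
    rec = SeqRecord(Seq(ref.sequence), id=ref.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(
    path: str | Path, ncr_span: tuple[int, int] | None = None
) -> CircularReference:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(recs)}")
    seq = str(recs[0].seq).upper()
    if ncr_span is None:
        ncr_span = (0, len(seq))
    return CircularReference(name=recs[0].id, sequence=seq, ncr_span=ncr_span)


# -- FASTQ ------------------------------------------------------------------

def write_fastq(reads: ReadSet, path: str | Path) -> None:
    """Write reads with a constant-quality string (gzip if path ends .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    qual = chr(PLACEHOLDER_QUALITY + 33) * reads.read_length
    with opener(path, "wt") as fh:
        for i, rid in enumerate(reads.ids):
            fh.write(f"@{rid}\n{reads.sequence(i)}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> ReadSet:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            ids.append(rec.id)
            rows.append(encode_bases(str(rec.seq).upper()))
    if not rows:
        raise ValueError(f"{path}: empty FASTQ")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: mixed read lengths {sorted(lengths)}")
    return ReadSet(ids=ids, codes=np.stack(rows), read_length=lengths.pop())


# -- SAM --------------------------------------------------------------------

def write_sam(
    alignments: Sequence[Alignment],
    ref: CircularReference,
    path: str | Path,
    ref_name: str | None = None,
) -> None:
    """Export minimal SAM: strand flag, 1-based POS, MAPQ 255, CIGAR <len>M."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref_name or ref.name, "LN": ref.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = aln.read_id
            a.reference_id = 0
            a.reference_start = aln.start  # pysam stores 0-based; SAM text is 1-based
            a.mapping_quality = 255
            a.flag = 16 if aln.is_reverse else 0
            seq = decode_bases(aln.observed)
            if aln.is_reverse:
                seq = str(Seq(seq).reverse_complement())
            a.query_sequence = seq
            a.cigarstring = f"{len(aln.observed)}M"
            a.set_tag("NM", aln.n_mismatches)
            out.write(a)


def read_sam(path: str | Path, ref_version: str = "original") -> list[Alignment]:
    """Import ungapped SAM records as alignments (observed bases ref-oriented)."""
    alignments: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for i, rec in enumerate(fh.fetch(until_eof=True)):
            if rec.is_unmapped:
                continue
            cigar = rec.cigartuples
            if cigar is None or len(cigar) != 1 or cigar[0][0] != 0:
                raise ValueError(
                    f"{path}: record {rec.query_name!r} has non-simple CIGAR "
                    f"{rec.cigarstring!r}; only ungapped <len>M is supported"
                )
            seq = rec.query_sequence.upper()
            if rec.is_reverse:
                seq = str(Seq(seq).reverse_complement())
            codes = np.frombuffer(seq.encode(), np.uint8).copy()
            obs = np.full(len(seq), 255, np.uint8)
            for j, base in enumerate("ACGT"):
                obs[codes == ord(base)] = j
            alignments.append(
                Alignment(
                    read_id=rec.query_name,
                    read_index=i,
                    ref_version=ref_version,
                    start=rec.reference_start,
                    is_reverse=rec.is_reverse,
                    n_mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    observed=obs,
                )
            )
    return alignments


# -- tabular ----------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed TSV ({err})") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in required:
        if df[col].isna().any():
            row = int(df[df[col].isna()].index[0]) + 2  # 1-based incl. header
            raise ValueError(f"{path}: empty value in column {col!r} at line {row}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return validate_ct_table(_read_tsv(path, CT_COLUMNS))


def read_timecourse(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, TIMECOURSE_COLUMNS)
    validate_ct_table(df[CT_COLUMNS])
    return df


def read_dntp_panel(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, DNTP_COLUMNS)


def read_pileup_tsv(path: str | Path, ref: CircularReference) -> PileupMatrix:
    """Import an external pileup TSV: position, ref, A, C, G, T counts."""
    df = _read_tsv(path, ["position", "ref", "A", "C", "G", "T"])
    counts = np.zeros((ref.length, 4), dtype=np.int64)
    pos = df["position"].to_numpy(dtype=np.int64)
    if (pos < 0).any() or (pos >= ref.length).any() or len(np.unique(pos)) != len(pos):
        raise ValueError(f"{path}: positions must be unique and within [0, L)")
    for j, base in enumerate("ACGT"):
        counts[pos, j] = df[base].to_numpy(dtype=np.int64)
    return PileupMatrix(ref_codes=ref.codes, counts=counts, provenance="imported")


def write_pileup_tsv(pileup: PileupMatrix, path: str | Path) -> None:
    bases = np.array(list("ACGT"))
    df = pd.DataFrame(
        {
            "position": np.arange(pileup.length),
            "ref": bases[pileup.ref_codes],
            "A": pileup.counts[:, 0],
            "C": pileup.counts[:, 1],
            "G": pileup.counts[:, 2],
            "T": pileup.counts[:, 3],
        }
    )
    write_tsv(df, path)


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "read": np.arange(len(truth.start)),
            "start": truth.start,
            "strand": np.where(truth.strand, "-", "+"),
            "mate": truth.mate,
        }
    )
    write_tsv(df, path)


def write_coverage_tsv(values: np.ndarray, path: str | Path) -> None:
    write_tsv(
        pd.DataFrame({"position": np.arange(len(values)), "value": values}), path
    )
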