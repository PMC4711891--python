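"""Mutation-load statistics from pileup allele counts.

The mutation load (ML) of a sample is the aggregate frequency of
non-reference base observations per sequenced base.  Two conventions are
computed and reported side by side, because they answer subtly different
questions and coincide only under uniform coverage:

``ml_per_site_mean``
    mean over covered positions of the per-site mutant-allele frequency —
    the headline "ML (mean) per site frequency" figure;
``ml_pooled``
    total mismatches divided by total aligned bases — the convention the
    per-allele columns use, so the four per-allele rates sum exactly to it.

Per-allele stratification is by the identity of the mis-incorporated
(observed non-reference) allele: the rate for base X is the count of X
observed at positions whose reference is not X, divided by total bases.
Rates are reported on the ×10^-4 scale; all internal arithmetic is in raw
fractions.

No minimum-depth or minimum-frequency filter is applied: raw low-frequency
mismatch rates necessarily include sequencing false positives, so ML values
are comparable only between samples from the same sequencing run, where the
technology's error floor is shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pileup import PileupMatrix

SCALE = 1e4  # reporting scale for ML figures
TABLE_COLUMNS = ["run", "sample", "total_bases", "ml_total", "A", "C", "G", "T"]


@dataclass
class MutationLoadReport:
    """Total and per-mis-incorporated-allele mismatch rates for one sample."""

    sample: str
    run: str
    total_bases: int
    total_mismatches: int
    covered_sites: int
    zero_depth_sites: int
    ml_per_site_mean: float  # ×10^-4 scale
    ml_pooled: float  # ×10^-4 scale
    per_allele: dict[str, float] = field(default_factory=dict)  # ×10^-4 scale
    per_allele_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ml_total(self) -> float:
        """Headline ML figure: the per-site mean convention."""
        return self.ml_per_site_mean

    @property
    def ml_percent(self) -> float:
        """Pooled ML expressed in percent (e.g. 4.3 ×10^-4 -> 0.043%)."""
        return self.ml_pooled / SCALE * 100.0

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "run": self.run,
            "total_bases": self.total_bases,
            "total_mismatches": self.total_mismatches,
            "covered_sites": self.covered_sites,
            "zero_depth_sites": self.zero_depth_sites,
            "ml_per_site_mean_e4": self.ml_per_site_mean,
            "ml_pooled_e4": self.ml_pooled,
            "ml_percent": self.ml_percent,
            "per_allele_e4": self.per_allele,
            "per_allele_counts": self.per_allele_counts,
        }


@dataclass
class RunComparison:
    """Within-run pairwise ML comparison plus per-allele homogeneity."""

    sample_a: str
    sample_b: str
    run: str
    ml_ratio: float
    anova_f: float
    anova_p: float


def snp_frequencies(pileup: PileupMatrix) -> pd.DataFrame:
    """Per-position frequencies of the three non-reference alleles.

    Each covered position contributes one row with the frequency of every
    base other than the reference (count divided by depth).  Zero-depth
    positions are skipped; their number is available from
    :func:`mutation_load`.
    """
    depth = pileup.depth
    covered = np.flatnonzero(depth > 0)
    bases = np.array(list("ACGT"))
    rows = []
    for p in covered:
        ref_code = pileup.ref_codes[p]
        d = depth[p]
        freqs = {
            bases[c]: pileup.counts[p, c] / d for c in range(4) if c != ref_code
        }
        rows.append({"position": int(p), "ref": bases[ref_code], **freqs})
    return pd.DataFrame(rows)


def _mutant_counts(pileup: PileupMatrix) -> np.ndarray:
    """Per-position count of non-reference observations."""
    L = pileup.length
    ref_count = pileup.counts[np.arange(L), pileup.ref_codes]
    return pileup.depth - ref_count


def mutation_load(
    pileup: PileupMatrix, sample: str = "sample", run: str = "run"
) -> MutationLoadReport:
    """Compute both ML conventions and the per-allele rates from a pileup."""
    depth = pileup.depth
    total_bases = int(depth.sum())
    if total_bases == 0:
        raise ValueError("mutation load undefined: pileup has zero total depth")
    mutant = _mutant_counts(pileup)
    covered = depth > 0
    per_site_freq = mutant[covered] / depth[covered]
    total_mismatches = int(mutant.sum())

    per_allele: dict[str, float] = {}
    per_allele_counts: dict[str, int] = {}
    for code, base in enumerate("ACGT"):
        at_nonref = pileup.ref_codes != code
        n = int(pileup.counts[at_nonref, code].sum())
        per_allele_counts[base] = n
        per_allele[base] = n / total_bases * SCALE

    return MutationLoadReport(
        sample=sample,
        run=run,
        total_bases=total_bases,
        total_mismatches=total_mismatches,
        covered_sites=int(covered.sum()),
        zero_depth_sites=int((~covered).sum()),
        ml_per_site_mean=float(per_site_freq.mean() * SCALE),
        ml_pooled=total_mismatches / total_bases * SCALE,
        per_allele=per_allele,
        per_allele_counts=per_allele_counts,
    )


def per_allele_table(reports: Sequence[MutationLoadReport]) -> pd.DataFrame:
    """Tabulate reports one row per sample, plus per-run column means.

    Columns: run, sample, total_bases, ml_total (×10^-4) and the four
    per-allele rates (×10^-4).  Mean rows (sample = ``mean``) summarise each
    run, since the per-base error spectrum is a run-level property.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = [
        {
            "run": r.run,
            "sample": r.sample,
            "total_bases": r.total_bases,
            "ml_total": r.ml_total,
            "A": r.per_allele["A"],
            "C": r.per_allele["C"],
            "G": r.per_allele["G"],
            "T": r.per_allele["T"],
        }
        for r in reports
    ]
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    means = (
        df.groupby("run", sort=False)[["ml_total", "A", "C", "G", "T"]]
        .mean()
        .reset_index()
        .assign(sample="mean", total_bases=pd.NA)
    )
    return pd.concat([df, means[TABLE_COLUMNS]], ignore_index=True)


def compare_within_run(
    report_a: MutationLoadReport, report_b: MutationLoadReport
) -> RunComparison:
    """Compare two samples sequenced in the same run.

    The ML ratio is meaningful only within a run (shared error floor);
    comparing across runs is refused.  Per-allele homogeneity — whether the
    four per-allele rates differ between samples to similar extents — is
    assessed by one-way ANOVA across the samples' per-allele rate vectors.
    """
    if report_a.run != report_b.run:
        raise ValueError(
            f"cross-run comparison refused ({report_a.run!r} vs {report_b.run!r})"
        )
    if report_b.ml_total == 0:
        raise ValueError("denominator sample has zero mutation load")
    ratio = report_a.ml_total / report_b.ml_total
    a = np.array([report_a.per_allele[b] for b in "ACGT"])
    b = np.array([report_b.per_allele[b] for b in "ACGT"])
    f, p = stats.f_oneway(a, b)
    return RunComparison(
        sample_a=report_a.sample,
        sample_b=report_b.sample,
        run=report_a.run,
        ml_ratio=ratio,
        anova_f=float(f),
        anova_p=float(p),
    )
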