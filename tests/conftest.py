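"""Shared fixtures: small references, simulated read sets, printed ML table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtload import (
    CircularReference,
    MutationLoadReport,
    ReadSimParams,
    generate_reference,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_ref() -> CircularReference:
    """A 2 kb circular reference used by mapper and coverage tests."""
    return generate_reference(length=2000, ncr_span=(1800, 2000), seed=11)


@pytest.fixture(scope="session")
def mt_ref() -> CircularReference:
    """Full-length (16,299 bp) synthetic circular mitochondrial stand-in."""
    return generate_reference(seed=1)


@pytest.fixture(scope="session")
def clean_readset(small_ref):
    """Error-free paired reads at depth 20 on the small reference."""
    params = ReadSimParams(seed=7, mean_depth=20, error_rate=0.0)
    return simulate_reads(small_ref, params)


def make_report(
    sample: str,
    run: str,
    total_bases: int,
    ml_total: float,
    a: float,
    c: float,
    g: float,
    t: float,
) -> MutationLoadReport:
    """Build a report from published-style table values (×10^-4 scale)."""
    per_allele = {"A": a, "C": c, "G": g, "T": t}
    pooled = a + c + g + t
    return MutationLoadReport(
        sample=sample,
        run=run,
        total_bases=total_bases,
        total_mismatches=int(round(pooled / 1e4 * total_bases)),
        covered_sites=16_299,
        zero_depth_sites=0,
        ml_per_site_mean=ml_total,
        ml_pooled=pooled,
        per_allele=per_allele,
        per_allele_counts={
            k: int(round(v / 1e4 * total_bases)) for k, v in per_allele.items()
        },
    )


@pytest.fixture(scope="session")
def published_ml_table() -> pd.DataFrame:
    """Mutation-load table of a published mouse liver mtDNA deep-sequencing
    experiment: two sequencing runs of wild-type / knockout littermate pairs,
    with total bases, total ML and per-mis-incorporated-allele rates
    (×10^-4).  Used as a worked-arithmetic fixture."""
    rows = [
        ("run1", "WT1", 87_561_081, 4.3, 1.39, 1.07, 0.82, 0.99),
        ("run1", "KO2", 25_034_992, 3.3, 1.00, 0.86, 0.67, 0.77),
        ("run1", "WT3", 112_639_285, 3.4, 1.10, 0.78, 0.62, 0.86),
        ("run1", "KO4", 5_968_068, 5.8, 2.22, 1.19, 0.82, 1.53),
        ("run2", "WT3", 182_010_153, 9.9, 3.19, 2.61, 1.58, 2.36),
        ("run2", "KO4", 11_635_983, 22.1, 7.73, 5.07, 3.40, 5.66),
    ]
    return pd.DataFrame(
        rows,
        columns=["run", "sample", "total_bases", "ml_total", "A", "C", "G", "T"],
    )


@pytest.fixture(scope="session")
def published_reports(published_ml_table):
    return [
        make_report(r["sample"], r["run"], r["total_bases"], r["ml_total"],
                    r["A"], r["C"], r["G"], r["T"])
        for _, r in published_ml_table.iterrows()
    ]
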