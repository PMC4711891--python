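"""Simulated quantitative assays: qPCR Ct tables, repletion time courses, dNTP panels.

These generators produce the tabular inputs of the relative-quantification
stages with known ground truth, so the 2^-ΔΔCt estimator, the
depletion–repletion recovery analysis and the dNTP pool statistics can be
validated by parameter recovery.

Table schemas (single header row, TSV on disk):

``CtTable``      columns ``sample, group, gene_role, replicate, ct``
                 with ``gene_role`` in {``mt_target``, ``nuclear_reference``}
                 and ``ct`` in cycles.
``DntpPanel``    columns ``sample, group, species, quantity`` with
                 ``species`` in {dATP, dCTP, dGTP, dTTP} and ``quantity``
                 in pmol per mg mitochondrial protein.

A repletion time course is a CtTable with an extra leading ``timepoint``
column.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample", "group", "gene_role", "replicate", "ct"]
TIMECOURSE_COLUMNS = ["timepoint"] + CT_COLUMNS
DNTP_COLUMNS = ["sample", "group", "species", "quantity"]
GENE_ROLES = ("mt_target", "nuclear_reference")
DNTP_SPECIES = ("dATP", "dCTP", "dGTP", "dTTP")

#: Baseline cycle-threshold values used by the simulator.  The nuclear
#: single-copy reference amplifies late; the multi-copy mt target amplifies
#: early.  Only differences of Ct matter downstream, so the absolute values
#: are conventional.
NUCLEAR_BASELINE_CT = 24.0
MT_BASELINE_CT = 16.0


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the CtTable schema and basic invariants; returns the table."""
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CtTable missing columns: {missing}")
    bad_role = set(df["gene_role"]) - set(GENE_ROLES)
    if bad_role:
        raise ValueError(f"unknown gene_role values: {sorted(bad_role)}")
    ct = df["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or (ct <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    return df


def simulate_qpcr(
    group_specs: Sequence[tuple[str, float, int]],
    ct_noise_sd: float = 0.15,
    seed: int = 0,
    n_replicates: int = 3,
    sample_prefix: str | None = None,
) -> pd.DataFrame:
    """Simulate a replicate qPCR Ct table with known relative mtDNA levels.

    Each spec is ``(group, true_relative_level, n_samples)``; a group label
    may appear in several specs with different true levels (distinct cell
    lines within one condition).  Per sample, nuclear-reference Ct replicates
    are drawn about a fixed baseline and mt-target Ct replicates about
    ``baseline_mt - log2(true_level)``, so a halving of mtDNA costs exactly
    one extra cycle.  Gaussian cycle noise of sd ``ct_noise_sd`` is added to
    every replicate independently.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for group, level, n in group_specs:
        if level <= 0:
            raise ValueError("true relative levels must be > 0")
        if n < 1:
            raise ValueError("each group spec needs n >= 1 samples")
        for _ in range(n):
            counter += 1
            prefix = sample_prefix or group
            sample = f"{prefix}_s{counter}"
            mt_mean = MT_BASELINE_CT - np.log2(level)
            for role, mean in (
                ("mt_target", mt_mean),
                ("nuclear_reference", NUCLEAR_BASELINE_CT),
            ):
                noise = rng.normal(0.0, ct_noise_sd, size=n_replicates)
                for rep in range(n_replicates):
                    rows.append(
                        (sample, group, role, rep + 1, mean + noise[rep])
                    )
    return validate_ct_table(pd.DataFrame(rows, columns=CT_COLUMNS))


def simulate_repletion(
    timepoints: Sequence,
    profiles: Mapping[str, Sequence[float]],
    noise_sd: float = 0.0,
    n_lines: int = 4,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a depletion–repletion time course as a stacked CtTable.

    ``profiles`` maps each condition (e.g. control / mutant / supplemented)
    to its true mtDNA level at every timepoint, expressed as a fraction of
    the pre-depletion baseline.  Each of ``n_lines`` cell lines per condition
    carries a line-specific overall scale factor (lines differ in absolute
    copy number); recovery fractions are ratios within a line, so the scale
    cancels downstream.
    """
    timepoints = list(timepoints)
    for cond, prof in profiles.items():
        if len(prof) != len(timepoints):
            raise ValueError(
                f"profile for {cond!r} has {len(prof)} values, "
                f"expected {len(timepoints)} timepoints"
            )
    rng = np.random.default_rng(seed)
    frames = []
    for cond, prof in profiles.items():
        line_scale = np.exp(rng.normal(0.0, 0.2, size=n_lines))
        for j in range(n_lines):
            sample = f"{cond}_line{j + 1}"
            for t, frac in zip(timepoints, prof):
                if frac <= 0:
                    raise ValueError("profile fractions must be > 0")
                level = frac * line_scale[j]
                mt_mean = MT_BASELINE_CT - np.log2(level)
                for role, mean in (
                    ("mt_target", mt_mean),
                    ("nuclear_reference", NUCLEAR_BASELINE_CT),
                ):
                    noise = rng.normal(0.0, noise_sd, size=n_replicates)
                    for rep in range(n_replicates):
                        frames.append(
                            (t, sample, cond, role, rep + 1, mean + noise[rep])
                        )
    df = pd.DataFrame(frames, columns=TIMECOURSE_COLUMNS)
    validate_ct_table(df[CT_COLUMNS])
    return df


def simulate_dntp(
    group_means: Mapping[str, Mapping[str, float]],
    cv: float = 0.0,
    n: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-sample dNTP quantities (pmol / mg mitochondrial protein).

    ``group_means[group][species]`` is the true group mean.  Per-sample
    quantities are lognormal with the requested coefficient of variation and
    mean equal to the group mean (``sigma^2 = log(1 + cv^2)``, mean-corrected
    ``mu``); ``cv=0`` returns the means exactly.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    rows = []
    for group, means in group_means.items():
        unknown = set(means) - set(DNTP_SPECIES)
        if unknown:
            raise ValueError(f"unknown dNTP species: {sorted(unknown)}")
        for i in range(n):
            sample = f"{group}_s{i + 1}"
            for species in DNTP_SPECIES:
                if species not in means:
                    continue
                mean = means[species]
                if mean <= 0:
                    raise ValueError("group means must be > 0")
                if cv == 0:
                    q = mean
                else:
                    q = rng.lognormal(np.log(mean) - sigma2 / 2, sigma)
                rows.append((sample, group, species, q))
    return pd.DataFrame(rows, columns=DNTP_COLUMNS)
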