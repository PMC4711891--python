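"""Relative quantification and group statistics for the qPCR and dNTP assays.

Implements the Livak 2^-ΔΔCt method for relative mtDNA copy number
(mitochondrial target vs single-copy nuclear reference gene, normalised to
the mean ΔCt of a control group), recovery fractions for depletion–repletion
time courses, relative dNTP levels with per-species rank tests, and a
coefficient-of-variation metric for dNTP pool balance ("equimolarity").

Group summaries are mean ± standard error of the mean (SEM); two-group
comparisons use Student's t-test or the Mann-Whitney rank test, and one-way
ANOVA for more than two groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assays import CT_COLUMNS, DNTP_SPECIES, validate_ct_table


@dataclass
class CopyNumberResult:
    """2^-ΔΔCt fold changes per sample with group-level summaries.

    ``per_sample`` has columns sample, group, delta_ct, ddct, fold;
    ``group_stats`` has columns group, n, mean_fold, sem_fold, percent.
    The reference group's mean fold change is 1 (100%) by construction.
    """

    per_sample: pd.DataFrame
    group_stats: pd.DataFrame
    reference_group: str
    test: str
    p_values: dict[str, float] = field(default_factory=dict)
    dropped_samples: list[str] = field(default_factory=list)

    def group_percent(self, group: str) -> float:
        row = self.group_stats.loc[self.group_stats["group"] == group]
        return float(row["percent"].iloc[0])


@dataclass
class RecoveryResult:
    """Percent-of-original mtDNA per line and timepoint."""

    per_line: pd.DataFrame  # columns: line, condition, timepoint, percent
    condition_stats: pd.DataFrame  # condition, timepoint, n, mean, sem
    baseline_timepoint: object
    excluded_lines: list[str] = field(default_factory=list)

    def condition_percent(self, condition: str, timepoint) -> float:
        m = self.condition_stats
        row = m.loc[(m["condition"] == condition) & (m["timepoint"] == timepoint)]
        return float(row["mean"].iloc[0])


@dataclass
class DntpSummary:
    """Per-species relative levels plus pool-balance metrics per group."""

    relative: pd.DataFrame  # species, relative_percent, p_value, n_case, n_control
    control_group: str
    case_group: str
    excluded_species: tuple[str, ...] = ()


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def ddct(
    ct_table: pd.DataFrame,
    reference_group: str,
    test: str = "t",
) -> CopyNumberResult:
    """Relative mtDNA copy number by the 2^-ΔΔCt method.

    Per sample, replicate Ct values are averaged per gene, then
    ``ΔCt = mean Ct(mt_target) - mean Ct(nuclear_reference)``;
    ``ΔΔCt = ΔCt - mean ΔCt(reference group)``; the fold change is
    ``2^-ΔΔCt`` (amplification efficiency fixed at 2).  Samples missing
    either gene are dropped with a record.  Each non-reference group is
    compared with the reference group on per-sample fold changes.
    """
    validate_ct_table(ct_table)
    agg = (
        ct_table.groupby(["sample", "group", "gene_role"])["ct"]
        .mean()
        .unstack("gene_role")
        .reset_index()
    )
    dropped = []
    for col in ("mt_target", "nuclear_reference"):
        if col not in agg.columns:
            agg[col] = np.nan
    bad = agg["mt_target"].isna() | agg["nuclear_reference"].isna()
    if bad.any():
        dropped = agg.loc[bad, "sample"].tolist()
        agg = agg.loc[~bad].copy()
    agg["delta_ct"] = agg["mt_target"] - agg["nuclear_reference"]

    ref_mask = agg["group"] == reference_group
    if not ref_mask.any():
        raise ValueError(f"reference group {reference_group!r} has no samples")
    ref_mean_dct = agg.loc[ref_mask, "delta_ct"].mean()
    agg["ddct"] = agg["delta_ct"] - ref_mean_dct
    agg["fold"] = 2.0 ** (-agg["ddct"])
    # report fold changes relative to the mean of the controls: rescale so
    # the reference group's arithmetic mean fold is exactly 1 (with Ct noise
    # the exponential otherwise leaves it slightly above 1)
    agg["fold"] /= agg.loc[ref_mask, "fold"].mean()

    groups = []
    for g, sub in agg.groupby("group", sort=False):
        folds = sub["fold"].to_numpy()
        groups.append(
            {
                "group": g,
                "n": len(folds),
                "mean_fold": folds.mean(),
                "sem_fold": _sem(folds),
                "percent": 100.0 * folds.mean(),
            }
        )
    group_stats = pd.DataFrame(groups)

    p_values = {}
    ref_folds = agg.loc[ref_mask, "fold"].to_numpy()
    for g, sub in agg.groupby("group", sort=False):
        if g == reference_group:
            continue
        try:
            p_values[g] = group_compare(
                sub["fold"].to_numpy(), ref_folds, method=test
            )
        except ValueError:
            # degenerate comparison (e.g. zero variance in a noise-free
            # simulation): record no p-value rather than fail the estimate
            p_values[g] = float("nan")
    return CopyNumberResult(
        per_sample=agg[["sample", "group", "delta_ct", "ddct", "fold"]],
        group_stats=group_stats,
        reference_group=reference_group,
        test=test,
        p_values=p_values,
        dropped_samples=dropped,
    )


def recovery_fraction(
    timecourse: pd.DataFrame, baseline_timepoint
) -> RecoveryResult:
    """Percent of pre-depletion mtDNA per line at every timepoint.

    ``timecourse`` is a stacked CtTable with a ``timepoint`` column (see
    :func:`mtload.assays.simulate_repletion`).  The relative level of a line
    at time t is ``2^-(ΔCt(t) - ΔCt(baseline))`` — a within-line ratio, so
    any line-specific overall scale cancels (scale invariance).  Lines
    without a baseline measurement are excluded with a record.
    """
    validate_ct_table(timecourse[CT_COLUMNS])
    agg = (
        timecourse.groupby(["timepoint", "sample", "group", "gene_role"])["ct"]
        .mean()
        .unstack("gene_role")
        .reset_index()
    )
    agg["delta_ct"] = agg["mt_target"] - agg["nuclear_reference"]

    base = agg.loc[agg["timepoint"] == baseline_timepoint].set_index("sample")[
        "delta_ct"
    ]
    excluded = sorted(set(agg["sample"]) - set(base.index))
    agg = agg.loc[agg["sample"].isin(base.index)].copy()
    if agg.empty:
        raise ValueError(f"no line has a baseline at {baseline_timepoint!r}")
    agg["percent"] = 100.0 * 2.0 ** -(
        agg["delta_ct"] - agg["sample"].map(base).to_numpy()
    )
    per_line = agg.rename(columns={"sample": "line", "group": "condition"})[
        ["line", "condition", "timepoint", "percent"]
    ]
    cond = (
        per_line.groupby(["condition", "timepoint"])["percent"]
        .agg(n="size", mean="mean", sem=_sem)
        .reset_index()
    )
    return RecoveryResult(
        per_line=per_line,
        condition_stats=cond,
        baseline_timepoint=baseline_timepoint,
        excluded_lines=excluded,
    )


def dntp_relative(
    panel: pd.DataFrame,
    control_group: str,
    case_group: str | None = None,
    exclude_species: Sequence[str] = (),
    test: str = "mannwhitney",
) -> DntpSummary:
    """Per-species dNTP level of a case group relative to controls.

    The relative level of species X is ``100 * mean(case X) / mean(control
    X)``; each species is tested case-vs-control (Mann-Whitney by default,
    matching small non-normal assay samples).  Species in
    ``exclude_species`` (e.g. a nucleotide whose control measurements were
    too low to be reliable) are dropped from the summary.
    """
    groups = [g for g in panel["group"].unique() if g != control_group]
    if case_group is None:
        if len(groups) != 1:
            raise ValueError("case_group required when panel has several cases")
        case_group = groups[0]
    rows = []
    for species in DNTP_SPECIES:
        if species in exclude_species:
            continue
        sub = panel.loc[panel["species"] == species]
        ctrl = sub.loc[sub["group"] == control_group, "quantity"].to_numpy()
        case = sub.loc[sub["group"] == case_group, "quantity"].to_numpy()
        if len(ctrl) == 0 or len(case) == 0:
            continue
        ctrl_mean = ctrl.mean()
        if ctrl_mean == 0:
            raise ValueError(f"control mean for {species} is zero")
        p = (
            group_compare(case, ctrl, method=test)
            if min(len(case), len(ctrl)) >= 3
            else float("nan")
        )
        rows.append(
            {
                "species": species,
                "relative_percent": 100.0 * case.mean() / ctrl_mean,
                "p_value": p,
                "n_case": len(case),
                "n_control": len(ctrl),
            }
        )
    return DntpSummary(
        relative=pd.DataFrame(rows),
        control_group=control_group,
        case_group=case_group,
        excluded_species=tuple(exclude_species),
    )


def pool_balance(
    panel: pd.DataFrame,
    group: str,
    exclude_species: Sequence[str] = (),
) -> dict:
    """Pool-balance metrics for one group: CV of species means and max/min.

    The coefficient of variation (sample sd / mean) across the usable
    species-level means is 0 for a perfectly equimolar pool and grows with
    asymmetry; the max/min ratio is reported alongside.  This is a
    package-defined summary statistic for "how equimolar is this pool".
    """
    sub = panel.loc[
        (panel["group"] == group) & ~panel["species"].isin(exclude_species)
    ]
    means = sub.groupby("species")["quantity"].mean()
    if len(means) < 2:
        raise ValueError("need at least two usable species")
    m = means.to_numpy(dtype=float)
    if np.all(m == 0):
        raise ValueError("all species means are zero")
    return {
        "group": group,
        "species_means": means.to_dict(),
        "cv": float(np.std(m, ddof=1) / m.mean()),
        "max_min_ratio": float(m.max() / m.min()),
    }


def group_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    *more_groups: np.ndarray,
    method: str = "t",
) -> float:
    """Two-sided p-value comparing group means/distributions.

    ``method`` is ``"t"`` (Student's t, equal-variance), ``"mannwhitney"``
    (exact when both n <= 8 with no ties, normal approximation with tie
    correction otherwise) or ``"anova"`` (one-way, for >= 2 groups).  A
    zero-variance t-test is refused with a pointer to the rank test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method == "anova":
        groups = [a, b, *[np.asarray(g, float) for g in more_groups]]
        if any(len(g) < 2 for g in groups):
            raise ValueError("ANOVA needs >= 2 observations per group")
        return float(stats.f_oneway(*groups).pvalue)
    if more_groups:
        raise ValueError(f"method {method!r} compares exactly two groups")
    if method == "t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs >= 2 observations per group")
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError(
                "zero variance in both groups; use method='mannwhitney'"
            )
        return float(stats.ttest_ind(a, b).pvalue)
    if method == "mannwhitney":
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        small = max(len(a), len(b)) <= 8
        how = "exact" if (no_ties and small) else "asymptotic"
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=how).pvalue
        )
    raise ValueError(f"unknown method {method!r}")
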