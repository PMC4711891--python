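# Methods

This note documents the models implemented in `mtload`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data do and do not emulate.

## Synthetic sequencing data

The read simulator emulates a MiSeq-style shotgun experiment on a circular
mitochondrial genome.

**Reference.** `generate_reference` draws an i.i.d. uniform A/C/G/T
sequence (default length 16,299 bp, the length of the mouse mitochondrial
assembly). A designated non-coding-region (NCR) span defaults to the last
~5.4% of the genome, mirroring the position of the mouse control region. A
random sequence is a structural stand-in, not a biological one: it has no
repeats, gene structure or strand-composition bias, which makes read
placement essentially always unique. Mapping ambiguity is therefore tested
with purpose-built repeat fixtures rather than with the default reference.

**Fragments and reads.** Fragment starts are uniform on the circle;
fragment lengths are Normal(200 bp, 20 bp) truncated below at the read
length, modelling a 200 bp paired-end library. Each fragment yields a read
from each end (default 100 bp), on opposite strands; fragment orientation
is a fair coin flip, so each strand contributes half the reads. Fragments
may wrap the origin — those reads are exactly the ones the rotation rescue
exists for. The number of fragments is `mean_depth · L / (2 · read_length)`
so the expected emitted base count equals `mean_depth · L`.

**Coverage trough.** `coverage_bias ≤ 1` thins fragments whose midpoint
falls inside the NCR span, reproducing the small coverage trough such
experiments show near the major non-coding region. Keying the thinning on
the midpoint makes the depth transition a symmetric ~1-fragment-length ramp
at both NCR edges; the realised inside/outside depth ratio converges to
`coverage_bias` away from the ramps.

**Errors.** Every emitted base is substituted, independently, with
probability `error_rate · run_multiplier`, to a uniformly chosen different
base. `run_multiplier` models run-level batch effects: the same library
re-sequenced on a noisier run shows uniformly elevated error rates, which a
single multiplicative factor captures. Substitutions are applied in
reference orientation before reverse-complementing reverse-strand reads;
under the uniform substitution model this is distributionally identical to
corrupting the read in read orientation, and it lets the truth table record
every error by reference position and substituted-in allele directly in the
frame the pileup uses. Effective rates are validated to `[0, 0.01)` — the
regime of interest is 10⁻⁴–10⁻³ per base.

**Heteroplasmies.** A site's alternate allele is placed per read by an
independent Bernoulli draw at the site frequency (no linkage). This
suffices for single-site load statistics; haplotype structure is out of
scope.

**Quality.** FASTQ quality strings are a constant Q30 placeholder. Base
quality is not modelled and the pipeline applies no base- or
mapping-quality filter; the analysis this package implements uses raw
counts, and comparability is instead guaranteed by comparing samples only
within a sequencing run.

**Truth table.** Per-read origins (start, strand, mate), injected-error
counts per position, substituted-allele totals and heteroplasmy placements
are recorded exactly; the realised total equals the sum of per-allele
counts by construction, and tests verify it also equals an independent
recount against the reference.

## Mapping and the rotation rescue

The internal mapper is deliberately minimal because simulated reads carry
substitutions only: exact k-mer seeding (default k=31, drawn from the
read's 5′ end, falling back to the 3′ end when the 5′ seed finds nothing)
proposes candidate positions on either strand; every candidate is verified
by full-length Hamming comparison; the unique best placement with at most
`max_mismatches` (default 5 per 100 bp — far above the expected ≤0.1
errors per read at 10⁻³/base, yet effectively impossible for a random
placement to satisfy) is reported. Two equally good placements leave the
read unmapped rather than arbitrarily placed. Mates are mapped
independently: coverage and pileup statistics need no proper-pair logic.

Reads spanning the linearisation origin have no full-length placement and
come back unmapped. The reference is therefore cut at `⌊L/2⌋` and spliced
so the original start and end are juxtaposed; mapping is repeated against
this rotated copy, on which the former junction is interior. Coordinates
translate by `p_original = (p_rotated + ⌊L/2⌋) mod L`; for even L the
rotation is an involution. Per base, the version with strictly higher
coverage is taken forward; ties keep the original version, making the
merge deterministic. On error-free uniform simulations the original-only
profile shows a near-total depletion within one read length of the origin,
while the merged profile is flat to within sampling noise (tested against
a Monte-Carlo expectation of the windowed range under ideal circular
sampling).

Coverage profiles use difference-array accumulation; the 2 kb
sliding-window profile is a circular centred moving average
(`scipy.ndimage.uniform_filter1d`, wrap mode; for even windows the centre
sits half a position left, the filter's convention) divided by its
maximum, so the windowed profile always peaks at exactly 1.

## Mutation-load statistics

Two ML conventions are computed because they answer different questions
and coincide only under uniform coverage: the **per-site mean** of the
per-position mutant frequency (headline figure, insensitive to
coverage-weighting) and the **pooled** rate, total mismatches over total
aligned bases (the convention under which the per-allele columns sum
exactly to the total). Per-allele stratification is by the identity of the
mis-incorporated (observed non-reference) allele — the incorporated
nucleotide, not the reference base — so the four rates partition the
mismatch count. Zero-depth sites are excluded from the per-site mean
(frequency undefined) and reported as a count. ×10⁻⁴ and percent scales
are presentation only; internal arithmetic is in raw fractions.

No minimum-depth or minimum-frequency threshold is applied. The raw rates
therefore include the sequencing platform's false-positive floor; the
package's comparison operation refuses cross-run comparisons, and the
per-run summary rows exist because the error spectrum is a run-level
property. Within-run pairs are summarised by the ML ratio and a one-way
ANOVA across the two samples' per-allele rate vectors (a coarse
homogeneity check on 4 observations per sample; with n=4 per group its
power is limited, which is inherent to the 4-allele design).

## qPCR copy number, repletion, dNTP pools

**Ct simulation.** The nuclear single-copy reference gene amplifies around
a fixed baseline (24 cycles); the mitochondrial target around
`16 − log₂(true level)`, so halving mtDNA costs exactly one cycle.
Replicates (default triplicates) get independent Gaussian cycle noise
(default sd 0.15 cycles, a typical SYBR-green replicate scatter).
Group specs may repeat a group label with different true levels to model
distinct cell lines within a condition.

**Estimator.** Replicate Cts are averaged per gene before differencing
(standard Livak usage); amplification efficiency is fixed at exactly 2 (no
efficiency correction); ΔΔCt is taken against the mean ΔCt of the control
group, and folds are rescaled so the control-group arithmetic mean fold is
exactly 1 — the "relative to the mean of the controls" presentation.
Without that rescaling, averaging `2^(noise)` across samples leaves the
control mean slightly above 1 (Jensen); the residual relative bias on
non-control groups from the same effect is ~`(ln2 · sd_ΔCt)²/2` ≈ 0.4% at
the default noise, which parameter-recovery tests bound at 5%. Group
summaries are mean ± SEM; two-group comparisons default to Student's t
with Mann-Whitney on request.

**Repletion.** Each condition's profile lists true levels as fractions of
the pre-depletion baseline; each simulated line carries a lognormal overall
scale (lines differ in absolute copy number). Recovery per line and
timepoint is `100 · 2^−(ΔCt(t)−ΔCt(baseline))`, a within-line ratio, so
the scale cancels exactly (scale invariance is property-tested). Lines
missing the baseline are excluded and reported.

**dNTP panels.** Per-sample quantities (pmol per mg mitochondrial protein,
the assay's implied unit) are lognormal with mean equal to the group mean
and the requested coefficient of variation (`σ² = log(1+cv²)`,
mean-corrected `μ`); `cv=0` returns means exactly. Relative levels are
`100 · mean(case)/mean(control)` per species with a Mann-Whitney test per
species (exact enumeration when both groups ≤ 8 and untied, normal
approximation with tie correction otherwise — group sizes in this field
are 3–8). No multiple-testing correction is applied across the four
species; results are reported per species. Species flagged unreliable
(e.g. a nucleotide whose control-sample signal is too low to quantify) are
excluded from both the relative summary and the balance metric.

**Pool balance.** The field describes pools as "close to equimolar"
without naming a statistic; the package defines the summary as the
coefficient of variation of the species-level means within a group
(sample sd, ddof=1, over the 2–4 usable species), plus the max/min ratio.
CV is scale-invariant — pools at different absolute abundances compare
directly — and 0 iff perfectly equimolar.

## Statistical tests

`group_compare` wraps scipy: equal-variance two-sided t-test (refusing
zero-variance inputs with a pointer to the rank test), Mann-Whitney as
above, and one-way ANOVA for ≥2 groups. Type-I error of the rank test at
the package's typical n=6 is verified ≈5% by a seeded 1000-replicate null
simulation.

## Reproducibility and problem sizes

All randomness flows from `numpy.random.default_rng` seeded explicitly;
pipeline stages derive independent seeds from one global seed by hashing
stable stage labels, so adding a stage never perturbs another's stream.
Identical config and seed reproduce byte-identical FASTQ/truth outputs
(checksummed in the run manifest).

Default study sizes mirror the experimental designs the simulators
emulate: n=6 animals per group for tissue copy number, 4–5 cell lines for
repletion, n=5 per group for dNTP panels, triplicate Ct measurements.
The full-scale recovery study in `scripts/acceptance.py` uses ≥10⁷
simulated bases (~640× coverage of the 16.3 kb genome), at which the
binomial sampling error of a 3.4×10⁻⁴ rate is ~1.7%, comfortably inside
the 5% recovery tolerance; unit tests use smaller genomes (2–4 kb) and
depths chosen so the tested contrasts exceed sampling noise by a wide
margin.

## Known limitations

- No indel errors, PCR duplicates, quality-score profiles, NUMT
  contamination, strand bias or linkage between heteroplasmic sites; the
  simulator validates estimators, it does not benchmark mappers.
- The internal mapper is ungapped by design and unsuitable for reads with
  indels; externally produced SAM (any mapper) can be imported instead,
  restricted to simple `<len>M` alignments.
- Copy-number estimation is relative only (no standard-curve calibration,
  no Pfaffl efficiency correction, no mixed-effects replicate model).
- Passing parameter-recovery tests on synthetic data shows the estimators
  are correct under the stated models; real libraries add context-dependent
  error spectra and coverage structure that the i.i.d. error model and
  uniform random genome do not capture.
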