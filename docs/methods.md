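# Methods

## Scope and model

`tcrshare` analyses clonal sharing between sorted T-cell subsets at two
resolutions: bulk TCRβ clonotype tables (a clonotype is a unique junction
nucleotide sequence, optionally extended with allele-stripped V/J context for
gDNA-style assays) and single-cell TCRαβ chain reconstructions. Sampling of
sequences from a subject's repertoire is modelled as multinomial draws from a
fixed clone frequency distribution; the binomial is used in place of the
hypergeometric throughout, appropriate when the sampled volume is small
relative to the compartment.

## Overlap statistics

The Morisita–Horn index is computed on relative frequencies over the union of
clonotype keys: MH = 2Σpᵢqᵢ/(Σpᵢ² + Σqᵢ²). This is algebraically identical to
the count-based Morisita–Horn (the form popularised by ecology packages), and
the test suite verifies agreement between both formulations to 1e-12. MH is
exactly 0 iff the key sets are disjoint, exactly 1 for identical frequency
vectors, symmetric, and invariant under uniform count scaling.

Clopper–Pearson intervals are exact binomial intervals computed from Beta
quantiles, with closed forms at the boundaries (k = 0 lower limit 0, k = n
upper limit 1). Two-sided intervals split α across the tails. The detection
limit φ_max = 1 − α^(1/n) is the one-sided upper limit at zero successes and
is used as the reference implementation; the Beta-quantile route and a
bisection on the defining tail equation serve as cross-checks. `n` may be the
number of sequenced cells (single-cell assays) or of in-frame sequences
obtained (bulk assays); the caller chooses and the detection-limit record
carries the `n` used.

Contamination adjudication is deliberately a point comparison, not a formal
test: the observed shared frequency mass on one side is compared with the
upper limit of the exact two-sided 95% CI on the measured sort-impurity rate
(k impure events out of n re-analysed). Both numbers and their margin are
always reported so users can apply stricter decision rules. Mass at or below
the ceiling is labelled `explainable_by_contamination`.

## Diversity comparison

The diversity statistic is the minimal number m of clonotypes, taken in
decreasing frequency order, whose cumulative frequency reaches a target
fraction (default 0.25). Minimality is the defining property: the top m reach
the target, the top m−1 do not; an exhaustive-scan oracle enforces this in
the tests. The cumulative comparison is done on integer counts against
fraction × total with a 1e-9 relative guard, so exact-boundary cases (e.g.
100 equal clones at fraction 0.25 → 25) are stable.

Group comparison pools all values, assigns ranks 1..n (average ranks on
ties), and applies the two-sided equal-variance Student t test with
n_a + n_b − 2 degrees of freedom to the ranks. With 2–3 samples per group a
permutation test or exact rank-sum test cannot reach the 5% level, and a t
test on raw counts is not justified; ranking makes the test invariant under
any strictly monotone transform of the values. For two groups of three with
complete separation this yields t = 3.674, df = 4, p = 0.0213 — the smallest
attainable p in that configuration. If both groups are internally tied the
pooled rank variance collapses and the statistic diverges (p → 0); a fully
tied pool raises a degenerate-input error instead.

## Single-cell clonotype clustering

Non-productive reconstructions are discarded first; within one cell and
locus, chains with the same identity (junction plus allele-stripped V/D/J
calls — gene labels are truncated at the first `*`) are merged by summing
TPM. The filter F_h sorts a locus's chains by decreasing TPM and keeps the
minimal prefix whose TPM sum reaches h × total (h = 0.95): the discarded tail
carries under 5% of the locus expression and is treated as spurious. Numerical
choices: the cumulative comparison carries a 1e-12 relative guard; TPM ties
are broken lexicographically on the identity key, and a warning is emitted
when a tie straddles the cutoff, since the filter's definition orders only
by TPM and reproducibility requires a deterministic rule. An all-zero-TPM locus retains all chains with a warning — a literal
reading would keep an arbitrary single chain, but rank order is meaningless
without expression evidence. This is a documented divergence.

Cells are grouped into clusters by a canonical key per equivalence relation:
(1) the filtered α identity-key set, (2) the filtered β set, (3) the union of
both filtered sets (locus labels inside each identity key prevent α/β
collisions), (4) the α and β sets jointly. A cell is ineligible when the
required set is empty; relation 4 requires at least one productive chain per
locus. The reference configuration is relation 4 with at most two productive
chains per locus after filtering; over-cap cells are excluded *after*
filtering and reported, never silently dropped. Because each relation is a
true equivalence, grouping by key coincides with the transitive closure of
pairwise equivalence; the tests verify this against an O(n²) union-find
oracle. Singleton clusters are retained in output, with `expanded_clusters`
(n ≥ 2 cells) as the expansion filter.

## Synthetic data generator

The generators emulate the study conditions the analysis targets, not raw
sequencing: clonotype keys are random in-frame-length nucleotide strings
(length a multiple of 3 in [30, 60]) because the analysis treats keys as
opaque; no V(D)J recombination model, sequencing error or PCR bias is
simulated. Frequency profiles are uniform, geometric(r) (oligoclonal decay)
or zipf(s). Sorting contamination is modelled at the read level: each read of
one subset is replaced with probability c by a read from the partner subset's
true distribution, symmetrically — matching the interpretation that shared
mass below the purity ceiling reflects clones physically transferred during
sorting. A single master seed spawns independent child generators per
component, so streams are stable when generators are added.

Single-cell generation assigns each cell a clone, drops each true chain with
a per-locus dropout probability, draws chain TPM from LogNormal(μ = 5,
σ = 1), and adds, at rate `spurious_rate`, a random-identity contig at
`spurious_scale` (default 0.02) times the cell's top true-chain TPM in the
same locus. Tying the spurious TPM to the same cell's expression makes the
F_h bound deterministic: scale/(1+scale) < 1−h guarantees removal whenever a
true chain survives in that locus. Dual-TCR clones are generated at 9%
(dual-α) and 4.5% (dual-β), mirroring the reference dataset's cluster
composition. Dropout defaults are d_α = 0.35, d_β = 0.13: with independent
per-locus dropout no pair can reproduce both of the reference dataset's
chain-detection margins (≥1 chain 81%, both chains 56.6%) simultaneously, so the defaults
match the paired-detection rate (0.65 × 0.87 ≈ 0.566), the margin that
controls eligibility for paired-relation clustering. Allele suffixes on
segment calls vary randomly per observation to exercise allele-insensitive
identity.

What passing tests on these inputs do **not** show: robustness to real
reconstruction artefacts (chimeric contigs, shared junctions across
subjects), to non-multinomial sampling (PCR amplification bias, UMI
deduplication), or to subset annotation errors. The partition-recovery test
additionally uses σ = 0.5 for within-cell TPM draws: under heavier
within-cell imbalance F_h can legitimately split a dual-TCR clone whose minor
chain falls below 5% of the locus total — an inherent property of the filter,
not an implementation artefact.

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale as the package's own
choice of demonstration size: 1,000 random repertoire pairs for the MH
cross-check (tolerance 1e-12); φ_max closed form vs. bisection over
n = 1..10⁴ (1e-10) and a 20,000-replicate multinomial calibration at n = 59
(miss rate 5% ± 0.5 absolute); 200 random cell sets of ≤100 cells against the
clustering oracle; 10⁴ random TPM vectors of length ≤8 against the filter
scan; 1,000 simulated subset pairs at 1,500 reads for the contamination-mass
calibration (mean 0.03 ± 0.005); 120 cells over 40 clones for partition
recovery (adjusted Rand index exactly 1). Frequencies are exact count ratios
compared at 1e-9 absolute.

## Known limitations

- Repertoire overlap assumes identical clonotype key modes on both sides;
  junction-only and junction+V/J tables are not comparable and are rejected.
- The contamination model covers symmetric two-subset sorting impurity only;
  three-way sorts are analysed pairwise.
- The rank t test presumes exchangeability under the null; with heavy ties
  across groups its behaviour degrades gracefully (average ranks) but the
  printed p is then approximate.
- No rarefaction or alternative diversity indices (Shannon, Jaccard,
  clonality) are provided; the top-fraction clone count is the only
  diversity statistic by design.
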