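# tcrshare

Clonal-sharing analysis for bulk and single-cell T-cell receptor (TCR)
repertoires.

When regulatory (Treg) and conventional (Tconv) CD4+ T cells are sorted from
the same blood or tumor sample and their TCRβ repertoires sequenced, shared
clonotypes — identical junction (CDR3) nucleotide sequences — are evidence
that one subset's clones converted into the other (induced Treg). Two
statistical traps make this inference delicate: a clone absent from one
library may simply have been missed at finite sequencing depth, and clones
genuinely present in both libraries may be sorting contamination rather than
biology. `tcrshare` implements the statistics needed to walk that line, for
immunologists analysing sorted-subset AIRR-seq data and for methodologists
who want the primitives with explicit oracles.

## What it computes

**Overlap and similarity.** For repertoires with clonotype frequencies
*p*ᵢ, *q*ᵢ over the union of keys, the Morisita–Horn similarity

&nbsp;&nbsp;&nbsp;&nbsp;MH = 2 Σᵢ *p*ᵢ*q*ᵢ / (Σᵢ *p*ᵢ² + Σᵢ *q*ᵢ²)

(0 = no shared clonotypes, 1 = identical distributions), plus exact set
overlap counts (pairwise and three-way Venn regions) and the shared
frequency mass per side.

**Detection limits and contamination.** The one-sided (1−α) Clopper–Pearson
upper limit at zero observations, φ_max = 1 − α^(1/n), bounds the frequency
of any clone that escaped detection among *n* sampled cells or sequences;
its inverse 1 − (1−*f*)ⁿ is the confidence of detecting a clone at frequency
*f*. Observed shared mass is adjudicated against the exact two-sided CI upper
limit on a measured sort-impurity rate (*k* impure events out of *n*
re-analysed).

**Diversity.** The number of clones covering the most-expanded 25% of each
repertoire, compared between groups by a two-sided equal-variance *t* test on
the pooled ranks (suited to groups of 2–3 samples where exact rank tests
cannot reach the 5% level).

**Single-cell clonotype clustering.** Per-cell reconstructed TCRα/β chains
are filtered per locus by the cumulative-expression filter F_h (keep the
minimal top-TPM prefix reaching h = 0.95 of the locus total), and cells are
grouped into clonotype clusters as equivalence classes under identical
filtered α sets, β sets, their union, or both loci simultaneously (the
reference configuration, restricted to ≤2 productive chains per locus).
Chain identity ignores allele suffixes on V/D/J calls.

**Synthetic data.** Generators for oligoclonal/polyclonal repertoires,
subset pairs with planted shared clones and read-level sorting contamination,
and single-cell chain tables with TPM noise, chain dropout and spurious
low-TPM contigs — all with recorded ground truth for recovery tests.

## Worked example

```python
from tcrshare import (generate_paired_subsets, overlap_report, phi_max,
                      ContaminationModel, contamination_verdict)

rep_a, rep_b, truth = generate_paired_subsets(
    n_clones_a=150, n_clones_b=150, n_shared=5,
    distribution=("geometric", 0.9), contamination_rate=0.01,
    n_reads=3000, seed=11)

report = overlap_report(rep_a, rep_b, "Treg", "Tconv")
print(report.n_shared, round(report.mh, 4), round(report.shared_mass_in_b, 4))
# 34 0.021 0.7663

model = ContaminationModel.from_counts(k=3, n=200)     # sort-purity re-analysis
verdict = contamination_verdict(report, model, side="b")
print(round(model.ci_high, 4), verdict.verdict)
# 0.0432 exceeds_contamination
```

34 clonotypes are observed in both subsets; the Morisita–Horn index of 0.021
says the frequency distributions are nevertheless highly dissimilar. The
shared clonotypes carry 77% of the Tconv repertoire — far above the 4.3%
contamination ceiling (the 95% CI upper limit on 3/200 impure sort events) —
so the sharing cannot be explained by sort impurity: here it reflects the
five genuinely shared expanded clones planted by the generator. The
`examples/` directory holds one narrative script per capability
(`repertoire_basics.py`, `bulk_overlap.py`, `detection_limits.py`,
`diversity_rank_test.py`, `single_cell_clusters.py`); each prints the numbers
it computes with a line on what they mean.

A thin CLI mirrors the library: `tcrshare compare`, `tcrshare diversity`,
`tcrshare sc-cluster`, `tcrshare simulate` (see `--help`).

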