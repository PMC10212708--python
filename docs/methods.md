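# Methods

## Allele-specific counting

At each heterozygous X-linked SNP the counter tallies reads by the base
aligned at the site: `n_ref`, `n_alt`, and `n_other` for any third base.
Reads that are unmapped, secondary, supplementary or duplicate-flagged are
excluded, as are reads below the mapping-quality or base-quality thresholds
(both default 20, conventional for allele-specific expression work; both
configurable). A read whose alignment has a deletion or reference skip at
the site contributes to no bucket. Overlapping mates are counted
independently — no mate de-duplication — which is the simplest contract and
at worst double-counts fragments symmetrically in both alleles. Counting is
unstranded. Site positions are 1-based (VCF convention); emitted BED is
0-based half-open.

The reference-allele frequency is `n_ref / (n_ref + n_alt)`; `n_other` is
kept for QC but never enters the denominator. With zero informative reads
the frequency is undefined and the caller maps it to `no_call`.

## Gene-level classification

Counts from a gene's multiple SNPs are pooled by summation before one
gene-level frequency is computed. This weights sites by depth and is robust
when individual sites are shallow; per-site records remain available for
QC. The status rules, in order of precedence:

| rule | status |
|---|---|
| FPKM < 1 | `not_expressed` |
| pooled depth < 10 or frequency undefined | `no_call` |
| f ∈ [0.25, 0.75] | `biallelic` |
| otherwise (minor fraction < 0.25) | `monoallelic` |

Notes on the genuinely open choices:

* The biallelic band is stated in the field on the *minor*-allele
  frequency ("between 25% and 75%"), which is self-contradictory since a
  minor-allele fraction cannot exceed 50%. We interpret the band on the
  reference-allele fraction, making the monoallelic rule (minor < 25%) its
  exact complement. Both boundaries are inclusive, deterministically.
* The 10-read floor (`min_depth`) is our addition: without it a single
  read would yield a confident monoallelic call. It is configurable.
* Classification is symmetric under swapping ref/alt labels, so the
  (arbitrary) choice of reference haplotype cannot change any status.

## Positional clustering test

Erosion and partial silencing are not positionally uniform; to test whether
monoallelic genes concentrate toward distal Xq we use the statistic
`median(coord of monoallelic) − median(coord of biallelic)` and permute
status labels over gene positions. The p-value is one-sided toward larger
coordinates with the add-one correction, so p ≥ 1/(1+n_perm) and
permutation resampling is seeded. Medians were chosen over means for
robustness to the handful of proximal escape-like genes; the null
calibration (acceptance suite) shows a ≤7% empirical rejection rate at
nominal 5% over 200 null datasets.

## Dosage and expression utilities

* Expressed-gene filter: keep genes with ≥ 1 FPKM in at least one sample
  (idempotent; monotone in the threshold).
* X:A ratio: sum of chrX FPKM over sum of chr1 FPKM, computed after the
  expressed-gene filter (whether to filter first is genuinely ambiguous;
  filtering is the default and both toggles are exposed), with XIST
  included among chrX genes by default.
* DEG selection: fold change `(mean_A + ε) / (mean_B + ε)` with ε = 0.01 to
  avoid division by zero; a gene is selected when `max(FC, 1/FC)` reaches
  the fold threshold and, when p-values are supplied externally, p < 0.05.
  The differential-expression model that produces those p-values is out of
  scope — only the cutoff rule is implemented. Group means (not medians)
  are used.
* qPCR: `2^−ΔΔCt` with ΔCt = Ct(target) − Ct(reference) per condition.

## Sample-level state call

Among informative genes (monoallelic ∪ biallelic) the biallelic fraction is
mapped to a state: ≥ 0.7 → class I (XaXa); ≤ 0.3 with XIST expressed →
class II (XaXi, XIST+); ≤ 0.3 without XIST → class III-like; otherwise
partial XCI; undefined (no informative genes) → indeterminate. Clean
pre-XCI samples sit near fraction 1 and clean post-XCI samples near 0, so
the call is insensitive to the exact 0.7/0.3 placement; the band between
covers partial-XCI samples. These numeric thresholds are this package's
convention, not a published rule. XIST "expressed" uses the same 1-FPKM
threshold as other genes. The class III-like label deliberately does not
assert erosion: distinguishing a stably inactive Xi from an eroded Xe needs
evidence (e.g. reactivation of previously silenced genes over time) the
pipeline may not have; the JSON report says so.

## Synthetic-data generator

The generator emulates the data a bulk RNA-seq ASE analysis consumes, with
known truth:

* **Panel.** Genes at strictly increasing non-overlapping coordinates on
  chrX (155 Mb length model) and chr1 (248 Mb); each X gene gets 1–3
  heterozygous SNPs inside its span; a dedicated XIST row sits at 73.8 Mb
  on chrX with no SNPs. Under positional bias, silenced labels are drawn
  with probability proportional to coordinate, concentrating silencing
  toward distal Xq.
* **Expression.** FPKM is log-normal (default log-mean 2, log-sd 1 — a
  realistic right-skewed bulk distribution with median ≈ 7 FPKM and ~9% of
  genes below 1 FPKM). A silenced gene's FPKM is multiplied by
  `silenced_dosage_factor` (default 0.5: one of two alleles, no
  compensatory upregulation), which by construction makes the post-XCI X:A
  ratio half the pre-XCI one.
* **Counts.** Site depth is negative-binomial with mean
  `mean_depth × FPKM / median FPKM` (dispersion 0.1; Poisson at 0), mean
  depth 50 by default — the source libraries' depth is not published, so
  this is a deliberately ordinary bulk coverage choice. The
  reference-read count is beta-binomial with intraclass correlation ρ
  (default 0.01) around p = 0.5 for biallelic genes and p = seq_error (or
  1 − seq_error) for monoallelic genes, seq_error default 0.002. Silencing
  direction is fixed per gene, and for post-XCI one shared haplotype is
  silenced chromosome-wide (non-random XCI). All generators are seeded and
  bitwise reproducible.

What the generator does **not** emulate: reference-mapping bias, genotyping
error in the site list, indels, phasing, isoform structure, batch effects,
or cell-to-cell heterogeneity within a sample. Passing recovery tests
therefore shows the pipeline's logic is correct under a clean but
realistically noisy count model, not that real libraries are free of those
artifacts.

## Problem sizes and numerics

The recovery experiment uses 200 X-linked genes, mean depth 50, ρ = 0.01,
seq_error = 0.002, across three scenarios and ten seeds each (30 runs);
per-gene accuracy is assessed among genes with FPKM ≥ 1 and pooled depth
≥ 10, where miscalls are dominated by binomial noise at marginal depth.
The permutation-test calibration uses 200 null datasets of 200 genes with
199 permutations each (p granularity 1/200), and 999 permutations for the
constructed distal instance. SAM fixtures stay under 1000 reads; fixtures
are always written as plain SAM and converted/indexed at run time. Ties in
gene ordering are broken by gene id for deterministic output; reruns of the
pipeline with the same config are byte-identical.
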