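# Methods

`cernaforge` implements a plasma circRNA profiling and competing-endogenous-RNA
(ceRNA) network analysis for a small two-group study (cases vs controls). This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic data do and do not establish.

## Consensus circRNA identification

Each caller's output is a set of back-spliced junction (BSJ) observations
(chromosome, start, end, strand, junction-read count, sample). A junction is a
consensus circRNA when both callers report it with start and end each within
`junction_match_tolerance` bp (default 0 — exact coordinates; ±2 bp
accommodates caller wobble but is not the default because exact matching is
conservative and reproducible). Two matching policies are exposed:
`per_sample` (default) requires at least one sample in which both callers
observe the junction; `pooled` only requires both callers to report it
somewhere. The per-sample consensus read count is the maximum of the two
callers' counts — a monotone, caller-symmetric combination chosen because the
two callers measure the same junction with high consistency and no principled
averaging rule is available. Unstranded (`.`) calls match either strand,
since one supported caller emits unstranded junctions.

Support filtering keeps a circRNA iff it has at least `min_reads` (default 2)
BSJ reads in strictly more than half of all samples. "More than half" is a
strict majority of the pooled samples; the same rule evaluated within one
group defines group-exclusive expression (below).

Annotation against gene models uses the precedence
`protein_coding > sense_intronic > lncRNA > intergenic`: a circRNA is
protein-coding when both junction endpoints fall on exons of one coding
transcript; sense-intronic when contained in an intron of a same-strand
transcript; lncRNA when it overlaps an lncRNA transcript; otherwise
intergenic. Exon count and spliced length are computed from the host
transcript's exons between the junction endpoints (intervals clipped to the
junction). Characterization histograms use 200-bp length bins up to 2000 bp
with one open bin, and unit bins 1–10 plus ">10" for exon and isoform counts.

## Quantification and group comparison

circRNA abundance is BSJ reads per million total mapped reads ("BSJ-TPM"):
`tpm[i,s] = counts[i,s] / mapped_totals[s] * 1e6`. The global case/control
abundance shift is tested with Welch's two-sample t-test on
`log10(mean TPM + 1)` of the per-feature group averages, mirroring a
density-curve comparison of average expression per group; Welch rather than
the pooled-variance form because the groups are small and unbalanced (10 vs
8). Per-feature log2 fold changes use a pseudocount of 0.01 TPM, which keeps
group-exclusive features finite while ranking them extreme.

A feature is group-exclusive iff it passes the support rule within its own
group **and** has zero counts in every sample of the other group. The
support rule is evaluated within-group (not study-wide): a feature silent in
one group could never pass a pooled majority, which would make the definition
vacuous for balanced designs.

## Differential expression

Counts are modelled per feature as negative binomial with
`mu_ij = s_j * m_g(j)` and variance `mu + alpha * mu^2`:

* **Prefilter.** A feature is kept iff its mean raw count across all samples
  reaches the class threshold (5 mRNA / 2 circRNA / 50 miRNA). The mean form
  is sample-size independent.
* **Size factors** `s_j` are median-of-ratios against the geometric-mean
  reference over features observed in every sample, renormalized to
  geometric mean 1. When no feature is all-nonzero (common for sparse
  circRNA matrices) the factors fall back to library-size ratios with a
  warning.
* **Dispersion** `alpha` is estimated per feature by Cox–Reid adjusted
  profile maximum likelihood (the adjustment subtracts half the log
  determinant of the weighted information, `0.5*(log W_case +
  log W_control)` for the two-group design), bounded in [1e-8, 100]. There
  is no cross-feature shrinkage, so results approximate rather than
  replicate shrinkage-based NB pipelines.
* **Fit.** For the intercept+group design with offset the group means have a
  one-dimensional score equation solved by a safeguarded Newton iteration;
  the Wald statistic is `log(m_case/m_control) / SE` with
  `SE^2 = 1/W_case + 1/W_control`. Fitted group means are floored at half a
  read per group (a continuity floor) so all-zero groups give finite, large
  fold changes instead of infinities.
* **Inference.** The Wald statistic is referred to a t distribution with
  n − 2 degrees of freedom. The usual normal reference is anti-conservative
  at n = 9/9 (empirical type-I rate ≈ 0.065–0.07 at nominal 0.05 in null NB
  simulations); the t reference brings it to ≈ 0.05.
* **Significance.** A feature is Up iff linear fold change > 1.5 and raw
  p < 0.05; Down iff fold change < 1/1.5 and p < 0.05; else NS. Raw p (not
  the BH-adjusted value, which is always reported alongside) gates
  significance, following the protocol this pipeline operationalizes. A
  `log2_fc_threshold` switch gates on |log2 FC| instead, for the variant
  reading of the threshold.

## Target prediction

A candidate site is a target window whose bases pair antiparallel with the
miRNA seed (positions 2–8), Watson-Crick or G:U, with at most one wobble by
default and no mismatches. Each candidate is extended into a local duplex:
the miRNA 3′ region extends toward the target 5′ side through an
energy-space dynamic program allowing single-strand bulges up to 3 nt (no
internal mismatch loops — a deliberate simplification; mismatched 3′
regions simply terminate the helix), and miRNA position 1 may stack on the
other side. Duplex free energy is the sum of nearest-neighbor stacking terms
from the packaged Turner-2004 RNA parameter table plus bulge penalties,
duplex initiation (+4.10) and terminal A:U/G:U penalties (+0.50), all
kcal/mol at 37 °C (sources in `nn_params.py`). One best site per
(miRNA, target) pair is reported — ties broken by smallest position — and
only pairs at or below the energy threshold (default −20 kcal/mol) are
emitted. Seed-only pairing (≈ −9 kcal/mol) never passes the gate; a planted
full-length complement (≈ −35) always does.

This is a miRanda-inspired re-implementation, not a port: numerical equality
with miRanda's printed "Total Energy" values is not claimed, because the
underlying target sequences are not available; the printed pair table serves
as a format and threshold fixture.

## Network assembly

Duplex hits are joined to both endpoints' DE statuses; edges with any NS
endpoint are dropped. The inverse-expression constraint retains edges
joining one Up and one Down feature, applied to both the circRNA–miRNA and
miRNA–mRNA layers; this structurally forces circRNA and mRNA within a triple
to share direction (the sponge logic: an up-regulated circRNA absorbs a
down-regulated miRNA, de-repressing its down-regulated targets, and vice
versa). Triples are all (circRNA, miRNA, mRNA) combinations through a
shared miRNA; nodes outside any triple are excluded. Summary percentages
round half away from zero to one decimal (14/24 prints as 58.3).

## Enrichment and correlation patterns

Term over-representation is the hypergeometric upper tail P(X ≥ k) with BH
FDR across terms; significance requires FDR < 0.05 **and** p < 0.01. The
universe defaults to all genes of the annotation present in the expression
data.

The group-wise regulatory-pattern comparison computes Pearson correlations
(Spearman available) for every network (circRNA, mRNA) pair over each
group's samples; constant vectors give undefined entries excluded from
summaries. "Parallel vs chaotic" is operationalized as two statistics per
group — coherence (mean defined correlation) and the fraction of positive
entries — plus the correlation between the two groups' vectorized matrices.
These are documented surrogates for a visual claim, not a reproduction of a
published statistic.

## Synthetic data

`synthetic_data.simulate_study` generates the full study the pipeline
expects. Defaults are the emulated study conditions: 10 case / 8 control
samples; 300 circRNAs, 150 miRNAs, 1000 mRNAs (desk-scale stand-ins for the
study's thousands of features, chosen so the default test suite and
acceptance run complete in well under a minute per simulation); NB means
20/200/100 with dispersions 0.3/0.2/0.2 so the class prefilters (2/50/5)
retain most features; mapped totals log-normal around 10^6 so BSJ-TPM values
are O(1)–O(100); a global ×0.5 down-shift of case circRNA means; 10% DE
per class at fold change 4 (circRNA DE almost all down, mRNA DE mostly up);
10 case- and 40 control-exclusive circRNAs (zero counts in the other group
by construction, own-group means boosted to pass support); per-caller
junction dropout of 15%, giving a controllable true consensus; full-length
complementary response elements planted between 5% of (DE miRNA, DE target)
pairs at recorded non-overlapping positions; and a case-group shared latent
factor (log-scale sd 0.4) multiplying the counts of the features in planted
inverse pairs, which induces the parallel positive case-group correlations
while leaving controls unstructured. All draws come from one RNG stream
ordered by (class, feature, sample), so a seed fixes the bundle bytes.

What the generator does **not** emulate: read-level sequencing artifacts,
library-composition effects and linear/circular isoform competition, gene
length bias, realistic genome coordinates and real GO/KEGG structure, and
correlated dispersion across features. Passing recovery tests therefore
demonstrates the estimators' correctness under the assumed NB model, not
robustness to real-data violations of it.

## Numerical conventions and degenerate inputs

Energies are reported to 0.01 kcal/mol; both the hyphen-minus and the
typeset Unicode minus are accepted in energy fields. Coordinates are 0-based
half-open internally; `chr_start_end` identifiers reproduce input
coordinates verbatim. Empty call files, empty networks and empty histograms
are valid and round-trip as headers. Group-mean solutions are floored rather
than allowed to diverge; features whose dispersion optimization fails are
flagged, given missing p, and excluded from status calls. Deterministic
orderings: consensus sorted by (chrom, start, end), hits by (miRNA, target),
enrichment by p-value with a stable sort.
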