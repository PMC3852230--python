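# Methods

This note records the models, conventions, parameter choices and known
limitations of the package, in the order the pipeline runs.

## Coordinates and gene models

All coordinates are 0-based half-open internally; GTF is read and written
1-based inclusive, BED 0-based half-open. "Length" in the catalog filter
means spliced (mature transcript) length, the convention of the lincRNA
catalog literature, and the > 200 bp threshold is strict. Exclusion of
candidates overlapping known genes is exonic and **strand-ignorant** by
default: intergenicity is a property of the locus, not of the strand. The
strand-aware variant is a keyword switch (`strand_aware=True`), and the
rejection report records one primary reason per transcript (first failure
in the fixed order length → exon count → coding label → overlap) plus the
full list, so alternative filter policies can be audited.

Merging uses transitive same-strand exonic overlap (≥ 1 bp; abutting
exons do not merge under the half-open convention). Identical exon chains
collapse to one representative chosen by source priority
(ensembl > ucsc > refseq > assembled > other), then lexicographic id —
a pure tie-break for determinism. Gene identifiers are taken from member
transcripts when the input provides them, else generated from the sorted
coordinate order, which makes the merge invariant to input order.

De novo assembled transcripts additionally need FPKM ≥ 1 and ≥ 2 reads on
every junction; those two defaults are this package's own, exposed in
`FilterConfig`, since only the *kind* of filter ("low expression, few
supporting junction reads") is established, not its values. When no
external coding-potential label is available, `surrogate_coding_label`
provides a deliberately simple ORF-length rule (longest forward-frame
ATG→stop ORF ≥ 100 codons ⇒ coding); it is plumbing, not a classifier.

## Expression calls and τ

Each condition's representative value is the median over its samples
(robust to the over-represented ES group; even counts average the central
pair). The calls keep the printed inequality directions deliberately
asymmetric: *expressed* is FPKM ≥ 1 in at least one condition
(inclusive), *ES-expressed* is ES median > 1 (strict). τ is computed on
raw representative FPKM; a log2(FPKM+1) variant exists as a switch
(`tau(..., log2=True)`) but is off by default since no transform is part
of the index's definition here. *ES-biased* requires ES-expressed,
τ > 0.9, **and** the profile maximum in the ES condition — τ alone is
direction-blind, and "biased toward ES" names a direction. The default
profile has 17 conditions (ES + 16 tissues).

## Statistics

* Odds ratios are sample (cross-product) ratios ad/bc, +inf when bc = 0
  and ad > 0, 1 when both vanish.
* Fisher p-values come from the margin-conditioned hypergeometric pmf
  (scipy's distribution); the two-sided p sums tables with probability
  ≤ observed × (1 + 1e-7), the standard small-p rule with a relative
  guard against ties in floating point.
* The rank-sum test enumerates all C(m+n, m) labelings exactly when
  m + n ≤ 12 (midranks under ties) and otherwise uses the normal
  approximation with tie and 0.5-continuity corrections. The switch point
  is an implementation choice for testability and is configurable.
* BH and BY adjustments delegate to statsmodels' step-up implementations;
  BY is BH scaled by c(m) = Σ 1/i, clipped at 1.

## Guilt-by-association annotation

GCC is asymmetric. The directional form used is the midrank-weight
version, GCC(x|y) = Σⱼ (2·rank(yⱼ) − n − 1)·xⱼ / Σⱼ (2·rank(xⱼ) − n − 1)·xⱼ,
which equals the classic sorted-order formula when y has no ties and the
tie-averaged value under midranks. Because no canonical symmetrization
exists, `correlation` returns the direction with larger absolute value
and both raw directions remain available (`gcc_directional`). Constant
profiles make the denominator vanish; pairs involving them are NaN in
batch mode (logged per gene) and raise in scalar mode.

The neighbor cutoff (≥ 0.9) is inclusive. The enrichment universe is the
set of protein-coding genes that survive the low-expression filter
(representative FPKM ≥ 1 in at least one condition; genes below in *all*
conditions are removed) and carry ≥ 1 annotation after true-path
propagation to is_a/part_of ancestors. The hypergeometric test is the
standard (unconditional) over-representation tail; a parent-child
conditional variant is out of scope. Slim projection takes **all** slim
ancestors of each enriched term (roots excluded); the "most specific
covering terms" variant is available as `most_specific=True`. Set-level
association per slim term uses one-sided (greater) Fisher tests with BY
adjustment, significance = adjusted p ≤ 0.05 and OR > 1; one-sided
greater is used because enrichment (OR > 1) is the direction of interest.
Degenerate partitions and terms held by no gene are skipped with recorded
reasons rather than tested.

## Evolutionary dating

Homolog presence is alignment-block coverage **strictly** above 0.8 of
the gene span (exon-union coverage is a switch; span is the default since
whole-locus liftover blocks are the expected input). The parsimony rule
is strict: presence in *every* member of a nested clade on the focal→root
path and absence in *every* outgroup; of the 2⁶ = 64 presence patterns
on the default 7-taxon tree exactly 7 are datable, all others are
undated. This reproduces the qualitative behavior that a noticeable
minority of genes cannot be dated. Branch labels are emitted as the
clade's sorted leaf set, so user trees of any shape and taxon naming
work; ordinal ages count nested clades outward (0 = focal-specific).
Per-species minimum alignment identity filtering is supported but off by
default — identity summaries in the source material are descriptive, not
filters. Age-set comparisons use the rank-sum test on ordinal ages.
Mean DAF < 0.1 (strict) over exonic variants flags purifying selection;
genes with no exonic variant get no flag rather than 0.

## Regulome

Promoter = [TSS − 3000, TSS + 1000) on the transcript strand, clipped at
position 0; a gene's promoter is the union over its transcripts. Peak
overlap is any shared base (half-open). The gene-body statistic for the
rank test is the fraction of the gene span covered by the peak union; a
score-weighted variant is possible but the coverage fraction is the
default per-gene statistic. The enrichment background is an explicit
argument everywhere (the pipeline's default contrast is ES-biased
lincRNAs vs all other catalog lincRNAs) — no silent background choice.
HERVH holding is a case-sensitive substring match on repeat name *and*
family labels (rmsk-style names like `HERVH-int`).

## Synthetic data: what it emulates, what it does not

The generator produces every input at desk scale on a toy genome (two
10 Mb chromosomes, non-overlapping 20 kb slots): 500 coding genes, 200
lincRNAs, 5 ES samples + 16 single-sample tissues, 30 contaminants (10
per violation class, each violating exactly one filter), 5 co-expression
modules (4 lincRNAs + 10 coding genes each, tied to one ontology leaf
term with a slim ancestor through an is_a→part_of chain), 20 ES-exclusive
lincRNAs, ages cycling over all 7 branches plus 10 patchy genes, and
planted promoter/body peaks (rates 0.9 vs 0.1), HERVH elements (rates
0.8 vs 0.05) and Beta(1, 50) vs Beta(5, 5) DAFs (15 purifying genes).

Numerical choices made once: ES-exclusive expression is LogNormal(μ = 2,
σ = 0.25) in ES samples and 0 elsewhere (τ = 1 by construction); module
latent profiles are Uniform(2, 6) per condition, which keeps module
members above the low-expression floor and bounds their τ near 0.71, far
from the 0.9 biased threshold, so a module can never masquerade as
ES-biased; background genes are i.i.d. Uniform(0.5, 4); expression noise
is multiplicative lognormal (positivity preserved). Robustness-sweep
tests use noise_sd = 0.05, at which planted module correlations stay
above the highest sweep cutoff (0.95) for both GCC and Pearson.

What passing on this generator does **not** show: real FPKM matrices have
correlated noise, batch effects across heterogeneous datasets and
dynamic-range compression that the i.i.d. multiplicative noise model does
not emulate; real catalogs have overlapping isoform clusters far messier
than the planted slots; real alignment coverage is bimodal rather than
two-point (0.95/0.40); and the real GO DAG is orders of magnitude larger.
The end-to-end tests therefore demonstrate correctness of the
computations and bookkeeping, not field performance of the thresholds.

All generators are pure functions of (config, seed): identical inputs
give byte-identical bundles, and each bundle carries a `truth.json`
ledger consumed by the end-to-end tests.

## Pipeline and problem sizes

The pipeline (catalog → call → annotate → date → regulome) is fully
deterministic; the config seed exists for future stochastic extensions.
Stage failures abort with the stage name and leave partial outputs plus
an `INCOMPLETE` MANIFEST. The bundled study sizes (200 lincRNAs × 500
coding genes × 17 conditions) run the complete pipeline in a few seconds;
correlation matrices are computed vectorized (rank-weight matrix
products), so ~10⁵ lincRNA×coding pairs per second are practical.

## Known limitations

* CPC-style coding-potential classification, read mapping/assembly,
  liftOver, MACS peak calling and conservation scoring are out of scope;
  their outputs are inputs here.
* The GCC symmetrization (larger |value|) is one defensible choice among
  several; both directions are exposed for users who need a specific one.
* The GO-slim projection ignores relationship types beyond is_a/part_of.
* The hypergeometric enrichment is unconditional; nested terms are
  partially redundant, mitigated but not removed by the slim projection.
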