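# Methods

## Scope and design

`rloopkit` reconstructs, as a tested library, the inference path of a
strand-aware R-loop analysis of ssDRIP-seq libraries: treatment replicates
against RNase-H-treated controls, strand-asymmetry assessment, genomic
annotation, profiling, and the companion protein-interactor screening
statistics. The atomic data unit is the aligned *fragment* (the sequenced
insert), not the single read: the synthetic generator emits fragments
directly, so mate-pair logic never arises. All coordinates are 0-based
half-open; "overlap" always means sharing at least 1 bp, so touching
intervals do not overlap.

## Synthetic data generator

The generator produces the study conditions every test and the acceptance
script run under. Defaults:

| parameter | default | meaning |
|---|---|---|
| genome_length / n_chroms | 2 Mb / 2 | uneven split (1.3 Mb + 0.7 Mb) so cross-chromosome indexing bugs surface |
| n_genes | 120 | non-overlapping, log-normal lengths (median ≈ 3 kb, long-tailed), 85% protein-coding / 10% pseudogene / 5% other |
| n_stranded / n_unstranded | 30 / 30 | stranded loops balanced between + and − |
| rloop_len_mean ± sd | 1000 ± 200 bp | truncated at 200 bp |
| enrichment_fold | 8 | total fragment rate inside a loop relative to background |
| asymmetry | 0.1 | minority-strand share of planted signal at stranded loops; unstranded split 50/50 |
| depth_per_sample | 50 000 | exact library size (multinomial allocation) |
| frag_len_mean ± sd | 250 ± 50 bp | Normal, truncated ≥ 1 |
| n_replicates | 4 | treatment and RNase-H each |
| subthreshold_frac | 0.05 | fragments given a mapping-like score < 20, to exercise the filter |
| min_rloop_gap | 3 kb | minimum separation between planted loops |

Fragment midpoints are drawn from a mixture of a uniform background over
both strands and one component per planted loop whose weight equals
`(fold − 1) × 2 × loop_length`; with a fixed library size the background
rate cancels from the mixture probabilities, so `background_rate`
(0.01 fragments/bp/strand) only matters in the Poisson-depth mode
(`depth_per_sample=None`). A plus-class loop routes `1/(1+a)` of its extra
fragments to the plus strand, so the expected majority:minority ratio is
`1/a`. RNase-H libraries contain background only, which is exactly the
biology the control emulates: the enzyme removes every hybrid. The 8× fold
and the 50k depth are a choice of a clearly detectable but not trivial
signal (≈ 33 expected midpoints per 200 bp window inside a loop versus ≈ 4
in the background); the minimum 3 kb gap between planted loops keeps broad-
mode linking (1 kb gaps) from fusing adjacent truths into one cluster, which
would otherwise make Jaccard-based scoring ambiguous rather than reveal a
caller defect.

Chromatin-mark tracks are a flat baseline (1.0) with iid Gaussian noise
(sd 0.1 per 10 bp bin) plus Gaussian bumps at target-class loops
(sd = loop length / 4, peak height `(fold − 1) ×` baseline).

What the generator does **not** emulate: base-level sequence and mappability
structure, GC or fragment-length bias, read-pair orientation, PCR-duplicate
families beyond exact-coordinate duplicates, copy-number variation, or any
correlation between background rate and chromatin state. Tests passing on
this generator therefore demonstrate correctness of the inference given the
declared signal model, not performance on real libraries.

## Enrichment caller

Window counts use fragment-midpoint assignment (each fragment falls in
exactly one window per step phase, keeping counts Poisson-like); coverage
tracks elsewhere use overlap-bp weighting so coverage mass is conserved
exactly in integer arithmetic. These are the two counting conventions in the
package and each is used consistently.

Defaults: 200 bp windows, 100 bp step, chosen for ~1 kb R-loops. The local
background is the classic maximum of the genome-wide control rate and the
control rates in 1/5/10 kb spans centred on the window, scaled by the
treatment:control library ratio, floored at max(global rate, one fragment
per genome) so the expectation is strictly positive even for empty controls.
Only windows with ≥ 1 treatment fragment are tested; BH adjustment is over
all tested windows genome-wide, with ties broken by original index (stable
sort). Narrow peaks merge significant windows that overlap or touch; broad
peaks extend through flanking windows with q ≤ 0.1 and merge across gaps up
to 1 kb, and a broad region is kept only if it contains a fully significant
seed — which guarantees broad peaks contain every narrow peak they overlap.
Exact numerical equality with any external peak caller is a non-goal; the
analysis-level results (recovery, classification) are the contract.

## Pipeline conventions

- "Found in at least three samples" is operationalised as transitive
  ≥ 1 bp-overlap clustering (connected components) with ≥ 3 *distinct*
  replicates contributing; narrow and broad calls from one replicate count
  once; the retained interval is the cluster union.
- q ≤ 0.001 (inclusive), configurable.
- Strand asymmetry is a within-replicate contrast: each strand is tested
  against the opposite strand of the same library, library-ratio scaled;
  RNase-H plays no role there. The same reproducibility merge is then
  applied per strand.
- A total R-loop overlapping both plus- and minus-asymmetry intervals is
  classified unstranded — operationally a locus with hybrid signal on both
  strands.
- All genomic text outputs are sorted by (chrom, start) for diff-stability;
  rerunning any stage on the same inputs is byte-identical.

## Annotation

Feature assignment uses the R-loop midpoint under the priority
promoter-TSS > downstream-TTS > exon > intron > intergenic, with windows
strand-aware (promoter −2.5/+0.5 kb around the TSS, downstream −0.5/+2.5 kb
around the gene end). When the winning genic feature belongs to a
pseudogene-biotype gene the class becomes "pseudogene". The midpoint rule
makes classes mutually exclusive, so observed counts always sum to the
number of R-loops. The expected model is the genomic bp share of each class
under the exact same per-base priority partition, which makes the
calibration identity exact: loops placed uniformly give ratios of 1, loops
placed entirely in promoter bases give ratio = 1 / promoter share. Within a
priority level, overlapping windows of different genes are resolved by
gene-id order — a deterministic, documented tie-break for a rare case.

Gene-level overlap tables extend the gene span by the promoter and
downstream windows (one contiguous span, body ± 2.5 kb) so promoter R-loops
count toward their gene; the same extended span is used for TF-peak
binding, while the separate proximal/distal classification uses the gene
body ± 1 kb. "Expressed" means CPM > 1; expressed genes split into
low/mid/high tertiles at ranks ⌈n/3⌉ and ⌈2n/3⌉ of the CPM-ascending
order with ties broken by gene id, so labels are a deterministic function
of the CPM multiset.

## Profiling and QC

Metaplots average per-bp signal in [mid − flank, mid + flank) rebinned to
n_bins (defaults 5 kb, 100 bins; 2·flank must divide evenly). Centers
clipped at a chromosome edge are kept and averaged over covered bp only
(NaN elsewhere), with the clipped count reported. The PCA operates on
samples × bins CPM-normalised coverage (500 bp bins), z-scored per bin
("scale = TRUE" convention) with zero-variance bins dropped and counted,
via singular value decomposition.

## Interactor screening

The abundance filter requires mean pseudocounted enrichment > 2 and a
one-sided Welch t-test p < 0.05 on log(abundance + 0.5). The test choice is
a documented, pluggable default: many genuine interactors are undetected in
every control, so a pseudocount rule is mandatory, and the heavy-tailed
abundances argue for the log scale. The PSM filter is strict on spectra
(combined PSM > 10) and inclusive on fold (≥ 2). The Fisher overlap test is
one-sided (enrichment) and computed as an exact hypergeometric upper tail
in rational arithmetic (`fractions.Fraction`), so it agrees with a
full-enumeration oracle to floating-point precision on any table; scipy's
implementation is used as an independent cross-check in the tests, never as
the implementation.

## Numerical and degenerate-input choices

- Poisson tails come from the regularised incomplete gamma function
  (`scipy.stats.poisson.sf`), verified against arbitrary-precision
  summation to 1e−9 relative error for counts ≤ 100 and λ ∈ [0.01, 50].
- p-values are clipped away from 0 at the smallest positive double before
  BH adjustment.
- Empty inputs: an empty fragment set yields empty scans and empty peak
  lists; zero-library CPM normalisation, empty control pools, zero R-loops
  in observed/expected, < 3 PCA samples, and all-zero-variance PCA matrices
  raise errors naming the problem.
- Determinism: every stochastic component takes an explicit seed; library
  streams are derived from (seed, role, replicate) so adding a replicate
  does not reshuffle existing ones.

## Problem sizes

The default experiment — 2 Mb genome, 8 libraries of 50k fragments — runs
the full pipeline in about one second; the test suite's larger campaigns
(100 null experiments, 10-seed recovery, 20-seed profiling and PCA) were
sized to give stable pass/fail behaviour at comfortable margins while
remaining desk-scale.

## Known limitations

- The caller is a self-contained Poisson local-lambda scanner; it does not
  model duplicate rates, estimate fragment size, refine summits, or call
  without a control.
- Recovery metrics use symmetric-Jaccard matching; a caller that merges two
  planted loops into one interval is penalised even if both are "detected".
- The two-class (stranded/unstranded) decision reduces a continuous
  asymmetry spectrum to overlap booleans; an `ambiguous` locus overlapping
  both strand calls is folded into unstranded rather than surfaced as a
  fourth class.
- Gene-ontology enrichment and external protein-network retrieval are out
  of scope.
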