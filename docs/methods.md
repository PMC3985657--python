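# Methods

## Scope and model

omegatx analyses a two-group replicated expression experiment — a wild-type
control strain versus an RNA polymerase mutant (the motivating case is a
cyanobacterial ΔrpoZ strain lacking the ω subunit) — and the promoter
architecture of the regulated genes. It has two computational cores:

1. **Expression pipeline.** Probe-level intensities are collapsed to genes
   by the arithmetic mean, samples are quantile-normalized on the linear
   scale, intensities are log2-transformed, and each gene is tested with a
   two-sided Welch t-test (mutant vs. control replicates). A gene is called
   *up* if log2FC ≥ 1 and P < 0.05, *down* if log2FC ≤ −1 and P < 0.05
   (fold-change boundary inclusive, significance boundary exclusive).
   Expression level is the mean log2 control signal; genes are stratified
   into half-open level bins and the percent up/down per bin summarizes how
   regulation depends on expression level.

2. **Promoter-element discovery.** For each 60-nt upstream sequence
   (promoter-relative coordinates −60..−1, −1 adjacent to the TSS, TSS
   excluded), a 6-nt −10 element is placed so that it fits inside
   −14..−5 (admissible starts −14..−10), choosing the per-sequence starts
   that jointly maximize the total information content of the ungapped
   alignment, R = Σ_j (2 − H_j) bits with H_j the Shannon entropy of column
   j's base frequencies. Holding the −10 placements fixed, a 6-nt −35
   element is placed 16–18 nt upstream (spacer = nucleotides strictly
   between the elements), again maximizing alignment information content
   over the three spacer choices per sequence. The extended −10 flag tests
   for TG immediately 5′ of the −10 hexamer; the spacer A+T fraction
   characterizes the inter-element region.

## Optimizer

The objective is stated by the constrained-alignment problem; the optimizer
is a package design choice:

- **exhaustive** — exact scan of all |choices|^N combinations (vectorized,
  chunked), used automatically when that count is ≤ 10^7. Combinations are
  enumerated with sequences in gene-id order and candidates in
  ascending-offset order, so the first optimum found is the lexicographically
  smallest — i.e. the documented tie-break (most upstream offset, then
  gene-id order) falls out of the enumeration order.
- **coordinate ascent** — sweep the sequences, re-placing each element to
  maximize total IC holding the others fixed, until no move improves; a
  move that keeps the score but is more upstream is also accepted (this
  cannot cycle: the pair (score, index vector) improves lexicographically).
  `restarts` seeded random initializations (plus one all-upstream start) are
  run and the best kept. With only 5 (or 3) choices per sequence this
  reliably reaches the exhaustive optimum on sizes where that can be
  checked.
- **gibbs** — leave-one-out Gibbs sampling with a 0.5 pseudocount in the
  predictive frequencies, best visited state polished by coordinate ascent;
  useful for escaping plateaus, not the default.

Numerical choices: zero-frequency terms contribute 0 to the entropy sum; no
pseudocounts inside the objective (a configurable pseudocount exists only
for exported frequency matrices); the small-sample correction
e(n) = 3/(2·ln2·n) is off in the optimizer — at fixed n it shifts every
candidate equally and cannot change the argmax — and available when
reporting logo values (note the corrected IC can dip below 0 at small n).
Score comparisons use a 1e−12 tolerance. N characters carry no count mass;
sequences whose every admissible window is all-N are excluded with a
warning.

## Statistical choices

- **Welch t-test** (unequal variances, Satterthwaite df) rather than a
  pooled-variance test, because the target design has unequal replicate
  numbers (4 control vs. 3 mutant). Genes with zero variance in both groups
  get p = 1 at equal means, p = 0 otherwise. P-values are uncorrected by
  default (the classification thresholds are raw-P thresholds);
  Benjamini–Hochberg adjustment is available behind `adjust=True`.
- **Quantile normalization** maps every column onto the mean of the
  per-rank order statistics. Tied values within a column receive the mean
  of the reference values their ranks span. Dialect note: on tie-free data
  this is idempotent, rank-preserving and leaves all columns with identical
  sorted values, and agrees exactly with R limma's `normalizeQuantiles`;
  with ties the averaging perturbs the column distribution slightly, so the
  identity and idempotence contracts are exact only tie-free (and limma's
  tie handling — interpolation at the mean tied rank — differs for ties
  spanning three or more ranks).
- **Element contrast**: total and per-position IC differences between two
  promoter groups (e.g. down- vs. up-regulated genes), with an optional
  permutation p-value obtained by shuffling group labels over the pooled
  promoters and realigning each permuted group; p = (1 + #{|d*| ≥ |d|}) /
  (n_perm + 1).
- **Top-100 overlap**: percent intersection of the 100 most highly
  expressed genes under two rankings (e.g. raw vs. normalized signal), ties
  at the cut broken by gene id.

## Synthetic data: what it emulates, what it does not

`generate_promoters` plants a TATAAT-consensus −10 at a random admissible
start and a TTGACA-consensus −35 at a random 16–18 nt spacer in i.i.d.
background; each element position emits the consensus base with probability
`conservation` (default 0.9, a strongly conserved element that still leaves
mismatches), the remaining mass split evenly over the other three bases.
Optional features mirror the biology of strong promoters: a planted TG
extended −10 (`extended10_prob`) and an A+T bias inside the spacer
(`spacer_at_bias`). `generate_expression` draws gene levels normal on the
log2 scale (mean 10, sd 2.5 — the shape of typical log2 microarray signal),
adds a planted ±2 log2FC to a `de_fraction` of genes with replicate log2
noise of sd 0.25, and couples the effect sign to expression level
(`level_coupling` = 0.8: high-level genes tend to be planted down,
low-level genes up), reproducing the observed pattern that downregulation
concentrates among highly expressed genes. Replicates default to 4 control
vs. 3 mutant.

The generators do not emulate probe hybridization physics, dye or
background effects, correlated noise across genes, operon structure, or
phylogenetic correlation between promoters. A green recovery test therefore
establishes that the pipeline inverts its own stated generative model —
not that it would reproduce a particular laboratory dataset.

## Degenerate inputs and edge rules

Upstream windows that would cross a linear replicon end are dropped with a
logged warning (circular extraction is opt-in). log2 transforms clamp at a
configurable linear floor (default 1.0) to avoid −∞. Expression bins are
half-open [e_i, e_{i+1}) with open-ended first/last bins; empty bins are
reported with n = 0 and undefined percentages as NaN. Single-sample
matrices make quantile normalization a warned no-op.

## Known limitations

- The optimizer's exactness guarantee applies to the exhaustive mode only;
  the heuristics carry a local-optimality guarantee plus empirical
  agreement with the exhaustive optimum at checkable sizes.
- The permutation contrast realigns with coordinate ascent at few restarts
  for speed; its p-values are conditional on that aligner.
- No multiple-testing correction by default: the classification reproduces
  a raw-P workflow, and corrected calls will be more conservative.
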