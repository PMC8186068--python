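# Methods

## Statistical model

The tests are one-sided over-representation tests on the gene universe
defined by the array annotation: every gene linked to at least one probe.
Genes absent from the annotation are dropped from gene sets before
anything is computed; significant CpGs without gene links are counted in
diagnostics but contribute to no gene.

Writing `w_ij = 1/k` for a probe annotated to `k` genes, the equivalent
probe count of gene *j* is `N_j = Σ_i w_ij`, and the gene score for a
significant set *A* is `S_j = min(Σ_{i∈A} w_ij, 1)`.  The per-set overlap
statistic is `ES_g = Σ_{j∈g} S_j`, floored to an integer for the tail
computation (the observed outcome is included in the tail: `P(X ≥ x)`
with `x = floor(ES_g)`).  The floor is applied with a 1e-9 epsilon so
sums of reciprocal weights that are integral in exact arithmetic (e.g.
three probes of weight 1/3) are not truncated a unit low.

The probability weighting function is the empirical probability that a
gene is differentially methylated (`S_j > 0`) as a function of its probe
count, estimated by a tricube moving average over genes sorted by count
(ties broken by gene id, so results are order-stable).  The window is
centered, of odd width `2·floor(span·L/2) + 1` with span defaulting to
0.5 (the default of the standard tricube smoother this mirrors); at the
edges the window is truncated and the kernel weights renormalised, which
makes the smoother exact on constant inputs.  Implementation is a ratio
of two convolutions (indicator and ones vector), evaluated by
scipy.signal with automatic direct/FFT selection; FFT round-off is
clipped back into [0, 1].

Method variants differ in two places only:

| variant  | overlap x                      | PWF ordering counts |
|----------|--------------------------------|---------------------|
| HGT      | integer count of genes with S>0 | — (odds fixed at 1) |
| HGT-mod  | integer count of genes with S>0 | raw probe counts    |
| GOmeth   | floor(ES_g)                     | equivalent counts N_j |

The urn has `m1 = |g ∩ universe|` white and `m2 = U − m1` black balls and
`n` draws, where `n` is the *integer* number of genes with `S_j > 0`:
draws from an urn must be integers, and the fractional weighting already
enters through `x` and the odds.  The differential methylation indicator
feeding the PWF is `S_j > 0`, not `S_j = 1`: a gene whose only
significant probe is shared is still differentially methylated.

The Wallenius upper tail is evaluated with
`scipy.stats.nchypergeom_wallenius`; `odds = 1` is routed to
`scipy.stats.hypergeom`, where the reduction to the central distribution
is exact.  An exhaustive enumeration of ordered draw sequences
(`wallenius_oracle`, urns up to 12 balls) is kept in the package as the
independent correctness anchor used by the tests.  Extremely significant
sets can underflow the tail to 0.0 in double precision.

Degenerate cases: a set whose universe intersection is empty or is the
whole universe has undefined odds and is dropped with a warning before
testing; an out-of-set PWF mean of zero (essentially impossible on real
data) caps the odds at 1e6 with a warning; an all-unannotated significant
set yields all-zero scores, `x = 0` and p = 1 everywhere, with a warning.
P-values are reported unadjusted plus one adjusted column
(Benjamini-Hochberg by default, Holm by option, via statsmodels).

## Region-level testing

Regions are stored 0-based half-open (BED-native); CSV input is converted
from 1-based inclusive coordinates by default, the common DMR-caller
convention.  A probe overlaps a region if its single basepair lies inside
it (≥ 1 bp overlap at probe resolution); strand is ignored.  Filtering
keeps regions with `no_cpgs ≥ 3` and `|mean Δβ| ≥ 0.1` by default —
removal is for strictly smaller values, and either threshold can be
disabled (some analyses run unfiltered).  The region test is, by
construction, the probe test applied to the union of probes under the
surviving regions; there is no hidden state, and the identity is asserted
byte-for-byte in the tests.

## Feature restriction

Restricting to genomic features (TSS1500, TSS200, Body, ...) keeps only
gene links carrying at least one requested label; probes losing all links
become unannotated but remain on the array.  Weights and equivalent
counts are then *recomputed* on the restricted link set — a probe that
keeps one of its two links gets weight 1, not 0.5.  This is an
interpretive choice (reusing full-annotation weights would be the
alternative); recomputation is preferred because the restricted link set
defines the universe actually being tested, and the conservation property
(each annotated probe distributes unit mass) then continues to hold
within the restricted table.

## Synthetic data

The generator emulates the composition features that create the biases,
not methylation values themselves:

* **CpGs per gene**: negative binomial with dispersion r = 1.2 and mean
  27, clipped below at 1, giving a realized median raw count ≈ 20,
  minimum 1 and a tail into the hundreds on a 10,000-gene array —
  EPIC-like summary features.  The family is configurable (`fixed` and
  `uniform` specs exist for deterministic layouts).
* **Multi-gene probes** (default 9% of gene-annotated probes): a shared
  probe is a *merged* pair — one probe of a gene fused with one probe of
  the next gene in the layout, so each gene's raw link count is exactly
  its drawn count and the equivalent counts split the shared probe 0.5
  each.  Genes co-occurring in the same synthetic set are placed adjacent
  with probability 0.5, so shared probes preferentially connect
  functionally related genes — the arrangement that makes multi-gene bias
  concentrate in gene sets rather than wash out.
* **Unannotated probes** (default 30% of all probes) are interleaved on
  the same chromosomes at unoccupied positions.
* Genes are laid out contiguously on up to 20 synthetic chromosomes with
  20–300 bp gaps between probes and ~2 kb gaps between genes, so
  region-overlap logic is exercised on realistic clustered coordinates.

Gene sets sample genes uniformly (sizes uniform on 10–500 by default).
All generators are pure functions of (config, seed).

What the generator does *not* emulate: beta-value distributions,
cell-type composition, probe-level measurement noise beyond the null
normal model, chromosome-scale structure, and the correlation between a
real gene set's biology and its probe density.  Calibration results on
synthetic nulls therefore demonstrate that the tests control type-I error
under the modelled biases; they do not measure power or ranking quality
on real biology.

The null two-group experiment draws per-probe values for both groups from
one shared normal model (probe means N(0,1), probe standard deviations
lognormal with log-sd 0.25), ranks probes by the ordinary two-sample
pooled t-statistic and takes a fixed top-N as "significant" — a pure-null
stand-in for resampling normal samples from a real cohort, where
moderated statistics would add nothing under the null.

## Problem sizes and numerics

The calibration experiments run at 10,000 genes, 300 gene sets, 50
replicates per condition, and significant-set sizes 50–10,000 — chosen as
the smallest sizes at which the composition targets (median, fractions)
are tightly realized and per-size medians over replicates are stable;
the full three-method experiment completes in about a minute on one CPU.
The per-set tail computations are vectorised over sets; the tester
precomputes the membership matrix, both gene orderings and the smoother
denominator once per (annotation, collection) pair, so repeated null
replicates cost only scoring, one convolution and one batch of tail
evaluations each.

## Known limitations

* Only Wallenius' noncentral model is provided (sequential biased
  sampling); Fisher's noncentral variant is a different model and is out
  of scope, as is estimating odds from data.
* The region test offers no gene-body-interval comparator (the annotation
  carries single basepair positions, not gene coordinate ranges).
* Annotation follows the manifest's gene links; alternative annotation
  strategies (e.g. fixed ±2 kb promoter windows) are not implemented.
* `n` (urn draws) counts significant genes without fractional weighting;
  an alternative fractional definition is conceivable but the printed
  model uses the integer count.
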