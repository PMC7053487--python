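# Methods

This note documents the models, estimators, defaults and deliberate
design choices behind each stage of the pipeline, what the synthetic
generator does and does not emulate, and the numerical conventions
used throughout.

## Differential expression and the signature

Intensities are assumed log2-scale and pre-normalised; the pipeline
deliberately starts downstream of array normalisation. Per probe, the
statistic is the Welch two-sample *t* between undifferentiated and
differentiated samples; significance is a two-sided permutation test of
condition labels. When the number of distinct label splits C(n, n₂) is
at most `n_perm` (default 1000) the permutation distribution is
enumerated exhaustively and the observed split counts itself (so
p ≥ 1/#splits); otherwise `n_perm` random splits are drawn with the
run's seed and p = (1 + b)/(n_perm + 1). Probes with zero variance in
both groups have an undefined *t*; they are recorded with p = 1 and a
warning rather than dropped. Benjamini–Hochberg adjustment is applied
across all probes of a cell line (the step-up definition is kept as an
independent oracle in the test suite).

A probe is differential iff its anti-logged fold change
2^(mean_diff − mean_undiff) is strictly > 2 or < 0.5 **and** its BH
q-value is < 0.05 — strict inequalities, following the "over 2 or
under 0.5" rule. Probes collapse to genes by keeping the probe with the
largest |t| per gene; unmapped probes are dropped with a warning. The
cross-line signature is the strict intersection of per-line DEG gene
sets; genes whose direction disagrees between lines are excluded and
reported separately (the design anticipates the all-upregulated outcome
but does not assume it).

## Term enrichment and the κ term network

Enrichment is the right-tail hypergeometric p
Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n), BH-adjusted across terms; term members
are intersected with the declared universe before testing. Term-term
agreement is Cohen's κ = (p_o − p_e)/(1 − p_e) on the 2×2 gene-membership
table. The κ universe defaults to all genes annotated to ≥ 1 tested
term — not the expression universe — to avoid inflating agreement
through jointly-absent genes. Functional groups are connected components
of the κ ≥ 0.4 graph; this is deterministic, unlike iterative
leading-term merging heuristics, and is the package's own grouping
definition.

## Mutual-information network inference

Two MI estimators are exposed, with different jobs:

* `method="bins"` (default): plug-in MI on rank-based equal-frequency
  bins, B = max(2, ⌊n^⅓⌋) per axis. It is deterministic, exactly
  symmetric (cell contributions are summed in sorted order to defeat
  floating-point non-associativity), exactly invariant under strictly
  monotone transforms of either argument, and cheap enough to score
  thousands of candidate pairs per bootstrap round. Its known
  limitation: discretisation places a ceiling on the value for strongly
  dependent pairs (at n = 2000, B = 12 the ceiling for a Gaussian
  ρ = 0.9 pair is ≈ 0.74 nats vs the true 0.83), which is irrelevant
  for thresholding and ranking but disqualifies it as a point estimate
  of strong dependence.
* `method="knn"` (k = 8): a deterministic Kraskov–Stögbauer–
  Grassberger k-nearest-neighbour estimator computed on ordinal ranks
  (hence monotone-invariant). It tracks the Gaussian closed form
  −½ ln(1 − ρ²) within 0.05 nats at n = 2000 across ρ ∈ {0, 0.5, 0.9}
  (validated against both the closed form and scikit-learn's estimator)
  and is the estimator of record when the MI value itself is reported.
  k = 8 trades a little variance for near-zero bias at n ≈ 10³.

The significance threshold is the (1 − α) quantile (α = 0.05) of a
permutation null: random gene pairs with one profile permuted. Inside
bootstrap rounds the permutation is applied **before** the round's
column resampling, so the null carries the same duplicated-sample
structure as the resampled data. This matters: resampling with
replacement induces spurious MI between independent profiles (duplicated
samples land in identical bin pairs), and a naive post-resampling
permutation null under-estimates the null by enough to produce per-round
false-positive rates above 50% at n = 200. With the structured null the
per-round rate is calibrated at ≈ 5%.

Each bootstrap round (default 50) resamples samples with replacement,
recomputes candidate MI, applies the threshold, then DPI — for every
triangle (x, y, z), edge (x, z) is marked when
mi(x,z) < (1 − tolerance)·min(mi(x,y), mi(y,z)), decisions taken on the
round's graph and applied simultaneously; exact ties survive at the
default 0% tolerance. Thresholding precedes DPI within each round, and
DPI runs per round rather than once on the consensus. The consensus
keeps edges supported in ≥ 50% of rounds; a Poisson-consensus
alternative (support count improbable under the mean detection rate,
Bonferroni 0.05) is available via `consensus="poisson"`. Candidate
edges are restricted to TF → (signature ∪ TF) pairs, mirroring the use
of a TF panel as regulators and the signature as targets; a TF–TF pair
yields directed edges in both orientations.

## Master-regulator analysis

Per TF, the one-sided Fisher exact p of regulon × signature membership
(computed as the hypergeometric survival function; the test suite
checks agreement with `scipy.stats.fisher_exact` and with full
enumeration for small universes), BH across TFs, MR iff q < 0.05.
Common MRs are the strict intersection of per-line MR sets. The common
network is the edge-level intersection of the per-line networks
(node-level union is available via `mode="nodes"`), restricted to
common MRs regulating signature genes, and optionally filtered by
binding-site/promoter overlap: an edge survives iff ≥ 1 recorded
binding site of its TF overlaps the target's promoter by ≥ 1 bp on the
same chromosome, strand-agnostic. Promoters default to −2000..+500
around the TSS, strand-aware; validated and predicted binding-site
records are treated alike.

## Motif scanning

Column log-odds are ln((c + pc·bg)/(total + pc)) − ln(bg) with
pseudocount pc = 1 spread by the background (uniform 0.25 by default).
The relative score rescales a word's score between the per-matrix
minimum and maximum achievable (column-wise min/max sums), making it
invariant to multiplying all counts by a constant. Both strands are
scanned — a minus-strand hit at offset i means the reverse complement
of window[i:i+L] matches — with hits kept at relative score ≥ 0.8 (an
RSAT-like default; no cutoff is inherent to the method) and any
ambiguous base suppressing the hit. Clusters are single-linkage merges
of hits whose start-to-start gap is ≤ 50 bp; the 50-bp gap and the 0.8
cutoff are configurable since neither is canonical.

## qPCR and ChIP quantification

ΔCt = Ct_target − Ct_reference within each replicate (reference GAPDH
by default); ΔΔCt is the difference of group means versus the control
group; RQ = 2^−ΔΔCt with amplification efficiency fixed at 2 (no
efficiency correction). The two-sided Student's *t* is computed on
replicate ΔCt values — the log-scale, near-normal domain — not on RQ.
Groups missing the reference are skipped with an error record. ChIP
enrichment is percent-of-input: the input Ct is first shifted by
log2(1/f) for an input fraction f (default 1%, configurable; the
dilution used in any given experiment is a property of that
experiment), then percent = 100·2^(Ct_input_adj − Ct_IP).

## Conservation

Distances between aligned homologs use the Kimura two-parameter model,
d = −½ ln(1−2P−Q) − ¼ ln(1−2Q), with gap/ambiguous columns excluded
pairwise and an explicit saturation error when the logs are undefined.
K2P was chosen over pooled-rate composite-likelihood distances because
it is closed-form per pair and therefore directly testable; the choice
is recorded in the tree metadata consumers can inspect (`notes`).
Neighbour joining follows Saitou–Nei with the Q-criterion; exact ties
choose the pair whose smallest contained leaf labels sort first, making
the output fully deterministic. The last three nodes are resolved by
the three-point formula, giving an unrooted tree with a trifurcating
root; negative branch lengths are clamped to zero and counted. On
additive matrices the algorithm recovers the generating topology and
branch lengths exactly (property-tested for 4–8 taxa, cross-checked
against scikit-bio's NJ).

Position classification: ≥ 1 bp overlap with the gene body is
``inside``; otherwise the hit is ``upstream``/``downstream`` relative
to the gene's strand; hits on another chromosome, or farther than
500 kb (configurable — "far away" has no canonical cutoff) from the
nearest gene boundary, are ``distal``. The signed distance is negative
upstream.

## The synthetic generator

The expression model is linear-Gaussian on the log2 scale: TF profiles
are N(8, 1); each target follows exactly one planted TF,
target = 8 + w·(TF − 8) + N(0, σ), with |w| ~ U(0.6, 1.0) and random
sign, σ = 0.5 by default. Defaults are the desk-scale study
conditions: 20 TFs, 200 targets partitioned into regulons of 5–30
genes, 100 samples per condition, 3 cell lines, log2 effect 2.0
(fourfold). Five TFs are planted as master regulators and the signature
is the union of their regulons, applied as a differentiation effect in
every cell line so the per-line signatures intersect by construction.
The weight floor of 0.6 follows a design signal-to-noise calculation:
pooled across conditions a signature target carries extra variance
effect²/4, so the weakest planted correlation is
0.6/√(0.36 + 1 + 0.25) ≈ 0.47, comfortably above the n = 200 MI
detection threshold. About 20% of genes carry two probes (probe
replicate noise 0.2·σ, so the noiseless limit stays exactly noiseless)
to exercise probe collapsing. Ground truth (regulons, weights,
masters, signature, probe map) is returned with the data and written
beside simulated bundles.

What the generator does **not** emulate: probe-level array artefacts
(cross-hybridisation, saturation), combinatorial regulation (each
target has one parent), feedback, TF–TF coupling, batch effects, and
condition-dependent network rewiring. Passing plant-and-recover tests
therefore demonstrates correctness of the inference machinery under
the model's assumptions, not robustness of those assumptions on real
microarray data.

The genome fixture plants one consensus instance of each of three
strong retinoid-receptor-like matrices (direct/inverted AGGTCA repeats,
count ratio 30:1) in a 400-bp random window, arranged as three
well-separated clusters, and lays TF-binding sites inside target
promoters for every planted edge except those of one deliberately
unbound TF (the negative control for the promoter filter). The qPCR
generator emits Ct = base − log2(fold) + N(0, σ_ct) with σ_ct = 0.1,
three replicates, and the reference gene forced to fold 1. The homolog
generator mutates a 118-base master sequence at per-species divergences
(0 / 0.02 / 0.05 / 0.15 / 0.30 for the five default species,
transition:transversion 2:1), substitution-only so the copies are
already aligned, and plants coordinates realising one inside, two
downstream, one (minus-strand) upstream and one distal homolog.

## Numerical conventions and edge cases

Coordinates are 0-based half-open everywhere inside the package (BED
convention); the CLI prints 1-based positions. Gene symbols are
case-sensitive with no aliasing. MI is reported in nats. Constant
vectors give MI 0 with a warning; empty regulons give Fisher p = 1;
an empty signature intersection is a valid empty result, not an error.
All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`-derived child streams, so every pipeline
product — including simulated files on disk — is byte-reproducible
from its seed.

## Problem sizes

The default test and acceptance runs use the desk-scale conditions
above (3 × 264 probes × 200 samples for the discovery chain; 1000 null
probes and ≥ 1000 independent null MI pairs for the calibrations;
n = 2000 for the Gaussian MI check; 100 random 10-node graphs and 1000
interval pairs for the oracle equivalences). These sizes were chosen so
the complete suite documents the method's behaviour in minutes on a
single CPU while keeping every statistical check adequately powered.
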