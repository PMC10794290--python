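# Methods

## Model

Each assayed site *i* carries read counts **X**<sub>i</sub> =
(R<sub>i</sub>, M<sub>i</sub>, X<sub>1i</sub>, X<sub>2i</sub>) over the
reference allele, the dominant alternative allele and the two remaining
alleles, with K<sub>i</sub> = R + M + X₁ + X₂. Conditional on the
alternative allele frequency θ<sub>i</sub> and a per-read error probability
e<sub>i</sub>,

X<sub>i</sub> | θ<sub>i</sub> ~ Multinomial(K<sub>i</sub>; p_R, p_M, e/3, e/3),
 p_R = θe/3 + (1−θ)(1−e), p_M = θ(1−e) + (1−θ)e/3.

The error mechanism is symmetric: a misread base lands on each of the three
wrong alleles with probability e/3. Reads are assumed independent given θ;
the model knows nothing about strand, position in read, or mapping
ambiguity beyond what the mean qualities encode.

A two-group prior completes the model: θ = 0 with probability π₀, else
θ ~ g(·). The local false discovery rate at site *i* is the posterior null
probability

ψ<sub>i</sub> = π₀·P(X|θ=0) / [π₀·P(X|θ=0) + (1−π₀)·P(X|θ>0)],

with P(X|θ>0) approximated by the equal-weight average of the fixed-θ
likelihood over an atom set {θ<sub>l</sub>} — the empirical distribution of
allele frequencies at suspected mutant sites. The form of g(·) is never
parameterised; fitting, e.g., a beta family was deliberately avoided in
favour of the nonparametric atom set.

## Error rates from qualities

Each allele class U gets Q<sup>U</sup> = (BQ<sup>U</sup>+MQ<sup>U</sup>)/2;
the site quality Q is the count-weighted mean over classes with at least
one read; e = 10^(−Q/10), clamped to [10⁻¹⁰, 0.75]. The lower clamp keeps
log(e/3) finite; the upper one refuses to assert that the three wrong
alleles are jointly likelier than the right one. A config switch replaces
all per-site rates with a global e = 0.01 (Phred 20), which barely changes
call sets in practice and speeds up nothing here (the vectorised pass is
indifferent), but mirrors common caller defaults.

Zero-count classes may carry meaningless qualities in count-table output;
they receive zero weight and never enter the mean.

## The iterative fit

Starting values: π₀⁽⁰⁾ = fraction of sites with M = 0 (configurable);
atoms = {M/K at every site with M > 0} in "empirical" mode, or N = 1000
seeded uniform(0,1] draws in the "uniform" and "uniform/empirical" modes.
Each iteration:

1. score every site: ψ from the current (π₀, atoms), each site using its
   own e<sub>i</sub>;
2. tentative calls = {i : ψ<sub>i</sub> ≤ τ} (log₁₀-scale comparison,
   boundary inclusive);
3. π₀ ← 1 − |tentative calls| / p;
4. atoms ← empirical AFs of tentative calls with M > 0 (skipped entirely in
   "uniform" mode; kept unchanged if the update would be empty).

Stop when |Δπ₀| < ε (default 0.001) or after max_iter = 100 iterations
(non-convergence is flagged, results still returned). The iteration order
(score → call → update π₀ → update atoms) is this package's choice; the
per-iteration trajectory of (π₀, atom count, call count) is recorded so the
fit is auditable. On data with clearly separated variants the loop
converges in 2–4 iterations.

The final calls are the last tentative set intersected with the
post-filters M/K ≥ AFT (0.01) and K ≥ DPT (10). Post-filters run after the
loop by default: applying them before the fit would redefine what π₀
estimates (the non-mutant proportion of the filtered rather than the
original site universe). A switch moves them into pre-processing for users
who want that semantics.

The atom set keeps duplicates with weight 1/s — it is exactly the empirical
distribution, not its support. A site being scored is not excluded from the
atom set when it contributed to it; at realistic atom counts (s ≫ 1) the
self-contribution is O(1/s) and removing it would complicate the vectorised
pass for no observable gain.

## Decision rule

With loss l_I for a false call and l_II for a missed variant, the posterior
expected loss of decision δ at one site is δ·l_I·ψ + (1−δ)·l_II·(1−ψ), so
calling is optimal exactly when l_I·ψ ≤ l_II·(1−ψ), i.e. ψ ≤
l_II/(l_I+l_II). `LossSpec` implements this risk-minimizing threshold (an
exhaustive-enumeration test over all decision vectors confirms optimality);
raising the type-I loss therefore makes calling harder, as it must. In
routine use the threshold τ is supplied directly (`--lfdr-threshold`),
which takes precedence over the loss pair.

## Numerical choices

All likelihood arithmetic is in natural-log space with the 0·log 0 = 0
convention for zero-count classes; mixture averages use log-sum-exp;
posterior probabilities are formed as log ψ = a − logaddexp(a, b) with
a = ln π₀ + log P₀, b = ln(1−π₀) + log P₁, exact at π₀ ∈ {0, 1}. This is a
correctness requirement, not an optimisation: thresholds of 10⁻³⁰⁰ and
likelihood ratios of 10⁻¹⁰⁰⁰ arise in routine use and are far outside
linear double range. Output VCFs therefore carry `L10LFDR` (log₁₀ ψ) as the
authoritative score; `LFDR` is the clamped linear value and renders as 0
below ~10⁻³⁰⁸. Atoms at θ = 1 with e = 0 give −∞ per-atom log-likelihoods
for any R > 0; log-sum-exp handles them (the atom contributes nothing). If
both hypotheses have zero likelihood the result is flagged undefined and
never called. The genome-scale pass evaluates the (sites × atoms) matrix in
blocks of 512 sites to bound memory; a 20,000-site table with ~13,000
initial atoms fits comfortably and completes in seconds per iteration.

Dominant-allele ties in `select_alleles` break by higher mean class quality,
then alphabetical base order — deterministic and documented. Sites with a
non-ACGT reference base are dropped with a warning rather than guessed.

## Prioritization

Re-scoring an external caller's list is a single estimate-then-score pass:
π₀ = (p − n_called)/p over the p assayed (pre-filtered) sites, atoms = the
empirical AFs of the called sites with M > 0, then one LFDR pass over the
called sites only, ranked ascending by log₁₀ ψ with (chrom, pos)
tie-breaks. The caller's ALT allele is trusted for identity; counts come
from the table, and when the caller's ALT is not the table's dominant
alternative the ALT's own count is scored as M (logged). Thresholding the
ranking is a subset operation, so sensitivity against any truth set cannot
increase — the point is that error-driven false positives (few alternative
reads at high depth) receive ψ near 1 and are removed first, while true
variants at AFs the atom set covers sit at ψ ≈ 0.

## The simulator

`simulate_dataset` draws θ from the two-group prior and counts from the
exact model multinomial, then emits a bam-readcount-dialect table whose
qualities invert the error model (BQ = MQ = Q = −10·log₁₀ e on every
class), so parsing the text back recovers both the counts and e exactly.
Defaults are the package's flagship study conditions: p = 20,000 sites,
π₀ = 0.95, fixed depth 100, e = 0.01, and a bimodal g(·) with equal-weight
components — truncated normal(0.5, 0.05) for heterozygous sites and
1 − |normal(0, 0.02)| for homozygous ones — the shape germline AFs take in
targeted panels. The component shapes and spreads are this package's
choice; only the concentration near 0.5 and 1.0 is essential.

What the simulator does *not* emulate: strand bias, mapping artifacts,
quality miscalibration (beyond an optional per-class quality jitter),
indels, correlated errors, and contamination. Passing tests on synthetic
data therefore demonstrate correctness of the inference machinery under
the model's own assumptions, not robustness to real-data artifact modes —
that is what the BQ/MQ pre-filters (defaults 20/30) are for, and why
synthetic runs disable them: simulated reads carry uniform calibrated
qualities, so there are no low-quality artifacts to exclude, and with
e = 0.01 the calibrated quality (Q = 20) sits below the default MQ floor
by construction.

A generative e of exactly 0 (useful for deterministic limit checks) has no
finite Phred representation; the simulator emits the conventional quality
cap of 93 in that case.

## Problem sizes

The test suite runs the full pipeline at p = 2,000 for unit-level checks
and p = 20,000 (the flagship conditions) for end-to-end recovery,
mode-agreement and prioritization checks; exact-arithmetic oracle
comparisons enumerate all count compositions up to K = 15. These sizes make
the whole suite complete in about half a minute while leaving the binomial
error of every stochastic assertion far below its tolerance.

## Known limitations

- Germline, single-sample, SNV-only: no indels, no tumor/normal pairing,
  no joint calling across replicates (conflicting calls between replicates
  are out of scope).
- π₀ estimation is tied to the call threshold; extremely lax τ inflates the
  called fraction and biases π₀ low. Stringent thresholds (10⁻²⁰ and below)
  estimate π₀ best.
- The uniform g-mode never updates its atoms and is known to separate
  mutant from non-mutant sites less sharply; it is retained for comparison.
- Precision/sensitivity evaluation matches on (chrom, pos, alt) by default;
  position-only matching is an explicit relaxation flag.
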