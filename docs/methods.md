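# Methods

## The copying model

The endogenous male X chromosome is treated as a mosaic of segments
copied from a panel of n reference haplotypes typed at L biallelic
markers. The hidden chain over copying states uses the uniform rate
matrix Q with every off-diagonal entry equal to q and diagonal
−(n−1)q, so the transition matrix over a genetic distance r is
exp(Q·r), which for this Q has the two-value closed form used
throughout (stay = 1/n + (1−1/n)e^(−nqr), switch = (1−e^(−nqr))/n). The
closed form is exact, and it is what makes the forward recursion O(n)
per site instead of O(n²): the transition operator is switch·J +
(stay−switch)·I, so a forward update is a scalar broadcast plus an
elementwise product. The inner loop is compiled with numba; the update
is also exposed in pure numpy (`hmm.forward_pass`) and the two are
cross-checked against a dense matrix-vector recursion in the tests.

Only covered markers enter the recursion. Because the chain is Markov
with a uniform rate matrix, skipping uncovered markers and transitioning
over the summed map distance is exact, not an approximation.

The initial state distribution is uniform 1/n, consistent with every
haplotype having equal prior copying probability.

Emissions marginalize a two-layer mixture per covered marker: the copied
allele passes through a mis-copying error ε_r (mutation since the common
ancestor, gene conversion, panel errors), then each aligned sequence is
contaminant with probability c — drawing its allele from the contaminant
population's alternative-allele frequency p_l — or endogenous otherwise,
and is flipped with the per-base error ε_g either way. Read counts are
binomial in the resulting per-sequence alternative probability. The
binomial coefficient is retained (it is constant in both the state and
c) so reported log-likelihoods are true log-probabilities. Since each
marker is biallelic, the n per-state emissions take at most two values;
these are computed per site and *selected* by the copied allele rather
than blended linearly — the blended form e₀ + (e₁−e₀)·h loses ~5
significant digits when e₁ ≪ e₀ and visibly breaks agreement with the
path-enumeration oracle.

With a single covered marker (or widely spaced markers) the model
reduces to a two-component mixture over the endogenous allele with the
panel allele frequency as prior — the "two-consensus" limit — which is
asserted exactly in the tests.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| c | contamination fraction | estimated in [0, 0.5] | above 0.5 the roles of endogenous and contaminant become unidentifiable |
| ε_g | per-base error (sequencing error, post-mortem damage, mismapping) | estimated from data | pooled mismatch fraction at non-marker positions within 5 bp of a panel marker; floored at 10⁻⁶ when no mismatch is seen |
| ε_r | mis-copying error per marker | 10⁻³ | keeps the copying path from being broken by isolated mismatches while contributing little to the contamination signal |
| q | copying jump rate per Morgan per target haplotype | 300 | standard copying-model jump scale; transitions saturate to the stationary distribution over a few tenths of a centimorgan for panels of tens of haplotypes |
| min_bq | minimum base quality counted | 20 (Phred) | conventional aDNA filter; mapping quality (>30 recommended) is filtered upstream when the pileup is generated |

## Estimation and uncertainty

ℓ(c) is maximized with bounded L-BFGS-B from three starting points
(0.02, 0.1, 0.3); agreement with a dense grid search (step 10⁻³, then
10⁻⁵ refinement) is asserted within 2×10⁻³ in the tests. For an interior
optimum the standard error is (−ℓ″(ĉ))^(−1/2) with a central-difference
second derivative (relative step 10⁻⁴, absolute floor 10⁻⁶ — a balance
of truncation against cancellation for log-likelihoods of magnitude
10³–10⁶) and the 95% CI is ĉ ± 1.96·se clipped to [0, 0.5]. When
ĉ ≤ 10⁻⁴ the model's boundary at c = 0 invalidates the Fisher
construction (the first derivative need not vanish), so the interval is
instead {c : L(c) ≥ e^(−1.96²/2)·L(ĉ)} — the 14.7% likelihood region —
found by quadratic interpolation of the one-sided derivatives at 0 and
then verified by bisection on ℓ itself. The threshold is computed as
e^(−z²/2) with z = 1.96 rather than hard-coded, keeping the two CI
constructions mutually consistent (they agree to within a few percent
for optima just inside the boundary tolerance, which is also tested). A
saturated estimate at the 0.5 bound mirrors the likelihood-region
construction there and warns. Estimates from fewer than 100 covered
markers are flagged low-confidence.

## What the synthetic data emulate

`synthetic_panel` draws marker frequencies from Beta(0.8, 0.8) truncated
to [0.05, 0.95], mimicking a common-variant (MAF > 5%) panel, and places
markers uniformly on a 1.8-Morgan map (roughly the human X). Haplotype
alleles are generated through a latent-uniform copula: each haplotype
carries a uniform variate refreshed between adjacent markers with
probability 0.1, and the allele is 1 iff the latent falls below p_l.
This keeps the per-marker marginal exactly Bernoulli(p_l) (so empirical
panel frequencies track the generating frequencies, asserted at r > 0.9)
while inducing strong linkage between neighbouring markers. A simple
allele-flipping Markov chain was rejected because it cannot satisfy the
marginal-frequency requirement. Population frequency columns diverge
from the base frequencies by the Balding–Nichols model
Beta(p(1−F)/F, (1−p)(1−F)/F).

Two generative modes are used deliberately:

* **Under the model** — a copying path through the panel itself, read
  counts emitted exactly as the emission model assumes (the truth is the
  path, so no ε_r enters the generator). This isolates estimator
  correctness: calibration, CI coverage, and pseudohaploid robustness
  are measured here.
* **Mixed sources** — an endogenous individual built as a mutated
  (1% allele flips) copying mosaic and a contaminant individual drawn
  from a drifted population column, neither present in the panel, each
  "sequenced" deeply (10×) and then mixed at the count level at
  fraction c with a Poisson target depth. Sources are deep so that the
  mixture is a faithful emulation of mixing two full-depth alignment
  files; at shallow source depth the missing-marker fallback
  (substituting the other source's allele fraction) materially distorts
  the realized contamination fraction. This mode exhibits the realistic
  attenuation of ĉ at high contamination.

Default study conditions for the simulation experiments: n = 50
haplotypes, L = 20 000 markers, 0.5× mean coverage, ε_g = 0.01 (a
realistic aggregate of sequencing error plus residual aDNA damage),
25–100 replicates per scenario. These sizes are the package's chosen
desk-scale study design; variance at these sizes is small enough that
mean biases of ~0.005 are resolvable.

What the generator does **not** emulate: strand-specific C→T damage
profiles (damage is folded into ε_g as an aggregate error), read-length
and fragmentation structure, reference bias in alignment, panel phasing
or genotyping errors beyond ε_r, and linkage between the contaminant
individual's markers (contaminant haplotypes in "freqs" mode are
LD-free draws). Passing tests therefore demonstrate correctness of the
inference machinery and the direction/magnitude of the model's known
biases under idealized reads, not performance on damaged empirical
libraries.

## Numerical and edge-case choices

* Forward scaling: the forward vector is normalized to sum 1 at every
  site and log scale factors accumulated; no underflow for any chain
  length.
* Sites with depth 0 are absent from the count table; emission of a
  zero-depth site is a domain error rather than silently 1.
* Bases matching neither panel allele are discarded and tallied (the
  emission model is strictly biallelic); treating them as alternative
  would conflate damage-induced third alleles with contamination.
* The pileup decoder strips start/end marks, indel spans, deletion
  placeholders and reference skips, and aligns qualities to real base
  calls only; `N` bases are not counted as mismatches in the error-rate
  tallies.
* Monomorphic flanking window for ε_g: 5 bp on either side of each
  marker, excluding marker positions themselves.
* Boundary tolerance for "estimate at zero": 10⁻⁴ in c — a floating
  point realization of "the MLE is on the boundary".
* `pseudohaploid` keeps the alternative read with probability
  n_alt/depth, which is exactly a uniform choice among the site's reads.
* Panels carry no pseudoautosomal markers; PAR1/PAR2 should be excluded
  when building real panels since they are diploid in males and would
  inflate apparent heterozygosity. The VCF panel builder trusts its
  input marker list.

## Known limitations

* Contamination above ~20% is systematically underestimated (the
  copying model partially absorbs a contaminant haplotype); the
  mixed-source tests pin the direction and rough magnitude of this
  attenuation rather than correcting it.
* A strongly mis-specified contaminant ancestry (intercontinental-scale
  frequency divergence) biases ĉ downward, never upward — conservative
  for screening, but moderately contaminated samples can look cleaner
  than they are.
* Single-source contamination only; ε_r and q are fixed, not estimated.
* Female (diploid) samples are out of scope.
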