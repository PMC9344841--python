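# xcontam

Contamination estimation for male X-chromosome ancient DNA from
low-coverage sequence data.

Estimating how much of an ancient DNA (aDNA) library comes from modern
contaminating individuals is a mandatory quality-control step before any
population-genetic analysis. For male samples, the single-copy X chromosome
gives a clean signal: a haploid chromosome cannot be heterozygous, so any
systematic mismatch between aligned sequences and the true endogenous
haplotype betrays contamination. Classical estimators need at least two
sequences per site to detect that mismatch, which discards almost all data
at low coverage — with Poisson depth at 0.1× mean coverage only about
0.47% of sites carry two or more sequences. `xcontam` instead models the
endogenous X haplotype as a mosaic copy of a reference haplotype panel
(a Li & Stephens copying hidden Markov model), which lets *every* covered
site contribute to the likelihood, including sites covered by a single
sequence only.

## Model

Hidden states are the n haplotypes of a reference panel; at marker l the
chain copies haplotype s_l. Transitions over a genetic-map gap r (Morgans)
come from exponentiating a uniform rate matrix with off-diagonal rate
q = 300:

    stay   = 1/n + (1 − 1/n) e^(−n q r)
    switch = (1/n) (1 − e^(−n q r))

Emissions are a two-layer mixture. The copied allele is transmitted with
mis-copying error ε_r = 10⁻³:

    P(t_l = 1 | s_l = i) = (1 − ε_r) 1{i_l = 1} + ε_r 1{i_l = 0}

and each aligned sequence is contaminant with probability c, drawing its
allele from the contaminant population frequency p_l, or endogenous
otherwise, with per-base error ε_g on either source:

    P(alt | t_l = 0) = (1 − c) ε_g + c (p_l (1 − ε_g) + (1 − p_l) ε_g)
    P(alt | t_l = 1) = (1 − c)(1 − ε_g) + c (p_l (1 − ε_g) + (1 − p_l) ε_g)

The read counts (c_l0 reference, c_l1 alternative) at a covered marker are
Binomial(c_l0 + c_l1, p_alt(s_l)). A scaled forward algorithm yields the
log-likelihood ℓ(c); the contamination fraction is estimated by bounded
L-BFGS-B over c ∈ [0, 0.5]. Standard errors come from the observed Fisher
information; when the MLE sits at c = 0 the 95% interval is instead the
set of c whose likelihood exceeds e^(−1.96²/2) ≈ 14.7% of the maximum.
ε_g is estimated from monomorphic sites flanking the panel markers.

## Worked example

Simulate a 50-haplotype panel of 20 000 common X markers, a sample at
0.5× coverage with 10% contamination, and re-estimate:

```sh
xcontam simulate --n 50 --sites 20000 --coverage 0.5 \
    --contamination 0.1 --seed 7 --out demo
xcontam estimate --pileup demo/sim.pileup --panel demo/panel.tsv \
    --contaminant-pop CEU --out demo_est
```

prints

```
INFO xcontam: estimated eps_g = 0.0104811 from flanking sites
c_hat: 0.09866909576200594
se: 0.009993320152168115
ci_low: 0.07908218826375643
ci_high: 0.11825600326025545
method: fisher
loglik: -4594.529740692269
n_sites: 7903
...
```

The per-base error rate (truth 0.01) is recovered from the flanking
monomorphic sites, and the contamination estimate ĉ = 0.099 (95% CI
0.079–0.118) recovers the simulated 10% from the 7 903 covered markers.
The same record is written to `demo_est/estimate.json`. Real data enter
through `samtools mpileup` output (mapping quality should be filtered to
\>30 when generating the pileup; bases below quality 20 are dropped here)
plus a panel built from a phased VCF with
`xcontam.build_panel_from_vcf` (biallelic SNVs, MAF > 5% recommended).

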