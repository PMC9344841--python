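"""Haplotype-copying HMM: transitions, emissions, scaled forward likelihood.

The endogenous male X chromosome is modeled as a mosaic copy of the n
haplotypes in a reference panel (a Li & Stephens copying model).  The
hidden state at marker l is the haplotype currently being copied; the
observation is the pair of read counts (n_ref, n_alt) at that marker,
emitted through a two-layer mixture: the copied allele is mis-copied with
rate ``eps_r``, and each aligned sequence is contaminant with probability
``c`` (drawing its allele from the contaminant population frequency p_l)
or endogenous otherwise, with a per-base error ``eps_g`` on either source.
The log-likelihood as a function of c is the quantity maximized downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import gammaln

from .io import ReadCountTable, ReferencePanel

__all__ = [
    "ModelParams",
    "transition_probs",
    "genotype_prob",
    "p_alt_given_genotype",
    "site_emission",
    "forward_pass",
    "ForwardModel",
    "forward_loglik",
]


@dataclass
class ModelParams:
    """Parameters of the contamination HMM.

    c : contamination fraction, in [0, 0.5].
    eps_g : per-base error rate (sequencing error + aDNA damage + mismapping).
    eps_r : mis-copying error rate of the Li & Stephens layer; default 1e-3.
    q : copying jump rate per Morgan per target haplotype; default 300.
    contaminant_pop : panel population label whose allele frequencies proxy
        the contamination source.
    """

    c: float
    eps_g: float
    eps_r: float = 1e-3
    q: float = 300.0
    contaminant_pop: str = "ALL"

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 0.5:
            raise ValueError(f"c={self.c} outside [0, 0.5]")
        if not 0.0 <= self.eps_g < 0.5:
            raise ValueError(f"eps_g={self.eps_g} outside [0, 0.5)")
        if not 0.0 <= self.eps_r < 0.5:
            raise ValueError(f"eps_r={self.eps_r} outside [0, 0.5)")
        if self.q <= 0:
            raise ValueError(f"q={self.q} must be positive")


def transition_probs(r: float, n: int, q: float) -> tuple[float, float]:
    """Stay/switch probabilities of the copying chain over map distance r.

    The transition matrix is exp(Q r) for the uniform rate matrix with
    off-diagonal q and diagonal -(n-1)q, which has the closed form

        stay   = 1/n + (1 - 1/n) exp(-n q r)
        switch = (1/n) (1 - exp(-n q r))

    so that stay + (n-1) switch = 1.

    Parameters
    ----------
    r : genetic distance in Morgans (>= 0).
    n : number of reference haplotypes (>= 2).
    q : jump rate per Morgan per target haplotype.
    """
    if r < 0:
        raise ValueError(f"map distance r={r} must be non-negative")
    e = np.exp(-n * q * r)
    stay = 1.0 / n + (1.0 - 1.0 / n) * e
    switch = (1.0 - e) / n
    return float(stay), float(switch)


def genotype_prob(hap_allele: int, eps_r: float) -> tuple[float, float]:
    """P(endogenous genotype = 0 / 1 | copied haplotype carries hap_allele).

    The copied allele is transmitted faithfully with probability 1 - eps_r
    and flipped with probability eps_r.
    """
    if hap_allele == 0:
        return 1.0 - eps_r, eps_r
    return eps_r, 1.0 - eps_r


def p_alt_given_genotype(t: int, c: float, eps_g: float, p: float) -> float:
    """P(a single aligned sequence supports the alternative allele | genotype t).

    A sequence is contaminant with probability c, in which case its allele
    follows the contaminant population frequency p; otherwise it reflects
    the endogenous genotype t.  Either way it is flipped with the per-base
    error eps_g.
    """
    contam = p * (1.0 - eps_g) + (1.0 - p) * eps_g
    if t == 0:
        return (1.0 - c) * eps_g + c * contam
    return (1.0 - c) * (1.0 - eps_g) + c * contam


def site_emission(
    n_ref: int,
    n_alt: int,
    hap_alleles: np.ndarray,
    params: ModelParams,
    p: float,
) -> np.ndarray:
    """Emission probability of the read counts under each of the n states.

    Marginalizes the latent endogenous genotype over the copying-error
    layer, then evaluates the binomial probability of ``n_alt`` alternative
    reads out of ``n_ref + n_alt`` at the resulting per-sequence
    alternative probability.  The binomial coefficient is included, so
    values are true probabilities.
    """
    depth = n_ref + n_alt
    if depth < 1:
        raise ValueError("site_emission requires depth >= 1; pre-filter empty sites")
    hap = np.asarray(hap_alleles, dtype=np.float64)
    p_t1 = hap * (1.0 - params.eps_r) + (1.0 - hap) * params.eps_r
    pa0 = p_alt_given_genotype(0, params.c, params.eps_g, p)
    pa1 = p_alt_given_genotype(1, params.c, params.eps_g, p)
    p_alt = pa0 * (1.0 - p_t1) + pa1 * p_t1
    comb = np.exp(gammaln(depth + 1) - gammaln(n_alt + 1) - gammaln(n_ref + 1))
    return comb * p_alt**n_alt * (1.0 - p_alt) ** n_ref


def forward_pass(
    emissions: np.ndarray,
    stay: np.ndarray,
    switch: np.ndarray,
    init: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Scaled forward recursion for the uniform-rate copying chain.

    ``emissions`` is (S, n); ``stay``/``switch`` are the S-1 per-gap
    transition values; ``init`` the initial state distribution.  Because the
    transition matrix is switch * J + (stay - switch) * I, the update
    collapses to O(n) per site:

        alpha' = e * (switch * sum(alpha) + (stay - switch) * alpha)

    The forward vector is normalized to sum 1 at every site and the log
    scale factors accumulated, so no underflow occurs for any chain length.

    Returns (log-likelihood, final normalized forward vector).
    """
    a = init * emissions[0]
    norm = a.sum()
    if not norm > 0 or not np.isfinite(norm):
        raise FloatingPointError("non-finite or zero likelihood at marker 0")
    loglik = np.log(norm)
    a = a / norm
    for s in range(1, emissions.shape[0]):
        a = emissions[s] * (switch[s - 1] + (stay[s - 1] - switch[s - 1]) * a)
        norm = a.sum()
        if not norm > 0 or not np.isfinite(norm):
            raise FloatingPointError(f"non-finite or zero likelihood at marker {s}")
        loglik += np.log(norm)
        a = a / norm
    return float(loglik), a


class ForwardModel:
    """Pre-compiled forward log-likelihood as a function of c.

    Extracts the covered markers once (haplotype alleles, counts, binomial
    coefficients, contaminant frequencies, map gaps between consecutive
    covered markers) so that repeated likelihood evaluations during
    optimization stay cheap.  Because each marker is biallelic, the n
    emission values per site take at most two distinct values (one per
    copied allele), which are computed site-wise and broadcast into the
    recursion.

    Transitions are computed between consecutive *covered* markers with
    the summed intervening map distance; this is exact for the uniform
    rate matrix by the Markov property.
    """

    def __init__(
        self,
        counts: ReadCountTable,
        panel: ReferencePanel,
        contaminant_pop: str,
        eps_g: float,
        eps_r: float = 1e-3,
        q: float = 300.0,
    ) -> None:
        if counts.n_sites < 1:
            raise ValueError("empty read-count table")
        if contaminant_pop not in panel.pop_freqs:
            raise KeyError(
                f"population {contaminant_pop!r} not in panel; available: "
                f"{sorted(panel.pop_freqs)}"
            )
        idx = counts.marker_index
        if idx[-1] >= panel.n_markers:
            raise ValueError("read-count table references markers beyond the panel")
        self.n = panel.n_hap
        self.n_sites = counts.n_sites
        self.eps_g = float(eps_g)
        self.eps_r = float(eps_r)
        self.q = float(q)
        self.hap = panel.haplotypes[:, idx].T.astype(np.float64)  # (S, n)
        self.p = panel.pop_freqs[contaminant_pop][idx]
        self.k_alt = counts.n_alt.astype(np.float64)
        self.k_ref = counts.n_ref.astype(np.float64)
        depth = self.k_alt + self.k_ref
        self.log_comb = (
            gammaln(depth + 1) - gammaln(self.k_alt + 1) - gammaln(self.k_ref + 1)
        )
        gaps = np.diff(panel.genetic_map[idx])
        e = np.exp(-self.n * self.q * gaps)
        self.stay = 1.0 / self.n + (1.0 - 1.0 / self.n) * e
        self.switch = (1.0 - e) / self.n

    def _site_emission_pair(self, c: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-site emission for a state copying allele 0 vs allele 1."""
        contam = self.p * (1.0 - self.eps_g) + (1.0 - self.p) * self.eps_g
        pa_t0 = (1.0 - c) * self.eps_g + c * contam
        pa_t1 = (1.0 - c) * (1.0 - self.eps_g) + c * contam
        # copying-error layer: genotype is the copied allele w.p. 1 - eps_r
        pa_hap0 = (1.0 - self.eps_r) * pa_t0 + self.eps_r * pa_t1
        pa_hap1 = self.eps_r * pa_t0 + (1.0 - self.eps_r) * pa_t1
        comb = np.exp(self.log_comb)
        e0 = comb * pa_hap0**self.k_alt * (1.0 - pa_hap0) ** self.k_ref
        e1 = comb * pa_hap1**self.k_alt * (1.0 - pa_hap1) ** self.k_ref
        return e0, e1

    def emissions(self, c: float) -> np.ndarray:
        """Full (S, n) emission matrix at contamination rate c."""
        e0, e1 = self._site_emission_pair(c)
        return np.where(self.hap > 0.5, e1[:, None], e0[:, None])

    def loglik(self, c: float) -> float:
        """Scaled forward log-likelihood at contamination rate c."""
        e0, e1 = self._site_emission_pair(c)
        ll, bad = _forward_kernel(e0, e1, self.hap, self.stay, self.switch)
        if bad >= 0:
            raise FloatingPointError(f"non-finite or zero likelihood at marker {bad}")
        return float(ll)


@njit(cache=True)
def _forward_kernel(e0, e1, hap, stay, switch):  # pragma: no cover - numba
    S, n = hap.shape
    a = np.empty(n)
    norm = 0.0
    for i in range(n):
        a[i] = (e1[0] if hap[0, i] > 0.5 else e0[0]) / n
        norm += a[i]
    if not norm > 0.0 or not np.isfinite(norm):
        return 0.0, 0
    ll = np.log(norm)
    for i in range(n):
        a[i] /= norm
    for s in range(1, S):
        sw = switch[s - 1]
        ds = stay[s - 1] - sw
        norm = 0.0
        for i in range(n):
            e = e1[s] if hap[s, i] > 0.5 else e0[s]
            a[i] = e * (sw + ds * a[i])
            norm += a[i]
        if not norm > 0.0 or not np.isfinite(norm):
            return 0.0, s
        ll += np.log(norm)
        for i in range(n):
            a[i] /= norm
    return ll, -1


def forward_loglik(
    counts: ReadCountTable,
    panel: ReferencePanel,
    params: ModelParams,
) -> tuple[float, int]:
    """HMM log-likelihood of the read counts over covered markers.

    Uses a uniform 1/n initial state distribution, closed-form stay/switch
    transitions between consecutive covered markers, binomial emissions,
    and per-site scaling.  Returns (log-likelihood, number of covered
    markers used).
    """
    fm = ForwardModel(
        counts,
        panel,
        contaminant_pop=params.contaminant_pop,
        eps_g=params.eps_g,
        eps_r=params.eps_r,
        q=params.q,
    )
    return fm.loglik(params.c), fm.n_sites
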