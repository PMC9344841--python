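"""Model-faithful synthetic data: panels, copy paths, read counts, mixing.

Two generative modes are provided.  "Under-the-model" simulation draws a
copying path through the panel itself and emits read counts exactly as the
emission model assumes; it is the right tool for correctness and
calibration checks.  "Mixed-source" simulation builds an endogenous and a
contaminant haplotype that are *not* panel members (a mutated copying
mosaic, and an individual drawn from drifted population frequencies) and
mixes their reads at the count level, emulating the mixing of two
alignment files from different individuals.

Population allele frequencies diverge from the panel base frequencies via
the Balding-Nichols model: p_pop ~ Beta(p (1-F)/F, (1-p)(1-F)/F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import ReadCountTable, ReferencePanel

logger = logging.getLogger(__name__)

__all__ = [
    "CopyPath",
    "SimConfig",
    "synthetic_panel",
    "simulate_copy_path",
    "simulate_read_counts",
    "mix_sources",
    "pseudohaploid",
    "frac_depth_ge2",
    "sample_individual_haplotype",
    "reads_from_haplotype",
    "write_synthetic_pileup",
]

_BASES = np.array(list("ACGT"))


@dataclass
class CopyPath:
    """Latent copying path: the reference haplotype copied at each marker."""

    states: np.ndarray  # length L, values in [0, n)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)


@dataclass
class SimConfig:
    """Read-count simulation settings.

    coverage : mean depth per panel marker (Poisson rate).
    c_true : fraction of sequences originating from the contaminant.
    eps_g : per-base error applied to both endogenous and contaminant reads.
    contaminant_pop : panel population whose frequencies generate
        contaminant alleles.
    seed : RNG seed.
    """

    coverage: float = 0.5
    c_true: float = 0.0
    eps_g: float = 0.01
    contaminant_pop: str = "CEU"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.c_true <= 1.0:
            raise ValueError("c_true must lie in [0, 1]")
        if not 0.0 <= self.eps_g < 0.5:
            raise ValueError("eps_g must lie in [0, 0.5)")


def synthetic_panel(
    n: int = 50,
    L: int = 1000,
    seed: int = 0,
    map_length_morgan: float = 1.8,
    freq_populations: Mapping[str, float] | None = None,
    linkage_refresh: float = 0.1,
) -> ReferencePanel:
    """Generate a random reference panel with realistic allele frequencies.

    Marker frequencies are Beta(0.8, 0.8) truncated to [0.05, 0.95],
    mimicking a common-variant (MAF > 5%) panel.  Haplotypes are drawn with
    linkage along the chromosome: each haplotype carries a latent uniform
    that is refreshed between adjacent markers with probability
    ``linkage_refresh`` and the allele at marker l is 1 iff the latent is
    below p_l, so marginals match p_l exactly while neighbouring markers
    are strongly correlated.  Markers are uniformly spaced on a genetic map
    of total length ``map_length_morgan`` (default 1.8, roughly the human X).

    ``freq_populations`` maps population label -> Balding-Nichols F used to
    drift that population's frequency column away from the base
    frequencies (F = 0 reproduces them exactly).  Default: {"CEU": 0.0}.
    """
    if n < 2 or L < 1:
        raise ValueError("need n >= 2 haplotypes and L >= 1 markers")
    rng = np.random.default_rng(seed)
    if freq_populations is None:
        freq_populations = {"CEU": 0.0}

    freqs = np.empty(L)
    remaining = np.arange(L)
    while remaining.size:
        draw = rng.beta(0.8, 0.8, size=remaining.size)
        ok = (draw >= 0.05) & (draw <= 0.95)
        freqs[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]

    # latent-uniform copula: refresh w.p. linkage_refresh between markers
    fresh_vals = rng.random((n, L))
    refresh = rng.random((n, L)) < linkage_refresh
    refresh[:, 0] = True
    # carry the last refreshed value forward along each haplotype
    idx = np.where(refresh, np.arange(L), 0)
    idx = np.maximum.accumulate(idx, axis=1)
    u = np.take_along_axis(np.where(refresh, fresh_vals, 0.0), idx, axis=1)
    haps = (u < freqs).astype(np.uint8)

    spacing = max(1, int(150_000_000 / (L + 1)))
    positions = spacing * np.arange(1, L + 1, dtype=np.int64)
    genetic_map = np.linspace(0.0, map_length_morgan, L)

    pop_freqs: dict[str, np.ndarray] = {}
    for pop, F in freq_populations.items():
        pop_freqs[pop] = balding_nichols(freqs, F, rng)

    pair_idx = rng.integers(0, 4, size=L)
    offset = rng.integers(1, 4, size=L)
    ref_allele = _BASES[pair_idx]
    alt_allele = _BASES[(pair_idx + offset) % 4]

    return ReferencePanel(
        haplotypes=haps,
        chrom="X",
        positions=positions,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        genetic_map=genetic_map,
        pop_freqs=pop_freqs,
    )


def balding_nichols(
    base_freqs: np.ndarray,
    F: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drift allele frequencies by the Balding-Nichols model with divergence F."""
    if F < 0 or F >= 1:
        raise ValueError("F must lie in [0, 1)")
    if F == 0:
        return np.array(base_freqs, copy=True)
    a = base_freqs * (1.0 - F) / F
    b = (1.0 - base_freqs) * (1.0 - F) / F
    return rng.beta(a, b)


def simulate_copy_path(panel: ReferencePanel, q: float = 300.0, seed: int = 0) -> CopyPath:
    """Draw a copying path through the panel under the transition model.

    Uses the refresh formulation of the uniform-rate chain: over a map gap
    r the state is redrawn uniformly with probability 1 - exp(-n q r) and
    kept otherwise, which reproduces the stay/switch closed form exactly.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    rng = np.random.default_rng(seed)
    n, L = panel.n_hap, panel.n_markers
    gaps = np.diff(panel.genetic_map)
    p_refresh = 1.0 - np.exp(-n * q * gaps)
    refresh = np.empty(L, dtype=bool)
    refresh[0] = True
    refresh[1:] = rng.random(L - 1) < p_refresh
    draws = rng.integers(0, n, size=L)
    idx = np.maximum.accumulate(np.where(refresh, np.arange(L), 0))
    return CopyPath(states=draws[idx])


def simulate_read_counts(
    panel: ReferencePanel,
    path: CopyPath,
    sim: SimConfig,
) -> ReadCountTable:
    """Emit read counts under the model, given the true copying path.

    Depth per marker is Poisson(coverage); each sequence is contaminant
    with probability ``c_true`` (allele Bernoulli(p_l), where p_l is the
    contaminant population frequency) and endogenous otherwise (allele =
    the path haplotype's allele); either allele is flipped with the
    per-base error ``eps_g``.  The truth is the path itself, so no
    mis-copying error enters the generator.  Markers with depth 0 are
    omitted.
    """
    if sim.contaminant_pop not in panel.pop_freqs:
        raise KeyError(f"population {sim.contaminant_pop!r} not in panel")
    rng = np.random.default_rng(sim.seed)
    L = panel.n_markers
    depth = rng.poisson(sim.coverage, size=L)
    covered = np.flatnonzero(depth >= 1)
    d = depth[covered]
    p = panel.pop_freqs[sim.contaminant_pop][covered]
    endo_allele = panel.haplotypes[path.states[covered], covered].astype(np.float64)

    n_contam = rng.binomial(d, sim.c_true)
    p_alt_contam = p * (1 - sim.eps_g) + (1 - p) * sim.eps_g
    p_alt_endo = endo_allele * (1 - sim.eps_g) + (1 - endo_allele) * sim.eps_g
    alt_contam = rng.binomial(n_contam, p_alt_contam)
    alt_endo = rng.binomial(d - n_contam, p_alt_endo)
    n_alt = alt_contam + alt_endo
    return ReadCountTable(marker_index=covered, n_ref=d - n_alt, n_alt=n_alt)


def sample_individual_haplotype(
    panel: ReferencePanel,
    seed: int = 0,
    mode: str = "copy_path",
    q: float = 300.0,
    mutation_rate: float = 0.01,
    pop: str | None = None,
) -> np.ndarray:
    """Draw one haploid X chromosome that is not a panel member.

    ``mode="copy_path"``: a copying mosaic of panel haplotypes with
    independent allele flips at ``mutation_rate`` (an individual from the
    panel's population, related to but distinct from every panel
    haplotype).  ``mode="freqs"``: independent Bernoulli draws from the
    population frequency column ``pop`` (an individual from a drifted,
    possibly diverged population, with no linkage to the panel).
    """
    rng = np.random.default_rng(seed)
    if mode == "copy_path":
        path = simulate_copy_path(panel, q=q, seed=int(rng.integers(2**31)))
        hap = panel.haplotypes[path.states, np.arange(panel.n_markers)].astype(np.int64)
        flips = rng.random(panel.n_markers) < mutation_rate
        return np.where(flips, 1 - hap, hap)
    if mode == "freqs":
        if pop is None or pop not in panel.pop_freqs:
            raise KeyError(f"mode='freqs' needs a valid population, got {pop!r}")
        return (rng.random(panel.n_markers) < panel.pop_freqs[pop]).astype(np.int64)
    raise ValueError(f"unknown mode {mode!r}")


def reads_from_haplotype(
    panel: ReferencePanel,
    haplotype: np.ndarray,
    coverage: float,
    eps_g: float,
    seed: int = 0,
) -> ReadCountTable:
    """Sequence a single haploid individual at Poisson(coverage) depth."""
    rng = np.random.default_rng(seed)
    L = panel.n_markers
    depth = rng.poisson(coverage, size=L)
    covered = np.flatnonzero(depth >= 1)
    d = depth[covered]
    a = np.asarray(haplotype, dtype=np.float64)[covered]
    p_alt = a * (1 - eps_g) + (1 - a) * eps_g
    n_alt = rng.binomial(d, p_alt)
    return ReadCountTable(marker_index=covered, n_ref=d - n_alt, n_alt=n_alt)


def mix_sources(
    endog: ReadCountTable,
    contam: ReadCountTable,
    c: float,
    coverage_target: float,
    seed: int = 0,
) -> ReadCountTable:
    """Mix two read-count tables at contamination fraction c.

    Emulates mixing two alignment files at the count level: at each marker
    covered by either source, the output depth is Poisson(coverage_target)
    and each output read is drawn from the contaminant source's empirical
    alternative-allele fraction with probability c, else from the
    endogenous source's.  A marker missing in one source falls back to the
    other (counted and logged); markers missing in both are skipped.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("c must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    union = np.union1d(endog.marker_index, contam.marker_index)

    def frac_at(table: ReadCountTable, markers: np.ndarray) -> np.ndarray:
        out = np.full(len(markers), np.nan)
        pos = np.searchsorted(table.marker_index, markers)
        ok = (pos < table.n_sites) & (
            table.marker_index[np.minimum(pos, table.n_sites - 1)] == markers
        )
        out[ok] = table.n_alt[pos[ok]] / table.depth[pos[ok]]
        return out

    f_e = frac_at(endog, union)
    f_c = frac_at(contam, union)
    n_fallback = int(np.isnan(f_e).sum() + np.isnan(f_c).sum())
    if n_fallback:
        logger.info("%d marker-source pairs fell back to the other source", n_fallback)
    f_e = np.where(np.isnan(f_e), f_c, f_e)
    f_c = np.where(np.isnan(f_c), f_e, f_c)

    depth = rng.poisson(coverage_target, size=len(union))
    keep = depth >= 1
    d = depth[keep]
    n_from_contam = rng.binomial(d, c)
    n_alt = rng.binomial(n_from_contam, f_c[keep]) + rng.binomial(
        d - n_from_contam, f_e[keep]
    )
    return ReadCountTable(
        marker_index=union[keep], n_ref=d - n_alt, n_alt=n_alt
    )


def pseudohaploid(counts: ReadCountTable, seed: int = 0) -> ReadCountTable:
    """Thin every covered site to exactly one read, chosen uniformly."""
    rng = np.random.default_rng(seed)
    take_alt = rng.random(counts.n_sites) < counts.n_alt / counts.depth
    return ReadCountTable(
        marker_index=counts.marker_index,
        n_ref=(~take_alt).astype(np.int64),
        n_alt=take_alt.astype(np.int64),
    )


def frac_depth_ge2(lam: float) -> float:
    """Poisson probability that a site is covered by at least two sequences.

    With per-site depth ~ Poisson(lam), this is 1 - e^(-lam) (1 + lam): the
    fraction of the genome usable by estimators that require two
    overlapping sequences to observe heterozygosity.
    """
    if lam < 0:
        raise ValueError("mean depth must be non-negative")
    return float(1.0 - np.exp(-lam) * (1.0 + lam))


# ---------------------------------------------------------------------------
# Pileup emission (so the CLI path is testable end to end)
# ---------------------------------------------------------------------------

def write_synthetic_pileup(
    path: str | Path,
    panel: ReferencePanel,
    counts: ReadCountTable,
    eps_g: float = 0.0,
    flank_coverage: float = 0.0,
    flank_bp: int = 2,
    seed: int = 0,
    qual_char: str = "I",
) -> None:
    """Write counts as samtools-style pileup text.

    Marker lines reproduce ``counts`` exactly ('.' for reference-supporting
    bases, the alternative allele letter otherwise).  When
    ``flank_coverage`` > 0, monomorphic positions within ``flank_bp`` of
    each covered marker are also emitted with Poisson depth and per-base
    errors at rate ``eps_g``, providing the material from which the
    error-rate estimator works.
    """
    rng = np.random.default_rng(seed)
    marker_pos = set(int(p) for p in panel.positions)
    lines: list[tuple[int, str]] = []
    for j in range(counts.n_sites):
        l = int(counts.marker_index[j])
        pos = int(panel.positions[l])
        nr, na = int(counts.n_ref[j]), int(counts.n_alt[j])
        bases = "." * nr + panel.alt_allele[l] * na
        quals = qual_char * (nr + na)
        lines.append(
            (pos, f"{panel.chrom}\t{pos}\t{panel.ref_allele[l]}\t{nr + na}\t{bases}\t{quals}")
        )
        if flank_coverage > 0:
            for off in range(-flank_bp, flank_bp + 1):
                fpos = pos + off
                if off == 0 or fpos in marker_pos or fpos < 1:
                    continue
                d = int(rng.poisson(flank_coverage))
                if d < 1:
                    continue
                ref = str(_BASES[int(rng.integers(4))])
                n_err = int(rng.binomial(d, eps_g))
                err_bases = "".join(
                    str(_BASES[(list(_BASES).index(ref) + int(k)) % 4])
                    for k in rng.integers(1, 4, size=n_err)
                )
                bases = "." * (d - n_err) + err_bases
                lines.append(
                    (fpos, f"{panel.chrom}\t{fpos}\t{ref}\t{d}\t{bases}\t{qual_char * d}")
                )
    lines.sort(key=lambda t: t[0])
    with open(path, "w") as f:
        for _, line in lines:
            f.write(line + "\n")
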