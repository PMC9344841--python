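"""Maximum-likelihood contamination estimation with confidence intervals.

The contamination rate c is estimated by maximizing the copying-HMM
log-likelihood over [0, 0.5] with bounded L-BFGS-B.  Uncertainty comes
from the observed Fisher information (central-difference second
derivative) when the optimum is interior; when the MLE sits at the c = 0
boundary the first derivative need not vanish there, so instead the
likelihood is approximated by the quadratic matching its one-sided first
and second derivatives and the 95% interval is the set of c whose
likelihood is at least exp(-1.96^2 / 2) ~ 14.7% of the maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .hmm import ForwardModel
from .io import ReadCountTable, ReferencePanel

logger = logging.getLogger(__name__)

__all__ = [
    "ContaminationEstimate",
    "LIKELIHOOD_REGION_THRESHOLD",
    "estimate_error_rate",
    "confidence_interval",
    "fit_contamination",
]

#: Relative-likelihood cutoff defining the 95% likelihood-region CI for one
#: parameter: exp(-1.96^2 / 2) ~ 0.147.
LIKELIHOOD_REGION_THRESHOLD: float = float(np.exp(-(1.96**2) / 2.0))

#: MLEs at or below this value are treated as sitting on the c = 0 boundary.
BOUNDARY_TOL: float = 1e-4

#: Below this many covered markers the estimate is flagged low-confidence.
MIN_SITES: int = 100


@dataclass
class ContaminationEstimate:
    """MLE of the contamination fraction with uncertainty.

    ``method`` is ``"fisher"`` for the interior-optimum standard-error
    construction and ``"likelihood_region"`` for the boundary construction
    (in which case ``se`` is None).
    """

    c_hat: float
    se: float | None
    ci_low: float
    ci_high: float
    loglik: float
    n_sites: int
    method: str
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.c_hat <= self.ci_high <= 0.5 + 1e-12:
            raise ValueError(
                f"invalid interval ordering: {self.ci_low}, {self.c_hat}, "
                f"{self.ci_high}"
            )


def estimate_error_rate(
    positions: np.ndarray,
    n_match: np.ndarray,
    n_mismatch: np.ndarray,
    panel: ReferencePanel,
    flank_bp: int = 5,
) -> float:
    """Estimate the per-base error rate from monomorphic flanking sites.

    Takes per-position base tallies (e.g. from
    :func:`xcontam.io.pileup_base_tallies`), keeps positions that are *not*
    panel markers but lie within ``flank_bp`` of one, and returns the
    pooled mismatch fraction against the pileup reference.  Such sites are
    presumed monomorphic, so any mismatch reflects sequencing error, aDNA
    damage or mismapping rather than true variation.

    A floor of 1e-6 is applied when no mismatches are observed, and values
    are capped just below 0.5.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    positions = np.asarray(positions, dtype=np.int64)
    marker_pos = panel.positions
    is_marker = np.isin(positions, marker_pos)
    j = np.searchsorted(marker_pos, positions)
    dist_right = np.where(
        j < len(marker_pos), np.abs(marker_pos[np.minimum(j, len(marker_pos) - 1)] - positions), np.iinfo(np.int64).max
    )
    dist_left = np.where(
        j > 0, np.abs(positions - marker_pos[np.maximum(j - 1, 0)]), np.iinfo(np.int64).max
    )
    near = np.minimum(dist_left, dist_right) <= flank_bp
    use = near & ~is_marker
    total = int(np.asarray(n_match)[use].sum() + np.asarray(n_mismatch)[use].sum())
    if total == 0:
        raise ValueError(
            "no usable bases at monomorphic flanking sites; "
            "supply eps_g manually"
        )
    bad = int(np.asarray(n_mismatch)[use].sum())
    eps = bad / total
    if eps == 0.0:
        warnings.warn(
            "no mismatches observed at monomorphic sites; flooring eps_g at 1e-6",
            stacklevel=2,
        )
        eps = 1e-6
    return min(eps, 0.5 - 1e-9)


def _fisher_ci(
    loglik_fn,
    c_hat: float,
    lo: float,
    hi: float,
) -> tuple[float, float, float] | None:
    """Fisher-information CI at an interior optimum.

    Central-difference second derivative with relative step 1e-4 (absolute
    floor 1e-6).  Returns (ci_low, ci_high, se), or None when the curvature
    is not negative (the caller then falls back to the likelihood region).
    """
    h = max(1e-4 * c_hat, 1e-6)
    center = min(max(c_hat, lo + h), hi - h)
    f0 = loglik_fn(center)
    d2 = (loglik_fn(center + h) - 2.0 * f0 + loglik_fn(center - h)) / h**2
    if not np.isfinite(d2) or d2 >= 0:
        return None
    se = 1.0 / np.sqrt(-d2)
    return (
        max(lo, c_hat - 1.96 * se),
        min(hi, c_hat + 1.96 * se),
        float(se),
    )


def _region_ci_at_lower_boundary(
    loglik_fn,
    lo: float,
    hi: float,
) -> tuple[float, float]:
    """Likelihood-region CI when the MLE sits at the lower bound.

    Approximates the log-likelihood near ``lo`` by the quadratic matching
    the one-sided first and second derivatives, solves for the c where the
    relative likelihood drops to exp(-1.96^2/2), then verifies/refines that
    crossing on the true log-likelihood by bisection.
    """
    drop = -np.log(LIKELIHOOD_REGION_THRESHOLD)  # 1.9208 log-units
    h = 1e-4
    f0 = loglik_fn(lo)
    f1 = loglik_fn(lo + h)
    f2 = loglik_fn(lo + 2 * h)
    d1 = (-3.0 * f0 + 4.0 * f1 - f2) / (2.0 * h)
    d2 = (f0 - 2.0 * f1 + f2) / h**2

    def quad(c: float) -> float:
        dc = c - lo
        return d1 * dc + 0.5 * d2 * dc * dc

    # bisect the quadratic for quad(c) = -drop, if it ever gets there
    if quad(hi) > -drop:
        c_guess = hi
    else:
        a, b = lo, hi
        for _ in range(80):
            mid = 0.5 * (a + b)
            if quad(mid) > -drop:
                a = mid
            else:
                b = mid
        c_guess = 0.5 * (a + b)

    # verify on the true log-likelihood around the quadratic's solution
    if loglik_fn(hi) - f0 > -drop:
        return lo, hi
    a, b = lo, hi
    if loglik_fn(c_guess) - f0 > -drop:
        a = c_guess
    else:
        b = c_guess
    for _ in range(60):
        mid = 0.5 * (a + b)
        if loglik_fn(mid) - f0 > -drop:
            a = mid
        else:
            b = mid
    return lo, 0.5 * (a + b)


def confidence_interval(
    loglik_fn,
    c_hat: float,
    boundary_tol: float = BOUNDARY_TOL,
    bounds: tuple[float, float] = (0.0, 0.5),
) -> tuple[float, float, float | None, str]:
    """95% confidence interval for the contamination MLE.

    Interior optimum: standard error from the observed Fisher information
    (negative central-difference second derivative), CI = c_hat +/- 1.96 se,
    clipped to ``bounds``.  Optimum within ``boundary_tol`` of a bound:
    the 14.7% likelihood-region construction (quadratic interpolation of
    the one-sided derivatives, verified on the true likelihood).

    Returns (ci_low, ci_high, se_or_None, method).
    """
    lo, hi = bounds
    if c_hat <= lo + boundary_tol:
        ci_low, ci_high = _region_ci_at_lower_boundary(loglik_fn, lo, hi)
        return ci_low, ci_high, None, "likelihood_region"
    if c_hat >= hi - boundary_tol:
        warnings.warn(
            "saturated contamination estimate at the upper bound; "
            "likelihood-region interval mirrored at the boundary",
            stacklevel=2,
        )
        hi_ci, lo_ci = _region_ci_at_lower_boundary(
            lambda c: loglik_fn(hi - (c - lo)), lo, hi
        )
        return hi - lo_ci, hi, None, "likelihood_region"
    res = _fisher_ci(loglik_fn, c_hat, lo, hi)
    if res is None:
        warnings.warn(
            "non-negative curvature at interior optimum; "
            "falling back to the likelihood-region interval",
            stacklevel=2,
        )
        drop = -np.log(LIKELIHOOD_REGION_THRESHOLD)
        fmax = loglik_fn(c_hat)
        grid = np.linspace(lo, hi, 501)
        vals = np.array([loglik_fn(c) for c in grid])
        inside = grid[vals >= fmax - drop]
        return float(inside.min()), float(inside.max()), None, "likelihood_region"
    ci_low, ci_high, se = res
    return ci_low, ci_high, se, "fisher"


def fit_contamination(
    counts: ReadCountTable,
    panel: ReferencePanel,
    contaminant_pop: str,
    eps_g: float,
    eps_r: float = 1e-3,
    q: float = 300.0,
) -> ContaminationEstimate:
    """Maximum-likelihood contamination estimate with a 95% CI.

    Maximizes the forward log-likelihood over c in [0, 0.5] with bounded
    L-BFGS-B (tolerance 1e-6 in c) from several starting points, then
    attaches the confidence interval via :func:`confidence_interval`.
    Raises RuntimeError carrying the best coarse-grid point if no optimizer
    start converges.
    """
    fm = ForwardModel(
        counts, panel, contaminant_pop=contaminant_pop,
        eps_g=eps_g, eps_r=eps_r, q=q,
    )

    def nll(c: np.ndarray | float) -> float:
        return -fm.loglik(float(np.atleast_1d(c)[0]))

    best = None
    for x0 in (0.02, 0.1, 0.3):
        res = minimize(
            nll,
            x0=[x0],
            method="L-BFGS-B",
            bounds=[(0.0, 0.5)],
            options={"ftol": 1e-12, "gtol": 1e-10, "eps": 1e-6},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        grid = np.linspace(0.0, 0.5, 51)
        vals = [-nll(c) for c in grid]
        i = int(np.argmax(vals))
        raise RuntimeError(
            f"optimizer failed to converge; best coarse grid point "
            f"c={grid[i]:.3f} with loglik={vals[i]:.3f}"
        )
    c_hat = float(best.x[0])
    ll_hat = -float(best.fun)
    ci_low, ci_high, se, method = confidence_interval(fm.loglik, c_hat)
    low_conf = fm.n_sites < MIN_SITES
    if low_conf:
        logger.warning(
            "only %d covered markers; contamination estimate is low-confidence",
            fm.n_sites,
        )
    return ContaminationEstimate(
        c_hat=c_hat,
        se=se,
        ci_low=float(ci_low),
        ci_high=float(min(ci_high, 0.5)),
        loglik=ll_hat,
        n_sites=fm.n_sites,
        method=method,
        low_confidence=low_conf,
    )
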