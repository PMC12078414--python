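"""MAP/MaxEnt inversion of remote CCR rates into a Ramachandran distribution.

The posterior point estimate minimizes, over the probability simplex,

    T * D_KL(p || q)  +  (1/2) * sum_j (Gamma_j(p) - Gamma_j)^2 / sigma_j^2

with a Gaussian likelihood over the rates and an entropy (relative to the
prior q) regularizer whose temperature T expresses confidence in the
prior.  The predicted rate is linear in p: Gamma_j(p) = tau_j * sum_bins
p * A_j, with tau_j the dynamical proxy and A_j the structural-amplitude
surface.

Stationarity confines the minimizer to the low-dimensional exponential
family p(c) ~ q * exp(-(1/T) sum_j c_j tau_j A_j), where the natural
parameters c_j are the scaled data residuals; the solver iterates this
fixed point with damping and then polishes the natural parameters with a
quasi-Newton step, which is deterministic and immune to the grid size.
D_KL uses natural logarithms (the temperature absorbs the base); the
Jensen-Shannon reporting metric uses log2 separately.

Temperature selection: T = 1 by default; an L-curve over a temperature
ladder with maximum-curvature corner detection is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .gridmetrics import RamachandranGrid
from .physmodel import RateSurface

__all__ = [
    "InversionProblem",
    "LCurvePoint",
    "MaxEntResult",
    "DEFAULT_TEMPERATURE",
    "PRIOR_FLOOR",
    "predicted_rate",
    "kl_divergence",
    "objective",
    "maxent_map",
    "maxent_weights",
    "l_curve",
    "save_l_curve",
]

log = logging.getLogger(__name__)

DEFAULT_TEMPERATURE = 1.0
PRIOR_FLOOR = 1e-12


@dataclass
class InversionProblem:
    """One residue's inversion inputs.

    ``rates`` maps rate id -> observed Gamma (s-1); ``taus`` maps rate id
    -> proxy correlation time (s); ``surfaces`` provide A_j(phi, psi);
    ``sigmas`` default to 1 per rate (unit experimental weight).
    """

    rates: dict[str, float]
    surfaces: dict[str, RateSurface]
    taus: dict[str, float]
    prior: RamachandranGrid
    sigmas: dict[str, float] | float = 1.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if not self.rates:
            raise ValueError("at least one rate is required")
        for rid in self.rates:
            if rid not in self.surfaces or rid not in self.taus:
                raise ValueError(f"rate {rid!r} lacks a surface or a tau")
            if self.surfaces[rid].resolution != self.prior.resolution:
                raise ValueError(f"surface {rid!r} resolution differs from "
                                 "the prior grid")
        for s in self.sigma_vector():
            if s <= 0:
                raise ValueError("sigmas must be positive")

    @property
    def rate_ids(self) -> list[str]:
        return sorted(self.rates)

    def sigma_vector(self) -> np.ndarray:
        if isinstance(self.sigmas, dict):
            return np.array([self.sigmas[r] for r in self.rate_ids])
        return np.full(len(self.rates), float(self.sigmas))

    def design_matrix(self) -> np.ndarray:
        """F[j, bin] = tau_j * A_j ravelled over the grid."""
        return np.stack([self.taus[r] * self.surfaces[r].values.ravel()
                         for r in self.rate_ids])

    def observed_vector(self) -> np.ndarray:
        return np.array([self.rates[r] for r in self.rate_ids])


@dataclass(frozen=True)
class LCurvePoint:
    temperature: float
    chi2: float
    dkl: float


@dataclass
class MaxEntResult:
    grid: RamachandranGrid
    chi2: float
    dkl: float
    objective: float
    iterations: int
    converged: bool


def predicted_rate(p: RamachandranGrid, surface: RateSurface,
                   tau: float) -> float:
    """Gamma(p) = tau * sum p * A -- linear in p."""
    if p.resolution != surface.resolution:
        raise ValueError("grid and surface resolutions differ")
    return float(tau * np.sum(p.probabilities * surface.values))


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """D_KL(p || q) in nats; 0 log 0 = 0; infinite when p > 0 where q = 0."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    mask = p > 0
    if np.any(q[mask] == 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def objective(p: RamachandranGrid, problem: InversionProblem) -> float:
    """T * D_KL(p || q) + 1/2 chi^2 at a candidate distribution."""
    dkl = kl_divergence(p.probabilities, problem.prior.probabilities)
    if not np.isfinite(dkl):
        return float("inf")
    sig = problem.sigma_vector()
    chi2 = 0.0
    for rid, s in zip(problem.rate_ids, sig):
        g = predicted_rate(p, problem.surfaces[rid], problem.taus[rid])
        chi2 += ((g - problem.rates[rid]) / s) ** 2
    return problem.temperature * dkl + 0.5 * chi2


# ---------------------------------------------------------------------------
# Core solver (flat arrays; grid-agnostic)
# ---------------------------------------------------------------------------

def _p_of_c(log_q: np.ndarray, F: np.ndarray, c: np.ndarray,
            T: float) -> np.ndarray:
    logits = log_q - (F.T @ c) / T
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def maxent_weights(q: np.ndarray, F: np.ndarray, observed: np.ndarray,
                   sigma: np.ndarray | float = 1.0,
                   T: float = DEFAULT_TEMPERATURE,
                   c0: np.ndarray | None = None,
                   max_iter: int = 500, tol: float = 1e-12,
                   damping: float = 0.5):
    """Minimize T*D_KL(p||q) + chi^2/2 over the simplex (flat arrays).

    ``F`` has shape (m, n_bins).  Returns (p, info).  Deterministic:
    initialization at the prior (c = 0) unless ``c0`` is given; damped
    fixed-point iteration on the natural parameters followed by a
    quasi-Newton polish (the objective is convex in p, so independent
    starts meet at the same optimum).
    """
    q = np.asarray(q, dtype=float).ravel()
    q = np.clip(q, PRIOR_FLOOR, None)
    q = q / q.sum()
    log_q = np.log(q)
    F = np.atleast_2d(np.asarray(F, dtype=float))
    observed = np.asarray(observed, dtype=float)
    m = len(observed)
    sig2 = (np.full(m, sigma) if np.isscalar(sigma)
            else np.asarray(sigma, dtype=float)) ** 2

    def residual_map(c):
        p = _p_of_c(log_q, F, c, T)
        return (F @ p - observed) / sig2, p

    def value(c):
        p = _p_of_c(log_q, F, c, T)
        mask = p > 0
        dkl = float(np.sum(p[mask] * (np.log(p[mask]) - log_q[mask])))
        r = F @ p - observed
        return T * dkl + 0.5 * float(np.sum(r * r / sig2))

    def value_and_grad(c):
        p = _p_of_c(log_q, F, c, T)
        mask = p > 0
        dkl = float(np.sum(p[mask] * (np.log(p[mask]) - log_q[mask])))
        r = F @ p - observed
        val = T * dkl + 0.5 * float(np.sum(r * r / sig2))
        # grad = Cov_p(F) (c - r / sig2) / T; vanishes at the fixed point
        mean_f = F @ p
        cov = (F * p) @ F.T - np.outer(mean_f, mean_f)
        return val, cov @ (c - r / sig2) / T

    c = np.zeros(m) if c0 is None else np.asarray(c0, dtype=float).copy()
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        target, _ = residual_map(c)
        step = target - c
        if np.max(np.abs(step)) <= tol * (1.0 + np.max(np.abs(c))):
            converged = True
            break
        c = c + damping * step
    res = minimize(value_and_grad, c, jac=True, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    c_best = res.x if res.fun <= value(c) else c
    # never worsen the prior start
    if value(np.zeros(m)) < value(c_best):
        c_best = np.zeros(m)
    p = _p_of_c(log_q, F, c_best, T)
    r = F @ p - observed
    mask = p > 0
    dkl = float(np.sum(p[mask] * (np.log(p[mask]) - log_q[mask])))
    chi2 = float(np.sum(r * r / sig2))
    # convergence judged by the stationarity residual of the polished point
    fp_res = np.max(np.abs(r / sig2 - c_best)) / (1.0 + np.max(np.abs(c_best)))
    info = {"iterations": it, "converged": bool(converged or fp_res < 1e-6),
            "chi2": chi2, "dkl": dkl, "objective": T * dkl + 0.5 * chi2,
            "c": c_best}
    return p, info


def maxent_map(problem: InversionProblem,
               c0: np.ndarray | None = None,
               max_iter: int = 500, tol: float = 1e-12) -> MaxEntResult:
    """MAP Ramachandran distribution for one residue's rate set."""
    p, info = maxent_weights(problem.prior.probabilities,
                             problem.design_matrix(),
                             problem.observed_vector(),
                             problem.sigma_vector(),
                             problem.temperature, c0=c0,
                             max_iter=max_iter, tol=tol)
    n = problem.prior.probabilities.shape[0]
    grid = RamachandranGrid.from_values(problem.prior.resolution,
                                        p.reshape(n, n))
    if not info["converged"]:
        log.warning("MaxEnt solver did not fully converge (T=%.3g); "
                    "returning best iterate", problem.temperature)
    return MaxEntResult(grid, info["chi2"], info["dkl"], info["objective"],
                        info["iterations"], info["converged"])


# ---------------------------------------------------------------------------
# L-curve temperature selection
# ---------------------------------------------------------------------------

def _menger_curvature(x, y):
    """Curvature at interior points of a polyline (zeros at the ends)."""
    kappa = np.zeros(len(x))
    for i in range(1, len(x) - 1):
        a = np.array([x[i - 1], y[i - 1]])
        b = np.array([x[i], y[i]])
        c = np.array([x[i + 1], y[i + 1]])
        ab, bc, ca = b - a, c - b, a - c
        area2 = abs(ab[0] * bc[1] - ab[1] * bc[0])
        denom = (np.linalg.norm(ab) * np.linalg.norm(bc)
                 * np.linalg.norm(ca))
        kappa[i] = 2.0 * area2 / denom if denom > 0 else 0.0
    return kappa


def l_curve(problem: InversionProblem, temperatures
            ) -> tuple[list[LCurvePoint], float]:
    """Solve across a temperature ladder and pick the corner temperature.

    The corner maximizes the Menger curvature of the (log10 chi2,
    log10 D_KL) curve; a degenerate (flat) curve falls back to the default
    T = 1 with a warning.
    """
    temps = sorted(float(t) for t in temperatures)
    if len(temps) < 3:
        raise ValueError("need at least three temperatures for an L-curve")
    points = []
    for t in temps:
        r = maxent_map(replace(problem, temperature=t))
        points.append(LCurvePoint(t, r.chi2, r.dkl))
    chi2 = np.array([p.chi2 for p in points])
    dkl = np.array([p.dkl for p in points])
    tiny = 1e-300
    if np.ptp(np.log10(chi2 + tiny)) < 1e-6 or np.ptp(
            np.log10(dkl + tiny)) < 1e-6:
        log.warning("degenerate L-curve; falling back to T = %.1f",
                    DEFAULT_TEMPERATURE)
        return points, DEFAULT_TEMPERATURE
    kappa = _menger_curvature(np.log10(chi2 + tiny), np.log10(dkl + tiny))
    return points, temps[int(np.argmax(kappa))]


def save_l_curve(path, points) -> None:
    """Delimited text: temperature, chi2, dkl."""
    with open(path, "w") as fh:
        fh.write("T\tchi2\tdkl\n")
        for p in points:
            fh.write(f"{p.temperature:.6g}\t{p.chi2:.8e}\t{p.dkl:.8e}\n")
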