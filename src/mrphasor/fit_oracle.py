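"""Iterative mono- and bi-exponential least-squares fitting baseline.

Levenberg-Marquardt fits of per-pixel decays, used as an independent check on
the phasor-based quantification.  The bi-exponential "weighted average"
decay constant uses integral weighting (weights proportional to
``A_i * tau_i``) by default, consistent with phasor fractions being integral
fractions; amplitude weighting is exposed as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .phasor_core import SampledAxis, SignalStack

__all__ = ["FitResult", "fit_monoexp", "fit_biexp", "fit_map"]

# taus outside [0.01, 100] * axis span are considered unrealistic (misfit)
_TAU_BOUNDS_REL = (0.01, 100.0)


@dataclass
class FitResult:
    """Outcome of an exponential decay fit."""

    amplitudes: tuple
    taus: tuple
    tau_avg: float
    converged: bool
    misfit: bool
    residual_norm: float

    @property
    def n_components(self) -> int:
        return len(self.taus)


def _loglinear_init(signal: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Initial (A, tau) from log-linear regression of the first half of samples."""
    half = max(signal.size // 2, 3)
    s, t = signal[:half], x[:half]
    pos = s > 0
    if pos.sum() < 2:
        return float(max(signal.max(), 1e-12)), float(x[-1] - x[0] + 1e-12)
    slope, intercept = np.polyfit(t[pos], np.log(s[pos]), 1)
    tau = -1.0 / slope if slope < 0 else float(x[-1] - x[0])
    return float(np.exp(intercept)), float(max(tau, 1e-6))


def _weighted_average(amps, taus, weighting: str) -> float:
    a = np.asarray(amps, dtype=float)
    t = np.asarray(taus, dtype=float)
    if weighting == "integral":
        w = a * t
    elif weighting == "amplitude":
        w = a
    else:
        raise ValueError("weighting must be 'integral' or 'amplitude'")
    if w.sum() <= 0:
        return float("nan")
    return float(np.sum(w * t) / w.sum())


def fit_monoexp(signal, axis: SampledAxis) -> FitResult:
    """LM fit of ``A * exp(-x/tau)`` (x measured from the first sample).

    Non-convergence is flagged in the result, never raised.
    """
    s = np.asarray(signal, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 samples")
    if s.sum() <= 0:
        raise ValueError("positive total signal required")
    x = axis.relative
    a0, tau0 = _loglinear_init(s, x)

    def resid(p):
        return p[0] * np.exp(-x / np.abs(p[1])) - s

    try:
        sol = optimize.least_squares(resid, [a0, tau0], method="lm", max_nfev=2000)
        converged = bool(sol.success)
        a, tau = float(sol.x[0]), float(abs(sol.x[1]))
        rnorm = float(np.linalg.norm(sol.fun))
    except Exception:
        converged, a, tau, rnorm = False, a0, tau0, float("inf")
    span = x[-1] - x[0]
    misfit = (not converged) or not (_TAU_BOUNDS_REL[0] * span <= tau <= _TAU_BOUNDS_REL[1] * span)
    return FitResult(amplitudes=(a,), taus=(tau,), tau_avg=tau,
                     converged=converged, misfit=misfit, residual_norm=rnorm)


def fit_biexp(signal, axis: SampledAxis, n_starts: int = 3, seed: int = 0,
              weighting: str = "integral") -> FitResult:
    """Multi-start LM fit of ``A1*exp(-x/tau1) + A2*exp(-x/tau2)``.

    Components are sorted so ``tau1 < tau2``.  The reported average is the
    weighted average of the two decay constants (see module docstring).
    Degenerate solutions (nearly equal taus or a vanishing amplitude) and
    unrealistic taus are flagged as misfits.
    """
    s = np.asarray(signal, dtype=float)
    if s.size < 5:
        raise ValueError("need at least 5 samples for a bi-exponential fit")
    if s.sum() <= 0:
        raise ValueError("positive total signal required")
    x = axis.relative
    span = float(x[-1] - x[0])
    a0, tau0 = _loglinear_init(s, x)
    rng = np.random.default_rng(seed)

    starts = [np.array([0.5 * a0, max(0.3 * tau0, 1e-6), 0.5 * a0, 3.0 * tau0])]
    for _ in range(n_starts - 1):
        f1, f2 = rng.uniform(0.7, 1.3, 2)
        starts.append(np.array([0.5 * a0 * f1, max(0.2 * tau0 * f1, 1e-6),
                                0.5 * a0 * f2, 5.0 * tau0 * f2]))

    def resid(p):
        return (p[0] * np.exp(-x / np.abs(p[1])) +
                p[2] * np.exp(-x / np.abs(p[3])) - s)

    best, best_norm = None, np.inf
    for p0 in starts:
        try:
            sol = optimize.least_squares(resid, p0, method="lm", max_nfev=4000)
        except Exception:
            continue
        norm = float(np.linalg.norm(sol.fun))
        if norm < best_norm:
            best, best_norm = sol, norm

    if best is None:
        return FitResult(amplitudes=(np.nan, np.nan), taus=(np.nan, np.nan),
                         tau_avg=float("nan"), converged=False, misfit=True,
                         residual_norm=float("inf"))
    a1, t1, a2, t2 = best.x
    t1, t2 = abs(t1), abs(t2)
    if t1 > t2:
        a1, a2, t1, t2 = a2, a1, t2, t1
    converged = bool(best.success)
    amp_total = abs(a1) + abs(a2)
    degenerate = (t2 - t1) < 0.01 * t2 or min(abs(a1), abs(a2)) < 1e-3 * amp_total
    unrealistic = not (_TAU_BOUNDS_REL[0] * span <= t1 and t2 <= _TAU_BOUNDS_REL[1] * span)
    misfit = (not converged) or degenerate or unrealistic or a1 < 0 or a2 < 0
    tau_avg = _weighted_average([max(a1, 0), max(a2, 0)], [t1, t2], weighting)
    return FitResult(amplitudes=(float(a1), float(a2)), taus=(float(t1), float(t2)),
                     tau_avg=tau_avg, converged=converged, misfit=misfit,
                     residual_norm=best_norm)


def fit_map(stack: SignalStack, model: str = "mono", mask: np.ndarray | None = None,
            weighting: str = "integral", seed: int = 0):
    """Per-pixel fits over a stack.

    Returns ``(tau_avg map, misfit mask)`` as arrays over the spatial grid;
    pixels outside ``mask`` (or with zero signal) are NaN.
    """
    if model not in ("mono", "bi"):
        raise ValueError("model must be 'mono' or 'bi'")
    shape = stack.spatial_shape
    tau = np.full(shape, np.nan)
    misfit = np.zeros(shape, dtype=bool)
    if mask is None:
        mask = stack.data.sum(axis=-1) > 0
    flat = stack.data.reshape(-1, stack.axis.n)
    fmask = mask.ravel()
    ftau = tau.reshape(-1)
    fmis = misfit.reshape(-1)
    for i in np.nonzero(fmask)[0]:
        s = flat[i]
        if s.sum() <= 0:
            continue
        res = (fit_monoexp(s, stack.axis) if model == "mono"
               else fit_biexp(s, stack.axis, seed=seed, weighting=weighting))
        ftau[i] = res.tau_avg
        fmis[i] = res.misfit
    return tau, misfit
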