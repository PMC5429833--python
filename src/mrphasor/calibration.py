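"""Mono-exponential reference locus and phasor-to-decay-constant inversion.

For a densely and long-enough sampled axis the phasors of mono-exponential
decays lie on the universal semicircle of radius 0.5 centered at (0.5, 0):
``G = (1/(1+(w*tau)^2), w*tau/(1+(w*tau)^2))`` with ``w = 2*pi/duration``.
For truncated or undersampled axes the locus deviates from that circle, so it
is built numerically for the actual sampling scheme and inverted by
root-finding on the phase coordinate, which is strictly monotone in the decay
constant.

Two equivalent-on-locus estimators are provided.  The default inverts the
*phase* coordinate (strictly monotone increasing in tau); multi-exponential
mixtures leave the locus radially but their phase still defines an average
decay constant bounded by the component constants.  The alternative inverts
the *modulus* (strictly monotone decreasing in tau); for multi-exponential
pixels it weighs the slow components more heavily, and it is the variant
whose average exceeds a mono-exponential least-squares fit of the same
multi-exponential decay — the bias direction observed when comparing
phasor maps against mono-exponential fitting.  Both recover the generating
tau exactly for mono-exponential signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phasor_core import PhasorField, PhasorPoint, SampledAxis, compute_phasor

__all__ = [
    "ReferenceLocus",
    "ParamMap",
    "build_reference_locus",
    "invert_phasor_to_tau",
    "tau_map",
    "adc_from_tau",
    "B_TO_ADC",
]

# decay exp(-b*D) with b in s/mm^2 has tau_b = 1/D in mm^2/s * 1e-3;
# 1e-3 mm^2/s = 1e-9 m^2/s, so ADC[1e-9 m^2/s] = 1e3 / tau_b[s/mm^2]
B_TO_ADC = 1.0e3


@dataclass(frozen=True)
class ReferenceLocus:
    """Phasor curve of mono-exponential decays on a given sampling scheme.

    ``points[i]`` is the phasor of ``exp(-(x_k - x_0)/taus[i])`` where ``x_k``
    are the axis sample coordinates; the phase is strictly monotone in tau
    (verified at construction).
    """

    taus: np.ndarray
    re: np.ndarray
    im: np.ndarray
    axis: SampledAxis
    harmonic: int = 1
    modulus_monotone: bool = True  # modulus inversion requires this

    @property
    def phase(self) -> np.ndarray:
        return np.arctan2(self.im, self.re)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.re, self.im])

    def phasor_of_tau(self, taus) -> np.ndarray:
        """Exact phasor(s) of mono-exponential decays with the given taus."""
        return _monoexp_phasors(self.axis, np.asarray(taus, dtype=float), self.harmonic)


@dataclass
class ParamMap:
    """Per-pixel average decay constant (T2 in ms, or ADC in 1e-9 m^2/s)."""

    value: np.ndarray
    valid: np.ndarray
    units: str
    out_of_range: np.ndarray | None = None


def _monoexp_phasors(axis: SampledAxis, taus: np.ndarray, harmonic: int = 1) -> np.ndarray:
    """Vectorized phasors of exp(-x_rel/tau), index kernel, for a tau vector."""
    x = axis.relative
    n = axis.n
    kernel = np.exp(2j * np.pi * harmonic * np.arange(n) / n)
    scalar = np.isscalar(taus) or np.ndim(taus) == 0
    t = np.atleast_1d(np.asarray(taus, dtype=float))
    with np.errstate(over="ignore", under="ignore"):
        s = np.exp(-x[None, :] / t[:, None])
    g = s @ kernel / s.sum(axis=1)
    return g[0] if scalar else g


def build_reference_locus(
    axis: SampledAxis,
    tau_min: float | None = None,
    tau_max: float | None = None,
    n_grid: int = 512,
    harmonic: int = 1,
) -> ReferenceLocus:
    """Build the mono-exponential reference locus on a logarithmic tau grid.

    Defaults: ``tau_min = 0.1 * (first step spacing)``, ``tau_max = 100 *
    (axis span)``.  Construction fails if the phase is not strictly monotone
    over the grid (axis unsuitable for phase inversion).
    """
    dx = float(np.min(np.diff(axis.values)))
    if tau_min is None:
        tau_min = 0.1 * dx
    if tau_max is None:
        tau_max = 100.0 * axis.span
    if not (0 < tau_min < tau_max):
        raise ValueError("need 0 < tau_min < tau_max")
    if n_grid < 64:
        raise ValueError("n_grid must be >= 64")
    taus = np.geomspace(tau_min, tau_max, n_grid)
    g = _monoexp_phasors(axis, taus, harmonic)
    phase = np.arctan2(g.imag, g.real)
    if np.any(np.diff(phase) <= 0):
        raise ValueError(
            "reference phase is not strictly monotone in tau over the grid; "
            "this sampling scheme cannot be phase-inverted"
        )
    mod_ok = bool(np.all(np.diff(np.hypot(g.real, g.imag)) < 0))
    return ReferenceLocus(taus=taus, re=g.real, im=g.imag, axis=axis,
                          harmonic=harmonic, modulus_monotone=mod_ok)


def _coord_of(g: np.ndarray, method: str) -> np.ndarray:
    if method == "phase":
        return np.arctan2(np.atleast_1d(g).imag, np.atleast_1d(g).real)
    return np.hypot(np.atleast_1d(g).real, np.atleast_1d(g).imag)


def _invert_coords(values: np.ndarray, locus: ReferenceLocus, method: str = "phase",
                   n_iter: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bracketed bisection of coordinate -> tau on the exact
    forward model (coordinate = phase, increasing in tau, or modulus,
    decreasing).

    Returns (taus, out_of_range mask). Values outside the locus range are
    clipped to the grid edges.
    """
    if method not in ("phase", "modulus"):
        raise ValueError("method must be 'phase' or 'modulus'")
    if method == "modulus" and not locus.modulus_monotone:
        raise ValueError("reference modulus is not strictly monotone in tau on "
                         "this axis; use the phase method")
    grid = _coord_of(locus.re + 1j * locus.im, method)
    sign = 1.0 if method == "phase" else -1.0  # make the grid increasing
    grid = sign * grid
    v = sign * values
    lo_v, hi_v = grid[0], grid[-1]
    out = (v < lo_v) | (v > hi_v) | ~np.isfinite(v)
    v = np.clip(v, lo_v, hi_v)

    # bracket on the precomputed grid, then bisect in log-tau on the exact model
    idx = np.clip(np.searchsorted(grid, v), 1, locus.taus.size - 1)
    lo = np.log(locus.taus[idx - 1])
    hi = np.log(locus.taus[idx])
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        g = _monoexp_phasors(locus.axis, np.exp(mid), locus.harmonic)
        mid_v = sign * _coord_of(g, method)
        below = mid_v < v
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    taus = np.exp(0.5 * (lo + hi))
    taus = np.where(out & (sign * values > hi_v), locus.taus[-1], taus)
    taus = np.where(out & (sign * values < lo_v), locus.taus[0], taus)
    return taus, out


def invert_phasor_to_tau(p: PhasorPoint, locus: ReferenceLocus,
                         method: str = "phase") -> float:
    """Decay constant whose reference coordinate matches the phasor's.

    ``method="phase"`` (default) matches the phase angle; ``"modulus"``
    matches the distance from the origin (see module docstring for how the
    two differ on multi-exponential pixels).  A phasor at the origin
    (constant, non-decaying signal) has no finite decay constant and returns
    ``inf``.  Coordinates outside the locus range are clipped to the
    corresponding grid edge with a warning.
    """
    if p.modulus < 1e-12:
        warnings.warn("phasor at origin: infinite decay constant", stacklevel=2)
        return float("inf")
    value = p.phase if method == "phase" else p.modulus
    taus, out = _invert_coords(np.array([value]), locus, method)
    if out[0]:
        warnings.warn(
            f"{method} {value:.4f} outside the locus range; clipped to grid edge",
            stacklevel=2,
        )
    return float(taus[0])


def adc_from_tau(tau_b: np.ndarray | float):
    """Convert a b-axis decay constant (s/mm^2) to ADC in 1e-9 m^2/s."""
    return B_TO_ADC / tau_b


def tau_map(field: PhasorField, locus: ReferenceLocus, method: str = "phase") -> ParamMap:
    """Per-pixel phasor inversion of a whole field.

    For b-value axes the decay constant is converted to an apparent diffusion
    coefficient in 1e-9 m^2/s; otherwise the axis units (ms) are kept.
    """
    if field.axis is not None and not np.array_equal(field.axis.values, locus.axis.values):
        raise ValueError("locus was built for a different sampling axis than the field")
    if method == "phase":
        coords = np.arctan2(field.im, field.re)
    else:
        coords = np.hypot(field.re, field.im)
    flat = coords[field.valid]
    taus = np.full(field.spatial_shape, np.nan)
    oor = np.zeros(field.spatial_shape, dtype=bool)
    if flat.size:
        inv, out = _invert_coords(flat, locus, method)
        # near-origin phasors: no finite decay constant
        mod = np.hypot(field.re[field.valid], field.im[field.valid])
        inv = np.where(mod < 1e-12, np.inf, inv)
        taus[field.valid] = inv
        oor[field.valid] = out
    if locus.axis.kind == "b_value":
        with np.errstate(divide="ignore"):
            value = np.where(np.isnan(taus), np.nan, adc_from_tau(taus))
        units = "1e-9 m^2/s"
    else:
        value = taus
        units = locus.axis.unit
    return ParamMap(value=value, valid=field.valid.copy(), units=units, out_of_range=oor)
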