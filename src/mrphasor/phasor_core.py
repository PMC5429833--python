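"""First-harmonic phasor transform of per-pixel decays and spectra.

A signal sampled at ``n`` steps is normalized by its sum and projected on the
first harmonic of the discrete Fourier basis::

    G = sum_k s[k] * exp(+i * 2*pi * h * k / n) / sum_k s[k],   k = 0..n-1

The (Re, Im) coordinates of ``G`` depend only on the *shape* of the signal:
fast decays approach (1, 0), a constant signal maps to the origin, and any
positive mixture of signals maps to the integral-weighted mixture of their
phasors.  The kernel sign is fixed to ``+i`` so that decaying signals have
``Im >= 0``.

The sample index ``k`` always starts at 0 at the first acquired step, even for
non-uniform or subsampled axes; the absolute sample coordinates are only used
by the calibration module when building reference loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AxisKind",
    "SampledAxis",
    "SignalStack",
    "PhasorPoint",
    "PhasorField",
    "PhasorError",
    "compute_phasor",
    "compute_phasor_field",
    "subsample_axis",
    "from_printed_steps",
    "mean_filter",
]

AXIS_KINDS = ("echo_time", "b_value", "chemical_shift")

# unit labels per axis kind; cosmetic only, never enters the math
_AXIS_UNITS = {"echo_time": "ms", "b_value": "s/mm^2", "chemical_shift": "ppm"}


class PhasorError(ValueError):
    """Raised for signals that have no well-defined phasor."""


class AxisKind:
    ECHO_TIME = "echo_time"
    B_VALUE = "b_value"
    CHEMICAL_SHIFT = "chemical_shift"


@dataclass(frozen=True)
class SampledAxis:
    """Non-spatial sampling vector (echo times, b-values or spectral channels).

    Parameters
    ----------
    values:
        Strictly increasing sample coordinates. Units: ms for echo times,
        s/mm^2 for b-values, ppm (or channel index) for spectra.
    kind:
        One of ``{"echo_time", "b_value", "chemical_shift"}``. Determines
        downstream unit labels only; the phasor math is kind-agnostic.
    """

    values: np.ndarray
    kind: str = AxisKind.ECHO_TIME

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("axis values must be one-dimensional")
        if vals.size < 3:
            raise ValueError("axis needs at least 3 samples for phasor analysis")
        if not np.all(np.isfinite(vals)):
            raise ValueError("axis values must be finite")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("axis values must be strictly increasing")
        if self.kind not in AXIS_KINDS:
            raise ValueError(f"unknown axis kind {self.kind!r}; expected one of {AXIS_KINDS}")
        object.__setattr__(self, "values", vals)
        vals.setflags(write=False)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def unit(self) -> str:
        return _AXIS_UNITS[self.kind]

    @property
    def relative(self) -> np.ndarray:
        """Sample coordinates measured from the first acquired step."""
        return self.values - self.values[0]

    @property
    def span(self) -> float:
        return float(self.values[-1] - self.values[0])

    def subset(self, indices) -> "SampledAxis":
        idx = _check_indices(indices, self.n)
        return SampledAxis(self.values[idx], self.kind)


@dataclass
class SignalStack:
    """Magnitude image stack: spatial grid x sampled axis (last dimension)."""

    data: np.ndarray
    axis: SampledAxis
    spacing: tuple | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim < 2:
            raise ValueError("stack must have at least one spatial dimension")
        if data.shape[-1] != self.axis.n:
            raise ValueError(
                f"last stack dimension ({data.shape[-1]}) must equal axis length ({self.axis.n})"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("stack contains non-finite values")
        if np.any(data < 0):
            raise ValueError("stack must be non-negative (magnitude data)")
        self.data = data

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:-1]


@dataclass(frozen=True)
class PhasorPoint:
    """First-harmonic phasor coordinates (dimensionless)."""

    re: float
    im: float

    @property
    def modulus(self) -> float:
        return float(np.hypot(self.re, self.im))

    @property
    def phase(self) -> float:
        return float(np.arctan2(self.im, self.re))

    def conjugate(self) -> "PhasorPoint":
        return PhasorPoint(self.re, -self.im)

    def __iter__(self):
        yield self.re
        yield self.im


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates over a spatial grid.

    Invalid pixels (below intensity threshold, or undefined phasor) carry NaN
    in ``re``/``im`` and must be excluded from all statistics via ``valid``.
    """

    re: np.ndarray
    im: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    axis: SampledAxis | None = None
    harmonic: int = 1

    @property
    def spatial_shape(self) -> tuple:
        return self.re.shape

    def points(self) -> np.ndarray:
        """(n_valid, 2) array of the valid phasor coordinates."""
        return np.column_stack([self.re[self.valid], self.im[self.valid]])


def _check_indices(indices, n: int) -> np.ndarray:
    idx = np.asarray(indices, dtype=int)
    if idx.ndim != 1 or idx.size < 3:
        raise ValueError("need at least 3 sample indices")
    if np.any(np.diff(idx) <= 0):
        raise ValueError("indices must be strictly increasing")
    if idx[0] < 0 or idx[-1] >= n:
        raise IndexError(f"indices out of range [0, {n})")
    return idx


def _phasor_kernel(n: int, harmonic: int) -> np.ndarray:
    k = np.arange(n)
    return np.exp(2j * np.pi * harmonic * k / n)


def compute_phasor(signal, harmonic: int = 1) -> PhasorPoint:
    """Normalized first-harmonic DFT of a single signal.

    Parameters
    ----------
    signal:
        Real vector of length ``n >= 3`` with positive total.
    harmonic:
        Positive integer harmonic number, must satisfy ``harmonic < n/2``.

    Returns
    -------
    PhasorPoint
        Invariant under multiplication of the signal by any positive scalar;
        ``|G| <= 1`` for non-negative input.
    """
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1 or s.size < 3:
        raise ValueError("signal must be a 1-D vector of length >= 3")
    if not np.all(np.isfinite(s)):
        raise ValueError("signal contains non-finite values")
    if harmonic < 1 or harmonic >= s.size / 2:
        raise ValueError(f"harmonic must satisfy 1 <= h < n/2, got {harmonic}")
    if s.sum() <= 0:
        raise PhasorError("zero or negative total signal: phasor undefined")
    s = s / s.max()  # scale-invariant and robust to subnormal inputs
    g = np.dot(s, _phasor_kernel(s.size, harmonic)) / s.sum()
    return PhasorPoint(float(g.real), float(g.imag))


def mean_filter(image: np.ndarray, radius: int) -> np.ndarray:
    """Square mean filter of half-width ``radius`` over the first two axes.

    The window shrinks at image borders (the mean is taken over in-bounds
    pixels only), so a constant image is exactly preserved.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return image
    size = [2 * radius + 1, 2 * radius + 1] + [1] * (image.ndim - 2)
    summed = ndimage.uniform_filter(image, size=size, mode="constant", cval=0.0)
    counts = ndimage.uniform_filter(np.ones(image.shape[:2]), size=size[:2],
                                    mode="constant", cval=0.0)
    counts = counts.reshape(counts.shape + (1,) * (image.ndim - 2))
    return summed / counts


def preprocess_stack(stack: SignalStack, mean_filter_radius: int = 0,
                     noise_floor_sigma: float = 0.0) -> SignalStack:
    """Spatial mean filtering followed by Rician noise-floor removal.

    See :func:`compute_phasor_field` for the parameter semantics; exposed so
    that other estimators (e.g. the least-squares fitting baseline) can run
    on exactly the same preprocessed signals as the phasor transform.
    """
    data = stack.data
    if mean_filter_radius > 0:
        data = np.clip(mean_filter(data, mean_filter_radius), 0.0, None)
    if noise_floor_sigma > 0:
        floor = 0.5 * np.pi * noise_floor_sigma ** 2
        data = np.sqrt(np.clip(data ** 2 - floor, 0.0, None))
    if data is stack.data:
        return stack
    return SignalStack(data, stack.axis, stack.spacing)


def compute_phasor_field(
    stack: SignalStack,
    harmonic: int = 1,
    intensity_threshold: float = 0.05,
    threshold_absolute: bool = False,
    mean_filter_radius: int = 0,
    noise_floor_sigma: float = 0.0,
) -> PhasorField:
    """Per-pixel phasor transform of a whole stack.

    A spatial mean filter of the given radius is applied to every non-spatial
    step *before* the phasor computation.  Pixels whose total (filtered)
    intensity falls below the threshold are marked invalid.

    Parameters
    ----------
    intensity_threshold:
        If ``threshold_absolute`` is False (default), interpreted as a
        fraction of the 99th percentile of the per-pixel total intensity
        (default 0.05); otherwise an absolute total-intensity cutoff.
    noise_floor_sigma:
        Known per-channel Gaussian noise level of the magnitude data.  When
        positive, the Rician noise floor is removed from the (mean-filtered)
        magnitudes by the power-law correction ``sqrt(max(m^2 -
        (pi/2)*sigma^2, 0))`` — ``(pi/2)*sigma^2`` is the squared mean of a
        pure-noise magnitude sample, so zero-signal steps land near zero
        while high-signal steps are barely touched.  This de-biases phasors
        that the noise floor would otherwise drag towards the origin.
    """
    if intensity_threshold < 0:
        raise ValueError("intensity threshold must be >= 0")
    n = stack.axis.n
    if harmonic < 1 or harmonic >= n / 2:
        raise ValueError(f"harmonic must satisfy 1 <= h < n/2, got {harmonic}")

    data = preprocess_stack(stack, mean_filter_radius, noise_floor_sigma).data

    intensity = data.sum(axis=-1)
    if threshold_absolute:
        cutoff = float(intensity_threshold)
    else:
        cutoff = float(intensity_threshold) * float(np.percentile(intensity, 99))
    valid = (intensity > cutoff) & (intensity > 0)
    if not valid.any():
        warnings.warn("no pixel passes the intensity threshold", stacklevel=2)

    kernel = _phasor_kernel(n, harmonic)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = data @ kernel / intensity
    re = np.where(valid, g.real, np.nan)
    im = np.where(valid, g.imag, np.nan)
    return PhasorField(re=re, im=im, intensity=intensity, valid=valid,
                       axis=stack.axis, harmonic=harmonic)


def subsample_axis(stack: SignalStack, indices) -> SignalStack:
    """Restrict a stack to a subset of non-spatial steps (0-based indices).

    No interpolation is performed: the returned stack carries the subset of
    the axis values, and downstream phasor math uses the reduced axis.
    """
    idx = _check_indices(indices, stack.axis.n)
    return SignalStack(stack.data[..., idx], stack.axis.subset(idx), stack.spacing)


def from_printed_steps(steps) -> list:
    """Convert 1-based printed step numbers (ImageJ convention) to 0-based."""
    steps = list(steps)
    if any(s < 1 for s in steps):
        raise ValueError("printed step numbers are 1-based and must be >= 1")
    return [s - 1 for s in steps]
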