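"""Barycentric unmixing of phasors and endmember estimation.

Two-component mixtures lie on the segment between the two reference phasors;
three-component mixtures lie inside their triangle.  The fraction of
component ``i`` is the signed area of the triangle formed by the pixel phasor
and the two *other* references, divided by the signed area of the reference
triangle — so fractions always sum to 1 exactly, and points outside the
triangle are detectable through negative fractions (display clamps, analysis
does not).

Endmembers of an elongated two-component cloud are estimated by a total
least-squares line through the cloud, intersected with the mono-exponential
reference locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import ReferenceLocus, adc_from_tau
from .phasor_core import PhasorField, PhasorPoint

__all__ = [
    "ComponentSet",
    "FractionMaps",
    "ExtrapolationResult",
    "unmix_two",
    "unmix_three",
    "fraction_maps",
    "extrapolate_cloud_to_locus",
]

_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class ComponentSet:
    """Two or three labeled reference phasors (endmembers)."""

    refs: tuple
    labels: tuple
    taus: tuple | None = None

    def __post_init__(self) -> None:
        refs = tuple(PhasorPoint(*r) if not isinstance(r, PhasorPoint) else r
                     for r in self.refs)
        object.__setattr__(self, "refs", refs)
        if len(refs) not in (2, 3):
            raise ValueError("need exactly 2 or 3 reference phasors")
        if len(self.labels) != len(refs):
            raise ValueError("one label per reference required")
        pts = np.array([[r.re, r.im] for r in refs])
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                if np.allclose(pts[i], pts[j], atol=1e-12):
                    raise ValueError(f"references {self.labels[i]!r} and {self.labels[j]!r} coincide")
        if len(refs) == 3 and abs(_signed_area(*pts)) < _COLLINEAR_TOL:
            raise ValueError("three references are collinear: triangle unmixing ill-posed")

    @classmethod
    def from_taus(cls, taus, locus: ReferenceLocus, labels=None) -> "ComponentSet":
        """Place references on the locus at the given decay constants."""
        g = locus.phasor_of_tau(np.asarray(taus, dtype=float))
        refs = tuple(PhasorPoint(float(z.real), float(z.imag)) for z in np.atleast_1d(g))
        if labels is None:
            labels = tuple(f"tau={t:g}" for t in taus)
        return cls(refs=refs, labels=tuple(labels), taus=tuple(float(t) for t in taus))

    def __len__(self) -> int:
        return len(self.refs)

    @property
    def array(self) -> np.ndarray:
        return np.array([[r.re, r.im] for r in self.refs])


@dataclass
class FractionMaps:
    """Per-pixel component fractions; raw values sum to 1 where valid."""

    fractions: np.ndarray  # spatial shape + (n_components,)
    valid: np.ndarray
    labels: tuple
    clamped: np.ndarray = field(init=False)  # pixels with out-of-[0,1] raw fractions

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            bad = (self.fractions < 0) | (self.fractions > 1)
        self.clamped = self.valid & bad.any(axis=-1)

    def clamped_fractions(self) -> np.ndarray:
        """Fractions clamped to [0, 1] for display; raw values are retained."""
        return np.clip(self.fractions, 0.0, 1.0)

    def rgb(self) -> np.ndarray:
        """RGB composite (3 components -> R, G, B channels; 2 -> R, G)."""
        out = np.zeros(self.valid.shape + (3,))
        clamped = self.clamped_fractions()
        for c in range(self.fractions.shape[-1]):
            out[..., c] = np.where(self.valid, clamped[..., c], 0.0)
        return out


def _signed_area(a, b, c) -> float:
    return 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))


def unmix_three(p: PhasorPoint, refs: ComponentSet) -> tuple[float, float, float]:
    """Barycentric fractions of a phasor w.r.t. a reference triangle.

    ``f_i = area(p, ref_j, ref_k) / area(ref_i, ref_j, ref_k)`` with signed
    areas; the fractions sum to 1 exactly.  Points outside the triangle give
    negative fractions (not clamped here).
    """
    if len(refs) != 3:
        raise ValueError("unmix_three needs exactly 3 references")
    fr = _barycentric(np.array([[p.re, p.im]]), refs.array)[0]
    return float(fr[0]), float(fr[1]), float(fr[2])


def _barycentric(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    a, b, c = tri
    total = _signed_area(a, b, c)
    x, y = points[..., 0], points[..., 1]
    f1 = 0.5 * ((b[0] - x) * (c[1] - y) - (c[0] - x) * (b[1] - y)) / total
    f2 = 0.5 * ((c[0] - x) * (a[1] - y) - (a[0] - x) * (c[1] - y)) / total
    f3 = 1.0 - f1 - f2  # barycentric partition of unity, exact
    return np.stack([f1, f2, f3], axis=-1)


def unmix_two(p: PhasorPoint, refs: ComponentSet) -> tuple[float, float]:
    """Fractions along the segment between two references.

    ``f1`` is the orthogonal projection parameter of the phasor onto the
    segment ref2 -> ref1; ``f1 + f2 = 1``.
    """
    if len(refs) != 2:
        raise ValueError("unmix_two needs exactly 2 references")
    fr = _project_two(np.array([[p.re, p.im]]), refs.array)[0]
    return float(fr[0]), float(fr[1])


def _project_two(points: np.ndarray, refs: np.ndarray) -> np.ndarray:
    r1, r2 = refs
    d = r1 - r2
    f1 = ((points - r2) @ d) / (d @ d)
    return np.stack([f1, 1.0 - f1], axis=-1)


def fraction_maps(field: PhasorField, refs: ComponentSet) -> FractionMaps:
    """Per-pixel unmixing of a phasor field (2 or 3 components)."""
    pts = np.stack([field.re, field.im], axis=-1)
    if len(refs) == 3:
        fr = _barycentric(pts, refs.array)
    else:
        fr = _project_two(pts, refs.array)
    fr = np.where(field.valid[..., None], fr, np.nan)
    return FractionMaps(fractions=fr, valid=field.valid.copy(), labels=refs.labels)


@dataclass
class ExtrapolationResult:
    """Endmember decay constants from a cloud/locus intersection."""

    tau_low: float
    tau_high: float
    n_intersections: int
    flags: tuple = ()

    @property
    def taus(self) -> tuple[float, float]:
        return (self.tau_low, self.tau_high)

    def adcs(self) -> tuple[float, float]:
        """Endmember ADCs in 1e-9 m^2/s, ascending (ADC = 1/tau, so the
        larger b-axis decay constant is the smaller diffusion coefficient)."""
        return (adc_from_tau(self.tau_high), adc_from_tau(self.tau_low))


def extrapolate_cloud_to_locus(
    points,
    locus: ReferenceLocus,
    min_points: int = 10,
    elongation_threshold: float = 3.0,
) -> ExtrapolationResult:
    """Fit a total-least-squares line through a phasor cloud and intersect it
    with the reference locus to estimate the two endmember decay constants.

    The cloud must be elongated (ratio of principal-axis standard deviations
    above ``elongation_threshold``), otherwise two-reference unmixing is
    ill-posed.  If the line misses the locus on one side, the locus point
    closest to the line is returned and flagged.
    """
    if isinstance(points, PhasorField):
        pts = points.points()
    else:
        pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array of phasor coordinates")
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.shape[0] < min_points:
        raise ValueError(f"need at least {min_points} phasor points, got {pts.shape[0]}")

    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= 0:
        raise ValueError("degenerate cloud: all points identical")
    elong = np.sqrt(evals[1] / max(evals[0], 1e-30))
    if elong < elongation_threshold:
        raise ValueError(
            f"cloud not elongated (principal-axis ratio {elong:.2f} < "
            f"{elongation_threshold}); two-reference unmixing is ill-posed"
        )
    direction = evecs[:, 1]
    normal = evecs[:, 0]

    # signed distance of locus points to the TLS line; zero crossings are
    # intersections, interpolated in log-tau
    d = (locus.points - center) @ normal
    sign_change = np.nonzero(np.diff(np.sign(d)) != 0)[0]
    crossings = []
    for i in sign_change:
        w = d[i] / (d[i] - d[i + 1])
        log_tau = (1 - w) * np.log(locus.taus[i]) + w * np.log(locus.taus[i + 1])
        crossings.append(float(np.exp(log_tau)))

    flags: list[str] = []
    if len(crossings) >= 2:
        tau_low, tau_high = min(crossings), max(crossings)
        if len(crossings) > 2:
            flags.append("multiple_intersections")
    else:
        nearest = float(locus.taus[np.argmin(np.abs(d))])
        flags.append("missed_locus")
        warnings.warn(
            "TLS line does not intersect the locus twice; returning nearest "
            "locus point for the missing endmember", stacklevel=2,
        )
        if len(crossings) == 1:
            tau_low, tau_high = sorted([crossings[0], nearest])
        else:
            tau_low = tau_high = nearest
    return ExtrapolationResult(tau_low=tau_low, tau_high=tau_high,
                               n_intersections=len(crossings), flags=tuple(flags))
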