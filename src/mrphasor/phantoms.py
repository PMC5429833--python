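"""Synthetic phantom stacks with full ground truth.

Generates multi-exponential decay images (echo-time or b-value axes) and
multi-Gaussian spectral grids on labeled geometric regions, with optional
Gaussian or Rician noise.  Every stack comes with sidecar ground truth
(region label map, per-pixel component fractions, component decay constants)
so tests never have to re-derive expected values.

Component fractions are *integral* fractions by default: the amplitude of
each component is scaled so its summed signal over the axis equals the
requested fraction of the pixel total.  This matches the phasor mixing rule,
where a pixel's phasor is the integral-weighted combination of the component
phasors.  Amplitude-fraction mode is available for callers that want
``f_i`` to be the raw amplitude weight instead.

SNR is defined as (mean signal at the first step inside tissue) / sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .phasor_core import AxisKind, SampledAxis, SignalStack

__all__ = [
    "Region",
    "PhantomSpec",
    "GroundTruth",
    "generate_stack",
    "add_rician_noise",
    "stem_phantom",
    "brain_phantom",
    "diffusion_phantom",
    "mrsi_phantom",
    "multi_tissue_phantom",
    "tau_to_b_axis_tau",
]

_SHAPES = ("disk", "annulus", "rect")


def tau_to_b_axis_tau(adc: float) -> float:
    """Decay constant on a b-axis (s/mm^2) for an ADC in 1e-9 m^2/s."""
    return 1.0e3 / adc


@dataclass(frozen=True)
class Region:
    """A labeled geometric region carrying a component mixture.

    ``shape`` is one of ``disk`` (params: cy, cx, r), ``annulus``
    (cy, cx, r_in, r_out) or ``rect`` (y0, x0, y1, x1; half-open).
    ``components`` is a list of ``(tau, fraction)`` for decay phantoms or
    ``(center_channel, sigma, fraction)`` for spectral phantoms; fractions
    must sum to 1.  ``random_fractions=True`` replaces the fixed fractions by
    per-pixel random draws (the fixed values are ignored): iid
    Dirichlet(1,..,1) when ``fraction_smoothing == 0``, otherwise spatially
    correlated fields (softmax of Gaussian-smoothed noise with the given
    smoothing length), emulating tissue-like gradual composition changes
    that remain meaningful under spatial mean filtering.
    """

    label: str
    shape: str
    params: tuple
    components: tuple
    amplitude: float = 1.0
    random_fractions: bool = False
    fraction_smoothing: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown region shape {self.shape!r}; expected {_SHAPES}")
        comps = tuple(tuple(float(v) for v in c) for c in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError(f"region {self.label!r}: needs at least one component")
        fr = sum(c[-1] for c in comps)
        if not self.random_fractions and abs(fr - 1.0) > 1e-9:
            raise ValueError(f"region {self.label!r}: fractions sum to {fr}, expected 1")
        if self.amplitude <= 0:
            raise ValueError(f"region {self.label!r}: amplitude must be positive")

    def mask(self, shape: tuple) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        if self.shape == "disk":
            cy, cx, r = self.params
            return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        if self.shape == "annulus":
            cy, cx, r_in, r_out = self.params
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            return (d2 > r_in ** 2) & (d2 <= r_out ** 2)
        y0, x0, y1, x1 = self.params
        return (yy >= y0) & (yy < y1) & (xx >= x0) & (xx < x1)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic stack; reproducible from ``seed``."""

    shape: tuple
    regions: tuple
    axis: SampledAxis
    noise: str = "none"  # none | gaussian | rician
    sigma: float = 0.0
    seed: int = 0
    fraction_mode: str = "integral"  # integral | amplitude

    def __post_init__(self) -> None:
        problems = []
        if len(self.shape) != 2 or any(s < 1 for s in self.shape):
            problems.append(f"shape: expected 2 positive dims, got {self.shape}")
        if self.noise not in ("none", "gaussian", "rician"):
            problems.append(f"noise: unknown model {self.noise!r}")
        if self.sigma < 0:
            problems.append(f"sigma: must be >= 0, got {self.sigma}")
        if self.fraction_mode not in ("integral", "amplitude"):
            problems.append(f"fraction_mode: {self.fraction_mode!r}")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            problems.append(f"regions: duplicate labels in {labels}")
        if not self.regions:
            problems.append("regions: empty")
        if problems:
            raise ValueError("invalid phantom spec: " + "; ".join(problems))
        object.__setattr__(self, "regions", tuple(self.regions))


@dataclass
class GroundTruth:
    """Sidecar truth for a generated stack."""

    label_map: np.ndarray            # 0 = background, i = regions[i-1]
    region_labels: tuple             # names, index i-1 <-> label i
    component_values: tuple          # unique tau (or (center, sigma)) identifiers
    fraction_maps: np.ndarray        # spatial + (n_components,), integral fractions
    clean_stack: "SignalStack"       # noiseless signals
    sigma: float = 0.0

    def region_mask(self, name: str) -> np.ndarray:
        idx = self.region_labels.index(name) + 1
        return self.label_map == idx


def add_rician_noise(signal: np.ndarray, sigma: float, seed=None) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((s + e1)^2 + e2^2), e ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s = np.asarray(signal, dtype=float)
    if sigma == 0:
        return s.copy()
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, s.shape)
    e2 = rng.normal(0.0, sigma, s.shape)
    return np.sqrt((s + e1) ** 2 + e2 ** 2)


def _component_profiles(components, axis: SampledAxis) -> np.ndarray:
    """Unit-amplitude per-component signal profiles, (n_comp, n_steps)."""
    x = axis.relative
    profiles = []
    for comp in components:
        if axis.kind == AxisKind.CHEMICAL_SHIFT:
            center, sigma, _ = comp
            k = np.arange(axis.n)
            profiles.append(np.exp(-0.5 * ((k - center) / sigma) ** 2))
        else:
            tau, _ = comp
            profiles.append(np.exp(-x / tau))
    return np.array(profiles)


def _component_key(comp, kind: str):
    return (comp[0], comp[1]) if kind == AxisKind.CHEMICAL_SHIFT else comp[0]


def generate_stack(spec: PhantomSpec) -> tuple[SignalStack, GroundTruth]:
    """Render a phantom spec into a stack plus ground-truth sidecars.

    Per-pixel noiseless signal is the fraction-weighted sum of the component
    profiles (integral fractions by default, see module docstring), scaled by
    the region amplitude; noise is applied afterwards.  Deterministic for a
    given spec (seed included).
    """
    ny, nx = spec.shape
    n = spec.axis.n
    rng = np.random.default_rng(spec.seed)

    keys: list = []
    for r in spec.regions:
        for c in r.components:
            key = _component_key(c, spec.axis.kind)
            if key not in keys:
                keys.append(key)
    n_comp = len(keys)

    clean = np.zeros((ny, nx, n))
    label_map = np.zeros((ny, nx), dtype=int)
    fraction_maps = np.zeros((ny, nx, n_comp))

    for i, region in enumerate(spec.regions, start=1):
        m = region.mask(spec.shape)
        label_map[m] = i
        profiles = _component_profiles(region.components, spec.axis)
        sums = profiles.sum(axis=1)
        n_pix = int(m.sum())
        n_rc = len(region.components)
        if region.random_fractions and region.fraction_smoothing > 0:
            from scipy.ndimage import gaussian_filter
            fields = rng.standard_normal((n_rc, ny, nx))
            fields = np.stack([gaussian_filter(f, region.fraction_smoothing)
                               for f in fields])
            # softmax with gain chosen to spread fractions over (0, 1)
            gain = 2.5 / max(fields.std(), 1e-12)
            w = np.exp(gain * fields)
            fr = (w / w.sum(axis=0))[:, m].T
        elif region.random_fractions:
            fr = rng.dirichlet(np.ones(n_rc), size=n_pix)
        else:
            fr = np.tile([c[-1] for c in region.components], (n_pix, 1))
        if spec.fraction_mode == "integral":
            amps = fr / sums[None, :]
        else:
            amps = fr
        mixed = amps @ profiles
        # scale each pixel so its reference level (first step for decays, peak
        # channel for spectra) equals the region amplitude -> SNR = amplitude/sigma
        if spec.axis.kind == AxisKind.CHEMICAL_SHIFT:
            ref = mixed.max(axis=1)
        else:
            ref = mixed[:, 0]
        clean[m] = mixed * (region.amplitude / ref)[:, None]
        # integral fractions are invariant under per-pixel scaling
        integral = amps * sums[None, :]
        integral /= integral.sum(axis=1, keepdims=True)
        for j, c in enumerate(region.components):
            fraction_maps[m, keys.index(_component_key(c, spec.axis.kind))] += integral[:, j]

    clean_stack = SignalStack(clean.copy(), spec.axis)
    if spec.noise == "rician":
        noisy = add_rician_noise(clean, spec.sigma, rng)
    elif spec.noise == "gaussian":
        noisy = np.clip(clean + rng.normal(0.0, spec.sigma, clean.shape), 0.0, None)
    else:
        noisy = clean
    stack = SignalStack(noisy, spec.axis)
    truth = GroundTruth(
        label_map=label_map,
        region_labels=tuple(r.label for r in spec.regions),
        component_values=tuple(keys),
        fraction_maps=fraction_maps,
        clean_stack=clean_stack,
        sigma=spec.sigma,
    )
    return stack, truth


def _sigma_for_snr(regions, axis: SampledAxis, snr: float | None) -> float:
    """Noise level giving the requested first-step-signal SNR (amplitude 1 regions)."""
    if not snr:
        return 0.0
    return 1.0 / snr


# ---------------------------------------------------------------------------
# presets emulating the demonstration datasets


def echo_axis(n_echoes: int = 64, spacing: float = 7.23) -> SampledAxis:
    return SampledAxis(spacing * np.arange(1, n_echoes + 1), kind=AxisKind.ECHO_TIME)


def stem_phantom(shape=(128, 128), n_echoes: int = 64, spacing: float = 7.23,
                 noise: str = "none", snr: float | None = None, seed: int = 0) -> PhantomSpec:
    """Plant-stem-like phantom: pith, vascular ring, cortex, epidermis and four
    mono-exponential reference tubes (two at 105 ms, two at 130 ms)."""
    ny, nx = shape
    cy, cx = ny // 2, nx // 2
    r = min(ny, nx) // 2
    regions = (
        Region("pith", "disk", (cy, cx, 0.30 * r), ((120.0, 0.6), (400.0, 0.4))),
        Region("vascular", "annulus", (cy, cx, 0.30 * r, 0.42 * r), ((60.0, 0.5), (250.0, 0.5))),
        Region("cortex", "annulus", (cy, cx, 0.42 * r, 0.58 * r), ((90.0, 1.0),)),
        Region("epidermis", "annulus", (cy, cx, 0.58 * r, 0.64 * r), ((35.0, 1.0),)),
        Region("tube_105_a", "disk", (0.14 * ny, 0.14 * nx, 0.09 * r), ((105.0, 1.0),)),
        Region("tube_105_b", "disk", (0.14 * ny, 0.86 * nx, 0.09 * r), ((105.0, 1.0),)),
        Region("tube_130_a", "disk", (0.86 * ny, 0.14 * nx, 0.09 * r), ((130.0, 1.0),)),
        Region("tube_130_b", "disk", (0.86 * ny, 0.86 * nx, 0.09 * r), ((130.0, 1.0),)),
    )
    axis = echo_axis(n_echoes, spacing)
    return PhantomSpec(shape=shape, regions=regions, axis=axis, noise=noise,
                       sigma=_sigma_for_snr(regions, axis, snr), seed=seed)


def multi_tissue_phantom(shape=(128, 128), taus=(40.0, 105.0, 130.0, 200.0),
                         n_echoes: int = 64, spacing: float = 7.23,
                         noise: str = "none", snr: float | None = None,
                         seed: int = 0) -> PhantomSpec:
    """Concentric mono-exponential tissues, one decay constant per ring."""
    ny, nx = shape
    cy, cx = ny // 2, nx // 2
    r = 0.9 * (min(ny, nx) // 2)
    edges = np.linspace(0, r, len(taus) + 1)
    regions = []
    for i, tau in enumerate(taus):
        if i == 0:
            regions.append(Region(f"tissue_{tau:g}", "disk", (cy, cx, edges[1]),
                                  ((float(tau), 1.0),)))
        else:
            regions.append(Region(f"tissue_{tau:g}", "annulus",
                                  (cy, cx, edges[i], edges[i + 1]), ((float(tau), 1.0),)))
    axis = echo_axis(n_echoes, spacing)
    return PhantomSpec(shape=shape, regions=tuple(regions), axis=axis, noise=noise,
                       sigma=_sigma_for_snr(regions, axis, snr), seed=seed)


def brain_phantom(shape=(128, 128), taus=(40.0, 80.0, 500.0), n_echoes: int = 10,
                  spacing: float = 17.4, noise: str = "none", snr: float | None = None,
                  seed: int = 0, random_fractions: bool = True,
                  fraction_smoothing: float = 8.0) -> PhantomSpec:
    """Brain-like three-component phantom (short/intermediate/long decays) with
    spatially varying random fractions inside a disk.

    The default axis takes every other echo of a 20-echo, 8.7 ms train
    (10 echoes, 17.4 ms apart): long-decay components need the longer
    acquisition window to be distinguishable."""
    ny, nx = shape
    comps = tuple((float(t), 1.0 / len(taus)) for t in taus)
    regions = (
        Region("brain", "disk", (ny // 2, nx // 2, 0.45 * min(ny, nx)), comps,
               random_fractions=random_fractions,
               fraction_smoothing=fraction_smoothing),
    )
    axis = echo_axis(n_echoes, spacing)
    return PhantomSpec(shape=shape, regions=regions, axis=axis, noise=noise,
                       sigma=_sigma_for_snr(regions, axis, snr), seed=seed)


def b_value_axis(n_b: int = 13, b_max: float = 1200.0) -> SampledAxis:
    """0 plus n-1 values from 300 to b_max (s/mm^2)."""
    values = np.concatenate([[0.0], np.linspace(300.0, b_max, n_b - 1)])
    return SampledAxis(values, kind=AxisKind.B_VALUE)


def diffusion_phantom(shape=(128, 128), adcs=(0.65, 3.1), n_b: int = 13,
                      noise: str = "none", snr: float | None = None,
                      seed: int = 0) -> PhantomSpec:
    """Two-pool diffusion phantom: tissue, fluid, and a partial-volume ring of
    mixtures between them (ADCs in 1e-9 m^2/s)."""
    ny, nx = shape
    cy, cx = ny // 2, nx // 2
    r = min(ny, nx) // 2
    tau_a, tau_b = (tau_to_b_axis_tau(a) for a in adcs)
    mix = []
    for i, f in enumerate(np.linspace(0.1, 0.9, 9)):
        mix.append(Region(f"mix_{i}", "rect",
                          (int(0.82 * ny), int(i * nx / 9), int(0.92 * ny), int((i + 1) * nx / 9)),
                          ((tau_a, round(1 - f, 10)), (tau_b, round(f, 10)))))
    regions = (
        Region("tissue", "disk", (cy, cx, 0.35 * r), ((tau_a, 1.0),)),
        Region("fluid", "annulus", (cy, cx, 0.35 * r, 0.55 * r), ((tau_b, 1.0),)),
        *mix,
    )
    axis = b_value_axis(n_b)
    return PhantomSpec(shape=shape, regions=regions, axis=axis, noise=noise,
                       sigma=_sigma_for_snr(regions, axis, snr), seed=seed)


def mrsi_phantom(shape=(80, 80), n_channels: int = 128, line_sigma: float = 3.0,
                 centers=(16.0, 40.0, 64.0, 88.0, 112.0), noise: str = "none",
                 snr: float | None = None, seed: int = 0) -> PhantomSpec:
    """Five-region spectral phantom, one Gaussian line per region at distinct
    channel positions (channel axis maps linearly to 0.4-5.4 ppm)."""
    ny, nx = shape
    band = ny // len(centers)
    regions = tuple(
        Region(f"peak_{i}", "rect", (i * band, 0, (i + 1) * band if i < len(centers) - 1 else ny, nx),
               ((float(c), line_sigma, 1.0),))
        for i, c in enumerate(centers)
    )
    ppm = np.linspace(0.4, 5.4, n_channels)
    axis = SampledAxis(ppm, kind=AxisKind.CHEMICAL_SHIFT)
    return PhantomSpec(shape=shape, regions=regions, axis=axis, noise=noise,
                       sigma=_sigma_for_snr(regions, axis, snr), seed=seed)
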