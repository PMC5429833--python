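import numpy as np
import pytest

from mrphasor import SampledAxis, build_reference_locus
from mrphasor.phantoms import b_value_axis, echo_axis


@pytest.fixture(scope="session")
def echo64() -> SampledAxis:
    """64 echoes, 7.23 ms inter-echo spacing."""
    return echo_axis(64, 7.23)


@pytest.fixture(scope="session")
def locus64(echo64):
    return build_reference_locus(echo64)


@pytest.fixture(scope="session")
def b13() -> SampledAxis:
    """13 b-values: 0 plus 300..1200 s/mm^2."""
    return b_value_axis(13)


def naive_phasor(signal, harmonic=1):
    """Independent O(n) complex-summation oracle (pure Python, no numpy dot)."""
    import cmath

    n = len(signal)
    total = 0.0
    acc = 0j
    for k, s in enumerate(signal):
        total += float(s)
        acc += float(s) * cmath.exp(2j * cmath.pi * harmonic * k / n)
    acc /= total
    return acc.real, acc.imag


def monoexp(axis, tau):
    return np.exp(-axis.relative / tau)
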