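import numpy as np
import pytest

from coldcop import DecaySeries, GradientScheme

#: The experimental acquisition: diffusion time 90 ms, gradient pulse 1.9 ms.
DELTA = 0.0019
BIG_DELTA = 0.090


@pytest.fixture
def scheme8() -> GradientScheme:
    """Eight-gradient acquisition with the experimental timing parameters."""
    return GradientScheme(
        gradients=tuple(np.linspace(0.05, 0.5, 8)), delta=DELTA, big_delta=BIG_DELTA
    )


@pytest.fixture
def scheme16() -> GradientScheme:
    return GradientScheme(
        gradients=tuple(np.linspace(0.05, 0.5, 16)), delta=DELTA, big_delta=BIG_DELTA
    )


def make_decay(
    scheme: GradientScheme,
    d: float,
    i0: float = 1000.0,
    sigma: float = 0.0,
    seed: int = 0,
    peak_id: str = "pk",
    shift_ppm: float = 1.0,
) -> DecaySeries:
    """Stejskal–Tanner decay with optional multiplicative Gaussian noise."""
    clean = i0 * np.exp(-d * scheme.b_values())
    if sigma > 0:
        rng = np.random.default_rng(seed)
        clean = clean * (1.0 + rng.normal(0.0, sigma, size=len(clean)))
    return DecaySeries(peak_id=peak_id, shift_ppm=shift_ppm, intensities=tuple(clean))
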