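"""Spectral synthesis of stationary Gaussian noise with a prescribed ACF.

White Gaussian noise is shaped in the Fourier domain: its transform is
multiplied by the square root of the power spectral density implied by the
target autocorrelation (Wiener-Khinchin), then transformed back.  Negative
spectral values — possible for fitted ACF families that are not nonnegative
definite — are clipped to zero and counted.  To suppress the wrap-around
correlation of the circular embedding, twice the requested length is
generated and the first half returned, then the series is re-standardized to
mean 0 and the requested marginal SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import AcfModel

__all__ = ["ColoredNoiseRequest", "acf_to_psd", "generate_colored_gaussian"]


@dataclass(frozen=True)
class ColoredNoiseRequest:
    n: int
    dt: float
    acf: AcfModel
    marginal_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not self.marginal_sd > 0:
            raise ValueError("marginal_sd must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


def acf_to_psd(acf: AcfModel, n: int, dt: float, return_clipped: bool = False):
    """Discrete PSD of the circularly symmetrized ACF sequence.

    Evaluates the ACF at lags ``0..n-1`` (in seconds), symmetrizes it
    circularly (``c_sym[j] = c[min(j, n-j)]``) and takes the real DFT.
    Negative values are clipped to 0; with ``return_clipped=True`` the number
    of clipped bins is returned alongside.
    """
    k = np.arange(n)
    c = np.asarray(acf(dt * np.minimum(k, n - k)), dtype=float)
    spec = np.fft.fft(c).real
    clipped = int(np.sum(spec < 0))
    spec = np.maximum(spec, 0.0)
    if not np.any(spec > 0):
        raise ValueError("ACF produced an all-zero spectrum")
    if return_clipped:
        return spec, clipped
    return spec


def generate_colored_gaussian(req: ColoredNoiseRequest) -> np.ndarray:
    """Generate a stationary Gaussian series with the requested ACF.

    Deterministic given ``req.seed``.  The output has exactly mean 0 and SD
    ``req.marginal_sd`` (re-standardized after filtering, since clipping and
    windowing perturb the variance slightly).
    """
    rng = np.random.default_rng(req.seed)
    if req.acf.family == "white":
        z = rng.standard_normal(req.n)
    else:
        n_gen = 2 * req.n  # discard half: removes circular wrap-around bias
        psd = acf_to_psd(req.acf.normalized(), n_gen, req.dt)
        white = rng.standard_normal(n_gen)
        shaped = np.fft.ifft(np.fft.fft(white) * np.sqrt(psd)).real
        z = shaped[: req.n]
    z = z - z.mean()
    sd = z.std()
    if sd == 0:
        raise ValueError("degenerate colored-noise draw (zero variance)")
    return z * (req.marginal_sd / sd)
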