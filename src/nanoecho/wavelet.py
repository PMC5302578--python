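"""Minimal periodized Daubechies-4 discrete wavelet transform.

Only dyadic sub-band *energies* are needed downstream, so this
implements the analysis filter bank (circular convolution + decimation)
without bookkeeping for perfect reconstruction.  With a 50 MHz sampling
rate the level-k detail band is fs/2^(k+1) … fs/2^k, i.e. levels 1–4
cover 12.5–25, 6.25–12.5, 3.125–6.25 and 1.5625–3.125 MHz and the
level-4 approximation holds 0–1.5625 MHz.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d

__all__ = ["DB4_DEC_LO", "DB4_DEC_HI", "dwt_band_energies"]

# Daubechies-4 (8-tap) decomposition low-pass filter, pywt ordering.
DB4_DEC_LO = np.array([
    -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
    -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
    0.7148465705525415, 0.23037781330885523,
])
# Quadrature-mirror high-pass: h1[n] = (−1)^n · h0[L−1−n]
DB4_DEC_HI = DB4_DEC_LO[::-1].copy()
DB4_DEC_HI[1::2] *= -1.0


def _analysis_step(x: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    lo = convolve1d(x, DB4_DEC_LO[::-1], axis=axis, mode="wrap")
    hi = convolve1d(x, DB4_DEC_HI[::-1], axis=axis, mode="wrap")
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(None, None, 2)
    return lo[tuple(sl)], hi[tuple(sl)]


def dwt_band_energies(x: np.ndarray, levels: int = 4,
                      axis: int = -1) -> np.ndarray:
    """Sub-band energies of a ``levels``-deep Daubechies-4 decomposition.

    Parameters
    ----------
    x : ndarray
        Real signal(s); transformed along ``axis``.
    levels : int
        Decomposition depth; ``x.shape[axis]`` must be >= 2**levels.

    Returns
    -------
    ndarray with shape ``x.shape`` minus ``axis`` plus a trailing axis of
    length ``levels + 1`` ordered ``[d1, d2, ..., d_levels, a_levels]``
    (finest detail first, approximation last).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 2 ** levels:
        raise ValueError(f"signal length {n} too short for {levels} levels")
    energies = []
    approx = x
    for _ in range(levels):
        approx, detail = _analysis_step(approx, axis)
        energies.append(np.sum(detail ** 2, axis=axis))
    energies.append(np.sum(approx ** 2, axis=axis))
    return np.stack(energies, axis=-1)
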