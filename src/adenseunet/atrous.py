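"""Reference implementation of discrete atrous (dilated) convolution.

For a signal ``F`` and kernel ``k`` the dilated convolution with rate ``l``
is ``(F *_l k)(p) = sum_{s + l t = p} F(s) k(t)``: kernel taps are spaced
``l`` samples apart, so the receptive field grows without extra weights.
With ``l = 1`` this is the ordinary discrete convolution
``(F * k)(p) = sum_{s + t = p} F(s) k(t)``.

This module is a plain-NumPy executable definition, independent of the
autodiff engine used by the network layers; the network's convolutions are
checked against it (and against zero-inflated standard convolution) in the
test suite.
"""

from __future__ import annotations

import itertools

import numpy as np


def atrous_convolve(signal, kernel, rate: int) -> np.ndarray:
    """Dilated (atrous) convolution of a 1-D or 2-D signal, "same" output.

    Parameters
    ----------
    signal : array_like, 1-D or 2-D
    kernel : array_like, same number of dimensions as ``signal``
    rate : int
        Dilation rate ``l >= 1``; taps of the kernel are applied at spacing
        ``rate``.  ``rate = 1`` gives standard convolution.

    Returns
    -------
    numpy.ndarray with the same shape as ``signal`` (zero-padded "same"
    convention, centred like ``scipy.signal.convolve(..., mode="same")``
    with the zero-inflated kernel).
    """
    rate = int(rate)
    if rate < 1:
        raise ValueError("rate must be >= 1")
    signal = np.asarray(signal, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if signal.ndim not in (1, 2):
        raise ValueError("signal must be 1-D or 2-D")
    if kernel.ndim != signal.ndim:
        raise ValueError("kernel dimensionality must match the signal")
    eff = tuple((k - 1) * rate + 1 for k in kernel.shape)
    if any(e > s for e, s in zip(eff, signal.shape)):
        raise ValueError("dilated kernel larger than the (padded) signal")

    # full convolution accumulated tap by tap:  out[s + rate*t] += F[s] k[t]
    full_shape = tuple(s + e - 1 for s, e in zip(signal.shape, eff))
    full = np.zeros(full_shape)
    for t in itertools.product(*(range(k) for k in kernel.shape)):
        sl = tuple(
            slice(ti * rate, ti * rate + s) for ti, s in zip(t, signal.shape)
        )
        full[sl] += kernel[t] * signal
    # centre-crop to "same"
    off = tuple((e - 1) // 2 for e in eff)
    out_sl = tuple(slice(o, o + s) for o, s in zip(off, signal.shape))
    return full[out_sl]


def inflate_kernel(kernel, rate: int) -> np.ndarray:
    """Insert ``rate - 1`` zeros between consecutive kernel taps."""
    rate = int(rate)
    if rate < 1:
        raise ValueError("rate must be >= 1")
    kernel = np.asarray(kernel, dtype=float)
    shape = tuple((k - 1) * rate + 1 for k in kernel.shape)
    out = np.zeros(shape)
    out[tuple(slice(None, None, rate) for _ in kernel.shape)] = kernel
    return out
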