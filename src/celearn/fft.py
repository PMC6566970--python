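"""Frequency-magnitude features for raw sensor windows.

The "automatic" feature path: each channel of each window is mapped through
the unnormalized discrete Fourier transform and the per-bin modulus is
taken,

    x' = |F_C(x)|,

channel by channel.  All ``L`` bins are kept (including the conjugate
symmetric half of the spectrum of a real signal), so the output row has
exactly the dimension of the input window — a 6 x 128 window becomes 768
features.  Because ``|DFT|`` is invariant under circular time shifts, the
features are unaffected by where a periodic movement falls inside its
window, which is what makes them far more discriminative than raw samples
for windowed activity data.
"""

from __future__ import annotations

import numpy as np

from .containers import FeatureTable, RawWindowSet

__all__ = ["fft_magnitude"]


def fft_magnitude(windows: RawWindowSet) -> FeatureTable:
    """Per-channel DFT magnitude spectra, concatenated in channel order.

    Returns an unlabeled :class:`FeatureTable` with ``C * L`` columns per
    window, named ``<channel>_fft_<bin>``.  The DFT is unnormalized (no
    ``1/L`` factor) and all ``L`` bins per channel are retained so output
    and input dimensions match.
    """
    values = np.asarray(windows.values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("window values contain NaN or Inf")
    n, c, length = values.shape
    spectra = np.abs(np.fft.fft(values, axis=-1))
    features = spectra.reshape(n, c * length)
    names = [
        f"{ch}_fft_{b:03d}"
        for ch in windows.channel_names
        for b in range(length)
    ]
    return FeatureTable(features=features, feature_names=names)
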