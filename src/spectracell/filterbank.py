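"""Biorthogonal filter taps and the 3×3 kernels that seed every LSBDU.

The spectral downsampling unit is initialized from the Bior2.2 biorthogonal
wavelet family. Of that family's four filters only two have a 3-tap nonzero
support — the reconstruction low-pass and the decomposition high-pass — and
those are the ones that fit a 3×3 kernel:

    lowpass  = (√2/4,  √2/2, √2/4)
    highpass = (√2/4, −√2/2, √2/4)

Both are symmetric about their center; the high-pass sums to zero exactly, so
it annihilates constant signals. The 2-D kernels are separable tensor
products: ``phi = outer(low, low)`` (the LL product, rescaled to unit DC gain
so a constant image passes through the low branch unchanged) and
``psi = outer(high, high)`` (the HH product, zero-sum by construction since
``(Σh)² = 0``). A single high-pass kernel per channel is required by the
per-channel decomposition, and the HH product is the unique symmetric
zero-sum tensor product of these taps.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

__all__ = ["TapPair", "Kernel2DPair", "bior22_taps", "make_kernels"]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class TapPair:
    """A 1-D analysis pair: 3-tap low-pass and zero-sum high-pass filters."""

    lowpass: np.ndarray
    highpass: np.ndarray

    def __post_init__(self) -> None:
        low = np.asarray(self.lowpass, dtype=np.float64)
        high = np.asarray(self.highpass, dtype=np.float64)
        if low.shape != (3,) or high.shape != (3,):
            raise ValueError("taps must be length-3 vectors")
        if abs(high.sum()) > 1e-12:
            raise ValueError("high-pass taps must sum to zero")
        if not (np.allclose(low, low[::-1]) and np.allclose(high, high[::-1])):
            raise ValueError("taps must be symmetric about their center")
        object.__setattr__(self, "lowpass", low)
        object.__setattr__(self, "highpass", high)


@dataclass(frozen=True)
class Kernel2DPair:
    """A 3×3 low-pass kernel ``phi`` (unit sum) and high-pass ``psi`` (zero sum)."""

    phi: np.ndarray
    psi: np.ndarray


def bior22_taps() -> TapPair:
    """Return the 3-tap nonzero support of the Bior2.2 analysis pair.

    The low-pass is the family's reconstruction low-pass, the high-pass its
    decomposition high-pass; the longer 5/6-tap members cannot fit a 3×3
    kernel and are excluded.
    """
    low = np.array([_SQRT2 / 4, _SQRT2 / 2, _SQRT2 / 4])
    high = np.array([_SQRT2 / 4, -_SQRT2 / 2, _SQRT2 / 4])
    return TapPair(lowpass=low, highpass=high)


def make_kernels(taps: TapPair) -> Kernel2DPair:
    """Build the separable 3×3 kernel pair from 1-D taps.

    ``phi`` is the outer product of the low-pass with itself, rescaled so its
    nine entries sum to 1 (DC gain 1): a constant image passes through the
    low branch unchanged. ``psi`` is the outer product of the high-pass with
    itself; its entries sum to 0 automatically.

    Raises
    ------
    ValueError
        If the low-pass taps sum to zero, making unit-sum normalization
        impossible.
    """
    low_sum = float(np.sum(taps.lowpass))
    if abs(low_sum) < 1e-12:
        raise ValueError("low-pass taps sum to zero; cannot normalize phi to unit sum")
    phi = np.outer(taps.lowpass, taps.lowpass)
    phi = phi / phi.sum()
    psi = np.outer(taps.highpass, taps.highpass)
    return Kernel2DPair(phi=phi, psi=psi)
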