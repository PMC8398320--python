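"""Temporal preprocessing: band-pass filtering, the 15-band filter bank,
epoch cropping and anti-aliased resampling.

Filtering is zero-phase (forward-backward 4th-order Butterworth) and applied
per epoch, per channel.  Band-pass precedes cropping in the decoding
pipelines so filter transients fall partly outside the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = ["BandSpec", "bandpass", "make_filter_bank", "crop", "resample"]


@dataclass(frozen=True)
class BandSpec:
    """A band-pass frequency band in Hz."""

    low: float
    high: float
    name: str = ""

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band ({self.low}, {self.high}) Hz")

    def label(self) -> str:
        return self.name or f"{self.low:g}-{self.high:g}Hz"


#: broadband analysis band used for plain CSP decoding
BROADBAND = BandSpec(8.0, 30.0, "mu+beta")

#: multi-resolution filter bank: the broad mu+beta band, four canonical
#: rhythm bands, five 6-Hz bands starting at 7 Hz, and five overlapping
#: 6-Hz bands starting at 10 Hz.
_FILTER_BANK_EDGES = [
    (8, 30), (4, 7), (8, 13), (13, 30), (30, 40),
    (7, 13), (13, 19), (19, 25), (25, 31), (31, 37),
    (10, 16), (16, 22), (22, 28), (28, 34), (34, 40),
]


def make_filter_bank() -> list[BandSpec]:
    """The fixed 15-band multi-resolution filter bank, in canonical order."""
    return [BandSpec(float(lo), float(hi)) for lo, hi in _FILTER_BANK_EDGES]


def bandpass(e, band: BandSpec, order: int = 4):
    """Zero-phase Butterworth band-pass, independently per channel and trial.

    Shape is unchanged.  Raises if the band does not fit below the Nyquist
    frequency of ``e.fs``.
    """
    from .io_types import Epochs

    nyq = e.fs / 2.0
    if band.high >= nyq:
        raise ValueError(f"band high edge {band.high} Hz >= Nyquist {nyq} Hz at fs={e.fs}")
    sos = signal.butter(order, [band.low, band.high], btype="bandpass", fs=e.fs, output="sos")
    # sosfiltfilt pads by odd reflection, mitigating per-epoch edge effects
    out = signal.sosfiltfilt(sos, e.data, axis=0)
    return Epochs(out, e.labels.copy(), e.fs, list(e.channels), e.t0)


def crop(e, start_s: float, stop_s: float):
    """Restrict to the half-open window ``[start_s, stop_s)`` (seconds from
    stimulus onset); the output has ``round((stop - start) * fs)`` samples.
    """
    from .io_types import Epochs

    if stop_s <= start_s:
        raise ValueError(f"empty window [{start_s}, {stop_s})")
    i0 = int(round((start_s - e.t0) * e.fs))
    n_out = int(round((stop_s - start_s) * e.fs))
    if i0 < 0 or i0 + n_out > e.n_samples:
        raise ValueError(
            f"window [{start_s}, {stop_s}) s outside epoch support "
            f"[{e.t0}, {e.t0 + e.n_samples / e.fs}) s"
        )
    return Epochs(
        e.data[i0 : i0 + n_out].copy(), e.labels.copy(), e.fs, list(e.channels), start_s
    )


def resample(e, fs_target: float):
    """Anti-aliased polyphase resampling to ``fs_target`` Hz.

    Integer down-sampling ratios (512 -> 128, 1000 -> 100) are exact; the new
    trial length is ``round(T * fs_target / fs)``.
    """
    from .io_types import Epochs

    if fs_target <= 0:
        raise ValueError(f"fs_target must be positive, got {fs_target}")
    if fs_target > e.fs:
        raise ValueError(f"upsampling ({e.fs} -> {fs_target} Hz) is not supported")
    if fs_target == e.fs:
        return e.copy()
    frac = Fraction(fs_target / e.fs).limit_denominator(1000)
    out = signal.resample_poly(e.data, frac.numerator, frac.denominator, axis=0)
    return Epochs(out, e.labels.copy(), float(fs_target), list(e.channels), e.t0)
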