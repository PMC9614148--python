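"""Integer-coefficient denoising filters for arterial blood pressure signals.

Two causal filters whose coefficients are exact integers (up to a
power-of-two / power-of-C scale factor), so the recursion can run on
fixed-point hardware in real time:

* a comb **notch** filter with stop bands at 0 Hz, the mains fundamental
  ``f1`` and all its harmonics — removes AC interference and baseline
  drift.  It is built as an all-pass branch minus a comb band-pass branch,

  .. math:: F_1(z) = z^{-N(R-P)/2} - \\left[\\frac{1-z^{-R}}{Q(1-z^{-P})}\\right]^N

  with ``P = fs/f1``, ``R = P Q`` and ``Q`` a power of two;
* a moving-average **low-pass** filter with first spectral zero at ``f2``
  — removes EMG-like high-frequency interference,

  .. math:: F_2(z) = \\left[\\frac{1-z^{-C}}{C(1-z^{-1})}\\right]^N

  with ``C = fs/f2``.

Both transfer functions reduce to symmetric FIR kernels (the comb
denominators divide the numerators exactly), hence both have exactly
linear phase: a pure shift of ``N(R-P)/2`` resp. ``N(C-1)/2`` samples
realigns the output with the input.  :func:`preprocess` cascades the two
and performs that realignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .types import ABPRecord

__all__ = [
    "NotchFilterSpec",
    "LowpassFilterSpec",
    "design_notch",
    "design_lowpass",
    "notch_coefficients",
    "lowpass_coefficients",
    "notch_fir",
    "lowpass_fir",
    "apply_notch",
    "apply_lowpass",
    "notch_response",
    "lowpass_response",
    "preprocess",
]


@dataclass(frozen=True)
class NotchFilterSpec:
    """Design parameters of the integer-coefficient comb notch filter."""

    fs: float
    f1: float
    N: int = 2
    Q: int = 64

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("filter order N must be >= 1")
        if self.Q < 2 or (self.Q & (self.Q - 1)) != 0:
            raise ValueError(f"gain Q must be a power of two >= 2, got {self.Q}")
        p = self.fs / self.f1
        if abs(p - round(p)) > 1e-9 or round(p) < 1:
            raise ValueError(
                f"fs must be an integer multiple of the notch frequency: "
                f"fs/f1 = {self.fs}/{self.f1} is not an integer"
            )
        if (self.R - self.P) * self.N % 2 != 0:
            raise ValueError("N*(R-P) must be even for a linear-phase design")

    @property
    def P(self) -> int:
        """Denominator comb order, ``fs / f1``."""
        return int(round(self.fs / self.f1))

    @property
    def R(self) -> int:
        """Numerator comb order, ``P * Q``."""
        return self.P * self.Q

    @property
    def group_delay(self) -> int:
        """Passband group delay in samples, ``N (R - P) / 2``."""
        return self.N * (self.R - self.P) // 2


@dataclass(frozen=True)
class LowpassFilterSpec:
    """Design parameters of the integer-coefficient moving-average low-pass."""

    fs: float
    f2: float
    N: int = 2

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("filter order N must be >= 1")
        c = self.fs / self.f2
        if abs(c - round(c)) > 1e-9:
            raise ValueError(
                f"fs must be an integer multiple of the cut frequency: "
                f"fs/f2 = {self.fs}/{self.f2} is not an integer"
            )
        if round(c) < 2:
            raise ValueError("delay length C = fs/f2 must be >= 2")

    @property
    def C(self) -> int:
        """Comb delay length, ``fs / f2``."""
        return int(round(self.fs / self.f2))

    @property
    def group_delay(self) -> int:
        """Passband group delay in samples, ``floor(N (C - 1) / 2)``."""
        return self.N * (self.C - 1) // 2


def design_notch(fs: float, f1: float, N: int = 2, Q: int = 64) -> NotchFilterSpec:
    """Design the comb notch filter with stop bands at 0, f1, 2*f1, ... Hz.

    The defaults (``N=2``, ``Q=64``) at ``fs=250`` Hz, ``f1=50`` Hz give
    ``P=5`` and ``R=320``.
    """
    return NotchFilterSpec(fs=float(fs), f1=float(f1), N=int(N), Q=int(Q))


def design_lowpass(fs: float, f2: float, N: int = 2) -> LowpassFilterSpec:
    """Design the moving-average low-pass with first zero at ``f2`` Hz.

    The defaults (``N=2``) at ``fs=250`` Hz, ``f2=62.5`` Hz give ``C=4``.
    """
    return LowpassFilterSpec(fs=float(fs), f2=float(f2), N=int(N))


def _poly_power(p: np.ndarray, n: int) -> np.ndarray:
    out = np.array([1], dtype=np.int64)
    for _ in range(n):
        out = np.convolve(out, p)
    return out


def notch_coefficients(spec: NotchFilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rational transfer-function coefficients ``(b, a)`` of the notch.

    All entries are exact integers; ``a[0] == Q**N`` carries the scale.
    For the default design this reproduces the numerator
    ``-1 + 4096 z^-315 - 8190 z^-320 + 4096 z^-325 - z^-640`` over the
    denominator ``4096 (1 - 2 z^-5 + z^-10)``.
    """
    P, R, N, Q = spec.P, spec.R, spec.N, spec.Q
    comb_p = np.zeros(P + 1, dtype=np.int64)
    comb_p[0], comb_p[-1] = 1, -1  # 1 - z^-P
    comb_r = np.zeros(R + 1, dtype=np.int64)
    comb_r[0], comb_r[-1] = 1, -1  # 1 - z^-R
    a = Q**N * _poly_power(comb_p, N)  # Q^N (1 - z^-P)^N
    b = -_poly_power(comb_r, N)  # -(1 - z^-R)^N
    shift = spec.group_delay  # all-pass branch z^-shift * a
    b[shift : shift + a.size] += a
    return b, a


def lowpass_coefficients(spec: LowpassFilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rational transfer-function coefficients ``(b, a)`` of the low-pass.

    ``a[0] == C**N``; the first-order recursion ``y(n) = y(n-1) +
    (x(n) - x(n-C)) / C`` applied ``N`` times is the equivalent real-time
    form.
    """
    C, N = spec.C, spec.N
    comb_c = np.zeros(C + 1, dtype=np.int64)
    comb_c[0], comb_c[-1] = 1, -1  # 1 - z^-C
    comb_1 = np.array([1, -1], dtype=np.int64)  # 1 - z^-1
    b = _poly_power(comb_c, N)
    a = C**N * _poly_power(comb_1, N)
    return b, a


def notch_fir(spec: NotchFilterSpec) -> np.ndarray:
    """Equivalent FIR kernel of the notch (exact polynomial long division).

    ``(1 - z^-R) / (1 - z^-P)`` is the geometric comb
    ``1 + z^-P + ... + z^-(R-P)``, so the rational form collapses to a
    symmetric FIR of length ``N (R - P) + 1``.
    """
    P, R, N, Q = spec.P, spec.R, spec.N, spec.Q
    comb_sum = np.zeros(R - P + 1, dtype=np.int64)
    comb_sum[::P] = 1  # 1 + z^-P + ... + z^-(R-P)
    h = -_poly_power(comb_sum, N).astype(float) / float(Q**N)
    h[spec.group_delay] += 1.0
    return h


def lowpass_fir(spec: LowpassFilterSpec) -> np.ndarray:
    """Equivalent FIR kernel of the low-pass, length ``N (C - 1) + 1``."""
    C, N = spec.C, spec.N
    box = np.ones(C, dtype=np.int64)
    return _poly_power(box, N).astype(float) / float(C**N)


def _apply(record: ABPRecord, b: np.ndarray, a: np.ndarray) -> ABPRecord:
    y = lfilter(b.astype(float), a.astype(float), record.samples)
    return ABPRecord(
        samples=y,
        fs=record.fs,
        annotations=record.annotations,
        transient_samples=record.transient_samples,
        meta=dict(record.meta),
    )


def apply_notch(record: ABPRecord, spec: NotchFilterSpec) -> ABPRecord:
    """Run the notch recursion causally with zero initial state."""
    if abs(record.fs - spec.fs) > 1e-9:
        raise ValueError(
            f"record sampled at {record.fs} Hz but filter designed for {spec.fs} Hz"
        )
    return _apply(record, *notch_coefficients(spec))


def apply_lowpass(record: ABPRecord, spec: LowpassFilterSpec) -> ABPRecord:
    """Run the low-pass recursion causally with zero initial state."""
    if abs(record.fs - spec.fs) > 1e-9:
        raise ValueError(
            f"record sampled at {record.fs} Hz but filter designed for {spec.fs} Hz"
        )
    return _apply(record, *lowpass_coefficients(spec))


def _check_band(f: np.ndarray, fs: float) -> None:
    if np.any(f < 0) or np.any(f > fs / 2 + 1e-12):
        raise ValueError(f"frequency must lie in [0, {fs / 2}] Hz")


def notch_response(spec: NotchFilterSpec, f):
    """Complex frequency response of the notch at frequency ``f`` (Hz).

    Evaluates the closed form
    ``H1(w) = exp(-j w N (R-P)/2) * (1 - [sin(wR/2) / (Q sin(wP/2))]^N)``
    with the removable singularities at multiples of ``fs/P`` (where both
    sines vanish) filled in by their limits, so the magnitude is exactly 0
    at 0 Hz, ``f1`` and every harmonic of ``f1``.
    """
    scalar = np.isscalar(f)
    f = np.atleast_1d(np.asarray(f, dtype=float))
    _check_band(f, spec.fs)
    P, R, N, Q = spec.P, spec.R, spec.N, spec.Q
    w = 2.0 * np.pi * f / spec.fs
    num = np.sin(w * R / 2.0)
    den = Q * np.sin(w * P / 2.0)
    singular = np.abs(np.sin(w * P / 2.0)) < 1e-9
    ratio = np.empty_like(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio[~singular] = num[~singular] / den[~singular]
    # l'Hopital at w = 2 pi k / P: both sines vanish (R is a multiple of P)
    ratio[singular] = (R * np.cos(w[singular] * R / 2.0)) / (
        Q * P * np.cos(w[singular] * P / 2.0)
    )
    h = np.exp(-1j * w * spec.group_delay) * (1.0 - ratio**N)
    return complex(h[0]) if scalar else h


def lowpass_response(spec: LowpassFilterSpec, f):
    """Complex frequency response of the low-pass at frequency ``f`` (Hz).

    ``H2(w) = [exp(-j w (C-1)/2) sin(wC/2) / (C sin(w/2))]^N`` with the
    limit 1 at DC; the magnitude is 1 at 0 Hz and 0 at ``f2`` and its
    harmonics up to Nyquist.
    """
    scalar = np.isscalar(f)
    f = np.atleast_1d(np.asarray(f, dtype=float))
    _check_band(f, spec.fs)
    C, N = spec.C, spec.N
    w = 2.0 * np.pi * f / spec.fs
    singular = np.abs(np.sin(w / 2.0)) < 1e-12
    ratio = np.empty_like(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio[~singular] = np.sin(w[~singular] * C / 2.0) / (
            C * np.sin(w[~singular] / 2.0)
        )
    ratio[singular] = 1.0
    h = (np.exp(-1j * w * (C - 1) / 2.0) * ratio) ** N
    return complex(h[0]) if scalar else h


def preprocess(
    record: ABPRecord,
    notch: NotchFilterSpec | None = None,
    lowpass: LowpassFilterSpec | None = None,
) -> ABPRecord:
    """Denoise an ABP record: notch (AC + drift) then low-pass (EMG).

    The combined linear-phase group delay (318 samples for the default
    250 Hz design) is compensated by advancing the output, so detected
    beat positions align with the raw record.  The output keeps the input
    length; the tail is padded with the last filtered value.  The leading
    ``transient_samples`` span — where causal zero-state filtering has not
    yet converged — is flagged on the returned record and skipped by beat
    detection.
    """
    if notch is None:
        notch = design_notch(record.fs, 50.0)
    if lowpass is None:
        lowpass = design_lowpass(record.fs, record.fs / 4.0)
    delay = notch.group_delay + lowpass.group_delay
    # combined FIR length minus one; past this lag the causal output is exact
    settle = notch.N * (notch.R - notch.P) + lowpass.N * (lowpass.C - 1)
    if record.samples.size < settle:
        warnings.warn(
            f"record of {record.samples.size} samples is shorter than the "
            f"{settle}-sample filter transient; output is transient-dominated",
            stacklevel=2,
        )
    y = apply_lowpass(apply_notch(record, notch), lowpass).samples
    if y.size > delay:
        aligned = np.concatenate([y[delay:], np.full(delay, y[-1])])
    else:
        aligned = y
    return ABPRecord(
        samples=aligned,
        fs=record.fs,
        annotations=record.annotations,
        transient_samples=max(record.transient_samples, settle - delay),
        meta=dict(record.meta),
    )
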