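"""Loop (jittered-sequence) deconvolution by frequency-domain inverse filtering.

Model: the averaged multi-ISI steady-state record y is the circular
convolution of the implicit transient response x with the binary impulse
train s, plus residual noise.  In the DFT domain

    X(k) = Y(k) conj(S(k)) / (|S(k)|^2 + lambda)

which for lambda = 0 is exact division Y/S.  The jittered sequence is
designed so |S(k)| stays well away from zero in the band of interest;
bins below a configurable floor abort the lambda = 0 path.
"""

from __future__ import annotations

import numpy as np

from .core import SteadyStateRecord, TransientAEP, ValidationError
from .sequences import DEFAULT_CDEC_BAND, ImpulseTrain

SPECTRUM_FLOOR = 1e-8
IMAG_RESIDUE_TOL = 1e-9


def clad_deconvolve(
    record: SteadyStateRecord | np.ndarray,
    train: ImpulseTrain,
    ridge: float = 0.0,
    floor: float = SPECTRUM_FLOOR,
) -> TransientAEP:
    """Recover the transient response from a quasi-periodic averaged record.

    ``ridge`` is the Tikhonov constant added to |S|^2 in the inverse
    filter; the default 0 performs exact inverse filtering and requires
    all |S(k)| above ``floor``.
    """
    y = record.waveform if isinstance(record, SteadyStateRecord) else np.asarray(record, float)
    if y.size != train.n:
        raise ValidationError(
            f"record length {y.size} != impulse train length {train.n}")
    if ridge < 0:
        raise ValidationError("ridge must be >= 0")
    spectrum = np.fft.fft(train.samples)
    mags = np.abs(spectrum)
    if ridge == 0.0:
        bad = np.flatnonzero(mags < floor)
        if bad.size:
            raise ValidationError(
                f"|S(k)| below floor {floor} at bins {bad.tolist()[:16]}; "
                "use a ridge or a better-conditioned sequence")
    x_hat = np.fft.ifft(np.fft.fft(y) * np.conj(spectrum) / (mags**2 + ridge))
    signal_rms = np.sqrt(np.mean(np.abs(x_hat) ** 2))
    imag_rms = np.sqrt(np.mean(x_hat.imag**2))
    if signal_rms > 0 and imag_rms > IMAG_RESIDUE_TOL * signal_rms:
        raise ValidationError(
            f"imaginary residue {imag_rms:.3g} exceeds tolerance "
            f"(model violation): inputs are not real/circular")
    return TransientAEP(waveform=x_hat.real, fs=train.fs)


def predicted_noise_gain(
    train: ImpulseTrain,
    ridge: float = 0.0,
    band: tuple[float, float] = DEFAULT_CDEC_BAND,
    floor: float = SPECTRUM_FLOOR,
) -> float:
    """Closed-form in-band noise gain of the (possibly ridged) inverse filter.

    Per-bin gain is |S| / (|S|^2 + lambda); at lambda = 0 this reduces to
    the sequence's noise gain factor, and as lambda → ∞ the filter (and
    its gain) vanishes.
    """
    if ridge < 0:
        raise ValidationError("ridge must be >= 0")
    f_lo, f_hi = band
    spectrum = np.fft.rfft(train.samples)
    freqs = np.fft.rfftfreq(train.n, d=1.0 / train.fs)
    in_band = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    if not np.any(in_band):
        raise ValidationError(f"no DFT bins inside band {band}")
    mags = np.abs(spectrum[in_band])
    if ridge == 0.0:
        bad = np.flatnonzero(mags < floor)
        if bad.size:
            raise ValidationError(
                f"|S(k)| below floor {floor} at in-band bins {bad.tolist()[:16]}")
    gains = mags / (mags**2 + ridge)
    return float(np.sqrt(np.mean(gains**2)))
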