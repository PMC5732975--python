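"""Harmonic representation and statistical comparison of steady-state records.

A four-cycle record at fundamental f0 concentrates its energy at the DFT
bins that are multiples of the cycle count; the first three harmonics
(f0, 2 f0, 3 f0) summarize it as a six-element real vector (Re, Im per
harmonic) under an RMS amplitude convention.  Differences between
synthetic and recorded responses are tested pointwise (one-sample t per
time sample, no multiplicity correction) and jointly (one-sample
Hotelling T² on the six-element difference vectors, with a confidence
ellipse per harmonic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SteadyStateRecord, ValidationError


@dataclass(frozen=True)
class HarmonicSet:
    """Complex coefficients of harmonics 1..H, |c_h| = RMS amplitude (µV)."""

    f0: float
    coefficients: np.ndarray  # complex, length H
    n_cycles: int
    n_samples: int

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.coefficients)

    def as_vector(self) -> np.ndarray:
        """Interleaved (Re, Im) pairs: 2H real elements."""
        return np.column_stack(
            [self.coefficients.real, self.coefficients.imag]).ravel()


@dataclass(frozen=True)
class DiffTrace:
    mean: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray
    alpha: float

    @property
    def significant_fraction_pct(self) -> float:
        return 100.0 * float(self.mask.sum()) / self.mask.size


@dataclass(frozen=True)
class HotellingResult:
    n: int
    p: int
    mean: np.ndarray
    covariance: np.ndarray
    t2: float
    f: float
    p_value: float
    alpha: float
    ellipse_center: np.ndarray
    ellipse_axes: np.ndarray  # semi-axis lengths
    ellipse_directions: np.ndarray  # unit vectors, columns

    @property
    def df(self) -> tuple[int, int]:
        return (self.p, self.n - self.p)


def harmonic_set(record: SteadyStateRecord, n_harmonics: int = 3) -> HarmonicSet:
    """First-H harmonic coefficients of an integer-cycle record.

    The h-th harmonic lives at DFT bin h·C (C = number of cycles); the
    coefficient is scaled so its magnitude equals the RMS amplitude of
    that sinusoid (peak/√2).
    """
    if record.n_cycles is None:
        raise ValidationError("record must carry n_cycles (integer-cycle window)")
    c = int(record.n_cycles)
    length = record.n
    if length % c:
        raise ValidationError("record length not an integer multiple of the cycle")
    if n_harmonics * c >= (length // 2 + 1):
        raise ValidationError("requested harmonics exceed the Nyquist range")
    spectrum = np.fft.rfft(record.waveform)
    bins = c * np.arange(1, n_harmonics + 1)
    coefficients = spectrum[bins] * np.sqrt(2.0) / length
    f0 = record.fs * c / length
    return HarmonicSet(f0=f0, coefficients=coefficients, n_cycles=c, n_samples=length)


def reconstruct(hset: HarmonicSet, length: int | None = None) -> np.ndarray:
    """Inverse-synthesize the waveform carried by the stored harmonics."""
    length = hset.n_samples if length is None else int(length)
    spectrum = np.zeros(length // 2 + 1, dtype=complex)
    bins = hset.n_cycles * np.arange(1, hset.coefficients.size + 1)
    spectrum[bins] = hset.coefficients * length / np.sqrt(2.0)
    return np.fft.irfft(spectrum, n=length)


def pointwise_ttest(diff: np.ndarray, alpha: float = 0.05) -> DiffTrace:
    """Two-sided one-sample t-test against zero at every time sample.

    ``diff`` is subjects × samples.  No multiple-comparison correction is
    applied (by design).  Zero-variance columns get p = 1 when the mean is
    zero, else p = 0.
    """
    diff = np.atleast_2d(np.asarray(diff, dtype=float))
    if diff.shape[0] < 3:
        raise ValidationError("need at least 3 subjects for the pointwise test")
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_1samp(diff, 0.0, axis=0)
        p = np.asarray(result.pvalue, dtype=float)
    mean = diff.mean(axis=0)
    degenerate = diff.std(axis=0) == 0
    p[degenerate & (mean == 0)] = 1.0
    p[degenerate & (mean != 0)] = 0.0
    return DiffTrace(mean=mean, p_values=p, mask=p < alpha, alpha=alpha)


def hotelling_one_sample(vectors: np.ndarray, alpha: float = 0.05) -> HotellingResult:
    """One-sample Hotelling T² that the mean vector is zero.

    T² = n m' S⁻¹ m with sample mean m and covariance S; the F reference
    is F(p, n−p) via F = T² (n−p) / (p (n−1)).  The confidence ellipse for
    the mean is centered at m with semi-axes sqrt(eig(S/n)) scaled by
    sqrt(p (n−1)/(n−p) · F_α(p, n−p)).
    """
    x = np.atleast_2d(np.asarray(vectors, dtype=float))
    n, p = x.shape
    if n <= p:
        raise ValidationError(f"need n > p (got n={n}, p={p})")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1).reshape(p, p)
    try:
        solved = np.linalg.solve(cov, mean)
    except np.linalg.LinAlgError as err:
        raise ValidationError("singular sample covariance") from err
    t2 = float(n * mean @ solved)
    f = t2_to_f(t2, n, p)
    p_value = float(stats.f.sf(f, p, n - p))
    f_crit = stats.f.ppf(1 - alpha, p, n - p)
    scale = p * (n - 1) / (n - p) * f_crit
    eigvals, eigvecs = np.linalg.eigh(cov / n)
    eigvals = np.clip(eigvals, 0, None)
    return HotellingResult(
        n=n, p=p, mean=mean, covariance=cov, t2=t2, f=f, p_value=p_value,
        alpha=alpha, ellipse_center=mean,
        ellipse_axes=np.sqrt(eigvals * scale)[::-1],
        ellipse_directions=eigvecs[:, ::-1],
    )


def t2_to_f(t2: float, n: int, p: int) -> float:
    """Convert a Hotelling T² statistic to its F(p, n−p) equivalent."""
    if n <= p:
        raise ValidationError(f"need n > p (got n={n}, p={p})")
    return float(t2 * (n - p) / (p * (n - 1)))


def outlier_policy(vectors: np.ndarray, quantile: float = 0.975) -> np.ndarray:
    """Kept subject indices under a robust Mahalanobis-distance screen.

    Subjects whose robust squared distance exceeds the χ²(p) ``quantile``
    are removed.  This is a documented stand-in for a normality-driven
    manual exclusion; with degenerate (zero-variance) data nobody is
    removed.
    """
    x = np.atleast_2d(np.asarray(vectors, dtype=float))
    n, p = x.shape
    if n < 5:
        raise ValidationError("need at least 5 subjects for outlier screening")
    centered = x - np.median(x, axis=0)
    if np.allclose(centered, 0):
        return np.arange(n)
    d2 = _robust_mahalanobis_sq(x)
    cutoff = stats.chi2.ppf(quantile, df=p)
    return np.flatnonzero(d2 <= cutoff)


def _robust_mahalanobis_sq(x: np.ndarray) -> np.ndarray:
    """Squared robust distances (Minimum Covariance Determinant estimate)."""
    from sklearn.covariance import MinCovDet

    n, p = x.shape
    def _recalibrate(d2: np.ndarray) -> np.ndarray:
        # robust distances are inflated at moderate n; put the sample
        # median on the chi2 median
        med = np.median(d2)
        return d2 * stats.chi2.ppf(0.5, df=p) / med if med > 0 else d2

    try:
        mcd = MinCovDet(random_state=0).fit(x)
        d2 = _recalibrate(mcd.mahalanobis(x))
        # one reweighting pass: classical estimate on the clearly clean set
        keep = d2 <= stats.chi2.ppf(0.975, df=p)
        if keep.sum() > p + 1:
            center = x[keep].mean(axis=0)
            cov = np.cov(x[keep], rowvar=False, ddof=1).reshape(p, p)
            diff = x - center
            d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.pinv(cov), diff)
            d2 = _recalibrate(d2)
        return d2
    except (ValueError, np.linalg.LinAlgError):
        # degenerate scatter: fall back to classical distances with a pinv
        center = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, ddof=1).reshape(p, p)
        inv = np.linalg.pinv(cov)
        diff = x - center
        return np.einsum("ij,jk,ik->i", diff, inv, diff)
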