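"""Autocorrelation-aware statistics for MD-style time series.

Serially correlated frames carry fewer independent observations than their
raw count.  The statistical inefficiency

    g = 1 + 2 * sum_tau (1 - tau/n) * C(tau)

(C = normalised autocorrelation, sum truncated at its first non-positive
value) converts a series of length n into an effective sample size
N_eff = (T - t0 + 1)/g, where t0 is an equilibration point chosen to
maximise N_eff of the remaining suffix.  Standard errors are SD/sqrt(N_eff);
replicate simulations are combined by error propagation
SEM_total = sqrt(sum SEM_i^2) or, for occupancy-type quantities, from the
spread of replicate means as SD/sqrt(3).  Two-sample comparisons use a
Welch t-test with N_eff in place of the raw sample sizes.

Significance labels follow the convention *: p<0.05, **: p<0.001,
***: p<0.0001 (note the non-standard ** threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = ["StatSummary", "SignificanceResult", "statistical_inefficiency",
           "detect_equilibration", "sem_single", "sem_propagate",
           "sem_triplicate", "ttest_neff", "star_label"]


@dataclass(frozen=True)
class StatSummary:
    """Summary of one observable series."""

    mean: float
    sd: float
    g: float
    t0: int
    n_eff: float
    sem: float
    sem_defined: bool = True

    def __str__(self):
        return (f"mean={self.mean:.6g} ± {self.sem:.3g} (SD={self.sd:.3g}, "
                f"g={self.g:.3g}, t0={self.t0}, N_eff={self.n_eff:.1f})")


@dataclass(frozen=True)
class SignificanceResult:
    p_value: float
    stars: str
    test: str
    n_eff: tuple
    defined: bool = True


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    """Normalised autocorrelation C(tau) for tau = 0..n-1 via FFT."""
    n = x.size
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]


def statistical_inefficiency(series) -> float:
    """g ≥ 1; the factor by which serial correlation inflates the variance of
    the mean.  Truncates the autocorrelation sum at its first non-positive
    value (initial-positive-sequence style).  An exactly constant series has
    no correlation information and returns 1 with a warning."""
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValidationError("need at least 10 points to estimate g")
    if not np.all(np.isfinite(x)):
        raise ValidationError("series must be finite")
    if np.ptp(x) == 0:
        warnings.warn("constant series: statistical inefficiency undefined, using g=1")
        return 1.0
    c = _autocorrelation(x)
    n = x.size
    g = 1.0
    for tau in range(1, n):
        if c[tau] <= 0:
            break
        g += 2.0 * (1.0 - tau / n) * c[tau]
    return max(g, 1.0)


def detect_equilibration(series, n_candidates: int = 50):
    """Pick the equilibration start t0 maximising N_eff = (n - t0)/g of the
    suffix, scanning ``n_candidates`` evenly spaced candidates over the
    first 90% of the series.  Returns ``(t0, g_t0, n_eff)``."""
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValidationError("need at least 10 points")
    candidates = np.unique(np.linspace(0, int(0.9 * x.size), n_candidates).astype(int))
    best = (0, 1.0, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t0 in candidates:
            suffix = x[t0:]
            if suffix.size < 10:
                continue
            g = statistical_inefficiency(suffix)
            n_eff = suffix.size / g
            if n_eff > best[2]:
                best = (int(t0), g, n_eff)
    return best


def sem_single(series) -> StatSummary:
    """Mean ± SEM of one series with equilibration detection and the
    statistical-inefficiency correction: SEM = SD(suffix)/sqrt(N_eff)."""
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        return StatSummary(float(x[0]) if x.size else np.nan, 0.0, 1.0, 0,
                           float(x.size), 0.0)
    t0, g, n_eff = detect_equilibration(x)
    suffix = x[t0:]
    sd = float(suffix.std(ddof=1))
    defined = n_eff >= 2
    if not defined:
        warnings.warn("N_eff < 2: SEM unreliable")
    return StatSummary(float(suffix.mean()), sd, g, t0, n_eff,
                       sd / np.sqrt(n_eff), sem_defined=defined)


def sem_propagate(sems) -> float:
    """Combine independent SEMs by error propagation: sqrt(sum s_i^2)."""
    s = np.asarray(sems, dtype=float)
    if np.any(s < 0):
        raise ValidationError("SEMs must be non-negative")
    return float(np.sqrt((s ** 2).sum()))


def sem_triplicate(means) -> float:
    """SEM from replicate simulation means: SD(means)/sqrt(n) (n = 3 for the
    standard triplicate design); sample SD with n-1 denominator."""
    m = np.asarray(means, dtype=float)
    if m.size < 2:
        raise ValidationError("need at least 2 replicate means")
    return float(m.std(ddof=1) / np.sqrt(m.size))


def star_label(p: float) -> str:
    if np.isnan(p):
        return "ns"
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ttest_neff(a, b, mode: str = "timeseries") -> SignificanceResult:
    """Two-sided Welch t-test with effective sample sizes.

    ``mode="timeseries"``: a, b are correlated series; variances and N_eff
    come from :func:`sem_single` (decorrelation + equilibration detection).
    ``mode="triplicate"``: a, b are small arrays of replicate means
    (typically 3), used directly with N_eff = len.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "timeseries":
        sa, sb = sem_single(a), sem_single(b)
        ma, mb = sa.mean, sb.mean
        va, vb = sa.sd ** 2, sb.sd ** 2
        na, nb = sa.n_eff, sb.n_eff
    elif mode == "triplicate":
        if a.size < 2 or b.size < 2:
            raise ValidationError("triplicate mode needs >= 2 replicate means per group")
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = float(a.size), float(b.size)
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    se2 = va / na + vb / nb
    if se2 == 0:
        if ma == mb:
            return SignificanceResult(1.0, "ns", f"welch-{mode}", (na, nb))
        return SignificanceResult(np.nan, "ns", f"welch-{mode}", (na, nb), defined=False)
    t = (ma - mb) / np.sqrt(se2)
    # Welch–Satterthwaite degrees of freedom on the effective sample sizes
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return SignificanceResult(float(p), star_label(p), f"welch-{mode}", (na, nb))
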