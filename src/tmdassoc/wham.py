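"""WHAM estimation of a 1-D PMF from umbrella-sampling windows.

The weighted histogram analysis method merges the biased histograms
{n_ij} of windows i (bias U_i, N_i samples) into one unbiased profile by
iterating the coupled equations

    p_j = ( Σ_i n_ij ) / ( Σ_i N_i exp[(f_i - U_i(r_j)) / kT] )
    f_i = -kT ln Σ_j exp(-U_i(r_j)/kT) p_j

to self-consistency; w(r_j) = -kT ln p_j up to an additive constant fixed
by anchoring (conventionally w = 0 at the dissociated distance, 20 Å).
Per-bin uncertainties come from Monte-Carlo bootstrap over decorrelated
samples (resampling N_eff,i points per window, where N_eff accounts for the
statistical inefficiency of each window's series).

The module is organised like a statsmodels estimator: build
:class:`UmbrellaPMF` from data, call :meth:`~UmbrellaPMF.fit`, and work with
the returned :class:`PMFResult`.  Functional wrappers (:func:`solve_wham`,
:func:`bootstrap_pmf`, :func:`anchor`, :func:`convergence_scan`) cover the
same operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from . import constants
from .exceptions import ConvergenceError, ValidationError, WindowGapError
from .windows import UmbrellaWindowSeries
from .stats import statistical_inefficiency

__all__ = ["UmbrellaPMF", "PMFResult", "solve_wham", "bootstrap_pmf",
           "anchor", "convergence_scan"]


@dataclass
class PMFResult:
    """A fitted PMF: binned w(r) with window shifts and (optionally)
    bootstrap errors.  ``w(r_zero) = 0`` after anchoring."""

    bin_centers: np.ndarray      # populated bins only, Å
    w: np.ndarray                # kcal/mol
    f: np.ndarray                # per-window free-energy shifts, kcal/mol
    temperature: float
    n_iter: int
    converged: bool
    r_zero: float | None = None
    sd: np.ndarray | None = None  # per-bin bootstrap SD, kcal/mol
    model: "UmbrellaPMF | None" = None

    def __call__(self, r):
        """Piecewise-linear interpolation of w(r)."""
        return np.interp(r, self.bin_centers, self.w)

    def anchor(self, r_zero: float = 20.0) -> "PMFResult":
        """Shift so the interpolated w(r_zero) = 0 (idempotent)."""
        lo, hi = self.bin_centers[0], self.bin_centers[-1]
        if not lo <= r_zero <= hi:
            raise ValidationError(f"anchor {r_zero} outside PMF range [{lo}, {hi}] Å")
        return replace(self, w=self.w - self(r_zero), r_zero=r_zero)

    def bootstrap(self, n_trials: int = 200, seed: int = 0) -> "PMFResult":
        if self.model is None:
            raise ValidationError("bootstrap requires the fitted model")
        sd = self.model._bootstrap_sd(self, n_trials=n_trials, seed=seed)
        return replace(self, sd=sd)

    def association(self, **kwargs):
        """Binding thermodynamics from this profile; see
        :func:`tmdassoc.association.associate`."""
        from .association import associate
        return associate(self, **kwargs)

    def summary(self) -> str:
        lines = [
            "Umbrella-sampling PMF (WHAM)",
            "=" * 44,
            f"windows:        {len(self.f)}",
            f"temperature:    {self.temperature:g} K",
            f"bins (pop.):    {self.bin_centers.size} "
            f"[{self.bin_centers[0]:.2f}, {self.bin_centers[-1]:.2f}] Å",
            f"iterations:     {self.n_iter} ({'converged' if self.converged else 'NOT converged'})",
            f"anchor:         {'w(%g Å) = 0' % self.r_zero if self.r_zero is not None else 'none'}",
            f"min w(r):       {self.w.min():.3f} kcal/mol at r = "
            f"{self.bin_centers[np.argmin(self.w)]:.2f} Å",
        ]
        if self.sd is not None:
            lines.append(f"median boot SD: {np.median(self.sd):.4f} kcal/mol")
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd
        data = {"r": self.bin_centers, "w": self.w}
        if self.sd is not None:
            data["sd"] = self.sd
        return pd.DataFrame(data)

    def plot(self, ax=None, **kwargs):
        """PMF curve with the bootstrap error band (if available)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.bin_centers, self.w, **kwargs)
        if self.sd is not None:
            ax.fill_between(self.bin_centers, self.w - self.sd, self.w + self.sd,
                            alpha=0.3, color="red")
        ax.set_xlabel("d$_{COM-COM}$ (Å)")
        ax.set_ylabel("w(r) (kcal/mol)")
        return ax


class UmbrellaPMF:
    """WHAM model for a set of umbrella windows.

    Parameters
    ----------
    windows : sequence of UmbrellaWindowSeries
        Biased reaction-coordinate series (≥ 2 windows; sorted internally).
    temperature : float
        Kelvin.
    bin_width : float
        Histogram bin width in Å.  Bin centers are aligned to multiples of
        the width, so the conventional 20 Å anchor coincides with a bin
        center at the default width.
    bin_range : (lo, hi), optional
        Coordinate range; default is [min center - 2σ, max center + 2σ]
        (σ = per-window harmonic width), widened to cover every sample.
    """

    def __init__(self, windows, temperature: float = 300.0, bin_width: float = 0.1,
                 bin_range=None):
        windows = sorted(windows, key=lambda w: w.bias.center)
        if len(windows) < 1:
            raise ValidationError("WHAM needs at least 1 window")
        if any(w.n_samples == 0 for w in windows):
            raise ValidationError("every window needs at least one sample")
        self.windows = windows
        self.temperature = float(temperature)
        self.kt = constants.kt(temperature)
        self.bin_width = float(bin_width)
        self._setup_grid(bin_range)
        self._histogram()
        self._check_overlap()

    # -- setup -------------------------------------------------------------

    def _setup_grid(self, bin_range):
        if bin_range is None:
            kt = self.kt
            sig = np.array([np.sqrt(kt / (w.bias.force_constant *
                                          (1.0 if w.bias.half_factor else 2.0)))
                            for w in self.windows])
            centers = np.array([w.bias.center for w in self.windows])
            lo = (centers - 2 * sig).min()
            hi = (centers + 2 * sig).max()
            lo = min(lo, min(w.values.min() for w in self.windows))
            hi = max(hi, max(w.values.max() for w in self.windows))
        else:
            lo, hi = bin_range
        width = self.bin_width
        # snap bin CENTERS onto the k*width lattice, rounded so that lattice
        # points like 20.0 are exact floats (the anchor convention relies on it)
        i0 = int(np.floor(lo / width))
        i1 = int(np.ceil(hi / width))
        self.bin_centers_all = np.round(np.arange(i0, i1 + 1) * width, 9)
        self.bin_edges = np.concatenate([self.bin_centers_all - width / 2,
                                         [self.bin_centers_all[-1] + width / 2]])

    def _histogram(self):
        self.counts = np.array([np.histogram(w.values, bins=self.bin_edges)[0]
                                for w in self.windows])
        self.n_per_window = self.counts.sum(axis=1)
        # bias energy of every window at every bin center, in kT units
        self.u_kt = np.array([w.bias.energy(self.bin_centers_all)
                              for w in self.windows]) / self.kt

    def _check_overlap(self):
        pop = [set(np.flatnonzero(c)) for c in self.counts]
        gaps = []
        for i in range(len(pop) - 1):
            if not pop[i] & pop[i + 1]:
                a, b = self.windows[i].bias.center, self.windows[i + 1].bias.center
                gaps.append((a, b))
        if gaps:
            raise WindowGapError(
                "non-overlapping neighbouring windows (no shared populated bin): "
                + ", ".join(f"{a:g}–{b:g} Å" for a, b in gaps))

    # -- solver ------------------------------------------------------------

    def _solve(self, counts, n_per_window, tol, max_iter, f_init=None):
        """Self-consistent iteration; returns (ln p over all bins, f, iters, ok).

        Runs in linear space with the bias Boltzmann factors exp(-U_i(r_j)/kT)
        precomputed once (they underflow harmlessly far from each window's
        center); each iteration is two small matrix products.
        """
        m_j = counts.sum(axis=0).astype(float)        # (n_bins,)
        populated = m_j > 0
        boltz = self._bias_boltzmann()                # (n_win, n_bins)
        f_kt = np.zeros(len(n_per_window)) if f_init is None else f_init / self.kt
        n = np.asarray(n_per_window, dtype=float)
        delta = np.inf
        n_iter = 0
        with np.errstate(divide="ignore", over="ignore"):
            for n_iter in range(1, int(max_iter) + 1):
                denom = (n * np.exp(f_kt)) @ boltz    # Σ_i N_i e^{f_i} e^{-u_ij}
                p = np.where(populated, m_j / denom, 0.0)
                z = boltz @ p
                f_new = -np.log(z)
                f_new -= f_new[0]
                delta = np.max(np.abs(f_new - f_kt)) * self.kt
                f_kt = f_new
                if delta < tol:
                    break
            ln_p = np.where(populated, np.log(np.where(populated, p, 1.0)), -np.inf)
        return ln_p, f_kt * self.kt, n_iter, delta < tol, delta

    def _bias_boltzmann(self):
        if not hasattr(self, "_boltz_cache"):
            self._boltz_cache = np.exp(-self.u_kt)
        return self._boltz_cache

    def fit(self, tol: float = 1e-7, max_iter: int = 100_000,
            anchor_at: float | None = 20.0, strict: bool = True) -> PMFResult:
        """Iterate WHAM to self-consistency.

        ``tol`` is on the per-window shifts f_i in kcal/mol.  ``anchor_at``
        sets the zero of the profile (None leaves the raw gauge).  With
        ``strict`` a failure to converge raises :class:`ConvergenceError`.
        """
        ln_p, f, n_iter, converged, resid = self._solve(
            self.counts, self.n_per_window, tol, max_iter)
        if not converged and strict:
            raise ConvergenceError(
                f"WHAM did not converge in {max_iter} iterations "
                f"(residual {resid:.3g} kcal/mol > tol {tol:g})")
        populated = np.isfinite(ln_p)
        w = -self.kt * ln_p[populated]
        result = PMFResult(self.bin_centers_all[populated], w, f,
                           self.temperature, n_iter, converged, model=self)
        if anchor_at is not None:
            result = result.anchor(anchor_at)
        return result

    # -- bootstrap ---------------------------------------------------------

    def _bootstrap_sd(self, result: PMFResult, n_trials: int, seed: int) -> np.ndarray:
        if n_trials < 2:
            raise ValidationError("bootstrap needs at least 2 trials")
        rng = np.random.default_rng(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_eff = [max(2, int(w.n_samples / statistical_inefficiency(w.values)))
                     for w in self.windows]
        populated_full = np.isin(self.bin_centers_all, result.bin_centers)
        trials = np.full((n_trials, populated_full.sum()), np.nan)
        f_warm = result.f.copy()
        for t in range(n_trials):
            counts = np.empty_like(self.counts)
            for i, w in enumerate(self.windows):
                resampled = rng.choice(w.values, size=n_eff[i], replace=True)
                counts[i] = np.histogram(resampled, bins=self.bin_edges)[0]
            ln_p, f_t, *_ = self._solve(counts, counts.sum(axis=1),
                                        tol=1e-6, max_iter=50_000, f_init=f_warm)
            f_warm = f_t
            w_t = -self.kt * ln_p[populated_full]
            if result.r_zero is not None:
                ok = np.isfinite(w_t)
                w_t = w_t - np.interp(result.r_zero,
                                      result.bin_centers[ok], w_t[ok])
            trials[t] = np.where(np.isfinite(w_t), w_t, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sd = np.nanstd(trials, axis=0, ddof=1)
        return np.nan_to_num(sd, nan=np.inf)


# -- functional wrappers -----------------------------------------------------

def solve_wham(windows, temperature: float = 300.0, bin_width: float = 0.1,
               tol: float = 1e-7, max_iter: int = 100_000,
               anchor_at: float | None = 20.0) -> PMFResult:
    """Fit a PMF to umbrella windows (see :class:`UmbrellaPMF`)."""
    return UmbrellaPMF(windows, temperature, bin_width).fit(
        tol=tol, max_iter=max_iter, anchor_at=anchor_at)


def bootstrap_pmf(windows, n_trials: int = 200, seed: int = 0, **fit_kwargs) -> PMFResult:
    """Fit plus Monte-Carlo bootstrap errors (``sd`` attribute filled in)."""
    return solve_wham(windows, **fit_kwargs).bootstrap(n_trials=n_trials, seed=seed)


def anchor(profile: PMFResult, r_zero: float = 20.0) -> PMFResult:
    """Shift a profile so w(r_zero) = 0."""
    return profile.anchor(r_zero)


def convergence_scan(windows, fractions=(0.25, 0.5, 0.75, 1.0),
                     temperature: float = 300.0, bin_width: float = 0.1,
                     anchor_at: float | None = 20.0, tol: float = 1e-7):
    """Re-fit on growing prefixes of every window.

    Returns ``(profiles, max_deviations)``: one :class:`PMFResult` per
    fraction and the maximal |Δw| between successive profiles (evaluated on
    the later profile's bins), a direct convergence diagnostic.
    """
    fractions = list(fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValidationError("fractions must lie in (0, 1]")
    profiles = []
    for frac in fractions:
        subset = []
        for w in windows:
            n = int(round(frac * w.n_samples))
            if n < 1:
                raise ValidationError(
                    f"fraction {frac} empties window centered at {w.bias.center} Å")
            subset.append(UmbrellaWindowSeries(w.bias, w.times[:n], w.values[:n],
                                               label=w.label))
        profiles.append(solve_wham(subset, temperature=temperature,
                                   bin_width=bin_width, anchor_at=anchor_at, tol=tol))
    max_dev = []
    for prev, cur in zip(profiles, profiles[1:]):
        lo = max(prev.bin_centers[0], cur.bin_centers[0])
        hi = min(prev.bin_centers[-1], cur.bin_centers[-1])
        mask = (cur.bin_centers >= lo) & (cur.bin_centers <= hi)
        max_dev.append(float(np.max(np.abs(cur.w[mask] - prev(cur.bin_centers[mask])))))
    return profiles, max_dev
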