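"""Synthetic biased sampling on analytic landscapes, and correlated series.

The umbrella "simulator" is a Metropolis random walk on the 1-D reaction
coordinate whose stationary density in window i is the biased Boltzmann
density  p_i(r) ∝ exp(-[w(r) + U_i(r)] / kT).  Only the stationary
distribution matters for WHAM correctness; the walk's serial correlation is
itself useful, since it exercises the statistical-inefficiency machinery the
same way correlated MD frames do.

Reproducibility: each window draws from an independent child RNG seeded with
``cfg.seed + window_index``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .exceptions import ValidationError
from .landscape import FreeEnergyLandscape
from .windows import BiasSpec, UmbrellaWindowSeries
from . import constants

__all__ = ["SamplerConfig", "simulate_umbrella_series", "generate_ar1_series"]


@dataclass(frozen=True)
class SamplerConfig:
    """Metropolis sampler settings.

    Parameters
    ----------
    temperature : float
        Kelvin; sets the Boltzmann factor.
    proposal_sigma : float
        Standard deviation of the Gaussian step proposal, Å.  ~0.3 Å gives
        ~50-70% acceptance for the default landscapes and biases.
    n_steps : int
        Post-burn-in steps per window.
    stride : int
        Keep every ``stride``-th post-burn-in step.
    burn_in : int
        Steps discarded before recording starts.  Default chosen as 10% of
        ``n_steps`` by :func:`simulate_umbrella_series` when left at -1.
    seed : int
        Base seed; window i uses ``seed + i``.
    """

    temperature: float = 300.0
    proposal_sigma: float = 0.3
    n_steps: int = 20_000
    stride: int = 1
    burn_in: int = -1
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0, got {self.temperature}")
        if self.proposal_sigma <= 0:
            raise ValidationError("proposal_sigma must be > 0")
        if self.n_steps <= 0 or self.stride <= 0:
            raise ValidationError("n_steps and stride must be positive")

    @property
    def effective_burn_in(self) -> int:
        burn = self.burn_in if self.burn_in >= 0 else self.n_steps // 10
        if burn >= self.n_steps + burn and burn < 0:  # pragma: no cover - guarded above
            raise ValidationError("burn_in must be < total steps")
        return burn


def simulate_umbrella_series(landscape: FreeEnergyLandscape, biases, cfg: SamplerConfig
                             ) -> list[UmbrellaWindowSeries]:
    """Sample every umbrella window of ``biases`` on ``landscape``.

    All windows are advanced in lockstep (vectorised across windows) but each
    consumes only its own RNG stream, so adding/removing windows does not
    perturb the others' samples.

    Returns one :class:`UmbrellaWindowSeries` per bias, in input order.
    ``times`` are the post-burn-in step indices that were kept.
    """
    biases = list(biases)
    if not biases:
        raise ValidationError("need at least one bias window")
    centers = np.array([b.center for b in biases], dtype=float)
    if np.any(np.diff(centers) < 0):
        raise ValidationError("biases must be ordered by center")
    for b in biases:
        if not landscape.contains(b.center):
            raise ValidationError(
                f"bias center {b.center} Å outside landscape grid "
                f"[{landscape.r_min}, {landscape.r_max}] Å")

    beta = 1.0 / constants.kt(cfg.temperature)
    burn = cfg.effective_burn_in
    n_total = burn + cfg.n_steps
    n_win = len(biases)

    # Per-window RNG streams, pre-drawn so the time loop is vectorised.
    steps = np.empty((n_win, n_total))
    logu = np.empty((n_win, n_total))
    for i in range(n_win):
        rng = np.random.default_rng(cfg.seed + i)
        steps[i] = rng.normal(0.0, cfg.proposal_sigma, n_total)
        logu[i] = np.log(rng.random(n_total))

    k = np.array([b.force_constant for b in biases])
    half = np.where([b.half_factor for b in biases], 0.5, 1.0)
    grid, wgrid = landscape.grid_r, landscape.w
    lo, hi = landscape.r_min, landscape.r_max

    def energy(r):
        return np.interp(r, grid, wgrid) + half * k * (r - centers) ** 2

    r = centers.copy()
    e = energy(r)
    kept = np.empty((n_win, (cfg.n_steps + cfg.stride - 1) // cfg.stride))
    kept_times = np.empty(kept.shape[1])
    j = 0
    for t in range(n_total):
        r_new = r + steps[:, t]
        inside = (r_new >= lo) & (r_new <= hi)
        e_new = np.where(inside, energy(np.clip(r_new, lo, hi)), np.inf)
        accept = logu[:, t] < -beta * (e_new - e)
        r = np.where(accept, r_new, r)
        e = np.where(accept, e_new, e)
        tt = t - burn
        if tt >= 0 and tt % cfg.stride == 0:
            kept[:, j] = r
            kept_times[j] = tt
            j += 1

    return [
        UmbrellaWindowSeries(b, kept_times[:j].copy(), kept[i, :j].copy(),
                             label=f"win{i:02d}_c{b.center:g}")
        for i, b in enumerate(biases)
    ]


def generate_ar1_series(rho: float, n: int, seed: int = 0,
                        mean: float = 0.0, sigma: float = 1.0) -> np.ndarray:
    """Stationary Gaussian AR(1) series x_t = rho x_{t-1} + sqrt(1-rho^2) e_t.

    Marginal distribution is exactly N(mean, sigma^2) for every t (the first
    value is drawn from the stationary law, not burnt in).  Statistical
    inefficiency of the result is (1+rho)/(1-rho).
    """
    if not -1.0 < rho < 1.0:
        raise ValidationError(f"AR(1) correlation must satisfy |rho| < 1, got {rho}")
    if n < 1:
        raise ValidationError("series length must be >= 1")
    rng = np.random.default_rng(seed)
    x0 = rng.normal()
    if n == 1:
        return mean + sigma * np.array([x0])
    innov = rng.normal(size=n - 1) * np.sqrt(1.0 - rho ** 2)
    # lfilter computes x_t = rho*x_{t-1} + innov_t; zi carries rho*x0 forward.
    tail, _ = lfilter([1.0], [1.0, -rho], innov, zi=np.array([rho * x0]))
    return mean + sigma * np.concatenate([[x0], tail])
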