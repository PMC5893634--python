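"""Binding thermodynamics of in-membrane helix dimerization from a PMF.

Following the two-body membrane derivation (Johnston et al.), the
area-scale association constant is

    K_a = ||Ω||/(2π)^2 ∫_0^D r exp(-w(r)/k_B T) dr        [Å²]

where D is the largest separation still counted as a dimer and ||Ω|| is the
configurational-restriction factor: the product of the sampled ranges of
the two helix-packing angles in the dimer state,

    ||Ω|| = [max θ_a - min θ_a] · [max θ_b - min θ_b]     [rad²]

compared to the (2π)² available to free monomers.  The mole-fraction
constant and standard free energy follow as

    K_x = K_a N_L / A,      ΔG = -RT ln K_x

with N_L lipids per leaflet of area A.  The association barrier read off
the PMF also yields a coarse transition-state-theory upper bound on the
association rate, k = k‡ exp(-ΔG‡/RT), with k‡ a collision frequency
(10^5–10^6 s⁻¹ for a transmembrane protein).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np

from . import constants
from .exceptions import ValidationError

__all__ = ["AssociationResult", "omega_norm", "association_constant",
           "mole_fraction_constant", "delta_g", "find_minima_and_barrier",
           "tst_rate", "associate"]

TWO_PI_SQ = (2 * np.pi) ** 2

#: default lipid count per leaflet and leaflet area (Å²); 85 lipids at the
#: ~70 Å² DOPC area per lipid.  Both are plain user inputs.
DEFAULT_N_LIPIDS = 85
DEFAULT_AREA = 5950.0


@dataclass
class AssociationResult:
    """All inputs and outputs of one association free-energy evaluation."""

    omega: float                 # rad², ≤ (2π)²
    k_a: float                   # Å²
    k_x: float                   # dimensionless
    delta_g: float               # kcal/mol
    dimer_cutoff: float          # D, Å
    temperature: float           # K
    n_lipids: float
    area: float                  # Å²
    barrier: float | None = None       # ΔG‡, kcal/mol
    tst_rate: float | None = None      # s⁻¹
    tst_prefactor: float | None = None
    minima: list = field(default_factory=list)   # (r, w) pairs

    def summary(self) -> str:
        lines = [
            "TM helix association thermodynamics",
            "=" * 44,
            f"||Ω||:          {self.omega:.4g} rad²  "
            f"({self.omega / TWO_PI_SQ:.3%} of (2π)²)",
            f"K_a:            {self.k_a:.4g} Å²   (D = {self.dimer_cutoff:g} Å)",
            f"K_x:            {self.k_x:.4g}      (N_L/A = {self.n_lipids:g}/"
            f"{self.area:g} Å⁻²)",
            f"ΔG:             {self.delta_g:.2f} kcal/mol at {self.temperature:g} K",
        ]
        if self.minima:
            locs = ", ".join(f"{r:.1f}" for r, _ in self.minima)
            lines.append(f"PMF minima at:  {locs} Å")
        if self.barrier is not None:
            lines.append(f"ΔG‡:            {self.barrier:.2f} kcal/mol")
        if self.tst_rate is not None:
            lines.append(f"TST rate ≤      {self.tst_rate:.3g} s⁻¹ "
                         f"(k‡ = {self.tst_prefactor:.3g} s⁻¹)")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text


def omega_norm(theta_a, theta_b, dimer_mask=None) -> float:
    """Configurational restriction ||Ω|| from two angle series (radians).

    ``dimer_mask`` restricts both series to dimer-state frames before the
    ranges are taken.
    """
    theta_a = np.asarray(theta_a, dtype=float)
    theta_b = np.asarray(theta_b, dtype=float)
    if dimer_mask is not None:
        mask = np.asarray(dimer_mask, dtype=bool)
        theta_a, theta_b = theta_a[mask], theta_b[mask]
    if theta_a.size == 0 or theta_b.size == 0:
        raise ValidationError("no dimer-state frames to take angle ranges over")
    omega = float(np.ptp(theta_a) * np.ptp(theta_b))
    return min(omega, TWO_PI_SQ)


def association_constant(pmf, dimer_cutoff: float = 12.0,
                         temperature: float | None = None,
                         omega: float = TWO_PI_SQ) -> float:
    """K_a in Å² by trapezoidal quadrature of r·exp(-w/kT) over the PMF grid.

    The integral nominally starts at r = 0, but a PMF exists only from the
    smallest sampled bin; integration therefore starts there (a warning is
    issued if the profile is not strongly repulsive at its inner edge, i.e.
    if the neglected region could contribute).  The value of w at the dimer
    cutoff D is obtained by interpolation and included as the final node.
    """
    r, w, temperature = _profile_arrays(pmf, temperature)
    if dimer_cutoff < r[0]:
        raise ValidationError(
            f"dimer cutoff D = {dimer_cutoff} Å below the smallest PMF bin {r[0]:.2f} Å")
    if w[0] < w.min() + 2.0:
        warnings.warn(
            f"PMF at its inner edge ({r[0]:.2f} Å) is only {w[0] - w.min():.2f} "
            "kcal/mol above the minimum; the truncated r < r_min region may "
            "contribute to K_a")
    kt = constants.kt(temperature)
    mask = r <= dimer_cutoff
    rr = np.append(r[mask], dimer_cutoff)
    ww = np.append(w[mask], np.interp(dimer_cutoff, r, w))
    integrand = rr * np.exp(-ww / kt)
    return float(omega / TWO_PI_SQ * np.trapezoid(integrand, rr))


def mole_fraction_constant(k_a: float, n_lipids: float = DEFAULT_N_LIPIDS,
                           area: float = DEFAULT_AREA) -> float:
    """K_x = K_a · N_L / A (dimensionless)."""
    if k_a < 0:
        raise ValidationError("K_a must be non-negative")
    if n_lipids <= 0 or area <= 0:
        raise ValidationError("lipid count and area must be positive")
    return k_a * n_lipids / area


def delta_g(k_x: float, temperature: float = 300.0) -> float:
    """ΔG = -RT ln K_x in kcal/mol; K_x > 1 gives a favourable (negative) ΔG."""
    if k_x <= 0:
        raise ValidationError("K_x must be positive to take a free energy")
    return float(-constants.R_KCAL * temperature * np.log(k_x))


def _profile_arrays(pmf, temperature):
    """Accept a PMFResult-like object or an (r, w) pair."""
    if hasattr(pmf, "bin_centers"):
        r = np.asarray(pmf.bin_centers, dtype=float)
        w = np.asarray(pmf.w, dtype=float)
        temperature = temperature if temperature is not None else pmf.temperature
    else:
        r, w = (np.asarray(a, dtype=float) for a in pmf)
        temperature = temperature if temperature is not None else 300.0
    return r, w, temperature


def find_minima_and_barrier(pmf, smooth_window: int = 5, min_prominence: float = 0.5,
                            plateau_span: float = 2.0):
    """Locate local PMF minima and the association barrier.

    Minima are prominence-filtered local minima of a moving-average-smoothed
    profile (``min_prominence`` in kcal/mol rejects the shallow wiggles a
    converged but noisy profile shows on its dissociated plateau), refined
    on the raw profile.  The barrier ΔG‡ is the maximum of w between the
    global minimum and the dissociated plateau (the mean of the outermost
    ``plateau_span`` Å), measured relative to that plateau and clipped at 0.
    A monotone profile yields no minima and barrier 0 with a warning.
    Returns ``(minima, barrier)`` with minima as (r, w) pairs.
    """
    from scipy.signal import find_peaks
    r, w, _ = _profile_arrays(pmf, None)
    if r.size < 5:
        raise ValidationError("need at least 5 bins to locate minima")
    k = max(1, int(smooth_window))
    kernel = np.ones(k) / k
    ws = np.convolve(w, kernel, mode="same") if k > 1 else w
    idx, _ = find_peaks(-ws, prominence=min_prominence)
    # refine each on the raw profile within the smoothing neighbourhood
    minima = []
    for i in idx:
        lo = max(0, i - k)
        hi = min(len(w), i + k + 1)
        j = lo + int(np.argmin(w[lo:hi]))
        minima.append((float(r[j]), float(w[j])))
    minima = sorted(set(minima))
    # interior vertex of a profile whose smoothed form has no detected peak
    if not minima and len(w) >= 3:
        j = int(np.argmin(w))
        if 0 < j < len(w) - 1 and w.max() - w[j] >= min_prominence \
                and j not in (0, len(w) - 1):
            minima = [(float(r[j]), float(w[j]))]
    if not minima:
        warnings.warn("monotone PMF: no minima found, barrier set to 0")
        return [], 0.0
    plateau = float(np.mean(w[r >= r[-1] - plateau_span]))
    j_min = int(np.argmin(w))
    between = w[j_min:][r[j_min:] <= r[-1] - plateau_span]
    barrier = float(max(0.0, (between.max() if between.size else plateau) - plateau))
    return minima, barrier


def tst_rate(barrier: float, prefactor: float = 1e5,
             temperature: float = 300.0) -> float:
    """Transition-state-theory rate bound k = k‡ exp(-ΔG‡/RT) in s⁻¹."""
    if barrier < 0:
        raise ValidationError("barrier must be non-negative")
    if prefactor <= 0:
        raise ValidationError("prefactor must be positive")
    return float(prefactor * np.exp(-barrier / (constants.R_KCAL * temperature)))


def associate(pmf, theta_a=None, theta_b=None, omega: float | None = None,
              dimer_cutoff: float = 12.0, temperature: float | None = None,
              n_lipids: float = DEFAULT_N_LIPIDS, area: float = DEFAULT_AREA,
              prefactor: float = 1e5, dimer_mask=None) -> AssociationResult:
    """Full chain PMF → (K_a, K_x, ΔG, barrier, TST rate).

    Supply either precomputed ``omega`` or the two θ series (optionally with
    a ``dimer_mask``; by default frames are masked to the dimer state using
    the reaction-coordinate values when the series carry them).
    """
    r, w, temperature = _profile_arrays(pmf, temperature)
    if omega is None:
        if theta_a is None or theta_b is None:
            raise ValidationError("need either omega or both theta series")
        omega = omega_norm(theta_a, theta_b, dimer_mask)
    k_a = association_constant(pmf, dimer_cutoff, temperature, omega)
    k_x = mole_fraction_constant(k_a, n_lipids, area)
    dg = delta_g(k_x, temperature) if k_x > 0 else np.inf
    minima, barrier = find_minima_and_barrier(pmf)
    rate = tst_rate(barrier, prefactor, temperature)
    return AssociationResult(omega=omega, k_a=k_a, k_x=k_x, delta_g=dg,
                             dimer_cutoff=dimer_cutoff, temperature=temperature,
                             n_lipids=n_lipids, area=area, barrier=barrier,
                             tst_rate=rate, tst_prefactor=prefactor,
                             minima=minima)
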