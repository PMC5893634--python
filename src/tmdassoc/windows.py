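"""Umbrella-window data structures and their plain-text on-disk formats.

A window couples a harmonic bias U(r) = (k/2)(r - r0)^2 to a time series of
reaction-coordinate samples.  On disk a window set is a metadata file with one
line per window::

    <series path>  <bias center Å>  <force constant kcal/mol/Å²>

(the layout consumed by Grossfield's WHAM program) plus one two-column
whitespace ``time  value`` file per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import FormatError, ValidationError

__all__ = [
    "BiasSpec",
    "UmbrellaWindowSeries",
    "paper_window_centers",
    "default_bias_specs",
    "read_window_metadata",
    "write_window_set",
]


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic umbrella bias.

    ``half_factor=True`` means U(r) = (k/2)(r-r0)^2; set it False for data
    restrained with the U(r) = k (r-r0)^2 convention (e.g. AMBER NMR
    restraints) so WHAM sees the same energies the sampler did.
    """

    center: float
    force_constant: float
    half_factor: bool = True

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValidationError(f"force constant must be > 0, got {self.force_constant}")

    def energy(self, r):
        """Bias energy in kcal/mol at coordinate value(s) r."""
        dr2 = (np.asarray(r, dtype=float) - self.center) ** 2
        return (0.5 if self.half_factor else 1.0) * self.force_constant * dr2


@dataclass
class UmbrellaWindowSeries:
    """One biased window: its bias spec plus sampled reaction-coordinate values."""

    bias: BiasSpec
    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("times and values must be 1-D arrays of equal length")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("window values must be finite")
        if not self.label:
            self.label = f"win_{self.bias.center:g}"

    @property
    def n_samples(self) -> int:
        return int(self.values.size)


def paper_window_centers() -> np.ndarray:
    """The 20-window layout used for the integrin TMD PMFs.

    Centers run 8 → 11 Å in 0.5 Å steps and 11 → 24 Å in 1 Å steps.
    """
    return np.concatenate([np.arange(8.0, 11.0, 0.5), np.arange(11.0, 24.0 + 1e-9, 1.0)])


def default_bias_specs(centers=None, stiff_below: float = 10.0,
                       k_soft: float = 4.0, k_stiff: float = 20.0) -> list[BiasSpec]:
    """Bias specs for a window layout: k = 4 kcal/mol/Å², stiffened to
    20 kcal/mol/Å² for the tightly-bound windows (centers ≤ ``stiff_below`` Å)
    where the underlying profile is steep and a soft spring would yield
    skewed, poorly overlapping histograms."""
    centers = paper_window_centers() if centers is None else np.asarray(centers, float)
    return [
        BiasSpec(float(c), k_stiff if c <= stiff_below else k_soft)
        for c in centers
    ]


def read_window_metadata(path) -> list[UmbrellaWindowSeries]:
    """Read a window metadata file and every series it references.

    Returns windows sorted by bias center.  Series paths are resolved
    relative to the metadata file's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    windows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 'path center force_constant', got {raw!r}")
        series_path = Path(parts[0])
        if not series_path.is_absolute():
            series_path = path.parent / series_path
        try:
            center = float(parts[1])
            k = float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric center/force constant in {raw!r}") from exc
        if not series_path.exists():
            raise FileNotFoundError(
                f"series file {series_path} for window centered at {center} Å (line {lineno}) not found")
        data = np.loadtxt(series_path, ndmin=2)
        if data.shape[1] < 2:
            raise FormatError(f"{series_path}: expected two columns (time, value)")
        windows.append(UmbrellaWindowSeries(BiasSpec(center, k), data[:, 0], data[:, 1],
                                            label=series_path.stem))
    windows.sort(key=lambda w: w.bias.center)
    return windows


def write_window_set(windows, out_dir, metadata_name: str = "windows.meta") -> Path:
    """Write each window's series and a metadata file; returns the metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, win in enumerate(windows):
        fname = f"{win.label or f'window_{i:02d}'}.dat"
        np.savetxt(out_dir / fname, np.column_stack([win.times, win.values]), fmt="%.6g")
        lines.append(f"{fname}\t{win.bias.center:g}\t{win.bias.force_constant:g}")
    meta = out_dir / metadata_name
    meta.write_text("\n".join(lines) + "\n")
    return meta
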