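"""Synthetic pure-compound ¹H NMR spectra.

Generates libraries of first-order multiplets (singlet/doublet/triplet/
quartet) with Lorentzian lineshapes on a uniform ppm grid, emulating
small-molecule standards acquired at 400 MHz.  The simulator exists so the
whole identification pipeline can be exercised and validated without any
acquired spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectralLibrary, Spectrum, default_grid, normalize_max

__all__ = ["SimulatorConfig", "lorentzian_line", "generate_multiplet", "generate_library"]

#: binomial line patterns of first-order multiplets
_PATTERNS = {
    "s": np.array([1.0]),
    "d": np.array([1.0, 1.0]),
    "t": np.array([1.0, 2.0, 1.0]),
    "q": np.array([1.0, 3.0, 3.0, 1.0]),
}


@dataclass
class SimulatorConfig:
    """Study conditions for the synthetic library.

    Defaults emulate ¹H spectra of flavor-type small molecules in DMSO-d6 at
    400 MHz: 2–8 first-order multiplets per compound with centers on
    0.5–9.5 ppm, scalar couplings of 2–12 Hz and a Lorentzian half-width of
    0.0015 ppm (≈0.6 Hz).
    """

    n_compounds: int = 24
    multiplets_per_compound: tuple[int, int] = (2, 8)
    ppm_range: tuple[float, float] = (0.5, 9.5)
    linewidth_gamma: float = 0.0015
    J_range: tuple[float, float] = (2.0, 12.0)
    spectrometer_freq: float = 400.0
    amplitude_range: tuple[float, float] = (0.2, 1.0)
    seed: int = 0
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.linewidth_gamma <= 0:
            raise ValueError("linewidth_gamma must be positive")
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be positive")
        if self.J_range[0] < 0 or self.J_range[1] < self.J_range[0]:
            raise ValueError("J_range must be a non-negative (low, high) pair")
        lo, hi = self.multiplets_per_compound
        if lo < 1 or hi < lo:
            raise ValueError("multiplets_per_compound must be an ordered positive range")
        glo, ghi = min(self.grid[0], self.grid[-1]), max(self.grid[0], self.grid[-1])
        if not (glo <= self.ppm_range[0] < self.ppm_range[1] <= ghi):
            raise ValueError("ppm_range must lie within the grid")


def lorentzian_line(
    center: float, gamma: float, amplitude: float, grid: np.ndarray
) -> np.ndarray:
    """Lorentzian profile ``amplitude · γ² / ((x − center)² + γ²)`` on ``grid``.

    ``gamma`` is the half-width at half-maximum in ppm, the natural lineshape
    parameter of liquid-state NMR.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(grid, dtype=np.float64)
    return amplitude * gamma**2 / ((x - center) ** 2 + gamma**2)


def generate_multiplet(
    center: float,
    pattern: str,
    J: float,
    freq: float,
    grid: np.ndarray,
    gamma: float = 0.0015,
    amplitude: float = 1.0,
) -> np.ndarray:
    """First-order multiplet: 1–4 Lorentzian lines split by ``J``/``freq`` ppm.

    Line amplitudes follow the binomial pattern 1 / 1:1 / 1:2:1 / 1:3:3:1,
    scaled so the pattern's largest line has height ``amplitude`` when lines
    do not overlap.
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"pattern must be one of {sorted(_PATTERNS)}, got {pattern!r}")
    if freq <= 0:
        raise ValueError("freq must be positive")
    weights = _PATTERNS[pattern]
    weights = weights / weights.max()
    n = weights.size
    split_ppm = J / freq
    # line positions symmetric about the multiplet center
    offsets = (np.arange(n) - (n - 1) / 2.0) * split_ppm
    out = np.zeros(np.asarray(grid).shape, dtype=np.float64)
    for off, w in zip(offsets, weights):
        out += lorentzian_line(center + off, gamma, amplitude * w, grid)
    return out


def generate_library(config: SimulatorConfig) -> SpectralLibrary:
    """Draw ``config.n_compounds`` random synthetic spectra, unit-max each.

    A pure function of its config: the same seed yields bit-identical
    libraries.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    grid = np.asarray(config.grid, dtype=np.float64)
    patterns = sorted(_PATTERNS)
    entries = []
    lo_m, hi_m = config.multiplets_per_compound
    for i in range(config.n_compounds):
        n_mult = int(rng.integers(lo_m, hi_m + 1))
        inten = np.zeros(grid.shape)
        for _ in range(n_mult):
            center = rng.uniform(*config.ppm_range)
            pattern = patterns[rng.integers(len(patterns))]
            J = rng.uniform(*config.J_range)
            amp = rng.uniform(*config.amplitude_range)
            inten += generate_multiplet(
                center,
                pattern,
                J,
                config.spectrometer_freq,
                grid,
                gamma=config.linewidth_gamma,
                amplitude=amp,
            )
        spec = Spectrum(
            grid.copy(),
            inten,
            name=f"synthetic-{i:03d}",
            meta={"sf_mhz": config.spectrometer_freq, "n_multiplets": n_mult,
                  "synthetic": True},
        )
        entries.append(normalize_max(spec))
    return SpectralLibrary(entries=entries)
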