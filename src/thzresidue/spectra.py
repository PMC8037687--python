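"""Frequency grids and absorbance spectra.

The atomic data unit of the pipeline is a single absorbance trace sampled on a
fixed, uniformly spaced frequency grid in the terahertz band.  The instrument
regime emulated throughout the package is a 30 GHz spectral resolution over
0.1-3.0 THz, which gives a 97-point grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrequencyGrid", "Spectrum", "default_grid"]

#: Tolerance used when comparing frequencies to grid points (well below the
#: 30 GHz grid step, well above float64 rounding on values of order 1 THz).
FREQ_TOL = 1e-9


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform frequency axis: ``values[k] = start + k * step`` (THz).

    ``stop`` is an inclusive upper bound; the last grid point is the largest
    ``start + k * step`` not exceeding ``stop`` (within tolerance).
    """

    start: float = 0.1
    stop: float = 3.0
    step: float = 0.03

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")
        if self.stop < self.start:
            raise ValueError("grid stop must be >= start")

    @property
    def values(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + FREQ_TOL)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.values)

    def nearest_index(self, freq: float) -> int:
        """Index of the grid point closest to ``freq``."""
        return int(np.argmin(np.abs(self.values - freq)))


def default_grid() -> FrequencyGrid:
    """The 97-point 0.1-3.0 THz grid at 30 GHz resolution."""
    return FrequencyGrid(0.1, 3.0, 0.03)


@dataclass
class Spectrum:
    """One absorbance trace aligned to a :class:`FrequencyGrid`.

    ``frequencies`` is stored explicitly (rather than the grid object) so that
    band-intercepted spectra, whose axis is a contiguous slice of a parent
    grid, are first-class values.
    """

    frequencies: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.frequencies.shape != self.absorbance.shape:
            raise ValueError(
                f"frequency axis ({self.frequencies.shape}) and absorbance "
                f"({self.absorbance.shape}) are misaligned"
            )
        if self.frequencies.ndim != 1:
            raise ValueError("a Spectrum is one-dimensional")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frequencies)
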