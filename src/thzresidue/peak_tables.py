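"""Packaged reference peak tables for the three benzimidazole pesticides.

Two tables ship with the package:

* ``peak_table.csv`` — per-molecule absorption peak positions from quantum
  chemistry (DFT, single isolated molecule) and from pellet transmission
  measurements, with vibrational-mode annotations carried as opaque strings.
* ``mixture_peaks.csv`` — the peaks observed in the four mixture pellets
  (M1 = BNL+BCM, M2 = BNL+TBZ, M3 = BCM+TBZ, M4 = BNL+BCM+TBZ) and the
  component each peak originates from.

The experimental ``intensity`` column encodes the qualitative intensity
ordering of the measured spectra (e.g. the 0.70 THz line is the strongest of
benomyl's three); absolute units are arbitrary.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "COMPONENTS",
    "MIXTURES",
    "MIXTURE_COMPONENTS",
    "CLASS_NAMES",
    "CLASS_INDEX",
    "load_peak_table",
    "load_mixture_table",
    "experimental_peaks",
    "dft_peaks",
    "mixture_peaks",
]

#: Pure pesticide components.
COMPONENTS = ("BNL", "BCM", "TBZ")

#: Mixture sample identifiers.
MIXTURES = ("M1", "M2", "M3", "M4")

#: Which components each mixture contains.
MIXTURE_COMPONENTS = {
    "M1": ("BNL", "BCM"),
    "M2": ("BNL", "TBZ"),
    "M3": ("BCM", "TBZ"),
    "M4": ("BNL", "BCM", "TBZ"),
}

#: Integer class labels 1-9 for the nine imaging classes: tape background,
#: pesticide-free control leaf, the three single residues, and the four
#: mixtures.
CLASS_NAMES = {
    1: "BG",
    2: "CK",
    3: "BNL",
    4: "BCM",
    5: "TBZ",
    6: "M1",
    7: "M2",
    8: "M3",
    9: "M4",
}

CLASS_INDEX = {name: idx for idx, name in CLASS_NAMES.items()}

#: Components deposited on the leaf for each class (empty for BG and CK).
CLASS_COMPONENTS = {
    1: (),
    2: (),
    3: ("BNL",),
    4: ("BCM",),
    5: ("TBZ",),
    6: MIXTURE_COMPONENTS["M1"],
    7: MIXTURE_COMPONENTS["M2"],
    8: MIXTURE_COMPONENTS["M3"],
    9: MIXTURE_COMPONENTS["M4"],
}


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("thzresidue.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_peak_table() -> pd.DataFrame:
    """Full packaged pure-component peak table (DFT + experiment)."""
    return _read_csv("peak_table.csv")


def load_mixture_table() -> pd.DataFrame:
    """Packaged mixture peak table (observed peaks and their origins)."""
    return _read_csv("mixture_peaks.csv")


def _molecule_rows(molecule: str, source: str) -> pd.DataFrame:
    table = load_peak_table()
    rows = table[(table.molecule == molecule) & (table.source == source)]
    if rows.empty:
        raise ValueError(
            f"unknown molecule {molecule!r}; valid ids are {COMPONENTS}"
        )
    return rows.sort_values("frequency_THz")


def experimental_peaks(molecule: str) -> pd.DataFrame:
    """Measured peak positions/intensities for one pure component."""
    return _molecule_rows(molecule, "experiment")


def dft_peaks(molecule: str) -> pd.DataFrame:
    """DFT-computed peak positions for one pure component."""
    return _molecule_rows(molecule, "dft")


def mixture_peaks(mixture: str) -> pd.DataFrame:
    """Observed peaks of one mixture pellet, with per-peak origin."""
    table = load_mixture_table()
    rows = table[table.mixture == mixture]
    if rows.empty:
        raise ValueError(f"unknown mixture {mixture!r}; valid ids are {MIXTURES}")
    return rows.sort_values("frequency_THz")
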