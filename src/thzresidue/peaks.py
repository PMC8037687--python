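"""Absorption-peak detection, DFT-to-experiment matching, and fingerprint
selection for the benzimidazole pesticides.

The matching problem is tiny (at most six peaks per list) but the pairing is
not always obvious — thiabendazole's computed 1.35 THz mode pairs with the
measured 1.24 THz peak while 1.56 pairs with 1.66 — so peaks are paired by a
globally optimal one-to-one assignment (maximum number of within-tolerance
pairs, then minimum total absolute shift) rather than greedily.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks

from .peak_tables import (
    COMPONENTS,
    MIXTURE_COMPONENTS,
    experimental_peaks,
    dft_peaks,
    mixture_peaks,
)
from .spectra import Spectrum

__all__ = [
    "PeakList",
    "PeakMatch",
    "detect_peaks",
    "match_peaks",
    "select_fingerprints",
    "packaged_peaklist",
    "packaged_mixture_peaklist",
]

#: Cost assigned to out-of-tolerance pairs; any feasible assignment beats it.
_INFEASIBLE = 1e9


@dataclass
class PeakList:
    """Molecule-tagged list of (frequency, intensity) peaks."""

    molecule: str
    frequencies: np.ndarray
    intensities: np.ndarray
    source: str = "detected"  # {"experiment", "dft", "detected"}

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frequencies.shape != self.intensities.shape:
            raise ValueError("frequencies and intensities are misaligned")
        if len(self.frequencies) and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("peak frequencies must be strictly increasing")
        if len(self.frequencies) and (
            self.frequencies.min() < 0 or self.frequencies.max() > 3.5
        ):
            raise ValueError("peak frequencies must lie within 0-3.5 THz")
        if np.any(self.intensities < 0):
            raise ValueError("peak intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class PeakMatch:
    """One-to-one pairing of a DFT peak list with an experimental one.

    Each pair is ``(dft_frequency, exp_frequency, shift)`` with
    ``shift = dft - exp`` and ``|shift| <= tolerance``.
    """

    pairs: list = field(default_factory=list)
    unmatched_dft: list = field(default_factory=list)
    unmatched_exp: list = field(default_factory=list)
    tolerance: float = 0.15


def packaged_peaklist(molecule: str, source: str = "experiment") -> PeakList:
    """PeakList view of the packaged pure-component table."""
    table = experimental_peaks(molecule) if source == "experiment" else dft_peaks(molecule)
    return PeakList(
        molecule,
        table.frequency_THz.to_numpy(),
        table.intensity.to_numpy(),
        source=source,
    )


def packaged_mixture_peaklist(mixture: str) -> PeakList:
    """PeakList view of the packaged mixture table."""
    table = mixture_peaks(mixture)
    return PeakList(
        mixture,
        table.frequency_THz.to_numpy(),
        table.intensity.to_numpy(),
        source="experiment",
    )


def detect_peaks(
    spectrum: Spectrum,
    min_prominence: float | None = None,
    molecule: str = "unknown",
) -> PeakList:
    """Strict local maxima of a spectrum with a prominence floor.

    ``min_prominence`` defaults to 5% of the spectrum's absorbance range,
    which keeps genuine absorption lines while rejecting shoulders riding on
    the tails of stronger neighbours.
    """
    if len(spectrum) < 3:
        raise ValueError("peak detection needs at least 3 points")
    x = spectrum.absorbance
    if not np.all(np.isfinite(x)):
        raise ValueError("spectrum contains non-finite values")
    if min_prominence is None:
        min_prominence = 0.05 * float(x.max() - x.min())
    idx, _ = find_peaks(x, prominence=max(min_prominence, 1e-12))
    return PeakList(molecule, spectrum.frequencies[idx], x[idx], source="detected")


def match_peaks(dft: PeakList, exp: PeakList, tolerance: float = 0.15) -> PeakMatch:
    """Globally optimal one-to-one DFT-to-experiment peak assignment.

    Maximizes the number of pairs within ``tolerance`` and, among those,
    minimizes the total absolute shift.  Unpaired peaks on either side are
    reported as unmatched (missing modes are typically buried in instrument
    noise).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    d, e = dft.frequencies, exp.frequencies
    if len(d) == 0 or len(e) == 0:
        return PeakMatch([], list(d), list(e), tolerance)
    cost = np.abs(d[:, None] - e[None, :])
    cost = np.where(cost <= tolerance, cost, _INFEASIBLE)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (float(d[i]), float(e[j]), float(d[i] - e[j]))
        for i, j in zip(rows, cols)
        if cost[i, j] < _INFEASIBLE
    ]
    used_d = {p[0] for p in pairs}
    used_e = {p[1] for p in pairs}
    return PeakMatch(
        pairs=sorted(pairs),
        unmatched_dft=[float(f) for f in d if float(f) not in used_d],
        unmatched_exp=[float(f) for f in e if float(f) not in used_e],
        tolerance=tolerance,
    )


def _contains(frequencies: np.ndarray, freq: float, tol: float) -> bool:
    return bool(len(frequencies)) and bool(np.min(np.abs(frequencies - freq)) <= tol)


def select_fingerprints(
    pure: list,
    mixtures: list,
    tol: float = 0.05,
    mixture_components: dict | None = None,
) -> list:
    """Select the fingerprint frequencies of a set of components.

    A fingerprint must be attributable to exactly one component (no other
    component has a pure peak within ``tol``) and must survive mixing: peaks
    present in *every* mixture containing the component are retained.  If a
    component has no such peak, the strongest of its peaks seen in at least
    one mixture is used instead (the benomyl rule: only its most intense line
    survives in any mixture).  A component absent from all mixtures, or with
    no qualifying peak at all, contributes its strongest pure peak and a
    warning is emitted.

    Returns the union of the selected frequencies, sorted.
    """
    if mixture_components is None:
        mixture_components = MIXTURE_COMPONENTS
    selected: list[float] = []
    for plist in pure:
        comp = plist.molecule
        others = np.concatenate(
            [q.frequencies for q in pure if q.molecule != comp] or [np.array([])]
        )
        unique = [
            (float(f), float(a))
            for f, a in zip(plist.frequencies, plist.intensities)
            if not _contains(others, float(f), tol)
        ]
        mixes = [
            m for m in mixtures if comp in mixture_components.get(m.molecule, ())
        ]
        if not mixes or not unique:
            warnings.warn(
                f"component {comp}: no qualifying fingerprint; "
                "falling back to its strongest pure peak",
                stacklevel=2,
            )
            best = float(plist.frequencies[np.argmax(plist.intensities)])
            selected.append(best)
            continue
        in_all = [
            f for f, _ in unique
            if all(_contains(m.frequencies, f, tol) for m in mixes)
        ]
        if in_all:
            selected.extend(in_all)
            continue
        in_any = [
            (f, a) for f, a in unique
            if any(_contains(m.frequencies, f, tol) for m in mixes)
        ]
        if in_any:
            # Tie-break by absorption intensity.
            selected.append(max(in_any, key=lambda fa: fa[1])[0])
        else:
            warnings.warn(
                f"component {comp}: none of its peaks appear in any mixture; "
                "falling back to its strongest pure peak",
                stacklevel=2,
            )
            selected.append(float(plist.frequencies[np.argmax(plist.intensities)]))
    return sorted(set(selected))
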