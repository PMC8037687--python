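"""Spectral extraction from hyperspectral cubes into labeled datasets.

Mirrors the extraction protocol of the emulated study: per-pixel spectra are
averaged over 3x3-pixel regions of interest (100 ROIs per leaf), intercepted
to the 0.2-2.2 THz band where the instrument signal is clean (67 of the 97
grid points), and assembled into a labeled matrix with a stratified 70/30
train/test split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion

from .peak_tables import CLASS_NAMES
from .spectra import FREQ_TOL, Spectrum
from .synthetic import HyperCube

__all__ = [
    "ROISpec",
    "LabeledDataset",
    "intercept_band",
    "band_indices",
    "extract_roi_spectra",
    "assemble_dataset",
    "fingerprint_features",
]

DEFAULT_BAND = (0.2, 2.2)


@dataclass(frozen=True)
class ROISpec:
    """Square region-of-interest sampler: ``size`` x ``size`` pixel windows."""

    size: int = 3
    n_per_leaf: int = 100
    sampling_seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError(f"ROI size must be odd and >= 1, got {self.size}")
        if self.n_per_leaf < 1:
            raise ValueError("n_per_leaf must be >= 1")


@dataclass
class LabeledDataset:
    """Matrix of extracted spectra with integer class labels 1-9."""

    spectra: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # (n_samples,), values 1-9
    is_train: np.ndarray  # (n_samples,), boolean split flag
    frequencies: np.ndarray  # (n_features,) THz
    class_names: dict = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.is_train = np.asarray(self.is_train, dtype=bool)
        n = len(self.spectra)
        if len(self.labels) != n or len(self.is_train) != n:
            raise ValueError("labels/split length does not match spectra rows")
        bad = set(np.unique(self.labels)) - set(CLASS_NAMES)
        if bad:
            raise ValueError(f"labels outside 1..9: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def train(self) -> tuple[np.ndarray, np.ndarray]:
        return self.spectra[self.is_train], self.labels[self.is_train]

    @property
    def test(self) -> tuple[np.ndarray, np.ndarray]:
        return self.spectra[~self.is_train], self.labels[~self.is_train]


def band_indices(frequencies: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Indices of grid points with ``lo <= f <= hi`` (closed interval)."""
    frequencies = np.asarray(frequencies)
    mask = (frequencies >= lo - FREQ_TOL) & (frequencies <= hi + FREQ_TOL)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise ValueError(
            f"band [{lo}, {hi}] THz contains no grid points of "
            f"[{frequencies[0]}, {frequencies[-1]}]"
        )
    return idx


def intercept_band(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Restrict a spectrum to the closed band ``[lo, hi]`` THz."""
    idx = band_indices(spectrum.frequencies, lo, hi)
    return Spectrum(
        spectrum.frequencies[idx],
        spectrum.absorbance[idx],
        meta={**spectrum.meta, "band": (lo, hi)},
    )


def _valid_roi_centers(cube: HyperCube, size: int) -> np.ndarray:
    """(k, 2) array of centers whose full window fits the cube (and leaf)."""
    half = size // 2
    h, w = cube.leaf_mask.shape
    interior = np.zeros((h, w), dtype=bool)
    if h > 2 * half and w > 2 * half:
        interior[half : h - half, half : w - half] = True
    if cube.leaf_mask.any():
        # Erosion by the ROI footprint keeps centers whose whole window is leaf.
        eroded = binary_erosion(
            cube.leaf_mask, structure=np.ones((size, size), dtype=bool)
        )
        interior &= eroded
    return np.argwhere(interior)


def extract_roi_spectra(cube: HyperCube, roi: ROISpec | None = None) -> list[Spectrum]:
    """Sample ``n_per_leaf`` ROI-averaged spectra from one cube.

    ROI centers are drawn uniformly without replacement from all positions
    whose full window lies inside the leaf mask (inside the whole cube for
    background cubes, whose mask is empty); each returned spectrum is the
    arithmetic mean over the window's pixels.
    """
    roi = roi or ROISpec()
    centers = _valid_roi_centers(cube, roi.size)
    if len(centers) < roi.n_per_leaf:
        raise ValueError(
            f"cube admits only {len(centers)} valid {roi.size}x{roi.size} ROI "
            f"positions; {roi.n_per_leaf} requested"
        )
    rng = np.random.default_rng(roi.sampling_seed)
    chosen = centers[rng.choice(len(centers), size=roi.n_per_leaf, replace=False)]
    half = roi.size // 2
    out = []
    for i, j in chosen:
        window = cube.data[i - half : i + half + 1, j - half : j + half + 1]
        out.append(
            Spectrum(
                cube.grid.values,
                window.mean(axis=(0, 1)),
                meta={"center": (int(i), int(j)), "true_class": cube.true_class},
            )
        )
    return out


def assemble_dataset(
    cubes,
    roi: ROISpec | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    split_seed: int = 0,
    train_fraction: float = 0.7,
    required_classes=None,
) -> LabeledDataset:
    """Extract, band-intercept, label, and split spectra from many cubes.

    Rows are ``n_cubes * n_per_leaf`` band-intercepted ROI spectra; the
    train/test split is stratified per class, with ``floor(train_fraction*n)``
    training rows per class, shuffled by ``split_seed``.  Each cube's ROI
    sampling stream is derived from the ROI seed and the cube's position so
    replicate cubes do not share sampling patterns.
    """
    cubes = list(cubes)
    roi = roi or ROISpec()
    present = {c.true_class for c in cubes}
    if required_classes is not None:
        missing = sorted(set(required_classes) - present)
        if missing:
            names = [CLASS_NAMES.get(c, str(c)) for c in missing]
            raise ValueError(f"no cubes for classes {missing} ({names})")
    if not cubes:
        raise ValueError("no cubes supplied")

    rows, labels = [], []
    freqs = None
    for k, cube in enumerate(cubes):
        cube_roi = dataclasses.replace(roi, sampling_seed=roi.sampling_seed + k)
        for spec in extract_roi_spectra(cube, cube_roi):
            clipped = intercept_band(spec, *band)
            if freqs is None:
                freqs = clipped.frequencies
            rows.append(clipped.absorbance)
            labels.append(cube.true_class)
    X = np.asarray(rows)
    y = np.asarray(labels)

    is_train = np.zeros(len(y), dtype=bool)
    rng = np.random.default_rng(split_seed)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        n_train = int(np.floor(train_fraction * len(idx)))
        is_train[idx[:n_train]] = True
    return LabeledDataset(X, y, is_train, freqs)


def fingerprint_features(
    spectra: np.ndarray, frequencies: np.ndarray, fingerprints
) -> np.ndarray:
    """Columns of ``spectra`` at the grid points nearest each fingerprint."""
    frequencies = np.asarray(frequencies)
    idx = [int(np.argmin(np.abs(frequencies - f))) for f in fingerprints]
    return np.asarray(spectra)[:, idx]
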