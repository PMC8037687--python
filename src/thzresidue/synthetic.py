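"""Synthetic terahertz spectra and hyperspectral leaf cubes.

The instrument data this package targets (transmission THz images of pesticide
residues on Toona sinensis leaves) are not publicly deposited, so this module
generates surrogate data with the statistical structure the downstream
analysis assumes:

* pure-component absorbance spectra built as sums of Lorentzian lines at the
  packaged experimental peak centers on a 0.1-3.0 THz grid (30 GHz step);
* mixture spectra as amplitude-scaled sums of the component line systems,
  with benomyl lines strongly suppressed in mixtures (benomyl is unstable and
  degrades to carbendazim, so its fingerprints all but vanish when mixed);
* 250x250-pixel hyperspectral cubes of a leaf fixed on transparent tape, with
  an elliptical leaf region, a midrib/vein pattern of elevated absorbance, a
  sloped leaf baseline modulated by smooth optical-thickness and scattering
  fields, a textured tape background, and Gaussian absorbance noise that is
  spatially correlated over the instrument's beam-spot scale.

All randomness flows from explicit integer seeds; identical configuration
yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .peak_tables import CLASS_COMPONENTS, CLASS_NAMES, COMPONENTS, experimental_peaks
from .spectra import FrequencyGrid, Spectrum, default_grid

__all__ = [
    "GeneratorConfig",
    "HyperCube",
    "simulate_pure_spectrum",
    "simulate_mixture_spectrum",
    "simulate_leaf_cube",
    "simulate_study",
]


def _default_class_amplitudes() -> dict:
    return {c: 1.0 for c in COMPONENTS}


def _default_bnl_scale() -> dict:
    # Benomyl line scaling per mixture class.  Weak but visible in M1 (its
    # 0.70 THz line survives); below detection threshold in M2 and M4.
    return {"M1": 0.3, "M2": 0.04, "M4": 0.04}


@dataclass
class GeneratorConfig:
    """Tunable knobs of the synthetic-data generator.

    Absorbance is in arbitrary units throughout (the emulated instrument's
    dynamic range is not known); only relative structure matters.
    """

    #: Per-component scale applied to that component's line system.
    class_amplitudes: dict = field(default_factory=_default_class_amplitudes)
    #: Scale applied to benomyl lines inside each mixture class.
    bnl_mixture_scale: dict = field(default_factory=_default_bnl_scale)
    #: Lorentzian half-width at half-maximum (THz); one grid step by default.
    line_width: float = 0.03
    #: Flat baseline of pellet-style spectra and of the tape background.
    pellet_baseline: float = 0.05
    tape_baseline: float = 0.05
    #: Leaf tissue baseline: offset + slope * frequency (absorbance per THz).
    leaf_baseline_offset: float = 0.05
    leaf_baseline_slope: float = 0.1
    #: Extra absorbance on midrib/vein pixels.
    vein_contrast: float = 0.08
    #: Log-sd of the smooth per-pixel optical-thickness field that multiplies
    #: the whole leaf spectrum (Beer-Lambert: absorbance scales with path).
    thickness_jitter: float = 0.15
    #: Sd of the smooth per-pixel linear baseline tilt (absorbance per THz)
    #: emulating frequency-dependent scattering from leaf microstructure.
    scatter_slope_sd: float = 0.03
    #: Sd of the smooth tape-texture field on exposed background pixels.
    tape_texture_sd: float = 0.015
    #: Per-pixel standard deviation of additive Gaussian absorbance noise.
    #: In cubes the noise is spatially correlated over ``noise_corr`` pixels
    #: (the THz beam spot spans neighbouring pixels), so small-window
    #: averaging does not remove it; single simulated spectra use white noise.
    noise_sd: float = 0.02
    noise_corr: float = 1.5
    seed: int = 0
    cube_height: int = 250
    cube_width: int = 250

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.line_width <= 0:
            raise ValueError("line_width must be > 0")
        if self.cube_height < 1 or self.cube_width < 1:
            raise ValueError("cube dimensions must be positive")
        for mix, scale in self.bnl_mixture_scale.items():
            if not 0.0 <= scale <= 1.0:
                raise ValueError(
                    f"bnl_mixture_scale[{mix!r}] = {scale} outside [0, 1]"
                )


def _lorentzian_sum(
    freqs: np.ndarray, centers: np.ndarray, amplitudes: np.ndarray, hwhm: float
) -> np.ndarray:
    """Sum of Lorentzian lines A / (1 + ((f - f0)/w)^2) on ``freqs``."""
    d = (freqs[None, :] - np.asarray(centers)[:, None]) / hwhm
    return (np.asarray(amplitudes)[:, None] / (1.0 + d * d)).sum(axis=0)


def _mixture_id(components: tuple) -> str | None:
    key = frozenset(components)
    for mix, comps in {
        "M1": ("BNL", "BCM"),
        "M2": ("BNL", "TBZ"),
        "M3": ("BCM", "TBZ"),
        "M4": ("BNL", "BCM", "TBZ"),
    }.items():
        if key == frozenset(comps):
            return mix
    return None


def _component_lines(
    components, grid: FrequencyGrid, config: GeneratorConfig
) -> np.ndarray:
    """Noise-free, baseline-free line system of a component set."""
    components = tuple(components)
    for c in components:
        if c not in COMPONENTS:
            raise ValueError(f"unknown molecule {c!r}; valid ids are {COMPONENTS}")
    mix = _mixture_id(components)
    total = np.zeros(len(grid))
    for c in components:
        table = experimental_peaks(c)
        amps = table.intensity.to_numpy() * config.class_amplitudes.get(c, 1.0)
        if c == "BNL" and mix is not None:
            amps = amps * config.bnl_mixture_scale.get(mix, 1.0)
        total += _lorentzian_sum(
            grid.values, table.frequency_THz.to_numpy(), amps, config.line_width
        )
    return total


def simulate_pure_spectrum(
    molecule: str,
    grid: FrequencyGrid | None = None,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Pellet-style spectrum of one pure pesticide.

    The noise-free trace is a flat baseline plus the molecule's Lorentzian
    line system, so its local maxima sit at the packaged experimental peak
    centers (to within one grid step).
    """
    return simulate_mixture_spectrum([molecule], grid=grid, config=config, rng=rng)


def simulate_mixture_spectrum(
    components,
    grid: FrequencyGrid | None = None,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Pellet-style spectrum of a set of components sharing one baseline.

    With ``noise_sd = 0`` the output is exactly the amplitude-scaled sum of
    the component line systems plus a single flat baseline (additivity).
    Benomyl lines are scaled by ``config.bnl_mixture_scale`` for the standard
    two- and three-component mixtures.
    """
    components = tuple(components)
    if not components:
        raise ValueError("component list is empty; nothing to simulate")
    grid = grid or default_grid()
    config = config or GeneratorConfig()
    absorbance = config.pellet_baseline + _component_lines(components, grid, config)
    if config.noise_sd > 0:
        rng = rng or np.random.default_rng(config.seed)
        absorbance = absorbance + rng.normal(0.0, config.noise_sd, size=len(grid))
    return Spectrum(
        grid.values,
        absorbance,
        meta={"components": components, "noise_sd": config.noise_sd},
    )


@dataclass
class HyperCube:
    """H x W x F absorbance cube with frequency axis and ground truth."""

    data: np.ndarray
    grid: FrequencyGrid
    leaf_mask: np.ndarray
    true_class: int
    seed: int

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x F")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid has {len(self.grid)}"
            )
        if self.leaf_mask.shape != self.data.shape[:2]:
            raise ValueError("leaf_mask shape does not match cube")
        if self.true_class not in CLASS_NAMES:
            raise ValueError(f"true_class must be in 1..9, got {self.true_class}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def pixel_spectrum(self, i: int, j: int) -> Spectrum:
        return Spectrum(self.grid.values, self.data[i, j], meta={"pixel": (i, j)})


def _leaf_geometry(
    height: int, width: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical leaf with a sinusoidal margin, midrib, and side veins.

    Purely synthetic geometry: the emulated study fixes leaves flat on tape
    but describes no segmentation, so any connected leaf-like region serves.
    Returns ``(leaf_mask, vein_mask)`` with ``vein_mask`` a subset of the leaf.
    """
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    semi_y = 0.28 * height * (0.95 + 0.1 * rng.random())
    semi_x = 0.40 * width * (0.95 + 0.1 * rng.random())
    phase = rng.uniform(0, 2 * np.pi)
    ii, jj = np.mgrid[0:height, 0:width]
    dy = (ii - cy) / semi_y
    dx = (jj - cx) / semi_x
    r = np.hypot(dy, dx)
    ang = np.arctan2(dy, dx)
    leaf = r <= 1.0 + 0.05 * np.sin(6 * ang + phase)
    # Midrib along the long axis plus oblique secondary veins.
    midrib = np.abs(ii - cy) <= max(1.0, 0.006 * height)
    period = max(8.0, width / 18.0)
    upper = (np.mod(ii - cy + jj - cx, period) < 1.5) & (ii < cy)
    lower = (np.mod(ii - cy - (jj - cx), period) < 1.5) & (ii > cy)
    vein = leaf & (midrib | upper | lower)
    return leaf, vein


def _smooth_field(
    height: int, width: int, rng: np.random.Generator, sd: float, scale: int = 8
) -> np.ndarray:
    """Spatially smooth zero-mean Gaussian field (coarse grid, bilinear up)."""
    if sd == 0:
        return np.zeros((height, width))
    ch = max(2, int(np.ceil(height / scale)) + 1)
    cw = max(2, int(np.ceil(width / scale)) + 1)
    coarse = rng.normal(0.0, sd, size=(ch, cw))
    field = zoom(coarse, (height / ch, width / cw), order=1, grid_mode=True,
                 mode="nearest")
    return field[:height, :width]


def _correlated_noise(
    shape: tuple, rng: np.random.Generator, sd: float, corr: float
) -> np.ndarray:
    """Spatially correlated, frequency-independent Gaussian noise.

    White noise filtered with a Gaussian of width ``corr`` pixels in the two
    spatial axes only, rescaled so the per-pixel standard deviation is ``sd``.
    """
    white = rng.normal(0.0, 1.0, size=shape)
    if corr <= 0:
        return sd * white
    filt = gaussian_filter(white, sigma=(corr, corr, 0.0), mode="wrap")
    half = max(4, int(np.ceil(4 * corr)))
    impulse = np.zeros((2 * half + 1, 2 * half + 1))
    impulse[half, half] = 1.0
    gain = np.sqrt((gaussian_filter(impulse, corr, mode="constant") ** 2).sum())
    return filt * (sd / gain)


def simulate_leaf_cube(
    true_class: int,
    config: GeneratorConfig | None = None,
    grid: FrequencyGrid | None = None,
) -> HyperCube:
    """One hyperspectral cube of the requested class.

    Class 1 (BG) is pure tape: flat baseline plus noise, all-false leaf mask.
    Classes 2-9 place a leaf on the tape; leaf pixels carry the sloped leaf
    baseline, vein pixels an extra contrast increment, and residue classes
    3-9 add the class's (suppression-scaled) pesticide line system.
    """
    config = config or GeneratorConfig()
    grid = grid or default_grid()
    if true_class not in CLASS_NAMES:
        raise ValueError(f"true_class must be in 1..9, got {true_class}")
    h, w, f = config.cube_height, config.cube_width, len(grid)
    rng = np.random.default_rng(config.seed)
    tape = config.tape_baseline + _smooth_field(h, w, rng, config.tape_texture_sd)
    data = np.repeat(tape[:, :, None], f, axis=2)
    if true_class == 1:
        leaf = np.zeros((h, w), dtype=bool)
    else:
        leaf, vein = _leaf_geometry(h, w, rng)
        leaf_base = config.leaf_baseline_offset + config.leaf_baseline_slope * grid.values
        spec = leaf_base + _component_lines(
            CLASS_COMPONENTS[true_class], grid, config
        )
        # Smooth per-pixel optical thickness (multiplicative, Beer-Lambert)
        # and scattering tilt (additive, zero-mean at the band center).
        thickness = np.exp(_smooth_field(h, w, rng, config.thickness_jitter))
        tilt = _smooth_field(h, w, rng, config.scatter_slope_sd)
        f_centered = grid.values - grid.values.mean()
        data[leaf] = (
            thickness[leaf, None] * spec[None, :]
            + tilt[leaf, None] * f_centered[None, :]
        )
        data[vein] += config.vein_contrast
    if config.noise_sd > 0:
        data += _correlated_noise((h, w, f), rng, config.noise_sd, config.noise_corr)
    return HyperCube(data, grid, leaf, true_class, config.seed)


def simulate_study(
    config: GeneratorConfig | None = None,
    replicates_per_class: int = 26,
    n_background: int | None = None,
    grid: FrequencyGrid | None = None,
) -> list[HyperCube]:
    """Full multi-class study: leaf cubes for classes 2-9 plus BG cubes.

    Produces ``replicates_per_class`` cubes for each of the eight solution
    classes (the emulated study made 26 replicates of each, 208 leaf samples
    in total) and ``n_background`` tape-only cubes (default: same count).
    Cube seeds are derived as ``seed + class * 1000 + replicate``.
    """
    config = config or GeneratorConfig()
    if replicates_per_class < 1:
        raise ValueError("replicates_per_class must be >= 1")
    if n_background is None:
        n_background = replicates_per_class
    cubes = []
    for cls in sorted(CLASS_NAMES):
        n = n_background if cls == 1 else replicates_per_class
        for rep in range(n):
            cube_cfg = dataclasses.replace(
                config, seed=config.seed + cls * 1000 + rep
            )
            cubes.append(simulate_leaf_cube(cls, cube_cfg, grid=grid))
    return cubes
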