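"""Generator behaviour: line positions, mixture rules, cube structure."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thzresidue.peak_tables import CLASS_COMPONENTS, experimental_peaks
from thzresidue.peaks import detect_peaks
from thzresidue.synthetic import (
    GeneratorConfig,
    simulate_leaf_cube,
    simulate_mixture_spectrum,
    simulate_pure_spectrum,
    simulate_study,
)

GRID_STEP = 0.03


def expected_leaf_peaks(cls):
    """Packaged experimental peak set of a class, after benomyl suppression.

    Benomyl lines are below the detection prominence in M2 and M4; in M1 only
    its strongest line (0.70 THz) survives.
    """
    freqs = sorted(
        float(f)
        for c in CLASS_COMPONENTS[cls]
        for f in experimental_peaks(c).frequency_THz
    )
    bnl = {0.70, 1.07, 2.20}
    if cls in (7, 9):  # M2, M4: no benomyl peak survives
        return [f for f in freqs if f not in bnl]
    if cls == 6:  # M1: only the 0.70 THz benomyl line survives
        return [f for f in freqs if f not in (1.07, 2.20)]
    return freqs


@pytest.mark.parametrize(
    "molecule, centers",
    [
        ("BNL", [0.70, 1.07, 2.20]),
        ("BCM", [1.16, 1.35, 2.32]),
        ("TBZ", [0.92, 1.24, 1.66, 1.95, 2.58]),
    ],
)
def test_pure_spectrum_peaks_at_packaged_centers(molecule, centers, noise_free_cfg):
    spec = simulate_pure_spectrum(molecule, config=noise_free_cfg)
    detected = detect_peaks(spec).frequencies
    assert len(detected) == len(centers)
    assert np.all(np.abs(detected - np.array(centers)) <= GRID_STEP + 1e-12)


def test_zero_amplitude_gives_flat_baseline():
    cfg = GeneratorConfig(
        noise_sd=0.0, class_amplitudes={"BNL": 0.0, "BCM": 0.0, "TBZ": 0.0}
    )
    spec = simulate_pure_spectrum("BNL", config=cfg)
    assert np.allclose(spec.absorbance, cfg.pellet_baseline)
    assert len(detect_peaks(spec, min_prominence=1e-6)) == 0


def test_bcm_argmax_at_one_packaged_center(noise_free_cfg, grid):
    spec = simulate_pure_spectrum("BCM", config=noise_free_cfg)
    peak_freq = spec.frequencies[int(np.argmax(spec.absorbance))]
    assert min(abs(peak_freq - c) for c in (1.16, 1.35, 2.32)) <= GRID_STEP


def test_unknown_molecule_error_names_valid_ids(noise_free_cfg):
    with pytest.raises(ValueError, match="BNL"):
        simulate_pure_spectrum("DDT", config=noise_free_cfg)


def test_m1_mixture_shows_four_printed_peaks(noise_free_cfg):
    spec = simulate_mixture_spectrum(["BNL", "BCM"], config=noise_free_cfg)
    detected = detect_peaks(spec).frequencies
    assert len(detected) == 4
    assert np.all(
        np.abs(detected - np.array([0.70, 1.16, 1.35, 2.32])) <= GRID_STEP + 1e-12
    )


def test_singleton_mixture_equals_pure(noise_free_cfg):
    mix = simulate_mixture_spectrum(["BCM"], config=noise_free_cfg)
    pure = simulate_pure_spectrum("BCM", config=noise_free_cfg)
    assert np.array_equal(mix.absorbance, pure.absorbance)


def test_m4_suppresses_benomyl_completely(noise_free_cfg):
    spec = simulate_mixture_spectrum(["BNL", "BCM", "TBZ"], config=noise_free_cfg)
    detected = detect_peaks(spec).frequencies
    assert not np.any(np.abs(detected - 0.70) <= 0.05)


def test_empty_component_list_rejected(noise_free_cfg):
    with pytest.raises(ValueError, match="empty"):
        simulate_mixture_spectrum([], config=noise_free_cfg)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    comps=st.sets(st.sampled_from(["BNL", "BCM", "TBZ"]), min_size=2),
    amp=st.floats(0.2, 2.0),
)
def test_mixture_additivity_at_unit_scales(comps, amp):
    """Noise-free mixture = sum of component line systems + one baseline."""
    cfg = GeneratorConfig(
        noise_sd=0.0,
        class_amplitudes={c: amp for c in ("BNL", "BCM", "TBZ")},
        bnl_mixture_scale={"M1": 1.0, "M2": 1.0, "M4": 1.0},
    )
    comps = sorted(comps)
    mix = simulate_mixture_spectrum(comps, config=cfg).absorbance
    parts = [simulate_pure_spectrum(c, config=cfg).absorbance for c in comps]
    reconstructed = sum(parts) - (len(parts) - 1) * cfg.pellet_baseline
    assert np.max(np.abs(mix - reconstructed)) <= 1e-9


def test_background_cube_has_no_leaf_and_no_lines():
    cfg = GeneratorConfig(noise_sd=0.0, cube_height=32, cube_width=32, seed=3)
    cube = simulate_leaf_cube(1, cfg)
    assert not cube.leaf_mask.any()
    # tape texture is flat in frequency: no local maxima anywhere
    spread = cube.data.max(axis=2) - cube.data.min(axis=2)
    assert np.max(spread) <= 1e-12


@pytest.mark.parametrize("cls", range(3, 10))
def test_leaf_pixels_carry_class_peak_set(cls):
    """Noise-free leaf pixels show exactly the class's suppressed peak set."""
    cfg = GeneratorConfig(noise_sd=0.0, cube_height=48, cube_width=48, seed=7)
    cube = simulate_leaf_cube(cls, cfg)
    expected = expected_leaf_peaks(cls)
    pixels = np.argwhere(cube.leaf_mask)
    for px in (pixels[3], pixels[len(pixels) // 2]):
        detected = detect_peaks(cube.pixel_spectrum(*px)).frequencies
        assert len(detected) == len(expected), (cls, detected, expected)
        assert np.all(np.abs(detected - np.array(expected)) <= GRID_STEP + 1e-12)


def test_cube_determinism_bit_identical():
    cfg = GeneratorConfig(cube_height=40, cube_width=40, seed=7)
    a = simulate_leaf_cube(6, cfg)
    b = simulate_leaf_cube(6, cfg)
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(a.leaf_mask, b.leaf_mask)


def test_invalid_class_rejected():
    with pytest.raises(ValueError, match="1..9"):
        simulate_leaf_cube(10, GeneratorConfig(cube_height=16, cube_width=16))


def test_leaf_mask_area_fraction(tiny_study):
    for cube in tiny_study:
        if cube.true_class == 1:
            continue
        frac = cube.leaf_mask.mean()
        assert 0.2 <= frac <= 0.8, (cube.true_class, frac)


def test_study_counts(tiny_study):
    leaf = [c for c in tiny_study if c.true_class >= 2]
    assert len(leaf) == 8 * 2
    classes = sorted(c.true_class for c in leaf)
    assert classes == sorted(list(range(2, 10)) * 2)
    cfg = GeneratorConfig(cube_height=24, cube_width=24, seed=0)
    assert len([c for c in simulate_study(cfg, 1) if c.true_class >= 2]) == 8
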