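"""Peak detection, optimal DFT/experiment matching, fingerprint selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thzresidue.peaks import (
    PeakList,
    detect_peaks,
    match_peaks,
    packaged_mixture_peaklist,
    packaged_peaklist,
    select_fingerprints,
)
from thzresidue.spectra import Spectrum
from thzresidue.synthetic import GeneratorConfig, simulate_pure_spectrum


def brute_force_match(dft, exp, tol):
    """Enumerate all one-to-one assignments: max pairs, then min total shift."""
    best = (0, 0.0, [])
    nd, ne = len(dft), len(exp)
    for k in range(min(nd, ne), -1, -1):
        found = None
        for d_idx in itertools.combinations(range(nd), k):
            for e_perm in itertools.permutations(range(ne), k):
                costs = [abs(dft[i] - exp[j]) for i, j in zip(d_idx, e_perm)]
                if all(c <= tol for c in costs):
                    total = sum(costs)
                    if found is None or total < found[0]:
                        found = (total, sorted(zip(d_idx, e_perm)))
        if found is not None:
            return k, found[0], found[1]
    return 0, 0.0, []


def test_detect_peaks_on_synthetic_bcm():
    spec = simulate_pure_spectrum("BCM", config=GeneratorConfig(noise_sd=0.0))
    freqs = detect_peaks(spec).frequencies
    assert len(freqs) == 3
    assert np.all(np.abs(freqs - np.array([1.16, 1.35, 2.32])) <= 0.031)


def test_detect_peaks_monotone_ramp_is_empty():
    spec = Spectrum(np.linspace(0.1, 3.0, 50), np.linspace(0, 1, 50))
    assert len(detect_peaks(spec)) == 0


def test_detect_peaks_two_triangles():
    f = np.linspace(0.0, 1.0, 21)
    tri = lambda c: np.maximum(0.0, 1.0 - np.abs(f - c) / 0.1)
    spec = Spectrum(f + 0.1, tri(0.25) + tri(0.75))
    freqs = detect_peaks(spec).frequencies
    assert np.allclose(freqs, [0.35, 0.85])


def test_detect_peaks_rejects_nonfinite(grid):
    spec = Spectrum(grid.values, np.ones(len(grid)))
    spec.absorbance = spec.absorbance.copy()
    spec.absorbance[5] = np.nan  # bypass constructor validation
    with pytest.raises(ValueError, match="finite"):
        detect_peaks(spec)


def test_match_bcm_reproduces_printed_shifts():
    match = match_peaks(packaged_peaklist("BCM", "dft"), packaged_peaklist("BCM"))
    shifts = {(d, e): s for d, e, s in match.pairs}
    assert shifts[(1.15, 1.16)] == pytest.approx(-0.01)
    assert shifts[(1.36, 1.35)] == pytest.approx(0.01)
    assert shifts[(2.32, 2.32)] == pytest.approx(0.0)
    assert match.unmatched_dft == [0.49, 2.64]
    assert match.unmatched_exp == []


def test_match_identical_lists_zero_shift():
    pl = packaged_peaklist("TBZ")
    match = match_peaks(pl, pl)
    assert len(match.pairs) == len(pl)
    assert all(s == 0.0 for _, _, s in match.pairs)
    assert not match.unmatched_dft and not match.unmatched_exp


def test_match_tbz_equals_brute_force_and_table():
    dft, exp = packaged_peaklist("TBZ", "dft"), packaged_peaklist("TBZ")
    match = match_peaks(dft, exp, tolerance=0.15)
    k, total, pairs_idx = brute_force_match(
        dft.frequencies, exp.frequencies, 0.15
    )
    assert len(match.pairs) == k
    assert sum(abs(s) for _, _, s in match.pairs) == pytest.approx(total)
    # the printed pairing crosses: computed 1.35 <-> measured 1.24, 1.56 <-> 1.66
    shifts = {(d, e): s for d, e, s in match.pairs}
    assert shifts[(1.35, 1.24)] == pytest.approx(0.11)
    assert shifts[(1.56, 1.66)] == pytest.approx(-0.10)
    assert match.unmatched_dft == [0.23]


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.data())
def test_match_equals_brute_force_on_random_lists(data):
    freqs = st.lists(
        st.floats(0.1, 3.4), min_size=0, max_size=5, unique=True
    )
    d = sorted(data.draw(freqs))
    e = sorted(data.draw(freqs))
    tol = data.draw(st.sampled_from([0.05, 0.15, 0.5]))
    dl = PeakList("A", np.array(d), np.ones(len(d)))
    el = PeakList("B", np.array(e), np.ones(len(e)))
    match = match_peaks(dl, el, tolerance=tol)
    k, total, _ = brute_force_match(d, e, tol)
    assert len(match.pairs) == k
    assert sum(abs(s) for _, _, s in match.pairs) == pytest.approx(total, abs=1e-9)


def test_match_symmetry():
    a, b = packaged_peaklist("TBZ", "dft"), packaged_peaklist("TBZ")
    fwd = match_peaks(a, b)
    rev = match_peaks(b, a)
    assert sorted((e, d, -s) for d, e, s in fwd.pairs) == sorted(rev.pairs)


def test_fingerprint_selection_reproduces_printed_set():
    pure = [packaged_peaklist(m) for m in ("BNL", "BCM", "TBZ")]
    mixes = [packaged_mixture_peaklist(m) for m in ("M1", "M2", "M3", "M4")]
    assert select_fingerprints(pure, mixes) == [0.70, 1.24, 1.95, 2.32]


def test_fingerprint_single_component_falls_back_to_strongest():
    pure = [packaged_peaklist("BNL")]
    with pytest.warns(UserWarning, match="strongest"):
        result = select_fingerprints(pure, [])
    assert result == [0.70]  # strongest of benomyl's three lines


def test_fingerprint_disjoint_components_keep_all_peaks():
    a = PeakList("A", np.array([0.5, 1.5]), np.array([1.0, 0.4]))
    b = PeakList("B", np.array([1.0, 2.0]), np.array([0.8, 0.9]))
    mix = PeakList("AB", np.array([0.5, 1.0, 1.5, 2.0]), np.ones(4))
    result = select_fingerprints(
        [a, b], [mix], mixture_components={"AB": ("A", "B")}
    )
    # brute-force uniqueness: every peak belongs to exactly one component and
    # appears in the only mixture, so all four are fingerprints
    assert result == [0.5, 1.0, 1.5, 2.0]
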