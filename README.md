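# thzresidue

Identification and visualization of trace benzimidazole pesticide residues
on plant leaves from terahertz (THz) hyperspectral images.

Benomyl (BNL), carbendazim (BCM) and thiabendazole (TBZ) are widely used
benzimidazole fungicides with nearly identical molecular scaffolds, which
makes mixed residues hard to tell apart spectroscopically. In the 0.1–3 THz
band, however, each has a distinct set of crystalline-phase absorption
peaks (BNL: 0.70, 1.07, 2.20 THz; BCM: 1.16, 1.35, 2.32 THz; TBZ: 0.92,
1.24, 1.66, 1.95, 2.58 THz). This package implements the full analysis
chain for identifying single and mixed residues (classes BG, CK, BNL, BCM,
TBZ, M1 = BNL+BCM, M2 = BNL+TBZ, M3 = BCM+TBZ, M4 = BNL+BCM+TBZ, labelled
1–9) from per-pixel absorbance spectra, for researchers in THz spectroscopy
and chemometrics:

* **`synthetic_thz` generator** (`thzresidue.synthetic`) — Lorentzian-line
  spectra and 250×250-pixel hyperspectral leaf-on-tape cubes with leaf
  geometry, optical-thickness and scattering nuisance fields, benomyl
  suppression in mixtures, and seeded, spatially correlated noise. The
  original instrument data are not deposited; the generator supplies data
  with the structure the analysis assumes.
* **Preprocessing** (`thzresidue.preprocess`) — 3×3 ROI mean-spectrum
  extraction (100 per leaf), band interception to 0.2–2.2 THz (67 grid
  points), dataset assembly with a stratified 70/30 split.
* **Peak analysis** (`thzresidue.peaks`) — prominence-based peak detection;
  globally optimal DFT↔experiment peak matching (max pairs within
  tolerance, then min total |shift|, shift = DFT − experiment); fingerprint
  selection, which returns {0.70, 1.24, 1.95, 2.32} THz on the packaged
  tables.
* **Clustering** (`thzresidue.cluster`) — fuzzy c-means
  (J = Σᵢₖ uᵢₖᵐ‖xₖ − vᵢ‖², m = 2, t = 20) with Sammon projection
  (E = (Σd\*)⁻¹ Σ (d\* − d)²/d\*) and assignment-optimal clustering
  accuracy.
* **Classifiers** (`thzresidue.nnmodels`) — a 1-D deep CNN (two convolution
  modules of 32/64 filters, five batch-normalised dense layers, dropout,
  softmax/cross-entropy, Adam) and a 40-40-40-9 MLP trained full-batch by
  Rprop or Fletcher–Reeves / Polak–Ribière / Powell–Beale conjugate
  gradients — all implemented natively in NumPy, scikit-learn estimator
  style (`fit`/`predict`/`predict_proba`, `random_state`).
* **Residue maps** (`thzresidue.residue_map`) — per-pixel classification of
  whole cubes, 250×250 label-map reconstruction, majority-label residue
  calls, lossless PNG rendering.

## Worked example

```python
import dataclasses
from thzresidue import (GeneratorConfig, simulate_study, simulate_pure_spectrum,
                        assemble_dataset, ROISpec, detect_peaks, match_peaks,
                        packaged_peaklist, train_dcnn, DCNNSpec, evaluate,
                        simulate_leaf_cube, predict_map)

# Peak analysis: detect thiabendazole's lines, match them to DFT modes
spec = simulate_pure_spectrum("TBZ", config=GeneratorConfig(noise_sd=0.0))
print("TBZ peaks (THz):", detect_peaks(spec).frequencies)
for d, e, s in match_peaks(packaged_peaklist("TBZ", "dft"),
                           packaged_peaklist("TBZ")).pairs:
    print(f"DFT {d:.2f} -> measured {e:.2f}   shift {s:+.2f}")

# A small 9-class study: simulate, extract ROI spectra, train, evaluate
cfg = GeneratorConfig(cube_height=48, cube_width=48, seed=0)
cubes = simulate_study(cfg, replicates_per_class=3)
ds = assemble_dataset(cubes, roi=ROISpec(n_per_leaf=60), split_seed=0)
model = train_dcnn(ds, DCNNSpec(epochs=60))
report = evaluate(model, ds, split="test")
print(f"overall test accuracy: {report.overall:.3f}")

# Classify every pixel of a held-out cube and call its residue type
cube = simulate_leaf_cube(8, dataclasses.replace(cfg, seed=123456))
label_map = predict_map(model, cube)
print("majority call:", label_map.majority_class, "| true class:", cube.true_class)
```

Output:

```
TBZ peaks (THz): [0.91 1.24 1.66 1.96 2.59]
DFT 0.91 -> measured 0.92   shift -0.01
DFT 1.35 -> measured 1.24   shift +0.11
DFT 1.56 -> measured 1.66   shift -0.10
DFT 1.90 -> measured 1.95   shift -0.05
DFT 2.62 -> measured 2.58   shift +0.04
overall test accuracy: 0.925
majority call: 8 | true class: 8
```

Detected peaks snap to the 30 GHz grid (0.91 ≈ 0.92, 1.96 ≈ 1.95,
2.59 ≈ 2.58 THz). The matcher reproduces the crossed thiabendazole pairing
(computed 1.35 THz ↔ measured 1.24 THz). At this miniature scale the
network already separates the nine classes well — errors concentrate in
the mixture classes, whose spectra differ only through the suppressed
benomyl lines — and the per-pixel majority vote still recovers the correct
residue class of an unseen leaf.

A command-line interface mirrors the library:
`thzresidue simulate | extract | cluster | train | evaluate | visualize`
(see `thzresidue --help`).

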