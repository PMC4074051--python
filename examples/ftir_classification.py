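"""Classify IR spectromicroscopy pixels as archaeal or bacterial.

Simulates a hyperspectral map with a known archaeal fraction, classifies
every pixel by its CH3/CH2 stretching-band ratio (threshold 0.75), prints
the percent archaeal biomass and runs PCA-LDA chemometrics on the lipid
window.
"""

import numpy as np

import phylospectra as ps
from phylospectra.synthetic import default_band_params, gaussian_bands

smap, truth = ps.simulate_spectral_map(40, 40, archaeal_fraction=0.387,
                                       noise_sd=0.005, seed=10)
cls = ps.classify_map(smap, threshold=0.75)
counts = cls.table["label"].value_counts()
print("pixel labels:", {k: int(v) for k, v in counts.items()})
print(f"percent archaeal biomass: {ps.percent_archaeal(cls):.1f}% "
      f"(ground truth {100 * truth.true_archaeal_fraction:.1f}%)")

# univariate composition of one archaeal pixel
arch_idx = cls.table.index[cls.table["label"] == "archaeal"][0]
prof = ps.band_ratio_profile(smap.wavenumbers, smap.absorbance[arch_idx])
print(f"band-ratio profile: lipid/protein = {prof.lipid_to_protein:.2f}, "
      f"carbohydrate/protein = {prof.carbohydrate_to_protein:.2f}")

# PCA-LDA on two synthetic spectral groups differing in CH2 content
rng = np.random.default_rng(11)
wn = smap.wavenumbers
bands = default_band_params()
spectra, labels = [], []
for ch2, lab in ((0.5, "site_A"), (0.8, "site_B")):
    for _ in range(25):
        amps = {"ch3_asym": 0.4, "ch2_asym": ch2, "ch3_sym": 0.22,
                "ch2_sym": 0.7 * ch2, "amide_i": 1.4, "amide_ii": 1.0,
                "carb_1": 0.4, "carb_2": 0.35}
        spectra.append(gaussian_bands(wn, {k: (*bands[k], a) for k, a in amps.items()})
                       + rng.normal(0, 0.01, len(wn)))
        labels.append(lab)
res = ps.pca_lda(np.array(spectra), np.array(labels), wn, windows=[(2800, 3100)])
top = res.wavenumbers[np.argmax(np.abs(res.loadings[:, 0]))]
print(f"PCA-LDA: LD1 explains {res.explained[0]:.1%}; "
      f"strongest loading at {top:.0f} cm-1")
# The strongest LD1 loading falls on the CH2 band that was planted to differ,
# showing the discriminant recovered the chemical cause of the separation.
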