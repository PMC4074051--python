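"""Synthetic data generators with known ground truth.

Every downstream stage of the package (eOTU discovery, community
statistics, FTIR classification, ISR fingerprinting) is testable against
these generators without any external download:

* a latent log-normal community mapped to probe-level PM/MM fluorescence
  with configurable mismatch background, sibling cross-hybridization and
  multiplicative noise;
* hyperspectral IR maps built from Gaussian lipid/protein/carbohydrate
  bands, with archaeal pixels drawn above the 0.75 CH3/CH2 amplitude ratio
  and bacterial pixels below, plus a per-pixel label map as ground truth;
* intergenic-spacer sequence pairs with an exact planted substitution count.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eotu import ProbeTable
from .ftir import SpectralMap

__all__ = [
    "SyntheticCommunity",
    "SpectralGroundTruth",
    "simulate_community",
    "simulate_probe_table",
    "simulate_spectral_map",
    "simulate_isr_pair",
    "gaussian_bands",
    "default_band_params",
    "recovery_report",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# community and probe table


@dataclass(frozen=True)
class SyntheticCommunity:
    """Latent community behind a simulated array experiment.

    ``taxa`` are unique 7-rank lineage strings; ``abundances`` is a
    taxon x sample table of non-negative relative abundances;
    ``taxon_means`` holds each taxon's geometric-mean abundance;
    ``marker_genes`` maps each lineage to its simulated marker-gene
    sequence (the pool probes are sliced from, and the classifier's
    reference).
    """

    taxa: list[str]
    abundances: pd.DataFrame
    taxon_means: np.ndarray
    marker_genes: dict[str, str]
    seed: int

    def reference(self) -> list[tuple[str, str]]:
        """(sequence, lineage) pairs for the naive-Bayes classifier."""
        return [(seq, lin) for lin, seq in self.marker_genes.items()]


def _lineage(genus_idx: int, species_idx: int, n_archaeal_genera: int) -> str:
    dom = "Archaea" if genus_idx < n_archaeal_genera else "Bacteria"
    g = genus_idx
    return ";".join(
        [dom, f"Phy{g:03d}", f"Cls{g:03d}", f"Ord{g:03d}", f"Fam{g:03d}", f"Gen{g:03d}",
         f"Sp{g:03d}_{species_idx}"]
    )


def simulate_community(
    n_taxa: int,
    n_samples: int,
    log_sd: float = 1.0,
    seed: int = 0,
    taxa_per_genus: int = 1,
    archaeal_fraction: float = 0.25,
    gene_length: int = 400,
    log_mean_range: tuple[float, float] = (math.log(100.0), math.log(10000.0)),
) -> SyntheticCommunity:
    """Log-normal community with taxon-specific mean abundance.

    Abundance of taxon t in sample s is exp(mu_t + log_sd * z_ts) with
    mu_t uniform over *log_mean_range* — a heavy-tailed community giving
    realistic probe-intensity dynamic range.  Lineages follow a generated
    7-rank taxonomy: each genus holds ``taxa_per_genus`` sibling species
    and owns its own family/order/class/phylum chain, so siblings (which
    cross-hybridize in :func:`simulate_probe_table`) share all higher
    ranks.  Roughly ``archaeal_fraction`` of genera are placed in the
    archaeal domain.
    """
    if n_taxa < 2 or n_samples < 2:
        raise ValueError("need n_taxa >= 2 and n_samples >= 2")
    if log_sd <= 0:
        raise ValueError("log_sd must be positive")
    if taxa_per_genus < 1:
        raise ValueError("taxa_per_genus must be >= 1")
    rng = np.random.default_rng(seed)
    n_genera = math.ceil(n_taxa / taxa_per_genus)
    n_arch = round(archaeal_fraction * n_genera)
    taxa = [
        _lineage(t // taxa_per_genus, t % taxa_per_genus, n_arch) for t in range(n_taxa)
    ]
    mu = rng.uniform(*log_mean_range, size=n_taxa)
    z = rng.standard_normal((n_taxa, n_samples))
    abund = np.exp(mu[:, None] + log_sd * z)
    samples = [f"S{j + 1}" for j in range(n_samples)]
    genes = {
        lin: "".join(rng.choice(_BASES, size=gene_length)) for lin in taxa
    }
    return SyntheticCommunity(
        taxa,
        pd.DataFrame(abund, index=taxa, columns=samples),
        np.exp(mu),
        genes,
        seed,
    )


def simulate_probe_table(
    community: SyntheticCommunity,
    probes_per_taxon: int = 10,
    affinity_sd: float = 0.2,
    mm_fraction: float = 0.2,
    crosshyb: float = 0.0,
    noise_sd: float = 0.01,
    background: float = 50.0,
    seed: int = 0,
) -> ProbeTable:
    """Map latent abundances to probe-level PM/MM intensities.

    PM of probe p (taxon t, sample s) is
    ``affinity_p * (abund_ts + crosshyb * sum of sibling abundances) + background``
    under multiplicative log-normal noise of log-scale sd *noise_sd*
    (which keeps every intensity positive);
    MM replaces the specific signal by ``mm_fraction`` of it.  Sibling
    taxa are species sharing the genus (rank-6) parent — cross-
    hybridization emulates sequence-similarity bleed between close
    relatives on 25-mers.  Each probe's 25-mer is sliced from its taxon's
    simulated marker gene and annotated with the taxon's lineage.
    """
    if probes_per_taxon < 5:
        raise ValueError("probes_per_taxon must be >= 5 (smaller sets are undiscoverable)")
    if not 0 <= mm_fraction < 1:
        raise ValueError("mm_fraction must be in [0, 1)")
    if not 0 <= crosshyb < 1:
        raise ValueError("crosshyb must be in [0, 1)")
    rng = np.random.default_rng(seed)
    abund = community.abundances.to_numpy()
    taxa = community.taxa
    n_taxa, n_samples = abund.shape

    genus = [lin.split(";")[5] for lin in taxa]
    sib_sum = np.zeros_like(abund)
    for i, gi in enumerate(genus):
        for j, gj in enumerate(genus):
            if i != j and gi == gj:
                sib_sum[i] += abund[j]
    signal = abund + crosshyb * sib_sum

    probe_ids, seqs, lins = [], [], []
    pm = np.empty((n_taxa * probes_per_taxon, n_samples))
    mm = np.empty_like(pm)
    for t, lin in enumerate(taxa):
        gene = community.marker_genes[lin]
        starts = rng.integers(0, len(gene) - 25 + 1, size=probes_per_taxon)
        affin = np.exp(rng.normal(0.0, affinity_sd, size=probes_per_taxon))
        for i in range(probes_per_taxon):
            row = t * probes_per_taxon + i
            probe_ids.append(f"t{t:03d}_p{i:02d}")
            seqs.append(gene[starts[i] : starts[i] + 25])
            lins.append(lin)
            specific = affin[i] * signal[t]
            pm[row] = (specific + background) * np.exp(
                noise_sd * rng.standard_normal(n_samples)
            )
            mm[row] = (mm_fraction * specific + background) * np.exp(
                noise_sd * rng.standard_normal(n_samples)
            )
    samples = list(community.abundances.columns)
    idx = pd.Index(probe_ids, name="probe_id")
    return ProbeTable(
        pd.DataFrame(pm, index=idx, columns=samples),
        pd.DataFrame(mm, index=idx, columns=samples),
        pd.Series(seqs, index=idx),
        pd.Series(lins, index=idx),
        marker_genes=community.reference(),
    )


def recovery_report(eotus, probes: ProbeTable) -> tuple[int, float]:
    """Compare discovered eOTUs against the generator's ground truth.

    Returns (number of eOTUs, fraction whose classified family matches the
    majority family annotation of their member probes).  On clean
    simulations the eOTU count should equal the simulated taxon count and
    the family accuracy should be 1.0.
    """
    n = len(eotus.eotu_ids)
    if n == 0:
        return 0, float("nan")
    hits = 0
    for e in eotus.eotu_ids:
        true_fams = [probes.family(p) for p in eotus.members[e]]
        majority = max(set(true_fams), key=true_fams.count)
        hits += eotus.family(e) == majority
    return n, hits / n


# ---------------------------------------------------------------------------
# IR spectra


@dataclass(frozen=True)
class SpectralGroundTruth:
    """Per-pixel domain labels behind a simulated IR map."""

    label_map: pd.DataFrame  # columns x, y, label
    true_archaeal_fraction: float

    def recomputed_fraction(self) -> float:
        counts = self.label_map["label"].value_counts()
        a = int(counts.get("archaeal", 0))
        b = int(counts.get("bacterial", 0))
        return a / (a + b) if a + b else float("nan")

    def to_csv(self, path) -> None:
        self.label_map.to_csv(path, index=False)


def default_band_params() -> dict[str, tuple[float, float]]:
    """(center, sigma) in cm-1 for the simulated absorption bands."""
    return {
        "ch3_asym": (2965.0, 9.0),
        "ch2_asym": (2924.0, 9.0),
        "ch3_sym": (2875.0, 9.0),
        "ch2_sym": (2850.0, 9.0),
        "amide_i": (1655.0, 18.0),
        "amide_ii": (1550.0, 12.0),
        "carb_1": (1080.0, 25.0),
        "carb_2": (1045.0, 22.0),
    }


def gaussian_bands(wavenumbers: np.ndarray, bands: dict[str, tuple[float, float, float]]) -> np.ndarray:
    """Sum of Gaussian bands; each value is (center, sigma, amplitude)."""
    wn = np.asarray(wavenumbers, float)
    spec = np.zeros_like(wn)
    for center, sigma, amp in bands.values():
        spec += amp * np.exp(-((wn - center) ** 2) / (2.0 * sigma**2))
    return spec


def simulate_spectral_map(
    width: int,
    height: int,
    archaeal_fraction: float,
    band_params: dict[str, tuple[float, float]] | None = None,
    noise_sd: float = 0.005,
    seed: int = 0,
    background_fraction: float = 0.2,
    ratio_margin: float = 0.10,
    pixel_size: float = 2.0,
) -> tuple[SpectralMap, SpectralGroundTruth]:
    """Hyperspectral map with known archaeal/bacterial/background labels.

    Non-background pixels get a sum of Gaussian bands (lipid CH stretches,
    Amide I/II, a carbohydrate envelope) on a gentle per-pixel linear
    baseline plus white noise.  Archaeal pixels draw their CH3/CH2
    amplitude ratio uniformly above ``0.75 + ratio_margin``; bacterial
    pixels below ``0.75 - ratio_margin``, so the classification threshold
    separates the classes with a controlled margin.  The wavenumber axis
    descends 3100 -> 900 cm-1 in 2 cm-1 steps.  The stored
    ``true_archaeal_fraction`` is recomputed exactly from the label map.
    """
    if not 0 <= archaeal_fraction <= 1:
        raise ValueError("archaeal_fraction must be in [0, 1]")
    if width < 1 or height < 1:
        raise ValueError("map dimensions must be positive")
    bands = dict(band_params) if band_params else default_band_params()
    rng = np.random.default_rng(seed)
    wn = np.arange(3100.0, 900.0 - 1e-9, -2.0)

    n_pix = width * height
    n_bg = round(background_fraction * n_pix)
    n_fg = n_pix - n_bg
    n_arch = round(archaeal_fraction * n_fg)
    labels = np.array(
        ["archaeal"] * n_arch + ["bacterial"] * (n_fg - n_arch) + ["background"] * n_bg
    )
    rng.shuffle(labels)

    pixels = np.array([(x, y) for y in range(height) for x in range(width)])
    absorb = np.empty((n_pix, len(wn)))
    for i, lab in enumerate(labels):
        slope = rng.uniform(-0.02, 0.02)
        offset = rng.uniform(0.0, 0.02)
        baseline = offset + slope * (wn - 900.0) / 2200.0
        if lab == "background":
            spec = baseline
        else:
            amide = rng.uniform(0.8, 1.2)
            ch2 = rng.uniform(0.4, 0.8) * amide
            if lab == "archaeal":
                r = rng.uniform(0.75 + ratio_margin, 1.30)
            else:
                r = rng.uniform(0.25, 0.75 - ratio_margin)
            ch3 = r * ch2
            amps = {
                "ch3_asym": ch3,
                "ch2_asym": ch2,
                "ch3_sym": 0.55 * ch3,
                "ch2_sym": 0.70 * ch2,
                "amide_i": 1.4 * amide,
                "amide_ii": amide,
                "carb_1": rng.uniform(0.2, 0.6) * amide,
                "carb_2": rng.uniform(0.2, 0.6) * amide,
            }
            spec = baseline + gaussian_bands(
                wn, {name: (*bands[name], amps[name]) for name in amps}
            )
        if noise_sd > 0:
            spec = spec + rng.normal(0.0, noise_sd, size=len(wn))
        absorb[i] = spec

    smap = SpectralMap(wn, absorb, pixels, pixel_size)
    label_map = pd.DataFrame(
        {"x": pixels[:, 0], "y": pixels[:, 1], "label": labels}
    )
    true_frac = n_arch / n_fg if n_fg else float("nan")
    return smap, SpectralGroundTruth(label_map, true_frac)


# ---------------------------------------------------------------------------
# ISR sequences


def simulate_isr_pair(length: int, n_snps: int, seed: int = 0) -> tuple[str, str]:
    """Random sequence pair differing at exactly *n_snps* positions (no indels)."""
    if length < 1:
        raise ValueError("length must be positive")
    if not 0 <= n_snps <= length:
        raise ValueError("n_snps must be in [0, length]")
    rng = np.random.default_rng(seed)
    a = rng.choice(_BASES, size=length)
    b = a.copy()
    sites = rng.choice(length, size=n_snps, replace=False)
    for s in sites:
        options = [x for x in "ACGT" if x != a[s]]
        b[s] = options[rng.integers(0, 3)]
    return "".join(a), "".join(b)
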