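"""SR-FTIR spectromicroscopy analysis of microbial biomass.

Mid-infrared absorbance spectra carry a lipid fingerprint that separates the
two prokaryotic domains: archaeal isoprenoid ether lipids are methyl-rich
(CH3 stretching near 2965 and 2875 cm-1) while bacterial acyl ester lipids
are methylene-rich (CH2 stretching near 2924 and 2850 cm-1).  The ratio of
the CH3 to the CH2 stretching-band absorbance therefore classifies each
~2 um pixel of a hyperspectral map as archaeal (ratio >= 0.75) or bacterial
(ratio < 0.75), and the fraction of archaeal pixels estimates percent
archaeal biomass.  The module also provides Amide-II normalization,
univariate band-ratio profiles (protein / lipid / carbohydrate indices) and
PCA-LDA chemometric ordination over configurable spectral windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "SpectralMap",
    "PixelClassification",
    "BandRatioProfile",
    "PCALDAResult",
    "baseline_correct",
    "peak_height",
    "noise_floor",
    "amide2_normalize",
    "ch3_ch2_ratio",
    "classify_ratio",
    "classify_map",
    "percent_archaeal",
    "pca_lda",
    "band_ratio_profile",
]

# Band windows (cm^-1).  The CH3 window brackets the asymmetric methyl
# stretch (2965 cm-1, with methoxy CH features up to 2975); the CH2 window
# brackets the asymmetric methylene stretch (2924 cm-1).
CH3_BAND = (2960.0, 2975.0)
CH2_BAND = (2916.0, 2936.0)
LIPID_WINDOW = (2800.0, 3000.0)
AMIDE2_BAND = (1540.0, 1560.0)
# narrow enough to stay clear of the Amide I shoulder near 1655 cm-1
AMIDE2_BASELINE = (1500.0, 1600.0)
CARB_WINDOW = (900.0, 1200.0)
QUIET_ZONE = (1800.0, 2200.0)

ARCHAEAL = "archaeal"
BACTERIAL = "bacterial"
BACKGROUND = "background"


# ---------------------------------------------------------------------------
# containers


@dataclass
class SpectralMap:
    """Pixel grid of IR absorbance spectra on a shared wavenumber axis.

    ``wavenumbers`` is stored in descending order (instrument convention);
    ``absorbance`` has one row per pixel; ``pixels`` holds the (x, y) grid
    coordinate of each row.  ``pixel_size`` is the edge length of one pixel
    in micrometres (2 um for the synchrotron maps this emulates).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    pixels: np.ndarray
    pixel_size: float = 2.0

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.pixels = np.asarray(self.pixels, dtype=int)
        d = np.diff(self.wavenumbers)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("wavenumber axis must be strictly monotone")
        if np.all(d > 0):  # normalize to descending
            self.wavenumbers = self.wavenumbers[::-1]
            self.absorbance = self.absorbance[:, ::-1]
        if self.absorbance.shape != (len(self.pixels), len(self.wavenumbers)):
            raise ValueError("absorbance shape does not match pixels x wavenumbers")
        if np.isnan(self.absorbance).any():
            raise ValueError("absorbance contains missing values")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def spectrum(self, i: int) -> np.ndarray:
        return self.absorbance[i]

    def resampled(self, step: float = 2.0) -> "SpectralMap":
        """Linear interpolation onto a common descending grid with spacing *step*."""
        lo, hi = self.wavenumbers.min(), self.wavenumbers.max()
        grid = np.arange(hi, lo - 1e-9, -step)
        asc = self.wavenumbers[::-1]
        vals = np.empty((self.n_pixels, len(grid)))
        for i in range(self.n_pixels):
            vals[i] = np.interp(grid[::-1], asc, self.absorbance[i, ::-1])[::-1]
        return SpectralMap(grid, vals, self.pixels.copy(), self.pixel_size)

    # -- dense CSV dialect: first column wavenumber, remaining columns "x:y"
    def to_csv(self, path) -> None:
        cols = {f"{x}:{y}": self.absorbance[i] for i, (x, y) in enumerate(self.pixels)}
        df = pd.DataFrame({"wavenumber": self.wavenumbers, **cols})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pixel_size: float = 2.0, resample: float | None = 2.0) -> "SpectralMap":
        df = pd.read_csv(path)
        wn = df["wavenumber"].to_numpy(float)
        pix_cols = [c for c in df.columns if c != "wavenumber"]
        pixels = np.array([[int(p) for p in c.split(":")] for c in pix_cols])
        absorb = df[pix_cols].to_numpy(float).T
        smap = cls(wn, absorb, pixels, pixel_size)
        return smap.resampled(resample) if resample else smap


@dataclass
class PixelClassification:
    """Per-pixel CH3/CH2 ratio and domain label under a fixed threshold."""

    table: pd.DataFrame  # columns x, y, ratio, label
    threshold: float = 0.75

    def __post_init__(self) -> None:
        fg = self.table[self.table["label"] != BACKGROUND]
        bad = fg[(fg["ratio"] >= self.threshold) != (fg["label"] == ARCHAEAL)]
        if len(bad):
            raise ValueError("labels inconsistent with ratio/threshold rule")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, threshold: float = 0.75) -> "PixelClassification":
        t = pd.read_csv(path, sep="\t")
        return cls(t, threshold)


@dataclass
class BandRatioProfile:
    protein_index: float
    lipid_index: float
    carbohydrate_index: float

    @property
    def lipid_to_protein(self) -> float:
        return self.lipid_index / self.protein_index

    @property
    def carbohydrate_to_protein(self) -> float:
        return self.carbohydrate_index / self.protein_index


@dataclass
class PCALDAResult:
    scores: np.ndarray      # spectra x discriminants
    loadings: np.ndarray    # window wavenumbers x discriminants
    explained: np.ndarray   # variance fraction per discriminant
    wavenumbers: np.ndarray
    labels: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# spectral primitives


def _window_mask(wavenumbers: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = min(window), max(window)
    mask = (wavenumbers >= lo) & (wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"window {window} outside wavenumber axis")
    return mask


def baseline_correct(wavenumbers, values, window, n_edge: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Linear rubber-band baseline over *window*.

    Subtracts the straight line through the two window endpoints and returns
    ``(window_wavenumbers, corrected_values)`` restricted to the window.
    Each endpoint is the mean of the ``n_edge`` outermost grid points, which
    keeps the anchor robust to single-channel noise while leaving an exactly
    linear segment at zero.
    """
    wavenumbers = np.asarray(wavenumbers, float)
    values = np.asarray(values, float)
    mask = _window_mask(wavenumbers, window)
    wn = wavenumbers[mask]
    v = values[mask]
    order = np.argsort(wn)
    m = min(n_edge, max(len(wn) // 2, 1))
    lo_idx, hi_idx = order[:m], order[-m:]
    x0, y0 = wn[lo_idx].mean(), v[lo_idx].mean()
    x1, y1 = wn[hi_idx].mean(), v[hi_idx].mean()
    if x1 == x0:
        line = np.full_like(v, y0)
    else:
        line = y0 + (wn - x0) * (y1 - y0) / (x1 - x0)
    return wn, v - line


def peak_height(wavenumbers, values, band, baseline_window) -> float:
    """Maximum baseline-corrected absorbance inside *band*."""
    wn, corr = baseline_correct(wavenumbers, values, baseline_window)
    sel = _window_mask(wn, band)
    return float(corr[sel].max())


def noise_floor(wavenumbers, values, zone: tuple[float, float] = QUIET_ZONE) -> float:
    """Noise estimate: std of the linearly detrended quiet zone (no fundamental bands)."""
    wavenumbers = np.asarray(wavenumbers, float)
    values = np.asarray(values, float)
    mask = _window_mask(wavenumbers, zone)
    wn, v = wavenumbers[mask], values[mask]
    coef = np.polyfit(wn, v, 1)
    return float(np.std(v - np.polyval(coef, wn)))


def amide2_normalize(wavenumbers, values, noise_mult: float = 3.0) -> np.ndarray | None:
    """Divide the spectrum by its Amide II (1550 +/- 10 cm-1) peak height.

    Returns ``None`` when the Amide II height does not exceed ``noise_mult``
    times the quiet-zone noise floor — the pixel holds no protein biomass and
    is treated as background.
    """
    h = peak_height(wavenumbers, values, AMIDE2_BAND, AMIDE2_BASELINE)
    if h <= noise_mult * noise_floor(wavenumbers, values):
        return None
    return np.asarray(values, float) / h


def ch3_ch2_ratio(
    wavenumbers,
    values,
    ch3_band=CH3_BAND,
    ch2_band=CH2_BAND,
    baseline_window=LIPID_WINDOW,
    noise_mult: float = 3.0,
) -> float | None:
    """CH3/CH2 stretching-band peak-height ratio of one spectrum.

    Heights are taken after a linear baseline over the 2800-3000 cm-1 lipid
    window.  Returns ``None`` (background) when the CH2 height does not rise
    above the noise floor, since the ratio is then undefined.
    """
    wn, corr = baseline_correct(wavenumbers, values, baseline_window)
    ch2 = corr[_window_mask(wn, ch2_band)].max()
    if ch2 <= noise_mult * noise_floor(wavenumbers, values):
        return None
    ch3 = corr[_window_mask(wn, ch3_band)].max()
    return float(max(ch3, 0.0) / ch2)


# ---------------------------------------------------------------------------
# map-level operations


def classify_ratio(ratio: float, threshold: float = 0.75) -> str:
    """Domain call for one CH3/CH2 ratio: archaeal at or above the threshold
    (the 0.75 bound is closed on the archaeal side), bacterial below."""
    return ARCHAEAL if ratio >= threshold else BACTERIAL


def classify_map(smap: SpectralMap, threshold: float = 0.75, noise_mult: float = 3.0) -> PixelClassification:
    """Label every pixel archaeal / bacterial / background.

    A pixel is background when either its Amide II protein band or its CH2
    lipid band fails to clear ``noise_mult`` times the quiet-zone noise
    floor.  Otherwise the CH3/CH2 ratio decides: archaeal when the ratio is
    >= *threshold* (closed bound), bacterial below.
    """
    rows = []
    for i, (x, y) in enumerate(smap.pixels):
        spec = smap.absorbance[i]
        ratio = ch3_ch2_ratio(smap.wavenumbers, spec, noise_mult=noise_mult)
        if ratio is None or amide2_normalize(smap.wavenumbers, spec, noise_mult) is None:
            rows.append((x, y, np.nan, BACKGROUND))
        else:
            rows.append((x, y, ratio, classify_ratio(ratio, threshold)))
    table = pd.DataFrame(rows, columns=["x", "y", "ratio", "label"])
    return PixelClassification(table, threshold)


def percent_archaeal(classification: PixelClassification) -> float:
    """Percent archaeal biomass = 100 * archaeal / (archaeal + bacterial) pixels."""
    counts = classification.table["label"].value_counts()
    n_arch = int(counts.get(ARCHAEAL, 0))
    n_bact = int(counts.get(BACTERIAL, 0))
    if n_arch + n_bact == 0:
        raise ValueError("no non-background pixels to classify")
    return 100.0 * n_arch / (n_arch + n_bact)


def pca_lda(
    spectra,
    labels,
    wavenumbers,
    windows=((2800.0, 3100.0),),
    n_pc: int | None = None,
    var_explained: float = 0.99,
) -> PCALDAResult:
    """PCA followed by linear discriminant analysis on spectral windows.

    Spectra are restricted to the union of *windows*, reduced by PCA (enough
    components for ``var_explained`` of the variance unless ``n_pc`` is
    given) and discriminated by LDA on the PC scores.  Loadings are the LDA
    directions back-projected onto the wavenumber axis, so band features
    driving the separation appear at their physical positions.
    """
    spectra = np.asarray(spectra, float)
    labels = np.asarray(labels)
    wavenumbers = np.asarray(wavenumbers, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("PCA-LDA needs at least two label groups")
    mask = np.zeros(len(wavenumbers), bool)
    for w in windows:
        mask |= _window_mask(wavenumbers, tuple(w))
    X = spectra[:, mask]
    max_pc = min(X.shape[0] - 1, X.shape[1])
    if n_pc is None:
        full = PCA(n_components=min(max_pc, X.shape[0] - 1)).fit(X)
        n_pc = int(np.searchsorted(np.cumsum(full.explained_variance_ratio_), var_explained) + 1)
    if not 0 < n_pc <= max_pc:
        raise ValueError(f"n_pc must be in (0, {max_pc}]")
    pca = PCA(n_components=n_pc).fit(X)
    Z = pca.transform(X)
    n_disc = min(len(np.unique(labels)) - 1, n_pc)
    lda = LinearDiscriminantAnalysis(n_components=n_disc).fit(Z, labels)
    scores = lda.transform(Z)
    directions = lda.scalings_[:, :n_disc]
    loadings = pca.components_.T @ directions
    explained = np.asarray(lda.explained_variance_ratio_[:n_disc], float)
    return PCALDAResult(scores, loadings, explained, wavenumbers[mask], labels)


def band_ratio_profile(wavenumbers, values, noise_mult: float = 3.0) -> BandRatioProfile | None:
    """Univariate composition indices of a single spectrum.

    protein = Amide II peak height; lipid = integrated baseline-corrected
    area 2800-3000 cm-1; carbohydrate = integrated area 900-1200 cm-1.
    Ratios to protein give depth-independent composition measures.  Returns
    ``None`` when the protein index is at the noise floor (background).
    """
    protein = peak_height(wavenumbers, values, AMIDE2_BAND, AMIDE2_BASELINE)
    if protein <= noise_mult * noise_floor(wavenumbers, values):
        return None
    lipid = _integrated_area(wavenumbers, values, LIPID_WINDOW)
    carb = _integrated_area(wavenumbers, values, CARB_WINDOW)
    return BandRatioProfile(protein, lipid, carb)


def _integrated_area(wavenumbers, values, window) -> float:
    wn, corr = baseline_correct(wavenumbers, values, window)
    order = np.argsort(wn)
    return float(np.trapezoid(corr[order], wn[order]))
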