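# Methods

`phylospectra` couples two independent views of an archaea-dominated
biofilm community: a genetic view from probe-level 16S rRNA oligonucleotide
array fluorescence, and a chemical view from mid-infrared spectromicroscopy.
This note records the models, the defaults that matter, the numerical
choices, and what the synthetic generators do and do not emulate.

## Empirical OTU discovery

An eOTU is not a reference-sequence cluster: it is a set of 25-mer probes
whose log2 fluorescence intensities (FI) co-vary across samples, discovered
from the data themselves.

1. **Responsive filter.** A probe enters the analysis when its perfect-match
   intensity beats its mismatch control, PM ≥ `pm_over_mm` × MM, in at
   least `min_samples` arrays (defaults 1.3 and 3). The 1.3 factor is a
   deliberately permissive default — the biological literature for this
   assay style states the PM/MM comparison but not the factor — and is
   exposed as a parameter.
2. **Probe-set clustering.** Probes sharing a family-rank annotation form
   an eligibility group. Within a group, an edge connects two probes when
   the Pearson correlation of log2(PM) across samples is ≥ `r_min`
   (default 0.85, the conventional threshold for this assay); probe-sets
   are connected components of size ≥ `min_set_size` (default 5). Components
   were chosen over cliques or agglomerative schemes because they are
   deterministic and parameter-free beyond `r_min`; probes with zero
   variance across samples have no defined correlation and are excluded
   with a warning. Spearman correlation is available as an option.
3. **HybScore.** The eOTU abundance proxy per sample is the arithmetic mean
   of log2(PM) over member probes.
4. **Presence.** An eOTU is called present in a sample when at least
   `pos_fraction` (default 0.9, high-stringency array practice) of its
   member probes are responsive there.
5. **Taxonomy.** An RDP-style naive-Bayes classifier scores each reference
   leaf by the product over query k-mers (k = 8) of the word likelihood
   (m(w) + 0.5)/(M + 1), where m(w) counts the leaf's sequences containing
   word w and M is the leaf's sequence count. Bootstrap replicates resample
   ⌈L/k⌉ k-mers with replacement; the reported lineage is the best leaf's,
   truncated at the deepest rank whose bootstrap support reaches the cutoff
   (default 0.8; support exactly at the cutoff passes). eOTU queries are
   the member 25-mers concatenated in ascending probe-id order with
   junction-spanning k-mers excluded, which makes the word-based score
   independent of concatenation order. A query sharing no k-mer with any
   reference is returned unclassified at the root rather than tie-broken.
6. **Control screening.** eOTUs present in any DNA-extraction blank are
   removed, as are eOTUs present in spring-water samples but in no biofilm
   sample.

## Community statistics

**Idealized tree.** Taxonomic assignments are prefix-merged into a rank
tree with unit branch lengths; each eOTU leaf hangs on one extra unit edge
under its deepest classified rank. This replaces a sequence-derived
phylogeny, so branch lengths carry rank counts, not evolutionary time.

**Weighted UniFrac.** For each branch, the weight is the branch length
times |p_i − p_j|, where p is the branch's leaf-subtree share of the
sample's total abundance; the root carries no edge. The normalized variant
divides by Σ b (p_i + p_j), bounding distances in [0, 1], and is the
default for ordination and clustering because it is comparable across
sample depths. The triangle inequality is not asserted — normalization
choices can violate it.

**NMDS.** Kruskal stress-1 is minimized by SMACOF majorization alternating
isotonic regression (disparities from the dissimilarity order, ties
averaged) with the Guttman transform. The first restart starts from
classical Torgerson scaling, the remaining `n_restarts − 1` (default 20
total) from seeded random configurations; convergence tolerance 1e-6,
maximum 300 iterations. Stress decreases monotonically within a restart
(tracked and tested). Coordinates are unique only up to rotation and
reflection, so only stress and configuration shape are comparable between
implementations.

**PERMANOVA.** Anderson's pseudo-F from within/between sums of squared
distances, one-factor design, labels permuted freely. When the number of
distinct label arrangements is at most `n_perm` (default 9999) the null
distribution is enumerated exhaustively and p is the fraction of
arrangements (observed included) with F ≥ observed; otherwise
p = (1 + exceedances)/(1 + n_perm). F ties are resolved with a 1e-12
slack so that mirror-image labelings count as exceedances.

**Welch screening.** Per-eOTU and per-family two-sided Welch tests with
Welch–Satterthwaite degrees of freedom. Raw p-values are thresholded at
α = 0.05 with no multiplicity correction by default, matching the original
reporting style; Benjamini–Hochberg is available behind a flag. Family
aggregation sums HybScores per sample on the log scale (the literal
reading of "aggregated HybScores"); a linear-scale option (sum of
2^HybScore, re-logged) is provided because the original scale is ambiguous.
Degenerate inputs: both groups zero-variance with equal means gives p = 1;
with unequal means p = 0 with a warning.

**Permutation FDR.** Group labels are permuted (default 100 times) and the
screen re-run; the mean null discovery count and its ratio to the observed
count are reported. This is a stated stand-in for a procedure whose
original description is not available, not a reconstruction of it.

## SR-FTIR classification

Archaeal isoprenoid ether lipids are methyl-rich, bacterial acyl ester
lipids methylene-rich, so the CH3/CH2 stretching-band absorbance ratio
separates the domains pixel by pixel at a threshold of 0.75 (closed on the
archaeal side: ratio = 0.75 is archaeal).

Estimator choices, since the ratio's operational definition is open: peak
*heights* (robust at 4 cm⁻¹ resolution) after a linear rubber-band baseline
over 2800–3000 cm⁻¹; the CH3 height is searched in 2960–2975 cm⁻¹
(asymmetric methyl stretch plus methoxy features), the CH2 height in
2916–2936 cm⁻¹ (asymmetric methylene stretch). Baseline endpoints average
the three outermost grid points to resist single-channel noise. All spectra
are resampled onto a common 2 cm⁻¹ descending grid at ingestion.

A pixel is background when either its Amide II height (1550 ± 10 cm⁻¹,
local baseline 1500–1600 chosen to clear the Amide I shoulder) or its CH2
height fails to exceed 3× the noise floor, estimated as the standard
deviation of the linearly detrended 1800–2200 cm⁻¹ quiet zone. Percent
archaeal biomass is the pixel fraction 100 × archaeal/(archaeal +
bacterial); background pixels are excluded. Area weighting is not applied.

PCA-LDA restricts spectra to a window set (lipid 2800–3100 cm⁻¹ for
archaeal comparisons; carbohydrate + lipid, 900–1280 and 2800–3100 cm⁻¹,
for bacterial ones), retains principal components explaining 99% of the
variance unless `n_pc` is given, and fits LDA on the PC scores. Loadings
are the LDA directions back-projected to the wavenumber axis so that
discriminating bands appear at their physical positions. Univariate
indices: protein = Amide II peak height, lipid = integrated 2800–3000 cm⁻¹
area, carbohydrate = integrated 900–1200 cm⁻¹ area, each baseline-corrected,
reported with their ratios to protein.

## Marker utilities

Percent archaea = 100 × archaeal/(archaeal + bacterial) 16S copies, rounded
half-up to two decimals to match the source table's formatting. The ISR
comparison uses Needleman–Wunsch global alignment (match +1, mismatch −1,
gap −5); the gap penalty is deliberately stiff relative to the mismatch
penalty because strain-level spacer variation is substitution-dominated
and a cheap gap occasionally lets a coincidental repeat rewrite
substitutions as indels. SNPs are aligned columns where both characters
are non-gap and differ. Spacer trimming is anchor-motif based, with the
flanking motifs supplied by the user.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for every test.

* **Community.** Taxon abundances are log-normal per taxon × sample with
  taxon-specific log-means uniform on [ln 100, ln 10000] — a heavy-tailed
  community giving realistic probe dynamic range. The generated taxonomy
  assigns each genus its own family/order/class/phylum chain; sibling
  species within a genus (requested via `taxa_per_genus`) share all higher
  ranks and are the only taxa that cross-hybridize, mimicking
  sequence-similarity bleed on 25-mers without a thermodynamic model.
* **Probe table.** PM = affinity × (abundance + crosshyb × sibling
  abundance) + background, under multiplicative log-normal noise (log-sd
  `noise_sd`, default 0.01) which keeps intensities positive; MM replaces
  the specific signal by `mm_fraction` (default 0.2) of it. Background is
  a constant 50 intensity units; the spike-in rescaling of the real assay
  is modeled as already applied, i.e. all samples share one scale. The
  noise model is a calibration choice, not a claim about array chemistry.
* **IR maps.** Non-background pixels are sums of Gaussian bands (CH
  stretches, Amide I/II, a two-component carbohydrate envelope) on a gentle
  per-pixel linear baseline plus white noise; archaeal pixels draw their
  CH3/CH2 amplitude ratio above 0.75 + margin, bacterial below
  0.75 − margin (margin 0.10). The axis descends 3100 → 900 cm⁻¹ in 2 cm⁻¹
  steps. No scattering physics, atmospheric lines, or detector artifacts
  are simulated, so passing tests demonstrate correctness of the band
  arithmetic, not robustness to beamline artifacts.
* **ISR pairs.** The second sequence differs from the first at exactly
  `n_snps` positions drawn without replacement; no indels.

Problem sizes used by the test suite and the acceptance script — 30 taxa ×
8 samples for end-to-end discovery, 40 × 40 pixel maps, 200 nt spacer
pairs, 200-case oracle sweeps, 1000-replicate null calibrations — were
chosen as the smallest sizes at which the statistical assertions (binomial
3-SE bounds, 18-of-20 seed criteria) are meaningful.

## Known limitations

* The idealized tree compresses phylogenetic signal to rank counts; UniFrac
  distances are not comparable with sequence-tree UniFrac values.
* The published array results (1300 bacterial + 37 archaeal eOTUs, 290/1337
  significant, Adonis p = 0.008/0.003/0.058, NMDS stress 0.0088/0.0223)
  derive from raw CEL data that this package does not parse; they are not
  regression targets here. The package's property-level checks (exact
  recovery of simulated communities, oracle equivalence of every statistic)
  stand in for them.
* Bootstrap support is resampling-based and therefore optimistic for
  references with many near-identical leaves.
* The FTIR background mask assumes a usable 1800–2200 cm⁻¹ quiet zone;
  spectra with strong CO2/water-vapor contamination there would need
  pre-cleaning the package does not provide.
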