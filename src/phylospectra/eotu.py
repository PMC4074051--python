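"""Empirical OTU (eOTU) discovery from probe-level 16S array intensities.

An eOTU is defined operationally: a set of taxonomically related 25-mer
probes whose log2 fluorescence intensities co-vary across samples.  The
pipeline is

1. responsive-probe filtering — a probe must beat its mismatch (MM) control
   (PM >= pm_over_mm * MM) in at least ``min_samples`` arrays;
2. probe-set clustering — within each family-level eligibility group,
   connect probe pairs whose Pearson correlation of log2(PM) across samples
   is >= ``r_min`` (0.85) and take connected components of size
   >= ``min_set_size``;
3. HybScore — the per-sample mean log2(PM) over member probes, the eOTU's
   abundance proxy;
4. presence calls per sample (fraction of responsive member probes);
5. taxonomy — an RDP-style bootstrapped naive-Bayes classifier run on the
   concatenated member 25-mers (k-mers spanning probe junctions excluded);
6. control screening — eOTUs detected in extraction blanks, or only in
   spring-water samples, are removed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

__all__ = [
    "ProbeTable",
    "EOTUTable",
    "ClassificationResult",
    "filter_responsive",
    "cluster_probe_sets",
    "hybscore",
    "call_presence",
    "classify_taxonomy",
    "classify_probe_set",
    "remove_control_eotus",
    "discover_eotus",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
FAMILY_RANK = 4  # zero-based index of the family rank in a 7-rank lineage

_PROBE_ALPHABET = set("ACGT")


# ---------------------------------------------------------------------------
# containers


@dataclass
class ProbeTable:
    """Per-probe PM/MM fluorescence intensities plus taxonomic annotation.

    ``pm`` and ``mm`` are probe x sample DataFrames sharing index (probe_id)
    and columns (sample_id); ``sequences`` and ``lineages`` are Series on
    the same probe index.  Lineages are semicolon-delimited 7-rank strings.
    """

    pm: pd.DataFrame
    mm: pd.DataFrame
    sequences: pd.Series
    lineages: pd.Series
    marker_genes: list[tuple[str, str]] | None = None  # (sequence, lineage) reference

    def __post_init__(self) -> None:
        if self.pm.shape != self.mm.shape or list(self.pm.columns) != list(self.mm.columns):
            raise ValueError("pm and mm must share shape and sample ordering")
        if not self.pm.index.equals(self.mm.index):
            raise ValueError("pm and mm must share the probe index")
        if self.pm.index.has_duplicates:
            raise ValueError("duplicate probe_id")
        if (self.pm.to_numpy() <= 0).any() or (self.mm.to_numpy() <= 0).any():
            raise ValueError("intensities must be positive")
        bad = [s for s in self.sequences if len(s) != 25 or not set(s) <= _PROBE_ALPHABET]
        if bad:
            raise ValueError(f"{len(bad)} probe sequences are not 25-mers over ACGT")

    @property
    def samples(self) -> list[str]:
        return list(self.pm.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.pm.index)

    def family(self, probe_id: str) -> str:
        return self.lineages.loc[probe_id].split(";")[FAMILY_RANK]

    # -- long-form TSV: probe_id, sequence, lineage, sample_id, pm, mm
    def to_tsv(self, path) -> None:
        long = self.to_long()
        long.to_csv(path, sep="\t", index=False)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for pid in self.pm.index:
            for s in self.pm.columns:
                rows.append(
                    (pid, self.sequences.loc[pid], self.lineages.loc[pid], s,
                     self.pm.at[pid, s], self.mm.at[pid, s])
                )
        return pd.DataFrame(rows, columns=["probe_id", "sequence", "lineage", "sample_id", "pm", "mm"])

    @classmethod
    def from_tsv(cls, path) -> "ProbeTable":
        long = pd.read_csv(path, sep="\t")
        pm = long.pivot(index="probe_id", columns="sample_id", values="pm")
        mm = long.pivot(index="probe_id", columns="sample_id", values="mm")
        meta = long.drop_duplicates("probe_id").set_index("probe_id")
        return cls(pm, mm, meta["sequence"], meta["lineage"])


@dataclass
class EOTUTable:
    """Discovered probe-sets with lineage, HybScores and presence calls.

    ``lineages`` maps eotu_id to a (possibly truncated) list of
    ``(taxon, bootstrap_support)`` pairs, root-most rank first.
    """

    members: dict[str, list[str]]
    lineages: dict[str, list[tuple[str, float]]]
    hybscore: pd.DataFrame  # eotu x sample, log2 FI units
    present: pd.DataFrame   # eotu x sample, bool

    def __post_init__(self) -> None:
        ids = list(self.members)
        if sorted(ids) != sorted(self.hybscore.index):
            raise ValueError("hybscore rows must match eOTU ids")
        all_probes = [p for ps in self.members.values() for p in ps]
        if len(all_probes) != len(set(all_probes)):
            raise ValueError("member probes must be disjoint across eOTUs")

    @property
    def eotu_ids(self) -> list[str]:
        return list(self.members)

    def family(self, eotu_id: str) -> str:
        """Family-rank name, or 'unclassified' when truncated above family."""
        lin = self.lineages[eotu_id]
        if len(lin) <= FAMILY_RANK:
            return "unclassified"
        return lin[FAMILY_RANK][0]

    def lineage_string(self, eotu_id: str) -> str:
        return ";".join(name for name, _ in self.lineages[eotu_id])

    def subset(self, keep: Sequence[str]) -> "EOTUTable":
        keep = list(keep)
        return EOTUTable(
            {e: self.members[e] for e in keep},
            {e: self.lineages[e] for e in keep},
            self.hybscore.loc[keep],
            self.present.loc[keep],
        )

    def to_tsv(self, path, member_path=None) -> None:
        rows = []
        for e in self.members:
            lin = self.lineages[e]
            rows.append(
                (
                    e,
                    ";".join(n for n, _ in lin),
                    ";".join(f"{s:.2f}" for _, s in lin),
                    len(self.members[e]),
                    "".join("1" if v else "0" for v in self.present.loc[e]),
                    *self.hybscore.loc[e].tolist(),
                )
            )
        cols = ["eotu_id", "lineage", "support_per_rank", "n_probes", "presence_flags",
                *self.hybscore.columns]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        if member_path is not None:
            pd.DataFrame(
                [(e, p) for e, ps in self.members.items() for p in ps],
                columns=["eotu_id", "probe_id"],
            ).to_csv(member_path, sep="\t", index=False)


@dataclass
class ClassificationResult:
    """Outcome of the bootstrapped naive-Bayes classifier for one query."""

    assignment: list[tuple[str, float]]  # truncated at the support cutoff
    full_lineage: list[str]              # best-leaf lineage, untruncated
    supports: np.ndarray                 # bootstrap support per rank of full_lineage
    log_scores: np.ndarray               # full-data log score per reference leaf
    leaf_lineages: list[str]             # lineage string per reference leaf


# ---------------------------------------------------------------------------
# operations


def filter_responsive(probes: ProbeTable, pm_over_mm: float = 1.3, min_samples: int = 3) -> set[str]:
    """Probes with PM >= pm_over_mm * MM in at least *min_samples* arrays."""
    if probes.pm.empty:
        raise ValueError("empty probe table")
    if pm_over_mm <= 1:
        raise ValueError("pm_over_mm must exceed 1")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    hits = (probes.pm.to_numpy() >= pm_over_mm * probes.mm.to_numpy()).sum(axis=1)
    return {pid for pid, h in zip(probes.probe_ids, hits) if h >= min_samples}


def _correlation(log_pm: np.ndarray, method: str) -> np.ndarray:
    if method == "pearson":
        return np.corrcoef(log_pm)
    if method == "spearman":
        ranks = np.apply_along_axis(rankdata, 1, log_pm)
        return np.corrcoef(ranks)
    raise ValueError(f"unknown correlation method {method!r}")


def cluster_probe_sets(
    probes: ProbeTable,
    responsive: Iterable[str],
    r_min: float = 0.85,
    min_set_size: int = 5,
    method: str = "pearson",
) -> list[list[str]]:
    """Connected components of the thresholded log2-FI correlation graph.

    Probes are first grouped by their family-rank annotation (taxonomic
    eligibility); edges connect pairs with correlation >= r_min within a
    group; components smaller than *min_set_size* are discarded.  Probes
    with zero variance across samples have undefined correlation and are
    excluded with a warning.  Output is deterministic: members sorted,
    sets ordered by their smallest member probe_id.
    """
    if not 0 < r_min <= 1:
        raise ValueError("r_min must be in (0, 1]")
    if min_set_size < 2:
        raise ValueError("min_set_size must be >= 2")
    if len(probes.samples) < 3:
        raise ValueError("correlation clustering needs at least 3 samples")
    responsive = set(responsive)
    groups: dict[str, list[str]] = {}
    for pid in probes.probe_ids:
        if pid in responsive:
            groups.setdefault(probes.family(pid), []).append(pid)

    sets: list[list[str]] = []
    for fam in sorted(groups):
        pids = sorted(groups[fam])
        log_pm = np.log2(probes.pm.loc[pids].to_numpy())
        variances = log_pm.var(axis=1)
        degenerate = [p for p, v in zip(pids, variances) if v == 0]
        if degenerate:
            warnings.warn(
                f"{len(degenerate)} zero-variance probe(s) excluded from clustering in family {fam}"
            )
            keep = variances > 0
            pids = [p for p, k in zip(pids, keep) if k]
            log_pm = log_pm[keep]
        if len(pids) < min_set_size:
            continue
        corr = _correlation(log_pm, method)
        adj = csr_matrix(np.triu(corr >= r_min, k=1))
        n_comp, labels = connected_components(adj, directed=False)
        for c in range(n_comp):
            comp = [p for p, l in zip(pids, labels) if l == c]
            if len(comp) >= min_set_size:
                sets.append(sorted(comp))
    sets.sort(key=lambda s: s[0])
    return sets


def _check_ids(probe_set: Sequence[str], probes: ProbeTable) -> list[str]:
    probe_set = list(probe_set)
    if not probe_set:
        raise ValueError("empty probe set")
    missing = [p for p in probe_set if p not in probes.pm.index]
    if missing:
        raise KeyError(f"unknown probe ids: {missing}")
    return probe_set


def hybscore(probe_set: Sequence[str], probes: ProbeTable) -> pd.Series:
    """HybScore: per-sample arithmetic mean of log2(PM) over member probes."""
    probe_set = _check_ids(probe_set, probes)
    return np.log2(probes.pm.loc[probe_set]).mean(axis=0)


def call_presence(
    probe_set: Sequence[str],
    probes: ProbeTable,
    pm_over_mm: float = 1.3,
    pos_fraction: float = 0.9,
) -> pd.Series:
    """Present in a sample iff >= pos_fraction of member probes are responsive there."""
    if not 0 < pos_fraction <= 1:
        raise ValueError("pos_fraction must be in (0, 1]")
    probe_set = _check_ids(probe_set, probes)
    resp = probes.pm.loc[probe_set].to_numpy() >= pm_over_mm * probes.mm.loc[probe_set].to_numpy()
    frac = resp.mean(axis=0)
    return pd.Series(frac >= pos_fraction, index=probes.samples)


# -- RDP-style bootstrapped naive Bayes -------------------------------------


def _kmer_positions(segments: Sequence[str], k: int) -> list[str]:
    """k-mers of each segment separately; junction words between segments excluded."""
    words = []
    for seg in segments:
        words.extend(seg[i : i + k] for i in range(len(seg) - k + 1))
    return words


def _classify_words(
    segments: Sequence[str],
    reference: Iterable[tuple[str, str]],
    k: int,
    n_bootstrap: int,
    cutoff: float,
    seed: int,
) -> ClassificationResult:
    words = _kmer_positions(segments, k)
    if not words:
        raise ValueError("query shorter than k")
    # leaves = unique lineages; a leaf may hold several reference sequences
    by_leaf: dict[str, list[str]] = {}
    for seq, lineage in reference:
        by_leaf.setdefault(lineage, []).append(seq)
    if not by_leaf:
        raise ValueError("empty reference")
    leaf_lineages = sorted(by_leaf)
    vocab = sorted(set(words))
    widx = {w: i for i, w in enumerate(vocab)}
    word_ids = np.array([widx[w] for w in words])

    # log P(word | leaf) with the word prior (m(w) + 0.5) / (M + 1)
    loglik = np.empty((len(leaf_lineages), len(vocab)))
    shared = np.zeros(len(leaf_lineages), dtype=int)
    for li, lin in enumerate(leaf_lineages):
        seqs = by_leaf[lin]
        M = len(seqs)
        kmer_sets = [
            {s[i : i + k] for i in range(len(s) - k + 1)} for s in seqs
        ]
        m = np.array([sum(w in ks for ks in kmer_sets) for w in vocab])
        shared[li] = int((m > 0).sum())
        loglik[li] = np.log((m + 0.5) / (M + 1.0))

    total_len = sum(len(s) for s in segments)
    log_scores = loglik[:, word_ids].sum(axis=1)

    if shared.max() == 0:  # no evidence at all: unclassified at root
        return ClassificationResult([], [], np.zeros(0), log_scores, leaf_lineages)

    best = int(np.argmax(log_scores))
    best_path = leaf_lineages[best].split(";")

    rng = np.random.default_rng(seed)
    n_draw = math.ceil(total_len / k)
    idx = rng.integers(0, len(words), size=(n_bootstrap, n_draw))
    boot_scores = loglik[:, word_ids[idx]].sum(axis=2)  # leaves x boots
    winners = boot_scores.argmax(axis=0)

    depth = len(best_path)
    supports = np.zeros(depth)
    winner_paths = [leaf_lineages[w].split(";") for w in winners]
    for d in range(depth):
        prefix = best_path[: d + 1]
        supports[d] = np.mean([wp[: d + 1] == prefix for wp in winner_paths])

    keep = 0
    for d in range(depth):
        if supports[d] >= cutoff:
            keep = d + 1
        else:
            break
    assignment = [(best_path[d], float(supports[d])) for d in range(keep)]
    return ClassificationResult(assignment, best_path, supports, log_scores, leaf_lineages)


def classify_taxonomy(
    query: str,
    reference: Iterable[tuple[str, str]],
    k: int = 8,
    n_bootstrap: int = 100,
    cutoff: float = 0.8,
    seed: int = 0,
) -> ClassificationResult:
    """Bootstrapped word-presence naive-Bayes taxonomic classification.

    Scores every reference leaf by the product over query k-mers of the
    word likelihood (m(w)+0.5)/(M+1), where m(w) counts the leaf's
    sequences containing w and M is the leaf's sequence count.  Bootstraps
    resample ceil(L/k) k-mers with replacement; the reported lineage is the
    best leaf's, truncated at the deepest rank whose bootstrap support
    reaches *cutoff* (>= cutoff passes).
    """
    if len(query) < k:
        raise ValueError("query shorter than k")
    return _classify_words([query], reference, k, n_bootstrap, cutoff, seed)


def classify_probe_set(
    probe_set: Sequence[str],
    probes: ProbeTable,
    reference: Iterable[tuple[str, str]],
    k: int = 8,
    n_bootstrap: int = 100,
    cutoff: float = 0.8,
    seed: int = 0,
) -> ClassificationResult:
    """Classify an eOTU by its concatenated member 25-mers.

    Probes are taken in ascending probe_id order; k-mers spanning the
    junction between two probes are excluded, so the classification is
    insensitive to concatenation order.
    """
    probe_set = sorted(_check_ids(probe_set, probes))
    segments = [probes.sequences.loc[p] for p in probe_set]
    return _classify_words(segments, reference, k, n_bootstrap, cutoff, seed)


def remove_control_eotus(
    eotus: EOTUTable,
    blank_samples: Iterable[str] = (),
    water_samples: Iterable[str] = (),
    biofilm_samples: Iterable[str] = (),
) -> EOTUTable:
    """Drop contamination and water-only eOTUs.

    Removes every eOTU present in any extraction-blank sample, and every
    eOTU present in at least one spring-water sample but in no biofilm
    sample.  The three sample sets must be disjoint.
    """
    blank, water, biofilm = set(blank_samples), set(water_samples), set(biofilm_samples)
    if blank & water or blank & biofilm or water & biofilm:
        raise ValueError("blank/water/biofilm sample sets must be disjoint")
    keep = []
    for e in eotus.eotu_ids:
        pres = eotus.present.loc[e]
        in_blank = any(pres.get(s, False) for s in blank)
        in_water = any(pres.get(s, False) for s in water)
        in_biofilm = any(pres.get(s, False) for s in biofilm)
        if in_blank or (in_water and not in_biofilm):
            continue
        keep.append(e)
    return eotus.subset(keep)


# ---------------------------------------------------------------------------
# pipeline


def discover_eotus(
    probes: ProbeTable,
    reference: Iterable[tuple[str, str]] | None = None,
    pm_over_mm: float = 1.3,
    min_samples: int = 3,
    r_min: float = 0.85,
    min_set_size: int = 5,
    pos_fraction: float = 0.9,
    k: int = 8,
    n_bootstrap: int = 100,
    cutoff: float = 0.8,
    seed: int = 0,
) -> EOTUTable:
    """Full eOTU discovery: filter, cluster, score, call presence, classify.

    When *reference* is None (no marker-gene reference available) each eOTU
    falls back to the majority lineage annotation of its member probes with
    nominal support 1.0.
    """
    responsive = filter_responsive(probes, pm_over_mm, min_samples)
    probe_sets = cluster_probe_sets(probes, responsive, r_min, min_set_size)
    members: dict[str, list[str]] = {}
    lineages: dict[str, list[tuple[str, float]]] = {}
    hyb_rows, pres_rows, ids = [], [], []
    reference = list(reference) if reference is not None else None
    for i, pset in enumerate(probe_sets):
        eid = f"eotu_{i + 1:04d}"
        ids.append(eid)
        members[eid] = pset
        hyb_rows.append(hybscore(pset, probes))
        pres_rows.append(call_presence(pset, probes, pm_over_mm, pos_fraction))
        if reference is not None:
            res = classify_probe_set(pset, probes, reference, k, n_bootstrap, cutoff, seed + i)
            lineages[eid] = res.assignment
        else:
            lin = pd.Series([probes.lineages.loc[p] for p in pset]).mode().iloc[0]
            lineages[eid] = [(name, 1.0) for name in lin.split(";")]
    hyb = pd.DataFrame(hyb_rows, index=ids)
    pres = pd.DataFrame(pres_rows, index=ids)
    return EOTUTable(members, lineages, hyb, pres)
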