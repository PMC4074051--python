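"""Community-level statistics on eOTU abundance (HybScore) tables.

The phylogenetic signal comes from an *idealized* tree: eOTU taxonomic
assignments are prefix-merged into a rank tree with unit branch lengths,
standing in for a sequence-derived phylogeny.  On that tree the module
computes weighted UniFrac distances, average-linkage dendrograms,
non-metric multidimensional scaling (Kruskal stress-1, SMACOF with
isotonic regression), PERMANOVA (Anderson's pseudo-F with exhaustive
enumeration on small designs), per-eOTU and family-aggregated Welch
tests, and a permutation false-discovery check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.stats import t as t_dist
from skbio import DistanceMatrix, TreeNode
from sklearn.isotonic import IsotonicRegression
from sympy.utilities.iterables import multiset_permutations

from .eotu import EOTUTable

__all__ = [
    "build_idealized_tree",
    "weighted_unifrac",
    "hierarchical_cluster",
    "NMDSResult",
    "nmds",
    "PermanovaResult",
    "permanova",
    "welch_test",
    "eotu_screen",
    "family_aggregate_screen",
    "FDRResult",
    "permutation_fdr",
]


# ---------------------------------------------------------------------------
# idealized tree and UniFrac


def build_idealized_tree(lineages: Mapping[str, Sequence[str]]) -> TreeNode:
    """Prefix-merge taxonomic paths into a unit-branch-length rank tree.

    Each eOTU becomes a leaf (named by its id) hanging on a unit edge under
    its deepest classified rank; shared rank prefixes share internal nodes.
    Truncated lineages simply attach higher up, so a leaf's depth equals
    its number of classified ranks + 1.
    """
    if not lineages:
        raise ValueError("no lineages supplied")
    root = TreeNode(name="root")
    index: dict[tuple, TreeNode] = {(): root}
    for eotu_id in sorted(lineages):
        path = tuple(lineages[eotu_id])
        if not path:
            raise ValueError(f"empty lineage for {eotu_id!r}")
        for d in range(1, len(path) + 1):
            key = path[:d]
            if key not in index:
                node = TreeNode(name=key[-1], length=1.0)
                index[key[:-1]].append(node)
                index[key] = node
        leaf = TreeNode(name=eotu_id, length=1.0)
        index[path].append(leaf)
    return root


def weighted_unifrac(
    abundances: pd.DataFrame, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac between all sample pairs.

    Branch proportion = abundance of the branch's leaf subtree divided by
    the sample's total abundance; the root carries no edge.  Raw distance
    is sum over branches of length * |p_i - p_j|; the normalized variant
    divides by the theoretical maximum sum of length * (p_i + p_j),
    bounding the distance in [0, 1].
    """
    if (abundances.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = abundances.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total abundance: {bad}")
    leaf_names = {t.name for t in tree.tips()}
    if leaf_names != set(abundances.index):
        raise ValueError("tree leaves must match abundance rows exactly")

    props = abundances.div(totals, axis=1)
    samples = list(abundances.columns)
    lengths, branch_props = [], []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._wuf = props.loc[node.name].to_numpy(copy=True)
        else:
            node._wuf = np.sum([c._wuf for c in node.children], axis=0)
        lengths.append(node.length)
        branch_props.append(node._wuf)
    for node in tree.postorder(include_self=False):
        del node._wuf
    L = np.asarray(lengths)
    P = np.asarray(branch_props)  # branches x samples

    n = len(samples)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw = float(np.sum(L * np.abs(P[:, i] - P[:, j])))
            if normalized:
                denom = float(np.sum(L * (P[:, i] + P[:, j])))
                raw = raw / denom if denom > 0 else 0.0
            dist[i, j] = dist[j, i] = raw
    return DistanceMatrix(dist, ids=samples)


# ---------------------------------------------------------------------------
# clustering and ordination


def hierarchical_cluster(dm: DistanceMatrix, method: str = "average"):
    """Agglomerative clustering of a distance matrix (UPGMA by default).

    Labels are sorted lexicographically before linkage so ties break
    deterministically.  Returns ``(Z, labels)`` where Z is a scipy linkage
    matrix over the sorted labels.
    """
    if len(dm.ids) < 2:
        raise ValueError("need at least two samples to cluster")
    labels = sorted(dm.ids)
    condensed = dm.filter(labels).condensed_form()
    return scipy_linkage(condensed, method=method), labels


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame
    stress: float
    stress_history: list[float]  # per-iteration stress of the winning restart


def _kruskal_stress(dhat: np.ndarray, d: np.ndarray) -> float:
    return math.sqrt(float(np.sum((dhat - d) ** 2) / np.sum(d**2)))


def _pairwise(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(X), 1)
    return D[iu]


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
    tol: float = 1e-6,
) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    SMACOF-style majorization alternates an isotonic regression of the
    configuration distances onto the dissimilarity order (yielding the
    disparities) with a Guttman transform.  The first restart starts from
    classical (Torgerson) scaling, the rest from seeded random
    configurations; the restart with the lowest final stress wins.
    """
    n = len(dm.ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    delta = dm.condensed_form()
    iu = np.triu_indices(n, 1)
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    best = None
    for restart in range(max(n_restarts, 1)):
        if restart == 0:
            X = _classical_mds(dm.data, k)
            if np.allclose(X, 0):
                X = rng.standard_normal((n, k))
        else:
            X = rng.standard_normal((n, k))
        history: list[float] = []
        prev = np.inf
        for _ in range(max_iter):
            d = _pairwise(X)
            if np.all(d == 0):
                X = X + 1e-9 * rng.standard_normal(X.shape)
                d = _pairwise(X)
            dhat = iso.fit_transform(delta, d)
            s = _kruskal_stress(dhat, d)
            history.append(s)
            if prev - s < tol:
                break
            prev = s
            # Guttman transform with disparities dhat
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = np.zeros((n, n))
            B[iu] = -ratio
            B = B + B.T
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
        final = history[-1] if history else float("inf")
        if best is None or final < best[0]:
            best = (final, X, history)
    stress, X, history = best
    coords = pd.DataFrame(X, index=list(dm.ids), columns=[f"NMDS{i+1}" for i in range(k)])
    return NMDSResult(coords, stress, history)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    n = len(labels)
    a = len(uniq)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore"):  # perfectly separated groups give F = inf
        return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA (Adonis) on a distance matrix.

    Pseudo-F follows Anderson's sums-of-squared-distances formulation.
    When the number of distinct label arrangements is at most *n_perm* the
    null distribution is enumerated exhaustively (p = proportion of
    arrangements, the observed one included, with F >= observed);
    otherwise labels are permuted at random and
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    groups = pd.Series(groups)
    labels = groups.loc[list(dm.ids)].to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")
    d2 = dm.data**2
    f_obs = _pseudo_f(d2, labels, uniq)

    n_distinct = math.factorial(len(labels))
    for c in counts:
        n_distinct //= math.factorial(int(c))
    eps = 1e-12
    if n_distinct <= n_perm:
        count = 0
        for perm in multiset_permutations(list(labels)):
            if _pseudo_f(d2, np.array(perm), uniq) >= f_obs - eps:
                count += 1
        return PermanovaResult(f_obs, count / n_distinct, n_distinct, True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(labels), uniq) >= f_obs - eps:
            count += 1
    return PermanovaResult(f_obs, (1 + count) / (1 + n_perm), n_perm, False)


# ---------------------------------------------------------------------------
# Welch screening


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test (two-sided).

    Returns (t, Welch-Satterthwaite df, p).  Degenerate conventions: both
    groups zero-variance with equal means -> p = 1; zero variance in both
    groups with unequal means -> p = 0 (flagged with a warning).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float("nan"), 1.0
        warnings.warn("zero variance in both groups with unequal means; p -> 0 limit")
        return math.copysign(float("inf"), x.mean() - y.mean()), float("nan"), 0.0
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)


def _two_groups(groups: Mapping[str, str] | pd.Series, samples) -> tuple[list, list, list]:
    groups = pd.Series(groups).loc[list(samples)]
    uniq = sorted(groups.unique())
    if len(uniq) != 2:
        raise ValueError("Welch screening needs exactly two sample groups")
    g1 = [s for s in samples if groups[s] == uniq[0]]
    g2 = [s for s in samples if groups[s] == uniq[1]]
    return uniq, g1, g2


def _screen_frame(scores: pd.DataFrame, groups, alpha: float) -> pd.DataFrame:
    uniq, g1, g2 = _two_groups(groups, scores.columns)
    rows = []
    for unit in scores.index:
        x = scores.loc[unit, g1].to_numpy(float)
        y = scores.loc[unit, g2].to_numpy(float)
        t, df, p = welch_test(x, y)
        rows.append((unit, t, df, p, x.mean(), y.mean(), p < alpha))
    return pd.DataFrame(
        rows,
        columns=["unit", "t", "df", "p_value", f"mean_{uniq[0]}", f"mean_{uniq[1]}", "significant"],
    ).set_index("unit")


def eotu_screen(
    eotus: EOTUTable,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Welch test per eOTU on HybScores between two sample groups.

    Raw p-values are thresholded at *alpha* by default (no multiplicity
    correction); ``correction='bh'`` applies Benjamini-Hochberg to the
    significance flags instead.
    """
    table = _screen_frame(eotus.hybscore, groups, alpha)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        rej, q, *_ = multipletests(table["p_value"], alpha=alpha, method="fdr_bh")
        table["q_value"] = q
        table["significant"] = rej
    elif correction != "none":
        raise ValueError("correction must be 'none' or 'bh'")
    return table


def family_aggregate_screen(
    eotus: EOTUTable,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    scale: str = "log",
) -> pd.DataFrame:
    """Welch test per family on aggregated HybScores.

    Families aggregate by summing member HybScores per sample (the literal
    log-scale reading of "aggregated HybScores"); ``scale='linear'`` sums
    2**HybScore and re-logs instead.  eOTUs not classified to family depth
    pool into 'unclassified'.
    """
    fams = pd.Series({e: eotus.family(e) for e in eotus.eotu_ids})
    if scale == "log":
        agg = eotus.hybscore.groupby(fams).sum()
    elif scale == "linear":
        agg = np.log2((2.0**eotus.hybscore).groupby(fams).sum())
    else:
        raise ValueError("scale must be 'log' or 'linear'")
    return _screen_frame(agg, groups, alpha)


@dataclass
class FDRResult:
    observed_count: int
    expected_null_count: float
    ratio: float
    n_permutations: int


def permutation_fdr(
    eotus: EOTUTable,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
    level: str = "eotu",
) -> FDRResult:
    """Permutation estimate of the expected false-discovery count.

    Group labels are permuted *n_perm* times and the screen re-run; the
    mean number of units passing *alpha* under permutation estimates the
    null discovery count, reported with its ratio to the observed count
    (NaN with a warning when nothing was observed).
    """
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    screen = eotu_screen if level == "eotu" else family_aggregate_screen
    if level not in ("eotu", "family"):
        raise ValueError("level must be 'eotu' or 'family'")
    groups = pd.Series(groups)
    observed = int(screen(eotus, groups, alpha)["significant"].sum())
    rng = np.random.default_rng(seed)
    values = groups.to_numpy()
    counts = []
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(values), index=groups.index)
        counts.append(int(screen(eotus, perm, alpha)["significant"].sum()))
    expected = float(np.mean(counts))
    if observed == 0:
        warnings.warn("no observed discoveries; FDR ratio undefined")
        ratio = float("nan")
    else:
        ratio = expected / observed
    return FDRResult(observed, expected, ratio, n_perm)
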