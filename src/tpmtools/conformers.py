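"""Stable binding-conformation identification from pair interaction energies.

A fragment-based energy decomposition of a receptor/cofactor/ligand complex
yields, for every sampled conformation, a vector of pair interaction
energies (PIEs, kJ/mol) between the ligand and each fragment of the
receptor–cofactor complex.  Summing a conformation's vector gives its total
interaction energy with the complex; summing over conformations per fragment
ranks the residues (and the cofactor) that drive binding.

Conformations are grouped by agglomerative hierarchical clustering on their
PIE vectors (Ward linkage on Euclidean distances by default), cluster totals
are compared all-pairs with the Tukey–Kramer test (valid for unequal cluster
sizes), and the clusters statistically indistinguishable from the
strongest-binding one (most negative mean total PIE) are flagged stable.

The ligand binding energy bookkeeping identity
``dG_bind = E_complex - (E_receptor + E_ligand)`` is provided for component
energies computed elsewhere; no quantum-chemical energies are evaluated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import studentized_range

__all__ = [
    "PIEMatrix",
    "ClusterResult",
    "EnergyTriple",
    "total_pie_per_conformation",
    "fragment_pie_profile",
    "cluster_conformations",
    "pairwise_q_statistics",
    "tukey_kramer",
    "compact_letter_display",
    "select_stable_clusters",
    "analyze_pie_matrix",
    "delta_g_bind",
]


@dataclass
class PIEMatrix:
    """Conformations x fragments table of pair interaction energies (kJ/mol)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.columns.duplicated().any():
            raise ValueError("fragment labels must be unique")
        if self.table.index.duplicated().any():
            raise ValueError("conformation ids must be unique")
        values = self.table.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("PIE matrix contains non-numeric cells")
        if not np.all(np.isfinite(values)):
            raise ValueError("PIE matrix contains missing or non-finite cells")

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @property
    def conformation_ids(self) -> list:
        return list(self.table.index)

    @property
    def fragment_labels(self) -> list:
        return list(self.table.columns)

    @property
    def n_conformations(self) -> int:
        return self.table.shape[0]


def total_pie_per_conformation(m: PIEMatrix) -> pd.Series:
    """Total interaction energy of each conformation with the complex:
    sum over all fragment pairs of its PIE row."""
    return m.table.sum(axis=1)


def fragment_pie_profile(
    m: PIEMatrix, labels: np.ndarray | None = None, cluster: int | None = None
) -> pd.Series:
    """Per-fragment PIE totals over a set of conformations.

    With ``cluster`` given (and ``labels`` assigning conformations to
    clusters), sums over that cluster only; otherwise over all
    conformations.  Used to rank residue and cofactor contributions.
    """
    if cluster is None:
        return m.table.sum(axis=0)
    if labels is None:
        raise ValueError("cluster labels required to subset by cluster")
    labels = np.asarray(labels)
    if labels.shape[0] != m.n_conformations:
        raise ValueError("labels length does not match number of conformations")
    mask = labels == cluster
    if not mask.any():
        raise ValueError(f"unknown cluster id: {cluster}")
    return m.table.loc[mask].sum(axis=0)


@dataclass
class ClusterResult:
    """Partition of conformations with per-cluster energy statistics."""

    labels: np.ndarray
    per_conformation_total: pd.Series
    per_cluster_stats: pd.DataFrame  # index cluster id; columns n, mean, sd
    linkage_info: dict
    linkage_matrix: np.ndarray | None = None
    letters: dict[int, str] | None = None
    stable_ids: list[int] | None = None

    @property
    def cluster_ids(self) -> list[int]:
        return list(self.per_cluster_stats.index)

    def groups(self) -> dict[int, np.ndarray]:
        totals = self.per_conformation_total.to_numpy()
        return {c: totals[self.labels == c] for c in self.cluster_ids}


def _auto_n_clusters(Z: np.ndarray) -> int:
    """Largest relative gap in merge heights decides the cut."""
    heights = Z[:, 2]
    if heights[-1] <= 0:
        return 1
    pos = heights[heights > 0]
    floor = pos.min() * 1e-9
    h = np.maximum(heights, floor)
    ratios = h[1:] / h[:-1]
    i = int(np.argmax(ratios))
    # cutting between merge i and i+1 leaves n_merges - i clusters
    return Z.shape[0] - i


def cluster_conformations(
    m: PIEMatrix,
    n_clusters: int | None = None,
    cut_height: float | None = None,
    linkage: str = "ward",
) -> ClusterResult:
    """Agglomerative clustering of conformations on their PIE vectors.

    Euclidean distance with Ward linkage by default ("complete" and
    "average" are accepted).  Give exactly one of ``n_clusters`` or
    ``cut_height``; with neither, the cut is placed at the largest relative
    gap in the dendrogram merge heights.  Cluster labels are renumbered by
    first occurrence in input order, making the partition deterministic and
    permutation-equivariant.
    """
    if n_clusters is not None and cut_height is not None:
        raise ValueError("give at most one of n_clusters / cut_height")
    n = m.n_conformations
    if n_clusters is not None and n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} conformations")
    X = m.values
    if n == 1:
        raw = np.array([1])
        Z = np.empty((0, 4))
    else:
        Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
        if cut_height is not None:
            raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
        else:
            k = n_clusters if n_clusters is not None else _auto_n_clusters(Z)
            raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    # renumber by first appearance
    mapping: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        labels[i] = mapping[r]

    totals = total_pie_per_conformation(m)
    tvals = totals.to_numpy()
    ids = sorted(set(labels))
    stats = pd.DataFrame(
        {
            "n": [int(np.sum(labels == c)) for c in ids],
            "mean": [float(np.mean(tvals[labels == c])) for c in ids],
            "sd": [float(np.std(tvals[labels == c], ddof=1)) if np.sum(labels == c) > 1 else float("nan") for c in ids],
        },
        index=pd.Index(ids, name="cluster"),
    )
    info = {
        "method": linkage,
        "metric": "euclidean",
        "n_clusters": len(ids),
        "cut": "height" if cut_height is not None else ("maxclust" if n_clusters is not None else "auto-gap"),
    }
    return ClusterResult(
        labels=labels,
        per_conformation_total=totals,
        per_cluster_stats=stats,
        linkage_info=info,
        linkage_matrix=Z,
    )


def dendrogram_newick(result: ClusterResult, leaf_names: list[str] | None = None) -> str:
    """Export the clustering dendrogram as Newick text with merge heights."""
    Z = result.linkage_matrix
    if Z is None or Z.shape[0] == 0:
        name = (leaf_names or ["conf_0"])[0]
        return f"{name};"
    tree = hierarchy.to_tree(Z)
    names = leaf_names or [f"conf_{i}" for i in range(Z.shape[0] + 1)]

    def rec(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = rec(node.get_left()), rec(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(tree) + ";"


# ---------------------------------------------------------------------------
# Tukey–Kramer all-pairs comparison and compact letter display


def _pooled_variance(groups: dict[int, np.ndarray]) -> tuple[float, int]:
    ns = {g: v.size for g, v in groups.items()}
    N, k = sum(ns.values()), len(groups)
    ss = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    df = N - k
    return ss / df, df


def pairwise_q_statistics(groups: dict[int, np.ndarray]) -> pd.DataFrame:
    """Studentized-range statistics for all unordered group pairs.

    q_ab = |mean_a - mean_b| / sqrt(s2_pooled/2 * (1/n_a + 1/n_b)); the
    Kramer adjustment makes the statistic valid for unequal group sizes.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    s2, df = _pooled_variance(groups)
    rows = []
    ids = sorted(groups)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            va, vb = groups[a], groups[b]
            diff = float(vb.mean() - va.mean())
            se = np.sqrt(s2 / 2 * (1 / va.size + 1 / vb.size))
            if se > 0:
                q = abs(diff) / se
            else:
                q = 0.0 if diff == 0 else np.inf
            rows.append({"cluster_a": a, "cluster_b": b, "mean_diff": diff, "q_statistic": q})
    out = pd.DataFrame(rows)
    out.attrs["df"] = df
    out.attrs["k"] = len(ids)
    out.attrs["pooled_variance"] = s2
    return out


def tukey_kramer(groups: dict[int, np.ndarray], alpha: float = 0.05):
    """All-pairs Tukey–Kramer test with compact letter display.

    Returns ``(table, letters)``: a table of pairwise rows (mean_diff,
    q_statistic, p_adjusted, reject) with ``table.attrs`` holding alpha,
    the pooled-variance df, and the group count; and a dict mapping group id
    to its letter string.  Two groups share a letter iff their comparison is
    not rejected at ``alpha``.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    table = pairwise_q_statistics(groups)
    df, k = table.attrs["df"], table.attrs["k"]
    q = table["q_statistic"].to_numpy()
    p = np.empty_like(q)
    finite = np.isfinite(q)
    p[finite] = studentized_range.sf(q[finite], k, df)
    p[~finite] = 0.0
    p[q == 0.0] = 1.0
    table["p_adjusted"] = p
    table["reject"] = p < alpha
    table.attrs["alpha"] = alpha

    means = {g: float(v.mean()) for g, v in groups.items()}
    rejected = {
        frozenset((r.cluster_a, r.cluster_b))
        for r in table.itertuples()
        if r.reject
    }
    letters = compact_letter_display(means, rejected)
    return table, letters


def compact_letter_display(
    means: dict[int, float], rejected_pairs: set[frozenset]
) -> dict[int, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; letter order
    follows ascending mean (most negative mean — strongest binding — gets
    'a').  Guarantees: no rejected pair shares a letter, and every
    non-rejected pair shares at least one.
    """
    order = sorted(means, key=lambda g: (means[g], g))
    columns: list[set] = [set(order)]
    for pair in sorted(rejected_pairs, key=lambda p: sorted(str(x) for x in p)):
        a, b = sorted(pair, key=lambda g: (means[g], g))
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb columns contained in another
        columns = [
            c for c in columns if c and not any(c < other for other in columns)
        ]
    # deduplicate while keeping one copy of identical columns
    uniq: list[set] = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    uniq.sort(key=lambda c: min((means[g], g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in means}
    for i, col in enumerate(uniq):
        tag = alphabet[i] if i < 26 else f"z{i}"
        for g in col:
            letters[g] += tag
    return {g: "".join(sorted(letters[g])) for g in means}


def select_stable_clusters(means: dict[int, float], letters: dict[int, str]) -> list[int]:
    """Clusters statistically indistinguishable from the strongest binder.

    The strongest-binding cluster is the one with the most negative mean
    total PIE; every cluster whose letter set equals that cluster's letter
    set belongs to the same indistinguishable group and is returned.
    """
    best = min(means, key=lambda g: (means[g], g))
    target = set(letters[best])
    return sorted(g for g in means if set(letters[g]) == target)


def analyze_pie_matrix(
    m: PIEMatrix,
    n_clusters: int | None = None,
    cut_height: float | None = None,
    linkage: str = "ward",
    alpha: float = 0.05,
) -> tuple[ClusterResult, pd.DataFrame]:
    """Full chain: cluster, Tukey–Kramer letters, stable-cluster selection."""
    result = cluster_conformations(m, n_clusters=n_clusters, cut_height=cut_height, linkage=linkage)
    groups = result.groups()
    if len(groups) < 2:
        only = result.cluster_ids[0]
        result.letters = {only: "a"}
        result.stable_ids = [only]
        return result, pd.DataFrame()
    table, letters = tukey_kramer(groups, alpha=alpha)
    means = {c: result.per_cluster_stats.loc[c, "mean"] for c in result.cluster_ids}
    result.letters = letters
    result.stable_ids = select_stable_clusters(means, letters)
    return result, table


@dataclass(frozen=True)
class EnergyTriple:
    """Component free energies (kJ/mol) of complex, receptor, and ligand."""

    e_complex: float
    e_receptor: float
    e_ligand: float

    def __post_init__(self) -> None:
        for name in ("e_complex", "e_receptor", "e_ligand"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def delta_g_bind(e: EnergyTriple) -> float:
    """Binding energy: E_complex - (E_receptor + E_ligand), kJ/mol."""
    return e.e_complex - (e.e_receptor + e.e_ligand)
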