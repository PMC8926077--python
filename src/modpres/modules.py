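"""Module detection on a coexpression network.

Average-linkage clustering of the TOM dissimilarity, a deterministic
tree-variant dynamic cut (static height cut + minimum size + branch
separation), module eigengenes, intramodular connectivity (kIM), module
membership (kME), hub genes, and the dataset-module correlation QC used when
a network combines several cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset
from .network import CoexpressionNetwork

GREY = "grey"

#: conventional module colour sequence, assigned by decreasing module size
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


class ModuleError(ValueError):
    pass


@dataclass
class Dendrogram:
    """Average-linkage merge history (scipy linkage matrix) over gene leaves."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        h = self.heights
        if np.any(np.diff(h) < -1e-12):
            raise ModuleError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1


@dataclass
class ModulePartition:
    """Gene-to-module assignment with eigengenes and connectivity measures."""

    labels: pd.Series  # gene id -> module colour name; GREY = unassigned
    eigengenes: pd.DataFrame = field(default=None)  # modules x samples
    prop_var_explained: pd.Series = field(default=None)
    kim: pd.Series = field(default=None)  # intramodular connectivity per gene
    kme: pd.DataFrame = field(default=None)  # genes x modules
    kme_p: pd.DataFrame = field(default=None)
    hubs: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def module_names(self) -> List[str]:
        """Non-grey module names, ordered by decreasing size."""
        sizes = self.labels[self.labels != GREY].value_counts()
        return list(sizes.index)

    def module_genes(self, name: str) -> pd.Index:
        return self.labels.index[self.labels == name]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"module": self.labels})
        if self.kim is not None:
            out["kIM"] = self.kim
        if self.kme is not None:
            own = [
                self.kme.at[g, m] if m != GREY and m in self.kme.columns else np.nan
                for g, m in self.labels.items()
            ]
            out["kME_own"] = own
        if self.hubs:
            hubset = {g for hs in self.hubs.values() for g in hs}
            out["hub"] = [int(g in hubset) for g in self.labels.index]
        return out


# --------------------------------------------------------------------------- #


def cluster_genes(dissimilarity: np.ndarray, gene_ids=None) -> Dendrogram:
    """Deterministic average-linkage agglomeration of a gene dissimilarity."""
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ModuleError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ModuleError("dissimilarity must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ModuleError("dissimilarity diagonal must be zero")
    if d.min() < 0:
        raise ModuleError("dissimilarity must be non-negative")
    if gene_ids is None:
        gene_ids = pd.RangeIndex(d.shape[0])
    merges = linkage(squareform((d + d.T) / 2, checks=False), method="average")
    return Dendrogram(merges=merges, gene_ids=pd.Index(gene_ids))


def _qualifying_branches(
    merges: np.ndarray,
    min_module_size: int,
    cut_height: float,
    min_gap: float,
) -> List[np.ndarray]:
    """Minimal dendrogram branches that qualify as modules.

    A branch (internal node) qualifies iff it has at least
    ``min_module_size`` leaves, its own merge height is <= ``cut_height``,
    and the gap between its parent's merge height and its own is >=
    ``min_gap`` (it is cleanly separated from the rest of the tree).  Only
    minimal qualifying branches are kept: once a branch is accepted, its
    ancestors are blocked, so nested candidates resolve to the tightest ones.
    Returns the accepted branches' leaf index arrays.
    """
    n = merges.shape[0] + 1
    size = np.ones(2 * n - 1, dtype=int)
    height = np.zeros(2 * n - 1)
    children: Dict[int, Tuple[int, int]] = {}
    blocked = np.zeros(2 * n - 1, dtype=bool)  # subtree contains an accepted node
    accepted: List[int] = []
    for j in range(n - 1):
        a, b, h = int(merges[j, 0]), int(merges[j, 1]), merges[j, 2]
        node = n + j
        children[node] = (a, b)
        size[node] = size[a] + size[b]
        height[node] = h
        for child in (a, b):
            if (
                child >= n
                and not blocked[child]
                and size[child] >= min_module_size
                and height[child] <= cut_height
                and (h - height[child]) >= min_gap
            ):
                accepted.append(child)
                blocked[child] = True
        blocked[node] = blocked[a] or blocked[b]

    def leaves(node: int) -> np.ndarray:
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend(children[v])
        return np.sort(np.array(out, dtype=int))

    return [leaves(v) for v in accepted]


def cut_tree_dynamic(
    dendro: Dendrogram,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
    min_gap_fraction: float = 0.05,
) -> pd.Series:
    """Deterministic tree-variant dynamic cut.

    Modules are the minimal dendrogram branches with at least
    ``min_module_size`` leaves that complete below the
    ``cut_height_quantile`` quantile of merge heights and are separated from
    their parent merge by a height gap of at least ``min_gap_fraction`` of
    the tree's total height range.  The separation requirement is what makes
    the cut behave like a dynamic tree cut rather than a flat one: tightly
    coexpressed blocks attach to the rest of the tree far above their own
    internal merges, whereas branches of unstructured genes merge onward
    almost immediately and are left unassigned.  All unassigned genes get the
    reserved label ``grey``; modules are named by decreasing size along the
    conventional colour sequence.
    """
    if min_module_size < 2:
        raise ModuleError("min_module_size must be >= 2")
    genes = dendro.gene_ids
    n = dendro.n_leaves
    if min_module_size > n:
        warnings.warn("min_module_size exceeds the gene count; all genes grey",
                      stacklevel=2)
        return pd.Series(GREY, index=genes, name="module")
    heights = dendro.heights
    cut = float(np.quantile(heights, cut_height_quantile))
    h_range = float(heights.max() - heights.min())
    branches = _qualifying_branches(
        dendro.merges, min_module_size, cut, min_gap_fraction * h_range
    )
    labels = pd.Series(GREY, index=genes, name="module")
    branches.sort(key=lambda idx: (-idx.size, int(idx[0])))
    for rank, idx in enumerate(branches):
        name = (
            COLOR_SEQUENCE[rank]
            if rank < len(COLOR_SEQUENCE)
            else f"module{rank + 1}"
        )
        labels.iloc[idx] = name
    return labels


# --------------------------------------------------------------------------- #


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    return (x - mu) / sd


def module_eigengenes(
    ds: ExpressionDataset, labels: pd.Series
) -> Tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardized expression
    submatrix (unit-norm sample scores), oriented to correlate positively with
    the module's mean expression profile, plus the proportion of module
    variance it explains."""
    modules = [m for m in labels.unique() if m != GREY]
    sizes = labels.value_counts()
    small = [m for m in modules if sizes[m] < 2]
    if small:
        raise ModuleError(f"modules below 2 genes: {small}")
    x = ds.matrix()
    gene_pos = {g: i for i, g in enumerate(ds.gene_ids)}
    eig, pve = {}, {}
    # stable module order: decreasing size, ties by name
    modules.sort(key=lambda m: (-sizes[m], m))
    for m in modules:
        idx = [gene_pos[g] for g in labels.index[labels == m]]
        sub = x[idx]
        sd = sub.std(axis=1, ddof=1)
        if np.any(sd == 0):
            bad = [labels.index[labels == m][i] for i in np.flatnonzero(sd == 0)[:5]]
            raise ModuleError(f"zero-variance genes in module {m!r}: {bad}")
        z = _standardize(sub)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_profile = z.mean(axis=0)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        eig[m] = e
        pve[m] = float(s[0] ** 2 / (s**2).sum())
    eigengenes = pd.DataFrame(eig, index=ds.sample_ids).T
    return eigengenes, pd.Series(pve, name="prop_var_explained")


def intramodular_connectivity(
    network: CoexpressionNetwork, labels: pd.Series
) -> pd.Series:
    """kIM_i: sum of gene i's adjacencies to the other genes of its module
    (grey genes are scored against the grey set; informational only)."""
    if not network.gene_ids.equals(pd.Index(labels.index)):
        raise ModuleError("labels do not match the network gene set")
    a = network.adjacency
    kim = np.zeros(network.n_genes)
    lab = labels.to_numpy()
    for m in np.unique(lab):
        idx = np.flatnonzero(lab == m)
        sub = a[np.ix_(idx, idx)]
        kim[idx] = sub.sum(axis=1) - np.diag(sub)
    return pd.Series(kim, index=labels.index, name="kIM")


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t transform at
    n - 2 degrees of freedom."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def module_membership(
    ds: ExpressionDataset, eigengenes: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """kME: correlation of every gene with every module eigengene, with
    two-sided p-values from the t transform."""
    n = ds.n_samples
    if n < 4:
        raise ModuleError("module membership needs at least 4 samples")
    if not ds.sample_ids.equals(pd.Index(eigengenes.columns)):
        raise ModuleError("eigengenes computed on different samples")
    x = _standardize(ds.matrix())
    e = eigengenes.to_numpy()
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, ddof=1, keepdims=True)
    r = x @ ez.T / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    kme = pd.DataFrame(r, index=ds.gene_ids, columns=eigengenes.index)
    pvals = pd.DataFrame(
        correlation_pvalues(r, n), index=ds.gene_ids, columns=eigengenes.index
    )
    return kme, pvals


def identify_hubs(
    partition: ModulePartition, top_n: int = 10, alpha: float = 0.05
) -> Dict[str, List[str]]:
    """Top ``top_n`` member genes per module by intramodular connectivity,
    restricted to genes significantly correlated with their own module
    eigengene (kME p < alpha)."""
    if partition.kim is None or partition.kme_p is None:
        raise ModuleError("partition lacks kIM/kME; build it via detect_modules")
    hubs: Dict[str, List[str]] = {}
    for m in partition.module_names:
        genes = partition.module_genes(m)
        sig = [g for g in genes if partition.kme_p.at[g, m] < alpha]
        sig.sort(key=lambda g: (-partition.kim[g], g))
        hubs[m] = sig[:top_n]
    return hubs


def dataset_module_correlation(
    partition: ModulePartition, dataset_indicator: pd.Series
) -> pd.DataFrame:
    """Correlation of each module eigengene with each dataset's one-vs-rest
    indicator, with Benjamini-Hochberg adjusted two-sided p-values.

    Used as QC when a network combines samples from several cohorts: a module
    driven by one cohort rather than biology shows a significant correlation.
    """
    if partition.eigengenes is None:
        raise ModuleError("partition lacks eigengenes")
    datasets = pd.unique(dataset_indicator)
    if len(datasets) < 2:
        raise ModuleError("need at least 2 datasets among the samples")
    e = partition.eigengenes
    n = e.shape[1]
    rows = []
    for m in e.index:
        for d in datasets:
            ind = (dataset_indicator.loc[e.columns] == d).astype(float).to_numpy()
            if ind.std() == 0:
                raise ModuleError(f"constant dataset indicator for {d!r}")
            r = float(np.corrcoef(e.loc[m].to_numpy(), ind)[0, 1])
            rows.append({"module": m, "dataset": d, "r": r,
                         "p": float(correlation_pvalues(np.array([r]), n)[0])})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


# --------------------------------------------------------------------------- #


def detect_modules(
    ds: ExpressionDataset,
    network: CoexpressionNetwork,
    dissimilarity: Optional[np.ndarray] = None,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
    min_gap_fraction: float = 0.05,
    top_n_hubs: int = 10,
    hub_alpha: float = 0.05,
) -> Tuple[ModulePartition, Dendrogram]:
    """Full module-detection stage: cluster the TOM dissimilarity, cut the
    tree, then attach eigengenes, kIM, kME and hub lists."""
    from .network import tom_dissimilarity

    if dissimilarity is None:
        dissimilarity = tom_dissimilarity(network)
    dendro = cluster_genes(dissimilarity, gene_ids=network.gene_ids)
    labels = cut_tree_dynamic(
        dendro,
        min_module_size=min_module_size,
        cut_height_quantile=cut_height_quantile,
        min_gap_fraction=min_gap_fraction,
    )
    partition = ModulePartition(labels=labels)
    if (labels != GREY).any():
        eigengenes, pve = module_eigengenes(ds, labels)
        kme, kme_p = module_membership(ds, eigengenes)
        partition.eigengenes = eigengenes
        partition.prop_var_explained = pve
        partition.kme = kme
        partition.kme_p = kme_p
    partition.kim = intramodular_connectivity(network, labels)
    if partition.eigengenes is not None:
        partition.hubs = identify_hubs(partition, top_n=top_n_hubs, alpha=hub_alpha)
    return partition, dendro
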