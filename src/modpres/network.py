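"""Signed weighted coexpression networks.

Correlation, soft-threshold selection against the scale-free topology
criterion, the signed adjacency transform and the topological overlap matrix
(TOM).  The signed adjacency is ``a_ij = ((1 + r_ij) / 2) ** beta`` so that
perfectly anticorrelated genes are unconnected; raising raw correlations to an
integer power would lose the sign for even powers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset


class NetworkError(ValueError):
    pass


@dataclass
class CoexpressionNetwork:
    """Symmetric signed adjacency in [0, 1] with unit diagonal."""

    adjacency: np.ndarray
    beta: int
    gene_ids: pd.Index
    signed: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NetworkError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise NetworkError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise NetworkError("adjacency values must lie in [0, 1]")
        np.fill_diagonal(a, 1.0)
        self.adjacency = a
        self.gene_ids = pd.Index(self.gene_ids)

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    def connectivity(self) -> np.ndarray:
        """Whole-network connectivity k_i = sum_{j != i} a_ij."""
        return self.adjacency.sum(axis=0) - np.diag(self.adjacency)


@dataclass
class SoftThresholdScan:
    """Result of evaluating the scale-free fit over a grid of soft powers."""

    grid: List[int]
    fits: List[float]  # signed R^2 per candidate (NaN where degenerate)
    slopes: List[float]
    mean_connectivity: List[float]
    target: float
    selected_beta: int
    target_reached: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.grid,
                "fit_r2": self.fits,
                "slope": self.slopes,
                "mean_connectivity": self.mean_connectivity,
                "selected": [b == self.selected_beta for b in self.grid],
            }
        )


# --------------------------------------------------------------------------- #


def correlation_matrix(ds: ExpressionDataset) -> pd.DataFrame:
    """Pairwise Pearson correlation of gene expression profiles.

    Raises
    ------
    NetworkError
        If fewer than 3 samples are available or any gene has zero variance
        (the offending gene ids are listed).
    """
    x = ds.matrix()
    if x.shape[1] < 3:
        raise NetworkError("correlation needs at least 3 samples")
    sd = x.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = list(ds.gene_ids[zero[:10]])
        raise NetworkError(f"zero-variance genes: {names}")
    cor = np.corrcoef(x)
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=ds.gene_ids, columns=ds.gene_ids)


def signed_adjacency(cor, beta: int, gene_ids=None) -> CoexpressionNetwork:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2) ** beta with unit diagonal."""
    if beta < 1:
        raise NetworkError(f"soft power beta must be >= 1, got {beta}")
    if isinstance(cor, pd.DataFrame):
        gene_ids = cor.index if gene_ids is None else gene_ids
        cor = cor.to_numpy()
    elif gene_ids is None:
        gene_ids = pd.RangeIndex(cor.shape[0])
    adj = ((1.0 + np.asarray(cor, dtype=float)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return CoexpressionNetwork(adjacency=adj, beta=int(beta), gene_ids=gene_ids)


def scale_free_fit(
    network: CoexpressionNetwork, n_bins: int = 10
) -> Tuple[float, float]:
    """Scale-free topology fit of the connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width bins; the fit is the
    R^2 of the regression of log10(bin frequency) on log10(mean connectivity
    per non-empty bin), signed with ``-sign(slope)`` so only a decreasing
    frequency-connectivity relationship counts as scale-free.

    Returns (signed R^2, slope).
    """
    if network.n_genes < n_bins:
        raise NetworkError(f"need at least {n_bins} genes for {n_bins} bins")
    k = network.connectivity()
    if np.ptp(k) == 0:
        raise NetworkError("degenerate degree distribution: all connectivities equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    keep = counts > 0
    mean_k = np.array(
        [k[idx == b].mean() if counts[b] else np.nan for b in range(n_bins)]
    )
    # log-log regression over non-empty bins with positive mean connectivity
    keep &= mean_k > 0
    if keep.sum() < 3:
        raise NetworkError("fewer than 3 usable connectivity bins")
    lx = np.log10(mean_k[keep])
    ly = np.log10(counts[keep] / network.n_genes)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    if ss_tot == 0:
        raise NetworkError("degenerate frequency distribution in log-log regression")
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(-np.sign(slope) * r2), float(slope)


def select_soft_threshold(
    cor,
    grid: Optional[Sequence[int]] = None,
    target: float = 0.90,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Pick the smallest soft power whose scale-free fit reaches ``target``.

    If no candidate reaches the target, the power maximizing the fit is
    selected and ``target_reached`` is False.
    """
    grid = list(grid) if grid is not None else list(range(1, 21))
    if not grid:
        raise NetworkError("empty soft-power grid")
    if any(b2 <= b1 for b1, b2 in zip(grid, grid[1:])):
        raise NetworkError("soft-power grid must be strictly increasing")
    fits, slopes, mean_k = [], [], []
    for beta in grid:
        net = signed_adjacency(cor, beta)
        mean_k.append(float(net.connectivity().mean()))
        try:
            r2, slope = scale_free_fit(net, n_bins=n_bins)
        except NetworkError:
            r2, slope = np.nan, np.nan
        fits.append(r2)
        slopes.append(slope)
    reaching = [b for b, f in zip(grid, fits) if np.isfinite(f) and f >= target]
    if reaching:
        selected, reached = reaching[0], True
    else:
        finite = [(f, b) for b, f in zip(grid, fits) if np.isfinite(f)]
        if not finite:
            raise NetworkError("scale-free fit undefined for every candidate power")
        selected, reached = max(finite)[1], False
    return SoftThresholdScan(
        grid=grid,
        fits=fits,
        slopes=slopes,
        mean_connectivity=mean_k,
        target=target,
        selected_beta=selected,
        target_reached=reached,
    )


def topological_overlap(network: CoexpressionNetwork) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j,
    with connectivities k excluding the diagonal; TOM_ii = 1.
    """
    a = network.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def tom_dissimilarity(network: CoexpressionNetwork) -> np.ndarray:
    """1 - TOM, the clustering dissimilarity."""
    return 1.0 - topological_overlap(network)


def export_edge_list(
    network: CoexpressionNetwork, path, cutoff: float = 0.0
) -> pd.DataFrame:
    """Write edges with weight >= cutoff as TSV (gene_a, gene_b, weight)."""
    iu = np.triu_indices(network.n_genes, k=1)
    w = network.adjacency[iu]
    keep = w >= cutoff
    out = pd.DataFrame(
        {
            "gene_a": network.gene_ids[iu[0][keep]],
            "gene_b": network.gene_ids[iu[1][keep]],
            "weight": w[keep],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return out
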