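"""Module preservation statistics and differential preservation.

Quantifies how well modules detected in a reference coexpression network are
preserved in a test network, via

* cross-tabulation of module memberships with upper-tail hypergeometric
  (Fisher exact) overlap p-values computed in log space, and
* permutation Z statistics: three density statistics (meanAdj,
  propVarExplained, meanSignAwareKME) and three connectivity statistics
  (cor.kIM, cor.kME, cor.cor), each standardized against a null obtained by
  drawing random gene sets of matched size from the test universe.

Z_density and Z_connectivity are the medians of their statistic classes and
Z_summary is their mean; modules with Z_summary > 10 are flagged as
well-preserved.  The differential score for a module observed in two test
networks A and B is delta Z_summary = Z_summary(A) - Z_summary(B); a positive
value is a gain of preservation (GOP) relative to B, a negative one a loss
(LOP).

The statsmodels-style entry point is :class:`ModulePreservation` (a model
built from the reference and test data) whose :meth:`~ModulePreservation.fit`
runs the permutations and returns :class:`ModulePreservationResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .datasets import ExpressionDataset
from .modules import GREY, ModulePartition
from .network import CoexpressionNetwork

DENSITY_STATS = ("meanAdj", "propVarExplained", "meanSignAwareKME")
CONNECTIVITY_STATS = ("cor.kIM", "cor.kME", "cor.cor")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS

WELL_PRESERVED_THRESHOLD = 10.0


class PreservationError(ValueError):
    pass


# --------------------------------------------------------------------------- #
# cross-tabulation


@dataclass
class CrossTabulation:
    """Gene-overlap contingency table between two module partitions with
    -log10 upper-tail Fisher exact p-values."""

    counts: pd.DataFrame  # reference modules x test modules
    neg_log10_p: pd.DataFrame
    universe_size: int


def hypergeom_upper_tail_neg_log10_p(k: int, universe: int, size_a: int, size_b: int) -> float:
    """-log10 P(X >= k) for the overlap of two gene sets of sizes ``size_a``
    and ``size_b`` drawn from ``universe`` genes.

    Evaluated entirely in log space (log-gamma terms combined by logsumexp),
    so overlaps whose p-value underflows double precision (for example
    magnitudes around 1e-310 seen for near-identical large modules) still
    yield a finite -log10 p.
    """
    if not (0 <= size_a <= universe and 0 <= size_b <= universe):
        raise PreservationError("module sizes exceed the universe")
    lo = max(0, size_a + size_b - universe)
    hi = min(size_a, size_b)
    if k > hi:
        raise PreservationError(f"overlap {k} exceeds min module size {hi}")
    if k <= lo:
        return 0.0  # upper tail covers the whole support: p = 1
    x = np.arange(k, hi + 1)
    log_pmf = (
        gammaln(size_a + 1) - gammaln(x + 1) - gammaln(size_a - x + 1)
        + gammaln(universe - size_a + 1)
        - gammaln(size_b - x + 1)
        - gammaln(universe - size_a - size_b + x + 1)
        - (gammaln(universe + 1) - gammaln(size_b + 1) - gammaln(universe - size_b + 1))
    )
    log_p = logsumexp(log_pmf)
    return float(max(0.0, -log_p / math.log(10.0)))


def cross_tabulate(
    ref_labels: pd.Series, test_labels: pd.Series
) -> CrossTabulation:
    """Contingency table of reference vs test module labels over one shared
    gene universe, with -log10 Fisher exact upper-tail p per module pair."""
    if set(ref_labels.index) != set(test_labels.index):
        raise PreservationError("label maps cover different gene universes")
    test_labels = test_labels.loc[ref_labels.index]
    counts = pd.crosstab(ref_labels, test_labels)
    counts.index.name, counts.columns.name = "reference", "test"
    universe = len(ref_labels)
    ref_sizes = counts.sum(axis=1)
    test_sizes = counts.sum(axis=0)
    neg_log10 = counts.astype(float).copy()
    for r in counts.index:
        for c in counts.columns:
            neg_log10.at[r, c] = hypergeom_upper_tail_neg_log10_p(
                int(counts.at[r, c]), universe, int(ref_sizes[r]), int(test_sizes[c])
            )
    return CrossTabulation(counts=counts, neg_log10_p=neg_log10, universe_size=universe)


# --------------------------------------------------------------------------- #
# preservation statistics


class _SideData:
    """Precomputed per-network quantities reused across permutations."""

    def __init__(self, ds: ExpressionDataset, network: CoexpressionNetwork):
        if not ds.gene_ids.equals(network.gene_ids):
            raise PreservationError("dataset and network gene universes differ")
        self.gene_ids = ds.gene_ids
        x = ds.matrix()
        sd = x.std(axis=1, ddof=1)
        if np.any(sd == 0):
            bad = list(ds.gene_ids[np.flatnonzero(sd == 0)[:5]])
            raise PreservationError(f"zero-variance genes: {bad}")
        self.xstd = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        self.n_samples = x.shape[1]
        self.cor = np.corrcoef(x)
        np.fill_diagonal(self.cor, 1.0)
        self.adj = network.adjacency

    def eigengene(self, idx: np.ndarray) -> Tuple[np.ndarray, float]:
        """Unit-norm first right singular vector of the standardized module
        submatrix, oriented along the module mean profile, plus the
        proportion of variance it explains."""
        z = self.xstd[idx]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        if np.dot(e, z.mean(axis=0)) < 0:
            e = -e
        return e, float(s[0] ** 2 / (s**2).sum())

    def kme_to(self, eigengene: np.ndarray) -> np.ndarray:
        """Correlation of every gene with the given eigengene profile."""
        ez = (eigengene - eigengene.mean()) / eigengene.std(ddof=1)
        return np.clip(self.xstd @ ez / (self.n_samples - 1), -1.0, 1.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _stats_for_gene_set(idx: np.ndarray, ref: _SideData, test: _SideData) -> Dict[str, float]:
    m = idx.size
    tri = np.triu_indices(m, k=1)

    adj_t = test.adj[np.ix_(idx, idx)]
    adj_r = ref.adj[np.ix_(idx, idx)]
    mean_adj = float(adj_t[tri].mean())

    e_r, _ = ref.eigengene(idx)
    e_t, pve_t = test.eigengene(idx)
    kme_r = ref.kme_to(e_r)
    kme_t = test.kme_to(e_t)
    mean_sign_aware = float(np.mean(np.sign(kme_r[idx]) * kme_t[idx]))

    kim_r = adj_r.sum(axis=1) - np.diag(adj_r)
    kim_t = adj_t.sum(axis=1) - np.diag(adj_t)

    return {
        "meanAdj": mean_adj,
        "propVarExplained": pve_t,
        "meanSignAwareKME": mean_sign_aware,
        "cor.kIM": _pearson(kim_r, kim_t),
        "cor.kME": _pearson(kme_r, kme_t),
        "cor.cor": _pearson(ref.cor[np.ix_(idx, idx)][tri], test.cor[np.ix_(idx, idx)][tri]),
    }


def observed_statistics(
    ref_data: ExpressionDataset,
    ref_network: CoexpressionNetwork,
    partition: ModulePartition,
    test_data: ExpressionDataset,
    test_network: CoexpressionNetwork,
    module: str,
) -> Dict[str, float]:
    """The six preservation statistics of one reference module evaluated in
    the test network."""
    ref = _SideData(ref_data, ref_network)
    test = _SideData(test_data, test_network)
    _check_universe(ref, test)
    genes = partition.module_genes(module)
    if len(genes) < 2:
        raise PreservationError(f"module {module!r} has fewer than 2 genes")
    missing = [g for g in genes if g not in test.gene_ids]
    if missing:
        raise PreservationError(f"module genes missing from test universe: {missing[:10]}")
    idx = np.array([test.gene_ids.get_loc(g) for g in genes])
    return _stats_for_gene_set(idx, ref, test)


def _check_universe(ref: _SideData, test: _SideData) -> None:
    if not ref.gene_ids.equals(test.gene_ids):
        raise PreservationError(
            "reference and test must share one gene universe (same ids, same order)"
        )


def permutation_null(
    ref: _SideData,
    test: _SideData,
    module_sizes: Mapping[str, int],
    observed: Mapping[str, Mapping[str, float]],
    n_perm: int = 500,
    seed: Optional[int] = None,
) -> Dict[str, pd.DataFrame]:
    """Permutation null for every module size: each permutation draws a
    uniform random gene set of the module's size from the test universe and
    recomputes all six statistics.

    Returns per module a DataFrame indexed by statistic with columns
    ``null_mean``, ``null_sd`` and ``p`` (add-one permutation p-value of the
    observed statistic).
    """
    if n_perm < 50:
        raise PreservationError("n_perm must be >= 50")
    n_genes = len(test.gene_ids)
    for mod, size in module_sizes.items():
        if size > n_genes:
            raise PreservationError(f"module {mod!r} larger than the universe")
    rng = np.random.default_rng(seed)
    draws: Dict[str, List[Dict[str, float]]] = {m: [] for m in module_sizes}
    for _ in range(n_perm):
        for mod, size in module_sizes.items():
            idx = rng.choice(n_genes, size=size, replace=False)
            draws[mod].append(_stats_for_gene_set(np.sort(idx), ref, test))
    out = {}
    for mod in module_sizes:
        null = pd.DataFrame(draws[mod], columns=list(ALL_STATS))
        obs = pd.Series(observed[mod])
        n_ge = (null >= obs).sum(axis=0)
        out[mod] = pd.DataFrame(
            {
                "null_mean": null.mean(axis=0),
                "null_sd": null.std(axis=0, ddof=1),
                "p": (1.0 + n_ge) / (n_perm + 1.0),
            }
        )
    return out


# --------------------------------------------------------------------------- #
# model / results


@dataclass
class PreservationResult:
    """Per-module preservation summary for one reference-vs-test comparison."""

    table: pd.DataFrame  # per-module rows: observed stats, Z's, Z_summary...
    n_permutations: int
    seed: Optional[int]

    @property
    def z_summary(self) -> pd.Series:
        return self.table["Z_summary"]


class ModulePreservationResults(PreservationResult):
    """Results object returned by :meth:`ModulePreservation.fit`."""

    def summary(self) -> pd.DataFrame:
        cols = (
            ["size"]
            + [f"obs.{s}" for s in ALL_STATS]
            + [f"Z.{s}" for s in ALL_STATS]
            + ["Z_density", "Z_connectivity", "Z_summary", "well_preserved"]
        )
        return self.table[cols].copy()

    def __str__(self) -> str:
        show = self.table[
            ["size", "Z_density", "Z_connectivity", "Z_summary", "well_preserved"]
        ]
        head = (
            f"Module preservation (n_perm={self.n_permutations}, "
            f"seed={self.seed}, well-preserved at Z_summary > "
            f"{WELL_PRESERVED_THRESHOLD:g})"
        )
        return head + "\n" + show.to_string(float_format=lambda v: f"{v:.2f}")

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "module"
        out.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


class ModulePreservation:
    """Preservation of reference modules in a test network.

    Parameters
    ----------
    ref_data, ref_network, ref_partition
        The reference condition's expression data, signed network and module
        partition (module assignment is only needed on the reference side).
    test_data, test_network
        The test condition's expression data and signed network, over the
        same gene universe in the same order.
    """

    def __init__(
        self,
        ref_data: ExpressionDataset,
        ref_network: CoexpressionNetwork,
        ref_partition: ModulePartition,
        test_data: ExpressionDataset,
        test_network: CoexpressionNetwork,
    ):
        self._ref = _SideData(ref_data, ref_network)
        self._test = _SideData(test_data, test_network)
        _check_universe(self._ref, self._test)
        self.partition = ref_partition
        self.modules = ref_partition.module_names  # grey excluded
        if not self.modules:
            raise PreservationError("reference partition has no non-grey modules")

    def fit(
        self, n_perm: int = 500, seed: Optional[int] = None
    ) -> ModulePreservationResults:
        """Run the permutation test and assemble per-module Z statistics."""
        gene_pos = {g: i for i, g in enumerate(self._test.gene_ids)}
        observed, sizes = {}, {}
        for mod in self.modules:
            genes = self.partition.module_genes(mod)
            idx = np.array([gene_pos[g] for g in genes])
            observed[mod] = _stats_for_gene_set(idx, self._ref, self._test)
            sizes[mod] = idx.size
        null = permutation_null(
            self._ref, self._test, sizes, observed, n_perm=n_perm, seed=seed
        )
        rows = []
        for mod in self.modules:
            row: Dict[str, object] = {"module": mod, "size": sizes[mod]}
            zs: Dict[str, float] = {}
            for stat in ALL_STATS:
                obs = observed[mod][stat]
                mu = null[mod].at[stat, "null_mean"]
                sd = null[mod].at[stat, "null_sd"]
                if not np.isfinite(sd) or sd == 0:
                    warnings.warn(
                        f"module {mod!r}: statistic {stat} has zero/undefined "
                        "permutation SD; excluded from Z aggregation",
                        stacklevel=2,
                    )
                    z = np.nan
                else:
                    z = (obs - mu) / sd
                zs[stat] = z
                row[f"obs.{stat}"] = obs
                row[f"null_mean.{stat}"] = mu
                row[f"null_sd.{stat}"] = sd
                row[f"Z.{stat}"] = z
                row[f"p.{stat}"] = null[mod].at[stat, "p"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                z_den = np.nanmedian([zs[s] for s in DENSITY_STATS])
                z_con = np.nanmedian([zs[s] for s in CONNECTIVITY_STATS])
            z_sum = (z_den + z_con) / 2.0
            if not np.isfinite(z_sum):
                raise PreservationError(
                    f"Z_summary undefined for module {mod!r} "
                    "(an entire statistic class lost its permutation SD)"
                )
            row["Z_density"] = z_den
            row["Z_connectivity"] = z_con
            row["Z_summary"] = z_sum
            row["well_preserved"] = bool(z_sum > WELL_PRESERVED_THRESHOLD)
            rows.append(row)
        table = pd.DataFrame(rows).set_index("module")
        return ModulePreservationResults(table=table, n_permutations=n_perm, seed=seed)


def module_preservation(
    ref_data: ExpressionDataset,
    ref_network: CoexpressionNetwork,
    ref_partition: ModulePartition,
    test_data: ExpressionDataset,
    test_network: CoexpressionNetwork,
    n_perm: int = 500,
    seed: Optional[int] = None,
) -> ModulePreservationResults:
    """Functional wrapper around :class:`ModulePreservation`."""
    model = ModulePreservation(
        ref_data, ref_network, ref_partition, test_data, test_network
    )
    return model.fit(n_perm=n_perm, seed=seed)


# --------------------------------------------------------------------------- #
# differential preservation


@dataclass
class DifferentialPreservationTable:
    """Per-module delta Z_summary between two test networks with GOP/LOP call."""

    table: pd.DataFrame  # columns: Z_summary_A, Z_summary_B, delta_z, call

    def sorted(self) -> pd.DataFrame:
        return self.table.sort_values("delta_z", ascending=False)

    def to_tsv(self, path) -> None:
        out = self.sorted().copy()
        out.index.name = "module"
        out.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


def _as_z_series(result) -> pd.Series:
    if isinstance(result, PreservationResult):
        return result.z_summary
    if isinstance(result, pd.Series):
        return result
    if isinstance(result, Mapping):
        return pd.Series(result, dtype=float)
    raise PreservationError(f"cannot extract Z_summary from {type(result)!r}")


def delta_z_summary(
    result_a, result_b
) -> DifferentialPreservationTable:
    """Differential preservation: delta_z = Z_summary(A) - Z_summary(B) per
    module, with call GOP (delta_z > 0), LOP (delta_z < 0) or neutral
    (delta_z == 0).

    Accepts fitted :class:`ModulePreservationResults` objects, or plain
    module -> Z_summary mappings/Series (both over the same reference
    partition's modules).
    """
    za, zb = _as_z_series(result_a), _as_z_series(result_b)
    if set(za.index) != set(zb.index):
        raise PreservationError("results cover different module sets")
    zb = zb.loc[za.index]
    delta = za - zb
    call = np.where(delta > 0, "GOP", np.where(delta < 0, "LOP", "neutral"))
    table = pd.DataFrame(
        {"Z_summary_A": za, "Z_summary_B": zb, "delta_z": delta, "call": call}
    )
    table.index.name = "module"
    return DifferentialPreservationTable(table=table)
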