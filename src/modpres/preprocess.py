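"""Preprocessing chain for expression matrices.

Probe-to-gene summarization, low-abundance filtering, log2 transformation with
per-sample median alignment, parametric empirical-Bayes batch correction
(location/scale model), least-squares covariate adjustment, correlation-based
sample outlier removal and PCA scores for QC.

The driver :func:`preprocess_pipeline` enforces the canonical order:
summarize -> filter -> normalize -> correct_batch -> adjust_covariates ->
remove_outliers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


# --------------------------------------------------------------------------- #
# probe summarization


def summarize_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: Mapping[str, str],
    metadata: Optional[pd.DataFrame] = None,
) -> ExpressionDataset:
    """Collapse probe-level intensities to gene level by averaging.

    Probes without a map entry are dropped (the count is logged).  Gene order
    follows first appearance of each gene among the mapped probes.
    """
    if not probe_to_gene:
        raise PreprocessError("empty probe-to-gene map")
    mapped = probe_matrix.index[probe_matrix.index.isin(probe_to_gene)]
    n_dropped = probe_matrix.shape[0] - len(mapped)
    if n_dropped:
        logger.info("summarize_probes: dropped %d unmapped probes", n_dropped)
    if not len(mapped):
        raise PreprocessError("no probe maps to any gene")
    sub = probe_matrix.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name="gene_id")
    order = genes.drop_duplicates()
    summarized = sub.groupby(genes, sort=False).mean().loc[order]
    return ExpressionDataset(summarized, metadata)


# --------------------------------------------------------------------------- #
# abundance filter


def filter_low_abundance(ds: ExpressionDataset, percentile: float = 5.0) -> ExpressionDataset:
    """Drop genes whose mean abundance is strictly below the given percentile
    of all gene means (linear-interpolation percentile definition)."""
    if not 0 <= percentile < 100:
        raise PreprocessError("percentile must lie in [0, 100)")
    means = ds.values.mean(axis=1)
    cutoff = np.percentile(means.to_numpy(), percentile)
    keep = means >= cutoff
    if not keep.any():
        raise PreprocessError("abundance filter would remove every gene")
    logger.info(
        "filter_low_abundance: removed %d of %d genes below the %.3g percentile",
        int((~keep).sum()), ds.n_genes, percentile,
    )
    return ExpressionDataset(ds.values.loc[keep], ds.metadata.copy())


# --------------------------------------------------------------------------- #
# transformation / normalization


def normalize(ds: ExpressionDataset, already_log: bool = True) -> ExpressionDataset:
    """log2-transform if needed, then align each sample's median to the global
    median of sample medians."""
    values = ds.values
    if not already_log:
        arr = values.to_numpy()
        bad = np.argwhere(arr <= 0)
        if bad.size:
            g, s = bad[0]
            raise PreprocessError(
                f"non-positive value {arr[g, s]!r} at gene "
                f"{values.index[g]!r}, sample {values.columns[s]!r}: "
                "cannot log2-transform"
            )
        values = np.log2(values)
    medians = values.median(axis=0)
    target = float(np.median(medians.to_numpy()))
    shifted = values - medians + target
    return ExpressionDataset(shifted, ds.metadata.copy())


# --------------------------------------------------------------------------- #
# batch correction: parametric empirical-Bayes location/scale model


@dataclass
class BatchModel:
    """Fitted batch model: per-batch per-gene location (gamma) and scale
    (delta^2) effects with their empirical-Bayes shrunken counterparts, plus
    the per-batch prior hyperparameters.  With a single batch the model is the
    identity."""

    batches: List[str]
    gamma_hat: Dict[str, np.ndarray]
    delta2_hat: Dict[str, np.ndarray]
    gamma_star: Dict[str, np.ndarray]
    delta2_star: Dict[str, np.ndarray]
    priors: Dict[str, Dict[str, float]]
    identity: bool = False


def _aprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var()
    return (2 * s2 + m**2) / s2


def _bprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var()
    return (m * s2 + m**3) / s2


def _posterior_iteration(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
    max_iter: int = 500,
) -> Tuple[np.ndarray, np.ndarray]:
    """Iterative solution of the coupled EB posterior estimates."""
    n = z_batch.shape[1]
    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n * tau2 * gamma_hat + delta2_star * gamma_bar) / (
            n * tau2 + delta2_star
        )
        ss = ((z_batch - gamma_new[:, None]) ** 2).sum(axis=1)
        delta2_new = (b + 0.5 * ss) / (n / 2 + a - 1)
        change = max(
            np.abs(gamma_new - gamma_star).max(),
            np.abs(delta2_new - delta2_star).max(),
        )
        gamma_star, delta2_star = gamma_new, delta2_new
        if change < conv:
            break
    return gamma_star, delta2_star


def correct_batch(ds: ExpressionDataset) -> Tuple[ExpressionDataset, BatchModel]:
    """Remove additive/multiplicative batch effects by parametric empirical
    Bayes (gene standardization; per-batch moment estimates of gamma and
    delta^2; shrinkage toward batch-level normal / inverse-gamma priors fitted
    by the method of moments; adjust and back-transform).

    Requires every batch to have >= 2 samples.  With one batch the input is
    returned unchanged together with an identity model.
    """
    batch = ds.metadata["batch"].astype(str)
    levels = list(pd.unique(batch))
    if len(levels) == 1:
        model = BatchModel(levels, {}, {}, {}, {}, {}, identity=True)
        return ds.copy(), model
    counts = batch.value_counts()
    singles = counts[counts < 2]
    if len(singles):
        raise PreprocessError(
            f"batches with a single sample (variance undefined): {list(singles.index)}"
        )
    x = ds.matrix()
    n_total = x.shape[1]
    members = {b: np.flatnonzero((batch == b).to_numpy()) for b in levels}

    # gene-wise standardization against the batch-weighted grand mean and
    # pooled variance
    batch_means = np.column_stack([x[:, members[b]].mean(axis=1) for b in levels])
    weights = np.array([len(members[b]) / n_total for b in levels])
    grand_mean = batch_means @ weights
    fitted = np.zeros_like(x)
    for j, b in enumerate(levels):
        fitted[:, members[b]] = batch_means[:, [j]]
    var_pooled = ((x - fitted) ** 2).mean(axis=1)
    if np.any(var_pooled <= 0):
        raise PreprocessError("genes with zero pooled variance; filter them first")
    sd_pooled = np.sqrt(var_pooled)
    z = (x - grand_mean[:, None]) / sd_pooled[:, None]

    gamma_hat, delta2_hat, gamma_star, delta2_star, priors = {}, {}, {}, {}, {}
    z_adj = z.copy()
    for b in levels:
        zb = z[:, members[b]]
        g_hat = zb.mean(axis=1)
        d2_hat = zb.var(axis=1, ddof=1)
        gamma_bar, tau2 = float(g_hat.mean()), float(g_hat.var())
        a, bp = _aprior(d2_hat), _bprior(d2_hat)
        g_star, d2_star = _posterior_iteration(zb, g_hat, d2_hat, gamma_bar, tau2, a, bp)
        z_adj[:, members[b]] = (zb - g_star[:, None]) / np.sqrt(d2_star)[:, None]
        gamma_hat[b], delta2_hat[b] = g_hat, d2_hat
        gamma_star[b], delta2_star[b] = g_star, d2_star
        priors[b] = {"gamma_bar": gamma_bar, "tau2": tau2, "a": a, "b": bp}

    corrected = z_adj * sd_pooled[:, None] + grand_mean[:, None]
    out = ExpressionDataset(
        pd.DataFrame(corrected, index=ds.gene_ids, columns=ds.sample_ids),
        ds.metadata.copy(),
    )
    model = BatchModel(levels, gamma_hat, delta2_hat, gamma_star, delta2_star, priors)
    return out, model


# --------------------------------------------------------------------------- #
# covariate adjustment


def adjust_covariates(
    ds: ExpressionDataset, covariate_names: Sequence[str] = ("age", "sex")
) -> ExpressionDataset:
    """Regress each gene on the named covariates (ordinary least squares) and
    subtract the fitted covariate contribution, retaining the gene-wise grand
    mean.  Constant covariates are dropped with a warning; collinear covariate
    sets raise an error."""
    missing = [c for c in covariate_names if c not in ds.metadata.columns]
    if missing:
        raise PreprocessError(f"covariates not in metadata: {missing}")
    cov = ds.metadata.loc[:, list(covariate_names)].astype(float)
    if cov.isna().any().any():
        raise PreprocessError("missing covariate values")
    keep = []
    for c in covariate_names:
        if cov[c].nunique() <= 1:
            warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=2)
        else:
            keep.append(c)
    if not keep:
        return ds.copy()
    design = cov[keep].to_numpy()
    design = design - design.mean(axis=0)  # centred: intercept = grand mean
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise PreprocessError(f"collinear covariates: {keep}")
    x = ds.matrix()
    centred = x - x.mean(axis=1, keepdims=True)
    coef, *_ = np.linalg.lstsq(design, centred.T, rcond=None)
    adjusted = x - (design @ coef).T
    return ExpressionDataset(
        pd.DataFrame(adjusted, index=ds.gene_ids, columns=ds.sample_ids),
        ds.metadata.copy(),
    )


# --------------------------------------------------------------------------- #
# sample outliers


def remove_outlier_samples(
    ds: ExpressionDataset, z_cut: float = -2.5
) -> Tuple[ExpressionDataset, List[str], np.ndarray]:
    """Flag samples whose standardized mean inter-sample correlation falls
    below ``z_cut``.

    Returns the filtered dataset, the removed sample ids, and the
    average-linkage sample dendrogram (scipy linkage matrix, distance
    1 - correlation) for inspection.  If the mean correlations have zero
    variance no sample is an outlier.
    """
    if ds.n_samples < 3:
        raise PreprocessError("need at least 3 samples for outlier detection")
    x = ds.matrix()
    cor = np.corrcoef(x.T)
    np.fill_diagonal(cor, np.nan)
    mean_cor = np.nanmean(cor, axis=1)
    sd = mean_cor.std()
    z = np.zeros_like(mean_cor) if sd == 0 else (mean_cor - mean_cor.mean()) / sd
    flagged = z < z_cut
    if flagged.all():
        raise PreprocessError("every sample flagged as outlier")
    dist = 1.0 - np.nan_to_num(cor, nan=1.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    tree = linkage(squareform(dist, checks=False), method="average")
    removed = list(ds.sample_ids[flagged])
    if removed:
        logger.info("remove_outlier_samples: removed %s", removed)
    kept = ds.sample_ids[~flagged]
    return ds.subset_samples(kept), removed, tree


# --------------------------------------------------------------------------- #
# PCA QC


def pca_scores(ds: ExpressionDataset, k: int) -> Tuple[pd.DataFrame, np.ndarray]:
    """Scores of the samples on the top-k principal components of the
    gene-centred matrix, plus the variance-explained fractions."""
    if k <= 0:
        raise PreprocessError("k must be >= 1")
    if k > min(ds.n_genes, ds.n_samples):
        raise PreprocessError("k exceeds matrix rank bound")
    x = ds.matrix()
    centred = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    var_frac = s**2 / (s**2).sum()
    scores = pd.DataFrame(
        (vt[:k].T * s[:k]),
        index=ds.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return scores, var_frac[:k]


# --------------------------------------------------------------------------- #
# driver


def preprocess_pipeline(
    ds: ExpressionDataset,
    probe_matrix: Optional[pd.DataFrame] = None,
    probe_to_gene: Optional[Mapping[str, str]] = None,
    percentile: float = 5.0,
    already_log: bool = True,
    covariates: Sequence[str] = ("age", "sex"),
    outlier_z_cut: float = -2.5,
) -> Tuple[ExpressionDataset, Dict[str, object]]:
    """Run the full preprocessing chain in its fixed order and return the
    cleaned dataset plus a log dictionary of per-stage bookkeeping.

    Refuses datasets whose batches span conditions: batch correction is run
    without protecting the condition labels, which is only safe when each
    batch belongs to a single condition.
    """
    info: Dict[str, object] = {}
    if probe_matrix is not None:
        if probe_to_gene is None:
            raise PreprocessError("probe matrix given without a probe map")
        ds = summarize_probes(probe_matrix, probe_to_gene, ds.metadata if ds else None)
    span = ds.metadata.groupby("batch", observed=True)["condition"].nunique()
    if (span > 1).any():
        raise PreprocessError(
            f"batches spanning multiple conditions: {list(span[span > 1].index)}"
        )
    info["n_genes_in"] = ds.n_genes
    ds = filter_low_abundance(ds, percentile)
    info["n_genes_after_filter"] = ds.n_genes
    ds = normalize(ds, already_log=already_log)
    ds, batch_model = correct_batch(ds)
    info["batch_identity"] = batch_model.identity
    ds = adjust_covariates(ds, covariates)
    ds, removed, tree = remove_outlier_samples(ds, outlier_z_cut)
    info["outliers_removed"] = removed
    info["sample_tree"] = tree
    info["n_samples_out"] = ds.n_samples
    return ds, info
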