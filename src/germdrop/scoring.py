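"""Signature scoring and pseudobulk-vs-bulk correlation audits.

Module (identity) scores compare each cell's mean expression of a gene
signature with that of expression-bin-matched control genes, cancelling
depth and abundance effects.  The correlation audit sums single-cell counts
into per-time pseudobulk profiles and measures the Pearson correlation of
logCPM against matching whole-tissue bulk samples, with and without the
dissociation-responsive gene set removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bulk_de import log_cpm
from .cell_pipeline import ClusterAssignment, NormMatrix
from .io_formats import BulkCounts, CountMatrix


def module_score(
    norm: NormMatrix,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell signature score against expression-bin-matched controls.

    Genes are ranked by average normalized expression across cells and cut
    into ``n_bins`` equal-size bins.  For each signature gene, ``n_ctrl``
    control genes are drawn from its bin (with replacement when the bin is
    smaller than ``n_ctrl``); the score is the mean expression of the
    signature genes minus the mean expression over the pooled control
    draws.
    """
    gene_idx = {g: i for i, g in enumerate(norm.genes)}
    members = [gene_idx[g] for g in gene_set if g in gene_idx]
    if not gene_set or not members:
        raise ValueError("gene_set is empty or absent from the matrix")

    avg = norm.values.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    n_genes = len(order)
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)

    rng = np.random.default_rng(seed)
    ctrl_idx = []
    for gi in members:
        pool = np.flatnonzero(bins == bins[gi])
        replace = len(pool) < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl_idx = np.concatenate(ctrl_idx)

    sig_mean = norm.values[:, members].mean(axis=1)
    ctrl_mean = norm.values[:, ctrl_idx].mean(axis=1)
    return sig_mean - ctrl_mean


def score_signatures(
    norm: NormMatrix,
    signatures: dict[str, list[str]],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Module scores for several signatures; cells x signatures."""
    cols = {
        name: module_score(norm, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        for name, genes in signatures.items()
    }
    return pd.DataFrame(cols, index=pd.Index(norm.barcodes, name="barcode"))


def score_clusters(scores: pd.DataFrame, clusters: ClusterAssignment) -> pd.DataFrame:
    """Mean and SD of each signature score per cluster plus the argmax.

    ``scores`` rows must align with the clustered cells (same barcodes).
    """
    if clusters.barcodes and list(scores.index) != list(clusters.barcodes):
        raise ValueError("score rows do not match the clustered cell universe")
    if len(scores) != len(clusters.labels):
        raise ValueError("score rows do not match the number of clustered cells")
    rows = []
    for c in np.unique(clusters.labels):
        sub = scores.iloc[np.flatnonzero(clusters.labels == c)]
        means = sub.mean(axis=0)
        rows.append(
            {
                "cluster": int(c),
                **{f"mean_{s}": float(means[s]) for s in scores.columns},
                **{f"sd_{s}": float(sub[s].std(ddof=0)) for s in scores.columns},
                "top_signature": str(means.idxmax()),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def pseudobulk(matrix: CountMatrix, groups: dict[str, object]) -> pd.DataFrame:
    """Exact per-gene count sums per group (genes x groups).

    Every barcode must appear in ``groups``; sums are integer-exact so the
    grand total per gene is conserved.
    """
    missing = [b for b in matrix.barcodes if b not in groups]
    if missing:
        raise ValueError(f"ungrouped barcodes: {missing[:5]}")
    labels = [groups[b] for b in matrix.barcodes]
    uniq = sorted(set(labels), key=str)
    out = {}
    arr = np.array(labels, dtype=object)
    for g in uniq:
        mask = np.array([l == g for l in labels])
        out[g] = np.asarray(matrix.values[mask].sum(axis=0)).ravel().astype(np.int64)
    return pd.DataFrame(out, index=pd.Index(matrix.genes, name="gene"))


def correlation_audit(
    pseudo: pd.DataFrame,
    bulk: BulkCounts,
    exclude_set: list[str],
    prior: float = 0.5,
) -> pd.DataFrame:
    """Pearson correlation of pseudobulk vs whole-tissue bulk logCPM.

    Bulk samples are averaged (on logCPM) per time point and correlated with
    the matching pseudobulk group over the shared gene universe, with and
    without removing ``exclude_set``.  Returns per-time r_all, r_excluded
    and the delta.
    """
    shared = [g for g in pseudo.index if g in set(bulk.genes)]
    if len(shared) < 10:
        raise ValueError("fewer than 10 shared genes between pseudobulk and bulk")
    bulk_pos = {g: i for i, g in enumerate(bulk.genes)}
    bulk_rows = [bulk_pos[g] for g in shared]

    pb_cpm = log_cpm(pseudo.loc[shared].to_numpy(), None, prior=prior)
    bulk_cpm_all = log_cpm(bulk, None, prior=prior)[bulk_rows, :]

    exclude = set(exclude_set)
    keep_mask = np.array([g not in exclude for g in shared])

    rows = []
    for group in pseudo.columns:
        t = int(group)
        cols = [i for i, s in enumerate(bulk.samples) if s.time_point_h == t and not s.protoplast]
        if not cols:
            raise ValueError(f"no whole-tissue bulk samples at time {t}")
        bulk_prof = bulk_cpm_all[:, cols].mean(axis=1)
        pb_prof = pb_cpm[:, list(pseudo.columns).index(group)]
        r_all = float(np.corrcoef(pb_prof, bulk_prof)[0, 1])
        r_exc = float(np.corrcoef(pb_prof[keep_mask], bulk_prof[keep_mask])[0, 1])
        rows.append(
            {
                "time_point_h": t,
                "r_all": r_all,
                "r_excluded": r_exc,
                "delta": r_exc - r_all,
            }
        )
    return pd.DataFrame(rows).set_index("time_point_h")
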