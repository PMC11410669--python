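"""Two-genotype droplet demultiplexing from allele-informative UMI counts.

In a mixed two-ecotype droplet experiment, a real single cell carries SNPs
from one genotype only, while doublets and ambient background carry a
mixture.  Each barcode's genotype-informative UMIs are therefore counted per
allele, embedded as (log10(n_A+1), log10(n_B+1)), and classified by
two-stage density clustering: a coarse DBSCAN pass (``eps_background``)
separates the low-count background cloud, and a finer pass (``eps_margin``)
on the remainder resolves the two singlet arms and the balanced doublet
cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import AlleleObservationTable
from .synthetic_data import DropletTruth

NOISE = -1

CALL_GENO_A = "GENO_A"
CALL_GENO_B = "GENO_B"
CALL_DOUBLET = "DOUBLET"
CALL_BACKGROUND = "BACKGROUND"
CALL_UNASSIGNED = "UNASSIGNED"

#: minimum per-allele depth for the per-barcode doublet override
DOUBLET_OVERRIDE_MIN_DEPTH = 10


@dataclass
class AlleleCounts:
    """Per-barcode counts of UMIs informative for genotype A vs B."""

    barcodes: list[str]
    n_A: np.ndarray
    n_B: np.ndarray

    def __post_init__(self):
        self.n_A = np.asarray(self.n_A, dtype=np.int64)
        self.n_B = np.asarray(self.n_B, dtype=np.int64)
        if not (len(self.barcodes) == len(self.n_A) == len(self.n_B)):
            raise ValueError("barcodes and counts must align")
        if (self.n_A < 0).any() or (self.n_B < 0).any():
            raise ValueError("negative UMI counts")

    def __len__(self) -> int:
        return len(self.barcodes)


@dataclass
class DemuxParams:
    """Clustering parameters for genotype calling.

    ``eps_background``/``eps_margin`` are DBSCAN radii on the log10(count+1)
    embedding; defaults mirror a mid-germination sample (0.4 / 0.3).
    ``doublet_balance_delta`` is the allele-balance margin: a cluster with
    mean A-fraction in (delta, 1-delta) is called DOUBLET.
    """

    eps_background: float = 0.4
    eps_margin: float = 0.3
    min_pts: int = 10
    doublet_balance_delta: float = 0.2

    def __post_init__(self):
        if self.eps_background <= 0 or self.eps_margin <= 0:
            raise ValueError("eps values must be positive")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if not (0 < self.doublet_balance_delta < 0.5):
            raise ValueError("doublet_balance_delta must lie in (0, 0.5)")


@dataclass
class GenotypeCalls:
    table: pd.DataFrame  # barcode, call, n_A, n_B, stage1_label, stage2_label
    warnings: list[str] = field(default_factory=list)


def collapse_allele_umis(observations: AlleleObservationTable) -> AlleleCounts:
    """Collapse read-level allele observations to per-barcode UMI counts.

    Observations are grouped by (barcode, umi); each UMI votes for its
    majority allele, and exact ties are discarded (a UMI is one molecule and
    must not be double-counted).
    """
    if len(observations) == 0:
        return AlleleCounts([], np.array([], int), np.array([], int))
    tab = (
        observations.assign(is_a=(observations["allele"] == "A").astype(int))
        .groupby(["barcode", "umi"], sort=True)["is_a"]
        .agg(["sum", "count"])
    )
    a_votes = tab["sum"]
    b_votes = tab["count"] - tab["sum"]
    umi_allele = np.where(a_votes > b_votes, "A", np.where(b_votes > a_votes, "B", "tie"))
    per_bc = (
        pd.DataFrame({"barcode": tab.index.get_level_values(0), "allele": umi_allele})
        .groupby("barcode", sort=True)["allele"]
        .value_counts()
        .unstack(fill_value=0)
    )
    barcodes = list(per_bc.index)
    n_a = per_bc["A"].to_numpy() if "A" in per_bc else np.zeros(len(barcodes), int)
    n_b = per_bc["B"].to_numpy() if "B" in per_bc else np.zeros(len(barcodes), int)
    return AlleleCounts(barcodes, n_a, n_b)


def embed_allele_counts(counts: AlleleCounts) -> np.ndarray:
    """Embed each barcode at (log10(n_A + 1), log10(n_B + 1))."""
    return np.column_stack(
        [np.log10(counts.n_A + 1.0), np.log10(counts.n_B + 1.0)]
    )


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Deterministic DBSCAN with Euclidean metric.

    A point is core iff its closed eps-ball contains >= ``min_pts`` points
    (itself included).  Clusters are maximal density-connected sets grown
    from core points in input order; border points join the first core
    cluster that reaches them.  Unreached points are labeled :data:`NOISE`.
    """
    points = np.asarray(points, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    n = len(points)
    if n == 0:
        return np.array([], dtype=int)
    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, r=eps)  # closed ball
    is_core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, NOISE, dtype=int)
    cluster = 0
    for i in range(n):
        if not is_core[i] or labels[i] != NOISE:
            continue
        labels[i] = cluster
        frontier = [i]
        while frontier:
            p = frontier.pop(0)
            for q in sorted(neighbors[p]):
                if labels[q] == NOISE:
                    labels[q] = cluster
                    if is_core[q]:
                        frontier.append(q)
        cluster += 1
    return labels


def call_genotypes(counts: AlleleCounts, params: DemuxParams) -> GenotypeCalls:
    """Call each barcode as genotype A/B, doublet, background or unassigned.

    Stage 1 clusters the embedding at ``eps_background``; the cluster whose
    centroid has the smallest total UMI count (in original count units) is
    the ambient background.  Stage 2 re-clusters all non-background barcodes
    at ``eps_margin``; each cluster is classified by its mean A-fraction
    ``f``: f >= 1-delta -> GENO_A, f <= delta -> GENO_B, otherwise DOUBLET.
    Stage-2 noise is UNASSIGNED.  Barcodes with zero informative UMIs are
    always BACKGROUND.  A high-depth barcode (min(n_A, n_B) >= 10) with
    balanced alleles inside a genotype cluster is rescued as DOUBLET.
    """
    if len(counts) < params.min_pts:
        raise ValueError(f"need at least min_pts={params.min_pts} barcodes")
    msgs: list[str] = []
    n_a, n_b = counts.n_A.astype(float), counts.n_B.astype(float)
    total = n_a + n_b
    points = embed_allele_counts(counts)

    stage1 = dbscan(points, params.eps_background, params.min_pts)
    stage2 = np.full(len(counts), NOISE, dtype=int)
    calls = np.full(len(counts), CALL_UNASSIGNED, dtype=object)

    s1_ids = [c for c in np.unique(stage1) if c != NOISE]
    background_cluster = None
    if s1_ids:
        centroid_totals = {c: total[stage1 == c].mean() for c in s1_ids}
        background_cluster = min(centroid_totals, key=lambda c: (centroid_totals[c], c))
        if len(s1_ids) == 1 and not (stage1 == NOISE).any():
            msgs.append(
                "all barcodes fell in a single stage-1 cluster; eps_background "
                "is likely too large — calling everything BACKGROUND"
            )
            warnings.warn(msgs[-1])
            calls[:] = CALL_BACKGROUND
            calls[total == 0] = CALL_BACKGROUND
            return GenotypeCalls(_calls_frame(counts, calls, stage1, stage2), msgs)
        calls[stage1 == background_cluster] = CALL_BACKGROUND

    nonbg = np.flatnonzero(
        (stage1 != background_cluster) if background_cluster is not None else np.ones(len(counts), bool)
    )
    if len(nonbg):
        sub_labels = dbscan(points[nonbg], params.eps_margin, params.min_pts)
        stage2[nonbg] = sub_labels
        for c in np.unique(sub_labels):
            if c == NOISE:
                continue
            members = nonbg[sub_labels == c]
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = n_a[members] / np.maximum(total[members], 1.0)
            f = float(np.mean(frac))
            d = params.doublet_balance_delta
            if f >= 1.0 - d:
                cluster_call = CALL_GENO_A
            elif f <= d:
                cluster_call = CALL_GENO_B
            else:
                cluster_call = CALL_DOUBLET
            calls[members] = cluster_call
            if cluster_call in (CALL_GENO_A, CALL_GENO_B):
                # rescue deeply sequenced, allele-balanced doublets hiding
                # inside a singlet arm
                depth = np.minimum(n_a[members], n_b[members])
                bal = n_a[members] / np.maximum(total[members], 1.0)
                override = (depth >= DOUBLET_OVERRIDE_MIN_DEPTH) & (bal > d) & (bal < 1.0 - d)
                calls[members[override]] = CALL_DOUBLET

    calls[total == 0] = CALL_BACKGROUND
    return GenotypeCalls(_calls_frame(counts, calls, stage1, stage2), msgs)


def _calls_frame(counts: AlleleCounts, calls, stage1, stage2) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "call": calls,
            "n_A": counts.n_A,
            "n_B": counts.n_B,
            "stage1_label": stage1,
            "stage2_label": stage2,
        }
    )


_TRUTH_TO_CALL = {"A": CALL_GENO_A, "B": CALL_GENO_B, "doublet_AB": CALL_DOUBLET, "": CALL_BACKGROUND}


def demux_metrics(calls: GenotypeCalls, truth: DropletTruth) -> dict:
    """Score genotype calls against simulation ground truth.

    Barcodes absent from the call table (no informative UMIs observed) are
    treated as BACKGROUND, matching the zero-count rule.  Returns a
    JSON-serializable report with the confusion matrix, per-class
    precision/recall, singlet balanced accuracy, doublet recall, background
    recall and the unassigned fraction.
    """
    tt = truth.table.set_index("barcode")
    call_map = dict(zip(calls.table["barcode"], calls.table["call"]))
    missing = set(call_map) - set(tt.index)
    if missing:
        raise ValueError(f"calls contain barcodes absent from truth: {sorted(missing)[:5]}")

    expected, observed = [], []
    for bc, row in tt.iterrows():
        expected.append(_TRUTH_TO_CALL[row["genotype"]])
        observed.append(call_map.get(bc, CALL_BACKGROUND))
    expected = np.array(expected, dtype=object)
    observed = np.array(observed, dtype=object)

    classes = [CALL_GENO_A, CALL_GENO_B, CALL_DOUBLET, CALL_BACKGROUND, CALL_UNASSIGNED]
    confusion = {
        e: {o: int(((expected == e) & (observed == o)).sum()) for o in classes}
        for e in classes[:4]
    }
    precision, recall = {}, {}
    for c in classes:
        tp = float(((expected == c) & (observed == c)).sum())
        n_true = float((expected == c).sum())
        n_called = float((observed == c).sum())
        recall[c] = tp / n_true if n_true else float("nan")
        precision[c] = tp / n_called if n_called else float("nan")

    singlet_recalls = [recall[c] for c in (CALL_GENO_A, CALL_GENO_B) if not np.isnan(recall[c])]
    report = {
        "confusion": confusion,
        "precision": precision,
        "recall": recall,
        "singlet_balanced_accuracy": float(np.mean(singlet_recalls)) if singlet_recalls else float("nan"),
        "doublet_recall": recall[CALL_DOUBLET],
        "background_recall": recall[CALL_BACKGROUND],
        "fraction_unassigned": float((observed == CALL_UNASSIGNED).mean()),
        "n_barcodes": int(len(expected)),
    }
    return report
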