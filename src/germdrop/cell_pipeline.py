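"""Single-cell QC, normalization, clustering and marker detection.

The demultiplexed cells are filtered with MAD-based QC (3 MADs below the
median of log10 counts or log10 genes detected), normalized with
library-size factors, reduced to highly variable genes (positive biological
variance above a mean-variance trend), embedded by PCA, connected in a
shared-nearest-neighbour graph and clustered by Louvain modularity
maximization.  Markers per cluster come from a tie-corrected Wilcoxon
rank-sum test at p < 0.01.

Every step is deterministic given its input and seed: kNN distance ties
break by cell index and the Louvain sweep order is a fixed seeded shuffle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm
import statsmodels.api as sm

from .io_formats import CountMatrix

MAD_SCALE = 1.4826  # consistency constant for normally distributed data


@dataclass
class QCReport:
    removed_barcodes: list[str]
    threshold_log10_counts: float
    threshold_log10_genes: float

    def to_dict(self) -> dict:
        return {
            "removed_barcodes": self.removed_barcodes,
            "threshold_log10_counts": self.threshold_log10_counts,
            "threshold_log10_genes": self.threshold_log10_genes,
            "n_removed": len(self.removed_barcodes),
        }


@dataclass
class NormMatrix:
    """Log-normalized expression (cells x genes) with its size factors."""

    values: np.ndarray
    barcodes: list[str]
    genes: list[str]
    size_factors: np.ndarray

    def __post_init__(self):
        if abs(float(np.mean(self.size_factors)) - 1.0) > 1e-9:
            raise ValueError("size factors must average to 1")
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")


@dataclass
class GeneVarModel:
    table: pd.DataFrame  # gene, mean, total_var, trend_var, bio_var, hvg

    @property
    def hvgs(self) -> list[str]:
        return list(self.table.index[self.table["hvg"]])


@dataclass
class SNNGraph:
    n_nodes: int
    edges_u: np.ndarray
    edges_v: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if len(self.weights) and (self.weights.min() <= 0 or self.weights.max() > 1):
            raise ValueError("SNN weights must lie in (0, 1]")


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per cell, 0..K-1
    modularity: float
    barcodes: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _to_dense(matrix: CountMatrix) -> np.ndarray:
    return np.asarray(matrix.values.todense(), dtype=float)


def qc_filter_cells(matrix: CountMatrix, nmads: float = 3.0) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells by the MAD rule.

    A cell is removed when its log10 total counts, or log10 genes detected,
    falls strictly more than ``nmads`` median absolute deviations (scaled by
    1.4826) below the respective median.
    """
    if matrix.shape[0] < 10:
        raise ValueError("need at least 10 cells for MAD-based QC")
    totals = np.asarray(matrix.values.sum(axis=1)).ravel()
    genes_det = np.asarray((matrix.values > 0).sum(axis=1)).ravel()
    log_tot = np.log10(totals + 1.0)
    log_gen = np.log10(genes_det + 1.0)

    def threshold(x: np.ndarray) -> float:
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med))) * MAD_SCALE
        return med - nmads * mad

    thr_tot = threshold(log_tot)
    thr_gen = threshold(log_gen)
    keep = (log_tot >= thr_tot) & (log_gen >= thr_gen)
    if not keep.any():
        raise ValueError("QC removed every cell; input is degenerate")
    removed = [b for b, k in zip(matrix.barcodes, keep) if not k]
    kept = [b for b, k in zip(matrix.barcodes, keep) if k]
    return matrix.subset_barcodes(kept), QCReport(removed, thr_tot, thr_gen)


def filter_genes(matrix: CountMatrix) -> CountMatrix:
    """Drop genes with zero total count across all cells."""
    colsum = np.asarray(matrix.values.sum(axis=0)).ravel()
    return matrix.subset_genes(colsum > 0)


def size_factors(matrix: CountMatrix) -> np.ndarray:
    """Library-size factors rescaled to mean 1."""
    totals = np.asarray(matrix.values.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError("all-zero cell(s) present; run qc_filter_cells first")
    return totals / totals.mean()


def normalize_log(matrix: CountMatrix, factors: np.ndarray) -> NormMatrix:
    """log2(count / size_factor + 1) per entry."""
    factors = np.asarray(factors, float)
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    dense = _to_dense(matrix)
    vals = np.log2(dense / factors[:, None] + 1.0)
    return NormMatrix(vals, list(matrix.barcodes), list(matrix.genes), factors / factors.mean())


def model_gene_var(norm: NormMatrix, span: float = 0.3) -> GeneVarModel:
    """Mean-variance trend decomposition for HVG selection.

    The variance trend is a local linear (tricube-weighted, LOWESS) fit of
    per-gene variance on per-gene mean, evaluated at each gene's mean and
    floored at zero.  Biological variance = total - trend; a gene is highly
    variable iff its biological variance is positive.
    """
    if norm.values.shape[1] < 20:
        raise ValueError("need at least 20 genes to fit a variance trend")
    mean = norm.values.mean(axis=0)
    var = norm.values.var(axis=0, ddof=1)
    if np.allclose(var, 0):
        warnings.warn("expression matrix is constant; no HVGs")
        trend = np.zeros_like(var)
    else:
        fitted = sm.nonparametric.lowess(
            var, mean, frac=span, it=0, return_sorted=False
        )
        trend = np.maximum(np.nan_to_num(fitted), 0.0)
    bio = var - trend
    table = pd.DataFrame(
        {
            "mean": mean,
            "total_var": var,
            "trend_var": trend,
            "bio_var": bio,
            "hvg": bio > 0,
        },
        index=pd.Index(norm.genes, name="gene"),
    )
    return GeneVarModel(table)


def pca_reduce(norm: NormMatrix, hvgs: list[str], d: int = 30) -> np.ndarray:
    """Project cells onto the top-d principal components of the HVG submatrix.

    Deterministic sign convention: in each loading vector the
    largest-magnitude entry is made positive.
    """
    gene_idx = {g: i for i, g in enumerate(norm.genes)}
    cols = [gene_idx[g] for g in hvgs if g in gene_idx]
    if not cols:
        raise ValueError("no HVGs present in the matrix")
    X = norm.values[:, cols]
    if d >= min(X.shape):
        raise ValueError(f"d={d} must be smaller than min(cells, HVGs)={min(X.shape)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(d):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    return U[:, :d] * s[:d]


def _knn_sets(embedding: np.ndarray, k: int) -> list[np.ndarray]:
    """k nearest neighbours per point (self excluded, ties by index)."""
    n = len(embedding)
    sets = []
    block = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, block):
        D = cdist(embedding[start : start + block], embedding)
        for r in range(D.shape[0]):
            i = start + r
            dist = D[r].copy()
            dist[i] = np.inf  # exclude self
            order = np.lexsort((np.arange(n), dist))
            sets.append(order[:k])
    return sets


def snn_graph(embedding: np.ndarray, k: int = 10) -> SNNGraph:
    """Shared-nearest-neighbour graph with Jaccard edge weights.

    Two cells are joined iff their kNN sets share a member or each contains
    the other; the weight is the Jaccard index of the two kNN sets, each
    augmented with its own cell.
    """
    embedding = np.asarray(embedding, float)
    n = len(embedding)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    knn = _knn_sets(embedding, k)
    aug = [set(nb) | {i} for i, nb in enumerate(knn)]
    raw = [set(nb) for nb in knn]

    # candidate pairs: share a raw neighbour, or one lists the other
    owners: dict[int, list[int]] = {}
    for i, nb in enumerate(knn):
        for j in nb:
            owners.setdefault(int(j), []).append(i)
    candidates = set()
    for members in owners.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                candidates.add((members[a], members[b]))
    for i, nb in enumerate(raw):
        for j in nb:
            candidates.add((min(i, int(j)), max(i, int(j))))

    us, vs, ws = [], [], []
    for u, v in sorted(candidates):
        if u == v:
            continue
        if raw[u] & raw[v] or (v in raw[u] and u in raw[v]):
            inter = len(aug[u] & aug[v])
            if inter == 0:
                continue
            w = inter / len(aug[u] | aug[v])
            us.append(u)
            vs.append(v)
            ws.append(w)
    return SNNGraph(n, np.array(us, int), np.array(vs, int), np.array(ws, float))


def _modularity(adj: list[dict[int, float]], labels: np.ndarray, resolution: float, two_m: float) -> float:
    """Weighted modularity: sum_c [2 S_c / 2m - gamma (D_c / 2m)^2]."""
    deg = np.array([sum(nb.values()) for nb in adj])
    intra = {}
    comm_deg = {}
    for i, nb in enumerate(adj):
        comm_deg[labels[i]] = comm_deg.get(labels[i], 0.0) + deg[i]
        for j, w in nb.items():
            if labels[i] == labels[j]:
                intra[labels[i]] = intra.get(labels[i], 0.0) + w  # both directions
    q = 0.0
    for c, d in comm_deg.items():
        q += intra.get(c, 0.0) / two_m - resolution * (d / two_m) ** 2
    return q


def louvain(graph: SNNGraph, resolution: float = 1.0, seed: int = 0) -> ClusterAssignment:
    """Two-phase Louvain modularity maximization.

    The node sweep order is shuffled once per level with the given seed and
    then fixed; local moves repeat until no gain exceeds 1e-12, then the
    graph is aggregated, until the partition is stable.
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)

    # adjacency at the current aggregation level
    adj: list[dict[int, float]] = [dict() for _ in range(n)]
    for u, v, w in zip(graph.edges_u, graph.edges_v, graph.weights):
        u, v = int(u), int(v)
        adj[u][v] = adj[u].get(v, 0.0) + float(w)
        adj[v][u] = adj[v].get(u, 0.0) + float(w)
    self_w = np.zeros(n)

    membership = np.arange(n)  # original node -> current community
    while True:
        m_nodes = len(adj)
        two_m = float(sum(sum(nb.values()) for nb in adj) + 2.0 * self_w.sum())
        if two_m == 0:
            break
        deg = np.array([sum(nb.values()) for nb in adj]) + 2.0 * self_w
        comm = np.arange(m_nodes)
        comm_deg = deg.copy()
        order = rng.permutation(m_nodes)
        improved = False
        moved = True
        while moved:
            moved = False
            for i in order:
                ci = comm[i]
                links = {}
                for j, w in adj[i].items():
                    links[comm[j]] = links.get(comm[j], 0.0) + w
                comm_deg[ci] -= deg[i]
                best_c, best_gain = ci, 0.0
                base = links.get(ci, 0.0) - resolution * comm_deg[ci] * deg[i] / two_m
                for c, w_ic in links.items():
                    if c == ci:
                        continue
                    gain = (w_ic - resolution * comm_deg[c] * deg[i] / two_m) - base
                    if gain > best_gain + 1e-12:
                        best_gain, best_c = gain, c
                comm_deg[best_c] += deg[i]
                if best_c != ci:
                    comm[i] = best_c
                    moved = True
                    improved = True
        # compact community ids
        uniq, comm = np.unique(comm, return_inverse=True)
        membership = comm[membership]
        if not improved or len(uniq) == m_nodes:
            break
        # aggregate
        k = len(uniq)
        new_adj: list[dict[int, float]] = [dict() for _ in range(k)]
        new_self = np.zeros(k)
        for i, nb in enumerate(adj):
            ci = comm[i]
            new_self[ci] += self_w[i]
            for j, w in nb.items():
                cj = comm[j]
                if ci == cj:
                    if i < j:
                        new_self[ci] += w
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
        adj, self_w = new_adj, new_self

    # relabel communities by first occurrence for determinism
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, c in enumerate(membership):
        if c not in seen:
            seen[c] = len(seen)
        labels[i] = seen[c]

    full_adj: list[dict[int, float]] = [dict() for _ in range(n)]
    for u, v, w in zip(graph.edges_u, graph.edges_v, graph.weights):
        u, v = int(u), int(v)
        full_adj[u][v] = full_adj[u].get(v, 0.0) + float(w)
        full_adj[v][u] = full_adj[v].get(u, 0.0) + float(w)
    two_m = float(sum(sum(nb.values()) for nb in full_adj))
    mod = _modularity(full_adj, labels, resolution, two_m) if two_m else 0.0
    return ClusterAssignment(labels=labels, modularity=mod)


def rank_sum_markers(
    in_expr: np.ndarray, out_expr: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Wilcoxon rank-sum with tie correction.

    Returns (z, p) per gene using the normal approximation; genes with zero
    rank variance (all values tied) get p = 1.
    """
    n1, n2 = in_expr.shape[0], out_expr.shape[0]
    N = n1 + n2
    both = np.concatenate([in_expr, out_expr], axis=0)
    ranks = pd.DataFrame(both).rank(axis=0).to_numpy()
    R1 = ranks[:n1].sum(axis=0)
    mu = n1 * (N + 1) / 2.0

    tie_term = np.zeros(both.shape[1])
    for g in range(both.shape[1]):
        _, counts = np.unique(both[:, g], return_counts=True)
        tie_term[g] = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    z = np.zeros(both.shape[1])
    pos = sigma2 > 0
    z[pos] = (R1[pos] - mu) / np.sqrt(sigma2[pos])
    p = np.where(pos, 2.0 * norm.sf(np.abs(z)), 1.0)
    return z, np.minimum(p, 1.0)


def find_markers(
    norm: NormMatrix, clusters: ClusterAssignment, p_cut: float = 0.01
) -> pd.DataFrame:
    """Upregulated marker genes per cluster (cluster vs rest).

    Reports genes with two-sided rank-sum p < ``p_cut`` and positive log2FC
    of mean normalized expression; clusters with fewer than 3 cells are
    skipped with a warning.  log2FC uses a pseudocount of 1e-9.
    """
    labels = clusters.labels
    if len(labels) != norm.values.shape[0]:
        raise ValueError("cluster labels must align with cells")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters to find markers")
    eps = 1e-9
    rows = []
    for c in np.unique(labels):
        mask = labels == c
        if mask.sum() < 3:
            warnings.warn(f"cluster {c} has fewer than 3 cells; skipped")
            continue
        in_e, out_e = norm.values[mask], norm.values[~mask]
        _, p = rank_sum_markers(in_e, out_e)
        mean_in, mean_out = in_e.mean(axis=0), out_e.mean(axis=0)
        l2fc = np.log2((mean_in + eps) / (mean_out + eps))
        frac_in = (in_e > 0).mean(axis=0)
        frac_out = (out_e > 0).mean(axis=0)
        hit = (p < p_cut) & (l2fc > 0)
        for gi in np.flatnonzero(hit):
            rows.append(
                {
                    "cluster": int(c),
                    "gene": norm.genes[gi],
                    "log2FC": float(l2fc[gi]),
                    "p": float(p[gi]),
                    "frac_in": float(frac_in[gi]),
                    "frac_out": float(frac_out[gi]),
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "gene", "log2FC", "p", "frac_in", "frac_out"])


@dataclass
class PipelineResult:
    matrix: CountMatrix
    norm: NormMatrix
    qc_report: QCReport
    gene_var: GeneVarModel
    embedding: np.ndarray
    clusters: ClusterAssignment
    markers: pd.DataFrame


def run_cell_pipeline(
    matrix: CountMatrix,
    nmads: float = 3.0,
    d: int = 30,
    k: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
    min_total_umis: int = 100,
) -> PipelineResult:
    """QC -> normalize -> HVG -> PCA -> SNN -> Louvain -> markers."""
    totals = np.asarray(matrix.values.sum(axis=1)).ravel()
    keep = [b for b, t in zip(matrix.barcodes, totals) if t >= min_total_umis]
    matrix = matrix.subset_barcodes(keep)
    filtered, report = qc_filter_cells(matrix, nmads=nmads)
    filtered = filter_genes(filtered)
    factors = size_factors(filtered)
    norm = normalize_log(filtered, factors)
    gv = model_gene_var(norm)
    hvgs = gv.hvgs if len(gv.hvgs) >= d + 1 else list(norm.genes)
    d_eff = min(d, min(len(hvgs), norm.values.shape[0]) - 1)
    emb = pca_reduce(norm, hvgs, d=d_eff)
    graph = snn_graph(emb, k=k)
    assignment = louvain(graph, resolution=resolution, seed=seed)
    clusters = ClusterAssignment(
        labels=assignment.labels,
        modularity=assignment.modularity,
        barcodes=list(filtered.barcodes),
    )
    markers = find_markers(norm, clusters)
    return PipelineResult(filtered, norm, report, gv, emb, clusters, markers)
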