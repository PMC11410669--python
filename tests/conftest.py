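import numpy as np
import pytest

from germdrop import synthetic_data as sd


@pytest.fixture(scope="session")
def demux_scenario():
    """Full two-genotype droplet scenario with doublets and empties (seed 7)."""
    cfg = sd.SimConfig(seed=7)
    rng = np.random.default_rng(7)
    profiles = sd.simulate_embryo_profiles(cfg, rng)
    matrix, obs, truth = sd.simulate_droplets(cfg, profiles, rng)
    return cfg, profiles, matrix, obs, truth


@pytest.fixture(scope="session")
def clean_cells_scenario():
    """3-state, 3000-cell scenario without doublets or empties (seed 3)."""
    cfg = sd.SimConfig(seed=3, n_empty=0, doublet_rate=0.0)
    rng = np.random.default_rng(3)
    profiles = sd.simulate_embryo_profiles(cfg, rng)
    matrix, obs, truth = sd.simulate_droplets(cfg, profiles, rng)
    return cfg, profiles, matrix, truth


@pytest.fixture(scope="session")
def bulk_scenario():
    """Paired whole/protoplast bulk counts with spiked genes (seed 11)."""
    cfg = sd.SimConfig(seed=11)
    rng = np.random.default_rng(11)
    return cfg, *sd.simulate_bulk_pair(cfg, rng)


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """O(n^2) density-reachability oracle matching the stated DBSCAN rules.

    Core iff the closed eps-ball holds >= min_pts points (self included);
    clusters grown from cores in input order; border points take the first
    core cluster that reaches them.
    """
    points = np.asarray(points, float)
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    nbrs = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in nbrs])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            p = queue.pop(0)
            for q in sorted(nbrs[p]):
                if labels[q] == -1:
                    labels[q] = cid
                    if core[q]:
                        queue.append(int(q))
        cid += 1
    return labels


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel cluster ids by first occurrence so partitions compare exactly."""
    out = np.full(len(labels), -1)
    seen = {}
    for i, l in enumerate(labels):
        if l == -1:
            continue
        if l not in seen:
            seen[l] = len(seen)
        out[i] = seen[l]
    return out


def adjusted_rand_index(a, b) -> float:
    import pandas as pd
    from scipy.special import comb

    ct = pd.crosstab(np.asarray(a), np.asarray(b)).to_numpy()
    s = comb(ct, 2).sum()
    r = comb(ct.sum(axis=1), 2).sum()
    c = comb(ct.sum(axis=0), 2).sum()
    n = comb(ct.sum(), 2)
    expected = r * c / n
    return float((s - expected) / ((r + c) / 2 - expected))
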