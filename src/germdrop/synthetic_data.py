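"""Synthetic droplet and bulk RNA-seq data with known ground truth.

Emulates the statistical structure of a two-ecotype germination experiment:
droplet mixtures of two genotypes with doublets, ambient background and empty
droplets; negative-binomial cell-state expression whose state proportions
shift across germination time points; and paired whole-embryo / protoplast
bulk counts with spiked dissociation-response genes.

All randomness flows through a single :class:`numpy.random.Generator`; a
fixed seed yields byte-identical outputs.

Negative-binomial parameterization throughout: ``var = mu + dispersion *
mu**2`` (the same convention as the GLM engine in :mod:`germdrop.bulk_de`,
so parameter recovery is well-posed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import BulkCounts, CountMatrix, SampleInfo

MARKERS_PER_STATE = 20
MARKER_FOLD = 16.0
MARKER_OFF_MEAN = 0.01
#: Beta concentration (a+b) for the per-droplet ambient fraction rho.
AMBIENT_BETA_CONCENTRATION = 20.0
#: Empty droplets draw their (small) library at this fraction of the cell mean.
EMPTY_LIBRARY_FRACTION = 0.05
#: Fraction of genes carrying temporal expression changes in the bulk pair.
TIME_EFFECT_FRACTION = 0.30
#: Per-interval |log2 shift| range for interval-walk time-effect genes.
TIME_SHIFT_RANGE = (1.5, 4.0)
#: |log2 offset| range for single-time spike genes (chosen so the gene's
#: own time-vs-rest contrast clears 1.5 and the induced opposite contrasts
#: at other times, -delta/2, stay clear of it on both sides).
SPIKE_RANGE = (2.0, 2.4)
#: Mean bulk library size (deep libraries, so fold-changes are estimable).
BULK_LIBSIZE = 3.0e6
#: Minimum baseline relative expression for a gene to carry a planted
#: differential effect (expected count ~150 at the default depth).
MIN_DE_BASE_REL = 0.1


def _default_state_props() -> dict[int, list[float]]:
    # Three states whose prevalence shifts across germination, echoing the
    # drift from a shared early transcriptional state toward specialized ones.
    return {
        12: [0.70, 0.20, 0.10],
        24: [0.30, 0.50, 0.20],
        48: [0.10, 0.30, 0.60],
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the simulated study design exercised by the test suite:
    3,000 cells over three time points (12/24/48 h), a 50/50 two-genotype
    mix, 5% doublets, 2,000 empty droplets, 2% mean ambient contamination,
    NB dispersion 0.2, and 100 dissociation-responsive genes with
    |log2FC| in [2, 4].
    """

    n_genes: int = 2000
    n_states: int = 3
    state_props_by_time: dict[int, list[float]] = field(default_factory=_default_state_props)
    n_cells: int = 3000
    n_empty: int = 2000
    doublet_rate: float = 0.05
    ambient_fraction_mean: float = 0.02
    libsize_log_mean: float = math.log(2000.0)
    libsize_log_sd: float = 0.3
    nb_dispersion: float = 0.2
    #: dispersion for bulk replicates (BCV 0.1, the convention for isogenic
    #: model-organism lines; droplet data are far more overdispersed)
    bulk_nb_dispersion: float = 0.01
    p_informative: float = 0.05
    allele_error: float = 0.005
    genotype_mix: float = 0.5
    n_protoplast_genes: int = 100
    protoplast_lfc_range: tuple[float, float] = (2.0, 4.0)
    bulk_replicates: int = 3
    time_points_h: list[int] = field(default_factory=lambda: [12, 24, 48])
    #: fraction of time-effect genes whose temporal shifts are sign-inverted
    #: in the protoplast arm (0 = fully concordant dynamics)
    protoplast_discordant_fraction: float = 0.0
    read_duplicates: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("doublet_rate", "ambient_fraction_mean", "p_informative",
                     "allele_error", "genotype_mix", "protoplast_discordant_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.ambient_fraction_mean < 1.0):
            raise ValueError("ambient_fraction_mean must lie in [0, 1)")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_states * MARKERS_PER_STATE > self.n_genes:
            raise ValueError(
                f"{self.n_states} states x {MARKERS_PER_STATE} markers exceed {self.n_genes} genes"
            )
        if set(self.state_props_by_time) != set(self.time_points_h):
            raise ValueError("state_props_by_time keys must equal time_points_h")
        for t, props in self.state_props_by_time.items():
            props = np.asarray(props, dtype=float)
            if props.shape != (self.n_states,):
                raise ValueError(f"time {t}: expected {self.n_states} state proportions")
            if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
                raise ValueError(f"time {t}: proportions must be nonnegative and sum to 1")
        lo, hi = self.protoplast_lfc_range
        if not (0 < lo <= hi):
            raise ValueError("protoplast_lfc_range must satisfy 0 < min <= max")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "state_props_by_time" in raw:
            raw["state_props_by_time"] = {int(k): v for k, v in raw["state_props_by_time"].items()}
        if "protoplast_lfc_range" in raw:
            raw["protoplast_lfc_range"] = tuple(raw["protoplast_lfc_range"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StateProfiles:
    """Per-state mean expression programs with exclusive marker sets."""

    means: np.ndarray  # states x genes, strictly positive
    marker_sets: dict[int, list[int]]  # state -> exclusive marker gene indices

    def ambient_profile(self, props: Sequence[float]) -> np.ndarray:
        return np.asarray(props, float) @ self.means


@dataclass
class DropletTruth:
    """Ground truth per barcode, the acceptance surface for demultiplexing."""

    table: pd.DataFrame  # barcode, is_cell, state, genotype, ambient_fraction, time_point_h

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=0)


@dataclass
class BulkTruth:
    protoplast_gene_set: list[str]
    true_lfc: dict[str, float]
    time_signature_truth: dict[int, list[str]]
    #: planted single-time spike genes per time point (subset of
    #: time_signature_truth by construction)
    spike_truth: dict[int, list[str]]
    time_effect_genes: list[str]
    #: per-interval sign of the whole-embryo shift for time-effect genes
    interval_shifts: pd.DataFrame  # genes x intervals, log2 shifts (whole arm)
    discordant_genes: list[str]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, var = mu + phi mu^2) via the Gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-300) * dispersion)
    return rng.poisson(lam)


def simulate_embryo_profiles(config: SimConfig, rng: np.random.Generator) -> StateProfiles:
    """Draw Gamma-distributed expression programs with exclusive markers.

    Baseline means are Gamma(shape=0.5, scale=2) per gene and state
    (mean 1).  Each state receives a disjoint block of
    :data:`MARKERS_PER_STATE` marker genes whose mean is multiplied by
    :data:`MARKER_FOLD` in the home state and set near zero elsewhere.
    """
    config.validate()
    means = rng.gamma(0.5, 2.0, size=(config.n_states, config.n_genes))
    means = np.maximum(means, 1e-6)
    marker_sets: dict[int, list[int]] = {}
    for s in range(config.n_states):
        idx = list(range(s * MARKERS_PER_STATE, (s + 1) * MARKERS_PER_STATE))
        marker_sets[s] = idx
        means[:, idx] = MARKER_OFF_MEAN
        means[s, idx] = np.maximum(rng.gamma(0.5, 2.0, size=len(idx)), 0.25) * MARKER_FOLD
    return StateProfiles(means=means, marker_sets=marker_sets)


def _umi_tags(n: int) -> list[str]:
    return [f"u{i:06d}" for i in range(n)]


def simulate_droplets(
    config: SimConfig, profiles: StateProfiles, rng: np.random.Generator
) -> tuple[CountMatrix, pd.DataFrame, DropletTruth]:
    """Simulate a two-genotype droplet experiment.

    Returns the barcode x gene count matrix, the read-level allele
    observation table and the per-barcode ground truth.  Cells are split
    evenly across time points; each cell's state is drawn from its time
    point's state proportions.  Doublets merge two independent cells'
    ambient-mixed expectations (library = sum of two draws) and carry
    genotype ``doublet_AB``; empty droplets draw a small library from the
    ambient profile alone.  Each UMI emits an allele observation with
    probability ``p_informative``; observed alleles follow the droplet
    genotype (fair coin per UMI for doublets and empties) and flip with
    probability ``allele_error``.
    """
    config.validate()
    n_cells, n_empty = config.n_cells, config.n_empty
    times = np.array(config.time_points_h)
    cell_times = times[np.arange(n_cells) % len(times)]

    genotypes = np.where(rng.random(n_cells) < config.genotype_mix, "A", "B").astype(object)
    is_doublet = rng.random(n_cells) < config.doublet_rate
    m = config.ambient_fraction_mean
    if m > 0:
        c = AMBIENT_BETA_CONCENTRATION
        rho = rng.beta(m * c, (1.0 - m) * c, size=n_cells)
    else:
        rho = np.zeros(n_cells)

    states = np.empty(n_cells, dtype=int)
    partner_states = np.full(n_cells, -1, dtype=int)
    ambient_by_time = {
        int(t): profiles.ambient_profile(config.state_props_by_time[int(t)])
        for t in times
    }
    for t in times:
        mask = cell_times == t
        props = np.asarray(config.state_props_by_time[int(t)], float)
        states[mask] = rng.choice(config.n_states, size=mask.sum(), p=props)
        dmask = mask & is_doublet
        partner_states[dmask] = rng.choice(config.n_states, size=dmask.sum(), p=props)

    libsizes = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n_cells)
    partner_libs = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n_cells)

    n_total = n_cells + n_empty
    counts = np.zeros((n_total, config.n_genes), dtype=np.int64)
    for i in range(n_cells):
        amb = ambient_by_time[int(cell_times[i])]
        expect = (1.0 - rho[i]) * profiles.means[states[i]] + rho[i] * amb
        expect = expect / expect.sum() * libsizes[i]
        if is_doublet[i]:
            e2 = (1.0 - rho[i]) * profiles.means[partner_states[i]] + rho[i] * amb
            e2 = e2 / e2.sum() * partner_libs[i]
            expect = expect + e2
        counts[i] = _nb_sample(rng, expect, config.nb_dispersion)

    mean_lib = math.exp(config.libsize_log_mean + 0.5 * config.libsize_log_sd**2)
    empty_log_mean = config.libsize_log_mean + math.log(EMPTY_LIBRARY_FRACTION)
    empty_times = times[np.arange(n_empty) % len(times)]
    empty_libs = rng.lognormal(empty_log_mean, config.libsize_log_sd, size=n_empty)
    for j in range(n_empty):
        amb = ambient_by_time[int(empty_times[j])]
        expect = amb / amb.sum() * empty_libs[j]
        counts[n_cells + j] = _nb_sample(rng, expect, config.nb_dispersion)

    barcodes = [f"BC{i:05d}" for i in range(n_total)]
    genes = [f"g{i:04d}" for i in range(config.n_genes)]

    # Allele observations: binomial thinning of each droplet's UMIs.
    totals = counts.sum(axis=1)
    rows_bc, rows_umi, rows_allele = [], [], []
    for i in range(n_total):
        n_inf = rng.binomial(int(totals[i]), config.p_informative)
        if n_inf == 0:
            continue
        if i < n_cells and not is_doublet[i]:
            alleles = np.full(n_inf, genotypes[i])
        else:
            alleles = np.where(rng.random(n_inf) < 0.5, "A", "B").astype(object)
        flip = rng.random(n_inf) < config.allele_error
        alleles = np.where(
            flip, np.where(alleles == "A", "B", "A"), alleles
        ).astype(object)
        reps = rng.integers(1, 4, size=n_inf) if config.read_duplicates else np.ones(n_inf, int)
        for u, (a, r) in enumerate(zip(alleles, reps)):
            for _ in range(int(r)):
                rows_bc.append(barcodes[i])
                rows_umi.append(f"u{u:06d}")
                rows_allele.append(a)
    obs = pd.DataFrame({"barcode": rows_bc, "umi": rows_umi, "allele": rows_allele})

    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "is_cell": [True] * n_cells + [False] * n_empty,
            "state": list(states) + [-1] * n_empty,
            "genotype": [
                "doublet_AB" if is_doublet[i] else genotypes[i] for i in range(n_cells)
            ]
            + [""] * n_empty,
            "ambient_fraction": list(rho) + [1.0] * n_empty,
            "time_point_h": list(cell_times) + list(empty_times),
        }
    )

    meta = {
        barcodes[i]: {"time_point_h": int(cell_times[i]), "replicate": 1}
        for i in range(n_cells)
    }
    matrix = CountMatrix(sp.csr_matrix(counts), barcodes, genes, meta)
    return matrix, obs, DropletTruth(truth)


def _time_contrasts(offsets: np.ndarray) -> np.ndarray:
    """Per-time contrast of each gene's log2 offset vs the mean of the others."""
    T = offsets.shape[1]
    out = np.empty_like(offsets)
    for t in range(T):
        others = [u for u in range(T) if u != t]
        out[:, t] = offsets[:, t] - offsets[:, others].mean(axis=1)
    return out


def simulate_bulk_pair(
    config: SimConfig,
    rng: np.random.Generator,
    base_rel: np.ndarray | None = None,
) -> tuple[BulkCounts, BulkTruth]:
    """Simulate paired whole-embryo / protoplast bulk counts.

    ``base_rel`` optionally supplies the baseline relative expression per
    gene (e.g. the population mean of droplet state profiles, so bulk and
    single-cell arms describe the same tissue); by default an independent
    Gamma(0.5, 2) spectrum is drawn.

    A random :data:`TIME_EFFECT_FRACTION` of genes carry temporal effects.
    Half of them are single-time spikes (a signed log2 offset of
    U:data:`SPIKE_RANGE` at one time point, zero elsewhere — the archetype
    of a time-exclusive gene); the other half follow interval walks with
    log2 shifts of ±U[1.5, 4] between successive time points (each interval
    active with probability 1/2, at least one per gene), which are mostly
    multi-time.  Protoplast samples additionally apply a fixed signed log2
    fold-change (magnitudes uniform in ``protoplast_lfc_range``) to
    ``n_protoplast_genes`` genes, identically at every time point.
    ``time_signature_truth`` lists genes whose true time-vs-rest contrast
    exceeds 1.5 in absolute value at exactly one time point, so the lists
    are disjoint by construction.
    """
    config.validate()
    if config.bulk_replicates < 2 or len(config.time_points_h) < 2:
        raise ValueError("need >= 2 replicates and >= 2 time points")
    G = config.n_genes
    times = list(config.time_points_h)
    T = len(times)
    genes = [f"g{i:04d}" for i in range(G)]

    if base_rel is None:
        base_rel = np.maximum(rng.gamma(0.5, 2.0, size=G), 1e-4)
    else:
        base_rel = np.maximum(np.asarray(base_rel, float), 1e-4)
        if base_rel.shape != (G,):
            raise ValueError("base_rel must have one entry per gene")
        base_rel = base_rel / base_rel.mean()  # Gamma(0.5, 2) has mean 1

    # differential effects are planted on expressed genes only: a response
    # on a silent gene is not observable at any depth
    eligible = np.flatnonzero(base_rel >= MIN_DE_BASE_REL)
    n_te = int(round(TIME_EFFECT_FRACTION * G))
    n_te = min(n_te, len(eligible) - config.n_protoplast_genes)
    te_idx = rng.choice(eligible, size=n_te, replace=False)
    n_spike = n_te // 2
    spike_idx, walk_idx = te_idx[:n_spike], te_idx[n_spike:]

    offsets_whole = np.zeros((G, T))  # genes x times, log2
    slo, shi = SPIKE_RANGE
    spike_time = {}
    for gi in spike_idx:
        t_i = int(rng.integers(T))
        sign = -1.0 if rng.random() < 0.5 else 1.0
        offsets_whole[gi, t_i] = sign * rng.uniform(slo, shi)
        spike_time[int(gi)] = int(times[t_i])

    lo, hi = TIME_SHIFT_RANGE
    shifts = np.zeros((G, T - 1))
    for gi in walk_idx:
        active = rng.random(T - 1) < 0.5
        if not active.any():
            active[rng.integers(T - 1)] = True
        mags = rng.uniform(lo, hi, size=T - 1)
        signs = np.where(rng.random(T - 1) < 0.5, -1.0, 1.0)
        shifts[gi] = np.where(active, signs * mags, 0.0)
    offsets_whole[walk_idx] = np.concatenate(
        [np.zeros((len(walk_idx), 1)), np.cumsum(shifts[walk_idx], axis=1)], axis=1
    )

    # Optionally invert temporal dynamics for a fraction of time-effect genes
    # in the protoplast arm (drives the discordance statistic).
    n_disc = int(round(config.protoplast_discordant_fraction * n_te))
    disc_idx = rng.choice(te_idx, size=n_disc, replace=False) if n_disc else np.array([], int)
    offsets_proto = offsets_whole.copy()
    offsets_proto[disc_idx] = -offsets_whole[disc_idx]

    proto_idx = rng.choice(eligible, size=config.n_protoplast_genes, replace=False)
    plo, phi = config.protoplast_lfc_range
    pmags = rng.uniform(plo, phi, size=config.n_protoplast_genes)
    psigns = np.where(rng.random(config.n_protoplast_genes) < 0.5, -1.0, 1.0)
    proto_lfc = np.zeros(G)
    proto_lfc[proto_idx] = psigns * pmags

    samples: list[SampleInfo] = []
    cols = []
    for t_i, t in enumerate(times):
        for proto in (False, True):
            off = offsets_proto if proto else offsets_whole
            rel = base_rel * np.exp2(off[:, t_i] + (proto_lfc if proto else 0.0))
            prob = rel / rel.sum()
            for rep in range(1, config.bulk_replicates + 1):
                lib = rng.lognormal(math.log(BULK_LIBSIZE), 0.1)
                cols.append(_nb_sample(rng, prob * lib, config.bulk_nb_dispersion))
                tag = "p" if proto else "np"
                samples.append(SampleInfo(f"t{t}_{tag}_r{rep}", int(t), proto, rep))
    values = np.stack(cols, axis=1)

    contrasts = _time_contrasts(offsets_whole)
    exclusive = np.abs(contrasts) > 1.5
    sig_truth: dict[int, list[str]] = {int(t): [] for t in times}
    for gi in range(G):
        hits = np.flatnonzero(exclusive[gi])
        if len(hits) == 1:
            sig_truth[int(times[hits[0]])].append(genes[gi])

    truth = BulkTruth(
        protoplast_gene_set=[genes[i] for i in sorted(proto_idx)],
        true_lfc={genes[i]: float(proto_lfc[i]) for i in sorted(proto_idx)},
        time_signature_truth=sig_truth,
        spike_truth={
            int(t): sorted(genes[gi] for gi, st in spike_time.items() if st == int(t))
            for t in times
        },
        time_effect_genes=[genes[i] for i in sorted(te_idx)],
        interval_shifts=pd.DataFrame(
            np.diff(offsets_whole, axis=1),
            index=genes,
            columns=[f"{times[i]}-{times[i + 1]}" for i in range(T - 1)],
        ),
        discordant_genes=[genes[i] for i in sorted(disc_idx)],
    )
    return BulkCounts(values, genes, samples), truth


def simulate_protoplast_audit_scenario(
    config: SimConfig, rng: np.random.Generator
) -> tuple[CountMatrix, BulkCounts, list[str]]:
    """Cells with a dissociation response vs whole-tissue bulk without one.

    The single-cell arm perturbs a random protoplast-responsive gene set
    (signed log2 fold-changes drawn from ``protoplast_lfc_range``) in every
    state profile before simulating droplets; the matched whole-tissue bulk
    counts are drawn from the unperturbed per-time population means.  Used
    to audit pseudobulk-vs-bulk correlation with and without excluding the
    perturbed genes.
    """
    config.validate()
    profiles = simulate_embryo_profiles(config, rng)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]

    proto_idx = rng.choice(config.n_genes, size=config.n_protoplast_genes, replace=False)
    lo, hi = config.protoplast_lfc_range
    lfc = rng.uniform(lo, hi, size=config.n_protoplast_genes)
    signs = np.where(rng.random(config.n_protoplast_genes) < 0.5, -1.0, 1.0)
    factor = np.ones(config.n_genes)
    factor[proto_idx] = np.exp2(signs * lfc)

    perturbed = StateProfiles(
        means=profiles.means * factor[None, :], marker_sets=profiles.marker_sets
    )
    matrix, _, _ = simulate_droplets(config, perturbed, rng)

    samples, cols = [], []
    for t in config.time_points_h:
        amb = profiles.ambient_profile(config.state_props_by_time[int(t)])
        prob = amb / amb.sum()
        for rep in range(1, config.bulk_replicates + 1):
            lib = rng.lognormal(math.log(BULK_LIBSIZE), 0.1)
            cols.append(_nb_sample(rng, prob * lib, config.bulk_nb_dispersion))
            samples.append(SampleInfo(f"t{t}_np_r{rep}", int(t), False, rep))
    bulk = BulkCounts(np.stack(cols, axis=1), genes, samples)
    return matrix, bulk, [genes[i] for i in sorted(proto_idx)]
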