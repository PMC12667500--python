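"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design this pipeline targets: two species
(a noise-damaged and a noise-resistant model), control vs 24-h-post-noise
conditions with three biological replicates each, negative-binomial counts
(gamma-Poisson, variance mu + alpha*mu^2) with per-sample size factors,
a one-to-one ortholog map covering a shared subset of genes, planted DEGs
with controlled cross-species quadrant structure plus species-specific
DEGs, annotation terms with one planted enriched term, a sparse random
interaction graph with one planted high-degree hub, and small assay tables
(qPCR Ct values, a viability plate, ABR detectability grids).

Everything is driven by a single integer seed; identical configurations
produce identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import log
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import AnnotationSet, CountMatrix, OrthologMap

QUADRANT_LABELS = ("Q1", "Q2", "Q3", "Q4")
#: per-species effect signs (species A, species B) for each quadrant
QUADRANT_SIGNS = {"Q1": (1, 1), "Q2": (-1, 1), "Q3": (-1, -1), "Q4": (1, -1)}

ABR_FREQS_KHZ = (4, 8, 16, 24, 32)
ABR_GRID_DB = tuple(range(5, 95, 5))
ABR_CEILING_DB = 90


def _default_abr_thresholds() -> dict[str, dict[int, int]]:
    # pre-exposure audiogram plus persistent post-noise elevation, capped at
    # the 90 dB reporting ceiling
    pre = {4: 40, 8: 30, 16: 25, 24: 35, 32: 45}
    shift2, shift14 = 45, 40
    return {
        "Pre-NE": pre,
        "2DPN": {f: min(t + shift2, ABR_CEILING_DB) for f, t in pre.items()},
        "14DPN": {f: min(t + shift14, ABR_CEILING_DB) for f, t in pre.items()},
    }


@dataclass
class SynthConfig:
    """All knobs of the synthetic study; defaults mirror the target design."""

    seed: int = 0
    n_genes: int = 2000
    n_orthologs: int = 1500
    replicates_per_group: int = 3
    #: natural-log bounds of the log-uniform baseline mean expression
    baseline_mean_log_range: tuple[float, float] = (log(20.0), log(500.0))
    #: NB dispersion alpha shared by all genes (variance mu + alpha*mu^2)
    dispersion: float = 0.1
    #: planted ortholog pairs per quadrant (Q1..Q4); defaults are the
    #: concordance structure observed in the study this emulates
    planted_quadrant_counts: tuple[int, int, int, int] = (43, 41, 51, 69)
    planted_effect_log2fc: float = 1.5
    #: planted species-specific DEGs (A-up, A-down, B-up, B-down); the
    #: network stage consumes the B-specific sets
    planted_specific_counts: tuple[int, int, int, int] = (160, 170, 50, 80)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    # annotations
    n_terms: int = 50
    planted_term_enrichment: float = 0.8
    term_size_range: tuple[int, int] = (20, 100)
    # interaction graph
    graph_n_nodes: int = 300
    graph_n_edges: int = 600
    hub_extra_degree: int = 60
    # assays
    ct_noise_sd: float = 0.2
    true_ddct: float = -1.0
    od_negative: float = 1.0
    od_positive: float = 0.15
    od_noise_sd: float = 0.02
    true_viability_pct: float = 55.0
    wells_per_role: int = 6
    abr_thresholds: dict = field(default_factory=_default_abr_thresholds)
    abr_flip_prob: float = 0.0

    def validate(self) -> None:
        def bad(name: str, why: str):
            raise ConfigError(f"{name}: {why}")

        if self.n_genes < 1:
            bad("n_genes", "must be >= 1")
        if not (0 <= self.n_orthologs <= self.n_genes):
            bad("n_orthologs", "must be between 0 and n_genes")
        if self.replicates_per_group < 2:
            bad("replicates_per_group", "must be >= 2")
        lo, hi = self.baseline_mean_log_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            bad("baseline_mean_log_range", "must be a finite (lo, hi) with lo <= hi")
        if not (self.dispersion >= 0 and np.isfinite(self.dispersion)):
            bad("dispersion", "must be a finite nonnegative real")
        qc = tuple(self.planted_quadrant_counts)
        if len(qc) != 4 or any(c < 0 for c in qc):
            bad("planted_quadrant_counts", "must be four nonnegative integers")
        if sum(qc) > self.n_orthologs:
            bad("planted_quadrant_counts", "sum exceeds n_orthologs")
        sc = tuple(self.planted_specific_counts)
        if len(sc) != 4 or any(c < 0 for c in sc):
            bad("planted_specific_counts", "must be four nonnegative integers")
        if sum(qc) + max(sc[0] + sc[1], sc[2] + sc[3]) > self.n_genes:
            bad("planted_specific_counts", "planted genes exceed n_genes")
        slo, shi = self.size_factor_range
        if not (0 < slo <= shi):
            bad("size_factor_range", "must satisfy 0 < lo <= hi")
        if self.n_terms < 1:
            bad("n_terms", "must be >= 1")
        if not (0.0 <= self.planted_term_enrichment <= 1.0):
            bad("planted_term_enrichment", "must lie in [0, 1]")
        if self.graph_n_nodes < 2:
            bad("graph_n_nodes", "must be >= 2")
        if self.graph_n_edges < 0:
            bad("graph_n_edges", "must be >= 0")
        if self.hub_extra_degree < 0:
            bad("hub_extra_degree", "must be >= 0")
        if self.ct_noise_sd < 0 or self.od_noise_sd < 0:
            bad("ct_noise_sd/od_noise_sd", "noise SDs must be >= 0")
        if not (0.0 <= self.abr_flip_prob < 1.0):
            bad("abr_flip_prob", "must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure recorded by the generators."""

    up_a: set = field(default_factory=set)
    down_a: set = field(default_factory=set)
    up_b: set = field(default_factory=set)
    down_b: set = field(default_factory=set)
    #: (gene_a, gene_b) -> quadrant label for planted ortholog pairs
    quadrants: dict = field(default_factory=dict)
    enriched_term: str | None = None
    hub: str | None = None

    def validate(self) -> None:
        if self.up_a & self.down_a or self.up_b & self.down_b:
            raise ValidationError("truly-up and truly-down sets overlap")
        for (a, b), lab in self.quadrants.items():
            sa, sb = QUADRANT_SIGNS[lab]
            if (a in self.up_a) != (sa > 0) or (a in self.down_a) != (sa < 0):
                raise ValidationError(f"quadrant label of {a!r} contradicts its effect")
            if (b in self.up_b) != (sb > 0) or (b in self.down_b) != (sb < 0):
                raise ValidationError(f"quadrant label of {b!r} contradicts its effect")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "up_a": sorted(self.up_a),
            "down_a": sorted(self.down_a),
            "up_b": sorted(self.up_b),
            "down_b": sorted(self.down_b),
            "quadrants": [[a, b, lab] for (a, b), lab in sorted(self.quadrants.items())],
            "enriched_term": self.enriched_term,
            "hub": self.hub,
        }
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            up_a=set(obj["up_a"]),
            down_a=set(obj["down_a"]),
            up_b=set(obj["up_b"]),
            down_b=set(obj["down_b"]),
            quadrants={(a, b): lab for a, b, lab in obj["quadrants"]},
            enriched_term=obj["enriched_term"],
            hub=obj["hub"],
        )


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with E = mean and Var = mean + dispersion*mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, dispersion * mean)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SynthConfig,
) -> tuple[CountMatrix, CountMatrix, OrthologMap, GroundTruth]:
    """Two-species count matrices with planted DEG/quadrant structure.

    Counts are NB(mean = s_j * mu_i * 2**(beta_i * x_j), dispersion alpha)
    where x_j indicates the treated condition and beta_i is 0 for null
    genes and +-planted_effect_log2fc for planted genes.  The ortholog map
    links gene i of species A to gene i of species B for i < n_orthologs.
    """
    config.validate()
    rng = _rng(config, 1)
    G, n_orth = config.n_genes, config.n_orthologs
    genes_a = [f"gA{i:05d}" for i in range(G)]
    genes_b = [f"gB{i:05d}" for i in range(G)]
    omap = OrthologMap(pairs=[(genes_a[i], genes_b[i]) for i in range(n_orth)])

    beta_a = np.zeros(G)
    beta_b = np.zeros(G)
    truth = GroundTruth()
    eff = float(config.planted_effect_log2fc)

    qc = tuple(config.planted_quadrant_counts)
    orth_pick = rng.choice(n_orth, size=sum(qc), replace=False) if sum(qc) else np.array([], int)
    pos = 0
    for lab, count in zip(QUADRANT_LABELS, qc):
        sa, sb = QUADRANT_SIGNS[lab]
        for i in orth_pick[pos : pos + count]:
            beta_a[i] = sa * eff
            beta_b[i] = sb * eff
            if eff > 0:
                truth.quadrants[(genes_a[i], genes_b[i])] = lab
        pos += count

    # species-specific planting: pools exclude quadrant genes, and B's pool
    # excludes partners of A-specific picks so no accidental overlap pair
    planted_orth = set(int(i) for i in orth_pick)
    a_up_n, a_down_n, b_up_n, b_down_n = config.planted_specific_counts
    pool_a = np.array([i for i in range(G) if i not in planted_orth])
    pick_a = rng.choice(pool_a, size=min(a_up_n + a_down_n, pool_a.size), replace=False)
    for k, i in enumerate(pick_a):
        beta_a[i] = eff if k < a_up_n else -eff
    pool_b = np.array(
        [i for i in range(G) if i not in planted_orth and (i >= n_orth or beta_a[i] == 0)]
    )
    pick_b = rng.choice(pool_b, size=min(b_up_n + b_down_n, pool_b.size), replace=False)
    for k, i in enumerate(pick_b):
        beta_b[i] = eff if k < b_up_n else -eff

    if eff > 0:
        truth.up_a = {genes_a[i] for i in np.flatnonzero(beta_a > 0)}
        truth.down_a = {genes_a[i] for i in np.flatnonzero(beta_a < 0)}
        truth.up_b = {genes_b[i] for i in np.flatnonzero(beta_b > 0)}
        truth.down_b = {genes_b[i] for i in np.flatnonzero(beta_b < 0)}
    truth.validate()

    r = config.replicates_per_group
    x = np.array([0] * r + [1] * r)
    lo, hi = config.baseline_mean_log_range
    slo, shi = config.size_factor_range

    def make_matrix(species: str, gene_ids: list[str], beta: np.ndarray) -> CountMatrix:
        mu = np.exp(rng.uniform(lo, hi, size=G))
        s = np.exp(rng.uniform(np.log(slo), np.log(shi), size=2 * r))
        mean = mu[:, None] * s[None, :] * 2.0 ** (beta[:, None] * x[None, :])
        y = nb_sample(rng, mean, config.dispersion)
        sample_ids = [
            f"{species}_{'control' if xi == 0 else 'treated'}_{j % r + 1}"
            for j, xi in enumerate(x)
        ]
        meta = pd.DataFrame(
            {
                "species": species,
                "condition": ["control" if xi == 0 else "treated" for xi in x],
                "replicate": [j % r + 1 for j in range(2 * r)],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        counts = pd.DataFrame(y, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
        return CountMatrix(counts=counts, meta=meta)

    cm_a = make_matrix("A", genes_a, beta_a)
    cm_b = make_matrix("B", genes_b, beta_b)
    return cm_a, cm_b, omap, truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    config: SynthConfig,
    truth: GroundTruth,
    genes: list[str],
    planted_set: set[str] | None = None,
) -> AnnotationSet:
    """Random term memberships over ``genes`` with one planted enriched term.

    The planted term includes each gene of ``planted_set`` (default: the
    species-B truly-up set) with probability ``planted_term_enrichment``,
    then is padded with random genes to a typical term size.  Updates
    ``truth.enriched_term`` in place.
    """
    config.validate()
    if not genes:
        raise ValidationError("gene list must be nonempty")
    rng = _rng(config, 2)
    genes = list(genes)
    gene_set = set(genes)
    if planted_set is None:
        planted_set = truth.up_b & gene_set or truth.up_a & gene_set
    planted = sorted(planted_set & gene_set)

    lo, hi = config.term_size_range
    hi = min(hi, len(genes))
    lo = min(lo, hi)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(1, config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        terms[f"T{t:04d}"] = (f"synthetic term {t}", frozenset(members.tolist()))

    planted_id = f"T{config.n_terms:04d}"
    keep = [g for g in planted if rng.random() < config.planted_term_enrichment]
    target = max(int(rng.integers(lo, hi + 1)), len(keep))
    # pad only with non-planted genes, so planted genes enter the term at
    # exactly the configured rate
    others = [g for g in genes if g not in planted_set]
    pad = rng.choice(others, size=target - len(keep), replace=False) if target > len(keep) else []
    members = frozenset(keep) | frozenset(list(pad))
    if not members:  # degenerate: nothing planted and zero pad
        members = frozenset(rng.choice(genes, size=max(lo, 1), replace=False).tolist())
    terms[planted_id] = ("planted enriched term", members)
    truth.enriched_term = planted_id
    return AnnotationSet(terms=terms, universe=frozenset(gene_set))


# ---------------------------------------------------------------------------
# Interaction graph
# ---------------------------------------------------------------------------

def simulate_ppi(
    config: SynthConfig, genes: list[str], hub_candidates: list[str] | None = None
) -> tuple[nx.Graph, str | None]:
    """Random simple undirected graph over a sample of ``genes`` with one
    designated hub that receives ``hub_extra_degree`` extra distinct edges.

    ``hub_candidates`` restricts which nodes may be designated the hub
    (e.g. the up-regulated genes).  Returns (graph, hub id); the hub is
    None when hub_extra_degree is 0.
    """
    config.validate()
    if config.graph_n_nodes < 2:
        raise ConfigError("graph_n_nodes: must be >= 2")
    if len(genes) < config.graph_n_nodes:
        raise ConfigError("graph_n_nodes: exceeds the number of available genes")
    rng = _rng(config, 3)
    nodes = sorted(rng.choice(sorted(genes), size=config.graph_n_nodes, replace=False).tolist())
    n = len(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    total_pairs = n * (n - 1) // 2
    m = min(config.graph_n_edges, total_pairs)
    if m:
        idx = rng.choice(total_pairs, size=m, replace=False)
        # map a flat pair index to (i, j), i < j
        for k in np.sort(idx):
            i = int((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * k)) // 2)
            j = int(k - i * (2 * n - i - 1) // 2 + i + 1)
            g.add_edge(nodes[i], nodes[j])
    hub = None
    if config.hub_extra_degree > 0:
        pool = nodes
        if hub_candidates is not None:
            pool = sorted(set(nodes) & set(hub_candidates)) or nodes
        hub = pool[int(rng.integers(len(pool)))]
        candidates = sorted(set(nodes) - set(g.neighbors(hub)) - {hub})
        extra = min(config.hub_extra_degree, len(candidates))
        for v in rng.choice(candidates, size=extra, replace=False):
            g.add_edge(hub, v)
    return g, hub


# ---------------------------------------------------------------------------
# Assays
# ---------------------------------------------------------------------------

def simulate_assays(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic assay tables: qPCR Ct records, a viability plate, and ABR
    waveform-detectability grids.

    Ct values are true values plus Gaussian noise (SD ``ct_noise_sd``) with
    the treated group's target gene shifted by ``true_ddct`` cycles.  The
    plate carries experiment / negative / positive wells around the
    configured OD levels.  ABR detectability is a step function of
    intensity at the planted per-frequency thresholds, with optional flip
    noise.
    """
    config.validate()
    rng = _rng(config, 4)
    r = config.replicates_per_group

    ref_ct, base_ct = 18.0, 25.0
    rows = []
    for group, shift in (("control", 0.0), ("treated", config.true_ddct)):
        for j in range(1, r + 1):
            rows.append(
                {
                    "sample_id": f"{group}_{j}",
                    "group": group,
                    "ct_target": base_ct + shift + rng.normal(0, config.ct_noise_sd),
                    "ct_reference": ref_ct + rng.normal(0, config.ct_noise_sd),
                }
            )
    ct = pd.DataFrame(rows)

    frac = config.true_viability_pct / 100.0
    od_exp = config.od_positive + frac * (config.od_negative - config.od_positive)
    wells = []
    for role, level in (
        ("experiment", od_exp),
        ("negative", config.od_negative),
        ("positive", config.od_positive),
    ):
        for j in range(1, config.wells_per_role + 1):
            wells.append(
                {
                    "well": f"{role[:3]}_{j}",
                    "role": role,
                    "od": level + rng.normal(0, config.od_noise_sd),
                }
            )
    plate = pd.DataFrame(wells)

    abr_rows = []
    for timepoint, per_freq in config.abr_thresholds.items():
        for freq in ABR_FREQS_KHZ:
            thr = per_freq[freq]
            for db in ABR_GRID_DB:
                det = db >= thr
                if config.abr_flip_prob and rng.random() < config.abr_flip_prob:
                    det = not det
                abr_rows.append(
                    {
                        "timepoint": timepoint,
                        "frequency_khz": freq,
                        "intensity_db": db,
                        "detectable": bool(det),
                    }
                )
    abr = pd.DataFrame(abr_rows)
    return ct, plate, abr
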