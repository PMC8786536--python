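"""Synthetic multi-omics, network and cohort generator with ground truth.

Emulates the statistical structure the pipeline assumes: a paired
tumor/normal cohort with planted epigenetically induced (EI) genes
(expression up, promoter methylation down, negatively coupled per
sample), planted epigenetically suppressed (ES) genes (the mirror
image), a scale-free interaction network whose planted driver nodes
have EI/ES-enriched neighborhoods, and a survival cohort with a
planted marker hazard effect.

Expression is log-normal per gene with effects additive on the log2
scale; promoter methylation is logit-normal per probe around a
gene-level promoter mean, with effects additive on the beta scale.
Coupling shares a per-sample latent factor with opposite signs between
the two layers of a planted gene, producing the negative methylation-
expression correlation the classifier filters on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import NORMAL, TUMOR, OmicsMatrix
from .preprocess import GeneModel, ProbeAnnotation

_LOGIT_EPS = 1e-6


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _LOGIT_EPS, 1 - _LOGIT_EPS)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """All knobs for the generator; defaults mirror the study design
    (41 tumor/normal pairs, a 160-patient staining cohort with 60%
    marker-high prevalence and a planted marker hazard ratio of 4.465).
    """

    n_pairs: int = 41
    n_genes: int = 2000
    min_probes_per_gene: int = 1
    max_probes_per_gene: int = 5
    n_ei: int = 100
    n_es: int = 50
    expr_effect: float = 2.0       # log2 shift in planted tumor expression
    meth_effect: float = 0.3       # beta-scale shift in planted tumor methylation
    coupling: float = 0.8          # shared latent factor weight, in [0, 1]
    expr_sigma: float = 0.5        # per-gene log2 noise sd
    meth_sigma: float = 0.4        # logit-scale promoter noise sd
    probe_sigma: float = 0.15      # logit-scale probe offset sd
    network_nodes: int = 10_000
    edges_per_new_node: int = 10
    n_drivers: int = 4
    driver_wiring: float = 0.5     # fraction of driver neighbors from EI/ES nodes
    cohort_n: int = 160
    marker_prevalence: float = 0.6
    marker_log_hr: float = math.log(4.465)
    baseline_median_months: float = 48.0
    censor_horizon_months: float = 120.0
    stage_base_logit: float = -2.75    # logit P(stage III-IV) for marker-low
    stage_marker_logodds: float = 2.3  # added log-odds of late stage if marker-high
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.n_genes < 1:
            raise ValueError("n_pairs and n_genes must be positive")
        if self.n_ei + self.n_es > self.n_genes:
            raise ValueError("n_ei + n_es exceeds n_genes")
        for name in ("expr_effect", "meth_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [0, 1]")
        if not 0 <= self.driver_wiring <= 1:
            raise ValueError("driver_wiring must lie in [0, 1]")
        if not 1 <= self.min_probes_per_gene <= self.max_probes_per_gene:
            raise ValueError("invalid probes-per-gene range")
        if self.censor_horizon_months < 0:
            raise ValueError("censoring horizon must be non-negative")
        # Planted baselines live in (0.40, 0.70) for EI and (0.30, 0.60)
        # for ES; the shifted mean must stay a valid beta.
        if self.meth_effect > 0.38:
            raise ValueError(
                "meth_effect too large: shifted promoter means would leave [0, 1]"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthLabels:
    """Planted ground truth: gene class, driver flags, patient marker state."""

    gene_class: dict[str, str] = field(default_factory=dict)  # EI | ES | null
    driver_genes: set[str] = field(default_factory=set)
    marker_state: dict[str, int] = field(default_factory=dict)

    @property
    def ei_genes(self) -> list[str]:
        return sorted(g for g, c in self.gene_class.items() if c == "EI")

    @property
    def es_genes(self) -> list[str]:
        return sorted(g for g, c in self.gene_class.items() if c == "ES")


def _sample_names(n_pairs: int) -> tuple[list[str], pd.Series, pd.Series]:
    tumor = [f"P{i + 1:03d}_T" for i in range(n_pairs)]
    normal = [f"P{i + 1:03d}_N" for i in range(n_pairs)]
    samples = tumor + normal
    groups = pd.Series(
        {s: (TUMOR if s.endswith("_T") else NORMAL) for s in samples}
    )
    pairs = pd.Series({s: s.split("_")[0] for s in samples})
    return samples, groups, pairs


def plant_gene_labels(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TruthLabels:
    """Draw the planted EI/ES gene assignment (the first random choice
    of :func:`simulate_omics`, exposed for network-only experiments)."""
    rng = config.rng() if rng is None else rng
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    planted = rng.choice(config.n_genes, size=config.n_ei + config.n_es, replace=False)
    ei_idx = set(planted[: config.n_ei].tolist())
    es_idx = set(planted[config.n_ei:].tolist())
    return TruthLabels(
        gene_class={
            g: ("EI" if i in ei_idx else "ES" if i in es_idx else "null")
            for i, g in enumerate(genes)
        }
    )


def simulate_omics(
    config: SimulationConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, dict[str, ProbeAnnotation], list[GeneModel], TruthLabels]:
    """Paired expression + probe-level methylation with planted EI/ES genes.

    Returns (expression TPM-like matrix, probe beta matrix, probe
    annotation, gene models, truth labels). Probes are placed inside
    each gene's promoter window so the preprocessing stage maps them
    back deterministically.
    """
    rng = config.rng()
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    samples, groups, pairs = _sample_names(config.n_pairs)
    n_s = len(samples)
    is_tumor = np.array([groups[s] == TUMOR for s in samples], dtype=float)

    labels = plant_gene_labels(config, rng)
    ei_idx = {i for i, g in enumerate(genes) if labels.gene_class[g] == "EI"}
    es_idx = {i for i, g in enumerate(genes) if labels.gene_class[g] == "ES"}

    # gene models: one chromosome, TSS spaced far apart, alternating strand
    models = [
        GeneModel(g, "chr1", 10_000 * (i + 1), "+" if i % 2 == 0 else "-")
        for i, g in enumerate(genes)
    ]

    # --- expression (log2 scale) ------------------------------------------
    base_log2 = rng.uniform(3.0, 8.0, size=config.n_genes)
    sign = np.zeros(config.n_genes)
    for i in ei_idx:
        sign[i] = 1.0
    for i in es_idx:
        sign[i] = -1.0
    latent = rng.standard_normal((config.n_genes, n_s))  # shared factor
    eps_e = rng.standard_normal((config.n_genes, n_s))
    c = config.coupling
    planted_mask = (sign != 0).astype(float)[:, None]
    noise_e = np.where(
        planted_mask > 0,
        c * latent + math.sqrt(max(0.0, 1 - c * c)) * eps_e,
        eps_e,
    )
    log2_expr = (
        base_log2[:, None]
        + config.expr_effect * sign[:, None] * is_tumor[None, :]
        + config.expr_sigma * noise_e
    )
    expr = pd.DataFrame(np.exp2(log2_expr), index=genes, columns=samples)

    # --- methylation (promoter means on beta scale, probes logit-normal) ---
    base_beta = rng.uniform(0.2, 0.8, size=config.n_genes)
    base_beta[list(ei_idx)] = rng.uniform(0.40, 0.70, size=len(ei_idx))
    base_beta[list(es_idx)] = rng.uniform(0.30, 0.60, size=len(es_idx))
    mean_beta = (
        base_beta[:, None]
        - config.meth_effect * sign[:, None] * is_tumor[None, :]
    )
    if mean_beta.min() < 0.005 or mean_beta.max() > 0.995:
        raise ValueError("meth_effect pushes promoter means outside [0, 1]")
    eps_m = rng.standard_normal((config.n_genes, n_s))
    noise_m = np.where(
        planted_mask > 0,
        -c * latent + math.sqrt(max(0.0, 1 - c * c)) * eps_m,
        eps_m,
    )
    promoter_logit = _logit(mean_beta) + config.meth_sigma * noise_m

    n_probes = rng.integers(
        config.min_probes_per_gene, config.max_probes_per_gene + 1,
        size=config.n_genes,
    )
    probe_rows = []
    annotations: dict[str, ProbeAnnotation] = {}
    probe_values = []
    counter = 0
    for i, gene in enumerate(genes):
        model = models[i]
        if model.strand == "+":
            lo, hi = model.tss - 800, model.tss + 200
        else:
            lo, hi = model.tss - 200, model.tss + 800
        positions = rng.integers(lo, hi + 1, size=n_probes[i])
        offsets = rng.normal(0.0, config.probe_sigma, size=n_probes[i])
        for k in range(n_probes[i]):
            counter += 1
            pid = f"cg{counter:07d}"
            annotations[pid] = ProbeAnnotation(pid, "chr1", int(positions[k]))
            probe_rows.append(pid)
            probe_values.append(_expit(promoter_logit[i] + offsets[k]))
    beta = pd.DataFrame(np.vstack(probe_values), index=probe_rows, columns=samples)

    expr_m = OmicsMatrix(expr, groups, pairs)
    beta_m = OmicsMatrix(beta, groups, pairs)
    beta_m.validate_beta()
    expr_m.validate_expression()
    return expr_m, beta_m, annotations, models, labels


def simulate_network(config: SimulationConfig, labels: TruthLabels) -> nx.Graph:
    """Scale-free background network with EI/ES-enriched driver nodes.

    Background edges come from preferential attachment; planted driver
    nodes (chosen among EI/ES genes) then have a fraction
    ``driver_wiring`` of their neighbors rewired to EI/ES-labelled
    nodes, preserving their degree and simplicity of the graph.
    """
    n_planted = len([g for g, cls in labels.gene_class.items() if cls != "null"])
    if config.network_nodes < n_planted:
        raise ValueError("network_nodes smaller than the planted gene count")
    rng = np.random.default_rng(config.seed + 1)
    net = nx.barabasi_albert_graph(
        config.network_nodes,
        config.edges_per_new_node,
        seed=int(rng.integers(2**31 - 1)),
    )
    planted_genes = sorted(g for g, c in labels.gene_class.items() if c != "null")
    null_genes = sorted(g for g, c in labels.gene_class.items() if c == "null")
    names = (planted_genes + null_genes)[: config.network_nodes]
    names += [f"X{i + 1:05d}" for i in range(config.network_nodes - len(names))]
    # permute so planted genes are not systematically early (high-degree) nodes
    perm = rng.permutation(config.network_nodes)
    net = nx.relabel_nodes(net, {int(i): names[perm[i]] for i in range(config.network_nodes)})

    eies = [g for g in planted_genes if net.has_node(g)]
    eies_set = set(eies)
    drivers = sorted(
        rng.choice(np.array(eies), size=min(config.n_drivers, len(eies)), replace=False).tolist()
    )
    labels.driver_genes = set(drivers)
    for d in drivers:
        neighbors = sorted(net.neighbors(d))
        degree = len(neighbors)
        target = int(round(config.driver_wiring * degree))
        current = [v for v in neighbors if v in eies_set]
        deficit = target - len(current)
        if deficit <= 0:
            continue
        replaceable = [v for v in neighbors if v not in eies_set]
        candidates = sorted(eies_set - set(neighbors) - {d})
        k = min(deficit, len(replaceable), len(candidates))
        drop = rng.choice(np.array(replaceable), size=k, replace=False)
        add = rng.choice(np.array(candidates), size=k, replace=False)
        for old, new in zip(drop, add):
            net.remove_edge(d, old)
            net.add_edge(d, new)
    return net


def simulate_cohort(
    config: SimulationConfig, labels: TruthLabels | None = None
) -> pd.DataFrame:
    """Survival cohort with a planted marker effect on the hazard.

    Staining scores {1,2} (marker-low) or {3,4} (marker-high); event
    times exponential with hazard scaled by exp(marker_log_hr) for
    marker-high patients; independent uniform administrative censoring
    on [0, censor_horizon]; TNM late stage drawn with a configurable
    log-odds shift for marker-high patients. Binary covariates mimic a
    resected liver-cancer cohort and are independent of the marker.
    """
    if config.cohort_n < 2:
        raise ValueError("cohort_n must be at least 2")
    rng = np.random.default_rng(config.seed + 2)
    n = config.cohort_n
    patients = [f"PT{i + 1:04d}" for i in range(n)]
    marker = (rng.uniform(size=n) < config.marker_prevalence).astype(int)
    score = np.where(marker == 1, rng.integers(3, 5, size=n), rng.integers(1, 3, size=n))
    lam0 = math.log(2.0) / config.baseline_median_months
    lam = lam0 * np.exp(config.marker_log_hr * marker)
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(0.0, config.censor_horizon_months, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    stage_p = _expit(config.stage_base_logit + config.stage_marker_logodds * marker)
    covariates = {
        "age_gt55": rng.uniform(size=n) < 0.5,
        "male": rng.uniform(size=n) < 0.79,
        "hbv": rng.uniform(size=n) < 0.72,
        "alt_gt35": rng.uniform(size=n) < 0.40,
        "ast_gt31": rng.uniform(size=n) < 0.48,
        "tb_gt12": rng.uniform(size=n) < 0.46,
        "alb_gt40": rng.uniform(size=n) < 0.41,
        "tumor_gt5cm": rng.uniform(size=n) < 0.50,
    }
    df = pd.DataFrame(
        {
            "patient_id": patients,
            "staining_score": score,
            "marker_level": np.where(score <= 2, "low", "high"),
            "marker_true": marker,
            "tnm_late": (rng.uniform(size=n) < stage_p).astype(int),
            **{k: v.astype(int) for k, v in covariates.items()},
            "time": time,
            "event": event,
        }
    )
    if labels is not None:
        labels.marker_state = dict(zip(patients, marker.tolist()))
    return df
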