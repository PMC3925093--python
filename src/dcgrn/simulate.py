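"""Synthetic nonlinear regulatory networks and knockout-style expression.

This module is a documented stand-in for external benchmark generators
(the DREAM in-silico pipelines, SynTReN): it produces acyclic
regulatory topologies with Hill-type steady-state kinetics and
knockout/observational expression designs so the whole
simulate -> infer -> evaluate pipeline runs without any downloads.  It
does not clone any external generator's kinetics library.

Model: genes are evaluated in topological order; a target's expression
is

    x_t = baseline_t + sum_over_regulators  sign * k * link(x_reg)

with ``link`` a saturating response built from the Hill occupancy
``u = x^h / (theta^h + x^h)`` (link = u, u^2 or sin(pi*u/2) per config),
plus additive centered Gaussian noise, floored at 0 to mimic
nonnegative abundance.  A knockout clamps a gene to exactly 0 (null
mutant) for one sample; the knockout design is one wild-type sample
plus one knockout per gene.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dependence import dependence_matrix
from .errors import DcgrnError, InvalidInputError
from .evaluation import GoldStandard, align_gold, aupr, auroc
from .expression import ExpressionMatrix
from .inference import METHODS, infer_network

LINKS = ("hill", "quadratic", "sine")
DESIGNS = ("knockout", "random", "pooled")

# seeded sampling ranges for kinetic parameters (expression units)
_BASELINE_RANGE = (0.2, 1.0)
_STRENGTH_RANGE = (0.5, 2.0)
_THRESHOLD_RANGE = (0.3, 1.5)
_HILL_COEFFS = (1, 2, 3, 4)
_ROOT_RANGE = (0.0, 2.0)  # random-design draw for regulator-free genes


@dataclass
class RegulatoryNetwork:
    """Directed acyclic regulatory topology with per-edge kinetics.

    ``edges`` holds (regulator, target, sign) triples; ``edge_kinetics``
    maps (regulator, target) to (strength k, threshold theta, Hill
    coefficient h); ``baselines`` gives each gene's regulator-free
    expression level.
    """

    genes: list[str]
    edges: list[tuple[str, str, int]]
    baselines: dict[str, float]
    edge_kinetics: dict[tuple[str, str], tuple[float, float, float]]

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for reg, tgt, sign in self.edges:
            if reg == tgt:
                raise InvalidInputError(f"self-edge on {reg!r}")
            if reg not in gene_set or tgt not in gene_set:
                raise InvalidInputError(f"edge {reg}->{tgt} references unknown gene")
            if sign not in (-1, 1):
                raise InvalidInputError(f"edge sign must be +/-1, got {sign}")
            if (reg, tgt) not in self.edge_kinetics:
                raise InvalidInputError(f"missing kinetics for edge {reg}->{tgt}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_edges_from((r, t) for r, t, _ in self.edges)
        return g

    def to_gold_standard(self) -> GoldStandard:
        """The true topology as a labeled edge set for evaluation."""
        return GoldStandard(
            edges=[(r, t, 1) for r, t, _ in self.edges],
            node_names=list(self.genes),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for expression simulation.

    ``design`` picks the sampling scheme: "knockout" (wild type plus one
    null mutant per gene, n_genes + 1 samples), "random" (root genes
    drawn uniformly per sample) or "pooled" (the knockout block padded
    with random samples up to ``n_samples``).  ``noise_sd`` is the sd of
    the additive Gaussian noise in expression units; ``seed`` is
    mandatory so every simulation is reproducible.
    """

    seed: int
    design: str = "knockout"
    n_samples: int | None = None
    noise_sd: float = 0.1
    link: str = "hill"

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise InvalidInputError(f"unknown design {self.design!r}")
        if self.link not in LINKS:
            raise InvalidInputError(f"unknown link {self.link!r}")
        if self.noise_sd < 0:
            raise InvalidInputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.design in ("random", "pooled") and (
            self.n_samples is None or self.n_samples < 2
        ):
            raise InvalidInputError(
                f"design {self.design!r} needs n_samples >= 2"
            )


def sample_topology(n_genes: int, n_edges: int, seed: int) -> RegulatoryNetwork:
    """Uniformly sample an acyclic topology with seeded kinetics.

    Genes are ordered G1..Gn and every edge points from a
    lower-indexed gene to a higher-indexed one (ordered-ancestor
    constraint), which guarantees acyclicity; the ``n_edges`` ordered
    pairs are drawn uniformly without replacement.
    """
    if n_genes < 2:
        raise InvalidInputError(f"need at least 2 genes, got {n_genes}")
    max_edges = n_genes * (n_genes - 1) // 2
    if not 1 <= n_edges <= max_edges:
        raise InvalidInputError(
            f"n_edges must be in [1, {max_edges}] for {n_genes} genes, got {n_edges}"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    all_pairs = [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes)]
    chosen = rng.choice(len(all_pairs), size=n_edges, replace=False)
    edges = []
    kinetics = {}
    for idx in sorted(int(c) for c in chosen):
        i, j = all_pairs[idx]
        reg, tgt = genes[i], genes[j]
        sign = int(rng.choice((1, -1)))
        k = float(rng.uniform(*_STRENGTH_RANGE))
        theta = float(rng.uniform(*_THRESHOLD_RANGE))
        h = float(rng.choice(_HILL_COEFFS))
        edges.append((reg, tgt, sign))
        kinetics[(reg, tgt)] = (k, theta, h)
    baselines = {g: float(rng.uniform(*_BASELINE_RANGE)) for g in genes}
    return RegulatoryNetwork(
        genes=genes, edges=edges, baselines=baselines, edge_kinetics=kinetics
    )


def _link_response(x: np.ndarray, theta: float, h: float, link: str) -> np.ndarray:
    u = x**h / (theta**h + x**h)
    if link == "hill":
        return u
    if link == "quadratic":
        return u**2
    return np.sin(np.pi * u / 2.0)


def simulate_expression(
    net: RegulatoryNetwork, cfg: SimulationConfig
) -> ExpressionMatrix:
    """Steady-state expression under the configured sampling design."""
    dig = net.digraph()
    if not nx.is_directed_acyclic_graph(dig):
        raise InvalidInputError("regulatory network contains a cycle")
    order = list(nx.topological_sort(dig))
    idx = {g: i for i, g in enumerate(net.genes)}
    regulators: dict[str, list[tuple[int, int, float, float, float]]] = {
        g: [] for g in net.genes
    }
    for reg, tgt, sign in net.edges:
        k, theta, h = net.edge_kinetics[(reg, tgt)]
        regulators[tgt].append((idx[reg], sign, k, theta, h))

    n_ko = net.n_genes + 1  # wild type + one null mutant per gene
    if cfg.design == "knockout":
        n_samples, n_random = n_ko, 0
    elif cfg.design == "random":
        n_samples, n_random = cfg.n_samples, cfg.n_samples
    else:  # pooled
        if cfg.n_samples <= n_ko:
            raise InvalidInputError(
                f"pooled design needs n_samples > {n_ko} for {net.n_genes} genes"
            )
        n_samples, n_random = cfg.n_samples, cfg.n_samples - n_ko
    # clamped[s] = gene index knocked out in sample s (or -1)
    clamped = np.full(n_samples, -1, dtype=int)
    if cfg.design in ("knockout", "pooled"):
        clamped[1 : net.n_genes + 1] = np.arange(net.n_genes)
    random_rows = np.zeros(n_samples, dtype=bool)
    if n_random:
        random_rows[n_samples - n_random :] = True

    rng = np.random.default_rng(cfg.seed)
    # noise-free latent steady states; knockouts clamp the latent level so
    # the null mutant propagates downstream
    latent = np.zeros((n_samples, net.n_genes))
    for gene in order:
        j = idx[gene]
        regs = regulators[gene]
        col = np.full(n_samples, net.baselines[gene])
        if not regs and n_random:
            col[random_rows] = rng.uniform(*_ROOT_RANGE, size=n_random)
        for ridx, sign, k, theta, h in regs:
            col = col + sign * k * _link_response(latent[:, ridx], theta, h, cfg.link)
        col = np.maximum(col, 0.0)
        col[clamped == j] = 0.0
        latent[:, j] = col
    # measurement noise corrupts the observed matrix only (it does not feed
    # back into regulation); a null mutant still reads exactly 0
    x = latent
    if cfg.noise_sd > 0:
        x = np.maximum(latent + rng.normal(0.0, cfg.noise_sd, size=latent.shape), 0.0)
        for s in range(n_samples):
            if clamped[s] >= 0:
                x[s, clamped[s]] = 0.0

    sample_names = []
    for s in range(n_samples):
        if clamped[s] >= 0:
            sample_names.append(f"ko_{net.genes[clamped[s]]}")
        elif random_rows[s]:
            sample_names.append(f"rand_{s}")
        else:
            sample_names.append("wild_type")
    return ExpressionMatrix(
        values=x, gene_names=list(net.genes), sample_names=sample_names
    )


def benchmark_ensemble(
    n_replicates: int,
    net_size: int,
    n_edges: int,
    cfg: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """ROC/PR areas for every measure x method over seeded replicates.

    Each replicate samples a fresh topology, simulates expression under
    ``cfg`` (the config's own seed is replaced by one derived from
    ``seed``), builds both the dCor and MI dependence matrices, runs
    REL/CLR/MRNET on each, and scores both areas against the true
    topology.  Returns a tidy table with columns replicate, measure,
    method, roc_area, pr_area.
    """
    if n_replicates < 1:
        raise InvalidInputError(f"n_replicates must be >= 1, got {n_replicates}")
    rows = []
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep, child in enumerate(children):
        topo_seed, sim_seed = (int(s) % 2**31 for s in child.generate_state(2))
        try:
            net = sample_topology(net_size, n_edges, topo_seed)
            expr = simulate_expression(
                net, dataclasses.replace(cfg, seed=sim_seed)
            )
            gold = net.to_gold_standard()
            for measure in ("dc", "mi"):
                m = dependence_matrix(expr, measure)
                for method in METHODS:
                    ranking = align_gold(infer_network(m, method), gold)
                    rows.append(
                        {
                            "replicate": rep,
                            "measure": measure,
                            "method": method,
                            "roc_area": auroc(ranking),
                            "pr_area": aupr(ranking),
                        }
                    )
        except DcgrnError as exc:  # pragma: no cover - defensive
            raise type(exc)(f"replicate {rep}: {exc}") from exc
    return pd.DataFrame(rows)
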