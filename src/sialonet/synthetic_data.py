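"""Synthetic multi-batch transcriptome generator with planted structure.

Emulates the statistical structure of a merged case/control microarray
study of Sjögren's syndrome salivary glands: log2-scale expression with
additive per-gene batch shifts, a planted set of differentially expressed
(DE) genes, two latent case subgroups expressed as pathway-level mean
shifts, a scale-free protein-protein interactome carrying a dense module of
DE genes, and a directed acyclic gene network in which designated driver
roots regulate that module.  Every generated artifact is recorded in a
:class:`TruthManifest` so downstream stages can be scored against ground
truth.

A single global seed is fanned out to one independent generator per
component, so regenerating (say) the interactome never perturbs the
expression draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from sialonet.enrich import GeneSetCollection
from sialonet.errors import ConfigError

# stream ids for the per-component RNG fan-out
_STREAM_EXPRESSION = 0
_STREAM_PATHWAYS = 1
_STREAM_DE = 2
_STREAM_CLUSTERS = 3
_STREAM_INTERACTOME = 4
_STREAM_MODULE = 5
_STREAM_DAG = 6
_STREAM_BATCH = 7

#: size of the dense interactome module planted over DE genes (also the
#: target set the planted drivers of the directed network must regulate)
PLANTED_MODULE_SIZE = 10
#: total node count of the generated directed gene network
DIRECTED_NETWORK_SIZE = 200
#: layer depth within which each planted driver covers the module
DRIVER_COVERAGE_DEPTH = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the merged-study design the generator emulates: 30 case
    and 23 control salivary-gland samples over 17,479 genes drawn from four
    source datasets (batches), scored against 26 curated pathways.  Effect
    magnitudes are in log2 units.
    """

    n_genes: int = 17479
    n_samples_per_group: tuple[int, int] = (30, 23)  # (case, control)
    n_batches: int = 4
    batch_shift_sd: float = 0.5
    n_de_genes: int = 400
    de_effect: float = 1.5
    n_pathways: int = 26
    pathway_size: tuple[int, int] = (15, 40)
    n_active_pathways_per_cluster: int = 6
    cluster_shift: float = 1.0
    interactome_attachment: int = 2
    n_planted_drivers: int = 3
    driver_fanout: int = 5
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        counts = {
            "n_genes": self.n_genes,
            "n_batches": self.n_batches,
            "n_de_genes": self.n_de_genes,
            "n_pathways": self.n_pathways,
            "n_planted_drivers": self.n_planted_drivers,
            "driver_fanout": self.driver_fanout,
            "interactome_attachment": self.interactome_attachment,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        n_case, n_control = self.n_samples_per_group
        if n_case < 1 or n_control < 1:
            raise ConfigError("both groups need at least one sample")
        if self.n_de_genes > self.n_genes:
            raise ConfigError(
                f"n_de_genes ({self.n_de_genes}) exceeds n_genes ({self.n_genes})"
            )
        lo, hi = self.pathway_size
        if lo < 5:
            raise ConfigError(f"pathway_size min must be >= 5, got {lo}")
        if lo > hi:
            raise ConfigError("pathway_size range is inverted")
        if hi > self.n_genes:
            raise ConfigError(
                f"pathway_size max ({hi}) exceeds gene universe ({self.n_genes})"
            )
        if 2 * self.n_active_pathways_per_cluster > self.n_pathways:
            raise ConfigError(
                "need n_pathways >= 2 * n_active_pathways_per_cluster "
                "(active pathway sets of the two clusters are disjoint)"
            )
        for name in ("batch_shift_sd", "de_effect", "cluster_shift", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        return self

    def rng(self, stream: int) -> np.random.Generator:
        """Per-component generator: independent stream under the global seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class TruthManifest:
    """Ground truth for everything the generator planted."""

    de_genes: dict[str, int] = field(default_factory=dict)  # gene -> +1 / -1
    cluster_labels: dict[str, int] = field(default_factory=dict)  # case sample -> 1/2
    active_pathways: dict[str, list[str]] = field(default_factory=dict)
    planted_module: list[str] = field(default_factory=list)
    planted_drivers: list[str] = field(default_factory=list)
    batch_labels: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "TruthManifest":
        return cls(
            de_genes={g: int(s) for g, s in payload.get("de_genes", {}).items()},
            cluster_labels={
                s: int(c) for s, c in payload.get("cluster_labels", {}).items()
            },
            active_pathways={
                k: list(v) for k, v in payload.get("active_pathways", {}).items()
            },
            planted_module=list(payload.get("planted_module", [])),
            planted_drivers=list(payload.get("planted_drivers", [])),
            batch_labels=dict(payload.get("batch_labels", {})),
        )


def gene_universe(config: SyntheticConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


# ---------------------------------------------------------------------------
# deterministic planted structure (shared across generator entry points)


def _pathway_membership(
    universe: list[str], config: SyntheticConfig
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Pathway gene memberships plus the two clusters' active pathways."""
    rng = config.rng(_STREAM_PATHWAYS)
    lo, hi = config.pathway_size
    width = len(str(config.n_pathways))
    sets: dict[str, list[str]] = {}
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"P{i + 1:0{width}d}"] = sorted(universe[j] for j in members)
    names = list(sets)
    chosen = rng.choice(
        len(names), size=2 * config.n_active_pathways_per_cluster, replace=False
    )
    k = config.n_active_pathways_per_cluster
    active = {
        "1": sorted(names[j] for j in chosen[:k]),
        "2": sorted(names[j] for j in chosen[k:]),
    }
    return sets, active


def _de_gene_signs(universe: list[str], config: SyntheticConfig) -> dict[str, int]:
    rng = config.rng(_STREAM_DE)
    idx = rng.choice(len(universe), size=config.n_de_genes, replace=False)
    genes = [universe[j] for j in idx]
    n_up = (config.n_de_genes + 1) // 2
    return {g: (1 if pos < n_up else -1) for pos, g in enumerate(genes)}


def _planted_module(universe: list[str], config: SyntheticConfig) -> list[str]:
    """Subset of *upregulated* DE genes that forms the dense module."""
    signs = _de_gene_signs(universe, config)
    up = sorted(g for g, s in signs.items() if s > 0)
    rng = config.rng(_STREAM_MODULE)
    size = min(PLANTED_MODULE_SIZE, len(up))
    idx = rng.choice(len(up), size=size, replace=False)
    return sorted(up[j] for j in idx)


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthManifest]:
    """Simulate the log2 expression matrix with planted DE and subgroups.

    Returns (matrix genes x samples, sample annotation, truth manifest).
    Case samples carry ``sign * de_effect`` on the planted DE genes; the two
    case subgroups additionally carry ``+cluster_shift`` on the member genes
    of their active pathways; every sample carries its batch's additive
    per-gene shift; i.i.d. Gaussian noise with sd ``noise_sd`` is added on
    top.
    """
    config.validate()
    universe = gene_universe(config)
    n_case, n_control = config.n_samples_per_group
    samples = [f"case_{i + 1:03d}" for i in range(n_case)] + [
        f"ctrl_{i + 1:03d}" for i in range(n_control)
    ]
    groups = ["case"] * n_case + ["control"] * n_control

    # interleaved batch assignment keeps every batch mixed in group
    batches = [f"batch{(i % config.n_batches) + 1}" for i in range(len(samples))]

    rng_expr = config.rng(_STREAM_EXPRESSION)
    baseline = rng_expr.normal(7.0, 1.0, size=config.n_genes)
    noise = rng_expr.normal(0.0, config.noise_sd, size=(config.n_genes, len(samples)))

    rng_batch = config.rng(_STREAM_BATCH)
    batch_shift = rng_batch.normal(
        0.0, config.batch_shift_sd, size=(config.n_genes, config.n_batches)
    )

    values = baseline[:, None] + noise
    batch_index = {f"batch{b + 1}": b for b in range(config.n_batches)}
    for j, batch in enumerate(batches):
        values[:, j] += batch_shift[:, batch_index[batch]]

    gene_pos = {g: i for i, g in enumerate(universe)}
    de_signs = _de_gene_signs(universe, config)
    de_rows = np.array([gene_pos[g] for g in de_signs])
    de_sign_vec = np.array([de_signs[g] for g in de_signs], dtype=float)
    case_cols = np.arange(n_case)
    if len(de_rows):
        values[np.ix_(de_rows, case_cols)] += (
            de_sign_vec[:, None] * config.de_effect
        )

    # two latent case subgroups via pathway-level shifts
    pathway_sets, active = _pathway_membership(universe, config)
    rng_cluster = config.rng(_STREAM_CLUSTERS)
    order = rng_cluster.permutation(n_case)
    half = (n_case + 1) // 2
    cluster_of = {}
    for rank, case_idx in enumerate(order):
        cluster_of[samples[case_idx]] = 1 if rank < half else 2
    for cluster_id in ("1", "2"):
        member_genes = sorted(
            {g for name in active[cluster_id] for g in pathway_sets[name]}
        )
        rows = np.array([gene_pos[g] for g in member_genes], dtype=int)
        cols = np.array(
            [j for j in range(n_case) if cluster_of[samples[j]] == int(cluster_id)],
            dtype=int,
        )
        if len(rows) and len(cols):
            values[np.ix_(rows, cols)] += config.cluster_shift

    matrix = pd.DataFrame(values, index=pd.Index(universe, name="gene_id"),
                          columns=samples)
    annotation = pd.DataFrame(
        {"sample_id": samples, "batch": batches, "group": groups}
    )
    manifest = TruthManifest(
        de_genes=dict(de_signs),
        cluster_labels=dict(cluster_of),
        active_pathways=active,
        batch_labels=dict(zip(samples, batches)),
    )
    return matrix, annotation, manifest


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    universe: list[str], config: SyntheticConfig
) -> GeneSetCollection:
    """The pathway collection whose member genes drive the planted subgroups."""
    config.validate()
    if not universe:
        raise ConfigError("gene universe is empty")
    if config.pathway_size[1] > len(universe):
        raise ConfigError("pathway_size max exceeds the gene universe")
    sets, _ = _pathway_membership(universe, config)
    return GeneSetCollection(
        sets={name: set(genes) for name, genes in sets.items()},
        descriptions={name: "synthetic pathway" for name in sets},
    )


# ---------------------------------------------------------------------------
# interactome


def generate_interactome(
    universe: list[str],
    config: SyntheticConfig,
    manifest: TruthManifest | None = None,
) -> nx.Graph:
    """Scale-free interactome with a planted near-clique over DE genes.

    Backbone: preferential attachment with ``interactome_attachment`` edges
    per incoming node (a tree when that is 1); on top of it the planted
    module genes are fully interconnected, so they dominate the degree ranks
    of the DE-induced subgraph.
    """
    config.validate()
    if len(universe) < 10:
        raise ConfigError("interactome needs a universe of >= 10 genes")
    rng = config.rng(_STREAM_INTERACTOME)
    seed_int = int(rng.integers(0, 2**31 - 1))
    m = min(config.interactome_attachment, len(universe) - 1)
    backbone = nx.barabasi_albert_graph(len(universe), m, seed=seed_int)
    # relabel preferential-attachment indices onto shuffled gene ids
    perm = rng.permutation(len(universe))
    mapping = {i: universe[perm[i]] for i in range(len(universe))}
    graph = nx.relabel_nodes(backbone, mapping)

    module = _planted_module(universe, config)
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            graph.add_edge(a, b)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    if manifest is not None:
        manifest.planted_module = list(module)
    return graph


# ---------------------------------------------------------------------------
# directed gene network


def generate_directed_network(
    universe: list[str],
    config: SyntheticConfig,
    manifest: TruthManifest | None = None,
) -> nx.DiGraph:
    """Layered DAG whose planted driver roots regulate the planted module.

    Each driver is a root wired to the module through a shared forward
    (topological) order, so its downstream neighborhood within
    ``DRIVER_COVERAGE_DEPTH`` layers covers the whole module; filler nodes
    carry sparse forward edges (and the occasional single edge into the
    module) so non-driver roots are not enriched.  Acyclicity holds by
    construction: all edges point forward in one global order.
    """
    config.validate()
    if config.n_planted_drivers < 1:
        raise ConfigError("need at least one planted driver")
    rng = config.rng(_STREAM_DAG)
    module = _planted_module(universe, config)
    if not module:
        raise ConfigError("planted module is empty; increase n_de_genes")

    non_module = [g for g in universe if g not in set(module)]
    drivers = sorted(
        non_module[j]
        for j in rng.choice(len(non_module), size=config.n_planted_drivers,
                            replace=False)
    )
    remaining = [g for g in non_module if g not in set(drivers)]
    n_filler = max(
        0, min(DIRECTED_NETWORK_SIZE - len(module) - len(drivers), len(remaining))
    )
    filler = [
        remaining[j]
        for j in rng.choice(len(remaining), size=n_filler, replace=False)
    ]

    net = nx.DiGraph()
    net.add_nodes_from(drivers + module + filler)

    # one global forward order over the module: heap-like branching so every
    # driver reaching the first `fanout` members reaches all within depth
    module_order = [module[j] for j in rng.permutation(len(module))]
    f = config.driver_fanout
    for i, parent in enumerate(module_order):
        for child in module_order[f + i * f : f + (i + 1) * f]:
            net.add_edge(parent, child)
    entry = module_order[:f]
    for driver in drivers:
        for child in entry:
            net.add_edge(driver, child)
        # a couple of driver-specific extra edges for wiring variety
        extra = rng.choice(len(module_order), size=min(2, len(module_order)),
                           replace=False)
        for j in extra:
            if module_order[j] != driver:
                net.add_edge(driver, module_order[j])

    # filler wiring: sparse forward edges so downstream sets stay small, and
    # rare single edges into *leaf* module members (no module children), so
    # no filler neighborhood accumulates target-set overlap via cascades
    module_leaves = [
        g for g in module_order if net.out_degree(g) == 0
    ] or module_order[-1:]
    filler_order = [filler[j] for j in rng.permutation(len(filler))]
    for i, node in enumerate(filler_order):
        n_children = int(rng.integers(0, 3))
        later = filler_order[i + 1 :]
        if later and n_children:
            picks = rng.choice(len(later), size=min(n_children, len(later)),
                               replace=False)
            for j in picks:
                net.add_edge(node, later[j])
        if rng.random() < 0.08:
            net.add_edge(node, module_leaves[int(rng.integers(len(module_leaves)))])

    net.remove_edges_from(nx.selfloop_edges(net))
    if not nx.is_directed_acyclic_graph(net):  # pragma: no cover - by construction
        raise RuntimeError("internal consistency error: generated network has a cycle")
    if manifest is not None:
        manifest.planted_drivers = list(drivers)
        if not manifest.planted_module:
            manifest.planted_module = list(module)
    return net


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SyntheticDataset:
    """Everything one synthetic study comprises."""

    matrix: pd.DataFrame
    annotation: pd.DataFrame
    gene_sets: GeneSetCollection
    interactome: nx.Graph
    directed_network: nx.DiGraph
    manifest: TruthManifest


def generate_all(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full input bundle for one synthetic study."""
    config.validate()
    universe = gene_universe(config)
    matrix, annotation, manifest = generate_expression(config)
    gene_sets = generate_gene_sets(universe, config)
    interactome = generate_interactome(universe, config, manifest)
    directed = generate_directed_network(universe, config, manifest)
    return SyntheticDataset(
        matrix=matrix,
        annotation=annotation,
        gene_sets=gene_sets,
        interactome=interactome,
        directed_network=directed,
        manifest=manifest,
    )
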