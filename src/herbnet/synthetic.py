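"""Synthetic inputs with the statistical structure the pipeline assumes.

Every upstream data source of the screening pipeline — a compound table with
ADME descriptors, a compound→target bipartite map, a disease target list, a
protein-interaction graph, a gene-set database and a two-group expression
matrix — is emulated here so the whole analysis is testable end to end
without any database access. Each generator plants known structure
(threshold-straddling ADME values, a controlled target overlap, a densely
wired hub module, over-represented gene sets, up/down-regulated genes) and
records it in a :class:`SyntheticTruth`, giving downstream stages a ground
truth to be checked against.

Determinism: one global seed fans out into named substreams (one per
generator), so the same config yields bit-identical outputs and adding a new
generator does not perturb the existing ones.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .adme import Component, write_components
from .errors import ConfigurationError

GENE_WIDTH = 4  # G0001-style tokens; widened automatically for big universes


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults matching the analysis
    conditions the pipeline is designed for (desk-scale instances)."""

    seed: int = 0
    # compound table
    n_components: int = 20
    ob_range: tuple[float, float] = (10.0, 60.0)  # percent; straddles the 30 cutoff
    dl_range: tuple[float, float] = (0.0, 0.5)  # unitless; straddles 0.18
    # target universe
    targets_per_component: tuple[int, int] = (5, 15)  # uniform integer range
    n_background_genes: int = 500
    n_disease_targets: int = 80
    overlap_fraction: float = 0.3
    # interaction graph
    background_model: str = "regular"  # "regular" | "er" | "pa"
    background_degree: int = 3  # regular-model degree
    edge_prob: float = 0.03  # ER edge probability
    pa_attachment: int = 2  # preferential-attachment edges per new node
    n_graph_background: int = 100
    hub_module_size: int = 5
    # gene-set database
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    n_planted_terms: int = 3
    planted_term_size: int = 10
    planted_hub_fraction: float = 0.8  # >= this fraction of a planted term is hubs
    # expression matrix
    n_genes: int = 500
    n_per_group: int = 4
    effect_log2: float = 4.0
    noise_sd: float = 0.5
    n_planted_up: int = 5
    n_planted_down: int = 5

    def validate(self) -> None:
        for name in ("ob_range", "dl_range", "targets_per_component", "term_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: min {lo} > max {hi}")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ConfigurationError("overlap_fraction must be in [0, 1]")
        if self.n_background_genes < self.n_disease_targets:
            raise ConfigurationError("universe smaller than the disease target list")
        if self.hub_module_size < 3:
            raise ConfigurationError("planted hub module needs at least 3 nodes")
        if self.n_graph_background + self.hub_module_size < 3 * self.hub_module_size:
            raise ConfigurationError("graph too small for the planted hub module")
        if self.background_model not in {"regular", "er", "pa"}:
            raise ConfigurationError(f"unknown background model {self.background_model!r}")
        if self.n_per_group < 2:
            raise ConfigurationError("need at least 2 samples per group")


@dataclass
class SyntheticTruth:
    """What was planted, for downstream recovery checks."""

    planted_hub_ids: set[str] = field(default_factory=set)
    planted_term_ids: set[str] = field(default_factory=set)
    planted_up: set[str] = field(default_factory=set)
    planted_down: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: sorted(v) for k, v in asdict(self).items()}, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(**{k: set(v) for k, v in d.items()})


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Named substream of the global seed (stable across generator additions)."""
    key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), key]))


def gene_universe(config: SimConfig) -> list[str]:
    width = max(GENE_WIDTH, len(str(config.n_background_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(config.n_background_genes)]


def gen_component_table(config: SimConfig) -> list[Component]:
    """Compound table with OB/DL drawn uniformly from the configured ranges.

    When a range straddles its screening threshold (30 for OB, 0.18 for DL)
    the draw is repeated (deterministically) until both sides of the
    threshold are represented, so the ADME filter always has work to do.
    """
    config.validate()
    rng = _rng(config, "components")
    n = config.n_components
    (ob_lo, ob_hi), (dl_lo, dl_hi) = config.ob_range, config.dl_range
    for _ in range(1000):
        ob = rng.uniform(ob_lo, ob_hi, size=n)
        dl = rng.uniform(dl_lo, dl_hi, size=n)
        ok = True
        if ob_lo < 30.0 < ob_hi and n >= 2:
            ok &= bool((ob > 30.0).any() and (ob <= 30.0).any())
        if dl_lo < 0.18 < dl_hi and n >= 2:
            ok &= bool((dl > 0.18).any() and (dl <= 0.18).any())
        if ok:
            break
    return [
        Component(f"C{i + 1:03d}", f"compound-{i + 1:03d}", round(float(ob[i]), 2), round(float(dl[i]), 3))
        for i in range(n)
    ]


def gen_target_universe(
    config: SimConfig,
    component_ids: list[str] | None = None,
    disease_symbols: list[str] | None = None,
) -> tuple[dict[str, set[str]], list[str], list[str]]:
    """(component→targets map, disease target list, universe).

    The intersection between the union of component targets and the disease
    list has size ``round(overlap_fraction * n_disease)`` exactly: overlap
    genes are sampled from the disease list and each is forced onto at least
    one component; non-overlap disease genes are excluded from the sampling
    pool. An explicit ``disease_symbols`` list (e.g. a published table) can
    replace the generated one; its symbols are added to the universe.
    """
    config.validate()
    rng = _rng(config, "targets")
    universe = gene_universe(config)
    if disease_symbols is not None:
        disease = sorted(dict.fromkeys(s.strip().upper() for s in disease_symbols if s.strip()))
        universe = sorted(set(universe) | set(disease))
    else:
        disease = sorted(rng.choice(universe, size=config.n_disease_targets, replace=False))
    n_overlap = round(config.overlap_fraction * len(disease))
    overlap = set(rng.choice(disease, size=n_overlap, replace=False)) if n_overlap else set()
    pool = sorted((set(universe) - set(disease)) | overlap)
    if component_ids is None:
        component_ids = [f"C{i + 1:03d}" for i in range(config.n_components)]
    lo, hi = config.targets_per_component
    if hi > len(pool):
        raise ConfigurationError("targets_per_component exceeds the sampling pool")
    mapping: dict[str, set[str]] = {}
    for cid in component_ids:
        size = int(rng.integers(lo, hi + 1))
        mapping[cid] = set(rng.choice(pool, size=size, replace=False))
    used = set().union(*mapping.values()) if mapping else set()
    for g in sorted(overlap - used):  # force every overlap gene onto some component
        cid = component_ids[int(rng.integers(len(component_ids)))]
        mapping[cid].add(g)
    for cid in component_ids:  # drop stray non-overlap disease genes (defensive)
        mapping[cid] -= set(disease) - overlap
    return mapping, disease, universe


def _background_graph(config: SimConfig, nodes: list[str], rng: np.random.Generator) -> nx.Graph:
    n = len(nodes)
    seed = int(rng.integers(2**31))
    if config.background_model == "regular":
        d = config.background_degree
        if d >= n or (d * n) % 2:
            raise ConfigurationError("infeasible regular-graph parameters")
        base = nx.random_regular_graph(d, n, seed=seed)
    elif config.background_model == "er":
        base = nx.gnp_random_graph(n, config.edge_prob, seed=seed)
    else:
        base = nx.barabasi_albert_graph(n, config.pa_attachment, seed=seed)
    return nx.relabel_nodes(base, dict(enumerate(nodes)))


def gen_ppi_with_planted_hubs(config: SimConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Interaction graph with an m-clique hub module wired above threshold.

    Background nodes are sampled from the gene universe and wired by the
    configured background model. The m planted nodes form a clique, and each
    is additionally wired to its own disjoint set of
    ``ceil(2 * median background degree) + 2`` background nodes — enough to
    clear the degree criterion (degree > 2 × median) with margin while the
    clique supplies the triangle-based measures. With the degree-concentrated
    regular background no background node can reach twice the median degree,
    so the screen recovers exactly the planted module.
    """
    config.validate()
    rng = _rng(config, "graph")
    m, n_bg = config.hub_module_size, config.n_graph_background
    universe = gene_universe(config)
    if n_bg + m > len(universe):
        raise ConfigurationError("graph larger than the gene universe")
    chosen = list(rng.choice(universe, size=n_bg + m, replace=False))
    bg_nodes, hub_nodes = chosen[:n_bg], chosen[n_bg:]
    g = _background_graph(config, bg_nodes, rng)
    med_bg = float(np.median([d for _, d in g.degree()]))
    wiring = math.ceil(2 * med_bg) + 2
    if m * wiring > n_bg:
        raise ConfigurationError(
            f"cannot wire {m} hubs to {wiring} disjoint background nodes each "
            f"(only {n_bg} background nodes)"
        )
    pool = list(rng.permutation(bg_nodes))
    for i, h in enumerate(hub_nodes):
        for other in hub_nodes[i + 1 :]:
            g.add_edge(h, other)
        for t in pool[i * wiring : (i + 1) * wiring]:
            g.add_edge(h, t)
    assert nx.number_of_selfloops(g) == 0
    return g, SyntheticTruth(planted_hub_ids=set(hub_nodes))


def gen_geneset_db(config: SimConfig, hub_ids: set[str]):
    """GMT-style database with terms planted to be hub-enriched.

    Random terms are drawn uniformly from the universe; each of the
    ``n_planted_terms`` planted terms has at least ``planted_hub_fraction``
    of its members drawn from ``hub_ids`` (term size shrinks if the hub list
    is small), making it detectably over-represented in a hub query.
    """
    # local import: enrichment depends only on types, avoid cycle at module load
    from .enrichment import CATEGORIES, GeneSet

    config.validate()
    if not hub_ids:
        raise ConfigurationError("hub_ids must be non-empty")
    rng = _rng(config, "genesets")
    universe = sorted(set(gene_universe(config)) | set(hub_ids))
    lo, hi = config.term_size_range
    if hi > len(universe):
        raise ConfigurationError("term size exceeds the universe")
    sets: list[GeneSet] = []
    cat_cycle = 0
    for i in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        cat = CATEGORIES[cat_cycle % len(CATEGORIES)]
        cat_cycle += 1
        sets.append(GeneSet(f"T{i + 1:04d}", cat, cat, members))
    hubs = sorted(hub_ids)
    non_hubs = sorted(set(universe) - hub_ids)
    planted_ids = set()
    for j in range(config.n_planted_terms):
        size = config.planted_term_size
        n_hub = min(math.ceil(config.planted_hub_fraction * size), len(hubs))
        size = min(size, math.floor(n_hub / config.planted_hub_fraction))
        chosen_hubs = list(rng.choice(hubs, size=n_hub, replace=False))
        filler = list(rng.choice(non_hubs, size=size - n_hub, replace=False))
        cat = CATEGORIES[cat_cycle % len(CATEGORIES)]
        cat_cycle += 1
        tid = f"PLANTED{j + 1:02d}"
        planted_ids.add(tid)
        sets.append(GeneSet(tid, cat, cat, frozenset(chosen_hubs + filler)))
    return sets, SyntheticTruth(planted_term_ids=planted_ids)


def gen_expression_matrix(config: SimConfig):
    """(matrix genes × samples, group labels, truth with planted up/down genes).

    Per-gene baselines are uniform on [5, 10] (log2-scale microarray-like);
    case samples of planted genes are shifted by ±``effect_log2``; iid
    Gaussian noise with sd ``noise_sd`` everywhere.
    """
    config.validate()
    rng = _rng(config, "expression")
    universe = gene_universe(config)
    genes = universe[: config.n_genes] if config.n_genes <= len(universe) else [
        f"G{i + 1:06d}" for i in range(config.n_genes)
    ]
    n_up, n_down = config.n_planted_up, config.n_planted_down
    planted = list(rng.choice(genes, size=n_up + n_down, replace=False))
    up, down = set(planted[:n_up]), set(planted[n_up:])
    npg = config.n_per_group
    samples = [f"ctrl_{i + 1}" for i in range(npg)] + [f"case_{i + 1}" for i in range(npg)]
    groups = pd.Series(["control"] * npg + ["case"] * npg, index=samples, name="group")
    base = rng.uniform(5.0, 10.0, size=len(genes))
    effect = np.zeros(len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in up:
        effect[gene_pos[g]] = config.effect_log2
    for g in down:
        effect[gene_pos[g]] = -config.effect_log2
    values = np.empty((len(genes), 2 * npg))
    values[:, :npg] = base[:, None]
    values[:, npg:] = (base + effect)[:, None]
    values += rng.normal(0.0, config.noise_sd, size=values.shape)
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    matrix.index.name = "gene"
    return matrix, groups, SyntheticTruth(planted_up=up, planted_down=down)


def write_bundle(
    config: SimConfig,
    outdir: str | Path,
    components: list[Component] | None = None,
    disease_symbols: list[str] | None = None,
) -> SyntheticTruth:
    """Generate every pipeline input into ``outdir`` and return the merged truth.

    Files written: components.tsv, targets.tsv, disease.tsv, network.sif,
    genesets.gmt, expression.tsv, groups.tsv, truth.json. Published compound
    or disease tables can be passed in to replace the generated ones (their
    ids/symbols are then used by the other generators).
    """
    from .enrichment import write_gmt
    from .topology import write_graph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if components is None:
        components = gen_component_table(config)
    write_components(components, outdir / "components.tsv")
    mapping, disease, _ = gen_target_universe(
        config, component_ids=[c.id for c in components], disease_symbols=disease_symbols
    )
    rows = [(cid, g) for cid in sorted(mapping) for g in sorted(mapping[cid])]
    pd.DataFrame(rows, columns=["component_id", "gene"]).to_csv(
        outdir / "targets.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene": disease}).to_csv(outdir / "disease.tsv", sep="\t", index=False)
    graph, truth = gen_ppi_with_planted_hubs(config)
    write_graph(graph, outdir / "network.sif")
    genesets, t2 = gen_geneset_db(config, truth.planted_hub_ids)
    write_gmt(genesets, outdir / "genesets.gmt")
    matrix, groups, t3 = gen_expression_matrix(config)
    matrix.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6g")
    groups.rename_axis("sample").reset_index().to_csv(outdir / "groups.tsv", sep="\t", index=False)
    truth.planted_term_ids = t2.planted_term_ids
    truth.planted_up, truth.planted_down = t3.planted_up, t3.planted_down
    truth.to_json(outdir / "truth.json")
    return truth
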