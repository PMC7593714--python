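"""End-to-end orchestration of the screening pipeline.

Stage order mirrors the screening workflow: ADME filter → target assembly →
graph centralities → hub screening → enrichment of the hub list →
expression validation. Every intermediate artifact is written to the output
directory with deterministic ordering, so two runs on identical inputs
produce byte-identical files. A stage failure aborts the run, naming the
stage; artifacts from earlier stages are retained for inspection.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import adme, enrichment, expression, hubs, targets, topology
from .errors import HerbnetError, PipelineError

log = logging.getLogger(__name__)

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    components: str
    targets: str
    disease: str
    network: str
    genesets: str
    expression: str | None = None
    groups: str | None = None
    ct_table: str | None = None
    outdir: str = "herbnet_out"
    ob_min: float = adme.OB_MIN_DEFAULT
    dl_min: float = adme.DL_MIN_DEFAULT
    degree_factor: float = 2.0
    alpha: float = 0.05
    adjust: str = "none"  # enrichment significance on raw p by default
    background: str = "auto"
    expression_alpha: float = 0.05
    genes_of_interest: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise HerbnetError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        missing = {"components", "targets", "disease", "network", "genesets"} - set(raw)
        if missing:
            raise HerbnetError(f"config missing required keys: {sorted(missing)}")
        return cls(**raw)


@dataclass
class RunReport:
    config: dict
    version: str = VERSION
    components_in: int = 0
    components_retained: int = 0
    n_component_targets: int = 0
    disease_entries: int = 0
    disease_unique: int = 0
    n_common: int = 0
    n_component_only: int = 0
    n_disease_only: int = 0
    n_nodes: int = 0
    n_edges: int = 0
    n_hubs: int = 0
    n_hub_edges: int = 0
    n_significant_terms: int = 0
    terms_per_category: dict = field(default_factory=dict)
    de_calls: dict = field(default_factory=dict)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except (HerbnetError, OSError) as e:
                raise PipelineError(name, str(e)) from e
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))

    @_stage("adme_screen")
    def s_adme():
        comps = adme.read_components(config.components)
        retained = adme.apply_adme_filter(comps, config.ob_min, config.dl_min)
        adme.write_components(retained, outdir / "retained.tsv")
        adme.write_summary(len(comps), retained, outdir / "adme_summary.json")
        report.components_in, report.components_retained = len(comps), len(retained)
        return retained

    @_stage("target_assembly")
    def s_targets():
        mapping = targets.read_target_map(config.targets)
        comp_targets = set().union(*mapping.values()) if mapping else set()
        disease_table = targets.read_gene_table(config.disease)
        n_cells, n_unique = targets.count_table_entries(disease_table)
        disease_set, _ = targets.normalize_symbols(disease_table.to_numpy().ravel())
        common, comp_only, dis_only = targets.venn_partition(comp_targets, disease_set)
        targets.write_venn(common, comp_only, dis_only, outdir / "venn.json")
        targets.write_symbol_list(common, outdir / "common_targets.txt")
        report.n_component_targets = len(comp_targets)
        report.disease_entries, report.disease_unique = n_cells, n_unique
        report.n_common, report.n_component_only, report.n_disease_only = (
            len(common),
            len(comp_only),
            len(dis_only),
        )

    @_stage("graph_topology")
    def s_topology():
        g = topology.load_graph(config.network)
        ct = topology.centrality_table(g)
        topology.write_centrality(ct, outdir / "centrality.tsv", outdir / "medians.json")
        report.n_nodes, report.n_edges = g.number_of_nodes(), g.number_of_edges()
        return g, ct

    @_stage("hub_screening")
    def s_hubs(g, ct):
        res = hubs.screen_hubs(ct, config.degree_factor)
        subnet = hubs.hub_subnetwork(g, res.hubs)
        targets.write_symbol_list(set(res.hubs), outdir / "hubs.txt")
        (outdir / "hubs_ranked.txt").write_text("".join(h + "\n" for h in res.hubs))
        topology.write_graph(subnet, outdir / "hub_network.sif")
        hubs.write_screening_report(g, res, subnet, outdir / "screening_report.json")
        report.n_hubs, report.n_hub_edges = len(res.hubs), subnet.number_of_edges()
        return res

    @_stage("enrichment")
    def s_enrich(res):
        db = enrichment.read_gmt(config.genesets)
        results = enrichment.hypergeom_enrich(set(res.hubs), db, background=config.background)
        if config.adjust != "none":
            enrichment.adjust_results(results, config.adjust)
        on = "p_adj" if config.adjust != "none" else "p_raw"
        sig, counts = enrichment.significant_terms(results, config.alpha, on=on)
        enrichment.write_enrichment(results, outdir / "enrichment.tsv")
        enrichment.write_category_counts(counts, outdir / "counts.json")
        report.n_significant_terms = len(sig)
        report.terms_per_category = counts

    @_stage("expression_analysis")
    def s_expression(res):
        if not (config.expression and config.groups):
            return
        matrix = expression.read_expression(config.expression)
        groups = expression.read_groups(config.groups)
        goi = config.genes_of_interest or list(res.hubs)
        table, skipped = expression.fold_direction_report(
            matrix, groups, goi, alpha=config.expression_alpha
        )
        table.to_csv(outdir / "de_results.tsv", sep="\t", float_format="%.6g")
        if skipped:
            log.info("expression: %d genes of interest absent from matrix", len(skipped))
        counts = table["direction"].value_counts().to_dict()
        report.de_calls = {k: int(counts.get(k, 0)) for k in ("up", "down", "ns")}
        if config.ct_table:
            rel = expression.delta_delta_ct(expression.read_ct_table(config.ct_table))
            rel.to_csv(outdir / "relexpr.tsv", sep="\t", float_format="%.6g")

    s_adme()
    s_targets()
    g, ct = s_topology()
    res = s_hubs(g, ct)
    s_enrich(res)
    s_expression(res)
    write_report(report, outdir / "report.json", fmt="json")
    write_report(report, outdir / "report.md", fmt="markdown")
    return report


def write_report(report: RunReport, path: str | Path, fmt: str = "json") -> None:
    """JSON is the source of truth; markdown is rendered from the same dict."""
    d = asdict(report)
    if fmt == "json":
        Path(path).write_text(json.dumps(d, sort_keys=True, indent=1) + "\n")
        return
    lines = ["# Screening run report", ""]
    for key in sorted(d):
        if key == "config":
            continue
        lines.append(f"- **{key}**: {d[key]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> RunReport:
    d = json.loads(Path(path).read_text())
    return RunReport(**d)
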