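"""Fixture-seeded demonstration bundle.

Builds a complete pipeline input directory from the packaged worked-example
tables (the 11-compound ADME table and the 259-entry disease-target grid)
plus synthetic targets, network, gene sets and expression data generated
from one seed. The published disease grid is kept verbatim (duplicates
included) so the pipeline reports both the raw entry count and the
deduplicated one, while the generated compound→target map realises the
configured overlap against the deduplicated symbols.
"""

from __future__ import annotations

import shutil
from pathlib import Path

from . import datasets, synthetic
from .adme import read_components
from .pipeline import PipelineConfig


def make_demo_bundle(
    bundle_dir: str | Path, seed: int = 7, config: synthetic.SimConfig | None = None
) -> Path:
    bundle = Path(bundle_dir)
    cfg = config or synthetic.SimConfig(seed=seed)
    cfg.seed = seed
    comps = read_components(datasets.pinellia_components_path())
    cells = [
        str(c)
        for c in datasets.load_asthma_target_table().to_numpy().ravel()
        if isinstance(c, str) and c.strip()
    ]
    synthetic.write_bundle(cfg, bundle, components=comps, disease_symbols=cells)
    # keep the published grid as the disease table (pre-deduplication counts)
    shutil.copyfile(datasets.asthma_targets_path(), bundle / "disease.tsv")
    return bundle


def make_demo_config(bundle_dir: str | Path, outdir: str | Path, seed: int = 7) -> PipelineConfig:
    bundle = Path(bundle_dir)
    return PipelineConfig(
        components=str(bundle / "components.tsv"),
        targets=str(bundle / "targets.tsv"),
        disease=str(bundle / "disease.tsv"),
        network=str(bundle / "network.sif"),
        genesets=str(bundle / "genesets.gmt"),
        expression=str(bundle / "expression.tsv"),
        groups=str(bundle / "groups.tsv"),
        outdir=str(outdir),
        seed=seed,
    )
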