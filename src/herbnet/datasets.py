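"""Packaged worked-example tables.

Two small published tables ship with the package: the ADME descriptor table
of the 11 screened *Pinellia ternata* compounds and the 259-entry
asthma-target table. They drive the worked examples and the fixture-based
pipeline demo.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .adme import Component, read_components
from .targets import read_gene_table


def _data(name: str):
    return files("herbnet.data").joinpath(name)


def pinellia_components_path() -> str:
    return str(_data("pinellia_components.tsv"))


def asthma_targets_path() -> str:
    return str(_data("asthma_targets.tsv"))


def load_pinellia_components() -> list[Component]:
    """The 11 ADME-screened compounds (id, name, OB %, DL)."""
    return read_components(pinellia_components_path())


def load_asthma_target_table() -> pd.DataFrame:
    """The asthma-target table as the published grid (259 non-empty cells)."""
    return read_gene_table(asthma_targets_path())
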