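"""Assembly of compound-derived and disease-derived target gene sets.

Target lists arriving from pharmacophore mapping and from disease-gene
databases use inconsistent casing and contain duplicates. Symbols are
normalised (uppercase, stripped, deduplicated; punctuation such as hyphens is
preserved — no alias resolution is attempted) and the two lists are merged
into a three-way Venn partition: common targets, compound-only targets and
disease-only targets. The common set is the candidate pool for the downstream
interaction-network analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class TargetSet:
    label: str  # one of {"component", "disease", "common"}
    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self):
        if self.label not in {"component", "disease", "common"}:
            raise ValueError(f"unknown target-set label {self.label!r}")


def normalize_symbols(raw) -> tuple[set[str], int]:
    """Uppercase, strip whitespace, drop empties, collapse duplicates.

    Returns the normalised set and the number of duplicates collapsed
    (occurrences beyond the first of each normalised symbol).
    """
    out: set[str] = set()
    dupes = 0
    for s in raw:
        if s is None or (isinstance(s, float) and pd.isna(s)):
            continue
        sym = str(s).strip().upper()
        if not sym:
            continue
        if sym in out:
            dupes += 1
        else:
            out.add(sym)
    return out, dupes


def venn_partition(
    component_targets: set[str], disease_targets: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """(common, component_only, disease_only): disjoint, union = input union."""
    common = component_targets & disease_targets
    return common, component_targets - common, disease_targets - common


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a gene table laid out as a TSV grid (any number of columns).

    A single-column file whose first cell is a 'gene' header has the header
    dropped; multi-column grids (as printed in publications) are taken as-is.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, skip_blank_lines=True)
    if df.shape[1] == 1 and len(df) and str(df.iloc[0, 0]).strip().lower() == "gene":
        df = df.iloc[1:].reset_index(drop=True)
    return df


def count_table_entries(table: pd.DataFrame) -> tuple[int, int]:
    """(non-empty cell count, deduplicated symbol count) of a gene-table grid.

    The raw cell count is what a published table reports before duplicate
    entries are removed; both counts are surfaced.
    """
    cells = [
        v
        for v in table.to_numpy().ravel()
        if v is not None and not pd.isna(v) and str(v).strip()
    ]
    unique, _ = normalize_symbols(cells)
    return len(cells), len(unique)


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    """Read a compound→target bipartite map (TSV: component_id, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    cid, gene = cols.get("component_id", df.columns[0]), cols.get("gene", df.columns[1])
    mapping: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        genes, _ = normalize_symbols([row[gene]])
        mapping.setdefault(str(row[cid]), set()).update(genes)
    return mapping


def write_venn(
    common: set[str], component_only: set[str], disease_only: set[str], path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "common": sorted(common),
                "component_only": sorted(component_only),
                "disease_only": sorted(disease_only),
            },
            indent=1,
        )
        + "\n"
    )


def write_symbol_list(genes: set[str], path: str | Path) -> None:
    """One symbol per line, sorted."""
    Path(path).write_text("".join(g + "\n" for g in sorted(genes)))
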