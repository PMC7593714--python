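"""ADME screening of candidate herbal compounds.

Candidate compounds exported from a systems-pharmacology database carry two
pharmacokinetic descriptors: oral bioavailability (OB, percent of an oral
dose reaching systemic circulation) and drug-likeness (DL, a unitless
structural similarity to known drugs). The screen retains a compound only if
it is strictly above both thresholds (OB > 30 %, DL > 0.18), the standard
cutoffs used in network-pharmacology studies of herbal formulae.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import EmptyInputError, ValidationError

OB_MIN_DEFAULT = 30.0
DL_MIN_DEFAULT = 0.18


@dataclass(frozen=True)
class Component:
    """One candidate compound with its ADME descriptors.

    ``ob`` is on the percent scale (30.7 means 30.7 %, never a fraction);
    ``dl`` is a unitless score, typically in [0, 1].
    """

    id: str
    name: str
    ob: float
    dl: float

    def __post_init__(self):
        if not self.id:
            raise ValidationError("component id must be non-empty")


def read_components(path: str | Path) -> list[Component]:
    """Read a compound table (TSV with columns id, name, OB, DL).

    Column matching is case-insensitive. OB values above 100 % are suspicious
    (the scale may be wrong) and trigger a warning, not an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    for req in ("id", "name", "ob", "dl"):
        if req not in cols:
            raise ValidationError(f"{path}: missing required column '{req}'")
    out = []
    for i, row in df.iterrows():
        ob, dl = row[cols["ob"]], row[cols["dl"]]
        if pd.isna(ob) or pd.isna(dl):
            raise ValidationError(f"{path}: row {i} ({row[cols['id']]}): missing OB or DL")
        out.append(Component(str(row[cols["id"]]), str(row[cols["name"]]), float(ob), float(dl)))
    return out


def write_components(components: list[Component], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.id, c.name, c.ob, c.dl) for c in components],
        columns=["id", "name", "OB", "DL"],
    )
    df.to_csv(path, sep="\t", index=False)


def apply_adme_filter(
    components: list[Component],
    ob_min: float = OB_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
) -> list[Component]:
    """Retain components with ob > ob_min AND dl > dl_min (both strict).

    Input order is preserved and the input list is not modified. Missing or
    NaN descriptors raise :class:`ValidationError` naming the offending row.
    """
    if not (math.isfinite(ob_min) and math.isfinite(dl_min)):
        raise ValidationError("thresholds must be finite")
    for c in components:
        if math.isnan(c.ob) or math.isnan(c.dl):
            raise ValidationError(f"component '{c.id}': OB/DL missing or NaN")
        if c.ob > 100.0:
            warnings.warn(f"component '{c.id}': OB {c.ob} exceeds 100 %", stacklevel=2)
    return [c for c in components if c.ob > ob_min and c.dl > dl_min]


def adme_summary(retained: list[Component]) -> tuple[float, float, float, float]:
    """Componentwise extrema (min_ob, max_ob, min_dl, max_dl) of a retained set."""
    if not retained:
        raise EmptyInputError("cannot summarise an empty component set")
    obs = [c.ob for c in retained]
    dls = [c.dl for c in retained]
    return (min(obs), max(obs), min(dls), max(dls))


def write_summary(n_in: int, retained: list[Component], path: str | Path) -> None:
    """One-line JSON summary {n_in, n_out, extrema} next to the retained table."""
    if retained:
        extrema = dict(zip(("min_ob", "max_ob", "min_dl", "max_dl"), adme_summary(retained)))
    else:
        extrema = None
    Path(path).write_text(
        json.dumps({"n_in": n_in, "n_out": len(retained), "extrema": extrema}, sort_keys=True)
        + "\n"
    )
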