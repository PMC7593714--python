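"""Expression-validation statistics.

Two independent checks that nominated targets behave as expected in
expression data:

* a two-group comparison of a (log-scale) expression matrix, gene by gene,
  with Welch's unequal-variance t test — emulating the case/control contrast
  one runs on a public expression series; and
* relative qPCR quantification by the comparative-Ct method, 2^-ΔΔCt, with a
  reference gene per sample and the control-group mean ΔCt as calibrator.

Expression values are assumed already normalised/log-scale; no preprocessing
pipeline is included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

GROUPS = ("control", "case")


@dataclass
class DEResult:
    gene: str
    mean_control: float
    mean_case: float
    diff: float  # case - control, log-scale difference
    t: float
    p: float


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes × samples TSV; first column gene symbols, header sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_groups(path: str | Path) -> pd.Series:
    """TSV with columns sample, group; group values 'control'/'case'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    bad = sorted(set(s) - set(GROUPS))
    if bad:
        raise ValidationError(f"unknown group labels {bad}; expected {GROUPS}")
    return s


def _split(matrix: pd.DataFrame, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    ctrl = [s for s in matrix.columns if groups.get(s) == "control"]
    case = [s for s in matrix.columns if groups.get(s) == "case"]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValidationError("each group needs at least 2 samples")
    return matrix[ctrl].to_numpy(float), matrix[case].to_numpy(float)


def welch_compare(matrix: pd.DataFrame, groups: pd.Series, gene: str) -> DEResult:
    """Welch two-sided t test of case vs control for one gene.

    The sign of ``diff`` (case − control) carries the direction. Zero
    variance in both groups is statistically degenerate and raises.
    """
    if gene not in matrix.index:
        raise ValidationError(f"gene {gene!r} not in matrix")
    ctrl, case = _split(matrix.loc[[gene]], groups)
    a, b = ctrl.ravel(), case.ravel()
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        raise DegenerateInputError(f"gene {gene!r}: zero variance in both groups")
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return DEResult(
        gene=gene,
        mean_control=float(np.mean(a)),
        mean_case=float(np.mean(b)),
        diff=float(np.mean(b) - np.mean(a)),
        t=float(t),
        p=float(p),
    )


def welch_table(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Vectorised Welch test for every gene; columns mean_ctrl, mean_case, diff, t, p."""
    ctrl, case = _split(matrix, groups)
    t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    out = pd.DataFrame(
        {
            "mean_ctrl": ctrl.mean(axis=1),
            "mean_case": case.mean(axis=1),
            "diff": case.mean(axis=1) - ctrl.mean(axis=1),
            "t": t,
            "p": p,
        },
        index=matrix.index,
    )
    out.index.name = "gene"
    return out


def fold_direction_report(
    matrix: pd.DataFrame,
    groups: pd.Series,
    genes_of_interest,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene call up/down/ns at strict p < alpha; unknown genes are skipped.

    Returns (table, skipped). The table has one row per known gene with
    columns mean_ctrl, mean_case, diff, t, p, direction.
    """
    known = [g for g in genes_of_interest if g in matrix.index]
    skipped = [g for g in genes_of_interest if g not in matrix.index]
    rows = []
    for g in known:
        r = welch_compare(matrix, groups, g)
        if r.p < alpha:
            direction = "up" if r.diff > 0 else "down"
        else:
            direction = "ns"
        rows.append((g, r.mean_control, r.mean_case, r.diff, r.t, r.p, direction))
    table = pd.DataFrame(
        rows, columns=["gene", "mean_ctrl", "mean_case", "diff", "t", "p", "direction"]
    ).set_index("gene")
    return table, skipped


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample, group, gene, ct; gene is 'target' or 'reference'."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "gene": str})
    need = {"sample", "group", "gene", "ct"}
    if not need <= set(df.columns):
        raise ValidationError(f"Ct table needs columns {sorted(need)}")
    return df


def delta_delta_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative expression by the comparative-Ct (2^-ΔΔCt) method.

    ΔCt_s = Ct(target, s) − Ct(reference, s); the calibrator is the
    arithmetic mean ΔCt over control samples; relative expression is
    2^−(ΔCt_s − calibrator). By construction the geometric mean of the
    control group's relative expression is exactly 1.
    """
    piv = ct.pivot_table(index="sample", columns="gene", values="ct", aggfunc="first")
    groups = ct.drop_duplicates("sample").set_index("sample")["group"]
    missing = sorted(
        set(piv.index) - set(piv.index[piv.get("reference", pd.Series(dtype=float)).notna()])
        if "reference" in piv
        else set(piv.index)
    )
    if "target" not in piv or piv["target"].isna().any():
        bad = sorted(piv.index[piv["target"].isna()]) if "target" in piv else sorted(piv.index)
        raise ValidationError(f"missing target Ct for samples: {bad}")
    if missing:
        raise ValidationError(f"missing reference Ct for samples: {missing}")
    dct = piv["target"] - piv["reference"]
    controls = [s for s in dct.index if groups.get(s) == "control"]
    if not controls:
        raise ValidationError("no control samples to calibrate against")
    calibrator = float(dct.loc[controls].mean())
    rel = np.power(2.0, -(dct - calibrator))
    out = pd.DataFrame(
        {"group": [groups[s] for s in dct.index], "delta_ct": dct, "rel_expr": rel}
    )
    out.index.name = "sample"
    return out


def group_summary(rel: pd.DataFrame) -> pd.DataFrame:
    """Group mean ± SEM of relative expression (as reported in qPCR figures)."""
    g = rel.groupby("group")["rel_expr"]
    return pd.DataFrame({"mean": g.mean(), "sem": g.sem(), "n": g.size()})
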