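"""Hypergeometric over-representation analysis of a gene list.

Given a query list (e.g. screened hub genes), a gene-set database (GMT) and
a background universe, each term is scored with the one-sided hypergeometric
upper tail: with N background genes, K of which belong to the term, and a
query of n background genes hitting the term k times,

    p_raw = P(X >= k),   X ~ Hypergeometric(N, K, n).

Tails are computed exactly through scipy's log-gamma implementation, no
normal approximation. The default background is the union of all gene-set
members ("auto"), which is reproducible; an explicit universe can be given.
An EASE-style conservative variant (testing k-1 instead of k, as some
annotation servers do) is available behind a flag, off by default.
Benjamini–Hochberg adjustment is optional; the default significance filter
uses raw p < alpha.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError

CATEGORIES = ("BP", "MF", "CC", "KEGG")

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    category: str  # one of CATEGORIES
    members: frozenset[str]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"term {self.term_id}: unknown category {self.category!r}")
        if not self.members:
            raise ValidationError(f"term {self.term_id}: empty member set")


@dataclass
class EnrichmentResult:
    term_id: str
    category: str
    k: int  # query hits in the term
    K: int  # term size within the background
    n: int  # query size within the background
    N: int  # background size
    p_raw: float
    p_adj: float
    hit_symbols: frozenset[str]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: ``term<TAB>description<TAB>member...`` per line.

    The category is taken from the description field when it is one of
    BP/MF/CC/KEGG (or a ``CAT|...`` prefix); otherwise BP is assumed.
    """
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            desc = fields[1]
            cat = desc.split("|", 1)[0].strip()
            if cat not in CATEGORIES:
                cat = "BP"
            members = frozenset(m.strip().upper() for m in fields[2:] if m.strip())
            sets.append(GeneSet(fields[0], desc, cat, members))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.name, *sorted(s.members)]) + "\n")


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: set[str],
    db: list[GeneSet],
    background: set[str] | str = "auto",
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Score every term in ``db`` against ``query``; sorted by ascending p_raw.

    Query genes outside the background are dropped (count logged). Raw
    p-values are returned with ``p_adj`` initialised equal to ``p_raw``;
    apply :func:`adjust_results` for BH adjustment.
    """
    if background == "auto":
        bg: set[str] = set()
        for s in db:
            bg |= s.members
    else:
        bg = set(background)
    if not bg:
        raise ConfigurationError("background universe is empty")
    q = {g.strip().upper() for g in query}
    dropped = q - bg
    if dropped:
        log.info("dropping %d query genes outside the background", len(dropped))
    q &= bg
    N, n = len(bg), len(q)
    results = []
    for s in db:
        members = s.members & bg
        hits = q & members
        k, K = len(hits), len(members)
        kk = max(k - 1, 0) if ease else k
        results.append(
            EnrichmentResult(
                term_id=s.term_id,
                category=s.category,
                k=k,
                K=K,
                n=n,
                N=N,
                p_raw=hypergeom_tail(kk, N, K, n),
                p_adj=hypergeom_tail(kk, N, K, n),
                hit_symbols=frozenset(hits),
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def adjust_pvalues(p: list[float], method: str = "BH") -> list[float]:
    """Multiple-testing adjustment: 'none' (identity) or 'BH' step-up."""
    for v in p:
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"p-value {v} outside [0, 1]")
    if method == "none" or not p:
        return list(p)
    if method != "BH":
        raise ConfigurationError(f"unknown adjustment method {method!r}")
    return list(multipletests(p, method="fdr_bh")[1])


def adjust_results(results: list[EnrichmentResult], method: str = "BH") -> list[EnrichmentResult]:
    adj = adjust_pvalues([r.p_raw for r in results], method)
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


def significant_terms(
    results: list[EnrichmentResult], alpha: float = 0.05, on: str = "p_raw"
) -> tuple[list[EnrichmentResult], dict[str, int]]:
    """Strict filter p < alpha on p_raw or p_adj, plus per-category counts."""
    if on not in {"p_raw", "p_adj"}:
        raise ConfigurationError(f"unknown significance column {on!r}")
    sig = [r for r in results if getattr(r, on) < alpha]
    counts = {c: 0 for c in CATEGORIES}
    for r in sig:
        counts[r.category] += 1
    return sig, counts


def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    rows = [
        (r.term_id, r.category, r.k, r.K, r.n, r.N, r.p_raw, r.p_adj, ",".join(sorted(r.hit_symbols)))
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["term_id", "category", "k", "K", "n", "N", "p_raw", "p_adj", "hits"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_category_counts(counts: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(counts, sort_keys=True) + "\n")
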