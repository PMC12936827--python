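"""Hypergeometric over-representation analysis against GMT term sets.

A query protein set (e.g. the screen's core) is tested against every term
of a user-supplied GMT collection: with N annotated background proteins, K
of them in the term, and a query of n annotated proteins hitting k, the
enrichment p-value is the upper tail P(X >= k) of Hypergeometric(N, K, n).
By the default annotation-restricted convention, the background universe
counts only proteins carrying at least one annotation in the loaded
collection, which keeps the urn well-defined; the full input background is
available by flag.  Benjamini-Hochberg q-values are reported across the
tested terms.

The intersectional comparison partitions the significant terms of several
query sets into their Venn regions (shared-by-all first).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "TermSet",
    "EnrichmentRecord",
    "read_gmt",
    "hypergeom_tail",
    "hypergeom_ora",
    "intersect_enrichments",
    "enrichment_frame",
]


@dataclass(frozen=True)
class TermSet:
    """One annotation term with its member gene symbols (upper-cased)."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric over-representation outcome for one term."""

    term_id: str
    term_name: str
    k: int  # query hits in the term
    K: int  # annotated background members of the term
    n: int  # annotated query size
    N: int  # annotated background size
    p: float
    q: float = float("nan")


def read_gmt(path: str | Path) -> list[TermSet]:
    """Parse a standard GMT file (term, description, members...).

    Members are upper-cased for matching; duplicate members within a term
    are deduplicated (logged); a duplicate term id is a hard error.
    """
    path = Path(path)
    terms: list[TermSet] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                )
            term_id, term_name, *members = fields
            if term_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
            seen.add(term_id)
            members = [m.strip().upper() for m in members if m.strip()]
            if len(members) != len(set(members)):
                logger.info("term %s: duplicate members deduplicated", term_id)
            terms.append(TermSet(term_id=term_id, term_name=term_name, members=frozenset(members)))
    return terms


def hypergeom_tail(k, N, K, n):
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n); vectorised.

    sf(k - 1) is exact on the integer support, so k = 0 gives 1.
    """
    return stats.hypergeom.sf(np.asarray(k) - 1, N, K, n)


def hypergeom_ora(
    query: set[str],
    background: set[str],
    terms: list[TermSet],
    alpha: float = 0.05,
    restrict_to_annotated: bool = True,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric enrichment of a query set per term.

    The query must be a subset of the background.  With the default
    annotation-restricted universe, N and n count only proteins that belong
    to at least one term of the collection; terms with no annotated
    background member (K = 0) are skipped.
    """
    query = {g.upper() for g in query}
    background = {g.upper() for g in background}
    stray = query - background
    if stray:
        raise ValueError(f"query protein(s) outside the background: {sorted(stray)}")

    if restrict_to_annotated:
        annotated = set().union(*(t.members for t in terms)) if terms else set()
        universe = background & annotated
    else:
        universe = background
    q_ann = query & universe
    N, n = len(universe), len(q_ann)

    records: list[EnrichmentRecord] = []
    for t in terms:
        members = t.members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(q_ann & members)
        p = float(hypergeom_tail(k, N, K, n)) if n else 1.0
        records.append(EnrichmentRecord(t.term_id, t.term_name, k, K, n, N, min(p, 1.0)))

    qvals = bh_fdr([r.p for r in records])
    records = [
        EnrichmentRecord(r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p, float(qv))
        for r, qv in zip(records, qvals)
    ]
    return sorted(records, key=lambda r: (r.p, r.term_id))


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "term_name": [r.term_name for r in records],
            "k": [r.k for r in records],
            "K": [r.K for r in records],
            "n": [r.n for r in records],
            "N": [r.N for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
        }
    )


def intersect_enrichments(
    results: dict[str, list[EnrichmentRecord]] | list[list[EnrichmentRecord]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Venn partition of the significant terms across several result tables.

    Significance for region membership is raw p < alpha (q is reported in
    the per-table output).  Returns one row per non-empty Venn region, the
    all-shared region first, then by decreasing region size.
    """
    if isinstance(results, dict):
        names = list(results)
        tables = [results[k] for k in names]
    else:
        names = [f"set{i + 1}" for i in range(len(results))]
        tables = list(results)
    if len(tables) < 2:
        raise ValueError("need at least 2 enrichment tables to intersect")

    sig = [frozenset(r.term_id for r in tab if r.p < alpha) for tab in tables]
    union = set().union(*sig)
    regions: dict[tuple[str, ...], set[str]] = {}
    for term in union:
        membership = tuple(name for name, s in zip(names, sig) if term in s)
        regions.setdefault(membership, set()).add(term)

    def sort_key(item):
        membership, terms = item
        return (-len(membership), -len(terms), membership)

    rows = []
    for membership, terms in sorted(regions.items(), key=sort_key):
        rows.append(
            {
                "region": "&".join(membership),
                "n_sets": len(membership),
                "count": len(terms),
                "terms": ";".join(sorted(terms)),
            }
        )
    return pd.DataFrame(rows, columns=["region", "n_sets", "count", "terms"])
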