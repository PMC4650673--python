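"""Hypergeometric over-representation of GO terms and KEGG pathways.

With N annotated elements in the background, n of them differentially
expressed, M annotated to a term and m of those differential, the enrichment
p-value is the exact upper tail

    P(X >= m) = sum_{i=m..min(n,M)} C(M,i) C(N-M, n-i) / C(N,n),

followed by a Bonferroni correction over the tested terms. The background is
restricted to annotated elements; terms without any differential member are
not tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

NAMESPACES = (
    "GO:biological_process",
    "GO:cellular_component",
    "GO:molecular_function",
    "KEGG",
)


@dataclass
class AnnotationCatalog:
    """term_id -> member-set map with display names and namespaces."""

    members: Mapping[str, frozenset]
    names: Mapping[str, str] = field(default_factory=dict)
    namespaces: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term, mem in self.members.items():
            if not mem:
                raise ValueError(f"term {term} has no members")

    @property
    def background(self) -> frozenset:
        """Union of all annotated elements."""
        out: set = set()
        for mem in self.members.values():
            out |= mem
        return frozenset(out)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "AnnotationCatalog":
        """Build from a long table ``element_id, term_id, term_name, namespace``."""
        required = {"element_id", "term_id", "term_name", "namespace"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        members: dict[str, set] = {}
        names: dict[str, str] = {}
        namespaces: dict[str, str] = {}
        for row in table.itertuples(index=False):
            members.setdefault(row.term_id, set()).add(str(row.element_id))
            names[row.term_id] = str(row.term_name)
            namespaces[row.term_id] = str(row.namespace)
        return cls(
            {t: frozenset(m) for t, m in members.items()}, names, namespaces
        )

    def to_table(self) -> pd.DataFrame:
        rows = [
            (el, term, self.names.get(term, term), self.namespaces.get(term, "KEGG"))
            for term in sorted(self.members)
            for el in sorted(self.members[term])
        ]
        return pd.DataFrame(
            rows, columns=["element_id", "term_id", "term_name", "namespace"]
        )


def hypergeom_upper_tail(m: int, M: int, n: int, N: int) -> float:
    """Exact P(X >= m) for X ~ Hypergeom(N population, M marked, n drawn)."""
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= M, n <= N; got M={M}, n={n}, N={N}")
    if not (0 <= m <= min(n, M)):
        raise ValueError(f"require 0 <= m <= min(n, M); got m={m}, M={M}, n={n}")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def bonferroni_adjust(p_raws: Sequence[float], k: int) -> np.ndarray:
    """Family-wise correction min(1, p*k) over k tested terms, order kept."""
    p = np.asarray(list(p_raws), dtype=float)
    if k < p.size:
        raise ValueError(f"k={k} smaller than number of p-values ({p.size})")
    return np.minimum(1.0, p * k)


def enrich_terms(
    catalog: AnnotationCatalog,
    diff_ids: Iterable[str],
    background_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test every term with at least one differential member.

    The background is the annotated universe: the catalog's elements,
    optionally intersected with an explicit ``background_ids``. ``diff_ids``
    outside the background are ignored (unannotated elements carry no term
    information). Rows are sorted by raw p ascending, ties broken by m
    descending then term_id; Bonferroni uses k = number of tested terms.
    """
    annotated = catalog.background
    background = (
        annotated if background_ids is None else annotated & set(map(str, background_ids))
    )
    diff = set(map(str, diff_ids)) & background
    N, n = len(background), len(diff)
    if n == 0:
        warnings.warn("no annotated differential elements; empty enrichment")
        return pd.DataFrame(
            columns=["term_id", "term_name", "namespace", "m", "n", "M", "N",
                     "pct_diff", "pct_all", "p_raw", "p_bonferroni"]
        )
    rows = []
    for term, mem in catalog.members.items():
        mem = mem & background
        m, M = len(mem & diff), len(mem)
        if m == 0:
            continue
        rows.append(
            {
                "term_id": term,
                "term_name": catalog.names.get(term, term),
                "namespace": catalog.namespaces.get(term, "KEGG"),
                "m": m,
                "n": n,
                "M": M,
                "N": N,
                "pct_diff": 100.0 * m / n,
                "pct_all": 100.0 * M / N,
                "p_raw": hypergeom_upper_tail(m, M, n, N),
            }
        )
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = bonferroni_adjust(df["p_raw"], k=len(df))
    df = df.sort_values(
        ["p_raw", "m", "term_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return df


def format_enrichment_table(records: pd.DataFrame) -> pd.DataFrame:
    """Render rows as ``term  m (pct_diff%)  M (pct_all%)  p``.

    Percentages are rounded to two decimals; rows with m = 0 never reach this
    point (they are not tested).
    """
    out = pd.DataFrame(
        {
            "term": records["term_name"],
            "diff_annotated": [
                f"{m} ({100.0 * m / n:.2f}%)"
                for m, n in zip(records["m"], records["n"])
            ],
            "all_annotated": [
                f"{M} ({100.0 * M / N:.2f}%)"
                for M, N in zip(records["M"], records["N"])
            ],
            "p_value": [f"{p:.6g}" for p in records["p_raw"]],
        }
    )
    return out


def format_percentage(m: int, n: int, decimals: int = 1) -> str:
    """Count-over-total percentage in the reporting style, e.g. 98/156 -> '62.8%'."""
    return f"{100.0 * m / n:.{decimals}f}%"
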