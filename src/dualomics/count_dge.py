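"""Differential expression between two un-replicated count libraries.

Implements the exact conditional test of Audic & Claverie for digital
expression profiles: given that a gene collects ``x`` fragments out of the
``N1`` mapped in library 1, the count ``y`` out of ``N2`` in library 2 is,
under equal expression, distributed as

    p(i | x) = (N2/N1)^i * (x+i)! / (x! i!) * (1 + N2/N1)^-(x+i+1),

a negative-binomial law with ``x+1`` successes and success probability
``N1/(N1+N2)``. The two-sided p-value doubles the smaller conditional tail
and clips at 1. Expression level is reported as FPKM, multiplicity is
controlled by Benjamini-Hochberg (or Benjamini-Yekutieli) FDR, and genes are
called up/down at FDR <= 0.001 and |log2 ratio| >= 1 by default.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR_CUT = 0.001
DEFAULT_LOG2_CUT = 1.0
DEFAULT_FPKM_FLOOR = 0.001

_TINY = np.nextafter(0.0, 1.0)


def compute_fpkm(count: int, library_total: int, length_nt: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = count * 1e9 / (library_total * length_nt). The same formula serves
    RPKM; only what was counted upstream (fragments vs reads) differs.
    """
    if library_total < 1:
        raise ValueError(f"library_total must be >= 1, got {library_total}")
    if length_nt < 1:
        raise ValueError(f"length_nt must be >= 1, got {length_nt}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return count * 1e9 / (float(library_total) * float(length_nt))


def _ac_log_pmf(i: np.ndarray, x: int, n1: int, n2: int) -> np.ndarray:
    """log p(i|x) for the equal-expression conditional distribution."""
    log_q = np.log(n2) - np.log(n1)
    log_1pq = np.log1p(n2 / n1)
    i = np.asarray(i, dtype=float)
    return (
        gammaln(x + i + 1.0)
        - gammaln(x + 1.0)
        - gammaln(i + 1.0)
        + i * log_q
        - (x + i + 1.0) * log_1pq
    )


def ac_conditional_pmf(i: int, x: int, n1: int, n2: int) -> float:
    """P(library-2 count = i | library-1 count = x) under equal expression."""
    if i < 0 or x < 0 or n1 < 1 or n2 < 1:
        raise ValueError("require i, x >= 0 and N1, N2 >= 1")
    return float(np.exp(_ac_log_pmf(np.array([i]), x, n1, n2)[0]))


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact p-value for unequal expression of one gene.

    p = min(1, 2 * min(P(Y <= y | x), P(Y >= y | x))), computed in log space
    so counts of 1e6 and beyond cannot overflow. Returns a value in (0, 1].
    """
    if x < 0 or y < 0 or n1 < 1 or n2 < 1:
        raise ValueError("require x, y >= 0 and N1, N2 >= 1")
    log_pmf = _ac_log_pmf(np.arange(y + 1), x, n1, n2)
    lower = np.exp(logsumexp(log_pmf))  # P(Y <= y)
    upper = 1.0 - lower + np.exp(log_pmf[-1])  # P(Y >= y)
    p = 2.0 * min(lower, upper)
    return float(min(1.0, max(p, _TINY)))


def ac_pvalues(
    xs: Sequence[int], ys: Sequence[int], n1: int, n2: int
) -> np.ndarray:
    """Vector of :func:`ac_pvalue` over paired counts."""
    return np.array([ac_pvalue(x, y, n1, n2) for x, y in zip(xs, ys)])


def fdr_adjust(
    p_values: Iterable[float], method: Literal["bh", "by"] = "bh"
) -> np.ndarray:
    """Step-up FDR adjustment (Benjamini-Hochberg, or Benjamini-Yekutieli
    for arbitrary dependency), order-matched to the input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    return multipletests(p, method=sm_method)[1]


def classify_deg(
    fdr: float,
    log2_ratio: float,
    fdr_cut: float = DEFAULT_FDR_CUT,
    log2_cut: float = DEFAULT_LOG2_CUT,
) -> str:
    """Call a gene up/down/not_de; both thresholds inclusive."""
    if fdr <= fdr_cut and log2_ratio >= log2_cut:
        return "up"
    if fdr <= fdr_cut and log2_ratio <= -log2_cut:
        return "down"
    return "not_de"


def fold_change_bins(
    records: pd.DataFrame, bin_edges: Sequence[float] = (2.0, 10.0)
) -> pd.DataFrame:
    """Count DE genes per direction and fold-change magnitude bin.

    Default bins follow the reporting convention 2-10-fold (inclusive both
    ends) and >10-fold; |fold| = 2**|log2_ratio|.
    """
    lo, hi = bin_edges
    de = records[records["call"] != "not_de"]
    fold = 2.0 ** np.abs(de["log2_ratio"].to_numpy())
    out = []
    for direction in ("up", "down"):
        mask = (de["call"] == direction).to_numpy()
        out.append((direction, f"{lo:g}-{hi:g}x", int(((fold >= lo) & (fold <= hi) & mask).sum())))
        out.append((direction, f">{hi:g}x", int(((fold > hi) & mask).sum())))
    return pd.DataFrame(out, columns=["direction", "bin", "count"])


def run_dge(
    counts: pd.DataFrame,
    n1: int | None = None,
    n2: int | None = None,
    fdr_cut: float = DEFAULT_FDR_CUT,
    log2_cut: float = DEFAULT_LOG2_CUT,
    fdr_method: Literal["bh", "by"] = "bh",
    fpkm_floor: float = DEFAULT_FPKM_FLOOR,
) -> pd.DataFrame:
    """Full two-library DE analysis of a count table.

    Parameters
    ----------
    counts
        Columns ``gene_id, length, count_1, count_2``.
    n1, n2
        Library-wide mapped-fragment totals; summed from the table if omitted.
    fpkm_floor
        Substituted for a zero FPKM before the log2 ratio so the ratio stays
        finite; the p-value always uses the raw counts.

    Returns
    -------
    DataFrame with ``gene_id, fpkm_1, fpkm_2, log2_ratio, p_value, fdr, call``
    in input gene order.
    """
    required = {"gene_id", "length", "count_1", "count_2"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if counts["gene_id"].duplicated().any():
        raise ValueError("gene_id values must be unique")
    n1 = int(counts["count_1"].sum()) if n1 is None else int(n1)
    n2 = int(counts["count_2"].sum()) if n2 is None else int(n2)
    if n1 < 1 or n2 < 1:
        raise ValueError("library totals must be positive")

    lengths = counts["length"].to_numpy()
    x = counts["count_1"].to_numpy()
    y = counts["count_2"].to_numpy()
    fpkm_1 = x * 1e9 / (n1 * lengths.astype(float))
    fpkm_2 = y * 1e9 / (n2 * lengths.astype(float))
    log2_ratio = np.log2(np.maximum(fpkm_2, fpkm_floor) / np.maximum(fpkm_1, fpkm_floor))
    p = ac_pvalues(x, y, n1, n2)
    fdr = fdr_adjust(p, method=fdr_method)
    calls = [classify_deg(f, r, fdr_cut, log2_cut) for f, r in zip(fdr, log2_ratio)]
    return pd.DataFrame(
        {
            "gene_id": counts["gene_id"].to_numpy(),
            "fpkm_1": fpkm_1,
            "fpkm_2": fpkm_2,
            "log2_ratio": log2_ratio,
            "p_value": p,
            "fdr": fdr,
            "call": calls,
        }
    )
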