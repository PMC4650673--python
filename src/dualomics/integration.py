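"""Transcript-protein integration: matching, trend split, overlap test.

Differentially expressed proteins are matched to transcripts through an
accession map, matched pairs are split by whether their log2 fold changes
share sign (same trend) or oppose (opposite trend), a Pearson correlation is
computed within each subset, and the significance of platform overlap is
assessed with a Yates-continuity-corrected chi-squared test on the 2x2
detected/not-detected table.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats


def normalize_accession(acc: str) -> str:
    """Case-fold and strip a trailing version suffix (``XP_123.2`` -> ``xp_123``)."""
    acc = str(acc).strip().lower()
    head, _, tail = acc.rpartition(".")
    if head and tail.isdigit():
        return head
    return acc


def match_ids(
    protein_records: pd.DataFrame,
    dge_records: pd.DataFrame,
    id_map: pd.DataFrame,
    protein_p_cut: float = 0.05,
    mrna_p_cut: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Pair differential proteins with differential transcripts.

    Parameters
    ----------
    protein_records
        Protein table with ``protein_id, ratio, p_value``.
    dge_records
        Transcript table with ``gene_id, log2_ratio, p_value``.
    id_map
        Two columns ``protein_id, transcript_id``; accessions are normalized
        (case-folded, version suffix stripped) before matching, duplicate
        protein rows keep the first target with a warning.

    Returns
    -------
    (records, residual): records has one row per pair significant on both
    platforms (p < cutoff each side) with both log2 ratios and a trend label
    in {same, opposite, indeterminate}; residual lists differential protein
    accessions with no differential transcript partner.
    """
    mapping: dict[str, str] = {}
    dupes = 0
    for row in id_map.itertuples(index=False):
        key = normalize_accession(row.protein_id)
        if key in mapping:
            dupes += 1
            continue
        mapping[key] = normalize_accession(row.transcript_id)
    if dupes:
        warnings.warn(f"{dupes} duplicate protein ids in map; first match kept")

    prot = protein_records[protein_records["p_value"] < protein_p_cut]
    mrna = dge_records[dge_records["p_value"] < mrna_p_cut]
    mrna_lfc = {
        normalize_accession(g): float(r)
        for g, r in zip(mrna["gene_id"], mrna["log2_ratio"])
    }

    rows, residual = [], []
    for row in prot.itertuples(index=False):
        key = normalize_accession(row.protein_id)
        target = mapping.get(key)
        if target is None or target not in mrna_lfc:
            residual.append(str(row.protein_id))
            continue
        p_lfc = math.log2(row.ratio)
        m_lfc = mrna_lfc[target]
        if p_lfc == 0.0 or m_lfc == 0.0:
            trend = "indeterminate"
        elif (p_lfc > 0) == (m_lfc > 0):
            trend = "same"
        else:
            trend = "opposite"
        rows.append(
            {
                "protein_id": key,
                "transcript_id": target,
                "protein_log2_ratio": p_lfc,
                "mrna_log2_ratio": m_lfc,
                "trend": trend,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=["protein_id", "transcript_id", "protein_log2_ratio",
                 "mrna_log2_ratio", "trend"],
    )
    return records, residual


def pearson_r(xs, ys) -> float:
    """Product-moment correlation; requires length >= 3 and non-zero variance."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 3:
        raise ValueError("need equal-length sequences of at least 3 points")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(stats.pearsonr(xs, ys).statistic)


def split_by_trend(records: pd.DataFrame) -> dict:
    """Partition matched pairs by trend and correlate within each subset.

    Returns a dict with per-trend counts and the Pearson r of
    (mrna_log2_ratio, protein_log2_ratio) for the same- and opposite-trend
    subsets (None when a subset has fewer than 3 pairs).
    """
    out: dict = {"n_matched": int(len(records))}
    for trend in ("same", "opposite", "indeterminate"):
        sub = records[records["trend"] == trend]
        out[f"n_{trend}"] = int(len(sub))
        if trend == "indeterminate":
            continue
        try:
            out[f"r_{trend}"] = pearson_r(
                sub["mrna_log2_ratio"], sub["protein_log2_ratio"]
            )
        except ValueError:  # fewer than 3 pairs, or degenerate variance
            out[f"r_{trend}"] = None
    return out


def yates_chi2(table) -> tuple[float, float]:
    """Chi-squared with Yates continuity correction on a 2x2 overlap table.

    chi2 = sum (max(|O-E| - 0.5, 0))^2 / E with expected counts from the
    margins; the correction is clamped at zero so an exact-fit table scores 0
    rather than manufacturing signal. p from chi2 with 1 df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("need a non-negative 2x2 table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all margins of the 2x2 table must be positive")
    expected = np.outer(row, col) / total
    corrected = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    statistic = float((corrected**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, max(min(p, 1.0), np.nextafter(0.0, 1.0))


def overlap_table(
    protein_detected: set, transcript_detected: set, universe: set
) -> np.ndarray:
    """2x2 counts (protein detected yes/no x transcript detected yes/no)
    over a shared element universe."""
    universe = set(universe)
    pd_yes = protein_detected & universe
    td_yes = transcript_detected & universe
    a = len(pd_yes & td_yes)
    b = len(pd_yes - td_yes)
    c = len(td_yes - pd_yes)
    d = len(universe) - a - b - c
    return np.array([[a, b], [c, d]])


def integrate(
    protein_records: pd.DataFrame,
    dge_records: pd.DataFrame,
    id_map: pd.DataFrame,
    protein_p_cut: float = 0.05,
    mrna_p_cut: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Run the whole integration stage; returns (records, summary).

    The summary carries the trend split with per-subset r plus the Yates
    chi-squared statistic and p for platform-overlap independence, computed
    over the union of mapped accessions on either platform.
    """
    records, residual = match_ids(
        protein_records, dge_records, id_map, protein_p_cut, mrna_p_cut
    )
    summary = split_by_trend(records)
    summary["n_unmatched_proteins"] = len(residual)

    mapping = {
        normalize_accession(r.protein_id): normalize_accession(r.transcript_id)
        for r in id_map.itertuples(index=False)
    }
    # universe: every element quantified on either platform, in transcript
    # space; "detected" on a platform = differential there at its cutoff
    prot_all = {
        mapping[normalize_accession(p)]
        for p in protein_records["protein_id"]
        if normalize_accession(p) in mapping
    }
    trans_all = {normalize_accession(g) for g in dge_records["gene_id"]}
    universe = prot_all | trans_all
    prot_diff = {
        mapping[normalize_accession(r.protein_id)]
        for r in protein_records.itertuples(index=False)
        if r.p_value < protein_p_cut and normalize_accession(r.protein_id) in mapping
    }
    trans_diff = {
        normalize_accession(r.gene_id)
        for r in dge_records.itertuples(index=False)
        if r.p_value < mrna_p_cut
    }
    try:
        tab = overlap_table(prot_diff, trans_diff, universe)
        statistic, p = yates_chi2(tab)
        summary["overlap_chi2"] = statistic
        summary["overlap_p"] = p
    except ValueError:
        summary["overlap_chi2"] = None
        summary["overlap_p"] = None
    return records, summary
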