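"""iTRAQ protein quantification from peptide reporter-ion ratios.

Each protein's peptides carry a treatment/control reporter ratio (tag 119
over tag 115 in the two-label design). Peptides shared between protein
isoforms are excluded. The protein fold change is the geometric mean of its
peptide ratios; significance is a two-sided one-sample t test of the natural
log ratios against 0 (the log-ratio dispersion is the same information as the
exponentiated confidence half-width, or "error factor", that search engines
report). Proteins are called up at p <= 0.05 and ratio > 1.2, down at
p <= 0.05 and ratio < 0.8.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_P_CUT = 0.05
DEFAULT_UP_CUT = 1.2
DEFAULT_DOWN_CUT = 0.8

_TINY = np.nextafter(0.0, 1.0)


class QuantificationError(ValueError):
    """Raised when a protein has no usable (non-shared) peptides."""


def aggregate_protein_ratio(ratios, shared=None):
    """Aggregate one protein's peptide ratios.

    Returns ``(ratio, n_peptides, mean_log_ratio, sd_log_ratio)`` where ratio
    is the geometric mean over non-shared peptides and sd is the sample
    standard deviation of natural-log ratios (0 when a single peptide).
    """
    ratios = np.asarray(ratios, dtype=float)
    if shared is not None:
        ratios = ratios[~np.asarray(shared, dtype=bool)]
    if ratios.size == 0:
        raise QuantificationError("no distinct (non-shared) peptides to quantify")
    if np.any(ratios <= 0):
        raise ValueError("peptide ratios must be positive")
    logs = np.log(ratios)
    mean_log = float(logs.mean())
    sd_log = float(logs.std(ddof=1)) if logs.size > 1 else 0.0
    return math.exp(mean_log), int(logs.size), mean_log, sd_log


def protein_pvalue(mean_log_ratio: float, sd_log_ratio: float, n_peptides: int) -> float:
    """Two-sided p for a non-unit protein ratio: t = x̄ √N / s, N−1 df.

    A single peptide cannot estimate dispersion, so n=1 returns 1 (the caller
    flags it untestable). Zero dispersion with a non-zero mean returns the
    smallest positive float (degenerate, flagged upstream).
    """
    if n_peptides < 1:
        raise ValueError("n_peptides must be >= 1")
    if n_peptides == 1:
        return 1.0
    if sd_log_ratio == 0.0:
        return 1.0 if mean_log_ratio == 0.0 else _TINY
    t = mean_log_ratio * math.sqrt(n_peptides) / sd_log_ratio
    p = 2.0 * stats.t.sf(abs(t), df=n_peptides - 1)
    return float(min(1.0, max(p, _TINY)))


def signed_fold(ratio: float) -> float:
    """Reporting convention: 4.255 stays 4.255, 1/7.143 becomes −7.143."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def classify_dep(
    ratio: float,
    p_value: float,
    p_cut: float = DEFAULT_P_CUT,
    up_cut: float = DEFAULT_UP_CUT,
    down_cut: float = DEFAULT_DOWN_CUT,
) -> str:
    """Call a protein: inclusive on p, strict on the fold cuts."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if p_value <= p_cut and ratio > up_cut:
        return "up"
    if p_value <= p_cut and ratio < down_cut:
        return "down"
    return "not_de"


def quantify_proteins(
    peptides: pd.DataFrame,
    p_cut: float = DEFAULT_P_CUT,
    up_cut: float = DEFAULT_UP_CUT,
    down_cut: float = DEFAULT_DOWN_CUT,
    median_center: bool = False,
) -> pd.DataFrame:
    """Protein-level table from a peptide ratio table.

    Parameters
    ----------
    peptides
        Columns ``protein_id, peptide_id, ratio, is_shared``.
    median_center
        Optionally divide every ratio by the global median of non-shared
        peptide ratios before aggregation (off by default).

    Returns
    -------
    DataFrame ``protein_id, n_peptides, ratio, signed_fold, p_value, call,
    flags`` in first-appearance protein order. Proteins whose peptides are all
    shared are dropped. Flags: ``untestable`` (single peptide),
    ``degenerate_sd`` (zero dispersion, non-unit ratio).
    """
    required = {"protein_id", "peptide_id", "ratio", "is_shared"}
    missing = required - set(peptides.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    usable = peptides[~peptides["is_shared"].astype(bool)].copy()
    if median_center and len(usable):
        usable["ratio"] = usable["ratio"] / usable["ratio"].median()

    rows = []
    for pid in usable["protein_id"].drop_duplicates():
        r = usable.loc[usable["protein_id"] == pid, "ratio"].to_numpy()
        ratio, n, mean_log, sd_log = aggregate_protein_ratio(r)
        p = protein_pvalue(mean_log, sd_log, n)
        flags = []
        if n == 1:
            flags.append("untestable")
        elif sd_log == 0.0 and mean_log != 0.0:
            flags.append("degenerate_sd")
        rows.append(
            {
                "protein_id": pid,
                "n_peptides": n,
                "ratio": ratio,
                "signed_fold": signed_fold(ratio),
                "p_value": p,
                "call": classify_dep(ratio, p, p_cut, up_cut, down_cut),
                "flags": ";".join(flags) or "-",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "n_peptides", "ratio", "signed_fold", "p_value", "call", "flags"],
    )
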