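"""Synthetic dual-omics study generator with known ground truth.

Emulates the data structures of a two-condition egg-diapause study at desk
scale: two un-replicated RNA-seq count libraries with a planted
differentially expressed subset, per-protein iTRAQ peptide-ratio sets with
log-normal noise, GO/KEGG-style annotation catalogs with planted enriched
terms, and a partial protein-transcript correspondence whose matched pairs
carry planted same-trend / opposite-trend log-ratio structure.

Counts are Poisson around length-free relative rates — the same sampling
model the exact two-library test assumes — with an optional gamma-mixed
over-dispersion switch to probe the test's behaviour when that assumption
fails. A single master seed determines every output byte; each stage draws
from its own offset stream so one stage can be regenerated without
disturbing the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import write_tsv

# stage offsets added to the master seed, one independent stream per stage
_STREAM = {"map": 1, "counts": 2, "peptides": 3, "annotations": 4}


@dataclass
class SimConfig:
    """All knobs of the synthetic study; the seed fully determines output."""

    seed: int = 0
    # transcriptome
    n_genes: int = 5000
    n1: int = 2_000_000
    n2: int = 2_000_000
    baseline_log_mean: float = 4.0   # natural-log mean of per-gene relative rate
    baseline_log_sd: float = 1.2
    length_range: tuple[int, int] = (200, 5000)
    de_fraction: float = 0.1
    fold_changes: tuple[float, ...] = (2.0, 4.0, 8.0)
    overdispersion: float = 0.0      # gamma-mixing CV; 0 = pure Poisson
    # proteome
    n_proteins: int = 400
    peptides_per_protein: tuple[int, int] = (2, 8)
    peptide_log_sd: float = 0.15
    shared_peptide_fraction: float = 0.1
    protein_de_fraction: float = 0.25
    protein_fold_changes: tuple[float, ...] = (1.5, 2.0)
    # annotation catalogs
    n_terms: int = 200
    term_size: tuple[int, int] = (10, 60)
    n_enriched_terms: int = 5
    enrichment_odds: float = 5.0
    # integration structure
    matched_fraction: float = 0.4
    same_trend_fraction: float = 0.7
    pair_log2_mean: float = 1.5      # mean |log2 fold| of a matched pair
    pair_log2_sd: float = 0.5
    pair_corr: float = 0.8           # magnitude correlation within a pair

    def __post_init__(self):
        for name in ("de_fraction", "matched_fraction", "same_trend_fraction",
                     "shared_peptide_fraction", "protein_de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("library totals must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.seed + _STREAM[stage])

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load from a flat key: value config file (YAML subset)."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self).items()
        }
        Path(path).write_text(
            yaml.safe_dump(data, sort_keys=True), encoding="utf-8"
        )


def _gene_ids(n: int) -> list[str]:
    return [f"gene{idx:05d}" for idx in range(n)]


def _protein_ids(n: int) -> list[str]:
    return [f"prot{idx:04d}" for idx in range(n)]


def gen_id_map(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plan the protein-transcript correspondence and its trend structure.

    Each matched pair receives a planted (mrna, protein) log2 fold drawn from
    a bivariate normal on magnitudes (correlation ``pair_corr``); same-trend
    pairs share the sign, opposite-trend pairs oppose it. The planted values
    feed the count and peptide generators so the emitted tables realise the
    planned structure.
    """
    rng = config.rng("map")
    genes = _gene_ids(config.n_genes)
    prots = _protein_ids(config.n_proteins)
    n_matched = int(round(config.matched_fraction * config.n_proteins))
    matched_prots = list(rng.choice(prots, size=n_matched, replace=False))
    matched_genes = list(rng.choice(genes, size=n_matched, replace=False))

    rows = []
    cov = config.pair_log2_sd**2 * np.array(
        [[1.0, config.pair_corr], [config.pair_corr, 1.0]]
    )
    for pid, gid in zip(matched_prots, matched_genes):
        mag = rng.multivariate_normal([config.pair_log2_mean] * 2, cov)
        mag = np.abs(mag)
        sign = rng.choice([-1.0, 1.0])
        same = rng.random() < config.same_trend_fraction
        mrna_lfc = sign * mag[0]
        prot_lfc = sign * mag[1] if same else -sign * mag[1]
        rows.append(
            {
                "protein_id": pid,
                "transcript_id": gid,
                "mrna_log2": mrna_lfc,
                "protein_log2": prot_lfc,
                "trend": "same" if same else "opposite",
            }
        )
    truth = pd.DataFrame(
        rows, columns=["protein_id", "transcript_id", "mrna_log2",
                       "protein_log2", "trend"]
    )
    id_map = truth[["protein_id", "transcript_id"]].copy()
    return id_map, truth


def gen_counts(
    config: SimConfig, fold_overrides: dict[str, float] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-library count table with planted fold changes.

    count_1 ~ Poisson(lam_g * N1 / sum lam), count_2 ~ Poisson(lam_g * f_g *
    N2 / sum(lam*f)); f_g = 1 for non-DE genes, cycles through the configured
    fold set (alternating direction) for the planted subset, and is fixed by
    ``fold_overrides`` for genes tied to matched protein pairs.
    """
    rng = config.rng("counts")
    genes = np.array(_gene_ids(config.n_genes))
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1,
                           size=config.n_genes)
    lam = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                            size=config.n_genes))

    fold = np.ones(config.n_genes)
    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    for j, idx in enumerate(de_idx):
        fc = config.fold_changes[j % len(config.fold_changes)]
        fold[idx] = fc if j % 2 == 0 else 1.0 / fc
    if fold_overrides:
        pos = {g: i for i, g in enumerate(genes)}
        for gid, f in fold_overrides.items():
            fold[pos[gid]] = f

    rate1 = lam / lam.sum() * config.n1
    rate2 = lam * fold / (lam * fold).sum() * config.n2
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion**2
        rate1 = rate1 * rng.gamma(shape, 1.0 / shape, size=config.n_genes)
        rate2 = rate2 * rng.gamma(shape, 1.0 / shape, size=config.n_genes)
    counts = pd.DataFrame(
        {
            "gene_id": genes,
            "length": lengths,
            "count_1": rng.poisson(rate1),
            "count_2": rng.poisson(rate2),
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "true_fold": fold,
            "is_de": (fold != 1.0).astype(int),
        }
    )
    return counts, truth


def gen_peptides(
    config: SimConfig, ratio_overrides: dict[str, float] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide-ratio table: per protein, n peptides with log ratio ~
    Normal(log r_true, peptide_log_sd); a configured fraction marked shared."""
    rng = config.rng("peptides")
    prots = _protein_ids(config.n_proteins)

    r_true = np.ones(config.n_proteins)
    n_de = int(round(config.protein_de_fraction * config.n_proteins))
    de_idx = rng.choice(config.n_proteins, size=n_de, replace=False)
    for j, idx in enumerate(de_idx):
        fc = config.protein_fold_changes[j % len(config.protein_fold_changes)]
        r_true[idx] = fc if j % 2 == 0 else 1.0 / fc
    if ratio_overrides:
        pos = {p: i for i, p in enumerate(prots)}
        for pid, r in ratio_overrides.items():
            r_true[pos[pid]] = r

    lo, hi = config.peptides_per_protein
    rows = []
    for i, pid in enumerate(prots):
        n_pep = int(rng.integers(lo, hi + 1))
        logs = rng.normal(np.log(r_true[i]), config.peptide_log_sd, size=n_pep)
        shared = rng.random(n_pep) < config.shared_peptide_fraction
        for j in range(n_pep):
            rows.append(
                {
                    "protein_id": pid,
                    "peptide_id": f"{pid}_pep{j:02d}",
                    "ratio": float(np.exp(logs[j])),
                    "is_shared": int(shared[j]),
                }
            )
    peptides = pd.DataFrame(rows, columns=["protein_id", "peptide_id", "ratio", "is_shared"])
    truth = pd.DataFrame(
        {
            "protein_id": prots,
            "true_ratio": r_true,
            "is_de": (r_true != 1.0).astype(int),
        }
    )
    return peptides, truth


def gen_annotations(
    config: SimConfig,
    diff_ids,
    background_ids,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotation catalog with planted enriched terms.

    Background terms sample members uniformly from ``background_ids``;
    planted terms over-sample ``diff_ids`` with the configured odds.
    """
    rng = config.rng("annotations")
    background = np.array(sorted(map(str, background_ids)))
    diff = set(map(str, diff_ids))
    lo, hi = config.term_size
    if hi > len(background):
        raise ValueError("term_size upper bound exceeds background size")

    weights = np.where(np.isin(background, sorted(diff)), config.enrichment_odds, 1.0)
    weights = weights / weights.sum()
    rows, truth_rows = [], []
    for t in range(config.n_terms):
        term = f"term{t:04d}"
        planted = t < config.n_enriched_terms
        size = int(rng.integers(lo, hi + 1))
        p = weights if planted else None
        members = rng.choice(background, size=size, replace=False, p=p)
        namespace = "KEGG" if t % 2 == 0 else "GO:biological_process"
        for el in members:
            rows.append(
                {
                    "element_id": el,
                    "term_id": term,
                    "term_name": f"synthetic pathway {t}",
                    "namespace": namespace,
                }
            )
        truth_rows.append(
            {
                "term_id": term,
                "is_enriched": int(planted),
                "odds": config.enrichment_odds if planted else 1.0,
            }
        )
    annotations = pd.DataFrame(
        rows, columns=["element_id", "term_id", "term_name", "namespace"]
    )
    truth = pd.DataFrame(truth_rows, columns=["term_id", "is_enriched", "odds"])
    return annotations, truth


def simulate_all(config: SimConfig, out_dir: str | Path | None = None) -> dict:
    """Generate every pipeline input plus the truth table.

    The id-map stage is planned first so matched pairs' planted log2 folds
    can be imposed on the count and peptide generators; the emitted tables
    therefore realise the planned trend structure. Returns a dict of
    DataFrames; when ``out_dir`` is given, writes counts.tsv, peptides.tsv,
    annotations.tsv, id_map.tsv, truth.tsv and the config snapshot.
    """
    id_map, pair_truth = gen_id_map(config)
    fold_overrides = {
        r.transcript_id: 2.0**r.mrna_log2 for r in pair_truth.itertuples(index=False)
    }
    ratio_overrides = {
        r.protein_id: 2.0**r.protein_log2 for r in pair_truth.itertuples(index=False)
    }
    counts, gene_truth = gen_counts(config, fold_overrides)
    peptides, prot_truth = gen_peptides(config, ratio_overrides)
    diff_ids = gene_truth.loc[gene_truth["is_de"] == 1, "gene_id"]
    annotations, term_truth = gen_annotations(
        config, diff_ids, gene_truth["gene_id"]
    )

    truth_long = pd.concat(
        [
            gene_truth.assign(kind="gene").rename(columns={"gene_id": "id", "true_fold": "value"})[
                ["kind", "id", "value", "is_de"]],
            prot_truth.assign(kind="protein").rename(columns={"protein_id": "id", "true_ratio": "value"})[
                ["kind", "id", "value", "is_de"]],
            term_truth.assign(kind="term", is_de=term_truth["is_enriched"]).rename(
                columns={"term_id": "id", "odds": "value"})[["kind", "id", "value", "is_de"]],
            pair_truth.assign(kind="pair", value=pair_truth["mrna_log2"],
                              is_de=(pair_truth["trend"] == "same").astype(int)).rename(
                columns={"protein_id": "id"})[["kind", "id", "value", "is_de"]],
        ],
        ignore_index=True,
    )
    out = {
        "counts": counts,
        "peptides": peptides,
        "annotations": annotations,
        "id_map": id_map,
        "gene_truth": gene_truth,
        "protein_truth": prot_truth,
        "term_truth": term_truth,
        "pair_truth": pair_truth,
        "truth": truth_long,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tsv(counts, out_dir / "counts.tsv")
        write_tsv(peptides, out_dir / "peptides.tsv")
        write_tsv(annotations, out_dir / "annotations.tsv")
        write_tsv(id_map, out_dir / "id_map.tsv")
        write_tsv(truth_long, out_dir / "truth.tsv")
        config.to_file(out_dir / "sim_config.yaml")
    return out
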