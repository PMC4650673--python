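"""End-to-end orchestration: DGE -> proteins -> enrichment -> integration.

Owns the file dialects, the run manifest and the summary report whose counts
are always re-derivable by filtering the stage tables (total DE genes =
up + down exactly, and likewise for proteins).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, count_dge, enrichment, integration, proteome
from .io import read_tsv, write_tsv
from .simulate import SimConfig, simulate_all


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    seed: int | None
    version: str = __version__
    parameters: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def record(self, name: str, outputs: list[str], seconds: float) -> None:
        self.stages.append(
            {"stage": name, "outputs": outputs, "wall_time_s": round(seconds, 3)}
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "parameters": self.parameters,
                    "stages": self.stages,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )


def summarize(
    dge: pd.DataFrame,
    proteins: pd.DataFrame,
    enrich: pd.DataFrame | None = None,
    integration_summary: dict | None = None,
    n_top_terms: int = 5,
) -> dict:
    """Reporting surface: up/down/total counts, fold-change bins, top terms.

    Totals are sums of the per-direction counts by construction, so they can
    always be re-derived by filtering the stage tables.
    """
    deg_up = int((dge["call"] == "up").sum())
    deg_down = int((dge["call"] == "down").sum())
    prot_up = int((proteins["call"] == "up").sum())
    prot_down = int((proteins["call"] == "down").sum())
    bins = count_dge.fold_change_bins(dge)
    summary = {
        "deg_up": deg_up,
        "deg_down": deg_down,
        "deg_total": deg_up + deg_down,
        "protein_up": prot_up,
        "protein_down": prot_down,
        "protein_total": prot_up + prot_down,
        "fold_change_bins": {
            f"{r.direction}_{r.bin}": int(r.count) for r in bins.itertuples(index=False)
        },
    }
    if enrich is not None and len(enrich):
        summary["top_terms"] = [
            {"term_id": r.term_id, "term_name": r.term_name, "p_raw": float(r.p_raw)}
            for r in enrich.head(n_top_terms).itertuples(index=False)
        ]
    if integration_summary:
        summary["integration"] = integration_summary
    return summary


def run_all(
    out_dir: str | Path,
    counts_path: str | Path | None = None,
    peptides_path: str | Path | None = None,
    annotations_path: str | Path | None = None,
    id_map_path: str | Path | None = None,
    sim_config: SimConfig | None = None,
    n1: int | None = None,
    n2: int | None = None,
    fdr_cut: float = count_dge.DEFAULT_FDR_CUT,
    log2_cut: float = count_dge.DEFAULT_LOG2_CUT,
    fdr_method: str = "bh",
    p_cut: float = proteome.DEFAULT_P_CUT,
    up_cut: float = proteome.DEFAULT_UP_CUT,
    down_cut: float = proteome.DEFAULT_DOWN_CUT,
    alpha: float = 0.05,
    enrich_filter: str = "raw",
) -> RunManifest:
    """Run every stage; either load the four input tables or simulate them.

    Returns the manifest; all stage outputs land in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=sim_config.seed if sim_config is not None else None,
        parameters={
            "fdr_cut": fdr_cut, "log2_cut": log2_cut, "fdr_method": fdr_method,
            "p_cut": p_cut, "up_cut": up_cut, "down_cut": down_cut,
            "alpha": alpha, "enrich_filter": enrich_filter,
        },
    )

    if sim_config is not None:
        t0 = time.perf_counter()
        sim = simulate_all(sim_config, out_dir / "sim")
        counts_path = out_dir / "sim" / "counts.tsv"
        peptides_path = out_dir / "sim" / "peptides.tsv"
        annotations_path = out_dir / "sim" / "annotations.tsv"
        id_map_path = out_dir / "sim" / "id_map.tsv"
        manifest.record(
            "simulate",
            [str(counts_path), str(peptides_path), str(annotations_path),
             str(id_map_path), str(out_dir / "sim" / "truth.tsv")],
            time.perf_counter() - t0,
        )
        del sim

    def _load(path, stage):
        if path is None or not Path(path).exists():
            raise StageError(f"{stage}: missing input file {path}")
        return read_tsv(path)

    t0 = time.perf_counter()
    dge = count_dge.run_dge(
        _load(counts_path, "dge"), n1=n1, n2=n2, fdr_cut=fdr_cut,
        log2_cut=log2_cut, fdr_method=fdr_method,
    )
    write_tsv(dge, out_dir / "dge.tsv")
    manifest.record("dge", [str(out_dir / "dge.tsv")], time.perf_counter() - t0)

    t0 = time.perf_counter()
    proteins = proteome.quantify_proteins(
        _load(peptides_path, "proteins"), p_cut=p_cut, up_cut=up_cut, down_cut=down_cut
    )
    write_tsv(proteins, out_dir / "proteins.tsv")
    manifest.record("proteins", [str(out_dir / "proteins.tsv")], time.perf_counter() - t0)

    t0 = time.perf_counter()
    catalog = enrichment.AnnotationCatalog.from_table(
        _load(annotations_path, "enrichment")
    )
    diff_ids = set(dge.loc[dge["call"] != "not_de", "gene_id"].astype(str))
    enrich = enrichment.enrich_terms(catalog, diff_ids)
    col = "p_raw" if enrich_filter == "raw" else "p_bonferroni"
    enrich_sig = enrich[enrich[col] <= alpha] if len(enrich) else enrich
    write_tsv(enrich_sig, out_dir / "enrichment.tsv")
    manifest.record("enrichment", [str(out_dir / "enrichment.tsv")], time.perf_counter() - t0)

    t0 = time.perf_counter()
    records, integ_summary = integration.integrate(
        proteins, dge, _load(id_map_path, "integration"),
        protein_p_cut=p_cut, mrna_p_cut=0.05,
    )
    write_tsv(records, out_dir / "integration.tsv")
    manifest.record("integration", [str(out_dir / "integration.tsv")], time.perf_counter() - t0)

    summary = summarize(dge, proteins, enrich_sig, integ_summary)
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2) + "\n", encoding="utf-8"
    )
    manifest.record("summary", [str(out_dir / "summary.json")], 0.0)
    manifest.write(out_dir / "manifest.json")
    return manifest
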