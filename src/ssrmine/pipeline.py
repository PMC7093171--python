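"""One-command orchestration: mine -> regions -> stats -> markers, and the
genotype-table diversity report.

Every stage writes a plain TSV so each step is independently testable and
re-runnable; re-running with identical inputs and config (including seed)
yields byte-identical reports.  Each report header carries the config hash.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from . import __version__
from .config import PipelineConfig
from .markers import export_candidates, screen_candidates
from .mining import mine_fasta, write_loci_tsv
from .popgen import GenotypeTable, diversity_table, panel_summary
from .regions import assign_loci, build_region_model, read_bed_intervals
from .repeat_stats import build_summary_tables

logger = logging.getLogger("ssrmine")

__all__ = ["run_pipeline", "run_popgen"]


def _header(config: PipelineConfig) -> list[str]:
    return [
        f"ssrmine {__version__}",
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
    ]


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with path.open("w") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=f"%.{config.table_decimals + 2}f")


def run_pipeline(
    fasta: str | Path,
    gff: str | Path,
    te_track: str | Path | None,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "ssrmine_out",
) -> dict:
    """Execute the full genome characterisation pipeline.

    Writes loci.tsv, region_lengths.tsv, summary_by_type.tsv,
    motif_ranking.tsv, summary_by_region.tsv, marker candidate FASTA/TSV and
    run.log under *out_dir*; returns the in-memory tables.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome: Mapping[str, str] = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
    }
    seq_lengths = {sid: len(s) for sid, s in genome.items()}
    logger.info("mining %d sequences (%d bp)", len(genome), sum(seq_lengths.values()))

    loci = mine_fasta(fasta, config.thresholds)
    write_loci_tsv(loci, out_dir / "loci.tsv", header_lines=_header(config))

    te_intervals = read_bed_intervals(te_track) if te_track else None
    model = build_region_model(gff, te_intervals, seq_lengths)
    _write_table(model.region_lengths_frame(), out_dir / "region_lengths.tsv", config)

    assigned = assign_loci(loci, model)
    if config.te_exclusive:
        assigned = assigned.copy()
        assigned.loc[assigned["te"], "region"] = "TE"
    tables = build_summary_tables(assigned, model)
    _write_table(tables["by_type"], out_dir / "summary_by_type.tsv", config)
    _write_table(tables["by_motif"], out_dir / "motif_ranking.tsv", config)
    _write_table(tables["by_region"], out_dir / "summary_by_region.tsv", config)

    candidates = screen_candidates(loci, genome, config.screen)
    markers_df = export_candidates(
        candidates, out_dir / "markers.fasta", out_dir / "markers.tsv", config.screen
    )

    (out_dir / "run.log").write_text(
        "\n".join(
            _header(config)
            + [
                f"n_sequences={len(genome)}",
                f"genome_length_bp={model.genome_length_bp}",
                f"n_loci={len(loci)}",
                f"n_marker_candidates_pass={int(markers_df['passes'].sum()) if len(markers_df) else 0}",
                "config=" + config.to_json(),
            ]
        )
        + "\n"
    )
    return {
        "loci": loci,
        "assigned": assigned,
        "model": model,
        "tables": tables,
        "markers": markers_df,
    }


def run_popgen(
    genotype_tsv: str | Path,
    config: PipelineConfig | None = None,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Per-locus diversity report with panel summary and HWE flags.

    Loci whose exact-test P falls below ``config.hwe_alpha`` are flagged
    (``hwe_deviant``) as candidates for removal from a marker panel.
    """
    config = config or PipelineConfig()
    table = GenotypeTable.from_tsv(genotype_tsv)
    df = diversity_table(
        table,
        g=config.rarefaction_g,
        unbiased_he=config.unbiased_he,
        max_enum_arrays=config.hwe_max_enum,
        mc_reps=config.hwe_mc_reps,
        seed=config.seed,
    )
    df["hwe_deviant"] = df["hwe_p"] < config.hwe_alpha

    summary = panel_summary(df)
    summary_row = {
        "locus": "PANEL_MEAN",
        "n": df["n"].mean(),
        "k": summary["total_k"],
        "ho": summary["mean_ho"],
        "he": summary["mean_he"],
        "ar": summary["mean_ar"],
        "pic": summary["mean_pic"],
        "hwe_p": float("nan"),
        "hwe_deviant": bool(df["hwe_deviant"].any()),
    }
    report = pd.concat([df, pd.DataFrame([summary_row])], ignore_index=True)
    if out is not None:
        with Path(out).open("w") as fh:
            for line in _header(config):
                fh.write(f"# {line}\n")
            report.to_csv(fh, sep="\t", index=False, float_format="%.4f")
    return report
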