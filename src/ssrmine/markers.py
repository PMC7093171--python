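"""Screening of tetranucleotide SSR loci for marker development.

Tetranucleotide repeats genotype more cleanly than dinucleotides (larger
allele spacing, less stutter), so candidate marker loci are tetranucleotide
runs with a moderate copy number, 200 bp of clean flanking sequence on each
side, and no second SSR inside either flank.  Primer design proper (Tm,
dimers) is downstream of this module; the primer-length and product-size
constraints a designer should respect are carried along as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mining import SSRLocus

__all__ = ["ScreenConfig", "MarkerCandidate", "screen_candidates", "export_candidates"]


@dataclass(frozen=True)
class ScreenConfig:
    """Candidate filter settings.

    rcn window default 7-15; flanks 200 bp either side; product size window
    190-450 bp and primer length 18-23 bp are recorded for downstream primer
    design.  ``require_unique_flanks`` adds an exact-substring uniqueness
    check of each flank against the whole genome (quadratic-ish; off by
    default).
    """

    unit_length: int = 4
    rcn_min: int = 7
    rcn_max: int = 15
    flank_len: int = 200
    product_min: int = 190
    product_max: int = 450
    primer_len_min: int = 18
    primer_len_max: int = 23
    require_unique_flanks: bool = False

    def __post_init__(self) -> None:
        if self.rcn_min > self.rcn_max:
            raise ValueError("rcn_min must be <= rcn_max")
        if self.product_min >= self.product_max:
            raise ValueError("product_min must be < product_max")
        if self.flank_len <= 0:
            raise ValueError("flank_len must be positive")


@dataclass
class MarkerCandidate:
    locus: SSRLocus
    left_flank: str
    right_flank: str
    passes: bool
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.locus.seq_id}:{self.locus.start}-{self.locus.end}"

    def flanked_sequence(self) -> str:
        return self.left_flank + self.locus.sequence() + self.right_flank


def _overlaps_flank(other: SSRLocus, lo: int, hi: int) -> bool:
    return other.start <= hi and other.end >= lo


def screen_candidates(
    loci: Sequence[SSRLocus],
    genome: Mapping[str, str],
    cfg: ScreenConfig | None = None,
) -> list[MarkerCandidate]:
    """Evaluate every tetranucleotide locus against the marker criteria.

    Each candidate is either passing or carries at least one machine-readable
    rejection reason: ``rcn-below-min``, ``rcn-above-max``,
    ``insufficient-flank``, ``ssr-in-flank``, ``non-unique-flank``.
    Loci of other unit lengths are not evaluated at all.
    """
    cfg = cfg or ScreenConfig()
    by_seq: dict[str, list[SSRLocus]] = {}
    for l in loci:
        by_seq.setdefault(l.seq_id, []).append(l)

    out: list[MarkerCandidate] = []
    for locus in loci:
        if locus.unit_length != cfg.unit_length:
            continue
        if locus.seq_id not in genome:
            raise ValueError(f"locus sequence id {locus.seq_id!r} absent from genome")
        seq = genome[locus.seq_id]
        reasons: list[str] = []
        if locus.rcn < cfg.rcn_min:
            reasons.append("rcn-below-min")
        if locus.rcn > cfg.rcn_max:
            reasons.append("rcn-above-max")

        left_start = locus.start - cfg.flank_len  # 1-based
        right_end = locus.end + cfg.flank_len
        if left_start < 1 or right_end > len(seq):
            reasons.append("insufficient-flank")
            left = seq[max(left_start, 1) - 1 : locus.start - 1]
            right = seq[locus.end : min(right_end, len(seq))]
        else:
            left = seq[left_start - 1 : locus.start - 1]
            right = seq[locus.end : right_end]
            for other in by_seq[locus.seq_id]:
                if other is locus:
                    continue
                if _overlaps_flank(other, left_start, locus.start - 1) or _overlaps_flank(
                    other, locus.end + 1, right_end
                ):
                    reasons.append("ssr-in-flank")
                    break
            if cfg.require_unique_flanks and not reasons:
                if not _flanks_unique(genome, locus.seq_id, left, right, left_start, right_end):
                    reasons.append("non-unique-flank")

        out.append(
            MarkerCandidate(
                locus=locus,
                left_flank=left,
                right_flank=right,
                passes=not reasons,
                rejection_reasons=reasons,
            )
        )
    return out


def _flanks_unique(
    genome: Mapping[str, str],
    seq_id: str,
    left: str,
    right: str,
    left_start: int,
    right_end: int,
) -> bool:
    """Exact-containment uniqueness: each flank occurs once in the genome."""
    for flank, home_start in ((left, left_start), (right, right_end - len(right) + 1)):
        if not flank:
            continue
        for sid, seq in genome.items():
            pos = seq.find(flank)
            while pos != -1:
                if not (sid == seq_id and pos + 1 == home_start):
                    return False
                pos = seq.find(flank, pos + 1)
    return True


def export_candidates(
    candidates: Iterable[MarkerCandidate],
    fasta_path: str | Path,
    tsv_path: str | Path,
    cfg: ScreenConfig | None = None,
    passing_only_fasta: bool = True,
) -> pd.DataFrame:
    """Write flanked candidate sequences (FASTA) and a metadata table (TSV).

    The TSV lists every evaluated candidate with its verdict and the primer
    and product-size constraints from the config; the FASTA holds the
    ``left flank + repeat + right flank`` sequence of (by default) the
    passing candidates, named ``seq_id:start-end``.
    """
    cfg = cfg or ScreenConfig()
    candidates = list(candidates)
    records = [
        SeqRecord(
            Seq(c.flanked_sequence()),
            id=c.name,
            description=f"motif={c.locus.motif} rcn={c.locus.rcn}",
        )
        for c in candidates
        if c.passes or not passing_only_fasta
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    rows = [
        {
            "name": c.name,
            "seq_id": c.locus.seq_id,
            "start": c.locus.start,
            "end": c.locus.end,
            "motif": c.locus.motif,
            "canonical_motif": c.locus.canonical_motif,
            "rcn": c.locus.rcn,
            "passes": c.passes,
            "rejection_reasons": ";".join(c.rejection_reasons),
            "flank_len": cfg.flank_len,
            "primer_len_min": cfg.primer_len_min,
            "primer_len_max": cfg.primer_len_max,
            "product_min": cfg.product_min,
            "product_max": cfg.product_max,
        }
        for c in candidates
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "name", "seq_id", "start", "end", "motif", "canonical_motif", "rcn",
            "passes", "rejection_reasons", "flank_len", "primer_len_min",
            "primer_len_max", "product_min", "product_max",
        ],
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    return df
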