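"""Detection of perfect mono- to hexanucleotide SSRs in nucleotide sequences.

A perfect SSR is a maximal uninterrupted tandem run of a primitive 1-6 bp
unit.  Runs are found per unit length with a vectorised phase-shift
comparison (``seq[i] == seq[i+k]``), trimmed to complete units, filtered by
per-unit-length minimum repeat copy number, and resolved greedily so that
every base belongs to at most one reported locus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motifs import canonical_motif, is_primitive

__all__ = [
    "SSRLocus",
    "MiningThresholds",
    "find_perfect_ssrs",
    "mine_fasta",
    "loci_to_frame",
    "frame_to_loci",
    "write_loci_tsv",
    "read_loci_tsv",
    "loci_to_gff3",
]

#: TSV column order for locus tables.
LOCUS_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "unit_length",
    "motif",
    "canonical_motif",
    "rcn",
    "length_bp",
]


@dataclass(frozen=True, order=True)
class SSRLocus:
    """One perfect repeat run.

    Coordinates are 1-based inclusive (GFF3 convention).  ``motif`` is the
    unit as read on the forward strand starting at ``start``; ``rcn`` counts
    complete units only, so ``length_bp == unit_length * rcn`` always holds
    and a trailing partial unit is not part of the span.
    """

    seq_id: str
    start: int
    end: int
    motif: str = field(compare=False)
    canonical_motif: str = field(compare=False)
    unit_length: int = field(compare=False)
    rcn: int = field(compare=False)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def sequence(self) -> str:
        """Span sequence (the unit repeated rcn times)."""
        return self.motif * self.rcn

    def __post_init__(self) -> None:
        if self.length_bp != self.unit_length * self.rcn:
            raise ValueError(
                f"span {self.seq_id}:{self.start}-{self.end} is not "
                f"{self.rcn} complete copies of a {self.unit_length} bp unit"
            )


_DEFAULT_MIN_RCN = {1: 12, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class MiningThresholds:
    """Minimum repeat copy number per unit length (1..6).

    Defaults are the widely used genome-survey settings: mono >= 12,
    di >= 7, tri >= 5, tetra/penta/hexa >= 4.
    """

    min_rcn: Mapping[int, int] = field(default_factory=lambda: dict(_DEFAULT_MIN_RCN))

    def __post_init__(self) -> None:
        if set(self.min_rcn) != {1, 2, 3, 4, 5, 6}:
            raise ValueError("min_rcn must map every unit length 1..6")
        for k, v in self.min_rcn.items():
            if int(v) < 2:
                raise ValueError(f"min_rcn[{k}] must be >= 2, got {v}")

    @classmethod
    def from_string(cls, text: str) -> "MiningThresholds":
        """Parse a comma list ``"12,7,5,4,4,4"`` (mono..hexa)."""
        parts = [int(x) for x in text.split(",")]
        if len(parts) != 6:
            raise ValueError("expected six comma-separated thresholds (mono..hexa)")
        return cls(dict(zip(range(1, 7), parts)))


_VALID_RE = re.compile(r"[^ACGTN]")
_BASE_CODES = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _BASE_CODES[_b] = True


def _candidate_runs(arr: np.ndarray, valid: np.ndarray, seq: str, k: int, min_rcn: int):
    """Yield (start0, span_len, motif) for maximal perfect runs of unit length k."""
    n = arr.size
    if n < k * min_rcn:
        return
    eq = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
    if not eq.any():
        return
    padded = np.empty(eq.size + 2, dtype=bool)
    padded[0] = padded[-1] = False
    padded[1:-1] = eq
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[0::2], edges[1::2]  # half-open runs in eq coords
    for i, j in zip(starts, ends):
        run_len = int(j - i) + k  # bases covered by the chained equalities
        rcn = run_len // k
        if rcn < min_rcn:
            continue
        motif = seq[i : i + k]
        if k > 1 and not is_primitive(motif):
            continue  # explained by a shorter unit
        yield int(i), rcn * k, motif


def find_perfect_ssrs(
    seq: str,
    thresholds: MiningThresholds | None = None,
    seq_id: str = "seq",
) -> list[SSRLocus]:
    """Mine all perfect SSRs of unit length 1-6 from one sequence.

    Input may be mixed case (soft-masking is ignored); ``N`` terminates runs;
    any other character raises a ValueError naming its 1-based position.
    Overlaps between candidate runs of different unit lengths are resolved
    greedily left to right, preferring smaller units, then earlier starts,
    then longer runs; each base is consumed by at most one locus.
    """
    thresholds = thresholds or MiningThresholds()
    if not seq:
        return []
    seq = seq.upper()
    m = _VALID_RE.search(seq)
    if m:
        raise ValueError(
            f"invalid character {m.group()!r} at position {m.start() + 1} of {seq_id}"
        )
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = _BASE_CODES[arr]

    candidates: list[tuple[int, int, int, str]] = []
    for k in range(1, 7):
        for start0, span, motif in _candidate_runs(
            arr, valid, seq, k, thresholds.min_rcn[k]
        ):
            candidates.append((start0, k, -span, motif))

    candidates.sort()
    loci: list[SSRLocus] = []
    consumed_until = -1  # last 0-based index claimed so far
    for start0, k, neg_span, motif in candidates:
        if start0 <= consumed_until:
            continue
        span = -neg_span
        loci.append(
            SSRLocus(
                seq_id=seq_id,
                start=start0 + 1,
                end=start0 + span,
                motif=motif,
                canonical_motif=canonical_motif(motif),
                unit_length=k,
                rcn=span // k,
            )
        )
        consumed_until = start0 + span - 1
    return loci


def mine_fasta(
    fasta: str | Path | Iterable,
    thresholds: MiningThresholds | None = None,
) -> list[SSRLocus]:
    """Mine every record of a FASTA file (or iterable of SeqRecords)."""
    if isinstance(fasta, (str, Path)):
        records: Iterator = SeqIO.parse(str(fasta), "fasta")
    else:
        records = iter(fasta)
    loci: list[SSRLocus] = []
    for rec in records:
        loci.extend(find_perfect_ssrs(str(rec.seq), thresholds, seq_id=rec.id))
    loci.sort()
    return loci


def loci_to_frame(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    rows = [
        (l.seq_id, l.start, l.end, l.unit_length, l.motif, l.canonical_motif, l.rcn, l.length_bp)
        for l in loci
    ]
    return pd.DataFrame(rows, columns=LOCUS_COLUMNS)


def frame_to_loci(df: pd.DataFrame) -> list[SSRLocus]:
    return [
        SSRLocus(
            seq_id=str(r.seq_id),
            start=int(r.start),
            end=int(r.end),
            motif=str(r.motif),
            canonical_motif=str(r.canonical_motif),
            unit_length=int(r.unit_length),
            rcn=int(r.rcn),
        )
        for r in df.itertuples(index=False)
    ]


def write_loci_tsv(loci: Iterable[SSRLocus], path: str | Path, header_lines: Iterable[str] = ()) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        loci_to_frame(loci).to_csv(fh, sep="\t", index=False)


def read_loci_tsv(path: str | Path) -> list[SSRLocus]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return frame_to_loci(df)


def loci_to_gff3(loci: Iterable[SSRLocus], source: str = "ssrmine") -> str:
    """Render loci as GFF3 ``microsatellite`` features."""
    lines = ["##gff-version 3"]
    for l in loci:
        attrs = f"ID=ssr_{l.seq_id}_{l.start};motif={l.motif};canonical_motif={l.canonical_motif};rcn={l.rcn}"
        lines.append(
            "\t".join(
                [l.seq_id, source, "microsatellite", str(l.start), str(l.end), ".", "+", ".", attrs]
            )
        )
    return "\n".join(lines) + "\n"
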