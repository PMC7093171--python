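"""Synthetic genomes and genotype tables with exact machine-readable truth.

The genome simulator emulates the input bundle of a genome-wide SSR survey:
multi-sequence FASTA with i.i.d. background at a chosen GC fraction, gene
models (5'UTR / CDS exons / introns / 3'UTR on both strands) written as
GFF3, a transposable-element interval overlay (BED), and perfect SSRs
planted at controlled per-region densities with controlled motif and
repeat-copy-number distributions.  After planting, the sequences are
"scrubbed": the miner is run and any accidental background run that meets
the thresholds is broken by a point substitution, so the truth table is the
exact, complete mining result by construction.

The genotype simulator draws diploid genotypes under Hardy-Weinberg
equilibrium (optionally with inbreeding coefficient F):
P(het i,j) = 2 p_i p_j (1 - F);  P(hom i) = p_i^2 + F p_i (1 - p_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mining import MiningThresholds, SSRLocus, find_perfect_ssrs, loci_to_frame
from .motifs import canonical_motif, is_primitive
from .popgen import GenotypeTable
from .regions import RegionClass

__all__ = [
    "GenomeSimSpec",
    "GenotypeSimSpec",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_genotypes",
    "random_genotype_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSimSpec:
    """Parameters of one synthetic genome.

    Defaults give a compact mammal-like test genome: three 120 kb sequences
    at GC 0.42, six multi-exon genes per sequence, a TE overlay covering a
    few percent of the sequence, and 500 planted SSRs whose unit-length mix
    (mono-heavy, hexa-rare) and per-region densities (intron/intergenic
    heavy, coding sparse) follow the qualitative pattern of mammalian
    genome surveys.
    """

    seq_lengths: tuple[int, ...] = (120_000, 120_000, 120_000)
    gc: float = 0.42
    genes_per_seq: int = 6
    exons_per_gene: tuple[int, int] = (2, 4)
    utr5_len: tuple[int, int] = (100, 250)
    utr3_len: tuple[int, int] = (200, 400)
    cds_exon_len: tuple[int, int] = (200, 400)
    intron_len: tuple[int, int] = (800, 2500)
    intergenic_gap: tuple[int, int] = (2_000, 6_000)
    te_per_seq: int = 25
    te_len: tuple[int, int] = (300, 2_000)
    n_ssrs: int = 500
    region_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "intergenic": 0.40,
            "intron": 0.30,
            "TE": 0.15,
            "5'UTR": 0.04,
            "CDS": 0.06,
            "3'UTR": 0.05,
        }
    )
    unit_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.22, 3: 0.18, 4: 0.06, 5: 0.13, 6: 0.01}
    )
    rcn_ranges: Mapping[int, tuple[int, int]] = field(
        default_factory=lambda: {
            1: (12, 30), 2: (7, 20), 3: (5, 15), 4: (4, 15), 5: (4, 10), 6: (4, 8),
        }
    )
    thresholds: MiningThresholds = field(default_factory=MiningThresholds)

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0,1)")
        for k, (lo, hi) in self.rcn_ranges.items():
            if lo < self.thresholds.min_rcn[k]:
                raise ValueError(
                    f"rcn range for unit length {k} starts below the mining threshold"
                )


@dataclass
class SimulatedGenome:
    """In-memory simulation bundle plus (optionally) the files written."""

    sequences: dict[str, str]
    gff_text: str
    te_intervals: list[tuple[str, int, int]]  # 1-based inclusive
    truth: pd.DataFrame
    seed: int
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def seq_lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.sequences.items()}


# region codes for the simulator's own truth paint (independent of the
# region-model builder so end-to-end tests compare two derivations)
_SIM_CODE = {"intergenic": 0, "5'UTR": 1, "CDS": 2, "intron": 3, "3'UTR": 4}


def _allocate(total: int, weights: Mapping) -> dict:
    """Largest-remainder allocation of *total* items over weight classes."""
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    w = w / w.sum()
    raw = w * total
    base = np.floor(raw).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i]] += 1
    return {k: int(b) for k, b in zip(keys, base)}


def _sample_motif(k: int, rng: np.random.Generator) -> str:
    while True:
        motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
        if is_primitive(motif):
            return motif


def _clean_plant(motif: str, rcn: int, thresholds: MiningThresholds) -> bool:
    """True if motif*rcn mines back as exactly one locus equal to itself."""
    span = motif * rcn
    found = find_perfect_ssrs(span, thresholds)
    return (
        len(found) == 1
        and found[0].start == 1
        and found[0].end == len(span)
        and found[0].motif == motif
    )


def _free_slots(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, as 0-based [start, end]."""
    padded = np.empty(mask.size + 2, dtype=bool)
    padded[0] = padded[-1] = False
    padded[1:-1] = mask
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(s), int(e) - 1) for s, e in zip(edges[0::2], edges[1::2])]


def _gene_layout(spec: GenomeSimSpec, rng: np.random.Generator, seq_len: int):
    """Lay out genes along one sequence.

    Returns (genes, region_code_array).  Each gene is a dict with strand,
    exon and CDS intervals (0-based inclusive) for GFF3 rendering.
    """
    codes = np.zeros(seq_len, dtype=np.uint8)
    genes = []
    pos = int(rng.integers(*spec.intergenic_gap))
    for _ in range(spec.genes_per_seq):
        n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        u_left = int(rng.integers(*spec.utr5_len))
        u_right = int(rng.integers(*spec.utr3_len))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            u_left, u_right = u_right, u_left
        cds_lens = [int(rng.integers(*spec.cds_exon_len)) for _ in range(n_ex)]
        intron_lens = [int(rng.integers(*spec.intron_len)) for _ in range(n_ex - 1)]

        # genome-order pieces: [left UTR + CDS1] intron [CDS2] ... [CDSn + right UTR]
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        p = pos
        for i in range(n_ex):
            ex_start = p
            if i == 0:
                codes[p : p + u_left] = (
                    _SIM_CODE["5'UTR"] if strand == "+" else _SIM_CODE["3'UTR"]
                )
                p += u_left
            c_start = p
            codes[p : p + cds_lens[i]] = _SIM_CODE["CDS"]
            p += cds_lens[i]
            cds.append((c_start, p - 1))
            if i == n_ex - 1:
                codes[p : p + u_right] = (
                    _SIM_CODE["3'UTR"] if strand == "+" else _SIM_CODE["5'UTR"]
                )
                p += u_right
            exons.append((ex_start, p - 1))
            if i < n_ex - 1:
                codes[p : p + intron_lens[i]] = _SIM_CODE["intron"]
                p += intron_lens[i]
        if p >= seq_len - spec.intergenic_gap[0]:
            # ran out of room; discard this gene's paint and stop
            codes[pos:p] = 0
            break
        genes.append({"start": pos, "end": p - 1, "strand": strand, "exons": exons, "cds": cds})
        pos = p + int(rng.integers(*spec.intergenic_gap))
        if pos >= seq_len - 10_000:
            break
    return genes, codes


def _render_gff(seq_ids: Sequence[str], genes_by_seq: Mapping[str, list], seed: int) -> str:
    lines = ["##gff-version 3", f"# ssrmine simulated annotation seed={seed}"]
    g = 0
    for sid in seq_ids:
        for gene in genes_by_seq[sid]:
            g += 1
            gid, tid = f"gene{g}", f"gene{g}.t1"
            s, e, strand = gene["start"] + 1, gene["end"] + 1, gene["strand"]
            lines.append(f"{sid}\tsim\tgene\t{s}\t{e}\t.\t{strand}\t.\tID={gid}")
            lines.append(f"{sid}\tsim\tmRNA\t{s}\t{e}\t.\t{strand}\t.\tID={tid};Parent={gid}")
            for i, (xs, xe) in enumerate(gene["exons"], 1):
                lines.append(
                    f"{sid}\tsim\texon\t{xs + 1}\t{xe + 1}\t.\t{strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}"
                )
            for i, (cs, ce) in enumerate(gene["cds"], 1):
                lines.append(
                    f"{sid}\tsim\tCDS\t{cs + 1}\t{ce + 1}\t.\t{strand}\t0\t"
                    f"ID={tid}.cds{i};Parent={tid}"
                )
    return "\n".join(lines) + "\n"


def _place_tes(
    spec: GenomeSimSpec, rng: np.random.Generator, codes: np.ndarray
) -> list[tuple[int, int]]:
    """TE intervals (0-based inclusive) inside intergenic/intron stretches."""
    host = (codes == _SIM_CODE["intergenic"]) | (codes == _SIM_CODE["intron"])
    tes: list[tuple[int, int]] = []
    free = host.copy()
    for _ in range(spec.te_per_seq):
        length = int(rng.integers(*spec.te_len))
        slots = [s for s in _free_slots(free) if s[1] - s[0] + 1 >= length + 2]
        if not slots:
            break
        s0, e0 = slots[int(rng.integers(0, len(slots)))]
        start = int(rng.integers(s0 + 1, e0 - length + 1))
        tes.append((start, start + length - 1))
        free[max(0, start - 1) : start + length + 1] = False
    return sorted(tes)


def _fix_plant_flanks(arr: np.ndarray, start0: int, k: int, length: int, rng) -> None:
    """Make a planted run non-extendable at the unit phase on either side."""
    end0 = start0 + length - 1
    if start0 > 0 and arr[start0 - 1] == arr[start0 - 1 + k]:
        choices = [b for b in _BASES if b != arr[start0 - 1 + k]]
        arr[start0 - 1] = choices[int(rng.integers(0, len(choices)))]
    if end0 + 1 < arr.size and arr[end0 + 1] == arr[end0 + 1 - k]:
        choices = [b for b in _BASES if b != arr[end0 + 1 - k]]
        arr[end0 + 1] = choices[int(rng.integers(0, len(choices)))]


def simulate_genome(
    spec: GenomeSimSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SimulatedGenome:
    """Generate a synthetic genome bundle with an exact SSR truth table.

    Identical (spec, seed) pairs give byte-identical outputs.  When
    ``out_dir`` is given, writes genome.fasta, annotation.gff3, te.bed and
    truth.tsv there.
    """
    spec = spec or GenomeSimSpec()
    rng = np.random.default_rng(seed)
    seq_ids = [f"scf{i + 1}" for i in range(len(spec.seq_lengths))]

    p = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )
    arrays: dict[str, np.ndarray] = {}
    genes_by_seq: dict[str, list] = {}
    codes_by_seq: dict[str, np.ndarray] = {}
    tes_by_seq: dict[str, list[tuple[int, int]]] = {}
    for sid, n in zip(seq_ids, spec.seq_lengths):
        arrays[sid] = _BASES[rng.choice(4, size=n, p=p)]
        genes_by_seq[sid], codes_by_seq[sid] = _gene_layout(spec, rng, n)
        tes_by_seq[sid] = _place_tes(spec, rng, codes_by_seq[sid])

    # availability masks per region class (TE handled separately)
    te_mask = {sid: np.zeros(n, dtype=bool) for sid, n in zip(seq_ids, spec.seq_lengths)}
    for sid in seq_ids:
        for s, e in tes_by_seq[sid]:
            te_mask[sid][s : e + 1] = True

    n_per_class = _allocate(spec.n_ssrs, spec.region_weights)
    unit_alloc = {
        cls: _allocate(cnt, spec.unit_weights) for cls, cnt in n_per_class.items()
    }

    free = {}
    for cls, code in _SIM_CODE.items():
        free[cls] = {
            sid: (codes_by_seq[sid] == code) & ~te_mask[sid] for sid in seq_ids
        }
    free["TE"] = {sid: te_mask[sid].copy() for sid in seq_ids}

    truth_rows: list[dict] = []
    planted_spans: dict[str, list[tuple[int, int, int]]] = {sid: [] for sid in seq_ids}

    for cls in n_per_class:
        for k, count in unit_alloc[cls].items():
            for _ in range(count):
                lo, hi = spec.rcn_ranges[k]
                placed = False
                for _attempt in range(200):
                    rcn = int(rng.integers(lo, hi + 1))
                    motif = _sample_motif(k, rng)
                    if not _clean_plant(motif, rcn, spec.thresholds):
                        continue
                    length = k * rcn
                    slot_choices = []
                    for sid in seq_ids:
                        for s, e in _free_slots(free[cls][sid]):
                            if e - s + 1 >= length + 4:
                                slot_choices.append((sid, s, e))
                    if not slot_choices:
                        continue
                    sid, s0, e0 = slot_choices[int(rng.integers(0, len(slot_choices)))]
                    start = int(rng.integers(s0 + 2, e0 - length))
                    unit = np.frombuffer(motif.encode(), dtype=np.uint8)
                    arrays[sid][start : start + length] = np.tile(unit, rcn)
                    _fix_plant_flanks(arrays[sid], start, k, length, rng)
                    free_region = free[cls][sid]
                    free_region[max(0, start - 2) : start + length + 2] = False
                    # a plant also blocks every other class at those bases
                    for other in free.values():
                        other[sid][max(0, start - 2) : start + length + 2] = False
                    region_label = (
                        cls
                        if cls != "TE"
                        else next(
                            name
                            for name, code in _SIM_CODE.items()
                            if code == codes_by_seq[sid][start]
                        )
                    )
                    truth_rows.append(
                        {
                            "seq_id": sid,
                            "start": start + 1,
                            "end": start + length,
                            "unit_length": k,
                            "motif": motif,
                            "canonical_motif": canonical_motif(motif),
                            "rcn": rcn,
                            "length_bp": length,
                            "region": region_label,
                            "te": bool(te_mask[sid][start]),
                        }
                    )
                    planted_spans[sid].append((start, start + length - 1, k))
                    placed = True
                    break
                if not placed:
                    raise ValueError(
                        f"could not place a unit-{k} SSR in region {cls}: "
                        "spec densities appear infeasible"
                    )

    _scrub(spec, rng, seq_ids, arrays, planted_spans, truth_rows)

    truth_columns = [
        "seq_id", "start", "end", "unit_length", "motif", "canonical_motif",
        "rcn", "length_bp", "region", "te",
    ]
    truth = (
        pd.DataFrame(truth_rows, columns=truth_columns)
        .sort_values(["seq_id", "start"])
        .reset_index(drop=True)
    )
    sequences = {sid: arrays[sid].tobytes().decode("ascii") for sid in seq_ids}
    te_intervals = [
        (sid, s + 1, e + 1) for sid in seq_ids for s, e in tes_by_seq[sid]
    ]
    gff_text = _render_gff(seq_ids, genes_by_seq, seed)

    sim = SimulatedGenome(
        sequences=sequences,
        gff_text=gff_text,
        te_intervals=te_intervals,
        truth=truth,
        seed=seed,
    )
    if out_dir is not None:
        sim.paths = _write_bundle(sim, Path(out_dir))
    return sim


def _scrub(spec, rng, seq_ids, arrays, planted_spans, truth_rows) -> None:
    """Break accidental threshold-passing runs until mining == truth."""
    truth_keys = {
        (r["seq_id"], r["start"], r["end"], r["motif"]) for r in truth_rows
    }
    protected = {
        sid: _spans_mask(arrays[sid].size, planted_spans[sid]) for sid in seq_ids
    }
    for _iteration in range(40):
        dirty = False
        for sid in seq_ids:
            seq = arrays[sid].tobytes().decode("ascii")
            for locus in find_perfect_ssrs(seq, spec.thresholds, seq_id=sid):
                key = (sid, locus.start, locus.end, locus.motif)
                if key in truth_keys:
                    continue
                dirty = True
                _break_run(arrays[sid], locus, protected[sid], rng)
            # re-assert non-extendability of every plant after mutations
            for s, e, k in planted_spans[sid]:
                _fix_plant_flanks(arrays[sid], s, k, e - s + 1, rng)
        if not dirty:
            return
    raise RuntimeError("scrubbing did not converge; spec too repeat-dense")


def _spans_mask(n: int, spans: list[tuple[int, int, int]]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e, _k in spans:
        mask[s : e + 1] = True
    return mask


def _break_run(arr: np.ndarray, locus: SSRLocus, protected: np.ndarray, rng) -> None:
    """Point-substitute a non-protected base inside an accidental run."""
    lo, hi = locus.start - 1, locus.end - 1
    candidates = [i for i in range(lo, hi + 1) if not protected[i]]
    if not candidates:  # run extends a plant; mutate just outside the plant
        for i in (lo - 1, hi + 1):
            if 0 <= i < arr.size and not protected[i]:
                candidates = [i]
                break
    if not candidates:
        raise RuntimeError(f"cannot break accidental run at {locus.seq_id}:{locus.start}")
    i = candidates[len(candidates) // 2]
    avoid = {arr[i]}
    for j in (i - 1, i + 1):
        if 0 <= j < arr.size:
            avoid.add(arr[j])
    choices = [b for b in _BASES if b not in avoid] or [
        b for b in _BASES if b != arr[i]
    ]
    arr[i] = choices[int(rng.integers(0, len(choices)))]


def _write_bundle(sim: SimulatedGenome, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "genome.fasta",
        "gff": out_dir / "annotation.gff3",
        "te_bed": out_dir / "te.bed",
        "truth": out_dir / "truth.tsv",
    }
    with paths["fasta"].open("w") as fh:
        for sid, seq in sim.sequences.items():
            fh.write(f">{sid} ssrmine simulated seed={sim.seed}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["gff"].write_text(sim.gff_text)
    with paths["te_bed"].open("w") as fh:
        fh.write(f"# ssrmine simulated TE track seed={sim.seed}\n")
        for sid, s, e in sim.te_intervals:
            fh.write(f"{sid}\t{s - 1}\t{e}\tTE\n")
    with paths["truth"].open("w") as fh:
        fh.write(f"# ssrmine simulated truth seed={sim.seed}\n")
        sim.truth.to_csv(fh, sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeSimSpec:
    """Parameters of a simulated co-dominant genotyping experiment.

    Defaults mirror a small captive-population study design: 36 diploid
    individuals, no inbreeding (F=0, i.e. Hardy-Weinberg equilibrium) and no
    missing data.  ``loci`` maps locus name -> allele frequency vector.
    """

    loci: Mapping[str, Sequence[float]]
    n_individuals: int = 36
    f_inbreeding: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.f_inbreeding < 1:
            raise ValueError("F must be in [0,1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0,1)")
        for name, freqs in self.loci.items():
            arr = np.asarray(freqs, dtype=float)
            if arr.size == 0 or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"locus {name!r}: frequencies must be >=0 and sum to 1")


def _allele_labels(n: int) -> list[str]:
    # fragment-length style labels, 4 bp ladder
    return [str(200 + 4 * i) for i in range(n)]


def simulate_genotypes(spec: GenotypeSimSpec, seed: int = 0) -> GenotypeTable:
    """Draw a genotype table under the spec's inbreeding model."""
    rng = np.random.default_rng(seed)
    individuals = [f"ind{i + 1:03d}" for i in range(spec.n_individuals)]
    calls: dict[str, list[tuple[str, str] | None]] = {}
    for name, freqs in spec.loci.items():
        p = np.asarray(freqs, dtype=float)
        labels = _allele_labels(p.size)
        col: list[tuple[str, str] | None] = []
        for _ in range(spec.n_individuals):
            if spec.missing_rate and rng.random() < spec.missing_rate:
                col.append(None)
                continue
            if spec.f_inbreeding and rng.random() < spec.f_inbreeding:
                a = labels[int(rng.choice(p.size, p=p))]
                col.append((a, a))
            else:
                i, j = rng.choice(p.size, size=2, p=p)
                pair = tuple(sorted((labels[int(i)], labels[int(j)])))
                col.append(pair)  # type: ignore[arg-type]
        calls[name] = col
    return GenotypeTable(individuals=individuals, loci=list(spec.loci), calls=calls)


def random_genotype_spec(
    n_loci: int,
    rng: np.random.Generator,
    n_individuals: int = 36,
    alleles_range: tuple[int, int] = (2, 6),
    f_inbreeding: float = 0.0,
    missing_rate: float = 0.0,
) -> GenotypeSimSpec:
    """Spec with Dirichlet(1) allele frequencies at random allele counts."""
    loci = {}
    for i in range(n_loci):
        k = int(rng.integers(alleles_range[0], alleles_range[1] + 1))
        freqs = rng.dirichlet(np.ones(k))
        loci[f"L{i + 1:04d}"] = tuple(float(x) for x in freqs)
    return GenotypeSimSpec(
        loci=loci,
        n_individuals=n_individuals,
        f_inbreeding=f_inbreeding,
        missing_rate=missing_rate,
    )
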