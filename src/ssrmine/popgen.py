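"""Per-locus diversity statistics for diploid co-dominant genotype tables.

Implements the marker-characterisation panel: number of alleles (k),
observed heterozygosity (Ho), expected heterozygosity (He, Nei's unbiased
estimator by default), polymorphism information content (PIC, Botstein's
formula), allelic richness (Ar, hypergeometric rarefaction to g gene
copies) and an exact conditional test of Hardy-Weinberg equilibrium
(complete enumeration of genotype arrays given the allele counts when the
array space is small, Monte-Carlo permutation of gene copies otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeTable",
    "LocusDiversity",
    "allele_counts",
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "pic",
    "allelic_richness",
    "hwe_exact_test",
    "locus_diversity",
    "diversity_table",
    "panel_summary",
]

MISSING = "NA"


@dataclass
class GenotypeTable:
    """Individuals x loci diploid genotypes.

    ``calls[locus]`` is a list aligned with ``individuals``; each entry is an
    unordered allele pair (stored sorted) or None for missing.  Allele labels
    are arbitrary strings (typically fragment lengths).
    """

    individuals: list[str]
    loci: list[str]
    calls: dict[str, list[tuple[str, str] | None]]

    def __post_init__(self) -> None:
        for locus in self.loci:
            if locus not in self.calls:
                raise ValueError(f"no genotype column for locus {locus!r}")
            if len(self.calls[locus]) != len(self.individuals):
                raise ValueError(f"locus {locus!r}: call count != individual count")

    def pairs(self, locus: str) -> list[tuple[str, str]]:
        """Typed (non-missing) genotypes at one locus."""
        if locus not in self.calls:
            raise ValueError(f"unknown locus {locus!r}")
        return [p for p in self.calls[locus] if p is not None]

    def n_typed(self, locus: str) -> int:
        return len(self.pairs(locus))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        """Read a genotype TSV: column ``individual`` then one ``a/b`` column
        per locus, ``NA`` for missing."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if "individual" not in df.columns:
            raise ValueError("genotype table must have an 'individual' column")
        loci = [c for c in df.columns if c != "individual"]
        calls: dict[str, list[tuple[str, str] | None]] = {}
        for locus in loci:
            col = []
            for v in df[locus]:
                if pd.isna(v) or v == MISSING:
                    col.append(None)
                    continue
                parts = str(v).split("/")
                if len(parts) != 2:
                    raise ValueError(f"locus {locus!r}: malformed genotype {v!r}")
                col.append(tuple(sorted(parts)))
            calls[locus] = col
        return cls(individuals=list(df["individual"]), loci=loci, calls=calls)

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with Path(path).open("w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("individual\t" + "\t".join(self.loci) + "\n")
            for i, ind in enumerate(self.individuals):
                cells = []
                for locus in self.loci:
                    pair = self.calls[locus][i]
                    cells.append(MISSING if pair is None else f"{pair[0]}/{pair[1]}")
                fh.write(ind + "\t" + "\t".join(cells) + "\n")


def allele_counts(pairs: Sequence[tuple[str, str]]) -> dict[str, int]:
    """Gene-copy counts per allele over typed genotypes."""
    if not pairs:
        raise ValueError("no typed individuals")
    counts: dict[str, int] = {}
    for a, b in pairs:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    return counts


def allele_frequencies(pairs: Sequence[tuple[str, str]]) -> dict[str, float]:
    """Allele frequencies over the 2N gene copies; sums to 1."""
    counts = allele_counts(pairs)
    total = sum(counts.values())
    return {a: c / total for a, c in sorted(counts.items())}


def observed_heterozygosity(pairs: Sequence[tuple[str, str]]) -> float:
    """Fraction of typed individuals carrying two distinct alleles."""
    if not pairs:
        raise ValueError("no typed individuals")
    return sum(1 for a, b in pairs if a != b) / len(pairs)


def expected_heterozygosity(
    freqs: Mapping[str, float], n: int, unbiased: bool = True
) -> float:
    """Gene diversity 1 - sum(p_i^2), by default with Nei's small-sample
    correction 2n/(2n-1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    gene_div = 1.0 - sum(p * p for p in freqs.values())
    if not unbiased:
        return gene_div
    return (2 * n) / (2 * n - 1) * gene_div


def pic(freqs: Mapping[str, float]) -> float:
    """Polymorphism information content (Botstein):
    1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = list(freqs.values())
    if not p:
        raise ValueError("empty frequency map")
    s2 = sum(x * x for x in p)
    s4 = sum(x ** 4 for x in p)
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return 1.0 - s2 - (s2 * s2 - s4)


def allelic_richness(counts: Mapping[str, int], g: int) -> float:
    """Expected number of distinct alleles in a rarefied sample of g gene
    copies (hypergeometric rarefaction).

    Ar = sum_a [1 - C(2N - N_a, g) / C(2N, g)]; equals the observed allele
    count at g = 2N and is non-decreasing in g.
    """
    total = sum(counts.values())
    if not 1 <= g <= total:
        raise ValueError(f"rarefaction size g={g} must be in 1..{total}")
    denom = math.comb(total, g)
    ar = 0.0
    for c in counts.values():
        ar += 1.0 - math.comb(total - c, g) / denom
    return ar


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

_LN2 = math.log(2.0)
_TOL = 1e-9


class _EnumerationTooLarge(Exception):
    pass


def _genotype_count_matrix(pairs: Sequence[tuple[str, str]], alleles: list[str]) -> np.ndarray:
    idx = {a: i for i, a in enumerate(alleles)}
    K = len(alleles)
    m = np.zeros((K, K), dtype=int)
    for a, b in pairs:
        i, j = sorted((idx[a], idx[b]))
        m[i, j] += 1
    return m


def _array_stat(cell_counts: np.ndarray, het: int) -> float:
    """Log of the variable part of the conditional probability of an array."""
    return het * _LN2 - float(gammaln(cell_counts + 1).sum())


def _enumerate_arrays(allele_copies: list[int], max_arrays: int):
    """Yield (stat, het) for every genotype array with the given allele
    counts.  Raises _EnumerationTooLarge past *max_arrays* leaves."""
    K = len(allele_copies)
    cells = [(i, j) for i in range(K) for j in range(i, K)]
    n_cells = len(cells)
    counts = np.zeros(n_cells, dtype=int)
    produced = 0
    out: list[tuple[float, int]] = []

    def rec(ci: int, remaining: list[int], het: int) -> None:
        nonlocal produced
        if ci == n_cells:
            if any(remaining):
                return
            produced += 1
            if produced > max_arrays:
                raise _EnumerationTooLarge
            out.append((_array_stat(counts, het), het))
            return
        i, j = cells[ci]
        # copies of allele i cannot be consumed by any later cell once the
        # row of i is finished
        if i == j:
            hi = remaining[i] // 2
            for n in range(hi + 1):
                counts[ci] = n
                remaining[i] -= 2 * n
                rec(ci + 1, remaining, het)
                remaining[i] += 2 * n
        else:
            hi = min(remaining[i], remaining[j])
            last_of_row = j == K - 1
            for n in range(hi + 1):
                if last_of_row and remaining[i] - n != 0:
                    continue
                counts[ci] = n
                remaining[i] -= n
                remaining[j] -= n
                rec(ci + 1, remaining, het + n)
                remaining[i] += n
                remaining[j] += n
        counts[ci] = 0

    rec(0, list(allele_copies), 0)
    return out


def _logsumexp(vals: np.ndarray) -> float:
    m = vals.max()
    return float(m + np.log(np.exp(vals - m).sum()))


def _hwe_p_enumeration(obs: np.ndarray, allele_copies: list[int], max_arrays: int) -> float:
    obs_cells = obs[np.triu_indices(obs.shape[0])]
    obs_het = int(obs.sum() - np.trace(obs))
    obs_stat = _array_stat(obs_cells, obs_het)
    stats = np.array([s for s, _ in _enumerate_arrays(allele_copies, max_arrays)])
    total = _logsumexp(stats)
    le = stats[stats <= obs_stat + _TOL]
    return float(np.exp(_logsumexp(le) - total))


def _hwe_p_montecarlo(
    obs: np.ndarray, allele_copies: list[int], reps: int, rng: np.random.Generator
) -> float:
    K = len(allele_copies)
    n_ind = int(obs.sum())
    copies = np.repeat(np.arange(K), allele_copies)
    lgamma_table = gammaln(np.arange(n_ind + 2))
    obs_cells = obs[np.triu_indices(K)]
    obs_het = int(obs.sum() - np.trace(obs))
    obs_stat = _array_stat(obs_cells, obs_het)

    hits = 0
    chunk = max(1, min(reps, 20000))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        M = rng.permuted(np.tile(copies, (b, 1)), axis=1)
        a1, a2 = M[:, 0::2], M[:, 1::2]
        lo = np.minimum(a1, a2)
        hi = np.maximum(a1, a2)
        cell = lo * K + hi
        flat = (np.arange(b)[:, None] * (K * K) + cell).ravel()
        cellcounts = np.bincount(flat, minlength=b * K * K).reshape(b, K * K)
        het = (a1 != a2).sum(axis=1)
        stat = het * _LN2 - lgamma_table[cellcounts + 1].sum(axis=1)
        # constant cells (zeros) contribute gammaln(1)=0, so full-matrix sums
        # match the upper-triangle stat
        hits += int((stat <= obs_stat + _TOL).sum())
        done += b
    return (1 + hits) / (reps + 1)


def hwe_exact_test(
    pairs: Sequence[tuple[str, str]],
    max_enum_arrays: int = 200_000,
    mc_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    all genotype arrays no more probable than the observed one (exact
    probabilities test).  Complete enumeration is used while the array space
    stays below ``max_enum_arrays``; otherwise a Monte-Carlo permutation of
    gene copies with ``mc_reps`` replicates and the (hits+1)/(reps+1)
    estimator, which keeps the P value in (0, 1].  Monomorphic loci return
    1.0 by convention.
    """
    if not pairs:
        raise ValueError("no typed individuals")
    alleles = sorted({a for p in pairs for a in p})
    if len(alleles) == 1:
        return 1.0
    obs = _genotype_count_matrix(pairs, alleles)
    copies = [int(obs[i, :].sum() + obs[:, i].sum()) for i in range(len(alleles))]
    try:
        return _hwe_p_enumeration(obs, copies, max_enum_arrays)
    except _EnumerationTooLarge:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return _hwe_p_montecarlo(obs, copies, mc_reps, rng)


# ---------------------------------------------------------------------------
# Per-locus and panel reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusDiversity:
    """One row of the marker-panel diversity table."""

    locus: str
    n: int
    k: int
    ho: float
    he: float
    ar: float
    pic: float
    hwe_p: float


def locus_diversity(
    table: GenotypeTable,
    locus: str,
    g: int | None = None,
    unbiased_he: bool = True,
    max_enum_arrays: int = 200_000,
    mc_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> LocusDiversity:
    pairs = table.pairs(locus)
    if not pairs:
        raise ValueError(f"locus {locus!r} has no typed individuals")
    counts = allele_counts(pairs)
    freqs = allele_frequencies(pairs)
    n = len(pairs)
    g = 2 * n if g is None else g
    return LocusDiversity(
        locus=locus,
        n=n,
        k=len(counts),
        ho=observed_heterozygosity(pairs),
        he=expected_heterozygosity(freqs, n, unbiased=unbiased_he),
        ar=allelic_richness(counts, min(g, 2 * n)),
        pic=pic(freqs),
        hwe_p=hwe_exact_test(pairs, max_enum_arrays, mc_reps, seed),
    )


def diversity_table(
    table: GenotypeTable,
    g: int | None = None,
    unbiased_he: bool = True,
    max_enum_arrays: int = 200_000,
    mc_reps: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus diversity statistics for every locus of a genotype table.

    Rarefaction size g defaults to the minimum 2N over loci (so Ar is
    comparable across loci with different missingness).
    """
    if not table.loci:
        raise ValueError("genotype table has no loci")
    if g is None:
        g = min(2 * table.n_typed(locus) for locus in table.loci)
    rng = np.random.default_rng(seed)
    rows = [
        locus_diversity(
            table, locus, g=g, unbiased_he=unbiased_he,
            max_enum_arrays=max_enum_arrays, mc_reps=mc_reps, seed=rng,
        )
        for locus in table.loci
    ]
    return pd.DataFrame(
        [(r.locus, r.n, r.k, r.ho, r.he, r.ar, r.pic, r.hwe_p) for r in rows],
        columns=["locus", "n", "k", "ho", "he", "ar", "pic", "hwe_p"],
    )


def panel_summary(df: pd.DataFrame) -> dict[str, float]:
    """Panel-level summary of a per-locus diversity table.

    Requires columns k, ho, he, ar, pic; returns the total allele count,
    arithmetic means and min/max ranges.
    """
    if len(df) == 0:
        raise ValueError("empty panel")
    out: dict[str, float] = {
        "n_loci": int(len(df)),
        "total_k": int(df["k"].sum()),
    }
    for col in ("ho", "he", "ar", "pic"):
        out[f"mean_{col}"] = float(df[col].mean())
        out[f"min_{col}"] = float(df[col].min())
        out[f"max_{col}"] = float(df[col].max())
    return out
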