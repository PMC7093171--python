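import itertools
import math

import numpy as np
import pytest

from ssrmine.popgen import (
    GenotypeTable,
    allele_counts,
    allele_frequencies,
    allelic_richness,
    diversity_table,
    expected_heterozygosity,
    hwe_exact_test,
    locus_diversity,
    observed_heterozygosity,
    panel_summary,
    pic,
)
from ssrmine.simulate import GenotypeSimSpec, simulate_genotypes


def test_allele_frequencies_counting():
    assert allele_frequencies([("A", "A"), ("A", "B")]) == {"A": 0.75, "B": 0.25}
    assert allele_frequencies([("A", "A")]) == {"A": 1.0}
    with pytest.raises(ValueError):
        allele_frequencies([])


def test_allele_frequencies_match_counting_oracle(rng):
    for _ in range(20):
        pairs = [
            tuple(sorted(rng.choice(list("ABCD"), size=2)))
            for _ in range(int(rng.integers(1, 40)))
        ]
        freqs = allele_frequencies(pairs)
        flat = [a for p in pairs for a in p]
        for a, f in freqs.items():
            assert f == pytest.approx(flat.count(a) / len(flat))
        assert sum(freqs.values()) == pytest.approx(1.0)


def test_observed_heterozygosity():
    assert observed_heterozygosity([("A", "A"), ("A", "B")]) == 0.5
    assert observed_heterozygosity([("A", "A"), ("B", "B")]) == 0.0


def test_expected_heterozygosity_unbiased():
    # {A/A, A/B}: gene diversity 0.375, x 4/3 -> 0.5
    f = allele_frequencies([("A", "A"), ("A", "B")])
    assert expected_heterozygosity(f, 2) == pytest.approx(0.5)
    assert expected_heterozygosity(f, 2, unbiased=False) == pytest.approx(0.375)
    assert expected_heterozygosity({"A": 1.0}, 10) == 0.0


def test_pic_values():
    assert pic({"a": 0.5, "b": 0.5}) == pytest.approx(0.375)
    assert pic({"a": 1.0}) == 0.0
    assert pic({c: 0.25 for c in "abcd"}) == pytest.approx(0.703125)
    with pytest.raises(ValueError):
        pic({})


def test_pic_bounded_by_gene_diversity(rng):
    for _ in range(30):
        k = int(rng.integers(2, 7))
        p = rng.dirichlet(np.ones(k))
        freqs = dict(enumerate(p))
        gd = 1 - sum(x * x for x in p)
        assert pic(freqs) <= gd + 1e-12


def test_allelic_richness_toy_vs_enumeration():
    """2N=8 copies with counts {5,2,1}, g=4: exact mean over all C(8,4)
    subsamples."""
    counts = {"a": 5, "b": 2, "c": 1}
    pool = ["a"] * 5 + ["b"] * 2 + ["c"]
    brute = np.mean(
        [len({pool[i] for i in s}) for s in itertools.combinations(range(8), 4)]
    )
    assert allelic_richness(counts, 4) == pytest.approx(float(brute), abs=1e-12)


def test_allelic_richness_properties():
    counts = {"a": 5, "b": 2, "c": 1}
    assert allelic_richness(counts, 8) == pytest.approx(3.0)  # g = 2N -> k
    assert allelic_richness({"a": 9}, 4) == 1.0
    vals = [allelic_richness(counts, g) for g in range(1, 9)]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))  # non-decreasing
    with pytest.raises(ValueError):
        allelic_richness(counts, 9)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test([("A", "A")] * 10) == 1.0


def test_hwe_two_allele_matches_het_count_enumeration():
    """Exact P equals an independent enumeration over heterozygote counts."""

    def oracle(n11, n12, n22):
        n = n11 + n12 + n22
        na, nb = 2 * n11 + n12, 2 * n22 + n12

        def weight(h):
            if (na - h) % 2 or h > min(na, nb):
                return 0.0
            a, b = (na - h) // 2, (nb - h) // 2
            return 2**h / (math.factorial(a) * math.factorial(h) * math.factorial(b))

        w = {h: weight(h) for h in range(min(na, nb) + 1)}
        tot = sum(w.values())
        return sum(x for x in w.values() if x <= w[n12] * (1 + 1e-9)) / tot

    for n11, n12, n22 in [(1, 2, 2), (3, 1, 1), (0, 5, 0), (2, 0, 3), (10, 5, 3)]:
        pairs = [("A", "A")] * n11 + [("A", "B")] * n12 + [("B", "B")] * n22
        assert hwe_exact_test(pairs) == pytest.approx(oracle(n11, n12, n22), abs=1e-9)


def test_hwe_montecarlo_agrees_with_enumeration():
    pairs = (
        [("A", "A")] * 4 + [("A", "B")] * 6 + [("B", "C")] * 5
        + [("C", "C")] * 3 + [("A", "C")] * 2
    )
    exact = hwe_exact_test(pairs)
    mc = hwe_exact_test(pairs, max_enum_arrays=1, mc_reps=100_000, seed=3)
    assert mc == pytest.approx(exact, abs=0.01)
    assert 0 < mc <= 1


def test_statistics_invariant_to_labels_and_order(rng):
    pairs = [tuple(sorted(rng.choice(list("ABC"), size=2))) for _ in range(25)]
    relabel = {"A": "250", "B": "104", "C": "308"}
    relabelled = [tuple(sorted((relabel[a], relabel[b]))) for a, b in pairs]
    shuffled = list(pairs)
    rng.shuffle(shuffled)
    for variant in (relabelled, shuffled):
        assert observed_heterozygosity(variant) == observed_heterozygosity(pairs)
        assert sorted(allele_frequencies(variant).values()) == pytest.approx(
            sorted(allele_frequencies(pairs).values())
        )
        assert pic(allele_frequencies(variant)) == pytest.approx(
            pic(allele_frequencies(pairs))
        )
        assert hwe_exact_test(variant) == pytest.approx(hwe_exact_test(pairs))


def test_genotype_table_round_trip(tmp_path):
    spec = GenotypeSimSpec(loci={"L1": (0.5, 0.5), "L2": (0.2, 0.3, 0.5)},
                           n_individuals=12, missing_rate=0.1)
    table = simulate_genotypes(spec, seed=5)
    path = tmp_path / "geno.tsv"
    table.to_tsv(path, header_lines=["seed=5"])
    back = GenotypeTable.from_tsv(path)
    assert back.individuals == table.individuals
    assert back.calls == table.calls


def test_diversity_table_and_panel_summary():
    spec = GenotypeSimSpec(
        loci={"L1": (0.5, 0.5), "L2": (0.25, 0.25, 0.25, 0.25), "L3": (1.0,)},
        n_individuals=30,
    )
    table = simulate_genotypes(spec, seed=11)
    df = diversity_table(table, mc_reps=2000, seed=0)
    assert list(df["locus"]) == ["L1", "L2", "L3"]
    mono = df[df["locus"] == "L3"].iloc[0]
    assert mono["k"] == 1 and mono["pic"] == 0.0 and mono["hwe_p"] == 1.0
    for _, row in df.iterrows():
        assert 0 <= row["ho"] <= 1 and 0 <= row["he"] < 1
        assert 1 <= row["ar"] <= row["k"] + 1e-12
        assert 0 < row["hwe_p"] <= 1
    s = panel_summary(df)
    assert s["total_k"] == df["k"].sum()
    assert s["mean_ho"] == pytest.approx(df["ho"].mean())
    assert s["min_pic"] == df["pic"].min()


def test_ho_near_half_under_hwe_with_equifrequent_alleles():
    spec = GenotypeSimSpec(loci={"L1": (0.5, 0.5)}, n_individuals=10_000)
    table = simulate_genotypes(spec, seed=21)
    ho = observed_heterozygosity(table.pairs("L1"))
    se = math.sqrt(0.25 / 10_000)
    assert abs(ho - 0.5) < 3 * se


def test_locus_diversity_missing_handling():
    table = GenotypeTable(
        individuals=["i1", "i2", "i3"],
        loci=["L1"],
        calls={"L1": [("A", "B"), None, ("A", "A")]},
    )
    d = locus_diversity(table, "L1")
    assert d.n == 2 and d.k == 2 and d.ho == 0.5
    empty = GenotypeTable(individuals=["i1"], loci=["L1"], calls={"L1": [None]})
    with pytest.raises(ValueError, match="no typed"):
        locus_diversity(empty, "L1")
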