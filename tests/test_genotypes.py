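"""QC filter and GCTA GRM, checked against scalar brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cavityepp.genotypes import (
    GenotypeMatrix,
    allele_frequencies,
    filter_call_rate,
    grm_gcta,
    read_dosage_csv,
    read_vcf,
    write_dosage_csv,
    write_vcf,
)
from cavityepp.pedigree import social_relatedness_matrix
from cavityepp.synthetic_data import SimulationConfig, simulate_population


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def grm_scalar_oracle(dosages: np.ndarray) -> np.ndarray:
    """Naive per-pair scalar-loop GCTA estimator (pairwise-complete loci)."""
    n, m = dosages.shape
    called = ~np.isnan(dosages)
    p = np.array(
        [np.nansum(dosages[:, k]) / (2.0 * called[:, k].sum()) for k in range(m)]
    )
    out = np.full((n, n), np.nan)
    for j in range(n):
        for k in range(n):
            if j == k:
                total, cnt = 0.0, 0
                for l in range(m):
                    if not called[j, l]:
                        continue
                    x = dosages[j, l]
                    total += (x * x - (1 + 2 * p[l]) * x + 2 * p[l] ** 2) / (
                        2 * p[l] * (1 - p[l])
                    )
                    cnt += 1
                out[j, j] = 1.0 + total / cnt
            else:
                total, cnt = 0.0, 0
                for l in range(m):
                    if not (called[j, l] and called[k, l]):
                        continue
                    total += (
                        (dosages[j, l] - 2 * p[l])
                        * (dosages[k, l] - 2 * p[l])
                        / (2 * p[l] * (1 - p[l]))
                    )
                    cnt += 1
                if cnt:
                    out[j, k] = total / cnt
    return out


def brute_force_filter(dos: np.ndarray, threshold: float):
    """Exhaustive search over all removal orders; returns the set of stable
    (rows, cols) fixed points reachable by greedy removal in any order."""
    n, m = dos.shape

    def stable(rows, cols):
        sub = dos[np.ix_(sorted(rows), sorted(cols))]
        cr_i = 1 - np.isnan(sub).mean(axis=1)
        cr_l = 1 - np.isnan(sub).mean(axis=0)
        return (cr_i >= threshold).all() and (cr_l >= threshold).all()

    results = set()
    frontier = [(frozenset(range(n)), frozenset(range(m)))]
    seen = set()
    while frontier:
        rows, cols = frontier.pop()
        if (rows, cols) in seen:
            continue
        seen.add((rows, cols))
        if stable(rows, cols):
            results.add((rows, cols))
            continue
        sub = dos[np.ix_(sorted(rows), sorted(cols))]
        rlist, clist = sorted(rows), sorted(cols)
        cr_i = 1 - np.isnan(sub).mean(axis=1)
        cr_l = 1 - np.isnan(sub).mean(axis=0)
        for i, cr in zip(rlist, cr_i):
            if cr < threshold:
                frontier.append((rows - {i}, cols))
        for j, cr in zip(clist, cr_l):
            if cr < threshold:
                frontier.append((rows, cols - {j}))
    return results


# ---------------------------------------------------------------------------
# call-rate filter
# ---------------------------------------------------------------------------

class TestCallRateFilter:
    def test_low_call_rate_individual_removed(self):
        dos = np.ones((3, 10))
        dos[0, :4] = np.nan  # 60% call rate < 70%
        g = GenotypeMatrix(["a", "b", "c"], [f"L{i}" for i in range(10)], dos)
        filtered, report = filter_call_rate(g, 0.70)
        assert report.removed_individuals == ["a"]
        assert filtered.ids == ["b", "c"]

    def test_fully_observed_unchanged(self, tiny_matrix):
        full = GenotypeMatrix(
            tiny_matrix.ids,
            tiny_matrix.loci,
            np.nan_to_num(tiny_matrix.dosages, nan=1.0),
        )
        filtered, report = filter_call_rate(full, 0.70)
        assert filtered.ids == full.ids and filtered.loci == full.loci
        assert not report.removed_individuals and not report.removed_loci

    def test_two_pass_matches_brute_force(self):
        # crafted 4x5: individual 0 misses 2/5 loci (60%); after removing it,
        # locus 2's call rate among the rest is fine, so only ind 0 goes
        dos = np.ones((4, 5))
        dos[0, [0, 1]] = np.nan
        dos[1, 2] = np.nan  # locus 2: 3/4 called = 75% with ind0, 2/3 without
        g = GenotypeMatrix(
            [f"i{r}" for r in range(4)], [f"L{c}" for c in range(5)], dos
        )
        filtered, _ = filter_call_rate(g, 0.70)
        kept = (
            frozenset(g.ids.index(i) for i in filtered.ids),
            frozenset(g.loci.index(l) for l in filtered.loci),
        )
        assert kept in brute_force_filter(dos, 0.70)

    def test_all_removed_raises(self):
        dos = np.full((2, 4), np.nan)
        dos[:, 0] = 1.0  # 25% call rate everywhere
        g = GenotypeMatrix(["a", "b"], ["L0", "L1", "L2", "L3"], dos)
        with pytest.raises(ValueError, match="0.9"):
            filter_call_rate(g, 0.9)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFrequencies:
    def test_simple_and_monomorphic(self):
        dos = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        g = GenotypeMatrix(["a", "b", "c"], ["L0", "L1"], dos)
        freqs = allele_frequencies(g)
        assert freqs.loc["L0", "freq"] == 0.5
        assert not freqs.loc["L0", "monomorphic"]
        assert freqs.loc["L1", "freq"] == 0.0
        assert freqs.loc["L1", "monomorphic"]

    def test_matches_direct_count(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, size=(50, 20)).astype(float)
        dos[rng.uniform(size=dos.shape) < 0.1] = np.nan
        g = GenotypeMatrix(
            [f"i{r}" for r in range(50)], [f"L{c}" for c in range(20)], dos
        )
        freqs = allele_frequencies(g)
        for c in range(20):
            col = dos[:, c]
            obs = col[~np.isnan(col)]
            assert freqs.iloc[c]["freq"] == pytest.approx(
                obs.sum() / (2 * len(obs)), abs=0
            )

    def test_zero_calls_raises(self):
        dos = np.array([[0.0, np.nan], [1.0, np.nan]])
        g = GenotypeMatrix(["a", "b"], ["L0", "L1"], dos)
        with pytest.raises(ValueError, match="zero non-missing"):
            allele_frequencies(g)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

class TestGrmGcta:
    def test_identical_homozygotes_at_half_freq(self):
        # two of four individuals identical with dosages in {0,2}; freq 0.5
        # at every locus by construction.  Hand evaluation of the estimator:
        # each term (x-2p)^2 / (2p(1-p)) = 1 / 0.5 = 2, so the duplicate
        # pair's off-diagonal is 2.0 -- equal to their (fully homozygous,
        # F = 1) diagonal, as it must be for genetic copies.
        dos = np.array(
            [
                [0.0, 2.0, 0.0, 2.0],
                [0.0, 2.0, 0.0, 2.0],
                [2.0, 0.0, 2.0, 0.0],
                [2.0, 0.0, 2.0, 0.0],
            ]
        )
        g = GenotypeMatrix(["a", "b", "c", "d"], list("WXYZ"), dos)
        grm = grm_gcta(g)
        assert grm.get("a", "b") == pytest.approx(2.0, abs=1e-12)
        assert grm.get("a", "a") == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_scalar_oracle_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        m = int(rng.integers(8, 15))
        dos = rng.integers(0, 3, size=(n, m)).astype(float)
        dos[rng.uniform(size=dos.shape) < 0.1] = np.nan
        g = GenotypeMatrix(
            [f"i{r}" for r in range(n)], [f"L{c}" for c in range(m)], dos
        )
        freqs = allele_frequencies(g)
        poly = ~freqs["monomorphic"].to_numpy()
        # oracle computed on the same polymorphic subset the GRM uses
        keep = (freqs["freq"].to_numpy() >= 1 / (2 * n)) & (
            freqs["freq"].to_numpy() <= 1 - 1 / (2 * n)
        )
        oracle = grm_scalar_oracle(dos[:, keep])
        grm = grm_gcta(g)
        both = ~np.isnan(oracle)
        assert np.allclose(grm.values[both], oracle[both], atol=1e-10, rtol=0)

    def test_duplicate_individual_matches_oracle(self):
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 3, size=(5, 10)).astype(float)
        dos = np.vstack([dos, dos[0]])  # duplicate of individual 0
        g = GenotypeMatrix(
            [f"i{r}" for r in range(6)], [f"L{c}" for c in range(10)], dos
        )
        n = 6
        freqs = allele_frequencies(g)
        keep = (freqs["freq"].to_numpy() >= 1 / (2 * n)) & (
            freqs["freq"].to_numpy() <= 1 - 1 / (2 * n)
        )
        oracle = grm_scalar_oracle(dos[:, keep])
        grm = grm_gcta(g)
        assert grm.get("i0", "i5") == pytest.approx(oracle[0, 5], abs=1e-10)

    def test_order_invariance(self, tiny_matrix):
        grm = grm_gcta(tiny_matrix)
        perm_ids = tiny_matrix.ids[::-1]
        perm_loci = tiny_matrix.loci[::-1]
        grm_perm = grm_gcta(tiny_matrix.subset(ids=perm_ids, loci=perm_loci))
        for a in tiny_matrix.ids:
            for b in tiny_matrix.ids:
                assert grm.get(a, b) == pytest.approx(
                    grm_perm.get(a, b), abs=1e-12
                )

    def test_parent_offspring_and_unrelated_means(self, small_population):
        genotypes, nests, pedigree, truth = small_population
        aut = [l for l in genotypes.loci if l.startswith("SNP")]
        grm = grm_gcta(genotypes.subset(loci=aut))
        idx = {i: r for r, i in enumerate(grm.ids)}
        po, unrel = [], []
        mothers = list(nests["mother_id"])
        for off, row in truth.offspring.iterrows():
            if row["is_parasite"]:
                continue
            po.append(grm.values[idx[off], idx[row["true_mother"]]])
            # a mother from the other plot is pedigree-unrelated
            other = [
                m for m in mothers
                if m != row["true_mother"] and m.split("_")[1][:3] != off[:3]
            ][0]
            unrel.append(grm.values[idx[off], idx[other]])
        assert 0.45 < np.mean(po) < 0.55
        assert -0.05 < np.mean(unrel) < 0.05

    def test_grm_regression_on_social_expectation(self, small_population):
        """E[G] tracks additive relatedness: regression slope in [0.9, 1.1]."""
        genotypes, nests, pedigree, truth = small_population
        aut = [l for l in genotypes.loci if l.startswith("SNP")]
        grm = grm_gcta(genotypes.subset(loci=aut))
        # restrict to offspring without EPP so the social pedigree is true
        clean = [
            o for o, row in truth.offspring.iterrows()
            if not row["is_epo"] and not row["is_parasite"]
        ]
        parents = sorted(
            set(nests["mother_id"]) | set(nests["father_id"])
        )
        ids = parents + clean
        expected = social_relatedness_matrix(pedigree, ids)
        idx = [grm.ids.index(i) for i in ids]
        observed = grm.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(ids), k=1)
        x, y = expected[iu], observed[iu]
        slope = np.polyfit(x, y, 1)[0]
        assert 0.9 < slope < 1.1


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

class TestIO:
    def test_dosage_csv_roundtrip(self, tiny_matrix, tmp_path):
        path = tmp_path / "dos.csv"
        write_dosage_csv(tiny_matrix, path)
        back = read_dosage_csv(path)
        assert back.ids == tiny_matrix.ids
        assert back.loci == tiny_matrix.loci
        np.testing.assert_array_equal(back.dosages, tiny_matrix.dosages)

    def test_vcf_roundtrip(self, tiny_matrix, tmp_path):
        path = tmp_path / "g.vcf"
        write_vcf(tiny_matrix, path)
        back = read_vcf(path)
        assert back.ids == tiny_matrix.ids
        assert back.loci == tiny_matrix.loci
        np.testing.assert_array_equal(back.dosages, tiny_matrix.dosages)

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t1\tv1\tA\tG,T\t.\t.\t.\tGT\t0/1\t1/2\n"
        )
        with pytest.raises(ValueError, match="multiallelic"):
            read_vcf(path)
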