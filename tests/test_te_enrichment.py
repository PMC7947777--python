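import numpy as np
import pytest

from macrosyn import te_enrichment as tee
from macrosyn.types import ChromosomeSet, TERecord

CHROMS = ChromosomeSet({"c1": 1_000_000, "c2": 600_000}, {})


class TestOverlapStats:
    def test_contained_and_clipped(self):
        regions = [("c1", 0, 500)]
        tes = [TERecord("c1", 100, 200, "LTR"), TERecord("c1", 490, 600, "DNA")]
        out = tee.overlap_stats(regions, tes)
        assert out["LTR"] == (1, 100)
        assert out["DNA"] == (1, 10)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(0)
        regions = sorted(
            ("c1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 900_000, 8), rng.integers(100, 50_000, 8))
        )
        tes = [
            TERecord("c1", int(s), int(s) + int(l), cls)
            for s, l, cls in zip(
                rng.integers(0, 990_000, 60),
                rng.integers(50, 5_000, 60),
                rng.choice(["DNA", "LTR", "LINE"], 60),
            )
        ]
        got = tee.overlap_stats(regions, tes)
        # brute-force pairwise intersection
        expected = {}
        for te in tes:
            for _, rs, re_ in regions:
                ov = min(te.end, re_) - max(te.start, rs)
                if ov > 0:
                    c, s = expected.get(te.te_class, (0, 0))
                    expected[te.te_class] = (c + 1, s + ov)
        assert got == expected

    def test_unsorted_regions_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            tee.overlap_stats([("c1", 500, 600), ("c1", 0, 100)], [])


class TestRandomRegionSets:
    def test_reproducible_and_lengths_preserved(self):
        regions = [("c1", 0, 10_000), ("c1", 50_000, 75_000)]
        set1 = list(tee.random_region_sets(regions, CHROMS, n_perm=3, seed=42))
        set2 = list(tee.random_region_sets(regions, CHROMS, n_perm=3, seed=42))
        assert set1 == set2
        for regs in set1:
            assert sorted(e - s for _, s, e in regs) == [10_000, 25_000]
            for chrom, s, e in regs:
                assert 0 <= s and e <= CHROMS.lengths[chrom]

    def test_mean_total_span_preserved(self):
        regions = [("c1", 0, 10_000), ("c1", 50_000, 75_000)]
        totals = [
            sum(e - s for _, s, e in regs)
            for regs in tee.random_region_sets(regions, CHROMS, n_perm=20, seed=1)
        ]
        assert set(totals) == {35_000}

    def test_region_longer_than_autosomes_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            list(
                tee.random_region_sets(
                    [("c1", 0, 2_000_000)], CHROMS, n_perm=1, seed=0
                )
            )


class TestPermutationEnrichment:
    def test_whole_autosome_regions_fold_one(self):
        rng = np.random.default_rng(3)
        tes = []
        for chrom, length in CHROMS.lengths.items():
            for s in rng.integers(0, length - 1000, 300):
                tes.append(TERecord(chrom, int(s), int(s) + 500, "LTR"))
        tes.sort(key=lambda t: (t.chrom, t.start))
        regions = sorted((c, 0, CHROMS.lengths[c]) for c in CHROMS.lengths)
        res = tee.permutation_enrichment(regions, tes, CHROMS, n_perm=100, seed=0)
        assert res["LTR"].fold == pytest.approx(1.0)

    def test_warns_on_tiny_n_perm(self):
        tes = [TERecord("c1", 0, 100, "DNA")]
        with pytest.warns(UserWarning):
            tee.permutation_enrichment([("c1", 0, 1000)], tes, CHROMS, n_perm=50, seed=0)

    def test_p_invariant_to_class_relabeling(self):
        rng = np.random.default_rng(4)
        tes = [
            TERecord("c1", int(s), int(s) + 300, "LTR")
            for s in sorted(rng.integers(0, 999_000, 200))
        ]
        regions = [("c1", 100_000, 160_000), ("c1", 400_000, 430_000)]
        r1 = tee.permutation_enrichment(regions, tes, CHROMS, n_perm=300, seed=9)
        relabeled = [TERecord(t.chrom, t.start, t.end, "DNA") for t in tes]
        r2 = tee.permutation_enrichment(regions, relabeled, CHROMS, n_perm=300, seed=9)
        assert r1["LTR"].p_empirical == r2["DNA"].p_empirical
        assert r1["LTR"].observed_count == r2["DNA"].observed_count


class TestExpectedSpan:
    def test_fold_identity_with_fractions(self):
        # fold = (class fraction in regions) / (region fraction of autosomes)
        autosome_total = 278_000_000
        region_total = 0.124 * autosome_total
        class_total = 40_000_000
        observed = 0.295 * class_total
        exp = tee.expected_span(class_total, region_total, autosome_total)
        assert observed / exp == pytest.approx(0.295 / 0.124, rel=1e-12)

    def test_degenerate_cases(self):
        assert tee.expected_span(0, 10, 100) == 0.0
        with pytest.raises(ValueError):
            tee.expected_span(10, 10, 0)


class TestWindowDensity:
    def test_full_and_empty_windows(self):
        chroms = ChromosomeSet({"c1": 300_000})
        tes = [TERecord("c1", 0, 100_000, "LTR")]
        df = tee.window_density(tes, chroms, window=100_000)
        assert list(df["LTR"]) == [1.0, 0.0, 0.0]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        chroms = ChromosomeSet({"c1": 250_000})
        tes = sorted(
            (
                TERecord("c1", int(s), min(int(s) + int(l), 250_000), "DNA")
                for s, l in zip(
                    rng.integers(0, 249_000, 40), rng.integers(100, 30_000, 40)
                )
            ),
            key=lambda t: t.start,
        )
        df = tee.window_density(tes, chroms, window=100_000)
        base = np.zeros(250_000, dtype=bool)
        for t in tes:
            base[t.start : t.end] = True
        for _, row in df.iterrows():
            frac = base[int(row.start) : int(row.end)].mean()
            assert row["DNA"] == pytest.approx(frac)

    def test_span_bounded_by_region_length(self, small_pair):
        cfg, _, B, _, truth = small_pair
        from macrosyn.simulate import plant_tes

        tes = plant_tes(B, cfg, seed=77)
        regions = [("chr1", 0, 200_000)]
        out = tee.overlap_stats(regions, [t for t in tes if t.chrom == "chr1"])
        for cls, (_, span) in out.items():
            assert span <= 200_000


class TestEndDistanceCorrelation:
    def test_gradient_toward_ends(self):
        chroms = ChromosomeSet({"c1": 2_000_000})
        df = tee.window_density([], chroms, window=100_000)
        mid = (df["start"] + df["end"]) / 2
        dist = np.minimum(mid, 2_000_000 - mid)
        df["TE"] = 1.0 - dist / dist.max()  # dense at ends
        res = tee.end_distance_correlation(df, chroms, classes=["TE"])
        assert res["TE"].statistic < -0.9

    def test_uniform_density_null(self):
        rng = np.random.default_rng(12)
        chroms = ChromosomeSet({"c1": 5_000_000})
        ps = []
        for _ in range(20):
            df = tee.window_density([], chroms, window=100_000)
            df["TE"] = rng.uniform(0, 1, len(df))
            ps.append(tee.end_distance_correlation(df, chroms, classes=["TE"])["TE"].p_value)
        assert float(np.median(ps)) > 0.05

    def test_too_few_windows(self):
        chroms = ChromosomeSet({"c1": 200_000})
        df = tee.window_density([], chroms, window=100_000)
        with pytest.raises(ValueError):
            tee.end_distance_correlation(df, chroms, classes=[])
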