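import math
from dataclasses import replace

import numpy as np
import pytest

from macrosyn.simulate import (
    SimulationConfig,
    evolve_descendant,
    plant_tes,
    simulate_ancestor,
    simulate_coverage,
    simulate_expression,
)


def cfg(**kw):
    base = dict(seed=1, n_chrom=3, genes_per_chrom=50)
    base.update(kw)
    return SimulationConfig(**base)


class TestAncestor:
    def test_counts_and_ranks(self):
        g = simulate_ancestor(cfg(n_chrom=2, genes_per_chrom=5))
        assert len(g.genes) == 10
        by = g.genes_by_chrom()
        for genes in by.values():
            assert [x.rank for x in genes] == list(range(len(genes)))
        assert g.chromosomes.roles["chr1"] == "X"

    def test_deterministic(self):
        a = simulate_ancestor(cfg(seed=9))
        b = simulate_ancestor(cfg(seed=9))
        assert a.genes == b.genes and a.chromosomes.lengths == b.chromosomes.lengths

    def test_length_means_match_config(self):
        # law of large numbers: realized gene/gap means near lognormal means
        c = cfg(seed=2, n_chrom=5, genes_per_chrom=2000)
        g = simulate_ancestor(c)
        lens = np.array([x.end - x.start for x in g.genes])
        mu, sigma = c.gene_len
        expected = math.exp(mu + sigma**2 / 2)
        assert abs(lens.mean() - expected) / expected < 0.1

    def test_zero_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            simulate_ancestor(cfg(n_chrom=0))


class TestEvolve:
    def test_zero_events_identity_order(self):
        anc = simulate_ancestor(cfg())
        des, truth, ortho = evolve_descendant(
            anc,
            cfg(n_inversions=0, n_translocations=0, n_fissions=0, n_fusions=0),
            seed=3,
        )
        assert truth.junctions == []
        anc_order = {c: [g.gene_id for g in gs] for c, gs in anc.genes_by_chrom().items()}
        des_order = {c: [g.gene_id for g in gs] for c, gs in des.genes_by_chrom().items()}
        assert anc_order == des_order

    def test_single_translocation_two_junctions(self):
        anc = simulate_ancestor(cfg())
        _, truth, _ = evolve_descendant(
            anc,
            cfg(n_inversions=0, n_translocations=1, n_fissions=0, n_fusions=0),
            seed=4,
        )
        assert len(truth.junctions) == 2
        assert len({c for c, _ in truth.junctions}) == 2  # inter-chromosomal

    def test_protect_x_never_touches_x(self):
        anc = simulate_ancestor(cfg(n_chrom=6, genes_per_chrom=60))
        c = cfg(
            n_chrom=6,
            genes_per_chrom=60,
            n_inversions=20,
            n_translocations=20,
            n_fissions=5,
            n_fusions=2,
            protect_x=True,
        )
        des, truth, _ = evolve_descendant(anc, c, seed=5)
        assert truth.x_label == "chr1"
        for ev in truth.events:
            assert "chr1" not in ev.chroms
        # X gene order untouched
        anc_x = [g.gene_id for g in anc.genes_by_chrom()["chr1"]]
        des_x = [g.gene_id for g in des.genes_by_chrom()["chr1"]]
        assert anc_x == des_x

    def test_ortholog_table_is_bijection(self):
        anc = simulate_ancestor(cfg())
        des, _, ortho = evolve_descendant(anc, cfg(), seed=6)
        a_ids = [a for a, _ in ortho]
        b_ids = [b for _, b in ortho]
        assert len(set(a_ids)) == len(ortho) == len(anc.genes)
        assert set(b_ids) == {g.gene_id for g in des.genes}

    def test_gene_intervals_never_overlap(self):
        anc = simulate_ancestor(cfg(n_chrom=4, genes_per_chrom=80))
        c = cfg(
            n_chrom=4, genes_per_chrom=80,
            n_inversions=10, n_translocations=10, n_fissions=2, n_fusions=1,
        )
        des, _, _ = evolve_descendant(anc, c, seed=7)
        for genes in des.genes_by_chrom().values():
            ordered = sorted(genes, key=lambda g: g.start)
            for g1, g2 in zip(ordered, ordered[1:]):
                assert g1.end <= g2.start

    def test_junctions_lie_inside_chromosomes(self):
        anc = simulate_ancestor(cfg())
        des, truth, _ = evolve_descendant(anc, cfg(), seed=8)
        for chrom, pos in truth.junctions:
            assert 0 <= pos < des.chromosomes.lengths[chrom]

    def test_infeasible_events_rejected(self):
        anc = simulate_ancestor(cfg(n_chrom=2))  # one X + one autosome
        with pytest.raises(ValueError, match="infeasible"):
            evolve_descendant(
                anc, cfg(n_chrom=2, n_translocations=1, protect_x=True), seed=9
            )


class TestPlantTes:
    def test_zero_fractions_empty(self):
        g = simulate_ancestor(cfg())
        c = replace(cfg(), te_class_fractions={})
        assert plant_tes(g, c, seed=1) == []

    def test_fraction_realized_within_half_point(self):
        c = cfg(seed=3, n_chrom=3, genes_per_chrom=300)
        g = simulate_ancestor(c)
        tes = plant_tes(g, c, seed=2)
        total = sum(g.chromosomes.lengths.values())
        for cls, frac in c.te_class_fractions.items():
            bp = sum(t.length for t in tes if t.te_class == cls)
            assert abs(bp / total - frac) <= 0.005, cls

    def test_same_class_tes_disjoint(self):
        c = cfg(seed=4, n_chrom=2, genes_per_chrom=200)
        g = simulate_ancestor(c)
        tes = plant_tes(g, c, seed=5)
        by = {}
        for t in tes:
            by.setdefault((t.te_class, t.chrom), []).append((t.start, t.end))
        for ivals in by.values():
            ivals.sort()
            for a, b in zip(ivals, ivals[1:]):
                assert a[1] <= b[0]

    def test_divergence_mixture_sampled(self):
        c = cfg(seed=5, n_chrom=3, genes_per_chrom=300)
        g = simulate_ancestor(c)
        tes = plant_tes(g, c, seed=6)
        div = np.array([t.divergence_pct for t in tes])
        assert np.all(div >= 0)
        scale, (lo, hi), weight = c.te_age_mixture
        recent = float(np.mean(div < lo))
        assert abs(recent - weight) < 0.1

    def test_deterministic(self):
        c = cfg(seed=6)
        g = simulate_ancestor(c)
        assert plant_tes(g, c, seed=7) == plant_tes(g, c, seed=7)


class TestCoverage:
    def test_x_at_half_male_depth(self):
        c = cfg(seed=7, n_chrom=3, genes_per_chrom=400)
        g = simulate_ancestor(c)
        dm, df = simulate_coverage(g, c, seed=8)
        x_m = dm.loc[dm.chrom == "chr1", "depth"].mean()
        a_m = dm.loc[dm.chrom != "chr1", "depth"].mean()
        assert x_m / a_m == pytest.approx(0.5, abs=0.05)
        assert df["depth"].mean() == pytest.approx(c.depth_f, rel=0.03)

    def test_window_tiling(self):
        c = cfg(seed=8)
        g = simulate_ancestor(c)
        dm, _ = simulate_coverage(g, c, seed=9)
        for chrom, length in g.chromosomes.lengths.items():
            sub = dm[dm.chrom == chrom]
            assert len(sub) == math.ceil(length / c.coverage_window)
            assert sub["end"].max() == length

    def test_positive_depth_required(self):
        g = simulate_ancestor(cfg())
        with pytest.raises(ValueError):
            simulate_coverage(g, replace(cfg(), depth_m=0.0), seed=1)


class TestExpression:
    def test_truth_empty_when_no_bias_planted(self):
        c = replace(cfg(), frac_male_biased=0.0)
        g = simulate_ancestor(c)
        *_, mb = simulate_expression(g, c, seed=1)
        assert mb == []

    def test_x_fraction_of_male_biased(self):
        c = cfg(seed=9, n_chrom=4, genes_per_chrom=250, frac_male_biased=0.1)
        g = simulate_ancestor(c)
        *_, mb = simulate_expression(g, c, seed=2)
        chrom_of = {x.gene_id: x.chrom for x in g.genes}
        on_x = sum(chrom_of[gid] == "chr1" for gid in mb)
        assert abs(on_x / len(mb) - c.male_biased_x_frac) <= 0.1

    def test_zero_x_shift_indistinguishable(self):
        # self-consistency: no X shift means X and autosome TPM match
        from macrosyn import stats

        ps = []
        for seed in range(5):
            c = SimulationConfig(
                seed=seed, n_chrom=4, genes_per_chrom=250,
                x_log2_shift=0.0, frac_male_biased=0.0,
            )
            g = simulate_ancestor(c)
            tpm, *_ = simulate_expression(g, c, seed=seed + 50)
            fa = tpm[[col for col in tpm.columns if col.startswith("FA")]].mean(axis=1)
            chrom_of = {x.gene_id: x.chrom for x in g.genes}
            is_x = np.array([chrom_of[gid] == "chr1" for gid in tpm.index])
            ps.append(
                stats.wilcoxon_rank_sum(
                    np.log10(fa[is_x]), np.log10(fa[~is_x])
                ).p_value
            )
        assert float(np.median(ps)) > 0.01

    def test_de_table_consistent_with_truth(self):
        c = cfg(seed=10, n_chrom=3, genes_per_chrom=200, frac_male_biased=0.05)
        g = simulate_ancestor(c)
        _, _, de, mb = simulate_expression(g, c, seed=3)
        assert set(de.columns) == {"qval", "b_M", "b_FW", "b_N"}
        assert (de.loc[mb, "qval"] < 0.05).all()
        assert (de.loc[mb, "b_M"] > 0.5).all()

    def test_replicates_required(self):
        g = simulate_ancestor(cfg())
        with pytest.raises(ValueError):
            simulate_expression(g, replace(cfg(), n_reps=1), seed=1)
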