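"""Gene-set construction, Wilkinson combination, ensemble calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phytoarray as pa
from phytoarray.genesets import ensemble_set_test, rank_sum_p


class TestBuildGeneSets:
    def test_n_stress_membership_exact(self):
        design = pa.simulate_design(seed=2)
        sets = {s.set_id: s for s in pa.build_gene_sets(design)}
        gs = sets["HL_Pro|N stress"]
        ann = design.target_annotation()
        expected = ann.index[(ann["phylogroup"] == "HL_Pro")
                             & ann["gene"].isin(pa.GENE_SETS["N stress"])]
        assert sorted(gs.members) == sorted(expected)

    def test_rubisco_set_is_rbcl_only(self):
        design = pa.simulate_design(seed=2)
        ann = design.target_annotation()
        for gs in pa.build_gene_sets(design):
            if gs.label == "RuBisCO":
                assert (ann.loc[gs.members, "gene"] == "rbcL").all()

    def test_empty_scope_omitted(self):
        design = pa.simulate_design(n_phylogroups=1, strains_per_group=2,
                                    targets_per_strain=3, seed=0)
        # 3 targets per strain -> only the first three core genes present;
        # labels with no annotated members are dropped
        labels = {s.label for s in pa.build_gene_sets(design)}
        assert "RuBisCO" not in labels
        assert "N stress" in labels

    def test_unknown_label_rejected(self):
        design = pa.simulate_design(n_phylogroups=1, strains_per_group=2,
                                    seed=0)
        with pytest.raises(ValueError, match="unknown"):
            pa.build_gene_sets(design, labels=["banana stress"])

    def test_strain_scope(self):
        design = pa.simulate_design(n_phylogroups=2, strains_per_group=2,
                                    seed=1)
        sets = pa.build_gene_sets(design, scope_mode="strain")
        assert all(s.scope_kind == "strain" for s in sets)
        ann = design.target_annotation()
        for s in sets:
            assert (ann.loc[s.members, "strain_id"] == s.scope).all()


class TestWilkinson:
    def test_k1_identity(self):
        assert pa.wilkinson_combine([0.2], r=1) == pytest.approx(0.2)

    def test_k2_r1_closed_form(self):
        # Beta(1, 2) CDF: 1 - (1 - p_(1))^2
        assert pa.wilkinson_combine([0.1, 0.5], r=1) == pytest.approx(
            1 - 0.9 ** 2)

    def test_k3_r3_closed_form(self):
        # Beta(3, 1) CDF: p_(3)^3
        assert pa.wilkinson_combine([0.2, 0.3, 0.5], r=3) == pytest.approx(
            0.5 ** 3)

    def test_r_out_of_range(self):
        with pytest.raises(ValueError):
            pa.wilkinson_combine([0.1, 0.2], r=3)

    def test_uniform_under_uniform_inputs(self):
        """10,000 combinations of independent uniforms stay uniform
        (Kolmogorov band at alpha = 0.01)."""
        rng = np.random.default_rng(8)
        draws = rng.random((10000, 4))
        combined = stats.beta.cdf(np.sort(draws, axis=1)[:, 1], 2, 3)
        d = stats.kstest(combined, "uniform")
        assert d.pvalue > 0.01


class TestBaseStatistics:
    def test_ranksum_extreme_matches_hypergeometric_enumeration(self):
        """All 5 members above all 95 non-members: the one-sided exact
        rank-sum p equals 1 / C(100, 5), the count of the single most
        extreme member placement."""
        members = np.arange(96, 101, dtype=float)
        non = np.arange(1, 96, dtype=float)
        p = rank_sum_p(members, non, alternative="greater")
        assert p == pytest.approx(1.0 / math.comb(100, 5), rel=1e-12)

    def test_permutation_add_one_floor(self):
        """An observed statistic beyond every permutation gets the add-one
        estimate 1 / (n_perm + 1)."""
        rng = np.random.default_rng(0)
        t = np.concatenate([rng.normal(0, 1, 60), np.full(6, 30.0)])
        de = np.zeros(66, bool)
        mask = np.zeros(66, bool)
        mask[60:] = True
        res = ensemble_set_test(t, de, mask, np.random.default_rng(1),
                                n_perm=200)
        assert res["base_p"]["meant"] == pytest.approx(1 / 201)
        assert res["p_combined"] == pytest.approx(1 / 201)

    def test_degenerate_scores_give_p_one(self):
        t = np.ones(30)
        mask = np.zeros(30, bool)
        mask[:5] = True
        res = ensemble_set_test(t, np.zeros(30, bool), mask,
                                np.random.default_rng(0), n_perm=100)
        assert res["p_combined"] == 1.0

    def test_null_combined_p_uniform(self, null_sim_compact):
        """200 random member sets drawn from a zero-effect simulation:
        the calibrated combined p is KS-uniform at alpha = 0.01."""
        design, sheet, _truth, expr = null_sim_compact
        de = pa.run_differential_expression(expr, sheet)
        res = de["T24_urea_vs_T24_control"]
        ann = design.target_annotation()
        universe = res.index.intersection(
            ann.index[ann["phylogroup"] == "HL_Pro"])
        block = res.loc[universe]
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            mask = np.zeros(len(universe), bool)
            mask[rng.choice(len(universe), 8, replace=False)] = True
            out = ensemble_set_test(block["t"].to_numpy(),
                                    block["de"].to_numpy(), mask, rng,
                                    n_perm=2000)
            ps.append(out["p_combined"])
        d = stats.kstest(np.asarray(ps), "uniform")
        assert d.pvalue > 0.01


class TestArtifactFilter:
    @pytest.mark.parametrize("direction,a_g,a_tot,expected", [
        (+1, 1.5, 1.2, True),    # up and ratio > 1
        (+1, 1.1, 1.2, False),   # up but below the phylogroup total
        (-1, 0.8, 0.9, True),    # down and ratio < 1
        (-1, 0.95, 0.9, False),
    ])
    def test_rule(self, direction, a_g, a_tot, expected):
        assert pa.artifact_filter(direction, a_g, a_tot) is expected

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            pa.artifact_filter(1, 1.5, 0.0)

    @pytest.mark.parametrize("direction,a_g,expected", [
        (+1, 1.25, True),
        (+1, 1.15, False),
        (-1, 0.80, True),    # 0.80 < 1/1.2
        (-1, 0.90, False),
    ])
    def test_magnitude_classification(self, direction, a_g, expected):
        assert pa.classify_magnitude(direction, a_g) is expected


class TestResponseRecovery:
    def test_implanted_responses_recovered(self, default_sim,
                                           default_set_results):
        """Implanted set responses come back significant, retained, and
        with the right sign; the pure-abundance scenario yields none."""
        _design, _m, _sheet, truth = default_sim
        res = default_set_results
        hits = res.set_index(["phylogroup", "label", "contrast"])
        recovered = 0
        implanted = [e for e in truth.config.effects if e.kind == "set"]
        for e in implanted:
            key = (e.phylogroup, e.label,
                   f"T24_{e.treatment}_vs_T24_control")
            row = hits.loc[key]
            ok = (row["significant"] and row["retained"]
                  and np.sign(row["direction"]) == np.sign(e.log2fc))
            recovered += bool(ok)
        assert recovered / len(implanted) >= 0.8

    def test_pure_abundance_shift_removed(self, default_sim,
                                          default_set_results):
        _design, _m, _sheet, truth = default_sim
        res = default_set_results
        for e in truth.config.effects:
            if e.kind != "all":
                continue
            cell = res[(res["phylogroup"] == e.phylogroup)
                       & (res["contrast"]
                          == f"T24_{e.treatment}_vs_T24_control")]
            assert not (cell["significant"] & cell["retained"]).any()

    def test_summary_table_shape(self, default_set_results):
        arrows = pa.summarize_responses(default_set_results)
        assert set(arrows["arrow"]) <= {"o", "up", "down", "UP*", "DOWN*"}
        assert len(arrows) == len(default_set_results)
        sig = arrows[arrows["significant"]]
        assert (sig["arrow"] != "o").all()
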