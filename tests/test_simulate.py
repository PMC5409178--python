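"""Synthetic-data generators: distributions, determinism, symmetries."""

import math

import numpy as np
import pytest

from dupfit import phylo
from dupfit.fitness import estimate_s_closed_form, logistic_trajectory
from dupfit.simulate import (
    NULL_SD,
    ScreenDesign,
    SimAlignmentConfig,
    SimCompetitionConfig,
    calibrated_bio_sd,
    simulate_alignment,
    simulate_competition,
    simulate_screen,
    simulate_sectoring,
)

from conftest import DEPTH1_TREE


class TestCompetition:
    def test_counts_conserve_total(self):
        cc = simulate_competition(SimCompetitionConfig(true_s=-0.02, seed=1))
        assert all(t == 50_000 for t in cc.totals)

    def test_neutral_large_n_stays_near_start(self):
        cfg = SimCompetitionConfig(true_s=0.0, n_cells=5_000_000, seed=2)
        cc = simulate_competition(cfg)
        for r in cc.red:
            assert r / cfg.n_cells == pytest.approx(0.5, abs=0.002)

    def test_expected_frequency_follows_logistic(self):
        # E[R(20)] = 2/3 when odds double over 20 generations
        cfg = SimCompetitionConfig(true_s=math.log(2) / 20, seed=3)
        reps = [
            simulate_competition(
                SimCompetitionConfig(true_s=cfg.true_s, seed=k)
            ).red[0]
            for k in range(300)
        ]
        se = math.sqrt(2 / 9 / 50_000 / 300)
        assert np.mean(reps) / 50_000 == pytest.approx(2 / 3, abs=4 * se)

    def test_seed_determinism(self):
        cfg = SimCompetitionConfig(true_s=-0.01, bio_sd=0.002, seed=7)
        assert simulate_competition(cfg) == simulate_competition(cfg)

    def test_binomial_variance_without_biological_noise(self):
        p = logistic_trajectory(0.5, -0.01, 20.0)
        fracs = [
            simulate_competition(
                SimCompetitionConfig(true_s=-0.01, seed=k)
            ).red[0]
            / 50_000
            for k in range(1000)
        ]
        var_expected = p * (1 - p) / 50_000
        mc_se = var_expected * math.sqrt(2 / 999)
        assert np.var(fracs, ddof=1) == pytest.approx(var_expected, abs=3 * mc_se)

    def test_rejects_degenerate_config(self):
        with pytest.raises(ValueError):
            SimCompetitionConfig(R0=1.0)
        with pytest.raises(ValueError):
            SimCompetitionConfig(timepoints=(40.0, 20.0))
        with pytest.raises(ValueError):
            SimCompetitionConfig(bio_sd=-0.1)


class TestCalibration:
    def test_bio_sd_below_target(self):
        assert 0 < calibrated_bio_sd() < NULL_SD

    def test_null_screen_sd_matches_target(self):
        # the point of the calibration: fitted null-well SD ~= 0.0017
        s_hats = []
        for k in range(800):
            cc = simulate_competition(
                SimCompetitionConfig(bio_sd=calibrated_bio_sd(), seed=k)
            )
            s_hats.append(estimate_s_closed_form(cc).s)
        sd = np.std(s_hats, ddof=1)
        assert sd == pytest.approx(NULL_SD, rel=0.10)


class TestScreen:
    def test_eight_by_eight_has_64_wells(self):
        design = ScreenDesign.all_by_all([f"g{i}" for i in range(8)])
        assert len(design.wells) == 64
        assert design.controls == 16

    def test_diagonal_is_self_competition(self):
        design = ScreenDesign.all_by_all(list("abc"))
        assert sum(g == r for g, r in design.wells) == 3

    def test_label_swap_negates_expected_s(self):
        design = ScreenDesign(("A",), ("B",), controls=0)
        swapped = ScreenDesign(("B",), ("A",), controls=0)
        fits = []
        for d in (design, swapped):
            cfg = SimCompetitionConfig(seed=0)
            df = simulate_screen(d, {"A": 0.0, "B": -0.05}, cfg)
            wells = df.groupby("well_id")
            (wid, grp), = list(wells)
            from dupfit.io import counts_to_wells

            fits.append(estimate_s_closed_form(counts_to_wells(df)[0]).s)
        assert fits[0] == pytest.approx(-0.05, abs=0.005)
        assert fits[1] == pytest.approx(0.05, abs=0.005)

    def test_missing_wells_omitted(self):
        design = ScreenDesign.all_by_all(list("ab"))
        df = simulate_screen(
            design,
            {"a": 0.0, "b": 0.0},
            SimCompetitionConfig(seed=0),
            missing_wells=[("a", "b")],
        )
        assert df.well_id.nunique() == 3
        assert not ((df.green_genotype == "a") & (df.red_genotype == "b")).any()

    def test_unknown_genotype_rejected(self):
        design = ScreenDesign.all_by_all(list("ab"))
        with pytest.raises(KeyError):
            simulate_screen(design, {"a": 0.0}, SimCompetitionConfig(seed=0))


class TestAlignment:
    def test_seed_determinism(self):
        cfg = SimAlignmentConfig(tree=DEPTH1_TREE, length=40, seed=9)
        assert simulate_alignment(cfg) == simulate_alignment(cfg)

    def test_near_zero_rate_region_is_invariant(self):
        cfg = SimAlignmentConfig(
            tree=DEPTH1_TREE, length=60, regions=((10, 30, 1e-9),), seed=4
        )
        aln = simulate_alignment(cfg)
        segments = {seq[10:30] for seq in aln.values()}
        assert len(segments) == 1

    def test_single_branch_identity_probability(self):
        # P(unchanged) over one branch matches the matrix exponential of
        # the equal-exchangeability model (scaling-and-squaring oracle)
        from scipy.linalg import expm

        b, rho = 0.8, 0.35
        model = SimAlignmentConfig(tree="(a:0.4,b:0.4);", length=1).model()
        p_model = model.transition_matrix(b * rho)[0, 0]
        p_oracle = expm(model.rate_matrix * b * rho)[0, 0]
        assert p_model == pytest.approx(p_oracle, abs=1e-12)
        n, same = 4000, 0
        cfg = SimAlignmentConfig(tree=f"(a:{b/2},b:{b/2});", length=n,
                                 regions=((0, n, rho),), seed=11)
        aln = simulate_alignment(cfg)
        same = sum(x == y for x, y in zip(aln["a"], aln["b"]))
        p_pair = sum(
            model.frequencies[i] * model.transition_matrix(b * rho)[i, i]
            for i in range(20)
        )
        se = math.sqrt(p_pair * (1 - p_pair) / n)
        assert same / n == pytest.approx(p_pair, abs=4 * se)

    def test_region_validation(self):
        with pytest.raises(ValueError):
            SimAlignmentConfig(tree=DEPTH1_TREE, length=20, regions=((0, 30, 0.1),))
        with pytest.raises(ValueError):
            SimAlignmentConfig(tree=DEPTH1_TREE, length=20, regions=((0, 10, 1.5),))
        with pytest.raises(ValueError):
            SimAlignmentConfig(
                tree=DEPTH1_TREE, length=20, regions=((0, 10, 0.1), (5, 15, 0.1))
            )
        with pytest.raises(ValueError):
            SimAlignmentConfig(
                tree=DEPTH1_TREE, length=20, regions=((0, 10, 0.1),),
                shifted_regions={3: "DUP"},
            )

    def test_shifted_region_needs_flagged_clade(self):
        cfg = SimAlignmentConfig(
            tree=DEPTH1_TREE, length=20, regions=((0, 10, 0.1),),
            shifted_regions={0: "DUP"},
        )
        with pytest.raises(ValueError, match="flagged clade"):
            simulate_alignment(cfg)


class TestSectoring:
    @pytest.mark.parametrize(
        "p,expect", [(0.0, (0, 94)), (1.0, (94, 0))]
    )
    def test_degenerate_probabilities(self, p, expect):
        assert simulate_sectoring(p, 94, seed=0) == expect

    def test_binomial_expectation(self):
        draws = [simulate_sectoring(29 / 94, 94, seed=k)[0] for k in range(500)]
        se = math.sqrt(94 * (29 / 94) * (65 / 94) / 500)
        assert np.mean(draws) == pytest.approx(29, abs=4 * se)

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            simulate_sectoring(1.2, 10)
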