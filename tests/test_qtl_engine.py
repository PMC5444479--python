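"""Scans, thresholds, support intervals, two-QTL scans and model selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from seedmqtl import (
    GeneticMap,
    GenotypeMatrix,
    LodCurve,
    PlantedEpistasis,
    PlantedQtl,
    QtlEffect,
    QtlModel,
    RilDesign,
    ScanConfig,
    SeedMqtlError,
    SimTruth,
    calc_genoprob,
    derive_penalties,
    fit_qtl_model,
    inverse_map_function,
    lod_support_interval,
    permutation_threshold,
    ril_recombination_fraction,
    scan_cim,
    scan_hk,
    scan_two,
    scantwo_permutations,
    significant_peaks,
    simulate_metabolome,
    simulate_ril_population,
    stepwise_mqm,
)
from seedmqtl.core_io import AA, BB, HET, MISSING, rng_for
from seedmqtl.qtl_engine import permutation_maxima


def _single_marker_map():
    return GeneticMap(
        pd.DataFrame(
            {"chrom": ["1"], "pos_cm": [0.0]},
            index=pd.Index(["m1"], name="marker"),
        )
    )


def _chrom_map(positions, chrom="1", prefix="m"):
    return GeneticMap(
        pd.DataFrame(
            {"chrom": [chrom] * len(positions), "pos_cm": positions},
            index=pd.Index([f"{prefix}{i}" for i in range(len(positions))],
                           name="marker"),
        )
    )


def _enumerate_posterior(obs, grid, marker_idx, eps, which="kosambi"):
    """Brute-force genotype posterior by summing over all hidden sequences."""
    g = len(grid)
    r = [inverse_map_function(grid[j + 1] - grid[j], which) for j in range(g - 1)]
    R = [ril_recombination_fraction(x) for x in r]

    def emit(j, s):
        if j not in marker_idx:
            return 1.0
        o = obs[marker_idx.index(j)]
        if o in (HET, MISSING):
            return 1.0
        return 1 - eps if o == s else eps

    post = np.zeros((g, 2))
    for states in itertools.product((0, 1), repeat=g):
        p = 0.5 * emit(0, states[0])
        for j in range(1, g):
            p *= (1 - R[j - 1]) if states[j] == states[j - 1] else R[j - 1]
            p *= emit(j, states[j])
        for j in range(g):
            post[j, states[j]] += p
    return post / post.sum(axis=1, keepdims=True)


class TestGenoprob:
    def test_typed_marker_is_certain_without_error(self):
        gmap = _single_marker_map()
        calls = pd.DataFrame({"m1": [AA, BB]}, index=["i0", "i1"])
        gp = calc_genoprob(GenotypeMatrix(calls), gmap, ScanConfig(genotyping_error=0))
        np.testing.assert_allclose(gp.probs["1"][0, 0], [1.0, 0.0])
        np.testing.assert_allclose(gp.probs["1"][1, 0], [0.0, 1.0])

    def test_all_missing_individual_gets_uniform_prior(self):
        gmap = _chrom_map([0.0, 10.0, 20.0])
        calls = pd.DataFrame(
            {"m0": [MISSING], "m1": [MISSING], "m2": [MISSING]}, index=["i0"]
        )
        gp = calc_genoprob(GenotypeMatrix(calls), gmap, ScanConfig())
        np.testing.assert_allclose(gp.probs["1"][0], 0.5, atol=1e-12)

    @pytest.mark.parametrize("eps", [0.0001, 0.05])
    def test_matches_exhaustive_enumeration_two_markers(self, eps):
        gmap = _chrom_map([0.0, 10.0])
        combos = list(itertools.product([AA, BB, HET, MISSING], repeat=2))
        calls = pd.DataFrame(combos, columns=["m0", "m1"],
                             index=[f"i{k}" for k in range(len(combos))])
        cfg = ScanConfig(genotyping_error=eps, step_cm=1000)
        gp = calc_genoprob(GenotypeMatrix(calls), gmap, cfg)
        grid = gp.grid["pos_cm"].to_numpy()
        for k, obs in enumerate(combos):
            expected = _enumerate_posterior(list(obs), grid, [0, 1], eps)
            np.testing.assert_allclose(gp.probs["1"][k], expected, atol=1e-10)

    def test_matches_enumeration_four_markers_with_pseudomarkers(self):
        gmap = _chrom_map([0.0, 2.0, 5.0, 9.0])
        rng = np.random.default_rng(3)
        combos = rng.choice([AA, BB, HET, MISSING], size=(12, 4))
        calls = pd.DataFrame(combos, columns=[f"m{i}" for i in range(4)],
                             index=[f"i{k}" for k in range(12)])
        cfg = ScanConfig(genotyping_error=0.0001, step_cm=2.0)
        gp = calc_genoprob(GenotypeMatrix(calls), gmap, cfg)
        grid = gp.grid["pos_cm"].to_numpy()
        marker_idx = [int(np.flatnonzero(np.isclose(grid, p))[0])
                      for p in [0.0, 2.0, 5.0, 9.0]]
        for k in range(len(combos)):
            expected = _enumerate_posterior(
                list(combos[k]), grid, marker_idx, 0.0001
            )
            np.testing.assert_allclose(gp.probs["1"][k], expected, atol=1e-10)

    def test_probabilities_sum_to_one(self, study_genoprob):
        for chrom, probs in study_genoprob.probs.items():
            np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-10)


class TestScanHk:
    def test_matches_direct_regression_at_typed_markers(self, study_genoprob,
                                                        study_pop):
        rng = np.random.default_rng(8)
        x = study_pop.calls["m3_10"].replace(
            {AA: -1.0, BB: 1.0, HET: 0.0, MISSING: np.nan}
        ).astype(float)
        y = 0.4 * x.fillna(0) + rng.standard_normal(len(x))
        curve = scan_hk(study_genoprob, pd.Series(y.to_numpy(),
                                                  index=study_pop.individuals))
        col = study_genoprob.column_at("3", 3.4 * 9)
        # direct least squares on the expected dosage at that column
        d = study_genoprob.dosage[:, col]
        yv = y.to_numpy()
        dc = d - d.mean()
        yc = yv - yv.mean()
        r2 = (dc @ yc) ** 2 / ((dc @ dc) * (yc @ yc))
        expected = -(len(yv) / 2) * np.log10(1 - r2)
        assert curve.table["lod"].iloc[col] == pytest.approx(expected, abs=1e-8)

    def test_null_trait_stays_below_threshold_mostly(self, study_genoprob):
        rng = rng_for(77, "null-check")
        y = rng.standard_normal(study_genoprob.n_individuals)
        thr = permutation_threshold(
            study_genoprob, y, ScanConfig(), n_perm=500, rng=rng
        )
        assert scan_hk(study_genoprob, y).max_lod < thr + 2.0

    def test_zero_variance_trait_gives_flat_curve(self, study_genoprob):
        y = np.ones(study_genoprob.n_individuals)
        curve = scan_hk(study_genoprob, y)
        assert (curve.table["lod"] == 0).all()

    def test_too_few_individuals_rejected(self):
        gmap = _single_marker_map()
        calls = pd.DataFrame({"m1": [AA] * 4 + [BB] * 4},
                             index=[f"i{k}" for k in range(8)])
        gp = calc_genoprob(GenotypeMatrix(calls), gmap, ScanConfig())
        with pytest.raises(SeedMqtlError, match="informative"):
            scan_hk(gp, np.arange(8.0))


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum_of_maxima(self, study_genoprob):
        rng = rng_for(5, "alpha1")
        y = rng.standard_normal(study_genoprob.n_individuals)
        maxima = permutation_maxima(study_genoprob, y, 200, rng_for(5, "m"))
        cfg = ScanConfig(alpha=1 - 1e-12)
        thr = permutation_threshold(study_genoprob, y, cfg, n_perm=200,
                                    rng=rng_for(5, "m"))
        assert thr == pytest.approx(maxima.min())

    def test_same_seed_same_threshold(self, study_genoprob):
        y = rng_for(6, "y").standard_normal(study_genoprob.n_individuals)
        t1 = permutation_threshold(study_genoprob, y, ScanConfig(), n_perm=200,
                                   rng=rng_for(6, "t"))
        t2 = permutation_threshold(study_genoprob, y, ScanConfig(), n_perm=200,
                                   rng=rng_for(6, "t"))
        assert t1 == t2

    def test_too_few_permutations_rejected(self, study_genoprob):
        y = np.arange(float(study_genoprob.n_individuals))
        with pytest.raises(SeedMqtlError):
            permutation_threshold(study_genoprob, y, ScanConfig(), n_perm=50)


class TestSupportInterval:
    def _curve(self, pos_lod: dict, chrom="1"):
        return LodCurve(
            pd.DataFrame(
                {"chrom": chrom, "pos_cm": list(pos_lod), "lod": list(pos_lod.values())}
            )
        )

    def test_hand_example_with_flanking_marker_expansion(self):
        gmap = _chrom_map([0.0, 15.0])
        curve = self._curve({0.0: 1.0, 5.0: 3.0, 10.0: 2.9, 15.0: 1.2})
        si = lod_support_interval(curve, gmap, "1", 1.5)
        assert (si.lo_cm, si.apex_cm, si.hi_cm) == (0.0, 5.0, 15.0)
        assert (si.lo_marker, si.hi_marker) == ("m0", "m1")

    def test_apex_at_chromosome_end(self):
        gmap = _chrom_map([0.0, 10.0])
        curve = self._curve({0.0: 8.0, 5.0: 2.0, 10.0: 1.0})
        si = lod_support_interval(curve, gmap, "1", 1.5)
        assert si.lo_cm == 0.0 and si.apex_cm == 0.0

    def test_zero_drop_degenerates_to_apex_plateau(self):
        gmap = _chrom_map([0.0, 20.0])
        curve = self._curve({0.0: 1.0, 5.0: 4.0, 10.0: 4.0, 15.0: 2.0, 20.0: 1.0})
        si = lod_support_interval(curve, gmap, "1", 0.0)
        assert si.apex_cm == 5.0  # leftmost tie
        assert si.hi_cm >= 10.0  # plateau included (then marker expansion)


@pytest.fixture(scope="module")
def coarse(study_pop, study_map):
    return calc_genoprob(study_pop, study_map, ScanConfig(), step_cm=5.0)


class TestScanTwo:
    def test_nesting_full_ge_add_ge_single(self, coarse):
        y = rng_for(9, "pair").standard_normal(coarse.n_individuals)
        st2 = scan_two(coarse, y)
        assert (st2.lod_full >= st2.lod_add - 1e-8).all()
        singles = np.maximum(st2.lod_one[st2.pairs[:, 0]], st2.lod_one[st2.pairs[:, 1]])
        assert (st2.lod_add >= singles - 1e-6).all()

    def test_additive_pair_shows_no_interaction(self, study_pop, study_map, coarse):
        truth = SimTruth(
            traits=["t"],
            planted_qtls={"t": [PlantedQtl("1", 17.0, 0.4, 16.0),
                                PlantedQtl("4", 51.0, 0.4, 16.0)]},
            noise_sd={"t": 0.8},
        )
        pheno = simulate_metabolome(study_pop, study_map, truth, seed=14)
        st2 = scan_two(coarse, pheno.values["t"])
        perms = scantwo_permutations(coarse, pheno.values["t"],
                                     ScanConfig(rng_seed=14), n_perm=100)
        int_thr = float(np.quantile(perms.max_int, 0.95))
        assert st2.lod_int.max() < int_thr

    def test_masking_pair_interaction_significant(self, study_pop, study_map, coarse):
        truth = SimTruth(
            traits=["t"],
            epistatic_pairs={"t": [PlantedEpistasis(("4", 47.6), ("5", 64.6),
                                                    0.8, "masking")]},
            noise_sd={"t": 0.8},
        )
        pheno = simulate_metabolome(study_pop, study_map, truth, seed=15)
        st2 = scan_two(coarse, pheno.values["t"])
        perms = scantwo_permutations(coarse, pheno.values["t"],
                                     ScanConfig(rng_seed=15), n_perm=100)
        int_thr = float(np.quantile(perms.max_int, 0.95))
        lod, pair = st2.max_interaction()
        assert lod > int_thr
        chroms = {st2.grid["chrom"].iloc[pair[0]], st2.grid["chrom"].iloc[pair[1]]}
        assert chroms == {"4", "5"}


class TestPenalties:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_heavy_at_least_light_and_reproducible(self, study_pop, study_map, seed):
        gp = calc_genoprob(study_pop, study_map, ScanConfig(), step_cm=10.0)
        y = rng_for(seed, "pen").standard_normal(gp.n_individuals)
        p1 = derive_penalties(
            scantwo_permutations(gp, y, ScanConfig(), 100, rng_for(seed, "p")), 0.05
        )
        p2 = derive_penalties(
            scantwo_permutations(gp, y, ScanConfig(), 100, rng_for(seed, "p")), 0.05
        )
        assert p1 == p2
        main, heavy, light = p1
        assert heavy >= light >= 0
        assert main > 0

    def test_smaller_alpha_gives_larger_penalties(self, study_pop, study_map):
        gp = calc_genoprob(study_pop, study_map, ScanConfig(), step_cm=10.0)
        y = rng_for(4, "pen").standard_normal(gp.n_individuals)
        perms = scantwo_permutations(gp, y, ScanConfig(), 200, rng_for(4, "p"))
        loose = derive_penalties(perms, 0.10)
        strict = derive_penalties(perms, 0.01)
        # main and heavy are quantiles, hence monotone in alpha; light is a
        # difference of quantiles and only guaranteed non-negative
        assert strict[0] >= loose[0]
        assert strict[1] >= loose[1]
        assert strict[2] >= 0 and loose[2] >= 0


class TestCim:
    def test_covariates_excluded_within_window(self, study_genoprob, study_pop,
                                               study_map):
        truth = SimTruth(
            traits=["t"],
            planted_qtls={"t": [PlantedQtl("2", 20.4, 0.45, 20.0),
                                PlantedQtl("2", 51.0, 0.45, 20.0)]},
            noise_sd={"t": 0.77},
        )
        pheno = simulate_metabolome(study_pop, study_map, truth, seed=5)
        cfg = ScanConfig(rng_seed=5)
        curve, details = scan_cim(study_genoprob, pheno.values["t"], cfg,
                                  return_details=True)
        mk = study_map.table
        grid = study_genoprob.grid
        for ci, names in details.items():
            chrom = grid["chrom"].iloc[ci]
            pos = float(grid["pos_cm"].iloc[ci])
            for nm in names:
                if nm in mk.index and mk.loc[nm, "chrom"] == chrom:
                    assert abs(float(mk.loc[nm, "pos_cm"]) - pos) >= 10.0

    def test_separates_linked_qtls_where_im_blurs(self, study_genoprob, study_pop,
                                                  study_map):
        truth = SimTruth(
            traits=["t"],
            planted_qtls={"t": [PlantedQtl("2", 20.4, np.sqrt(0.18), 18.0),
                                PlantedQtl("2", 51.0, np.sqrt(0.18), 18.0)]},
            noise_sd={"t": np.sqrt(0.64)},
        )
        pheno = simulate_metabolome(study_pop, study_map, truth, seed=5)
        cfg = ScanConfig(rng_seed=5)
        im = scan_hk(study_genoprob, pheno.values["t"], cfg)
        cim = scan_cim(study_genoprob, pheno.values["t"], cfg)

        def dip(curve):
            sub = curve.chrom("2")
            lod = sub["lod"].to_numpy()
            pos = sub["pos_cm"].to_numpy()
            p1 = lod[(pos > 15) & (pos < 26)].max()
            p2 = lod[(pos > 45) & (pos < 56)].max()
            valley = lod[(pos >= 26) & (pos <= 45)].min()
            return min(p1, p2) - valley

        assert dip(cim) > dip(im)
        assert dip(cim) > 5.0


class TestStepwiseAndFit:
    def test_null_trait_returns_empty_model(self, study_genoprob):
        cfg = ScanConfig(penalties=(3.0, 5.0, 2.0))
        empty = 0
        for seed in range(10):
            y = rng_for(seed, "null-step").standard_normal(
                study_genoprob.n_individuals
            )
            m = stepwise_mqm(study_genoprob, y, cfg)
            empty += m.n_qtls == 0
        assert empty >= 9

    def test_three_qtl_recovery_single_replicate(self, study_pop, study_map,
                                                 study_genoprob):
        truth = SimTruth(
            traits=["t"],
            planted_qtls={"t": [PlantedQtl("1", 34.0, np.sqrt(0.10), 10.0),
                                PlantedQtl("3", 51.0, np.sqrt(0.10), 10.0),
                                PlantedQtl("5", 17.0, -np.sqrt(0.10), 10.0)]},
            noise_sd={"t": np.sqrt(0.70)},
        )
        pheno = simulate_metabolome(study_pop, study_map, truth, seed=21)
        cfg = ScanConfig(rng_seed=21, penalties=(2.7, 4.3, 1.8))
        y = pheno.values["t"]
        thr = permutation_threshold(study_genoprob, y, cfg, n_perm=300,
                                    rng=rng_for(21, "thr"))
        peaks = significant_peaks(scan_hk(study_genoprob, y, cfg), thr)
        m = stepwise_mqm(study_genoprob, y, cfg, [(c, p) for c, p, _ in peaks])
        assert m.n_qtls == 3
        for chrom, pos in [("1", 34.0), ("3", 51.0), ("5", 17.0)]:
            assert any(
                q.chrom == chrom and s.lo_cm <= pos <= s.hi_cm
                for q, s in zip(m.qtls, m.support)
            )
        # effect signs follow the planted (BB - AA)/2 contrasts
        signs = {q.chrom: np.sign(q.effect) for q in m.qtls}
        assert signs["1"] > 0 and signs["5"] < 0

    def test_fit_empty_model_zero_r2(self, study_genoprob):
        y = rng_for(2, "fit").standard_normal(study_genoprob.n_individuals)
        m = fit_qtl_model(study_genoprob, y, QtlModel(trait="t"))
        assert m.combined_r2 == 0.0 and m.n_qtls == 0

    def test_per_qtl_r2_bounded_by_combined(self, study_pop, study_map,
                                            study_genoprob):
        truth = SimTruth(
            traits=["t"],
            planted_qtls={"t": [PlantedQtl("1", 17.0, 0.3, 9.0),
                                PlantedQtl("2", 34.0, 0.3, 9.0)]},
            noise_sd={"t": 0.9},
        )
        pheno = simulate_metabolome(study_pop, study_map, truth, seed=6)
        model = QtlModel(trait="t",
                         qtls=[QtlEffect("1", 17.0), QtlEffect("2", 34.0)])
        fit = fit_qtl_model(study_genoprob, pheno.values["t"], model)
        assert 0 < fit.combined_r2 <= 100
        for q in fit.qtls:
            assert 0 <= q.r2 <= fit.combined_r2 + 1e-9

    def test_coincident_qtls_rejected_naming_positions(self, study_genoprob):
        y = rng_for(3, "fit").standard_normal(study_genoprob.n_individuals)
        model = QtlModel(trait="t",
                         qtls=[QtlEffect("1", 17.0), QtlEffect("1", 17.0)])
        with pytest.raises(SeedMqtlError, match="17"):
            fit_qtl_model(study_genoprob, y, model)

    def test_effect_recovery_within_three_se(self, study_map):
        """Estimated additive effects stay near the planted contrast."""
        effect = np.sqrt(0.15)
        hits = 0
        reps = 20
        for rep in range(reps):
            _, geno = simulate_ril_population(
                RilDesign(n_individuals=300), seed=500 + rep
            )
            truth = SimTruth(
                traits=["t"],
                planted_qtls={"t": [PlantedQtl("2", 34.0, effect, 15.0)]},
                noise_sd={"t": np.sqrt(0.85)},
            )
            pheno = simulate_metabolome(geno, study_map, truth, seed=500 + rep)
            gp = calc_genoprob(geno, study_map, ScanConfig())
            fit = fit_qtl_model(
                gp, pheno.values["t"], QtlModel(trait="t", qtls=[QtlEffect("2", 34.0)])
            )
            se = np.sqrt(0.85 / 300)  # residual sd / sqrt(n), unit dosage variance
            hits += abs(fit.qtls[0].effect - effect) <= 3 * se
        assert hits >= int(0.95 * reps) - 1
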