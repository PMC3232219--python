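import math

import numpy as np
import pytest

from devodiverge import (
    AgeGrid,
    TargetTable,
    correlation_excess_distribution,
    negative_excess_test,
    profile_correlations,
    screen_candidates,
    target_enrichment,
    transfection_inhibition_test,
)
from devodiverge.trajectory_fit import TrajectoryModel


def _model(coeffs, fid="g", sp="human"):
    c = np.asarray(coeffs, dtype=float)
    return TrajectoryModel(fid, sp, len(c) - 1, c, 10, 0.0, 5)


def _grid(G=20):
    return AgeGrid(points=np.linspace(8.0, 14.0, G), span=(8.0, 14.0))


SPECIES = ("human", "chimpanzee", "macaque")


class TestTargetEnrichment:
    def test_two_of_two_in_focal_universe_four(self):
        targets = TargetTable({"r": {"f1", "f2"}})
        p, k_in, k_bg = target_enrichment("r", {"f1", "f2"}, {"b1", "b2"}, targets)
        assert p == pytest.approx(1.0 / 6.0, rel=1e-12)  # 1 / C(4,2)
        assert (k_in, k_bg) == (2, 0)

    def test_disjoint_targets_give_p_one(self):
        targets = TargetTable({"r": {"b1", "b2"}})
        p, _, _ = target_enrichment("r", {"f1", "f2"}, {"b1", "b2"}, targets)
        assert p == 1.0

    def test_no_targets_in_universe_flagged_p_one(self):
        targets = TargetTable({"r": {"zz"}})
        with pytest.warns(UserWarning):
            p, _, _ = target_enrichment("r", {"f1"}, {"b1"}, targets)
        assert p == 1.0

    def test_matches_exhaustive_hypergeometric_enumeration(self, rng):
        for _ in range(30):
            M = int(rng.integers(10, 200))
            n_focal = int(rng.integers(2, M - 1))
            K = int(rng.integers(1, M))
            universe = [f"g{i}" for i in range(M)]
            focal = set(universe[:n_focal])
            background = set(universe[n_focal:])
            tset = set(np.array(universe)[rng.choice(M, K, replace=False)])
            p, k_in, _ = target_enrichment("r", focal, background, TargetTable({"r": tset}))
            # exact tail by direct combinatorial sum
            exact = sum(
                math.comb(K, j) * math.comb(M - K, n_focal - j)
                for j in range(k_in, min(K, n_focal) + 1)
            ) / math.comb(M, n_focal)
            assert p == pytest.approx(exact, rel=1e-9)


class TestProfileCorrelations:
    def _mirror_pair(self):
        reg = {sp: _model([1.0 + i, 0.5, -0.1], "r", sp) for i, sp in enumerate(SPECIES)}
        tgt = {
            sp: _model(-np.array([1.0 + i, 0.5, -0.1]), "t", sp)
            for i, sp in enumerate(SPECIES)
        }
        return reg, tgt

    @pytest.mark.parametrize("mode", ["profile", "species_diff"])
    def test_exact_negative_curves_give_minus_one(self, mode):
        reg, tgt = self._mirror_pair()
        r = profile_correlations(reg, {"t": tgt}, _grid(), mode=mode)["t"]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_identical_species_curves_degenerate_in_species_diff(self):
        reg = {sp: _model([1.0, 0.5], "r", sp) for sp in SPECIES}
        tgt = {sp: _model([2.0, -0.5], "t", sp) for sp in SPECIES}
        r = profile_correlations(reg, {"t": tgt}, _grid(), mode="species_diff")["t"]
        assert np.isnan(r)

    def test_species_diff_invariant_to_shared_curve(self, rng):
        shared = rng.normal(size=4)
        reg = {sp: _model(rng.normal(size=4), "r", sp) for sp in SPECIES}
        tgt = {sp: _model(rng.normal(size=4), "t", sp) for sp in SPECIES}
        r1 = profile_correlations(reg, {"t": tgt}, _grid(), mode="species_diff")["t"]
        reg2 = {
            sp: _model(reg[sp].coefficients + shared, "r", sp) for sp in SPECIES
        }
        r2 = profile_correlations(reg2, {"t": tgt}, _grid(), mode="species_diff")["t"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_coupled_pair_strongly_negative_uncoupled_weak(self, small_bundle,
                                                           small_models_grid):
        models, grid = small_models_grid
        truth = small_bundle.truth
        rid = truth.regulators.index[truth.regulators.coupled][0]
        tgts = sorted(small_bundle.targets.pairs[rid])
        rs = profile_correlations(
            models[rid], {g: models[g] for g in tgts}, grid, mode="profile"
        )
        assert all(r < -0.9 for r in rs.values())


class TestNegativeExcess:
    def test_exact_binomial_tail(self):
        cors = {"e": {f"t{i}": (-0.9 if i < 8 else 0.0) for i in range(10)}}
        # force the background rate to 0.2 via four non-enriched regulators
        for j, frac in enumerate([0.2, 0.2, 0.2, 0.2]):
            cors[f"n{j}"] = {f"x{i}": (-0.9 if i < int(frac * 10) else 0.0) for i in range(10)}
        out = negative_excess_test(["e"], [f"n{j}" for j in range(4)], cors)
        p, freq, bg = out["e"]
        exact = sum(
            math.comb(10, k) * 0.2**k * 0.8 ** (10 - k) for k in range(8, 11)
        )
        assert bg == pytest.approx(0.2)
        assert freq == pytest.approx(0.8)
        assert p == pytest.approx(exact, rel=1e-9)
        assert p == pytest.approx(7.79e-5, rel=2e-3)

    def test_zero_hits_gives_p_one(self):
        cors = {"e": {f"t{i}": 0.0 for i in range(10)},
                "n0": {f"x{i}": (-0.9 if i < 2 else 0.0) for i in range(10)}}
        p, _, _ = negative_excess_test(["e"], ["n0"], cors)["e"]
        assert p == 1.0

    def test_positive_tail_for_tf_mode(self):
        cors = {"e": {f"t{i}": (0.95 if i < 9 else 0.0) for i in range(10)},
                "n0": {f"x{i}": (0.95 if i < 1 else 0.0) for i in range(10)}}
        p, freq, bg = negative_excess_test(
            ["e"], ["n0"], cors, cutoff=0.9, tail="positive"
        )["e"]
        assert freq == pytest.approx(0.9)
        assert p < 1e-6

    def test_zero_background_with_hits_flagged_p_zero(self):
        cors = {"e": {"t0": -0.9}, "n0": {"x0": 0.0}}
        with pytest.warns(UserWarning):
            p, _, _ = negative_excess_test(["e"], ["n0"], cors)["e"]
        assert p == 0.0


class TestScreenCandidates:
    def test_implanted_regulators_flagged_decoys_not(self, small_bundle,
                                                     small_models_grid):
        models, grid = small_models_grid
        b = small_bundle
        truth = b.truth.genes
        focal = list(truth.index[truth.dtype == "III"])
        background = list(truth.index[truth.dtype.isin(["I", "II"])])
        results, perm = screen_candidates(
            b.regulator_expression.feature_ids, focal, background,
            models, grid, b.targets, n_perm=100, seed=2,
        )
        coupled = set(b.truth.regulators.index[b.truth.regulators.coupled])
        flagged = {r.regulator_id for r in results if r.candidate}
        assert coupled <= flagged
        assert len(flagged - coupled) <= 2  # decoys essentially never pass
        assert perm.expected_enriched < perm.observed_enriched

    def test_null_focal_set_within_permutation_band(self, small_bundle,
                                                    small_models_grid, rng):
        """With a randomly drawn pseudo-focal set, the observed enrichment
        count should sit inside the permutation distribution's 95% band."""
        models, grid = small_models_grid
        b = small_bundle
        genes = list(b.truth.genes.index)
        perm_genes = rng.permutation(genes)
        focal = list(perm_genes[:60])
        background = list(perm_genes[60:260])
        results, perm = screen_candidates(
            b.regulator_expression.feature_ids, focal, background,
            models, grid, b.targets, n_perm=200, seed=3,
        )
        assert perm.p_empirical > 0.025

    def test_n_perm_zero_skips_expectation(self, small_bundle, small_models_grid):
        models, grid = small_models_grid
        b = small_bundle
        truth = b.truth.genes
        focal = list(truth.index[truth.dtype == "III"])
        background = list(truth.index[truth.dtype.isin(["I", "II"])])
        results, perm = screen_candidates(
            b.regulator_expression.feature_ids, focal, background,
            models, grid, b.targets, n_perm=0,
        )
        assert perm is None
        assert any(r.candidate for r in results)

    def test_too_few_regulators_error(self, small_bundle, small_models_grid):
        models, grid = small_models_grid
        with pytest.raises(ValueError):
            screen_candidates(["r1"], ["a"], ["b"], models, grid,
                              small_bundle.targets)


class TestCorrelationExcess:
    def test_excess_sums_to_zero(self, rng):
        tc = rng.uniform(-1, 1, 200)
        nc = rng.uniform(-1, 1, 800)
        ex = correlation_excess_distribution(tc, nc, n_perm=20, seed=0)
        assert ex.observed_excess.sum() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(ex.permuted_excess.sum(axis=1), 0.0, atol=1e-12)

    def test_null_labels_stay_within_envelope(self):
        rng = np.random.default_rng(17)
        pool = rng.uniform(-1, 1, 1000)
        tc, nc = pool[:150], pool[150:]
        ex = correlation_excess_distribution(tc, nc, n_perm=200, seed=4)
        lo = ex.permuted_excess.min(axis=0)
        hi = ex.permuted_excess.max(axis=0)
        outside = np.sum((ex.observed_excess < lo) | (ex.observed_excess > hi))
        assert outside <= 1

    def test_coupled_targets_exceed_envelope_in_strong_negative_bins(
        self, small_bundle, small_models_grid
    ):
        models, grid = small_models_grid
        b = small_bundle
        truth = b.truth
        focal = list(truth.genes.index[truth.genes.dtype == "III"])
        coupled = list(truth.regulators.index[truth.regulators.coupled])
        decoys = list(truth.regulators.index[~truth.regulators.coupled])
        tc, nc = [], []
        for rid in coupled + decoys:
            tgts = b.targets.pairs[rid]
            rs = profile_correlations(
                models[rid], {g: models[g] for g in focal}, grid, mode="profile"
            )
            for g, r in rs.items():
                (tc if g in tgts else nc).append(r)
        ex = correlation_excess_distribution(tc, nc, n_perm=100, seed=5)
        strong_neg = ex.bin_edges[1:] <= -0.9
        envelope_hi = ex.permuted_excess.max(axis=0)
        assert (ex.observed_excess[strong_neg] > envelope_hi[strong_neg]).all()

    def test_too_few_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_excess_distribution(
                rng.uniform(-1, 1, 10), rng.uniform(-1, 1, 10),
                bin_edges=np.array([-1.0, 1.0]),
            )


class TestTransfectionInhibition:
    def test_strong_downshift_detected(self):
        effects = {f"t{i}": -1.0 for i in range(20)}
        effects.update({f"o{i}": 0.0 for i in range(20)})
        p = transfection_inhibition_test(
            effects, [f"t{i}" for i in range(20)], [f"o{i}" for i in range(20)]
        )
        assert p < 1e-6

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(20):
            vals = rng.normal(size=40)
            effects = {f"g{i}": v for i, v in enumerate(vals)}
            ps.append(
                transfection_inhibition_test(
                    effects, [f"g{i}" for i in range(20)],
                    [f"g{i}" for i in range(20, 40)],
                )
            )
        assert 0.3 < np.median(ps) < 0.7

    def test_empty_target_set_errors(self):
        with pytest.raises(ValueError):
            transfection_inhibition_test({"a": 1.0}, [], ["a"])
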