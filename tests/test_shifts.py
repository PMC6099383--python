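"""Birth-death shift likelihoods, AICc bookkeeping, and the stepwise search."""

import math

import numpy as np
import pytest

from divrates import read_newick
from divrates.bd import clade_richness_loglik
from divrates.shifts import (
    ShiftModel,
    _Shift,
    _assignment,
    _class_data,
    _class_loglik,
    aicc,
    backbone_loglik,
    default_threshold,
    fit_class_parameters,
    summarize_shifts,
)
from divrates.simulate import PlantedShift, simulate_bd_tree


class TestBackboneLikelihood:
    def test_yule_closed_form_three_tips(self, cherry_tree):
        # (N-2) ln b - b * total branch length, conditioned on the crown age
        for b in (0.1, 0.3, 1.0):
            expected = math.log(b) - b * 5.0
            assert backbone_loglik(cherry_tree, b, 0.0) == pytest.approx(expected)

    def test_invariant_under_tip_relabeling(self):
        t1 = read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        t2 = read_newick("((X:1,Y:1):1,(W:1.5,Z:1.5):0.5);")
        assert backbone_loglik(t1, 0.2, 0.1) == pytest.approx(
            backbone_loglik(t2, 0.2, 0.1)
        )

    def test_near_critical_limit_finite(self, cherry_tree):
        vals = [
            backbone_loglik(cherry_tree, 0.2, d)
            for d in (0.19, 0.1999, 0.19999999)
        ]
        assert all(np.isfinite(vals))
        # approaches a finite limit smoothly
        assert abs(vals[-1] - vals[-2]) < 1e-3

    def test_rejects_nonpositive_speciation(self, cherry_tree):
        with pytest.raises(ValueError):
            backbone_loglik(cherry_tree, 0.0, 0.0)


class TestCladeRichnessLikelihood:
    def test_pure_birth_closed_form(self):
        # P(n=1 | b=0.1, t=10) = e^{-1}
        assert clade_richness_loglik(1, 10.0, 0.1, 0.0) == pytest.approx(-1.0)
        # P(n|t) = e^{-bt}(1-e^{-bt})^{n-1}
        b, t, n = 0.2, 15.0, 7
        expected = -b * t + (n - 1) * math.log1p(-math.exp(-b * t))
        assert clade_richness_loglik(n, t, b, 0.0) == pytest.approx(expected)

    def test_normalization_sums_to_one(self):
        for b, d, t in [(0.2, 0.1, 15.0), (0.1, 0.075, 40.0)]:
            n = np.arange(1, 20000)
            total = np.exp(clade_richness_loglik(n, t, b, d)).sum()
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_simulator_frequencies(self):
        # Monte-Carlo clade sizes at (b=0.2, d=0.1, t=15), conditioned on
        # survival, against the geometric law within 3 SEs
        b, d, t, reps = 0.2, 0.1, 15.0, 4000
        rng = np.random.default_rng(99)
        sizes = []
        while len(sizes) < reps:
            n_alive = 1
            now = 0.0
            while n_alive > 0:
                now += rng.exponential(1.0 / ((b + d) * n_alive))
                if now >= t:
                    break
                n_alive += 1 if rng.random() < b / (b + d) else -1
            if n_alive > 0:
                sizes.append(n_alive)
        sizes = np.asarray(sizes)
        for n in (1, 2, 5):
            p_hat = np.mean(sizes == n)
            p_true = math.exp(float(clade_richness_loglik(n, t, b, d)))
            se = math.sqrt(p_true * (1 - p_true) / reps)
            assert abs(p_hat - p_true) <= 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clade_richness_loglik(0, 10.0, 0.1, 0.0)
        with pytest.raises(ValueError):
            clade_richness_loglik(5, -1.0, 0.1, 0.0)
        with pytest.raises(ValueError):
            clade_richness_loglik(5, 10.0, -0.1, 0.0)


class TestAicc:
    def test_hand_evaluation(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(24.0 + 12.0 / 7.0)

    def test_limits_to_aic(self):
        assert aicc(-10.0, 2, 10**9) == pytest.approx(24.0, abs=1e-6)

    def test_monotone_in_loglik(self):
        assert aicc(-11.0, 2, 50) > aicc(-10.0, 2, 50)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_default_threshold_lookup(self):
        assert default_threshold(234) == 6.7
        assert default_threshold(45) == 2.3
        with pytest.raises(ValueError):
            default_threshold(150)


class TestParameterFitting:
    def test_yule_parameter_recovery(self):
        tree, _ = simulate_bd_tree(0.1, 0.0, ntips=100, seed=7)
        rc = fit_class_parameters(tree)
        # ~2 SE band for a Yule rate from N-2 informative splits
        se = 0.1 / math.sqrt(tree.n_tips - 2)
        assert rc.b == pytest.approx(0.1, abs=2.5 * se)
        assert rc.d == pytest.approx(0.0, abs=0.02)

    def test_refit_is_a_fixed_point(self):
        tree, _ = simulate_bd_tree(0.15, 0.05, ntips=60, seed=13)
        rc1 = fit_class_parameters(tree, seed=0)
        rc2 = fit_class_parameters(tree, seed=0)
        assert rc1.loglik == pytest.approx(rc2.loglik, abs=1e-8)

    def test_multistart_stability_across_seeds(self):
        tree, _ = simulate_bd_tree(0.15, 0.05, ntips=60, seed=13)
        rc1 = fit_class_parameters(tree, seed=1)
        rc2 = fit_class_parameters(tree, seed=2)
        assert rc1.loglik == pytest.approx(rc2.loglik, abs=1e-4)
        assert rc1.b == pytest.approx(rc2.b, rel=0.02)


class TestModelComposition:
    def test_redundant_shift_preserves_loglik_exactly(self):
        tree, _ = simulate_bd_tree(0.12, 0.04, ntips=40, seed=5)
        richness = {lab: 1 + (i % 4) for i, lab in enumerate(sorted(tree.tip_labels))}
        model = ShiftModel(tree, richness)
        base = model._fit_structure([], n_starts=3, seed=0)
        classes, loglik, base_aicc = base
        # plant a shift whose class copies the background parameters
        target = next(
            i for i in range(1, len(model._flat.nodes))
            if not model._flat.is_tip[i]
        )
        branch_class, node_class = _assignment(model._flat, [_Shift(target, "stem")])
        rc = classes[0]
        total = 0.0
        for c in (0, 1):
            data = _class_data(model._flat, branch_class, node_class, c, True)
            total += _class_loglik(rc.r, rc.eps, data)
        assert total == pytest.approx(loglik, abs=1e-9)
        # the richer model can only have worse AICc at equal likelihood
        assert aicc(total, model._k(2), model.n_obs) > base_aicc

    def test_stepwise_aicc_never_worse_than_single_class(self):
        tree, _ = simulate_bd_tree(
            0.05, 0.0, ntips=80,
            shift=PlantedShift(b=0.3, at_count=30, min_clade=15), seed=10,
        )
        model = ShiftModel(tree)
        single = model._fit_structure([], n_starts=5, seed=0)
        res = model.fit(threshold=6.7, seed=0)
        assert res.aicc <= single[2] + 1e-9

    def test_planted_shift_recovered_on_small_tree(self):
        tree, info = simulate_bd_tree(
            0.05, 0.0, ntips=80,
            shift=PlantedShift(b=0.3, at_count=30, min_clade=15), seed=10,
        )
        res = ShiftModel(tree).fit(threshold=6.7, seed=0)
        assert res.n_shifts >= 1
        assert info["shift_tips"] in [sh["bipartition"] for sh in res.shifts]

    def test_raising_threshold_never_adds_shifts(self):
        tree, _ = simulate_bd_tree(
            0.05, 0.0, ntips=80,
            shift=PlantedShift(b=0.3, at_count=30, min_clade=15), seed=10,
        )
        model = ShiftModel(tree)
        counts = [
            model.fit(threshold=thr, seed=0).n_shifts for thr in (2.0, 6.7, 50.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_results_surface(self):
        tree, _ = simulate_bd_tree(0.1, 0.0, ntips=30, seed=2)
        res = ShiftModel(tree).fit(threshold=6.7, seed=0)
        assert res.k == 3 * len(res.classes) - 1
        assert res.n_obs == 30 + 29
        assert "AICc" in res.summary()
        d = res.to_dict()
        assert set(d) >= {"loglik", "k", "aicc", "classes", "shifts"}


class TestShiftSummaries:
    def _fake_result(self, tree, shifts):
        res = ShiftModel(tree).fit(threshold=1e9, seed=0)  # single class
        res.shifts = shifts
        return res

    def test_frequency_counting_and_cutoff(self, cherry_tree):
        bip = frozenset({"A", "B"})
        sh = {"bipartition": bip, "delta_r": 0.01, "age_stem": 2.0}
        results = [self._fake_result(cherry_tree, [dict(sh)]) for _ in range(10)]
        for res in results[6:]:
            res.shifts = []
        out = summarize_shifts(results, min_frequency=0.5)
        assert len(out) == 1
        assert out.frequency.iloc[0] == pytest.approx(0.6)
        assert summarize_shifts(results, min_frequency=0.75).empty

    def test_direction_matches_delta_sign(self, cherry_tree):
        up = {"bipartition": frozenset({"A"}), "delta_r": 0.02, "age_stem": 1.0}
        down = {"bipartition": frozenset({"B"}), "delta_r": -0.01, "age_stem": 1.0}
        out = summarize_shifts(
            [self._fake_result(cherry_tree, [up, down])], min_frequency=0.0
        )
        by_bip = out.set_index("tips_preview").direction
        assert by_bip.loc["A"] == "up"
        assert by_bip.loc["B"] == "down"
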