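import itertools

import numpy as np
import pandas as pd
import pytest

from connsig.curves import (
    CorrelationCurve,
    correlation_curve,
    fdr_bh,
    load_curve,
    permutation_test,
    save_curve,
)
from connsig.expression import profile_from_scores
from connsig.glm import DesignMatrix, build_design, fit_edge_glm

from conftest import identity_ranking, random_effect_matrix


def brute_force_curve(effect_a, effect_b, ranking):
    """Independent re-implementation: re-sort, re-slice and re-correlate each
    submatrix size from scratch with explicit loops."""
    labels = effect_a.region_labels
    ranks = ranking.rank_of()
    ordered = sorted(labels, key=lambda name: ranks[name])
    out = []
    for size in range(len(labels), 2, -1):
        keep = ordered[:size]
        idx = [labels.index(r) for r in keep]
        xa, xb = [], []
        for row in range(size):
            for col in range(row):
                xa.append(effect_a.effect[idx[row], idx[col]])
                xb.append(effect_b.effect[idx[row], idx[col]])
        out.append(np.corrcoef(xa, xb)[0, 1])
    return np.array(out)


class TestCorrelationCurve:
    def test_self_correlation_is_flat_one(self, rng):
        labels = [f"R{i}" for i in range(5)]
        eff = random_effect_matrix(labels, rng)
        curve = correlation_curve(eff, eff, identity_ranking(labels))
        assert len(curve.sizes) == 3  # 5 regions -> sizes 5, 4, 3
        np.testing.assert_allclose(curve.r_values, 1.0, atol=1e-12)
        assert curve.auc == pytest.approx(3.0)

    def test_negation_flips_the_curve(self, rng):
        labels = [f"R{i}" for i in range(5)]
        a = random_effect_matrix(labels, rng)
        b = random_effect_matrix(labels, rng)
        ranking = identity_ranking(labels)
        plus = correlation_curve(a, b, ranking)
        b.effect = -b.effect
        minus = correlation_curve(a, b, ranking)
        np.testing.assert_allclose(minus.r_values, -plus.r_values, atol=1e-12)
        assert minus.auc == pytest.approx(-plus.auc)

    def test_matches_brute_force_oracle(self, rng):
        labels = [f"R{i}" for i in range(6)]
        scores = pd.Series(rng.standard_normal(6), index=labels)
        ranking = profile_from_scores(scores)
        for _ in range(5):
            a = random_effect_matrix(labels, rng)
            b = random_effect_matrix(labels, rng)
            curve = correlation_curve(a, b, ranking)
            np.testing.assert_allclose(
                curve.r_values, brute_force_curve(a, b, ranking), atol=1e-12
            )

    def test_structural_counts_at_full_scale(self, rng):
        labels = [f"R{i}" for i in range(106)]
        a = random_effect_matrix(labels, rng)
        b = random_effect_matrix(labels, rng)
        curve = correlation_curve(a, b, identity_ranking(labels))
        assert len(curve.sizes) == 104
        assert curve.sizes[0] == 106 and curve.sizes[-1] == 3
        assert 106 * 105 // 2 == 5565  # full-size edge-vector length

    def test_positive_scaling_invariance(self, rng):
        labels = [f"R{i}" for i in range(7)]
        a = random_effect_matrix(labels, rng)
        b = random_effect_matrix(labels, rng)
        ranking = identity_ranking(labels)
        base = correlation_curve(a, b, ranking)
        a.effect = 17.3 * a.effect
        scaled = correlation_curve(a, b, ranking)
        np.testing.assert_allclose(base.r_values, scaled.r_values, atol=1e-12)

    def test_degenerate_submatrix_warns_and_records_zero(self, rng):
        labels = [f"R{i}" for i in range(4)]
        a = random_effect_matrix(labels, rng)
        b = random_effect_matrix(labels, rng)
        a.effect[:, :] = 1.0  # constant edges -> zero variance everywhere
        np.fill_diagonal(a.effect, 0.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            curve = correlation_curve(a, b, identity_ranking(labels))
        assert np.all(curve.r_values == 0.0)
        assert set(curve.degenerate) == {4, 3}

    def test_serialization_roundtrip_preserves_auc(self, rng, tmp_path):
        labels = [f"R{i}" for i in range(6)]
        a = random_effect_matrix(labels, rng)
        b = random_effect_matrix(labels, rng)
        curve = correlation_curve(a, b, identity_ranking(labels))
        save_curve(curve, None, tmp_path / "c")
        back = load_curve(tmp_path / "c")
        assert back.auc == pytest.approx(curve.auc)
        assert back.auc == pytest.approx(np.sum(back.r_values))


def patient_frame(alleles, rng):
    n = len(alleles)
    return pd.DataFrame(
        {
            "subject_id": [f"p{i}" for i in range(n)],
            "group": "patient",
            "allele_count": alleles,
            "gender": rng.integers(0, 2, size=n),
            "dose": rng.gamma(2, 3, size=n),
        }
    )


class TestPermutationTest:
    def test_floor_on_n_perm(self, rng):
        labels = [f"R{i}" for i in range(4)]
        cohort = patient_frame([0, 1, 2, 0, 1, 2, 0, 1], rng)
        design = build_design(cohort)
        y = rng.standard_normal((8, 6))
        pharm = {"ket_gt_mdz": random_effect_matrix(labels, rng)}
        with pytest.raises(ValueError, match="at least 100"):
            permutation_test(y, design, pharm, identity_ranking(labels), labels, n_perm=50)

    def test_matches_exhaustive_enumeration(self, rng):
        # 6 patients -> all 720 genotype relabelings enumerated with the
        # public operations; Monte-Carlo p must agree within 0.02
        labels = [f"R{i}" for i in range(5)]
        alleles = [0, 0, 1, 1, 2, 2]
        cohort = patient_frame(alleles, rng)
        design = build_design(cohort, covariates=())
        ranking = identity_ranking(labels)
        y = rng.standard_normal((6, 10))
        pharm = {"ket_gt_mdz": random_effect_matrix(labels, rng)}

        observed_fit = fit_edge_glm(y, design, labels)
        obs_auc = correlation_curve(observed_fit, pharm["ket_gt_mdz"], ranking).auc
        null = []
        for perm in itertools.permutations(range(6)):
            d = DesignMatrix(
                matrix=np.c_[np.ones(6), np.array(alleles, float)[list(perm)]],
                columns=["intercept", "allele_count"],
                interest="allele_count",
            )
            fit = fit_edge_glm(y, d, labels)
            null.append(correlation_curve(fit, pharm["ket_gt_mdz"], ranking).auc)
        exact_p = np.mean(np.array(null) >= obs_auc)

        res = permutation_test(
            y, design, pharm, ranking, labels, n_perm=10000, seed=11
        )["ket_gt_mdz"]
        assert res.observed_auc == pytest.approx(obs_auc, abs=1e-10)
        assert abs(res.p_raw - exact_p) < 0.02

    def test_engine_reproducible_and_add_one_bounded(self, rng):
        labels = [f"R{i}" for i in range(6)]
        cohort = patient_frame(list(np.tile([0, 1, 2], 10)), rng)
        design = build_design(cohort)
        y = rng.standard_normal((30, 15))
        pharm = {
            "ket_gt_pla": random_effect_matrix(labels, rng),
            "mdz_gt_pla": random_effect_matrix(labels, rng),
            "ket_gt_mdz": random_effect_matrix(labels, rng),
        }
        ranking = identity_ranking(labels)
        a = permutation_test(y, design, pharm, ranking, labels, n_perm=200, seed=5)
        b = permutation_test(y, design, pharm, ranking, labels, n_perm=200, seed=5)
        for name in pharm:
            np.testing.assert_array_equal(a[name].null_aucs, b[name].null_aucs)
            assert a[name].p_raw >= 1 / 201  # add-one estimator never reaches 0
            assert a[name].p_raw == b[name].p_raw
        assert a["mdz_gt_pla"].direction == "less"


class TestFdrBh:
    def test_three_value_analytic_example(self):
        adj, _ = fdr_bh(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04], atol=1e-12)

    def test_single_value_identity(self):
        adj, rej = fdr_bh(np.array([0.5]))
        assert adj[0] == pytest.approx(0.5)
        assert not rej[0]

    def test_matches_step_up_definition(self, rng):
        p = rng.uniform(size=20)
        adj, _ = fdr_bh(p)
        m = len(p)
        order = np.argsort(p)
        expect = np.empty(m)
        running = 1.0
        for rank_i in range(m - 1, -1, -1):
            running = min(running, p[order[rank_i]] * m / (rank_i + 1))
            expect[order[rank_i]] = running
        np.testing.assert_allclose(adj, expect, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([]))
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.0, 0.5]))
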