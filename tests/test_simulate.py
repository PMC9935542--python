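import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connsig.atlas import default_labels
from connsig.simulate import (
    SetEffect,
    SimulationConfig,
    nearest_correlation,
    perturbation_matrix,
    simulate_cohort,
    simulate_symptoms,
    simulate_timeseries,
    target_correlations,
)

LABELS10 = tuple(default_labels()["name"][:10])


def small_config(**kw):
    base = dict(
        seed=7,
        n_patients=30,
        n_controls=10,
        n_pharmaco=6,
        n_timepoints=60,
        region_labels=LABELS10,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestCohort:
    def test_hwe_counts_within_multinomial_envelope(self):
        # each genotype count must fall inside the 99% binomial envelope of
        # its HWE expectation (exact ppf bounds, the independent oracle)
        cfg = SimulationConfig(
            seed=1, n_patients=146, n_controls=0, n_pharmaco=0, allele_freq=0.277,
            region_labels=LABELS10,
        )
        cohort, _ = simulate_cohort(cfg)
        pat = cohort[cohort["group"] == "patient"]
        counts = pat["allele_count"].value_counts()
        p = 0.277
        probs = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
        for g, q in probs.items():
            lo = stats.binom.ppf(0.005, 146, q)
            hi = stats.binom.ppf(0.995, 146, q)
            assert lo <= counts.get(g, 0) <= hi

    def test_zero_allele_frequency(self):
        cohort, _ = simulate_cohort(small_config(allele_freq=0.0))
        assert (cohort["allele_count"] == 0).all()

    def test_determinism(self):
        cfg = small_config()
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_session_structure(self):
        cohort, sessions = simulate_cohort(small_config())
        merged = sessions.merge(cohort, on="subject_id")
        counts = merged.groupby("subject_id").size()
        pharm = cohort.loc[cohort["group"] == "pharmaco", "subject_id"]
        assert (counts[pharm] == 6).all()
        rest = cohort.loc[cohort["group"] != "pharmaco", "subject_id"]
        assert (counts[rest] == 1).all()

    def test_invalid_allele_freq(self):
        with pytest.raises(ValueError):
            small_config(allele_freq=1.5)

    def test_dose_and_gender_invariants(self):
        cohort, _ = simulate_cohort(small_config())
        assert (cohort["dose"] >= 0).all()
        assert cohort.loc[cohort["group"] != "patient", "dose"].eq(0).all()
        assert cohort["allele_count"].isin([0, 1, 2]).all()
        assert cohort["subject_id"].is_unique


class TestTimeseries:
    def test_planted_allele_effect_concentrates_in_signal_block(self):
        # Monte-Carlo check against the generating covariance: allele 2 vs 0
        # difference on signal edges should be positive and >= 2x outside
        signal = LABELS10[:4]
        cfg = small_config(
            n_timepoints=2000, signal_regions=signal, delta_allele=0.3,
            n_patients=24, n_controls=0, n_pharmaco=0,
        )
        cohort, sessions = simulate_cohort(cfg)
        cohort["allele_count"] = [0, 2] * 12  # planted contrast
        ts = simulate_timeseries(cohort, sessions, cfg)
        sig_idx = [cfg.region_labels.index(r) for r in signal]
        diffs = {0: [], 2: []}
        for _, row in cohort.iterrows():
            mat = np.corrcoef(ts.series[(row["subject_id"], "rest")], rowvar=False)
            diffs[row["allele_count"]].append(mat)
        d = np.mean(diffs[2], axis=0) - np.mean(diffs[0], axis=0)
        mask = np.zeros_like(d, dtype=bool)
        mask[np.ix_(sig_idx, sig_idx)] = True
        np.fill_diagonal(mask, False)
        tril = np.tril(np.ones_like(d, dtype=bool), -1)
        inside = d[mask & tril].mean()
        outside = np.abs(d[~mask & tril]).mean()
        assert inside > 0
        assert inside >= 2 * outside

    def test_null_model_has_no_genotype_differences(self):
        cfg = small_config(n_timepoints=2000, n_patients=20, n_controls=0, n_pharmaco=0)
        cohort, sessions = simulate_cohort(cfg)
        cohort["allele_count"] = [0, 2] * 10
        ts = simulate_timeseries(cohort, sessions, cfg)
        mats = {0: [], 2: []}
        for _, row in cohort.iterrows():
            mats[row["allele_count"]].append(
                np.corrcoef(ts.series[(row["subject_id"], "rest")], rowvar=False)
            )
        d = np.mean(mats[2], axis=0) - np.mean(mats[0], axis=0)
        assert np.abs(d[np.tril_indices(len(LABELS10), -1)]).max() < 0.05 * 3

    def test_seeded_runs_are_bit_identical(self):
        cfg = small_config(signal_regions=LABELS10[:3])
        cohort, sessions = simulate_cohort(cfg)
        a = simulate_timeseries(cohort, sessions, cfg)
        b = simulate_timeseries(cohort, sessions, cfg)
        for key in a.series:
            np.testing.assert_array_equal(a.series[key], b.series[key])

    def test_drug_condition_applies_only_post_infusion(self):
        cfg = small_config(
            signal_regions=LABELS10[:4], delta_ket=0.4, n_timepoints=4000,
            n_patients=0, n_controls=0, n_pharmaco=4,
        )
        cohort, sessions = simulate_cohort(cfg)
        ts = simulate_timeseries(cohort, sessions, cfg)
        sig = [0, 1, 2, 3]
        pre, post = [], []
        for sid in cohort["subject_id"]:
            pre.append(np.corrcoef(ts.series[(sid, "ketamine_pre")], rowvar=False))
            post.append(np.corrcoef(ts.series[(sid, "ketamine_post")], rowvar=False))
        d = np.mean(post, axis=0) - np.mean(pre, axis=0)
        block = d[np.ix_(sig, sig)][np.tril_indices(4, -1)]
        assert block.mean() > 0.2


class TestCorrelationProjection:
    def test_generated_matrices_are_valid_correlations(self):
        cfg = small_config(signal_regions=LABELS10[:6], delta_allele=0.45)
        for mat in target_correlations(cfg).values():
            np.testing.assert_allclose(mat, mat.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(mat), 1.0, atol=1e-12)
            assert np.linalg.eigvalsh(mat).min() >= -1e-10

    def test_projection_fixes_indefinite_input(self):
        m = np.full((4, 4), 0.9)
        m[0, 1] = m[1, 0] = -0.9  # incompatible with the rest
        np.fill_diagonal(m, 1.0)
        c = nearest_correlation(m)
        assert np.linalg.eigvalsh(c).min() >= 0
        np.testing.assert_allclose(np.diag(c), 1.0)

    def test_perturbation_counts_each_edge_once(self):
        p = perturbation_matrix(list("abcd"), [SetEffect(["a", "b"], ["a", "b"], 0.3)])
        assert p[0, 1] == pytest.approx(0.3)
        assert p[1, 0] == pytest.approx(0.3)
        assert p.sum() == pytest.approx(0.6)


class TestSymptoms:
    def test_noiseless_latent_score(self):
        cfg = small_config(
            sym_noise_sd=0.0, sym_edge_slope=0.0, sym_allele_slope=1.0, sym_intercept=3.0
        )
        cohort, _ = simulate_cohort(cfg)
        pat = cohort[cohort["group"] == "patient"].reset_index(drop=True)
        scores = simulate_symptoms(cohort, None, cfg)
        expected = np.clip(np.rint(3.0 - pat["allele_count"]), -7, 7)
        np.testing.assert_array_equal(scores["language_qualitative"], expected)

    def test_uncoupled_scores_show_null_association(self):
        cfg = small_config(
            n_patients=146, sym_allele_slope=0.0, sym_edge_slope=0.0
        )
        cohort, _ = simulate_cohort(cfg)
        pat = cohort[cohort["group"] == "patient"]
        scores = simulate_symptoms(cohort, None, cfg)
        r = np.corrcoef(pat["allele_count"], scores["language_qualitative"])[0, 1]
        assert abs(r) < 2 / np.sqrt(len(pat))  # inside the null 95% band

    def test_scores_respect_item_range(self):
        cfg = small_config(sym_allele_slope=5.0, sym_noise_sd=3.0)
        cohort, _ = simulate_cohort(cfg)
        scores = simulate_symptoms(cohort, None, cfg)
        for col in scores.columns.drop("subject_id"):
            assert scores[col].between(-7, 7).all()
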