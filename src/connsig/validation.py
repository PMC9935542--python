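"""Simulation studies that validate the statistical machinery end to end.

Each study regenerates synthetic datasets from scratch (cohort, time series,
ranking), runs the full analysis path being validated, and summarizes the
outcome across replicates:

* :func:`null_permutation_calibration` — type-I error and p-value uniformity
  of the AUC permutation test under genotype exchangeability;
* :func:`enrichment_study` — recovery of the headline curve shape (rising
  correlation as low-expression regions are stripped away) and power of the
  AUC test when a shared genotype/drug signal is planted in the
  top-expressing regions;
* :func:`glm_recovery_study` — bias of the per-edge allele-dose coefficient
  and sign recovery of the ketamine-vs-midazolam paired contrast;
* :func:`fnc_symptom_study` — detection, with correct signs, of planted
  striato-pallido-thalamic<->auditory-sensory-motor hyper-connectivity,
  superior-temporal<->temporo-occipital hypo-connectivity, and the
  genotype -> connectivity -> language-symptom coupling;
* :func:`fnc_null_calibration` / :func:`symptom_null_calibration` — nominal
  false-positive behaviour of the set-level and multivariate symptom tests.

Problem sizes default to reduced-scale versions of the emulated study (fewer
timepoints and, for the calibration studies, fewer regions/subjects) so a
full validation pass completes in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import default_labels, region_sets
from .connectivity import compute_connectivity
from .curves import correlation_curve, permutation_test
from .expression import profile_from_scores
from .glm import PHARM_CONTRASTS, build_design, fit_edge_glm, paired_contrast, stack_conn
from .networks import NetworkDef, fnc_test
from .simulate import (
    SetEffect,
    SimulationConfig,
    simulate_cohort,
    simulate_symptoms,
    simulate_timeseries,
)
from .symptoms import domain_manova, partial_corr

__all__ = [
    "null_permutation_calibration",
    "enrichment_study",
    "glm_recovery_study",
    "fnc_symptom_study",
    "fnc_null_calibration",
    "symptom_null_calibration",
    "simulate_effects",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


def _random_ranking(labels, rng):
    """A random but fixed expression ranking over the given regions."""
    scores = np.linspace(2.0, -2.0, len(labels))[rng.permutation(len(labels))]
    return profile_from_scores(pd.Series(scores, index=list(labels)))


def simulate_effects(cfg: SimulationConfig, contrasts=("ket_gt_mdz",)):
    """One synthetic dataset -> (patient conn stack, design, drug effects)."""
    cohort, sessions = simulate_cohort(cfg)
    ts = simulate_timeseries(cohort, sessions, cfg)
    labels = ts.region_labels
    patients = cohort[cohort["group"] == "patient"].reset_index(drop=True)
    conns = {key: compute_connectivity(mat, labels) for key, mat in ts.series.items()}
    conn_stack, _ = stack_conn([conns[(sid, "rest")] for sid in patients["subject_id"]])
    design = build_design(patients)
    pharm_ids = cohort.loc[cohort["group"] == "pharmaco", "subject_id"]
    by_session = {
        sid: {key: conns[(s, key)] for (s, key) in conns if s == sid} for sid in pharm_ids
    }
    pharm = {c: paired_contrast(by_session, PHARM_CONTRASTS[c]) for c in contrasts}
    return conn_stack, design, pharm, labels, patients, conns


def null_permutation_calibration(
    n_datasets: int = 200,
    n_patients: int = 80,
    n_regions: int = 30,
    n_timepoints: int = 100,
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I behaviour of the AUC permutation test on pure-null data.

    Every dataset is simulated without any planted effect, so genotype is
    exchangeable and the permutation p-value should be uniform.  Returns the
    empirical rejection rate at ``alpha`` and a Kolmogorov-Smirnov test of
    uniformity over the collected p-values.
    """
    labels = tuple(default_labels()["name"][:n_regions])
    seeds = _child_seeds(seed, n_datasets)
    pvals = np.empty(n_datasets)
    for i, s in enumerate(seeds):
        cfg = SimulationConfig(
            seed=int(s),
            n_patients=n_patients,
            n_controls=0,
            n_pharmaco=6,
            n_timepoints=n_timepoints,
            region_labels=labels,
        )
        conn_stack, design, pharm, lab, _, _ = simulate_effects(cfg)
        ranking = _random_ranking(lab, np.random.default_rng(int(s) + 1))
        res = permutation_test(
            conn_stack, design, pharm, ranking, lab, n_perm=n_perm, seed=int(s) + 2
        )
        pvals[i] = res["ket_gt_mdz"].p_raw
    ks = stats.kstest(pvals, "uniform")
    return {
        "p_values": pvals,
        "type1_rate": float(np.mean(pvals <= alpha)),
        "ks_p": float(ks.pvalue),
        "n_datasets": n_datasets,
        "n_perm": n_perm,
    }


def enrichment_study(
    n_seeds: int = 100,
    n_perm: int = 200,
    top_k: int = 20,
    n_timepoints: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    head: int = 30,
    tail: int = 30,
) -> dict:
    """Curve-shape and AUC power when signal sits in top-ranked regions.

    A shared genotype/drug perturbation is planted only on edges among the
    ``top_k`` highest-expressing regions of a known ranking.  Per replicate
    the study records (a) whether the mean correlation over the last
    ``tail`` curve points (smallest, most enriched submatrices) exceeds the
    mean over the first ``head`` points, and (b) whether the one-sided AUC
    permutation test rejects for the ketamine-vs-midazolam contrast.
    """
    labels = tuple(default_labels()["name"])
    seeds = _child_seeds(seed, n_seeds)
    enriched = np.zeros(n_seeds, dtype=bool)
    rejected = np.zeros(n_seeds, dtype=bool)
    aucs = np.empty(n_seeds)
    for i, s in enumerate(seeds):
        ranking = _random_ranking(labels, np.random.default_rng(int(s)))
        signal = tuple(ranking.ranking()[:top_k])
        cfg = SimulationConfig(
            seed=int(s),
            n_timepoints=n_timepoints,
            region_labels=labels,
            signal_regions=signal,
            background_allele_sd=0.03,
            background_drug_sd=0.03,
        )
        conn_stack, design, pharm, lab, _, _ = simulate_effects(cfg)
        snp = fit_edge_glm(conn_stack, design, lab, contrast_name="snp")
        curve = correlation_curve(snp, pharm["ket_gt_mdz"], ranking)
        enriched[i] = curve.r_values[-tail:].mean() > curve.r_values[:head].mean()
        res = permutation_test(
            conn_stack, design, pharm, ranking, lab, n_perm=n_perm, seed=int(s) + 2
        )["ket_gt_mdz"]
        rejected[i] = res.p_raw < alpha
        aucs[i] = res.observed_auc
    return {
        "enrichment_fraction": float(enriched.mean()),
        "rejection_fraction": float(rejected.mean()),
        "mean_auc": float(aucs.mean()),
        "n_seeds": n_seeds,
    }


def glm_recovery_study(
    n_seeds: int = 50,
    n_regions: int = 30,
    n_signal: int = 10,
    n_timepoints: int = 500,
    seed: int = 0,
) -> dict:
    """Bias of the allele-dose coefficient and drug-contrast sign recovery.

    The planted per-allele correlation increment is compared with the mean
    fitted coefficient over the signal-block edges (on the Fisher-z scale
    the two agree up to the mild atanh nonlinearity).  The sign flag records
    whether the mean ketamine-vs-midazolam paired contrast over the same
    edges is positive, as planted.
    """
    labels = tuple(default_labels()["name"][:n_regions])
    signal = labels[:n_signal]
    seeds = _child_seeds(seed, n_seeds)
    betas = np.empty(n_seeds)
    signs = np.zeros(n_seeds, dtype=bool)
    delta = None
    sig_idx = np.arange(n_signal)
    for i, s in enumerate(seeds):
        cfg = SimulationConfig(
            seed=int(s),
            n_timepoints=n_timepoints,
            region_labels=labels,
            signal_regions=signal,
        )
        delta = cfg.delta_allele
        conn_stack, design, pharm, lab, _, _ = simulate_effects(cfg)
        snp = fit_edge_glm(conn_stack, design, lab)
        block = snp.effect[np.ix_(sig_idx, sig_idx)]
        betas[i] = block[np.tril_indices(n_signal, -1)].mean()
        ket = pharm["ket_gt_mdz"].effect[np.ix_(sig_idx, sig_idx)]
        signs[i] = ket[np.tril_indices(n_signal, -1)].mean() > 0
    return {
        "planted_delta": float(delta),
        "mean_beta": float(betas.mean()),
        "bias_fraction": float(abs(betas.mean() - delta) / delta),
        "contrast_sign_fraction": float(signs.mean()),
        "n_seeds": n_seeds,
    }


def fnc_symptom_study(
    n_seeds: int = 50,
    n_timepoints: int = 500,
    delta_spt_asm: float = 0.2,
    delta_stg_to: float = -0.15,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Detection of planted network effects and the language-symptom coupling.

    Per allele copy, connectivity between the striato-pallido-thalamic (SPT)
    and auditory-sensory-motor (ASM) sets is raised by ``delta_spt_asm`` and
    connectivity between the superior-temporal (STG) and temporo-occipital
    (TO) sets lowered by ``delta_stg_to``.  Qualitative-language symptom
    sums couple negatively to the allele count and positively to the
    connectivity of one hypo-connected STG-TO edge, so the study also checks
    the two partial correlations the clinical analysis relies on.
    """
    sets = region_sets()
    labels = tuple(default_labels()["name"])
    spt, asm = NetworkDef("SPT", sets["SPT"]), NetworkDef("ASM", sets["ASM"])
    stg, to = NetworkDef("STG", sets["STG"]), NetworkDef("TO", sets["TO"])
    edge = ("pSTG l", "TOFusC r")
    seeds = _child_seeds(seed, n_seeds)
    hyper = np.zeros(n_seeds, dtype=bool)
    hypo = np.zeros(n_seeds, dtype=bool)
    sym_geno_neg = np.zeros(n_seeds, dtype=bool)
    sym_edge_pos = np.zeros(n_seeds, dtype=bool)
    for i, s in enumerate(seeds):
        cfg = SimulationConfig(
            seed=int(s),
            n_timepoints=n_timepoints,
            region_labels=labels,
            allele_set_effects=(
                SetEffect(sets["SPT"], sets["ASM"], delta_spt_asm),
                SetEffect(sets["STG"], sets["TO"], delta_stg_to),
            ),
        )
        conn_stack, design, _, lab, patients, conns = simulate_effects(cfg, contrasts=())
        res_ha = fnc_test(conn_stack, design, spt, asm, list(lab), with_contributions=False)
        hyper[i] = res_ha.effect > 0 and res_ha.p < alpha
        res_st = fnc_test(conn_stack, design, stg, to, list(lab), with_contributions=False)
        hypo[i] = res_st.effect < 0 and res_st.p < alpha

        ei, ej = lab.index(edge[0]), lab.index(edge[1])
        edge_vals = np.array(
            [conns[(sid, "rest")].z[ei, ej] for sid in patients["subject_id"]]
        )
        scores = simulate_symptoms(patients.assign(group="patient"), edge_vals, cfg)
        covs = design.matrix[:, [design.columns.index("gender"), design.columns.index("dose")]]
        lang = scores["language_qualitative"].to_numpy()
        r_geno, _, _ = partial_corr(patients["allele_count"].to_numpy(), lang, covs)
        r_edge, _, _ = partial_corr(edge_vals, lang, covs)
        sym_geno_neg[i] = r_geno < 0
        sym_edge_pos[i] = r_edge > 0
    return {
        "spt_asm_hyper_fraction": float(hyper.mean()),
        "stg_to_hypo_fraction": float(hypo.mean()),
        "genotype_symptom_negative_fraction": float(sym_geno_neg.mean()),
        "edge_symptom_positive_fraction": float(sym_edge_pos.mean()),
        "n_seeds": n_seeds,
    }


def fnc_null_calibration(
    n_runs: int = 200,
    n_patients: int = 80,
    n_timepoints: int = 60,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Null behaviour of the set-level SPT-ASM test (no planted effect)."""
    sets = region_sets()
    labels = tuple(default_labels()["name"])
    spt, asm = NetworkDef("SPT", sets["SPT"]), NetworkDef("ASM", sets["ASM"])
    seeds = _child_seeds(seed, n_runs)
    pvals = np.empty(n_runs)
    for i, s in enumerate(seeds):
        cfg = SimulationConfig(
            seed=int(s),
            n_patients=n_patients,
            n_controls=0,
            n_pharmaco=0,
            n_timepoints=n_timepoints,
            region_labels=labels,
        )
        cohort, sessions = simulate_cohort(cfg)
        ts = simulate_timeseries(cohort, sessions, cfg)
        conns = [
            compute_connectivity(ts.series[(sid, "rest")], ts.region_labels)
            for sid in cohort["subject_id"]
        ]
        conn_stack, lab = stack_conn(conns)
        design = build_design(cohort)
        res = fnc_test(conn_stack, design, spt, asm, lab, with_contributions=False)
        pvals[i] = res.p
    ks = stats.kstest(pvals, "uniform")
    return {
        "p_values": pvals,
        "false_positive_rate": float(np.mean(pvals <= alpha)),
        "ks_p": float(ks.pvalue),
        "n_runs": n_runs,
    }


def symptom_null_calibration(
    n_runs: int = 200, n_patients: int = 146, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Null behaviour of the per-domain Wilks-lambda test (no coupling)."""
    seeds = _child_seeds(seed, n_runs)
    pvals = np.empty(n_runs)
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        cohort = pd.DataFrame(
            {
                "subject_id": [f"p{k}" for k in range(n_patients)],
                "group": "patient",
                "allele_count": rng.binomial(2, 0.277, n_patients),
                "gender": rng.integers(0, 2, n_patients),
                "dose": rng.gamma(2, 3, n_patients),
            }
        )
        design = build_design(cohort)
        scores = rng.normal(0, 1.5, size=(n_patients, 3))
        pvals[i] = domain_manova(scores, design, domain="language").p
    ks = stats.kstest(pvals, "uniform")
    return {
        "p_values": pvals,
        "false_positive_rate": float(np.mean(pvals <= alpha)),
        "ks_p": float(ks.pvalue),
        "n_runs": n_runs,
    }
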