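"""End-to-end orchestration: simulate -> profiles -> connectivity -> GLM ->
curves/permutation -> network tests -> symptoms, with a hashed manifest.

The pipeline is deterministic: identical config (seed included) produces a
byte-identical report.  Each stage's outputs are written under the run
directory and hashed (SHA-256) into the manifest of the final report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import default_labels, region_sets, synthetic_atlas
from .connectivity import compute_connectivity, save_conn
from .curves import correlation_curve, permutation_test, save_curve
from .expression import assign_samples, build_profiles, save_profile
from .genetics import summarize_genotypes
from .glm import (
    PHARM_CONTRASTS,
    build_design,
    fit_edge_glm,
    paired_contrast,
    save_effect,
    stack_conn,
)
from .networks import NetworkDef, cluster_networks, fnc_all_pairs, fnc_test
from .simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_expression_samples,
    simulate_symptoms,
    simulate_timeseries,
    write_dataset,
)
from .symptoms import domain_tests, partial_corr

__all__ = ["RunConfig", "run_pipeline"]


def _json_default(o):
    if hasattr(o, "item"):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")

log = logging.getLogger("connsig")

STAGES = ("simulate", "profiles", "connect", "glm", "curves", "fnc", "symptoms")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-analysis run."""

    outdir: str = "connsig_run"
    seed: int = 0
    n_perm: int = 10000
    genes: tuple[str, ...] = ("GRIN1", "PV", "SLC17A7")
    allele_model: str = "additive"
    k_clusters: int = 10
    plant_top_k: int | None = 20  # plant effects in the top-k truly ranked regions
    auc_rule: str = "sum"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        self.genes = tuple(self.genes)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, stop_after: str = "symptoms") -> dict:
    """Execute the pipeline through ``stop_after`` and return the report.

    Stages run in dependency order; a stage failure aborts with the stage
    name.  The report bundle (JSON) lists every output file with its hash.
    """
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    last = STAGES.index(stop_after)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {"seed": config.seed, "n_perm": config.n_perm, "genes": list(config.genes)},
        "versions": {"connsig": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    sim = config.simulation.with_(seed=config.seed)

    def _stage(name):
        log.info("stage %s (seed=%d)", name, config.seed)

    try:
        # ------------------------------------------------------ simulate
        _stage("simulate")
        cohort, sessions = simulate_cohort(sim)
        patients = cohort[cohort["group"] == "patient"].reset_index(drop=True)
        counts = patients["allele_count"].value_counts().to_dict()
        gsum = summarize_genotypes(
            {"TT": counts.get(0, 0), "TC": counts.get(1, 0), "CC": counts.get(2, 0)}
        )
        report["stages"]["simulate"] = {
            "n_patients": len(patients),
            "allele_freq_c_pct": gsum.allele_freq_c_pct,
            "observed_pct": gsum.rounded_pct("observed"),
            "hwe_expected_pct": gsum.rounded_pct("expected"),
        }
        if last == 0:
            write_dataset(outdir, cohort, sessions, config=sim)
            return _finalize(report, outdir)

        # ------------------------------------------------------ profiles
        _stage("profiles")
        labels_df = default_labels()
        labels_df = labels_df[labels_df["name"].isin(sim.region_labels)].reset_index(drop=True)
        atlas = synthetic_atlas(labels=labels_df)
        samples, truth = simulate_expression_samples(sim, atlas)
        assignment = assign_samples(samples, atlas)
        profile = build_profiles(
            samples, assignment, genes=config.genes, regions=list(sim.region_labels)
        )
        save_profile(profile, outdir / "expression_profile.tsv")
        report["stages"]["profiles"] = {
            "n_samples": len(samples),
            "n_assigned": int(assignment.notna().sum()),
            "top5": profile.ranking()[:5],
        }
        if config.plant_top_k:
            top = truth.sort_values("true_rank")["region"].head(config.plant_top_k)
            sim = sim.with_(signal_regions=tuple(top))
        if last == 1:
            return _finalize(report, outdir)

        # ------------------------------------------------------ connect
        _stage("connect")
        ts = simulate_timeseries(cohort, sessions, sim)
        labels = ts.region_labels
        conns = {key: compute_connectivity(mat, labels) for key, mat in ts.series.items()}
        patient_conns = [conns[(sid, "rest")] for sid in patients["subject_id"]]
        conn_stack, _ = stack_conn(patient_conns)
        pharm_ids = cohort.loc[cohort["group"] == "pharmaco", "subject_id"]
        conn_by_session = {
            sid: {k: conns[(s, k)] for (s, k) in conns if s == sid}
            for sid in pharm_ids
        }
        report["stages"]["connect"] = {
            "n_sessions": len(conns),
            "n_edges": conn_stack.shape[1],
        }
        if last == 2:
            save_conn(patient_conns[0], outdir / "example_conn.tsv", outdir / "example_conn.json")
            return _finalize(report, outdir)

        # ------------------------------------------------------ glm
        _stage("glm")
        design = build_design(patients, allele_model=config.allele_model)
        snp_effect = fit_edge_glm(conn_stack, design, labels, contrast_name="snp")
        pharm_effects = {
            name: paired_contrast(conn_by_session, spec)
            for name, spec in PHARM_CONTRASTS.items()
        }
        save_effect(snp_effect, outdir / "effect_snp")
        for name, eff in pharm_effects.items():
            save_effect(eff, outdir / f"effect_{name}")
        report["stages"]["glm"] = {
            "design_columns": design.columns,
            "df": float(snp_effect.df),
        }
        if last == 3:
            return _finalize(report, outdir)

        # ------------------------------------------------------ curves
        _stage("curves")
        perm = permutation_test(
            conn_stack,
            design,
            pharm_effects,
            profile,
            labels,
            n_perm=config.n_perm,
            seed=config.seed,
            auc_rule=config.auc_rule,
        )
        curve_report = {}
        for name, eff in pharm_effects.items():
            curve = correlation_curve(snp_effect, eff, profile, auc_rule=config.auc_rule)
            save_curve(curve, perm[name], outdir / f"curve_{name}")
            curve_report[name] = {
                "auc": curve.auc,
                "p_raw": perm[name].p_raw,
                "p_fdr": perm[name].p_fdr,
                "direction": perm[name].direction,
            }
        report["stages"]["curves"] = curve_report
        if last == 4:
            return _finalize(report, outdir)

        # ------------------------------------------------------ fnc
        _stage("fnc")
        fnc_report = {}
        sets = region_sets()
        have = set(labels)
        if set(sets["SPT"]) <= have and set(sets["ASM"]) <= have:
            res = fnc_test(
                conn_stack,
                design,
                NetworkDef("SPT", sets["SPT"]),
                NetworkDef("ASM", sets["ASM"]),
                labels,
            )
            fnc_report["SPT_ASM"] = {
                "effect": res.effect,
                "t": res.statistic,
                "p": res.p,
                "n_contributing_edges": len(res.contributing_edges),
            }
        mean_conn = patient_conns[0].__class__(
            region_labels=labels,
            z=np.mean([c.z for c in patient_conns], axis=0),
        )
        nets = cluster_networks(mean_conn, k=min(config.k_clusters, len(labels)))
        pairs = fnc_all_pairs(conn_stack, design, nets, labels)
        sig = [
            {"pair": f"{r.name_a}~{r.name_b}", "effect": r.effect, "p_fdr": r.p_fdr}
            for r in pairs
            if r.p_fdr < 0.05
        ]
        fnc_report["clustered"] = {"k": len(nets), "n_tests": len(pairs), "significant": sig}
        with open(outdir / "fnc.json", "w") as fh:
            json.dump(fnc_report, fh, indent=2, sort_keys=True, default=_json_default)
        report["stages"]["fnc"] = fnc_report
        if last == 5:
            return _finalize(report, outdir)

        # ------------------------------------------------------ symptoms
        _stage("symptoms")
        ranked = profile.ranking()
        edge_regions = ranked[:2]
        i, j = labels.index(edge_regions[0]), labels.index(edge_regions[1])
        edge_vals = np.array([c.z[i, j] for c in patient_conns])
        symptoms = simulate_symptoms(patients, edge_vals, sim)
        symptoms.to_csv(outdir / "symptoms.tsv", sep="\t", index=False)
        results = domain_tests(symptoms, design)
        covs = design.matrix[:, [design.columns.index(c) for c in ("gender", "dose")]]
        r_edge, df_edge, p_edge = partial_corr(
            edge_vals, symptoms["language_qualitative"].to_numpy(), covs
        )
        sym_report = {
            "domains": {
                r.domain: {
                    "wilks_lambda": r.wilks_lambda,
                    "F": r.f_stat,
                    "df": list(r.df),
                    "p_fdr": r.p_fdr,
                    "partial_r": {k: v[0] for k, v in r.partial_r.items()},
                }
                for r in results
            },
            "edge_symptom": {
                "edge": list(edge_regions),
                "r": r_edge,
                "df": df_edge,
                "p": p_edge,
            },
        }
        with open(outdir / "symptom_tests.json", "w") as fh:
            json.dump(sym_report, fh, indent=2, sort_keys=True, default=_json_default)
        report["stages"]["symptoms"] = sym_report
    except Exception as err:  # annotate with the failing stage
        stage = list(report["stages"])[-1] if report["stages"] else "simulate"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {err}") from err

    write_dataset(outdir, cohort, sessions, config=sim)
    return _finalize(report, outdir)


def _finalize(report: dict, outdir: Path) -> dict:
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "report.json"
    )
    report["manifest"] = {str(p.relative_to(outdir)): _sha256(p) for p in files}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report
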