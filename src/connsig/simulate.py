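"""Synthetic cohorts with planted connectivity, expression and symptom structure.

The generator emulates the three data sources the analysis integrates:

1. a genotyped patient cohort (plus ungenotyped healthy controls) with one
   resting-state session each, where the risk-allele count perturbs the
   correlation structure of the BOLD time series on configurable region sets
   (additive model: the perturbation scales with the 0/1/2 allele count);
2. a pharmacological crossover sample in which every subject is scanned pre
   and post infusion under ketamine, midazolam and placebo, with
   drug-specific perturbations applied to the post-infusion sessions only;
3. a six-donor postmortem microarray-like expression table with samples
   located in atlas space, region-structured marker-gene levels and
   donor-specific affine intensity scales.

Time series are white multivariate Gaussian draws from a target correlation
matrix; additive edge perturbations are projected back to a valid correlation
matrix by eigenvalue clipping and diagonal renormalization, which keeps small
planted effects approximately linear in the allele count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import AtlasVolume, default_labels, synthetic_atlas

__all__ = [
    "SetEffect",
    "SimulationConfig",
    "RoiTimeSeriesSet",
    "simulate_cohort",
    "simulate_timeseries",
    "simulate_expression_samples",
    "simulate_symptoms",
    "perturbation_matrix",
    "nearest_correlation",
    "write_dataset",
]

MARKER_GENES = ("GRIN1", "PV", "SLC17A7")

SUBCATEGORIES = ("quantitative", "qualitative", "subjective")
DOMAINS = ("language", "affective", "motor")


@dataclass(frozen=True)
class SetEffect:
    """Additive correlation perturbation on all edges between two region sets.

    ``delta`` is added per allele copy (genetic effects) or once
    (pharmacological effects) to every edge (a, b), a != b.  When the two
    sets coincide the perturbation covers the within-set block.
    """

    regions_a: tuple[str, ...]
    regions_b: tuple[str, ...]
    delta: float

    def __init__(self, regions_a, regions_b, delta):
        object.__setattr__(self, "regions_a", tuple(regions_a))
        object.__setattr__(self, "regions_b", tuple(regions_b))
        object.__setattr__(self, "delta", float(delta))


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic dataset.

    Sample sizes and the allele frequency default to the study they emulate
    (146 patients, 142 controls, 28 crossover subjects, C-allele frequency
    27.7%).  Planted effect sizes are on the correlation scale.
    """

    seed: int = 0
    n_patients: int = 146
    n_controls: int = 142
    n_pharmaco: int = 28
    allele_freq: float = 0.277
    n_timepoints: int = 200
    region_labels: tuple[str, ...] = field(
        default_factory=lambda: tuple(default_labels()["name"])
    )
    # planted connectivity effects.  Within the signal block, genetic and
    # drug perturbations share one heterogeneous edge-weight pattern (drawn
    # once per seed), so the two datasets agree edge-by-edge there, as the
    # enrichment analysis assumes.  Outside the block, optional idiosyncratic
    # "background" effects (independent between the genetic and each drug
    # perturbation) dilute the full-matrix similarity the way unrelated
    # whole-brain effects do in real data.
    signal_regions: tuple[str, ...] = ()
    delta_allele: float = 0.15  # per C-allele, on edges among signal_regions
    delta_ket: float = 0.20  # ketamine post-infusion, same edges
    delta_mdz: float = -0.20  # midazolam post-infusion, same edges
    heterogeneous_signal: bool = True  # shared U(0.5, 1.5) edge weights in the block
    background_allele_sd: float = 0.0  # per-allele idiosyncratic effect sd, off-block
    background_drug_sd: float = 0.0  # per-drug idiosyncratic effect sd, off-block
    allele_set_effects: tuple[SetEffect, ...] = ()  # additional per-allele effects
    noise_sd: float = 1.0
    # nuisance structure (documented placeholders; the source study reports
    # neither the gender split nor the dose distribution)
    never_medicated_frac: float = 0.1
    dose_gamma_shape: float = 2.0
    dose_gamma_scale: float = 3.0
    dose_max: float = 30.0
    # expression generator
    genes: tuple[str, ...] = MARKER_GENES + ("GRIN2A",)
    n_donors: int = 6
    samples_per_region_donor: float = 3.0
    expression_noise_sd: float = 0.4
    # symptom generator (latent qualitative-language score
    #   a - b * allele_count + c * edge_connectivity + noise)
    sym_intercept: float = 0.0
    sym_allele_slope: float = 0.8
    sym_edge_slope: float = 2.0
    sym_noise_sd: float = 1.0
    sym_items: int = 7  # items per subcategory; sums live in [-7, 7]

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_freq <= 1.0:
            raise ValueError("allele_freq must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_timepoints < 10:
            raise ValueError("need at least 10 timepoints")
        self.region_labels = tuple(self.region_labels)
        self.signal_regions = tuple(self.signal_regions)
        self.allele_set_effects = tuple(
            e if isinstance(e, SetEffect) else SetEffect(**e)
            for e in self.allele_set_effects
        )
        unknown = set(self.signal_regions) - set(self.region_labels)
        if unknown:
            raise ValueError(f"signal regions not in region_labels: {sorted(unknown)}")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class RoiTimeSeriesSet:
    """Per-subject, per-session T x R BOLD-like time-series matrices."""

    region_labels: list[str]
    series: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        r = len(self.region_labels)
        for key, mat in self.series.items():
            if mat.shape[1] != r:
                raise ValueError(f"series {key} has wrong region count")


# ---------------------------------------------------------------------------
# cohort and sessions


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort table and session design, deterministically from the seed.

    Genotypes are i.i.d. Hardy-Weinberg draws at ``config.allele_freq`` (for
    controls too; their genotypes are unused by the genetic analyses but keep
    the table rectangular).  Gender is Bernoulli(0.5) except in the crossover
    sample, which is all-male as in the study it emulates.  Antipsychotic
    doses (haloperidol equivalents, mg/day) are zero for a never-medicated
    fraction and truncated-Gamma otherwise; controls and crossover subjects
    are unmedicated.
    """
    rng = np.random.default_rng(config.seed)
    p = config.allele_freq
    rows = []
    groups = (
        [("patient", config.n_patients)],
        [("control", config.n_controls)],
        [("pharmaco", config.n_pharmaco)],
    )
    for spec in groups:
        for group, n in spec:
            for i in range(n):
                sid = f"{group[:3]}-{i + 1:03d}"
                allele = int(rng.binomial(2, p))
                if group == "pharmaco":
                    gender, dose = 0, 0.0
                else:
                    gender = int(rng.integers(0, 2))
                    dose = 0.0
                    if group == "patient" and rng.random() >= config.never_medicated_frac:
                        dose = float(
                            min(
                                rng.gamma(config.dose_gamma_shape, config.dose_gamma_scale),
                                config.dose_max,
                            )
                        )
                rows.append((sid, group, allele, gender, dose))
    cohort = pd.DataFrame(
        rows, columns=["subject_id", "group", "allele_count", "gender", "dose"]
    )

    sess_rows = []
    for _, row in cohort.iterrows():
        if row["group"] == "pharmaco":
            order = 0
            for cond in ("ketamine", "midazolam", "placebo"):
                for phase in ("pre", "post"):
                    sess_rows.append((row["subject_id"], cond, phase, order))
                    order += 1
        else:
            sess_rows.append((row["subject_id"], "rest", "na", 0))
    sessions = pd.DataFrame(
        sess_rows, columns=["subject_id", "condition", "phase", "order_index"]
    )
    return cohort, sessions


# ---------------------------------------------------------------------------
# correlation-structure machinery


def perturbation_matrix(
    region_labels: tuple[str, ...] | list[str], effects: list[SetEffect] | tuple[SetEffect, ...]
) -> np.ndarray:
    """Symmetric R x R additive perturbation built from region-set effects."""
    labels = list(region_labels)
    index = {name: i for i, name in enumerate(labels)}
    r = len(labels)
    p = np.zeros((r, r))
    for eff in effects:
        ia = [index[name] for name in eff.regions_a]
        ib = [index[name] for name in eff.regions_b]
        mask = np.zeros((r, r), dtype=bool)
        mask[np.ix_(ia, ib)] = True
        mask |= mask.T  # each undirected edge counted once
        np.fill_diagonal(mask, False)
        p[mask] += eff.delta
    return p


def _build_perturbation(config: SimulationConfig, effects: list[SetEffect]) -> np.ndarray:
    return perturbation_matrix(config.region_labels, effects)


def nearest_correlation(m: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal renormalized to
    one; for matrices that are already positive definite with unit diagonal
    this is the identity map (up to floating point).
    """
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    w = np.clip(w, eig_floor, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    if not np.all(np.isfinite(c)):
        raise ValueError("correlation projection produced non-finite values")
    return c


def _signal_block_mask(config: SimulationConfig) -> np.ndarray:
    r = len(config.region_labels)
    mask = np.zeros((r, r), dtype=bool)
    if config.signal_regions:
        idx = [config.region_labels.index(name) for name in config.signal_regions]
        mask[np.ix_(idx, idx)] = True
        np.fill_diagonal(mask, False)
    return mask


def _symmetric_noise(rng: np.random.Generator, r: int, sd: float) -> np.ndarray:
    m = rng.normal(0.0, sd, size=(r, r))
    m = np.tril(m, -1)
    return m + m.T


def _planted_structure(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Deterministic perturbation components shared across all conditions.

    ``weights``: the signal-block edge pattern common to the genetic and drug
    effects (ones if ``heterogeneous_signal`` is off); ``bg_*``: mutually
    independent off-block background effect matrices.
    """
    r = len(config.region_labels)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    block = _signal_block_mask(config)
    weights = np.zeros((r, r))
    if block.any():
        if config.heterogeneous_signal:
            w = rng.uniform(0.5, 1.5, size=(r, r))
            w = np.tril(w, -1)
            w = w + w.T
        else:
            w = np.ones((r, r))
        weights[block] = w[block]
    out = {"weights": weights, "block": block}
    for name, sd in (
        ("bg_allele", config.background_allele_sd),
        ("bg_ketamine", config.background_drug_sd),
        ("bg_midazolam", config.background_drug_sd),
    ):
        bg = _symmetric_noise(rng, r, sd) if sd > 0 else np.zeros((r, r))
        bg[block] = 0.0  # backgrounds live off the shared signal block
        out[name] = bg
    return out


def _allele_perturbation(config: SimulationConfig, parts: dict[str, np.ndarray]) -> np.ndarray:
    p = config.delta_allele * parts["weights"] + parts["bg_allele"]
    p = p + _build_perturbation(config, list(config.allele_set_effects))
    return p


def _drug_perturbation(
    config: SimulationConfig, condition: str, parts: dict[str, np.ndarray]
) -> np.ndarray:
    delta = {"ketamine": config.delta_ket, "midazolam": config.delta_mdz, "placebo": 0.0}[
        condition
    ]
    p = delta * parts["weights"]
    if condition in ("ketamine", "midazolam"):
        p = p + parts[f"bg_{condition}"]
    return p


def target_correlations(config: SimulationConfig) -> dict[str, np.ndarray]:
    """The generating (projected) correlation matrix for every condition.

    Keys: ``base``, ``allele1``, ``allele2``, ``ketamine``, ``midazolam``,
    ``placebo`` (post-infusion matrices; pre-infusion sessions use ``base``).
    """
    r = len(config.region_labels)
    base = np.eye(r)
    parts = _planted_structure(config)
    pa = _allele_perturbation(config, parts)
    out = {
        "base": nearest_correlation(base),
        "allele1": nearest_correlation(base + pa),
        "allele2": nearest_correlation(base + 2 * pa),
    }
    for cond in ("ketamine", "midazolam", "placebo"):
        out[cond] = nearest_correlation(base + _drug_perturbation(config, cond, parts))
    return out


def simulate_timeseries(
    cohort: pd.DataFrame, sessions: pd.DataFrame, config: SimulationConfig
) -> RoiTimeSeriesSet:
    """Draw zero-mean multivariate-normal time series for every session.

    Patients' correlation matrices carry ``allele_count`` copies of the
    allele perturbation; crossover post-infusion sessions carry the drug
    perturbation of their condition; everything else uses the base matrix.
    Bit-identical for a fixed config (seed included).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    targets = target_correlations(config)
    chol = {k: np.linalg.cholesky(v) for k, v in targets.items()}
    group_of = dict(zip(cohort["subject_id"], cohort["group"]))
    allele_of = dict(zip(cohort["subject_id"], cohort["allele_count"]))
    series: dict[tuple[str, str], np.ndarray] = {}
    t = config.n_timepoints
    r = len(config.region_labels)
    for _, row in sessions.iterrows():
        sid = row["subject_id"]
        if group_of[sid] == "pharmaco":
            key = f"{row['condition']}_{row['phase']}"
            label = row["condition"] if row["phase"] == "post" else "base"
        else:
            key = "rest"
            if group_of[sid] == "patient" and allele_of[sid] > 0:
                label = f"allele{allele_of[sid]}"
            else:
                label = "base"
        draw = rng.standard_normal((t, r))
        series[(sid, key)] = config.noise_sd * (draw @ chol[label].T)
    return RoiTimeSeriesSet(region_labels=list(config.region_labels), series=series)


# ---------------------------------------------------------------------------
# expression samples


def simulate_expression_samples(
    config: SimulationConfig, atlas: AtlasVolume | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a donor-structured microarray-like sample table.

    Each region has a latent expression level shared (up to jitter) across
    the marker genes; donors sample regions at random locations inside the
    region's voxels and measure intensities on donor-specific affine scales
    (the within-donor z-scoring of the profiling pipeline must remove these).

    Returns
    -------
    samples : DataFrame
        Columns sample_id, donor_id, x, y, z plus one column per gene.
    truth : DataFrame
        Per-region latent level and true rank (1 = highest), for planting
        effects in "top expression" regions without re-estimating them.
    """
    if atlas is None:
        atlas = synthetic_atlas()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    labels = sorted(atlas.label_names)
    names = [atlas.label_names[k] for k in labels]
    r = len(labels)
    # latent region levels: an evenly spaced gradient assigned by a seeded
    # permutation, so the true ranking is unambiguous
    levels = np.linspace(2.0, -2.0, r)[rng.permutation(r)]
    gene_jitter = {g: rng.normal(0.0, 0.15, size=r) for g in config.genes}

    # voxel coordinates per region for sample placement
    coords = {}
    for lab in labels:
        vox = np.argwhere(atlas.label_grid == lab)
        coords[lab] = vox

    rows = []
    sid = 0
    for d in range(config.n_donors):
        scale = float(np.exp(rng.normal(0.0, 0.3)))
        offset = float(rng.normal(8.0, 1.0))
        for i, lab in enumerate(labels):
            n_samp = rng.poisson(config.samples_per_region_donor)
            for _ in range(n_samp):
                vox = coords[lab][rng.integers(len(coords[lab]))]
                jit = rng.uniform(-0.4, 0.4, size=3)
                xyz = (atlas.affine @ np.append(vox + jit, 1.0))[:3]
                vals = {
                    g: scale * (levels[i] + gene_jitter[g][i] + rng.normal(0.0, config.expression_noise_sd))
                    + offset
                    for g in config.genes
                }
                rows.append(
                    {
                        "sample_id": f"S{sid:05d}",
                        "donor_id": f"donor{d + 1}",
                        "x": xyz[0],
                        "y": xyz[1],
                        "z": xyz[2],
                        **vals,
                    }
                )
                sid += 1
    samples = pd.DataFrame(rows)
    order = np.argsort(-levels, kind="stable")
    rank = np.empty(r, dtype=int)
    rank[order] = np.arange(1, r + 1)
    truth = pd.DataFrame({"region": names, "level": levels, "true_rank": rank})
    return samples, truth


# ---------------------------------------------------------------------------
# symptoms


def simulate_symptoms(
    cohort: pd.DataFrame,
    planted_edge_connectivity: np.ndarray | None,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate bipolar-scale symptom sums for patients.

    The qualitative-language subcategory follows the latent model
    ``a - b * allele_count + c * edge + noise`` (``b, c >= 0``), then is
    discretized by rounding and clipping to the +/- item-count range; every
    other domain/subcategory is genotype-independent noise.  Higher allele
    counts therefore push the qualitative-language sum toward the negative
    (hypoactive) pole, and stronger planted-edge connectivity pushes it back
    up — the coupling structure the symptom analyses are meant to recover.

    Returns a wide table (one row per patient, one column per
    ``domain_subcategory`` sum).
    """
    patients = cohort[cohort["group"] == "patient"].reset_index(drop=True)
    n = len(patients)
    if planted_edge_connectivity is None:
        edge = np.zeros(n)
    else:
        edge = np.asarray(planted_edge_connectivity, dtype=float)
        if edge.shape != (n,):
            raise ValueError("planted_edge_connectivity must have one value per patient")
    if config.sym_allele_slope < 0 or config.sym_edge_slope < 0:
        raise ValueError("symptom coupling coefficients must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lo, hi = -config.sym_items, config.sym_items
    out = {"subject_id": patients["subject_id"]}
    for dom in DOMAINS:
        for sub in SUBCATEGORIES:
            if dom == "language" and sub == "qualitative":
                latent = (
                    config.sym_intercept
                    - config.sym_allele_slope * patients["allele_count"].to_numpy()
                    + config.sym_edge_slope * edge
                )
                if config.sym_noise_sd > 0:
                    latent = latent + rng.normal(0.0, config.sym_noise_sd, size=n)
            else:
                latent = rng.normal(0.0, max(config.sym_noise_sd, 1e-12), size=n)
            out[f"{dom}_{sub}"] = np.clip(np.rint(latent), lo, hi).astype(int)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# on-disk format


def write_dataset(
    outdir,
    cohort: pd.DataFrame,
    sessions: pd.DataFrame,
    ts: RoiTimeSeriesSet | None = None,
    config: SimulationConfig | None = None,
) -> None:
    """Write cohort/session tables (TSV), time series (TSV each), config (YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    sessions.to_csv(outdir / "sessions.tsv", sep="\t", index=False)
    if ts is not None:
        tsdir = outdir / "timeseries"
        tsdir.mkdir(exist_ok=True)
        for (sid, key), mat in ts.series.items():
            pd.DataFrame(mat, columns=ts.region_labels).to_csv(
                tsdir / f"{sid}__{key}.tsv", sep="\t", index=False
            )
    if config is not None:
        cfg = asdict(config)
        cfg["region_labels"] = list(cfg["region_labels"])
        cfg["signal_regions"] = list(cfg["signal_regions"])
        cfg["genes"] = list(cfg["genes"])
        cfg["allele_set_effects"] = [
            {"regions_a": list(e["regions_a"]), "regions_b": list(e["regions_b"]), "delta": e["delta"]}
            for e in cfg["allele_set_effects"]
        ]
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
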