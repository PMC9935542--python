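"""Regional marker-gene expression profiles from postmortem microarray samples.

Samples located in atlas (MNI-like) space are assigned to parcellation
regions, then aggregated donor-first into per-region gene z-scores:

1. z-score each gene across a donor's samples (removes donor-specific
   intensity scale and offset);
2. average samples within region, per donor;
3. average the regional values across donors (each donor contributes one
   value per region regardless of how many samples it placed there);
4. z-score the resulting regional vector across regions.

The combined score of a region is the mean z over the marker genes —
by default GRIN1 (constitutive NMDAR subunit), PV (parvalbumin) and SLC17A7
(VGLUT1, glutamatergic identity) — and regions are ranked in descending
order of that score (rank 1 = highest expression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas import AtlasVolume
from .simulate import MARKER_GENES

__all__ = [
    "RegionExpressionProfile",
    "assign_samples",
    "build_profiles",
    "profile_from_scores",
    "load_samples",
    "save_profile",
]


@dataclass
class RegionExpressionProfile:
    """Per-region gene z-scores, combined marker score, and descending rank.

    Attributes
    ----------
    table
        DataFrame indexed by region name with one z column per gene plus
        ``combined_score``, ``rank`` and ``n_samples``.  Regions without
        sample support carry NaN z-scores, are flagged in ``unsupported``
        and receive the last ranks (ties by region order).
    genes
        The marker genes combined into the score.
    """

    table: pd.DataFrame
    genes: tuple[str, ...]
    unsupported: tuple[str, ...] = field(default=())

    @property
    def regions(self) -> list[str]:
        return list(self.table.index)

    def ranking(self, include_unsupported: bool = False) -> list[str]:
        """Region names ordered by rank (highest expression first)."""
        ordered = self.table.sort_values("rank").index.tolist()
        if include_unsupported:
            return ordered
        drop = set(self.unsupported)
        return [r for r in ordered if r not in drop]

    def rank_of(self) -> pd.Series:
        return self.table["rank"]


def assign_samples(
    samples: pd.DataFrame, atlas: AtlasVolume, tolerance_mm: float = 2.0
) -> pd.Series:
    """Assign each sample to a parcellation region by its mm coordinates.

    A sample takes the label of its containing voxel; samples that land in
    background are assigned to the nearest labelled voxel centre within
    ``tolerance_mm`` (Euclidean, mm), else left unassigned (None).

    Returns
    -------
    Series mapping sample_id -> region name or None.
    """
    affine = np.asarray(atlas.affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("atlas affine is not invertible")
    inv = np.linalg.inv(affine)

    xyz = samples[["x", "y", "z"]].to_numpy(dtype=float)
    hom = np.c_[xyz, np.ones(len(xyz))]
    vox = (hom @ inv.T)[:, :3]
    idx = np.rint(vox).astype(int)

    shape = atlas.label_grid.shape
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    labels = np.zeros(len(samples), dtype=int)
    labels[inside] = atlas.label_grid[tuple(idx[inside].T)]

    # nearest labelled voxel for background hits, within tolerance
    need = labels == 0
    if need.any():
        lab_vox = np.argwhere(atlas.label_grid > 0)
        lab_mm = (np.c_[lab_vox, np.ones(len(lab_vox))] @ affine.T)[:, :3]
        tree = cKDTree(lab_mm)
        dist, j = tree.query(xyz[need], k=1)
        near = atlas.label_grid[tuple(lab_vox[j].T)]
        near[dist > tolerance_mm] = 0
        labels[need] = near

    names = [atlas.label_names.get(int(l)) if l > 0 else None for l in labels]
    return pd.Series(names, index=samples["sample_id"].to_numpy(), name="region")


def build_profiles(
    samples: pd.DataFrame,
    assignment: pd.Series,
    genes: tuple[str, ...] | list[str] = MARKER_GENES,
    min_samples: int = 1,
    regions: list[str] | None = None,
) -> RegionExpressionProfile:
    """Donor-normalized regional expression profile and marker ranking.

    Parameters
    ----------
    samples
        Sample table (sample_id, donor_id, x, y, z, gene columns).
    assignment
        sample_id -> region name (from :func:`assign_samples`); unassigned
        samples are dropped.
    genes
        Genes to z-score and combine (all must be sample columns).
    min_samples
        Minimum total sample support for a region to receive a z-score.
    regions
        Full region universe (defaults to the assigned regions); regions
        with insufficient support are ranked last and flagged.
    """
    genes = tuple(genes)
    missing = [g for g in genes if g not in samples.columns]
    if missing:
        raise ValueError(f"genes absent from sample table: {missing}")

    df = samples.set_index("sample_id")
    df = df.join(assignment.rename("region"))
    df = df[df["region"].notna()]

    # 1) within-donor z-score per gene
    for g in genes:
        grp = df.groupby("donor_id")[g]
        mu, sd = grp.transform("mean"), grp.transform("std")
        df[g] = (df[g] - mu) / sd

    # 2) region mean per donor, 3) mean across donors
    per_donor = df.groupby(["donor_id", "region"])[list(genes)].mean()
    regional = per_donor.groupby("region").mean()
    support = df.groupby("region").size()

    if regions is None:
        regions = sorted(regional.index)
    regional = regional.reindex(regions)
    n_samples = support.reindex(regions).fillna(0).astype(int)
    ok = n_samples >= min_samples
    if ok.sum() < 2:
        raise ValueError("fewer than 2 regions with sufficient sample support")
    regional.loc[~ok] = np.nan

    # 4) z across regions (supported regions only)
    z = regional.copy()
    for g in genes:
        v = z[g]
        z[g] = (v - v[ok].mean()) / v[ok].std(ddof=0)

    combined = z[list(genes)].mean(axis=1)
    # descending rank; unsupported regions last; ties by region order (stable)
    key = combined.fillna(-np.inf)
    order = np.argsort(-key.to_numpy(), kind="stable")
    rank = np.empty(len(regions), dtype=int)
    rank[order] = np.arange(1, len(regions) + 1)

    table = z.copy()
    table["combined_score"] = combined
    table["rank"] = rank
    table["n_samples"] = n_samples
    table.index.name = "region"
    return RegionExpressionProfile(
        table=table,
        genes=genes,
        unsupported=tuple(r for r, good in zip(regions, ok) if not good),
    )


def profile_from_scores(
    scores: pd.Series, genes: tuple[str, ...] = MARKER_GENES
) -> RegionExpressionProfile:
    """Build a profile directly from known per-region scores.

    Convenience for simulations where the latent expression level is known
    exactly; the score vector is z-scored across regions and ranked the same
    way :func:`build_profiles` ranks estimated profiles.
    """
    v = scores.astype(float)
    z = (v - v.mean()) / v.std(ddof=0)
    order = np.argsort(-z.to_numpy(), kind="stable")
    rank = np.empty(len(z), dtype=int)
    rank[order] = np.arange(1, len(z) + 1)
    table = pd.DataFrame({g: z for g in genes})
    table["combined_score"] = z
    table["rank"] = rank
    table["n_samples"] = 0
    table.index = scores.index
    table.index.name = "region"
    return RegionExpressionProfile(table=table, genes=tuple(genes))


def load_samples(path) -> pd.DataFrame:
    """Read a sample table from CSV (sample_id, donor_id, x, y, z, genes...)."""
    return pd.read_csv(path)


def save_profile(profile: RegionExpressionProfile, path) -> None:
    """Write the ranked regional profile as TSV."""
    profile.table.to_csv(path, sep="\t")
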