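import numpy as np
import pandas as pd
import pytest

from connsig.atlas import AtlasVolume, default_labels, synthetic_atlas
from connsig.expression import assign_samples, build_profiles, profile_from_scores
from connsig.simulate import SimulationConfig, simulate_expression_samples


def toy_atlas():
    """4x4x4 grid, identity affine (1 mm voxels), two labelled voxels."""
    grid = np.zeros((4, 4, 4), dtype=np.int32)
    grid[1, 1, 1] = 3
    grid[3, 3, 3] = 7
    return AtlasVolume(label_grid=grid, affine=np.eye(4), label_names={3: "A", 7: "B"})


def sample_row(sid, x, y, z):
    return {"sample_id": sid, "donor_id": "d1", "x": x, "y": y, "z": z, "G": 1.0}


class TestAssignSamples:
    def test_containment(self):
        atlas = toy_atlas()
        samples = pd.DataFrame([sample_row("s1", 1, 1, 1)])
        out = assign_samples(samples, atlas, tolerance_mm=2)
        assert out["s1"] == "A"

    def test_far_background_sample_is_unassigned(self):
        atlas = toy_atlas()
        samples = pd.DataFrame([sample_row("s1", 50, 50, 50)])
        out = assign_samples(samples, atlas, tolerance_mm=2)
        assert out["s1"] is None

    def test_nearest_label_within_tolerance(self):
        # 1.5 mm from the label-3 voxel centre; brute-force distances confirm
        atlas = toy_atlas()
        samples = pd.DataFrame([sample_row("s1", 1.0, 1.0, 2.5)])
        lab_vox = np.argwhere(atlas.label_grid > 0).astype(float)
        dists = np.linalg.norm(lab_vox - np.array([1.0, 1.0, 2.5]), axis=1)
        assert dists.min() == pytest.approx(1.5)
        out = assign_samples(samples, atlas, tolerance_mm=2)
        assert out["s1"] == "A"
        out_tight = assign_samples(samples, atlas, tolerance_mm=1)
        assert out_tight["s1"] is None

    def test_non_invertible_affine_rejected(self):
        atlas = toy_atlas()
        atlas.affine = np.zeros((4, 4))
        samples = pd.DataFrame([sample_row("s1", 1, 1, 1)])
        with pytest.raises(ValueError, match="invertible"):
            assign_samples(samples, atlas)


def toy_samples(values_by_region, donors=("d1",), gene="G"):
    rows = []
    i = 0
    for d in donors:
        for region, vals in values_by_region.items():
            for v in vals:
                rows.append(
                    {"sample_id": f"s{i}", "donor_id": d, "x": 0, "y": 0, "z": 0, gene: v}
                )
                i += 1
    samples = pd.DataFrame(rows)
    assignment = pd.Series(
        [r for d in donors for r, vals in values_by_region.items() for _ in vals],
        index=samples["sample_id"].to_numpy(),
    )
    return samples, assignment


class TestBuildProfiles:
    def test_two_point_z_score(self):
        # donor-averaged regional values (1, -1) -> z = +/-1 under the
        # population (2-point) sd; rank order follows the sign
        samples, assignment = toy_samples({"A": [2.0, 0.0], "B": [-1.0, -1.0, -1.0]})
        prof = build_profiles(samples, assignment, genes=("G",), regions=["A", "B", "C"], min_samples=1)
        # region C unsupported -> flagged, ranked last
        assert prof.unsupported == ("C",)
        z = prof.table["G"]
        assert z["A"] == pytest.approx(1.0)
        assert z["B"] == pytest.approx(-1.0)
        assert list(prof.table["rank"]) == [1, 2, 3]

    def test_identical_genes_average_to_single_gene_score(self, rng):
        vals = {f"R{i}": list(rng.normal(i, 1, size=4)) for i in range(5)}
        samples, assignment = toy_samples(vals)
        for g in ("G2", "G3"):
            samples[g] = samples["G"]
        single = build_profiles(samples, assignment, genes=("G",))
        triple = build_profiles(samples, assignment, genes=("G", "G2", "G3"))
        pd.testing.assert_series_equal(
            single.table["combined_score"], triple.table["combined_score"]
        )

    def test_matches_spreadsheet_style_oracle(self, rng):
        # 3 donors x 4 regions x 2 genes, recomputed independently with
        # explicit loops in the donor-first aggregation order
        donors, regions, genes = ["d1", "d2", "d3"], ["A", "B", "C", "D"], ["g1", "g2"]
        rows = []
        i = 0
        for d in donors:
            for r in regions:
                for _ in range(3):
                    rows.append(
                        {
                            "sample_id": f"s{i}",
                            "donor_id": d,
                            "x": 0, "y": 0, "z": 0,
                            "g1": rng.normal(), "g2": rng.normal(),
                        }
                    )
                    i += 1
        samples = pd.DataFrame(rows)
        assignment = pd.Series(
            [r for _ in donors for r in regions for _ in range(3)],
            index=samples["sample_id"].to_numpy(),
        )
        prof = build_profiles(samples, assignment, genes=tuple(genes))

        for g in genes:
            per_region = {}
            for r in regions:
                donor_means = []
                for d in donors:
                    dvals = samples[samples["donor_id"] == d]
                    zvals = (dvals[g] - dvals[g].mean()) / dvals[g].std(ddof=1)
                    keep = assignment.loc[dvals["sample_id"]].to_numpy() == r
                    donor_means.append(zvals[keep.tolist()].mean())
                per_region[r] = np.mean(donor_means)
            v = np.array([per_region[r] for r in regions])
            expect = (v - v.mean()) / v.std(ddof=0)
            np.testing.assert_allclose(prof.table[g].to_numpy(), expect, atol=1e-12)

    def test_ranking_invariant_to_donor_affine_rescale(self, rng):
        cfg = SimulationConfig(
            seed=5, region_labels=tuple(default_labels()["name"][:12]), genes=("GRIN1",)
        )
        labels = default_labels().iloc[:12]
        atlas = synthetic_atlas(labels=labels)
        samples, _ = simulate_expression_samples(cfg, atlas)
        assignment = assign_samples(samples, atlas)
        base = build_profiles(samples, assignment, genes=("GRIN1",))
        scaled = samples.copy()
        mask = scaled["donor_id"] == "donor1"
        scaled.loc[mask, "GRIN1"] = 10.0 * scaled.loc[mask, "GRIN1"] + 100.0
        rescaled = build_profiles(scaled, assignment, genes=("GRIN1",))
        pd.testing.assert_series_equal(base.table["rank"], rescaled.table["rank"])

    def test_sample_order_permutation_invariance(self, rng):
        samples, assignment = toy_samples(
            {f"R{i}": list(rng.normal(size=4)) for i in range(4)}, donors=("d1", "d2")
        )
        shuffled = samples.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = build_profiles(samples, assignment, genes=("G",))
        b = build_profiles(shuffled, assignment, genes=("G",))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_marker_gene_swap_runs_unchanged(self):
        cfg = SimulationConfig(seed=2, region_labels=tuple(default_labels()["name"][:10]))
        labels = default_labels().iloc[:10]
        atlas = synthetic_atlas(labels=labels)
        samples, _ = simulate_expression_samples(cfg, atlas)
        assignment = assign_samples(samples, atlas)
        prof = build_profiles(samples, assignment, genes=("GRIN2A", "PV", "SLC17A7"))
        assert sorted(prof.table["rank"]) == list(range(1, 11))

    def test_z_scores_are_standardized_across_regions(self, rng):
        samples, assignment = toy_samples(
            {f"R{i}": list(rng.normal(size=5)) for i in range(6)}
        )
        prof = build_profiles(samples, assignment, genes=("G",))
        z = prof.table["G"]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_supported_regions(self):
        samples, assignment = toy_samples({"A": [1.0]})
        with pytest.raises(ValueError, match="2 regions"):
            build_profiles(samples, assignment, genes=("G",))


class TestProfileFromScores:
    def test_rank_descends_with_score(self):
        prof = profile_from_scores(pd.Series({"A": 3.0, "B": -1.0, "C": 1.0}))
        assert list(prof.ranking()) == ["A", "C", "B"]
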