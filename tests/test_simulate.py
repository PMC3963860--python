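"""Ground-truth guarantees of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

import gpcrprofile as gp
from gpcrprofile import simulate as sim


def small_config(**kwargs) -> sim.SimConfig:
    defaults = dict(
        n_gpcr_assays=40,
        n_housekeeping=4,
        n_core_genes=5,
        planted_groups=[
            sim.PlantedGroup(("TG1", "OB1"), "over", 4),
            sim.PlantedGroup(("HA",), "over", 2),
            sim.PlantedGroup(("TG1", "OB1"), "under", 1),
        ],
        rng_seed=0,
    )
    defaults.update(kwargs)
    return sim.SimConfig(**defaults)


class TestGenerateCtDataset:
    def test_fixed_seed_is_bit_identical(self):
        a, ta = sim.generate_ct_dataset(small_config())
        b, tb = sim.generate_ct_dataset(small_config())
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(ta.true_ct, tb.true_ct)

    def test_zero_noise_replicates_equal_true_ct(self):
        ds, truth = sim.generate_ct_dataset(small_config(ct_noise_sd=0.0))
        obs = ds.observations
        for row in obs[~obs["is_sentinel"]].itertuples(index=False):
            assert row.ct == truth.true_ct.loc[row.gene_symbol, row.cell_type]

    def test_absent_genes_are_sentinel_in_every_replicate(self):
        ds, truth = sim.generate_ct_dataset(small_config())
        obs = ds.observations.set_index("gene_symbol")
        for gene in truth.absent_genes:
            rows = obs.loc[[gene]]
            assert rows["is_sentinel"].all()
            assert (rows["ct"] == 40.0).all()

    def test_replicate_design_follows_study(self):
        ds, _ = sim.generate_ct_dataset(small_config())
        counts = (
            ds.observations.groupby(["gene_symbol", "cell_type"])["replicate"]
            .count()
            .groupby("cell_type")
            .first()
        )
        assert counts["NSC"] == 3  # triplicates for the neural stem cells
        assert counts["TG1"] == counts["OB1"] == counts["HA"] == counts["U87"] == 2

    def test_replicate_mean_close_to_truth(self):
        # sd 0.3, 4 replicates: mean within 3 * 0.3/2 of truth for >= 99%
        config = small_config(n_gpcr_assays=300, replicates=4, rng_seed=3)
        ds, truth = sim.generate_ct_dataset(config)
        merged = gp.merge_replicates(ds)
        ok = total = 0
        for row in merged.data[~merged.data["all_sentinel"]].itertuples(index=False):
            total += 1
            err = abs(row.mean_ct - truth.true_ct.loc[row.gene_symbol, row.cell_type])
            ok += err <= 3 * 0.3 / 2
        assert ok / total >= 0.99

    def test_planted_separation_holds_exactly_before_noise(self):
        _, truth = sim.generate_ct_dataset(small_config())
        units = 2.0 ** (-truth.true_ct) * 1e12
        for gene, (cells, direction) in truth.group_membership.items():
            inside = units.loc[gene, list(cells)]
            outside = units.loc[gene].drop(list(cells))
            if direction == "over":
                assert inside.min() >= 4.0 * outside.max()
                assert (truth.true_ct.loc[gene].drop(list(cells)) > 31.5).all()
            else:
                assert outside.min() >= 4.0 * inside.max()

    def test_invalid_configs_rejected(self):
        with pytest.raises(sim.SimulationError):
            sim.SimConfig(n_gpcr_assays=0)
        with pytest.raises(sim.SimulationError):
            sim.SimConfig(cell_types=("TG1", "TG1"))
        with pytest.raises(sim.SimulationError):
            sim.SimConfig(ct_noise_sd=-0.1)
        with pytest.raises(sim.SimulationError):
            small_config(planted_groups=[sim.PlantedGroup(("NOPE",), "over", 2)])

    def test_zero_noise_classification_recovers_groups_exactly(self):
        ds, truth = sim.generate_ct_dataset(small_config(ct_noise_sd=0.0))
        matrix = gp.merge_replicates(ds)
        profiles = gp.normalize(matrix, gp.build_reference(matrix, grand_mean_ct=21.12))
        gpcr = set(matrix.genes("GPCR"))
        sub = gp.ExpressionProfile(
            data=profiles.data[profiles.data["gene"].isin(gpcr)].reset_index(drop=True),
            reference=profiles.reference,
            ct_cutoff=profiles.ct_cutoff,
        )
        got: dict[str, set] = {}
        for g in gp.classify_specificity(sub, f=3.0):
            for gene in g.members:
                got.setdefault(gene, set()).add((tuple(sorted(g.cell_types)), g.direction))
        for gene, (cells, direction) in truth.group_membership.items():
            assert (tuple(sorted(cells)), direction) in got[gene]


class TestStudyLikeDataset:
    def test_planted_bookkeeping_matches_study_counts(self, study_like):
        _, truth = study_like
        gpcr = truth.expressed.loc[[g for g in truth.expressed.index if g.startswith("GPCR")]]
        assert int(gpcr.any(axis=1).sum()) == 138
        assert int(gpcr.all(axis=1).sum()) == 26
        per_cell = gpcr.sum(axis=0)
        assert per_cell["OB1"] == 90
        assert per_cell["TG1"] == 83
        assert per_cell["f-NSC"] == 77
        assert per_cell["HA"] == 61
        assert per_cell["U87"] == 57

    def test_deterministic(self):
        a, _ = sim.generate_study_like_dataset(seed=5)
        b, _ = sim.generate_study_like_dataset(seed=5)
        pd.testing.assert_frame_equal(a.observations, b.observations)


class TestGenerateProteinSet:
    def test_oracle_counts_are_attached_and_reproducible(self):
        a = sim.generate_protein_set(5, seed=9)
        b = sim.generate_protein_set(5, seed=9)
        assert [p.record.sequence for p in a] == [p.record.sequence for p in b]
        assert [p.oracle_count for p in a] == [p.oracle_count for p in b]

    def test_topology_tiles_each_sequence(self):
        for sp in sim.generate_protein_set(10, seed=2):
            covered = []
            for start, end, _label in sorted(sp.record.topology):
                covered.extend(range(start, end + 1))
            assert covered == list(range(1, len(sp.record.sequence) + 1))

    def test_invalid_n_rejected(self):
        with pytest.raises(sim.SimulationError):
            sim.generate_protein_set(0)


class TestGenerateSpectralCounts:
    @pytest.fixture()
    def two_gene_profile(self):
        # identical digests, ten-fold transcript difference, many cell types
        cells = [f"c{i:03d}" for i in range(500)]
        lo = gp.ct_from_units(30000.0)
        hi = gp.ct_from_units(300000.0)
        frame = pd.DataFrame({c: {"LOW": lo, "HIGH": hi} for c in cells})
        return gp.profile_from_normalized_ct(frame)

    def test_zero_expected_peptides_is_always_nd(self):
        prof = gp.profile_from_units(
            pd.DataFrame({"TG1": {"X": 50000.0}, "OB1": {"X": 60000.0}, "HA": {"X": 70000.0}})
        )
        table = sim.generate_spectral_counts(prof, {"X": 0}, seed=0)
        assert not table.detected.any()

    def test_mean_count_ratio_tracks_transcript_ratio(self, two_gene_profile):
        table = sim.generate_spectral_counts(
            two_gene_profile, {"LOW": 6, "HIGH": 6}, seed=4
        )
        pivot = table.data.pivot(index="accession", columns="cell_type", values="spectra")
        mean_low = np.nan_to_num(pivot.loc["LOW"]).mean()
        mean_high = np.nan_to_num(pivot.loc["HIGH"]).mean()
        assert mean_high / mean_low == pytest.approx(10.0, rel=0.10)

    def test_fixed_seed_reproduces_table(self, two_gene_profile):
        a = sim.generate_spectral_counts(two_gene_profile, {"LOW": 6, "HIGH": 6}, seed=8)
        b = sim.generate_spectral_counts(two_gene_profile, {"LOW": 6, "HIGH": 6}, seed=8)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_key_mismatch_rejected(self, two_gene_profile):
        with pytest.raises(sim.SimulationError):
            sim.generate_spectral_counts(two_gene_profile, {"NOPE": 3}, seed=0)
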