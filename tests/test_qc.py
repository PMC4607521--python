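"""QC chain: call rate, allele frequencies, LD pruning, kinship, outgroup removal."""

import numpy as np
import pandas as pd
import pytest

from afrostruct import qc
from afrostruct.genio import MISSING
from afrostruct.qc import (
    SECOND_DEGREE_KINSHIP,
    allele_frequencies,
    filter_call_rate,
    kinship_matrix,
    ld_prune,
    remove_outgroup_admixed,
    remove_related,
)
from afrostruct.simdata import (
    PopulationSpec,
    SimulationScenario,
    draw_component_frequencies,
    simulate_genotypes,
)

from conftest import make_matrix


class TestCallRate:
    def test_complete_data_untouched(self):
        G = make_matrix(np.ones((10, 10), dtype=np.int8))
        G2, report = filter_call_rate(G, 0.98, 0.98)
        assert (G2.n_samples, G2.n_variants) == (10, 10)
        assert report.to_frame()["n_snps_removed"].sum() == 0

    def test_enumerated_fixture(self):
        # SNP 0 missing in 2/10 individuals -> call rate 0.8 < 0.9 -> removed
        d = np.ones((10, 10), dtype=np.int8)
        d[0, 0] = d[1, 0] = MISSING
        G = make_matrix(d)
        G2, report = filter_call_rate(G, 0.9, 0.0)
        assert G2.n_variants == 9
        assert report.stages[0].removed_snp_ids == ["v0"]
        assert G2.n_samples == 10

    def test_snps_filtered_before_samples(self):
        # individual 0 misses only SNP 0; once that SNP is gone its call rate is 1
        d = np.ones((5, 10), dtype=np.int8)
        d[:4, 0] = MISSING  # SNP 0: call rate 0.2
        d[0, 0] = MISSING
        G = make_matrix(d)
        G2, _ = filter_call_rate(G, 0.9, 0.98)
        assert G2.n_variants == 9
        assert G2.n_samples == 5

    def test_two_stage_thresholds_apply_sequentially(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (40, 60)).astype(np.int8)
        d[rng.random((40, 60)) < 0.05] = MISSING
        G = make_matrix(d)
        G1, _ = filter_call_rate(G, 0.9, 0.9)
        G2, rep = filter_call_rate(G1, 0.98, 0.98)
        # second pass on the survivors is strictly tighter
        assert G2.n_variants <= G1.n_variants
        obs = ~G2.missing_mask()
        assert (obs.mean(axis=0) >= 0.98).all()

    def test_all_filtered_raises(self):
        d = np.full((3, 3), MISSING, dtype=np.int8)
        d[0, 0] = 1
        with pytest.raises(qc.AllFilteredError):
            filter_call_rate(make_matrix(d), 0.9, 0.9)

    def test_idempotent_at_realistic_missingness(self):
        # at array-typical missingness the filter reaches its fixed point in
        # one pass (at extreme missingness sample removal can re-expose SNPs)
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (30, 40)).astype(np.int8)
        d[rng.random((30, 40)) < 0.03] = MISSING
        G = make_matrix(d)
        G1, _ = filter_call_rate(G, 0.9, 0.9)
        G2, rep = filter_call_rate(G1, 0.9, 0.9)
        assert (G2.n_samples, G2.n_variants) == (G1.n_samples, G1.n_variants)
        assert rep.to_frame()[["n_snps_removed", "n_samples_removed"]].sum().sum() == 0


class TestAlleleFrequencies:
    def test_simple_arithmetic(self):
        G = make_matrix(np.array([[0], [1], [2]], dtype=np.int8))
        pf = allele_frequencies(G)
        assert pf.freq[0, 0] == pytest.approx(0.5)
        assert pf.copies[0, 0] == 6

    def test_all_missing_flagged(self):
        d = np.array([[MISSING], [MISSING]], dtype=np.int8)
        pf = allele_frequencies(make_matrix(d))
        assert np.isnan(pf.freq[0, 0])
        assert pf.copies[0, 0] == 0

    def test_brute_force_recount(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (30, 25)).astype(np.int8)
        d[rng.random((30, 25)) < 0.2] = MISSING
        pops = ["a"] * 10 + ["b"] * 20
        G = make_matrix(d, pops)
        pf = allele_frequencies(G)
        for r, pop in enumerate(pf.populations):
            rows = [i for i, p in enumerate(pops) if p == pop]
            for j in range(25):
                vals = [d[i, j] for i in rows if d[i, j] != MISSING]
                if vals:
                    assert pf.freq[r, j] == pytest.approx(sum(vals) / (2 * len(vals)))
                    assert pf.copies[r, j] == 2 * len(vals)
                else:
                    assert np.isnan(pf.freq[r, j])


class TestLdPrune:
    def test_duplicated_column_one_removed(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, (50, 10)).astype(np.int8)
        d[:, 5] = d[:, 4]  # perfect LD pair
        G = make_matrix(d)
        G2, report = ld_prune(G, window_snps=10, step_snps=5, r2_max=0.4)
        removed = set(report.stages[0].removed_snp_ids)
        assert len(removed & {"v4", "v5"}) == 1

    def test_independent_snps_untouched(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, (500, 60)).astype(np.int8)
        G2, report = ld_prune(make_matrix(d), window_snps=30, step_snps=10, r2_max=0.4)
        assert report.stages[0].n_snps_removed == 0

    def test_post_prune_windows_clean_by_brute_force(self):
        # correlated blocks, then exhaustive pairwise verification
        rng = np.random.default_rng(6)
        base = rng.integers(0, 3, (80, 40)).astype(np.int8)
        d = base.copy()
        for j in range(1, 40, 3):  # copy-with-noise correlation structure
            flip = rng.random(80) < 0.1
            d[:, j] = np.where(flip, rng.integers(0, 3, 80), d[:, j - 1])
        G = make_matrix(d)
        window, step = 15, 5
        G2, _ = ld_prune(G, window_snps=window, step_snps=step, r2_max=0.4)
        g = G2.dosages_float()
        kept_pos = list(G2.variants["pos"])
        orig_pos = list(G.variants["pos"])
        start = 0
        while start < len(orig_pos):
            win_pos = set(orig_pos[start:start + window])
            idx = [k for k, p in enumerate(kept_pos) if p in win_pos]
            for x in range(len(idx)):
                for y in range(x + 1, len(idx)):
                    a, b = g[:, idx[x]], g[:, idx[y]]
                    r = np.corrcoef(a, b)[0, 1]
                    if np.isfinite(r):
                        assert r**2 <= 0.4 + 1e-12
            if start + window >= len(orig_pos):
                break
            start += step

    def test_zero_variance_snp_kept(self):
        d = np.ones((20, 5), dtype=np.int8)
        d[:, 2] = 2  # constant column, r2 = 0 by convention
        G2, report = ld_prune(make_matrix(d), 5, 2, 0.4)
        assert report.stages[0].n_snps_removed == 0

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, (60, 50)).astype(np.int8)
        d[:, 10] = d[:, 9]
        G1, _ = ld_prune(make_matrix(d), 20, 5, 0.4)
        G2, rep = ld_prune(G1, 20, 5, 0.4)
        assert rep.stages[0].n_snps_removed == 0


def _relative_scenario(relationship):
    return SimulationScenario(
        n_components=2, component_names=["X", "Y"],
        drift={"X": 0.1, "Y": 0.1}, n_snps=1747,
        populations=[
            PopulationSpec("P1", 20, {"X": 1.0}),
            PopulationSpec("P2", 20, {"Y": 1.0}),
        ],
        related_pairs=[("P1", relationship)],
        seed=13,
    )


class TestKinship:
    def test_duplicate_individual_near_half(self):
        sc = _relative_scenario("duplicate")
        G = simulate_genotypes(sc, draw_component_frequencies(sc))
        kin = kinship_matrix(G)
        dup = kin[(kin.id1 == "P1_000") & (kin.id2 == "P1_dup00")]
        assert abs(dup.kinship.iloc[0] - 0.5) < 0.05

    def test_parent_child_near_quarter(self):
        sc = _relative_scenario("parent_child")
        G = simulate_genotypes(sc, draw_component_frequencies(sc))
        kin = kinship_matrix(G)
        pc = kin[(kin.id1 == "P1_000") & (kin.id2 == "P1_child00")]
        assert abs(pc.kinship.iloc[0] - 0.25) < 0.07

    def test_unrelated_across_diverged_components_below_threshold(self):
        sc = SimulationScenario(
            n_components=2, component_names=["X", "Y"],
            drift={"X": 0.15, "Y": 0.15}, n_snps=1747,
            populations=[
                PopulationSpec("P1", 10, {"X": 1.0}),
                PopulationSpec("P2", 10, {"Y": 1.0}),
            ],
            seed=17,
        )
        G = simulate_genotypes(sc, draw_component_frequencies(sc))
        kin = kinship_matrix(G)
        assert (kin["kinship"] < SECOND_DEGREE_KINSHIP).all()

    def test_insufficient_overlap_flagged(self):
        d = np.ones((2, 120), dtype=np.int8)
        d[0, 50:] = MISSING  # only 50 jointly observed SNPs
        kin = kinship_matrix(make_matrix(d))
        assert kin["insufficient_overlap"].iloc[0]
        assert np.isnan(kin["kinship"].iloc[0])


class TestRemoveRelated:
    def _kin_frame(self, pairs):
        return pd.DataFrame(
            [{"id1": a, "id2": b, "kinship": k} for a, b, k in pairs]
        )

    def test_single_pair_one_removal(self):
        G = make_matrix(np.ones((3, 200), dtype=np.int8))
        ids = list(G.samples["sample_id"])
        kin = self._kin_frame([(ids[0], ids[1], 0.5), (ids[0], ids[2], 0.01)])
        G2, report = remove_related(G, kin)
        assert G2.n_samples == 2
        assert report.stages[0].n_samples_removed == 1

    def test_no_flags_identity(self):
        G = make_matrix(np.ones((3, 200), dtype=np.int8))
        ids = list(G.samples["sample_id"])
        kin = self._kin_frame([(ids[0], ids[1], 0.02)])
        G2, report = remove_related(G, kin)
        assert G2.n_samples == 3
        assert report.stages[0].n_samples_removed == 0

    def test_triangle_needs_two_removals(self):
        G = make_matrix(np.ones((4, 200), dtype=np.int8))
        ids = list(G.samples["sample_id"])
        kin = self._kin_frame(
            [(ids[0], ids[1], 0.3), (ids[0], ids[2], 0.3), (ids[1], ids[2], 0.3)]
        )
        G2, report = remove_related(G, kin)
        # exhaustive check: any 2-subset of the triangle breaks all pairs
        assert report.stages[0].n_samples_removed == 2
        remaining = set(G2.samples["sample_id"])
        assert ids[3] in remaining


class TestRemoveOutgroupAdmixed:
    def _q(self, values):
        return pd.DataFrame(
            {"african": [1 - v for v in values], "european": values},
            index=[f"i{k}" for k in range(len(values))],
        )

    def test_below_threshold_kept(self):
        kept, _ = remove_outgroup_admixed(self._q([0.09]), "european", 0.10)
        assert kept == ["i0"]

    def test_above_threshold_removed(self):
        kept, report = remove_outgroup_admixed(self._q([0.11]), "european", 0.10)
        assert kept == []
        assert report.stages[0].removed_sample_ids == ["i0"]

    def test_unknown_component_raises(self):
        with pytest.raises(KeyError):
            remove_outgroup_admixed(self._q([0.2]), "martian")

    def test_planted_outgroup_individuals_recovered(self):
        # 5 individuals carry 20% outgroup ancestry; all and only those removed
        values = [0.0] * 20 + [0.20] * 5
        kept, report = remove_outgroup_admixed(self._q(values), "european", 0.10)
        assert set(report.stages[0].removed_sample_ids) == {f"i{k}" for k in range(20, 25)}
        assert len(kept) == 20
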