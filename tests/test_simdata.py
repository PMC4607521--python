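"""Synthetic-genotype generator: calibration, generative identities, resampling."""

import numpy as np
import pytest

from afrostruct import simdata
from afrostruct.genio import MISSING
from afrostruct.popdist import hudson_fst_freqs
from afrostruct.simdata import (
    PopulationSpec,
    SimulationScenario,
    default_scenario,
    draw_component_frequencies,
    fit_drifts,
    resample_admixed_target,
    simulate_genotypes,
)

from conftest import make_matrix


def tiny_scenario(**overrides):
    base = dict(
        n_components=2,
        component_names=["X", "Y"],
        drift={"X": 0.1, "Y": 0.1},
        n_snps=50,
        populations=[
            PopulationSpec("P1", 5, {"X": 1.0}),
            PopulationSpec("P2", 5, {"Y": 1.0}),
        ],
        seed=7,
    )
    base.update(overrides)
    return SimulationScenario(**base)


class TestScenario:
    def test_default_shape(self):
        sc = default_scenario()
        assert sc.n_snps == 1747
        assert sc.n_components == 6
        assert len(sc.populations) >= 12
        moz = next(p for p in sc.populations if p.label == "Mozambique")
        assert moz.ancestry.get("NC-East", 0) >= 0.95

    def test_drift_fit_matches_linear_algebra_oracle(self):
        # independent oracle: normal equations solved densely
        fit = fit_drifts()
        comps = list(fit.drifts)
        A = np.zeros((15, 6))
        y = np.zeros(15)
        for r, ((a, b), v) in enumerate(simdata.COMPONENT_FST_CALIBRATION.items()):
            A[r, comps.index(a)] = 0.5
            A[r, comps.index(b)] = 0.5
            y[r] = v
        expected = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose([fit.drifts[c] for c in comps], expected, atol=1e-10)

    def test_nc_pair_predicted_within_fit_residual(self):
        fit = fit_drifts()
        pred = (fit.drifts["NC-East"] + fit.drifts["NC-West"]) / 2
        resid = fit.residuals[("NC-East", "NC-West")]
        assert pred - resid == pytest.approx(0.042, abs=1e-12)
        assert abs(pred - 0.042) <= fit.max_abs_residual + 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="drift"):
            tiny_scenario(drift={"X": 0.0, "Y": 0.1})
        with pytest.raises(ValueError, match="sum to 1"):
            tiny_scenario(populations=[PopulationSpec("P", 3, {"X": 0.5, "Y": 0.4})])
        with pytest.raises(ValueError, match="missing_rate"):
            tiny_scenario(missing_rate=1.0)
        with pytest.raises(ValueError, match="n_snps"):
            tiny_scenario(n_snps=0)


class TestComponentTreeFit:
    def test_prediction_identity_and_fit_quality(self):
        fit = simdata.fit_component_tree()
        f = fit.tree.effective_drifts()
        fm = fit.tree.mrca_drifts()
        for (a, b), v in simdata.COMPONENT_FST_CALIBRATION.items():
            pred = (f[a] + f[b] - 2 * fm[(a, b)]) / (2 * (1 - fm[(a, b)]))
            assert pred == pytest.approx(v + fit.residuals[(a, b)], abs=1e-9)
        assert fit.max_abs_residual < 0.02

    def test_tree_fit_beats_star_fit(self):
        # shared internal branches capture the non-additive structure the
        # star model cannot (e.g. the close NC-East/NC-West pair)
        assert simdata.fit_component_tree().max_abs_residual < fit_drifts().max_abs_residual

    def test_leaves_match_components(self):
        fit = simdata.fit_component_tree()
        assert sorted(fit.tree.leaves()) == sorted(
            {c for pair in simdata.COMPONENT_FST_CALIBRATION for c in pair}
        )

    def test_sister_components_positively_correlated(self):
        # nested draws share ancestral-branch drift: NC-East/NC-West residuals
        # around the ancestral frequency must correlate
        sc = simdata.default_scenario()
        fr = simdata.draw_component_frequencies(sc)
        i = fr.component_names.index("NC-East")
        j = fr.component_names.index("NC-West")
        k = fr.component_names.index("East-2")
        da = fr.freqs[i] - fr.ancestral
        db = fr.freqs[j] - fr.ancestral
        dc = fr.freqs[k] - fr.ancestral
        r_sister = np.corrcoef(da, db)[0, 1]
        r_distant = np.corrcoef(da, dc)[0, 1]
        assert r_sister > 0.5
        assert r_sister > r_distant


class TestComponentFrequencies:
    def test_no_drift_limit(self):
        sc = tiny_scenario(drift={"X": 1e-6, "Y": 1e-6}, n_snps=2000)
        freqs = draw_component_frequencies(sc)
        assert np.mean(np.abs(freqs.freqs - freqs.ancestral[None, :])) < 1e-2

    def test_beta_mean_and_variance_identities(self):
        # simulation oracle: replicate draws at fixed ancestral p
        sc = tiny_scenario(drift={"X": 0.15, "Y": 0.15}, n_snps=10_000,
                           ancestral_freq_low=0.3, ancestral_freq_high=0.300001)
        freqs = draw_component_frequencies(sc)
        p = 0.3
        draws = freqs.freqs.ravel()  # 20,000 replicate draws at p ~ 0.3
        se_mean = np.sqrt(0.15 * p * (1 - p) / draws.size)
        assert abs(draws.mean() - p) < 4 * se_mean
        assert draws.var() == pytest.approx(0.15 * p * (1 - p), rel=0.05)

    def test_deterministic_given_seed(self):
        sc = tiny_scenario()
        f1 = draw_component_frequencies(sc)
        f2 = draw_component_frequencies(sc)
        np.testing.assert_array_equal(f1.freqs, f2.freqs)


class TestSimulateGenotypes:
    def test_degenerate_frequencies_give_dosage_two(self):
        sc = tiny_scenario(missing_rate=0.0)
        freqs = draw_component_frequencies(sc)
        freqs.freqs[:] = 1.0
        G = simulate_genotypes(sc, freqs)
        assert (G.dosages == 2).all()

    def test_no_missing_when_rate_zero(self):
        sc = tiny_scenario(missing_rate=0.0)
        G = simulate_genotypes(sc, draw_component_frequencies(sc))
        assert not G.missing_mask().any()

    def test_dosage_domain_and_metadata_shape(self):
        sc = tiny_scenario(missing_rate=0.2)
        G = simulate_genotypes(sc, draw_component_frequencies(sc))
        assert set(np.unique(G.dosages)) <= {0, 1, 2, MISSING}
        assert len(G.samples) == G.dosages.shape[0]
        assert len(G.variants) == G.dosages.shape[1]

    def test_one_hot_population_matches_component_frequency(self):
        # binomial sampling oracle at n=500
        sc = tiny_scenario(
            populations=[PopulationSpec("P1", 500, {"X": 1.0})],
            n_snps=200, missing_rate=0.0,
        )
        freqs = draw_component_frequencies(sc)
        G = simulate_genotypes(sc, freqs)
        emp = G.dosages.mean(axis=0) / 2
        se = np.sqrt(freqs.freqs[0] * (1 - freqs.freqs[0]) / (2 * 500))
        assert (np.abs(emp - freqs.freqs[0]) < 4 * se + 1e-9).mean() > 0.99

    def test_bit_reproducible(self):
        sc = tiny_scenario(missing_rate=0.1, related_pairs=[("P1", "parent_child")])
        f = draw_component_frequencies(sc)
        G1 = simulate_genotypes(sc, f)
        G2 = simulate_genotypes(sc, f)
        np.testing.assert_array_equal(G1.dosages, G2.dosages)

    def test_related_pairs_appended(self):
        sc = tiny_scenario(related_pairs=[("P1", "duplicate"), ("P2", "parent_child")])
        G = simulate_genotypes(sc, draw_component_frequencies(sc))
        assert G.n_samples == 12
        assert (G.dosages[10] == G.dosages[0]).all()  # duplicate of P1's first

    def test_hudson_fst_converges_to_mean_drift(self):
        # module invariant: FST between one-hot pops -> (F_a+F_b)/2 at 20k SNPs
        sc = SimulationScenario(
            n_components=2, component_names=["X", "Y"],
            drift={"X": 0.08, "Y": 0.16}, n_snps=20_000,
            populations=[
                PopulationSpec("P1", 100, {"X": 1.0}),
                PopulationSpec("P2", 100, {"Y": 1.0}),
            ],
            seed=11,
        )
        G = simulate_genotypes(sc, draw_component_frequencies(sc))
        p1 = G.dosages[:100].mean(axis=0) / 2
        p2 = G.dosages[100:].mean(axis=0) / 2
        n = np.full(20_000, 100.0)
        fst = hudson_fst_freqs(p1, n, p2, n)
        assert fst == pytest.approx(0.12, abs=0.01)


class TestResampleAdmixedTarget:
    @pytest.fixture()
    def source(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(40, 300)).astype(np.int8)
        return make_matrix(d, ["donor"] * 20 + ["pop1"] * 20)

    def test_alpha_one_matches_donor_frequency(self, source):
        t = resample_admixed_target(source, "donor", "pop1", 1.0,
                                    n_individuals=2000, seed=1)
        donor_f = source.dosages[:20].mean(axis=0) / 2
        emp = t.dosages.mean(axis=0) / 2
        se = np.sqrt(np.maximum(donor_f * (1 - donor_f), 1e-9) / 4000)
        assert (np.abs(emp - donor_f) <= 4 * se + 1e-9).mean() > 0.99

    def test_half_mixture_linearity(self, source):
        # 5,000 allele copies: simulated freq ~ (a+b)/2 within 3 binomial SDs
        t = resample_admixed_target(source, "donor", "pop1", 0.5,
                                    n_individuals=2500, seed=2)
        a = source.dosages[:20].mean(axis=0) / 2
        b = source.dosages[20:].mean(axis=0) / 2
        expect = (a + b) / 2
        emp = t.dosages.mean(axis=0) / 2
        sd = np.sqrt(expect * (1 - expect) / 5000)
        assert (np.abs(emp - expect) <= 3 * sd + 1e-9).mean() > 0.98

    def test_defaults_to_donor_sample_size(self, source):
        t = resample_admixed_target(source, "donor", "pop1", 0.3, seed=3)
        assert t.n_samples == 20

    def test_unknown_label_raises(self, source):
        with pytest.raises(KeyError):
            resample_admixed_target(source, "nope", "pop1", 0.5, seed=1)

    def test_all_missing_snp_excluded(self, source):
        d = source.dosages.copy()
        d[:20, 7] = MISSING  # donor frequency undefined at SNP 7
        G = make_matrix(d, list(source.samples["population"]))
        t = resample_admixed_target(G, "donor", "pop1", 0.5, seed=4)
        assert t.n_variants == 299
        assert "v7" not in set(t.variants["id"])
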