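"""Perturbation ensemble, vulnerability maps, hazard mapping and
hazard-centrality statistics."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from hopfnet.dynamics import ModelParameters, SimulationConfig
from hopfnet.lesion import (
    LesionSummary,
    PerturbationEnsemble,
    hazard_centrality_association,
    hazard_map,
    link_vulnerability,
    nodal_vulnerability,
    run_perturbation_suite,
)
from hopfnet.observables import SimilarityDistribution, StaticFC


def fc_with_strengths(strengths):
    """Symmetric FC whose nodal strengths (off-diagonal row sums) are as
    requested, built from a uniform triangle scaled per node pair."""
    n = len(strengths)
    m = np.zeros((n, n))
    # distribute each node's strength equally over its n-1 edges; then
    # symmetrize by averaging the two per-edge requests
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = strengths[i] / (n - 1)
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


def summary_from_fc(values, sync=0.3, meta=0.05, dfc=None, amp=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return LesionSummary(
        fc=StaticFC(values),
        modularity=0.0,
        dfc=SimilarityDistribution(dfc if dfc is not None else [0.5, 0.6, 0.7]),
        synchrony=sync,
        metastability=meta,
        mean_amplitude=amp if amp is not None else np.full(n, 0.2),
    )


def make_ensemble(base_fc, lesion_fcs, partition=None, **kw):
    n = np.asarray(base_fc).shape[0]
    partition = partition or ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return PerturbationEnsemble(
        baseline=summary_from_fc(base_fc, **kw),
        lesions=[summary_from_fc(m, **kw) for m in lesion_fcs],
        a_lesion=-2.0,
        seed=0,
        labels=[f"R{i}" for i in range(n)],
        partition=partition,
    )


class TestRunPerturbationSuite:
    def test_ensemble_size_and_noop_lesion(self, small_connectome, fast_cfg):
        p = ModelParameters(a=0.04, omega0=0.2, G=0.01, lam=0.4, m=0.1, beta=0.02)
        ens = run_perturbation_suite(
            small_connectome, p, fast_cfg, a_lesion=0.04, max_pairs=2000
        )
        assert len(ens.lesions) == small_connectome.n_nodes
        # a_lesion equal to baseline a with a shared seed: bitwise-identical sets
        for les in ens.lesions:
            np.testing.assert_array_equal(les.fc.values, ens.baseline.fc.values)
            assert les.synchrony == ens.baseline.synchrony

    def test_lesion_reduces_target_amplitude(self, small_connectome, fast_cfg):
        p = ModelParameters(a=0.04, omega0=0.2, G=0.01, lam=0.4, m=0.1, beta=0.02)
        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(
                dt=fast_cfg.dt, duration=fast_cfg.duration, burn_in=fast_cfg.burn_in,
                tr=fast_cfg.tr, seed=seed, record_frequencies=False,
            )
            from hopfnet.dynamics import apply_perturbation, simulate

            base = simulate(small_connectome, p, cfg)
            les = simulate(
                small_connectome,
                apply_perturbation(p, [0], -2.0, n_nodes=small_connectome.n_nodes),
                cfg,
            )
            if np.abs(les.z[:, 0]).mean() < np.abs(base.z[:, 0]).mean():
                wins += 1
        assert wins >= 9

    def test_requires_oscillatory_baseline(self, small_connectome, fast_cfg):
        p = ModelParameters(a=-0.5, omega0=0.2, G=0.01, lam=0.4, m=0.1, beta=0.02)
        with pytest.raises(ValueError):
            run_perturbation_suite(small_connectome, p, fast_cfg)


class TestNodalVulnerability:
    def test_identical_fc_zero_maps(self):
        base = fc_with_strengths([2.0, 2.0, 2.0])
        ens = make_ensemble(base, [base, base])
        vm = nodal_vulnerability(ens)
        np.testing.assert_array_equal(vm.nodal_hyper, 0.0)
        np.testing.assert_array_equal(vm.nodal_hypo, 0.0)

    def test_hypo_single_scenario(self):
        base = fc_with_strengths([2.0, 2.0, 2.0])
        scen = base.copy()
        # reduce node 0's strength by 25%: scale its off-diagonal row/col
        scen[0, 1:] *= 0.75
        scen[1:, 0] *= 0.75
        ens = make_ensemble(base, [scen], partition=["A", "A", "B"])
        vm = nodal_vulnerability(ens)
        assert vm.nodal_hypo[0] == pytest.approx(-0.25)
        assert vm.nodal_hyper[0] == 0.0

    def test_hyper_mean_across_scenarios(self):
        base = fc_with_strengths([2.0, 2.0, 2.0])
        s1, s2 = base.copy(), base.copy()
        s1[0, 1:] *= 1.25
        s1[1:, 0] *= 1.25
        s2[0, 1:] *= 1.5
        s2[1:, 0] *= 1.5
        ens = make_ensemble(base, [s1, s2], partition=["A", "A", "B"])
        vm = nodal_vulnerability(ens)
        assert vm.nodal_hyper[0] == pytest.approx(np.mean([0.25, 0.5]))

    def test_sign_invariants(self):
        rng = np.random.default_rng(0)
        base = fc_with_strengths([2, 3, 1.5, 2.5])
        lesions = []
        for _ in range(4):
            m = base + 0.05 * rng.standard_normal(base.shape)
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            lesions.append(m)
        vm = nodal_vulnerability(make_ensemble(base, lesions))
        assert np.all(vm.nodal_hyper >= 0)
        assert np.all(vm.nodal_hypo <= 0)


class TestLinkVulnerability:
    def test_identical_zero(self):
        base = fc_with_strengths([2.0, 2.0, 2.0, 2.0])
        vm = link_vulnerability(make_ensemble(base, [base]))
        assert vm.link_hyper.loc["A", "B"] == 0.0
        assert vm.link_hypo.loc["A", "B"] == 0.0

    def test_single_scenario_divergence(self):
        n = 4
        base = np.full((n, n), 0.4)
        np.fill_diagonal(base, 1.0)
        scen = np.full((n, n), 0.5)
        np.fill_diagonal(scen, 1.0)
        vm = link_vulnerability(make_ensemble(base, [scen]))
        assert vm.link_hyper.loc["A", "B"] == pytest.approx(0.25)

    def test_separate_positive_negative_means(self):
        n = 4
        def scaled(f):
            m = np.full((n, n), 0.4 * f)
            np.fill_diagonal(m, 1.0)
            return m
        base = scaled(1.0)
        vm = link_vulnerability(make_ensemble(base, [scaled(1.2), scaled(0.9), scaled(1.4)]))
        assert vm.link_hyper.loc["A", "B"] == pytest.approx(0.3)
        assert vm.link_hypo.loc["A", "B"] == pytest.approx(-0.1)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        base = fc_with_strengths([2, 3, 2, 3, 2, 3])
        lesions = []
        for _ in range(3):
            m = base + 0.1 * rng.standard_normal(base.shape)
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            lesions.append(m)
        part = ["A", "A", "B", "B", "C", "C"]
        vm = link_vulnerability(make_ensemble(base, lesions, partition=part))
        np.testing.assert_allclose(vm.link_hyper.values, vm.link_hyper.values.T)


class TestHazardMap:
    def test_identical_sets_zero_hazard(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0.1, 0.6, (8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ens = make_ensemble(m, [m] * 8)
        h = hazard_map(ens, n_null=3)
        np.testing.assert_allclose(h.static_distance, 0.0, atol=1e-12)
        np.testing.assert_allclose(h.phase_distance, 0.0, atol=1e-12)
        np.testing.assert_allclose(h.hazard, 0.0, atol=1e-12)

    def test_phase_distance_three_four_five(self):
        """Baseline (0,0)+KS 0 vs lesion (0.6,0.8)+KS 0 gives distance 1."""
        base = np.full((6, 6), 0.4)
        np.fill_diagonal(base, 1.0)
        # two lesions spanning the sync/meta normalization range [0, 0.6]/[0, 0.8]
        ens = PerturbationEnsemble(
            baseline=summary_from_fc(base, sync=0.0, meta=0.0),
            lesions=[
                summary_from_fc(base, sync=0.6, meta=0.8),
                summary_from_fc(base, sync=0.0, meta=0.0),
            ],
            a_lesion=-2.0, seed=0,
            labels=[f"R{i}" for i in range(6)],
            partition=["A"] * 3 + ["B"] * 3,
        )
        h = hazard_map(ens, n_null=2)
        # identical dFC distributions: KS coordinate 0; sync/meta normalized
        # to {0, 1} each -> Euclidean sqrt(2) for lesion 0, 0 for lesion 1
        assert h.phase_distance[0] == pytest.approx(np.sqrt(2.0))
        assert h.phase_distance[1] == pytest.approx(0.0)
        # after unity normalization across lesions: hazard contribution 1 and 0
        assert h.hazard[0] >= h.hazard[1]

    def test_two_point_static_normalization(self):
        """Distances {d, d/2} for two lesions normalize to {1, 0}."""
        rng = np.random.default_rng(3)
        base = rng.uniform(0.2, 0.5, (6, 6))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 1.0)
        far = base * 0.5
        near = base * 0.75
        np.fill_diagonal(far, 1.0)
        np.fill_diagonal(near, 1.0)
        ens = make_ensemble(base, [far, near], partition=["A"] * 3 + ["B"] * 3)
        h = hazard_map(ens, n_null=3)
        order = np.argsort(h.static_distance)
        normalized = (h.static_distance - h.static_distance.min()) / np.ptp(
            h.static_distance
        )
        assert normalized[order[0]] == pytest.approx(0.0)
        assert normalized[order[1]] == pytest.approx(1.0)

    def test_hazard_in_unit_double_interval(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0.1, 0.6, (8, 8))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 1.0)
        lesions = []
        for _ in range(8):
            m = base + 0.1 * rng.standard_normal(base.shape)
            m = np.clip((m + m.T) / 2, 0.01, 0.95)
            np.fill_diagonal(m, 1.0)
            lesions.append(m)
        ens = make_ensemble(base, lesions)
        h = hazard_map(ens, n_null=3)
        assert np.all(h.hazard >= 0) and np.all(h.hazard <= 2 + 1e-12)


class TestHazardCentrality:
    def _centralities(self, n, rng):
        return pd.DataFrame(
            {
                "clustering": rng.random(n),
                "degree": rng.integers(1, n, n).astype(float),
                "strength": rng.random(n) * 5,
                "local_efficiency": rng.random(n),
            }
        )

    def test_hazard_equal_to_strength_r_one(self):
        rng = np.random.default_rng(5)
        ct = self._centralities(30, rng)
        from hopfnet.lesion import HazardMap

        h = HazardMap(
            static_distance=np.zeros(30), phase_distance=np.zeros(30),
            hazard=ct["strength"].to_numpy().copy(), labels=[str(i) for i in range(30)],
        )
        out = hazard_centrality_association(h, ct)
        assert out.loc["strength", "r"] == pytest.approx(1.0)

    def test_bh_adjustment_stepup(self):
        p_adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(p_adj, [0.04, 0.04, 0.04, 0.04])

    def test_independent_hazard_rarely_significant(self):
        rng = np.random.default_rng(6)
        n = 40
        ct = self._centralities(n, rng)
        from hopfnet.lesion import HazardMap

        n_any_significant = 0
        for rep in range(10):
            h = HazardMap(
                static_distance=np.zeros(n), phase_distance=np.zeros(n),
                hazard=rng.permutation(n).astype(float),
                labels=[str(i) for i in range(n)],
            )
            out = hazard_centrality_association(h, ct)
            if out["significant"].any():
                n_any_significant += 1
        assert n_any_significant <= 1
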