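"""FC, modularity, phases, dynamic-FC distribution, order parameter and
frequency estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopfnet.dynamics import RegionalSignals
from hopfnet.observables import (
    PhaseSeries,
    SimilarityDistribution,
    StaticFC,
    dfc_similarity_distribution,
    estimate_intrinsic_frequencies,
    fc_similarity,
    group_average_fc,
    hilbert_phases,
    instantaneous_fc,
    ks_distance,
    modularity,
    order_parameter,
    static_fc,
)

from conftest import oracle_ks, oracle_modularity


def signals(data, tr=0.72):
    return RegionalSignals(np.asarray(data, dtype=float), tr=tr)


class TestStaticFC:
    def test_identical_and_negated_columns(self):
        t = np.linspace(0, 10, 50)
        x = np.sin(t)
        fc = static_fc(signals(np.column_stack([x, x, -x])))
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)

    def test_hand_example(self):
        fc = static_fc(signals([[0, 0], [1, 2], [2, 1]]))
        assert fc.values[0, 1] == pytest.approx(0.5)

    def test_constant_column_flagged(self):
        with pytest.warns(UserWarning):
            fc = static_fc(signals([[1, 0], [1, 1], [1, 2]]))
        assert fc.values[0, 1] == 0.0
        assert fc.values[0, 0] == 1.0


class TestGroupAverageFC:
    def test_idempotent_on_identical_matrices(self):
        m = np.array([[1, 0.3], [0.3, 1]])
        fcs = [StaticFC(m.copy()) for _ in range(3)]
        np.testing.assert_allclose(group_average_fc(fcs).values, m, atol=1e-7)

    def test_fisher_mean_of_two_entries(self):
        a = np.array([[1, 0.2], [0.2, 1]])
        b = np.array([[1, 0.6], [0.6, 1]])
        out = group_average_fc([StaticFC(a), StaticFC(b)])
        expected = np.tanh((np.arctanh(0.2) + np.arctanh(0.6)) / 2)
        assert out.values[0, 1] == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.4202, abs=1e-4)

    def test_perfect_correlation_clipped(self):
        m = np.array([[1, 1.0], [1.0, 1]])
        out = group_average_fc([StaticFC(m)])
        assert np.isfinite(out.values).all()


class TestFCSimilarity:
    def test_self_similarity_one(self):
        rng = np.random.default_rng(0)
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1)
        assert fc_similarity(StaticFC(m), StaticFC(m)) == pytest.approx(1.0)

    def test_antiordered_triples(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.1
        a[0, 2] = a[2, 0] = 0.2
        a[1, 2] = a[2, 1] = 0.3
        b = np.eye(3)
        b[0, 1] = b[1, 0] = 0.3
        b[0, 2] = b[2, 0] = 0.2
        b[1, 2] = b[2, 1] = 0.1
        assert fc_similarity(StaticFC(a), StaticFC(b)) == pytest.approx(-1.0)

    def test_constant_triangle_rejected(self):
        m = np.full((3, 3), 0.5)
        with pytest.raises(ValueError):
            fc_similarity(StaticFC(m), StaticFC(m))


class TestModularity:
    def test_two_disconnected_dyads(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        assert modularity(StaticFC(w), ["A", "A", "B", "B"]) == pytest.approx(0.5)

    def test_single_module_is_zero(self):
        rng = np.random.default_rng(1)
        w = rng.random((6, 6))
        w = (w + w.T) / 2
        assert modularity(StaticFC(w), ["M"] * 6) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            w = rng.random((10, 10))
            w = (w + w.T) / 2
            part = rng.integers(0, 3, 10).astype(str)
            assert modularity(StaticFC(w), part) == pytest.approx(
                oracle_modularity(w, part), abs=1e-12
            )

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            modularity(StaticFC(np.zeros((3, 3))), ["A", "A", "B"])


class TestHilbertPhases:
    def test_cosine_phase_slope(self):
        tr = 0.72
        t = np.arange(400) * tr
        x = np.cos(2 * np.pi * 0.05 * t)
        p = hilbert_phases(signals(np.column_stack([x, x])), trim_fraction=0.1)
        mid = slice(50, -50)
        slope = np.diff(np.unwrap(p.phases[:, 0]))[mid].mean() / tr
        assert slope == pytest.approx(2 * np.pi * 0.05, rel=0.02)
        # identical columns: zero phase difference everywhere
        np.testing.assert_allclose(p.phases[:, 0], p.phases[:, 1])

    def test_quadrature_pair(self):
        tr = 0.72
        t = np.arange(400) * tr
        x = np.cos(2 * np.pi * 0.05 * t)
        y = np.sin(2 * np.pi * 0.05 * t)
        p = hilbert_phases(signals(np.column_stack([x, y])), trim_fraction=0.1)
        mid = slice(100, -100)
        diff = np.angle(np.exp(1j * (p.phases[mid, 1] - p.phases[mid, 0])))
        assert np.median(diff) == pytest.approx(-np.pi / 2, abs=0.05)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            hilbert_phases(signals(np.column_stack([np.ones(20), np.arange(20.0)])))


class TestInstantaneousFC:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.0, 1.0), (np.pi / 2, 0.0), (np.pi / 6, 0.5)],
    )
    def test_phase_difference_values(self, delta, expected):
        p = PhaseSeries(np.array([[0.0, delta]]), tr=1.0)
        m = instantaneous_fc(p, 0)
        assert m[0, 1] == pytest.approx(expected)
        assert m[1, 0] == pytest.approx(expected)
        assert m[0, 0] == pytest.approx(1.0)

    @given(st.floats(-3, 3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_common_phase_shift(self, shift):
        base = np.array([[0.1, 0.7, -1.2]])
        m1 = instantaneous_fc(PhaseSeries(base, 1.0), 0)
        m2 = instantaneous_fc(PhaseSeries(base + shift, 1.0), 0)
        np.testing.assert_allclose(m1, m2, atol=1e-12)


class TestDFCSimilarity:
    def test_identical_time_points_all_ones(self):
        p = PhaseSeries(np.tile([0.3, 1.1, -0.4], (5, 1)), tr=1.0)
        d = dfc_similarity_distribution(p)
        np.testing.assert_allclose(d.samples, 1.0)
        assert d.samples.size == 10  # 5*4/2

    def test_two_timepoints_single_sample(self):
        p = PhaseSeries(np.array([[0.0, 0.5, 1.0], [0.2, 0.4, 0.9]]), tr=1.0)
        assert dfc_similarity_distribution(p).samples.size == 1

    def test_orthogonal_upper_triangles(self):
        """Hand-built FC vectors (1,0,0) and (0,1,0) have cosine 0."""
        v1 = np.array([1.0, 0.0, 0.0])
        v2 = np.array([0.0, 1.0, 0.0])
        cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert cos == pytest.approx(0.0)
        # through the library: phases chosen so 1-|sin(d)| gives those triangles
        # (pair (0,1): d=0 -> 1; others pi/2 -> 0) etc.
        t0 = [0.0, 0.0, np.pi / 2]
        t1 = [0.0, np.pi / 2, 0.0]
        p = PhaseSeries(np.array([t0, t1]), tr=1.0)
        assert dfc_similarity_distribution(p).samples[0] == pytest.approx(0.0, abs=1e-12)

    def test_subsample_seeded_and_exhaustive_seed_independent(self):
        rng = np.random.default_rng(3)
        p = PhaseSeries(rng.uniform(-np.pi, np.pi, (30, 4)), tr=1.0)
        full1 = dfc_similarity_distribution(p, max_pairs=1000, seed=1)
        full2 = dfc_similarity_distribution(p, max_pairs=None, seed=9)
        np.testing.assert_array_equal(np.sort(full1.samples), np.sort(full2.samples))
        sub1 = dfc_similarity_distribution(p, max_pairs=50, seed=5)
        sub2 = dfc_similarity_distribution(p, max_pairs=50, seed=5)
        np.testing.assert_array_equal(sub1.samples, sub2.samples)
        assert sub1.samples.size == 50


class TestKSDistance:
    def test_examples(self):
        assert ks_distance(
            SimilarityDistribution([0.1, 0.5, 0.9]), SimilarityDistribution([0.1, 0.5, 0.9])
        ) == pytest.approx(0.0)
        assert ks_distance(
            SimilarityDistribution([0.0, 0.0]), SimilarityDistribution([1.0, 1.0])
        ) == pytest.approx(1.0)
        assert ks_distance(
            SimilarityDistribution([1.0, 2.0]), SimilarityDistribution([1.0, 3.0])
        ) == pytest.approx(0.5)

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(4)
        a = SimilarityDistribution(rng.random(40))
        b = SimilarityDistribution(rng.random(25))
        d1, d2 = ks_distance(a, b), ks_distance(b, a)
        assert d1 == pytest.approx(d2)
        assert 0 <= d1 <= 1

    def test_matches_bruteforce_ecdf_sweep(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.random(rng.integers(3, 12))
            b = rng.random(rng.integers(3, 12))
            got = ks_distance(SimilarityDistribution(a), SimilarityDistribution(b))
            assert got == pytest.approx(oracle_ks(a, b), abs=1e-9)


class TestOrderParameter:
    def test_identical_phases(self):
        p = PhaseSeries(np.full((6, 5), 0.7), tr=1.0)
        c = order_parameter(p)
        np.testing.assert_allclose(c.r, 1.0)
        assert c.metastability == pytest.approx(0.0)

    def test_balanced_quartet(self):
        p = PhaseSeries(np.array([[0, np.pi / 2, np.pi, 3 * np.pi / 2]]), tr=1.0)
        assert order_parameter(p).r[0] == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_pair(self):
        p = PhaseSeries(np.array([[0.0, np.pi / 2]]), tr=1.0)
        assert order_parameter(p).r[0] == pytest.approx(np.sqrt(2) / 2)

    def test_single_node_r_is_one(self):
        rng = np.random.default_rng(6)
        p = PhaseSeries(rng.uniform(-np.pi, np.pi, (10, 1)), tr=1.0)
        np.testing.assert_allclose(order_parameter(p).r, 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_r_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        p = PhaseSeries(rng.uniform(-np.pi, np.pi, (4, 7)), tr=1.0)
        r = order_parameter(p).r
        assert np.all((0 <= r) & (r <= 1))


def test_bandpass_filter_removes_out_of_band_tone():
    from hopfnet.observables import bandpass_filter, welch_peak_frequency

    tr = 0.72
    t = np.arange(800) * tr
    x = np.cos(2 * np.pi * 0.05 * t) + 2.0 * np.cos(2 * np.pi * 0.4 * t)
    out = bandpass_filter(signals(x[:, None]), band=(0.02, 0.12))
    peak = welch_peak_frequency(out.data, 1 / tr, (1e-3, 0.5 / tr - 1e-3))
    assert peak[0] == pytest.approx(0.05, abs=0.01)


class TestIntrinsicFrequencies:
    def test_pure_tone(self):
        t = np.arange(600) * 0.72
        x = np.cos(2 * np.pi * 0.05 * t)
        omega = estimate_intrinsic_frequencies([signals(np.column_stack([x, x]))])
        np.testing.assert_allclose(omega, 2 * np.pi * 0.05, rtol=0.05)

    def test_median_across_subjects(self):
        t = np.arange(600) * 0.72
        subs = [
            signals(np.cos(2 * np.pi * f * t)[:, None]) for f in (0.04, 0.05, 0.09)
        ]
        omega = estimate_intrinsic_frequencies(subs)
        assert omega[0] == pytest.approx(2 * np.pi * 0.05, rel=0.05)

    def test_dominant_tone_wins(self):
        t = np.arange(800) * 0.72
        x = 2 * np.cos(2 * np.pi * 0.03 * t) + np.cos(2 * np.pi * 0.10 * t)
        omega = estimate_intrinsic_frequencies([signals(x[:, None])])
        assert omega[0] == pytest.approx(2 * np.pi * 0.03, rel=0.1)

    def test_bad_band_rejected(self):
        t = np.arange(100) * 0.72
        s = signals(np.cos(t)[:, None])
        with pytest.raises(ValueError):
            estimate_intrinsic_frequencies([s], band=(0.2, 0.9))
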