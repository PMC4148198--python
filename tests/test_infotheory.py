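import numpy as np
import pytest

from gclnet.binary_net import ThresholdPolicy, build_uniform_graph
from gclnet.infotheory import (
    EntropyCurve,
    EventEnsemble,
    RangeResult,
    entropy_curve,
    entropy_from_counts,
    event_entropy,
    exact_asymptotic_entropy,
    grid_coverage,
    lossless_intervals,
    pareto_best,
    sample_event_patterns,
    sparse_encodable_range,
)


def bernoulli_entropy(p):
    if p in (0.0, 1.0):
        return 0.0
    return -p * np.log2(p) - (1 - p) * np.log2(1 - p)


class TestEntropyFromCounts:
    @pytest.mark.parametrize(
        "counts,expected",
        [([1] * 8, 3.0), ([5], 0.0), ([2, 1, 1], 1.5), ([1, 1], 1.0)],
    )
    def test_known_values(self, counts, expected):
        assert entropy_from_counts(counts) == pytest.approx(expected)

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            entropy_from_counts([])
        with pytest.raises(ValueError):
            entropy_from_counts([2, 0])

    def test_miller_madow_adds_bias_term(self):
        counts = [3, 2, 1]
        plain = entropy_from_counts(counts)
        mm = entropy_from_counts(counts, miller_madow=True)
        assert mm == pytest.approx(plain + 2 / (2 * 6 * np.log(2)))


class TestEventSampling:
    def test_distinct_patterns_are_distinct(self, rng):
        pats = sample_event_patterns(20, 500, 0.4, rng, distinct=True)
        assert len(np.unique(pats, axis=0)) == 500

    def test_degenerate_p_forces_single_pattern(self, rng):
        with pytest.raises(ValueError):
            sample_event_patterns(10, 4, 0.0, rng, strict=True)
        pats = sample_event_patterns(10, 4, 1.0, rng, strict=False)
        assert pats.shape == (1, 10) and pats.all()

    def test_truncation_when_support_is_small(self, rng):
        # at p=0.02 with 10 MFs only a handful of patterns are ever drawn
        pats = sample_event_patterns(10, 1000, 0.02, rng, strict=False)
        assert 1 < len(pats) < 1000
        assert len(np.unique(pats, axis=0)) == len(pats)


class TestEventEntropy:
    def test_injective_relay_saturates_at_log2_n(self):
        g = build_uniform_graph(30, 90, 1, seed=0)
        g.adjacency[:30, 0] = np.arange(30)  # cover every MF
        pol = ThresholdPolicy(kind="absolute", absolute_value=1)
        for p in (0.2, 0.5, 0.8):
            h, sd = event_entropy(
                g, pol, EventEnsemble(n_events=1024, p_mf=p, seed=1), reps=2
            )
            assert h == pytest.approx(10.0)
            assert sd == 0.0

    def test_wide_relay_plateau_at_desk_scale(self):
        """d=1 relay on the full-size net keeps >=99% of event information
        over the central activity range."""
        g = build_uniform_graph(176, 509, 1, seed=0)
        pol = ThresholdPolicy(kind="absolute", absolute_value=1)
        for p in (0.2, 0.5, 0.8):
            h, _ = event_entropy(
                g, pol, EventEnsemble(n_events=2**12, p_mf=p, seed=2), reps=1
            )
            assert h >= 0.99 * 12

    def test_monte_carlo_matches_enumeration_on_tiny_nets(self):
        """iid sampling converges to the exact Bernoulli-weighted entropy."""
        for seed, d, phi in [(0, 2, 1), (1, 3, 2), (2, 4, 4)]:
            g = build_uniform_graph(10, 25, d, seed=seed)
            pol = ThresholdPolicy(kind="absolute", absolute_value=phi)
            for p in (0.1, 0.3, 0.5, 0.7, 0.9):
                exact = exact_asymptotic_entropy(g, phi, p)
                h, sd = event_entropy(
                    g,
                    pol,
                    EventEnsemble(2**15, p, seed=3, distinct=False),
                    reps=5,
                    miller_madow=True,
                )
                tol = max(3 * sd, 0.05)
                assert abs(h - exact) < tol

    def test_entropy_bounded_by_cap_and_cells(self):
        g = build_uniform_graph(12, 6, 2, seed=4)
        pol = ThresholdPolicy(kind="absolute", absolute_value=1)
        h, _ = event_entropy(
            g, pol, EventEnsemble(2**10, 0.5, seed=5), reps=3, reinstantiate=True
        )
        assert 0.0 <= h <= min(10.0, 6.0)


class TestExactEntropy:
    def test_degenerate_inputs_have_zero_entropy(self):
        g = build_uniform_graph(8, 12, 2, seed=0)
        assert exact_asymptotic_entropy(g, 1, 0.0) == 0.0
        assert exact_asymptotic_entropy(g, 1, 1.0) == 0.0

    def test_relay_equals_n_times_binary_entropy(self):
        n_mf = 8
        g = build_uniform_graph(n_mf, 16, 1, seed=1)
        g.adjacency[:n_mf, 0] = np.arange(n_mf)
        for p in (0.25, 0.5, 0.6):
            assert exact_asymptotic_entropy(g, 1, p) == pytest.approx(
                n_mf * bernoulli_entropy(p)
            )

    def test_single_and_gate_population(self):
        # every GC computes the same AND of all inputs -> Bernoulli(p^n)
        n_mf = 6
        g = build_uniform_graph(n_mf, 9, n_mf, seed=2)
        p = 0.7
        assert exact_asymptotic_entropy(g, n_mf, p) == pytest.approx(
            bernoulli_entropy(p**n_mf)
        )

    def test_large_net_rejected(self):
        g = build_uniform_graph(30, 5, 2, seed=0)
        with pytest.raises(ValueError, match="Monte Carlo"):
            exact_asymptotic_entropy(g, 1, 0.5)


def make_curve(p, h, p_gc, n_events=1024):
    p = np.asarray(p, dtype=float)
    return EntropyCurve(
        p_mf_grid=p,
        entropy_bits=np.asarray(h, dtype=float),
        entropy_sd=np.zeros_like(p),
        p_gc=np.asarray(p_gc, dtype=float),
        n_events=n_events,
    )


class TestRanges:
    def test_full_and_empty_lossless(self):
        p = np.linspace(0, 1, 11)
        cap = 10.0
        full = lossless_intervals(make_curve(p, [cap] * 11, p))
        assert full.intervals == [[0.0, 1.0]]
        assert full.total_measure == pytest.approx(1.0)
        empty = lossless_intervals(make_curve(p, [0.0] * 11, p))
        assert empty.intervals == []

    def test_sparse_range_is_intersection(self):
        p = np.round(np.linspace(0, 1, 11), 2)
        h = [10.0 if 0.2 <= x <= 0.6 else 0.0 for x in p]
        p_gc = [x - 0.05 if 0.4 <= x <= 0.8 else x + 0.05 for x in p]
        res = sparse_encodable_range(make_curve(p, h, p_gc))
        assert res.intervals == [[0.4, 0.6]]
        assert res.total_measure == pytest.approx(0.2)

    def test_relay_sparse_range_is_empty(self):
        p = np.linspace(0, 1, 21)
        res = sparse_encodable_range(make_curve(p, [10.0] * 21, p))
        assert res.intervals == []

    def test_avg_sparseness_definition(self):
        p = np.linspace(0, 1, 5)
        res = lossless_intervals(make_curve(p, [10] * 5, [0.2] * 5))
        assert res.avg_output_sparseness == pytest.approx(0.8)

    def test_grid_coverage_ignores_degenerate_endpoints(self):
        p = np.linspace(0, 1, 11)
        h = [0.0] + [10.0] * 9 + [0.0]
        assert grid_coverage(make_curve(p, h, p)) == pytest.approx(1.0)


class TestPareto:
    def r(self, measure, sparse):
        return RangeResult(intervals=[], total_measure=measure,
                           avg_output_sparseness=sparse)

    def test_single_element_is_front(self):
        items = [(3, "fixed", self.r(0.5, 0.5))]
        assert pareto_best(items) == items

    def test_dominated_element_excluded(self):
        a = (2, "fixed", self.r(0.8, 0.7))
        b = (9, "fixed", self.r(0.5, 0.6))
        assert pareto_best([a, b]) == [a]

    def test_incomparable_elements_both_kept(self):
        a = (2, "fixed", self.r(0.9, 0.6))
        b = (3, "fixed", self.r(0.7, 0.8))
        assert sorted(x[0] for x in pareto_best([a, b])) == [2, 3]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pareto_best([])


class TestEntropyCurve:
    def test_curve_respects_bounds_and_determinism(self):
        pol = ThresholdPolicy(kind="fixed_relative")
        kwargs = dict(p_grid=7, n_events=256, reps=2, seed=3)
        a = entropy_curve(20, 60, 3, pol, **kwargs)
        b = entropy_curve(20, 60, 3, pol, **kwargs)
        assert np.array_equal(a.entropy_bits, b.entropy_bits)
        cap = np.log2(a.n_events)
        assert np.all(a.entropy_bits >= -1e-9)
        assert np.all(a.entropy_bits <= min(cap, 60) + 1e-9)
        assert np.all((a.p_gc >= 0) & (a.p_gc <= 1))

    def test_unity_nadt_keeps_activity_near_half(self):
        pol = ThresholdPolicy(kind="nadt", nadt_scale=1.0)
        curve = entropy_curve(30, 90, 6, pol, p_grid=9, n_events=256, reps=1, seed=0)
        mid = (curve.p_mf_grid >= 0.25) & (curve.p_mf_grid <= 0.75)
        assert np.all(np.abs(curve.p_gc[mid] - 0.5) < 0.25)
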