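"""Simulator contracts: limits, determinism, and distributional oracles."""

import numpy as np
import pytest

from fretpaint.errors import ConfigurationError
from fretpaint.synthetic_data import (
    GroundTruth,
    SimulationConfig,
    length_accessibility_profile,
    render_trace,
    simulate_dataset,
    simulate_trace,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(e_do=1.0), "e_do"),
            (dict(t_short=5.0, t_long=3.0), "t_short"),
            (dict(site_weights=[0.5, 0.5, 0.5, 0.5]), "sum to 1"),
            (dict(site_fret_levels=[0.1, 0.2]), "site_fret_levels"),
            (dict(frame_time=0.0), "frame_time"),
            (dict(p_short=1.5), "p_short"),
        ],
    )
    def test_invariant_violations_named(self, kwargs, match):
        with pytest.raises(ConfigurationError, match=match):
            SimulationConfig(**kwargs)


class TestSimulateTrace:
    def test_no_binding_limit(self):
        """k_on = 0, no bleach: empty ground truth, all frames at the leakage baseline."""
        cfg = SimulationConfig(k_on=0.0, bleach_rate=0.0, noise_sigma=0.0, seed=1)
        trace, truth = simulate_trace(cfg)
        assert truth.events == []
        assert truth.bleach_time is None
        e = trace.i_acceptor / (trace.i_acceptor + trace.i_donor)
        np.testing.assert_allclose(e, cfg.e_do, atol=1e-12)

    def test_noiseless_forced_event(self):
        """A forced 10-frame event at E_site=0.5, e_do=0: acceptor exactly half-total."""
        cfg = SimulationConfig(
            k_on=0.0, bleach_rate=0.0, noise_sigma=0.0, e_do=0.0, seed=1, n_frames=50
        )
        events = [(1.0, 1.0, 0, 0.5)]  # frames 10..19 inclusive
        trace = render_trace(cfg, "m0", events, bleach_time=None)
        expected = np.zeros(50)
        expected[10:20] = cfg.total_intensity * 0.5
        np.testing.assert_allclose(trace.i_acceptor, expected, atol=1e-9)
        np.testing.assert_allclose(
            trace.i_donor, cfg.total_intensity - expected, atol=1e-9
        )

    def test_frame_integration_attenuates_subframe_event(self):
        """An event half a frame long leaves a half-amplitude frame value."""
        cfg = SimulationConfig(
            k_on=0.0, bleach_rate=0.0, noise_sigma=0.0, e_do=0.0, seed=1, n_frames=10
        )
        trace = render_trace(cfg, "m0", [(0.5, 0.05, 0, 0.8)], bleach_time=None)
        np.testing.assert_allclose(
            trace.i_acceptor[5], cfg.total_intensity * 0.8 * 0.5, atol=1e-9
        )

    def test_bleach_truncates_signal(self):
        cfg = SimulationConfig(
            k_on=0.0, bleach_rate=0.0, noise_sigma=0.0, e_do=0.1, seed=1, n_frames=100
        )
        trace = render_trace(cfg, "m0", [], bleach_time=5.0)
        assert np.all(trace.total[:50] > 0)
        np.testing.assert_allclose(trace.total[50:], 0.0, atol=1e-9)

    def test_event_count_poisson_oracle(self):
        """Total event count sits within 3 Poisson SD of k_on * total unbound time.

        Oracle: direct count of generated ground-truth events vs the rate
        integral implied by each molecule's own unbound time.
        """
        cfg = SimulationConfig(
            k_on=0.05, t_short=0.2, t_long=0.5, p_short=0.5,
            bleach_rate=0.0, n_frames=2000, seed=77,
        )
        _, truths = simulate_dataset(cfg, 500)
        n_events = sum(len(t.events) for t in truths)
        unbound = sum(
            200.0 - sum(min(d, 200.0 - s) for (s, d, _, _) in t.events)
            for t in truths
        )
        expected = cfg.k_on * unbound
        assert abs(n_events - expected) < 3 * np.sqrt(expected)

    def test_dwell_mean_matches_mixture(self):
        """Ground-truth dwell mean converges to p*t_short + (1-p)*t_long."""
        cfg = SimulationConfig(
            k_on=0.05, bleach_rate=0.0, p_short=0.5, t_short=0.7, t_long=5.0,
            n_frames=2000, seed=5,
        )
        _, truths = simulate_dataset(cfg, 600)
        dwells = np.array([d for t in truths for (_, d, _, _) in t.events])
        assert len(dwells) >= 1e4 * 0.2  # enough statistics to test the mean
        mix_mean = 0.5 * 0.7 + 0.5 * 5.0
        mix_var = 2 * (0.5 * 0.7**2 + 0.5 * 5.0**2) - mix_mean**2
        se = np.sqrt(mix_var / len(dwells))
        assert abs(dwells.mean() - mix_mean) < 3 * se

    def test_bleach_times_exponential(self):
        """Observation times are Exp(1/bleach_rate) censored at the trace end."""
        cfg = SimulationConfig(k_on=0.0, bleach_rate=1 / 50.0, n_frames=2000, seed=9)
        _, truths = simulate_dataset(cfg, 1000)
        obs = np.array([t.observation_time(200.0) for t in truths])
        # censored-mean oracle: E[min(X, c)] = mean * (1 - exp(-c/mean))
        expected = 50.0 * (1 - np.exp(-200.0 / 50.0))
        assert abs(obs.mean() - expected) / expected < 0.1

    def test_bound_fraction_matches_truth_noiseless(self):
        """Fraction of frames above threshold equals ground-truth bound fraction."""
        cfg = SimulationConfig(
            k_on=0.02, bleach_rate=0.0, noise_sigma=0.0, e_do=0.0,
            site_fret_levels=[0.8] * 4, seed=21,
        )
        dataset, truths = simulate_dataset(cfg, 50)
        frac_frames = np.mean(
            [np.mean(tr.i_acceptor / (tr.total + 1e-300) > 0.4) for tr in dataset.traces]
        )
        bound = sum(
            sum(min(d, 200.0 - s) for (s, d, _, _) in t.events) for t in truths
        ) / (50 * 200.0)
        assert abs(frac_frames - bound) < 0.01


class TestSimulateDataset:
    def test_determinism(self):
        cfg = SimulationConfig(seed=42)
        ds1, gt1 = simulate_dataset(cfg, 5)
        ds2, gt2 = simulate_dataset(SimulationConfig(seed=42), 5)
        for a, b in zip(ds1.traces, ds2.traces):
            np.testing.assert_array_equal(a.i_donor, b.i_donor)
            np.testing.assert_array_equal(a.i_acceptor, b.i_acceptor)
        assert [g.events for g in gt1] == [g.events for g in gt2]

    def test_seed_changes_data(self):
        ds1, _ = simulate_dataset(SimulationConfig(seed=1), 2)
        ds2, _ = simulate_dataset(SimulationConfig(seed=2), 2)
        assert not np.array_equal(ds1.traces[0].i_donor, ds2.traces[0].i_donor)

    def test_single_molecule_dataset(self):
        ds, gts = simulate_dataset(SimulationConfig(seed=3), 1)
        assert ds.n_molecules == 1
        assert len(gts) == 1
        assert ds.construct_label == "4G-Tract"

    def test_ground_truth_invariants(self, small_dataset):
        _, _, truths = small_dataset
        for gt in truths:
            starts = [s for (s, _, _, _) in gt.events]
            assert starts == sorted(starts)
            for (s1, d1, _, _), (s2, _, _, _) in zip(gt.events, gt.events[1:]):
                assert s1 + d1 <= s2  # non-overlap
            if gt.bleach_time is not None:
                assert all(s < gt.bleach_time for (s, _, _, _) in gt.events)


class TestAccessibilityProfile:
    def test_zero_compaction_linear(self):
        for n in (1, 4, 10, 24):
            assert length_accessibility_profile(n, 2e-3, 0.0) == pytest.approx(n * 2e-3)

    def test_exponent_zero_at_four_tracts(self):
        for c in (0.0, 0.3, 1.0):
            assert length_accessibility_profile(4, 1e-3, c) == pytest.approx(4e-3)

    def test_per_tract_rate_strictly_decreasing(self):
        """Closed-form oracle: k_on/n = r (1-c)^(n-4) decreases for c > 0."""
        rates = [
            length_accessibility_profile(n, 1e-3, 0.05) / n for n in range(4, 25)
        ]
        assert all(b < a for a, b in zip(rates, rates[1:]))

    def test_invalid_compaction(self):
        with pytest.raises(ConfigurationError):
            length_accessibility_profile(4, 1e-3, 1.5)
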