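import numpy as np
import pytest

from colspike.core import StimulusSchedule, TrialSpikeTable
from colspike.tuning import (
    PSTH,
    compute_psth,
    direction_index,
    latency,
    modulation_ratio,
    orientation_index,
    responsiveness,
    tuning_summary,
)


class TestComputePSTH:
    def test_zero_spikes(self):
        p = compute_psth([np.empty(0)] * 5)
        assert np.all(p.rate_hz == 0.0)
        assert np.all(p.sem == 0.0)

    def test_single_spike_conservation(self):
        # one spike in one of 10 trials integrates to 1/10 spike
        trials = [np.empty(0)] * 9 + [np.array([0.267])]  # 0.2 s after screen update
        p = compute_psth(trials)
        integral = p.rate_hz.sum() * p.bin_ms / 1e3
        assert integral == pytest.approx(0.1, rel=0.01)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        dur = 0.55  # window span in seconds
        trials = [
            np.sort(rng.uniform(0.017, 0.567, rng.poisson(20 * dur)))
            for _ in range(50)
        ]
        p = compute_psth(trials)
        # interior bins only: smoothing bleeds mass over the window edges
        sel = (p.time_ms > -20) & (p.time_ms < 470)
        assert p.rate_hz[sel].mean() == pytest.approx(20.0, abs=2.0)

    def test_screen_delay_shift(self):
        trials = [np.array([0.067])] * 3  # exactly at the true stimulus update
        p = compute_psth(trials)
        assert abs(p.time_ms[int(np.argmax(p.rate_hz))]) <= 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            compute_psth([])


def _table(spikes_per_trial, schedule):
    n = len(spikes_per_trial)
    trials = schedule.trial_table().iloc[:n].reset_index(drop=True)
    return TrialSpikeTable(trials, spikes_per_trial)


class TestResponsiveness:
    sched = StimulusSchedule(repeats=2, spatial_frequencies_cpd=(1.0,))

    def test_zero_spikes_not_responsive(self):
        t = _table([np.empty(0)] * 20, self.sched)
        assert responsiveness(t, self.sched) is False

    def test_identical_distributions_not_responsive(self):
        rng = np.random.default_rng(1)
        spikes = [np.sort(rng.uniform(-0.25, 1.25, 10)) for _ in range(40)]
        t = _table(spikes, self.sched)
        assert responsiveness(t, self.sched) in (False,)  # same rate everywhere

    def test_strong_response_detected(self):
        rng = np.random.default_rng(2)
        spikes = []
        for _ in range(50):
            base = rng.uniform(-0.25, 0.067, rng.poisson(2 * 0.317))
            ev = rng.uniform(0.067, 1.067, rng.poisson(20 * 1.0))
            spikes.append(np.sort(np.concatenate([base, ev])))
        t = _table(spikes, self.sched)
        assert responsiveness(t, self.sched) is True


class TestLatency:
    def _psth(self, rate):
        t = np.arange(-50.0, 500.0, 1.0)
        return PSTH(t, rate, np.zeros_like(t))

    def test_step_recovered(self):
        t = np.arange(-50.0, 500.0, 1.0)
        from scipy.ndimage import gaussian_filter1d

        step = np.where(t >= 50.0, 50.0, 5.0)
        smoothed = gaussian_filter1d(step, 13.0)
        lat = latency(self._psth(smoothed))
        assert lat == pytest.approx(50.0, abs=6.5)

    def test_flat_none(self):
        assert latency(self._psth(np.full(550, 7.0))) is None

    def test_planted_latency_recovery(self):
        # 50 repeats of the preferred condition only
        from colspike.core import StimulusSchedule
        from colspike.synthetic import (
            ClassArchetype, CohortConfig, TuningSpec, make_cohort, synth_spikes,
        )

        arch = ClassArchetype(
            "L", ttp_width_ms=0.3, repolarization_ms=0.2,
            tuning=TuningSpec(90.0, 0.0, 0.0, 2.0, 20.0, 40.0),
        )
        sched = StimulusSchedule(
            directions_deg=(90.0,), spatial_frequencies_cpd=(1.0,), repeats=50
        )
        cfg = CohortConfig(counts={"L": 8}, archetypes=(arch,), schedule=sched)
        cohort = make_cohort(cfg, 0)
        tables, _ = synth_spikes(cohort, 1)
        for u in cohort.units:
            lat = latency(compute_psth(tables[u.unit_id].spikes))
            assert lat == pytest.approx(40.0, abs=10.0)

    def test_no_baseline_error(self):
        t = np.arange(0.0, 500.0, 1.0)
        with pytest.raises(ValueError):
            latency(PSTH(t, np.zeros_like(t), np.zeros_like(t)))


class TestSelectivityIndices:
    def test_di_values(self):
        assert direction_index(30.0, 10.0) == pytest.approx(0.5)
        assert direction_index(17.0, 0.0) == 1.0
        assert direction_index(9.0, 9.0) == 0.0

    def test_oi_values(self):
        assert orientation_index(40.0, 10.0) == pytest.approx(0.6)
        assert orientation_index(5.0, 5.0) == 0.0

    def test_zero_rates_error(self):
        with pytest.raises(ValueError):
            direction_index(0.0, 0.0)
        with pytest.raises(ValueError):
            orientation_index(0.0, 0.0)

    def test_rate_scale_invariance(self):
        for c in (0.5, 2.0, 11.0):
            assert direction_index(30.0 * c, 10.0 * c) == pytest.approx(0.5)
            assert orientation_index(40.0 * c, 10.0 * c) == pytest.approx(0.6)


class TestModulationRatio:
    def test_sinusoidal_ratio_one(self):
        rng = np.random.default_rng(3)
        f, m, n_trials = 4.0, 30.0, 400
        dt = 1e-4
        t = np.arange(0.0, 1.0, dt)
        rate = m * (1.0 + np.cos(2 * np.pi * f * t))
        trials = []
        for _ in range(n_trials):
            spikes = t[rng.random(t.size) < rate * dt] + 0.067
            trials.append(spikes)
        f1, f0, ratio, _ = modulation_ratio(trials, f)
        assert f0 == pytest.approx(m, rel=0.05)
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_constant_rate_complex(self):
        rng = np.random.default_rng(4)
        trials = [np.sort(rng.uniform(0.067, 1.067, 30)) for _ in range(100)]
        _, _, ratio, form = modulation_ratio(trials, 4.0)
        assert ratio < 0.2
        assert form == "complex"

    def test_ratio_above_one_is_simple(self):
        # spikes locked to the cycle peaks -> strongly modulated
        cycle_starts = 0.067 + np.arange(4) / 4.0
        trials = [cycle_starts + 0.001] * 20
        _, _, ratio, form = modulation_ratio(trials, 4.0)
        assert ratio > 1.0
        assert form == "simple"

    def test_no_spikes_error(self):
        with pytest.raises(ValueError):
            modulation_ratio([np.empty(0)] * 5, 4.0)

    def test_short_stimulus_error(self):
        with pytest.raises(ValueError):
            modulation_ratio([np.empty(0)], 0.5, stimulus_s=1.0)


class TestTuningSummary:
    def test_full_summary(self, tuned_cohort):
        cohort, tables, _ = tuned_cohort
        r = tuning_summary(0, tables[0], cohort.schedule)
        assert r.preferred_direction_deg == pytest.approx(90.0, abs=20.0)
        assert r.DI == pytest.approx(0.8, abs=0.1)
        assert r.OI == pytest.approx(0.6, abs=0.1)
        assert r.responsive is True
        assert r.cell_form in ("simple", "complex")
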