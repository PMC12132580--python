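import numpy as np
import pytest
from scipy.stats import expon, kstest

from colspike.core import LAYER_NAMES, StimulusSchedule
from colspike.laminar import compute_csd
from colspike.propagation import unit_propagation
from colspike.synthetic import (
    BurstModel,
    ClassArchetype,
    CohortConfig,
    CouplingEdge,
    PropagationSpec,
    TuningSpec,
    default_archetypes,
    default_cohort_config,
    direction_modulation,
    make_cohort,
    solve_tuning_shape,
    synth_lfp,
    synth_spikes,
    synth_template,
)


def small_config(**kw):
    return default_cohort_config(2, repeats=2, **kw)


class TestMakeCohort:
    def test_seeded_determinism(self):
        cfg = small_config()
        a = make_cohort(cfg, 42)
        b = make_cohort(cfg, 42)
        assert [u.unit_id for u in a.units] == [u.unit_id for u in b.units]
        for ua, ub in zip(a.units, b.units):
            assert ua.depth_um == ub.depth_um
            assert ua.snr == ub.snr
            np.testing.assert_array_equal(ua.template.voltages, ub.template.voltages)
        assert a.trials.equals(b.trials)

    def test_degenerate_depth_distribution(self):
        arch = ClassArchetype(
            "Z", ttp_width_ms=0.3, repolarization_ms=0.2,
            depth_distribution={"4C": 1.0},
        )
        cfg = CohortConfig(counts={"Z": 30}, archetypes=(arch,))
        cohort = make_cohort(cfg, 1)
        edges = np.asarray(cfg.boundaries.edges_um)
        i = LAYER_NAMES.index("4C")
        anchor = cfg.boundaries.anchor_um
        for u in cohort.units:
            assert edges[i] <= u.depth_um + anchor <= edges[i + 1]
            assert u.layer == "4C"

    def test_counting_and_unique_ids(self):
        cfg = default_cohort_config(20, include_positive=False, repeats=2)
        assert len(cfg.archetypes) == 9
        cohort = make_cohort(cfg, 3)
        ids = [u.unit_id for u in cohort.units]
        assert len(ids) == 180
        assert len(set(ids)) == 180

    def test_empty_archetypes_error(self):
        cfg = CohortConfig(counts={}, archetypes=())
        with pytest.raises(ValueError, match="archetype"):
            make_cohort(cfg, 0)

    def test_unknown_layer_error(self):
        arch = ClassArchetype(
            "Z", ttp_width_ms=0.3, repolarization_ms=0.2,
            depth_distribution={"4Z": 1.0},
        )
        cfg = CohortConfig(counts={"Z": 1}, archetypes=(arch,))
        with pytest.raises(ValueError, match="unknown layer"):
            make_cohort(cfg, 0)


class TestSynthTemplate:
    def test_flat_profile_equal_trough_times(self):
        arch = ClassArchetype(
            "F", ttp_width_ms=0.4, repolarization_ms=0.25,
            propagation_profile=PropagationSpec("flat"),
        )
        t = synth_template(arch, seed=0)
        troughs = np.argmin(t.voltages, axis=0)
        assert np.all(troughs == troughs[0])

    def test_triphasic_two_flanking_maxima(self):
        arch = ClassArchetype(
            "T", triphasic=True, ttp_width_ms=0.35, repolarization_ms=0.22
        )
        w = synth_template(arch, seed=0).soma_waveform
        i_tr = int(np.argmin(w))
        trough = abs(w[i_tr])
        assert w[:i_tr].max() >= 0.3 * trough
        assert w[i_tr:].max() >= 0.3 * trough

    def test_symmetric_profile_zero_asymmetry(self):
        # closed loop with the propagation stage on a noiseless template
        arch = ClassArchetype(
            "S", ttp_width_ms=0.4, repolarization_ms=0.25,
            propagation_profile=PropagationSpec("symmetric", 0.3),
        )
        prof = unit_propagation(synth_template(arch, seed=0))
        assert abs(prof.si_signed) < 0.05

    def test_width_unresolvable_error(self):
        arch = ClassArchetype("W", ttp_width_ms=1.7, repolarization_ms=0.2)
        with pytest.raises(ValueError, match="unresolvable"):
            synth_template(arch, seed=0)

    def test_eleven_channels_soma_center(self):
        t = synth_template(default_archetypes()[0], seed=0)
        assert t.n_channels == 11
        assert t.soma_channel == 5

    def test_width_recovery_all_archetypes(self):
        from colspike.waveform import classical_features, classify_polarity

        for arch in default_archetypes():
            t = synth_template(arch, seed=5, param_jitter=0.0)
            pol, tri = classify_polarity(t.soma_waveform)
            assert pol == arch.polarity
            assert tri == arch.triphasic
            f = classical_features(t.soma_waveform, t.sampling_rate_hz, polarity=pol)
            assert f.ttp_width_ms == pytest.approx(arch.ttp_width_ms, rel=0.1)
            assert f.amplitude_uV == pytest.approx(arch.amplitude_uV, rel=0.05)


class TestTuningShape:
    @pytest.mark.parametrize("di,oi", [(0.8, 0.6), (0.3, 0.5), (0.1, 0.7), (0.5, 0.3)])
    def test_targets_hit(self, di, oi):
        kappa, rho = solve_tuning_shape(di, oi, 3.0, 25.0)
        dirs = np.arange(0, 360, 10.0)
        m = direction_modulation(dirs, 0.0, kappa, rho)
        r = 3.0 + 25.0 * m
        r_p, r_n = r[0], r[18]
        r_o = 0.5 * (r[9] + r[27])
        got_di = (r_p - r_n) / (r_p + r_n)
        o_p = 0.5 * (r_p + r_n)
        got_oi = (o_p - r_o) / (o_p + r_o)
        assert got_di == pytest.approx(di, abs=0.02)
        assert got_oi == pytest.approx(oi, abs=0.02)

    def test_modulation_peaks_at_pref(self):
        kappa, rho = solve_tuning_shape(0.6, 0.4, 2.0, 20.0)
        dirs = np.arange(0, 360, 10.0)
        m = direction_modulation(dirs, 130.0, kappa, rho)
        assert dirs[int(np.argmax(m))] == 130.0
        assert m.max() == pytest.approx(1.0, abs=1e-9)


class TestSynthSpikes:
    def test_determinism(self):
        cfg = small_config()
        c1 = make_cohort(cfg, 5)
        c2 = make_cohort(cfg, 5)
        t1, _ = synth_spikes(c1, 9)
        t2, _ = synth_spikes(c2, 9)
        for u1, u2 in zip(c1.units, c2.units):
            np.testing.assert_array_equal(u1.spike_times_s, u2.spike_times_s)
        for k in t1:
            for a, b in zip(t1[k].spikes, t2[k].spikes):
                np.testing.assert_array_equal(a, b)

    def test_strictly_increasing_and_conservation(self, tuned_cohort):
        cohort, _tables, counts = tuned_cohort
        for u in cohort.units:
            assert np.all(np.diff(u.spike_times_s) > 0)
            assert u.spike_times_s.size == counts.total(u.unit_id)

    def test_conservation_with_bursts_and_coupling(self):
        arch = ClassArchetype(
            "B", ttp_width_ms=0.3, repolarization_ms=0.2,
            burst_model=BurstModel("bursty", 3.0, 3.0, 0.3),
            tuning=TuningSpec(evoked_rate_hz=15.0),
        )
        cfg = CohortConfig(
            counts={"B": 4},
            archetypes=(arch,),
            schedule=StimulusSchedule(repeats=2, spatial_frequencies_cpd=(1.0,)),
            edges=(CouplingEdge(0, 1, lag_ms=2.0, efficacy=0.3),),
        )
        cohort = make_cohort(cfg, 2)
        _, counts = synth_spikes(cohort, 4)
        for u in cohort.units:
            assert u.spike_times_s.size == counts.total(u.unit_id)
        assert counts.coupled_spikes[1] > 0
        assert counts.burst_spikes[0] > 0

    def test_di_recovery(self, tuned_cohort):
        from colspike.tuning import tuning_summary

        cohort, tables, _ = tuned_cohort
        for u in cohort.units:
            r = tuning_summary(u.unit_id, tables[u.unit_id], cohort.schedule)
            assert r.DI == pytest.approx(0.8, abs=0.1)

    def test_poisson_isi_exponential(self):
        arch = ClassArchetype(
            "P", ttp_width_ms=0.3, repolarization_ms=0.2,
            tuning=TuningSpec(baseline_rate_hz=20.0, evoked_rate_hz=0.0),
        )
        cfg = CohortConfig(
            counts={"P": 1}, archetypes=(arch,),
            schedule=StimulusSchedule(repeats=3, spatial_frequencies_cpd=(1.0,)),
        )
        cohort = make_cohort(cfg, 1)
        synth_spikes(cohort, 2)
        isi = np.diff(cohort.units[0].spike_times_s)
        rate = 1.0 / isi.mean()
        assert rate == pytest.approx(20.0, abs=3.0)
        assert kstest(isi, expon(scale=isi.mean()).cdf).pvalue > 0.01

    def test_trial_window_invariant(self, tuned_cohort):
        cohort, tables, _ = tuned_cohort
        lo, hi = tables[0].window
        for sp in tables[0].spikes:
            if sp.size:
                assert sp.min() >= lo and sp.max() <= hi


class TestSynthLFP:
    depths = np.arange(0.0, 2401.0, 20.0)

    def test_planted_reversal_recovered(self):
        lfp, _ = synth_lfp(1000.0, 5.0, self.depths)
        res = compute_csd(lfp, self.depths)
        assert abs(res.reversal_depth_um - 1000.0) <= 20.0

    def test_zero_amplitude(self):
        lfp, _ = synth_lfp(1000.0, 0.0, self.depths)
        assert np.abs(compute_csd(lfp, self.depths).csd).max() == 0.0

    def test_translation_equivariance(self):
        r1 = compute_csd(synth_lfp(1000.0, 5.0, self.depths)[0], self.depths)
        r2 = compute_csd(synth_lfp(1200.0, 5.0, self.depths)[0], self.depths)
        assert r2.reversal_depth_um - r1.reversal_depth_um == pytest.approx(200.0, abs=20.0)

    def test_sink_outside_span_error(self):
        with pytest.raises(ValueError, match="span"):
            synth_lfp(9000.0, 1.0, self.depths)

    def test_too_few_channels_error(self):
        with pytest.raises(ValueError, match="5 channels"):
            synth_lfp(30.0, 1.0, np.arange(0.0, 80.0, 20.0))
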