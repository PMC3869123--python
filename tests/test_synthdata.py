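"""Generator contracts: determinism, arrival arithmetic, closed-form
fluorescence, release statistics and regime-specific behaviour."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from synapse_modes import synthdata as sd
from synapse_modes.core import GroundTruth, StimulusTrain
from synapse_modes.morphology import attachment_distances
from synapse_modes.synthdata import (biexp_kernel, biexp_unit_charge_s,
                                     saturation)


class TestStimulusTrain:
    def test_regular_train_spacing(self):
        st = StimulusTrain.regular(100.0, 1.0, 20.0)
        assert st.spike_times_s.size == 2000
        np.testing.assert_allclose(np.diff(st.spike_times_s), 0.01, atol=1e-6)

    def test_irregular_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            StimulusTrain(100.0, 0.0, 1.0, np.array([0.0, 0.01, 0.025]))

    def test_truncation_keeps_early_spikes(self):
        st = StimulusTrain.regular(100.0, 1.0, 20.0).truncated(5.0)
        assert st.end_time_s == 5.0
        assert st.spike_times_s[-1] < 5.0


class TestCalibration:
    def test_condition_pq_scales(self):
        assert sd.load_calibration("control", 5.0).pq_scale == 1.0
        assert sd.load_calibration("gvia", 5.0).pq_scale == 0.0
        assert 0 < sd.load_calibration("tb204a", 5.0).pq_scale < 1

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            sd.load_calibration("control", 1.0)
        with pytest.raises(ValueError):
            sd.load_calibration("control", 5.0, "gcamp")

    def test_egta_monotonic_front_parameters(self):
        """More EGTA: never-faster front, never-earlier initiation."""
        cfgs = [sd.load_calibration("gvia", e) for e in (0.5, 5.0, 25.0)]
        speeds = [c.wave_speed_um_per_s for c in cfgs]
        onsets = [c.wave_onset_s for c in cfgs]
        assert speeds == sorted(speeds, reverse=True)
        assert onsets == sorted(onsets)

    def test_indicator_affinities(self):
        assert sd.load_calibration("gvia", 0.5, "fluo4").kd_uM == 0.345
        assert sd.load_calibration("gvia", 0.5, "fluo5f").kd_uM == 2.3


class TestMakeMorphology:
    def test_bouton_distances_strictly_increasing(self):
        morph, att = sd.make_morphology(seed=1, n_boutons=12)
        d = attachment_distances(att, morph)
        db = d[d.compartment == "bouton"].distance_um.to_numpy()
        assert db.size == 12
        assert np.all(np.diff(db) > 0)
        assert db.min() > 0 and db.max() <= 150.0

    def test_reference_is_80um_from_soma(self):
        morph, _ = sd.make_morphology(seed=4)
        from synapse_modes.morphology import path_distance
        assert path_distance(morph, morph.reference_node,
                             morph.soma_node) == pytest.approx(80.0)

    def test_same_seed_same_tree(self):
        m1, a1 = sd.make_morphology(seed=9)
        m2, a2 = sd.make_morphology(seed=9)
        assert a1 == a2
        assert [(n.x, n.y, n.z) for n in m1.nodes] == \
               [(n.x, n.y, n.z) for n in m2.nodes]


class TestWaveArrivals:
    def test_gvia_arrival_arithmetic(self):
        """onset 1 s + 74 µm at 74 µm/s -> arrival 2 s after stim start."""
        morph, att = sd.make_morphology(seed=1)
        cfg = sd.load_calibration("gvia", 0.5, wave_onset_s=1.0,
                                  wave_speed_um_per_s=74.0)
        stim = StimulusTrain.regular(100.0, 0.0, 20.0)
        arr = sd.simulate_wave_arrivals(morph, att, cfg, stim)
        d = attachment_distances(att, morph)
        for r in d.itertuples():
            expect = 1.0 + (r.distance_um / 74.0
                            if r.compartment == "bouton" else 0.0)
            assert arr[r.roi_id] == pytest.approx(expect)

    def test_control_arrivals_equal_first_spike(self):
        morph, att = sd.make_morphology(seed=1)
        cfg = sd.load_calibration("control", 0.5)
        stim = StimulusTrain.regular(100.0, 1.0, 20.0)
        arr = sd.simulate_wave_arrivals(morph, att, cfg, stim)
        assert set(arr.values()) == {1.0}

    def test_ttx_arrivals_scale_with_soma_distance(self):
        morph, att = sd.make_morphology(seed=1)
        cfg = sd.load_calibration("ttx", 0.5)
        stim = StimulusTrain.regular(100.0, 1.0, 20.0)
        arr = sd.simulate_wave_arrivals(morph, att, cfg, stim)
        dsoma = attachment_distances(att, morph, origin=morph.soma_node)
        for r in dsoma.itertuples():
            assert arr[r.roi_id] == pytest.approx(
                1.0 + r.distance_um / cfg.ttx_v_slow_um_per_s)

    def test_higher_egta_delays_every_bouton(self):
        """5 mM EGTA arrivals exceed 0.5 mM at every bouton, same seed."""
        morph, att = sd.make_morphology(seed=6)
        stim = StimulusTrain.regular(100.0, 1.0, 20.0)
        a_lo = sd.simulate_wave_arrivals(
            morph, att, sd.load_calibration("gvia", 0.5), stim)
        a_hi = sd.simulate_wave_arrivals(
            morph, att, sd.load_calibration("gvia", 5.0), stim)
        for rid in a_lo:
            assert a_hi[rid] > a_lo[rid]

    def test_fast_front_converges_to_control_profile(self):
        """wave_speed -> inf, wave_onset -> 0 reproduces the AP-driven
        (distance-independent) arrival profile."""
        morph, att = sd.make_morphology(seed=6)
        stim = StimulusTrain.regular(100.0, 1.0, 20.0)
        fast = sd.simulate_wave_arrivals(
            morph, att, sd.load_calibration("gvia", 0.5, wave_onset_s=0.0,
                                            wave_speed_um_per_s=1e9), stim)
        ctrl = sd.simulate_wave_arrivals(
            morph, att, sd.load_calibration("control", 0.5), stim)
        for rid in ctrl:
            assert fast[rid] == pytest.approx(ctrl[rid], abs=1e-6)

    def test_missing_attachment_is_config_error(self):
        morph, att = sd.make_morphology(seed=1)
        from synapse_modes.morphology import MorphologyError, ROIAttachment
        bad = att + [ROIAttachment("stray", 10 ** 6, "bouton")]
        with pytest.raises(MorphologyError):
            sd.simulate_wave_arrivals(morph, bad,
                                      sd.load_calibration("gvia", 0.5),
                                      StimulusTrain.regular(100.0, 1.0, 20.0))


class TestFluorescence:
    def test_noiseless_green_constant_before_arrival(self):
        cfg = sd.load_calibration("gvia", 0.5)
        stim = StimulusTrain.regular(100.0, 1.0, 20.0)
        rois = sd.simulate_fluorescence({"b": 5.0}, cfg, stim, seed=1,
                                        noiseless=True)
        s = rois[0]
        pre = s.green[s.frame_times_s < 5.0]
        expect = cfg.f_rest_au + cfg.f_max_au * saturation(cfg.rest_uM, cfg.kd_uM)
        np.testing.assert_allclose(pre, expect, rtol=1e-12)

    def test_plateau_matches_kd_saturation_closed_form(self):
        """Noiseless plateau ΔG/R equals the saturation value computed by
        hand from kd and the calcium step amplitude."""
        cfg = replace(sd.load_calibration("gvia", 0.5), relax_frac=0.0)
        stim = StimulusTrain.regular(100.0, 1.0, 60.0)
        rois = sd.simulate_fluorescence({"b": 2.0}, cfg, stim, seed=1,
                                        duration_s=50.0, noiseless=True)
        s = rois[0]
        from synapse_modes.imaging import compute_dgr
        dgr = compute_dgr(s)
        ca_plateau = cfg.rest_uM + cfg.bulk_amp_uM
        expect = cfg.f_max_au * (saturation(ca_plateau, cfg.kd_uM)
                                 - saturation(cfg.rest_uM, cfg.kd_uM)) \
            / cfg.red_mean_au
        assert dgr[-1] == pytest.approx(expect, rel=1e-3)

    def test_low_affinity_dye_reports_equal_or_later_onset(self):
        """At identical calcium, a 20%-rise onset with Fluo-5F is never
        earlier than with Fluo-4 (saturation compresses the early rise)."""
        stim = StimulusTrain.regular(100.0, 1.0, 20.0)
        from synapse_modes.imaging import onset_time
        onsets = {}
        for ind in ("fluo4", "fluo5f"):
            cfg = sd.load_calibration("gvia", 0.5, ind)
            rois = sd.simulate_fluorescence({"b": 3.0}, cfg, stim, seed=1,
                                            noiseless=True)
            onsets[ind] = onset_time(rois[0], 0.2, 1.0).onset_time_s
        assert onsets["fluo5f"] >= onsets["fluo4"] - 0.034  # one frame

    def test_determinism(self):
        cfg = sd.load_calibration("control", 0.5)
        cell1 = sd.simulate_cell(cfg, seed=42, with_trace=True)
        cell2 = sd.simulate_cell(cfg, seed=42, with_trace=True)
        pd.testing.assert_frame_equal(cell1.truth.events, cell2.truth.events)
        np.testing.assert_array_equal(cell1.trace.current_pa,
                                      cell2.trace.current_pa)
        np.testing.assert_array_equal(cell1.rois[0].green, cell2.rois[0].green)


class TestRelease:
    def test_no_pq_and_no_front_means_no_events(self):
        cfg = sd.load_calibration("gvia", 0.5, rate_scale=0.0,
                                  spont_rate_hz=0.0)
        stim = StimulusTrain.regular(100.0, 1.0, 20.0)
        truth = sd.simulate_release(stim, {"b": 2.0}, cfg, cfg.quantal, seed=1)
        assert truth.n_events == 0

    def test_sync_events_lie_near_spikes(self, control5_pair):
        cell, _, _ = control5_pair
        ev = cell.truth.events
        sync = ev[ev["mode"] == "sync"]
        spikes = cell.stim.spike_times_s
        lat = sync.time_s.to_numpy() - spikes[
            np.searchsorted(spikes, sync.time_s.to_numpy(), "right") - 1]
        assert lat.max() <= 0.0025  # within the clipped latency jitter

    def test_async_events_only_after_local_arrival(self, gvia5_pair):
        cell, _, _ = gvia5_pair
        ev = cell.truth.events
        asyn = ev[(ev["mode"] == "async")
                  & (ev.time_s > cell.stim.start_time_s)]
        # ignore the spontaneous background: check events allocated to
        # boutons whose front has not yet arrived are (almost) absent
        before = 0
        for r in asyn.itertuples():
            if r.time_s < cell.truth.arrivals_s[r.roi_id]:
                before += 1
        assert before <= 0.05 * len(asyn)

    def test_gvia_charge_is_dominantly_asynchronous(self, gvia5_pair):
        """Ground-truth event charge in the blocked-P/Q condition is >= 85%
        asynchronous (here: essentially all of it)."""
        cell, _, _ = gvia5_pair
        q = cell.truth.charge_by_mode(1.0)
        frac = q["async"] / (q["async"] + q["sync"])
        assert frac >= 0.85

    def test_killswitch_release_persists_past_truncation(self):
        """Stimulus truncated before bouton arrival: events still occur
        after the truncated end."""
        cfg = sd.load_calibration("gvia", 0.5, killswitch_end_s=2.0)
        cell = sd.simulate_cell(cfg, seed=13, with_trace=False)
        after = cell.truth.events.time_s > cell.stim.end_time_s
        assert after.sum() > 50

    def test_amplitudes_positive(self, gvia5_pair):
        cell, _, _ = gvia5_pair
        assert (cell.truth.events.amplitude_pA > 0).all()


class TestRenderTrace:
    def _truth(self, times, amps):
        return GroundTruth(pd.DataFrame({
            "time_s": times, "amplitude_pA": amps,
            "mode": ["async"] * len(times), "roi_id": ["b"] * len(times)}))

    def test_single_event_peak_amplitude(self):
        q = sd.QuantalModel(noise_sd_pA=0.0)
        tr = sd.render_epc_trace(self._truth([1.0], [600.0]), q, seed=1,
                                 duration_s=2.0)
        assert tr.current_pa.min() == pytest.approx(-600.0, rel=1e-3)
        t_min = tr.time_s[np.argmin(tr.current_pa)]
        assert t_min == pytest.approx(1.0, abs=0.001)

    def test_numeric_integral_matches_analytic(self):
        q = sd.QuantalModel(noise_sd_pA=0.0)
        tr = sd.render_epc_trace(self._truth([1.0], [600.0]), q, seed=1,
                                 duration_s=2.0)
        numeric = -np.trapezoid(tr.current_pa, tr.time_s)
        assert numeric == pytest.approx(600.0 * biexp_unit_charge_s(q),
                                        rel=1e-3)

    def test_superposition(self):
        q = sd.QuantalModel(noise_sd_pA=0.0)
        a = sd.render_epc_trace(self._truth([1.0], [600.0]), q, 1, 2.0)
        b = sd.render_epc_trace(self._truth([1.05], [400.0]), q, 1, 2.0)
        both = sd.render_epc_trace(self._truth([1.0, 1.05], [600.0, 400.0]),
                                   q, 1, 2.0)
        np.testing.assert_allclose(both.current_pa,
                                   a.current_pa + b.current_pa, atol=1e-9)

    def test_kernel_is_unit_peak(self):
        q = sd.QuantalModel()
        k = biexp_kernel(q, 1.0 / q.sample_rate_hz)
        assert k.max() == pytest.approx(1.0, abs=0.005)


class TestSynaptopHluorin:
    def test_zero_events_flat_trace(self):
        truth = GroundTruth(pd.DataFrame(
            {"time_s": [], "amplitude_pA": [], "mode": [], "roi_id": []}))
        stim = StimulusTrain.regular(100.0, 1.0, 20.0)
        sph = sd.simulate_sph(truth, ["b0"], seed=1, stim=stim,
                              noiseless=True)
        from synapse_modes.imaging import compute_dff
        np.testing.assert_allclose(compute_dff(sph[0]), 0.0, atol=1e-12)

    def test_cumulative_trace_monotone_before_noise(self, control5_pair):
        cell, _, _ = control5_pair
        sph = sd.simulate_sph(cell.truth, cell.bouton_ids, seed=2,
                              stim=cell.stim, noiseless=True)
        for s in sph:
            assert np.all(np.diff(s.green) >= 0)

    def test_control_and_gvia_rise_distributions_disjoint(self):
        """50%-rise times of exocytosis traces do not overlap between
        control and blocked-P/Q condition cells (5 mM EGTA)."""
        from synapse_modes.imaging import compute_dff, onset_from_series
        t50 = {}
        for cond, seed in (("control", 60), ("gvia", 61)):
            cfg = sd.load_calibration(cond, 5.0)
            cell = sd.simulate_cell(cfg, seed, with_trace=False)
            sph = sd.simulate_sph(cell.truth, cell.bouton_ids, seed,
                                  cell.stim)
            vals = []
            for s in sph:
                y = compute_dff(s)
                on, pk, _ = onset_from_series(s.frame_times_s, y, 0.5,
                                              cell.stim.start_time_s)
                if pk > 0.2:
                    vals.append(on)
            t50[cond] = np.array(vals)
        assert t50["control"].max() < t50["gvia"].min()
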