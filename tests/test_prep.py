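"""Preprocessing: kernel smoothing, double alignment, epoch means, J-space."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import graspspace as g
from graspspace.prep import EPOCH_EVENTS, binned_rates
from graspspace.synth import SessionData


def _manual_session(trials, spikes, kinematics, n_units, kin_rate=50.0):
    """Assemble a minimal SessionData from explicit trial rows and spikes."""
    conditions = pd.DataFrame(
        {
            "id": sorted(set(t["condition_id"] for t in trials)),
            "shape": "cube",
            "size_mm": 20.0,
            "grip_class": "power_cube",
            "block": 3,
        }
    )
    frame = pd.DataFrame(trials)
    frame.insert(0, "trial_id", np.arange(len(trials)))
    units = pd.DataFrame(
        {"unit_id": range(n_units), "area": "AIP", "subarray": "none"}
    )
    return SessionData(
        conditions=conditions,
        units=units,
        trials=frame,
        spikes=spikes,
        kinematics=kinematics,
        seed=0,
        config_hash="manual",
        kin_rate_hz=kin_rate,
    )


def _trial_row(condition_id="31", cue_on=0.6, plan=0.8, reaction=0.2):
    cue_off = cue_on + 0.7
    go = cue_off + plan
    movement = go + reaction
    return {
        "condition_id": condition_id,
        "fixation_on": 0.0,
        "cue_on": cue_on,
        "cue_off": cue_off,
        "go": go,
        "movement_onset": movement,
        "hold_on": movement + 0.3,
        "hold_off": movement + 0.8,
    }


class TestGaussianSmooth:
    def test_single_spike_peak_is_gaussian_density(self):
        sigma = 0.05
        grid = np.linspace(-0.5, 0.5, 1001)
        rate = g.gaussian_smooth(np.array([0.0]), sigma, grid)
        assert rate[500] == pytest.approx(1.0 / (sigma * np.sqrt(2 * np.pi)))

    def test_no_spikes_gives_zero(self):
        rate = g.gaussian_smooth(np.array([]), 0.05, np.linspace(0, 1, 100))
        assert np.all(rate == 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            g.gaussian_smooth(np.array([0.1]), 0.05, np.array([]))

    @given(
        st.lists(st.floats(0.0, 2.0), min_size=1, max_size=40),
        st.sampled_from([0.02, 0.05, 0.3]),
    )
    def test_mass_conservation(self, spikes, sigma):
        """Integral of the smoothed rate equals the spike count (rel 1e-6)."""
        spikes = np.sort(np.asarray(spikes))
        dt = 0.001
        grid = np.arange(-5.5 * sigma, 2.0 + 5.5 * sigma, dt)
        rate = g.gaussian_smooth(spikes, sigma, grid)
        assert np.trapezoid(rate, grid) == pytest.approx(len(spikes), rel=1e-6)

    def test_linearity_over_disjoint_supports(self):
        grid = np.linspace(0, 2, 2001)
        a = np.array([0.2, 0.3])
        b = np.array([1.6, 1.7])
        combined = g.gaussian_smooth(np.concatenate([a, b]), 0.05, grid)
        np.testing.assert_allclose(
            combined,
            g.gaussian_smooth(a, 0.05, grid) + g.gaussian_smooth(b, 0.05, grid),
            atol=1e-12,
        )

    def test_binned_path_matches_exact_kernel(self):
        """The fast binned estimator agrees with the exact kernel sum."""
        rng = np.random.default_rng(1)
        spikes = np.sort(rng.uniform(0.5, 2.5, 40))
        rates, times = binned_rates([spikes], 3.0, 0.001, 0.05)
        exact = g.gaussian_smooth(spikes, 0.05, times)
        assert np.abs(rates[0] - exact).max() < 0.5  # Hz, on ~100 Hz peaks


class TestDoubleAlign:
    def _curves(self, trials, value=5.0, t_stop=4.0, bin_width=0.01):
        n = int(t_stop / bin_width)
        times = (np.arange(n) + 0.5) * bin_width
        return (
            [np.full((1, n), value) for _ in trials],
            [times for _ in trials],
        )

    def test_constant_rate_invariance(self):
        trials = pd.DataFrame([_trial_row(), _trial_row(cue_on=0.75, plan=0.95)])
        trials.insert(0, "trial_id", [0, 1])
        rates, times = self._curves(range(2))
        tensor = g.double_align(
            rates, times, trials, (-0.2, 1.0), (-0.2, 0.9), 0.01
        )
        assert np.all(tensor.rates == 5.0)

    def test_bin_arithmetic(self):
        trials = pd.DataFrame([_trial_row()])
        trials.insert(0, "trial_id", [0])
        rates, times = self._curves(range(1))
        tensor = g.double_align(rates, times, trials, (0.0, 1.0), (0.0, 1.5), 0.01)
        assert tensor.rates.shape[2] == 250
        assert tensor.boundary == 100

    def test_step_at_go_lands_on_segment_boundary(self):
        rows = [_trial_row(cue_on=0.55, plan=0.7), _trial_row(cue_on=0.8, plan=1.0)]
        trials = pd.DataFrame(rows)
        trials.insert(0, "trial_id", [0, 1])
        bin_width = 0.01
        rates, times = [], []
        for row in rows:
            t = (np.arange(400) + 0.5) * bin_width
            r = np.where(t >= row["go"], 10.0, 2.0)[None, :]
            rates.append(r)
            times.append(t)
        tensor = g.double_align(rates, times, trials, (-0.2, 0.5), (-0.2, 0.5), bin_width)
        b = tensor.boundary
        go_zero = b + int(round(0.2 / bin_width))  # first bin at/after go
        assert np.all(tensor.rates[:, :, go_zero:] == 10.0)
        assert np.all(tensor.rates[:, :, go_zero - 1] == 2.0)

    def test_uncovered_trial_dropped_with_warning(self):
        rows = [_trial_row(), _trial_row(cue_on=0.5)]
        trials = pd.DataFrame(rows)
        trials.insert(0, "trial_id", [0, 1])
        rates, times = self._curves(range(2))
        # second trial's curve stops before go + 0.9
        rates[1] = rates[1][:, :150]
        times[1] = times[1][:150]
        with pytest.warns(UserWarning, match="dropped"):
            tensor = g.double_align(rates, times, trials, (-0.2, 1.0), (-0.2, 0.9), 0.01)
        assert tensor.n_trials == 1
        assert tensor.dropped_trials == [1]


class TestEpochMeans:
    def _session_with_counts(self):
        """1 unit, 2 trials: silent in fixation, 20 Hz in hold (trial 0) and
        homogeneous 10 Hz (trial 1)."""
        rows = [_trial_row(), _trial_row()]
        hold_on = rows[0]["hold_on"]
        spikes_t0 = [np.sort(hold_on + np.linspace(0.01, 0.49, 10))]
        rng = np.random.default_rng(0)
        # exactly 10 Hz everywhere: one spike per 100 ms
        t_end = rows[1]["hold_off"]
        spikes_t1 = [np.arange(0.05, t_end, 0.1)]
        kin = [np.zeros((int(t_end * 50) + 1, 27))] * 2
        return _manual_session(rows, [spikes_t0, spikes_t1], kin, n_units=1)

    def test_silent_fixation_twenty_hz_hold(self):
        session = self._session_with_counts()
        nspace = g.epoch_means(session, "hold")
        assert nspace.values[0, 0] == pytest.approx(20.0)

    def test_homogeneous_rate_cancels_after_baseline(self):
        session = self._session_with_counts()
        nspace = g.epoch_means(session, "hold")
        assert nspace.values[1, 0] == pytest.approx(0.0, abs=0.3)

    def test_raw_variant_skips_baseline(self):
        session = self._session_with_counts()
        raw = g.epoch_means(session, "hold", baseline_epoch=None)
        assert raw.values[1, 0] == pytest.approx(10.0, abs=0.3)

    def test_unknown_epoch_rejected(self):
        session = self._session_with_counts()
        with pytest.raises(ValueError, match="unknown epoch"):
            g.epoch_means(session, "reward")

    def test_matches_direct_count_oracle(self, tiny_session):
        """Epoch means equal spike counts / duration computed independently."""
        nspace = g.epoch_means(tiny_session, "cue", baseline_epoch=None)
        start_ev, end_ev = EPOCH_EVENTS["cue"]
        for t in (0, 37, 149):
            row = tiny_session.trials.iloc[t]
            t0, t1 = row[start_ev], row[end_ev]
            for u in (0, 17):
                train = tiny_session.spikes[t][u]
                expected = np.sum((train >= t0) & (train < t1)) / (t1 - t0)
                assert nspace.values[t, u] == pytest.approx(expected)


class TestRateTensorIO:
    def test_npz_sidecar_round_trip(self, tiny_session, tmp_path):
        tensor = g.build_rate_tensor(
            tiny_session,
            bin_width=0.01,
            sigma=0.05,
            window_cue=(-0.1, 0.4),
            window_go=(-0.1, 0.3),
            unit_index=np.array([0, 1]),
        )
        g.save_rate_tensor(tensor, tmp_path / "rates")
        loaded = g.load_rate_tensor(tmp_path / "rates")
        np.testing.assert_array_equal(loaded.rates, tensor.rates)
        np.testing.assert_array_equal(loaded.condition_ids, tensor.condition_ids)
        assert loaded.boundary == tensor.boundary
        assert loaded.window_go == tensor.window_go


class TestJSpace:
    def test_constant_trajectory_passes_through(self):
        rows = [_trial_row()]
        vec = np.linspace(-40, 40, 27)
        t_end = rows[0]["hold_off"]
        kin = [np.tile(vec, (int(t_end * 50) + 1, 1))]
        session = _manual_session(rows, [[np.empty(0)]], kin, n_units=1)
        jspace = g.build_jspace(session)
        np.testing.assert_allclose(jspace.values[0], vec, atol=1e-6)

    def test_wrong_channel_count_rejected(self):
        rows = [_trial_row()]
        kin = [np.zeros((140, 26))]
        session = _manual_session(rows, [[np.empty(0)]], kin, n_units=1)
        with pytest.raises(ValueError, match="27"):
            g.build_jspace(session)

    def test_cutoff_outside_passband_rejected(self, tiny_session):
        with pytest.raises(ValueError, match="passband"):
            g.build_jspace(tiny_session, cutoff_hz=3.0)

    def test_trial_noise_variance_matches_generator(self):
        """Same-condition J rows differ by ~N(0, 2 sigma^2) per channel."""
        cfg = g.GeneratorConfig(
            unit_counts={"AIP": 1, "F5": 1, "M1": 1},
            trials_per_condition=40,
            families=("cube",),
            kinematic_noise_deg=2.0,
        )
        session = g.generate_session(cfg, seed=21)
        jspace = g.build_jspace(session)
        frame = pd.DataFrame(jspace.values)
        frame["condition_id"] = jspace.condition_ids
        pooled = []
        for _, group in frame.groupby("condition_id"):
            resid = group.drop(columns="condition_id") - group.drop(
                columns="condition_id"
            ).mean()
            pooled.append(resid.to_numpy())
        var = np.concatenate(pooled).var(ddof=6)  # 6 condition means removed
        assert var == pytest.approx(4.0, rel=0.25)

    def test_row_order_shared_with_nspace(self, tiny_session):
        jspace = g.build_jspace(tiny_session)
        nspace = g.epoch_means(tiny_session, "hold")
        np.testing.assert_array_equal(jspace.trial_ids, nspace.trial_ids)
        np.testing.assert_array_equal(jspace.condition_ids, nspace.condition_ids)
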