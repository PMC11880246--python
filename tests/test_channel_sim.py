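"""Two-state gating simulator and trace rendering."""

import math

import numpy as np
import pytest
from scipy import stats

from bilayerlab import channel_sim as cs
from bilayerlab.exceptions import DomainError, InputError


def model(**kw):
    defaults = dict(
        conductance_pS=27.37,
        e_rev_mV=52.77,
        k_open_per_s=21.43,
        k_close_per_s=50.0,
    )
    defaults.update(kw)
    return cs.ChannelModel(**defaults)


class TestUnitaryCurrent:
    def test_pure_ca_prediction_matches_reported_amplitude(self):
        """g = 59.55 pS at -50 mV against the 150:15 mM Ca2+ Nernst
        potential predicts the measured -4.58 pA within 5%."""
        e_ca = 25.97 / 2 * math.log(10)
        i = cs.unitary_current(59.55, -50.0, e_ca)
        assert i == pytest.approx(-4.758, abs=0.001)
        assert i == pytest.approx(-4.58, rel=0.05)

    def test_zero_at_reversal(self):
        assert cs.unitary_current(59.55, 29.9, 29.9) == 0.0

    def test_ohmic_product(self):
        assert cs.unitary_current(27.37, 0.0, 52.77) == pytest.approx(-1.444, abs=0.001)

    def test_nonpositive_conductance_rejected(self):
        with pytest.raises(DomainError):
            cs.unitary_current(0.0, -50.0, 0.0)


class TestChannelModelValidation:
    def test_sampling_must_exceed_twice_cutoff(self):
        with pytest.raises(DomainError):
            model(sampling_rate_Hz=1500.0, filter_cutoff_Hz=1000.0)

    @pytest.mark.parametrize(
        "kw",
        [
            {"conductance_pS": -1.0},
            {"k_open_per_s": 0.0},
            {"k_close_per_s": -2.0},
            {"n_channels": 0},
            {"noise_sd_pA": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(DomainError):
            model(**kw)

    def test_from_bath_derives_reversal(self, kcl_bath):
        m = cs.ChannelModel.from_bath(
            27.37, kcl_bath, k_open_per_s=21.43, k_close_per_s=50.0
        )
        assert m.e_rev_mV == pytest.approx(59.80, abs=0.01)


class TestSimulateGating:
    def test_seed_required(self):
        with pytest.raises(InputError):
            cs.simulate_gating(model(), 1000.0)

    def test_reproducible_bitwise(self):
        a = cs.simulate_gating(model(), 5000.0, seed=42)
        b = cs.simulate_gating(model(), 5000.0, seed=42)
        assert np.array_equal(a.open_counts, b.open_counts)
        assert np.array_equal(a.dwells_ms, b.dwells_ms)

    def test_path_tiles_duration_and_alternates(self):
        p = cs.simulate_gating(model(), 20000.0, seed=3)
        assert p.dwells_ms.sum() == pytest.approx(20000.0, rel=1e-12)
        assert np.all(p.dwells_ms > 0)
        assert np.all(p.open_counts[1:] != p.open_counts[:-1])

    def test_symmetric_rates_give_half_open(self):
        m = model(k_open_per_s=40.0, k_close_per_s=40.0)
        p = cs.simulate_gating(m, 300_000.0, seed=11)
        tau_c = 1.0 / (m.k_open_per_s + m.k_close_per_s)
        se = math.sqrt(2 * 0.5 * 0.5 * tau_c / 300.0)
        assert p.open_fraction == pytest.approx(0.5, abs=3 * se)

    def test_stationary_open_fraction(self):
        m = model()
        p_stat = m.open_probability_stationary
        path = cs.simulate_gating(m, 300_000.0, seed=5)
        tau_c = 1.0 / (m.k_open_per_s + m.k_close_per_s)
        se = math.sqrt(2 * p_stat * (1 - p_stat) * tau_c / 300.0)
        assert path.open_fraction == pytest.approx(p_stat, abs=3 * se)

    def test_mean_open_dwell_matches_rate(self):
        m = model()
        path = cs.simulate_gating(m, 300_000.0, seed=6)
        dwells = path.dwell_times_ms("open")[1:-1]  # drop censored ends
        expected_ms = 1000.0 / m.k_close_per_s
        se = dwells.std(ddof=1) / math.sqrt(len(dwells))
        assert dwells.mean() == pytest.approx(expected_ms, abs=3 * se)

    @pytest.mark.parametrize("state, rate", [("open", 50.0), ("closed", 21.43)])
    def test_dwell_times_exponential_ks(self, state, rate):
        """KS test against the exponential at alpha = 0.01, n >= 5000."""
        m = model()
        path = cs.simulate_gating(m, 400_000.0, seed=7)
        dwells = path.dwell_times_ms(state)[1:-1] / 1000.0  # s, drop censored
        assert len(dwells) >= 5000
        res = stats.kstest(dwells, "expon", args=(0, 1.0 / rate))
        assert res.pvalue > 0.01

    def test_multichannel_counts_bounded_and_scaled(self):
        m = model(n_channels=3)
        path = cs.simulate_gating(m, 200_000.0, seed=8)
        assert path.open_counts.min() >= 0
        assert path.open_counts.max() <= 3
        npo = 3 * m.open_probability_stationary
        assert path.mean_open_count == pytest.approx(npo, rel=0.05)


class TestRenderTrace:
    def test_always_open_noiseless_is_constant(self):
        m = model(noise_sd_pA=0.0, filter_cutoff_Hz=None)
        path = cs.GatingPath(
            open_counts=np.array([1]), dwells_ms=np.array([1000.0]),
            total_duration_ms=1000.0,
        )
        tr = cs.render_trace(path, m, holding_mV=-50.0)
        assert tr.n_samples == 10000
        assert np.all(tr.current_pA == m.unitary_current(-50.0))

    def test_closed_trace_noise_mean_near_zero(self):
        m = model(noise_sd_pA=0.8, filter_cutoff_Hz=None)
        path = cs.GatingPath(
            open_counts=np.array([0]), dwells_ms=np.array([2000.0]),
            total_duration_ms=2000.0,
        )
        tr = cs.render_trace(path, m, holding_mV=-50.0, seed=9)
        n = tr.n_samples
        assert abs(tr.current_pA.mean()) < 3 * 0.8 / math.sqrt(n)

    def test_filter_reduces_noise_power(self):
        path = cs.GatingPath(
            open_counts=np.array([0]), dwells_ms=np.array([2000.0]),
            total_duration_ms=2000.0,
        )
        raw = cs.render_trace(
            path, model(filter_cutoff_Hz=None), holding_mV=0.0, seed=10
        )
        filt = cs.render_trace(
            path, model(filter_cutoff_Hz=1000.0), holding_mV=0.0, seed=10
        )
        assert np.mean(filt.current_pA**2) < np.mean(raw.current_pA**2)

    def test_seed_required_with_noise(self):
        path = cs.GatingPath(
            open_counts=np.array([0]), dwells_ms=np.array([100.0]),
            total_duration_ms=100.0,
        )
        with pytest.raises(InputError):
            cs.render_trace(path, model(), holding_mV=0.0)

    def test_reproducible_bitwise(self):
        a = cs.simulate_trace(model(), 2000.0, -50.0, seed=77)
        b = cs.simulate_trace(model(), 2000.0, -50.0, seed=77)
        assert np.array_equal(a.current_pA, b.current_pA)

    def test_subsample_events_can_vanish(self):
        """An opening much shorter than a sample period leaves no sample."""
        m = model(noise_sd_pA=0.0, filter_cutoff_Hz=None)
        path = cs.GatingPath(
            open_counts=np.array([0, 1, 0]),
            dwells_ms=np.array([10.05, 0.02, 9.93]),
            total_duration_ms=20.0,
        )
        tr = cs.render_trace(path, m, holding_mV=-50.0)
        assert np.all(tr.current_pA == 0.0)


class TestGatingPathValidation:
    def test_rejects_nonpositive_dwells(self):
        with pytest.raises(InputError):
            cs.GatingPath(
                open_counts=np.array([0, 1]),
                dwells_ms=np.array([5.0, 0.0]),
                total_duration_ms=5.0,
            )

    def test_rejects_repeated_counts(self):
        with pytest.raises(InputError):
            cs.GatingPath(
                open_counts=np.array([1, 1]),
                dwells_ms=np.array([5.0, 5.0]),
                total_duration_ms=10.0,
            )

    def test_rejects_mismatched_total(self):
        with pytest.raises(InputError):
            cs.GatingPath(
                open_counts=np.array([0, 1]),
                dwells_ms=np.array([5.0, 5.0]),
                total_duration_ms=11.0,
            )
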