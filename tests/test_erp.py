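"""ERP chain: rejection, baselining, window amplitudes, group statistics."""

import numpy as np
import pandas as pd
import pytest

from closurenet.containers import EpochSet
from closurenet.erp import (
    DEFAULT_WINDOWS,
    baseline_and_average,
    component_correlations,
    component_stats,
    mixed_anova_oracle_frame,
    reject_artifacts,
    window_amplitude,
)
from closurenet.simulate import EegSimConfig, simulate_eeg_epochs


def _flat_epochs(n_trials=4, value=0.0, sfreq=500.0):
    times = np.arange(-100, 501, 1000 / sfreq)
    data = np.full((n_trials, 4, len(times)), value)
    return EpochSet(data=data, times=times, ch_names=["PO5", "PO6", "PO7", "PO8"],
                    conditions=["ID"] * n_trials, sfreq=sfreq)


class TestRejectArtifacts:
    def test_excursion_above_limit_rejected_at_limit_retained(self):
        epochs = _flat_epochs(3)
        t200 = np.argmin(np.abs(epochs.times - 200))
        epochs.data[0, 1, t200] = 130.0   # above limit -> rejected
        epochs.data[1, 2, t200] = 120.0   # exactly at limit -> retained
        accepted, log = reject_artifacts(epochs, limit_uV=120.0)
        assert accepted.n_trials == 2
        assert np.max(np.abs(accepted.data)) <= 120.0
        assert log.loc[log.condition == "ID", "n_rejected"].item() == 1

    def test_clean_set_unchanged_and_idempotent(self):
        epochs = _flat_epochs(5, value=10.0)
        once, _ = reject_artifacts(epochs)
        twice, _ = reject_artifacts(once)
        np.testing.assert_array_equal(once.data, epochs.data)
        np.testing.assert_array_equal(twice.data, once.data)

    def test_window_outside_epochs_rejected(self):
        with pytest.raises(ValueError):
            reject_artifacts(_flat_epochs(), window_ms=(-500, 500))


class TestBaselineAndAverage:
    def test_constant_offset_removed(self):
        epochs = _flat_epochs(4, value=7.5)
        evoked = baseline_and_average(epochs)["ID"]
        np.testing.assert_allclose(evoked.data, 0.0, atol=1e-12)

    def test_baseline_interval_mean_exactly_zero_per_trial(self, rng):
        epochs = _flat_epochs(6)
        epochs.data = rng.normal(0, 20, size=epochs.data.shape)
        bmask = epochs.time_mask(-100, 0)
        base = epochs.data - epochs.data[:, :, bmask].mean(axis=2, keepdims=True)
        np.testing.assert_allclose(base[:, :, bmask].mean(axis=2), 0.0, atol=1e-12)

    def test_average_of_opposite_epochs_is_zero(self, rng):
        epochs = _flat_epochs(2)
        sig = rng.normal(0, 5, size=epochs.data.shape[1:])
        sig -= sig[:, epochs.time_mask(-100, 0)].mean(axis=1, keepdims=True)
        epochs.data[0] = sig
        epochs.data[1] = -sig
        evoked = baseline_and_average(epochs)["ID"]
        np.testing.assert_allclose(evoked.data, 0.0, atol=1e-12)

    def test_against_mne_reference(self):
        mne = pytest.importorskip("mne")
        cfg = EegSimConfig(noise_sd=5.0, sfreq=512.0)
        epochs = simulate_eeg_epochs(cfg, ["ID"] * 20, seed=3)
        evoked = baseline_and_average(epochs)["ID"]
        info = mne.create_info(epochs.ch_names, sfreq=epochs.sfreq, ch_types="eeg")
        arr = mne.EpochsArray(epochs.data * 1e-6, info,
                              tmin=epochs.times[0] / 1000.0, baseline=(None, 0),
                              verbose=False)
        ref = arr.average().data * 1e6
        np.testing.assert_allclose(evoked.data, ref, atol=1e-6)


class TestWindowAmplitude:
    def test_flat_zero_gives_zero(self):
        evoked = baseline_and_average(_flat_epochs())["ID"]
        amps = window_amplitude(evoked, DEFAULT_WINDOWS["N1"])
        assert amps == {"left": 0.0, "right": 0.0}

    def test_noiseless_injection_recovered_exactly(self):
        cfg = EegSimConfig(noise_sd=0.0)
        epochs = simulate_eeg_epochs(cfg, ["Repeat"], seed=0, group="control")
        evoked = baseline_and_average(epochs)["Repeat"]
        for comp in ("P1", "N1", "Ncl"):
            amps = window_amplitude(evoked, DEFAULT_WINDOWS[comp])
            expected = cfg.components[comp].amplitudes["control"]["Repeat"]
            assert amps["left"] == pytest.approx(expected, abs=1e-6)
            assert amps["right"] == pytest.approx(expected, abs=1e-6)

    def test_linear_in_signal(self, rng):
        epochs = _flat_epochs(1)
        epochs.data = rng.normal(0, 3, size=epochs.data.shape)
        ev = baseline_and_average(epochs)["ID"]
        a1 = window_amplitude(ev, DEFAULT_WINDOWS["Ncl"])
        ev.data = ev.data * 2
        a2 = window_amplitude(ev, DEFAULT_WINDOWS["Ncl"])
        assert a2["left"] == pytest.approx(2 * a1["left"])

    def test_missing_electrode_error(self):
        evoked = baseline_and_average(_flat_epochs())["ID"]
        bad = DEFAULT_WINDOWS["N1"].__class__("N1", (170, 200), ("PO9",), -1)
        with pytest.raises(ValueError):
            window_amplitude(evoked, bad)


def _amplitude_frame(rng, n_control=21, n_patient=19, group_shift=0.0, noise=2.0):
    rows = []
    for g, n in [("control", n_control), ("patient", n_patient)]:
        for s in range(n):
            for c in ["ID", "ID-1", "Repeat"]:
                mu = -5 + (group_shift if g == "patient" else 0) \
                    + (0.5 if c == "Repeat" else 0)
                rows.append({"subject": f"{g}{s}", "group": g, "condition": c,
                             "component": "N1", "hemisphere": "left",
                             "amplitude": rng.normal(mu, noise)})
    return pd.DataFrame(rows)


class TestComponentStats:
    def test_zero_effect_zero_noise_degenerate_gives_f_zero(self, rng):
        df = _amplitude_frame(rng)
        df["amplitude"] = 1.0
        res = component_stats(df)
        assert (res["F"] == 0.0).all()
        assert (res["p"] == 1.0).all()

    def test_matches_mixed_anova_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        df = _amplitude_frame(rng, group_shift=1.0)
        mine = component_stats(df).set_index("effect")
        long = mixed_anova_oracle_frame(df)
        ora = pg.mixed_anova(data=long, dv="amplitude", within="condition",
                             between="group", subject="subject").set_index("Source")
        for eff, src in [("group", "group"), ("condition", "condition"),
                         ("group * condition", "Interaction")]:
            assert mine.loc[eff, "F"] == pytest.approx(ora.loc[src, "F"], abs=1e-8)
            assert mine.loc[eff, "p"] == pytest.approx(ora.loc[src, "p_unc"], abs=1e-8)

    def test_one_sd_group_shift_detected_in_80pct_of_replicates(self):
        hits = 0
        n_rep = 25
        for r in range(n_rep):
            rng = np.random.default_rng(5000 + r)
            df = _amplitude_frame(rng, n_control=20, n_patient=20,
                                  group_shift=2.0, noise=2.0)  # 1 pooled SD
            res = component_stats(df).set_index("effect")
            hits += res.loc["group", "p"] < 0.05
        assert hits / n_rep >= 0.8

    def test_too_few_subjects_error(self, rng):
        df = _amplitude_frame(rng, n_control=1, n_patient=5)
        with pytest.raises(ValueError):
            component_stats(df)

    def test_cohens_d_sign_follows_group_difference(self, rng):
        df = _amplitude_frame(rng, group_shift=3.0, noise=0.5)
        res = component_stats(df).set_index("effect")
        # control mean (-5) below patient mean (-2): control - patient < 0
        assert res.loc["group", "cohens_d"] < 0


class TestComponentCorrelations:
    def test_perfect_correlation(self, rng):
        rows = []
        for s in range(8):
            x = rng.normal()
            for comp, val in [("P1", x), ("Ncl", x)]:
                rows.append({"subject": f"s{s}", "group": "control",
                             "condition": "ID", "component": comp,
                             "hemisphere": "left", "amplitude": val})
        res = component_correlations(pd.DataFrame(rows))
        assert res["r"].item() == pytest.approx(1.0)

    def test_matches_covariance_formula_on_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        rows = []
        for s, (a, b) in enumerate(zip(x, y)):
            rows.append({"subject": f"s{s}", "group": "g", "condition": "ID",
                         "component": "P1", "hemisphere": "left", "amplitude": a})
            rows.append({"subject": f"s{s}", "group": "g", "condition": "ID",
                         "component": "N1", "hemisphere": "left", "amplitude": b})
        res = component_correlations(pd.DataFrame(rows))
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert res["r"].item() == pytest.approx(r_hand, abs=1e-12)

    def test_independent_components_near_zero(self, rng):
        rows = []
        for s in range(1000):
            for comp in ("P1", "Ncl"):
                rows.append({"subject": f"s{s}", "group": "g", "condition": "ID",
                             "component": comp, "hemisphere": "left",
                             "amplitude": rng.normal()})
        res = component_correlations(pd.DataFrame(rows))
        assert abs(res["r"].item()) < 0.1


class TestFullChainRecovery:
    def test_group_condition_pattern_recovered_at_low_noise(self):
        from closurenet.erp import amplitude_table

        cfg = EegSimConfig(noise_sd=0.5, n_trials=20)
        evoked_by_subject, groups = {}, {}
        for g in ("control", "patient"):
            for s in range(3):
                subject = f"{g}{s}"
                labels = [c for c in ("ID", "ID-1", "Repeat") for _ in range(cfg.n_trials)]
                seed = s + (0 if g == "control" else 100)
                epochs = simulate_eeg_epochs(cfg, labels, seed=seed,
                                             group=g, subject=subject)
                accepted, _ = reject_artifacts(epochs)
                evoked_by_subject[subject] = baseline_and_average(accepted)
                groups[subject] = g
        table = amplitude_table(evoked_by_subject, groups)
        cell = table.groupby(["group", "condition", "component"])["amplitude"].mean()
        # closure negativity reduced (less negative) in patients
        assert cell["patient", "ID", "Ncl"] > cell["control", "ID", "Ncl"]
        # repetition enhances N1 negativity in both groups
        for g in ("control", "patient"):
            assert cell[g, "Repeat", "N1"] < cell[g, "ID", "N1"]
        # P1 repetition suppression only in controls
        assert cell["control", "Repeat", "P1"] < cell["control", "ID", "P1"] - 0.3
        assert abs(cell["patient", "Repeat", "P1"] - cell["patient", "ID", "P1"]) < 0.3
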