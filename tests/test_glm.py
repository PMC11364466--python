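import numpy as np
import pandas as pd
import pytest

from camwm.glm import (
    aggregate_to_networks,
    betas_to_table,
    build_design,
    detect_outlier_participants,
    double_gamma_hrf,
    estimate_betas,
)


@pytest.fixture()
def events():
    rows = []
    for k, onset in enumerate([10.0, 45.0, 80.0]):
        rows += [
            dict(trial_index=k, phase="encoding", onset=onset, duration=2.0),
            dict(trial_index=k, phase="delay", onset=onset + 2, duration=8.0),
            dict(trial_index=k, phase="response", onset=onset + 10, duration=3.0),
        ]
    return pd.DataFrame(rows)


class TestHRF:
    def test_first_gamma_peaks_at_five_seconds(self):
        # gamma(shape 6, scale 1) has mode (a-1)b = 5
        t, h = double_gamma_hrf(tr=0.1, ratio=0.0, oversample=10)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.05)

    def test_peak_normalized_to_one(self):
        _, h = double_gamma_hrf(tr=1.0)
        assert h.max() == pytest.approx(1.0)

    def test_tail_near_zero_at_32s(self):
        t, h = double_gamma_hrf(tr=1.0, length=32.0)
        assert abs(h[-1]) < 0.01

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            double_gamma_hrf(tr=1.0, peak_delay=-1)


class TestBuildDesign:
    def test_empty_events_gives_intercept_and_drift(self):
        d = build_design(pd.DataFrame(columns=["phase", "onset", "duration"]),
                         tr=1.0, n_frames=50)
        assert d.labels == ["intercept", "drift"]

    def test_phase_columns_present(self, events):
        d = build_design(events, tr=1.0, n_frames=120)
        assert [l for l in d.labels if l.startswith("phase:")] == \
            ["phase:encoding", "phase:delay", "phase:response"]

    def test_motion_expands_to_18_columns(self, events):
        rng = np.random.default_rng(0)
        d = build_design(events, tr=1.0, n_frames=120, motion=rng.normal(size=(120, 6)))
        assert sum(l.startswith(("mot", "dmot")) for l in d.labels) == 18

    def test_outlier_trial_removed_from_phase_regressors(self, events):
        flagged = events.assign(is_outlier_trial=events["trial_index"] == 1)
        d_flagged = build_design(flagged, tr=1.0, n_frames=120)
        deleted = events[events["trial_index"] != 1]
        d_deleted = build_design(deleted, tr=1.0, n_frames=120)
        for phase in ("encoding", "delay", "response"):
            np.testing.assert_allclose(d_flagged.column(f"phase:{phase}"),
                                       d_deleted.column(f"phase:{phase}"))
        assert any(l.startswith("fir:trial1") for l in d_flagged.labels)

    def test_rank_deficiency_names_columns(self, events):
        motion = np.zeros((120, 6))  # all-zero nuisance columns are collinear
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            build_design(events, tr=1.0, n_frames=120, motion=motion)

    def test_onset_outside_scan_rejected(self, events):
        with pytest.raises(ValueError):
            build_design(events, tr=1.0, n_frames=50)


class TestEstimateBetas:
    def test_noiseless_recovery(self, events):
        d = build_design(events, tr=1.0, n_frames=120)
        beta_true = np.linspace(0.5, 2.0, len(d.labels))
        y = d.matrix @ beta_true
        est, resid_var = estimate_betas(y, d)
        np.testing.assert_allclose(est["unit0"].to_numpy(), beta_true, atol=1e-8)
        assert resid_var["unit0"] == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_unbiasedness(self, events):
        d = build_design(events, tr=1.0, n_frames=120)
        beta_true = np.ones(len(d.labels))
        signal = d.matrix @ beta_true
        rng = np.random.default_rng(42)
        y = signal[:, None] + rng.normal(0, 1.0, size=(120, 200))
        est, _ = estimate_betas(y, d)
        i = d.labels.index("phase:delay")
        se = est.loc["phase:delay"].std(ddof=1) / np.sqrt(200)
        assert abs(est.loc["phase:delay"].mean() - 1.0) < 3 * se

    def test_residuals_orthogonal_to_design(self, events):
        d = build_design(events, tr=1.0, n_frames=120)
        rng = np.random.default_rng(1)
        y = rng.normal(size=(120, 3))
        est, _ = estimate_betas(y, d)
        resid = y - d.matrix @ est.to_numpy()
        assert np.abs(d.matrix.T @ resid).max() < 1e-8

    def test_unit_permutation_equivariance(self, events):
        d = build_design(events, tr=1.0, n_frames=120)
        rng = np.random.default_rng(2)
        y = rng.normal(size=(120, 4))
        est, _ = estimate_betas(y, d, unit_labels=["a", "b", "c", "d"])
        est_perm, _ = estimate_betas(y[:, [2, 0, 3, 1]], d,
                                     unit_labels=["c", "a", "d", "b"])
        pd.testing.assert_frame_equal(est[["a", "b", "c", "d"]],
                                      est_perm[["a", "b", "c", "d"]])

    def test_nans_require_mask(self, events):
        d = build_design(events, tr=1.0, n_frames=120)
        y = np.zeros((120, 1))
        y[3, 0] = np.nan
        with pytest.raises(ValueError):
            estimate_betas(y, d)
        est, _ = estimate_betas(y, d, mask_nan=True)
        assert np.isfinite(est.to_numpy()).all()


class TestAggregation:
    def _table(self, betas_by_region):
        return pd.DataFrame([
            dict(participant_id="p1", study_id="s1", unit=r, phase="delay", beta=b)
            for r, b in betas_by_region.items()])

    def test_mean_within_network(self):
        out = aggregate_to_networks(self._table({"r1": 1.0, "r2": 2.0, "r3": 3.0}),
                                    {"r1": "net", "r2": "net", "r3": "net"})
        assert out["beta"].iloc[0] == pytest.approx(2.0)

    def test_singleton_networks_identity(self):
        t = self._table({"r1": 1.0, "r2": 2.0})
        out = aggregate_to_networks(t, {"r1": "n1", "r2": "n2"})
        assert sorted(out["beta"]) == [1.0, 2.0]

    def test_grand_mean_conserved_with_equal_counts(self):
        t = self._table({"r1": 1.0, "r2": 3.0, "r3": 5.0, "r4": 7.0})
        out = aggregate_to_networks(t, {"r1": "a", "r2": "a", "r3": "b", "r4": "b"})
        assert out["beta"].mean() == pytest.approx(t["beta"].mean())

    def test_unmapped_region_is_an_error(self):
        with pytest.raises(KeyError, match="r2"):
            aggregate_to_networks(self._table({"r1": 1.0, "r2": 2.0}), {"r1": "n"})

    def test_betas_to_table_extracts_phases(self, events):
        d = build_design(events, tr=1.0, n_frames=120)
        est, _ = estimate_betas(np.zeros((120, 2)), d, unit_labels=["r1", "r2"])
        table = betas_to_table(est, "p1", "s1")
        assert set(table["phase"]) == {"encoding", "delay", "response"}
        assert len(table) == 6


class TestOutlierDetection:
    def _maps(self, n=11, flip=None):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        rows = []
        for i in range(n):
            v = -base if i == flip else base
            for phase in ("encoding", "delay"):
                for j, b in enumerate(v):
                    rows.append(dict(participant_id=f"p{i:02d}", unit=f"r{j}",
                                     phase=phase, beta=b))
        return pd.DataFrame(rows)

    def test_sign_flipped_participant_flagged(self):
        excluded, review, _ = detect_outlier_participants(self._maps(flip=4))
        assert excluded == ["p04"]
        assert review == []

    def test_identical_maps_exclude_nobody(self):
        excluded, _, corr = detect_outlier_participants(self._maps(flip=None))
        assert excluded == []
        assert (corr["correlation"] == 1.0).all()

    def test_infinite_threshold_excludes_nobody(self):
        excluded, _, _ = detect_outlier_participants(self._maps(flip=4),
                                                     threshold_sd=np.inf)
        assert excluded == []

    def test_zero_variance_map_goes_to_review(self):
        maps = self._maps()
        maps.loc[maps["participant_id"] == "p03", "beta"] = 7.0
        excluded, review, _ = detect_outlier_participants(maps)
        assert "p03" in review and "p03" not in excluded

    def test_participant_order_equivariance(self):
        maps = self._maps(flip=4)
        shuffled = maps.sample(frac=1.0, random_state=0)
        assert detect_outlier_participants(maps)[0] == \
            detect_outlier_participants(shuffled)[0]

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            detect_outlier_participants(self._maps(n=2))
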