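"""Feature builders: DTTAPS, transforms, vector contracts, labels."""

import numpy as np
import pytest

from submovekit.features import (
    AMPLITUDE_FEATURES,
    DURATION_FEATURES,
    INITIATION_FEATURES,
    SubmovementContext,
    build_amplitude_features,
    build_duration_features,
    build_initiation_features,
    build_training_tables,
    dttaps,
    feature_columns,
    signed_fourth_root,
    time_decay,
)
from submovekit.minjerk import Submovement


def make_ctx(start=(0, 0, 0), target=(30, 0, 40), subs=(), t_now=0.0, v=(0, 0, 0), a=(0, 0, 0), p=None):
    start = np.asarray(start, float)
    return SubmovementContext(
        start=start,
        target=np.asarray(target, float),
        initiated=list(subs),
        t_now=t_now,
        fingertip_p=start.copy() if p is None else np.asarray(p, float),
        fingertip_v=np.asarray(v, float),
        fingertip_a=np.asarray(a, float),
    )


class TestDttaps:
    def test_first_submovement_is_start_target_distance(self):
        assert dttaps(make_ctx(), 1) == pytest.approx(50.0)  # 3-4-5 scaled

    def test_later_submovement_subtracts_prior_amplitudes(self):
        sub = Submovement(0.0, 0.5, np.array([6.0, 0, 0]))
        ctx = make_ctx(target=(10, 0, 0), subs=[sub], t_now=0.6)
        assert dttaps(ctx, 2) == pytest.approx(4.0)

    def test_floor_when_priors_reach_target(self):
        sub = Submovement(0.0, 0.5, np.array([10.0, 0, 0]))
        ctx = make_ctx(target=(10, 0, 0), subs=[sub], t_now=0.6)
        assert dttaps(ctx, 2) == 0.1


class TestTransforms:
    @pytest.mark.parametrize("x,expected", [(16.0, 2.0), (-16.0, -2.0), (0.0, 0.0)])
    def test_signed_fourth_root(self, x, expected):
        assert signed_fourth_root(x) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "t,expected", [(0.0, 1.0), (0.05, np.exp(-1)), (1.0, np.exp(-20.0))]
    )
    def test_time_decay(self, t, expected):
        assert time_decay(t) == pytest.approx(expected)


class TestFeatureVectors:
    def test_fixed_lengths(self):
        # 15 pairwise distances + 6 timing/flags; 6 3D pairs * 3 + 6; C(5,2) + 2
        assert len(INITIATION_FEATURES) == 21
        assert len(AMPLITUDE_FEATURES) == 24
        assert len(DURATION_FEATURES) == 12

    def test_initiation_at_submovement_onset(self):
        sub = Submovement(0.0, 0.5, np.array([20.0, 0, 0]))
        ctx = make_ctx(subs=[sub], t_now=0.0)
        row = dict(zip(INITIATION_FEATURES, build_initiation_features(ctx)))
        assert row["t_since_onset"] == 0.0
        assert row["t_since_decay"] == 1.0
        assert row["t_remaining_norm"] == 1.0

    def test_in_target_flag(self):
        sub = Submovement(0.0, 0.5, np.array([30.0, 0, 40.0]))
        ctx = make_ctx(subs=[sub], t_now=0.5, p=(29.5, 0, 39.5))  # within 1.27 cm
        row = dict(zip(INITIATION_FEATURES, build_initiation_features(ctx)))
        assert row["in_target_now"] == 1.0
        assert row["in_target_planned"] == 1.0

    def test_amplitude_self_normalization(self):
        ctx = make_ctx(target=(50.0, 0, 0))
        feats, norm = build_amplitude_features(ctx, 1)
        row = dict(zip(AMPLITUDE_FEATURES, feats))
        assert norm == pytest.approx(50.0)
        assert (row["dx_start_target"], row["dy_start_target"], row["dz_start_target"]) == (
            pytest.approx(1.0), 0.0, 0.0,
        )

    def test_at_rest_kinematic_features_are_zero(self):
        feats, _ = build_amplitude_features(make_ctx(), 1)
        assert np.all(feats[-6:] == 0)
        dur = build_duration_features(make_ctx(), 1)
        assert np.all(dur[-2:] == 0)

    def test_coincident_positions_give_zero_distances(self):
        ctx = make_ctx(target=(0, 0, 0))
        dur = build_duration_features(ctx, 1)
        assert np.all(dur[:10] == 0)


class TestTrainingTables:
    @pytest.fixture(scope="class")
    def tables(self, decomposed_corpus):
        ds, truths, decomps, cfgs = decomposed_corpus
        return build_training_tables(ds, decomps), ds, decomps

    def test_row_counts(self, tables):
        (init_t, amp_t, dur_t), ds, decomps = tables
        n_subs = sum(len(d.submovements) for d in decomps.values())
        assert len(amp_t) == n_subs
        assert len(dur_t) == n_subs
        assert len(init_t) > len(amp_t)  # one row per timestep per window

    def test_labels_zero_before_next_onset(self, tables):
        (init_t, _, _), _, _ = tables
        before = init_t[init_t["meta_t"] < init_t["meta_t_next"] - 1e-9]
        assert (before["initiate__label"] == 0).all()
        after = init_t[init_t["meta_t"] >= init_t["meta_t_next"] - 1e-9]
        assert (after["initiate__label"] == 1).all()

    def test_feature_lengths_constant(self, tables):
        (init_t, amp_t, dur_t), _, _ = tables
        assert len(feature_columns(init_t)) == 21
        assert len(feature_columns(amp_t)) == 24
        assert len(feature_columns(dur_t)) == 12
        for t in (init_t, amp_t, dur_t):
            assert np.isfinite(t[feature_columns(t)].to_numpy()).all()

    def test_first_submovement_labels_undershoot(self, tables):
        """DTTAPS-normalized first-submovement amplitudes stay near or below
        1: submovements rarely exceed the remaining distance to target."""
        (_, amp_t, _), _, _ = tables
        first = amp_t[amp_t["meta_k"] == 1]
        mags = np.linalg.norm(first[["ax__label", "ay__label", "az__label"]].to_numpy(), axis=1)
        assert np.all(mags <= 1.3)
        assert np.mean(mags < 1.0) > 0.8

    def test_causality_row_reproducible_from_past_data(self, tables):
        """Recomputing a row's features from data at times <= its timestamp
        reproduces it exactly."""
        (init_t, _, _), ds, decomps = tables
        row = init_t.iloc[len(init_t) // 2]
        trial = next(tr for tr in ds.retained if tr.trial_id == row["meta_trial"])
        subs = sorted(decomps[trial.trial_id].submovements, key=lambda s: s.t0)
        k = int(row["meta_k"])
        t = float(row["meta_t"])
        i = int(round((t - trial.t.samples[0]) / trial.t.dt))
        ctx = SubmovementContext(
            trial.start, trial.target, subs[:k], t, trial.p[i], trial.v[i], trial.a[i]
        )
        assert all(s.t0 <= t + 1e-9 for s in ctx.initiated)
        recomputed = build_initiation_features(ctx)
        assert recomputed == pytest.approx(row[list(INITIATION_FEATURES)].to_numpy(float))
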