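"""MRIC matching, the zero-training classifier, and two-round selection."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icabci.mric import (DetectionFilterSet, MatchingError, SelectionReport,
                         _rank_kept, affected_windows, build_ica_s,
                         build_ica_t, classify_trial, evaluate_filters,
                         match_mrics, second_round_select)
from icabci.infomax import IcaConfig
from icabci.preprocessing import NINE_CHANNEL_SCHEME, TrialSet

NINE = list(NINE_CHANNEL_SCHEME.labels)  # FC3 FCz FC4 C3 Cz C4 CP3 CPz CP4
ROW = {lab: i for i, lab in enumerate(NINE)}


def make_A(peaks):
    """9x9 matrix whose column j has its largest |entry| at channel peaks[j]."""
    rng = np.random.default_rng(0)
    A = 0.2 * rng.standard_normal((9, 9))
    for j, lab in enumerate(peaks):
        A[ROW[lab], j] = 2.0 + 0.1 * j
    return A


class TestMatchMrics:
    def test_good_trial_assignment(self):
        """Columns 1, 3, 7 peaking at Cz, C3, C4 are matched to those roles."""
        peaks = ["FC3", "Cz", "FCz", "C3", "CP3", "CPz", "FC4", "C4", "CP4"]
        A = make_A(peaks)
        a = match_mrics(A, NINE)
        assert a.matched
        assert (a.ic_C3, a.ic_Cz, a.ic_C4) == (3, 1, 7)

    def test_identity_matches_basis_columns(self):
        a = match_mrics(np.eye(9), NINE)
        assert a.matched
        assert (a.ic_C3, a.ic_Cz, a.ic_C4) == (ROW["C3"], ROW["Cz"], ROW["C4"])

    def test_all_columns_peaking_elsewhere_unmatched(self):
        A = make_A(["FCz"] * 9)
        assert not match_mrics(A, NINE).matched

    def test_tie_rule_prefers_larger_projection(self):
        """Two columns peaking at C3: the larger magnitude wins."""
        A = make_A(["C3", "Cz", "C4", "C3", "FC3", "FCz", "FC4", "CP3", "CPz"])
        A[ROW["C3"], 0] = 5.0   # column 0 beats column 3 at C3
        a = match_mrics(A, NINE)
        assert a.matched and a.ic_C3 == 0

    def test_sign_is_ignored(self):
        A = np.eye(9)
        A[ROW["C3"], ROW["C3"]] = -3.0
        assert match_mrics(A, NINE).matched

    def test_missing_motor_channel_raises(self):
        with pytest.raises(MatchingError):
            match_mrics(np.eye(3), ["FC3", "FCz", "FC4"])


def tone_trial(amp_l, amp_f, amp_r, fs=250.0, dur=6.0, freq=12.0):
    """3-channel trial whose channels carry 12 Hz tones of set variances."""
    t = np.arange(int(dur * fs)) / fs
    s = np.sin(2 * np.pi * freq * t)
    return np.vstack([a * np.sqrt(2.0) * s for a in (amp_l, amp_f, amp_r)])


def identity_filters():
    return DetectionFilterSet(w_l=[1, 0, 0], w_f=[0, 1, 0], w_r=[0, 0, 1],
                              channel_labels=["a", "b", "c"])


class TestClassifyTrial:
    BAND = (10.0, 14.0)
    WIN = (0.5, 5.0)

    def test_min_var_ul_gives_right_hand(self):
        """Variances (0.5, 0.9, 1.2) for (u_l, u_f, u_r) -> class 2."""
        x = tone_trial(np.sqrt(0.5), np.sqrt(0.9), np.sqrt(1.2))
        assert classify_trial(identity_filters(), x, 250.0, self.BAND, self.WIN) == 2

    def test_min_var_ur_gives_left_hand(self):
        x = tone_trial(np.sqrt(1.2), np.sqrt(0.9), np.sqrt(0.5))
        assert classify_trial(identity_filters(), x, 250.0, self.BAND, self.WIN) == 1

    def test_min_var_uf_gives_foot(self):
        x = tone_trial(np.sqrt(1.2), np.sqrt(0.5), np.sqrt(0.9))
        assert classify_trial(identity_filters(), x, 250.0, self.BAND, self.WIN) == 3

    def test_three_way_tie_is_class_1(self):
        """Equal variances resolve in (u_r, u_l, u_f) order -> class 1."""
        x = tone_trial(1.0, 1.0, 1.0)
        assert classify_trial(identity_filters(), x, 250.0, self.BAND, self.WIN) == 1

    def test_scale_invariance(self):
        x = tone_trial(0.7, 1.1, 0.9)
        f = identity_filters()
        base = classify_trial(f, x, 250.0, self.BAND, self.WIN)
        for c in (1e-3, 7.0, 1e4):
            assert classify_trial(f, c * x, 250.0, self.BAND, self.WIN) == base


def trivial_trialset(labels, n_ch=3, n=None):
    rng = np.random.default_rng(0)
    labels = np.asarray(labels)
    trials = [rng.standard_normal((n_ch, 1500)) for _ in labels]
    return TrialSet(trials=trials, labels=labels,
                    trial_index=np.arange(1, len(labels) + 1),
                    window=(0.0, 6.0), fs=250.0,
                    channel_labels=["a", "b", "c"][:n_ch])


def test_evaluate_filters_perfect_on_degenerate_set():
    """All trials class 1 and a classifier that always answers 1 -> 1.0."""
    ts = trivial_trialset([1] * 5)
    f = DetectionFilterSet(w_l=[1, 0, 0], w_f=[1, 0, 0], w_r=[0.0, 0, 0.001],
                          channel_labels=["a", "b", "c"])
    # w_r has near-zero output variance so var(u_r) is always the minimum
    assert evaluate_filters(f, ts, (10, 14), (0.5, 5.0)) == 1.0


def test_random_filters_score_near_chance():
    rng = np.random.default_rng(1)
    ts = trivial_trialset(list(np.repeat([1, 2, 3], 10)))
    accs = []
    for _ in range(60):
        w = rng.standard_normal((3, 3))
        f = DetectionFilterSet(w_l=w[0], w_f=w[1], w_r=w[2],
                               channel_labels=["a", "b", "c"])
        accs.append(evaluate_filters(f, ts, (10, 14), (0.5, 5.0)))
    assert abs(np.mean(accs) - 1 / 3) < 0.05


class TestSecondRound:
    def make_report(self, accs, bad=()):
        n = len(accs)
        return SelectionReport(
            trial_index=np.arange(1, n + 1),
            round1_label=["bad" if i + 1 in bad else "good" for i in range(n)],
            accuracies=np.asarray(accs, dtype=float),
        )

    def test_mean_threshold_rule(self):
        """R = (0.9, 0.8, 0.4) plus two round-one zeros: threshold 0.7."""
        rep = self.make_report([0.9, 0.8, 0.4, 0.0, 0.0], bad=(4, 5))
        rep = second_round_select(rep)
        assert rep.threshold == pytest.approx(0.7)
        assert rep.kept_trials == [1, 2]

    def test_all_equal_accuracies_all_kept(self):
        rep = second_round_select(self.make_report([0.6] * 4))
        assert rep.kept_trials == [1, 2, 3, 4]

    def test_no_good_trials_raises(self):
        rep = self.make_report([0.0, 0.0], bad=(1, 2))
        with pytest.raises(MatchingError):
            second_round_select(rep)

    def test_absolute_and_quantile_rules(self):
        rep = second_round_select(self.make_report([0.9, 0.5, 0.3]), rule=0.6)
        assert rep.kept_trials == [1]
        rep = second_round_select(self.make_report([0.9, 0.5, 0.3]), rule="q0.5")
        assert rep.kept_trials == [1, 2]

    def test_top_m_ranking_and_monotonicity(self):
        """top_m is kept trials by descending accuracy (ties by index), and
        removing a kept trial never resurrects a sub-threshold one."""
        rep = self.make_report([0.9, 0.95, 0.9, 0.2, 0.85])
        rep = second_round_select(rep)
        full = _rank_kept(rep)[:3]
        assert full == [2, 1, 3]  # tie 0.9/0.9 broken by ascending index
        rep.kept_trials = [t for t in rep.kept_trials if t != 2]
        reduced = _rank_kept(rep)[:3]
        assert 4 not in reduced and set(reduced) <= {1, 3, 5}


class TestAffectedWindows:
    def test_paper_scenario(self):
        """Artifact trials 43 and 46 contaminate windows 34 through 46."""
        assert affected_windows({43, 46}, 75, 10, 1) == set(range(34, 47))

    def test_edges(self):
        assert affected_windows({1}, 75, 10, 1) == {1}
        assert affected_windows({75}, 75, 10, 1) == {66}

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            affected_windows({76}, 75, 10, 1)

    @settings(derandomize=True, max_examples=50)
    @given(st.sets(st.integers(1, 40), min_size=1, max_size=5),
           st.integers(5, 15))
    def test_matches_brute_force(self, bad, win):
        n = 40
        brute = {
            k for k, start in enumerate(range(1, n - win + 2), start=1)
            if any(start <= b < start + win for b in bad)
        }
        assert affected_windows(bad, n, win, 1) == brute


def noise_trialset(n_trials, n_ch=9, n_samples=400, seed=0):
    rng = np.random.default_rng(seed)
    labels = 1 + np.arange(n_trials) % 3
    return TrialSet(trials=[rng.standard_normal((n_ch, n_samples))
                            for _ in range(n_trials)],
                    labels=labels, trial_index=np.arange(1, n_trials + 1),
                    window=(0.0, n_samples / 250.0), fs=250.0,
                    channel_labels=list(NINE))


def test_ica_s_window_count():
    """75 trials with a 10-trial window at step 1 give 66 entries."""
    ts = noise_trialset(75, n_samples=200)
    sets = build_ica_s(ts, win=10, step=1, cfg=IcaConfig(seed=0, max_iter=4))
    assert len(sets) == 66
    for s in sets:
        if s is not None:
            assert s.matrix.shape == (3, 9)


def test_ica_s_single_window_and_validation():
    ts = noise_trialset(10, n_samples=200)
    sets = build_ica_s(ts, win=10, cfg=IcaConfig(seed=0, max_iter=4))
    assert len(sets) == 1
    with pytest.raises(ValueError):
        build_ica_s(ts, win=0)
    with pytest.raises(ValueError):
        build_ica_s(noise_trialset(5), win=10)


def test_filter_set_json_round_trip():
    f = DetectionFilterSet(w_l=[1.0, 2, 3], w_f=[0, 1, 0], w_r=[3, 2, 1.0],
                          channel_labels=["a", "b", "c"], origin=7)
    back = DetectionFilterSet.from_json(f.to_json())
    assert np.allclose(back.matrix, f.matrix)
    assert back.origin == 7
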