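"""Dynamic stopping: model cache, counter automaton, trials and sessions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ssvepds as s
from ssvepds.dynstop import _automaton

from conftest import CHUNK, FS, ORDER, small_classifier, small_session


def oracle_scan(labels, posts, N, P):
    """Independent reference implementation of the stopping rule.

    Walks the trace keeping an explicit run of qualifying evaluations: a
    qualifying evaluation has posterior >= P; a run is a maximal tail of
    qualifying evaluations with one common label, and the trial stops at the
    first index where the run length reaches N.
    """
    run_label, run_len = None, 0
    prev_label = None
    for k in range(len(labels)):
        lab, post = labels[k], posts[k]
        if post >= P:
            if lab == prev_label and run_label == lab:
                run_len += 1
            else:
                run_label, run_len = lab, 1
        else:
            run_label, run_len = None, 0
        prev_label = lab
        if run_len >= N:
            return k, lab, False
    return len(labels) - 1, labels[-1], True


def random_traces(n, seed, length=12, n_classes=3):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        size = rng.integers(1, length + 1)
        labels = rng.integers(1, n_classes + 1, size)
        posts = np.round(rng.uniform(0, 1, size), 3)
        yield labels, posts


class TestStopConfig:
    def test_defaults(self):
        cfg = s.StopConfig()
        assert cfg.N == 2 and cfg.P == 0.95
        assert cfg.chunk_samples == 131
        assert cfg.max_window == 8192  # 4 s at 2048 Hz

    @pytest.mark.parametrize("kw", [{"N": 0}, {"P": 1.5}, {"chunk_samples": 0},
                                    {"min_window": 10, "max_window": 5}])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            s.StopConfig(**kw)


class TestAutomaton:
    def test_immediate_satisfaction(self):
        k, lab, forced = _automaton([7, 7], [0.99, 0.98], 2, 0.95)
        assert (k, lab, forced) == (1, 7, False)

    def test_reset_on_label_change(self):
        k, lab, forced = _automaton([1, 2, 2], [0.99, 0.99, 0.99], 2, 0.95)
        assert (k, lab, forced) == (2, 2, False)

    def test_low_posterior_breaks_run(self):
        k, lab, forced = _automaton([1, 1, 1, 1], [0.99, 0.5, 0.99, 0.99],
                                    2, 0.95)
        assert (k, lab, forced) == (3, 1, False)

    def test_hold_variant_survives_low_posterior_repeat(self):
        k, lab, forced = _automaton([1, 1, 1], [0.99, 0.5, 0.99], 2, 0.95,
                                    hold_on_low_posterior=True)
        assert (k, lab, forced) == (2, 1, False)

    def test_N1_is_pure_threshold(self):
        k, lab, forced = _automaton([3, 2, 1], [0.5, 0.96, 0.99], 1, 0.95)
        assert (k, lab, forced) == (1, 2, False)

    def test_P0_is_pure_stability(self):
        k, lab, forced = _automaton([1, 2, 2], [0.0, 0.0, 0.0], 2, 0.0)
        assert (k, lab, forced) == (2, 2, False)

    def test_exhausted_trace_forces_last_label(self):
        k, lab, forced = _automaton([1, 2], [0.5, 0.5], 2, 0.95)
        assert (k, lab, forced) == (1, 2, True)

    def test_thousand_scripted_streams_match_oracle(self):
        for labels, posts in random_traces(1000, seed=42):
            for N in (1, 2, 3):
                for P in (0.0, 0.5, 0.95):
                    assert _automaton(labels, posts, N, P) == oracle_scan(
                        labels, posts, N, P
                    )

    @given(st.data())
    def test_property_matches_oracle(self, data):
        labels = data.draw(st.lists(st.integers(1, 3), min_size=1, max_size=15))
        posts = data.draw(st.lists(st.floats(0, 1), min_size=len(labels),
                                   max_size=len(labels)))
        N = data.draw(st.integers(1, 4))
        P = data.draw(st.floats(0, 1))
        assert _automaton(labels, posts, N, P) == oracle_scan(labels, posts, N, P)

    def test_raising_N_or_P_never_stops_earlier(self):
        for labels, posts in random_traces(200, seed=7):
            base, _, _ = _automaton(labels, posts, 2, 0.8)
            later_n, _, _ = _automaton(labels, posts, 3, 0.8)
            later_p, _, _ = _automaton(labels, posts, 2, 0.9)
            assert later_n >= base and later_p >= base


class TestModelCache:
    def test_cache_covers_all_chunk_multiples(self, fitted_clean):
        # 1 s at 512 Hz with 64-sample chunks -> 8 cached lengths
        assert fitted_clean.lengths_ == [64 * k for k in range(1, 9)]
        for w, (bank, model) in fitted_clean.models_.items():
            assert bank.window_len_ == w

    def test_full_scale_cache_count(self):
        """4 s at 2048 Hz in 131-sample chunks: floor(8192/131)=62 lengths."""
        cfg = s.SynthConfig(seed=55)
        topo = s.make_topographies(32, 5, seed=55)
        session = s.simulate_session(2, 4.0, cfg, topo)
        clf = s.DynamicStoppingClassifier().fit(session.data, session.labels)
        assert len(clf.lengths_) == 62
        assert clf.lengths_[0] == 131 and clf.lengths_[-1] == 8122
        assert set(clf.models_) == set(clf.lengths_)

    def test_uncached_length_rejected(self, fitted_clean):
        with pytest.raises(KeyError):
            fitted_clean.evaluate_window(np.zeros((8, 100)))

    def test_training_shorter_than_max_window_rejected(self, clean_session):
        clf = small_classifier(max_window=2 * int(FS))
        with pytest.raises(ValueError, match="shorter than"):
            clf.fit(clean_session.data, clean_session.labels)


class TestEvaluateWindow:
    def test_noiseless_window_confident_and_correct(self, noiseless_session):
        clf = small_classifier()
        clf.fit(noiseless_session.data, noiseless_session.labels)
        lab, post = clf.evaluate_window(noiseless_session.data[0][:, :256])
        assert lab == noiseless_session.labels[0]
        assert post > 0.99

    def test_deterministic(self, fitted_clean, clean_session):
        w = clean_session.data[0][:, :128]
        assert fitted_clean.evaluate_window(w) == fitted_clean.evaluate_window(w)

    def test_equals_composition_of_public_operations(self, fitted_clean,
                                                     noisy_session):
        """The engine's evaluation is the filter->CCA->LDA composition."""
        window = noisy_session.data[3][:, :192]
        bank, model = fitted_clean.models_[192]
        fw = s.apply_zero_phase(fitted_clean.coeffs_, window)
        f = s.extract_features(fw, bank)
        post = s.posterior(model, f)
        expect = (int(model.classes_[np.argmax(post)]), float(np.max(post)))
        assert fitted_clean.evaluate_window(window) == expect


class TestRunTrial:
    def _stream(self, data, chunk=CHUNK):
        rec = s.Recording(data, FS)
        return s.chunk_stream(rec, chunk)

    def test_stream_matches_trace_automaton(self, fitted_clean, noisy_session):
        """predict_stream equals applying the automaton to the full trace."""
        for i in range(6):
            trial = noisy_session.data[i]
            wins, labs, posts = fitted_clean.trace(trial)
            k, lab, forced = _automaton(labs, posts, fitted_clean.N,
                                        fitted_clean.P)
            d = fitted_clean.predict_stream(self._stream(trial))
            assert (d.stop_window, d.label, d.forced) == (wins[k], lab, forced)

    def test_stop_window_is_chunk_multiple(self, fitted_clean, clean_session):
        d = fitted_clean.predict_stream(self._stream(clean_session.data[0]))
        assert d.stop_window % CHUNK == 0
        assert d.stop_time == d.stop_window / FS
        assert len(d.trace) == d.stop_window // CHUNK

    def test_insufficient_data(self, fitted_clean):
        with pytest.raises(s.InsufficientDataError):
            fitted_clean.predict_stream(iter([]))

    def test_forced_timeout_at_max_window(self, chance_session):
        clf = small_classifier(P=1.0)  # unreachable posterior threshold
        clf.fit(chance_session.data, chance_session.labels)
        d = clf.predict_stream(self._stream(chance_session.data[0]))
        assert d.forced and d.stop_window == clf.lengths_[-1]


class TestRunSession:
    def test_noiseless_session_perfect_and_fast(self, noiseless_session):
        clf = small_classifier()
        clf.fit(noiseless_session.data, noiseless_session.labels)
        decisions, summary = clf.score_session(noiseless_session.data,
                                               noiseless_session.labels)
        assert summary["accuracy"] == 1.0
        # every trial stops at the earliest possible N * chunk window
        assert all(d.stop_window == clf.N * CHUNK for d in decisions)

    def test_chance_session_near_chance_and_forced(self, chance_session):
        clf = small_classifier()
        clf.fit(chance_session.data, chance_session.labels)
        heldout = small_session(snr=0.0, seed=305)  # fresh noise, no signal
        _, summary = clf.score_session(heldout.data, heldout.labels)
        assert summary["forced_fraction"] > 0.5
        # binomial 99% interval around chance (1/3, n=18)
        assert abs(summary["accuracy"] - 1 / 3) <= 2.576 * np.sqrt(
            (1 / 3) * (2 / 3) / heldout.n_trials
        )

    def test_per_target_breakdown(self, fitted_clean, clean_session):
        _, summary = fitted_clean.score_session(clean_session.data,
                                                clean_session.labels)
        table = summary["per_target"]
        assert sorted(table["target"]) == [1, 2, 3]
        assert table["n"].sum() == clean_session.n_trials

    def test_gap_counts_into_itr_denominator(self, fitted_clean, clean_session):
        _, without = fitted_clean.score_session(clean_session.data,
                                                clean_session.labels)
        _, with_gap = fitted_clean.score_session(clean_session.data,
                                                 clean_session.labels,
                                                 count_gap=True, gap_s=0.5)
        assert with_gap["itr"] < without["itr"]
        assert with_gap["mean_time_s"] == without["mean_time_s"]


class TestLatencyMonotonicity:
    def test_mean_stop_time_non_increasing_in_snr(self):
        """Stronger responses let the stopper decide earlier (30 trials per
        SNR condition, fresh held-out sessions)."""
        from conftest import small_config

        times = []
        for snr in (1.0, 3.0, 8.0):
            cfg = small_config(snr, 61)
            topo = s.make_topographies(8, 3, 0.5, seed=61)
            rng = cfg.rng()
            train = s.simulate_session(10, 1.0, cfg, topo, rng)
            held = s.simulate_session(10, 1.0, cfg, topo, rng)
            clf = small_classifier()
            clf.fit(train.data, train.labels)
            _, summary = clf.score_session(held.data, held.labels)
            times.append(summary["mean_time_s"])
        assert np.all(np.diff(times) <= 0.05)  # statistical slack
        assert times[-1] < times[0]


class TestFunctionalWrappers:
    def test_build_and_run(self, clean_session):
        cfg = s.StopConfig(N=2, P=0.9, chunk_samples=CHUNK, f_sample=FS,
                           max_window=int(FS))
        cache = s.build_model_cache(clean_session, cfg, filter_order=ORDER)
        rec = s.Recording(clean_session.data[0], FS)
        d = s.run_trial(s.chunk_stream(rec, CHUNK), cache)
        assert d.label in (1, 2, 3)
        decisions, summary = s.run_session(clean_session, cache)
        assert len(decisions) == clean_session.n_trials
        assert 0.0 <= summary["accuracy"] <= 1.0

    def test_stop_config_override_shrinks_horizon(self, fitted_clean,
                                                  clean_session):
        cfg = s.StopConfig(N=1, P=0.0, chunk_samples=CHUNK, f_sample=FS,
                           max_window=2 * CHUNK)
        rec = s.Recording(clean_session.data[0], FS)
        d = s.run_trial(s.chunk_stream(rec, CHUNK), fitted_clean, cfg)
        assert d.stop_window == CHUNK  # N=1, P=0 stops at the first window
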