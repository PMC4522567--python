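"""STDP rules: direct evaluation, trace bookkeeping, and an independent
full-history oracle that recomputes every trace from the raw spike times."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stdpnet.plasticity import (
    RULE_IDS,
    RuleParams,
    TraceState,
    WeightBoundsError,
    clip_weights,
    decay_traces,
    default_rule_params,
    dw_expdep,
    dw_powerlaw,
    dw_prepost_post,
    dw_prepost_pre,
    dw_triplet,
    normalize_divisive,
    on_pre_spike,
    on_post_spike,
    replay_events,
)


def _traces(n_pre=3, n_post=2, rule="prepost"):
    return TraceState.zeros(n_pre, n_post, default_rule_params(rule))


class TestTraces:
    def test_zero_traces_stay_zero(self):
        t = _traces()
        decay_traces(t, 5.0)
        assert not t.x_pre.any() and not t.x_post.any()

    def test_decay_closed_form(self):
        t = _traces()
        t.x_pre[:] = 1.0
        decay_traces(t, t.tau_pre)
        assert t.x_pre[0] == pytest.approx(math.exp(-1), rel=1e-12)

    @given(dt1=st.floats(0.0, 50.0), dt2=st.floats(0.0, 50.0))
    def test_decay_semigroup(self, dt1, dt2):
        a, b = _traces(), _traces()
        a.x_pre[:] = 1.0
        b.x_pre[:] = 1.0
        decay_traces(a, dt1)
        decay_traces(a, dt2)
        decay_traces(b, dt1 + dt2)
        assert a.x_pre[0] == pytest.approx(b.x_pre[0], rel=1e-9)

    def test_pre_spike_increments_by_one(self):
        t = _traces()
        t.x_pre[0] = 0.3
        on_pre_spike(t, [0])
        assert t.x_pre[0] == pytest.approx(1.3)

    def test_duplicate_indices_increment_once(self):
        t = _traces()
        on_pre_spike(t, [1, 1, 1])
        assert t.x_pre[1] == 1.0

    def test_multiple_inputs_bumped_others_untouched(self):
        t = _traces()
        on_pre_spike(t, [0, 2])
        assert list(t.x_pre) == [1.0, 0.0, 1.0]

    def test_empty_set_noop(self):
        t = _traces()
        on_pre_spike(t, [])
        assert not t.x_pre.any()


class TestRuleFormulas:
    def test_powerlaw_direct_value(self):
        p = RuleParams(rule_id="powerlaw", eta=0.01, x_tar=0.4, mu=1.0, w_max=1.0)
        assert dw_powerlaw(1.0, 0.5, p) == pytest.approx(0.01 * 0.6 * 0.5)

    def test_powerlaw_zero_crossing_and_ceiling(self):
        p = default_rule_params("powerlaw")
        assert dw_powerlaw(p.x_tar, 0.5, p) == 0.0
        assert dw_powerlaw(1.0, p.w_max, p) == 0.0

    def test_expdep_direct_value(self):
        p = RuleParams(rule_id="expdep", eta_post=0.01, beta=3.0, x_tar=0.4, w_max=1.0)
        expected = 0.01 * (1.0 - 0.4 * math.exp(-3.0))
        assert dw_expdep(1.0, 0.0, p) == pytest.approx(expected, rel=1e-12)

    def test_expdep_beta_zero_reduces_to_linear(self):
        p = RuleParams(rule_id="expdep", eta_post=0.01, beta=0.0, x_tar=0.4)
        assert dw_expdep(1.0, 0.3, p) == pytest.approx(0.01 * 0.6)

    def test_expdep_symmetric_zero_at_half_ceiling(self):
        p = RuleParams(rule_id="expdep", x_tar=0.7)
        assert dw_expdep(0.7, p.w_max / 2, p) == pytest.approx(0.0, abs=1e-15)

    def test_prepost_pre_direct_value_and_floor(self):
        p = RuleParams(rule_id="prepost", eta_pre=0.01, mu=1.0)
        assert dw_prepost_pre(0.5, 0.4, p) == pytest.approx(-0.002)
        assert dw_prepost_pre(0.5, 0.0, p) == 0.0
        assert dw_prepost_pre(0.0, 0.4, p) == 0.0

    def test_prepost_post_matches_powerlaw_form(self):
        pw = RuleParams(rule_id="powerlaw", eta=0.007, mu=0.9)
        pp = RuleParams(rule_id="prepost", eta_post=0.007, mu=0.9)
        x = np.linspace(0, 2, 7)
        w = np.linspace(0, 1, 7)
        np.testing.assert_allclose(dw_prepost_post(x, w, pp), dw_powerlaw(x, w, pw))

    def test_triplet_zero_traces(self):
        t = _traces(rule="triplet")
        p = default_rule_params("triplet")
        assert not dw_triplet("pre", t, p).any()
        assert not dw_triplet("post", t, p, post_neuron=0).any()

    def test_triplet_reduces_to_pair_stdp_without_triplet_term(self):
        p = default_rule_params("triplet", a3_plus=0.0, a2_plus=0.02)
        t = _traces(rule="triplet")
        t.x_pre[:] = 0.6
        t.x_post_slow[:] = 5.0  # must be ignored when A3+ = 0
        np.testing.assert_allclose(
            dw_triplet("post", t, p, post_neuron=1), 0.02 * t.x_pre
        )

    def test_triplet_isolated_pair_potentiation(self):
        # one pre spike, then one post spike lag dt later: potentiation
        # A2+ * exp(-lag/tau_pre) (slow post trace still zero at the event)
        p = default_rule_params("triplet", a2_plus=0.02)
        dt, lag_steps = 0.5, 6
        events = [(0, "pre", 0), (lag_steps, "post", 0)]
        w0 = np.full((1, 1), 0.5)
        w, snaps = replay_events(events, 1, 1, w0, p, dt)
        expected = 0.02 * math.exp(-lag_steps * dt / p.tau_pre)
        assert w[0, 0] - 0.5 == pytest.approx(expected, rel=1e-9)

    def test_out_of_bounds_weight_rejected(self):
        p = default_rule_params("powerlaw")
        with pytest.raises(WeightBoundsError):
            dw_powerlaw(1.0, 1.5, p)
        with pytest.raises(WeightBoundsError):
            dw_prepost_pre(1.0, -0.2, default_rule_params("prepost"))


class TestWeightMaintenance:
    def test_normalization_reaches_target_and_preserves_ratios(self):
        rng = np.random.default_rng(3)
        w = rng.random((30, 6))
        ratios = w[5] / w[17]
        normalize_divisive(w, 7.5)
        np.testing.assert_allclose(w.sum(axis=0), 7.5, rtol=1e-9)
        np.testing.assert_allclose(w[5] / w[17], ratios, rtol=1e-9)

    def test_normalization_identity_when_already_at_target(self):
        w = np.full((4, 2), 0.25)
        out = normalize_divisive(w.copy(), 1.0)
        np.testing.assert_allclose(out, w)

    def test_normalization_small_column_example(self):
        w = np.array([[0.2], [0.2]])
        normalize_divisive(w, 1.0)
        np.testing.assert_allclose(w.ravel(), [0.5, 0.5])

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(4)
        w = rng.random((20, 5))
        normalize_divisive(w, 3.0)
        again = normalize_divisive(w.copy(), 3.0)
        np.testing.assert_allclose(again, w, rtol=1e-12)

    def test_zero_column_left_with_warning(self):
        w = np.zeros((3, 2))
        w[:, 1] = 0.5
        with pytest.warns(RuntimeWarning):
            normalize_divisive(w, 1.0)
        assert not w[:, 0].any()
        np.testing.assert_allclose(w[:, 1].sum(), 1.0)

    def test_clip(self):
        w = np.array([-0.1, 0.5, 1.2])
        clip_weights(w, 1.0)
        np.testing.assert_allclose(w, [0.0, 0.5, 1.0])


# ---------------------------------------------------------------------------
# independent oracle: recompute every trace from the full spike history


def _oracle_traces(events, dt, tau_pre, tau_post, tau_slow, n_pre, n_post):
    """Trace values at each event, from raw spike times (no incremental state).

    Semantics mirror the simulator's event ordering: a post event at step s
    sees pre spikes at steps <= s (same-step inclusive); a pre event at step
    s sees post spikes at steps < s (same-step exclusive); the slow post
    trace at a post event excludes that event's own increment but includes
    earlier same-step post spikes of other neurons only via their own traces
    (traces are per-neuron, so cross-neuron terms never mix).
    """
    pre_hist = {i: [] for i in range(n_pre)}
    post_hist = {j: [] for j in range(n_post)}
    out = []
    for step, kind, idx in events:
        if kind == "pre":
            x_post = np.array(
                [
                    sum(math.exp(-(step - s) * dt / tau_post) for s in post_hist[j] if s < step)
                    for j in range(n_post)
                ]
            )
            out.append((step, kind, idx, {"x_post": x_post}))
            pre_hist[idx].append(step)
        else:
            x_pre = np.array(
                [
                    sum(math.exp(-(step - s) * dt / tau_pre) for s in pre_hist[i] if s <= step)
                    for i in range(n_pre)
                ]
            )
            slow = sum(
                math.exp(-(step - s) * dt / tau_slow) for s in post_hist[idx] if s < step
            )
            out.append((step, kind, idx, {"x_pre": x_pre, "x_post_slow": slow}))
            post_hist[idx].append(step)
    return out


def _oracle_replay(events, n_pre, n_post, w0, p, dt):
    """Weight trajectory with traces recomputed from history at every event."""
    w = np.array(w0, dtype=float, copy=True)
    trace_seq = _oracle_traces(
        events, dt, p.tau_pre, p.tau_post, p.tau_post_slow, n_pre, n_post
    )
    snaps = []
    for step, kind, idx, tr in trace_seq:
        if kind == "pre":
            if p.rule_id == "prepost":
                w[idx, :] += -p.eta_pre * tr["x_post"] * w[idx, :] ** p.mu
            elif p.rule_id == "triplet":
                w[idx, :] += -p.a2_minus * tr["x_post"]
        else:
            if p.rule_id == "powerlaw":
                w[:, idx] += p.eta * (tr["x_pre"] - p.x_tar) * (p.w_max - w[:, idx]) ** p.mu
            elif p.rule_id == "expdep":
                w[:, idx] += p.eta_post * (
                    tr["x_pre"] * np.exp(-p.beta * w[:, idx])
                    - p.x_tar * np.exp(-p.beta * (p.w_max - w[:, idx]))
                )
            elif p.rule_id == "prepost":
                w[:, idx] += (
                    p.eta_post * (tr["x_pre"] - p.x_tar) * (p.w_max - w[:, idx]) ** p.mu
                )
            else:
                w[:, idx] += tr["x_pre"] * (p.a2_plus + p.a3_plus * tr["x_post_slow"])
        np.clip(w, 0.0, p.w_max, out=w)
        snaps.append((step, kind, idx, w.copy()))
    return w, snaps


def _scripted_train(rng, n_pre, n_post, n_events=10, max_step=40):
    events = set()
    while len(events) < n_events:
        s = int(rng.integers(0, max_step))
        if rng.random() < 0.5:
            events.add((s, "pre", int(rng.integers(n_pre))))
        else:
            events.add((s, "post", int(rng.integers(n_post))))
    # simulator ordering: within a step, pre events precede post events
    return sorted(events, key=lambda e: (e[0], e[1] != "pre"))


@pytest.mark.parametrize("rule_id", RULE_IDS)
def test_incremental_matches_full_history_oracle(rule_id, rng):
    """Trace-based incremental updates == brute-force recomputation from the
    complete spike history, at every event of scripted <=10-spike trains."""
    p = default_rule_params(rule_id, w_max=1.0)
    for trial in range(5):
        n_pre, n_post = 4, 3
        events = _scripted_train(rng, n_pre, n_post)
        w0 = rng.random((n_pre, n_post)) * 0.5 + 0.25
        w_inc, snaps_inc = replay_events(events, n_pre, n_post, w0, p, dt=0.5)
        w_ora, snaps_ora = _oracle_replay(events, n_pre, n_post, w0, p, dt=0.5)
        assert len(snaps_inc) == len(snaps_ora)
        for (s1, k1, i1, wa), (s2, k2, i2, wb) in zip(snaps_inc, snaps_ora):
            assert (s1, k1, i1) == (s2, k2, i2)
            np.testing.assert_allclose(wa, wb, atol=1e-9, rtol=0)
        np.testing.assert_allclose(w_inc, w_ora, atol=1e-9, rtol=0)


@pytest.mark.parametrize("rule_id", RULE_IDS)
def test_weights_bounded_after_many_random_updates(rule_id, rng):
    """0 <= W <= w_max survives thousands of random spike events per rule."""
    p = default_rule_params(rule_id, w_max=1.0)
    n_pre, n_post = 6, 4
    events = []
    step = 0
    for _ in range(2500):
        step += int(rng.integers(0, 3))
        kind = "pre" if rng.random() < 0.6 else "post"
        idx = int(rng.integers(n_pre if kind == "pre" else n_post))
        events.append((step, kind, idx))
    w0 = rng.random((n_pre, n_post))
    w, _ = replay_events(events, n_pre, n_post, w0, p, dt=0.5)
    assert w.min() >= 0.0
    assert w.max() <= p.w_max + 1e-12


def test_powerlaw_selectivity_saturates_toward_pattern(rng):
    """Repeatedly pairing one fixed input pattern with postsynaptic firing
    drives active-input weights toward w_max and inactive ones toward 0."""
    p = default_rule_params("powerlaw")
    n_pre = 6
    active = [0, 1, 2]
    events = []
    step = 0
    for _ in range(250):
        for i in active:
            events.append((step, "pre", i))
        events.append((step + 2, "post", 0))
        step += 80  # traces decay out between pairings
    w0 = np.full((n_pre, 1), 0.5)
    w, _ = replay_events(events, n_pre, 1, w0, p, dt=0.5)
    assert w[active, 0].min() > 0.85
    assert w[[3, 4, 5], 0].max() < 0.05
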