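"""Windowing, agency indexes, TE matrices and EMD matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from socimotor import errors
from socimotor.dyad_agency import (
    compute_agency_profile,
    emd_1d,
    emd_matrix,
    mms_histogram,
    te_matrix,
    te_matrix_long,
    window_segment,
)
from socimotor.mms_core import SpikeTrain
from socimotor.session_io import SENSOR_ORDER, RunConfig


def test_window_grid_arithmetic():
    g = window_segment(5000, 1000)
    assert g.n_windows == 5
    assert list(g.starts) == [0, 1000, 2000, 3000, 4000]
    g2 = window_segment(1999, 1000)
    assert g2.n_windows == 1
    with pytest.raises(errors.InputError):
        window_segment(999, 1000)


def test_window_duration_at_128hz():
    cfg = RunConfig()
    assert cfg.window_samples / 128.0 == pytest.approx(7.8125)


def test_autonomy_variability_arithmetic():
    """variance/mean of {1,1,3,3} with the n-1 convention is 2/3."""
    apen = np.array([1.0, 1.0, 3.0, 3.0])
    mean = apen.mean()
    variability = apen.var(ddof=1) / mean
    assert mean == 2.0
    assert variability == pytest.approx(4 / 3 / 2)


def test_agency_profile_on_synthetic(short_session):
    cfg_sim, _, streams, _ = short_session
    cfg = RunConfig()
    profile = compute_agency_profile(
        {"child": streams[("child", "left_wrist")],
         "clinician": streams[("clinician", "left_wrist")]}, cfg)
    assert set(profile.windows["agent"]) == {"child", "clinician"}
    n_win = int(200 * 128 // cfg.window_samples)
    assert (profile.windows.groupby("agent").size() == n_win).all()
    for agent in ("child", "clinician"):
        s = profile.session[agent]
        assert s["autonomy_mean"] >= 0
        assert s["autonomy_variability"] >= 0
        assert np.isfinite(s["control"])
        assert s["agency_ratio_defined"]
        assert s["agency_ratio"] == pytest.approx(
            s["autonomy_mean"] / s["control"])


def test_agency_ratio_undefined_at_zero_control(monkeypatch, short_session):
    """control = -log2(1) = 0 must flag the ratio undefined."""
    from socimotor import dyad_agency as da

    _, _, streams, _ = short_session
    monkeypatch.setattr(da, "control_index", lambda fit, base=2.0: 0.0)
    profile = da.compute_agency_profile(
        {"child": streams[("child", "left_wrist")]}, RunConfig())
    s = profile.session["child"]
    assert not s["agency_ratio_defined"]
    assert np.isnan(s["agency_ratio"])


def _rand_trains(rng, n=6000):
    return {key: SpikeTrain((rng.random(n) < 0.02).astype(np.uint8), 128)
            for key in SENSOR_ORDER}


def test_te_matrix_independent_trains_near_zero(rng):
    trains = _rand_trains(rng)
    cfg = RunConfig(te_history_k=3)
    mat = te_matrix(trains, cfg)
    off = mat.values[~np.eye(6, dtype=bool)]
    assert np.all(off <= 0.01)
    assert np.all(np.diag(mat.values) == 0)


def test_te_matrix_copied_train_is_maximum(rng):
    trains = _rand_trains(rng)
    src = trains[("clinician", "right_wrist")].bits
    copied = np.zeros_like(src)
    copied[1:] = src[:-1]
    trains[("child", "right_wrist")] = SpikeTrain(copied, 128)
    cfg = RunConfig(te_history_k=3)
    mat = te_matrix(trains, cfg)
    target = "child:right_wrist"
    source = "clinician:right_wrist"
    peak = mat.loc[target, source]
    others = mat.values[mat.values != peak]
    assert peak == mat.values.max()
    assert peak > 10 * np.max(np.abs(others[others != 0]))
    # asymmetry: the reverse direction stays at noise level
    assert mat.loc[source, target] <= 0.01


def test_te_matrix_long_format(rng):
    mat = te_matrix(_rand_trains(rng, 4000), RunConfig(te_history_k=2))
    long = te_matrix_long(mat)
    assert len(long) == 36
    assert set(long.columns) == {"agent_i", "placement_i", "agent_j",
                                 "placement_j", "value"}


def _emd_lp_oracle(p, q, positions):
    """Optimal-transport LP between two histograms on given positions."""
    n = len(p)
    cost = np.abs(positions[:, None] - positions[None, :]).ravel()
    a_eq = []
    for i in range(n):  # row sums = p
        row = np.zeros((n, n))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(n):  # column sums = q
        col = np.zeros((n, n))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.concatenate([p, q]),
                  bounds=(0, None), method="highs")
    assert res.success
    return res.fun


def test_emd_identity_and_shift():
    h = np.array([0.2, 0.3, 0.5, 0.0])
    assert emd_1d(h, h) == 0.0
    a = np.array([1.0, 0, 0, 0])
    b = np.array([0, 0, 0, 1.0])
    assert emd_1d(a, b, bin_width=1.0) == pytest.approx(3.0)


def test_emd_matches_lp_oracle(rng):
    """Closed-form CDF distance equals the transport LP on <=8 bins."""
    for _ in range(100):
        n = int(rng.integers(2, 9))
        p = rng.random(n)
        q = rng.random(n)
        p, q = p / p.sum(), q / q.sum()
        ours = emd_1d(p, q, bin_width=1.0)
        lp = _emd_lp_oracle(p, q, np.arange(n, dtype=float))
        assert ours == pytest.approx(lp, abs=1e-9)


def test_emd_metric_axioms(rng):
    for _ in range(30):
        h = [rng.random(8) for _ in range(3)]
        h = [x / x.sum() for x in h]
        d01 = emd_1d(h[0], h[1])
        d12 = emd_1d(h[1], h[2])
        d02 = emd_1d(h[0], h[2])
        assert d01 == pytest.approx(emd_1d(h[1], h[0]))  # symmetry
        assert d02 <= d01 + d12 + 1e-12                  # triangle
        assert d01 >= 0


def test_emd_matrix_structure(rng):
    mms = {key: rng.random(200) for key in SENSOR_ORDER}
    mat = emd_matrix(mms, n_bins=32)
    v = mat.values
    np.testing.assert_allclose(v, v.T)
    assert np.all(np.diag(v) == 0)
    assert np.all(v >= 0)


def test_emd_matrix_empty_sensor_flagged(rng):
    mms = {key: rng.random(200) for key in SENSOR_ORDER}
    mms[("child", "torso")] = np.empty(0)
    mat = emd_matrix(mms)
    assert mat.loc["child:torso", "child:left_wrist"] != mat.loc[
        "child:torso", "child:torso"] or np.isnan(
        mat.loc["child:torso", "child:left_wrist"])
    assert np.isnan(mat.loc["child:torso", "clinician:torso"])


def test_mms_histogram_probability():
    h = mms_histogram(np.array([0.1, 0.5, 0.9, 0.5]), n_bins=10)
    assert h.sum() == pytest.approx(1.0)
    assert len(h) == 10


def test_jitter_raises_apen_and_lowers_te():
    """The autonomy knob moves ApEn up and clinician->child TE down."""
    from dataclasses import replace

    from scipy.stats import spearmanr

    from socimotor import infodyn, mms_core
    from socimotor.synthetic_dyad import DyadConfig, simulate_session

    jit, aps, tes = [], [], []
    for seed in range(6):
        for j in (0.0, 0.5, 1.0):
            cfg = replace(DyadConfig(duration_s=150, seed=seed,
                                     c_cl_to_ch=0.6), child_jitter=j)
            _, streams, _ = simulate_session(cfg)
            _, _, mc = mms_core.mms_from_stream(streams[("child", "left_wrist")])
            _, _, ml = mms_core.mms_from_stream(
                streams[("clinician", "left_wrist")])
            n = len(streams[("child", "left_wrist")])
            bc = mms_core.binarize(mc, n).bits
            bl = mms_core.binarize(ml, n).bits
            jit.append(j)
            tes.append(infodyn.transfer_entropy(bc, bl, k=20, l=20).value)
            aps.append(infodyn.approximate_entropy(
                bc, m=infodyn.auto_template_length(bc), r=0.5).value)
    assert spearmanr(jit, aps).statistic > 0
    assert spearmanr(jit, tes).statistic < 0
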