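"""Synthetic dyadic sessions with known ground truth.

The generator emulates the statistical structure of dyadic wearable
angular-speed recordings: each sensor's speed is a smooth slow
baseline plus sparse raised-cosine bursts whose peak amplitudes are
drawn from a Gamma(k, theta) law scaled to the agent's baseline
amplitude.  Spiking is a Poisson-like renewal process with a short
refractory floor; directional coupling makes a fraction of one
agent's spikes trigger, after a fixed lag, spikes in the other agent.
The child's "autonomy" knob is a jitter parameter spanning the scale
from totally deterministic to totally random: it gates whether
triggered (clinician-led) spikes occur and sets the regularity of the
child's own renewal spiking, from clock-like (jitter 0, controllable,
low entropy rate) to Poisson-random (jitter 1, autonomous, high
entropy rate), while holding the total spike rate approximately
fixed.  The child noise knob (`with_child_noise`) moves the amplitude
law along the maturation power law (iso-mean k*theta), since a pure
scale change is invisible to the scale-invariant MMS normalization.

Everything is seed-deterministic, and the emitted triaxial channels
are synthesized so their Euclidean norm reproduces the target speed
exactly, which is the only thing downstream analysis sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import RateError
from .gamma_process import fit_gamma_mle
from .session_io import (
    PLACEMENTS,
    SENSOR_ORDER,
    SensorStream,
    SessionManifest,
)

#: raised-cosine bump kernel width in samples (odd, peak at centre)
BUMP_WIDTH = 31
# minimum spike spacing: ~half the bump width, so consecutive bursts stay
# resolvable as distinct speed peaks downstream
_REFRACTORY = 15


@dataclass
class AgentParams:
    """Per-agent generative parameters (shared across the 3 sensors)."""

    spike_rate_hz: float = 2.0
    gamma_k: float = 2.0
    gamma_theta: float = 0.5
    baseline_amplitude: float = 20.0  # deg/s


@dataclass
class DyadConfig:
    """Full generative description of one synthetic dyadic session.

    Defaults mirror the recording conditions the pipeline targets:
    128 Hz, six sensors, ~55 min sessions, a child with a noisier
    Gamma amplitude law (k=2, theta=0.5) than the mature clinician
    (k=4, theta=0.25), and weak clinician-led coupling.
    """

    duration_s: float = 3300.0
    fs: float = 128.0
    child: AgentParams = field(default_factory=lambda: AgentParams(
        spike_rate_hz=2.0, gamma_k=2.0, gamma_theta=0.5, baseline_amplitude=20.0))
    clinician: AgentParams = field(default_factory=lambda: AgentParams(
        spike_rate_hz=2.0, gamma_k=4.0, gamma_theta=0.25, baseline_amplitude=25.0))
    c_cl_to_ch: float = 0.3
    c_ch_to_cl: float = 0.1
    lag_samples: int = 4
    child_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for c in (self.c_cl_to_ch, self.c_ch_to_cl):
            if not 0.0 <= c <= 1.0:
                raise ValueError("coupling probabilities must be in [0, 1]")
        if self.lag_samples < 1:
            raise ValueError("lag_samples must be >= 1")
        if not 0.0 <= self.child_jitter <= 1.0:
            raise ValueError("child_jitter must be in [0, 1]")
        for agent in (self.child, self.clinician):
            if agent.spike_rate_hz <= 0:
                raise RateError("spike rates must be positive")
            if agent.spike_rate_hz > self.fs / BUMP_WIDTH:
                raise RateError(
                    f"spike rate {agent.spike_rate_hz}/s overlaps "
                    f"{BUMP_WIDTH}-sample bumps at fs={self.fs}; lower the rate")


def with_child_noise(cfg: DyadConfig, theta: float) -> DyadConfig:
    """Set the child's noise level along the maturation power law.

    The MMS normalization is scale-invariant, so a pure change of the
    Gamma scale is invisible downstream; empirically, noisier motor
    output co-varies with a lower shape (log k falls linearly in
    log theta).  This knob therefore moves (k, theta) along the
    iso-mean line k*theta = const: the mean relative bump amplitude is
    preserved while the dispersion — and hence the estimated NSR —
    rises with theta.
    """
    mean_rel = cfg.child.gamma_k * cfg.child.gamma_theta
    return replace(cfg, child=replace(cfg.child, gamma_theta=theta,
                                      gamma_k=mean_rel / theta))


@dataclass
class GroundTruth:
    """What the generator actually drew, for oracle comparisons."""

    spike_idx: dict  # (agent, placement) -> sample indices
    amplitudes: dict  # (agent, placement) -> raw Gamma draws (unit scale)
    norm_amplitudes: dict  # (agent, placement) -> Eq-style normalized draws
    gamma_params: dict  # (agent, placement) -> (k, theta)
    n_triggered: dict  # 'cl_to_ch' / 'ch_to_cl' -> realized coupling events


def _renewal_spikes(rng, rate_hz, fs, n_samples, cv: float = 1.0):
    """Renewal spike indices with a refractory floor.

    ``cv`` is the coefficient of variation of the inter-spike
    intervals: 1 gives Poisson-like (exponential) spiking, values
    near 0 give near-periodic, clock-like spiking.  Intervals are
    Gamma-distributed with shape 1/cv^2.
    """
    if rate_hz <= 0:
        return np.empty(0, dtype=int)
    cv = min(max(cv, 0.05), 1.0)
    mean_gap = fs / rate_hz
    shape = 1.0 / cv ** 2
    n_expect = int(rate_hz * n_samples / fs * 2 + 50)
    gaps = rng.gamma(shape, mean_gap / shape, size=n_expect)
    gaps = np.maximum(np.round(gaps).astype(int), _REFRACTORY + 1)
    idx = np.cumsum(gaps)
    return idx[idx < n_samples]


def _dedupe(idx, n_samples):
    idx = np.unique(idx[(idx >= 0) & (idx < n_samples)])
    if len(idx) < 2:
        return idx
    keep = [idx[0]]
    for i in idx[1:]:
        if i - keep[-1] > _REFRACTORY:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def _bump_kernel():
    x = np.arange(BUMP_WIDTH)
    return 0.5 * (1 - np.cos(2 * np.pi * (x + 0.5) / BUMP_WIDTH))


def _speed_series(rng, n, baseline, spikes, amplitudes, fs):
    """Smooth baseline + amplitude-scaled bumps at spike times."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi, size=2)
    base = baseline * (1.0
                       + 0.05 * np.sin(2 * np.pi * 0.02 * t + phase[0])
                       + 0.03 * np.sin(2 * np.pi * 0.007 * t + phase[1]))
    impulse = np.zeros(n)
    impulse[spikes] = amplitudes * baseline
    bumps = np.convolve(impulse, _bump_kernel(), mode="same")
    return base + bumps


def _triaxial(rng, v, n):
    """Random smoothly varying unit direction times the target speed."""
    g = rng.normal(size=(n, 3))
    g = uniform_filter1d(g, size=65, axis=0, mode="nearest")
    norm = np.linalg.norm(g, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v[:, None] * (g / norm)


def simulate_session(cfg: DyadConfig, subject_id: str = "SYN01",
                     sex: str = "M", age: float = 9.0,
                     group_label: str = "NT", visit: int = 1):
    """Generate (manifest, streams, ground_truth) for one dyadic session.

    The clinician spikes independently; each clinician spike on a
    given placement triggers, with probability
    ``c_cl_to_ch * (1 - child_jitter)``, a child spike on the same
    placement ``lag_samples`` later.  The child's own independent
    rate is reduced by the expected triggered rate so the total child
    spike rate stays near its configured value regardless of coupling
    or jitter (the reverse direction is symmetric).  Same seed, same
    session, bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    spike_idx, amplitudes, norm_amps, gparams = {}, {}, {}, {}
    n_triggered = {"cl_to_ch": 0, "ch_to_cl": 0}
    streams = {}

    p_trig_ch = cfg.c_cl_to_ch * (1.0 - cfg.child_jitter)
    p_trig_cl = cfg.c_ch_to_cl * (1.0 - cfg.child_jitter)

    for placement in PLACEMENTS:
        cl = cfg.clinician
        ch = cfg.child
        cl_spikes = _renewal_spikes(rng, cl.spike_rate_hz, cfg.fs, n)

        # child: triggered spikes + an own renewal stream at reduced rate.
        # The jitter knob is the child's autonomy scale: it gates the
        # triggered (clinician-led) spikes and sets the regularity of the
        # child's own spiking, from clock-like (0) to Poisson-random (1).
        trig_mask = rng.random(len(cl_spikes)) < p_trig_ch
        trig_ch = cl_spikes[trig_mask] + cfg.lag_samples
        own_rate = max(ch.spike_rate_hz - p_trig_ch * cl.spike_rate_hz,
                       0.1 * ch.spike_rate_hz)
        ch_own = _renewal_spikes(rng, own_rate, cfg.fs, n,
                                 cv=max(cfg.child_jitter, 0.05))
        ch_spikes = _dedupe(np.concatenate([ch_own, trig_ch]), n)
        n_triggered["cl_to_ch"] += int(trig_mask.sum())

        # reverse direction: child spikes may trigger clinician spikes
        trig_mask_cl = rng.random(len(ch_spikes)) < p_trig_cl
        trig_cl = ch_spikes[trig_mask_cl] + cfg.lag_samples
        cl_spikes = _dedupe(np.concatenate([cl_spikes, trig_cl]), n)
        n_triggered["ch_to_cl"] += int(trig_mask_cl.sum())

        for agent, params, spikes in (("child", ch, ch_spikes),
                                      ("clinician", cl, cl_spikes)):
            amps = rng.gamma(params.gamma_k, params.gamma_theta, size=len(spikes))
            v = _speed_series(rng, n, params.baseline_amplitude, spikes,
                              amps, cfg.fs)
            w = _triaxial(rng, v, n)
            key = (agent, placement)
            streams[key] = SensorStream(agent=agent, placement=placement,
                                        fs=cfg.fs, t=t, w=w)
            spike_idx[key] = spikes
            amplitudes[key] = amps
            gparams[key] = (params.gamma_k, params.gamma_theta)
            # ground-truth normalized amplitudes: the [0,1] map evaluated
            # on the noiseless construction.  An isolated bump peaks at
            # baseline + a_i*A and its flanking minima sit at the baseline;
            # the series mean exceeds the baseline by the mean bump mass
            # m_bar, so peak deviation is |a_i*A - m_bar| and the flank
            # deviation is m_bar.
            if len(spikes):
                a_scaled = amps * params.baseline_amplitude
                m_bar = a_scaled.mean() * _bump_kernel().sum() * len(spikes) / n
                d = np.abs(a_scaled - m_bar)
                norm_amps[key] = d / (d + m_bar)
            else:
                norm_amps[key] = np.empty(0)

    manifest = SessionManifest(subject_id=subject_id, sex=sex, age=age,
                               group_label=group_label, visit=visit)
    truth = GroundTruth(spike_idx=spike_idx, amplitudes=amplitudes,
                        norm_amplitudes=norm_amps, gamma_params=gparams,
                        n_triggered=n_triggered)
    return manifest, streams, truth


# Table-1-like default sex composition of the 26-subject cohort
_DEFAULT_SEXES = {"NT": ["F"] * 7 + ["M"] * 4, "ASD": ["F"] * 3 + ["M"] * 12}


def make_cohort(n_nt: int = 11, n_asd: int = 15,
                effect: dict | None = None, seed: int = 0,
                duration_s: float = 3300.0, base_cfg: DyadConfig | None = None):
    """Simulate a labelled cohort of dyadic sessions.

    ``effect`` gives multiplicative/additive group shifts applied to
    the ASD-labelled sessions: ``theta`` (relative increase of the
    child Gamma scale, e.g. 1.0 doubles it), ``jitter`` (added to
    child_jitter) and ``coupling`` (added to c_cl_to_ch).  Subject
    parameters also carry mild seeded between-subject variation.
    Returns (sessions, labels) where sessions is a list of
    (manifest, streams, truth, cfg) and labels a DataFrame with
    subject_id, sex, group_label and the realized child parameters.
    """
    import pandas as pd

    if n_nt < 2 or n_asd < 2:
        raise ValueError("need at least 2 subjects per group")
    effect = dict(effect or {})
    if effect and all(v == 0 for v in effect.values()):
        import warnings

        warnings.warn("all effect shifts are zero: groups are exchangeable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    base = base_cfg or DyadConfig(duration_s=duration_s, seed=0)
    base = replace(base, duration_s=duration_s)

    sessions, rows = [], []
    specs = [("NT", i) for i in range(n_nt)] + [("ASD", i) for i in range(n_asd)]
    for group, i in specs:
        sexes = _DEFAULT_SEXES[group]
        sex = sexes[i % len(sexes)]
        sid = f"{'NT' if group == 'NT' else 'EP'}{i + 1:02d}"
        theta = base.child.gamma_theta * float(rng.lognormal(0, 0.1))
        jitter = float(np.clip(base.child_jitter + rng.normal(0, 0.05), 0, 1))
        coupling = float(np.clip(base.c_cl_to_ch + rng.normal(0, 0.03), 0, 1))
        if group == "ASD":
            theta *= 1.0 + effect.get("theta", 0.0)
            jitter = float(np.clip(jitter + effect.get("jitter", 0.0), 0, 1))
            coupling = float(np.clip(coupling + effect.get("coupling", 0.0), 0, 1))
        # noise shifts move along the maturation power law (iso-mean)
        cfg = replace(
            with_child_noise(base, theta),
            child_jitter=jitter,
            c_cl_to_ch=coupling,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        age = float(rng.uniform(4, 15))
        man, streams, truth = simulate_session(
            cfg, subject_id=sid, sex=sex, age=age, group_label=group)
        sessions.append((man, streams, truth, cfg))
        rows.append({"subject_id": sid, "sex": sex, "group_label": group,
                     "age": age, "child_theta": theta, "child_jitter": jitter,
                     "c_cl_to_ch": coupling})
    return sessions, pd.DataFrame(rows)


def oracle_gamma_fit(truth: GroundTruth, key=("child", "left_wrist")):
    """MLE on the ground-truth normalized amplitudes (pipeline oracle)."""
    return fit_gamma_mle(truth.norm_amplitudes[key], floor_n=3)
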