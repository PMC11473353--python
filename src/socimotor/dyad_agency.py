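"""Session-level socio-motor agency: windows, indexes and dyad matrices.

The session is cut into contiguous non-overlapping windows of 1000
samples (~7.8 s at 128 Hz), the time scale at which the binary spike
trains behave as locally stationary.  Within each window the agent's
autonomy index is the approximate entropy of the window's spike train;
the control index is -log2 of the session-level NSR (the Gamma scale
fitted to the session's MMS amplitudes).  Session summaries add the
autonomy variability (sample variance over mean of the per-window
autonomy) and the socio-motor agency ratio autonomy_mean / control.

Dyadic structure is captured by two 6x6 matrices over the sensors
(child left wrist, right wrist, torso; clinician same): the transfer
entropy matrix, whose child<->clinician blocks are the shared dyadic
space, and the Earth Mover's Distance matrix comparing per-sensor MMS
amplitude histograms on common [0, 1] bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import infodyn, mms_core
from .errors import InputError
from .gamma_process import GammaFit, control_index, fit_gamma_mle
from .session_io import SENSOR_ORDER, RunConfig, SensorStream

logger = logging.getLogger(__name__)


@dataclass
class WindowGrid:
    """Contiguous half-open windows [start, start + window_samples)."""

    window_samples: int
    starts: np.ndarray
    n_windows: int


@dataclass
class AgencyProfile:
    """Per-window and per-session agency indexes for one or two agents.

    ``windows`` has one row per (agent, window) with columns autonomy
    (ApEn bits), spike_rate (spikes/s) and embedding_delay (samples);
    ``session`` maps agent -> dict with the session Gamma fit derived
    quantities (nsr, control), autonomy_mean, autonomy_variability
    and agency_ratio (NaN when control == 0, flagged undefined).
    """

    windows: pd.DataFrame
    session: dict = field(default_factory=dict)


def window_segment(n_total: int, cfg: RunConfig | int = 1000) -> WindowGrid:
    """Non-overlapping contiguous windows; trailing remainder dropped."""
    w = cfg.window_samples if isinstance(cfg, RunConfig) else int(cfg)
    if n_total < w:
        raise InputError(f"series of {n_total} samples shorter than one "
                         f"window ({w})")
    n_win = n_total // w
    dropped = n_total - n_win * w
    if dropped:
        logger.info("dropping %d trailing samples (< 1 window)", dropped)
    return WindowGrid(window_samples=w,
                      starts=np.arange(n_win, dtype=int) * w,
                      n_windows=n_win)


def _session_pipeline(stream: SensorStream, cfg: RunConfig):
    """speed, peaks, MMS, spike train and session Gamma fit for one sensor."""
    v, p, m = mms_core.mms_from_stream(stream, amplitude_floor=cfg.amplitude_floor,
                                       flank_mode=cfg.mms_flank_mode)
    train = mms_core.binarize(m, len(v))
    fit = None
    try:
        fit = fit_gamma_mle(m.values, floor_n=cfg.gamma_floor_n)
    except Exception as exc:  # too few peaks etc.
        logger.warning("session Gamma fit unavailable: %s", exc)
    return v, p, m, train, fit


def compute_agency_profile(streams: dict[str, SensorStream],
                           cfg: RunConfig | None = None) -> AgencyProfile:
    """Windowed autonomy/control/spike-rate/delay indexes per agent.

    ``streams`` maps agent name -> that agent's analysis-hand sensor
    stream.  Per window: ApEn of the spike train (template length
    'auto' = rounded mean inter-spike interval of the session train),
    spike rate, and the AMI embedding delay of the window's continuous
    normalized speed.  Session level: control from the session MMS
    Gamma fit, autonomy mean/variability and the agency ratio.  With
    fewer than 2 windows the variability is reported missing, not an
    error.
    """
    cfg = cfg or RunConfig()
    rows = []
    session: dict = {}
    for agent, stream in streams.items():
        v, p, m, train, fit = _session_pipeline(stream, cfg)
        grid = window_segment(len(train), cfg)
        m_auto = (infodyn.auto_template_length(train.bits)
                  if cfg.apen_m == "auto" else int(cfg.apen_m))
        control = control_index(fit, base=cfg.log_base) if fit else np.nan
        # normalized speed for embedding-delay estimation
        v_norm = v.v / v.v.max() if v.v.max() > 0 else v.v
        for wi, start in enumerate(grid.starts):
            bits = train.bits[start:start + grid.window_samples]
            wtrain = mms_core.SpikeTrain(bits=bits, fs=train.fs)
            try:
                apen = infodyn.approximate_entropy(
                    bits, m=m_auto, r=cfg.apen_r, base=cfg.log_base).value
            except InputError:
                apen = np.nan
            try:
                delay = infodyn.average_mutual_information(
                    v_norm[start:start + grid.window_samples],
                    max_lag=cfg.ami_max_lag, n_bins=cfg.ami_bins,
                    base=cfg.log_base).delay
            except Exception:
                delay = np.nan
            rows.append({
                "agent": agent, "window": wi,
                "autonomy": apen,
                "spike_rate": mms_core.spike_rate(wtrain),
                "embedding_delay": delay,
            })
        per_win = np.array([r["autonomy"] for r in rows if r["agent"] == agent])
        per_win = per_win[np.isfinite(per_win)]
        autonomy_mean = float(per_win.mean()) if per_win.size else np.nan
        if per_win.size >= 2 and autonomy_mean != 0:
            variability = float(per_win.var(ddof=1) / autonomy_mean)
        else:
            variability = np.nan
        if fit is not None and control != 0 and np.isfinite(control):
            ratio = autonomy_mean / control
            ratio_defined = True
        else:
            ratio = np.nan
            ratio_defined = False
            if fit is not None and control == 0:
                logger.warning("agent %s: control index is 0; agency ratio "
                               "undefined", agent)
        session[agent] = {
            "gamma_fit": fit,
            "nsr": fit.theta if fit else np.nan,
            "control": control,
            "autonomy_mean": autonomy_mean,
            "autonomy_variability": variability,
            "agency_ratio": ratio,
            "agency_ratio_defined": ratio_defined,
            "spike_rate": mms_core.spike_rate(train),
            "n_windows": grid.n_windows,
        }
    return AgencyProfile(windows=pd.DataFrame(rows), session=session)


def te_matrix(trains: dict[tuple[str, str], mms_core.SpikeTrain],
              cfg: RunConfig | None = None) -> pd.DataFrame:
    """6x6 transfer-entropy matrix; entry (i, j) is TE from sensor j to i.

    Word counts are pooled across the session's windows before
    estimation (a k=20 binary history cannot be estimated inside a
    single ~1000-sample window); per-window estimation at deep
    histories is refused unless ``cfg.allow_undersampled`` is set.
    Diagonal (self -> self) entries are 0 by convention; the
    child<->clinician blocks are the shared dyadic space.
    """
    cfg = cfg or RunConfig()
    keys = [k for k in SENSOR_ORDER if k in trains]
    if len(keys) < 2:
        raise InputError("need at least two spike trains")
    lengths = {len(trains[k]) for k in keys}
    if len(lengths) != 1:
        raise InputError("spike trains must have equal length")
    n = lengths.pop()
    grid = window_segment(n, cfg)
    k_hist, l_hist = cfg.te_history_k, cfg.te_l
    if grid.window_samples < 2 ** min(k_hist, 16) and grid.n_windows == 1 \
            and not cfg.allow_undersampled:
        raise InputError(
            f"single window of {grid.window_samples} samples cannot support a "
            f"{k_hist}-deep history; pool more windows or set allow_undersampled")
    labels = [f"{a}:{p}" for a, p in keys]
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, ki in enumerate(keys):
        for j, kj in enumerate(keys):
            if i == j:
                continue
            pairs = [
                (trains[ki].bits[s:s + grid.window_samples],
                 trains[kj].bits[s:s + grid.window_samples])
                for s in grid.starts
            ]
            te = infodyn.transfer_entropy(None, None, k=k_hist, l=l_hist,
                                          base=cfg.log_base, pairs=pairs)
            mat.iloc[i, j] = te.value
    return mat


def emd_1d(p: np.ndarray, q: np.ndarray, bin_width: float = 1.0) -> float:
    """Earth Mover's Distance between two histograms on shared 1D bins.

    For histograms on a common ordered grid the optimal transport cost
    equals the L1 distance between the CDFs times the bin spacing.
    Inputs are normalized to probability first.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise InputError("histograms must share the same bins")
    if p.sum() <= 0 or q.sum() <= 0:
        raise InputError("histograms must have positive mass")
    p = p / p.sum()
    q = q / q.sum()
    return float(np.abs(np.cumsum(p - q)).sum() * bin_width)


def mms_histogram(values: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Probability histogram of MMS amplitudes on equal [0, 1] bins."""
    h, _ = np.histogram(np.asarray(values, dtype=float), bins=n_bins,
                        range=(0.0, 1.0))
    h = h.astype(float)
    return h / h.sum() if h.sum() > 0 else h


def emd_matrix(mms_by_sensor: dict[tuple[str, str], np.ndarray],
               n_bins: int = 32, frames: list[tuple[int, int]] | None = None,
               idx_by_sensor: dict | None = None) -> pd.DataFrame:
    """6x6 EMD matrix between per-sensor MMS amplitude histograms.

    Distances use ``n_bins`` equal bins on [0, 1]; the distance unit
    is one bin width (1/n_bins of the amplitude scale).  By default
    the whole session forms one frame; pass ``frames`` as (start, stop)
    sample intervals together with ``idx_by_sensor`` (peak indices) to
    average EMD over frames.  Sensors with an empty histogram yield
    NaN entries.
    """
    keys = [k for k in SENSOR_ORDER if k in mms_by_sensor]
    labels = [f"{a}:{p}" for a, p in keys]
    width = 1.0 / n_bins

    def frame_values(key, lo=None, hi=None):
        vals = np.asarray(mms_by_sensor[key], dtype=float)
        if lo is None:
            return vals
        idx = np.asarray(idx_by_sensor[key])
        sel = (idx >= lo) & (idx < hi)
        return vals[sel]

    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    frame_list = frames if frames else [(None, None)]
    for i, ki in enumerate(keys):
        for j in range(i + 1, len(keys)):
            kj = keys[j]
            dists = []
            for lo, hi in frame_list:
                vi = frame_values(ki, lo, hi)
                vj = frame_values(kj, lo, hi)
                if len(vi) == 0 or len(vj) == 0:
                    continue
                dists.append(emd_1d(mms_histogram(vi, n_bins),
                                    mms_histogram(vj, n_bins), width))
            d = float(np.mean(dists)) if dists else np.nan
            if not dists:
                logger.warning("empty MMS histogram for pair %s/%s; entry "
                               "flagged missing", labels[i], labels[j])
            mat.iloc[i, j] = d
            mat.iloc[j, i] = d
    return mat


def te_matrix_long(mat: pd.DataFrame) -> pd.DataFrame:
    """Long-format (agent_i, placement_i, agent_j, placement_j, value)."""
    rows = []
    for li in mat.index:
        ai, pi = li.split(":")
        for lj in mat.columns:
            aj, pj = lj.split(":")
            rows.append({"agent_i": ai, "placement_i": pi,
                         "agent_j": aj, "placement_j": pj,
                         "value": mat.loc[li, lj]})
    return pd.DataFrame(rows)
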