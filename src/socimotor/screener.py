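"""Sex-stratified LOOCV SVM screening on per-window agency features.

Windows are the training unit and subjects the cross-validation unit:
an RBF-kernel support vector machine is trained, separately for each
sex stratum, on the per-window feature vectors (autonomy, NSR, spike
rate, clinician-to-child transfer entropy, embedding delay) of all
subjects except one, then scores every window of the held-out
subject.  The fraction of that subject's windows labelled positive —
the positive rate — is the subject-level screening score, swept over
thresholds to produce a ROC curve whose trapezoidal area is the AUC.
All visits of a subject travel together in the held-out fold, and
feature standardization and median imputation use training-fold
statistics only, so no information leaks from the held-out subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import InputError, TrainingError

logger = logging.getLogger(__name__)

FEATURES = ["autonomy", "nsr", "spike_rate", "te", "embedding_delay"]


@dataclass
class ScreenResult:
    """Per-subject scores plus per-stratum and pooled ROC/AUC."""

    subjects: pd.DataFrame  # subject_id, sex, label, positive_rate, predicted
    roc: dict = field(default_factory=dict)  # stratum -> (fpr, tpr) arrays
    auc: dict = field(default_factory=dict)  # stratum -> float
    threshold: float = 0.5


def build_features(per_subject: dict, cfg=None) -> pd.DataFrame:
    """Assemble the per-window feature table across subjects.

    ``per_subject`` maps subject_id to a dict with keys ``windows``
    (the child rows of an AgencyProfile windows frame), ``nsr`` and
    ``te`` (session-level scalars broadcast to windows), ``sex`` and
    ``label`` (1 = ASD).  Rows whose autonomy is missing are dropped
    with a logged count; a subject with zero usable windows is
    excluded with a warning naming it.
    """
    rows = []
    for sid, d in per_subject.items():
        win = d["windows"]
        usable = win[np.isfinite(win["autonomy"])]
        dropped = len(win) - len(usable)
        if dropped:
            logger.info("subject %s: dropped %d windows with missing features",
                        sid, dropped)
        if len(usable) == 0:
            logger.warning("subject %s excluded: no usable windows", sid)
            continue
        for _, r in usable.iterrows():
            rows.append({
                "subject_id": sid,
                "window_id": int(r["window"]),
                "sex": d["sex"],
                "label": int(d["label"]),
                "autonomy": r["autonomy"],
                "nsr": d["nsr"],
                "spike_rate": r["spike_rate"],
                "te": d["te"],
                "embedding_delay": r["embedding_delay"],
            })
    return pd.DataFrame(rows)


def _fit_fold(train: pd.DataFrame, seed: int):
    """Median-impute + standardize + RBF SVM on training windows only."""
    X = train[FEATURES].to_numpy(dtype=float)
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    X = np.where(np.isfinite(X), X, med)
    y = train["label"].to_numpy()
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=1.0, gamma="scale",
                    class_weight="balanced", random_state=seed)),
    ])
    model.fit(X, y)
    return model, med


def loocv_screen(features: pd.DataFrame, threshold: float = 0.5,
                 seed: int = 0, stratify_sex: bool = True) -> ScreenResult:
    """Leave-one-person-out screening with per-subject positive rates.

    Within each sex stratum (or the whole cohort when
    ``stratify_sex=False``) every subject is held out in turn; the
    model never sees any of that subject's windows.  Requires at least
    two subjects per class per stratum.
    """
    required = {"subject_id", "sex", "label", *FEATURES}
    missing = required - set(features.columns)
    if missing:
        raise InputError(f"feature table missing columns {sorted(missing)}")
    strata = features.groupby("sex") if stratify_sex else [("all", features)]
    sub_rows = []
    roc, auc = {}, {}
    for stratum, df in strata:
        subjects = df.drop_duplicates("subject_id")[["subject_id", "label"]]
        if subjects["label"].nunique() < 2:
            raise TrainingError(
                f"stratum {stratum!r} has a single class; cannot train")
        if subjects.groupby("label").size().min() < 1 or len(subjects) < 3:
            raise TrainingError(
                f"stratum {stratum!r} too small for leave-one-out screening")
        for sid in subjects["subject_id"]:
            train = df[df["subject_id"] != sid]
            test = df[df["subject_id"] == sid]
            if train["label"].nunique() < 2:
                logger.warning("fold for %s degenerate (single training "
                               "class); skipped", sid)
                continue
            model, med = _fit_fold(train, seed)
            Xt = test[FEATURES].to_numpy(dtype=float)
            Xt = np.where(np.isfinite(Xt), Xt, med)
            pred = model.predict(Xt)
            rate = float(np.mean(pred == 1))
            sub_rows.append({
                "subject_id": sid, "sex": stratum,
                "label": int(test["label"].iloc[0]),
                "positive_rate": rate,
                "predicted": int(rate >= threshold),
                "n_windows": len(test),
            })
        sdf = pd.DataFrame([r for r in sub_rows if r["sex"] == stratum])
        if sdf["label"].nunique() == 2:
            fpr, tpr, a = roc_auc(sdf["positive_rate"].to_numpy(),
                                  sdf["label"].to_numpy())
            roc[stratum], auc[stratum] = (fpr, tpr), a
    subjects_df = pd.DataFrame(sub_rows)
    if subjects_df["label"].nunique() == 2:
        fpr, tpr, a = roc_auc(subjects_df["positive_rate"].to_numpy(),
                              subjects_df["label"].to_numpy())
        roc["pooled"], auc["pooled"] = (fpr, tpr), a
    return ScreenResult(subjects=subjects_df, roc=roc, auc=auc,
                        threshold=threshold)


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and its trapezoidal area.

    Sweeps the unique score values as thresholds (score >= threshold
    is positive), anchored at (0,0) and (1,1).  The trapezoidal AUC
    equals the Mann-Whitney pair-counting statistic with ties counted
    one half.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must align")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC undefined with a single class")
    thresholds = np.unique(scores)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for th in thresholds:
        pred = scores >= th
        tpr.append(float((pred & (labels == 1)).sum()) / n_pos)
        fpr.append(float((pred & (labels == 0)).sum()) / n_neg)
    fpr.append(1.0)
    tpr.append(1.0)
    fpr = np.asarray(fpr)
    tpr = np.asarray(tpr)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def features_from_sessions(sessions, cfg=None) -> pd.DataFrame:
    """Per-window feature table straight from simulated or loaded sessions.

    ``sessions`` is an iterable of (manifest, streams, ...) tuples
    (extra elements such as simulator ground truth are ignored).  For
    each session the analysis-hand wrist streams of both agents feed
    an agency profile; the clinician-to-child transfer entropy on the
    hand spike trains, pooled over the session's windows, is broadcast
    to that subject's windows along with the session NSR.
    """
    from . import dyad_agency, infodyn, mms_core
    from .session_io import RunConfig

    cfg = cfg or RunConfig()
    hand = cfg.hand_placement
    per_subject = {}
    for session in sessions:
        man, streams = session[0], session[1]
        ch = streams[("child", hand)]
        cl = streams[("clinician", hand)]
        profile = dyad_agency.compute_agency_profile(
            {"child": ch, "clinician": cl}, cfg)
        child_win = profile.windows[profile.windows["agent"] == "child"]
        _, _, m_ch = mms_core.mms_from_stream(ch)
        _, _, m_cl = mms_core.mms_from_stream(cl)
        n = len(ch)
        grid = dyad_agency.window_segment(n, cfg)
        bits_ch = mms_core.binarize(m_ch, n).bits
        bits_cl = mms_core.binarize(m_cl, n).bits
        pairs = [(bits_ch[s:s + grid.window_samples],
                  bits_cl[s:s + grid.window_samples]) for s in grid.starts]
        te = infodyn.transfer_entropy(None, None, k=cfg.te_history_k,
                                      l=cfg.te_l, base=cfg.log_base,
                                      pairs=pairs)
        per_subject[man.subject_id] = {
            "windows": child_win,
            "sex": man.sex,
            "label": int(man.group_label == "ASD"),
            "nsr": profile.session["child"]["nsr"],
            "te": te.value,
        }
    return build_features(per_subject, cfg)
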