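"""Outcome labelling, ROC analysis and cohort summary tables.

Ventilatory deterioration is a tidal-volume drop of at least 20 ml between
the baseline session (t0) and the post-trial session (t2).  The predictive
value of the baseline global inhomogeneity index is quantified with an
explicit threshold sweep: candidate cutoffs are the midpoints between sorted
distinct scores plus ±∞, the classification rule is score > cutoff, and the
area under the curve equals the Mann–Whitney U statistic normalized by
n_pos·n_neg (ties counted ½) — the sweep and the rank statistic are two
routes to the same quantity and are kept equal by construction and by test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .indices import SessionIndices

#: SessionIndices scalar columns summarized in cohort tables
_SUMMARY_COLUMNS = (
    "rr",
    "tiv_percent",
    "delta_eeli_percent",
    "ir",
    "ir_adapt",
    "gi",
    "rsbi_eit",
)


@dataclass(frozen=True)
class PatientRecord:
    """Three sessions of one patient plus tidal volumes and the outcome."""

    subject_id: str
    indices_t0: SessionIndices
    indices_t1: SessionIndices
    indices_t2: SessionIndices
    vt_t0: float
    vt_t2: float
    deteriorated: bool | None = None

    def session(self, label: str) -> SessionIndices:
        return {"t0": self.indices_t0, "t1": self.indices_t1, "t2": self.indices_t2}[label]

    def resolve_label(self, delta_ml: float = 20.0) -> bool:
        if self.deteriorated is not None:
            return self.deteriorated
        return deterioration_label(self.vt_t0, self.vt_t2, delta_ml)


@dataclass(frozen=True)
class ROCResult:
    """Threshold sweep plus the rank-based AUC for one score/label set."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    chosen_cutoff: float
    n_pos: int
    n_neg: int
    scores: np.ndarray
    labels: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass(frozen=True)
class OperatingPoint:
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


def deterioration_label(vt_t0: float, vt_t2: float, delta_ml: float = 20.0) -> bool:
    """True iff the tidal volume dropped by at least ``delta_ml`` (inclusive).

    The 20 ml default guards against measurement error: smaller differences
    do not count as deterioration.
    """
    if vt_t0 <= 0 or vt_t2 <= 0:
        raise ValueError(f"tidal volumes must be positive, got {vt_t0} and {vt_t2}")
    return (vt_t0 - vt_t2) >= delta_ml


def roc_curve(scores, labels) -> ROCResult:
    """ROC of ``scores`` against boolean ``labels`` (high score = positive).

    The positive-class direction is fixed: a high baseline GI predicts
    deterioration; no automatic direction flipping is performed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC requires both classes; got {n_pos} positive and {n_neg} negative"
        )

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    pred = scores[None, :] > thresholds[:, None]
    tp = (pred & labels[None, :]).sum(axis=1)
    fp = (pred & ~labels[None, :]).sum(axis=1)
    sensitivity = tp / n_pos
    specificity = (n_neg - fp) / n_neg

    ranks = rankdata(scores)  # average ranks → ties count ½
    auc = (float(ranks[labels].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    youden = sensitivity + specificity - 1.0
    chosen = float(thresholds[int(np.argmax(youden))])
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=float(auc),
        chosen_cutoff=chosen,
        n_pos=n_pos,
        n_neg=n_neg,
        scores=scores.copy(),
        labels=labels.copy(),
    )


def operating_point(roc: ROCResult, cutoff: float) -> OperatingPoint:
    """Exact confusion counts of the rule score > cutoff."""
    pred = roc.scores > cutoff
    tp = int(np.sum(pred & roc.labels))
    fp = int(np.sum(pred & ~roc.labels))
    fn = roc.n_pos - tp
    tn = roc.n_neg - fp
    return OperatingPoint(
        sensitivity=tp / roc.n_pos,
        specificity=tn / roc.n_neg,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def session_indices_from_row(row) -> SessionIndices:
    """Rebuild a :class:`SessionIndices` from a flattened table row."""
    thresholds = sorted(
        int(key.rsplit("_", 1)[1])
        for key in row.keys()
        if key.startswith("sp_rvd_sd_")
    )
    return SessionIndices(
        subject_id=str(row["subject_id"]),
        session_label=str(row["session_label"]),
        rr=float(row["rr"]),
        tiv_au=float(row["tiv_au"]),
        tiv_percent=float(row["tiv_percent"]),
        eeli_au=float(row["eeli_au"]),
        delta_eeli_percent=float(row["delta_eeli_percent"]),
        ir=float(row["ir"]),
        ir_adapt=float(row["ir_adapt"]),
        gi=float(row["gi"]),
        gi_raw=float(row["gi_raw"]),
        sp_rvd={t: float(row[f"sp_rvd_{t}"]) for t in thresholds},
        sp_rvd_sd={t: float(row[f"sp_rvd_sd_{t}"]) for t in thresholds},
        sp_rvd_mean={t: float(row[f"sp_rvd_mean_{t}"]) for t in thresholds},
        rsbi_eit=float(row["rsbi_eit"]),
        n_breaths_selected=int(row["n_breaths_selected"]),
        rvd_unreached=int(row["rvd_unreached"]),
    )


def records_from_frames(indices_df: pd.DataFrame, vt_df: pd.DataFrame,
                        delta_ml: float = 20.0) -> list:
    """Assemble PatientRecords from an indices table and a V_T table.

    ``indices_df`` holds one row per patient-session; ``vt_df`` must provide
    subject_id, vt_t0 and vt_t2.  Labels are derived from the tidal volumes.
    """
    vt = vt_df.set_index("subject_id")
    records = []
    for subject, grp in indices_df.groupby("subject_id", sort=True):
        sessions = {row["session_label"]: session_indices_from_row(row)
                    for _, row in grp.iterrows()}
        missing = [l for l in ("t0", "t1", "t2") if l not in sessions]
        if missing:
            raise ValueError(
                f"subject {subject} is missing session(s) {missing}; all three "
                "time points are required for cohort summaries"
            )
        if subject not in vt.index:
            raise ValueError(f"subject {subject} has no tidal-volume entry")
        vrow = vt.loc[subject]
        rec = PatientRecord(
            subject_id=str(subject),
            indices_t0=sessions["t0"],
            indices_t1=sessions["t1"],
            indices_t2=sessions["t2"],
            vt_t0=float(vrow["vt_t0"]),
            vt_t2=float(vrow["vt_t2"]),
        )
        records.append(
            PatientRecord(
                **{**rec.__dict__, "deteriorated": rec.resolve_label(delta_ml)}
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """One row per patient-session, with tidal volumes and the outcome."""
    rows = []
    for rec in records:
        label = rec.resolve_label()
        for session in ("t0", "t1", "t2"):
            row = rec.session(session).as_row()
            row["vt_t0"] = rec.vt_t0
            row["vt_t2"] = rec.vt_t2
            row["deteriorated"] = label
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(records, group_by: str | None = None,
                   log_gi: bool = False) -> pd.DataFrame:
    """Median and IQR of every index per time point, optionally per group.

    Quantiles use linear interpolation.  ``group_by='deterioration'`` splits
    the cohort by the outcome label; ``log_gi`` adds the natural-log GI (the
    transformation conventionally applied before parametric testing).
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("cohort summary requires at least 2 records")
    if group_by not in (None, "deterioration"):
        raise ValueError(f"unknown group_by {group_by!r}")

    if group_by is None:
        groups = {"all": records}
    else:
        groups = {
            "deteriorated": [r for r in records if r.resolve_label()],
            "stable": [r for r in records if not r.resolve_label()],
        }
        for name, grp in groups.items():
            if len(grp) == 0:
                raise ValueError(f"group {name!r} is empty")

    columns = list(_SUMMARY_COLUMNS)
    rows = []
    for gname, grp in groups.items():
        for session in ("t0", "t1", "t2"):
            table = pd.DataFrame([r.session(session).as_row() for r in grp])
            rvd_cols = [c for c in table.columns if c.startswith("sp_rvd_")]
            for col in columns + rvd_cols:
                vals = table[col].to_numpy(dtype=float)
                rows.append(_quantile_row(gname, session, col, vals))
            if log_gi:
                rows.append(
                    _quantile_row(gname, session, "log_gi",
                                  np.log(table["gi"].to_numpy(dtype=float)))
                )
        for vt_name, vals in (
            ("vt_t0", [r.vt_t0 for r in grp]),
            ("vt_t2", [r.vt_t2 for r in grp]),
        ):
            rows.append(_quantile_row(gname, "-", vt_name, np.asarray(vals, float)))
    return pd.DataFrame(rows)


def _quantile_row(group: str, session: str, index: str, vals: np.ndarray) -> dict:
    return {
        "group": group,
        "session": session,
        "index": index,
        "median": float(np.median(vals)),
        "q25": float(np.percentile(vals, 25)),
        "q75": float(np.percentile(vals, 75)),
        "n": int(len(vals)),
    }


def plot_roc(roc: ROCResult, path) -> None:
    """Write a ROC curve figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(1.0 - roc.specificity)
    fpr = (1.0 - roc.specificity)[order]
    tpr = roc.sensitivity[order]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
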