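"""Rate-corrected QT intervals, per-event QTc aggregation, and diLQTS adjudication.

Two correction rules are supported:

* Bazett: ``QTc = QT / RR**(1/2)`` — used by the alert firing rule.
* QRS-adjusted Fridericia: ``QTc = (QT - max(0, QRS - 100)) / RR**(1/3)`` —
  used by the outcome adjudication.  QT and QRS are in milliseconds, RR in
  seconds, so both corrections are the identity at RR = 1 s (for QRS <= 100).

diLQTS is adjudicated from the post-exposure window: true when the maximum
post QTc is >= 500 ms, or exceeds the pre-exposure maximum by more than
60 ms (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QtAggregates",
    "qtc_bazett",
    "qtc_adjusted_fridericia",
    "add_qtc_columns",
    "aggregate_qtc",
    "adjudicate_dilqts",
]

#: Post-exposure surveillance window (hours) after the anchor timestamp.
DEFAULT_POST_WINDOW_H = 1.0


def _check_positive(value, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be positive and finite")


def qtc_bazett(qt_ms, rr_s):
    """Bazett-corrected QT: ``qt_ms / rr_s**0.5``.

    Parameters
    ----------
    qt_ms : float or array-like
        QT interval in milliseconds, must be > 0.
    rr_s : float or array-like
        RR interval in seconds, must be > 0.

    Returns
    -------
    float or ndarray
        Corrected QT in milliseconds.
    """
    _check_positive(qt_ms, "qt_ms")
    _check_positive(rr_s, "rr_s")
    out = np.asarray(qt_ms, dtype=float) / np.asarray(rr_s, dtype=float) ** 0.5
    return float(out) if out.ndim == 0 else out


def qtc_adjusted_fridericia(qt_ms, qrs_ms, rr_s):
    """QRS-adjusted Fridericia correction.

    Returns ``(qt_ms - max(0, qrs_ms - 100)) / rr_s**(1/3)``: the QRS
    duration in excess of 100 ms is subtracted from QT before the cube-root
    rate correction, so the formula reduces to plain Fridericia for narrow
    complexes (QRS <= 100 ms).
    """
    _check_positive(qt_ms, "qt_ms")
    _check_positive(rr_s, "rr_s")
    qrs = np.asarray(qrs_ms, dtype=float)
    if np.any(qrs < 0):
        raise ValueError("qrs_ms must be non-negative")
    excess = np.maximum(0.0, qrs - 100.0)
    out = (np.asarray(qt_ms, dtype=float) - excess) / np.asarray(rr_s, dtype=float) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def add_qtc_columns(ecgs: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of an ECG table with both derived QTc columns.

    Expects columns ``qt_ms``, ``qrs_ms`` and ``rr_s``; adds
    ``qtc_bazett_ms`` and ``qtc_adjfrid_ms``.
    """
    out = ecgs.copy()
    out["qtc_bazett_ms"] = qtc_bazett(out["qt_ms"].to_numpy(), out["rr_s"].to_numpy())
    out["qtc_adjfrid_ms"] = qtc_adjusted_fridericia(
        out["qt_ms"].to_numpy(), out["qrs_ms"].to_numpy(), out["rr_s"].to_numpy()
    )
    return out


@dataclass(frozen=True)
class QtAggregates:
    """Pre/post QTc summaries for one index event.

    Missing windows are flagged by a zero count; the corresponding
    max/mean fields are NaN.
    """

    max_pre_qt: float
    mean_pre_qt: float
    max_post_qt: float
    mean_post_qt: float
    n_pre: int
    n_post: int


def aggregate_qtc(
    ecgs: pd.DataFrame,
    order_ts,
    t_anchor=None,
    post_window_h: float = DEFAULT_POST_WINDOW_H,
) -> QtAggregates:
    """Aggregate adjusted-Fridericia QTc before the order and after the anchor.

    Pre-window: all ECGs strictly before ``order_ts``.  Post-window: ECGs in
    the half-open interval ``(t_anchor, t_anchor + post_window_h]`` where
    ``t_anchor`` defaults to ``order_ts`` and is otherwise the later of the
    order and alert timestamps.

    ``ecgs`` needs columns ``ts`` and either ``qtc_adjfrid_ms`` or the raw
    fields from which it can be derived.  An empty table yields both windows
    flagged missing.
    """
    if post_window_h <= 0:
        raise ValueError("post_window_h must be positive")
    if t_anchor is None:
        t_anchor = order_ts
    if len(ecgs) == 0:
        return QtAggregates(np.nan, np.nan, np.nan, np.nan, 0, 0)
    if "qtc_adjfrid_ms" not in ecgs.columns:
        ecgs = add_qtc_columns(ecgs)
    ts = pd.to_datetime(ecgs["ts"])
    qtc = ecgs["qtc_adjfrid_ms"].to_numpy(dtype=float)

    pre = qtc[(ts < pd.Timestamp(order_ts)).to_numpy()]
    hi = pd.Timestamp(t_anchor) + pd.Timedelta(hours=post_window_h)
    post_mask = (ts > pd.Timestamp(t_anchor)) & (ts <= hi)
    post = qtc[post_mask.to_numpy()]

    return QtAggregates(
        max_pre_qt=float(pre.max()) if pre.size else np.nan,
        mean_pre_qt=float(pre.mean()) if pre.size else np.nan,
        max_post_qt=float(post.max()) if post.size else np.nan,
        mean_post_qt=float(post.mean()) if post.size else np.nan,
        n_pre=int(pre.size),
        n_post=int(post.size),
    )


def adjudicate_dilqts(agg: QtAggregates) -> bool | None:
    """Adjudicate drug-induced long-QT from pre/post aggregates.

    True iff ``max_post_qt >= 500`` (inclusive) or
    ``max_post_qt - max_pre_qt > 60`` (strict).  Returns ``None`` when the
    post window is empty (adjudication missing, not false).  With a missing
    pre-window maximum the delta clause evaluates false and the 500 ms
    clause alone decides.
    """
    if agg.n_post == 0 or not np.isfinite(agg.max_post_qt):
        return None
    if agg.max_post_qt >= 500.0:
        return True
    if agg.n_pre > 0 and np.isfinite(agg.max_pre_qt):
        return bool(agg.max_post_qt - agg.max_pre_qt > 60.0)
    return False
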