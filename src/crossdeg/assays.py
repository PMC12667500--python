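"""Quantification of the validation assays.

* qRT-PCR relative expression by the 2^-ddCt method with a reference gene
  and a calibrator group (per-sample dCt = Ct_target - Ct_reference;
  ddCt = dCt - mean calibrator dCt; RQ = 2**(-ddCt)).
* Cell viability from plate optical densities:
  100 * (OD - mean OD_positive) / (mean OD_negative - mean OD_positive),
  where negative controls define 100% and positive (no-cell) controls 0%.
  Values are not clipped.
* ABR thresholds from per-intensity waveform detectability on the
  5-90 dB SPL grid in 5 dB steps: the lowest intensity from which every
  higher intensity is also detectable; 90 dB SPL when nothing is
  detectable.  Threshold shifts are post minus pre, with shifts reaching
  the 90 dB ceiling flagged as censored.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .simulate import ABR_CEILING_DB, ABR_GRID_DB

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# qRT-PCR
# ---------------------------------------------------------------------------

def ddct_quantify(
    records: pd.DataFrame, calibrator_group: str = "control"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative quantities by 2^-ddCt.

    ``records`` needs columns ``sample_id``, ``group``, ``ct_target``,
    ``ct_reference``.  Returns (per-sample table with delta_ct/ddct/rq,
    per-group mean +- SD of RQ).
    """
    for col in ("sample_id", "group", "ct_target", "ct_reference"):
        if col not in records.columns:
            raise ValidationError(f"Ct table lacks column {col!r}")
    bad = records[~np.isfinite(records["ct_reference"].astype(float))]
    if len(bad):
        raise ValidationError(
            f"sample {bad.iloc[0]['sample_id']!r} has no finite reference Ct"
        )
    if not (records["group"] == calibrator_group).any():
        raise ValidationError(f"no sample in calibrator group {calibrator_group!r}")
    out = records.copy()
    out["delta_ct"] = out["ct_target"].astype(float) - out["ct_reference"].astype(float)
    cal_mean = out.loc[out["group"] == calibrator_group, "delta_ct"].mean()
    out["ddct"] = out["delta_ct"] - cal_mean
    out["rq"] = 2.0 ** (-out["ddct"])
    summary = (
        out.groupby("group")["rq"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
        .sort_values("group")
        .reset_index(drop=True)
    )
    return out, summary


# ---------------------------------------------------------------------------
# Viability
# ---------------------------------------------------------------------------

def relative_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-experimental-well viability percentage (unclipped).

    ``plate`` needs columns ``well``, ``role`` in {experiment, negative,
    positive} and ``od``.
    """
    for col in ("well", "role", "od"):
        if col not in plate.columns:
            raise ValidationError(f"plate table lacks column {col!r}")
    roles = set(plate["role"])
    for needed in ("negative", "positive"):
        if needed not in roles:
            raise ValidationError(f"plate has no {needed} control well")
    neg = plate.loc[plate["role"] == "negative", "od"].astype(float).mean()
    pos = plate.loc[plate["role"] == "positive", "od"].astype(float).mean()
    if neg == pos:
        raise DegenerateInputError(
            "mean negative and positive control ODs are equal"
        )
    exp = plate[plate["role"] == "experiment"].copy()
    exp["viability_pct"] = 100.0 * (exp["od"].astype(float) - pos) / (neg - pos)
    return exp.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ABR
# ---------------------------------------------------------------------------

def abr_threshold(series: pd.DataFrame) -> int:
    """Threshold (dB SPL) of one frequency's detectability series.

    ``series`` needs columns ``intensity_db`` and ``detectable`` covering
    the full 5-90 dB grid.  The threshold is the lowest intensity above
    which every flag is true; 90 when no intensity is detectable.
    Non-monotone detectability is logged (visual-scoring ambiguity).
    """
    got = sorted(int(v) for v in series["intensity_db"])
    if got != list(ABR_GRID_DB):
        off = set(got) ^ set(ABR_GRID_DB)
        raise ValidationError(
            f"intensity grid must be 5-90 dB in 5 dB steps; mismatch at {sorted(off)}"
        )
    s = series.sort_values("intensity_db")
    det = s["detectable"].astype(bool).to_numpy()
    grid = s["intensity_db"].astype(int).to_numpy()
    if not det.any():
        return ABR_CEILING_DB
    # lowest intensity from which detection persists upward
    idx = len(det)
    for i in range(len(det) - 1, -1, -1):
        if det[i]:
            idx = i
        else:
            break
    thr = int(grid[idx]) if idx < len(det) else ABR_CEILING_DB
    if det[:idx].any():
        log.warning(
            "non-monotone detectability below %d dB; using persistence rule", thr
        )
    return thr


def abr_thresholds(series: pd.DataFrame) -> pd.DataFrame:
    """Thresholds per (timepoint, frequency) group of a long ABR table."""
    keys = [k for k in ("timepoint", "frequency_khz") if k in series.columns]
    rows = []
    for key, grp in series.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(keys, key)) | {"threshold_db": abr_threshold(grp)})
    return pd.DataFrame(rows)


def threshold_shift(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Per-frequency shift = post - pre (dB), ceiling-censored shifts flagged.

    Both tables need columns ``frequency_khz`` and ``threshold_db`` on the
    same frequency grid.
    """
    fpre = sorted(pre["frequency_khz"].astype(int))
    fpost = sorted(post["frequency_khz"].astype(int))
    if fpre != fpost:
        raise ValidationError(
            f"frequency grids differ: pre {fpre} vs post {fpost}"
        )
    a = pre.set_index("frequency_khz")["threshold_db"]
    b = post.set_index("frequency_khz")["threshold_db"]
    out = pd.DataFrame(
        {
            "frequency_khz": a.index,
            "pre_db": a.to_numpy(),
            "post_db": b.reindex(a.index).to_numpy(),
        }
    )
    out["shift_db"] = out["post_db"] - out["pre_db"]
    out["censored"] = out["post_db"] >= ABR_CEILING_DB
    return out.reset_index(drop=True)
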