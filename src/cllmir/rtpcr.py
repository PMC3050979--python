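"""Relative RT-PCR quantification by the delta-delta-Ct method.

Per sample, replicate Ct values are averaged per target; the sample's
delta-Ct is mean Ct(target) minus mean Ct(reference small RNA, RNU44 by
default). Differencing against a calibrator sample (or the mean delta-Ct
of a calibrator group, conventionally the resting control B cells)
gives delta-delta-Ct, and fold change = 2**(-ddCt) under perfect
doubling per cycle. Replicate scatter is propagated in cycles as
sqrt(sd_target^2 + sd_reference^2).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["delta_ct", "delta_delta_ct"]

REFERENCE_DEFAULT = "RNU44"


def _validate_ct(table: pd.DataFrame) -> pd.DataFrame:
    needed = {"sample_id", "target", "ct"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = table["ct"].astype(float)
    if not ((ct > 0) & (ct < 50)).all():
        bad = table.loc[~((ct > 0) & (ct < 50))]
        raise ValueError(
            f"Ct values outside (0, 50) for rows: {bad.index.tolist()[:5]}"
        )
    return table


def delta_ct(table: pd.DataFrame, reference: str = REFERENCE_DEFAULT) -> pd.DataFrame:
    """Per (sample, target): replicate-mean delta-Ct vs the reference.

    Returns a frame with columns ``sample_id, target, delta_ct, sd``
    (sd in cycles, propagated from target and reference replicates).
    Raises if any sample with target rows lacks reference rows.
    """
    table = _validate_ct(table)
    agg = (
        table.groupby(["sample_id", "target"])["ct"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )
    refs = agg[agg["target"] == reference].set_index("sample_id")
    rows = []
    for (sid, tgt), grp in agg[agg["target"] != reference].groupby(
        ["sample_id", "target"], sort=True
    ):
        if sid not in refs.index:
            raise ValueError(
                f"sample {sid!r} has no reference ({reference!r}) measurements"
            )
        t = grp.iloc[0]
        r = refs.loc[sid]
        rows.append(
            (
                sid,
                tgt,
                float(t["mean"] - r["mean"]),
                float(np.sqrt(t["sd"] ** 2 + r["sd"] ** 2)),
            )
        )
    return pd.DataFrame(rows, columns=["sample_id", "target", "delta_ct", "sd"])


def delta_delta_ct(
    table: pd.DataFrame,
    reference: str = REFERENCE_DEFAULT,
    calibrator: str | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Relative expression per (sample, target) by delta-delta-Ct.

    ``calibrator`` is a sample id or an iterable of sample ids (a
    group); a group calibrates against the mean of its per-sample
    delta-Ct values, per target. Returns columns ``sample_id, target,
    delta_ct, delta_delta_ct, fold, replicate_sd``.
    """
    dct = delta_ct(table, reference=reference)
    if calibrator is None:
        raise ValueError("a calibrator sample or group must be designated")
    cal_ids = [calibrator] if isinstance(calibrator, str) else list(calibrator)
    missing = set(cal_ids) - set(dct["sample_id"])
    if missing:
        raise ValueError(f"calibrator samples absent from Ct table: {sorted(missing)}")

    cal_dct = (
        dct[dct["sample_id"].isin(cal_ids)]
        .groupby("target")["delta_ct"]
        .mean()
    )
    out = dct.copy()
    base = out["target"].map(cal_dct)
    if base.isna().any():
        bad = sorted(out.loc[base.isna(), "target"].unique())
        raise ValueError(f"calibrator has no measurements for targets: {bad}")
    out["delta_delta_ct"] = out["delta_ct"] - base
    out["fold"] = np.power(2.0, -out["delta_delta_ct"])
    out = out.rename(columns={"sd": "replicate_sd"})
    return out[
        ["sample_id", "target", "delta_ct", "delta_delta_ct", "fold", "replicate_sd"]
    ]
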