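"""Relative expression by the comparative-Ct (2^-ddCt) method.

Per animal and assay, replicate Ct values are averaged, the multiplexed
endogenous control (e.g. 18S rRNA) is subtracted (dCt), the calibrator
group's mean dCt is subtracted in turn (ddCt), and fold change is
2^(-ddCt) assuming ideal doubling per cycle.  An animal is *detected* for
an assay only when more than half of its target replicates amplified;
non-detected animals carry no dCt and are reported as a separate count,
never imputed into group fold changes.  Group fold change is the geometric
mean of per-animal folds over detected animals (equivalently
2^(-mean ddCt)).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

ND_TOKEN = "ND"

_REQUIRED = ["animal_id", "group", "assay_id", "replicate", "ct_target", "ct_control"]


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    """Read a Ct table; the literal token ``ND`` (or an empty cell) marks a
    non-detect and becomes NaN."""
    df = pd.read_csv(path, sep="\t", na_values=[ND_TOKEN], dtype={"animal_id": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    df["ct_target"] = pd.to_numeric(df["ct_target"], errors="coerce")
    df["ct_control"] = pd.to_numeric(df["ct_control"], errors="coerce")
    return df


def write_ct_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("ct_target", "ct_control"):
        out[col] = out[col].map(lambda v: ND_TOKEN if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def aggregate_ct(records: pd.DataFrame, nondetect_ct: float = 40.0) -> pd.DataFrame:
    """Per-(animal, assay) replicate aggregation.

    Ct values at or beyond ``nondetect_ct`` count as non-detects alongside
    NaN.  Returns one row per (animal_id, group, assay_id) with mean target
    and control Ct over detected replicates, a ``detected`` flag (majority
    rule) and ``delta_ct`` for detected animals.
    """
    df = records.copy()
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"Ct records missing column {col!r}")
    df.loc[df["ct_target"] >= nondetect_ct, "ct_target"] = np.nan
    df.loc[df["ct_control"] >= nondetect_ct, "ct_control"] = np.nan

    rows = []
    for (animal, group, assay), sub in df.groupby(
        ["animal_id", "group", "assay_id"], sort=True
    ):
        n_rep = len(sub)
        tgt = sub["ct_target"].dropna()
        ctl = sub["ct_control"].dropna()
        if ctl.empty:
            raise ValueError(
                f"control failure: all control replicates non-detect for "
                f"animal {animal!r}, assay {assay!r}"
            )
        detected = len(tgt) > n_rep / 2
        mean_t = float(tgt.mean()) if detected else math.nan
        delta = mean_t - float(ctl.mean()) if detected else math.nan
        rows.append(
            {
                "animal_id": animal,
                "group": group,
                "assay_id": assay,
                "n_replicates": n_rep,
                "n_detected": len(tgt),
                "ct_target_mean": mean_t,
                "ct_control_mean": float(ctl.mean()),
                "detected": detected,
                "delta_ct": delta,
            }
        )
    return pd.DataFrame(rows)


def relative_expression(
    aggregated: pd.DataFrame, calibrator_group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ddCt fold changes referenced to the calibrator group.

    Returns ``(per_animal, per_group)``: per detected animal the ddCt and
    fold = 2^(-ddCt); per (group, assay) the geometric-mean fold over
    detected animals and the non-detect count.  The calibrator group's own
    geometric-mean fold is 1 by construction.
    """
    if calibrator_group not in set(aggregated["group"]):
        raise ValueError(f"unknown calibrator group {calibrator_group!r}")

    cal = aggregated[(aggregated["group"] == calibrator_group) & aggregated["detected"]]
    cal_mean = cal.groupby("assay_id")["delta_ct"].mean()

    per_animal_rows = []
    for r in aggregated.itertuples():
        if not r.detected:
            continue
        if r.assay_id not in cal_mean.index:
            raise ValueError(
                f"calibrator group {calibrator_group!r} has no detected animal "
                f"for assay {r.assay_id!r}"
            )
        ddct = r.delta_ct - float(cal_mean[r.assay_id])
        per_animal_rows.append(
            {
                "animal_id": r.animal_id,
                "group": r.group,
                "assay_id": r.assay_id,
                "delta_ct": r.delta_ct,
                "delta_delta_ct": ddct,
                "fold": 2.0 ** (-ddct),
                "detected": True,
            }
        )
    per_animal = pd.DataFrame(per_animal_rows)

    group_rows = []
    for (group, assay), sub in aggregated.groupby(["group", "assay_id"], sort=True):
        det = per_animal[
            (per_animal["group"] == group) & (per_animal["assay_id"] == assay)
        ] if not per_animal.empty else per_animal
        n_nd = int((~sub["detected"]).sum())
        if len(det):
            gm_fold = float(2.0 ** (-det["delta_delta_ct"].mean()))
        else:
            gm_fold = math.nan
        group_rows.append(
            {
                "group": group,
                "assay_id": assay,
                "n_detected": len(det),
                "n_nondetect": n_nd,
                "geomean_fold": gm_fold,
            }
        )
    return per_animal, pd.DataFrame(group_rows)
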