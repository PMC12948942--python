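"""SCL-5 phenotype construction.

The 5-item Hopkins Symptom Checklist is scored 1 (not bothered) to
4 (very bothered) per item.  A person-wave receives a raw score only when
at least two items were answered; the raw score is the mean of answered
items multiplied by the number of items (5), giving a 5-20 scale.  Raw
scores are log-transformed to reduce right skew and standardized within an
analysis stratum before modelling.  The lockdown time covariate counts
calendar days since 2020-03-12.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

__all__ = [
    "LOCKDOWN_START",
    "score_scl5",
    "score_scl5_frame",
    "transform_scores",
    "overall_adolescent_score",
    "days_since_lockdown",
    "score_phenotype_table",
]

LOCKDOWN_START = _dt.date(2020, 3, 12)
N_ITEMS = 5
MIN_ITEMS = 2

ITEM_COLS = [f"item{j}" for j in range(1, 6)]


class ScoringError(ValueError):
    pass


def score_scl5(items) -> float:
    """Raw SCL-5 score from five ordinal responses (NaN/None = missing).

    Mean of answered items times 5 when at least two items were answered,
    otherwise NaN.  Items outside 1-4 raise.
    """
    arr = np.asarray([np.nan if v is None else v for v in items], dtype=float)
    if arr.shape != (N_ITEMS,):
        raise ScoringError(f"expected {N_ITEMS} items, got {arr.shape}")
    answered = ~np.isnan(arr)
    bad = answered & ((arr < 1) | (arr > 4) | (arr != np.round(arr)))
    if bad.any():
        raise ScoringError(f"item responses outside 1-4 at positions {np.where(bad)[0].tolist()}")
    if answered.sum() < MIN_ITEMS:
        return float("nan")
    return float(arr[answered].mean() * N_ITEMS)


def score_scl5_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`score_scl5` over the item1..item5 columns."""
    items = df[ITEM_COLS].to_numpy(dtype=float)
    answered = ~np.isnan(items)
    bad = answered & ((items < 1) | (items > 4) | (items != np.round(items)))
    if bad.any():
        rows = np.unique(np.where(bad)[0])[:10]
        ids = df.iloc[rows]["person_id"].tolist() if "person_id" in df else rows.tolist()
        raise ScoringError(f"item responses outside 1-4 in records {ids}")
    n_answered = answered.sum(axis=1)
    sums = np.where(answered, items, 0.0).sum(axis=1)
    raw = np.divide(
        sums, n_answered, out=np.full(len(items), np.nan), where=n_answered >= MIN_ITEMS
    ) * N_ITEMS
    return pd.Series(raw, index=df.index, name="raw_score")


def transform_scores(raw: pd.Series | np.ndarray) -> pd.Series:
    """Natural log, then z-score within the given stratum; NaN propagates.

    The stratum must contain at least two non-missing scores with nonzero
    variance; a degenerate stratum raises rather than returning NaN/inf.
    """
    s = pd.Series(np.asarray(raw, dtype=float))
    ok = s.notna()
    if ok.sum() < 2:
        raise ScoringError(f"stratum has {int(ok.sum())} non-missing scores; need >= 2")
    logged = np.log(s[ok])
    sd = logged.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ScoringError("stratum scores are constant; cannot standardize")
    out = pd.Series(np.nan, index=s.index, name="transformed_score")
    out[ok] = (logged - logged.mean()) / sd
    if isinstance(raw, pd.Series):
        out.index = raw.index
    return out


def overall_adolescent_score(raw_by_wave) -> float:
    """Mean raw score across available waves (NaN if none answered).

    The pooled-sample log-transform/standardization happens afterwards via
    :func:`transform_scores` on the resulting vector of person means.
    """
    arr = np.asarray(raw_by_wave, dtype=float)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def days_since_lockdown(date) -> int:
    """Calendar days between 2020-03-12 and ``date`` (>= that day)."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if isinstance(date, _dt.datetime):
        date = date.date()
    delta = (date - LOCKDOWN_START).days
    if delta < 0:
        raise ScoringError(f"{date} precedes the lockdown start {LOCKDOWN_START}")
    return int(delta)


def score_phenotype_table(
    pheno: pd.DataFrame, *, overall: bool = False, cutoff_flag: bool = False
) -> pd.DataFrame:
    """Score a long phenotype table (one row per person-wave).

    Adds ``raw_score`` and ``transformed_score`` (standardized within each
    (role, wave) stratum) and a ``days`` column copied from
    ``date_offset_days``.  With ``overall=True``, additionally returns one
    row per person with the mean-across-waves score standardized within the
    pooled sample (wave 0), appended below the per-wave rows.
    """
    out = pheno.copy()
    out["raw_score"] = score_scl5_frame(out)
    out["days"] = out["date_offset_days"].astype(int)
    out["transformed_score"] = np.nan
    for (_, _), idx in out.groupby(["role", "wave"]).groups.items():
        sub = out.loc[idx, "raw_score"]
        if sub.notna().sum() >= 2:
            out.loc[idx, "transformed_score"] = transform_scores(sub)
    if cutoff_flag:
        out["above_cutoff"] = (out["raw_score"] / N_ITEMS) >= 2.0
    if not overall:
        return out

    per_person = (
        out.groupby(["person_id", "family_id", "maternal_cluster_id", "role"])["raw_score"]
        .apply(lambda s: overall_adolescent_score(s.to_numpy()))
        .reset_index(name="raw_score")
    )
    per_person["wave"] = 0  # wave 0 marks the pooled overall score
    per_person["days"] = 0
    per_person["transformed_score"] = transform_scores(per_person["raw_score"])
    first = out.sort_values("wave").groupby("person_id", as_index=False).first()
    carry = [
        c
        for c in out.columns
        if c
        not in per_person.columns
        and c not in ITEM_COLS
        and c not in ("latent", "date_offset_days")
    ]
    per_person = per_person.merge(first[["person_id"] + carry], on="person_id", how="left")
    return pd.concat([out, per_person], ignore_index=True)
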