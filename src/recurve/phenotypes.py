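"""From raw calving records to the analysis table.

Reproductive efficiency (Re) expresses, as a percentage, how close a cow's
realized calving history is to the optimum of a first calving at
``afc_opt`` months (default 24) followed by one calf every ``ci_opt``
months (default 12).  Two formulations are provided:

* ``time`` (default): Re_n = 100 * (afc_opt + (n-1) ci_opt) / age_n —
  the ratio of the optimal to the realized age at the n-th calving;
* ``count``: Re_n = 100 * n / optimal_parity_count(age_n) — realized over
  optimal number of calvings at the cow's age.

Both are capped at 100 (a cow cannot beat the optimum) when ``cap`` is on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 365.25 / 12.0

AFC_OPT_MONTHS = 24.0
CI_OPT_MONTHS = 12.0
N_RES_CLASSES = 6


@dataclass
class ReReport:
    """Diagnostics accumulated while building / filtering the table."""

    n_input: int = 0
    n_output: int = 0
    dropped_cows_nonmonotone: list = field(default_factory=list)
    n_dropped_missing: int = 0
    n_dropped_max_cn: int = 0
    small_hys_groups: list = field(default_factory=list)


def optimal_age_months(cn, afc_opt: float = AFC_OPT_MONTHS, ci_opt: float = CI_OPT_MONTHS):
    return afc_opt + (np.asarray(cn, dtype=float) - 1.0) * ci_opt


def re_from_age(cn, age_months, afc_opt: float = AFC_OPT_MONTHS,
                ci_opt: float = CI_OPT_MONTHS, formula: str = "time",
                cap: bool = True):
    """Re at calving ``cn`` for a cow aged ``age_months`` at that calving."""
    cn = np.asarray(cn, dtype=float)
    age = np.asarray(age_months, dtype=float)
    if np.any(age <= 0):
        raise ValueError("ages must be positive")
    if formula == "time":
        re = 100.0 * optimal_age_months(cn, afc_opt, ci_opt) / age
    elif formula == "count":
        optimal_n = np.maximum(1.0, 1.0 + np.floor((age - afc_opt) / ci_opt))
        re = 100.0 * cn / optimal_n
    else:
        raise ValueError(f"unknown Re formula {formula!r}")
    if cap:
        re = np.minimum(re, 100.0)
    return re


def assign_hys(herd, year, season) -> str:
    """Deterministic herd-year-season contemporary group code."""
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in (herd, year, season)):
        raise ValueError("herd, year and season must all be present")
    return f"{herd}_{year}_{season}"


def flag_small_hys(codes: pd.Series, min_size: int = 3) -> list:
    counts = codes.value_counts()
    return sorted(counts.index[counts < min_size].tolist())


def compute_re(records: pd.DataFrame, birth_dates: pd.Series,
               afc_opt: float = AFC_OPT_MONTHS, ci_opt: float = CI_OPT_MONTHS,
               formula: str = "time", cap: bool = True,
               fc: pd.Series | None = None, fc_class: pd.Series | None = None,
               min_hys_size: int = 3) -> tuple[pd.DataFrame, ReReport]:
    """Build the per-calving analysis table from raw calving records.

    ``records`` needs columns cow, calving_date, herd, season;
    ``birth_dates`` maps cow id -> birth date.  Cows with non-monotone
    calving dates are rejected (listed in the report); rows with missing
    herd/season are dropped.  Optional ``fc``/``fc_class`` attach the
    cow's inbreeding coefficient / class.
    """
    report = ReReport(n_input=len(records))
    rec = records.copy()
    rec["calving_date"] = pd.to_datetime(rec["calving_date"])
    complete = rec[["cow", "calving_date", "herd", "season"]].notna().all(axis=1)
    report.n_dropped_missing = int((~complete).sum())
    rec = rec[complete]

    # calving order is taken as given: a cow whose dates are not strictly
    # increasing in input order carries a recording error and is rejected
    bad_cows = []
    for cow, grp in rec.groupby("cow", sort=False):
        d = grp["calving_date"].to_numpy()
        if len(d) > 1 and not (np.diff(d) > np.timedelta64(0, "ns")).all():
            bad_cows.append(cow)
    if bad_cows:
        report.dropped_cows_nonmonotone = bad_cows
        rec = rec[~rec["cow"].isin(bad_cows)]
    rec = rec.sort_values(["cow", "calving_date"], kind="mergesort")

    birth = pd.to_datetime(birth_dates)
    rec = rec[rec["cow"].isin(birth.index)]
    cn = rec.groupby("cow", sort=False).cumcount().to_numpy() + 1
    age_days = (rec["calving_date"].to_numpy()
                - birth.loc[rec["cow"]].to_numpy()).astype("timedelta64[D]").astype(float)
    age_months = age_days / DAYS_PER_MONTH

    table = pd.DataFrame(
        {
            "cow": rec["cow"].to_numpy(),
            "cn": cn,
            "age_months": age_months,
            "re": re_from_age(cn, age_months, afc_opt, ci_opt, formula, cap),
            "hys": [assign_hys(h, y, s) for h, y, s in
                    zip(rec["herd"], rec["calving_date"].dt.year, rec["season"])],
            "res_class": np.minimum(cn, N_RES_CLASSES),
            "year": rec["calving_date"].dt.year.to_numpy(),
        }
    )
    if fc is not None:
        table["fc"] = pd.Series(fc).reindex(table["cow"]).to_numpy()
    if fc_class is not None:
        table["fc_class"] = pd.Series(fc_class).reindex(table["cow"]).to_numpy()
    report.small_hys_groups = flag_small_hys(table["hys"], min_hys_size)
    report.n_output = len(table)
    return table.reset_index(drop=True), report


def filter_records(table: pd.DataFrame, max_cn: int = 9,
                   drop_incomplete: bool = True,
                   report: ReReport | None = None) -> tuple[pd.DataFrame, ReReport]:
    """Structural filters: calving-number cap and incomplete rows."""
    report = report or ReReport(n_input=len(table))
    out = table
    if drop_incomplete:
        complete = out.notna().all(axis=1)
        report.n_dropped_missing += int((~complete).sum())
        out = out[complete]
    over = out["cn"] > max_cn
    report.n_dropped_max_cn = int(over.sum())
    out = out[~over]
    if out.empty:
        raise ValueError("no records left after filtering")
    report.n_output = len(out)
    return out.reset_index(drop=True), report


def descriptive_stats(values) -> dict:
    """Mean, SD, min, max and CV% of a vector (CV missing when mean is 0)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    return {"mean": mean, "sd": sd, "min": float(v.min()),
            "max": float(v.max()), "cv_pct": cv, "n": int(v.size)}
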