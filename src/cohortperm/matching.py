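"""Exact 1:1 age/sex matching and demographic summary tables.

Matching is exact on the stratum key (integer age in years, sex): within each
stratum, ``min(n_cases, n_controls)`` pairs are formed by seeded uniform
sampling without replacement, and members in strata with no counterpart are
dropped and reported.  After matching, the two arms have identical age and
sex distributions by construction (standardized differences of exactly zero),
while unmatched covariates such as healthcare-contact intensity are left
free — which is the point of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class MatchingError(ValueError):
    pass


@dataclass
class MatchedCohorts:
    """1:1 matched pairs plus the members no stratum could absorb."""

    pairs: pd.DataFrame               # case_id, control_id, age, sex
    dropped_cases: list[str]
    dropped_controls: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self, arm: str) -> pd.Series:
        return self.pairs["case_id" if arm == "case" else "control_id"]


def exact_match(cases: pd.DataFrame, controls: pd.DataFrame,
                seed: int | np.random.Generator | None = None) -> MatchedCohorts:
    """Exact 1:1 matching on (age, sex) by seeded sampling without replacement.

    ``cases`` and ``controls`` need ``member_id``, ``age`` and ``sex``
    columns.  Raises :class:`MatchingError` when no stratum is shared.
    """
    for name, frame in (("cases", cases), ("controls", controls)):
        missing = {"member_id", "age", "sex"} - set(frame.columns)
        if missing:
            raise MatchingError(f"{name} table missing columns {sorted(missing)}")
        if frame[["age", "sex"]].isna().any().any():
            raise MatchingError(f"{name} table has missing age or sex")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def strata(frame: pd.DataFrame) -> dict:
        ordered = frame.sort_values("member_id")
        return {
            key: grp["member_id"].to_numpy()
            for key, grp in ordered.groupby(["age", "sex"], sort=True)
        }

    case_strata, control_strata = strata(cases), strata(controls)
    shared = sorted(set(case_strata) & set(control_strata))
    if not shared:
        raise MatchingError("cases and controls share no (age, sex) stratum")

    rows, dropped_cases, dropped_controls = [], [], []
    for key in sorted(set(case_strata) | set(control_strata)):
        cs = case_strata.get(key, np.array([], dtype=object))
        ks = control_strata.get(key, np.array([], dtype=object))
        k = min(cs.size, ks.size)
        picked_c = rng.choice(cs, size=k, replace=False) if k else np.array([], dtype=object)
        picked_k = rng.choice(ks, size=k, replace=False) if k else np.array([], dtype=object)
        for cid, kid in zip(picked_c, picked_k):
            rows.append((cid, kid, key[0], key[1]))
        dropped_cases.extend(sorted(set(cs) - set(picked_c)))
        dropped_controls.extend(sorted(set(ks) - set(picked_k)))

    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "age", "sex"])
    return MatchedCohorts(pairs, dropped_cases, dropped_controls)


def apply_matching(cohort: pd.DataFrame, matched: MatchedCohorts, arm: str) -> pd.DataFrame:
    """Subset a cohort table to its matched members (arm is 'case' or 'control')."""
    ids = matched.matched_ids(arm)
    return cohort[cohort["member_id"].isin(set(ids))].reset_index(drop=True)


def standardized_difference(x_case, x_control) -> float:
    """Standardized mean difference (pooled population SD); 0 when identical."""
    x1, x0 = np.asarray(x_case, float), np.asarray(x_control, float)
    pooled = np.sqrt((x1.var() + x0.var()) / 2.0)
    diff = x1.mean() - x0.mean()
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return float(diff / pooled)


def demographic_summary(cohort: pd.DataFrame, label: str = "") -> pd.Series:
    """One demographic-table column: counts, sex split, age, depression, facts.

    Standard deviations are population SDs over members (ddof=0).
    """
    if cohort.empty:
        raise MatchingError("cannot summarize an empty cohort")
    male = (cohort["sex"] == "male").mean() * 100.0
    out = pd.Series({
        "members": float(len(cohort)),
        "pct_male": male,
        "pct_female": 100.0 - male,
        "age_mean": cohort["age"].mean(),
        "age_sd": cohort["age"].std(ddof=0),
        "pct_depression": cohort["exposed_depression"].mean() * 100.0,
        "facts_per_year_mean": cohort["facts_per_year"].mean(),
        "facts_per_year_sd": cohort["facts_per_year"].std(ddof=0),
    }, name=label or None)
    return out.astype(float)


def demographic_table(populations: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Side-by-side demographic columns for several populations."""
    return pd.DataFrame({label: demographic_summary(frame, label)
                         for label, frame in populations.items()})
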