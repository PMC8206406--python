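"""Seeded generator of synthetic claims datasets with the statistical
structure the control-sensitivity analysis assumes.

The generator emulates a private-insurer claims feed: an age/sex-structured
membership, multi-year enrollment spans, age-increasing glucose-test ordering
(the informative-missingness mechanism), lab orders of which only a subset
return a value, latent type 2 diabetes and depression statuses joined through
a configurable comorbidity odds ratio, and diagnosis-code ("fact") intensity
gradients by age and disease burden.  Every member's latent state is recorded
in a truth table so parameter-recovery tests have an oracle.

Depression and diabetes are linked through a 2x2 latent joint distribution:
the user supplies the depression prevalence among the diabetes-free and the
true comorbidity odds ratio theta, which makes the quantity the downstream
association pipeline estimates an explicit config value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import codes
from .claims import ClaimsDataset, qualifying_windows, window_length_days

_EPOCH = np.datetime64("1970-01-01")


class ConfigError(ValueError):
    pass


def _day(datestr: str) -> int:
    return int((np.datetime64(datestr) - _EPOCH).astype(int))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic claims population.

    Ages are drawn from a truncated normal mixture; disease prevalences are
    logistic in age for diabetes and conditional on diabetes for depression;
    glucose-test ordering intensity rises linearly with age; background
    diagnosis ("fact") rates rise with age and with disease burden.  Rates
    are per member-year; lab values are percent (HbA1c) or mg/dL (glucose).
    """

    n_members: int = 100_000
    seed: int = 0

    # demographics
    age_mixture: tuple = ((0.35, 32.0, 9.0), (0.40, 52.0, 11.0), (0.25, 71.0, 9.0))
    age_min: int = 18
    age_max: int = 95
    sex_ratio_male: float = 0.48

    # enrollment
    enroll_start_first: str = "2008-01-01"
    enroll_start_last: str = "2014-12-31"
    p_enrolled_4y: float = 0.90          # probability the span covers >= window_years
    long_span_extra_mean_years: float = 2.0
    window_years: int = 4

    # latent disease structure.  Diabetes risk is logistic in age with a male
    # offset; depression risk is logit-quadratic in age (claims-coded
    # depression peaks in middle age) with the comorbidity odds ratio theta
    # acting multiplicatively on the odds for diabetic members.
    t2d_logit_intercept: float = -5.5    # p_t2d(age) = expit(intercept + slope*age + male*extra)
    t2d_logit_age_slope: float = 0.06
    t2d_logit_male_extra: float = 0.20
    p_depression_given_not_t2d: float = 0.2438   # at the reference age
    dep_reference_age: float = 50.0
    dep_logit_age_slope: float = 0.1484
    dep_logit_age_curv: float = -0.009058
    comorbidity_or: float = 1.28         # true depression-vs-T2D odds ratio (theta)

    # glucose/HbA1c testing intensity (orders per member-year, linear in age)
    test_intensity_base: float = -0.10
    test_intensity_age_slope: float = 0.018
    p_value_returned: float = 0.534      # fraction of orders with a returned value
    frac_hba1c: float = 0.40             # returned values that are HbA1c
    frac_fasting: float = 0.33           # glucose values coded as fasting

    # lab value distributions (normal, clipped positive), by latent T2D
    hba1c_mean_sd: tuple = (5.55, 0.40)
    hba1c_mean_sd_t2d: tuple = (7.90, 1.40)
    glucose_mean_sd: tuple = (95.0, 12.0)
    glucose_mean_sd_t2d: tuple = (170.0, 45.0)

    # background diagnosis ("fact") rate per member-year; the base may be
    # negative (the rate is clipped at zero) so the age gradient can be steep
    facts_base: float = -15.5
    facts_age_slope: float = 0.85
    facts_t2d_extra: float = 10.9
    facts_depression_extra: float = 8.0

    # disease code emission.  Depression coding is exact by default because
    # the exposure is *defined* as the presence of depression-care codes, so
    # the latent flag is the observed care status; sensitivity/false-positive
    # knobs exist for robustness experiments.
    t2d_dx_rate: float = 1.5             # T2D diagnoses per year once documented
    t2d_sensitivity: float = 0.95        # P(a true T2D member is coded at all)
    p_t2d_med: float = 0.85              # P(coded T2D member fills a T2D medication)
    med_refill_rate: float = 0.75        # extra pharmacy claims per year
    p_false_t2d_dx: float = 0.002        # stray T2D code on a diabetes-free member
    p_t1d: float = 0.003                 # members carrying type 1 codes (+ insulin)
    dep_dx_rate: float = 0.7
    dep_sensitivity: float = 1.0
    p_false_dep_dx: float = 0.0
    p_family_history: float = 0.05

    @property
    def p_depression_given_t2d(self) -> float:
        """Depression prevalence of diabetic members at the reference age."""
        return float(expit(logit(self.p_depression_given_not_t2d)
                           + np.log(self.comorbidity_or)))

    def p_depression(self, age: np.ndarray, t2d: np.ndarray) -> np.ndarray:
        """Depression probability by age and latent diabetes status.

        At any fixed age the depression-vs-diabetes odds ratio equals
        ``comorbidity_or``; the marginal over ages follows the quadratic
        age profile.
        """
        x = np.asarray(age, float) - self.dep_reference_age
        lg = (logit(self.p_depression_given_not_t2d)
              + self.dep_logit_age_slope * x
              + self.dep_logit_age_curv * x ** 2
              + np.log(self.comorbidity_or) * np.asarray(t2d, float))
        return expit(lg)

    def validate(self) -> None:
        if self.n_members <= 0:
            raise ConfigError("n_members must be positive")
        probs = {
            "sex_ratio_male": self.sex_ratio_male,
            "p_enrolled_4y": self.p_enrolled_4y,
            "p_depression_given_not_t2d": self.p_depression_given_not_t2d,
            "p_value_returned": self.p_value_returned,
            "frac_hba1c": self.frac_hba1c,
            "frac_fasting": self.frac_fasting,
            "t2d_sensitivity": self.t2d_sensitivity,
            "p_t2d_med": self.p_t2d_med,
            "p_false_t2d_dx": self.p_false_t2d_dx,
            "p_t1d": self.p_t1d,
            "dep_sensitivity": self.dep_sensitivity,
            "p_false_dep_dx": self.p_false_dep_dx,
            "p_family_history": self.p_family_history,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 < self.p_depression_given_not_t2d < 1.0:
            raise ConfigError("p_depression_given_not_t2d must be inside (0, 1)")
        if self.comorbidity_or <= 0:
            raise ConfigError("comorbidity_or must be positive")
        weights = [w for w, _, _ in self.age_mixture]
        if abs(sum(weights) - 1.0) > 1e-9 or min(weights) < 0:
            raise ConfigError("age_mixture weights must be non-negative and sum to 1")
        for rate in (self.t2d_dx_rate, self.dep_dx_rate, self.med_refill_rate):
            if rate < 0:
                raise ConfigError("rates must be non-negative")
        if self.window_years <= 0:
            raise ConfigError("window_years must be positive")

    def test_intensity(self, age: np.ndarray) -> np.ndarray:
        """Expected glucose-test orders per member-year at each age."""
        return np.clip(self.test_intensity_base
                       + self.test_intensity_age_slope * np.asarray(age, float), 0.0, None)

    def facts_rate(self, age: np.ndarray, t2d: np.ndarray, dep: np.ndarray) -> np.ndarray:
        """Background diagnosis-code rate per member-year."""
        rate = (self.facts_base + self.facts_age_slope * np.asarray(age, float)
                + self.facts_t2d_extra * np.asarray(t2d, float)
                + self.facts_depression_extra * np.asarray(dep, float))
        return np.clip(rate, 0.0, None)

    def p_t2d(self, age: np.ndarray, male: np.ndarray | None = None) -> np.ndarray:
        lg = self.t2d_logit_intercept + self.t2d_logit_age_slope * np.asarray(age, float)
        if male is not None:
            lg = lg + self.t2d_logit_male_extra * np.asarray(male, float)
        return expit(lg)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("age_mixture", "hba1c_mean_sd", "hba1c_mean_sd_t2d",
                    "glucose_mean_sd", "glucose_mean_sd_t2d"):
            if key in raw:
                raw[key] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x
                                 for x in raw[key]) if key == "age_mixture" else tuple(raw[key])
        return cls(**raw)


def _uniform_days(rng: np.random.Generator, counts: np.ndarray,
                  start_day: np.ndarray, horizon: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-member counts into (member_index, absolute day) pairs with
    dates uniform on each member's [start, start+horizon) interval."""
    idx = np.repeat(np.arange(counts.size), counts)
    if idx.size == 0:
        return idx, idx.copy()
    days = start_day[idx] + rng.integers(0, np.maximum(horizon[idx], 1))
    return idx, days


class _EventBuffer:
    """Accumulates event blocks as flat arrays before one DataFrame build.

    Events are ordered by (member, date) with remaining ties broken by the
    deterministic construction order, so a fixed seed yields a byte-identical
    table.
    """

    def __init__(self, member_ids: np.ndarray):
        self.member_ids = member_ids
        self.blocks: list[dict] = []

    def add(self, idx: np.ndarray, days: np.ndarray, kind: str, system: str,
            code: np.ndarray | str, value: np.ndarray | None = None) -> None:
        if idx.size == 0:
            return
        self.blocks.append({
            "idx": idx,
            "date": days,
            "kind": np.full(idx.size, kind, dtype=object),
            "system": np.full(idx.size, system, dtype=object),
            "code": (np.full(idx.size, code, dtype=object)
                     if isinstance(code, str) else np.asarray(code, dtype=object)),
            "value": np.full(idx.size, np.nan) if value is None else value,
        })

    def frame(self) -> pd.DataFrame:
        if not self.blocks:
            return pd.DataFrame({
                "member_id": pd.Series([], dtype=str),
                "date": pd.Series([], dtype="datetime64[ns]"),
                "kind": pd.Series([], dtype=str),
                "system": pd.Series([], dtype=str),
                "code": pd.Series([], dtype=str),
                "value": pd.Series([], dtype=float),
            })
        cols = {name: np.concatenate([b[name] for b in self.blocks])
                for name in ("idx", "date", "kind", "system", "code", "value")}
        order = np.lexsort((cols["date"], cols["idx"]))
        ev = pd.DataFrame({
            "member_id": self.member_ids[cols["idx"][order]],
            "date": pd.to_datetime(cols["date"][order], unit="D"),
            "kind": cols["kind"][order],
            "system": cols["system"][order],
            "code": cols["code"][order],
            "value": cols["value"][order].astype(float),
        })
        return ev


def generate(config: SyntheticConfig,
             seed: int | None = None) -> tuple[ClaimsDataset, pd.DataFrame]:
    """Generate a claims dataset and its latent truth table.

    Deterministic for a fixed seed (``config.seed`` unless overridden).
    Returns ``(dataset, truth)`` where ``truth`` has one row per member with
    columns ``member_id, true_t2d, true_depression, tested``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_members
    member_ids = np.array([f"M{i:07d}" for i in range(n)], dtype=object)

    # demographics
    weights = np.array([w for w, _, _ in config.age_mixture])
    means = np.array([m for _, m, _ in config.age_mixture])
    sds = np.array([s for _, _, s in config.age_mixture])
    comp = rng.choice(weights.size, size=n, p=weights)
    age = np.clip(np.round(rng.normal(means[comp], sds[comp])),
                  config.age_min, config.age_max).astype(int)
    sex = np.where(rng.random(n) < config.sex_ratio_male, "male", "female").astype(object)

    # enrollment: one span per member, starting uniformly in the intake range
    first, last = _day(config.enroll_start_first), _day(config.enroll_start_last)
    start_day = rng.integers(first, last + 1, size=n)
    long_span = rng.random(n) < config.p_enrolled_4y
    span_years = np.where(
        long_span,
        config.window_years + rng.exponential(config.long_span_extra_mean_years, n),
        rng.uniform(1.0, max(config.window_years - 0.1, 1.0), n),
    )
    span_days = np.maximum((span_years * 365.25).astype(int), 365)
    start_ts = pd.to_datetime(start_day, unit="D")
    birth_year = start_ts.year.to_numpy() - age

    # latent statuses
    t2d = rng.random(n) < config.p_t2d(age, male=(sex == "male"))
    dep = rng.random(n) < config.p_depression(age, t2d)

    wdays = window_length_days(config.window_years)
    horizon_window = np.minimum(span_days, wdays)   # phenotype-defining events
    wyears = horizon_window / 365.25

    buf = _EventBuffer(member_ids)

    # background diagnosis stream over the full span
    facts = config.facts_rate(age, t2d, dep)
    counts = rng.poisson(facts * span_days / 365.25)
    idx, days = _uniform_days(rng, counts, start_day, span_days)
    buf.add(idx, days, "diagnosis", "ICD9",
            np.array(codes.BACKGROUND_DX, dtype=object)[rng.integers(0, len(codes.BACKGROUND_DX), idx.size)])

    # T2D diagnoses and medications
    documented = t2d & (rng.random(n) < config.t2d_sensitivity)
    n_t2d_dx = np.where(
        documented, 1 + rng.poisson(np.maximum(config.t2d_dx_rate * wyears - 1, 0.0)), 0)
    false_t2d = ~t2d & (rng.random(n) < config.p_false_t2d_dx)
    n_t2d_dx = n_t2d_dx + false_t2d.astype(int)
    idx, days = _uniform_days(rng, n_t2d_dx, start_day, horizon_window)
    buf.add(idx, days, "diagnosis", "ICD9", "250.00")

    on_med = documented & (rng.random(n) < config.p_t2d_med)
    n_fills = np.where(on_med, 1 + rng.poisson(config.med_refill_rate * wyears), 0)
    idx, days = _uniform_days(rng, n_fills, start_day, horizon_window)
    med_codes = np.array(sorted(codes.T2D_MED_NDC), dtype=object)
    buf.add(idx, days, "pharmacy", "NDC", med_codes[rng.integers(0, med_codes.size, idx.size)])

    # type 1 diagnoses (excluded from every cohort downstream) + insulin
    t1d = rng.random(n) < config.p_t1d
    idx, days = _uniform_days(rng, t1d.astype(int), start_day, horizon_window)
    buf.add(idx, days, "diagnosis", "ICD9", "250.01")
    ins_codes = np.array(sorted(codes.INSULIN_NDC), dtype=object)
    idx, days = _uniform_days(rng, t1d.astype(int), start_day, horizon_window)
    buf.add(idx, days, "pharmacy", "NDC", ins_codes[rng.integers(0, ins_codes.size, idx.size)])

    # family history of diabetes
    famhx = rng.random(n) < config.p_family_history
    idx, days = _uniform_days(rng, famhx.astype(int), start_day, horizon_window)
    buf.add(idx, days, "diagnosis", "ICD9", "V18.0")

    # depression diagnoses
    dep_doc = dep & (rng.random(n) < config.dep_sensitivity)
    n_dep_dx = np.where(
        dep_doc, 1 + rng.poisson(np.maximum(config.dep_dx_rate * wyears - 1, 0.0)), 0)
    false_dep = ~dep & (rng.random(n) < config.p_false_dep_dx)
    n_dep_dx = n_dep_dx + false_dep.astype(int)
    idx, days = _uniform_days(rng, n_dep_dx, start_day, horizon_window)
    buf.add(idx, days, "diagnosis", "ICD9", "311")

    # glucose / HbA1c orders, a subset of which return values
    n_orders = rng.poisson(config.test_intensity(age) * wyears)
    oidx, odays = _uniform_days(rng, n_orders, start_day, horizon_window)
    cpt = np.array(sorted(codes.LAB_ORDER_CPT), dtype=object)
    buf.add(oidx, odays, "procedure", "CPT", cpt[rng.integers(0, cpt.size, oidx.size)])

    returned = rng.random(oidx.size) < config.p_value_returned
    ridx, rdays = oidx[returned], odays[returned]
    is_a1c = rng.random(ridx.size) < config.frac_hba1c
    loinc = np.empty(ridx.size, dtype=object)
    a1c_codes = np.array(sorted(codes.HBA1C_LOINC), dtype=object)
    loinc[is_a1c] = a1c_codes[rng.integers(0, a1c_codes.size, int(is_a1c.sum()))]
    glu = ~is_a1c
    fasting = rng.random(ridx.size) < config.frac_fasting
    rand_codes = np.array(sorted(codes.RANDOM_GLUCOSE_LOINC), dtype=object)
    loinc[glu & fasting] = "1558-6"
    n_rand = int((glu & ~fasting).sum())
    loinc[glu & ~fasting] = rand_codes[rng.integers(0, rand_codes.size, n_rand)]

    member_t2d = t2d[ridx]
    a1c_mu = np.where(member_t2d, config.hba1c_mean_sd_t2d[0], config.hba1c_mean_sd[0])
    a1c_sd = np.where(member_t2d, config.hba1c_mean_sd_t2d[1], config.hba1c_mean_sd[1])
    glu_mu = np.where(member_t2d, config.glucose_mean_sd_t2d[0], config.glucose_mean_sd[0])
    glu_sd = np.where(member_t2d, config.glucose_mean_sd_t2d[1], config.glucose_mean_sd[1])
    value = np.where(is_a1c, rng.normal(a1c_mu, a1c_sd), rng.normal(glu_mu, glu_sd))
    value = np.round(np.clip(value, 0.1, None), 1)
    buf.add(ridx, rdays, "lab_result", "LOINC", loinc.astype(str), value)

    members = pd.DataFrame({
        "member_id": member_ids, "sex": sex, "birth_year": birth_year,
    })
    enrollment = pd.DataFrame({
        "member_id": member_ids,
        "start": pd.to_datetime(start_day, unit="D"),
        "end": pd.to_datetime(start_day + span_days - 1, unit="D"),
    })
    ds = ClaimsDataset(members, enrollment, buf.frame())

    ordered = np.zeros(n, dtype=bool)
    np.add.at(ordered, oidx, True)
    truth = pd.DataFrame({
        "member_id": member_ids,
        "true_t2d": t2d,
        "true_depression": dep,
        "tested": ordered,
    })
    return ds, truth


def empirical_summary(ds: ClaimsDataset, truth: pd.DataFrame,
                      window_years: int = 4) -> dict:
    """Moments of a generated dataset that the generator targets.

    Returns a dict with per-age-decade glucose-test ordering intensity
    (orders per member-year over the observation window), latent prevalences,
    the value-return fraction, and the mean age of tested vs untested members.
    """
    windows = qualifying_windows(ds.enrollment, years=window_years)
    ev = ds.events
    orders = ev[(ev["kind"] == "procedure") & ev["code"].isin(codes.LAB_ORDER_CPT)]
    merged = orders.merge(windows, on="member_id")
    in_win = merged[(merged["date"] >= merged["start"]) & (merged["date"] <= merged["end"])]
    per_member = in_win.groupby("member_id").size().reindex(
        windows["member_id"], fill_value=0)

    info = windows.merge(ds.members, on="member_id")
    info["age"] = info["start"].dt.year - info["birth_year"]
    info["decade"] = (info["age"] // 10) * 10
    info["orders_per_year"] = per_member.to_numpy() / window_years
    by_decade = info.groupby("decade")["orders_per_year"].agg(["mean", "count"])

    results = ev[(ev["kind"] == "lab_result")
                 & ev["code"].isin(codes.GLUCOSE_LOINC | codes.HBA1C_LOINC)]
    n_orders = len(orders)
    merged_truth = truth.merge(ds.members, on="member_id")
    merged_truth["age"] = pd.to_datetime(
        ds.enrollment.set_index("member_id").loc[merged_truth["member_id"], "start"]
    ).dt.year.to_numpy() - merged_truth["birth_year"]

    dep_by_t2d = truth.groupby("true_t2d")["true_depression"].mean()
    return {
        "tests_by_decade": by_decade,
        "p_t2d": float(truth["true_t2d"].mean()),
        "p_depression": float(truth["true_depression"].mean()),
        "p_depression_by_t2d": dep_by_t2d.to_dict(),
        "value_return_fraction": float(len(results) / n_orders) if n_orders else float("nan"),
        "mean_age_tested": float(merged_truth.loc[merged_truth["tested"], "age"].mean()),
        "mean_age_untested": float(merged_truth.loc[~merged_truth["tested"], "age"].mean()),
    }


def write_truth(truth: pd.DataFrame, directory: str | Path) -> None:
    Path(directory).mkdir(parents=True, exist_ok=True)
    truth.to_csv(Path(directory) / "truth.csv", index=False)
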