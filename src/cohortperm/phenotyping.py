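"""Rule-based phenotyping: the type 2 diabetes case algorithm, four control
definition variants, and the depression exposure definition.

The case algorithm is a claims-adapted eMERGE-style rule tree: at least one
type 2 diabetes diagnosis, supported by either a diabetes medication or an
abnormal glucose / HbA1c value, and not explained by type-1-only coding.

All four control variants share the same exclusions (no diabetes diagnosis of
either type, no diabetes medication, no family-history code, a minimum number
of distinct claims) and differ only in the glucose-testing requirement:

* ``baseline``          — at least one returned glucose/HbA1c value, and every
                          returned value below its normal bound;
* ``ignore_lab_value``  — at least one returned value, values unchecked;
* ``ignore_lab``        — no lab condition at all;
* ``no_lab``            — no glucose/HbA1c order (CPT) and no returned value.

By construction baseline <= ignore_lab_value <= ignore_lab, no_lab <=
ignore_lab, and ignore_lab_value is disjoint from no_lab; the gap between
ignore_lab and the union of the other two is exactly the members with an
order but no returned value — the informative-missingness margin.

Numeric thresholds are config-overridable.  The defaults follow the usual
clinical conventions (abnormal: fasting glucose >= 126 mg/dL, random glucose
>= 200 mg/dL, HbA1c >= 6.5%; control-side normal bounds: < 110, < 140,
< 6.0%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codes
from .claims import ClaimsDataset, facts_per_year_table, qualifying_windows

CONTROL_VARIANTS = ("baseline", "ignore_lab_value", "ignore_lab", "no_lab")


class PhenotypingError(ValueError):
    pass


@dataclass
class CodeSets:
    """Named code vocabularies driving the rules engine (all config-loadable)."""

    t2d_dx: frozenset = codes.T2D_DX
    t1d_dx: frozenset = codes.T1D_DX
    depression_dx: frozenset = codes.DEPRESSION_DX
    family_history: frozenset = codes.FAMILY_HISTORY_DX
    fasting_glucose_loinc: frozenset = codes.FASTING_GLUCOSE_LOINC
    random_glucose_loinc: frozenset = codes.RANDOM_GLUCOSE_LOINC
    hba1c_loinc: frozenset = codes.HBA1C_LOINC
    lab_order_cpt: frozenset = codes.LAB_ORDER_CPT
    t2d_meds: frozenset = codes.T2D_MED_NDC
    insulin_meds: frozenset = codes.INSULIN_NDC

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            setattr(self, name, frozenset(getattr(self, name)))
        if self.t2d_dx & self.t1d_dx:
            raise PhenotypingError("t2d_dx and t1d_dx code sets overlap")

    @property
    def glucose_loinc(self) -> frozenset:
        return self.fasting_glucose_loinc | self.random_glucose_loinc

    @property
    def result_loinc(self) -> frozenset:
        return self.glucose_loinc | self.hba1c_loinc

    @property
    def diabetes_meds(self) -> frozenset:
        return self.t2d_meds | self.insulin_meds

    @classmethod
    def from_dict(cls, raw: dict) -> "CodeSets":
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PhenotypingError(f"unknown code set names: {sorted(unknown)}")
        return cls(**{k: frozenset(v) for k, v in raw.items()})


@dataclass
class PhenotypeConfig:
    """Window length, visit minimum, lab thresholds, and code sets."""

    window_years: int = 4
    min_visits: int = 2
    # case-side abnormal thresholds
    abnormal_fasting_glucose: float = 126.0
    abnormal_random_glucose: float = 200.0
    abnormal_hba1c: float = 6.5
    # control-side normal bounds (values must be strictly below these)
    normal_fasting_glucose: float = 110.0
    normal_random_glucose: float = 140.0
    normal_hba1c: float = 6.0
    code_sets: CodeSets = field(default_factory=CodeSets)

    def __post_init__(self) -> None:
        pairs = (
            (self.normal_fasting_glucose, self.abnormal_fasting_glucose),
            (self.normal_random_glucose, self.abnormal_random_glucose),
            (self.normal_hba1c, self.abnormal_hba1c),
        )
        for bound, threshold in pairs:
            if bound > threshold:
                raise PhenotypingError(
                    "control-side normal bound exceeds case-side abnormal threshold")
        if self.min_visits < 0:
            raise PhenotypingError("min_visits must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhenotypeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cs = raw.pop("code_sets", None)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PhenotypingError(f"unknown phenotype config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cs:
            cfg.code_sets = CodeSets.from_dict(cs)
        return cfg

    def to_dict(self) -> dict:
        out = asdict(self)
        out["code_sets"] = {k: sorted(v) for k, v in out["code_sets"].items()}
        return out


def _event_flags(events: pd.DataFrame, cfg: PhenotypeConfig) -> pd.DataFrame:
    """Per-event booleans for every rule the case/control trees consult.

    Code-set membership is evaluated on the factorized code vocabulary (tens
    of distinct codes, not millions of rows), which keeps prefix matching
    cheap on large claim tables.
    """
    cs = cfg.code_sets
    code_ids, uniques = pd.factorize(events["code"].astype(str))
    uniq = pd.Series(uniques, dtype=str)

    def member_of(codeset: frozenset, prefix: bool = False) -> np.ndarray:
        if not codeset:
            return np.zeros(len(events), dtype=bool)
        per_uniq = (uniq.str.startswith(tuple(codeset)) if prefix
                    else uniq.isin(codeset)).to_numpy()
        return per_uniq[code_ids]

    kind = events["kind"].to_numpy()
    value = pd.to_numeric(events["value"], errors="coerce").to_numpy()

    dx = kind == "diagnosis"
    rx = kind == "pharmacy"
    proc = kind == "procedure"
    lab = kind == "lab_result"

    is_fasting = lab & member_of(cs.fasting_glucose_loinc)
    is_random = lab & member_of(cs.random_glucose_loinc)
    is_a1c = lab & member_of(cs.hba1c_loinc)
    is_result = is_fasting | is_random | is_a1c

    with np.errstate(invalid="ignore"):
        abnormal = (
            (is_fasting & (value >= cfg.abnormal_fasting_glucose))
            | (is_random & (value >= cfg.abnormal_random_glucose))
            | (is_a1c & (value >= cfg.abnormal_hba1c))
        )
        # a result fails the control-side check unless strictly below its bound
        nonnormal = is_result & ~(
            (is_fasting & (value < cfg.normal_fasting_glucose))
            | (is_random & (value < cfg.normal_random_glucose))
            | (is_a1c & (value < cfg.normal_hba1c))
        )
    return pd.DataFrame({
        "member_id": events["member_id"].to_numpy(),
        "claim": True,
        "t2d_dx": dx & member_of(cs.t2d_dx, prefix=True),
        "t1d_dx": dx & member_of(cs.t1d_dx, prefix=True),
        "depression_dx": dx & member_of(cs.depression_dx, prefix=True),
        "family_history": dx & member_of(cs.family_history),
        "diabetes_med": rx & member_of(cs.diabetes_meds),
        "lab_order": proc & member_of(cs.lab_order_cpt),
        "lab_result": is_result,
        "abnormal_value": abnormal,
        "nonnormal_value": nonnormal,
    })


_FEATURE_COLUMNS = ("n_claims", "has_t2d_dx", "has_t1d_dx", "has_depression_dx",
                    "has_family_history", "has_diabetes_med", "n_orders",
                    "n_results", "has_abnormal", "has_nonnormal")


def _aggregate_features(flags: pd.DataFrame) -> pd.DataFrame:
    ids, uniques = pd.factorize(flags["member_id"], sort=True)
    n = uniques.size

    def count(col: str) -> np.ndarray:
        return np.bincount(ids, weights=flags[col].to_numpy(), minlength=n).astype(int)

    out = pd.DataFrame({
        "n_claims": count("claim"),
        "has_t2d_dx": count("t2d_dx") > 0,
        "has_t1d_dx": count("t1d_dx") > 0,
        "has_depression_dx": count("depression_dx") > 0,
        "has_family_history": count("family_history") > 0,
        "has_diabetes_med": count("diabetes_med") > 0,
        "n_orders": count("lab_order"),
        "n_results": count("lab_result"),
        "has_abnormal": count("abnormal_value") > 0,
        "has_nonnormal": count("nonnormal_value") > 0,
    }, index=pd.Index(uniques, name="member_id"))
    return out


def _empty_features(member_ids) -> pd.DataFrame:
    out = pd.DataFrame(index=pd.Index(member_ids, name="member_id"),
                       columns=_FEATURE_COLUMNS)
    out[["n_claims", "n_orders", "n_results"]] = 0
    out[[c for c in _FEATURE_COLUMNS if c.startswith("has_")]] = False
    return out


def member_features(events: pd.DataFrame, cfg: PhenotypeConfig) -> pd.Series:
    """Rule-tree features for a single member's windowed events."""
    if events.empty:
        return _empty_features(["_"]).iloc[0]
    feats = _aggregate_features(_event_flags(events, cfg))
    if len(feats) != 1:
        raise PhenotypingError("member_features expects events from a single member")
    return feats.iloc[0]


def _case_rule(f) -> "pd.Series | bool":
    # family-history is kept out of the default tree; claims lack structured
    # family history and V18.0 serves the control-side exclusion instead
    return (f["has_t2d_dx"]
            & (f["has_diabetes_med"] | f["has_abnormal"])
            & ~(f["has_t1d_dx"] & ~f["has_t2d_dx"]))


def _shared_control_exclusions(f, cfg: PhenotypeConfig):
    return (~f["has_t2d_dx"] & ~f["has_t1d_dx"] & ~f["has_diabetes_med"]
            & ~f["has_family_history"] & (f["n_claims"] >= cfg.min_visits))


def _control_rule(f, cfg: PhenotypeConfig, variant: str):
    if variant not in CONTROL_VARIANTS:
        raise PhenotypingError(
            f"unknown control variant {variant!r}; expected one of {CONTROL_VARIANTS}")
    ok = _shared_control_exclusions(f, cfg)
    if variant == "baseline":
        return ok & (f["n_results"] > 0) & ~f["has_nonnormal"]
    if variant == "ignore_lab_value":
        return ok & (f["n_results"] > 0)
    if variant == "ignore_lab":
        return ok
    return ok & (f["n_orders"] == 0) & (f["n_results"] == 0)  # no_lab


def classify_case(events: pd.DataFrame, cfg: PhenotypeConfig) -> bool:
    """Does the case rule tree fire for this member's windowed events?"""
    return bool(_case_rule(member_features(events, cfg)))


def classify_control(events: pd.DataFrame, cfg: PhenotypeConfig, variant: str) -> bool:
    """Control eligibility for one member under a named variant."""
    return bool(_control_rule(member_features(events, cfg), cfg, variant))


def classify_exposure(events: pd.DataFrame, cfg: PhenotypeConfig) -> bool:
    """Exposed iff any windowed diagnosis falls in the depression rollup."""
    return bool(member_features(events, cfg)["has_depression_dx"])


def _exclusion_reason(f, case, control, cfg: PhenotypeConfig, variant: str) -> np.ndarray:
    """First failing rule, in rule-tree order, for audit logs."""
    lab_reason = {
        "baseline": "no_normal_lab_value",
        "ignore_lab_value": "no_returned_lab_value",
        "ignore_lab": "unclassified",
        "no_lab": "has_lab_test",
    }[variant]
    conditions = [
        case | control,
        f["has_t2d_dx"].to_numpy(),
        f["has_t1d_dx"].to_numpy(),
        f["has_diabetes_med"].to_numpy(),
        f["has_family_history"].to_numpy(),
        (f["n_claims"] < cfg.min_visits).to_numpy(),
    ]
    choices = ["", "t2d_dx_not_case", "t1d_dx", "diabetes_med", "family_history",
               "below_min_visits"]
    return np.select(conditions, choices, default=lab_reason)


def build_cohorts(ds: ClaimsDataset, cfg: PhenotypeConfig,
                  variants: tuple[str, ...] = CONTROL_VARIANTS) -> dict[str, pd.DataFrame]:
    """Window, classify and label every eligible member, per control variant.

    Returns one cohort table per variant with columns ``member_id, status
    (case/control/excluded), variant, exposed_depression, age, sex,
    facts_per_year, exclusion_reason``.  The case set is identical across
    variants.  Raises :class:`PhenotypingError` naming the variant if the
    case or a control population comes out empty.
    """
    windows = qualifying_windows(ds.enrollment, years=cfg.window_years)
    if windows.empty:
        raise PhenotypingError("no member has a qualifying enrollment window")
    ev = ds.events.merge(windows, on="member_id", how="inner")
    ev = ev[(ev["date"] >= ev["start"]) & (ev["date"] <= ev["end"])]

    if ev.empty:
        feats = _empty_features(windows["member_id"])
    else:
        agg = _aggregate_features(_event_flags(ev, cfg))
        # members with a window but no windowed events still need a row
        pos = agg.index.get_indexer(windows["member_id"])
        hit = pos >= 0
        data = {}
        for col in _FEATURE_COLUMNS:
            dtype = int if col.startswith("n_") else bool
            arr = np.zeros(len(windows), dtype=dtype)
            arr[hit] = agg[col].to_numpy()[pos[hit]]
            data[col] = arr
        feats = pd.DataFrame(data, index=pd.Index(windows["member_id"],
                                                  name="member_id"))

    info = windows.merge(ds.members, on="member_id", how="left")
    age = (info["start"].dt.year - info["birth_year"]).to_numpy()
    sex = info["sex"].to_numpy()
    facts = facts_per_year_table(ds.events, windows, years=cfg.window_years).to_numpy()

    case = _case_rule(feats).to_numpy()
    exposed = feats["has_depression_dx"].to_numpy()
    if not case.any():
        raise PhenotypingError("case population is empty")

    out: dict[str, pd.DataFrame] = {}
    for variant in variants:
        control = _control_rule(feats, cfg, variant).to_numpy() & ~case
        if not control.any():
            raise PhenotypingError(f"control population is empty for variant {variant!r}")
        status = np.where(case, "case", np.where(control, "control", "excluded"))
        table = pd.DataFrame({
            "member_id": feats.index.to_numpy(),
            "status": status,
            "variant": variant,
            "exposed_depression": exposed,
            "age": age,
            "sex": sex,
            "facts_per_year": facts,
            "exclusion_reason": _exclusion_reason(feats, case, control, cfg, variant),
        })
        out[variant] = table.reset_index(drop=True)
    return out
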