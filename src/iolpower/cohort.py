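"""Cohort cleaning, selection/verification split and training-table construction.

A cohort is a :class:`pandas.DataFrame` of per-eye surgical records (one row
per eye, columns listed in :data:`COHORT_COLUMNS`) plus an
``exclusion_reason`` column: empty string for retained rows, a short reason
code for excluded ones.  Filters never drop rows — they mark them — so
every input case is accounted for and an exclusion report can be emitted.

The filter chain runs in a fixed, documented order (completeness, range
bounds, acuity consistency, post-operative CDVA, astigmatism, free-text
keywords, fellow-eye axial-length agreement, ±3σ outliers); the first
failing rule is the recorded reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .optics import OpticsConstants, iol_ideal, rx_05iol, srkt_elp

__all__ = [
    "COHORT_COLUMNS",
    "FilterCriteria",
    "DEFAULT_KEYWORD_LISTS",
    "MinMaxNormalizer",
    "PREDICTOR_COLUMNS",
    "TARGET_COLUMN",
    "retained",
    "apply_record_filters",
    "keyword_exclusion",
    "fellow_eye_al_filter",
    "sigma_filter",
    "run_filter_chain",
    "split_cohort",
    "fit_normalizer",
    "clear_out_of_range",
    "derive_targets",
    "build_training_table",
    "exclusion_report",
]

#: Canonical cohort CSV columns (see interface docs).
COHORT_COLUMNS = [
    "eye_id", "patient_id", "eye",
    "age_years", "k_d", "acd_mm", "al_mm", "rx_pre_d",
    "iol_implanted_d", "rx_post_d",
    "udva_pre", "cdva_pre", "udva_post", "cdva_post",
    "astig_pre_d", "days_postop",
    "surgery_text", "finding_text", "diagnosis_text",
]

#: Model predictors, in training order.
PREDICTOR_COLUMNS = ["k_d", "acd_mm", "al_mm", "age_years", "rx_pre_d"]
TARGET_COLUMN = "iol_ideal_d"

_NUMERIC_MANDATORY = [
    "age_years", "k_d", "acd_mm", "al_mm", "rx_pre_d",
    "iol_implanted_d", "rx_post_d",
    "udva_pre", "cdva_pre", "udva_post", "cdva_post",
    "astig_pre_d", "days_postop",
]

# Default free-text exclusion keywords: surgical complications, corneal /
# ocular pathology, and prior intraocular or corneal refractive surgery.
# Shipped as configuration; any list can be replaced wholesale.
DEFAULT_KEYWORD_LISTS: Dict[str, Tuple[str, ...]] = {
    "surgery_text": (
        "ruptura", "fenestrum", "vitrektom", "praskl", "sklivec",
        "prolaps", "explant", "sulc", "sulk", "rzp", "key hole",
    ),
    "finding_text": (
        "otok", "striat", "edem", "odchlípen", "PEX", "jizv", "amok",
        "aparát", "defekt", "degener", "endotelopati", "fibrin", "guttat",
        "haze", "hemoftalm", "hemophtalm", "luxov", "membrán", "precip",
        "zonul",
    ),
    "diagnosis_text": (
        "LASIK", "LASEK", "PRK", "LASER", "RELEX", "DMEK", "DALK", "PKP",
    ),
}


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion/exclusion bounds for record-level filtering.

    Defaults are the study criteria: ACD 1–5 mm, AL 15–40 mm, K 30–60 D,
    age 18–99 years, implanted IOL 6–35 D, post-operative CDVA at most
    0.3 logMAR, pre-operative corneal astigmatism at most 3.0 D, outcome
    measured at least 25 days after surgery, and uncorrected acuity no
    better than corrected within each epoch.
    """

    acd_mm: Tuple[float, float] = (1.0, 5.0)
    al_mm: Tuple[float, float] = (15.0, 40.0)
    k_d: Tuple[float, float] = (30.0, 60.0)
    age_years: Tuple[float, float] = (18.0, 99.0)
    iol_implanted_d: Tuple[float, float] = (6.0, 35.0)
    cdva_post_max: float = 0.3
    astig_pre_max_d: float = 3.0
    days_postop_min: float = 25.0
    #: if True, exclude when UDVA == CDVA (strict reading); default allows equality
    strict_udva_gt_cdva: bool = False
    keyword_lists: Mapping[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_KEYWORD_LISTS)
    )
    sigma_k: float = 3.0
    fellow_al_max_diff_mm: float = 1.0


def _ensure_reason_column(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    if "exclusion_reason" not in out.columns:
        out["exclusion_reason"] = ""
    out["exclusion_reason"] = out["exclusion_reason"].fillna("").astype(str)
    return out


def retained(cohort: pd.DataFrame) -> pd.DataFrame:
    """Rows not excluded by any filter so far."""
    if "exclusion_reason" not in cohort.columns:
        return cohort
    return cohort[cohort["exclusion_reason"] == ""]


def keyword_exclusion(
    case: Mapping[str, object],
    keyword_lists: Mapping[str, Sequence[str]] = DEFAULT_KEYWORD_LISTS,
) -> Optional[Tuple[str, str]]:
    """Case-insensitive substring match of free-text fields against keyword lists.

    Returns ``(field, matched_keyword)`` for the first match in field order,
    or ``None`` if the case is clean.  Empty/missing text never matches.
    """
    for field_name, keywords in keyword_lists.items():
        text = case.get(field_name)
        if text is None or (isinstance(text, float) and np.isnan(text)):
            continue
        low = str(text).casefold()
        if not low:
            continue
        for kw in keywords:
            if kw.casefold() in low:
                return field_name, kw
    return None


def apply_record_filters(
    cohort: pd.DataFrame,
    criteria: FilterCriteria = FilterCriteria(),
) -> pd.DataFrame:
    """Mark cases failing any record-level criterion (first failure recorded).

    Filter order: completeness -> range bounds -> acuity consistency ->
    post-op CDVA -> astigmatism -> follow-up delay -> keywords.  Idempotent:
    reapplying to an already-filtered cohort changes nothing.
    """
    out = _ensure_reason_column(cohort)
    open_mask = out["exclusion_reason"] == ""

    def mark(mask: pd.Series, reason: str) -> None:
        nonlocal open_mask
        hit = open_mask & mask.fillna(True)
        out.loc[hit, "exclusion_reason"] = reason
        open_mask = open_mask & ~hit

    # completeness of mandatory numeric fields
    numeric = out[_NUMERIC_MANDATORY].apply(pd.to_numeric, errors="coerce")
    mark(numeric.isna().any(axis=1), "incomplete")

    range_rules = [
        ("acd_mm", criteria.acd_mm, "ACD range"),
        ("al_mm", criteria.al_mm, "AL range"),
        ("k_d", criteria.k_d, "K range"),
        ("age_years", criteria.age_years, "age range"),
        ("iol_implanted_d", criteria.iol_implanted_d, "IOL power range"),
    ]
    for col, (lo, hi), reason in range_rules:
        mark(~numeric[col].between(lo, hi), reason)

    if criteria.strict_udva_gt_cdva:
        bad_acuity = (numeric["udva_pre"] <= numeric["cdva_pre"]) | (
            numeric["udva_post"] <= numeric["cdva_post"]
        )
    else:
        bad_acuity = (numeric["udva_pre"] < numeric["cdva_pre"]) | (
            numeric["udva_post"] < numeric["cdva_post"]
        )
    mark(bad_acuity, "acuity inconsistency")
    mark(numeric["cdva_post"] > criteria.cdva_post_max, "postop CDVA")
    mark(numeric["astig_pre_d"] > criteria.astig_pre_max_d, "astigmatism")
    mark(numeric["days_postop"] < criteria.days_postop_min, "followup delay")

    if open_mask.any():
        hits = out.loc[open_mask].apply(
            lambda row: keyword_exclusion(row, criteria.keyword_lists), axis=1
        )
        kw_mask = hits.notna()
        for idx in hits.index[kw_mask]:
            f, kw = hits.loc[idx]
            out.loc[idx, "exclusion_reason"] = f"keyword:{f}:{kw}"
    return out


def fellow_eye_al_filter(
    cohort: pd.DataFrame, max_diff_mm: float = 1.0
) -> pd.DataFrame:
    """Exclude both eyes of a patient whose axial lengths disagree by > 1 mm.

    Single-eye patients are unaffected.  More than two eyes per patient is
    a data error.
    """
    out = _ensure_reason_column(cohort)
    live = retained(out)
    counts = live.groupby("patient_id").size()
    if (counts > 2).any():
        bad = counts[counts > 2].index.tolist()
        raise ValueError(f"patients with more than two eyes: {bad}")
    for pid, grp in live.groupby("patient_id"):
        if len(grp) == 2:
            al = grp["al_mm"].astype(float).to_numpy()
            if abs(al[0] - al[1]) > max_diff_mm:
                out.loc[grp.index, "exclusion_reason"] = "fellow-eye AL difference"
    return out


def sigma_filter(
    cohort: pd.DataFrame,
    variables: Sequence[str] = ("k_d", "acd_mm", "al_mm", "age_years", "rx_pre_d", "rx_post_d"),
    k: float = 3.0,
) -> pd.DataFrame:
    """Single-pass ±kσ outlier exclusion over the currently retained cases.

    Per variable, mean and sample standard deviation are computed over the
    retained rows; any case strictly beyond k·STD from the mean in any
    listed variable is excluded (boundary cases retained).  The rule is
    applied once, not iterated.
    """
    out = _ensure_reason_column(cohort)
    live = retained(out)
    if len(live) < 3:
        raise ValueError("sigma filter needs at least 3 retained cases")
    outlier = pd.Series(False, index=live.index)
    for var in variables:
        x = live[var].astype(float)
        std = x.std(ddof=1)
        if std == 0 or not np.isfinite(std):
            warnings.warn(f"sigma filter: variable {var!r} has zero variance, skipped")
            continue
        outlier |= (x - x.mean()).abs() > k * std
    out.loc[outlier.index[outlier], "exclusion_reason"] = "3-sigma outlier"
    return out


def run_filter_chain(
    cohort: pd.DataFrame, criteria: FilterCriteria = FilterCriteria()
) -> pd.DataFrame:
    """Full documented filter chain: records -> fellow eye -> ±kσ."""
    out = apply_record_filters(cohort, criteria)
    out = fellow_eye_al_filter(out, criteria.fellow_al_max_diff_mm)
    out = sigma_filter(out, k=criteria.sigma_k)
    return out


def exclusion_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-case exclusion reasons for excluded cases (eye_id, reason)."""
    out = _ensure_reason_column(cohort)
    rep = out[out["exclusion_reason"] != ""][["eye_id", "exclusion_reason"]]
    return rep.reset_index(drop=True)


def split_cohort(
    cohort: pd.DataFrame,
    selection_fraction: float = 0.7,
    seed: int | np.random.Generator = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random case-level split into selection and verification sets.

    Deterministic for a fixed seed; the selection count is the rounded
    fraction of the retained cohort (within one case of exact).
    """
    if not 0.0 < selection_fraction < 1.0:
        raise ValueError("selection_fraction must lie strictly between 0 and 1")
    live = retained(cohort)
    n = len(live)
    if n == 0:
        raise ValueError("cannot split an empty cohort")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sel = int(round(selection_fraction * n))
    n_sel = min(max(n_sel, 1), n - 1)
    perm = rng.permutation(n)
    sel_idx = live.index[np.sort(perm[:n_sel])]
    ver_idx = live.index[np.sort(perm[n_sel:])]
    return live.loc[sel_idx].copy(), live.loc[ver_idx].copy()


class MinMaxNormalizer:
    """Per-column linear map sending the selection-set [min, max] to [−1, 1].

    Mirrors MATLAB's ``mapminmax`` convention.  The inverse transform is
    exact; columns with zero range are rejected at fit time.
    """

    def __init__(self) -> None:
        self.mins_: Optional[pd.Series] = None
        self.maxs_: Optional[pd.Series] = None

    @property
    def columns(self) -> List[str]:
        self._check_fitted()
        return list(self.mins_.index)

    def fit(self, table: pd.DataFrame) -> "MinMaxNormalizer":
        mins = table.min()
        maxs = table.max()
        degenerate = maxs <= mins
        if degenerate.any():
            bad = list(mins.index[degenerate])
            raise ValueError(f"constant column(s) cannot be normalized: {bad}")
        self.mins_, self.maxs_ = mins.astype(float), maxs.astype(float)
        return self

    def _check_fitted(self) -> None:
        if self.mins_ is None:
            raise RuntimeError("normalizer is not fitted")

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        cols = [c for c in table.columns if c in self.mins_.index]
        mn, mx = self.mins_[cols], self.maxs_[cols]
        return 2.0 * (table[cols] - mn) / (mx - mn) - 1.0

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        cols = [c for c in table.columns if c in self.mins_.index]
        mn, mx = self.mins_[cols], self.maxs_[cols]
        return (table[cols] + 1.0) / 2.0 * (mx - mn) + mn

    def transform_column(self, name: str, values: np.ndarray) -> np.ndarray:
        self._check_fitted()
        mn, mx = self.mins_[name], self.maxs_[name]
        return 2.0 * (np.asarray(values, dtype=float) - mn) / (mx - mn) - 1.0

    def inverse_transform_column(self, name: str, values: np.ndarray) -> np.ndarray:
        self._check_fitted()
        mn, mx = self.mins_[name], self.maxs_[name]
        return (np.asarray(values, dtype=float) + 1.0) / 2.0 * (mx - mn) + mn

    def to_dict(self) -> Dict[str, Dict[str, float]]:
        self._check_fitted()
        return {
            c: {"min": float(self.mins_[c]), "max": float(self.maxs_[c])}
            for c in self.mins_.index
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, float]]) -> "MinMaxNormalizer":
        obj = cls()
        obj.mins_ = pd.Series({c: v["min"] for c, v in d.items()}, dtype=float)
        obj.maxs_ = pd.Series({c: v["max"] for c, v in d.items()}, dtype=float)
        return obj


def fit_normalizer(
    selection_table: pd.DataFrame,
    columns: Sequence[str] = tuple(PREDICTOR_COLUMNS) + (TARGET_COLUMN,),
) -> MinMaxNormalizer:
    """Fit the [−1, 1] normalizer on the selection set (predictors + target)."""
    return MinMaxNormalizer().fit(selection_table[list(columns)].astype(float))


def clear_out_of_range(
    verification_table: pd.DataFrame,
    params: MinMaxNormalizer,
    columns: Sequence[str] = tuple(PREDICTOR_COLUMNS),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop verification cases with any predictor outside the selection range.

    Boundary values are retained (closed-interval convention).  Returns
    ``(kept, removed)``; the removed frame carries an ``exclusion_reason``.
    """
    tab = verification_table
    mask = pd.Series(False, index=tab.index)
    for col in columns:
        x = tab[col].astype(float)
        mask |= (x < params.mins_[col]) | (x > params.maxs_[col])
    removed = tab[mask].copy()
    removed["exclusion_reason"] = "outside selection range"
    return tab[~mask].copy(), removed


def derive_targets(
    cohort: pd.DataFrame, consts: OpticsConstants = OpticsConstants()
) -> pd.DataFrame:
    """Attach per-eye optical targets: ELP, Rx_05IOL and the ideal IOL power.

    ELP comes from the SRK/T chain at the configured A-constant; Rx_05IOL is
    evaluated at the implanted power; the training target is the ideal power
    that would have zeroed the residual refraction.  Optics domain errors
    are re-raised with the offending eye's identity attached.
    """
    out = cohort.copy()
    elp = np.empty(len(out))
    s05 = np.empty(len(out))
    ideal = np.empty(len(out))
    for i, (idx, row) in enumerate(out.iterrows()):
        try:
            e = srkt_elp(float(row["k_d"]), float(row["al_mm"]), consts).elp_mm
            s = rx_05iol(float(row["k_d"]), float(row["al_mm"]), e,
                         float(row["iol_implanted_d"]), consts)
            t = iol_ideal(float(row["iol_implanted_d"]), float(row["rx_post_d"]), s)
        except Exception as exc:
            raise type(exc)(f"eye {row.get('eye_id', idx)}: {exc}") from exc
        elp[i], s05[i], ideal[i] = e, s, t
    out["elp_mm"] = elp
    out["rx_05iol_d"] = s05
    out[TARGET_COLUMN] = ideal
    return out


def build_training_table(
    cohort: pd.DataFrame,
    consts: OpticsConstants = OpticsConstants(),
    normalizer: Optional[MinMaxNormalizer] = None,
) -> Tuple[pd.DataFrame, MinMaxNormalizer]:
    """Normalized (predictors, ideal-power target) table for model fitting.

    If ``normalizer`` is None it is fitted on this table (selection-set
    semantics); otherwise the provided parameters are reused
    (verification-set semantics).  Returns ``(normalized table, normalizer)``;
    the normalized frame keeps the cohort's row index.
    """
    derived = derive_targets(cohort, consts)
    cols = PREDICTOR_COLUMNS + [TARGET_COLUMN]
    if normalizer is None:
        normalizer = fit_normalizer(derived, cols)
    normed = normalizer.transform(derived[cols].astype(float))
    return normed, normalizer
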