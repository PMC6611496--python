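"""Refractive prediction-error statistics and the paired-test battery.

Errors are signed spectacle-plane refractions in diopters (positive =
hyperopic residual).  For the clinical baseline the error of an eye is its
achieved post-operative refraction relative to the emmetropic target; for a
model it is the back-calculated residual the eye would have shown had the
predicted lens been implanted.

Summaries follow the refractive-outcome reporting convention: mean signed
error, mean and median absolute error, sample STD, extremes, and the
percentage of eyes within +/-0.25/0.50/0.75/1.00 D (closed intervals,
|e| <= t).  Method comparisons use the Wilcoxon signed-rank test on paired
absolute errors, McNemar's test with Yates' continuity correction on the
within-threshold indicators, and the exact binomial sign test, with
Bonferroni adjustment across each emitted table.

The three paired tests are implemented here rather than delegated so that
the small-sample conventions (zero-difference handling, tie-corrected exact
null distributions, the Yates numerator clamp) are explicit and match the
brute-force enumerations used to validate them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PESummary",
    "SubgroupSpec",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_SUBGROUPS",
    "pe_summary",
    "al_subgroups",
    "assign_subgroup",
    "wilcoxon_paired",
    "mcnemar_yates",
    "sign_test",
    "bonferroni",
    "refractive_error_table",
    "evaluation_report",
]

DEFAULT_THRESHOLDS: Tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)


@dataclass(frozen=True)
class SubgroupSpec:
    """Axial-length subgroup: name plus a half-open/closed AL interval."""

    name: str
    al_min: float
    al_max: float
    min_closed: bool
    max_closed: bool

    def contains(self, al_mm: np.ndarray) -> np.ndarray:
        al = np.asarray(al_mm, dtype=float)
        lo = al >= self.al_min if self.min_closed else al > self.al_min
        hi = al <= self.al_max if self.max_closed else al < self.al_max
        return lo & hi


#: SHORT: AL <= 22; MEDIUM: 22 < AL < 24; LONG: AL >= 24.  A partition.
DEFAULT_SUBGROUPS: Tuple[SubgroupSpec, ...] = (
    SubgroupSpec("SHORT", -np.inf, 22.0, False, True),
    SubgroupSpec("MEDIUM", 22.0, 24.0, False, False),
    SubgroupSpec("LONG", 24.0, np.inf, True, False),
)


@dataclass(frozen=True)
class PESummary:
    """Prediction-error statistics for one method in one AL subgroup."""

    n: int
    me: float
    mae: float
    medae: float
    std: float
    min: float
    max: float
    pct_within: Dict[float, float]

    def as_dict(self) -> Dict[str, float]:
        d = {
            "n": self.n, "me": self.me, "mae": self.mae, "medae": self.medae,
            "std": self.std, "min": self.min, "max": self.max,
        }
        for t, p in self.pct_within.items():
            d[f"pct_within_{t:g}"] = p
        return d


def pe_summary(
    errors: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    closed: bool = True,
) -> PESummary:
    """Summary statistics of signed prediction errors.

    Percentages use |e| <= t by default (closed intervals; set
    ``closed=False`` for strict).  STD is the sample estimate (n-1).
    """
    e = np.asarray(list(errors), dtype=float)
    if e.size == 0:
        raise ValueError("pe_summary requires at least one error")
    a = np.abs(e)
    pct = {}
    for t in thresholds:
        inside = a <= t if closed else a < t
        pct[float(t)] = float(np.mean(inside) * 100.0)
    return PESummary(
        n=int(e.size),
        me=float(np.mean(e)),
        mae=float(np.mean(a)),
        medae=float(np.median(a)),
        std=float(np.std(e, ddof=1)) if e.size > 1 else float("nan"),
        min=float(np.min(e)),
        max=float(np.max(e)),
        pct_within=pct,
    )


def assign_subgroup(
    al_mm: np.ndarray, subgroups: Sequence[SubgroupSpec] = DEFAULT_SUBGROUPS
) -> np.ndarray:
    """Subgroup name per eye; every eye must fall in exactly one subgroup."""
    al = np.asarray(al_mm, dtype=float)
    out = np.full(al.shape, "", dtype=object)
    for spec in subgroups:
        m = spec.contains(al)
        if (out[m] != "").any():
            raise ValueError("subgroups overlap")
        out[m] = spec.name
    if (out == "").any():
        raise ValueError("subgroups do not cover every axial length")
    return out.astype(str)


def al_subgroups(
    table: pd.DataFrame,
    al_column: str = "al_mm",
    subgroups: Sequence[SubgroupSpec] = DEFAULT_SUBGROUPS,
) -> Dict[str, pd.DataFrame]:
    """Partition a per-eye table into AL subgroups plus the ALL group."""
    names = assign_subgroup(table[al_column].to_numpy(), subgroups)
    parts = {spec.name: table[names == spec.name] for spec in subgroups}
    parts["ALL"] = table
    return parts


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------

def _signed_ranks(d: np.ndarray) -> np.ndarray:
    return stats.rankdata(np.abs(d))


def wilcoxon_paired(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_threshold: int = 25,
) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired values.

    Zero differences are dropped.  For n <= ``exact_threshold`` the exact
    null distribution of the positive-rank sum is enumerated by dynamic
    programming over the observed (possibly tied, hence averaged) ranks and
    the doubled-tail p returned; beyond that, the normal approximation with
    tie correction is used (no continuity correction).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("wilcoxon_paired needs at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    ranks = _signed_ranks(d)
    w_pos = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    if n <= exact_threshold:
        # exact distribution over 2^n sign assignments via convolution on
        # doubled ranks (integers even with .5 average ranks)
        r2 = np.round(ranks * 2).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = (dist + shifted) / 2.0
        w2 = int(round(w_pos * 2))
        lower = dist[: w2 + 1].sum()
        upper = dist[w2:].sum()
        return float(min(1.0, 2.0 * min(lower, upper)))
    tie_sizes = np.unique(np.abs(d), return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_sizes**3 - tie_sizes) / 48.0
    if var <= 0:
        warnings.warn("degenerate rank variance; p = 1")
        return 1.0
    z = (w_pos - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def mcnemar_yates(
    within_a: Sequence[bool], within_b: Sequence[bool]
) -> float:
    """McNemar's test with Yates' continuity correction on paired indicators.

    Discordant counts b (a-only successes) and c (b-only); the statistic is
    chi2 = (max(|b - c| - 1, 0))^2 / (b + c) on 1 df, with the numerator
    clamped at zero when |b - c| < 1 (implementations differ; the clamp is
    this package's documented convention).
    """
    a = np.asarray(list(within_a), dtype=bool)
    bb = np.asarray(list(within_b), dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("paired indicators must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    if b + c == 0:
        warnings.warn("no discordant pairs; p = 1")
        return 1.0
    chi2 = max(abs(b - c) - 1.0, 0.0) ** 2 / (b + c)
    return float(stats.chi2.sf(chi2, df=1))


def sign_test(differences: Sequence[float]) -> float:
    """Two-sided exact binomial sign test on paired differences (zeros dropped)."""
    d = np.asarray(list(differences), dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    k = int(np.sum(d > 0))
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> List[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p); m defaults to len(p)."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, m * p) for p in ps]


# ---------------------------------------------------------------------------
# per-eye errors and the full report
# ---------------------------------------------------------------------------

def refractive_error_table(
    verification: pd.DataFrame,
    predictions: Mapping[str, np.ndarray],
    cr_column: str = "rx_post_d",
) -> pd.DataFrame:
    """Per-eye signed refractive errors for the clinical baseline and models.

    The CR column is the achieved post-operative refraction (target =
    emmetropia); each model column is the back-calculated residual
    ((IOL_implanted - IOL_predicted)/0.5)*Rx_05IOL + Rx_post.  Requires
    ``rx_05iol_d`` on the verification frame (see cohort.derive_targets).
    """
    from .optics import rx_predicted  # local import avoids cycle at module load

    need = {"eye_id", "al_mm", "iol_implanted_d", "rx_05iol_d", cr_column}
    missing = need - set(verification.columns)
    if missing:
        raise ValueError(f"verification table missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "eye_id": verification["eye_id"].to_numpy(),
            "al_mm": verification["al_mm"].to_numpy(dtype=float),
            "CR": verification[cr_column].to_numpy(dtype=float),
        },
        index=verification.index,
    )
    impl = verification["iol_implanted_d"].to_numpy(dtype=float)
    s05 = verification["rx_05iol_d"].to_numpy(dtype=float)
    rxp = verification[cr_column].to_numpy(dtype=float)
    for method, pred in predictions.items():
        pred = np.asarray(pred, dtype=float)
        if pred.shape[0] != len(verification):
            raise ValueError(f"{method}: prediction count mismatch")
        out[method] = [
            rx_predicted(i, p, s, r) for i, p, s, r in zip(impl, pred, s05, rxp)
        ]
    out["subgroup"] = assign_subgroup(out["al_mm"].to_numpy())
    return out


def evaluation_report(
    error_table: pd.DataFrame,
    methods: Optional[Sequence[str]] = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    min_n_for_tests: int = 5,
) -> Dict[str, object]:
    """Per-subgroup summaries and the pairwise test matrix.

    Returns a dict with ``summaries`` (subgroup -> method -> PESummary) and
    ``tests`` (subgroup -> list of test records with raw and
    Bonferroni-adjusted p-values; the family size m is the number of
    comparisons in that subgroup's table and is reported alongside).
    Subgroups with fewer than ``min_n_for_tests`` eyes get summaries only.
    """
    if methods is None:
        reserved = {"eye_id", "al_mm", "subgroup"}
        methods = [c for c in error_table.columns if c not in reserved]
    parts = al_subgroups(error_table)
    summaries: Dict[str, Dict[str, PESummary]] = {}
    tests: Dict[str, List[Dict[str, object]]] = {}
    for name, part in parts.items():
        if len(part) == 0:
            warnings.warn(f"subgroup {name}: empty, omitted from the report")
            continue
        summaries[name] = {
            m: pe_summary(part[m].to_numpy(), thresholds) for m in methods
        }
        records: List[Dict[str, object]] = []
        if len(part) >= min_n_for_tests:
            for m1, m2 in combinations(methods, 2):
                e1 = part[m1].to_numpy(dtype=float)
                e2 = part[m2].to_numpy(dtype=float)
                records.append(
                    {
                        "pair": (m1, m2), "test": "wilcoxon_abs_error",
                        "threshold": None,
                        "p": wilcoxon_paired(np.abs(e1), np.abs(e2)),
                    }
                )
                for t in thresholds:
                    w1 = np.abs(e1) <= t
                    w2 = np.abs(e2) <= t
                    records.append(
                        {
                            "pair": (m1, m2), "test": "mcnemar_yates",
                            "threshold": float(t), "p": mcnemar_yates(w1, w2),
                        }
                    )
                    records.append(
                        {
                            "pair": (m1, m2), "test": "sign_test",
                            "threshold": float(t),
                            "p": sign_test(np.abs(e1) - np.abs(e2)),
                        }
                    )
            m_family = len(records)
            adj = bonferroni([r["p"] for r in records], m_family)
            for r, pa in zip(records, adj):
                r["p_bonferroni"] = pa
                r["m"] = m_family
        else:
            warnings.warn(
                f"subgroup {name}: n = {len(part)} < {min_n_for_tests}, tests skipped"
            )
        tests[name] = records
    return {"summaries": summaries, "tests": tests}


def report_to_frames(report: Mapping[str, object]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten an evaluation report into (summary, tests) DataFrames."""
    srows = []
    for sub, by_method in report["summaries"].items():
        for method, summ in by_method.items():
            row = {"subgroup": sub, "method": method}
            row.update(summ.as_dict())
            srows.append(row)
    trows = []
    for sub, records in report["tests"].items():
        for r in records:
            trows.append(
                {
                    "subgroup": sub, "method_a": r["pair"][0],
                    "method_b": r["pair"][1], "test": r["test"],
                    "threshold": r["threshold"], "p": r["p"],
                    "p_bonferroni": r.get("p_bonferroni"), "m": r.get("m"),
                }
            )
    return pd.DataFrame(srows), pd.DataFrame(trows)
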