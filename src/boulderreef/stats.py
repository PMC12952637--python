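"""Statistical battery linking vegetation scores to substrate and terrain.

Everything here treats the 0-6 vegetation score as a numeric response:
Welch's unequal-variance t-test compares score (and indicator) means
between groups, and Pearson product-moment correlation measures the
score-indicator association, overall and within each bottom-type stratum.
Two-sided raw p-values throughout; no multiplicity correction is applied
and none is claimed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geomorph import BOTTOM_TYPES
from .vegetation import (
    COMMUNITY_DISPLAY,
    VegetationRecord,
    richness_dichotomy,
    round_half_up,
    tabulate_communities,
    tabulate_prevalence,
)


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float  # Welch-Satterthwaite, generally non-integer
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def _as_sample(x: Iterable[float], name: str, min_n: int) -> np.ndarray:
    a = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    if a.ndim != 1:
        raise StatsError(f"{name}: expected a 1-D sample")
    if len(a) < min_n:
        raise StatsError(f"{name}: need at least {min_n} observations, got {len(a)}")
    if not np.isfinite(a).all():
        raise StatsError(f"{name}: sample contains non-finite values")
    return a


def welch_t(a: Iterable[float], b: Iterable[float]) -> TestResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with
    Welch-Satterthwaite degrees of freedom.
    """
    a = _as_sample(a, "a", 2)
    b = _as_sample(b, "b", 2)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise StatsError("both samples constant and equal: t undefined")
        # constant unequal samples: infinite separation
        stat = np.inf if a.mean() > b.mean() else -np.inf
        return TestResult(float(stat), float(len(a) + len(b) - 2), 0.0,
                          len(a), len(b), float(a.mean()), float(b.mean()))
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def pearson_r(x: Iterable[float], y: Iterable[float]) -> CorrelationResult:
    """Pearson product-moment correlation with the two-sided t-based
    p-value, p from t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    x = _as_sample(x, "x", 3)
    y = _as_sample(y, "y", 3)
    if len(x) != len(y):
        raise StatsError(f"length mismatch: {len(x)} vs {len(y)}")
    if x.var() == 0 or y.var() == 0:
        raise StatsError("constant sample: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def mean_scores_by_bottom(records: list[VegetationRecord]) -> dict:
    """Mean vegetation score per bottom type, full precision plus the
    1-decimal half-up rounded value as conventionally printed."""
    out = {}
    for bt in BOTTOM_TYPES:
        scores = [r.score for r in records if r.bottom_type == bt]
        if not scores:
            raise StatsError(f"no records with bottom type {bt!r}")
        if any(s is None for s in scores):
            raise StatsError("records must be classified before scoring")
        m = float(np.mean(scores))
        out[bt] = {"mean": m, "mean_rounded": round_half_up(m, 1), "n": len(scores)}
    return out


@dataclass
class AnalysisReport:
    """Everything the analysis computes, assembled in presentation order."""

    n_records: int
    n_by_bottom: dict
    prevalence: pd.DataFrame
    communities: pd.DataFrame
    combinations: pd.DataFrame
    mean_scores: dict
    score_bottom_test: TestResult
    correlations: dict | None  # {stratum: {indicator: CorrelationResult}}
    richness_tests: dict | None  # {bottom: {indicator: TestResult}}
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, (TestResult, CorrelationResult)):
                return asdict(obj)
            if isinstance(obj, pd.DataFrame):
                return json.loads(obj.to_json(orient="index"))
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "n_records": self.n_records,
            "n_by_bottom": self.n_by_bottom,
            "prevalence": conv(self.prevalence),
            "communities": conv(self.communities),
            "combinations": json.loads(self.combinations.to_json(orient="records")),
            "mean_scores": conv(self.mean_scores),
            "score_bottom_test": conv(self.score_bottom_test),
            "correlations": conv(self.correlations),
            "richness_tests": conv(self.richness_tests),
            "warnings": list(self.warnings),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text(self) -> str:
        lines = [
            "Boulder-reef vegetation analysis",
            "=" * 40,
            f"records: {self.n_records} "
            f"(sand {self.n_by_bottom.get('sand', 0)}, cobble {self.n_by_bottom.get('cobble', 0)})",
            "",
            "Species prevalence (count, % of stratum):",
        ]
        for sp, row in self.prevalence.iterrows():
            lines.append(
                f"  {sp:22s} overall {int(row['count_overall']):5d} ({row['pct_overall']:5.1f}%)"
                f"  sand {int(row['count_sand']):5d} ({row['pct_sand']:5.1f}%)"
                f"  cobble {int(row['count_cobble']):5d} ({row['pct_cobble']:5.1f}%)"
            )
        lines += ["", "Community composition:"]
        for c, row in self.communities.iterrows():
            lines.append(
                f"  {COMMUNITY_DISPLAY[c]:40s} overall {int(row['count_overall']):5d} "
                f"({row['pct_overall']:5.1f}%)  sand {int(row['count_sand']):5d}  "
                f"cobble {int(row['count_cobble']):5d}"
            )
        ms = self.mean_scores
        t = self.score_bottom_test
        lines += [
            "",
            f"Mean vegetation score: sand {ms['sand']['mean_rounded']:.1f} "
            f"(n={ms['sand']['n']}), cobble {ms['cobble']['mean_rounded']:.1f} "
            f"(n={ms['cobble']['n']})",
            f"Welch's t (score ~ bottom type): t={t.statistic:.3f}, "
            f"df={t.df:.1f}, p={t.p_value:.3g}",
        ]
        if self.correlations is not None:
            lines += ["", "Score-indicator Pearson correlations (raw p):"]
            for stratum, block in self.correlations.items():
                for ind, c in block.items():
                    lines.append(
                        f"  {stratum:8s} {ind:18s} r={c.r:+.3f}  p={c.p_value:.3g}  n={c.n}"
                    )
        if self.richness_tests is not None:
            lines += ["", "Rich (score>=3) vs poor (score<=2), Welch's t per stratum:"]
            for bt, block in self.richness_tests.items():
                for ind, t2 in block.items():
                    lines.append(
                        f"  {bt:8s} {ind:18s} t={t2.statistic:+.3f}  p={t2.p_value:.3g}  "
                        f"(rich n={t2.n_a}, poor n={t2.n_b})"
                    )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines) + "\n"


_INDICATORS = ("relative_height", "surface_complexity")


def run_full_analysis(records: list[VegetationRecord]) -> AnalysisReport:
    """Assemble the full report: prevalence and community tables, mean
    scores and the bottom-type Welch test, score-indicator correlations
    (overall and per stratum) and rich/poor indicator comparisons.

    Records lacking valid indicators are excluded from the correlation and
    rich/poor blocks only; if no record carries indicators those blocks are
    omitted with a warning.
    """
    if not records:
        raise StatsError("no records to analyse")
    recs = [r if r.score is not None else r.classify() for r in records]
    warnings_ = []

    prevalence = tabulate_prevalence(recs)
    tables = tabulate_communities(recs)
    mean_scores = mean_scores_by_bottom(recs)
    sand_scores = [r.score for r in recs if r.bottom_type == "sand"]
    cobble_scores = [r.score for r in recs if r.bottom_type == "cobble"]
    score_test = welch_t(sand_scores, cobble_scores)

    with_ind = [
        r for r in recs
        if r.indicators is not None and r.indicators.valid
        and r.indicators.relative_height is not None
        and r.indicators.surface_complexity is not None
    ]
    n_dropped = len(recs) - len(with_ind)
    correlations = richness_tests = None
    if not with_ind:
        warnings_.append("no records carry valid geomorphic indicators; "
                         "correlation and rich/poor blocks skipped")
    else:
        if n_dropped:
            warnings_.append(
                f"{n_dropped} record(s) without valid indicators excluded from "
                "correlation and rich/poor blocks"
            )
        strata = {"overall": with_ind}
        for bt in BOTTOM_TYPES:
            strata[bt] = [r for r in with_ind if r.bottom_type == bt]
        correlations = {}
        for name, rs in strata.items():
            block = {}
            for ind in _INDICATORS:
                vals = [getattr(r.indicators, ind) for r in rs]
                scores = [r.score for r in rs]
                try:
                    block[ind] = pearson_r(scores, vals)
                except StatsError as exc:
                    warnings_.append(f"correlation {name}/{ind} skipped: {exc}")
            if block:
                correlations[name] = block
        richness_tests = {}
        for bt in BOTTOM_TYPES:
            rs = strata[bt]
            rich = [r for r in rs if richness_dichotomy(r.score) == "rich"]
            poor = [r for r in rs if richness_dichotomy(r.score) == "poor"]
            block = {}
            for ind in _INDICATORS:
                try:
                    block[ind] = welch_t(
                        [getattr(r.indicators, ind) for r in rich],
                        [getattr(r.indicators, ind) for r in poor],
                    )
                except StatsError as exc:
                    warnings_.append(f"rich/poor test {bt}/{ind} skipped: {exc}")
            if block:
                richness_tests[bt] = block

    return AnalysisReport(
        n_records=len(recs),
        n_by_bottom={bt: sum(r.bottom_type == bt for r in recs) for bt in BOTTOM_TYPES},
        prevalence=prevalence,
        communities=tables["communities"],
        combinations=tables["combinations"],
        mean_scores=mean_scores,
        score_bottom_test=score_test,
        correlations=correlations,
        richness_tests=richness_tests,
        warnings=warnings_,
    )
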