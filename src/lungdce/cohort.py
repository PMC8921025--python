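"""Cohort-level statistics: classical two-sided tests, spirometric
impairment classification and report tables.

The layer mirrors how such follow-up cohorts are analysed in practice:
paired t-tests for ipsilateral-vs-contralateral contrasts, unpaired
t-tests (Welch by default) for group and subgroup contrasts, Pearson
correlation between perfusion and spirometry, Shapiro-Wilk as the
normality check, and a fixed two-sided significance level of 0.05. No
multiple-testing correction is applied.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StatsConfig
from .containers import TestResult

__all__ = [
    "SchemaError",
    "paired_t",
    "unpaired_t",
    "t_from_summary",
    "pearson",
    "shapiro_wilk",
    "classify_spirometry",
    "category_distribution",
    "build_report",
    "CohortModel",
    "CohortResults",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("restrictive", "obstructive", "combined", "none")

SUBJECT_COLUMNS = (
    "subject_id",
    "group",
    "ecmo",
    "pbf_ipsi",
    "pbf_contra",
    "pbv_ipsi",
    "pbv_contra",
    "mtt_ipsi",
    "mtt_contra",
    "volume_ipsi",
    "volume_contra",
    "pbf_ratio",
)


class SchemaError(ValueError):
    """An input table is missing required columns."""


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def paired_t(x, y) -> TestResult:
    """Classical paired t-test, two-sided, df = n - 1."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("paired t-test needs n >= 3")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate data: zero-variance differences")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(float(t), float(n - 1), float(p), "paired t", (n,))


def _welch_df(s1: float, n1: int, s2: float, n2: int) -> float:
    v1, v2 = s1**2 / n1, s2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variant: str = "welch",
) -> TestResult:
    """Unpaired t-test from printed summary statistics (mean, SD, n).

    Applies the same formulas as :func:`unpaired_t`, enabling checks of
    published group comparisons without the raw data.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("degenerate data: both group SDs are zero")
    equal_var = {"student": True, "welch": False}.get(variant)
    if equal_var is None:
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    df = (n1 + n2 - 2) if equal_var else _welch_df(sd1, n1, sd2, n2)
    name = "unpaired t (Student)" if equal_var else "unpaired t (Welch)"
    return TestResult(float(res.statistic), float(df), float(res.pvalue), name, (n1, n2))


def unpaired_t(x, y, variant: str = "welch") -> TestResult:
    """Two-sided unpaired t-test; Welch (default) or Student variant."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    return t_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size, variant
    )


def pearson(x, y) -> tuple[float, TestResult]:
    """Pearson product-moment correlation with the exact t-based p-value.

    p follows from t = r*sqrt(n-2)/sqrt(1-r^2) on df = n - 2, two-sided.
    """
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("degenerate data: zero variance")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) < 1.0:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    else:
        t = math.inf if r > 0 else -math.inf
    return r, TestResult(float(t), float(n - 2), float(res.pvalue), "Pearson r", (n,))


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (two-sided W statistic)."""
    x = _as_array(x, "x")
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    res = sps.shapiro(x)
    return TestResult(float(res.statistic), float("nan"), float(res.pvalue), "Shapiro-Wilk", (x.size,))


def classify_spirometry(
    fev1_pct: float,
    fvc_pct: float,
    tiffeneau: float,
    config: StatsConfig | None = None,
) -> str:
    """Type of lung-function impairment from spirometric values.

    Conventional fixed cut-offs: an obstructive component iff the
    Tiffeneau index (FEV1/FVC) is below 0.70, a restrictive component iff
    FVC is below 80% of predicted; both present is "combined", neither is
    "none".
    """
    cfg = config or StatsConfig()
    if fev1_pct <= 0 or fvc_pct <= 0 or tiffeneau <= 0:
        raise ValueError("spirometric inputs must be positive")
    obstructive = tiffeneau < cfg.tiffeneau_cutoff
    restrictive = fvc_pct < cfg.fvc_pct_cutoff
    if obstructive and restrictive:
        return "combined"
    if obstructive:
        return "obstructive"
    if restrictive:
        return "restrictive"
    return "none"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def category_distribution(categories) -> tuple[dict[str, int], dict[str, int]]:
    """Counts and integer percentages (half-away-from-zero) per category.

    Counts conserve n; the rounded percentages need not sum to 100.
    """
    cats = list(categories)
    n = len(cats)
    if n < 1:
        raise ValueError("need at least one record")
    counts = {c: cats.count(c) for c in CATEGORIES if c in cats}
    for c in cats:
        if c not in counts:
            counts[c] = cats.count(c)
    pcts = {c: _round_half_away(100.0 * k / n) for c, k in counts.items()}
    return counts, pcts


# ---------------------------------------------------------------------------
# Report model
# ---------------------------------------------------------------------------

_PAIRED_PARAMS = (
    ("Lung volume (mL)", "volume_ipsi", "volume_contra"),
    ("Pulmonary blood flow (mL/100 mL/min)", "pbf_ipsi", "pbf_contra"),
    ("Pulmonary blood volume (mL/100 mL)", "pbv_ipsi", "pbv_contra"),
    ("Mean transit time (s)", "mtt_ipsi", "mtt_contra"),
)

_GROUP_PARAMS = (
    ("Lung volume ipsilateral", "volume_ipsi"),
    ("Lung volume contralateral", "volume_contra"),
    ("PBF ipsilateral (mL/100 mL/min)", "pbf_ipsi"),
    ("PBF contralateral (mL/100 mL/min)", "pbf_contra"),
    ("PBF ratio (ipsi/contra)", "pbf_ratio"),
    ("PBV ipsilateral (mL/100 mL)", "pbv_ipsi"),
    ("PBV contralateral (mL/100 mL)", "pbv_contra"),
    ("MTT ipsilateral (s)", "mtt_ipsi"),
    ("MTT contralateral (s)", "mtt_contra"),
)


@dataclass
class CohortResults:
    """Fitted cohort statistics: tables, test objects and group sizes."""

    tables: dict[str, pd.DataFrame]
    tests: dict[str, TestResult]
    group_sizes: dict[str, int]
    category_counts: dict[str, int] = field(default_factory=dict)
    category_percentages: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Cohort perfusion report", "=" * 40]
        lines.append(
            "Group sizes: "
            + ", ".join(f"{g}: n={n}" for g, n in self.group_sizes.items())
        )
        for name, table in self.tables.items():
            lines += ["", f"[{name}]", table.to_string(index=False)]
        if self.category_counts:
            lines += ["", "[respiratory impairment distribution]"]
            for cat, cnt in self.category_counts.items():
                lines.append(f"  {cat}: {cnt} ({self.category_percentages[cat]}%)")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_sizes": self.group_sizes,
            "category_counts": self.category_counts,
            "category_percentages": self.category_percentages,
            "tables": {k: v.to_dict(orient="records") for k, v in self.tables.items()},
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(directory / f"report_{name}.csv", index=False)


class CohortModel:
    """Statistical model of a perfusion follow-up cohort.

    Parameters
    ----------
    subjects : DataFrame
        One row per subject with per-side perfusion summaries (see
        ``SUBJECT_COLUMNS``).
    spirometry : DataFrame, optional
        Columns subject_id, fev1_pct, fvc_pct, tiffeneau for the subset
        with lung-function data.
    config : StatsConfig
        Test variant, significance level and spirometric cut-offs.
    """

    def __init__(
        self,
        subjects: pd.DataFrame,
        spirometry: pd.DataFrame | None = None,
        config: StatsConfig | None = None,
    ) -> None:
        missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
        if missing:
            raise SchemaError(f"subject table is missing columns: {missing}")
        self.subjects = subjects.reset_index(drop=True)
        self.spirometry = spirometry if spirometry is not None else pd.DataFrame()
        if len(self.spirometry):
            spiro_missing = [
                c
                for c in ("subject_id", "fev1_pct", "fvc_pct", "tiffeneau")
                if c not in self.spirometry.columns
            ]
            if spiro_missing:
                raise SchemaError(f"spirometry table is missing columns: {spiro_missing}")
        self.config = config or StatsConfig()

    # -- helpers ----------------------------------------------------------
    def _unpaired(self, x, y) -> TestResult:
        return unpaired_t(x, y, variant=self.config.unpaired_variant)

    @staticmethod
    def _ms(x) -> str:
        x = np.asarray(x, float)
        return f"{x.mean():.3g} ± {x.std(ddof=1):.3g}"

    # -- fit --------------------------------------------------------------
    def fit(self) -> CohortResults:
        cdh = self.subjects[self.subjects["group"] == "CDH"]
        control = self.subjects[self.subjects["group"] == "control"]
        tables: dict[str, pd.DataFrame] = {}
        tests: dict[str, TestResult] = {}
        warnings: list[str] = []

        # Ipsilateral vs contralateral within CDH (paired).
        if len(cdh) >= 3:
            rows = []
            for label, col_i, col_c in _PAIRED_PARAMS:
                res = paired_t(cdh[col_i], cdh[col_c])
                tests[f"paired:{col_i.split('_')[0]}"] = res
                rows.append(
                    {
                        "parameter": label,
                        "ipsilateral": self._ms(cdh[col_i]),
                        "contralateral": self._ms(cdh[col_c]),
                        "test": res.test_name,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
            tables["paired_ipsi_vs_contra"] = pd.DataFrame(rows)

        # CDH vs control (unpaired).
        if len(cdh) >= 2 and len(control) >= 2:
            rows = []
            for label, col in _GROUP_PARAMS:
                res = self._unpaired(cdh[col], control[col])
                tests[f"group:{col}"] = res
                rows.append(
                    {
                        "parameter": label,
                        "CDH": self._ms(cdh[col]),
                        "control": self._ms(control[col]),
                        "test": res.test_name,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
            tables["cdh_vs_control"] = pd.DataFrame(rows)
        elif len(control) == 0:
            warnings.append("no control subjects: group comparison omitted")

        # ECMO vs non-ECMO within CDH.
        ecmo = cdh[cdh["ecmo"].astype(bool)]
        non_ecmo = cdh[~cdh["ecmo"].astype(bool)]
        if len(ecmo) >= 2 and len(non_ecmo) >= 2:
            rows = []
            for label, col in (
                ("PBF ipsilateral (mL/100 mL/min)", "pbf_ipsi"),
                ("PBF contralateral (mL/100 mL/min)", "pbf_contra"),
            ):
                res = self._unpaired(ecmo[col], non_ecmo[col])
                tests[f"ecmo:{col}"] = res
                rows.append(
                    {
                        "parameter": label,
                        "ECMO": self._ms(ecmo[col]),
                        "no_ECMO": self._ms(non_ecmo[col]),
                        "test": res.test_name,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
            tables["ecmo_vs_non_ecmo"] = pd.DataFrame(rows)
        else:
            warnings.append("ECMO subgroup too small: comparison omitted")

        # Spirometry-dependent sections.
        counts: dict[str, int] = {}
        pcts: dict[str, int] = {}
        if len(self.spirometry):
            spiro = self.spirometry.copy()
            spiro["category"] = [
                classify_spirometry(r.fev1_pct, r.fvc_pct, r.tiffeneau, self.config)
                for r in spiro.itertuples()
            ]
            counts, pcts = category_distribution(spiro["category"])
            merged = cdh.merge(spiro, on="subject_id", how="inner")

            disorder = merged[merged["category"] != "none"]
            normal = merged[merged["category"] == "none"]
            if len(disorder) >= 2 and len(normal) >= 2:
                rows = []
                for label, col in (
                    ("PBF ipsilateral (mL/100 mL/min)", "pbf_ipsi"),
                    ("PBF contralateral (mL/100 mL/min)", "pbf_contra"),
                ):
                    res = self._unpaired(disorder[col], normal[col])
                    tests[f"disorder:{col}"] = res
                    rows.append(
                        {
                            "parameter": label,
                            "respiratory_disorder": self._ms(disorder[col]),
                            "normal_function": self._ms(normal[col]),
                            "test": res.test_name,
                            "p_value": res.p_value,
                            "significant": res.significant,
                        }
                    )
                tables["disorder_vs_normal"] = pd.DataFrame(rows)

            rows = []
            for label, col in (("FEV1 (% predicted)", "fev1_pct"), ("FVC (% predicted)", "fvc_pct")):
                if len(merged) >= 3:
                    r, res = pearson(merged["pbf_ipsi"], merged[col])
                    tests[f"correlation:{col}"] = res
                    rows.append(
                        {
                            "pair": f"ipsilateral PBF vs {label}",
                            "r": r,
                            "n": len(merged),
                            "p_value": res.p_value,
                            "significant": res.significant,
                        }
                    )
            if rows:
                tables["correlations"] = pd.DataFrame(rows)
        else:
            warnings.append("empty spirometry table: correlation section omitted")
            logger.warning("empty spirometry table: correlation section omitted")

        return CohortResults(
            tables=tables,
            tests=tests,
            group_sizes={"CDH": len(cdh), "control": len(control)},
            category_counts=counts,
            category_percentages=pcts,
            warnings=warnings,
        )


def build_report(
    subjects: pd.DataFrame,
    spirometry: pd.DataFrame | None = None,
    config: StatsConfig | None = None,
) -> CohortResults:
    """Fit the full cohort report (paired, group, subgroup and correlation
    sections) from the subject and spirometry tables."""
    return CohortModel(subjects, spirometry, config).fit()
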