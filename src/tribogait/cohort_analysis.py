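"""Condition-history categorization and exploratory cohort statistics.

Free-text condition histories are tagged into seven musculoskeletal groups
by case-insensitive keyword matching (multimorbid cases are multi-tagged;
prevalence counts unique participants).  Cohort-level summaries cover
multimorbidity and category co-occurrence, Pearson/Spearman correlations
between gait parameters and demographics, and ANOVA / Kruskal-Wallis
comparisons across (partially overlapping) history categories.  All
category-based comparisons are exploratory and flagged as such; raw
p-values are reported by default with an optional Benjamini-Hochberg
column.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "CATEGORY_KEYWORDS",
    "CategoryAssignment",
    "CohortReport",
    "categorize_history",
    "multimorbidity_summary",
    "correlate",
    "compare_groups",
    "build_report",
    "bmi_category",
    "benjamini_hochberg",
]

#: The seven history groups, by anatomical location, injury type or pathology.
CATEGORIES = ("spine_back", "knee", "ankle_foot", "hip", "fractures_breaks",
              "arthritis_joint", "other")

#: Keyword sets per category.  Substring matching after lowercasing and
#: punctuation stripping; config-extensible (the printed lists end in
#: "etc."). "flatfeet" tags ankle_foot as a reported history item and is
#: kept distinct from the sensor-derived flatfoot loading flag.
CATEGORY_KEYWORDS: dict[str, tuple[str, ...]] = {
    "spine_back": ("scoliosis", "hernia", "protrusion", "lumbar", "spine",
                   "vertebrae"),
    "knee": ("knee", "meniscus", "gonarthrosis", "ligament"),
    "ankle_foot": ("ankle", "sprain", "flatfeet", "plantar fasciitis"),
    "hip": ("hip", "displacement", "dysplasia", "labrum"),
    "fractures_breaks": ("fracture", "break", "fibula", "tibia"),
    "arthritis_joint": ("arthrosis", "arthritis", "joint", "osteochondrosis"),
}

_PUNCT = re.compile(r"[^\w\s]")

#: BMI bins: left-closed, right-open except the final bin.
BMI_BINS = (
    ("underweight", 0.0, 18.5),
    ("normal", 18.5, 25.0),
    ("overweight", 25.0, 30.0),
    ("obese", 30.0, 35.0),
    ("extremely_obese", 35.0, float("inf")),
)


def bmi_category(bmi: float) -> str:
    """Bin a BMI value; partitions (0, inf) so every participant gets one bin."""
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError("BMI must be finite and positive")
    for name, lo, hi in BMI_BINS:
        if lo <= bmi < hi or (hi == float("inf") and bmi >= lo):
            return name
    raise AssertionError("unreachable")  # bins partition (0, inf)


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryAssignment:
    participant_id: str
    categories: frozenset
    matched_keywords: tuple


def categorize_history(history_text: str, participant_id: str = "",
                       keywords: dict | None = None) -> CategoryAssignment:
    """Tag a free-text condition history with history categories.

    Case-insensitive substring matching after punctuation stripping;
    multimorbid texts receive every matching tag; text matching nothing
    (including the empty string) falls into 'other'.  Total and idempotent.
    """
    table = keywords or CATEGORY_KEYWORDS
    text = _PUNCT.sub(" ", str(history_text).lower())
    matched: list[str] = []
    cats = set()
    for category, kws in table.items():
        for kw in kws:
            if kw in text:
                cats.add(category)
                matched.append(kw)
    if not cats:
        cats = {"other"}
    return CategoryAssignment(participant_id=participant_id,
                              categories=frozenset(cats),
                              matched_keywords=tuple(matched))


def multimorbidity_summary(assignments: list[CategoryAssignment]) -> dict:
    """Mean categories/participant, 1..4+ distribution, co-occurrence matrix.

    The co-occurrence matrix entry (i, j) counts participants tagged with
    both categories; its diagonal is the unique-participant prevalence per
    category, so trace = sum of per-category unique counts.
    """
    if not assignments:
        raise ValueError("need at least one assignment")
    n = len(assignments)
    counts = [len(a.categories) for a in assignments]
    dist = {"1": 0, "2": 0, "3": 0, "4+": 0}
    for c in counts:
        dist[str(c) if c < 4 else "4+"] += 1
    matrix = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for a in assignments:
        cats = sorted(a.categories)
        for ci in cats:
            for cj in cats:
                matrix.loc[ci, cj] += 1
    return {
        "mean_categories": float(np.mean(counts)),
        "distribution": dist,
        "co_occurrence": matrix,
    }


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def correlate(cohort_table: pd.DataFrame, var_x: str, var_y: str,
              method: str = "pearson") -> tuple[float, float, int]:
    """Pearson or Spearman correlation with pairwise deletion of missing.

    Binary tags (e.g. a 0/1 history indicator against a continuous gait
    metric) go through Spearman on the coded values.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    pair = cohort_table[[var_x, var_y]].apply(pd.to_numeric).dropna()
    if len(pair) < 3:
        raise ValueError("need at least 3 paired non-missing values")
    x = pair[var_x].to_numpy(dtype=float)
    y = pair[var_y].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), len(pair)


def compare_groups(metric_by_category: dict,
                   tests: tuple[str, ...] = ("anova", "kruskal_wallis")
                   ) -> pd.DataFrame:
    """ANOVA and/or Kruskal-Wallis across history groups.

    Group membership may overlap (multimorbidity), so results carry an
    ``exploratory`` flag.  All-identical values trigger a degenerate-test
    warning and NaN statistics.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in metric_by_category.items()
              if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    values = list(groups.values())
    pooled = np.concatenate(values)
    degenerate = np.ptp(pooled) == 0
    if degenerate:
        warnings.warn("all values identical across groups; tests are degenerate",
                      stacklevel=2)
    rows = []
    for test in tests:
        if degenerate:
            stat, p = float("nan"), float("nan")
        elif test == "anova":
            stat, p = stats.f_oneway(*values)
        elif test == "kruskal_wallis":
            stat, p = stats.kruskal(*values)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"test": test, "statistic": float(stat),
                     "p_value": float(p), "n_groups": len(groups),
                     "exploratory": True})
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional column for the exploratory tables)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortReport:
    prevalence: pd.DataFrame
    mean_categories: float
    category_distribution: dict
    co_occurrence: pd.DataFrame
    correlations: pd.DataFrame
    group_comparisons: pd.DataFrame
    flatfoot_prevalence: pd.DataFrame

    def to_json(self) -> str:
        payload = {
            "prevalence": self.prevalence.to_dict(orient="records"),
            "mean_categories": self.mean_categories,
            "category_distribution": self.category_distribution,
            "co_occurrence": self.co_occurrence.to_dict(),
            "correlations": self.correlations.to_dict(orient="records"),
            "group_comparisons": self.group_comparisons.to_dict(orient="records"),
            "flatfoot_prevalence": self.flatfoot_prevalence.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.prevalence.to_csv(out / "prevalence.csv", index=False)
        self.co_occurrence.to_csv(out / "co_occurrence.csv")
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.group_comparisons.to_csv(out / "group_comparisons.csv", index=False)
        self.flatfoot_prevalence.to_csv(out / "flatfoot_prevalence.csv",
                                        index=False)


def build_report(cohort_table: pd.DataFrame, metrics: dict) -> CohortReport:
    """Assemble the full exploratory cohort report.

    ``cohort_table`` needs columns participant_id, age, sex, height_m,
    mass_kg, history_text; ``metrics`` maps participant_id to the per-trial
    metric dict (from GaitMetrics.to_dict()).  Deterministic given inputs.
    """
    if not metrics:
        raise ValueError("metrics must not be empty")
    ids_cohort = set(cohort_table["participant_id"])
    ids_metrics = set(metrics)
    mismatched = sorted(ids_metrics ^ ids_cohort)
    if mismatched:
        raise ValueError(f"participant id mismatch between cohort and metrics: "
                         f"{mismatched}")
    table = cohort_table.sort_values("participant_id").reset_index(drop=True)
    n = len(table)
    table = table.assign(
        bmi=table["mass_kg"] / table["height_m"] ** 2,
        cadence=[metrics[i]["cadence"] for i in table["participant_id"]],
        asymmetry_mean_pct=[metrics[i]["asymmetry_mean_pct"]
                            for i in table["participant_id"]],
        flatfoot_any=[bool(metrics[i]["flatfoot_left"]
                           or metrics[i]["flatfoot_right"])
                      for i in table["participant_id"]],
    )
    assignments = [categorize_history(row.history_text, row.participant_id)
                   for row in table.itertuples()]
    mm = multimorbidity_summary(assignments)

    prevalence = pd.DataFrame([
        {"category": c,
         "n": int(sum(c in a.categories for a in assignments)),
         "pct": 100.0 * sum(c in a.categories for a in assignments) / n}
        for c in CATEGORIES])

    corr_rows = []
    for var_x, var_y, method in (("age", "cadence", "pearson"),
                                 ("bmi", "cadence", "pearson"),
                                 ("age", "asymmetry_mean_pct", "pearson")):
        try:
            r, p, k = correlate(table, var_x, var_y, method)
        except ValueError:
            continue
        corr_rows.append({"var_x": var_x, "var_y": var_y, "method": method,
                          "coefficient": r, "p_value": p, "n": k})
    # binary history tags vs cadence: Spearman on {0,1} coding
    for c in CATEGORIES:
        tag = np.array([1.0 if c in a.categories else 0.0 for a in assignments])
        if 0 < tag.sum() < n:
            work = table.assign(tag=tag)
            try:
                r, p, k = correlate(work, "tag", "cadence", "spearman")
            except ValueError:
                continue
            corr_rows.append({"var_x": f"history:{c}", "var_y": "cadence",
                              "method": "spearman", "coefficient": r,
                              "p_value": p, "n": k})
    correlations = pd.DataFrame(corr_rows)

    by_cat = {}
    for c in CATEGORIES:
        vals = [row.asymmetry_mean_pct for row, a in zip(table.itertuples(),
                                                         assignments)
                if c in a.categories]
        if len(vals) >= 2:
            by_cat[c] = vals
    if len(by_cat) >= 2:
        comparisons = compare_groups(by_cat)
        comparisons.insert(0, "metric", "asymmetry_mean_pct")
    else:
        comparisons = pd.DataFrame(columns=["metric", "test", "statistic",
                                            "p_value", "n_groups", "exploratory"])

    ff_rows = [{"group": "overall",
                "n": n,
                "prevalence_pct": 100.0 * table["flatfoot_any"].mean()}]
    for sex in ("F", "M"):
        sub = table[table["sex"] == sex]
        if len(sub):
            ff_rows.append({"group": f"sex:{sex}", "n": len(sub),
                            "prevalence_pct": 100.0 * sub["flatfoot_any"].mean()})
    for c in CATEGORIES:
        mask = [c in a.categories for a in assignments]
        sub = table[np.array(mask)]
        if len(sub):
            ff_rows.append({"group": f"category:{c}", "n": len(sub),
                            "prevalence_pct": 100.0 * sub["flatfoot_any"].mean()})
    flatfoot_prevalence = pd.DataFrame(ff_rows)

    return CohortReport(
        prevalence=prevalence,
        mean_categories=mm["mean_categories"],
        category_distribution=mm["distribution"],
        co_occurrence=mm["co_occurrence"],
        correlations=correlations,
        group_comparisons=comparisons,
        flatfoot_prevalence=flatfoot_prevalence,
    )
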