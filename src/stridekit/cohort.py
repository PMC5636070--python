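"""Cross-sectional group comparisons, clinical stratification, and
longitudinal change classification for gait-parameter cohorts.

The analysis mirrors the statistical workflow of clinical wearable-gait
studies: per-subject walk summaries (one value per subject, both feet
pooled) are compared between PD patients and controls with independent
t-tests; stratified comparisons across three or more groups use one-way
ANOVA followed by all pairwise t-tests with Bonferroni correction (the
adjusted p is the raw p times the number of pairs, capped at one).
Subjects are stratified by Hoehn & Yahr stage, by UPDRS-III motor score
bands — low 1–12, middle 13–22, high ≥ 23 — or by the single UPDRS gait
or postural-stability items; controls always form their own stratum.

Longitudinal change classifies each returning patient by the clinician's
gait-item delta: unchanged rating → stable, lower rating (less impairment)
→ improved, higher rating → worsened; per-parameter changes are reported
in percent of the baseline value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UPDRS_BANDS",
    "SIGNIFICANCE_LEVEL",
    "ComparisonResult",
    "ChangeRecord",
    "StratificationError",
    "DegenerateDataError",
    "PairingError",
    "ReportError",
    "stratify_subjects",
    "compare_groups",
    "longitudinal_change",
    "build_report",
    "cohort_table",
    "REPORT_PARAMETERS",
]

#: UPDRS-III total-score bands: low 1–12, middle 13–22, high ≥ 23.
UPDRS_BANDS = ((0, 12, "low"), (13, 22, "middle"), (23, 10**6, "high"))

#: Two-sided significance level used throughout the reports.
SIGNIFICANCE_LEVEL = 0.05

#: Parameter rows of the standard cohort report (name, display unit).
REPORT_PARAMETERS = (
    ("stride_length", "m"),
    ("normalized_stride_length", "-"),
    ("stride_time", "s"),
    ("gait_velocity", "m/s"),
    ("cadence", "spm"),
    ("stance_time_pct", "%"),
    ("swing_time_pct", "%"),
    ("clearance", "cm"),
    ("hs_angle", "°"),
    ("to_angle", "°"),
)

_SCHEMES = ("group", "hoehn_yahr", "updrs_band", "gait_item", "postural_stability_item")


class StratificationError(ValueError):
    """A PD row lacks the clinical field the scheme stratifies by."""


class DegenerateDataError(ValueError):
    """All groups have zero within-group variance; tests are undefined."""


class PairingError(ValueError):
    """Baseline/follow-up rows do not belong to the same subject."""


class ReportError(ValueError):
    """Empty cohort or no usable parameter columns."""


# ---------------------------------------------------------------------------
# stratification


def _updrs_band(total: int) -> str:
    for lo, hi, name in UPDRS_BANDS:
        if lo <= total <= hi:
            return name
    raise StratificationError(f"UPDRS-III total {total} outside all bands")


def stratify_subjects(table: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Assign each subject-visit row to exactly one stratum.

    Returns a copy of ``table`` with a ``stratum`` column.  Controls form
    their own ``"control"`` stratum for every clinical scheme; a PD row
    missing the scheme's field raises :class:`StratificationError`.
    """
    if scheme not in _SCHEMES:
        raise StratificationError(f"unknown scheme {scheme!r}")
    out = table.copy()

    def assign(row) -> str:
        if scheme == "group":
            return str(row["group"])
        if row["group"] != "PD":
            return "control"
        if scheme == "updrs_band":
            value = row.get("updrs_iii_total")
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise StratificationError(
                    f"PD subject {row.get('subject_id')} lacks updrs_iii_total"
                )
            return _updrs_band(int(value))
        value = row.get(scheme)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise StratificationError(
                f"PD subject {row.get('subject_id')} lacks {scheme}"
            )
        return f"{scheme}_{int(value)}"

    out["stratum"] = [assign(row) for _, row in out.iterrows()]
    return out


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class ComparisonResult:
    """Outcome of one parameter's comparison across groups.

    For two groups this is an independent t-test; for three or more, a
    one-way ANOVA plus Bonferroni-adjusted pairwise t-tests.
    """

    grouping: str
    group_names: list[str]
    means: dict
    sems: dict
    ns: dict
    statistic: float          # t (2 groups) or F (>= 3 groups)
    p_value: float
    test: str                 # "t" | "anova"
    pairwise: dict = field(default_factory=dict)  # (a, b) -> dict

    def significant_pairs(self, alpha: float = SIGNIFICANCE_LEVEL) -> list:
        if self.test == "t":
            return [tuple(self.group_names)] if self.p_value < alpha else []
        return [
            pair
            for pair, res in self.pairwise.items()
            if res["p_adjusted"] < alpha
        ]


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    grouping: str = "group",
    equal_var: bool = True,
) -> ComparisonResult:
    """Two groups → independent t-test; three or more → one-way ANOVA with
    Bonferroni-corrected pairwise post-hoc t-tests.

    ``equal_var=True`` gives the classical pooled-variance Student test;
    set False for Welch's correction.
    """
    names = list(samples.keys())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for k, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    if all(np.var(a) == 0.0 for a in arrays.values()):
        raise DegenerateDataError("zero within-group variance in every group")

    means = {k: float(a.mean()) for k, a in arrays.items()}
    sems = {k: float(a.std(ddof=1) / np.sqrt(len(a))) for k, a in arrays.items()}
    ns = {k: int(len(a)) for k, a in arrays.items()}

    if len(names) == 2:
        t, p = stats.ttest_ind(arrays[names[0]], arrays[names[1]], equal_var=equal_var)
        return ComparisonResult(
            grouping=grouping,
            group_names=names,
            means=means,
            sems=sems,
            ns=ns,
            statistic=float(t),
            p_value=float(p),
            test="t",
        )

    f, p = stats.f_oneway(*arrays.values())
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            t, praw = stats.ttest_ind(arrays[a], arrays[b], equal_var=equal_var)
            pairwise[(a, b)] = {
                "t": float(t),
                "p_raw": float(praw),
                "p_adjusted": float(min(1.0, praw * n_pairs)),
            }
    return ComparisonResult(
        grouping=grouping,
        group_names=names,
        means=means,
        sems=sems,
        ns=ns,
        statistic=float(f),
        p_value=float(p),
        test="anova",
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# longitudinal change


@dataclass(frozen=True)
class ChangeRecord:
    """Within-subject change between baseline and follow-up visits.

    ``gait_class`` follows the UPDRS convention that a lower gait-item
    score means better gait: a decreased rating is classified improved, an
    increased rating worsened.
    """

    subject_id: str
    months_between: float | None
    percent_change: dict
    gait_class: str  # stable | improved | worsened


def _percent_change(baseline: float, followup: float) -> float:
    if baseline == 0 or not np.isfinite(baseline):
        return float("nan")
    return 100.0 * (followup - baseline) / baseline


def longitudinal_change(
    baseline: Mapping, followup: Mapping, parameters: Sequence[str] | None = None
) -> ChangeRecord:
    """Classify one subject's change from the gait-item delta and report
    per-parameter percent changes relative to baseline."""
    if baseline["subject_id"] != followup["subject_id"]:
        raise PairingError(
            f"subject mismatch: {baseline['subject_id']} vs {followup['subject_id']}"
        )
    if parameters is None:
        parameters = [name for name, _ in REPORT_PARAMETERS]
    delta = followup.get("gait_item", 0) - baseline.get("gait_item", 0)
    gait_class = "stable" if delta == 0 else ("improved" if delta < 0 else "worsened")
    pct = {
        name: _percent_change(float(baseline[name]), float(followup[name]))
        for name in parameters
        if name in baseline and name in followup
        and baseline[name] is not None and followup[name] is not None
    }
    months = None
    try:
        b = pd.Timestamp(baseline.get("visit_date"))
        f = pd.Timestamp(followup.get("visit_date"))
        months = float((f - b).days / 30.44)
    except (TypeError, ValueError):
        pass
    return ChangeRecord(
        subject_id=str(baseline["subject_id"]),
        months_between=months,
        percent_change=pct,
        gait_class=gait_class,
    )


# ---------------------------------------------------------------------------
# report


def cohort_table(subjects, summaries) -> pd.DataFrame:
    """Join subject metadata with per-walk summaries into one row per
    subject-visit.

    ``summaries`` maps subject_id → WalkSummary.
    """
    rows = []
    for rec in subjects:
        summary = summaries.get(rec.subject_id)
        if summary is None:
            continue
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": rec.age,
            "height": rec.height,
            "hoehn_yahr": rec.hoehn_yahr,
            "updrs_iii_total": rec.updrs_iii_total,
            "gait_item": rec.gait_item,
            "postural_stability_item": rec.postural_stability_item,
            "visit_date": rec.visit_date,
            "n_strides": summary.n_strides,
        }
        row.update(summary.means)
        row.update({f"cv_{k}": v for k, v in summary.cvs.items()})
        if summary.normalized_stride_length is not None:
            row["normalized_stride_length"] = summary.normalized_stride_length
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) and df.duplicated(["subject_id", "visit_date"]).any():
        raise ReportError("duplicate (subject_id, visit_date) rows")
    return df


@dataclass
class CohortReport:
    """Mean ± SEM grid with significance markers, per stratification."""

    tables: dict  # scheme -> DataFrame
    comparisons: dict  # scheme -> {parameter: ComparisonResult}

    def to_markdown(self) -> str:
        chunks = []
        for scheme, table in self.tables.items():
            chunks.append(f"## Stratification: {scheme}\n")
            chunks.append(table.to_markdown())
            chunks.append("")
        return "\n".join(chunks)


def build_report(
    table: pd.DataFrame, schemes: Sequence[str] = ("group",)
) -> CohortReport:
    """Summarize a cohort table into mean ± SEM grids per scheme.

    Each grid has one row per gait parameter and one column per stratum;
    entries are ``mean ± SEM`` with a ``*`` marker when the parameter
    differs significantly (p < 0.05 after Bonferroni for ≥ 3 strata).
    """
    if len(table) == 0:
        raise ReportError("empty cohort table")
    params = [name for name, _ in REPORT_PARAMETERS if name in table.columns]
    if not params:
        raise ReportError("no gait-parameter columns in the cohort table")

    tables, comparisons = {}, {}
    for scheme in schemes:
        strat = stratify_subjects(table, scheme)
        strata = sorted(strat["stratum"].unique())
        grid = {}
        comps = {}
        for name in params:
            cells = {}
            samples = {
                s: strat.loc[strat["stratum"] == s, name].dropna().to_numpy()
                for s in strata
            }
            samples = {s: v for s, v in samples.items() if len(v) >= 2}
            result = None
            if len(samples) >= 2:
                try:
                    result = compare_groups(samples, grouping=scheme)
                except DegenerateDataError:
                    result = None
            sig = set()
            if result is not None:
                for pair in result.significant_pairs():
                    sig.update(pair)
            for s in strata:
                values = strat.loc[strat["stratum"] == s, name].dropna()
                if len(values) == 0:
                    cells[s] = "-"
                    continue
                mean = values.mean()
                sem = values.std(ddof=1) / np.sqrt(len(values)) if len(values) > 1 else 0.0
                marker = " *" if s in sig else ""
                cells[s] = f"{mean:.2f} ± {sem:.2f}{marker}"
            grid[name] = cells
            if result is not None:
                comps[name] = result
        unit = dict(REPORT_PARAMETERS)
        frame = pd.DataFrame(grid).T
        frame.index = [f"{n} [{unit[n]}]" for n in frame.index]
        tables[scheme] = frame
        comparisons[scheme] = comps
    return CohortReport(tables=tables, comparisons=comparisons)
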