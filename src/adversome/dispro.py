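"""Within-cohort disproportionality analysis.

For every eligible drug (suspected in more than ``min_drug_reports`` cohort
reports) and every event (primary HLT with at least one cohort report), a
2x2 contingency table of report counts is formed:

    =================  ==============  ==============
                       event present   event absent
    =================  ==============  ==============
    drug suspected     a               b
    drug not suspected c               d
    =================  ==============  ==============

The reporting odds ratio ROR = (a*d)/(b*c) measures disproportional
reporting; its 95% CI uses the Woolf log-scale standard error
sqrt(1/a + 1/b + 1/c + 1/d), with the Haldane–Anscombe 0.5 continuity
correction applied to all four cells when any cell is zero.  A pair is a
signal of disproportionate reporting (SDR) when the whole CI exceeds 1
AND the two-sided Fisher exact p-value beats the Bonferroni-corrected
threshold alpha / n_tests, where n_tests counts only the pairs actually
analysed (those meeting the >=3-case rule a >= min_case).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .faers_io import ReportRecord, SUSPECT_ROLES
from .meddra import MedDRAHierarchy, SOCExclusionList, project_to_hlt

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report-count table for one drug–event pair within a cohort."""

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    event: str = ""

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SDRResult:
    """One drug–event disproportionality analysis with all decision flags."""

    drug: str
    event: str
    table: ContingencyTable
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    p_raw: float | None
    n_tests: int
    alpha_corrected: float
    computed: bool
    significant_ci: bool
    significant_corrected: bool
    is_sdr: bool


def project_cohort(
    cohort: list[ReportRecord],
    hierarchy: MedDRAHierarchy,
    exclusions: SOCExclusionList | None = None,
) -> list[frozenset[str]]:
    """Project every report's reactions onto primary HLTs (cached helper)."""
    return [project_to_hlt(r, hierarchy, exclusions) for r in cohort]


def eligible_drugs(
    cohort: list[ReportRecord], min_reports: int = 100
) -> list[str]:
    """Substances suspected (PS or SS) in strictly more than ``min_reports``
    cohort reports, sorted by descending report count (ties by name)."""
    counts: Counter[str] = Counter()
    for r in cohort:
        counts.update(r.suspected_substances())
    keep = [(s, c) for s, c in counts.items() if c > min_reports]
    keep.sort(key=lambda sc: (-sc[1], sc[0]))
    return [s for s, _ in keep]


def contingency(
    cohort: list[ReportRecord],
    drug: str,
    event: str,
    hierarchy: MedDRAHierarchy,
    exclusions: SOCExclusionList | None = None,
    projected: list[frozenset[str]] | None = None,
) -> ContingencyTable:
    """Build the 2x2 table; drug presence means suspected (PS or SS)."""
    if projected is None:
        projected = project_cohort(cohort, hierarchy, exclusions)
    a = b = c = d = 0
    for r, events in zip(cohort, projected):
        has_drug = drug in r.suspected_substances()
        has_event = event in events
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d, drug, event)


def ror_ci(
    table: ContingencyTable, z: float = Z_95
) -> tuple[float | None, float | None, float | None]:
    """Reporting odds ratio with Woolf CI and zero-cell correction.

    If any cell is zero, 0.5 is added to all four cells before computing
    both the point estimate and the CI.  Degenerate tables with an empty
    drug margin (a+b = 0) or event margin (a+c = 0) return ``None``.
    """
    if table.a + table.b == 0 or table.a + table.c == 0:
        return None, None, None
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def fisher_p(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher exact p-value of the 2x2 table.

    Two-sided uses the point-probability method: the sum of hypergeometric
    probabilities of all tables with the same margins whose probability does
    not exceed that of the observed table.  ``alternative='greater'`` gives
    the one-sided test of over-reporting.
    """
    res = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alternative
    )
    return float(res.pvalue)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Familywise significance threshold alpha / n_tests."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def detect_sdrs(
    cohort: list[ReportRecord],
    hierarchy: MedDRAHierarchy,
    exclusions: SOCExclusionList | None = None,
    min_case: int = 3,
    alpha: float = 0.05,
    min_drug_reports: int = 100,
    fisher_sided: str = "two-sided",
) -> list[SDRResult]:
    """Run the full disproportionality screen within a cohort.

    Pairs with fewer than ``min_case`` co-reports (the ``a`` cell) are kept
    in the output with ``computed=False`` but are excluded from the test
    count; the Bonferroni threshold alpha / n_tests is then applied
    uniformly to the computed pairs.  Results are ordered by drug (in
    eligibility order) then descending ROR.
    """
    if not cohort:
        return []
    projected = project_cohort(cohort, hierarchy, exclusions)
    drugs = eligible_drugs(cohort, min_drug_reports)
    event_counts: Counter[str] = Counter()
    for events in projected:
        event_counts.update(events)
    events_list = sorted(event_counts)

    n = len(cohort)
    suspected = [r.suspected_substances() for r in cohort]
    tables: list[ContingencyTable] = []
    for drug in drugs:
        has_drug = np.array([drug in s for s in suspected])
        n_drug = int(has_drug.sum())
        for event in events_list:
            has_event = np.array([event in ev for ev in projected])
            a = int((has_drug & has_event).sum())
            n_event = int(has_event.sum())
            tables.append(
                ContingencyTable(a, n_drug - a, n_event - a, n - n_drug - n_event + a,
                                 drug, event)
            )

    computed = [t.a >= min_case for t in tables]
    n_tests = sum(computed)
    alpha_corr = bonferroni_alpha(alpha, n_tests) if n_tests else float("nan")

    results: list[SDRResult] = []
    for t, comp in zip(tables, computed):
        if comp:
            ror, lo, hi = ror_ci(t)
            p = fisher_p(t, fisher_sided)
            sig_ci = lo is not None and lo > 1
            sig_corr = p < alpha_corr
        else:
            ror = lo = hi = p = None
            sig_ci = sig_corr = False
        results.append(
            SDRResult(
                drug=t.drug, event=t.event, table=t,
                ror=ror, ci_low=lo, ci_high=hi, p_raw=p,
                n_tests=n_tests, alpha_corrected=alpha_corr,
                computed=comp, significant_ci=sig_ci,
                significant_corrected=sig_corr,
                is_sdr=comp and sig_ci and sig_corr,
            )
        )

    drug_order = {d: i for i, d in enumerate(drugs)}
    results.sort(
        key=lambda r: (drug_order[r.drug], -(r.ror if r.ror is not None else -math.inf))
    )
    return results


def heatmap_table(
    sdrs: list[SDRResult], hierarchy: MedDRAHierarchy
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SOC-grouped significance matrices (corrected and uncorrected).

    Rows are HLTs ordered by primary SOC then name; columns are drugs in
    the order they appear in ``sdrs``.  Cells hold ``not_computed``,
    ``not_significant`` or ``significant``; the second table uses the
    uncorrected criterion (CI > 1 and raw p < alpha) so that corrected
    significance is always a subset of it.
    """
    drugs = list(dict.fromkeys(r.drug for r in sdrs))
    events = sorted(
        {r.event for r in sdrs},
        key=lambda h: (hierarchy.hlt_to_primary_soc.get(h, ""), h),
    )
    corrected = pd.DataFrame("not_computed", index=events, columns=drugs)
    uncorrected = pd.DataFrame("not_computed", index=events, columns=drugs)
    for r in sdrs:
        if not r.computed:
            continue
        corrected.loc[r.event, r.drug] = (
            "significant" if r.is_sdr else "not_significant"
        )
        raw_alpha = r.alpha_corrected * r.n_tests  # back out the uncorrected alpha
        sig_raw = r.significant_ci and r.p_raw is not None and r.p_raw < raw_alpha
        uncorrected.loc[r.event, r.drug] = (
            "significant" if sig_raw else "not_significant"
        )
    corrected.index.name = uncorrected.index.name = "hlt"
    return corrected, uncorrected


def co_suspect_summary(
    cohort_or_counts,
    drugs: list[str] | None = None,
) -> pd.DataFrame:
    """Overlap of co-suspected drug regimens, as counts and percentages.

    Either pass a cohort plus a drug list — counts are derived from the
    suspected substances of each report — or pass precomputed counts as a
    mapping ``{combination-name: count}`` that must include the key
    ``"any"`` (reports with at least one of the drugs); percentages are
    then computed over that denominator and rounded to one decimal.
    """
    if isinstance(cohort_or_counts, dict):
        counts = dict(cohort_or_counts)
    else:
        if drugs is None:
            raise ValueError("drug list required when passing a cohort")
        dset = set(drugs)
        counts = {"any": 0, "all": 0}
        for i, d1 in enumerate(drugs):
            for d2 in drugs[i + 1:]:
                counts[f"{d1}+{d2}"] = 0
        for r in cohort_or_counts:
            present = r.suspected_substances() & dset
            if not present:
                continue
            counts["any"] += 1
            if present == dset:
                counts["all"] += 1
            for i, d1 in enumerate(drugs):
                for d2 in drugs[i + 1:]:
                    if d1 in present and d2 in present:
                        counts[f"{d1}+{d2}"] += 1
    denom = counts["any"]
    rows = [
        {
            "combination": k,
            "count": v,
            "pct": round(100 * v / denom, 1) if denom and k != "any" else None,
        }
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows, columns=["combination", "count", "pct"])


def sdr_table(sdrs: list[SDRResult]) -> pd.DataFrame:
    """Flatten SDR results to one row per drug–event pair."""
    return pd.DataFrame(
        [
            {
                "drug": r.drug, "event": r.event,
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "ror": r.ror, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "p_raw": r.p_raw, "n_tests": r.n_tests,
                "alpha_corrected": r.alpha_corrected,
                "computed": r.computed, "significant_ci": r.significant_ci,
                "significant_corrected": r.significant_corrected, "is_sdr": r.is_sdr,
            }
            for r in sdrs
        ]
    )


def write_sdr_table(sdrs: list[SDRResult], path: str | Path) -> None:
    sdr_table(sdrs).to_csv(path, sep="\t", index=False, float_format="%.12g")
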