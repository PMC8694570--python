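"""Reading, deduplicating and selecting FAERS-style spontaneous reports.

The quarterly ASCII dialect is the public FAERS one: one table per file,
fields separated by ``$``, first row a header, no quoting.  Five tables
make up a quarter — demographics, drugs, reactions, indications, outcomes —
joined on ``primaryid``.  Column names follow the FAERS convention:

============  =====================================================
file role     required columns
============  =====================================================
demographics  primaryid caseid caseversion event_dt fda_dt sex
              age_grp occr_country occp_cod rept_cod
drugs         primaryid role_cod drugname
reactions     primaryid pt
indications   primaryid indi_pt
outcomes      primaryid outc_cod
============  =====================================================

Date fields may be ``YYYY``, ``YYYYMM`` or ``YYYYMMDD``; partial dates are
completed to the earliest consistent day so that window selection is
inclusive and reproducible.
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .meddra import MedDRAHierarchy, SOCExclusionList, project_to_hlt

logger = logging.getLogger(__name__)

SUSPECT_ROLES = frozenset({"primary-suspect", "secondary-suspect"})

_ROLE_CODES = {
    "PS": "primary-suspect",
    "SS": "secondary-suspect",
    "C": "concomitant",
    "I": "interacting",
}
_SEX_CODES = {"F": "F", "M": "M"}
_AGE_CODES = {
    "N": "newborn",
    "I": "infant",
    "C": "child",
    "T": "teenager",
    "A": "adult",
    "E": "elderly",
}
_OCCP_CODES = {
    "PH": "pharmacist",
    "MD": "physician",
    "OT": "other-health-professional",
    "CN": "consumer",
    "LW": "lawyer",
}
_REPT_CODES = {"EXP": "expedited", "30DAY": "expedited", "DIR": "direct", "PER": "periodic"}
_OUTC_CODES = {
    "DE": "death",
    "LT": "life-threatening",
    "DS": "disability",
    "RI": "required-intervention",
    "HO": "hospitalization",
    "CA": "congenital-anomaly",
    "OT": "other-serious",
}

#: Salt/ester suffixes stripped during active-ingredient normalization.
SALT_SUFFIXES = (
    " HYDROCHLORIDE",
    " DIHYDROCHLORIDE",
    " HYDROBROMIDE",
    " SULFATE",
    " SULPHATE",
    " BISULFATE",
    " SODIUM",
    " POTASSIUM",
    " CALCIUM",
    " PHOSPHATE",
    " DIHYDRATE",
    " MONOHYDRATE",
    " ACETATE",
    " MESYLATE",
    " MESILATE",
    " MALEATE",
    " FUMARATE",
    " TARTRATE",
    " BITARTRATE",
    " CITRATE",
    " BESYLATE",
    " SUCCINATE",
    " HCL",
)

#: Combination products split into component substances.  User-extensible:
#: pass an augmented mapping to :func:`normalize_substance`.
DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "LOPINAVIR/RITONAVIR": ("LOPINAVIR", "RITONAVIR"),
    "LOPINAVIR AND RITONAVIR": ("LOPINAVIR", "RITONAVIR"),
    "LOPINAVIR\\RITONAVIR": ("LOPINAVIR", "RITONAVIR"),
    "HYDROXYCHLOROQUINE SULFATE": ("HYDROXYCHLOROQUINE",),
    "ALCOHOL": ("ETHANOL",),
}


class SchemaError(ValueError):
    """A table is missing a required column."""


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report: normalized substance + reporter role."""

    substance: str
    role: str  # primary-suspect | secondary-suspect | concomitant | interacting


@dataclass
class ReportRecord:
    """One deduplicated spontaneous report."""

    report_id: str
    case_id: str
    case_version: int = 1
    occur_date: dt.date | None = None
    fda_receipt_date: dt.date | None = None
    sex: str = "unknown"
    age_group: str = "unknown"
    country: str = "unknown"
    occupation: str = "unknown"
    report_code: str = "unknown"
    outcomes: frozenset[str] = frozenset()
    drugs: list[DrugEntry] = field(default_factory=list)
    reaction_pts: frozenset[str] = frozenset()
    indication_pts: frozenset[str] = frozenset()

    @property
    def substances(self) -> frozenset[str]:
        return frozenset(d.substance for d in self.drugs)

    def suspected_substances(self) -> frozenset[str]:
        return frozenset(d.substance for d in self.drugs if d.role in SUSPECT_ROLES)

    def dedup_key(self) -> tuple:
        """Fields on which two distinct cases are considered duplicates."""
        return (
            self.sex,
            self.age_group,
            self.country,
            self.occur_date,
            self.substances,
            self.reaction_pts,
        )


@dataclass
class CohortSplit:
    """A partition of reports into an analysis cohort and its reference."""

    cohort: list[ReportRecord]
    reference: list[ReportRecord]
    selector_name: str


def normalize_substance(raw: str, synonyms: dict[str, tuple[str, ...]] | None = None) -> tuple[str, ...]:
    """Normalize a verbatim drug name to canonical substance(s).

    Uppercases, trims, strips one trailing salt/ester suffix, then applies
    the synonym table (which may split a combination product into several
    components).  Returns a tuple because of that splitting.
    """
    syn = DEFAULT_SYNONYMS if synonyms is None else synonyms
    name = " ".join(raw.upper().split())
    if name in syn:
        return syn[name]
    for suffix in SALT_SUFFIXES:
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return syn.get(name, (name,))


def parse_faers_date(raw: str) -> dt.date | None:
    """Parse YYYY / YYYYMM / YYYYMMDD to the earliest consistent day."""
    s = raw.strip()
    if not s or not s.isdigit():
        return None
    try:
        if len(s) == 4:
            return dt.date(int(s), 1, 1)
        if len(s) == 6:
            return dt.date(int(s[:4]), int(s[4:6]), 1)
        if len(s) == 8:
            return dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None
    return None


def format_faers_date(d: dt.date | None) -> str:
    return "" if d is None else d.strftime("%Y%m%d")


def _read_table(path: str | Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")
    except OSError as exc:
        raise OSError(f"cannot read FAERS table {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"table {path} missing required columns: {sorted(missing)}")
    return df


def read_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    indi_path: str | Path,
    outc_path: str | Path,
    synonyms: dict[str, tuple[str, ...]] | None = None,
    dropped_log: list[tuple[str, str]] | None = None,
) -> list[ReportRecord]:
    """Parse the five quarterly tables into one record per ``primaryid``.

    Drug, reaction, indication and outcome rows are attached to their
    demographics row by ``primaryid``; rows referencing an absent
    ``primaryid`` are logged (and appended to ``dropped_log`` as
    ``(table, primaryid)`` when given) and dropped.  Missing optional
    fields become ``unknown``/empty.
    """
    demo = _read_table(
        demo_path,
        {"primaryid", "caseid", "caseversion", "event_dt", "fda_dt", "sex",
         "age_grp", "occr_country", "occp_cod", "rept_cod"},
    )
    drug = _read_table(drug_path, {"primaryid", "role_cod", "drugname"})
    reac = _read_table(reac_path, {"primaryid", "pt"})
    indi = _read_table(indi_path, {"primaryid", "indi_pt"})
    outc = _read_table(outc_path, {"primaryid", "outc_cod"})

    records: dict[str, ReportRecord] = {}
    for row in demo.itertuples(index=False):
        pid = row.primaryid
        try:
            version = int(row.caseversion)
        except ValueError:
            version = 1
        records[pid] = ReportRecord(
            report_id=pid,
            case_id=row.caseid,
            case_version=version,
            occur_date=parse_faers_date(row.event_dt),
            fda_receipt_date=parse_faers_date(row.fda_dt),
            sex=_SEX_CODES.get(row.sex.strip().upper(), "unknown"),
            age_group=_AGE_CODES.get(row.age_grp.strip().upper(), "unknown"),
            country=row.occr_country.strip().upper() or "unknown",
            occupation=_OCCP_CODES.get(row.occp_cod.strip().upper(), "unknown"),
            report_code=_REPT_CODES.get(row.rept_cod.strip().upper(), "unknown"),
        )

    def _attach(table: pd.DataFrame, name: str, fn) -> None:
        for row in table.itertuples(index=False):
            rec = records.get(row.primaryid)
            if rec is None:
                logger.warning("%s row references absent primaryid %s; dropped", name, row.primaryid)
                if dropped_log is not None:
                    dropped_log.append((name, row.primaryid))
                continue
            fn(rec, row)

    def _add_drug(rec: ReportRecord, row) -> None:
        role = _ROLE_CODES.get(row.role_cod.strip().upper())
        if role is None:
            role = "concomitant"
        for substance in normalize_substance(row.drugname, synonyms):
            rec.drugs.append(DrugEntry(substance, role))

    _attach(drug, "drug", _add_drug)
    _attach(reac, "reaction", lambda rec, row: setattr(
        rec, "reaction_pts", rec.reaction_pts | {row.pt.strip()}))
    _attach(indi, "indication", lambda rec, row: setattr(
        rec, "indication_pts", rec.indication_pts | {row.indi_pt.strip()}))
    _attach(outc, "outcome", lambda rec, row: setattr(
        rec, "outcomes", rec.outcomes | {_OUTC_CODES.get(row.outc_cod.strip().upper(), "other-serious")}))

    return list(records.values())


def write_quarter(records: list[ReportRecord], out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write records back to the five $-delimited tables (inverse of read)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rev = lambda m: {v: k for k, v in m.items()}  # noqa: E731
    sex_r, age_r, occp_r = rev(_SEX_CODES), rev(_AGE_CODES), rev(_OCCP_CODES)
    rept_r = {"expedited": "EXP", "direct": "DIR", "periodic": "PER"}
    role_r, outc_r = rev(_ROLE_CODES), rev(_OUTC_CODES)

    demo_rows, drug_rows, reac_rows, indi_rows, outc_rows = [], [], [], [], []
    for r in records:
        demo_rows.append({
            "primaryid": r.report_id, "caseid": r.case_id, "caseversion": r.case_version,
            "event_dt": format_faers_date(r.occur_date),
            "fda_dt": format_faers_date(r.fda_receipt_date),
            "sex": sex_r.get(r.sex, ""), "age_grp": age_r.get(r.age_group, ""),
            "occr_country": "" if r.country == "unknown" else r.country,
            "occp_cod": occp_r.get(r.occupation, ""),
            "rept_cod": rept_r.get(r.report_code, ""),
        })
        for i, d in enumerate(r.drugs, 1):
            drug_rows.append({"primaryid": r.report_id, "drug_seq": i,
                              "role_cod": role_r[d.role], "drugname": d.substance})
        for pt in sorted(r.reaction_pts):
            reac_rows.append({"primaryid": r.report_id, "pt": pt})
        for pt in sorted(r.indication_pts):
            indi_rows.append({"primaryid": r.report_id, "indi_drug_seq": 1, "indi_pt": pt})
        for oc in sorted(r.outcomes):
            outc_rows.append({"primaryid": r.report_id, "outc_cod": outc_r[oc]})

    paths = {}
    specs = [
        ("demo", demo_rows, ["primaryid", "caseid", "caseversion", "event_dt", "fda_dt",
                             "sex", "age_grp", "occr_country", "occp_cod", "rept_cod"]),
        ("drug", drug_rows, ["primaryid", "drug_seq", "role_cod", "drugname"]),
        ("reac", reac_rows, ["primaryid", "pt"]),
        ("indi", indi_rows, ["primaryid", "indi_drug_seq", "indi_pt"]),
        ("outc", outc_rows, ["primaryid", "outc_cod"]),
    ]
    for name, rows, cols in specs:
        path = out / f"{prefix}{name.upper()}.txt"
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="$", index=False)
        paths[name] = path
    return paths


def deduplicate(
    reports: list[ReportRecord],
    log: list[tuple[str, str, str]] | None = None,
) -> list[ReportRecord]:
    """Two-stage deterministic deduplication.

    Stage 1 — case supersedence: for each ``case_id`` keep only the record
    with the highest ``case_version`` (ties broken by highest ``report_id``,
    lexicographic).  Stage 2 — exact-tuple collapse: among survivors,
    records agreeing on (sex, age_group, country, occur_date, substance
    set, reaction PT set) are collapsed to the one with the lowest
    ``report_id``.  Output preserves the input order of survivors.

    Every removal is appended to ``log`` as ``(removed_id, rule, kept_id)``.
    """
    if log is None:
        log = []

    best: dict[str, ReportRecord] = {}
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None or (r.case_version, r.report_id) > (cur.case_version, cur.report_id):
            best[r.case_id] = r
    stage1 = []
    for r in reports:
        if best[r.case_id] is r:
            stage1.append(r)
        else:
            log.append((r.report_id, "caseversion-superseded", best[r.case_id].report_id))

    keeper: dict[tuple, ReportRecord] = {}
    for r in stage1:
        key = r.dedup_key()
        cur = keeper.get(key)
        if cur is None or r.report_id < cur.report_id:
            keeper[key] = r
    out = []
    for r in stage1:
        kept = keeper[r.dedup_key()]
        if kept is r:
            out.append(r)
        else:
            log.append((r.report_id, "exact-tuple-duplicate", kept.report_id))
    return out


def write_dedup_log(log: list[tuple[str, str, str]], path: str | Path) -> None:
    pd.DataFrame(log, columns=["report_id", "rule", "kept_id"]).to_csv(path, sep="\t", index=False)


def select_window(
    reports: list[ReportRecord], start_date: dt.date, end_date: dt.date
) -> list[ReportRecord]:
    """Keep reports whose occurrence date — or, when that is missing, the
    date of first receipt by the regulator — falls in the inclusive window."""
    if start_date > end_date:
        raise ValueError(f"start_date {start_date} is after end_date {end_date}")
    out = []
    for r in reports:
        d = r.occur_date if r.occur_date is not None else r.fda_receipt_date
        if d is not None and start_date <= d <= end_date:
            out.append(r)
    return out


def split_by_smq(
    reports: list[ReportRecord],
    hierarchy: MedDRAHierarchy,
    smq_name: str,
    scope: str = "narrow",
) -> CohortSplit:
    """Split reports by SMQ membership of the *indication* field.

    A report joins the cohort when any of its indication PTs belongs to the
    SMQ term set at the given scope; reaction PTs play no role here.
    """
    terms = hierarchy.smq(smq_name, scope)
    cohort, reference = [], []
    for r in reports:
        (cohort if r.indication_pts & terms else reference).append(r)
    return CohortSplit(cohort, reference, f"smq:{smq_name}:{scope}")


# ---------------------------------------------------------------------------
# Descriptive summaries


def _month_of_first_report(r: ReportRecord) -> str | None:
    d = r.fda_receipt_date
    return None if d is None else f"{d.year:04d}-{d.month:02d}"


def describe(
    split: CohortSplit,
    hierarchy: MedDRAHierarchy | None = None,
    exclusions: SOCExclusionList | None = None,
    top_countries: int = 5,
) -> dict[str, pd.DataFrame]:
    """Tabulate cohort vs reference characteristics and frequency rankings.

    Returns a dict with a ``characteristics`` table (sex, country, occupation,
    report type, age group, month of first report, outcomes; count and
    percentage per cohort, percentages over non-missing values, missing shown
    as a count without a percentage), a ``drugs`` ranking (all-suspect and
    primary-suspect counts over the cohort) and — when a hierarchy is given —
    an ``hlts`` ranking of projected events.
    """
    groups = [("cohort", split.cohort), ("reference", split.reference)]

    def tabulate(rows, fn, missing_value="unknown", levels=None):
        out = {}
        for gname, recs in groups:
            vals = [fn(r) for r in recs]
            non_missing = [v for v in vals if v is not None and v != missing_value]
            counts = Counter(non_missing)
            n = len(non_missing)
            keys = levels if levels is not None else sorted(counts)
            for k in keys:
                c = counts.get(k, 0)
                rows.append({"section": rows_section, "level": k, "group": gname,
                             "count": c, "pct": round(100 * c / n, 1) if n else None})
            miss = len(vals) - n
            rows.append({"section": rows_section, "level": "Missing", "group": gname,
                         "count": miss, "pct": None})

    rows: list[dict] = []
    rows_section = "sex"
    tabulate(rows, lambda r: r.sex if r.sex in ("F", "M") else None)
    rows_section = "country"
    all_countries = Counter(
        r.country for r in split.cohort + split.reference if r.country != "unknown"
    )
    top = [c for c, _ in all_countries.most_common(top_countries)]
    tabulate(
        rows,
        lambda r: (r.country if r.country in top else "Other") if r.country != "unknown" else None,
        levels=top + ["Other"],
    )
    rows_section = "occupation"
    tabulate(rows, lambda r: r.occupation if r.occupation != "unknown" else None)
    rows_section = "report_code"
    tabulate(rows, lambda r: r.report_code if r.report_code != "unknown" else None)
    rows_section = "age_group"
    tabulate(rows, lambda r: r.age_group if r.age_group != "unknown" else None)
    rows_section = "month_first_report"
    tabulate(rows, _month_of_first_report)
    rows_section = "outcomes"
    for gname, recs in groups:
        counts = Counter(o for r in recs for o in r.outcomes)
        n = len(recs)
        for k in sorted(counts):
            rows.append({"section": "outcomes", "level": k, "group": gname,
                         "count": counts[k], "pct": round(100 * counts[k] / n, 1) if n else None})
    characteristics = pd.DataFrame(rows, columns=["section", "level", "group", "count", "pct"])

    n_cohort = len(split.cohort)
    all_suspect = Counter()
    primary_suspect = Counter()
    for r in split.cohort:
        all_suspect.update(r.suspected_substances())
        primary_suspect.update(
            {d.substance for d in r.drugs if d.role == "primary-suspect"}
        )
    drug_rows = [
        {
            "substance": s,
            "suspect_count": c,
            "suspect_pct": round(100 * c / n_cohort, 1) if n_cohort else None,
            "primary_suspect_count": primary_suspect.get(s, 0),
            "primary_suspect_pct": round(100 * primary_suspect.get(s, 0) / n_cohort, 1)
            if n_cohort else None,
        }
        for s, c in all_suspect.most_common()
    ]
    tables = {
        "characteristics": characteristics,
        "drugs": pd.DataFrame(
            drug_rows,
            columns=["substance", "suspect_count", "suspect_pct",
                     "primary_suspect_count", "primary_suspect_pct"],
        ),
    }

    if hierarchy is not None:
        hlt_counter = Counter()
        for r in split.cohort:
            hlt_counter.update(project_to_hlt(r, hierarchy, exclusions))
        tables["hlts"] = pd.DataFrame(
            [
                {"hlt": h, "count": c,
                 "pct": round(100 * c / n_cohort, 1) if n_cohort else None}
                for h, c in hlt_counter.most_common()
            ],
            columns=["hlt", "count", "pct"],
        )
    return tables
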