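import datetime as dt
from fractions import Fraction
from math import comb
from pathlib import Path

import pytest

from adversome.faers_io import DrugEntry, ReportRecord
from adversome.meddra import MedDRAHierarchy
from adversome import synthetic_data as sd


# ---------------------------------------------------------------------------
# Independent oracles


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p-value.

    Sums exact rational point probabilities of every table with the observed
    margins whose probability is at most that of the observed table (with
    the 1e-7 relative tolerance of the point-probability method).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    cutoff = p_obs + p_obs * Fraction(1, 10**7)
    return float(sum(p for p in probs if p <= cutoff))


# ---------------------------------------------------------------------------
# Hand-assembled fixtures


QUARTER_FIXTURE = {
    "demo": (
        "primaryid$caseid$caseversion$event_dt$fda_dt$sex$age_grp$occr_country$occp_cod$rept_cod\n"
        "1000011$100001$1$20200315$20200320$F$A$US$MD$EXP\n"
        "1000021$100002$1$202005$20200610$M$E$FR$CN$PER\n"
    ),
    "drug": (
        "primaryid$drug_seq$role_cod$drugname\n"
        "1000011$1$PS$HYDROXYCHLOROQUINE SULFATE\n"
        "1000011$2$C$PARACETAMOL\n"
        "1000021$1$PS$AZITHROMYCIN\n"
    ),
    "reac": (
        "primaryid$pt\n"
        "1000011$Electrocardiogram QT prolonged\n"
        "1000011$Hepatitis\n"
        "1000021$Diarrhoea\n"
    ),
    "indi": (
        "primaryid$indi_drug_seq$indi_pt\n"
        "1000011$1$COVID-19\n"
        "1000021$1$Hypertension\n"
    ),
    "outc": "primaryid$outc_cod\n1000011$HO\n",
}


def write_quarter_fixture(tmp_path: Path, extra_rows: dict[str, str] | None = None):
    """Write the 2-report hand fixture; returns the five paths in read order."""
    paths = {}
    for name, content in QUARTER_FIXTURE.items():
        if extra_rows and name in extra_rows:
            content = content + extra_rows[name]
        p = tmp_path / f"{name}.txt"
        p.write_text(content)
        paths[name] = p
    return [paths[k] for k in ("demo", "drug", "reac", "indi", "outc")]


DICT_FIXTURE = (
    "pt\tprimary_hlt\thlgt\tprimary_soc\n"
    "Electrocardiogram QT prolonged\tVentricular arrhythmias\tHLGT Cardiac arrhythmias\tCardiac disorders\n"
    "Torsade de pointes\tVentricular arrhythmias\tHLGT Cardiac arrhythmias\tCardiac disorders\n"
    "Hepatitis\tHepatocellular damage\tHLGT Hepatic disorders\tHepatobiliary disorders\n"
    "Diarrhoea\tDiarrhoea symptoms\tHLGT GI motility\tGastrointestinal disorders\n"
    "Blood pressure increased\tVascular tests\tHLGT Vascular tests\tInvestigations\n"
    "COVID-19\tCoronavirus infections\tHLGT Viral infections\tInfections and infestations\n"
    "Hypertension\tVascular hypertensive disorders\tHLGT Hypertension\tVascular disorders\n"
)

SMQ_FIXTURE = (
    "smq_name\tscope\tpt\n"
    "COVID-19\tnarrow\tCOVID-19\n"
    "COVID-19\tbroad\tCOVID-19\n"
    "COVID-19\tbroad\tBlood pressure increased\n"
)


@pytest.fixture
def dict_paths(tmp_path):
    d = tmp_path / "dict.tsv"
    s = tmp_path / "smq.tsv"
    d.write_text(DICT_FIXTURE)
    s.write_text(SMQ_FIXTURE)
    return d, s


@pytest.fixture
def hierarchy(dict_paths):
    from adversome.meddra import load_hierarchy

    return load_hierarchy(*dict_paths)


def make_report(report_id="1", case_id=None, case_version=1, drugs=None,
                reactions=("Hepatitis",), indications=("Hypertension",),
                occur=dt.date(2020, 3, 1), **kw) -> ReportRecord:
    return ReportRecord(
        report_id=report_id,
        case_id=case_id if case_id is not None else f"c{report_id}",
        case_version=case_version,
        occur_date=occur,
        fda_receipt_date=dt.date(2020, 4, 1),
        drugs=drugs if drugs is not None else [DrugEntry("ASPIRIN", "primary-suspect")],
        reaction_pts=frozenset(reactions),
        indication_pts=frozenset(indications),
        **kw,
    )


def contingency_cohort():
    """10 reports hand-built so that (drug=D, event=Hepatocellular damage)
    has the 2x2 table (a, b, c, d) = (3, 2, 1, 4)."""
    D = [DrugEntry("D", "primary-suspect")]
    other = [DrugEntry("X", "secondary-suspect")]
    reports = []
    for i in range(3):  # a: drug + event
        reports.append(make_report(f"a{i}", drugs=list(D), reactions=("Hepatitis",)))
    for i in range(2):  # b: drug, no event
        reports.append(make_report(f"b{i}", drugs=list(D), reactions=("Diarrhoea",)))
    reports.append(make_report("c0", drugs=list(other), reactions=("Hepatitis",)))  # c
    for i in range(4):  # d: neither
        reports.append(make_report(f"d{i}", drugs=list(other), reactions=("Diarrhoea",)))
    return reports


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """The tiny benchmark preset, generated once per session."""
    out = tmp_path_factory.mktemp("tiny")
    cfg = sd.default_benchmark_config("tiny")
    paths, truth = sd.generate(cfg, out)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def small_dataset():
    cfg = sd.default_benchmark_config("small")
    records, truth = sd.generate_records(cfg)
    return cfg, records, truth
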