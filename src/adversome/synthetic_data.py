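"""Synthetic spontaneous-report datasets with recorded ground truth.

Real quarterly pharmacovigilance extracts are large downloads and the
regulatory terminology is licensed, so the pipeline is exercised on
generated data that emulates the statistical structure the method assumes:
reports carry several drugs (with suspect roles) and several co-reported
events, drug–event effects are planted on the logit scale, syndromes are
planted as pairwise couplings between events, and a known fraction of
reports are exact duplicates.

Generative model, per report:

* drug exposures are independent Bernoulli(exposure_prob); each exposed
  drug is suspected with probability suspect_prob (first suspected drug
  is the primary suspect, the others secondary; unsuspected exposures are
  concomitant);
* the event vector starts from independent Bernoulli draws with
  logit P(event e) = baseline_logit_e + Σ_{exposed d} log_odds(d, e),
  then one Gibbs sweep over each syndrome's members (in listed order)
  applies the pairwise coupling — matching the Ising conditional the
  network estimator assumes;
* reports with no exposed drug or no event are resampled (every valid
  spontaneous report names at least one drug and one reaction);
* the indication field carries the epidemic-infection SMQ term with
  probability covid_indication_prob, otherwise a background indication;
* duplicates are exact copies under a fresh case/report id, injected at
  duplicate_rate; per-field missingness is applied last.

All randomness flows from one seed through named `numpy` SeedSequence
child streams, so sub-streams are independently reproducible.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .faers_io import DrugEntry, ReportRecord, write_quarter

COVID_PT = "COVID-19"
COVID_SMQ = "COVID-19"
_BACKGROUND_INDICATIONS = ("Hypertension", "Diabetes mellitus", "Rheumatoid arthritis")
_COUNTRIES = ("US", "FR", "IT", "GB", "JP")
_COUNTRY_P = (0.5, 0.15, 0.15, 0.1, 0.1)
_AGES = ("adult", "elderly", "teenager", "child")
_AGE_P = (0.6, 0.3, 0.06, 0.04)
_OCCS = ("physician", "pharmacist", "other-health-professional", "consumer", "lawyer")
_OCC_P = (0.35, 0.15, 0.25, 0.24, 0.01)
_REPTS = ("expedited", "direct", "periodic")
_REPT_P = (0.85, 0.05, 0.10)


@dataclass(frozen=True)
class DrugSpec:
    name: str
    exposure_prob: float
    suspect_prob: float = 0.9


@dataclass(frozen=True)
class EventSpec:
    pt: str
    hlt: str
    soc: str
    baseline_logit: float


@dataclass(frozen=True)
class EffectSpec:
    drug: str
    hlt: str
    log_odds: float


@dataclass(frozen=True)
class SyndromeSpec:
    members: tuple[str, ...]
    coupling: float


@dataclass
class SyntheticConfig:
    """Full description of one synthetic dataset."""

    n_reports: int
    seed: int
    drugs: list[DrugSpec]
    events: list[EventSpec]
    effects: list[EffectSpec] = field(default_factory=list)
    syndromes: list[SyndromeSpec] = field(default_factory=list)
    covid_indication_prob: float = 0.5
    duplicate_rate: float = 0.0
    missingness: dict[str, float] = field(default_factory=dict)
    sex_female_prob: float = 0.5
    window_start: dt.date = dt.date(2020, 1, 1)
    window_end: dt.date = dt.date(2020, 9, 30)

    def validate(self) -> None:
        probs = (
            [self.covid_indication_prob, self.duplicate_rate, self.sex_female_prob]
            + [d.exposure_prob for d in self.drugs]
            + [d.suspect_prob for d in self.drugs]
            + list(self.missingness.values())
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        hlts = [e.hlt for e in self.events]
        if len(set(hlts)) != len(hlts):
            raise ValueError("each HLT may appear in exactly one event spec")
        known = set(hlts)
        drug_names = {d.name for d in self.drugs}
        for eff in self.effects:
            if eff.hlt not in known:
                raise ValueError(f"effect on unknown HLT {eff.hlt!r}")
            if eff.drug not in drug_names:
                raise ValueError(f"effect for unknown drug {eff.drug!r}")
        seen: set[str] = set()
        for syn in self.syndromes:
            for m in syn.members:
                if m not in known:
                    raise ValueError(f"syndrome member {m!r} has no event spec")
                if m in seen:
                    raise ValueError(f"HLT {m!r} belongs to more than one syndrome")
                seen.add(m)
            if not np.isfinite(syn.coupling):
                raise ValueError("syndrome coupling must be finite")


@dataclass
class GroundTruth:
    """Planted structure, recorded at generation time."""

    true_sdr_pairs: set[tuple[str, str]]  # (drug, hlt) with a planted effect
    effect_sizes: dict[tuple[str, str], float]
    true_syndromes: list[set[str]]
    clone_ids: set[str]
    exposure: np.ndarray  # (n, n_drugs) pre-clone latent exposures
    event_states: np.ndarray  # (n, n_events) pre-clone latent event states
    report_ids: list[str]
    drug_names: list[str]
    event_hlts: list[str]

    def event_report_counts(self) -> dict[str, int]:
        return {h: int(c) for h, c in zip(self.event_hlts, self.event_states.sum(axis=0))}

    def to_json_dict(self) -> dict:
        return {
            "true_sdr_pairs": sorted(map(list, self.true_sdr_pairs)),
            "effect_sizes": {f"{d}|{h}": v for (d, h), v in self.effect_sizes.items()},
            "true_syndromes": [sorted(s) for s in self.true_syndromes],
            "clone_ids": sorted(self.clone_ids),
            "event_report_counts": self.event_report_counts(),
            "n_reports": len(self.report_ids),
        }


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["drugs", "events", "demo", "indication", "clones", "missing"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _sample_latents(cfg: SyntheticConfig, rng_d, rng_e):
    """Rejection-sample exposure and event matrices for all reports."""
    n, nd, ne = cfg.n_reports, len(cfg.drugs), len(cfg.events)
    exp_p = np.array([d.exposure_prob for d in cfg.drugs])
    base = np.array([e.baseline_logit for e in cfg.events])
    hlt_idx = {e.hlt: j for j, e in enumerate(cfg.events)}
    effect = np.zeros((nd, ne))
    dr_idx = {d.name: i for i, d in enumerate(cfg.drugs)}
    for eff in cfg.effects:
        effect[dr_idx[eff.drug], hlt_idx[eff.hlt]] += eff.log_odds

    def draw(m: int):
        exposure = (rng_d.random((m, nd)) < exp_p).astype(np.int8)
        logit = base + exposure @ effect
        x = (rng_e.random((m, ne)) < 1.0 / (1.0 + np.exp(-logit))).astype(np.int8)
        # one Gibbs pass over each syndrome's members, in listed order
        for syn in cfg.syndromes:
            members = [hlt_idx[h] for h in syn.members]
            for j in members:
                others = [k for k in members if k != j]
                eta = logit[:, j] + syn.coupling * x[:, others].sum(axis=1)
                x[:, j] = rng_e.random(m) < 1.0 / (1.0 + np.exp(-eta))
        return exposure, x

    exposure, x = draw(n)
    for _ in range(1000):
        bad = (exposure.sum(axis=1) == 0) | (x.sum(axis=1) == 0)
        if not bad.any():
            break
        e2, x2 = draw(int(bad.sum()))
        exposure[bad], x[bad] = e2, x2
    else:  # pragma: no cover - resampling failed to converge
        raise RuntimeError("rejection sampling did not converge; raise event/drug probabilities")
    return exposure, x


def _choice(rng, m, items, p):
    return rng.choice(len(items), size=m, p=np.asarray(p) / np.sum(p))


def generate_records(cfg: SyntheticConfig) -> tuple[list[ReportRecord], GroundTruth]:
    """Sample the dataset in memory; see the module docstring for the model."""
    cfg.validate()
    rng = _streams(cfg.seed)
    n = cfg.n_reports
    exposure, x = _sample_latents(cfg, rng["drugs"], rng["events"])
    suspect = (rng["drugs"].random(exposure.shape) < np.array(
        [d.suspect_prob for d in cfg.drugs])) & (exposure == 1)

    rd = rng["demo"]
    n_days = (cfg.window_end - cfg.window_start).days + 1
    occur_off = rd.integers(0, n_days, size=n)
    delay = rd.integers(0, 31, size=n)
    sex = np.where(rd.random(n) < cfg.sex_female_prob, "F", "M")
    age = np.array(_AGES)[_choice(rd, n, _AGES, _AGE_P)]
    country = np.array(_COUNTRIES)[_choice(rd, n, _COUNTRIES, _COUNTRY_P)]
    occ = np.array(_OCCS)[_choice(rd, n, _OCCS, _OCC_P)]
    rept = np.array(_REPTS)[_choice(rd, n, _REPTS, _REPT_P)]
    hosp = rd.random(n) < 0.30
    death = rd.random(n) < 0.05

    ri = rng["indication"]
    covid = ri.random(n) < cfg.covid_indication_prob
    bg = np.array(_BACKGROUND_INDICATIONS)[
        ri.integers(0, len(_BACKGROUND_INDICATIONS), size=n)
    ]

    rm = rng["missing"]
    none_missing = np.zeros(n, dtype=bool)
    miss = {f: rm.random(n) < p for f, p in cfg.missingness.items()}
    m_occur = miss.get("occur_date", none_missing)
    m_sex = miss.get("sex", none_missing)
    m_age = miss.get("age_group", none_missing)
    m_country = miss.get("country", none_missing)
    m_occ = miss.get("occupation", none_missing)

    records: list[ReportRecord] = []
    for i in range(n):
        case = 100000 + i
        occur = cfg.window_start + dt.timedelta(days=int(occur_off[i]))
        drugs = []
        suspected = np.flatnonzero(suspect[i])
        for k in np.flatnonzero(exposure[i]):
            if k in suspected:
                role = "primary-suspect" if k == suspected[0] else "secondary-suspect"
            else:
                role = "concomitant"
            drugs.append(DrugEntry(cfg.drugs[k].name, role))
        outcomes = set()
        if hosp[i]:
            outcomes.add("hospitalization")
        if death[i]:
            outcomes.add("death")
        records.append(
            ReportRecord(
                report_id=f"{case}1",
                case_id=str(case),
                case_version=1,
                occur_date=None if m_occur[i] else occur,
                fda_receipt_date=occur + dt.timedelta(days=int(delay[i])),
                sex="unknown" if m_sex[i] else str(sex[i]),
                age_group="unknown" if m_age[i] else str(age[i]),
                country="unknown" if m_country[i] else str(country[i]),
                occupation="unknown" if m_occ[i] else str(occ[i]),
                report_code=str(rept[i]),
                outcomes=frozenset(outcomes),
                drugs=drugs,
                reaction_pts=frozenset(
                    cfg.events[j].pt for j in np.flatnonzero(x[i])
                ),
                indication_pts=frozenset({COVID_PT if covid[i] else str(bg[i])}),
            )
        )

    # exact-copy duplicates under fresh case/report ids
    clone_ids: set[str] = set()
    n_clones = int(round(cfg.duplicate_rate * n))
    if n_clones:
        src = rng["clones"].choice(n, size=n_clones, replace=False)
        for k, i in enumerate(src):
            orig = records[i]
            case = 900000 + k
            clone = ReportRecord(
                report_id=f"{case}1",
                case_id=str(case),
                case_version=1,
                occur_date=orig.occur_date,
                fda_receipt_date=orig.fda_receipt_date,
                sex=orig.sex, age_group=orig.age_group, country=orig.country,
                occupation=orig.occupation, report_code=orig.report_code,
                outcomes=orig.outcomes, drugs=list(orig.drugs),
                reaction_pts=orig.reaction_pts, indication_pts=orig.indication_pts,
            )
            clone_ids.add(clone.report_id)
            records.append(clone)

    truth = GroundTruth(
        true_sdr_pairs={(e.drug, e.hlt) for e in cfg.effects},
        effect_sizes={(e.drug, e.hlt): e.log_odds for e in cfg.effects},
        true_syndromes=[set(s.members) for s in cfg.syndromes],
        clone_ids=clone_ids,
        exposure=exposure,
        event_states=x,
        report_ids=[r.report_id for r in records[:n]],
        drug_names=[d.name for d in cfg.drugs],
        event_hlts=[e.hlt for e in cfg.events],
    )
    return records, truth


def write_dictionary(cfg: SyntheticConfig, dict_path: str | Path, smq_path: str | Path) -> None:
    """Emit the synthetic terminology dictionary and SMQ files.

    Each event's PT (plus a synonym "<pt> NOS" mapping to the same HLT)
    goes under its HLT/HLGT/SOC; indication PTs are included under their
    own SOCs so every code in the dataset resolves.
    """
    lines = ["pt\tprimary_hlt\thlgt\tprimary_soc"]
    for e in cfg.events:
        hlgt = f"HLGT {e.hlt}"
        lines.append(f"{e.pt}\t{e.hlt}\t{hlgt}\t{e.soc}")
        lines.append(f"{e.pt} NOS\t{e.hlt}\t{hlgt}\t{e.soc}")
    lines.append(
        f"{COVID_PT}\tCoronavirus infections\tHLGT Viral infections\t"
        "Infections and infestations"
    )
    lines.append(
        "Coronavirus test positive\tVirus identification and serology\t"
        "HLGT Microbiology tests\tInvestigations"
    )
    for pt, hlt, soc in (
        ("Hypertension", "Vascular hypertensive disorders NEC", "Vascular disorders"),
        ("Diabetes mellitus", "Diabetes mellitus (incl subtypes)",
         "Metabolism and nutrition disorders"),
        ("Rheumatoid arthritis", "Rheumatoid arthropathies",
         "Musculoskeletal and connective tissue disorders"),
    ):
        lines.append(f"{pt}\t{hlt}\tHLGT {hlt}\t{soc}")
    Path(dict_path).write_text("\n".join(lines) + "\n")

    smq_lines = [
        "smq_name\tscope\tpt",
        f"{COVID_SMQ}\tnarrow\t{COVID_PT}",
        f"{COVID_SMQ}\tbroad\t{COVID_PT}",
        f"{COVID_SMQ}\tbroad\tCoronavirus test positive",
    ]
    Path(smq_path).write_text("\n".join(smq_lines) + "\n")


def generate(cfg: SyntheticConfig, out_dir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Generate the dataset and emit all pipeline input files.

    Writes the five $-delimited quarterly tables, the dictionary and SMQ
    TSVs, and the ground truth as JSON; returns the path map and the
    in-memory :class:`GroundTruth`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = generate_records(cfg)
    paths = write_quarter(records, out)
    paths["dictionary"] = out / "meddra_synthetic.tsv"
    paths["smq"] = out / "smq_synthetic.tsv"
    write_dictionary(cfg, paths["dictionary"], paths["smq"])
    paths["ground_truth"] = out / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth.to_json_dict(), indent=1))
    return paths, truth


# ---------------------------------------------------------------------------
# Benchmark presets

_SOCS = (
    "Cardiac disorders",
    "Hepatobiliary disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Nervous system disorders",
    "Gastrointestinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Renal and urinary disorders",
    "Infections and infestations",
    "Blood and lymphatic system disorders",
    "Psychiatric disorders",
)

_PRESET_SEEDS = {"tiny": 12001, "small": 12002, "medium": 12003}


def _preset_events(n_events: int, include_excluded_soc: bool) -> list[EventSpec]:
    events = []
    for j in range(n_events):
        soc = _SOCS[j % len(_SOCS)]
        # baselines spread so column counts range from common to rare
        baseline = -2.2 - 1.8 * (j / max(n_events - 1, 1))
        events.append(EventSpec(pt=f"Event PT {j:02d}", hlt=f"HLT {j:02d}", soc=soc,
                                baseline_logit=round(baseline, 3)))
    if include_excluded_soc:
        # two events in a non-specific SOC: projected away before analysis
        events.append(EventSpec("Drug level increased", "Drug level analyses",
                                "Investigations", -2.5))
        events.append(EventSpec("Fall", "Non-site specific injuries NEC",
                                "Injury, poisoning and procedural complications", -2.5))
    return events


def default_benchmark_config(scale: str) -> SyntheticConfig:
    """Shipped presets: ``tiny`` (200 reports, 8 drugs, 15 HLTs), ``small``
    (2,000 / 10 / 40) and ``medium`` (10,000 / 12 / 80), each with planted
    effects, syndromes and 2% duplicates under a fixed documented seed."""
    if scale not in _PRESET_SEEDS:
        raise ValueError(f"unknown scale {scale!r}; choose tiny, small or medium")
    seed = _PRESET_SEEDS[scale]
    if scale == "tiny":
        n, n_drugs, n_events = 200, 8, 15
        effects = [
            EffectSpec("DRUG00", "HLT 00", 2.5),
            EffectSpec("DRUG01", "HLT 03", 2.0),
            EffectSpec("DRUG02", "HLT 06", 1.0),
        ]
        syndromes = [
            SyndromeSpec(("HLT 01", "HLT 04", "HLT 07"), 1.5),
            SyndromeSpec(("HLT 02", "HLT 05", "HLT 08"), 1.5),
        ]
    elif scale == "small":
        n, n_drugs, n_events = 2000, 10, 40
        effects = [
            EffectSpec("DRUG00", "HLT 02", 2.5),
            EffectSpec("DRUG01", "HLT 05", 2.2),
            EffectSpec("DRUG02", "HLT 08", 2.0),
            EffectSpec("DRUG03", "HLT 11", 1.0),
            EffectSpec("DRUG04", "HLT 14", 0.5),
        ]
        syndromes = [
            SyndromeSpec(("HLT 01", "HLT 04", "HLT 07", "HLT 10"), 1.5),
            SyndromeSpec(("HLT 03", "HLT 06", "HLT 09", "HLT 12"), 1.5),
            SyndromeSpec(("HLT 13", "HLT 16", "HLT 19"), 1.5),
        ]
    else:
        n, n_drugs, n_events = 10000, 12, 80
        effects = [
            EffectSpec("DRUG00", "HLT 02", 2.5),
            EffectSpec("DRUG01", "HLT 05", 2.0),
            EffectSpec("DRUG02", "HLT 08", 1.5),
            EffectSpec("DRUG03", "HLT 11", 1.0),
            EffectSpec("DRUG04", "HLT 14", 0.5),
        ]
        syndromes = [
            SyndromeSpec(("HLT 01", "HLT 04", "HLT 07", "HLT 10"), 1.5),
            SyndromeSpec(("HLT 03", "HLT 06", "HLT 09", "HLT 12"), 1.5),
            SyndromeSpec(("HLT 13", "HLT 16", "HLT 19", "HLT 22"), 1.5),
        ]
    drugs = [
        DrugSpec(f"DRUG{i:02d}", exposure_prob=round(0.30 - 0.02 * i, 3),
                 suspect_prob=0.9)
        for i in range(n_drugs)
    ]
    return SyntheticConfig(
        n_reports=n,
        seed=seed,
        drugs=drugs,
        events=_preset_events(n_events, include_excluded_soc=True),
        effects=effects,
        syndromes=syndromes,
        covid_indication_prob=0.5,
        duplicate_rate=0.02,
        missingness={},
    )


def null_config(n_reports: int = 2000, seed: int = 0, n_drugs: int = 8,
                n_events: int = 20) -> SyntheticConfig:
    """A no-effect configuration: independent drugs and events, no
    syndromes, no duplicates — the null for type-I-error checks."""
    drugs = [DrugSpec(f"DRUG{i:02d}", 0.25, 0.9) for i in range(n_drugs)]
    return SyntheticConfig(
        n_reports=n_reports, seed=seed, drugs=drugs,
        events=_preset_events(n_events, include_excluded_soc=False),
        effects=[], syndromes=[], covid_indication_prob=1.0,
        duplicate_rate=0.0, missingness={},
    )


def config_to_dict(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    d["window_start"] = cfg.window_start.isoformat()
    d["window_end"] = cfg.window_end.isoformat()
    return d
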