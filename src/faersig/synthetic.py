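"""FAERS-like synthetic spontaneous-report generator with known ground truth.

Emulates the structure of quarterly FAERS extracts — demographics with
missingness, drug mentions with role codes, MedDRA-style preferred-term
reactions, therapy/event dates with Weibull-distributed onset lags, duplicate
case versions — while recording the ground truth (group labels, per-pair
counts, onset parameters) needed to test every downstream stage exactly.

Default demographic mixes mirror the published combination-cohort margins of
a large FAERS infliximab/azathioprine extraction so synthetic descriptive
tables look like real ones; signal structure is planted per (group, PT) as a
relative reporting rate multiplier on the baseline PT probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from faersig.cohort import load_lexicon
from faersig.faers_io import DrugEntry, ReactionEntry, SafetyReport, normalize_drug_name

GROUPS = ("A_only", "B_only", "A_plus_B", "excluded")

DRUG_A_NAMES = ("INFLIXIMAB", "REMICADE", "INFLECTRA")
DRUG_B_NAMES = ("AZATHIOPRINE", "IMURAN", "AZATHIOPRINE SODIUM")
OTHER_DRUGS = ("ASPIRIN", "METFORMIN", "LISINOPRIL", "IBUPROFEN", "OMEPRAZOLE")

FILLER_PTS = (
    "Headache", "Nausea", "Diarrhoea", "Pyrexia", "Fatigue", "Rash",
    "Arthralgia", "Infusion related reaction", "Vomiting", "Abdominal pain",
)
GI_INDI_PTS = ("Crohn's disease", "Colitis ulcerative")
OTHER_INDI_PTS = ("Rheumatoid arthritis", "Psoriasis", "Ankylosing spondylitis")
COUNTRIES = ("US", "CA", "GB", "FR", "DE", "JP")

_AGE_BAND_RANGES = {"<18": (1.0, 18.0), "18-45": (18.0, 45.0), "45-60": (45.0, 60.0),
                    "60-75": (60.0, 75.0), ">75": (75.0, 100.0)}
_WEIGHT_BAND_RANGES = {"<50 kg": (25.0, 50.0), "50-100 kg": (50.0, 100.0),
                       ">100 kg": (100.0, 160.0)}


def _default_tumor_rates() -> dict[str, float]:
    # 20 fixture PTs at a baseline that yields ~12% tumor-report prevalence
    lex = load_lexicon()
    return {pt: 0.0064 for pt in lex.pts[:20]}


@dataclass
class SyntheticConfig:
    """Full parameterization of the report generator."""

    n_reports: int = 10_000
    seed: int = 0
    sex_mix: dict[str, float] = field(default_factory=lambda: {
        "female": 0.4853, "male": 0.4010, "missing": 0.1137})
    age_mix: dict[str, float] = field(default_factory=lambda: {
        "<18": 0.1021, "18-45": 0.3294, "45-60": 0.1603, "60-75": 0.0950,
        ">75": 0.0138, "missing": 0.2994})
    weight_mix: dict[str, float] = field(default_factory=lambda: {
        "<50 kg": 0.0782, "50-100 kg": 0.4194, ">100 kg": 0.0561, "missing": 0.4463})
    indication_mix: dict[str, float] = field(default_factory=lambda: {
        "gastrointestinal": 0.8493, "other": 0.1507})
    reporter_mix: dict[str, float] = field(default_factory=lambda: {
        "MD": 0.3384, "CN": 0.1708, "OT": 0.2852, "PH": 0.1995, "LW": 0.0008,
        "missing": 0.0053})
    outcome_mix: dict[str, float] = field(default_factory=lambda: {
        "OT": 0.5691, "HO": 0.3124, "DE": 0.0405, "LT": 0.0369, "DS": 0.0160,
        "CA": 0.0040, "RI": 0.0008, "missing": 0.0203})
    group_mix: dict[str, float] = field(default_factory=lambda: {
        "A_only": 0.30, "B_only": 0.10, "A_plus_B": 0.15, "excluded": 0.45})
    background_pt_rates: dict[str, float] = field(default_factory=_default_tumor_rates)
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    onset_model: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "A_only": (1.0, 900.0), "B_only": (1.0, 900.0),
        "A_plus_B": (0.7, 900.0), "excluded": (1.0, 900.0)})
    duplicate_rate: float = 0.10
    date_missing_rate: float = 0.25
    child_age_months_rate: float = 0.2  # fraction of <18 ages emitted in months
    date_window: tuple[str, str] = ("2014-01-01", "2023-12-31")
    quarter_label: str = "2024Q2"

    def validate(self) -> None:
        for name in ("sex_mix", "age_mix", "weight_mix", "indication_mix",
                     "reporter_mix", "outcome_mix", "group_mix"):
            mix = getattr(self, name)
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} has a negative probability")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        rate_by_group_pt: dict[tuple[str, str], float] = {}
        for group, pt, lam in self.planted_signals:
            if group not in GROUPS:
                raise ValueError(f"unknown group in planted signal: {group!r}")
            if pt not in self.background_pt_rates:
                raise ValueError(f"planted PT {pt!r} has no baseline rate")
            if lam <= 0:
                raise ValueError("planted relative rate must be positive")
            rate_by_group_pt[(group, pt)] = lam * self.background_pt_rates[pt]
        if any(r > 1 for r in rate_by_group_pt.values()):
            raise ValueError("a planted rate exceeds 1; reduce lambda or baseline")
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")


@dataclass
class GroundTruth:
    """Exact generator bookkeeping for equality tests."""

    distinct_case_count: int
    group_by_case: dict[str, str]
    pair_counts: dict[str, dict[str, int]]  # group -> pt -> a-cell count
    tumor_flag_by_case: dict[str, bool]
    onset_model: dict[str, tuple[float, float]]
    n_duplicates: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _choice(rng: np.random.Generator, mix: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(mix)
    p = np.array([mix[k] for k in keys], dtype=float)
    p = p / p.sum()
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=n, p=p)]


def generate_reports(config: SyntheticConfig) -> tuple[list[dict], GroundTruth]:
    """Draw the synthetic reports as plain records plus exact ground truth.

    One record per distinct case; duplicate case versions are materialized
    only at file-writing time (the record is the version that deduplication
    must retain).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    groups = _choice(rng, config.group_mix, n)
    sexes = _choice(rng, config.sex_mix, n)
    age_bands = _choice(rng, config.age_mix, n)
    weight_bands = _choice(rng, config.weight_mix, n)
    indications = _choice(rng, config.indication_mix, n)
    reporters = _choice(rng, config.reporter_mix, n)
    outcomes = _choice(rng, config.outcome_mix, n)
    countries = _choice(rng, dict.fromkeys(COUNTRIES, 1 / len(COUNTRIES)), n)

    ages = np.full(n, np.nan)
    for band, (lo, hi) in _AGE_BAND_RANGES.items():
        m = age_bands == band
        ages[m] = rng.uniform(lo, hi - 1e-9, m.sum())
    weights = np.full(n, np.nan)
    for band, (lo, hi) in _WEIGHT_BAND_RANGES.items():
        m = weight_bands == band
        weights[m] = rng.uniform(lo, hi - 1e-9, m.sum())

    # tumor PT indicator matrix: baseline rate per PT, multiplied by the
    # planted relative reporting rate for (group, PT) pairs
    pts = list(config.background_pt_rates)
    base = np.array([config.background_pt_rates[p] for p in pts])
    rate = np.tile(base, (n, 1))
    for group, pt, lam in config.planted_signals:
        j = pts.index(pt)
        rate[groups == group, j] = min(base[j] * lam, 1.0)
    has_pt = rng.random((n, len(pts))) < rate

    filler_idx = rng.integers(0, len(FILLER_PTS), n)
    extra_conco = rng.random(n) < 0.5
    conco_idx = rng.integers(0, len(OTHER_DRUGS), n)
    a_name_idx = rng.integers(0, len(DRUG_A_NAMES), n)
    b_name_idx = rng.integers(0, len(DRUG_B_NAMES), n)
    other_idx = rng.integers(0, len(OTHER_DRUGS), n)
    combo_a_ps = rng.random(n) < 0.7
    combo_b_role = np.array(["SS", "C", "I"], dtype=object)[rng.integers(0, 3, n)]
    child_months = rng.random(n) < config.child_age_months_rate

    win_lo = date.fromisoformat(config.date_window[0])
    win_hi = date.fromisoformat(config.date_window[1])
    span = (win_hi - win_lo).days
    start_offsets = rng.integers(0, span + 1, n)
    onset_days = np.empty(n)
    for g, (shape, scale) in config.onset_model.items():
        m = groups == g
        onset_days[m] = scale * rng.weibull(shape, m.sum())
    onset_days = np.maximum(1, np.rint(onset_days)).astype(int)
    miss_event = rng.random(n) < config.date_missing_rate
    miss_start = rng.random(n) < config.date_missing_rate
    fda_offsets = rng.integers(0, span + 1, n)
    gi_idx = rng.integers(0, len(GI_INDI_PTS), n)
    oth_idx = rng.integers(0, len(OTHER_INDI_PTS), n)

    records: list[dict] = []
    pair_counts: dict[str, dict[str, int]] = {g: {} for g in GROUPS}
    group_by_case: dict[str, str] = {}
    tumor_flag: dict[str, bool] = {}

    for i in range(n):
        case_id = f"{10_000_000 + i}"
        g = str(groups[i])

        drugs: list[tuple[str, str, bool]] = []  # (name, role, is_target)
        if g == "A_only":
            drugs.append((DRUG_A_NAMES[a_name_idx[i]], "PS", True))
        elif g == "B_only":
            drugs.append((DRUG_B_NAMES[b_name_idx[i]], "PS", True))
        elif g == "A_plus_B":
            if combo_a_ps[i]:
                drugs.append((DRUG_A_NAMES[a_name_idx[i]], "PS", True))
                drugs.append((DRUG_B_NAMES[b_name_idx[i]], str(combo_b_role[i]), False))
            else:
                drugs.append((DRUG_B_NAMES[b_name_idx[i]], "PS", True))
                drugs.append((DRUG_A_NAMES[a_name_idx[i]], "SS", False))
        else:
            drugs.append((OTHER_DRUGS[other_idx[i]], "PS", True))
        if extra_conco[i]:
            drugs.append((OTHER_DRUGS[conco_idx[i]], "C", False))

        reactions = [FILLER_PTS[filler_idx[i]]]
        for j, pt in enumerate(pts):
            if has_pt[i, j]:
                reactions.append(pt)
                pair_counts[g][pt] = pair_counts[g].get(pt, 0) + 1
        tumor_flag[case_id] = len(reactions) > 1

        start = win_lo + timedelta(days=int(start_offsets[i]))
        event = start + timedelta(days=int(onset_days[i]))
        age_val: float | None = None if age_bands[i] == "missing" else float(ages[i])
        age_unit = "YR"
        if age_val is not None and age_bands[i] == "<18" and child_months[i]:
            age_val, age_unit = age_val * 12.0, "MON"

        records.append({
            "case_id": case_id,
            "group": g,
            "sex": {"female": "F", "male": "M"}.get(str(sexes[i]), ""),
            "age": None if age_val is None else round(age_val, 1),
            "age_cod": age_unit,
            "weight": None if weight_bands[i] == "missing" else round(float(weights[i]), 1),
            "country": str(countries[i]),
            "reporter": "" if reporters[i] == "missing" else str(reporters[i]),
            "outcome": "" if outcomes[i] == "missing" else str(outcomes[i]),
            "indication": str(indications[i]),
            "indi_pt": GI_INDI_PTS[gi_idx[i]] if indications[i] == "gastrointestinal"
                       else OTHER_INDI_PTS[oth_idx[i]],
            "drugs": drugs,
            "reactions": reactions,
            "start_date": None if miss_start[i] else start,
            "event_date": None if miss_event[i] else event,
            "onset_days": int(onset_days[i]),
            "fda_dt": int((win_lo + timedelta(days=int(fda_offsets[i]))).strftime("%Y%m%d")),
        })
        group_by_case[case_id] = g

    n_dup = int(round(config.duplicate_rate * n))
    truth = GroundTruth(
        distinct_case_count=n,
        group_by_case=group_by_case,
        pair_counts=pair_counts,
        tumor_flag_by_case=tumor_flag,
        onset_model=dict(config.onset_model),
        n_duplicates=n_dup,
    )
    return records, truth


def to_safety_reports(records: Sequence[dict]) -> list[SafetyReport]:
    """Materialize the final (post-dedup) SafetyReport for each record,
    bypassing the file round-trip; field conventions match faers_io."""
    out = []
    for rec in records:
        drugs = tuple(
            DrugEntry(name_raw=name, name_std=normalize_drug_name(name), role=role,
                      start_date=rec["start_date"] if is_target else None)
            for name, role, is_target in rec["drugs"]
        )
        age = rec["age"]
        if age is not None and rec["age_cod"] == "MON":
            age = age / 12.0
        out.append(SafetyReport(
            case_id=rec["case_id"],
            version_key=(2, rec["fda_dt"], 0),
            sex={"F": "female", "M": "male"}.get(rec["sex"]),
            age_years=age,
            weight_kg=rec["weight"],
            country=rec["country"],
            reporter=rec["reporter"] or None,
            outcome_codes=frozenset([rec["outcome"]]) if rec["outcome"] else frozenset(),
            event_date=rec["event_date"],
            therapy_start_date=rec["start_date"],
            drugs=drugs,
            reactions=tuple(ReactionEntry(pt=pt) for pt in rec["reactions"]),
            indication_class=rec["indication"],
        ))
    return out


def _dt(d: date | None) -> str:
    return d.strftime("%Y%m%d") if d is not None else ""


def write_quarter(records: Sequence[dict], truth: GroundTruth, config: SyntheticConfig,
                  outdir: str | Path) -> dict[str, Path]:
    """Write the records as `$`-delimited FAERS-dialect tables plus the
    ground-truth JSON. A deterministic subset of cases is emitted twice: an
    earlier case version with one perturbed field (weight blanked), so the
    latest-version dedup rule is exercised."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_dup = truth.n_duplicates
    dup_cases = {rec["case_id"] for rec in records[:n_dup]}

    demo, drug, reac, outc, ther, indi, rpsr = [], [], [], [], [], [], []

    def emit(rec: dict, version: int, perturb: bool) -> None:
        pid = f"{rec['case_id']}{version}"
        fda = rec["fda_dt"] - 1 if version == 1 else rec["fda_dt"]
        demo.append({
            "primaryid": pid, "caseid": rec["case_id"], "caseversion": version,
            "fda_dt": fda, "event_dt": _dt(rec["event_date"]),
            "age": "" if rec["age"] is None else rec["age"], "age_cod": rec["age_cod"],
            "sex": rec["sex"],
            "wt": "" if (rec["weight"] is None or perturb) else rec["weight"],
            "wt_cod": "KG", "reporter_country": rec["country"],
            "occp_cod": rec["reporter"],
        })
        for seq, (name, role, is_target) in enumerate(rec["drugs"], start=1):
            drug.append({"primaryid": pid, "caseid": rec["case_id"], "drug_seq": seq,
                         "role_cod": role, "drugname": name})
            if is_target and rec["start_date"] is not None:
                ther.append({"primaryid": pid, "caseid": rec["case_id"],
                             "dsg_drug_seq": seq, "start_dt": _dt(rec["start_date"]),
                             "end_dt": ""})
        for pt in rec["reactions"]:
            reac.append({"primaryid": pid, "caseid": rec["case_id"], "pt": pt})
        if rec["outcome"]:
            outc.append({"primaryid": pid, "caseid": rec["case_id"],
                         "outc_cod": rec["outcome"]})
        indi.append({"primaryid": pid, "caseid": rec["case_id"], "indi_drug_seq": 1,
                     "indi_pt": rec["indi_pt"]})
        rpsr.append({"primaryid": pid, "caseid": rec["case_id"], "rpsr_cod": "FGN"})

    for rec in records:
        if rec["case_id"] in dup_cases:
            emit(rec, version=1, perturb=True)
            emit(rec, version=2, perturb=False)
        else:
            emit(rec, version=1, perturb=False)

    tables = {"demo": demo, "drug": drug, "reac": reac, "outc": outc,
              "ther": ther, "indi": indi, "rpsr": rpsr}
    cols = {
        "demo": ["primaryid", "caseid", "caseversion", "fda_dt", "event_dt", "age",
                 "age_cod", "sex", "wt", "wt_cod", "reporter_country", "occp_cod"],
        "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
        "reac": ["primaryid", "caseid", "pt"],
        "outc": ["primaryid", "caseid", "outc_cod"],
        "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
        "indi": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
        "rpsr": ["primaryid", "caseid", "rpsr_cod"],
    }
    paths: dict[str, Path] = {}
    for name, rows in tables.items():
        p = outdir / f"{name.upper()}{config.quarter_label}.txt"
        pd.DataFrame(rows, columns=cols[name]).to_csv(p, sep="$", index=False)
        paths[name] = p
    truth.to_json(outdir / "ground_truth.json")
    return paths


def generate_quarter(config: SyntheticConfig, outdir: str | Path
                     ) -> tuple[dict[str, Path], GroundTruth]:
    """Generate one synthetic quarter on disk; bit-reproducible per seed."""
    records, truth = generate_reports(config)
    paths = write_quarter(records, truth, config, outdir)
    return paths, truth


def expected_tables(
    config: SyntheticConfig, truth: GroundTruth, group: str
) -> dict[str, tuple[int, int, int, int]]:
    """Exact (a, b, c, d) per PT for one group from generator bookkeeping,
    for equality tests against the pipeline's contingency construction.
    Only PTs with a >= 1 are returned."""
    n_total = truth.distinct_case_count
    n_group = sum(1 for g in truth.group_by_case.values() if g == group)
    out: dict[str, tuple[int, int, int, int]] = {}
    for pt in config.background_pt_rates:
        a = truth.pair_counts.get(group, {}).get(pt, 0)
        if a == 0:
            continue
        total_pt = sum(truth.pair_counts.get(g, {}).get(pt, 0) for g in GROUPS)
        c = total_pt - a
        out[pt] = (a, n_group - a, c, (n_total - n_group) - c)
    return out
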