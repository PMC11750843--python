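"""Reading, validation and deduplication of FAERS-style quarterly ASCII tables.

FAERS quarters ship as ``$``-delimited text files, one per table: DEMO
(demographics, one row per case version), DRUG (one row per drug mention with
a role code), REAC (one row per MedDRA preferred term), OUTC (outcome codes),
THER (therapy start/end dates), INDI (indications) and RPSR (report sources).
A case may appear in several quarters and under several case versions; the
analysis universe keeps exactly one :class:`SafetyReport` per case, the latest
version.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("demo", "drug", "reac", "outc", "ther", "indi", "rpsr")
MANDATORY_TABLES = ("demo", "drug", "reac")

ROLE_CODES = ("PS", "SS", "C", "I")
REPORTER_CODES = ("MD", "CN", "OT", "PH", "LW")
OUTCOME_CODES = ("OT", "HO", "DE", "LT", "DS", "CA", "RI")

#: years per unit for each FAERS age-unit code
AGE_UNIT_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: kg per unit for each FAERS weight-unit code
WEIGHT_UNIT_KG = {"KG": 1.0, "LBS": 0.453592, "GMS": 0.001}

AGE_MAX_YEARS = 120.0
WEIGHT_MAX_KG = 500.0

# Minimal aliasing for the pre-2012 legacy column names.
_COLUMN_ALIASES = {
    "isr": "primaryid",
    "case": "caseid",
    "gndr_cod": "sex",
    "drug_seq": "drug_seq",
}

# Indication preferred terms counted as gastrointestinal for Table-1-style
# summaries (flat lookup; substring match on a few stems covers variants).
GI_INDICATION_STEMS = (
    "crohn",
    "colitis",
    "inflammatory bowel",
    "gastro",
    "intestin",
    "coeliac",
    "celiac",
    "bowel",
)


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report."""

    name_raw: str
    name_std: str
    role: str  # PS / SS / C / I
    start_date: date | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"invalid drug role code: {self.role!r}")


@dataclass(frozen=True)
class ReactionEntry:
    """One MedDRA preferred term on a report, with its system organ class."""

    pt: str
    soc: str = "unmapped"


@dataclass(frozen=True)
class SafetyReport:
    """A deduplicated spontaneous report."""

    case_id: str
    version_key: tuple[int, int, int]  # (case version, receipt date, file order)
    sex: str | None = None  # "female" / "male" / None
    age_years: float | None = None
    weight_kg: float | None = None
    country: str | None = None
    reporter: str | None = None
    outcome_codes: frozenset[str] = frozenset()
    event_date: date | None = None
    therapy_start_date: date | None = None
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[ReactionEntry, ...] = ()
    indication_class: str | None = None  # "gastrointestinal" / "other" / None


@dataclass
class RawQuarter:
    """Parsed but not-yet-deduplicated tables for one quarter."""

    demo_rows: pd.DataFrame
    drug_rows: pd.DataFrame
    reac_rows: pd.DataFrame
    outc_rows: pd.DataFrame
    ther_rows: pd.DataFrame
    indi_rows: pd.DataFrame
    rpsr_rows: pd.DataFrame
    quarter_label: str
    parse_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not re.fullmatch(r"\d{4}Q[1-4]", self.quarter_label):
            raise ValueError(f"quarter label must match YYYYQ[1-4]: {self.quarter_label!r}")


def convert_age(value: float | None, unit_code: str | None) -> float | None:
    """Convert a FAERS (age, unit-code) pair to years.

    Unknown unit codes and results outside the plausibility window [0, 120]
    years yield missing.
    """
    if value is None or unit_code is None:
        return None
    factor = AGE_UNIT_YEARS.get(str(unit_code).strip().upper())
    if factor is None:
        logger.debug("unknown age unit code %r -> missing", unit_code)
        return None
    years = float(value) * factor
    if years < 0 or years > AGE_MAX_YEARS:
        return None
    return years


def convert_weight(value: float | None, unit_code: str | None) -> float | None:
    """Convert a FAERS (weight, unit-code) pair to kg; window (0, 500] kg."""
    if value is None:
        return None
    code = str(unit_code).strip().upper() if unit_code else "KG"
    factor = WEIGHT_UNIT_KG.get(code)
    if factor is None:
        logger.debug("unknown weight unit code %r -> missing", unit_code)
        return None
    kg = float(value) * factor
    if kg <= 0 or kg > WEIGHT_MAX_KG:
        return None
    return kg


def parse_faers_date(raw: str | None, day_precision_only: bool = False) -> date | None:
    """Parse a YYYYMMDD date string; YYYYMM and YYYY are padded to the first
    of the period unless ``day_precision_only`` is set, in which case partial
    dates are missing (required for time-to-onset arithmetic)."""
    if raw is None:
        return None
    s = str(raw).strip().split(".")[0]  # tolerate float-formatted ints
    if not s or not s.isdigit():
        return None
    try:
        if len(s) == 8:
            return date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if day_precision_only:
            return None
        if len(s) == 6:
            return date(int(s[:4]), int(s[4:6]), 1)
        if len(s) == 4:
            return date(int(s), 1, 1)
    except ValueError:
        return None
    return None


_DOSE_TOKEN = re.compile(r"^(\d+(\.\d+)?)?(mg|g|ml|mcg|iu)$|^\d+(\.\d+)?$")
_SALT_TOKENS = {
    "sodium", "hydrochloride", "hcl", "sulfate", "sulphate", "acetate",
    "citrate", "tartrate", "maleate", "mesylate", "besylate", "phosphate",
}


def normalize_drug_name(raw: str) -> str:
    """Lower-case a free-text drug name and trim trailing salt/dose tokens."""
    tokens = re.sub(r"[(),.]", " ", str(raw).lower()).split()
    while tokens and (_DOSE_TOKEN.match(tokens[-1]) or tokens[-1] in _SALT_TOKENS):
        tokens.pop()
    return " ".join(tokens)


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    df.columns = [_COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    return df


def read_quarter(paths: Mapping[str, str | Path], quarter_label: str = "2024Q2") -> RawQuarter:
    """Read one quarter's tables into a :class:`RawQuarter`.

    Parameters
    ----------
    paths
        Mapping from table name (``demo``, ``drug``, ...) to file path.
        DEMO, DRUG and REAC are mandatory; the rest default to empty tables.
    quarter_label
        Label of the quarter, ``YYYYQ[1-4]``.
    """
    tables: dict[str, pd.DataFrame] = {}
    parse_log: dict[str, int] = {}
    for name in TABLE_NAMES:
        key = name if name in paths else name.upper() if name.upper() in paths else None
        if key is None:
            if name in MANDATORY_TABLES:
                raise FileNotFoundError(f"mandatory table {name.upper()} not provided")
            tables[name] = pd.DataFrame(columns=["caseid"])
            continue
        path = Path(paths[key])
        if not path.exists():
            raise FileNotFoundError(f"table file does not exist: {path}")
        df = _read_table(path)
        if "caseid" not in df.columns:
            raise ValueError(f"{name.upper()} table at {path} lacks a caseid column")
        n_before = len(df)
        df = df[df["caseid"].str.strip() != ""]
        dropped = n_before - len(df)
        if dropped:
            logger.warning("%s: dropped %d rows with empty caseid", name.upper(), dropped)
        parse_log[f"{name}_rows"] = len(df)
        parse_log[f"{name}_malformed"] = dropped
        tables[name] = df.reset_index(drop=True)

    demo_cases = set(tables["demo"]["caseid"])
    for name in TABLE_NAMES:
        if name == "demo" or tables[name].empty:
            continue
        orphan = ~tables[name]["caseid"].isin(demo_cases)
        if orphan.any():
            logger.warning("%s: %d rows reference cases absent from DEMO; dropped",
                           name.upper(), int(orphan.sum()))
            parse_log[f"{name}_orphan"] = int(orphan.sum())
            tables[name] = tables[name][~orphan].reset_index(drop=True)

    return RawQuarter(
        demo_rows=tables["demo"],
        drug_rows=tables["drug"],
        reac_rows=tables["reac"],
        outc_rows=tables["outc"],
        ther_rows=tables["ther"],
        indi_rows=tables["indi"],
        rpsr_rows=tables["rpsr"],
        quarter_label=quarter_label,
        parse_log=parse_log,
    )


def _safe_float(s: str | None) -> float | None:
    if s is None:
        return None
    s = str(s).strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _classify_indication(indi_pts: Sequence[str]) -> str | None:
    if not indi_pts:
        return None
    for pt in indi_pts:
        low = pt.lower()
        if any(stem in low for stem in GI_INDICATION_STEMS):
            return "gastrointestinal"
    return "other"


def _int_or_zero(s: str | None) -> int:
    s = str(s).strip() if s is not None else ""
    return int(float(s)) if s and s.replace(".", "", 1).isdigit() else 0


def _assemble_versions(quarter: RawQuarter, file_order: int,
                       soc_map: Mapping[str, str] | None = None) -> list[SafetyReport]:
    """Build one SafetyReport candidate per (caseid, caseversion) DEMO row."""
    soc_map = soc_map or {}
    demo = quarter.demo_rows

    # child rows belong to one case *version*: key them by primaryid when the
    # table carries it, falling back to caseid for minimal inputs
    def grouped(df: pd.DataFrame) -> dict[str, list[dict]]:
        if df.empty or "caseid" not in df.columns:
            return {}
        key = "primaryid" if "primaryid" in df.columns else "caseid"
        out: dict[str, list[dict]] = {}
        for rec in df.to_dict("records"):
            out.setdefault(rec[key], []).append(rec)
        return out

    drugs_by_case = grouped(quarter.drug_rows)
    reacs_by_case = grouped(quarter.reac_rows)
    outc_by_case = grouped(quarter.outc_rows)
    ther_by_case = grouped(quarter.ther_rows)
    indi_by_case = grouped(quarter.indi_rows)

    reports: list[SafetyReport] = []
    for row in demo.to_dict("records"):
        case_id = row["caseid"]
        pid = row.get("primaryid", case_id)

        def rows_for(table: dict[str, list[dict]]) -> list[dict]:
            return table.get(pid) or table.get(case_id) or []

        version = _int_or_zero(row.get("caseversion"))
        fda_dt = _int_or_zero(row.get("fda_dt"))

        sex_raw = str(row.get("sex", "")).strip().upper()
        sex = {"F": "female", "M": "male"}.get(sex_raw)

        age = convert_age(_safe_float(row.get("age")), row.get("age_cod") or "YR")
        weight = convert_weight(_safe_float(row.get("wt")), row.get("wt_cod") or "KG")

        country = str(row.get("reporter_country", "")).strip() or None
        reporter = str(row.get("occp_cod", "")).strip().upper() or None
        if reporter is not None and reporter not in REPORTER_CODES:
            reporter = None

        outcomes = frozenset(
            c for rec in rows_for(outc_by_case)
            if (c := str(rec.get("outc_cod", "")).strip().upper()) in OUTCOME_CODES
        )

        # therapy start dates keyed by drug sequence number
        starts_by_seq: dict[int, date] = {}
        for rec in rows_for(ther_by_case):
            seq = _int_or_zero(rec.get("dsg_drug_seq") or rec.get("drug_seq"))
            d = parse_faers_date(rec.get("start_dt"), day_precision_only=True)
            if d is not None and (seq not in starts_by_seq or d < starts_by_seq[seq]):
                starts_by_seq[seq] = d

        drugs = []
        for rec in rows_for(drugs_by_case):
            role = str(rec.get("role_cod", "")).strip().upper()
            if role not in ROLE_CODES:
                continue
            raw = str(rec.get("drugname", "")).strip()
            seq = _int_or_zero(rec.get("drug_seq"))
            drugs.append(DrugEntry(
                name_raw=raw,
                name_std=normalize_drug_name(raw),
                role=role,
                start_date=starts_by_seq.get(seq),
            ))

        reactions = []
        seen_pts = set()
        for rec in rows_for(reacs_by_case):
            pt = str(rec.get("pt", "")).strip()
            if not pt or pt in seen_pts:
                continue
            seen_pts.add(pt)
            reactions.append(ReactionEntry(pt=pt, soc=soc_map.get(pt, "unmapped")))

        if not drugs or not reactions:
            logger.debug("case %s version %s lacks drugs or reactions; skipped", case_id, version)
            continue

        suspect_starts = [d.start_date for d in drugs
                          if d.role in ("PS", "SS") and d.start_date is not None]
        indi_pts = [str(rec.get("indi_pt", "")).strip()
                    for rec in rows_for(indi_by_case) if str(rec.get("indi_pt", "")).strip()]

        reports.append(SafetyReport(
            case_id=case_id,
            version_key=(version, fda_dt, file_order),
            sex=sex,
            age_years=age,
            weight_kg=weight,
            country=country,
            reporter=reporter,
            outcome_codes=outcomes,
            event_date=parse_faers_date(row.get("event_dt"), day_precision_only=True),
            therapy_start_date=min(suspect_starts) if suspect_starts else None,
            drugs=tuple(drugs),
            reactions=tuple(reactions),
            indication_class=_classify_indication(indi_pts),
        ))
    return reports


def deduplicate(quarters: Iterable[RawQuarter],
                soc_map: Mapping[str, str] | None = None) -> list[SafetyReport]:
    """Collapse all case versions across quarters to one report per case.

    The retained row is the one with the greatest (case version, receipt
    date, file order) key — latest case version, ties broken by latest
    receipt date, then last file order. Deterministic for any input order.
    """
    candidates: list[SafetyReport] = []
    for i, q in enumerate(quarters):
        candidates.extend(_assemble_versions(q, file_order=i, soc_map=soc_map))
    best: dict[str, SafetyReport] = {}
    for rep in sorted(candidates, key=lambda r: (r.case_id, r.version_key)):
        best[rep.case_id] = rep
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# Normalized table output (round-trippable)

def write_reports(reports: Sequence[SafetyReport], outdir: str | Path) -> dict[str, Path]:
    """Write reports to normalized CSVs: one row per report plus nested
    drug and reaction tables keyed by case_id."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def fmt_date(d: date | None) -> str:
        return d.isoformat() if d is not None else ""

    rep_rows, drug_rows, reac_rows = [], [], []
    for r in reports:
        rep_rows.append({
            "case_id": r.case_id,
            "caseversion": r.version_key[0],
            "fda_dt": r.version_key[1],
            "file_order": r.version_key[2],
            "sex": r.sex or "",
            "age_years": "" if r.age_years is None else repr(r.age_years),
            "weight_kg": "" if r.weight_kg is None else repr(r.weight_kg),
            "country": r.country or "",
            "reporter": r.reporter or "",
            "outcome_codes": ";".join(sorted(r.outcome_codes)),
            "event_date": fmt_date(r.event_date),
            "therapy_start_date": fmt_date(r.therapy_start_date),
            "indication_class": r.indication_class or "",
        })
        for d in r.drugs:
            drug_rows.append({
                "case_id": r.case_id, "name_raw": d.name_raw, "name_std": d.name_std,
                "role": d.role, "start_date": fmt_date(d.start_date),
            })
        for rx in r.reactions:
            reac_rows.append({"case_id": r.case_id, "pt": rx.pt, "soc": rx.soc})

    paths = {}
    for name, rows, cols in (
        ("reports", rep_rows, list(rep_rows[0].keys()) if rep_rows else ["case_id"]),
        ("drugs", drug_rows, ["case_id", "name_raw", "name_std", "role", "start_date"]),
        ("reactions", reac_rows, ["case_id", "pt", "soc"]),
    ):
        p = outdir / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(p, index=False)
        paths[name] = p
    return paths


def read_reports(indir: str | Path) -> list[SafetyReport]:
    """Read back the normalized tables written by :func:`write_reports`."""
    indir = Path(indir)
    reps = pd.read_csv(indir / "reports.csv", dtype=str, keep_default_na=False)
    drugs = pd.read_csv(indir / "drugs.csv", dtype=str, keep_default_na=False)
    reacs = pd.read_csv(indir / "reactions.csv", dtype=str, keep_default_na=False)

    def parse_iso(s: str) -> date | None:
        return date.fromisoformat(s) if s else None

    drugs_by_case: dict[str, list[DrugEntry]] = {}
    for rec in drugs.to_dict("records"):
        drugs_by_case.setdefault(rec["case_id"], []).append(DrugEntry(
            name_raw=rec["name_raw"], name_std=rec["name_std"], role=rec["role"],
            start_date=parse_iso(rec["start_date"]),
        ))
    reacs_by_case: dict[str, list[ReactionEntry]] = {}
    for rec in reacs.to_dict("records"):
        reacs_by_case.setdefault(rec["case_id"], []).append(
            ReactionEntry(pt=rec["pt"], soc=rec["soc"]))

    out = []
    for rec in reps.to_dict("records"):
        cid = rec["case_id"]
        out.append(SafetyReport(
            case_id=cid,
            version_key=(int(rec["caseversion"]), int(rec["fda_dt"]), int(rec["file_order"])),
            sex=rec["sex"] or None,
            age_years=float(rec["age_years"]) if rec["age_years"] else None,
            weight_kg=float(rec["weight_kg"]) if rec["weight_kg"] else None,
            country=rec["country"] or None,
            reporter=rec["reporter"] or None,
            outcome_codes=frozenset(c for c in rec["outcome_codes"].split(";") if c),
            event_date=parse_iso(rec["event_date"]),
            therapy_start_date=parse_iso(rec["therapy_start_date"]),
            drugs=tuple(drugs_by_case.get(cid, ())),
            reactions=tuple(reacs_by_case.get(cid, ())),
            indication_class=rec["indication_class"] or None,
        ))
    return out
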