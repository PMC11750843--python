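"""Cohort assignment and tumor-term restriction.

Each deduplicated report is assigned to exactly one of four mutually
exclusive groups based on FAERS drug role codes:

* ``A_only``   — drug A is a primary suspect and drug B appears in no role;
* ``B_only``   — symmetric;
* ``A_plus_B`` — one of the two is primary suspect and the other appears in
  any role (PS, SS, C or I);
* ``excluded`` — everything else (neither target drug is a primary suspect).

Reaction terms are restricted to a tumor lexicon: a flat PT -> SOC table
shipped as a package fixture (the full MedDRA dictionary is licensed and is
not redistributed here) or supplied by the user as a CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from faersig.faers_io import SafetyReport, normalize_drug_name

GROUPS = ("A_only", "B_only", "A_plus_B", "excluded")
ANALYSIS_GROUPS = ("A_only", "B_only", "A_plus_B")

AGE_BAND_EDGES = (18.0, 45.0, 60.0, 75.0)
AGE_BANDS = ("<18", "18-45", "45-60", "60-75", ">75")
WEIGHT_BANDS = ("<50 kg", "50-100 kg", ">100 kg")


@dataclass(frozen=True)
class CohortAssignment:
    case_id: str
    group: str
    matched_tumor_pts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class TumorLexicon:
    """Flat preferred-term -> system-organ-class lookup for tumor AEs."""

    entries: dict[str, str] = field(default_factory=dict)
    provenance_note: str = ""

    def __post_init__(self) -> None:
        if any(not soc for soc in self.entries.values()):
            raise ValueError("every lexicon PT needs a SOC")

    def __contains__(self, pt: str) -> bool:
        return pt in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pts(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def soc(self, pt: str) -> str:
        return self.entries.get(pt, "unmapped")


def load_lexicon(path: str | Path | None = None) -> TumorLexicon:
    """Load a tumor lexicon CSV (columns ``pt``, ``soc``); default is the
    bundled synthetic fixture of ~80 neoplasm preferred terms."""
    if path is None:
        with resources.files("faersig.data").joinpath("tumor_lexicon.csv").open() as fh:
            df = pd.read_csv(fh)
        note = "bundled synthetic neoplasm-PT fixture (not the licensed MedDRA dictionary)"
    else:
        df = pd.read_csv(path)
        note = f"user lexicon from {path}"
    if df["pt"].duplicated().any():
        raise ValueError("lexicon PTs must be unique")
    return TumorLexicon(entries=dict(zip(df["pt"], df["soc"])), provenance_note=note)


def load_synonyms(path: str | Path | None = None) -> dict[str, set[str]]:
    """Load the ingredient -> synonym table (columns ``ingredient``,
    ``synonym``) and return normalized synonym sets per ingredient."""
    if path is None:
        with resources.files("faersig.data").joinpath("drug_synonyms.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    out: dict[str, set[str]] = {}
    for ing, syn in zip(df["ingredient"], df["synonym"]):
        out.setdefault(str(ing).strip().lower(), set()).add(normalize_drug_name(syn))
    return out


def _mentions(report: SafetyReport, names: Iterable[str]) -> tuple[bool, bool]:
    """(has any entry as PS, has any entry in any role) for a synonym set."""
    names = set(names)
    as_ps = any_role = False
    for d in report.drugs:
        if d.name_std in names:
            any_role = True
            if d.role == "PS":
                as_ps = True
    return as_ps, any_role


def assign_group(report: SafetyReport, names_a: set[str], names_b: set[str]) -> CohortAssignment:
    """Assign one report to A_only / B_only / A_plus_B / excluded."""
    if not names_a or not names_b:
        raise ValueError("synonym sets must be non-empty")
    a_ps, a_any = _mentions(report, names_a)
    b_ps, b_any = _mentions(report, names_b)
    if (a_ps and b_any) or (b_ps and a_any):
        group = "A_plus_B"
    elif a_ps and not b_any:
        group = "A_only"
    elif b_ps and not a_any:
        group = "B_only"
    else:
        group = "excluded"
    return CohortAssignment(case_id=report.case_id, group=group)


def assign_groups(reports: Sequence[SafetyReport], names_a: set[str],
                  names_b: set[str]) -> dict[str, CohortAssignment]:
    """Vector form of :func:`assign_group`, keyed by case_id."""
    return {r.case_id: assign_group(r, names_a, names_b) for r in reports}


def filter_tumor_reports(
    reports: Sequence[SafetyReport], lexicon: TumorLexicon
) -> list[tuple[SafetyReport, tuple[str, ...]]]:
    """Keep reports with at least one reaction PT in the lexicon.

    Returns (report, matched PTs) pairs; reports are unchanged and their
    non-tumor reactions are retained (the match list is the flag).
    """
    if len(lexicon) == 0:
        raise ValueError("tumor lexicon is empty")
    kept = []
    for r in reports:
        matched = tuple(rx.pt for rx in r.reactions if rx.pt in lexicon)
        if matched:
            kept.append((r, matched))
    return kept


def age_band(age: float | None) -> str:
    """Band an age in years; edges are lower-closed / upper-open so 18, 45,
    60 and 75 each land in exactly one band."""
    if age is None:
        return "Missing"
    for edge, label in zip(AGE_BAND_EDGES, AGE_BANDS):
        if age < edge:
            return label
    return AGE_BANDS[-1]


def weight_band(weight: float | None) -> str:
    """Band a weight in kg: <50, [50, 100], >100."""
    if weight is None:
        return "Missing"
    if weight < 50:
        return WEIGHT_BANDS[0]
    if weight <= 100:
        return WEIGHT_BANDS[1]
    return WEIGHT_BANDS[2]


_CHARACTERISTICS = ("sex", "weight", "age", "indication", "reporter", "outcome")


def tabulate_clinical_characteristics(
    reports: Sequence[SafetyReport],
    assignments: Mapping[str, CohortAssignment],
    groups: Sequence[str] = ANALYSIS_GROUPS,
) -> pd.DataFrame:
    """Per-group frequency table of sex / weight band / age band / indication /
    reporter / outcome, with counts and within-group percentages.

    Outcome rows count reports (a report with several outcome codes counts
    once per code); percentages for outcomes are of the group size.
    """
    rows = []
    by_group: dict[str, list[SafetyReport]] = {g: [] for g in groups}
    for r in reports:
        a = assignments.get(r.case_id)
        if a is not None and a.group in by_group:
            by_group[a.group].append(r)

    def tally(characteristic: str, level: str, counts: dict[str, int]) -> None:
        for g in groups:
            n = len(by_group[g])
            c = counts.get(g, 0)
            rows.append({
                "characteristic": characteristic, "level": level, "group": g,
                "count": c, "percent": 0.0 if n == 0 else round(100.0 * c / n, 2),
            })

    def count_by(characteristic: str, levels: Sequence[str], key) -> None:
        per_level: dict[str, dict[str, int]] = {lv: {} for lv in levels}
        for g in groups:
            for r in by_group[g]:
                lv = key(r)
                if lv in per_level:
                    per_level[lv][g] = per_level[lv].get(g, 0) + 1
        for lv in levels:
            tally(characteristic, lv, per_level[lv])

    count_by("sex", ("Female", "Male", "Missing"),
             lambda r: {"female": "Female", "male": "Male"}.get(r.sex, "Missing"))
    count_by("weight", (*WEIGHT_BANDS, "Missing"), lambda r: weight_band(r.weight_kg))
    count_by("age", (*AGE_BANDS, "Missing"), lambda r: age_band(r.age_years))
    count_by("indication", ("Gastrointestinal disorders", "Others", "Missing"),
             lambda r: {"gastrointestinal": "Gastrointestinal disorders",
                        "other": "Others"}.get(r.indication_class, "Missing"))
    count_by("reporter", ("MD", "CN", "OT", "PH", "LW", "Missing"),
             lambda r: r.reporter if r.reporter else "Missing")

    outc_levels = ("OT", "HO", "DE", "LT", "DS", "CA", "RI", "Missing")
    per_level = {lv: {} for lv in outc_levels}
    for g in groups:
        for r in by_group[g]:
            codes = sorted(r.outcome_codes) if r.outcome_codes else ["Missing"]
            for c in codes:
                per_level[c][g] = per_level[c].get(g, 0) + 1
    for lv in outc_levels:
        tally("outcome", lv, per_level[lv])

    return pd.DataFrame(rows, columns=["characteristic", "level", "group", "count", "percent"])
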