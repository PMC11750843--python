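"""End-to-end orchestration: ingest -> dedup -> cohort -> signals ->
regression -> onset, with a run manifest for provenance.

Every result table of the analysis has a machine-readable CSV analogue in
the output directory; the manifest records stage row counts, input file
hashes, the configuration snapshot and the software version, so a rerun on
the same inputs and seed is hash-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

import faersig
from faersig import cohort as cohort_mod
from faersig import faers_io, onset_time, risk_regression, signal_stats

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    quarters: Sequence[Mapping[str, str | Path]] = ()
    quarter_labels: Sequence[str] = ()
    outdir: str | Path = "faersig_out"
    drug_a: str = "infliximab"
    drug_b: str = "azathioprine"
    lexicon_path: str | Path | None = None
    synonyms_path: str | Path | None = None
    criteria: signal_stats.SignalCriteria = field(default_factory=signal_stats.SignalCriteria)
    min_onset_n: int = 10
    seed: int = 0


@dataclass
class RunManifest:
    config: dict
    input_hashes: dict[str, str]
    stage_counts: dict[str, int]
    version: str
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config,
            "input_hashes": self.input_hashes,
            "stage_counts": self.stage_counts,
            "version": self.version,
            "seed": self.seed,
        }, indent=1, sort_keys=True))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def discover_quarter(indir: str | Path) -> dict[str, Path]:
    """Map table names to files in a directory of DEMO*/DRUG*/... tables."""
    indir = Path(indir)
    paths: dict[str, Path] = {}
    for name in faers_io.TABLE_NAMES:
        hits = sorted(indir.glob(f"{name.upper()}*"))
        if hits:
            paths[name] = hits[0]
    return paths


def run_all(config: PipelineConfig) -> RunManifest:
    """Run the full analysis; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lexicon = cohort_mod.load_lexicon(config.lexicon_path)
    if len(lexicon) == 0:
        raise RuntimeError("cohort stage: tumor lexicon is empty")
    synonyms = cohort_mod.load_synonyms(config.synonyms_path)
    names_a = synonyms[config.drug_a]
    names_b = synonyms[config.drug_b]

    counts: dict[str, int] = {}
    input_hashes: dict[str, str] = {}

    # --- ingest ---------------------------------------------------------
    quarters = []
    labels = list(config.quarter_labels) or ["2024Q2"] * len(config.quarters)
    for paths, label in zip(config.quarters, labels):
        q = faers_io.read_quarter(paths, quarter_label=label)
        quarters.append(q)
        for name, p in paths.items():
            input_hashes[f"{label}/{name}"] = _sha256(p)
    if not quarters:
        raise RuntimeError("ingest stage: no input quarters")
    counts["loaded_demo_rows"] = sum(len(q.demo_rows) for q in quarters)

    # --- dedup ----------------------------------------------------------
    reports = faers_io.deduplicate(quarters, soc_map=lexicon.entries)
    counts["deduplicated_reports"] = len(reports)
    faers_io.write_reports(reports, outdir / "normalized")

    # --- cohort ---------------------------------------------------------
    assignments = cohort_mod.assign_groups(reports, names_a, names_b)
    for g in cohort_mod.GROUPS:
        counts[f"group_{g}"] = sum(1 for a in assignments.values() if a.group == g)
    pd.DataFrame(
        [{"case_id": a.case_id, "group": a.group} for a in assignments.values()]
    ).to_csv(outdir / "assignments.csv", index=False)

    chars = cohort_mod.tabulate_clinical_characteristics(reports, assignments)
    chars.to_csv(outdir / "clinical_characteristics.csv", index=False)

    tumor_pairs = cohort_mod.filter_tumor_reports(reports, lexicon)
    counts["tumor_reports"] = len(tumor_pairs)

    # --- signals --------------------------------------------------------
    tables_by_group: dict[str, list] = {}
    all_tables = []
    for g in cohort_mod.ANALYSIS_GROUPS:
        tabs = signal_stats.build_tables(reports, assignments, lexicon, g)
        tables_by_group[g] = tabs
        all_tables.extend(tabs)
    if not all_tables:
        raise RuntimeError("signal stage: no (group, PT) pairs to test")
    prior = signal_stats.fit_gps_prior(all_tables)

    significant_pts: dict[str, set[str]] = {}
    for g in cohort_mod.ANALYSIS_GROUPS:
        df = signal_stats.evaluate_signals(tables_by_group[g], prior, lexicon,
                                           config.criteria)
        df.to_csv(outdir / f"signals_{g}.csv", index=False)
        significant_pts[g] = set(df.loc[df["significant"], "pt"])
        counts[f"signals_{g}"] = int(df["significant"].sum())
        counts[f"tested_pts_{g}"] = len(df)

    # --- regression -----------------------------------------------------
    def outcome_flags(groups: Sequence[str]) -> dict[str, bool]:
        flags = {}
        for r in reports:
            a = assignments[r.case_id]
            if a.group in groups:
                sig = significant_pts.get(a.group, set())
                flags[r.case_id] = any(rx.pt in sig for rx in r.reactions)
        return flags

    comparisons = (
        ("within_A_only", ("A_only",), ("sex", "age_band", "weight_band")),
        ("within_B_only", ("B_only",), ("sex", "age_band", "weight_band")),
        ("within_A_plus_B", ("A_plus_B",), ("sex", "age_band", "weight_band")),
        ("A_only_vs_combo", ("A_only", "A_plus_B"), ("sex", "age_band", "weight_band", "group")),
        ("B_only_vs_combo", ("B_only", "A_plus_B"), ("sex", "age_band", "weight_band", "group")),
    )
    for name, groups, terms in comparisons:
        try:
            design = risk_regression.build_design(
                reports, assignments, outcome_flags(groups), groups=groups, terms=terms)
            uni = []
            for t in design.terms:
                uni.extend(risk_regression.fit_univariate(design, t))
            risk_regression.estimates_frame(uni).to_csv(
                outdir / f"regression_{name}_univariate.csv", index=False)
            multi = risk_regression.fit_multivariate(design)
            risk_regression.estimates_frame(multi).to_csv(
                outdir / f"regression_{name}_multivariate.csv", index=False)
        except ValueError as exc:
            logger.warning("regression stage (%s) skipped: %s", name, exc)

    # --- onset ----------------------------------------------------------
    sig_cases = {r.case_id for r in reports
                 if any(rx.pt in significant_pts.get(assignments[r.case_id].group, set())
                        for rx in r.reactions)}
    sig_reports = [r for r in reports if r.case_id in sig_cases]
    records, excl = onset_time.compute_onsets(sig_reports, assignments, names_a, names_b)
    counts["onset_records"] = len(records)
    counts["onset_excluded_missing"] = excl["missing_dates"]
    counts["onset_excluded_negative"] = excl["negative"]
    pd.DataFrame([{"case_id": r.case_id, "group": r.group, "onset_days": r.onset_days}
                  for r in records]).to_csv(outdir / "onsets.csv", index=False)

    by_group = {g: [r.onset_days for r in records if r.group == g and r.onset_days > 0]
                for g in cohort_mod.ANALYSIS_GROUPS}
    weib_rows = []
    for g, vals in by_group.items():
        if len(vals) < config.min_onset_n:
            continue
        try:
            fit = onset_time.weibull_fit(vals, min_n=config.min_onset_n)
        except ValueError as exc:
            logger.warning("onset stage: Weibull fit skipped for %s: %s", g, exc)
            continue
        summ = onset_time.onset_summary(vals)
        weib_rows.append({
            "group": g, "n": fit.n, "median_days": summ["median"],
            "q25": summ["q25"], "q75": summ["q75"],
            "shape": fit.shape, "shape_lo95": fit.shape_lo95,
            "shape_hi95": fit.shape_hi95, "scale": fit.scale,
            "scale_lo95": fit.scale_lo95, "scale_hi95": fit.scale_hi95,
            "failure_type": fit.failure_type,
        })
    pd.DataFrame(weib_rows, columns=[
        "group", "n", "median_days", "q25", "q75", "shape", "shape_lo95",
        "shape_hi95", "scale", "scale_lo95", "scale_hi95", "failure_type",
    ]).to_csv(outdir / "weibull_summary.csv", index=False)

    cmp_rows = []
    for g in ("A_only", "B_only"):
        a_vals, b_vals = by_group.get(g, []), by_group.get("A_plus_B", [])
        if not a_vals or not b_vals:
            continue
        z, p = onset_time.rank_sum_compare(a_vals, b_vals)
        steps, lr_chi2, lr_p = onset_time.cumulative_incidence(
            {g: a_vals, "A_plus_B": b_vals})
        for grp, df in steps.items():
            df.assign(group=grp).to_csv(
                outdir / f"cuminc_{g}_vs_combo_{grp}.csv", index=False)
        cmp_rows.append({"comparison": f"{g}_vs_A_plus_B", "z": z, "p": p,
                         "logrank_chi2": lr_chi2, "logrank_p": lr_p})
    pd.DataFrame(cmp_rows, columns=["comparison", "z", "p", "logrank_chi2",
                                    "logrank_p"]).to_csv(
        outdir / "onset_comparisons.csv", index=False)

    # --- manifest -------------------------------------------------------
    manifest = RunManifest(
        config={
            "drug_a": config.drug_a, "drug_b": config.drug_b,
            "criteria": asdict(config.criteria),
            "min_onset_n": config.min_onset_n,
            "quarter_labels": list(labels),
        },
        input_hashes=input_hashes,
        stage_counts=counts,
        version=faersig.__version__,
        seed=config.seed,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
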