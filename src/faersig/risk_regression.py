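"""Univariate and multivariate logistic comparison of tumor-signal risk.

The outcome per report is whether it carries at least one significant tumor
preferred term; covariates are sex, age band, weight band and treatment
group as categorical factors. Reference levels: female, age <18, weight
<50 kg, combination group. Model fitting is delegated to statsmodels; the
bespoke content here is design construction, the univariate p<0.05 gate for
multivariate inclusion, and forest-plot-ready reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from faersig.cohort import CohortAssignment, age_band, weight_band
from faersig.faers_io import SafetyReport

logger = logging.getLogger(__name__)

REFERENCE_LEVELS = {
    "sex": "Female",
    "age_band": "<18",
    "weight_band": "<50 kg",
    "group": "A_plus_B",
}

_SE_UNBOUNDED = 50.0  # |log-OR| standard error above this flags separation


@dataclass(frozen=True)
class OrEstimate:
    term: str
    level: str
    or_point: float
    lo95: float
    hi95: float
    p: float
    separation: bool = False


@dataclass
class RegressionDesign:
    """Complete-case (or missing-as-level) design matrix source."""

    data: pd.DataFrame  # columns: outcome (bool) + categorical factors
    terms: tuple[str, ...]
    references: dict[str, str] = field(default_factory=lambda: dict(REFERENCE_LEVELS))

    def __post_init__(self) -> None:
        if "outcome" not in self.data.columns:
            raise ValueError("design needs an 'outcome' column")


def build_design(
    reports: Sequence[SafetyReport],
    assignments: Mapping[str, CohortAssignment],
    outcome_by_case: Mapping[str, bool],
    groups: Sequence[str] = ("A_only", "B_only", "A_plus_B"),
    terms: Sequence[str] = ("sex", "age_band", "weight_band", "group"),
    missing_as_level: bool = False,
) -> RegressionDesign:
    """Assemble the regression frame from reports + cohort assignments.

    ``outcome_by_case`` flags reports with >=1 significant tumor PT.
    Complete-case by default; with ``missing_as_level`` a "Missing" level is
    retained instead of dropping rows.
    """
    rows = []
    for r in reports:
        a = assignments.get(r.case_id)
        if a is None or a.group not in groups:
            continue
        rows.append({
            "case_id": r.case_id,
            "outcome": bool(outcome_by_case.get(r.case_id, False)),
            "sex": {"female": "Female", "male": "Male"}.get(r.sex, "Missing"),
            "age_band": age_band(r.age_years),
            "weight_band": weight_band(r.weight_kg),
            "group": a.group,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no reports in the requested groups")
    terms = tuple(t for t in terms if t in df.columns)
    if not missing_as_level:
        mask = np.ones(len(df), dtype=bool)
        for t in terms:
            mask &= df[t].to_numpy() != "Missing"
        df = df[mask].reset_index(drop=True)
    return RegressionDesign(data=df, terms=terms)


def _dummies(design: RegressionDesign, terms: Sequence[str]) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Reference-coded dummy matrix with an intercept; returns the matrix and
    the (term, level) pair behind each dummy column."""
    cols = {}
    labels: list[tuple[str, str]] = []
    for t in terms:
        ref = design.references.get(t)
        levels = [lv for lv in pd.unique(design.data[t]) if lv != ref]
        levels.sort()
        for lv in levels:
            cols[f"{t}[{lv}]"] = (design.data[t] == lv).astype(float)
            labels.append((t, lv))
    x = pd.DataFrame(cols, index=design.data.index)
    x.insert(0, "Intercept", 1.0)
    return x, labels


def _fit(design: RegressionDesign, terms: Sequence[str]) -> list[OrEstimate]:
    y = design.data["outcome"].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome must have both classes present")
    x, labels = _dummies(design, terms)
    if len(labels) == 0:
        raise ValueError(f"no non-reference levels for terms {terms}")
    model = sm.GLM(y, x, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    out = []
    for (term, level), name in zip(labels, x.columns[1:]):
        beta = float(res.params[name])
        se = float(res.bse[name])
        sep = not np.isfinite(se) or se > _SE_UNBOUNDED
        if sep:
            logger.warning("possible complete separation for %s=%s", term, level)
            out.append(OrEstimate(term=term, level=level, or_point=float(np.exp(beta)),
                                  lo95=0.0, hi95=float("inf"), p=float("nan"),
                                  separation=True))
        else:
            z = 1.959963984540054
            out.append(OrEstimate(
                term=term, level=level, or_point=float(np.exp(beta)),
                lo95=float(np.exp(beta - z * se)), hi95=float(np.exp(beta + z * se)),
                p=float(res.pvalues[name]),
            ))
    return out


def fit_univariate(design: RegressionDesign, term: str) -> list[OrEstimate]:
    """Single-factor logistic fit; Wald CI and p per non-reference level."""
    return _fit(design, [term])


def select_terms(design: RegressionDesign, alpha: float = 0.05) -> list[str]:
    """Univariate gate: terms with any level significant at ``alpha``."""
    selected = []
    for t in design.terms:
        try:
            ests = fit_univariate(design, t)
        except ValueError:
            continue
        if any(not e.separation and e.p < alpha for e in ests):
            selected.append(t)
    logger.info("univariate gate (p<%g) selected terms: %s", alpha, selected)
    return selected


def fit_multivariate(design: RegressionDesign, terms: Sequence[str] | None = None,
                     alpha: float = 0.05) -> list[OrEstimate]:
    """Joint logistic fit over the gated terms (default: univariate p<alpha)."""
    if terms is None:
        terms = select_terms(design, alpha=alpha)
    if not terms:
        raise ValueError("no terms passed the univariate gate")
    return _fit(design, terms)


def estimates_frame(estimates: Sequence[OrEstimate]) -> pd.DataFrame:
    """Forest-plot-ready table (term, level, OR, lo95, hi95, p)."""
    return pd.DataFrame(
        [{"term": e.term, "level": e.level, "or": e.or_point,
          "lo95": e.lo95, "hi95": e.hi95, "p": e.p, "separation": e.separation}
         for e in estimates],
        columns=["term", "level", "or", "lo95", "hi95", "p", "separation"],
    )
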