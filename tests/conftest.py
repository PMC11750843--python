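"""Shared fixtures: a tiny hand-written quarter and default lexicon/synonyms."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from faersig import cohort


FIXTURE_TABLES = {
    # 3 cases: 101 (infliximab PS, tumor PT, full dates), 102 (azathioprine PS +
    # infliximab C -> combination, empty sex), 103 (other drug PS -> excluded,
    # age reported in months)
    "demo": """\
        primaryid$caseid$caseversion$fda_dt$event_dt$age$age_cod$sex$wt$wt_cod$reporter_country$occp_cod
        1011$101$1$20240110$20200131$45$YR$F$70$KG$US$MD
        1021$102$1$20240215$$61$YR$$154$LBS$CA$PH
        1031$103$1$20240320$20230601$780$MON$M$$KG$GB$CN
        """,
    "drug": """\
        primaryid$caseid$drug_seq$role_cod$drugname
        1011$101$1$PS$REMICADE
        1011$101$2$C$ASPIRIN
        1021$102$1$PS$IMURAN
        1021$102$2$C$INFLIXIMAB
        1031$103$1$PS$METFORMIN
        """,
    "reac": """\
        primaryid$caseid$pt
        1011$101$Basal cell carcinoma
        1011$101$Headache
        1021$102$Lymphoma
        1031$103$Headache
        """,
    "outc": """\
        primaryid$caseid$outc_cod
        1011$101$HO
        1021$102$OT
        """,
    "ther": """\
        primaryid$caseid$dsg_drug_seq$start_dt$end_dt
        1011$101$1$20200101$
        1021$102$1$20230501$
        """,
    "indi": """\
        primaryid$caseid$indi_drug_seq$indi_pt
        1011$101$1$Crohn's disease
        1021$102$1$Colitis ulcerative
        1031$103$1$Rheumatoid arthritis
        """,
    "rpsr": """\
        primaryid$caseid$rpsr_cod
        1011$101$FGN
        """,
}


@pytest.fixture
def fixture_quarter_dir(tmp_path: Path) -> Path:
    d = tmp_path / "fixture_quarter"
    d.mkdir()
    for name, body in FIXTURE_TABLES.items():
        (d / f"{name.upper()}2024Q2.txt").write_text(textwrap.dedent(body))
    return d


@pytest.fixture
def fixture_paths(fixture_quarter_dir: Path) -> dict[str, Path]:
    return {name: fixture_quarter_dir / f"{name.upper()}2024Q2.txt"
            for name in FIXTURE_TABLES}


@pytest.fixture(scope="session")
def lexicon() -> cohort.TumorLexicon:
    return cohort.load_lexicon()


@pytest.fixture(scope="session")
def synonyms() -> dict[str, set[str]]:
    return cohort.load_synonyms()
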