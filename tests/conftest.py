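"""Shared fixtures: tiny hand-built quarter files and report factories."""

from __future__ import annotations

import numpy as np
import pytest

from pvsignal.faers_io import CleanReport, DrugEntry, RawCase


def make_clean_report(
    primaryid: int,
    reactions,
    ps_drug: str = "DRUG_A",
    year: int = 2015,
    indications=(),
    age: float | None = 60.0,
    sex: str | None = "F",
    **kwargs,
) -> CleanReport:
    defaults = dict(
        reporter="consumer",
        country="US",
        serious=True,
        outcomes=frozenset({"hospitalization"}),
        route="oral",
    )
    defaults.update(kwargs)
    return CleanReport(
        primaryid=primaryid,
        receipt_year=year,
        age_years=age,
        sex=sex,
        ps_drug=ps_drug,
        indications=frozenset(indications),
        reactions=frozenset(reactions),
        drugs=(DrugEntry(seq=1, name=ps_drug, prod_ai=ps_drug, role="PS", route="ORAL",
                         indications=tuple(indications)),),
        **defaults,
    )


def make_raw_case(
    primaryid: int,
    caseid: int | None = None,
    fda_dt: int = 20150601,
    reactions=("EVENT_A",),
    drugname: str = "DRUG_A",
    role: str = "PS",
    **kwargs,
) -> RawCase:
    defaults = dict(
        age=60.0, age_cod="YR", sex="F", occp_cod="CN", country="US",
        outcome_codes=("HO",),
    )
    defaults.update(kwargs)
    return RawCase(
        primaryid=primaryid,
        caseid=caseid if caseid is not None else primaryid // 10,
        fda_dt=fda_dt,
        drugs=(DrugEntry(seq=1, name=drugname, prod_ai=drugname, role=role, route="ORAL"),),
        reactions=tuple(reactions),
        **defaults,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


QUARTER_DEMO = """\
primaryid$caseid$fda_dt$age$age_cod$sex$occp_cod$reporter_country
100101$10010$20150312$72$YR$F$MD$US
100201$10020$20160704$18$MON$M$CN$DE
100301$10030$20170101$$YR$$PH$JP
"""

QUARTER_DRUG = """\
primaryid$drug_seq$role_cod$drugname$prod_ai$route
100101$1$PS$XARELTO$RIVAROXABAN$ORAL
100101$2$C$ASPIRIN$ASPIRIN$ORAL
100201$1$PS$WARFARIN$WARFARIN$ORAL
100201$2$SS$rivaroxaban$RIVAROXABAN$ORAL
100301$1$PS$RIVAROXABAN.$RIVAROXABAN$ORAL
"""

QUARTER_REAC = """\
primaryid$pt
100101$Gastrointestinal haemorrhage
100101$Epistaxis
100101$Anaemia
100201$Fall
100201$Dizziness
100301$Epistaxis
100301$Haematuria
"""

QUARTER_INDI = """\
primaryid$indi_drug_seq$indi_pt
100101$1$Atrial fibrillation
100101$1$Thrombosis
100301$1$Deep vein thrombosis
"""

QUARTER_OUTC = """\
primaryid$outc_cod
100101$HO
100101$DE
100201$OT
100301$LT
"""


@pytest.fixture
def quarter_dir(tmp_path):
    """A 3-report quarter with 5 DRUG rows, 7 REAC rows, joined indications."""
    files = {
        "demo": QUARTER_DEMO,
        "drug": QUARTER_DRUG,
        "reac": QUARTER_REAC,
        "indi": QUARTER_INDI,
        "outc": QUARTER_OUTC,
    }
    paths = {}
    for name, text in files.items():
        p = tmp_path / f"{name.upper()}.txt"
        p.write_text(text)
        paths[name] = p
    return paths
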