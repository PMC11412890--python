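"""Reading and cleaning of FAERS-style quarterly ASCII extracts.

FAERS ships each quarter as five "$"-delimited tables (DEMO, DRUG, REAC,
INDI, OUTC) keyed by a report-version identifier.  A *case* may appear as
several report versions across quarters; signal detection must see each
case once, so ingestion joins the tables into per-report records,
deduplicates by case, normalises demographic fields, and finally selects
the reports in which the drug under study is the primary suspect (PS).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DrugEntry",
    "RawCase",
    "CleanReport",
    "DedupAudit",
    "FaersFormatError",
    "read_quarter",
    "read_table",
    "deduplicate_cases",
    "normalize_age",
    "clean_cases",
    "filter_primary_suspect",
    "load_pt_soc_map",
    "load_ime_list",
    "load_deleted_caseids",
]


class FaersFormatError(ValueError):
    """A table header is missing a mandatory column."""


# Current-dialect names first; legacy (pre-2012 "ISR") names accepted as
# aliases so the same reader covers both packet generations.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "primaryid": ("primaryid", "isr"),
    "caseid": ("caseid", "case"),
    "fda_dt": ("fda_dt",),
    "age": ("age",),
    "age_cod": ("age_cod",),
    "sex": ("sex", "gndr_cod"),
    "occp_cod": ("occp_cod",),
    "reporter_country": ("reporter_country", "occr_country"),
    "drug_seq": ("drug_seq", "dsg_drug_seq"),
    "role_cod": ("role_cod",),
    "drugname": ("drugname",),
    "prod_ai": ("prod_ai",),
    "route": ("route",),
    "pt": ("pt",),
    "indi_drug_seq": ("indi_drug_seq",),
    "indi_pt": ("indi_pt",),
    "outc_cod": ("outc_cod", "outc_code"),
}

MANDATORY = {
    "demo": ("primaryid", "caseid"),
    "drug": ("primaryid", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "indi": ("primaryid", "indi_pt"),
    "outc": ("primaryid", "outc_cod"),
}

#: AGE_COD unit → divisor converting the stated value into years.
_AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 0.1,  # value is in decades: multiply by 10
    "MON": 12.0,
    "WK": 52.1429,
    "DY": 365.25,
    "HR": 8766.0,
}

SERIOUS_OUTCOME_CODES = {"DE", "LT", "HO", "DS", "CA", "RI"}

OUTCOME_LABELS = {
    "HO": "hospitalization",
    "DE": "death",
    "LT": "life-threatening",
    "DS": "disability",
    "RI": "required-intervention",
    "CA": "congenital-anomaly",
    "OT": "other",
}

REPORTER_LABELS = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health-professional",
    "RN": "other health-professional",
    "HP": "other health-professional",
    "LW": "lawyer",
}


@dataclass(frozen=True)
class DrugEntry:
    """One DRUG-table row with its per-drug indications joined from INDI."""

    seq: int
    name: str
    prod_ai: str
    role: str | None  # PS / SS / C / I or None
    route: str | None
    indications: tuple[str, ...] = ()


@dataclass
class RawCase:
    """One report version: a DEMO row joined to its DRUG/REAC/INDI/OUTC rows."""

    primaryid: int
    caseid: int
    fda_dt: int | None
    age: float | None
    age_cod: str | None
    sex: str | None
    occp_cod: str | None
    country: str | None
    outcome_codes: tuple[str, ...] = ()
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[str, ...] = ()


@dataclass
class CleanReport:
    """One deduplicated, normalised case ready for counting.

    ``ps_drug`` is set once :func:`filter_primary_suspect` has matched a
    primary-suspect entry; until then it names the report's own PS drug
    (or ``None`` when the report has no PS entry).
    """

    primaryid: int
    receipt_year: int | None
    age_years: float | None
    sex: str | None  # "F" / "M" / None
    reporter: str | None
    country: str | None
    serious: bool
    outcomes: frozenset[str]
    route: str | None
    ps_drug: str | None
    indications: frozenset[str]
    reactions: frozenset[str]
    drugs: tuple[DrugEntry, ...] = ()  # retained for suspect matching


@dataclass(frozen=True)
class DedupAudit:
    n_input: int
    n_kept: int
    n_dropped_duplicate: int
    n_dropped_deleted: int

    def __post_init__(self) -> None:
        total = self.n_kept + self.n_dropped_duplicate + self.n_dropped_deleted
        if total != self.n_input:
            raise ValueError("dedup audit counts do not add up")


def _canonical_columns(df: pd.DataFrame, table: str, path: str | Path) -> pd.DataFrame:
    df = df.rename(columns=str.lower)
    rename: dict[str, str] = {}
    for canon, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in df.columns:
                rename[alias] = canon
                break
    df = df.rename(columns=rename)
    for col in MANDATORY[table]:
        if col not in df.columns:
            raise FaersFormatError(
                f"{table.upper()} table {path}: mandatory column {col!r} missing"
            )
    return df


def read_table(path: str | Path, table: str) -> pd.DataFrame:
    """Read one "$"-delimited FAERS table as strings with canonical columns."""
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{table.upper()} table {path} is empty")
        return pd.DataFrame(columns=MANDATORY[table])
    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        engine="python",
        quoting=csv.QUOTE_NONE,
        keep_default_na=False,
        on_bad_lines="warn",
    )
    df = _canonical_columns(df, table, path)
    if df.empty:
        warnings.warn(f"{table.upper()} table {path} has a header but no rows")
    return df


def _to_int(value: str | None) -> int | None:
    if value is None:
        return None
    value = value.strip()
    if not value:
        return None
    try:
        return int(float(value))
    except ValueError:
        return None


def _to_float(value: str | None) -> float | None:
    if value is None:
        return None
    value = str(value).strip()
    if not value:
        return None
    try:
        return float(value)
    except ValueError:
        return None


def _opt(value) -> str | None:
    if value is None:
        return None
    value = str(value).strip()
    return value or None


def read_quarter(paths: Mapping[str, str | Path]) -> list[RawCase]:
    """Join one quarter's DEMO/DRUG/REAC/INDI/OUTC tables into RawCase records.

    Parameters
    ----------
    paths
        Mapping with keys ``demo``, ``drug``, ``reac`` and optionally
        ``indi``, ``outc``, each naming a "$"-delimited file.

    One :class:`RawCase` is produced per parseable DEMO row; rows whose
    report identifier cannot be parsed are counted and logged, never fatal.
    """
    demo = read_table(paths["demo"], "demo")
    drug = read_table(paths["drug"], "drug")
    reac = read_table(paths["reac"], "reac")
    indi = read_table(paths["indi"], "indi") if "indi" in paths else pd.DataFrame(columns=MANDATORY["indi"])
    outc = read_table(paths["outc"], "outc") if "outc" in paths else pd.DataFrame(columns=MANDATORY["outc"])

    def by_pid(df: pd.DataFrame) -> dict[int, list[dict]]:
        out: dict[int, list[dict]] = {}
        for row in df.to_dict("records"):
            pid = _to_int(row.get("primaryid"))
            if pid is None:
                continue
            out.setdefault(pid, []).append(row)
        return out

    drug_rows = by_pid(drug)
    reac_rows = by_pid(reac)
    indi_rows = by_pid(indi)
    outc_rows = by_pid(outc)

    cases: list[RawCase] = []
    n_bad = 0
    for row in demo.to_dict("records"):
        pid = _to_int(row.get("primaryid"))
        caseid = _to_int(row.get("caseid"))
        if pid is None or caseid is None:
            n_bad += 1
            continue
        # indications attach to drug entries through indi_drug_seq
        indis_by_seq: dict[int, list[str]] = {}
        for irow in indi_rows.get(pid, []):
            seq = _to_int(irow.get("indi_drug_seq")) or 0
            pt = _opt(irow.get("indi_pt"))
            if pt:
                indis_by_seq.setdefault(seq, []).append(pt)
        drugs = []
        for i, drow in enumerate(drug_rows.get(pid, [])):
            seq = _to_int(drow.get("drug_seq"))
            seq = seq if seq is not None else i + 1
            role = _opt(drow.get("role_cod"))
            drugs.append(
                DrugEntry(
                    seq=seq,
                    name=_opt(drow.get("drugname")) or "",
                    prod_ai=_opt(drow.get("prod_ai")) or "",
                    role=role.upper() if role else None,
                    route=_opt(drow.get("route")),
                    indications=tuple(indis_by_seq.get(seq, ())),
                )
            )
        reactions = tuple(
            pt for rrow in reac_rows.get(pid, []) if (pt := _opt(rrow.get("pt")))
        )
        outcomes = tuple(
            oc.upper()
            for orow in outc_rows.get(pid, [])
            if (oc := _opt(orow.get("outc_cod")))
        )
        cases.append(
            RawCase(
                primaryid=pid,
                caseid=caseid,
                fda_dt=_to_int(row.get("fda_dt")),
                age=_to_float(row.get("age")),
                age_cod=_opt(row.get("age_cod")),
                sex=_opt(row.get("sex")),
                occp_cod=_opt(row.get("occp_cod")),
                country=_opt(row.get("reporter_country")),
                outcome_codes=outcomes,
                drugs=tuple(drugs),
                reactions=reactions,
            )
        )
    if n_bad:
        logger.warning("read_quarter: %d DEMO rows with unparseable identifiers skipped", n_bad)
    return cases


def deduplicate_cases(
    cases: Iterable[RawCase],
    deleted_caseids: set[int] | None = None,
) -> tuple[list[RawCase], DedupAudit]:
    """Keep one version per case: latest ``fda_dt``, ties broken by primaryid.

    Cases listed in ``deleted_caseids`` (FDA deleted-case files, shipped
    from 2019Q1 on) are removed entirely.  Returns the kept records plus an
    audit whose counts always sum back to the input size.
    """
    deleted_caseids = deleted_caseids or set()
    cases = list(cases)
    n_deleted = sum(1 for c in cases if c.caseid in deleted_caseids)
    survivors = [c for c in cases if c.caseid not in deleted_caseids]
    best: dict[int, RawCase] = {}
    for c in survivors:
        cur = best.get(c.caseid)
        if cur is None:
            best[c.caseid] = c
            continue
        key = (c.fda_dt or 0, c.primaryid)
        cur_key = (cur.fda_dt or 0, cur.primaryid)
        if key > cur_key:
            best[c.caseid] = c
    kept = sorted(best.values(), key=lambda c: c.primaryid)
    audit = DedupAudit(
        n_input=len(cases),
        n_kept=len(kept),
        n_dropped_duplicate=len(survivors) - len(kept),
        n_dropped_deleted=n_deleted,
    )
    return kept, audit


def normalize_age(value: float | None, unit_code: str | None) -> float | None:
    """Convert a FAERS AGE/AGE_COD pair into years.

    Unknown unit codes and out-of-range results (outside [0, 130] years)
    yield ``None`` with a warning — bad demographics never abort a run.
    """
    if value is None:
        return None
    unit = (unit_code or "YR").strip().upper()
    if unit not in _AGE_UNIT_TO_YEARS:
        warnings.warn(f"unknown age unit code {unit_code!r}; treating age as missing")
        return None
    years = value / _AGE_UNIT_TO_YEARS[unit]
    if not (0.0 <= years <= 130.0):
        warnings.warn(f"age {value} {unit} = {years:.1f} years out of range; treated as missing")
        return None
    return years


def _first_ps_entry(drugs: Sequence[DrugEntry]) -> DrugEntry | None:
    for d in drugs:
        if d.role == "PS":
            return d
    return None


def clean_cases(
    cases: Iterable[RawCase],
    study_years: tuple[int, int] | None = None,
) -> list[CleanReport]:
    """Normalise deduplicated raw cases into :class:`CleanReport` records.

    Reports with no reaction PT are dropped (they cannot contribute to any
    contingency cell); reports outside ``study_years`` (receipt year range,
    inclusive) are dropped as out of window.
    """
    out: list[CleanReport] = []
    n_no_reac = 0
    n_out_of_window = 0
    for c in cases:
        reactions = frozenset(c.reactions)
        if not reactions:
            n_no_reac += 1
            continue
        year = c.fda_dt // 10000 if c.fda_dt else None
        if study_years is not None and year is not None:
            if not (study_years[0] <= year <= study_years[1]):
                n_out_of_window += 1
                continue
        sex = c.sex.upper() if c.sex else None
        if sex not in ("F", "M"):
            sex = None
        ps = _first_ps_entry(c.drugs)
        codes = {o for o in c.outcome_codes if o in OUTCOME_LABELS}
        out.append(
            CleanReport(
                primaryid=c.primaryid,
                receipt_year=year,
                age_years=normalize_age(c.age, c.age_cod),
                sex=sex,
                reporter=REPORTER_LABELS.get((c.occp_cod or "").upper()),
                country=c.country,
                serious=bool(codes & SERIOUS_OUTCOME_CODES),
                outcomes=frozenset(OUTCOME_LABELS[o] for o in codes),
                route=(ps.route.strip().lower() if ps and ps.route else None),
                ps_drug=(ps.name.strip().upper() if ps and ps.name else None),
                indications=frozenset(ps.indications) if ps else frozenset(),
                reactions=reactions,
                drugs=c.drugs,
            )
        )
    if n_no_reac:
        logger.warning("clean_cases: %d reports without reaction PTs excluded", n_no_reac)
    if n_out_of_window:
        logger.warning("clean_cases: %d reports outside study window excluded", n_out_of_window)
    return out


DEFAULT_NAME_PATTERNS = ("rivaroxaban", "xarelto")


def _matches(entry: DrugEntry, patterns: Sequence[str]) -> bool:
    name = entry.name.lower()
    ai = entry.prod_ai.lower()
    return any(p in name or p in ai for p in patterns)


def filter_primary_suspect(
    reports: Iterable[CleanReport],
    name_patterns: Sequence[str] = DEFAULT_NAME_PATTERNS,
) -> list[CleanReport]:
    """Select reports whose primary-suspect drug matches any name pattern.

    Matching is case-insensitive substring search over both the reported
    drug name and the product active ingredient.  The matching PS entry's
    indications and route are attached to the returned report and
    ``ps_drug`` is set to its (uppercased) drug name.
    """
    if not name_patterns:
        raise ValueError("name_patterns must be non-empty")
    patterns = [p.lower() for p in name_patterns]
    out: list[CleanReport] = []
    for r in reports:
        hit = next(
            (d for d in r.drugs if d.role == "PS" and _matches(d, patterns)), None
        )
        if hit is None:
            continue
        out.append(
            replace(
                r,
                ps_drug=hit.name.strip().upper() or hit.prod_ai.strip().upper(),
                indications=frozenset(hit.indications),
                route=hit.route.strip().lower() if hit.route else None,
            )
        )
    return out


def split_target_background(
    reports: Iterable[CleanReport],
    name_patterns: Sequence[str] = DEFAULT_NAME_PATTERNS,
) -> tuple[list[CleanReport], list[CleanReport]]:
    """Partition cleaned reports into target (PS drug matches) and background."""
    reports = list(reports)
    target = filter_primary_suspect(reports, name_patterns)
    target_ids = {r.primaryid for r in target}
    background = [r for r in reports if r.primaryid not in target_ids]
    return target, background


def load_pt_soc_map(path: str | Path) -> dict[str, str]:
    """Load a two-column (pt, soc) CSV into a PT→SOC dict (PT casefolded)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.rename(columns=str.lower)
    if not {"pt", "soc"} <= set(df.columns):
        raise FaersFormatError(f"PT→SOC map {path}: need columns 'pt' and 'soc'")
    return {str(r.pt).strip().casefold(): str(r.soc).strip() for r in df.itertuples()}


def load_ime_list(path: str | Path) -> frozenset[str]:
    """Load a one-column CSV of important-medical-event PT names (casefolded)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    col = df.columns[0]
    return frozenset(str(v).strip().casefold() for v in df[col] if str(v).strip())


def load_deleted_caseids(path: str | Path) -> set[int]:
    """Load a deleted-case file: one caseid per line."""
    out: set[int] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            v = _to_int(line)
            if v is not None:
                out.add(v)
    return out
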