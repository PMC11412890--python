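"""FAERS-like synthetic report generator with known ground truth.

The generator emulates the structure of a spontaneous-report extract —
per-report demographics with missingness, one primary-suspect drug drawn
from a power-law marginal (plus occasional concomitants), per-drug
indications, a Poisson-plus-one number of reaction PTs, duplicate case
versions, and receipt years 2014–2024 — so that every pipeline stage can
be exercised end to end without downloading anything.

Designated (drug, event) *signal pairs* reports the event at an elevated
relative rate: for reports of that drug the event's sampling probability
is multiplied by ρ ≥ 1 and the marginal renormalised.
:func:`expected_tables` returns the exact expected 2×2 cells implied by
that generative model, for parameter-recovery tests.

Default demographic and calendar distributions follow the published
profile of rivaroxaban reports (sex split 46/48/6, median age 72 with
IQR 61–80, consumer-majority reporters, US-majority countries, oral
route, 86% serious, 2015 reporting peak); the vocabulary is a scaled-down
20-drug × 100-event universe rather than a real dictionary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .faers_io import CleanReport, DrugEntry, RawCase

__all__ = [
    "SimConfig",
    "SimOutput",
    "generate_reports",
    "inject_duplicates",
    "expected_tables",
    "write_faers_tables",
    "write_ground_truth",
    "default_pt_to_soc",
]

# Receipt-year weights: share of reports per year 2014..2024 (2024 = Q1 only).
_YEAR_WEIGHTS = {
    2014: 3.67, 2015: 19.06, 2016: 17.93, 2017: 13.35, 2018: 11.91,
    2019: 8.38, 2020: 17.29, 2021: 2.89, 2022: 2.83, 2023: 2.25, 2024: 0.43,
}

_SEX_PROBS = {"F": 0.4624, "M": 0.4774, None: 0.0602}

_REPORTER_PROBS = {
    "CN": 0.5384, "MD": 0.2640, "PH": 0.1221, "OT": 0.0624, "LW": 0.0066, None: 0.0065,
}

_COUNTRY_PROBS = {
    "US": 0.7438, "DE": 0.0381, "JP": 0.0345, "FR": 0.0283, "GB": 0.0235, "OTHER": 0.1318,
}

_OUTCOME_PROBS = {  # marginal, multi-select
    "HO": 0.6024, "OT": 0.3196, "DE": 0.1484, "LT": 0.0434, "DS": 0.0189,
    "RI": 0.0028, "CA": 0.0001,
}

_INDICATION_PROBS = {
    "Atrial fibrillation": 0.3345,
    "Cerebrovascular accident prophylaxis": 0.1713,
    "Deep vein thrombosis": 0.1595,
    "Pulmonary embolism": 0.0807,
    "Thrombosis prophylaxis": 0.0754,
    "Other indication": 0.1786,
}


@dataclass(frozen=True)
class SimConfig:
    """Generative model parameters (defaults emulate the study conditions)."""

    n_reports: int = 10_000
    n_drugs: int = 20
    n_events: int = 100
    drug_exponent: float = 1.0  # power-law exponent of the drug marginal
    event_exponent: float = 1.0
    #: (drug index, event index, relative-reporting multiplier ρ ≥ 1)
    signal_pairs: tuple[tuple[int, int, float], ...] = ()
    mean_extra_events: float = 1.3  # events per report ~ 1 + Poisson(this)
    year_weights: Mapping[int, float] = field(default_factory=lambda: dict(_YEAR_WEIGHTS))
    age_mean: float = 70.0
    age_sd: float = 14.0
    age_missing_rate: float = 0.2083
    sex_probs: Mapping[str | None, float] = field(default_factory=lambda: dict(_SEX_PROBS))
    reporter_probs: Mapping[str | None, float] = field(default_factory=lambda: dict(_REPORTER_PROBS))
    country_probs: Mapping[str, float] = field(default_factory=lambda: dict(_COUNTRY_PROBS))
    indication_probs: Mapping[str, float] = field(default_factory=lambda: dict(_INDICATION_PROBS))
    oral_route_rate: float = 0.9869
    serious_rate: float = 0.8620
    outcome_probs: Mapping[str, float] = field(default_factory=lambda: dict(_OUTCOME_PROBS))
    concomitant_rate: float = 0.3  # chance of one extra role-C drug entry
    duplicate_case_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for _, _, rho in self.signal_pairs:
            if rho < 1.0:
                raise ValueError("signal multipliers must satisfy rho >= 1")
        for d, e, _ in self.signal_pairs:
            if not (0 <= d < self.n_drugs and 0 <= e < self.n_events):
                raise ValueError("signal pair indices out of range")
        probs = list(self.sex_probs.values()) + list(self.reporter_probs.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")

    def drug_name(self, index: int) -> str:
        return f"DRUG_{index:03d}"

    def event_name(self, index: int) -> str:
        return f"EVENT_{index:03d}"

    def drug_marginal(self) -> np.ndarray:
        w = (np.arange(self.n_drugs) + 1.0) ** (-self.drug_exponent)
        return w / w.sum()

    def event_marginal(self, drug: int | None = None) -> np.ndarray:
        """Event sampling probabilities, renormalised for a signal drug."""
        w = (np.arange(self.n_events) + 1.0) ** (-self.event_exponent)
        p = w / w.sum()
        if drug is not None:
            for d, e, rho in self.signal_pairs:
                if d == drug:
                    p = p.copy()
                    p[e] *= rho
            p = p / p.sum()
        return p


@dataclass
class SimOutput:
    cases: list[RawCase]
    config: SimConfig
    keep_primaryids: frozenset[int]  # ground truth after dedup


def _sample_categorical(rng: np.random.Generator, probs: Mapping, size: int) -> list:
    keys = list(probs.keys())
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return [keys[i] for i in idx]


def generate_reports(config: SimConfig) -> list[RawCase]:
    """Draw a full synthetic report set; byte-identical for a fixed seed.

    Each report gets one PS drug from the power-law drug marginal, 1–2
    indications, a 1 + Poisson(mean) count of reaction-PT draws (distinct
    PTs kept), demographics with the configured missingness, and an OUTC
    code set in which serious reports carry at least one serious code.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    years = np.array(_sample_categorical(rng, dict(config.year_weights), n))
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    fda_dt = years * 10_000 + months * 100 + days

    drugs = rng.choice(config.n_drugs, size=n, p=config.drug_marginal())

    # reaction PTs: variable-length iid draws, deduplicated per report
    k = 1 + rng.poisson(config.mean_extra_events, size=n)
    report_idx = np.repeat(np.arange(n), k)
    event_draws = np.empty(report_idx.shape[0], dtype=np.int64)
    base_p = config.event_marginal()
    signal_drugs = {d for d, _, _ in config.signal_pairs}
    plain = ~np.isin(drugs, list(signal_drugs)) if signal_drugs else np.ones(n, bool)
    plain_rows = plain[report_idx]
    event_draws[plain_rows] = rng.choice(config.n_events, size=int(plain_rows.sum()), p=base_p)
    for d in sorted(signal_drugs):
        rows = drugs[report_idx] == d
        event_draws[rows] = rng.choice(
            config.n_events, size=int(rows.sum()), p=config.event_marginal(d)
        )

    reactions_per_report: list[list[int]] = [[] for _ in range(n)]
    for i, e in zip(report_idx, event_draws):
        lst = reactions_per_report[i]
        if e not in lst:
            lst.append(int(e))

    ages = rng.normal(config.age_mean, config.age_sd, size=n).clip(1.0, 110.0).round(0)
    age_missing = rng.random(n) < config.age_missing_rate
    sexes = _sample_categorical(rng, dict(config.sex_probs), n)
    reporters = _sample_categorical(rng, dict(config.reporter_probs), n)
    countries = _sample_categorical(rng, dict(config.country_probs), n)
    oral = rng.random(n) < config.oral_route_rate
    serious = rng.random(n) < config.serious_rate
    concomitant = rng.random(n) < config.concomitant_rate
    conc_drug = rng.integers(0, config.n_drugs, size=n)
    n_indi = 1 + (rng.random(n) < 0.1)

    serious_codes = [c for c in _OUTCOME_PROBS if c != "OT"]
    outcome_draws = {
        c: rng.random(n) < p for c, p in config.outcome_probs.items()
    }

    indication_pool = _sample_categorical(rng, dict(config.indication_probs), 2 * n)

    cases: list[RawCase] = []
    for i in range(n):
        codes: list[str] = [c for c in outcome_draws if outcome_draws[c][i]]
        if serious[i] and not any(c in serious_codes for c in codes):
            codes.append("HO")
        if not serious[i]:
            codes = [c for c in codes if c not in serious_codes] or ["OT"]
        indis = tuple(dict.fromkeys(indication_pool[2 * i : 2 * i + n_indi[i]]))
        dname = config.drug_name(int(drugs[i]))
        entries = [
            DrugEntry(
                seq=1, name=dname, prod_ai=dname, role="PS",
                route="ORAL" if oral[i] else "UNKNOWN", indications=indis,
            )
        ]
        if concomitant[i]:
            cname = config.drug_name(int(conc_drug[i]))
            entries.append(DrugEntry(seq=2, name=cname, prod_ai=cname, role="C", route=None))
        pid = 100_000 + i
        cases.append(
            RawCase(
                primaryid=pid * 10 + 1,
                caseid=pid,
                fda_dt=int(fda_dt[i]),
                age=None if age_missing[i] else float(ages[i]),
                age_cod="YR",
                sex=sexes[i],
                occp_cod=reporters[i],
                country=countries[i],
                outcome_codes=tuple(codes),
                drugs=tuple(entries),
                reactions=tuple(config.event_name(e) for e in reactions_per_report[i]),
            )
        )
    return cases


def inject_duplicates(
    cases: Sequence[RawCase],
    rate: float,
    seed: int = 0,
) -> tuple[list[RawCase], frozenset[int]]:
    """Give a fraction of caseids 1–2 later report versions.

    Later versions have strictly later ``fda_dt`` and lightly perturbed
    demographics (reactions untouched, so signal ground truth survives
    deduplication).  Returns the augmented case list and the ground-truth
    set of primaryids that a correct latest-version dedup must keep.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("duplicate rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = list(cases)
    keep: dict[int, int] = {c.caseid: c.primaryid for c in cases}
    if rate > 0.0:
        dup_mask = rng.random(len(cases)) < rate
        for i in np.nonzero(dup_mask)[0]:
            orig = cases[int(i)]
            n_versions = int(rng.integers(1, 3))
            fda = orig.fda_dt or 20140101
            for v in range(n_versions):
                fda = fda + int(rng.integers(1, 300))
                new = RawCase(
                    primaryid=orig.primaryid + v + 1,
                    caseid=orig.caseid,
                    fda_dt=fda,
                    age=orig.age if rng.random() > 0.3 else None,
                    age_cod=orig.age_cod,
                    sex=orig.sex,
                    occp_cod=orig.occp_cod,
                    country=orig.country,
                    outcome_codes=orig.outcome_codes,
                    drugs=orig.drugs,
                    reactions=orig.reactions,
                )
                out.append(new)
                keep[orig.caseid] = new.primaryid
    return out, frozenset(keep.values())


def _p_event_in_report(p_e: float, mu: float) -> float:
    """P(event e appears at least once) for K ~ 1 + Poisson(mu) iid draws.

    E[(1−p)^K] = (1−p)·exp(−mu·p) by the Poisson pgf, hence the closed form.
    """
    return 1.0 - (1.0 - p_e) * math.exp(-mu * p_e)


def expected_tables(config: SimConfig) -> dict[tuple[int, int], dict[str, float]]:
    """Exact expected 2×2 cells per signal pair under the generative model.

    Counting matches the pipeline: distinct (report, event) combinations,
    with the target drug's reports as rows a/b and every other drug's as
    c/d.  Renormalisation of the event marginal for signal drugs is
    accounted for exactly.
    """
    n = config.n_reports
    mu = config.mean_extra_events
    pi = config.drug_marginal()
    out: dict[tuple[int, int], dict[str, float]] = {}
    per_drug_p = {d: config.event_marginal(d) for d in range(config.n_drugs)}
    g = {
        d: np.array([_p_event_in_report(p, mu) for p in per_drug_p[d]])
        for d in range(config.n_drugs)
    }
    for d, e, rho in config.signal_pairs:
        a = n * pi[d] * g[d][e]
        row_total = n * pi[d] * g[d].sum()
        c = sum(n * pi[dd] * g[dd][e] for dd in range(config.n_drugs) if dd != d)
        other_total = sum(
            n * pi[dd] * g[dd].sum() for dd in range(config.n_drugs) if dd != d
        )
        out[(d, e)] = {
            "a": float(a),
            "b": float(row_total - a),
            "c": float(c),
            "d": float(other_total - c),
            "rho": rho,
        }
    return out


# --------------------------------------------------------------------------
# FAERS-dialect writers


def _fmt(v) -> str:
    return "" if v is None else str(v)


def write_faers_tables(cases: Iterable[RawCase], outdir: str | Path) -> dict[str, Path]:
    """Write DEMO/DRUG/REAC/INDI/OUTC "$"-delimited files readable by
    :func:`pvsignal.faers_io.read_quarter` (round-trip tested)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name.upper()}.txt" for name in ("demo", "drug", "reac", "indi", "outc")}
    demo_rows = ["primaryid$caseid$fda_dt$age$age_cod$sex$occp_cod$reporter_country"]
    drug_rows = ["primaryid$drug_seq$role_cod$drugname$prod_ai$route"]
    reac_rows = ["primaryid$pt"]
    indi_rows = ["primaryid$indi_drug_seq$indi_pt"]
    outc_rows = ["primaryid$outc_cod"]
    for c in cases:
        age = "" if c.age is None else f"{c.age:g}"
        demo_rows.append(
            f"{c.primaryid}${c.caseid}${_fmt(c.fda_dt)}${age}${_fmt(c.age_cod)}"
            f"${_fmt(c.sex)}${_fmt(c.occp_cod)}${_fmt(c.country)}"
        )
        for d in c.drugs:
            drug_rows.append(
                f"{c.primaryid}${d.seq}${_fmt(d.role)}${d.name}${d.prod_ai}${_fmt(d.route)}"
            )
            for ind in d.indications:
                indi_rows.append(f"{c.primaryid}${d.seq}${ind}")
        for pt in c.reactions:
            reac_rows.append(f"{c.primaryid}${pt}")
        for oc in c.outcome_codes:
            outc_rows.append(f"{c.primaryid}${oc}")
    for name, rows in (
        ("demo", demo_rows), ("drug", drug_rows), ("reac", reac_rows),
        ("indi", indi_rows), ("outc", outc_rows),
    ):
        paths[name].write_text("\n".join(rows) + "\n")
    return paths


def write_ground_truth(
    output: SimOutput, path: str | Path
) -> None:
    """Ground-truth JSON: signal pairs (named), keep-version ids, config echo."""
    cfg = output.config
    payload = {
        "signal_pairs": [
            {
                "drug": cfg.drug_name(d),
                "event": cfg.event_name(e),
                "rho": rho,
            }
            for d, e, rho in cfg.signal_pairs
        ],
        "keep_primaryids": sorted(output.keep_primaryids),
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in asdict(cfg).items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def default_pt_to_soc(config: SimConfig, n_socs: int = 10) -> dict[str, str]:
    """Deterministic synthetic PT→SOC map: events cycle over ``n_socs`` SOCs."""
    return {
        config.event_name(e).casefold(): f"SOC_{e % n_socs:02d}"
        for e in range(config.n_events)
    }
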