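"""End-to-end orchestration: ingest (or simulate), analyse, export.

The exports are plot-ready tables rather than figures: a statistics TSV
(one row per term with counts, all five statistics and their bounds), a
decisions TSV, an UpSet membership matrix, Venn counts JSON, a volcano
table, a SOC×algorithm heatmap table and per-SOC IC trend series — every
figure in a disproportionality write-up is a direct rendering of one of
these files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contingency import build_combination_counts, stratify
from .descriptives import demographic_summary, indication_ranking, soc_report_proportions
from .dispro import BcpnnHyper, DisproResult, compute_all
from .faers_io import (
    CleanReport,
    DEFAULT_NAME_PATTERNS,
    clean_cases,
    deduplicate_cases,
    load_deleted_caseids,
    load_ime_list,
    load_pt_soc_map,
    read_quarter,
    split_target_background,
)
from .screen import ALGORITHMS, SignalCriteria, SignalDecision, evaluate_signals, overlap_summary
from .simulate import SimConfig, default_pt_to_soc, generate_reports, inject_duplicates
from .trend import ic_time_series, trend_frame

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_analysis", "export_plot_tables", "stats_frame", "decisions_frame"]


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one input source is set."""

    faers_dirs: tuple[str, ...] = ()  # quarterly directories with DEMO.txt etc.
    synthetic: SimConfig | None = None
    name_patterns: tuple[str, ...] = DEFAULT_NAME_PATTERNS
    study_years: tuple[int, int] = (2014, 2024)
    levels: tuple[str, ...] = ("PT",)
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    yates: bool = True
    zero_correction: bool = True
    bcpnn_hyper: BcpnnHyper = field(default_factory=BcpnnHyper)
    pt_to_soc_path: str | None = None
    ime_path: str | None = None
    deleted_cases_path: str | None = None
    subgroup_indications: tuple[str, ...] = ()
    trend_mode: str = "per_year"
    outdir: str = "pvsignal_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if bool(self.faers_dirs) == (self.synthetic is not None):
            raise ValueError("configure exactly one of faers_dirs or synthetic")
        if self.study_years[0] > self.study_years[1]:
            raise ValueError("empty study window")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "signal_pairs" in syn:
                syn["signal_pairs"] = tuple(tuple(p) for p in syn["signal_pairs"])
            raw["synthetic"] = SimConfig(**syn)
        if "criteria" in raw:
            raw["criteria"] = SignalCriteria(**raw["criteria"])
        if "bcpnn_hyper" in raw:
            raw["bcpnn_hyper"] = BcpnnHyper(**raw["bcpnn_hyper"])
        for key in ("faers_dirs", "name_patterns", "levels", "subgroup_indications"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "study_years" in raw:
            raw["study_years"] = tuple(raw["study_years"])
        return cls(**raw)


@dataclass
class RunResult:
    target: list[CleanReport]
    background: list[CleanReport]
    stats: dict[str, pd.DataFrame]  # level -> statistics table
    decisions: dict[str, pd.DataFrame]
    outdir: Path
    manifest: dict


def stats_frame(results: Mapping[str, DisproResult]) -> pd.DataFrame:
    """One row per term: cells plus all five statistics and bounds."""
    rows = []
    for term in sorted(results):
        r = results[term]
        t = r.table
        row = {
            "term": term, "a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.n,
            "ror": r.freq.ror.value, "ror_lo": r.freq.ror.lo, "ror_hi": r.freq.ror.hi,
            "ror_corrected": r.freq.ror.corrected,
            "prr": r.freq.prr.value, "prr_lo": r.freq.prr.lo, "prr_hi": r.freq.prr.hi,
            "chi2": r.freq.chi2.chi2, "p_chi2": r.freq.chi2.p, "chi2_yates": r.freq.chi2.yates,
            "ic": r.bcpnn.ic, "ic_sd": r.bcpnn.ic_sd,
            "ic025": r.bcpnn.ic025, "ic975": r.bcpnn.ic975,
            "ic_lo95": r.bcpnn.ic_lo95, "ic_hi95": r.bcpnn.ic_hi95,
        }
        if r.mgps is not None:
            row.update(
                expected=r.mgps.expected, ebgm=r.mgps.ebgm,
                eb05=r.mgps.eb05, eb95=r.mgps.eb95, qn=r.mgps.qn,
            )
        else:
            row.update(expected=np.nan, ebgm=np.nan, eb05=np.nan, eb95=np.nan, qn=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def decisions_frame(decisions: Sequence[SignalDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": d.term, "a": d.a,
                "positive_ror": d.positive_ror, "positive_prr": d.positive_prr,
                "positive_mhra": d.positive_mhra, "positive_bcpnn": d.positive_bcpnn,
                "positive_mgps": d.positive_mgps, "bcpnn_tier": d.bcpnn_tier,
                "ime": d.ime, "n_positive_algorithms": d.n_positive_algorithms,
            }
            for d in decisions
        ]
    )


def export_plot_tables(
    stats: pd.DataFrame,
    decisions: pd.DataFrame,
    outdir: str | Path,
    prefix: str = "PT",
    pt_to_soc: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write volcano, heatmap, UpSet-matrix and Venn-count files.

    Volcano x-coordinates are log2 of ROR, PRR and EB05; the IC variant
    uses the IC − 2SD bound directly since IC is already a base-2
    logarithm.  The y-coordinate is −ln(p) from the chi-square test with p
    floored at the smallest positive double before taking the log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tiny = float(np.finfo(float).tiny)
    p = stats["p_chi2"].clip(lower=tiny)
    with np.errstate(divide="ignore"):
        volcano = pd.DataFrame(
            {
                "term": stats["term"],
                "a": stats["a"],
                "x_log2_ror": np.log2(stats["ror"]),
                "x_log2_prr": np.log2(stats["prr"]),
                "x_ic025": stats["ic025"],
                "x_log2_eb05": np.log2(stats["eb05"]),
                "neg_ln_p": -np.log(p),
                "log2_count": np.log2(stats["a"].clip(lower=1)),
            }
        )
    paths["volcano"] = outdir / f"volcano_{prefix}.tsv"
    volcano.to_csv(paths["volcano"], sep="\t", index=False)

    flag_cols = {alg: f"positive_{alg.lower()}" for alg in ALGORITHMS}
    upset = decisions[["term", "a", "ime", *flag_cols.values()]].copy()
    upset[list(flag_cols.values())] = upset[list(flag_cols.values())].astype(int)
    paths["upset"] = outdir / f"upset_{prefix}.tsv"
    upset.to_csv(paths["upset"], sep="\t", index=False)

    pattern_counts: dict[str, int] = {}
    for _, row in decisions.iterrows():
        members = tuple(alg for alg in ALGORITHMS if row[flag_cols[alg]])
        if members:
            key = "&".join(members)
            pattern_counts[key] = pattern_counts.get(key, 0) + 1
    venn = {
        "per_algorithm": {
            alg: int(decisions[flag_cols[alg]].sum()) for alg in ALGORITHMS
        },
        "patterns": pattern_counts,
        "n_union": int(sum(pattern_counts.values())),
    }
    paths["venn"] = outdir / f"venn_{prefix}.json"
    paths["venn"].write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")

    if pt_to_soc is not None and prefix == "PT":
        dd = decisions.copy()
        dd["soc"] = [pt_to_soc.get(t.casefold(), "unmapped") for t in dd["term"]]
        rows = []
        for soc, grp in dd.groupby("soc"):
            for alg in ALGORITHMS:
                rows.append({"soc": soc, "algorithm": alg,
                             "n_positive_pts": int(grp[flag_cols[alg]].sum())})
        paths["heatmap"] = outdir / "heatmap_SOC.tsv"
        pd.DataFrame(rows).to_csv(paths["heatmap"], sep="\t", index=False)
    return paths


def _load_reports(config: RunConfig) -> tuple[list[CleanReport], list[CleanReport], dict]:
    """Ingest the configured source → (target, background, audit metadata)."""
    if config.synthetic is not None:
        sim = dataclasses.replace(config.synthetic, seed=config.seed)
        raw = generate_reports(sim)
        if sim.duplicate_case_rate > 0:
            raw, _ = inject_duplicates(raw, sim.duplicate_case_rate, seed=config.seed + 1)
    else:
        raw = []
        for qdir in config.faers_dirs:
            qdir = Path(qdir)
            paths = {}
            for name in ("demo", "drug", "reac", "indi", "outc"):
                for cand in (qdir / f"{name.upper()}.txt", qdir / f"{name}.txt"):
                    if cand.exists():
                        paths[name] = cand
                        break
            for mandatory in ("demo", "drug", "reac"):
                if mandatory not in paths:
                    raise FileNotFoundError(
                        f"quarter directory {qdir}: no {mandatory.upper()}.txt found"
                    )
            raw.extend(read_quarter(paths))
    deleted = (
        load_deleted_caseids(config.deleted_cases_path)
        if config.deleted_cases_path
        else None
    )
    deduped, audit = deduplicate_cases(raw, deleted)
    clean = clean_cases(deduped, study_years=config.study_years)
    target, background = split_target_background(clean, config.name_patterns)
    meta = {
        "dedup_audit": dataclasses.asdict(audit),
        "n_clean": len(clean),
        "n_target": len(target),
        "n_background": len(background),
    }
    return target, background, meta


def _analyse_level(
    target: list[CleanReport],
    background: list[CleanReport],
    level: str,
    config: RunConfig,
    pt_to_soc: Mapping[str, str] | None,
    ime: frozenset[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    counts = build_combination_counts(
        target, background, level=level, pt_to_soc=pt_to_soc
    )
    results = compute_all(
        counts,
        zero_correction=config.zero_correction,
        yates=config.yates,
        hyper=config.bcpnn_hyper,
    )
    decisions = evaluate_signals(results, ime_list=ime, criteria=config.criteria)
    return stats_frame(results), decisions_frame(decisions)


def run_analysis(config: RunConfig) -> RunResult:
    """Run the full pipeline and write every export under ``config.outdir``.

    Deterministic: rerunning with the same config and seed reproduces every
    output byte for byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.pt_to_soc_path:
        pt_to_soc = load_pt_soc_map(config.pt_to_soc_path)
    elif config.synthetic is not None:
        pt_to_soc = default_pt_to_soc(config.synthetic)
    else:
        pt_to_soc = None
    ime = load_ime_list(config.ime_path) if config.ime_path else frozenset()

    target, background, meta = _load_reports(config)
    if not target:
        raise RuntimeError("no target-drug reports after cleaning; check name_patterns")

    stats_by_level: dict[str, pd.DataFrame] = {}
    decisions_by_level: dict[str, pd.DataFrame] = {}
    for level in config.levels:
        stats, decisions = _analyse_level(target, background, level, config, pt_to_soc, ime)
        stats_by_level[level] = stats
        decisions_by_level[level] = decisions
        stats.to_csv(outdir / f"stats_{level}.tsv", sep="\t", index=False)
        decisions.to_csv(outdir / f"decisions_{level}.tsv", sep="\t", index=False)
        export_plot_tables(stats, decisions, outdir, prefix=level, pt_to_soc=pt_to_soc)

    # descriptives
    summary = demographic_summary(target)
    summary.rows.to_csv(outdir / "demographics.tsv", sep="\t", index=False)
    indication_ranking(target).to_csv(outdir / "indications.tsv", sep="\t", index=False)
    if pt_to_soc is not None:
        soc_report_proportions(target, pt_to_soc).to_csv(
            outdir / "soc_proportions.tsv", sep="\t", index=False
        )

    # per-SOC IC trend
    if pt_to_soc is not None:
        socs = sorted(set(pt_to_soc.values()))
        series = {
            soc: ic_time_series(
                target, background, soc, level="SOC",
                mode=config.trend_mode, pt_to_soc=pt_to_soc,
                hyper=config.bcpnn_hyper,
            )
            for soc in socs
        }
        trend_frame(series).to_csv(outdir / "trend_SOC.tsv", sep="\t", index=False)

    # indication subgroups: both target and background restricted to reports
    # carrying the indication on their PS drug
    for indication in config.subgroup_indications:
        sub_t, _ = stratify(target, "indication_PT", [indication])
        sub_b, _ = stratify(background, "indication_PT", [indication])
        sub_target, sub_background = sub_t[indication], sub_b[indication]
        if not sub_target:
            logger.warning("subgroup %r has no target reports; skipped", indication)
            continue
        subdir = outdir / f"subgroup_{indication.replace(' ', '_')}"
        subdir.mkdir(exist_ok=True)
        for level in config.levels:
            stats, decisions = _analyse_level(
                sub_target, sub_background, level, config, pt_to_soc, ime
            )
            stats.to_csv(subdir / f"stats_{level}.tsv", sep="\t", index=False)
            decisions.to_csv(subdir / f"decisions_{level}.tsv", sep="\t", index=False)

    manifest = {
        "pvsignal_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        "study_years": list(config.study_years),
        "levels": list(config.levels),
        **meta,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunResult(
        target=target,
        background=background,
        stats=stats_by_level,
        decisions=decisions_by_level,
        outdir=outdir,
        manifest=manifest,
    )
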