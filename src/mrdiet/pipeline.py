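"""End-to-end orchestration: select -> harmonize -> estimate -> diagnose
-> decide -> report.

``run_pipeline`` drives one outcome study against any number of exposure
studies, writes tidy TSV outputs plus a JSON run manifest, and is
deterministic given the config (every stochastic step is seeded from the
config seed).  Exposures left with no genome-wide-significant instruments
are reported as "no effective IVs" rather than errored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decision import DecisionOutcome, assemble_report_row, select_main_method
from .diagnostics import (
    DiagnosticsBundle,
    LooResult,
    PressoConfig,
    compute_diagnostics,
)
from .errors import ConfigurationError
from .estimators import (
    Z95,
    MrEstimate,
    RatioSet,
    egger,
    ivw,
    wald_ratio_estimate,
    wald_ratios,
    weighted_median,
)
from .instruments import ClumpConfig, LdProvider, f_statistics, ld_clump, significance_filter
from .summary_data import GwasRecord, HarmonizedSet, harmonize, read_gwas_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; serializable so the manifest can replay it."""

    exposures: list[dict]  # each {"label": ..., "path": ...}
    outcome_path: str
    outcome_label: str = "outcome"
    exposure_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)
    ld_path: str | None = None
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    presso: PressoConfig = field(default_factory=PressoConfig)
    n_boot: int = 1000
    alpha: float = 0.05
    palindrome_eaf_window: float = 0.08
    heterogeneity_main: str = "IVW_mre"
    seed: int = 20230609
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clump"] = dataclasses.asdict(self.clump)
        d["presso"] = dataclasses.asdict(self.presso)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("clump"), dict):
            d["clump"] = ClumpConfig(**d["clump"])
        if isinstance(d.get("presso"), dict):
            d["presso"] = PressoConfig(**d["presso"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ExposureResult:
    label: str
    n_input: int
    n_significant: int
    n_clumped: int
    n_harmonized: int
    mean_f: float | None = None
    f_strong: bool | None = None
    estimates: dict[str, MrEstimate] = field(default_factory=dict)
    diagnostics: DiagnosticsBundle | None = None
    decision: DecisionOutcome | None = None
    harmonized: HarmonizedSet | None = None
    note: str = ""


@dataclass
class PipelineResult:
    results: pd.DataFrame
    diagnostics: pd.DataFrame
    forest: pd.DataFrame
    manifest: dict
    exposures: list[ExposureResult]


def forest_data(
    ratios: RatioSet,
    estimates: dict[str, MrEstimate],
    loo: LooResult | None = None,
) -> pd.DataFrame:
    """Forest-plot data table: per-SNP Wald ratios with CIs, per-method
    summary rows, and leave-one-out rows.  Columns:
    label, estimate, ci_low, ci_high, kind."""
    rows = [
        {
            "label": vid,
            "estimate": float(b),
            "ci_low": float(b - Z95 * s),
            "ci_high": float(b + Z95 * s),
            "kind": "snp",
        }
        for vid, b, s in zip(ratios.variant_ids, ratios.beta, ratios.se)
    ]
    for key, est in estimates.items():
        rows.append(
            {
                "label": key,
                "estimate": est.beta,
                "ci_low": est.beta - Z95 * est.se,
                "ci_high": est.beta + Z95 * est.se,
                "kind": "method",
            }
        )
    if loo is not None:
        for r in loo.table.to_dict("records"):
            rows.append(
                {
                    "label": f"excluding {r['excluded_variant']}",
                    "estimate": r["beta"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "kind": "loo",
                }
            )
    return pd.DataFrame(rows)


def analyze_exposure(
    label: str,
    exposure_records: Sequence[GwasRecord],
    outcome_records: Sequence[GwasRecord],
    config: RunConfig,
    ld: LdProvider | None = None,
) -> ExposureResult:
    """Run the full per-exposure analysis on already-parsed records."""
    significant = significance_filter(exposure_records, config.clump.p_threshold)
    clumped = ld_clump(significant, ld, config.clump)
    result = ExposureResult(
        label=label,
        n_input=len(exposure_records),
        n_significant=len(significant),
        n_clumped=len(clumped),
        n_harmonized=0,
    )
    if not clumped:
        result.note = "no effective IVs"
        logger.info("%s: no instruments pass p < %g", label, config.clump.p_threshold)
        return result

    hset = harmonize(
        clumped,
        outcome_records,
        palindrome_eaf_window=config.palindrome_eaf_window,
        exposure_name=label,
        outcome_name=config.outcome_label,
    )
    result.harmonized = hset
    result.n_harmonized = len(hset)
    if len(hset) == 0:
        result.note = "no effective IVs"
        return result

    fstats = f_statistics(hset, config.clump.f_threshold)
    result.mean_f = fstats.mean_f
    result.f_strong = fstats.strong

    ratios = wald_ratios(hset)
    if len(hset) == 1:
        result.estimates["WaldRatio"] = est = wald_ratio_estimate(ratios)
        verdict = "positive" if est.pvalue < config.alpha else "null"
        result.decision = DecisionOutcome(
            "WaldRatio", verdict, ("single instrument: Wald ratio reported as-is",)
        )
        result.diagnostics = DiagnosticsBundle()
        return result

    result.estimates["IVW_fixed"] = ivw(ratios, "fixed")
    result.estimates["IVW_mre"] = ivw(ratios, "mre")
    egger_fit = None
    if len(hset) >= 3:
        egger_fit = egger(hset)
        result.estimates["Egger"] = egger_fit.slope
        result.estimates["Egger_intercept"] = egger_fit.intercept
        result.estimates["WeightedMedian"] = weighted_median(
            ratios, n_boot=config.n_boot, seed=config.seed
        )
    result.diagnostics = compute_diagnostics(
        hset, presso_config=config.presso, egger_fit=egger_fit
    )
    if len(hset) >= 3:
        result.decision = select_main_method(
            result.estimates,
            result.diagnostics,
            alpha=config.alpha,
            heterogeneity_main=config.heterogeneity_main,
        )
    else:
        est = result.estimates["IVW_fixed"]
        verdict = "positive" if est.pvalue < config.alpha else "null"
        result.decision = DecisionOutcome(
            "IVW", verdict, ("two instruments: IVW reported without diagnostics-based selection",)
        )
    return result


def _diagnostics_row(res: ExposureResult, outcome_label: str) -> dict:
    d = res.diagnostics or DiagnosticsBundle()
    return {
        "exposure": res.label,
        "outcome": outcome_label,
        "n_input": res.n_input,
        "n_significant": res.n_significant,
        "n_clumped": res.n_clumped,
        "n_harmonized": res.n_harmonized,
        "mean_f": res.mean_f,
        "f_strong": res.f_strong,
        "q": d.q,
        "q_df": d.q_df,
        "q_p": d.q_p,
        "egger_intercept": d.egger_intercept,
        "egger_intercept_p": d.egger_intercept_p,
        "presso_global_p": d.presso_global_p,
        "presso_outliers": ";".join(d.presso_outliers),
        "loo_no_single_driver": None if d.loo is None else d.loo.no_single_driver,
        "note": res.note,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the whole pipeline for every exposure in the config.

    Per-exposure failures become error rows; the call raises only if the
    outcome table is unreadable or every exposure fails.
    """
    outcome_records = read_gwas_table(config.outcome_path, config.outcome_columns)
    ld = LdProvider.from_tsv(config.ld_path) if config.ld_path else None

    results_frames: list[pd.DataFrame] = []
    diag_rows: list[dict] = []
    forest_frames: list[pd.DataFrame] = []
    exposures: list[ExposureResult] = []
    failures = 0

    for spec in config.exposures:
        label, path = spec["label"], spec["path"]
        try:
            exposure_records = read_gwas_table(path, config.exposure_columns)
            res = analyze_exposure(label, exposure_records, outcome_records, config, ld)
        except Exception as exc:  # per-exposure isolation
            logger.error("%s failed: %s", label, exc)
            failures += 1
            res = ExposureResult(label, 0, 0, 0, 0, note=f"error: {exc}")
        exposures.append(res)
        diag_rows.append(_diagnostics_row(res, config.outcome_label))
        if res.estimates and res.decision is not None and res.diagnostics is not None:
            results_frames.append(
                assemble_report_row(
                    label, config.outcome_label, res.estimates, res.diagnostics, res.decision
                )
            )
            if res.harmonized is not None and len(res.harmonized) >= 2:
                ff = forest_data(
                    wald_ratios(res.harmonized),
                    res.estimates,
                    res.diagnostics.loo,
                )
                ff.insert(0, "exposure", label)
                forest_frames.append(ff)
        else:
            results_frames.append(
                pd.DataFrame(
                    [
                        {
                            "exposure": label,
                            "outcome": config.outcome_label,
                            "method": "none",
                            "n_snp": 0,
                            "verdict": res.note or "no estimates",
                        }
                    ]
                )
            )

    if failures and failures == len(config.exposures):
        raise ConfigurationError("every exposure failed; see log for per-exposure errors")

    results = pd.concat(results_frames, ignore_index=True) if results_frames else pd.DataFrame()
    diagnostics = pd.DataFrame(diag_rows)
    forest = (
        pd.concat(forest_frames, ignore_index=True) if forest_frames else pd.DataFrame()
    )
    manifest = {
        "package": "mrdiet",
        "version": __version__,
        "config": config.to_dict(),
        "stages": [
            {
                "exposure": r.label,
                "n_input": r.n_input,
                "n_significant": r.n_significant,
                "n_clumped": r.n_clumped,
                "n_harmonized": r.n_harmonized,
                "note": r.note,
            }
            for r in exposures
        ],
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.10g")
        diagnostics.to_csv(out / "diagnostics.tsv", sep="\t", index=False, float_format="%.10g")
        forest.to_csv(out / "forest.tsv", sep="\t", index=False, float_format="%.10g")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        for res in exposures:
            if res.harmonized is not None:
                res.harmonized.write_tsv(out / f"harmonized_{res.label}.tsv")

    return PipelineResult(results, diagnostics, forest, manifest, exposures)


def replay_manifest(manifest_path, out_dir=None) -> PipelineResult:
    """Re-run a pipeline from its manifest; with identical inputs the
    outputs are byte-identical."""
    manifest = json.loads(Path(manifest_path).read_text())
    config = RunConfig.from_dict(manifest["config"])
    if out_dir is not None:
        config.out_dir = str(out_dir)
    return run_pipeline(config)
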