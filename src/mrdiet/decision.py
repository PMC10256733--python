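"""Method-selection rules and per-exposure report assembly.

The selection logic, applied at significance level alpha (default 0.05):

1. pleiotropy (Egger intercept p < alpha) without heterogeneity
   (Q p >= alpha)  ->  MR-Egger is the main method;
2. heterogeneity without pleiotropy  ->  multiplicative random-effects
   IVW is the main method, with the weighted median reported alongside;
3. neither  ->  fixed-effect IVW;
4. both  ->  no main method (indeterminate); all estimates are reported
   and MR-PRESSO outlier removal is suggested.

A verdict is "positive" when the main method's p < alpha AND the other
methods' betas share its sign; otherwise "null" ("indeterminate" for
rule 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .diagnostics import DiagnosticsBundle
from .errors import ConfigurationError
from .estimators import MrEstimate

#: canonical estimate keys expected by the decision rules
CORE_METHODS = ("IVW_fixed", "IVW_mre", "Egger", "WeightedMedian")

_MAIN_TO_KEY = {
    "IVW": "IVW_fixed",
    "IVW_mre": "IVW_mre",
    "Egger": "Egger",
    "WeightedMedian": "WeightedMedian",
    "WaldRatio": "WaldRatio",
}


@dataclass(frozen=True)
class DecisionOutcome:
    main_method: str | None
    verdict: str  # positive | null | indeterminate
    rationale: tuple[str, ...]

    def main_key(self) -> str | None:
        return None if self.main_method is None else _MAIN_TO_KEY[self.main_method]


def _signs_agree(main: MrEstimate, others: list[MrEstimate]) -> bool:
    main_sign = math.copysign(1.0, main.beta)
    return all(o.beta == 0.0 or math.copysign(1.0, o.beta) == main_sign for o in others)


def select_main_method(
    estimates: Mapping[str, MrEstimate],
    diagnostics: DiagnosticsBundle,
    alpha: float = 0.05,
    heterogeneity_main: str = "IVW_mre",
) -> DecisionOutcome:
    """Apply the selection rules above and derive a verdict.

    ``estimates`` must contain the keys in :data:`CORE_METHODS`.
    ``heterogeneity_main`` resolves the rule-2 disjunction (the
    multiplicative random-effects IVW by default, ``"WeightedMedian"``
    optionally).
    """
    missing = [k for k in CORE_METHODS if k not in estimates]
    if missing:
        raise ConfigurationError(f"missing required estimate(s): {', '.join(missing)}")
    if diagnostics.q_p is None or diagnostics.egger_intercept_p is None:
        raise ConfigurationError("decision rules need both Q p and Egger intercept p")
    if heterogeneity_main not in ("IVW_mre", "WeightedMedian"):
        raise ConfigurationError("heterogeneity_main must be 'IVW_mre' or 'WeightedMedian'")

    pleiotropy = diagnostics.egger_intercept_p < alpha
    heterogeneity = diagnostics.q_p < alpha
    rationale = [
        f"Egger intercept p = {diagnostics.egger_intercept_p:.4g} "
        f"({'<' if pleiotropy else '>='} alpha = {alpha}): "
        f"{'pleiotropy' if pleiotropy else 'no pleiotropy'}",
        f"Cochran's Q p = {diagnostics.q_p:.4g} "
        f"({'<' if heterogeneity else '>='} alpha = {alpha}): "
        f"{'heterogeneity' if heterogeneity else 'no heterogeneity'}",
    ]

    if pleiotropy and not heterogeneity:
        main = "Egger"
        rationale.append("rule 1: pleiotropy without heterogeneity -> MR-Egger")
    elif heterogeneity and not pleiotropy:
        main = heterogeneity_main
        rationale.append(
            f"rule 2: heterogeneity without pleiotropy -> {heterogeneity_main} "
            "(weighted median reported alongside)"
        )
    elif not pleiotropy and not heterogeneity:
        main = "IVW"
        rationale.append("rule 3: neither -> fixed-effect IVW")
    else:
        rationale.append(
            "rule 4: pleiotropy AND heterogeneity -> no single main method; "
            "consider MR-PRESSO outlier removal and re-analysis"
        )
        return DecisionOutcome(None, "indeterminate", tuple(rationale))

    main_est = estimates[_MAIN_TO_KEY[main]]
    others = [
        estimates[k]
        for k in ("IVW_fixed", "Egger", "WeightedMedian")
        if k != _MAIN_TO_KEY[main]
    ]
    significant = main_est.pvalue < alpha
    concordant = _signs_agree(main_est, others)
    rationale.append(
        f"main method {main}: p = {main_est.pvalue:.4g} "
        f"({'significant' if significant else 'not significant'}); "
        f"other methods' betas {'share its sign' if concordant else 'disagree in sign'}"
    )
    verdict = "positive" if significant and concordant else "null"
    return DecisionOutcome(main, verdict, tuple(rationale))


def format_or(value: float) -> str:
    """Render an odds ratio the way result tables print them: plain
    decimals in a readable range, scientific notation outside it."""
    if value == 0.0:
        return "0"
    if 1e-3 <= value < 1e4:
        return f"{value:.4g}"
    return f"{value:.2e}"


_REPORT_ORDER = ("IVW_fixed", "IVW_mre", "Egger", "Egger_intercept", "WeightedMedian", "WaldRatio")


def assemble_report_row(
    exposure: str,
    outcome: str,
    estimates: Mapping[str, MrEstimate],
    diagnostics: DiagnosticsBundle,
    decision: DecisionOutcome,
) -> pd.DataFrame:
    """One tidy row per method, with the shared diagnostics and decision
    fields repeated on each row (convenient for a master results table)."""
    rows = []
    for key in _REPORT_ORDER:
        est = estimates.get(key)
        if est is None:
            continue
        rows.append(
            {
                "exposure": exposure,
                "outcome": outcome,
                "method": key,
                "n_snp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "or": est.or_value,
                "or_ci_low": est.ci_low,
                "or_ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "or_display": f"{format_or(est.or_value)} "
                f"({format_or(est.ci_low)}-{format_or(est.ci_high)})",
                "q_p": diagnostics.q_p,
                "egger_intercept_p": diagnostics.egger_intercept_p,
                "presso_global_p": diagnostics.presso_global_p,
                "presso_n_outliers": len(diagnostics.presso_outliers),
                "main_method": decision.main_method,
                "verdict": decision.verdict,
            }
        )
    return pd.DataFrame(rows)
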