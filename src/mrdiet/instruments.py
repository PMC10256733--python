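"""Genetic instrument selection: significance filter, LD clumping, F-statistics.

Instruments must be genome-wide significant for the exposure
(p < 5e-8), mutually independent (greedy LD clumping at r^2 < 0.001
within a 10,000 kb window by default), and collectively strong
(mean per-SNP F above 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .summary_data import GwasRecord, HarmonizedSet

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class ClumpConfig:
    """Thresholds for instrument selection.

    The clumping window is an upper bound on the distance at which two
    variants can conflict; 10,000 kb is a deliberately generous default.
    """

    p_threshold: float = GENOME_WIDE_P
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    f_threshold: float = 10.0

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ConfigurationError("r2_threshold must be in [0, 1]")
        if self.window_kb <= 0:
            raise ConfigurationError("window_kb must be positive")
        if self.f_threshold < 0:
            raise ConfigurationError("f_threshold must be non-negative")


class LdProvider:
    """Pairwise r^2 lookup.  Absent pairs default to 0 (independence);
    r^2(v, v) is always 1."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._pairs: dict[tuple[str, str], float] = {}
        for (a, b), r2 in (pairs or {}).items():
            if not (0.0 <= r2 <= 1.0):
                raise ValidationError(f"r^2 for ({a}, {b}) outside [0, 1]: {r2}")
            self._pairs[(min(a, b), max(a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get((min(a, b), max(a, b)), 0.0)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LdProvider":
        pairs = {
            (str(r["variant_a"]), str(r["variant_b"])): float(r["r2"])
            for r in frame.to_dict("records")
        }
        return cls(pairs)

    @classmethod
    def from_tsv(cls, path) -> "LdProvider":
        """Long-format TSV with columns variant_a, variant_b, r2."""
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def significance_filter(
    records: Sequence[GwasRecord], p_threshold: float = GENOME_WIDE_P
) -> list[GwasRecord]:
    """Retain exactly the rows with pvalue strictly below the threshold,
    preserving input order.  An empty result is allowed."""
    return [r for r in records if r.pvalue < p_threshold]


def _chromosome_key(chromosome: str) -> tuple[int, int, str]:
    name = chromosome.lower().removeprefix("chr")
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def _genomic_key(record: GwasRecord) -> tuple:
    return (*_chromosome_key(record.chromosome), record.position, record.variant_id)


def ld_clump(
    records: Sequence[GwasRecord],
    ld: LdProvider | None = None,
    config: ClumpConfig | None = None,
) -> list[GwasRecord]:
    """Greedy LD clumping.

    Variants are visited in ascending p-value order (ties broken by
    variant_id); each accepted variant discards every remaining variant
    that is on the same chromosome, within ``window_kb``, and in LD at
    r^2 >= ``r2_threshold`` with it.  The accepted set is returned in
    genomic order.  Without an LD table all pairs count as r^2 = 0 and
    clumping is a no-op (logged prominently).
    """
    cfg = config or ClumpConfig()
    if ld is None:
        logger.warning(
            "ld_clump: no LD table supplied; all pairs treated as r^2 = 0, "
            "so clumping is a no-op at r2_threshold=%g",
            cfg.r2_threshold,
        )
        ld = LdProvider()
    window_bp = cfg.window_kb * 1000.0

    def conflicts(kept: GwasRecord, candidate: GwasRecord) -> bool:
        return (
            kept.chromosome == candidate.chromosome
            and abs(kept.position - candidate.position) <= window_bp
            and ld.r2(kept.variant_id, candidate.variant_id) >= cfg.r2_threshold
        )

    pending = sorted(records, key=lambda r: (r.pvalue, r.variant_id))
    accepted: list[GwasRecord] = []
    while pending:
        best = pending.pop(0)
        accepted.append(best)
        pending = [r for r in pending if not conflicts(best, r)]
    return sorted(accepted, key=_genomic_key)


@dataclass(frozen=True)
class FStatResult:
    per_snp: np.ndarray
    mean_f: float
    strong: bool


def f_statistics(instruments: HarmonizedSet, f_threshold: float = 10.0) -> FStatResult:
    """Per-SNP F = (gamma / sigma_gamma)^2 and their arithmetic mean.

    The strength flag is set when mean F strictly exceeds the threshold
    (the conventional weak-instrument guard at 10).
    """
    gamma, sigma_gamma, _, _ = instruments.arrays()
    per_snp = (gamma / sigma_gamma) ** 2
    mean_f = float(per_snp.mean()) if per_snp.size else float("nan")
    return FStatResult(per_snp=per_snp, mean_f=mean_f, strong=bool(mean_f > f_threshold))
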