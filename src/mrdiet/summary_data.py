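"""GWAS summary-statistic I/O, validation, and two-sample harmonization.

Two-sample Mendelian randomization needs, for every instrument SNP, the
exposure association (gamma, SE) and the outcome association (Gamma, SE)
expressed for the *same* effect allele.  Public GWAS tables disagree on
allele orientation and, occasionally, on reported strand, so the two
tables must be joined and reconciled before any estimator may run.  This
module owns that step.

Harmonization policy
--------------------
* Join on variant identifier only (catalog files are rsID-keyed).
* If the outcome lists the effect/other alleles swapped relative to the
  exposure, the outcome beta is negated and its allele frequency replaced
  by ``1 - eaf`` (``beta_flipped``).
* If the alleles only match after complementing both outcome alleles, the
  representation is treated as a strand difference (``strand_flipped``);
  a complement *plus* swap additionally negates the beta and is recorded
  as ``beta_flipped``.
* Palindromic variants (A/T or C/G) cannot be strand-resolved from the
  alleles.  They are oriented by comparing the two studies' effect-allele
  frequencies and dropped when either frequency is missing or lies within
  ``palindrome_eaf_window`` of 0.5 (default 0.08, i.e. drop when
  eaf is in [0.42, 0.58]).
* Every input variant appears exactly once in the audit trail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, NoSharedVariantsError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_SETS = (frozenset("AT"), frozenset("CG"))

MANDATORY_FIELDS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
)
OPTIONAL_FIELDS = ("eaf", "n")

#: identity column map; override entries to absorb catalog dialects
#: (e.g. ``{"beta": "hm_beta"}``).
DEFAULT_COLUMN_MAP = {name: name for name in MANDATORY_FIELDS + OPTIONAL_FIELDS}

# smallest representable two-sided p so records keep pvalue in (0, 1]
_MIN_P = 1e-320


def _two_sided_p(z: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(z)), _MIN_P))


@dataclass(frozen=True)
class GwasRecord:
    """One variant's summary statistics in one study.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for a
    binary trait, phenotype units for a quantitative one).
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            errs.append(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            errs.append(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            errs.append("identical effect and other alleles")
        if not math.isfinite(self.beta):
            errs.append("non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            errs.append("non-positive SE")
        if not (0.0 < self.pvalue <= 1.0):
            errs.append("p-value outside (0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            errs.append("EAF outside [0, 1]")
        if self.n is not None and self.n <= 0:
            errs.append("non-positive sample size")
        return errs

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_SETS


def _require_number(value) -> float:
    x = float(value)
    if math.isnan(x):
        raise ValueError("missing numeric value")
    return x


def _optional_number(value) -> float | None:
    if value is None:
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(x) else x


def parse_gwas_frame(
    frame: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> tuple[list[GwasRecord], list[tuple[int, str]]]:
    """Parse a summary-statistics DataFrame into validated records.

    Returns ``(records, rejections)`` where each rejection is
    ``(line_number, reason)``; line numbers count the header as line 1.
    Rows failing invariants are rejected with reasons, never silently
    dropped.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update(column_map or {})
    missing = [f for f in MANDATORY_FIELDS if cmap[f] not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"missing mandatory column(s): "
            + ", ".join(f"{f} (mapped to {cmap[f]!r})" for f in missing)
        )

    records: list[GwasRecord] = []
    rejections: list[tuple[int, str]] = []
    for offset, row in enumerate(frame.to_dict("records")):
        line_no = offset + 2  # header occupies line 1
        try:
            n_raw = _optional_number(row.get(cmap["n"]))
            rec = GwasRecord(
                variant_id=str(row[cmap["variant_id"]]).strip(),
                chromosome=str(row[cmap["chromosome"]]).strip(),
                position=int(_require_number(row[cmap["position"]])),
                effect_allele=str(row[cmap["effect_allele"]]).strip().upper(),
                other_allele=str(row[cmap["other_allele"]]).strip().upper(),
                beta=_require_number(row[cmap["beta"]]),
                se=_require_number(row[cmap["se"]]),
                pvalue=_require_number(row[cmap["pvalue"]]),
                eaf=_optional_number(row.get(cmap["eaf"])),
                n=int(n_raw) if n_raw is not None else None,
            )
        except (TypeError, ValueError) as exc:
            rejections.append((line_no, f"unparseable value: {exc}"))
            continue
        errs = rec.validation_errors()
        if errs:
            rejections.append((line_no, "; ".join(errs)))
        else:
            records.append(rec)
    return records, rejections


def read_gwas_table(
    path, column_map: Mapping[str, str] | None = None
) -> list[GwasRecord]:
    """Read a tab-separated (optionally gzipped) GWAS summary table.

    Rejected rows are logged with their line number and reason.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    records, rejections = parse_gwas_frame(frame, column_map)
    for line_no, reason in rejections:
        logger.warning("%s line %d rejected: %s", path, line_no, reason)
    logger.info("%s: parsed %d records, rejected %d rows", path, len(records), len(rejections))
    return records


class HarmonizationAction(str, Enum):
    KEPT = "kept"
    BETA_FLIPPED = "beta_flipped"
    STRAND_FLIPPED = "strand_flipped"
    DROPPED_PALINDROMIC = "dropped_palindromic"
    DROPPED_MISSING = "dropped_missing"
    DROPPED_INCOMPATIBLE = "dropped_incompatible"


_RETAINED = (
    HarmonizationAction.KEPT,
    HarmonizationAction.BETA_FLIPPED,
    HarmonizationAction.STRAND_FLIPPED,
)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A variant with exposure effect gamma and outcome effect Gamma aligned
    to the same effect allele."""

    variant_id: str
    gamma: float
    sigma_gamma: float
    Gamma: float
    sigma_Gamma: float
    action: HarmonizationAction = HarmonizationAction.KEPT
    chromosome: str = "1"
    position: int = 0
    effect_allele: str = "A"
    other_allele: str = "G"
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    n_exposure: int | None = None
    n_outcome: int | None = None


@dataclass(frozen=True)
class AuditEntry:
    variant_id: str
    action: HarmonizationAction
    detail: str = ""


@dataclass
class HarmonizedSet:
    """Ordered instruments shared by an exposure and an outcome study,
    plus a per-variant audit of what harmonization did."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument]
    audit: list[AuditEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(gamma, sigma_gamma, Gamma, sigma_Gamma) as float arrays."""
        g = np.array([i.gamma for i in self.instruments], dtype=float)
        sg = np.array([i.sigma_gamma for i in self.instruments], dtype=float)
        G = np.array([i.Gamma for i in self.instruments], dtype=float)
        sG = np.array([i.sigma_Gamma for i in self.instruments], dtype=float)
        return g, sg, G, sG

    @property
    def variant_ids(self) -> list[str]:
        return [i.variant_id for i in self.instruments]

    @classmethod
    def from_arrays(
        cls,
        gamma,
        sigma_gamma,
        Gamma,
        sigma_Gamma,
        variant_ids: Sequence[str] | None = None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "HarmonizedSet":
        gamma = np.asarray(gamma, dtype=float)
        sigma_gamma = np.broadcast_to(np.asarray(sigma_gamma, dtype=float), gamma.shape)
        Gamma = np.asarray(Gamma, dtype=float)
        sigma_Gamma = np.broadcast_to(np.asarray(sigma_Gamma, dtype=float), gamma.shape)
        if variant_ids is None:
            variant_ids = [f"rs{1000000 + j}" for j in range(gamma.size)]
        instruments = [
            HarmonizedInstrument(
                variant_id=str(v),
                gamma=float(g),
                sigma_gamma=float(sg),
                Gamma=float(G),
                sigma_Gamma=float(sG),
                chromosome=str(j % 22 + 1),
                position=1_000_000 + 50_000_000 * (j // 22),
            )
            for j, (v, g, sg, G, sG) in enumerate(
                zip(variant_ids, gamma, sigma_gamma, Gamma, sigma_Gamma)
            )
        ]
        audit = [AuditEntry(i.variant_id, HarmonizationAction.KEPT) for i in instruments]
        return cls(exposure_name, outcome_name, instruments, audit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [i.variant_id for i in self.instruments],
                "chromosome": [i.chromosome for i in self.instruments],
                "position": [i.position for i in self.instruments],
                "effect_allele": [i.effect_allele for i in self.instruments],
                "other_allele": [i.other_allele for i in self.instruments],
                "gamma": [i.gamma for i in self.instruments],
                "se_gamma": [i.sigma_gamma for i in self.instruments],
                "Gamma": [i.Gamma for i in self.instruments],
                "se_Gamma": [i.sigma_Gamma for i in self.instruments],
                "action": [i.action.value for i in self.instruments],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, exposure_name: str = "exposure", outcome_name: str = "outcome"
    ) -> "HarmonizedSet":
        instruments = [
            HarmonizedInstrument(
                variant_id=str(r["variant_id"]),
                gamma=float(r["gamma"]),
                sigma_gamma=float(r["se_gamma"]),
                Gamma=float(r["Gamma"]),
                sigma_Gamma=float(r["se_Gamma"]),
                action=HarmonizationAction(r.get("action", "kept")),
                chromosome=str(r.get("chromosome", "1")),
                position=int(r.get("position", 0)),
                effect_allele=str(r.get("effect_allele", "A")),
                other_allele=str(r.get("other_allele", "G")),
            )
            for r in frame.to_dict("records")
        ]
        audit = [AuditEntry(i.variant_id, i.action) for i in instruments]
        return cls(exposure_name, outcome_name, instruments, audit)

    @classmethod
    def read_tsv(
        cls, path, exposure_name: str = "exposure", outcome_name: str = "outcome"
    ) -> "HarmonizedSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"), exposure_name, outcome_name)

    def to_gwas_records(self) -> tuple[list[GwasRecord], list[GwasRecord]]:
        """Re-materialize the harmonized instruments as two record lists
        (useful for idempotence checks and round-tripping)."""
        exposure, outcome = [], []
        for i in self.instruments:
            exposure.append(
                GwasRecord(
                    variant_id=i.variant_id,
                    chromosome=i.chromosome,
                    position=i.position,
                    effect_allele=i.effect_allele,
                    other_allele=i.other_allele,
                    beta=i.gamma,
                    se=i.sigma_gamma,
                    pvalue=_two_sided_p(i.gamma / i.sigma_gamma),
                    eaf=i.eaf_exposure,
                    n=i.n_exposure,
                )
            )
            outcome.append(
                GwasRecord(
                    variant_id=i.variant_id,
                    chromosome=i.chromosome,
                    position=i.position,
                    effect_allele=i.effect_allele,
                    other_allele=i.other_allele,
                    beta=i.Gamma,
                    se=i.sigma_Gamma,
                    pvalue=_two_sided_p(i.Gamma / i.sigma_Gamma),
                    eaf=i.eaf_outcome,
                    n=i.n_outcome,
                )
            )
        return exposure, outcome


def _classify(
    exp: GwasRecord, out: GwasRecord, window: float
) -> tuple[HarmonizationAction, bool, str]:
    """Decide how the outcome record relates to the exposure record.

    Returns (action, negate_outcome_beta, detail).
    """
    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)

    if exp.is_palindromic:
        if frozenset(o) != frozenset(e):
            return HarmonizationAction.DROPPED_INCOMPATIBLE, False, (
                f"outcome alleles {o[0]}/{o[1]} incompatible with palindromic {e[0]}/{e[1]}"
            )
        if exp.eaf is None or out.eaf is None:
            return HarmonizationAction.DROPPED_PALINDROMIC, False, "palindromic with missing EAF"
        if abs(exp.eaf - 0.5) <= window or abs(out.eaf - 0.5) <= window:
            return HarmonizationAction.DROPPED_PALINDROMIC, False, (
                "palindromic with EAF too close to 0.5 to resolve strand"
            )
        flip = (exp.eaf - 0.5) * (out.eaf - 0.5) < 0
        action = HarmonizationAction.BETA_FLIPPED if flip else HarmonizationAction.KEPT
        return action, flip, "palindromic oriented by EAF concordance"

    if o == e:
        return HarmonizationAction.KEPT, False, ""
    if o == (e[1], e[0]):
        return HarmonizationAction.BETA_FLIPPED, True, "effect/other alleles swapped"
    oc = (COMPLEMENT[o[0]], COMPLEMENT[o[1]])
    if oc == e:
        return HarmonizationAction.STRAND_FLIPPED, False, "strand complement"
    if oc == (e[1], e[0]):
        return HarmonizationAction.BETA_FLIPPED, True, "strand complement + swap"
    return HarmonizationAction.DROPPED_INCOMPATIBLE, False, (
        f"outcome alleles {o[0]}/{o[1]} incompatible with exposure {e[0]}/{e[1]}"
    )


def harmonize(
    exposure: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
    palindrome_eaf_window: float = 0.08,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Inner-join exposure and outcome records and align effect alleles.

    See the module docstring for the policy.  Raises
    :class:`NoSharedVariantsError` when the variant intersection is empty.
    """
    if not exposure or not outcome:
        raise ConfigurationError("harmonize requires non-empty exposure and outcome record lists")
    for name, records in (("exposure", exposure), ("outcome", outcome)):
        ids = [r.variant_id for r in records]
        if len(ids) != len(set(ids)):
            raise ConfigurationError(f"duplicate variant_ids in {name} input")

    out_by_id = {r.variant_id: r for r in outcome}
    exp_ids = {r.variant_id for r in exposure}
    if not exp_ids & set(out_by_id):
        raise NoSharedVariantsError(
            f"no shared variants between {exposure_name!r} and {outcome_name!r}"
        )

    instruments: list[HarmonizedInstrument] = []
    audit: list[AuditEntry] = []
    for exp in exposure:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            audit.append(
                AuditEntry(exp.variant_id, HarmonizationAction.DROPPED_MISSING, "absent from outcome")
            )
            continue
        action, flip, detail = _classify(exp, out, palindrome_eaf_window)
        audit.append(AuditEntry(exp.variant_id, action, detail))
        if action not in _RETAINED:
            continue
        Gamma = -out.beta if flip else out.beta
        eaf_out = None if out.eaf is None else (1.0 - out.eaf if flip else out.eaf)
        instruments.append(
            HarmonizedInstrument(
                variant_id=exp.variant_id,
                gamma=exp.beta,
                sigma_gamma=exp.se,
                Gamma=Gamma,
                sigma_Gamma=out.se,
                action=action,
                chromosome=exp.chromosome,
                position=exp.position,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                eaf_exposure=exp.eaf,
                eaf_outcome=eaf_out,
                n_exposure=exp.n,
                n_outcome=out.n,
            )
        )
    for out in outcome:
        if out.variant_id not in exp_ids:
            audit.append(
                AuditEntry(out.variant_id, HarmonizationAction.DROPPED_MISSING, "absent from exposure")
            )

    logger.info(
        "harmonized %s vs %s: %d retained of %d audited variants",
        exposure_name,
        outcome_name,
        len(instruments),
        len(audit),
    )
    return HarmonizedSet(exposure_name, outcome_name, instruments, audit)
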