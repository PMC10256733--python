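"""Parsing, validation, and harmonization of GWAS summary statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mrdiet import (
    ConfigurationError,
    GwasRecord,
    HarmonizationAction,
    NoSharedVariantsError,
    harmonize,
    parse_gwas_frame,
    read_gwas_table,
)
from mrdiet.summary_data import COMPLEMENT


def _record(vid="rs1", ea="A", oa="G", beta=0.1, se=0.01, eaf=0.3, pos=1000, chrom="1", p=1e-9):
    return GwasRecord(
        variant_id=vid, chromosome=chrom, position=pos,
        effect_allele=ea, other_allele=oa, beta=beta, se=se, pvalue=p, eaf=eaf,
    )


def _table(rows, **extra_cols):
    base = {
        "variant_id": [r[0] for r in rows],
        "chromosome": "1",
        "position": [1000 * (i + 1) for i in range(len(rows))],
        "effect_allele": [r[1] for r in rows],
        "other_allele": [r[2] for r in rows],
        "eaf": [r[3] for r in rows],
        "beta": [r[4] for r in rows],
        "se": [r[5] for r in rows],
        "pvalue": 1e-9,
        "n": 1000,
    }
    base.update(extra_cols)
    return pd.DataFrame(base)


class TestParsing:
    def test_well_formed_rows_parse_identically(self, tmp_path):
        frame = _table([("rs1", "a", "g", 0.3, 0.1, 0.01),
                        ("rs2", "C", "T", 0.5, -0.2, 0.02),
                        ("rs3", "G", "A", 0.7, 0.05, 0.03)])
        path = tmp_path / "gwas.tsv"
        frame.to_csv(path, sep="\t", index=False)
        records = read_gwas_table(path)
        assert len(records) == 3
        # alleles are upper-cased
        assert (records[0].effect_allele, records[0].other_allele) == ("A", "G")
        assert records[1].beta == -0.2

    def test_non_positive_se_rejected_with_reason(self):
        frame = _table([("rs1", "A", "G", 0.3, 0.1, 0.0)])
        records, rejections = parse_gwas_frame(frame)
        assert records == []
        assert len(rejections) == 1
        line_no, reason = rejections[0]
        assert line_no == 2 and "non-positive SE" in reason

    def test_unparseable_numeric_rejected_with_line_number(self):
        frame = _table([("rs1", "A", "G", 0.3, "abc", 0.01),
                        ("rs2", "A", "G", 0.3, 0.1, 0.01)])
        records, rejections = parse_gwas_frame(frame)
        assert [r.variant_id for r in records] == ["rs2"]
        assert rejections[0][0] == 2 and "unparseable" in rejections[0][1]

    def test_missing_mandatory_column_is_configuration_error(self):
        frame = _table([("rs1", "A", "G", 0.3, 0.1, 0.01)]).drop(columns=["se"])
        with pytest.raises(ConfigurationError, match="se"):
            parse_gwas_frame(frame)

    def test_column_map_absorbs_catalog_dialects(self):
        frame = _table([("rs1", "A", "G", 0.3, 0.1, 0.01)]).rename(columns={"beta": "hm_beta"})
        records, rejections = parse_gwas_frame(frame, {"beta": "hm_beta"})
        assert not rejections and records[0].beta == 0.1

    def test_missing_eaf_is_allowed(self):
        frame = _table([("rs1", "A", "G", np.nan, 0.1, 0.01)])
        records, rejections = parse_gwas_frame(frame)
        assert not rejections and records[0].eaf is None


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = [_record(ea="A", oa="G", beta=0.10)]
        out = [_record(ea="G", oa="A", beta=0.30, eaf=0.7)]
        hset = harmonize(exp, out)
        (inst,) = hset.instruments
        assert inst.Gamma == pytest.approx(-0.30)
        assert inst.action is HarmonizationAction.BETA_FLIPPED
        assert inst.eaf_outcome == pytest.approx(0.3)

    def test_palindromic_with_ambiguous_eaf_dropped(self):
        exp = [_record(ea="A", oa="T", eaf=0.50)]
        out = [_record(ea="A", oa="T", eaf=0.50)]
        hset = harmonize(exp, out, palindrome_eaf_window=0.08)
        assert len(hset) == 0
        assert hset.audit[0].action is HarmonizationAction.DROPPED_PALINDROMIC

    def test_palindromic_with_informative_eaf_oriented_by_frequency(self):
        exp = [_record(ea="A", oa="T", eaf=0.8, beta=0.1)]
        concordant = harmonize(exp, [_record(ea="A", oa="T", eaf=0.75, beta=0.2)])
        assert concordant.instruments[0].Gamma == pytest.approx(0.2)
        discordant = harmonize(exp, [_record(ea="A", oa="T", eaf=0.25, beta=0.2)])
        assert discordant.instruments[0].Gamma == pytest.approx(-0.2)

    def test_strand_complement_retained_without_sign_change(self):
        exp = [_record(ea="A", oa="G", beta=0.1, eaf=0.3)]
        out = [_record(ea="T", oa="C", beta=0.3, eaf=0.31)]
        hset = harmonize(exp, out)
        (inst,) = hset.instruments
        assert inst.Gamma == pytest.approx(0.3)
        assert inst.action is HarmonizationAction.STRAND_FLIPPED

    def test_all_nonpalindromic_orientations_classified_by_enumeration(self):
        """Brute-force oracle: for every representation of the same variant
        (identity / swap / complement / complement+swap), harmonization must
        recover the original outcome effect."""
        exp = [_record(ea="A", oa="G", beta=0.1, eaf=0.3)]
        true_gamma_out = 0.25
        for swap, comp in itertools.product([False, True], repeat=2):
            ea, oa, beta, eaf = "A", "G", true_gamma_out, 0.3
            if swap:
                ea, oa, beta, eaf = oa, ea, -beta, 1 - eaf
            if comp:
                ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
            hset = harmonize(exp, [_record(ea=ea, oa=oa, beta=beta, eaf=eaf)])
            (inst,) = hset.instruments
            assert inst.Gamma == pytest.approx(true_gamma_out), (swap, comp)
            expected = (
                HarmonizationAction.BETA_FLIPPED if swap
                else HarmonizationAction.STRAND_FLIPPED if comp
                else HarmonizationAction.KEPT
            )
            assert inst.action is expected

    def test_incompatible_alleles_audited_not_silently_lost(self):
        exp = [_record(ea="A", oa="G")]
        out = [_record(ea="A", oa="C"), _record(vid="rs9", ea="A", oa="G")]
        with pytest.raises(NoSharedVariantsError):
            harmonize([_record(vid="rsX")], out)
        hset = harmonize(exp + [_record(vid="rs9")], out)
        actions = {e.variant_id: e.action for e in hset.audit}
        assert actions["rs1"] is HarmonizationAction.DROPPED_INCOMPATIBLE
        assert actions["rs9"] is HarmonizationAction.KEPT

    def test_audit_covers_union_of_inputs_exactly_once(self):
        exp = [_record(vid=f"rs{i}") for i in range(5)]
        out = [_record(vid=f"rs{i}") for i in range(3, 8)]
        hset = harmonize(exp, out)
        assert sorted(e.variant_id for e in hset.audit) == sorted(f"rs{i}" for i in range(8))
        retained = {i.variant_id for i in hset.instruments}
        dropped = {e.variant_id for e in hset.audit if e.action.value.startswith("dropped")}
        assert retained | dropped == {f"rs{i}" for i in range(8)}
        assert not retained & dropped

    def test_harmonization_is_idempotent(self, rng):
        from mrdiet import SimulationTruth, simulate_pair

        truth = SimulationTruth(J=30, beta_true=-0.4, palindromic_fraction=0.2, seed=7)
        exp_df, out_df, _ = simulate_pair(truth)
        exp, _ = parse_gwas_frame(exp_df.astype(str))
        out, _ = parse_gwas_frame(out_df.astype(str))
        first = harmonize(exp, out)
        second = harmonize(*first.to_gwas_records())
        assert len(second) == len(first)
        for a, b in zip(first.instruments, second.instruments):
            assert a.variant_id == b.variant_id
            assert b.action is HarmonizationAction.KEPT
            assert (a.gamma, a.Gamma) == (b.gamma, b.Gamma)

    def test_sign_coherence_under_full_outcome_recoding(self):
        """Recoding every outcome row to its opposite allele orientation
        (swap alleles, negate beta, flip eaf) leaves the harmonized
        numbers identical."""
        exp = [
            _record(vid="rs1", ea="A", oa="G", beta=0.1, eaf=0.3),
            _record(vid="rs2", ea="C", oa="G", beta=0.2, eaf=0.8),  # palindromic
        ]
        out = [
            _record(vid="rs1", ea="A", oa="G", beta=0.3, eaf=0.31),
            _record(vid="rs2", ea="C", oa="G", beta=-0.1, eaf=0.77),
        ]
        recoded = [
            GwasRecord(
                variant_id=r.variant_id, chromosome=r.chromosome, position=r.position,
                effect_allele=r.other_allele, other_allele=r.effect_allele,
                beta=-r.beta, se=r.se, pvalue=r.pvalue, eaf=1 - r.eaf,
            )
            for r in out
        ]
        a = harmonize(exp, out)
        b = harmonize(exp, recoded)
        for ia, ib in zip(a.instruments, b.instruments):
            assert ia.Gamma == pytest.approx(ib.Gamma)
            assert ia.sigma_Gamma == ib.sigma_Gamma
            assert ia.eaf_outcome == pytest.approx(ib.eaf_outcome)

    def test_empty_intersection_names_both_inputs(self):
        with pytest.raises(NoSharedVariantsError, match="fish.*nmosd"):
            harmonize(
                [_record(vid="rs1")], [_record(vid="rs2")],
                exposure_name="fish", outcome_name="nmosd",
            )
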