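"""Isoform classification tests, including a brute-force rule-table oracle."""

import numpy as np
import pytest

from tandemlocus.errors import ModelError
from tandemlocus.formats import AnnotatedLocus, Feature, SeqRecord
from tandemlocus.isoforms import (
    GeneModel,
    ala_fraction,
    build_gene_models,
    census_locus,
    classify_isoform,
    mature_peptide,
    thr_period_score,
)
from tandemlocus.synth import (
    ArrayConfig,
    build_provenance_pair,
    build_tandem_bac,
    design_afp_peptide,
    reverse_translate,
)


def make_gene_locus(protein, signal_aa=0, pro_aa=0, gly_tail=False,
                    gene="g1", two_exons=True):
    """Single-gene locus encoding `protein` with optional signal/propeptide
    annotation (signal in exon 1, intron between signal and rest)."""
    aa = protein + ("G" if gly_tail else "")
    cds = reverse_translate(aa + "*")
    sig_nt, pro_nt = 3 * signal_aa, 3 * pro_aa
    feats = []
    attrs = {"gene_name": gene}
    if signal_aa and two_exons:
        seq = "TTTT" + cds[:sig_nt] + "GTAAAG" + cds[sig_nt:] + "TTTT"
        e1s = 4
        c1 = (e1s, e1s + sig_nt)
        c2s = c1[1] + 6
        c2 = (c2s, c2s + len(cds) - sig_nt)
        feats.append(Feature("L", e1s, c1[1], "+", "exon",
                             dict(attrs, exon_number="1")))
        feats.append(Feature("L", *c1, strand="+", kind="CDS", attributes=dict(attrs)))
        feats.append(Feature("L", *c1, strand="+", kind="signal_peptide",
                             attributes=dict(attrs)))
        feats.append(Feature("L", c2[0], c2[1] + 4, "+", "exon",
                             dict(attrs, exon_number="2")))
        feats.append(Feature("L", *c2, strand="+", kind="CDS", attributes=dict(attrs)))
        if pro_aa:
            feats.append(Feature("L", c2[0], c2[0] + pro_nt, "+",
                                 "propeptide", dict(attrs)))
        feats.append(Feature("L", e1s, c2[1] + 4, "+", "gene", dict(attrs)))
    else:
        seq = "TTTT" + "ACGT" * 11 + "GTAAAG" + cds + "TTTT"
        # exon1 non-coding, exon2 carries the whole CDS
        feats.append(Feature("L", 4, 48, "+", "exon",
                             dict(attrs, exon_number="1")))
        c0 = 54
        feats.append(Feature("L", c0, c0 + len(cds) + 4, "+", "exon",
                             dict(attrs, exon_number="2")))
        feats.append(Feature("L", c0, c0 + len(cds), "+", "CDS", dict(attrs)))
        feats.append(Feature("L", 4, c0 + len(cds) + 4, "+", "gene",
                             dict(attrs)))
    rec = SeqRecord(id="L", seq=seq)
    return AnnotatedLocus(record=rec, features=feats)


class TestMaturePeptide:
    def test_skin_gene_unchanged(self):
        p = design_afp_peptide(37)
        locus = make_gene_locus(p)
        (model,) = build_gene_models(locus)
        out = mature_peptide(model, locus)
        assert out.seq == p
        assert out.seq[0] == "M"  # N-terminal Met retained

    def test_liver_gene_signal_pro_gly_removed(self):
        mature = design_afp_peptide(38).replace("M", "D", 1)
        full = "MKSAILLAVFLLSITQVSEA" + "SPDPAAKA" + mature
        locus = make_gene_locus(full, signal_aa=20, pro_aa=8, gly_tail=True)
        (model,) = build_gene_models(locus)
        out = mature_peptide(model, locus)
        assert out.seq == mature
        assert len(out.seq) == len(full) + 1 - 20 - 8 - 1

    def test_length_conservation(self):
        mature = design_afp_peptide(40).replace("M", "D", 1)
        full = "MKSAILLAVFLLSITQVSEA" + "SPDP" + mature
        locus = make_gene_locus(full, signal_aa=20, pro_aa=4, gly_tail=True)
        (model,) = build_gene_models(locus)
        out = mature_peptide(model, locus)
        assert len(out.seq) + 20 + 4 + 1 == len(full) + 1

    def test_signal_with_noncoding_exon1_is_inconsistent(self):
        p = design_afp_peptide(37)
        locus = make_gene_locus(p)
        (model,) = build_gene_models(locus)
        model.signal_peptide = Feature("L", 4, 10, "+", "signal_peptide", {})
        with pytest.raises(ModelError):
            mature_peptide(model, locus)


class TestPeptideStats:
    def test_periodic_thr_score_one(self):
        # Thr at 0-based 2, 13, 24 -> spacings {11, 11}
        aa = list("A" * 37)
        aa[2] = aa[13] = aa[24] = "T"
        score, pos, n, flag = thr_period_score(
            SeqRecord(id="p", seq="".join(aa), moltype="protein"))
        assert score == 1.0
        assert pos == [2, 13, 24]
        assert n == 2

    def test_mixed_spacings_half(self):
        aa = list("A" * 37)
        aa[2] = aa[13] = aa[20] = "T"
        score, _, _, _ = thr_period_score(
            SeqRecord(id="p", seq="".join(aa), moltype="protein"))
        assert score == 0.5

    def test_too_few_thr(self):
        score, _, _, flag = thr_period_score(
            SeqRecord(id="p", seq="AAAAAAAAAAAAAA", moltype="protein"))
        assert score == 0.0
        assert flag == "too_few_thr"

    def test_ala_fraction_pure(self):
        assert ala_fraction(SeqRecord(id="p", seq="AAAA",
                                      moltype="protein")) == 1.0

    def test_ala_fraction_mature_liver_like(self):
        # the classic 37-aa mature liver peptide is ~62% Ala
        p = "DTASDAAAAAALTAANAKAAAELTAANAAAAAAATAR"
        frac = ala_fraction(SeqRecord(id="p", seq=p, moltype="protein"))
        assert frac == pytest.approx(0.62, abs=0.02)


class TestClassification:
    def test_skin_rule_walkthrough(self):
        # no signal, 38 aa, Ala-rich, periodic Thr -> skin
        locus = make_gene_locus(design_afp_peptide(38))
        (model,) = build_gene_models(locus)
        call = classify_isoform(model, locus)
        assert call.isoform_class == "skin"
        assert call.evidence

    def test_maxi_rule(self):
        mature = design_afp_peptide(195).replace("M", "D", 1)
        full = "MKSAILLAVFLLSITQVSEA" + mature
        locus = make_gene_locus(full, signal_aa=20)
        (model,) = build_gene_models(locus)
        assert classify_isoform(model, locus).isoform_class == "maxi"

    def test_midi_rule(self):
        mature = design_afp_peptide(76).replace("M", "D", 1)
        full = "MKSAILLAVFLLSITQVSEA" + "SPDPAAKA" + mature
        locus = make_gene_locus(full, signal_aa=20, pro_aa=8, gly_tail=True)
        (model,) = build_gene_models(locus)
        assert classify_isoform(model, locus).isoform_class == "midi"

    def test_gig2_like_rule(self):
        rng = np.random.default_rng(3)
        from tandemlocus.synth import design_globular_peptide
        p = design_globular_peptide(rng, 147)
        locus = make_gene_locus(p)
        (model,) = build_gene_models(locus)
        call = classify_isoform(model, locus)
        assert call.isoform_class == "gig2_like"

    def test_pseudogene_short_aperiodic_remnant(self):
        locus = make_gene_locus("MGSDERKLIVNQPFYH")  # 16 aa, no Thr period
        (model,) = build_gene_models(locus)
        assert classify_isoform(model, locus).isoform_class == "pseudogene"

    def test_pseudogene_frameshift(self):
        locus = make_gene_locus(design_afp_peptide(38))
        (model,) = build_gene_models(locus)
        model.has_frameshift = True
        call = classify_isoform(model, locus)
        assert call.isoform_class == "pseudogene"
        assert "frameshift" in call.evidence

    def test_classification_is_pure_function(self):
        locus = make_gene_locus(design_afp_peptide(38))
        (model,) = build_gene_models(locus)
        c1 = classify_isoform(model, locus)
        c2 = classify_isoform(model, locus)
        assert c1.isoform_class == c2.isoform_class
        assert c1.evidence == c2.evidence


def _oracle_classify(has_signal, has_pro, missing_exon1, frameshift,
                     length, ala, period):
    """Independent brute-force re-statement of the rule table."""
    if missing_exon1 or frameshift or (length < 37 and period < 0.5):
        return "pseudogene"
    if ala < 0.15 and 100 <= length <= 200:
        return "gig2_like"
    if ala >= 0.40 and period >= 0.5:
        if has_signal and not has_pro and length >= 120:
            return "maxi"
        if has_signal and has_pro and 60 <= length < 120:
            return "midi"
        if has_signal and has_pro and length < 60:
            return "liver"
        if not has_signal and 37 <= length <= 60:
            return "skin"
    return "unclassified"


class TestOracleEquivalence:
    def test_200_random_gene_models(self):
        """classify_isoform agrees with the independent rule-table oracle
        across 200 random models spanning the rule lattice."""
        rng = np.random.default_rng(77)
        checked = 0
        for _ in range(200):
            has_signal = bool(rng.integers(0, 2))
            has_pro = bool(rng.integers(0, 2)) and has_signal
            length = int(rng.integers(10, 220))
            ala_target = float(rng.choice([0.05, 0.2, 0.5, 0.7]))
            periodic = bool(rng.integers(0, 2))
            # build a peptide hitting the targets
            aa = []
            for i in range(length):
                if periodic and i % 11 == 2:
                    aa.append("T")
                elif rng.random() < ala_target:
                    aa.append("A")
                else:
                    aa.append(rng.choice(list("GSDERKLIVNQPFYHW")))
            mature = "".join(aa)
            sig = "MKSAILLAVFLLSITQVSEA" if has_signal else ""
            pro = "SPDPAAKA" if has_pro else ""
            full = (sig + pro + mature) if has_signal else (
                "M" + mature[1:] if mature else "M")
            locus = make_gene_locus(full, signal_aa=20 if has_signal else 0,
                                    pro_aa=8 if has_pro else 0)
            (model,) = build_gene_models(locus)
            from tandemlocus.isoforms import peptide_features
            pep = mature_peptide(model, locus)
            feats = peptide_features(pep, model)
            expected = _oracle_classify(
                has_signal, has_pro, model.missing_exon1,
                model.has_frameshift, feats.length, feats.ala_fraction,
                feats.period_score)
            got = classify_isoform(model, locus).isoform_class
            assert got == expected, (
                f"signal={has_signal} pro={has_pro} len={feats.length} "
                f"ala={feats.ala_fraction:.2f} period={feats.period_score}"
            )
            checked += 1
        assert checked == 200


class TestCensus:
    def test_fixture_truth_recovered(self):
        cfg = ArrayConfig(n_units=3, unit_len=2_500, flank_left_len=800,
                          flank_right_len=800, vector_len=1_000, seed=7)
        locus, truth = build_tandem_bac(cfg)
        census = census_locus(locus)
        assert census["counts"] == {"liver": 3, "skin": 3}
        assert census["afp_count"] == 6
        for call in census["calls"]:
            assert call.isoform_class == truth.gene_classes[call.gene_id]

    def test_empty_locus(self, rng):
        from tandemlocus.synth import random_dna
        locus = AnnotatedLocus(record=SeqRecord(id="e",
                                                seq=random_dna(rng, 100)))
        census = census_locus(locus)
        assert census["counts"] == {}
        assert census["afp_count"] == 0

    def test_provenance_pair_census(self):
        la, lb, _ = build_provenance_pair(0.85, "replaced", seed=5)
        assert census_locus(la)["counts"] == {"gig2_like": 1}
        assert census_locus(lb)["counts"] == {"skin": 1}

    def test_gene_order_permutation(self):
        cfg = ArrayConfig(n_units=2, unit_len=2_000, flank_left_len=600,
                          flank_right_len=600, vector_len=800, seed=9)
        locus, _ = build_tandem_bac(cfg)
        c1 = census_locus(locus)
        locus.features = list(reversed(locus.features))
        c2 = census_locus(locus)
        assert c1["counts"] == c2["counts"]
        assert [c.gene_id for c in c1["calls"]] == \
               [c.gene_id for c in c2["calls"]]
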