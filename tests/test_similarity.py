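import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tandemlocus.errors import InputError
from tandemlocus.formats import AnnotatedLocus, Feature, SeqRecord
from tandemlocus.similarity import (
    annotate_blocks,
    closest_match_identity,
    dotplot_coords,
    exon_window_matches,
    global_identity,
    local_blocks,
    local_identity,
    make_dna_aligner,
    tandem_period,
)
from tandemlocus.synth import build_provenance_pair, random_dna

DNA = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _mutate(seq, positions):
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = rot[out[p]]
    return "".join(out)


class TestGlobalIdentity:
    def test_identical(self):
        r = global_identity(SeqRecord(id="a", seq="ACGTACGT"),
                            SeqRecord(id="b", seq="ACGTACGT"))
        assert r.identity == 1.0
        assert r.columns == 8

    def test_single_mismatch(self):
        r = global_identity(SeqRecord(id="a", seq="ACGT"),
                            SeqRecord(id="b", seq="ACGA"))
        assert r.identity == pytest.approx(0.75)
        assert (r.matches, r.columns) == (3, 4)

    def test_gap_columns_in_denominator(self):
        r = global_identity(SeqRecord(id="a", seq="ACGTACGT"),
                            SeqRecord(id="b", seq="ACGACGT"))
        assert r.columns == 8
        assert r.matches == 7

    def test_n_never_matches(self):
        r = global_identity(SeqRecord(id="a", seq="ANNT"),
                            SeqRecord(id="b", seq="ANNT"))
        assert r.matches == 2

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            SeqRecord(id="a", seq="")

    def test_moltype_mismatch(self):
        with pytest.raises(InputError):
            global_identity(SeqRecord(id="a", seq="ACGT"),
                            SeqRecord(id="b", seq="MAIV", moltype="protein"))

    @given(a=DNA, b=DNA)
    @settings(max_examples=40, deadline=None)
    def test_symmetry(self, a, b):
        ra = global_identity(SeqRecord(id="a", seq=a), SeqRecord(id="b", seq=b))
        rb = global_identity(SeqRecord(id="b", seq=b), SeqRecord(id="a", seq=a))
        assert ra.identity == pytest.approx(rb.identity)
        assert ra.score == pytest.approx(rb.score)

    def test_columns_at_least_max_len(self, rng):
        a = random_dna(rng, 80)
        b = random_dna(rng, 55)
        r = global_identity(SeqRecord(id="a", seq=a), SeqRecord(id="b", seq=b))
        assert r.columns >= 80


class TestClosestMatch:
    def test_subset_mean_one(self, rng):
        recs = [SeqRecord(id=f"s{i}", seq=random_dna(rng, 50))
                for i in range(4)]
        rows, mean = closest_match_identity(recs[:2], recs)
        assert mean == pytest.approx(1.0)

    def test_single_mismatch_pair(self, rng):
        src = random_dna(rng, 10)
        mut = _mutate(src, [4])
        rows, mean = closest_match_identity(
            [SeqRecord(id="q", seq=mut)], [SeqRecord(id="t", seq=src)])
        assert rows[0][2] == pytest.approx(0.9)

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            closest_match_identity([], [SeqRecord(id="t", seq="ACGT")])


class TestLocalBlocks:
    def test_self_scan_full_length_block(self, rng):
        seq = random_dna(rng, 2_000)
        locus = AnnotatedLocus(record=SeqRecord(id="s", seq=seq))
        blocks = local_blocks(locus, locus, min_len=100, min_identity=0.7)
        main = max(blocks, key=lambda b: b.columns)
        assert main.identity == pytest.approx(1.0)
        assert main.a_interval == (0, 2_000)

    def test_provenance_truth_overlap(self):
        """>=95% of matched bases fall in truth-homologous segments and the
        replaced CDS is <20% covered."""
        la, lb, truth = build_provenance_pair(0.85, "replaced", seed=5)
        blocks = local_blocks(la, lb, min_len=100, min_identity=0.70)
        assert blocks
        hom = np.zeros(len(la.record), bool)
        for seg in truth["homologous_segments"]:
            s, e = truth["segments_a"][seg]
            hom[s:e] = True
        tot = in_hom = 0
        cds_s, cds_e = truth["segments_a"]["cds"]
        cds_cov = np.zeros(cds_e - cds_s, bool)
        for b in blocks:
            s, e = b.a_interval
            tot += e - s
            in_hom += int(hom[s:e].sum())
            os_, oe = max(s, cds_s), min(e, cds_e)
            if oe > os_:
                cds_cov[os_ - cds_s:oe - cds_s] = True
        assert in_hom / tot >= 0.95
        assert cds_cov.mean() < 0.20

    def test_minus_strand_block_found(self, rng):
        core = random_dna(rng, 400)
        a = AnnotatedLocus(record=SeqRecord(
            id="a", seq=random_dna(rng, 300) + core + random_dna(rng, 300)))
        from tandemlocus.formats import revcomp
        b = AnnotatedLocus(record=SeqRecord(
            id="b", seq=random_dna(rng, 200) + revcomp(core) + random_dna(rng, 200)))
        blocks = local_blocks(a, b, min_len=100, min_identity=0.9)
        assert any(blk.b_strand == "-" and blk.columns >= 390
                   for blk in blocks)

    def test_blocks_satisfy_thresholds(self, rng):
        la, lb, _ = build_provenance_pair(0.85, "replaced", seed=8)
        blocks = local_blocks(la, lb, min_len=120, min_identity=0.75)
        for b in blocks:
            assert b.columns >= 120
            assert b.identity >= 0.75

    def test_oracle_equivalence_small_sequences(self, rng):
        """Best block score equals the full-DP local alignment score on
        short inputs with planted homology."""
        aligner = make_dna_aligner("local")
        for trial in range(10):
            core = random_dna(rng, 60)
            a = random_dna(rng, 40) + core + random_dna(rng, 40)
            b = random_dna(rng, 30) + _mutate(core, [5, 20, 44]) + random_dna(rng, 30)
            blocks = local_blocks(
                AnnotatedLocus(record=SeqRecord(id="a", seq=a)),
                AnnotatedLocus(record=SeqRecord(id="b", seq=b)),
                min_len=20, min_identity=0.6, margin=60)
            oracle = aligner.align(a, b).score
            rc_oracle = aligner.align(a, SeqRecord(id="x", seq=b).seq).score
            best = max((blk.score for blk in blocks), default=0)
            assert best == pytest.approx(max(oracle, rc_oracle))

    def test_dotplot_self_symmetric(self, rng):
        seq = random_dna(rng, 400) + random_dna(rng, 100)
        locus = AnnotatedLocus(record=SeqRecord(id="s", seq=seq))
        coords = dotplot_coords(locus, locus)
        pts = {(a, b) for a, b, s in coords if s == "+"}
        assert all((b, a) in pts for a, b in pts)


class TestAnnotateBlocks:
    def _locus(self, rng):
        seq = random_dna(rng, 1_000)
        feats = [
            Feature("L", 100, 200, "+", "exon", {}),
            Feature("L", 200, 500, "+", "intron", {}),
            Feature("L", 500, 700, "+", "exon", {}),
            Feature("L", 520, 700, "+", "CDS", {}),
        ]
        return AnnotatedLocus(record=SeqRecord(id="L", seq=seq), features=feats)

    def _block(self, s, e):
        from tandemlocus.similarity import SimilarityBlock
        return SimilarityBlock(a_interval=(s, e), b_interval=(s, e),
                               b_strand="+", identity=1.0, matches=e - s,
                               columns=e - s, score=e - s)

    def test_block_inside_intron(self, rng):
        locus = self._locus(rng)
        blocks, _ = annotate_blocks([self._block(250, 400)],
                                    locus.features, 1_000)
        assert blocks[0].feature_class == "intron"

    def test_majority_rule_70_30(self, rng):
        locus = self._locus(rng)
        # 70% intron (290..500), 30% CDS (520..610): 210 intron vs 90 CDS
        blocks, _ = annotate_blocks([self._block(290, 590)],
                                    locus.features, 1_000)
        assert blocks[0].feature_class == "intron"

    def test_no_majority_is_mixed(self, rng):
        locus = self._locus(rng)
        # half intron (400..500), half CDS (520..600), gap between
        blocks, _ = annotate_blocks([self._block(400, 600)],
                                    locus.features, 1_000)
        assert blocks[0].feature_class == "mixed"

    def test_provenance_contrast_ratio(self):
        la, lb, _ = build_provenance_pair(0.85, "replaced", seed=5)
        blocks = local_blocks(la, lb, min_len=100, min_identity=0.70)
        blocks, summary = annotate_blocks(blocks, la.features,
                                          len(la.record))
        assert summary.noncoding_to_coding_ratio >= 5


class TestTandemPeriod:
    def test_synthetic_array_period(self, small_bac):
        locus, _ = small_bac
        units = locus.by_kind("repeat_unit")
        pr = tandem_period(locus, (units[0].start, units[-1].end))
        assert pr.has_tandem
        assert abs(pr.raw_period - 2_000) <= 100
        assert pr.period == 2_000

    def test_random_sequence_no_structure(self, rng):
        locus = AnnotatedLocus(record=SeqRecord(id="r",
                                                seq=random_dna(rng, 20_000)))
        pr = tandem_period(locus)
        assert not pr.has_tandem
        assert pr.period is None


class TestExonWindow:
    def test_identical_exon_full_match(self, rng):
        host = random_dna(rng, 400)
        exon = random_dna(rng, 60)
        la = AnnotatedLocus(record=SeqRecord(id="a", seq=host[:200] + exon + host[200:]))
        f = Feature("a", 200, 260, "+", "exon", {})
        lb = AnnotatedLocus(record=SeqRecord(
            id="b", seq=random_dna(rng, 150) + exon + random_dna(rng, 150)))
        res = exon_window_matches(la, f, lb)
        assert res.matches == 60

    def test_44bp_exon_five_substitutions(self, rng):
        host = random_dna(rng, 500)
        exon = random_dna(rng, 44)
        mutated = _mutate(exon, [5, 12, 20, 30, 38])
        la = AnnotatedLocus(record=SeqRecord(id="a", seq=host[:100] + exon + host[100:]))
        f = Feature("a", 100, 144, "+", "exon", {})
        lb = AnnotatedLocus(record=SeqRecord(
            id="b", seq=random_dna(rng, 200) + mutated + random_dna(rng, 200)))
        res = exon_window_matches(la, f, lb)
        assert (res.matches, res.columns) == (39, 44)

    def test_no_similarity_zero_result(self):
        # A-homopolymer vs C-homopolymer: no match on either strand
        la = AnnotatedLocus(record=SeqRecord(id="a", seq="A" * 12))
        f = Feature("a", 0, 12, "+", "exon", {})
        lb = AnnotatedLocus(record=SeqRecord(id="b", seq="C" * 12))
        res = exon_window_matches(la, f, lb)
        assert res.matches == 0
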