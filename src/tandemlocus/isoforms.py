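"""Gene-model derived peptide maturation and isoform classification.

Classes: skin (no signal, short), liver (signal + propeptide, short),
midi (signal + propeptide, intermediate), maxi (signal only, long),
gig2_like (low-Ala, globular length), pseudogene, unclassified.  Rules are
applied in a fixed order and every fired rule is recorded as evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError, ModelError
from .formats import AnnotatedLocus, SeqRecord, translate_cds

# classification thresholds (documented, configurable)
MIN_SKIN_LEN = 37
MAX_SKIN_LEN = 60
MIDI_RANGE = (60, 120)
MAXI_MIN = 120
ALA_RICH = 0.40
ALA_POOR = 0.15
GIG2_LEN_RANGE = (100, 200)
PERIOD_OK = 0.5


@dataclass
class GeneModel:
    gene_id: str
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)
    signal_peptide: object = None
    propeptide: object = None
    mature_feature: object = None
    exon1_coding: bool = False
    has_internal_stop: bool = False
    has_frameshift: bool = False
    missing_exon1: bool = False

    @property
    def has_signal(self) -> bool:
        return self.signal_peptide is not None

    @property
    def has_propeptide(self) -> bool:
        return self.propeptide is not None


@dataclass
class PeptideFeatures:
    length: int
    ala_fraction: float
    thr_positions: list
    period_score: float
    n_period_repeats: int
    has_signal: bool
    has_propeptide: bool


@dataclass
class IsoformCall:
    gene_id: str
    isoform_class: str
    evidence: list
    features: PeptideFeatures | None = None


def build_gene_models(locus: AnnotatedLocus) -> list:
    """Group features by ``gene_name`` into :class:`GeneModel` objects."""
    models = []
    for gene_id in locus.gene_ids():
        feats = locus.gene_features(gene_id)
        exons = sorted((f for f in feats if f.kind == "exon"),
                       key=lambda f: f.start)
        cds = sorted((f for f in feats if f.kind == "CDS"),
                     key=lambda f: f.start)
        if not exons and not cds:
            continue
        sig = next((f for f in feats if f.kind == "signal_peptide"), None)
        pro = next((f for f in feats if f.kind == "propeptide"), None)
        mat = next((f for f in feats if f.kind == "mature_peptide"), None)
        gene_feat = next((f for f in feats if f.kind == "gene"), None)
        attrs = gene_feat.attributes if gene_feat else {}
        exon1_coding = bool(
            exons and cds and any(
                c.start < exons[0].end and c.end > exons[0].start for c in cds
            )
        )
        cds_len = sum(len(c) for c in cds)
        m = GeneModel(
            gene_id=gene_id, exons=exons, cds=cds,
            signal_peptide=sig, propeptide=pro, mature_feature=mat,
            exon1_coding=exon1_coding,
            has_frameshift=(cds_len % 3 != 0) or attrs.get("frameshift") == "true",
            missing_exon1=attrs.get("missing_exon1") == "true" or
                          (bool(cds) and len(exons) < 2 and
                           attrs.get("single_exon") != "true"),
        )
        models.append(m)
    return models


# ---------------------------------------------------------------------------
# Peptide operations
# ---------------------------------------------------------------------------

def _aa_len_within_cds(feature, cds_feats) -> int:
    nt = 0
    for c in cds_feats:
        nt += max(0, min(feature.end, c.end) - max(feature.start, c.start))
    return nt // 3


def mature_peptide(g: GeneModel, locus: AnnotatedLocus,
                   amidation_gly_removal: bool = True) -> SeqRecord:
    """Mature peptide after removing annotated signal/propeptide regions.

    Skin-style genes (no signal) return the full translation: the
    N-terminal Met is retained because acetylation is not a sequence
    change.  With ``amidation_gly_removal`` a C-terminal Gly is dropped.
    """
    if not g.cds:
        raise InputError(f"{g.gene_id}: no CDS")
    if g.has_signal and not g.exon1_coding and g.exons:
        raise ModelError(
            f"{g.gene_id}: signal peptide annotated but exon 1 is non-coding"
        )
    prot = translate_cds(locus, g.cds)
    g.has_internal_stop = "internal_stop=true" in prot.description
    seq = prot.seq
    removed = 0
    if g.has_signal:
        removed += _aa_len_within_cds(g.signal_peptide, g.cds)
    if g.has_propeptide:
        removed += _aa_len_within_cds(g.propeptide, g.cds)
    mature = seq[removed:]
    if g.has_signal and amidation_gly_removal and mature.endswith("G"):
        mature = mature[:-1]
    if not mature:
        raise ModelError(f"{g.gene_id}: nothing left after maturation")
    return SeqRecord(id=g.gene_id, seq=mature, moltype="protein",
                     description=prot.description)


def thr_period_score(p: SeqRecord, period: int = 11):
    """Fraction of consecutive Thr-Thr spacings equal to ``period``.

    Returns ``(score, thr_positions, n_period_repeats, flag)``; with fewer
    than two Thr the score is 0 and the flag is set.
    """
    pos = [i for i, aa in enumerate(p.seq) if aa == "T"]
    if len(pos) < 2:
        return 0.0, pos, 0, "too_few_thr"
    spacings = [b - a for a, b in zip(pos, pos[1:])]
    n_ok = sum(1 for s in spacings if s == period)
    return n_ok / len(spacings), pos, n_ok, ""


def ala_fraction(p: SeqRecord) -> float:
    if not p.seq:
        raise InputError("empty peptide")
    return p.seq.count("A") / len(p.seq)


def peptide_features(p: SeqRecord, g: GeneModel,
                     period: int = 11) -> PeptideFeatures:
    score, pos, n_rep, _flag = thr_period_score(p, period)
    return PeptideFeatures(
        length=len(p.seq), ala_fraction=ala_fraction(p),
        thr_positions=pos, period_score=score, n_period_repeats=n_rep,
        has_signal=g.has_signal, has_propeptide=g.has_propeptide,
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_isoform(g: GeneModel, locus: AnnotatedLocus) -> IsoformCall:
    """Ordered decision rules; every input receives exactly one class."""
    evidence = []
    try:
        pep = mature_peptide(g, locus)
    except (InputError, ModelError) as exc:
        return IsoformCall(g.gene_id, "pseudogene",
                           [f"untranslatable: {exc}"], None)
    feats = peptide_features(pep, g)

    # rule 1: pseudogene
    if g.missing_exon1:
        evidence.append("missing_exon1")
    if g.has_frameshift:
        evidence.append("frameshift")
    if feats.length < MIN_SKIN_LEN and feats.period_score < PERIOD_OK:
        evidence.append(
            f"short_remnant: {feats.length} aa < {MIN_SKIN_LEN} with "
            f"period_score {feats.period_score:.2f}"
        )
    if evidence:
        return IsoformCall(g.gene_id, "pseudogene", evidence, feats)

    # rule 2: gig2-like
    if (feats.ala_fraction < ALA_POOR
            and GIG2_LEN_RANGE[0] <= feats.length <= GIG2_LEN_RANGE[1]):
        evidence.append(
            f"low_ala {feats.ala_fraction:.2f} and length {feats.length} in "
            f"{GIG2_LEN_RANGE}"
        )
        return IsoformCall(g.gene_id, "gig2_like", evidence, feats)

    # rule 3: Ala-rich AFP classes
    if feats.ala_fraction >= ALA_RICH and feats.period_score >= PERIOD_OK:
        evidence.append(f"ala_rich {feats.ala_fraction:.2f}, "
                        f"periodic {feats.period_score:.2f}")
        if g.has_signal and not g.has_propeptide and feats.length >= MAXI_MIN:
            evidence.append(f"signal, no propeptide, length {feats.length} >= "
                            f"{MAXI_MIN}")
            return IsoformCall(g.gene_id, "maxi", evidence, feats)
        if (g.has_signal and g.has_propeptide
                and MIDI_RANGE[0] <= feats.length < MIDI_RANGE[1]):
            evidence.append(f"signal+propeptide, length {feats.length} in "
                            f"{MIDI_RANGE}")
            return IsoformCall(g.gene_id, "midi", evidence, feats)
        if g.has_signal and g.has_propeptide and feats.length < MIDI_RANGE[0]:
            evidence.append(f"signal+propeptide, length {feats.length} < "
                            f"{MIDI_RANGE[0]}")
            return IsoformCall(g.gene_id, "liver", evidence, feats)
        if (not g.has_signal
                and MIN_SKIN_LEN <= feats.length <= MAX_SKIN_LEN):
            evidence.append(f"no signal, length {feats.length} in "
                            f"[{MIN_SKIN_LEN},{MAX_SKIN_LEN}]")
            return IsoformCall(g.gene_id, "skin", evidence, feats)

    return IsoformCall(g.gene_id, "unclassified",
                       evidence or ["no rule fired"], feats)


AFP_CLASSES = ("skin", "liver", "midi", "maxi")


def census_locus(locus: AnnotatedLocus) -> dict:
    """Classify every gene; AFP count = skin+liver+midi+maxi."""
    models = build_gene_models(locus)
    calls = [classify_isoform(m, locus) for m in models]
    counts = {}
    for c in calls:
        counts[c.isoform_class] = counts.get(c.isoform_class, 0) + 1
    afp = sum(counts.get(k, 0) for k in AFP_CLASSES)
    return {
        "counts": dict(sorted(counts.items())),
        "afp_count": afp,
        "calls": sorted(calls, key=lambda c: c.gene_id),
    }
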