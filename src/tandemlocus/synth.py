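"""Synthetic locus/read generators with attached ground truth.

Everything the downstream stages consume can be generated here: a circular
tandem-array BAC molecule, error-bearing long reads, a deletion-derived
allele pair, a "provenance pair" of loci sharing only non-coding scaffold,
and toy multi-species gene-order loci for synteny analysis.  All generators
are deterministic under a fixed seed and attach truth (SNV lists, read
source intervals, homology maps) for oracle-style testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seqnum as sn
from .errors import ConfigError, PlanError
from .formats import AnnotatedLocus, Feature, SeqRecord

# Deterministic reverse-translation table (one codon per amino acid).
_AA2CODON = {
    "A": "GCC", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTC", "P": "CCA",
    "S": "TCC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTC",
    "*": "TAA",
}


def reverse_translate(protein: str) -> str:
    return "".join(_AA2CODON[a] for a in protein)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)
    return sn.decode(codes)


def design_afp_peptide(length: int = 38, period: int = 11) -> str:
    """An Ala-rich peptide with Thr at ``period``-residue intervals.

    Layout mirrors the small antifreeze isoforms: acidic residue at position
    2, periodic Thr along the helix, C-terminal Arg.
    """
    aa = ["A"] * length
    aa[0], aa[1] = "M", "D"
    pos = period - 1
    while pos < length - 1:
        aa[pos] = "T"
        pos += period
    aa[-1] = "R"
    return "".join(aa)


def design_globular_peptide(rng: np.random.Generator, length: int = 147) -> str:
    """A low-Ala globular-style peptide (used for the progenitor-like gene)."""
    pool = list("GSDERKLIVNQPFYHWTCM")
    aa = [pool[i] for i in rng.integers(0, len(pool), size=length)]
    aa[0] = "M"
    # sprinkle ~5% Ala
    n_ala = max(1, round(0.05 * length))
    for p in rng.choice(np.arange(1, length), size=n_ala, replace=False):
        aa[p] = "A"
    return "".join(aa)


_SIGNAL_AA = "MKSAILLAVFLLSITQVSEA"  # 20-aa toy secretory signal
_PRO_AA = "SPDPAAKA"  # 8-aa toy propeptide


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class ArrayConfig:
    vector_len: int = 7_500
    flank_left_len: int = 5_000
    flank_right_len: int = 5_000
    unit_len: int = 11_200
    n_units: int = 12
    per_unit_snv_rate: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ConfigError("n_units must be >= 1")
        for name in ("vector_len", "flank_left_len", "flank_right_len", "unit_len"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0.0 <= self.per_unit_snv_rate <= 1.0:
            raise ConfigError("per_unit_snv_rate must be in [0,1]")


@dataclass
class ReadSimConfig:
    n_reads: int = 1_000
    mean_len: int = 8_000
    sd_len: int = 4_000
    sub_rate: float = 0.08
    ins_rate: float = 0.05
    del_rate: float = 0.02
    min_len: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.mean_len <= self.min_len:
            raise ConfigError("mean_len must exceed min_len")


@dataclass
class ReadSet:
    reads: list
    truth: dict | None = None  # read_id -> [(component, (start, end)), ...]


@dataclass
class BacTruth:
    unit_template: str
    snvs: list  # (unit_index 1-based, pos in unit, ref, alt)
    components: list  # (name, start, end) tiling the molecule
    gene_classes: dict  # gene_name -> truth isoform class


# ---------------------------------------------------------------------------
# Gene cassettes
# ---------------------------------------------------------------------------

def _cassette(rng, gene_name, truth_class, with_signal):
    """Build a two-exon gene cassette: (sequence, relative features).

    Exon 1 is non-coding for the skin-style cassette; for the secreted style
    it carries the full signal-peptide coding sequence (intron phase 0).
    """
    mature = design_afp_peptide(38)
    feats = []
    parts = []
    off = 0

    def emit(seq):
        nonlocal off
        parts.append(seq)
        start = off
        off += len(seq)
        return start, off

    attrs = {"gene_name": gene_name, "isoform_class": truth_class}

    if not with_signal:
        cds_nt = reverse_translate(mature + "*")
        e1 = random_dna(rng, 44)
        emit(e1)
        feats.append(Feature("", 0, 44, "+", "exon", dict(attrs, exon_number="1")))
        intron = "GT" + random_dna(rng, 396) + "AG"
        emit(intron)
        e2_utr5 = random_dna(rng, 20)
        e2_utr3 = random_dna(rng, 60) + "AATAAA" + random_dna(rng, 20)
        s2, _ = emit(e2_utr5)
        c_s, c_e = emit(cds_nt)
        _, e2_end = emit(e2_utr3)
        feats.append(Feature("", s2, e2_end, "+", "exon", dict(attrs, exon_number="2")))
        feats.append(Feature("", c_s, c_e, "+", "CDS", dict(attrs)))
    else:
        cds_aa = _SIGNAL_AA + _PRO_AA + mature.replace("M", "", 1) + "G"
        # drop the designed Met of the mature part; the signal supplies
        # translation initiation, and a C-terminal Gly marks amidation
        cds_nt = reverse_translate(cds_aa + "*")
        sig_nt = 3 * len(_SIGNAL_AA)
        pro_nt = 3 * len(_PRO_AA)
        e1_utr5 = random_dna(rng, 12)
        s1, _ = emit(e1_utr5)
        c1_s, c1_e = emit(cds_nt[:sig_nt])
        feats.append(Feature("", s1, c1_e, "+", "exon", dict(attrs, exon_number="1")))
        feats.append(Feature("", c1_s, c1_e, "+", "CDS", dict(attrs)))
        feats.append(Feature("", c1_s, c1_e, "+", "signal_peptide", dict(attrs)))
        intron = "GT" + random_dna(rng, 396) + "AG"
        emit(intron)
        c2_s, c2_e = emit(cds_nt[sig_nt:])
        e2_utr3 = random_dna(rng, 60) + "AATAAA" + random_dna(rng, 20)
        _, e2_end = emit(e2_utr3)
        feats.append(Feature("", c2_s, e2_end, "+", "exon", dict(attrs, exon_number="2")))
        feats.append(Feature("", c2_s, c2_e, "+", "CDS", dict(attrs)))
        feats.append(
            Feature("", c2_s, c2_s + pro_nt, "+", "propeptide", dict(attrs))
        )
    feats.append(Feature("", 0, off, "+", "gene", dict(attrs)))
    return "".join(parts), feats


def _shift(feats, delta, seq_id):
    out = []
    for f in feats:
        out.append(
            Feature(seq_id, f.start + delta, f.end + delta, f.strand, f.kind,
                    dict(f.attributes))
        )
    return out


def _build_unit_template(rng, unit_len):
    """Random 50% GC unit with an embedded skin-style and liver-style gene.

    Each unit starts with a fixed DraI landmark (TTTAAA) so that the digest
    fragments carrying the gene cassettes are internal to the unit and
    recur once per unit copy (the basis of the Southern intensity oracle).
    """
    skin_seq, skin_feats = _cassette(rng, "SKIN", "skin", with_signal=False)
    liver_seq, liver_feats = _cassette(rng, "LIVER", "liver", with_signal=True)
    pad_needed = unit_len - len(skin_seq) - len(liver_seq)
    if pad_needed < 300:
        raise ConfigError("unit_len too small for the two gene cassettes")
    p1 = pad_needed // 3
    p2 = pad_needed // 3
    p3 = pad_needed - p1 - p2
    landmark = "TTTAAA"
    seq = (
        landmark + random_dna(rng, p1 - len(landmark)) + skin_seq
        + random_dna(rng, p2) + liver_seq
        + landmark + random_dna(rng, p3 - len(landmark))
    )
    feats = _shift(skin_feats, p1, "") + _shift(liver_feats, p1 + len(skin_seq) + p2, "")
    return seq, feats


def _mutate_outside_cds(rng, seq, rate, cds_intervals):
    """Substitute bases at `rate`, never inside CDS intervals; returns
    (new_seq, [(pos, ref, alt), ...])."""
    codes = sn.encode(seq)
    protected = np.zeros(len(codes), dtype=bool)
    for s, e in cds_intervals:
        protected[s:e] = True
    hit = (rng.random(len(codes)) < rate) & ~protected & (codes != 4)
    positions = np.flatnonzero(hit)
    snvs = []
    for pos in positions:
        ref = codes[pos]
        alt = (ref + 1 + rng.integers(0, 3)) % 4
        codes[pos] = alt
        snvs.append((int(pos), sn.decode(np.array([ref], dtype=np.uint8)),
                     sn.decode(np.array([alt], dtype=np.uint8))))
    return sn.decode(codes), snvs


def _build_array(cfg: ArrayConfig, rng):
    """Insert = flank_left + n mutated unit copies + flank_right.

    Returns (sequence, features-relative-to-insert, truth pieces).
    Polymorphisms are placed outside coding cassettes so truth isoform
    classes survive mutation (the real array's units differ mostly in
    non-coding DNA).
    """
    flank_left = random_dna(rng, cfg.flank_left_len)
    flank_right = random_dna(rng, cfg.flank_right_len)
    template, template_feats = _build_unit_template(rng, cfg.unit_len)
    cds_intervals = [(f.start, f.end) for f in template_feats if f.kind == "CDS"]

    parts = [flank_left]
    feats = [
        Feature("", 0, cfg.flank_left_len, ".", "misc", {"component": "flank_left"})
    ]
    snv_truth = []
    gene_classes = {}
    off = cfg.flank_left_len
    for u in range(1, cfg.n_units + 1):
        unit_seq, snvs = _mutate_outside_cds(
            rng, template, cfg.per_unit_snv_rate, cds_intervals
        )
        parts.append(unit_seq)
        feats.append(
            Feature(
                "", off, off + cfg.unit_len, "+", "repeat_unit",
                {
                    "component": "repeat",
                    "unit_index": str(u),
                    "snvs": ",".join(f"{p}:{r}>{a}" for p, r, a in snvs) or ".",
                },
            )
        )
        for p, r, a in snvs:
            snv_truth.append((u, p, r, a))
        for f in _shift(template_feats, off, ""):
            name = f.attributes["gene_name"]
            new_name = ("S" if name == "SKIN" else "L") + str(u)
            f.attributes["gene_name"] = new_name
            f.attributes["unit_index"] = str(u)
            feats.append(f)
            gene_classes[new_name] = f.attributes["isoform_class"]
        off += cfg.unit_len
    parts.append(flank_right)
    feats.append(
        Feature("", off, off + cfg.flank_right_len, ".", "misc",
                {"component": "flank_right"})
    )
    return "".join(parts), feats, template, snv_truth, gene_classes


def build_tandem_bac(cfg: ArrayConfig):
    """Circular BAC molecule: vector + flank + tandem units + flank.

    Returns ``(AnnotatedLocus, BacTruth)``; every injected SNV is recorded
    both as a ``repeat_unit`` feature attribute and in the truth object.
    """
    rng = np.random.default_rng(cfg.seed)
    vector = random_dna(rng, cfg.vector_len)
    insert, insert_feats, template, snvs, gene_classes = _build_array(cfg, rng)
    seq = vector + insert
    seq_id = f"bac_n{cfg.n_units}_seed{cfg.seed}"
    record = SeqRecord(id=seq_id, seq=seq, topology="circular",
                       description="synthetic tandem-array BAC")
    feats = [Feature(seq_id, 0, cfg.vector_len, ".", "misc", {"component": "vector"})]
    feats += _shift(insert_feats, cfg.vector_len, seq_id)
    locus = AnnotatedLocus(record=record, features=feats)
    components = [("vector", 0, cfg.vector_len)]
    for f in feats:
        comp = f.attributes.get("component")
        if comp and comp != "vector":
            components.append((comp, f.start, f.end))
    truth = BacTruth(unit_template=template, snvs=snvs,
                     components=sorted(components, key=lambda c: c[1]),
                     gene_classes=gene_classes)
    return locus, truth


def build_linear_array(cfg: ArrayConfig):
    """Linear allele-style locus (no vector): flank + units + flank."""
    rng = np.random.default_rng(cfg.seed)
    insert, insert_feats, template, snvs, gene_classes = _build_array(cfg, rng)
    seq_id = f"allele_n{cfg.n_units}_seed{cfg.seed}"
    record = SeqRecord(id=seq_id, seq=insert, topology="linear",
                       description="synthetic tandem-array allele")
    feats = _shift(insert_feats, 0, seq_id)
    locus = AnnotatedLocus(record=record, features=feats)
    truth = BacTruth(unit_template=template, snvs=snvs,
                     components=[(f.attributes["component"], f.start, f.end)
                                 for f in feats if "component" in f.attributes],
                     gene_classes=gene_classes)
    return locus, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_errors(codes, cfg: ReadSimConfig, rng):
    n = len(codes)
    out = codes.copy()
    if cfg.sub_rate > 0:
        sub = (rng.random(n) < cfg.sub_rate) & (out != 4)
        shifts = rng.integers(1, 4, size=int(sub.sum()))
        out[sub] = (out[sub] + shifts) % 4
    if cfg.ins_rate > 0 or cfg.del_rate > 0:
        u = rng.random(n)
        del_mask = u < cfg.del_rate
        ins_mask = (~del_mask) & (u < cfg.del_rate + cfg.ins_rate)
        counts = np.ones(n, dtype=np.int64)
        counts[del_mask] = 0
        counts[ins_mask] = 2
        expanded = np.repeat(out, counts)
        if ins_mask.any():
            ends = np.cumsum(counts)
            ins_out_idx = ends[ins_mask] - 1  # second copy slot
            expanded[ins_out_idx] = rng.integers(0, 4, size=len(ins_out_idx))
        out = expanded
    return out


def _truth_intervals(components, mol_len, start, length):
    """Intersect a circular read span with the component tiling."""
    out = []
    pos = 0
    remaining = length
    cur = start % mol_len
    while remaining > 0:
        for name, cs, ce in components:
            if cur < cs or cur >= ce:
                continue
            take = min(ce - cur, remaining)
            out.append((name, (pos, pos + take)))
            pos += take
            remaining -= take
            cur = (cur + take) % mol_len
            break
        else:  # pragma: no cover - tiling is complete by construction
            raise RuntimeError("component tiling has a gap")
    # merge adjacent same-component intervals
    merged = []
    for name, (s, e) in out:
        if merged and merged[-1][0] == name and merged[-1][1][1] == s:
            merged[-1] = (name, (merged[-1][1][0], e))
        else:
            merged.append((name, (s, e)))
    return merged


def simulate_reads(locus: AnnotatedLocus, cfg: ReadSimConfig,
                   components=None) -> ReadSet:
    """Simulate long reads from a circular molecule.

    Start positions are uniform on the circle; lengths log-normal (moment
    matched to ``mean_len``/``sd_len``) truncated to [min_len, molecule
    length].  Truth source intervals are recorded before errors are applied.
    """
    if locus.record.topology != "circular":
        raise ConfigError("simulate_reads requires a circular molecule")
    mol_len = len(locus.record)
    if cfg.mean_len >= mol_len:
        raise ConfigError("mean_len must be smaller than the molecule")
    if components is None:
        components = [
            (f.attributes["component"], f.start, f.end)
            for f in locus.features
            if "component" in f.attributes
        ]
        components.sort(key=lambda c: c[1])
    rng = np.random.default_rng(cfg.seed)
    m, s = float(cfg.mean_len), float(cfg.sd_len)
    sigma2 = np.log(1.0 + (s * s) / (m * m))
    mu = np.log(m) - sigma2 / 2.0
    lengths = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=cfg.n_reads)
    lengths = np.clip(np.round(lengths), cfg.min_len, mol_len).astype(np.int64)
    starts = rng.integers(0, mol_len, size=cfg.n_reads)
    doubled = sn.encode(locus.record.seq + locus.record.seq)
    reads, truth = [], {}
    for i in range(cfg.n_reads):
        start, length = int(starts[i]), int(lengths[i])
        clean = doubled[start : start + length]
        rid = f"read_{i:05d}"
        truth[rid] = _truth_intervals(components, mol_len, start, length)
        noisy = _apply_errors(clean, cfg, rng)
        reads.append(
            SeqRecord(id=rid, seq=sn.decode(noisy),
                      description=f"start={start} len={length}")
        )
    return ReadSet(reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# Allele pair
# ---------------------------------------------------------------------------

def build_allele_pair(cfg: ArrayConfig, deletion_plan=(), divergence: float = 0.02):
    """Allele A (full array) and allele B (A with units deleted + divergence).

    ``deletion_plan`` lists 1-based unit indices removed from allele B.
    Divergence substitutions are applied outside CDS and outside deleted
    spans; truth breakpoints are recorded as ``misc`` features on allele B.
    """
    plan = sorted(set(int(u) for u in deletion_plan))
    if len(plan) != len(list(deletion_plan)):
        raise PlanError("overlapping/duplicate deletions in plan")
    a_locus, a_truth = build_linear_array(cfg)
    for u in plan:
        if not 1 <= u <= cfg.n_units:
            raise PlanError(f"deletion index {u} outside 1..{cfg.n_units}")

    unit_spans = {
        int(f.attributes["unit_index"]): (f.start, f.end)
        for f in a_locus.features
        if f.kind == "repeat_unit"
    }
    delete = sorted(unit_spans[u] for u in plan)
    keep_mask = np.ones(len(a_locus.record), dtype=bool)
    for s, e in delete:
        keep_mask[s:e] = False

    # coordinate shift map: new position = old position - deleted bases before
    removed_before = np.cumsum(~keep_mask)
    seq_b = "".join(
        ch for ch, keep in zip(a_locus.record.seq, keep_mask) if keep
    )
    rng = np.random.default_rng(cfg.seed + 104729)  # distinct stream
    cds_new = []
    feats_b = []
    for f in a_locus.features:
        if not keep_mask[f.start : f.end].all():
            continue
        ns = f.start - int(removed_before[f.start])
        ne = f.end - int(removed_before[f.end - 1]) - (0 if keep_mask[f.end - 1] else 1)
        nf = Feature("", ns, ns + len(f), f.strand, f.kind, dict(f.attributes))
        feats_b.append(nf)
        if f.kind == "CDS":
            cds_new.append((nf.start, nf.end))
    seq_b, snvs = _mutate_outside_cds(rng, seq_b, divergence, cds_new)
    seq_id_b = f"alleleB_n{cfg.n_units}_seed{cfg.seed}"
    for f in feats_b:
        f.seq_id = seq_id_b
    # breakpoint truth
    for i, (s, e) in enumerate(delete, 1):
        bp = s - int(removed_before[s - 1]) if s > 0 else 0
        bp = max(1, bp)
        feats_b.append(
            Feature(seq_id_b, bp - 1, bp, ".", "misc",
                    {"deletion_index": str(i), "deleted_span": f"{s}-{e}"})
        )
    record_b = SeqRecord(id=seq_id_b, seq=seq_b, topology="linear",
                         description="deletion-derived allele")
    b_locus = AnnotatedLocus(record=record_b, features=feats_b)
    truth = {
        "deleted_units": plan,
        "breakpoints": delete,
        "substitutions": snvs,
        "allele_a_truth": a_truth,
    }
    return a_locus, b_locus, truth


# ---------------------------------------------------------------------------
# Provenance pair
# ---------------------------------------------------------------------------

def build_provenance_pair(shared_scaffold_identity: float = 0.85,
                          cds_model: str = "divergent", seed: int = 0):
    """Two single-gene loci sharing non-coding scaffold but not coding DNA.

    Locus A carries a globular low-Ala gene; locus B the derived gene whose
    coding exon 2 is either point-diverged or wholly replaced by a GC-rich
    Ala-codon repeat.  Truth marks which segments are homologous.
    """
    if not 0.5 < shared_scaffold_identity <= 1.0:
        raise ConfigError("shared_scaffold_identity must be in (0.5, 1.0]")
    if cds_model not in ("divergent", "replaced"):
        raise ConfigError(f"unknown cds_model {cds_model!r}")
    rng = np.random.default_rng(seed)

    up = random_dna(rng, 800)
    exon1 = random_dna(rng, 44)
    intron = "GT" + random_dna(rng, 596) + "AG"
    prot_a = design_globular_peptide(rng, 147)
    cds_a = reverse_translate(prot_a + "*")
    utr3 = random_dna(rng, 120) + "AATAAA" + random_dna(rng, 24)
    down = random_dna(rng, 800)

    def assemble(name, cds_nt, segs_mut):
        segs = dict(segs_mut)
        parts, feats, truth_segs = [], [], {}
        off = 0
        attrs = {"gene_name": name}
        for seg_name, seg_seq in (
            ("up_flank", segs["up"]), ("exon1", segs["exon1"]),
            ("intron", segs["intron"]), ("cds", cds_nt),
            ("utr3", segs["utr3"]), ("down_flank", segs["down"]),
        ):
            truth_segs[seg_name] = (off, off + len(seg_seq))
            parts.append(seg_seq)
            off += len(seg_seq)
        e1 = truth_segs["exon1"]
        cds = truth_segs["cds"]
        u3 = truth_segs["utr3"]
        feats.append(Feature("", e1[0], e1[1], "+", "exon",
                             dict(attrs, exon_number="1")))
        feats.append(Feature("", cds[0], u3[1], "+", "exon",
                             dict(attrs, exon_number="2")))
        feats.append(Feature("", cds[0], cds[1], "+", "CDS", dict(attrs)))
        feats.append(Feature("", truth_segs["intron"][0], truth_segs["intron"][1],
                             "+", "intron", dict(attrs)))
        feats.append(Feature("", e1[0], u3[1], "+", "gene", dict(attrs)))
        return "".join(parts), feats, truth_segs

    seq_a, feats_a, segs_a = assemble(
        "GIGLIKE", cds_a,
        {"up": up, "exon1": exon1, "intron": intron, "utr3": utr3, "down": down},
    )

    sub_rate = 1.0 - shared_scaffold_identity
    def mut(s):
        out, _ = _mutate_outside_cds(rng, s, sub_rate, [])
        return out

    if cds_model == "replaced":
        prot_b = design_afp_peptide(38)
        cds_b = reverse_translate(prot_b + "*")
    else:
        cds_b, _ = _mutate_outside_cds(rng, cds_a, 0.30, [])
    seq_b, feats_b, segs_b = assemble(
        "AFPLIKE", cds_b,
        {"up": mut(up), "exon1": mut(exon1), "intron": mut(intron),
         "utr3": mut(utr3), "down": mut(down)},
    )

    id_a, id_b = f"provA_seed{seed}", f"provB_seed{seed}"
    rec_a = SeqRecord(id=id_a, seq=seq_a, description="progenitor-like locus")
    rec_b = SeqRecord(id=id_b, seq=seq_b, description="derived locus")
    for f in feats_a:
        f.seq_id = id_a
    for f in feats_b:
        f.seq_id = id_b
    locus_a = AnnotatedLocus(record=rec_a, features=feats_a)
    locus_b = AnnotatedLocus(record=rec_b, features=feats_b)
    homologous = ["up_flank", "exon1", "intron", "utr3", "down_flank"]
    if cds_model == "divergent":
        homologous.append("cds")
    truth = {
        "segments_a": segs_a,
        "segments_b": segs_b,
        "homologous_segments": homologous,
        "cds_model": cds_model,
    }
    return locus_a, locus_b, truth


# ---------------------------------------------------------------------------
# Synteny scenarios
# ---------------------------------------------------------------------------

def build_synteny_scenario(scenario: dict, focal_family: str = "Gig2",
                           gene_len: int = 300, spacer: int = 100,
                           seed: int = 0) -> dict:
    """Toy loci with genes laid out in the given per-species order.

    ``scenario`` maps species -> ordered gene-name list (or (name, strand)
    tuples).  Duplicate names within one locus are an error except for the
    focal family.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for species, genes in scenario.items():
        if not genes and genes != []:
            raise ConfigError(f"{species}: empty gene list")
        names = []
        entries = []
        for g in genes:
            name, strand = (g if isinstance(g, tuple) else (g, "+"))
            if not name:
                raise ConfigError(f"{species}: empty gene name")
            if (name.lower() in (n.lower() for n in names)
                    and name.lower() != focal_family.lower()):
                raise ConfigError(f"{species}: duplicate gene name {name!r}")
            names.append(name)
            entries.append((name, strand))
        total = spacer + len(entries) * (gene_len + spacer)
        seq = random_dna(rng, max(total, spacer + 1))
        seq_id = f"{species.replace(' ', '_')}_locus"
        feats = []
        off = spacer
        for name, strand in entries:
            feats.append(
                Feature(seq_id, off, off + gene_len, strand, "gene",
                        {"gene_name": name})
            )
            off += gene_len + spacer
        record = SeqRecord(id=seq_id, seq=seq, description=f"toy locus: {species}")
        out[species] = AnnotatedLocus(record=record, features=feats)
    return out
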