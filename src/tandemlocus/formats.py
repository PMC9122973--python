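"""Core sequence/annotation types and file format I/O.

Internal convention: all coordinates are 0-based half-open on the forward
strand.  GFF3 and GenBank feature tables (1-based inclusive) are converted at
the I/O boundary; BED is native.  Reports that echo positions for humans use
1-based inclusive via :func:`to_one_based`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio import SeqIO

from .errors import (
    AlphabetError,
    BoundsError,
    ConfigError,
    FormatError,
    InputError,
    StrandError,
)

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

FEATURE_KINDS = frozenset(
    {
        "gene",
        "exon",
        "CDS",
        "intron",
        "five_prime_UTR",
        "three_prime_UTR",
        "repeat_unit",
        "signal_peptide",
        "propeptide",
        "mature_peptide",
        "probe",
        "pseudogene_fragment",
        "misc",
    }
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named sequence with explicit topology and molecule type."""

    id: str
    seq: str
    topology: str = "linear"  # linear | circular
    description: str = ""
    moltype: str = "dna"  # dna | protein

    def __post_init__(self) -> None:
        if not self.seq:
            raise InputError(f"record {self.id!r}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ConfigError(f"record {self.id!r}: bad topology {self.topology!r}")
        self.seq = self.seq.upper()
        alphabet = DNA_ALPHABET if self.moltype == "dna" else PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: illegal {self.moltype} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Feature:
    """A typed interval on a sequence (0-based half-open, forward strand)."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    kind: str = "misc"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ConfigError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-", "."):
            raise ConfigError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise BoundsError(
                f"feature {self.kind} {self.start}..{self.end}: invalid interval"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedLocus:
    """A sequence plus an ordered feature list; the universal substrate."""

    record: SeqRecord
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            self._check(f)

    def _check(self, f: Feature) -> None:
        if f.end > len(self.record):
            raise BoundsError(
                f"feature {f.kind} {f.start}..{f.end} exceeds sequence "
                f"{self.record.id!r} length {len(self.record)}"
            )

    def add(self, f: Feature) -> None:
        self._check(f)
        self.features.append(f)

    def by_kind(self, kind: str) -> list:
        return [f for f in self.features if f.kind == kind]

    def gene_ids(self) -> list:
        """Distinct gene names, in order of first appearance."""
        seen = []
        for f in self.features:
            g = f.attributes.get("gene_name")
            if g and g not in seen:
                seen.append(g)
        return seen

    def gene_features(self, gene_name: str) -> list:
        return [f for f in self.features if f.attributes.get("gene_name") == gene_name]


def to_one_based(start: int, end: int) -> tuple:
    """Convert an internal interval to 1-based inclusive for display."""
    return start + 1, end


def from_one_based(first: int, last: int) -> tuple:
    """Convert 1-based inclusive coordinates to the internal convention."""
    return first - 1, last


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path, moltype: str = "dna") -> list:
    """Read a FASTA file into a list of :class:`SeqRecord` (order preserved)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(
                SeqRecord(id=rec.id, seq=str(rec.seq), description=rec.description,
                          moltype=moltype)
            )
        except AlphabetError as exc:
            raise AlphabetError(str(exc)) from None
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list:
    """Read FASTQ; qualities are ignored by the whole pipeline."""
    records = [
        SeqRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTQ records found")
    return records


def read_reads(path) -> list:
    """Read long reads from FASTA or FASTQ, sniffing the first character."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


# ---------------------------------------------------------------------------
# Annotation dialects
# ---------------------------------------------------------------------------

_GFF_KIND_MAP = {
    "five_prime_utr": "five_prime_UTR",
    "three_prime_utr": "three_prime_UTR",
    "cds": "CDS",
    "repeat_region": "repeat_unit",
    "sig_peptide": "signal_peptide",
    "propep": "propeptide",
    "mat_peptide": "mature_peptide",
}


def _norm_kind(raw: str) -> str:
    if raw in FEATURE_KINDS:
        return raw
    return _GFF_KIND_MAP.get(raw.lower(), "misc")


def _parse_gff_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_annotation(path, dialect: str, sequence=None) -> AnnotatedLocus:
    """Read annotation into an :class:`AnnotatedLocus`.

    Parameters
    ----------
    path:
        Annotation file (GFF3, BED6, or GenBank flat file).
    dialect:
        One of ``gff3``, ``bed``, ``genbank_feature_table``.
    sequence:
        A :class:`SeqRecord` or FASTA path supplying the sequence for the
        GFF3/BED dialects (GenBank embeds its own via ORIGIN).
    """
    if dialect == "gff3":
        return _read_gff3(path, sequence)
    if dialect == "bed":
        return _read_bed(path, sequence)
    if dialect == "genbank_feature_table":
        return _read_genbank(path)
    raise ConfigError(f"unknown annotation dialect {dialect!r}")


def _resolve_sequence(sequence) -> SeqRecord:
    if sequence is None:
        raise ConfigError("this dialect requires a sidecar sequence")
    if isinstance(sequence, SeqRecord):
        return sequence
    records = read_fasta(sequence)
    return records[0]


def _read_gff3(path, sequence) -> AnnotatedLocus:
    record = _resolve_sequence(sequence)
    locus = AnnotatedLocus(record=record)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}: bad GFF3 line: {line[:80]}")
            seqid, _src, kind, start1, end1, _score, strand, _phase, attr = cols[:9]
            start, end = from_one_based(int(start1), int(end1))
            feat = Feature(
                seq_id=seqid,
                start=start,
                end=end,
                strand=strand if strand in "+-" else ".",
                kind=_norm_kind(kind),
                attributes=_parse_gff_attributes(attr),
            )
            if feat.end > len(record):
                raise BoundsError(
                    f"{path}: feature {attr[:40]!r} out of bounds "
                    f"({feat.start}..{feat.end} > {len(record)})"
                )
            locus.add(feat)
    return locus


def _read_bed(path, sequence) -> AnnotatedLocus:
    record = _resolve_sequence(sequence)
    locus = AnnotatedLocus(record=record)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: bad BED line: {line[:80]}")
            seqid = cols[0]
            start, end = int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            attrs = {"gene_name": name} if name else {}
            feat = Feature(seq_id=seqid, start=start, end=end, strand=strand,
                           kind="misc", attributes=attrs)
            if feat.end > len(record):
                raise BoundsError(f"{path}: BED feature {name!r} out of bounds")
            locus.add(feat)
    return locus


_GB_KIND_MAP = {
    "gene": "gene",
    "exon": "exon",
    "CDS": "CDS",
    "intron": "intron",
    "5'UTR": "five_prime_UTR",
    "3'UTR": "three_prime_UTR",
    "repeat_region": "repeat_unit",
    "sig_peptide": "signal_peptide",
    "propeptide": "propeptide",
    "mat_peptide": "mature_peptide",
}


def _read_genbank(path) -> AnnotatedLocus:
    recs = list(SeqIO.parse(str(path), "genbank"))
    if not recs:
        raise FormatError(f"{path}: no GenBank records found")
    rec = recs[0]
    topology = rec.annotations.get("topology", "linear")
    record = SeqRecord(id=rec.id or rec.name, seq=str(rec.seq),
                       topology=topology if topology in ("linear", "circular") else "linear",
                       description=rec.description or "")
    locus = AnnotatedLocus(record=record)
    for feat in rec.features:
        if feat.type == "source":
            continue
        kind = _GB_KIND_MAP.get(feat.type, "misc")
        strand = {1: "+", -1: "-"}.get(feat.location.strand, ".")
        qual = {k: v[0] if isinstance(v, list) and v else str(v)
                for k, v in feat.qualifiers.items()}
        gene = qual.get("gene") or qual.get("locus_tag") or qual.get("label")
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        multi = len(parts) > 1
        for i, part in enumerate(parts):
            attrs = dict(qual)
            if gene:
                attrs["gene_name"] = gene
            if multi:
                attrs["part_index"] = str(i)
            # join(..) CDS/exon locations expand to per-part features sharing
            # the gene attribute, mirroring GFF3 exon rows
            f = Feature(seq_id=record.id, start=int(part.start), end=int(part.end),
                        strand=strand, kind=kind, attributes=attrs)
            if f.end > len(record):
                raise BoundsError(f"{path}: feature {feat.type} out of bounds")
            locus.add(f)
    return locus


def write_gff3(path, locus: AnnotatedLocus, source: str = "tandemlocus") -> None:
    """Deterministic GFF3 writer (features sorted by start, end, kind)."""
    feats = sorted(locus.features, key=lambda f: (f.start, f.end, f.kind))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {locus.record.id} 1 {len(locus.record)}\n")
        for f in feats:
            start1, end1 = to_one_based(f.start, f.end)
            attrs = ";".join(f"{k}={v}" for k, v in sorted(f.attributes.items()))
            fh.write(
                "\t".join(
                    [
                        locus.record.id,
                        source,
                        f.kind,
                        str(start1),
                        str(end1),
                        ".",
                        f.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def write_bed(path, locus: AnnotatedLocus) -> None:
    feats = sorted(locus.features, key=lambda f: (f.start, f.end, f.kind))
    with open(path, "w") as fh:
        for f in feats:
            name = f.attributes.get("gene_name", f.kind)
            strand = f.strand if f.strand in "+-" else "."
            fh.write(
                f"{locus.record.id}\t{f.start}\t{f.end}\t{name}\t0\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# Feature sequence extraction and translation
# ---------------------------------------------------------------------------

def extract_feature_seq(locus: AnnotatedLocus, feature, force_revcomp: bool = False):
    """Extract the sequence of a feature (or transcript-ordered feature list).

    Minus-strand features are reverse complemented; a list of features is
    treated as the exons of one transcript, concatenated 5'->3'.  Requesting
    ``force_revcomp`` on an unstranded feature is an error.
    """
    feats = list(feature) if isinstance(feature, (list, tuple)) else [feature]
    if not feats:
        raise InputError("no features to extract")
    strands = {f.strand for f in feats}
    if len(strands) > 1:
        raise StrandError("mixed strands in one transcript")
    strand = strands.pop()
    if force_revcomp and strand == ".":
        raise StrandError("reverse complement requested for unstranded feature")
    for f in feats:
        if f.end > len(locus.record):
            raise BoundsError(f"feature {f.kind} {f.start}..{f.end} out of bounds")
    parts = [locus.record.seq[f.start : f.end] for f in sorted(feats, key=lambda f: f.start)]
    seq = "".join(parts)
    if strand == "-" or force_revcomp:
        seq = revcomp(seq)
    name = feats[0].attributes.get("gene_name", feats[0].kind)
    return SeqRecord(id=name, seq=seq, description=f"{feats[0].kind} extraction")


def extract_interval_one_based(locus: AnnotatedLocus, first: int, last: int) -> SeqRecord:
    """Extract using the 1-based inclusive numbering used in reports."""
    start, end = from_one_based(first, last)
    f = Feature(seq_id=locus.record.id, start=start, end=end, strand="+", kind="probe")
    return extract_feature_seq(locus, f)


def translate_cds(locus: AnnotatedLocus, cds_features) -> SeqRecord:
    """Translate the concatenated CDS of a gene.

    Trailing stop is removed; internal stops are retained as ``*`` and
    flagged in the description (pseudogene evidence).  A CDS length not
    divisible by 3 produces a frame flag and translation of the floor(len/3)
    codons.
    """
    feats = cds_features if isinstance(cds_features, (list, tuple)) else [cds_features]
    feats = [f for f in feats if f.kind == "CDS"]
    if not feats:
        raise InputError("no CDS features supplied")
    strand = feats[0].strand
    ordered = sorted(feats, key=lambda f: f.start, reverse=(strand == "-"))
    parts = []
    for f in ordered:
        s = locus.record.seq[f.start : f.end]
        parts.append(revcomp(s) if strand == "-" else s)
    nt = "".join(parts)
    if len(nt) < 3:
        raise InputError("concatenated CDS shorter than one codon")
    flags = []
    if len(nt) % 3 != 0:
        flags.append("frame_incomplete")
        nt = nt[: len(nt) - (len(nt) % 3)]
    protein = str(Seq(nt).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        flags.append("internal_stop=true")
    if not protein:
        raise InputError("CDS translates to an empty peptide")
    gene = feats[0].attributes.get("gene_name", "cds")
    return SeqRecord(
        id=gene,
        seq=protein,
        description=";".join(flags),
        moltype="protein",
    )
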