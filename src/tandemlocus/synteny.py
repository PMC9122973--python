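"""Microsynteny rows and relocation calls around a focal gene family.

Gene identity is by name string (case-insensitive); contiguous focal genes
collapse to one block so tandem expansions do not change flank calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, InputError
from .formats import AnnotatedLocus


@dataclass
class GeneOrder:
    species: str
    locus_id: str
    genes: list  # ordered (name, strand) tuples
    focal_family: str

    @classmethod
    def from_locus(cls, species: str, locus: AnnotatedLocus,
                   focal_family: str) -> "GeneOrder":
        feats = sorted((f for f in locus.features if f.kind == "gene"),
                       key=lambda f: f.start)
        genes = [(f.attributes.get("gene_name", "?"), f.strand) for f in feats]
        return cls(species=species, locus_id=locus.record.id, genes=genes,
                   focal_family=focal_family)


@dataclass
class SyntenyRow:
    species: str
    locus_id: str
    focal_count: int
    pseudo_count: int
    flank5: list  # nearest-first
    flank3: list
    flagged: bool = False  # focal family absent


@dataclass
class RelocationCall:
    species_pair: tuple
    verdict: str  # same_context | relocated | absent_in_one
    shared_flank5: list = field(default_factory=list)
    shared_flank3: list = field(default_factory=list)
    evidence: str = ""


def _is_focal(name: str, focal: str) -> bool:
    """Focal-family membership by name: exact, numbered (Gig2-3) or
    pseudogene-suffixed (Gig2psi) variants all count."""
    n, f = name.lower(), focal.lower()
    if not n.startswith(f):
        return False
    rest = n[len(f):].lstrip("-_.")
    return rest == "" or rest.isdigit() or rest.startswith("psi")


def flanks(order: GeneOrder, depth: int = 2, pseudo_suffix: str = "psi") -> SyntenyRow:
    """The ``depth`` nearest non-focal genes on each side of the focal block.

    Contiguous focal genes are treated as one block; an absent side gives an
    empty list; a locus without the focal family is returned flagged.
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    names = [g[0] for g in order.genes]
    focal_idx = [i for i, n in enumerate(names)
                 if _is_focal(n, order.focal_family)]
    pseudo_count = sum(1 for i in focal_idx
                       if pseudo_suffix in names[i].lower())
    if not focal_idx:
        return SyntenyRow(order.species, order.locus_id, 0, 0, [], [],
                          flagged=True)
    first, last = min(focal_idx), max(focal_idx)
    flank5 = [names[i] for i in range(first - 1, -1, -1)
              if i not in focal_idx][:depth]
    flank3 = [names[i] for i in range(last + 1, len(names))
              if i not in focal_idx][:depth]
    return SyntenyRow(order.species, order.locus_id, len(focal_idx),
                      pseudo_count, flank5, flank3)


def synteny_table(orders, depth: int = 2) -> list:
    """Rows in input (phylogeny) order; duplicate species+locus is an error."""
    if not orders:
        raise InputError("no gene orders supplied")
    seen = set()
    rows = []
    for o in orders:
        key = (o.species, o.locus_id)
        if key in seen:
            raise InputError(f"duplicate species+locus {key}")
        seen.add(key)
        rows.append(flanks(o, depth=depth))
    return rows


def render_table(rows) -> str:
    """Stable TSV rendering of a synteny table."""
    lines = ["species\tlocus\tfocal_count\tpseudo_count\tflank5\tflank3\tflagged"]
    for r in rows:
        lines.append(
            "\t".join([
                r.species, r.locus_id, str(r.focal_count),
                str(r.pseudo_count), ",".join(r.flank5) or ".",
                ",".join(r.flank3) or ".", "yes" if r.flagged else "no",
            ])
        )
    return "\n".join(lines) + "\n"


def parse_table(text: str) -> list:
    rows = []
    lines = [ln for ln in text.strip().split("\n") if ln]
    for ln in lines[1:]:
        sp, loc, fc, pc, f5, f3, flag = ln.split("\t")
        rows.append(SyntenyRow(
            species=sp, locus_id=loc, focal_count=int(fc),
            pseudo_count=int(pc),
            flank5=[] if f5 == "." else f5.split(","),
            flank3=[] if f3 == "." else f3.split(","),
            flagged=(flag == "yes"),
        ))
    return rows


def relocation_call(a: SyntenyRow, b: SyntenyRow) -> RelocationCall:
    """same_context if both sides share a flank gene; relocated if both
    species have the family but share none; absent_in_one otherwise."""
    pair = (a.species, b.species)
    if a.focal_count == 0 or b.focal_count == 0:
        return RelocationCall(pair, "absent_in_one",
                              evidence="focal family missing in one species")
    lower = lambda xs: {x.lower() for x in xs}
    s5 = sorted(lower(a.flank5) & lower(b.flank5))
    s3 = sorted(lower(a.flank3) & lower(b.flank3))
    if s5 and s3:
        return RelocationCall(pair, "same_context", s5, s3,
                              evidence="shared flanking genes on both sides")
    if not s5 and not s3:
        return RelocationCall(pair, "relocated",
                              evidence="no shared flank gene on either side")
    return RelocationCall(pair, "absent_in_one", s5, s3,
                          evidence="shared flank on one side only")
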