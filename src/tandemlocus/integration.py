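"""Opt-in integration analyses on locally cached GenBank records.

The pipeline never downloads; callers point :func:`accession_dir` at a
directory containing pre-fetched flat files (``<ACCESSION>.gb``).  Each
``target_*`` function recomputes one published quantity from those records
with the toolkit's own operations.  Sidecar GFF3 annotation named
``<ACCESSION>.gff3`` overrides embedded features when present.
"""

from __future__ import annotations

import os
import re
from collections import Counter
from pathlib import Path

from .formats import (
    AnnotatedLocus,
    extract_feature_seq,
    read_annotation,
    read_fasta,
    translate_cds,
)
from .isoforms import build_gene_models, census_locus, mature_peptide
from .similarity import (
    closest_match_identity,
    exon_window_matches,
    global_identity,
    tandem_period,
)

ACCESSION_ENV = "TANDEMLOCUS_ACCESSIONS"
AFP_ALLELE1 = "OK041463"
AFP_ALLELE2 = "OK041464"
GIG2_LOCUS = "OK041465"


def accession_dir(default: str | Path = "accessions") -> Path | None:
    """Directory holding cached records, or None when unavailable."""
    cand = Path(os.environ.get(ACCESSION_ENV, default))
    return cand if cand.is_dir() else None


def have_accessions(*accs: str, directory=None) -> bool:
    d = directory or accession_dir()
    if d is None:
        return False
    return all((d / f"{a}.gb").is_file() for a in accs)


def load_locus(acc: str, directory=None) -> AnnotatedLocus:
    d = directory or accession_dir()
    if d is None:
        raise FileNotFoundError("no accession cache directory")
    locus = read_annotation(d / f"{acc}.gb", "genbank_feature_table")
    sidecar = d / f"{acc}.gff3"
    if sidecar.is_file():
        locus = read_annotation(sidecar, "gff3", locus.record)
    return locus


def _afp_cds_groups(locus: AnnotatedLocus) -> dict:
    """gene name -> CDS feature list for AFP-style gene names."""
    groups = {}
    for g in locus.gene_ids():
        cds = [f for f in locus.gene_features(g) if f.kind == "CDS"]
        if cds:
            groups[g] = cds
    return groups


def target_afp_census(directory=None) -> int:
    """t2: intact AFP genes (skin+liver+midi+maxi) in allele 1."""
    locus = load_locus(AFP_ALLELE1, directory)
    return census_locus(locus)["afp_count"]


def target_tandem_period_kb(directory=None) -> float:
    """t4: tandem period of the allele-1 repeat region, in kb (1 decimal)."""
    locus = load_locus(AFP_ALLELE1, directory)
    end = min(len(locus.record), 145_000)
    pr = tandem_period(locus, (0, end))
    if not pr.has_tandem:
        raise ValueError("no tandem structure detected in repeat region")
    return round(pr.raw_period / 1000.0, 1)


def _find_genes(locus, pattern):
    rx = re.compile(pattern, re.IGNORECASE)
    return [g for g in locus.gene_ids() if rx.fullmatch(g)]


def target_maxi_identity_pct(directory=None) -> float:
    """t5: Maxi-1 vs Maxi-2 protein identity, percent."""
    locus = load_locus(AFP_ALLELE1, directory)
    names = _find_genes(locus, r"maxi[-_ ]?1") + _find_genes(locus, r"maxi[-_ ]?2")
    if len(names) != 2:
        raise ValueError(f"could not resolve the two Maxi genes: {names}")
    prots = [translate_cds(locus, [f for f in locus.gene_features(n)
                                   if f.kind == "CDS"]) for n in names]
    return 100.0 * global_identity(prots[0], prots[1]).identity


def target_allele2_cds_mean_identity_pct(directory=None) -> float:
    """t6: mean best DNA identity of allele-2 AFP CDS against allele 1."""
    l1 = load_locus(AFP_ALLELE1, directory)
    l2 = load_locus(AFP_ALLELE2, directory)
    set1 = [extract_feature_seq(l1, cds)
            for cds in _afp_cds_groups(l1).values()]
    set2 = [extract_feature_seq(l2, cds)
            for cds in _afp_cds_groups(l2).values()]
    _, mean = closest_match_identity(set2, set1)
    return 100.0 * mean


def target_exon1_matches(directory=None) -> int:
    """t7: matched bases in the 44-bp exon-1 window, S1 vs Gig2-3."""
    l1 = load_locus(AFP_ALLELE1, directory)
    lg = load_locus(GIG2_LOCUS, directory)
    s1 = _find_genes(l1, r"s[-_ ]?1a?") or _find_genes(l1, r"s1")
    if not s1:
        raise ValueError("cannot resolve gene S1 in allele 1")
    exons = sorted((f for f in l1.gene_features(s1[0]) if f.kind == "exon"),
                   key=lambda f: f.start)
    if not exons:
        raise ValueError("S1 exons not annotated")
    return exon_window_matches(l1, exons[0], lg).matches

def target_gig2_protein_length(directory=None) -> int:
    """t8: common length of the full-length Gig2 translations."""
    locus = load_locus(GIG2_LOCUS, directory)
    lengths = []
    for g, cds in _afp_cds_groups(locus).items():
        try:
            p = translate_cds(locus, cds)
        except Exception:
            continue
        if "internal_stop" not in p.description:
            lengths.append(len(p.seq))
    if not lengths:
        raise ValueError("no translatable Gig2 CDS found")
    full = [n for n in lengths if n >= max(lengths) - 5]
    return Counter(full).most_common(1)[0][0]


def target_midi_mature_length(directory=None) -> int:
    """t9: Midi mature peptide length after signal/propeptide removal."""
    locus = load_locus(AFP_ALLELE1, directory)
    names = _find_genes(locus, r"midi.*")
    if not names:
        raise ValueError("cannot resolve the Midi gene")
    models = {m.gene_id: m for m in build_gene_models(locus)}
    return len(mature_peptide(models[names[0]], locus).seq)


def target_allele2_repeat_region_identity(directory=None) -> tuple:
    """t10: identity (%) of the allele-2 skin/liver-pair region vs the
    allele-1 repeat region, plus the aligned span in kb."""
    l1 = load_locus(AFP_ALLELE1, directory)
    l2 = load_locus(AFP_ALLELE2, directory)
    genes2 = sorted(
        ((g, feats) for g, feats in _afp_cds_groups(l2).items()),
        key=lambda kv: min(f.start for f in kv[1]))
    if len(genes2) < 2:
        raise ValueError("allele 2 lacks the skin/liver gene pair")
    # span the first two genes (S1a, L1a) with generous margins, ~11.9 kb
    starts = [min(f.start for f in feats) for _, feats in genes2[:2]]
    ends = [max(f.end for f in feats) for _, feats in genes2[:2]]
    centre = (min(starts) + max(ends)) // 2
    half = 5_950
    s2 = max(0, centre - half)
    e2 = min(len(l2.record), centre + half)
    region2 = l2.record.seq[s2:e2]
    # locate the homologous repeat copy on allele 1 by seeding with the
    # first kilobase of the allele-2 region
    from .similarity import local_blocks
    probe = AnnotatedLocus(record=type(l2.record)(
        id="probe", seq=region2[:1000]))
    blocks = local_blocks(probe, l1, min_len=300, min_identity=0.8)
    if not blocks:
        raise ValueError("could not anchor allele-2 region on allele 1")
    anchor = max(blocks, key=lambda b: b.score).b_interval[0]
    s1 = max(0, anchor)
    e1 = min(len(l1.record), s1 + (e2 - s2))
    rec1 = type(l1.record)(id="a1", seq=l1.record.seq[s1:e1])
    rec2 = type(l2.record)(id="a2", seq=region2)
    res = global_identity(rec1, rec2)
    return 100.0 * res.identity, round(res.columns / 1000.0, 1)
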