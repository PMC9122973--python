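"""Virtual Southern blot: restriction digest, probe hybridization proxy,
band merging and allele scoring.

Hybridization stringency is modelled as a local-alignment threshold
(default identity >= 0.80 over >= 50 bp); fragments whose sizes differ by
less than the gel merge tolerance (default 5% relative) collapse into one
band whose intensity is the number of merged probe-positive fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EnzymeError, InputError
from .formats import SeqRecord, revcomp
from .similarity import make_dna_aligner, _identity_from_alignment


@dataclass
class Enzyme:
    name: str
    recognition: str
    cut_offset: int  # bases from recognition start, top strand

    def __post_init__(self) -> None:
        self.recognition = self.recognition.upper()
        if "N" in self.recognition or not set(self.recognition) <= set("ACGT"):
            raise EnzymeError(
                f"{self.name}: recognition site must be unambiguous ACGT"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise EnzymeError(f"{self.name}: cut_offset out of range")

    @property
    def palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


DRA_I = Enzyme(name="DraI", recognition="TTTAAA", cut_offset=3)

ENZYME_REGISTRY = {
    "DraI": DRA_I,
    "EcoRI": Enzyme("EcoRI", "GAATTC", 1),
    "BamHI": Enzyme("BamHI", "GGATCC", 1),
    "HindIII": Enzyme("HindIII", "AAGCTT", 1),
    "SspI": Enzyme("SspI", "AATATT", 3),
}


def load_enzyme_registry(path) -> dict:
    """Extend the built-in registry from a TSV (name, recognition, offset)."""
    registry = dict(ENZYME_REGISTRY)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, recognition, offset = line.split("\t")[:3]
            registry[name] = Enzyme(name, recognition, int(offset))
    return registry


@dataclass
class DigestResult:
    cut_positions: list  # 0-based, cut falls between base i-1 and i
    fragments: list  # (start, end, size); circular fragments may wrap
    topology: str
    length: int


@dataclass
class BandPrediction:
    size: int
    intensity: int
    best_probe_identity: float
    fragment_ids: list = field(default_factory=list)


def _find_sites(seq: str, pattern: str):
    out = []
    start = 0
    while True:
        i = seq.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def digest(seq: SeqRecord, enzyme: Enzyme) -> DigestResult:
    """All cut positions on the molecule, fragments per topology."""
    if seq.moltype != "dna":
        raise InputError("digest requires a DNA sequence")
    s = seq.seq
    cuts = {i + enzyme.cut_offset for i in _find_sites(s, enzyme.recognition)}
    if not enzyme.palindromic:
        # site on the bottom strand: recognition reads as its revcomp on top
        rc = revcomp(enzyme.recognition)
        for i in _find_sites(s, rc):
            cuts.add(i + len(enzyme.recognition) - enzyme.cut_offset)
    n = len(s)
    cut_list = sorted(c for c in cuts if 0 < c < n)
    if seq.topology == "linear":
        edges = [0] + cut_list + [n]
        fragments = [(a, b, b - a) for a, b in zip(edges, edges[1:])]
    else:
        if not cut_list:
            fragments = [(0, n, n)]
        else:
            fragments = []
            for a, b in zip(cut_list, cut_list[1:]):
                fragments.append((a, b, b - a))
            a = cut_list[-1]
            b = cut_list[0]
            fragments.append((a, b, n - a + b))  # wrap-around fragment
    return DigestResult(cut_positions=cut_list, fragments=fragments,
                        topology=seq.topology, length=n)


def _fragment_seq(d: DigestResult, seq: str, frag) -> str:
    a, b, size = frag
    if b >= a:
        return seq[a:b]
    return seq[a:] + seq[:b]


def probe_bands(d: DigestResult, seq: SeqRecord, probe: SeqRecord,
                min_identity: float = 0.80, min_span: int = 50,
                gel_merge_tol: float = 0.05,
                min_report_size: int = 200) -> list:
    """Probe-positive fragments merged into gel bands.

    A fragment is positive when its best local alignment to the probe
    (either strand) reaches ``min_identity`` over ``min_span`` columns.
    """
    if len(probe.seq) < min_span:
        raise InputError("probe shorter than min_span")
    aligner = make_dna_aligner("local")
    probes = (probe.seq, revcomp(probe.seq))
    positives = []  # (size, identity, fragment_id)
    for fid, frag in enumerate(d.fragments):
        size = frag[2]
        if size < min_report_size:
            continue
        fseq = _fragment_seq(d, seq.seq, frag)
        best_ident = 0.0
        hit = False
        for p in probes:
            if p in fseq:  # fast path for exact containment
                best_ident = 1.0
                hit = True
                break
            alns = aligner.align(fseq, p)
            try:
                aln = alns[0]
            except IndexError:
                continue
            if aln.score <= 0:
                continue
            res = _identity_from_alignment(aln, fseq, p)
            if res.columns >= min_span and res.identity >= min_identity:
                hit = True
                best_ident = max(best_ident, res.identity)
        if hit:
            positives.append((size, best_ident, fid))
    if not positives:
        return []
    positives.sort(key=lambda x: -x[0])
    bands = []
    current = [positives[0]]
    for p in positives[1:]:
        ref_size = current[-1][0]
        if ref_size > 0 and (ref_size - p[0]) / ref_size < gel_merge_tol:
            current.append(p)
        else:
            bands.append(current)
            current = [p]
    bands.append(current)
    out = []
    for group in bands:
        sizes = [g[0] for g in group]
        out.append(
            BandPrediction(
                size=int(round(float(np.mean(sizes)))),
                intensity=len(group),
                best_probe_identity=max(g[1] for g in group),
                fragment_ids=sorted(g[2] for g in group),
            )
        )
    out.sort(key=lambda b: -b.size)
    return out


def match_alleles(predicted: dict, observed, size_tol: float = 0.05) -> dict:
    """Greedy one-to-one matching of observed band sizes to each allele.

    ``predicted`` maps allele name -> list of BandPrediction (or sizes).
    Score = matched observed / total observed; coverage = matched predicted
    / total predicted.  Unexplained observed bands are reported per allele.
    """
    if not observed:
        raise InputError("observed band list is empty")
    obs = sorted(float(o) for o in observed)
    results = {}
    for allele, bands in predicted.items():
        sizes = sorted(
            float(b.size if isinstance(b, BandPrediction) else b)
            for b in bands
        )
        unmatched_pred = list(sizes)
        matched = 0
        unexplained = []
        for o in obs:
            best = None
            for p in unmatched_pred:
                if abs(np.log(o) - np.log(p)) <= np.log1p(size_tol):
                    if best is None or abs(p - o) < abs(best - o):
                        best = p
            if best is not None:
                unmatched_pred.remove(best)
                matched += 1
            else:
                unexplained.append(o)
        results[allele] = {
            "score": matched / len(obs),
            "coverage": (len(sizes) - len(unmatched_pred)) / len(sizes)
            if sizes else 0.0,
            "unexplained_observed": unexplained,
            "unmatched_predicted": unmatched_pred,
        }
    best_allele = max(results, key=lambda k: (results[k]["score"],
                                              results[k]["coverage"]))
    return {"per_allele": results, "assignment": best_allele}
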