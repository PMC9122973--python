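"""Local/global similarity mapping between loci.

Identity convention, used everywhere: matches / alignment columns, where gap
columns count in the denominator and N never counts as a match.  Blocks from
the seed-and-extend scan are always re-scored by alignment so reported
identities are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _seqnum as sn
from .errors import ConfigError, InputError
from .formats import AnnotatedLocus, SeqRecord, revcomp


@dataclass
class IdentityResult:
    matches: int
    columns: int
    identity: float
    a_span: tuple
    b_span: tuple
    score: float = 0.0


@dataclass
class SimilarityBlock:
    a_interval: tuple
    b_interval: tuple
    b_strand: str
    identity: float
    matches: int
    columns: int
    score: float
    feature_class: str = "unassigned"


@dataclass
class ContrastSummary:
    per_class: dict  # class -> {"matched_bases", "total_bases", "coverage"}
    noncoding_to_coding_ratio: float


# ---------------------------------------------------------------------------
# Aligners
# ---------------------------------------------------------------------------

def make_dna_aligner(mode: str = "global", match: float = 1.0,
                     mismatch: float = -1.0, gap_open: float = -2.0,
                     gap_extend: float = -1.0) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    # treat N as never matching: wildcard scores 0 against everything
    a.wildcard = "N"
    return a


def make_protein_aligner(mode: str = "global", gap_open: float = -10.0,
                         gap_extend: float = -1.0) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def _identity_from_alignment(aln, a_seq: str, b_seq: str) -> IdentityResult:
    t_idx, q_idx = aln.indices
    a_arr = np.frombuffer(a_seq.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b_seq.encode(), dtype=np.uint8)
    both = (t_idx >= 0) & (q_idx >= 0)
    ta = np.where(both, t_idx, 0)
    qa = np.where(both, q_idx, 0)
    eq = (a_arr[ta] == b_arr[qa]) & both
    not_n = (a_arr[ta] != ord("N")) & (b_arr[qa] != ord("N"))
    matches = int((eq & not_n).sum())
    columns = int(len(t_idx))
    t_cov = t_idx[t_idx >= 0]
    q_cov = q_idx[q_idx >= 0]
    a_span = (int(t_cov.min()), int(t_cov.max()) + 1) if len(t_cov) else (0, 0)
    b_span = (int(q_cov.min()), int(q_cov.max()) + 1) if len(q_cov) else (0, 0)
    return IdentityResult(
        matches=matches, columns=columns,
        identity=matches / columns if columns else 0.0,
        a_span=a_span, b_span=b_span, score=float(aln.score),
    )


def global_identity(a: SeqRecord, b: SeqRecord, **scoring) -> IdentityResult:
    """Optimal global alignment identity (gap columns in the denominator).

    Arguments are ordered canonically before aligning so the result is
    exactly symmetric: tie-breaking among co-optimal alignments would
    otherwise let the column count depend on argument order.
    """
    if not a.seq or not b.seq:
        raise InputError("empty sequence")
    if a.moltype != b.moltype:
        raise InputError(f"molecule types differ: {a.moltype} vs {b.moltype}")
    swap = (b.seq, b.id) < (a.seq, a.id)
    first, second = (b, a) if swap else (a, b)
    if a.moltype == "protein":
        aligner = make_protein_aligner("global", **scoring)
    else:
        aligner = make_dna_aligner("global", **scoring)
    aln = aligner.align(first.seq, second.seq)[0]
    res = _identity_from_alignment(aln, first.seq, second.seq)
    if swap:
        res.a_span, res.b_span = res.b_span, res.a_span
    return res


def local_identity(a_seq: str, b_seq: str, moltype: str = "dna") -> IdentityResult:
    if moltype == "protein":
        aligner = make_protein_aligner("local")
    else:
        aligner = make_dna_aligner("local")
    alns = aligner.align(a_seq, b_seq)
    try:
        aln = alns[0]
    except IndexError:
        return IdentityResult(0, 0, 0.0, (0, 0), (0, 0), 0.0)
    if aln.score <= 0:
        return IdentityResult(0, 0, 0.0, (0, 0), (0, 0), float(aln.score))
    return _identity_from_alignment(aln, a_seq, b_seq)


def closest_match_identity(set_a, set_b):
    """Per-a best global identity against set_b, plus the unweighted mean.

    Returns ``(rows, mean)`` with rows of ``(a_id, best_b_id, identity)``.
    """
    if not set_a or not set_b:
        raise InputError("both sets must be non-empty")
    moltypes = {r.moltype for r in list(set_a) + list(set_b)}
    if len(moltypes) > 1:
        raise InputError("molecule-type mismatch between sets")
    rows = []
    for a in set_a:
        best = None
        for b in set_b:
            res = global_identity(a, b)
            if best is None or res.identity > best[2]:
                best = (a.id, b.id, res.identity)
        rows.append(best)
    mean = float(np.mean([r[2] for r in rows]))
    return rows, mean


# ---------------------------------------------------------------------------
# Seed-and-extend local blocks
# ---------------------------------------------------------------------------

def seed_hits(a_seq: str, b_seq: str, seed_len: int = 12):
    """Exact seed matches: list of (a_pos, b_pos, strand)."""
    index = {}
    for j in range(len(b_seq) - seed_len + 1):
        km = b_seq[j : j + seed_len]
        if "N" in km:
            continue
        index.setdefault(km, []).append(j)
    hits = []
    b_rc = revcomp(b_seq)
    for i in range(len(a_seq) - seed_len + 1):
        km = a_seq[i : i + seed_len]
        for j in index.get(km, ()):
            hits.append((i, j, "+"))
    index_rc = {}
    for j in range(len(b_rc) - seed_len + 1):
        km = b_rc[j : j + seed_len]
        if "N" in km:
            continue
        index_rc.setdefault(km, []).append(j)
    for i in range(len(a_seq) - seed_len + 1):
        km = a_seq[i : i + seed_len]
        for j in index_rc.get(km, ()):
            hits.append((i, j, "-"))  # j is a position on revcomp(b)
    return hits


def _chain_hits(hits, max_gap: int = 500, max_diag_drift: int = 60):
    """Greedy diagonal chaining of seed hits -> candidate clusters."""
    clusters = []
    by_strand = {"+": [], "-": []}
    for h in hits:
        by_strand[h[2]].append(h)
    for strand, hs in by_strand.items():
        hs.sort(key=lambda h: (h[0] - h[1], h[0]))
        cur = None
        for a_pos, b_pos, _ in hs:
            d = a_pos - b_pos
            if (cur is not None and abs(d - cur["d"]) <= max_diag_drift
                    and 0 <= a_pos - cur["a_hi"] <= max_gap):
                cur["a_hi"] = max(cur["a_hi"], a_pos)
                cur["b_hi"] = max(cur["b_hi"], b_pos)
                cur["n"] += 1
                cur["d"] = d
            else:
                if cur is not None:
                    clusters.append(cur)
                cur = {"a_lo": a_pos, "a_hi": a_pos, "b_lo": b_pos,
                       "b_hi": b_pos, "d": d, "n": 1, "strand": strand}
        if cur is not None:
            clusters.append(cur)
    # merge clusters on nearby diagonals with overlapping ranges
    return clusters


def local_blocks(a, b, seed_len: int = 12, min_len: int = 100,
                 min_identity: float = 0.70, max_gap: int = 500,
                 margin: int = 100) -> list:
    """Map local homology blocks between two loci (both strands).

    Exact seeds are chained along diagonals; each chain is re-scored by a
    local alignment of the chained region (plus margin) so reported
    identities are exact.  Coordinates are forward-strand on both inputs.
    """
    if seed_len < 8:
        raise ConfigError("seed_len must be >= 8")
    a_seq = a.record.seq if isinstance(a, AnnotatedLocus) else a.seq
    b_seq = b.record.seq if isinstance(b, AnnotatedLocus) else b.seq
    hits = seed_hits(a_seq, b_seq, seed_len)
    clusters = _chain_hits(hits, max_gap=max_gap)
    blocks = []
    for c in clusters:
        span = c["a_hi"] - c["a_lo"] + seed_len
        if span < min_len and c["n"] * seed_len < min_len:
            continue
        a_lo = max(0, c["a_lo"] - margin)
        a_hi = min(len(a_seq), c["a_hi"] + seed_len + margin)
        b_lo = max(0, c["b_lo"] - margin)
        b_hi = min(len(b_seq), c["b_hi"] + seed_len + margin)
        sub_a = a_seq[a_lo:a_hi]
        if c["strand"] == "+":
            sub_b = b_seq[b_lo:b_hi]
        else:
            b_rc = revcomp(b_seq)
            sub_b = b_rc[b_lo:b_hi]
        if sub_a == sub_b:
            n_real = sum(1 for ch in sub_a if ch != "N")
            res = IdentityResult(n_real, len(sub_a), n_real / len(sub_a),
                                 (0, len(sub_a)), (0, len(sub_b)),
                                 float(n_real))
        else:
            res = local_identity(sub_a, sub_b)
        if res.columns < min_len or res.identity < min_identity:
            continue
        a_iv = (a_lo + res.a_span[0], a_lo + res.a_span[1])
        if c["strand"] == "+":
            b_iv = (b_lo + res.b_span[0], b_lo + res.b_span[1])
        else:
            rc_lo = b_lo + res.b_span[0]
            rc_hi = b_lo + res.b_span[1]
            b_iv = (len(b_seq) - rc_hi, len(b_seq) - rc_lo)
        blocks.append(
            SimilarityBlock(
                a_interval=a_iv, b_interval=b_iv, b_strand=c["strand"],
                identity=res.identity, matches=res.matches,
                columns=res.columns, score=res.score,
            )
        )
    blocks = _merge_blocks(blocks)
    blocks.sort(key=lambda blk: blk.a_interval)
    return blocks


def _overlap(x, y) -> int:
    return max(0, min(x[1], y[1]) - max(x[0], y[0]))


def _merge_blocks(blocks, min_frac: float = 0.5):
    """Collapse blocks overlapping >=50% on both axes onto the best scorer."""
    blocks = sorted(blocks, key=lambda b: -b.score)
    kept = []
    for b in blocks:
        redundant = False
        for k in kept:
            if k.b_strand != b.b_strand:
                continue
            oa = _overlap(k.a_interval, b.a_interval)
            ob = _overlap(k.b_interval, b.b_interval)
            la = b.a_interval[1] - b.a_interval[0]
            lb = b.b_interval[1] - b.b_interval[0]
            if la and lb and oa / la >= min_frac and ob / lb >= min_frac:
                redundant = True
                break
        if not redundant:
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# Block annotation and the coding vs non-coding contrast
# ---------------------------------------------------------------------------

_CLASS_PRIORITY = ("coding", "intron", "UTR/non-coding-exon", "intergenic")


def _class_mask(features, length: int) -> np.ndarray:
    """Per-base class index on the a-side: 0 coding, 1 intron, 2 UTR/nc-exon,
    3 intergenic.  CDS wins over exon; intron explicit or inferred none."""
    mask = np.full(length, 3, dtype=np.int8)
    for f in features:
        if f.kind == "exon":
            mask[f.start : f.end] = np.where(mask[f.start : f.end] == 3, 2,
                                             mask[f.start : f.end])
        elif f.kind in ("five_prime_UTR", "three_prime_UTR"):
            mask[f.start : f.end] = 2
    for f in features:
        if f.kind == "intron":
            mask[f.start : f.end] = 1
    for f in features:
        if f.kind == "CDS":
            mask[f.start : f.end] = 0
    return mask


def annotate_blocks(blocks, a_features, a_length: int,
                    majority: float = 0.60):
    """Classify blocks by majority base overlap against a-side features.

    Returns ``(blocks, ContrastSummary)``; blocks get ``feature_class`` set
    ("mixed" when no class reaches the majority fraction).  The summary
    apportions each block's matched bases across classes by overlap.
    """
    mask = _class_mask(a_features, a_length)
    totals = {c: int((mask == i).sum()) for i, c in enumerate(_CLASS_PRIORITY)}
    matched = {c: 0.0 for c in _CLASS_PRIORITY}
    for b in blocks:
        s, e = b.a_interval
        sub = mask[s:e]
        if len(sub) == 0:
            b.feature_class = "mixed"
            continue
        counts = np.bincount(sub, minlength=4)
        frac = counts / counts.sum()
        top = int(frac.argmax())
        b.feature_class = (_CLASS_PRIORITY[top] if frac[top] >= majority
                           else "mixed")
        for i, c in enumerate(_CLASS_PRIORITY):
            matched[c] += b.identity * counts[i]
    per_class = {}
    for c in _CLASS_PRIORITY:
        tot = totals[c]
        m = min(matched[c], tot)
        per_class[c] = {
            "matched_bases": m,
            "total_bases": tot,
            "coverage": (m / tot) if tot else 0.0,
        }
    noncoding_cov_num = sum(per_class[c]["matched_bases"]
                            for c in ("intron", "UTR/non-coding-exon"))
    noncoding_cov_den = sum(per_class[c]["total_bases"]
                            for c in ("intron", "UTR/non-coding-exon"))
    nc = noncoding_cov_num / noncoding_cov_den if noncoding_cov_den else 0.0
    cd = per_class["coding"]["coverage"]
    ratio = nc / cd if cd > 0 else float("inf") if nc > 0 else 0.0
    return blocks, ContrastSummary(per_class=per_class,
                                   noncoding_to_coding_ratio=ratio)


# ---------------------------------------------------------------------------
# Tandem periodicity
# ---------------------------------------------------------------------------

@dataclass
class PeriodResult:
    has_tandem: bool
    period: int | None  # rounded to nearest 100 bp
    raw_period: int | None
    boundaries: list = field(default_factory=list)
    support: int = 0


def tandem_period(locus, search_region=None, k: int = 16,
                  bin_width: int = 100, min_period: int = 200) -> PeriodResult:
    """Estimate the tandem period from the self-comparison seed diagonal.

    Adjacent occurrences of repeated k-mers vote for their spacing; the
    dominant spacing bin is the period.  Unit boundaries are phased to
    maximise identity between consecutive units.  Returns a "no tandem
    structure" result (not an exception) when there is no dominant
    off-diagonal signal.
    """
    seq = locus.record.seq if isinstance(locus, AnnotatedLocus) else locus.seq
    if search_region is not None:
        s, e = search_region
        seq = seq[s:e]
    else:
        s = 0
    n = len(seq)
    codes = sn.encode(seq)
    vals, valid = sn.kmer_codes(codes, k)
    positions = np.flatnonzero(valid)
    vals = vals[valid]
    order = np.argsort(vals, kind="stable")
    sv = vals[order]
    pos = positions[order]
    dists = []
    run_start = 0
    for i in range(1, len(sv) + 1):
        if i == len(sv) or sv[i] != sv[run_start]:
            if i - run_start > 1:
                p = np.sort(pos[run_start:i])
                d = np.diff(p)
                dists.append(d[d >= min_period])
            run_start = i
    if dists:
        dists = np.concatenate(dists)
    else:
        dists = np.empty(0, dtype=np.int64)
    threshold = max(20, int(0.02 * n))
    if len(dists) < threshold:
        return PeriodResult(has_tandem=False, period=None, raw_period=None)
    bins = (dists // bin_width).astype(np.int64)
    counts = np.bincount(bins)
    top = int(counts.argmax())
    if counts[top] < threshold:
        return PeriodResult(has_tandem=False, period=None, raw_period=None)
    in_bin = dists[bins == top]
    raw = int(np.median(in_bin))
    period = int(round(raw / 100.0)) * 100

    # phase boundaries: maximise identity between consecutive units
    arr = codes
    t = raw
    if n > 2 * t:
        m = (arr[:-t] == arr[t:]) & (arr[:-t] != 4)
        step = max(1, t // 200)
        best_p, best_score = 0, -1.0
        for p in range(0, t, step):
            w = m[p : p + t]
            if len(w) == 0:
                continue
            score = float(w.mean())
            if score > best_score:
                best_p, best_score = p, score
        boundaries = list(range(s + best_p, s + n - t + 1, t))
    else:
        boundaries = []
    return PeriodResult(has_tandem=True, period=period, raw_period=raw,
                        boundaries=boundaries, support=int(counts[top]))


# ---------------------------------------------------------------------------
# Exon-window matching
# ---------------------------------------------------------------------------

def exon_window_matches(a: AnnotatedLocus, a_exon, b, flank: int = 0):
    """Best local match of an exon (+- flank) in another locus.

    Returns an :class:`IdentityResult` whose matches/columns are restricted
    to the exon-only window of the alignment.
    """
    if a_exon.kind != "exon":
        raise InputError("a_exon must be an exon feature")
    s = max(0, a_exon.start - flank)
    e = min(len(a.record), a_exon.end + flank)
    query = a.record.seq[s:e]
    b_seq = b.record.seq if isinstance(b, AnnotatedLocus) else b.seq
    best = None
    for strand, target in (("+", b_seq), ("-", revcomp(b_seq))):
        res = local_identity(query, target)
        if best is None or res.score > best[1].score:
            best = (strand, res)
    strand, res = best
    if res.columns == 0:
        return IdentityResult(0, 0, 0.0, (0, 0), (0, 0), 0.0)
    if flank == 0:
        return res
    # restrict to the exon window of the query
    aligner = make_dna_aligner("local")
    target = b_seq if strand == "+" else revcomp(b_seq)
    aln = aligner.align(query, target)[0]
    t_idx, q_idx = aln.indices
    exon_lo = a_exon.start - s
    exon_hi = a_exon.end - s
    a_arr = np.frombuffer(query.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(target.encode(), dtype=np.uint8)
    inwin = (t_idx >= exon_lo) & (t_idx < exon_hi)
    both = inwin & (q_idx >= 0) & (t_idx >= 0)
    ta = np.where(both, t_idx, 0)
    qa = np.where(both, q_idx, 0)
    eq = (a_arr[ta] == b_arr[qa]) & both
    not_n = (a_arr[ta] != ord("N")) & (b_arr[qa] != ord("N"))
    matches = int((eq & not_n).sum())
    columns = int(inwin.sum())
    return IdentityResult(matches=matches, columns=columns,
                          identity=matches / columns if columns else 0.0,
                          a_span=(a_exon.start, a_exon.end),
                          b_span=res.b_span, score=res.score)


# ---------------------------------------------------------------------------
# Dot plot export
# ---------------------------------------------------------------------------

def dotplot_coords(a, b, seed_len: int = 12):
    """Seed-match coordinates for external plotting (forward-strand coords)."""
    a_seq = a.record.seq if isinstance(a, AnnotatedLocus) else a.seq
    b_seq = b.record.seq if isinstance(b, AnnotatedLocus) else b.seq
    out = []
    for a_pos, b_pos, strand in seed_hits(a_seq, b_seq, seed_len):
        if strand == "+":
            out.append((a_pos, b_pos, "+"))
        else:
            out.append((a_pos, len(b_seq) - b_pos - seed_len, "-"))
    out.sort()
    return out
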