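"""Tandem-array copy number from long-read category counts.

A read set from a circular BAC (vector + flanked tandem array) is classified
read-by-read into {vector, flank, repeat, ambiguous} by error-tolerant
canonical k-mer voting.  The unit count is then the repeat/vector coverage
ratio rescaled by the component lengths:

    n_hat = (C_repeat / C_vector) * (L_vector / L_unit)

with C either base counts (default; unbiased under variable read length) or
read counts.  Uncertainty is a seeded nonparametric bootstrap over reads; an
analytic ratio-of-Poissons SE is emitted alongside for comparison.  Outer
units are resolved separately by anchoring reads to flank sequence and
walking them unit-by-unit against the unit consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from . import _seqnum as sn
from .errors import ConfigError, EstimationError

CATEGORIES = ("vector", "flank", "repeat", "ambiguous")


@dataclass
class ComponentReference:
    """Named component sequences of the BAC molecule."""

    vector: str
    flank_left: str
    flank_right: str
    unit_consensus: str

    @classmethod
    def from_locus(cls, locus, truth=None):
        comps = {}
        for f in locus.features:
            name = f.attributes.get("component")
            if name:
                comps[name] = locus.record.seq[f.start : f.end]
        unit = None
        if truth is not None:
            unit = truth.unit_template
        else:
            units = [f for f in locus.features if f.kind == "repeat_unit"]
            if units:
                u = units[0]
                unit = locus.record.seq[u.start : u.end]
        if not all(k in comps for k in ("vector", "flank_left", "flank_right")):
            raise ConfigError("locus lacks vector/flank component annotation")
        if unit is None:
            raise ConfigError("no repeat unit available for the reference")
        return cls(vector=comps["vector"], flank_left=comps["flank_left"],
                   flank_right=comps["flank_right"], unit_consensus=unit)

    def lengths(self) -> dict:
        return {
            "vector": len(self.vector),
            "flank_left": len(self.flank_left),
            "flank_right": len(self.flank_right),
            "unit": len(self.unit_consensus),
        }


@dataclass
class CategoryCounts:
    read_count: dict
    base_count: dict
    n_reads_total: int
    mode: str = "bases"
    degenerate: bool = False
    # per-read tallies for bootstrap resampling (canonically sorted by id)
    read_ids: list = field(default_factory=list, repr=False)
    per_read_bases: np.ndarray | None = field(default=None, repr=False)
    per_read_category: list = field(default_factory=list, repr=False)


@dataclass
class CopyNumberEstimate:
    n_hat: float
    se: float
    ci95: tuple
    mode: str
    B: int
    n_reads_used: int
    se_poisson: float = float("nan")
    category_counts: CategoryCounts | None = None


@dataclass
class AnchoredResolution:
    units_resolved_left: float
    units_resolved_right: float
    variant_calls: list  # (unit_index, pos_in_unit, ref, alt, support)
    n_anchored_reads: int = 0


# ---------------------------------------------------------------------------
# Read classification
# ---------------------------------------------------------------------------

def _component_kmer_sets(ref: ComponentReference, k: int) -> dict:
    return {
        "vector": sn.kmer_set_both_strands(ref.vector, k),
        "flank": np.unique(np.concatenate([
            sn.kmer_set_both_strands(ref.flank_left, k),
            sn.kmer_set_both_strands(ref.flank_right, k),
        ])),
        "repeat": sn.kmer_set_both_strands(ref.unit_consensus, k),
    }


def _label_table(sets: dict):
    """Combined sorted k-mer table with per-component bit labels.

    One searchsorted against this table replaces three set-membership
    passes; bit i of the label marks membership in component i."""
    keys = np.unique(np.concatenate([sets["vector"], sets["flank"],
                                     sets["repeat"]]))
    labels = np.zeros(len(keys), dtype=np.uint8)
    for bit, name in enumerate(("vector", "flank", "repeat")):
        idx = np.searchsorted(keys, sets[name])
        labels[idx] |= np.uint8(1 << bit)
    return keys, labels


def classify_reads(reads, ref: ComponentReference, k: int = 15,
                   window: int = 500, stride: int = 3) -> CategoryCounts:
    """Classify reads by windowed canonical k-mer voting.

    Each 500-bp window votes for the component sharing the most canonical
    k-mers with it (ties and zero-vote windows are ambiguous).  Base counts
    assign window lengths to the winning category; read counts assign each
    read to its majority (by bases) category.  Deterministic and invariant
    to read order.  ``stride`` subsamples read k-mers; at the default
    window size votes stay dense even at 15% read error.
    """
    if k < 11:
        raise ConfigError("k must be >= 11")
    if stride < 1 or stride > window // 4:
        raise ConfigError("stride must be in [1, window/4]")
    read_list = list(reads.reads) if hasattr(reads, "reads") else list(reads)
    if not read_list:
        raise ConfigError("no reads to classify")
    sets = _component_kmer_sets(ref, k)
    keys, labels = _label_table(sets)

    order = sorted(range(len(read_list)), key=lambda i: read_list[i].id)
    read_ids = [read_list[i].id for i in order]
    per_read_bases = np.zeros((len(order), 4), dtype=np.int64)
    per_read_cat = []

    for row, i in enumerate(order):
        seq = read_list[i].seq
        codes = sn.encode(seq)
        vals, valid = sn.kmer_codes(codes, k)
        vals, valid = vals[::stride], valid[::stride]
        if len(vals) == 0:
            per_read_bases[row, 3] = len(seq)
            per_read_cat.append("ambiguous")
            continue
        idx = np.searchsorted(keys, vals)
        idx[idx == len(keys)] = 0
        lab = np.where((keys[idx] == vals) & valid, labels[idx], 0)
        hits = np.stack([(lab >> b) & 1 for b in range(3)]).astype(np.int32)
        # window aggregation (k-mer i sits at base i*stride)
        n_pos = len(seq)
        win_starts = np.arange(0, n_pos, window)
        edges = np.minimum((win_starts + stride - 1) // stride, len(vals) - 1)
        votes = np.add.reduceat(hits, edges, axis=1)  # 3 x n_windows
        win_lens = np.minimum(win_starts + window, n_pos) - win_starts
        best = votes.argmax(axis=0)
        best_v = votes.max(axis=0)
        sorted_votes = np.sort(votes, axis=0)
        tie = (best_v == 0) | (sorted_votes[-1] == sorted_votes[-2])
        cat = np.where(tie, 3, best)
        per_read_bases[row] += np.bincount(cat, weights=win_lens,
                                           minlength=4).astype(np.int64)
        maj = int(per_read_bases[row].argmax())
        per_read_cat.append(CATEGORIES[maj])

    base_count = {c: int(per_read_bases[:, i].sum()) for i, c in enumerate(CATEGORIES)}
    read_count = {c: per_read_cat.count(c) for c in CATEGORIES}
    degenerate = read_count["ambiguous"] == len(read_list)
    if degenerate:
        warnings.warn("all reads classified ambiguous; estimates will be degenerate")
    return CategoryCounts(
        read_count=read_count, base_count=base_count,
        n_reads_total=len(read_list), degenerate=degenerate,
        read_ids=read_ids, per_read_bases=per_read_bases,
        per_read_category=per_read_cat,
    )


# ---------------------------------------------------------------------------
# Copy-number estimation
# ---------------------------------------------------------------------------

def _point_estimate(c_repeat: float, c_vector: float, l_vector: int,
                    l_unit: int) -> float:
    if c_vector <= 0:
        raise EstimationError("no vector support")
    return (c_repeat / c_vector) * (l_vector / l_unit)


def copy_number_from_counts(c_repeat: float, c_vector: float, l_vector: int,
                            l_unit: int) -> float:
    """Bare ratio estimator (exposed for formula-level tests)."""
    return _point_estimate(c_repeat, c_vector, l_vector, l_unit)


def estimate_copy_number(counts: CategoryCounts, ref: ComponentReference,
                         mode: str = "bases", B: int = 1000,
                         seed: int = 0) -> CopyNumberEstimate:
    """Point estimate with bootstrap SE/CI (resampling reads).

    The ambiguous category is excluded from numerator and denominator.
    Bootstrap resampling indexes reads after a canonical sort by id, so the
    estimate is invariant to input read order under the same seed.
    """
    if mode not in ("bases", "reads"):
        raise ConfigError(f"unknown mode {mode!r}")
    lens = ref.lengths()
    l_vector, l_unit = lens["vector"], lens["unit"]

    if mode == "bases":
        c_rep = counts.base_count["repeat"]
        c_vec = counts.base_count["vector"]
    else:
        c_rep = counts.read_count["repeat"]
        c_vec = counts.read_count["vector"]
    n_hat = _point_estimate(c_rep, c_vec, l_vector, l_unit)

    # analytic ratio-of-Poissons SE on read counts (comparison only)
    n_rep_r = max(counts.read_count["repeat"], 1)
    n_vec_r = max(counts.read_count["vector"], 1)
    se_poisson = n_hat * float(np.sqrt(1.0 / n_rep_r + 1.0 / n_vec_r))

    rng = np.random.default_rng(seed)
    n = counts.n_reads_total
    if mode == "bases":
        contrib = counts.per_read_bases[:, [0, 2]].astype(float)  # vector, repeat
    else:
        cat_idx = np.array([CATEGORIES.index(c) for c in counts.per_read_category])
        contrib = np.stack([(cat_idx == 0), (cat_idx == 2)], axis=1).astype(float)
    boot = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        tot = contrib[idx].sum(axis=0)
        if tot[0] <= 0:
            boot[b] = np.nan
            continue
        boot[b] = (tot[1] / tot[0]) * (l_vector / l_unit)
    ok = boot[~np.isnan(boot)]
    if len(ok) == 0:
        raise EstimationError("bootstrap produced no valid replicates")
    se = float(ok.std(ddof=1)) if len(ok) > 1 else 0.0
    lo, hi = np.percentile(ok, [2.5, 97.5])
    ci95 = (min(float(lo), n_hat), max(float(hi), n_hat))
    return CopyNumberEstimate(
        n_hat=float(n_hat), se=se, ci95=ci95, mode=mode, B=B,
        n_reads_used=n, se_poisson=se_poisson, category_counts=counts,
    )


# ---------------------------------------------------------------------------
# Outer-unit anchoring
# ---------------------------------------------------------------------------

def _anchor_kmers(flank: str, other_seqs, k: int = 31) -> dict:
    """31-mers unique to this flank -> position of k-mer start in flank."""
    flank_set = {}
    for i in range(len(flank) - k + 1):
        km = flank[i : i + k]
        if "N" in km:
            continue
        flank_set.setdefault(km, i)
    other = set()
    for s in other_seqs:
        for i in range(len(s) - k + 1):
            other.add(s[i : i + k])
        rc = _rc(s)
        for i in range(len(rc) - k + 1):
            other.add(rc[i : i + k])
    return {km: pos for km, pos in flank_set.items() if km not in other}


def _rc(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _make_aligner():
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    # Left ends stay anchored (the walk starts at the flank junction, and a
    # periodic target would otherwise allow whole-unit placement shifts);
    # right end gaps are free so the read may stop mid-walk.
    a.right_gap_score = 0
    return a


def anchor_assemble(reads, ref: ComponentReference, min_support: int = 3,
                    anchor_k: int = 31, max_units: int = 64) -> AnchoredResolution:
    """Resolve outer units by anchoring reads to unique flank 31-mers.

    Anchored reads are oriented flank->array and their array portion is
    stacked against a tandem extension of the unit consensus; per-position
    base votes call substitution variants supported by >= ``min_support``
    reads.  Resolution per side is the length of the contiguous prefix (in
    units, fractional) where coverage stays >= ``min_support``.
    """
    read_list = list(reads.reads) if hasattr(reads, "reads") else list(reads)
    unit = ref.unit_consensus
    lu = len(unit)
    sides = {}
    for side in ("left", "right"):
        flank = ref.flank_left if side == "left" else ref.flank_right
        others = [ref.vector, ref.unit_consensus,
                  ref.flank_right if side == "left" else ref.flank_left]
        anchors = _anchor_kmers(flank, others, anchor_k)
        lf = len(flank)
        depth = np.zeros(0, dtype=np.int64)
        votes = {}  # pos -> {base: count}
        n_anchored = 0
        aligner = _make_aligner()
        for rec in read_list:
            seq = rec.seq
            hit = None
            for orient, s in (("fwd", seq), ("rev", _rc(seq))):
                for i in range(0, len(s) - anchor_k + 1, 7):
                    km = s[i : i + anchor_k]
                    if km in anchors:
                        hit = (orient, i, anchors[km])
                        break
                if hit:
                    break
            if hit is None:
                continue
            orient, read_pos, flank_pos = hit
            s = seq if orient == "fwd" else _rc(seq)
            if side == "left":
                # array starts after flank end; distance from anchor to
                # flank end tells where the array begins on the read
                to_junction = lf - flank_pos
                arr_seq = s[read_pos + to_junction :]
            else:
                # for the right flank the array precedes it; flip so the
                # junction is on the left and positions count into the array
                to_junction = flank_pos
                arr_seq = _rc(s[: max(read_pos - to_junction, 0)])
            if len(arr_seq) < 50:
                continue
            n_anchored += 1
            consensus = (unit if side == "left" else _rc(unit))
            n_units_cov = min(int(np.ceil(len(arr_seq) / lu)) + 1, max_units)
            target = consensus * n_units_cov
            aln = aligner.align(target[: len(arr_seq) + lu], arr_seq)[0]
            t_idx, q_idx = aln.indices
            if len(depth) < len(target):
                grown = np.zeros(len(target), dtype=np.int64)
                grown[: len(depth)] = depth
                depth = grown
            for tpos, qpos in zip(t_idx, q_idx):
                if tpos < 0 or qpos < 0:
                    continue
                depth[tpos] += 1
                base = arr_seq[qpos]
                votes.setdefault(int(tpos), {}).setdefault(base, 0)
                votes[int(tpos)][base] += 1
        # resolution: contiguous prefix with depth >= min_support
        if len(depth) == 0 or depth[0] < min_support:
            covered = 0
        else:
            below = np.flatnonzero(depth < min_support)
            covered = int(below[0]) if len(below) else len(depth)
        calls = []
        for pos in sorted(votes):
            if pos >= covered:
                continue
            unit_idx = pos // lu + 1
            pos_in_unit = pos % lu
            consensus = (unit if side == "left" else _rc(unit))
            ref_base = consensus[pos_in_unit]
            for base, cnt in sorted(votes[pos].items()):
                if base != ref_base and cnt >= min_support:
                    if side == "right":
                        # walked in reverse complement; report genomic-strand
                        # bases in unit coordinates counted from the right end
                        comp = str.maketrans("ACGTN", "TGCAN")
                        calls.append((-unit_idx, lu - 1 - pos_in_unit,
                                      ref_base.translate(comp),
                                      base.translate(comp), cnt))
                    else:
                        calls.append((unit_idx, pos_in_unit, ref_base, base, cnt))
        sides[side] = (covered / lu, calls, n_anchored)

    res_left, calls_left, n_left = sides["left"]
    res_right, calls_right, n_right = sides["right"]
    if n_left + n_right == 0:
        warnings.warn("no anchored reads; resolution 0.0/0.0")
    return AnchoredResolution(
        units_resolved_left=float(res_left),
        units_resolved_right=float(res_right),
        variant_calls=sorted(calls_left + calls_right),
        n_anchored_reads=n_left + n_right,
    )
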