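"""Pairwise total average nucleotide identity (tANI) between phage genomes.

tANI is defined here as ``100 * 2 * matched_bases / (len_a + len_b)``: the
number of identically aligned bases between two genomes, normalised by the
mean genome length.  It is symmetric, bounded by 100, and length-aware, in
the spirit of whole-genome intergenomic-similarity tools used for viral
taxonomy (VIRIDIC-like).  The estimator is a classic seed–chain–extend
scheme:

1. find all maximal shared k-mer runs between the two genomes, in both the
   forward and the reverse-complement orientation (prophages integrate on
   either strand, so the better orientation is kept, never both);
2. select the maximum-weight collinear chain of those anchors, trimming
   overlaps so no base is counted twice;
3. align the unanchored gaps between (and beyond) consecutive anchors with
   a fast edit-distance alignment and count the exactly matching bases.

A full Needleman–Wunsch global alignment (match +1, mismatch −1, gap −2)
serves as the exact but slow oracle for validating the estimator; positions
involving ``N`` never count as matches anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import LabeledMatrix, SequenceRecord

__all__ = [
    "SeedMatch",
    "TaniResult",
    "reverse_complement",
    "nw_identity_oracle",
    "seed_matches",
    "chain_seeds",
    "tani",
    "tani_matrix",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedMatch:
    """A maximal exact run shared by ``a`` and one orientation of ``b``.

    ``pos_b`` is an offset into ``b`` itself for forward matches, and into
    ``reverse_complement(b)`` for reverse-complement matches.
    """

    pos_a: int
    pos_b: int
    length: int
    orientation: str  # "forward" | "reverse-complement"


@dataclass(frozen=True)
class TaniResult:
    tani: float
    matched_bases: int
    orientation_used: str


# ---------------------------------------------------------------------------
# Exact oracle

def _make_aligner() -> Align.PairwiseAligner:
    # N scores -1 against everything (including N) so the optimal alignment
    # never gains by pairing ambiguous bases.
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    mat[:, :] = -1.0
    for base in "ACGT":
        mat[base, base] = 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _make_aligner()


def nw_identity_oracle(a: str, b: str) -> float:
    """Percent identity from an exact global alignment.

    Builds the full dynamic-programming table (match +1, mismatch −1,
    gap −2) and returns ``100 * 2 * matches / (len_a + len_b)`` for one
    optimal alignment.  Intended for sequences up to a few kb; this is the
    validation oracle, not the production estimator.
    """
    if not a or not b:
        raise ValueError("nw_identity_oracle requires non-empty sequences")
    alignment = _ALIGNER.align(a.upper(), b.upper())[0]
    matches = 0
    for (sa, ea), (sb, _eb) in zip(*alignment.aligned):
        seg_a = a[sa:ea].upper()
        seg_b = b[sb : sb + (ea - sa)].upper()
        matches += sum(
            1 for x, y in zip(seg_a, seg_b) if x == y and x != "N"
        )
    return 100.0 * 2.0 * matches / (len(a) + len(b))


# ---------------------------------------------------------------------------
# Seeding

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _matches_one_orientation(a: str, b: str, k: int, orientation: str) -> list[SeedMatch]:
    index = _kmer_index(a, k)
    # group shared k-mer hits by diagonal, then merge consecutive hits on a
    # diagonal into maximal runs
    diagonals: dict[int, list[int]] = {}
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        for i in index.get(kmer, ()):
            diagonals.setdefault(i - j, []).append(i)
    out: list[SeedMatch] = []
    for diag, starts in diagonals.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:]:
            if i == prev + 1:
                prev = i
                continue
            out.append(SeedMatch(run_start, run_start - diag, prev - run_start + k, orientation))
            run_start = prev = i
        out.append(SeedMatch(run_start, run_start - diag, prev - run_start + k, orientation))
    out.sort(key=lambda m: (m.pos_a, m.pos_b))
    return out


def seed_matches(a: str, b: str, k: int = 15) -> list[SeedMatch]:
    """All maximal shared k-mer runs between ``a`` and each orientation of
    ``b``; each run reported once with its maximal length."""
    if k < 8:
        raise ValueError("k must be >= 8")
    a, b = a.upper(), b.upper()
    fwd = _matches_one_orientation(a, b, k, "forward")
    rev = _matches_one_orientation(a, reverse_complement(b), k, "reverse-complement")
    return fwd + rev


# ---------------------------------------------------------------------------
# Chaining

def chain_seeds(matches: list[SeedMatch]) -> int:
    """Weight (total bases) of the maximum-weight collinear chain.

    Anchors in a chain must be strictly increasing in both coordinates;
    when a successor overlaps its predecessor in either sequence, its
    contribution is trimmed so no base is counted twice.
    """
    if not matches:
        return 0
    orientations = {m.orientation for m in matches}
    if len(orientations) > 1:
        raise ValueError("chain_seeds requires matches of a single orientation")
    ms = sorted(matches, key=lambda m: (m.pos_a, m.pos_b))
    n = len(ms)
    best = [m.length for m in ms]
    for j in range(n):
        mj = ms[j]
        for i in range(j):
            mi = ms[i]
            if mi.pos_a >= mj.pos_a or mi.pos_b >= mj.pos_b:
                continue
            overlap = max(
                0,
                mi.pos_a + mi.length - mj.pos_a,
                mi.pos_b + mi.length - mj.pos_b,
            )
            gain = mj.length - overlap
            if gain <= 0:
                continue
            cand = best[i] + gain
            if cand > best[j]:
                best[j] = cand
    return max(best)


def _chain_path(matches: list[SeedMatch]) -> list[SeedMatch]:
    """The anchors of the maximum-weight chain (same DP as chain_seeds)."""
    if not matches:
        return []
    ms = sorted(matches, key=lambda m: (m.pos_a, m.pos_b))
    n = len(ms)
    best = [m.length for m in ms]
    back = [-1] * n
    for j in range(n):
        mj = ms[j]
        for i in range(j):
            mi = ms[i]
            if mi.pos_a >= mj.pos_a or mi.pos_b >= mj.pos_b:
                continue
            overlap = max(
                0,
                mi.pos_a + mi.length - mj.pos_a,
                mi.pos_b + mi.length - mj.pos_b,
            )
            gain = mj.length - overlap
            if gain <= 0:
                continue
            if best[i] + gain > best[j]:
                best[j] = best[i] + gain
                back[j] = i
    j = int(np.argmax(best))
    path = []
    while j != -1:
        path.append(ms[j])
        j = back[j]
    return path[::-1]


# ---------------------------------------------------------------------------
# Gap filling

def _count_matches(a: str, b: str) -> int:
    """Exactly matching bases in an edit-distance-optimal alignment of two
    (short) segments; N never matches."""
    if not a or not b:
        return 0
    res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"]
    matches = 0
    i = j = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        length = int(num)
        num = ""
        if ch == "=":
            matches += sum(
                1 for x, y in zip(a[i : i + length], b[j : j + length]) if x == y and x != "N"
            )
            i += length
            j += length
        elif ch == "X":
            i += length
            j += length
        elif ch == "I":  # insertion in target -> consumes b
            j += length
        elif ch == "D":
            i += length
    return matches


def _anchor_matches(anchor: SeedMatch, a: str, b: str) -> int:
    seg_a = a[anchor.pos_a : anchor.pos_a + anchor.length]
    return sum(1 for x in seg_a if x != "N")


def _matched_bases_one_orientation(a: str, b_oriented: str, k: int) -> int:
    matches = _matches_one_orientation(a, b_oriented, k, "any")
    if not matches:
        return 0
    path = _chain_path(matches)
    total = 0
    prev_end_a = prev_end_b = 0
    for anchor in path:
        sa, sb = anchor.pos_a, anchor.pos_b
        # trim anchor start if it overlaps the previous anchor
        trim = max(0, prev_end_a - sa, prev_end_b - sb)
        sa += trim
        sb += trim
        length = anchor.pos_a + anchor.length - sa
        if length <= 0:
            continue
        # fill the unanchored gap before this anchor
        total += _count_matches(a[prev_end_a:sa], b_oriented[prev_end_b:sb])
        total += sum(1 for x in a[sa : sa + length] if x != "N")
        prev_end_a = sa + length
        prev_end_b = sb + length
    # trailing overhangs
    total += _count_matches(a[prev_end_a:], b_oriented[prev_end_b:])
    return total


def tani(a: str, b: str, k: int = 15) -> TaniResult:
    """Estimate tANI between two genomes.

    Both orientations of ``b`` are tried and the better one kept.  Pairs
    sharing no k-mer seed in either orientation report tANI 0 without
    attempting alignment.
    """
    if not a or not b:
        raise ValueError("tani requires non-empty sequences")
    a, b = a.upper(), b.upper()
    scores = {}
    for orientation, b_or in (
        ("forward", b),
        ("reverse-complement", reverse_complement(b)),
    ):
        scores[orientation] = _matched_bases_one_orientation(a, b_or, k)
    orientation = max(scores, key=lambda o: (scores[o], o == "forward"))
    matched = scores[orientation]
    value = 100.0 * 2.0 * matched / (len(a) + len(b))
    return TaniResult(tani=min(value, 100.0), matched_bases=matched, orientation_used=orientation)


def tani_matrix(records: list[SequenceRecord], k: int = 15) -> LabeledMatrix:
    """Symmetric all-against-all tANI matrix (diagonal 100), label order
    preserved from the input."""
    if len(records) < 2:
        raise ValueError("tani_matrix requires at least two records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = tani(records[i].sequence, records[j].sequence, k=k).tani
            values[i, j] = values[j, i] = v
    return LabeledMatrix(ids, values)
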