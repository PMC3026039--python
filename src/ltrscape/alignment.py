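"""Alignment kernels and column-level alignment analytics.

Two layers live here:

* an anchored, affine-gap, x-drop extension DP (numba) used by the
  seed-and-extend homology search — a gap of length g costs
  ``gap_open + gap_ext * g``, and alignment columns involving N score 0;
* a global (end-to-end) copy-vs-consensus alignment built on edlib's
  bit-parallel Needleman–Wunsch, exposed as paired column arrays on which
  identity, pairwise-deletion divergence, gap runs and windowed identity
  are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import edlib
import numpy as np
from numba import njit

from . import seqs

NEG_INF = -(10**9)


@njit(cache=True)
def _xdrop_kernel(a, b, match, mismatch, gap_open, gap_ext, xdrop):
    """Anchored x-drop extension of ``a`` vs ``b`` from their first bases.

    Gotoh three-state DP over an adaptive band; a cell dies when every state
    falls more than ``xdrop`` below the running best.  Returns
    ``(best_score, ai, bj)``: the best alignment of ``a[:ai]`` with
    ``b[:bj]`` over all paths anchored at cell (0, 0).
    """
    la = len(a)
    lb = len(b)
    H = np.full(lb + 1, NEG_INF, dtype=np.int64)
    F = np.full(lb + 1, NEG_INF, dtype=np.int64)  # gap consuming a (vertical)
    best = 0
    bi = 0
    bj = 0
    # row 0: leading gaps in b
    H[0] = 0
    prev_lo = 0
    prev_end = 0
    for j in range(1, lb + 1):
        v = -(gap_open + gap_ext * j)
        if v < best - xdrop:
            break
        H[j] = v
        prev_end = j

    for i in range(1, la + 1):
        ca = a[i - 1]
        cutoff = best - xdrop
        e = NEG_INF  # E state chain within the row
        h_left = NEG_INF  # H[i][j-1]
        diag = NEG_INF  # H[i-1][j-1]
        cur_lo = -1
        cur_end = -1
        j = prev_lo
        while j <= lb:
            inside = prev_lo <= j <= prev_end
            h_up = H[j] if inside else NEG_INF
            f_up = F[j] if inside else NEG_INF
            # vertical gap
            f = NEG_INF
            if f_up != NEG_INF:
                f = f_up - gap_ext
            if h_up != NEG_INF and h_up - gap_open - gap_ext > f:
                f = h_up - gap_open - gap_ext
            # horizontal gap
            if e != NEG_INF:
                e = e - gap_ext
            if h_left != NEG_INF and h_left - gap_open - gap_ext > e:
                e = h_left - gap_open - gap_ext
            # diagonal
            d = NEG_INF
            if j > 0 and diag != NEG_INF:
                cb = b[j - 1]
                if ca == 4 or cb == 4:
                    s = 0
                elif ca == cb:
                    s = match
                else:
                    s = mismatch
                d = diag + s
            h = d
            if e > h:
                h = e
            if f > h:
                h = f
            diag = h_up  # previous row H[j] becomes the diagonal for j+1
            if h < cutoff and e < cutoff and f < cutoff:
                H[j] = NEG_INF
                F[j] = NEG_INF
                h_left = NEG_INF
                e = NEG_INF
                # beyond the previous row's reach nothing can revive the row
                if j > prev_end:
                    break
            else:
                H[j] = h
                F[j] = f
                h_left = h
                if cur_lo < 0:
                    cur_lo = j
                cur_end = j
                if h > best:
                    best = h
                    bi = i
                    bj = j
                    cutoff = best - xdrop
            j += 1
        if cur_lo < 0:
            break
        prev_lo = cur_lo
        prev_end = cur_end
    return best, bi, bj


@dataclass(frozen=True)
class ExtensionResult:
    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int


def extend_anchored(a, b, anchor_a: int, anchor_b: int, scoring) -> ExtensionResult:
    """Gapped x-drop extension in both directions from an anchor pair.

    ``scoring`` is the ScanParams-like object carrying match/mismatch/
    gap_open/gap_ext/x_drop.  The anchor is the first base of an exact seed
    match; the returned intervals are the max-scoring trims on both sides.
    """
    fa = np.ascontiguousarray(a[anchor_a:])
    fb = np.ascontiguousarray(b[anchor_b:])
    fs, fi, fj = _xdrop_kernel(
        fa, fb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_ext, scoring.x_drop
    )
    ba = np.ascontiguousarray(a[:anchor_a][::-1])
    bb = np.ascontiguousarray(b[:anchor_b][::-1])
    bs, bi_, bj_ = _xdrop_kernel(
        ba, bb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_ext, scoring.x_drop
    )
    return ExtensionResult(
        score=int(fs + bs),
        a_start=anchor_a - bi_,
        a_end=anchor_a + fi,
        b_start=anchor_b - bj_,
        b_end=anchor_b + fj,
    )


# ---------------------------------------------------------------------------
# global copy-vs-consensus alignment (edlib) and column analytics


def _cigar_to_columns(cigar: str, query: np.ndarray, target: np.ndarray):
    """Expand an edlib extended CIGAR into paired column code arrays.

    edlib convention: query is the first sequence, target the second;
    'I' consumes query only (gap in target), 'D' consumes target only.
    """
    q_cols = []
    t_cols = []
    qi = ti = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + int(ch)
            continue
        n = num
        num = 0
        if ch in "=XM":
            q_cols.append(query[qi : qi + n])
            t_cols.append(target[ti : ti + n])
            qi += n
            ti += n
        elif ch == "I":
            q_cols.append(query[qi : qi + n])
            t_cols.append(np.full(n, seqs.GAP, dtype=np.uint8))
            qi += n
        elif ch == "D":
            q_cols.append(np.full(n, seqs.GAP, dtype=np.uint8))
            t_cols.append(target[ti : ti + n])
            ti += n
        else:  # pragma: no cover - edlib emits only =XMID
            raise ValueError(f"unexpected CIGAR op {ch!r}")
    return np.concatenate(q_cols), np.concatenate(t_cols)


def _trim_anchors(anchors):
    """Make sorted anchors non-overlapping by moving the later anchor's start
    forward the same amount on both axes, preserving its internal diagonal;
    any boundary artifact this introduces is repaired by the affine junction
    realignment."""
    out = []
    py = pc = 0
    for (y0, y1), (c0, c1) in anchors:
        delta = max(py - y0, pc - c0, 0)
        y0 += delta
        c0 += delta
        if y1 > y0 and c1 > c0:
            out.append(((y0, y1), (c0, c1)))
            py, pc = y1, c1
    return out


_AFFINE = None


def _affine_aligner():
    """Affine-gap global aligner for junction polishing: long indels stay in
    one piece (a second gap opening costs more than a few chance matches)."""
    global _AFFINE
    if _AFFINE is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -2
        a.open_gap_score = -10.1
        a.extend_gap_score = -0.1
        _AFFINE = a
    return _AFFINE


def _affine_columns(a: np.ndarray, b: np.ndarray):
    """Column arrays of an affine-gap global alignment of two short segments."""
    aligner = _affine_aligner()
    aln = aligner.align(seqs.decode(a), seqs.decode(b))[0]
    blocks_a, blocks_b = aln.aligned
    q_parts, t_parts = [], []
    pa = pb = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if a0 > pa:
            q_parts.append(a[pa:a0])
            t_parts.append(np.full(a0 - pa, seqs.GAP, np.uint8))
        if b0 > pb:
            q_parts.append(np.full(b0 - pb, seqs.GAP, np.uint8))
            t_parts.append(b[pb:b0])
        q_parts.append(a[a0:a1])
        t_parts.append(b[b0:b1])
        pa, pb = a1, b1
    if pa < len(a):
        q_parts.append(a[pa:])
        t_parts.append(np.full(len(a) - pa, seqs.GAP, np.uint8))
    if pb < len(b):
        q_parts.append(np.full(len(b) - pb, seqs.GAP, np.uint8))
        t_parts.append(b[pb:])
    return np.concatenate(q_parts), np.concatenate(t_parts)


@dataclass
class ColumnAlignment:
    """Columnwise global alignment of a genomic copy against a consensus span.

    ``copy_col`` / ``cons_col`` are uint8 code arrays of equal length with
    5 (GAP) marking gaps; ``cons_start`` is the consensus offset of the
    first consensus base in the alignment.
    """

    copy_col: np.ndarray
    cons_col: np.ndarray
    cons_start: int

    @classmethod
    def globally(cls, copy_codes: np.ndarray, cons_codes: np.ndarray, cons_start: int = 0):
        if len(copy_codes) == 0 or len(cons_codes) == 0:
            raise ValueError("cannot align empty sequences")
        res = edlib.align(
            seqs.decode(copy_codes), seqs.decode(cons_codes), mode="NW", task="path"
        )
        q, t = _cigar_to_columns(res["cigar"], copy_codes, cons_codes)
        return cls(copy_col=q, cons_col=t, cons_start=cons_start)

    @classmethod
    def stitched(cls, copy_codes, cons_codes, cons_start, anchors):
        """Global alignment assembled from collinear anchor segments.

        ``anchors`` are ((copy_start, copy_end), (cons_start, cons_end))
        pairs in *local* coordinates (copy / consensus-span frames), e.g.
        the chained local alignments of a candidate.  Segments inside an
        anchor and regions where both sequences have residues are aligned
        with the global DP; a region with sequence on one side only becomes
        a single clean gap run — this keeps a long indel as one event
        instead of letting the unit-cost DP shatter it against chance
        matches in unrelated sequence.
        """
        anchors = _trim_anchors(sorted(anchors, key=lambda a: a[1][0]))
        q_parts, t_parts = [np.zeros(0, np.uint8)], [np.zeros(0, np.uint8)]

        def emit(y0, y1, c0, c1, junction):
            a = copy_codes[y0:y1]
            b = cons_codes[c0:c1]
            if len(a) == 0 and len(b) == 0:
                return
            if len(a) == 0:
                q_parts.append(np.full(len(b), seqs.GAP, np.uint8))
                t_parts.append(b)
            elif len(b) == 0:
                q_parts.append(a)
                t_parts.append(np.full(len(a), seqs.GAP, np.uint8))
            elif junction:
                q, t = _affine_columns(a, b)
                q_parts.append(q)
                t_parts.append(t)
            elif len(a) == len(b) and np.mean((a != b) & (a < 4) & (b < 4)) <= 0.15:
                # substitution-dominated anchor interior: columnwise pairing.
                # A unit-cost DP here may trade adjacent mismatch pairs for
                # cost-tied gap pairs, which pairwise deletion would then
                # exclude, deflating the divergence of old copies.
                q_parts.append(a)
                t_parts.append(b)
            else:
                res = edlib.align(seqs.decode(a), seqs.decode(b), mode="NW", task="path")
                q, t = _cigar_to_columns(res["cigar"], a, b)
                q_parts.append(q)
                t_parts.append(t)

        # shrink each anchor at interior junctions so the junction window
        # carries exact-homology flanks that pin the gap placement
        W = 64
        n = len(anchors)
        py, pc = 0, 0
        for i, ((y0, y1), (c0, c1)) in enumerate(anchors):
            lead = W if i > 0 else 0
            trail = W if i < n - 1 else 0
            span = min(y1 - y0, c1 - c0)
            while lead + trail > max(span - 20, 0):
                lead = lead // 2 if lead >= trail else lead
                trail = trail // 2 if trail > lead else trail
                if lead + trail == 0:
                    break
            ys, cs = y0 + lead, c0 + lead
            ye, ce = y1 - trail, c1 - trail
            emit(py, ys, pc, cs, junction=i > 0)
            emit(ys, ye, cs, ce, junction=False)
            py, pc = ye, ce
        emit(py, len(copy_codes), pc, len(cons_codes), junction=n > 0)
        return cls(
            copy_col=np.concatenate(q_parts),
            cons_col=np.concatenate(t_parts),
            cons_start=cons_start,
        )

    def __len__(self):
        return len(self.copy_col)

    @cached_property
    def cons_pos(self) -> np.ndarray:
        """Consensus position of every column (position of the consensus base,
        or of the next consensus base for columns where the consensus is gapped)."""
        real = self.cons_col != seqs.GAP
        return self.cons_start + np.cumsum(real) - real.astype(int)

    @cached_property
    def copy_pos(self) -> np.ndarray:
        """Copy position of every column (next copy base at copy-gap columns)."""
        real = self.copy_col != seqs.GAP
        return np.cumsum(real) - real.astype(int)

    @cached_property
    def comparable(self) -> np.ndarray:
        """Columns where both rows carry a determined base (pairwise deletion)."""
        return (self.copy_col < 4) & (self.cons_col < 4)

    @cached_property
    def match_mask(self) -> np.ndarray:
        return self.comparable & (self.copy_col == self.cons_col)

    @property
    def n_comparable(self) -> int:
        return int(self.comparable.sum())

    @property
    def n_matches(self) -> int:
        return int(self.match_mask.sum())

    def identity(self) -> float:
        n = self.n_comparable
        return self.n_matches / n if n else float("nan")

    def divergence(self, min_columns: int = 50) -> float | None:
        """Proportion of nucleotide differences, pairwise-deletion style:
        gap and N columns are excluded from the denominator."""
        n = self.n_comparable
        if n < min_columns:
            return None
        return float((n - self.n_matches) / n)

    def gap_runs(self, row: str, min_len: int = 1):
        """Maximal gap runs in one row as
        ``(consensus offset, length, copy offset)``."""
        col = self.copy_col if row == "copy" else self.cons_col
        isgap = col == seqs.GAP
        out = []
        i = 0
        n = len(isgap)
        while i < n:
            if isgap[i]:
                j = i
                while j < n and isgap[j]:
                    j += 1
                if j - i >= min_len:
                    out.append((int(self.cons_pos[i]), j - i, int(self.copy_pos[i])))
                i = j
            else:
                i += 1
        return out

    def score_ratio(self, match=1, mismatch=-2, gap_open=6.0, gap_ext=0.2) -> float:
        """Alignment score over the perfect score on its scorable columns.

        N columns score 0 and do not count as scorable, so heavily
        gap-masked copies are judged only on their visible sequence.
        """
        n_scorable = self.n_comparable
        if n_scorable == 0:
            return 0.0
        score = self.n_matches * match + (n_scorable - self.n_matches) * mismatch
        for row in ("copy", "cons"):
            for _off, length, _cp in self.gap_runs(row):
                score -= gap_open + gap_ext * length
        return score / (n_scorable * match)
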