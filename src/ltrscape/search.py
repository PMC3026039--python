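"""Seed-and-extend homology search of family consensi against a genome.

A BLASTN-like stage: exact k-mer seeds (k-mers containing N are never
indexed), gapped x-drop extension with affine gaps, and chaining of
consensus-collinear local alignments into candidate copies.  Both strands
are searched by scanning the reverse complement of each consensus; all
coordinates are reported on the forward genome strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import seqs
from .alignment import ColumnAlignment, extend_anchored
from .errors import ParameterError
from .families import FamilyModel


@dataclass(frozen=True)
class ScanParams:
    """Scoring and chaining parameters (BLASTN-like defaults)."""

    k: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = 5  # a gap of length g costs gap_open + gap_ext * g
    gap_ext: int = 2
    x_drop: int = 20
    min_score: int = 30
    chain_gap: int = 2000
    overlap_tol: int = 100
    # a chain link must be a plain indel: at least one axis gap stays small
    # (a large simultaneous genome+consensus gap marks a different copy)
    chain_diag_slack: int = 300
    # a genome-contiguous link may jump backwards on the consensus by up to
    # this much: the signature of a tandem duplication
    chain_dup_max: int = 1000

    def __post_init__(self):
        if self.k < 8:
            raise ParameterError("word size k must be >= 8")


@dataclass
class LocalAlignment:
    """One gapped local alignment (HSP) of a consensus against the genome."""

    family: str
    strand: str
    arm: str
    g_start: int
    g_end: int
    q_start: int  # query frame: forward consensus for '+', its RC for '-'
    q_end: int
    score: int
    columns: int = 0
    matches: int = 0
    identity: float = float("nan")


@dataclass
class CandidateCopy:
    """Chained, same-family, consensus-collinear alignments at one locus."""

    family: str
    strand: str
    arm: str
    start: int
    end: int
    cons_start: int  # forward-consensus frame
    cons_end: int
    alignments: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def covered_segments(self, family: FamilyModel) -> set:
        out = set()
        for label, (s, e) in family.segments.items():
            if self.cons_start < e and s < self.cons_end:
                out.add(label)
        return out


class KmerIndex:
    """Exact k-mer positional index over a genome (forward strand).

    Arms are concatenated with k-long N spacers so window codes never span
    two arms; any window containing N is not indexed.
    """

    def __init__(self, genome: dict, k: int):
        if k < 8:
            raise ParameterError("word size k must be >= 8")
        if k > 31:
            raise ParameterError("word size k must fit 2 bits/base in int64")
        self.k = k
        self.arms = list(genome)
        spacer = np.full(k, seqs.N, dtype=np.uint8)
        chunks = []
        self.offsets = []
        pos = 0
        for arm in self.arms:
            self.offsets.append(pos)
            chunks.append(genome[arm])
            pos += len(genome[arm])
            chunks.append(spacer)
            pos += k
        self.concat = np.concatenate(chunks) if chunks else np.zeros(0, np.uint8)
        self.offsets = np.array(self.offsets, dtype=np.int64)
        self.arm_lens = np.array([len(genome[a]) for a in self.arms], dtype=np.int64)

        codes, valid = window_codes(self.concat, k)
        pos_all = np.flatnonzero(valid)
        code_sub = codes[pos_all]
        order = np.argsort(code_sub, kind="stable")
        self.sorted_codes = code_sub[order]
        self.sorted_pos = pos_all[order]

    def arm_of(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.arms[i], int(gpos - self.offsets[i])

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        return self.sorted_pos[lo:hi]

    def seeds_for(self, query: np.ndarray):
        """All exact seed matches of the query: (genome position, query position),
        sorted by genome position."""
        qcodes, qvalid = window_codes(query, self.k)
        qpos_all = np.flatnonzero(qvalid)
        lo = np.searchsorted(self.sorted_codes, qcodes[qpos_all], side="left")
        hi = np.searchsorted(self.sorted_codes, qcodes[qpos_all], side="right")
        n = hi - lo
        total = int(n.sum())
        g = np.empty(total, dtype=np.int64)
        q = np.empty(total, dtype=np.int64)
        at = 0
        for i in np.flatnonzero(n):
            cnt = int(n[i])
            g[at : at + cnt] = self.sorted_pos[lo[i] : hi[i]]
            q[at : at + cnt] = qpos_all[i]
            at += cnt
        order = np.lexsort((q, g))
        return g[order], q[order]


def window_codes(codes: np.ndarray, k: int):
    """Base-4 integer codes of all k-windows plus a validity mask (no N)."""
    n = len(codes)
    if n < k:
        return np.zeros(0, np.int64), np.zeros(0, bool)
    m = n - k + 1
    out = np.zeros(m, dtype=np.int64)
    s = codes.astype(np.int64)
    for t in range(k):
        out = out * 4 + np.minimum(s[t : t + m], 3)
    bad = (codes == seqs.N).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    return out, valid


def index_genome(genome: dict, k: int = 11) -> KmerIndex:
    """Build the exact k-mer seed index of a genome."""
    return KmerIndex(genome, k)


def _hsp_stats(aln: LocalAlignment, concat: np.ndarray, query: np.ndarray, goff: int):
    seg_g = concat[aln.g_start + goff : aln.g_end + goff]
    seg_q = query[aln.q_start : aln.q_end]
    if len(seg_g) == 0 or len(seg_q) == 0:
        return
    cols = ColumnAlignment.globally(seg_g, seg_q)
    aln.columns = len(cols)
    aln.matches = cols.n_matches
    aln.identity = cols.identity()


def _extend_all(index: KmerIndex, query: np.ndarray, params: ScanParams):
    """Extend seeds into HSPs, skipping seeds inside already-aligned regions."""
    gpos, qpos = index.seeds_for(query)
    window = int(len(query) * 1.4 + 3000)
    hsps = []  # (g_start, g_end, q_start, q_end, score) in concat coordinates
    active = []
    for g, q in zip(gpos, qpos):
        active = [h for h in active if h[1] > g]
        covered = False
        for gs, ge, qs, qe in active:
            if gs <= g < ge and qs - params.k <= q < qe + params.k:
                covered = True
                break
        if covered:
            continue
        g_lo = max(0, g - window)
        res = extend_anchored(
            index.concat[g_lo : g + window], query, int(g - g_lo), int(q), params
        )
        if res.score < params.min_score:
            continue
        hsp = (g_lo + res.a_start, g_lo + res.a_end, res.b_start, res.b_end, res.score)
        dup = any(
            min(h[1], hsp[1]) - max(h[0], hsp[0]) >= 0.9 * (hsp[1] - hsp[0])
            and min(h[3], hsp[3]) - max(h[2], hsp[2]) >= 0.9 * (hsp[3] - hsp[2])
            for h in hsps[-8:]
        )
        if not dup:
            hsps.append(hsp)
            active.append((hsp[0], hsp[1], hsp[2], hsp[3]))
    return hsps


def _chain(hsps: list, params: ScanParams):
    """Greedy chaining of genome- and consensus-collinear HSPs."""
    chains = []
    for h in sorted(hsps, key=lambda x: (x.g_start, x.q_start)):
        placed = False
        for chain in chains:
            last = chain[-1]
            g_gap = h.g_start - last.g_end
            q_gap = h.q_start - last.q_end
            q_floor = (
                -params.chain_dup_max if g_gap <= params.overlap_tol else -params.overlap_tol
            )
            if (
                -params.overlap_tol <= g_gap <= params.chain_gap
                and q_floor <= q_gap <= params.chain_gap
                and min(max(g_gap, 0), max(q_gap, 0)) <= params.chain_diag_slack
            ):
                chain.append(h)
                placed = True
                break
        if not placed:
            chains.append([h])
    return chains


def scan(
    library: list,
    genome: dict,
    params: ScanParams = ScanParams(),
    index: KmerIndex | None = None,
) -> list[CandidateCopy]:
    """Search every family consensus against both genome strands.

    Returns candidate copies: chained same-family, same-strand,
    consensus-collinear local alignments, with forward-strand genome
    coordinates and forward-frame consensus spans.
    """
    if not library:
        raise ParameterError("family library is empty")
    if index is None:
        index = KmerIndex(genome, params.k)
    if len(index.concat) == 0:
        return []
    candidates = []
    for fam in library:
        cons = fam.consensus
        for strand in "+-":
            query = cons if strand == "+" else seqs.revcomp(cons)
            raw = _extend_all(index, query, params)
            hsps = []
            for gs, ge, qs, qe, score in raw:
                arm, local = index.arm_of(gs)
                hsp = LocalAlignment(
                    family=fam.name,
                    strand=strand,
                    arm=arm,
                    g_start=local,
                    g_end=local + (ge - gs),
                    q_start=qs,
                    q_end=qe,
                    score=score,
                )
                _hsp_stats(hsp, index.concat, query, gs - local)
                hsps.append(hsp)
            by_arm = {}
            for h in hsps:
                by_arm.setdefault(h.arm, []).append(h)
            for arm, arm_hsps in by_arm.items():
                goff = int(index.offsets[index.arms.index(arm)])
                for chain in _chain(arm_hsps, params):
                    g0 = min(h.g_start for h in chain)
                    g1 = max(h.g_end for h in chain)
                    q0 = min(h.q_start for h in chain)
                    q1 = max(h.q_end for h in chain)
                    if strand == "+":
                        c0, c1 = q0, q1
                    else:
                        c0, c1 = len(cons) - q1, len(cons) - q0
                    candidates.append(
                        CandidateCopy(
                            family=fam.name,
                            strand=strand,
                            arm=arm,
                            start=g0,
                            end=g1,
                            cons_start=c0,
                            cons_end=c1,
                            alignments=chain,
                        )
                    )
    candidates.sort(key=lambda c: (c.arm, c.start, c.family))
    return candidates


def best_local_score(a: np.ndarray, b: np.ndarray, params: ScanParams = ScanParams()) -> int:
    """Best local-alignment score reachable by the seeded x-drop search.

    Every shared exact k-mer is used as an anchor; with no shared word the
    score is 0 (no seed, no alignment)."""
    index = KmerIndex({"a": np.asarray(a, np.uint8)}, params.k)
    gpos, qpos = index.seeds_for(np.asarray(b, np.uint8))
    best = 0
    for g, q in zip(gpos, qpos):
        res = extend_anchored(np.asarray(a, np.uint8), np.asarray(b, np.uint8), int(g), int(q), params)
        best = max(best, res.score)
    return best
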