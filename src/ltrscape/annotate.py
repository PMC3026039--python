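"""Annotation of candidate copies: family rules, condition, SV, divergence.

This is the bespoke classification layer of the census:

* family assignment — a candidate belongs to a family if it shows (1) a
  contiguous stretch of ≥400 aligned bp of the internal (pol/gag) region at
  ≥90% identity, or (2) ≥90% identity over at least half the LTR length;
* condition — solo-LTR (identity exclusively to the LTR), proviral (any
  internal-region identity), or unknown when unsequenced N gaps mask the
  region where internal sequence would lie;
* structural variation — maximal alignment gap runs ≥10 bp become del/ins
  events (ins matching adjacent consensus at ≥90% becomes dup), grading
  copies complete / moderately-fragmented (1–2 indels) / highly-fragmented
  (≥3);
* "partial" — summed deletions exceeding 3% of the consensus length;
* divergence — proportion of nucleotide differences with pairwise deletion
  of gap and N columns;
* target-site duplication — longest 4–6 bp exact duplicated word at the
  two junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import seqs
from .alignment import ColumnAlignment
from .errors import ConfigurationError
from .families import FamilyModel
from .search import CandidateCopy
from .sv import SVEvent

CONDITIONS = ("proviral", "solo-LTR", "unknown")
FRAGMENTATION = ("complete", "moderately-fragmented", "highly-fragmented", "unknown")


@dataclass(frozen=True)
class Thresholds:
    """Published classification thresholds (see class docstrings)."""

    family_pol_gag_min_span: int = 400
    family_min_identity: float = 0.90
    family_ltr_min_fraction: float = 0.5
    sv_min_indel: int = 10
    partial_del_fraction: float = 0.03
    recent_identity: float = 0.99
    old_divergence: float = 0.05
    cluster_distance: int = 10_000
    gene_flank: int = 1000
    # implementation-side knobs
    min_internal_columns: int = 30  # aligned internal bp needed to call proviral
    min_divergence_columns: int = 50
    reliability_floor: float = 0.4  # alignment score / perfect score over span
    dup_search_window: int = 500
    n_flank_fraction: float = 0.5  # N share that turns a solo call into unknown


@dataclass
class AnnotatedCopy:
    """One annotated genomic insertion (a census table row)."""

    id: str
    family: str
    lineage: str
    arm: str
    start: int  # 0-based half-open internally; tables are 1-based inclusive
    end: int
    strand: str
    condition: str
    divergence: float | None
    sv_events: list
    sv_determined: bool
    fragmentation: str
    partial: bool | None
    tsd: str | None
    rule: str  # family-assignment rule that accepted the copy
    reliable: bool
    cons_start: int
    cons_end: int
    compartment: str | None = None
    cluster: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# individual rules


def align_to_consensus(
    copy_codes: np.ndarray,
    family: FamilyModel,
    cons_start: int,
    cons_end: int,
    candidate: CandidateCopy | None = None,
) -> ColumnAlignment:
    """End-to-end alignment of a copy against the consensus span it covers.

    When the candidate's chained local alignments are supplied they anchor
    the global alignment (segment-wise DP between anchors); otherwise a
    plain global DP over the whole span is used.
    """
    cons = family.consensus[cons_start:cons_end]
    if candidate is None or not candidate.alignments:
        return ColumnAlignment.globally(copy_codes, cons, cons_start)
    L = family.length
    anchors = []
    for h in candidate.alignments:
        if candidate.strand == "+":
            y = (h.g_start - candidate.start, h.g_end - candidate.start)
            c = (h.q_start - cons_start, h.q_end - cons_start)
        else:
            y = (candidate.end - h.g_end, candidate.end - h.g_start)
            c = (L - h.q_end - cons_start, L - h.q_start - cons_start)
        anchors.append((y, c))
    return ColumnAlignment.stitched(copy_codes, cons, cons_start, anchors)


def assign_family(aln: ColumnAlignment, family: FamilyModel, th: Thresholds) -> str | None:
    """Family-membership rules; returns 'rule1', 'rule2' or None (rejected)."""
    segments = family.segments
    if segments["internal"][1] <= segments["internal"][0]:
        raise ConfigurationError(f"family {family.name} lacks an internal segment")

    comparable = aln.comparable
    match = aln.match_mask
    pos = aln.cons_pos

    # rule 1: >=400 contiguous aligned bp of the internal region at >=90%
    i0, i1 = segments["internal"]
    sel = comparable & (pos >= i0) & (pos < i1)
    vals = match[sel].astype(np.int64)
    w = th.family_pol_gag_min_span
    if len(vals) >= w:
        cum = np.concatenate([[0], np.cumsum(vals)])
        window_matches = cum[w:] - cum[:-w]
        # contiguity is over aligned internal columns (gap/N columns excluded)
        idx = np.flatnonzero(sel)
        contiguous = (idx[w - 1 :] - idx[: len(idx) - w + 1]) < w + w  # allow small gaps
        if np.any((window_matches >= th.family_min_identity * w) & contiguous):
            return "rule1"

    # rule 2: >=90% identity over >= half of either LTR
    for ltr in ("LTR5", "LTR3"):
        s, e = segments[ltr]
        sel = comparable & (pos >= s) & (pos < e)
        n = int(sel.sum())
        if n >= th.family_ltr_min_fraction * (e - s):
            ident = match[sel].mean() if n else 0.0
            if ident >= th.family_min_identity:
                return "rule2"
    return None


def classify_condition(
    aln: ColumnAlignment,
    family: FamilyModel,
    th: Thresholds,
    arm_codes: np.ndarray | None = None,
    g_start: int | None = None,
    g_end: int | None = None,
    strand: str = "+",
) -> str:
    """proviral / solo-LTR / unknown per the identity-to-segment rules."""
    i0, i1 = family.segments["internal"]
    pos = aln.cons_pos
    in_internal = (pos >= i0) & (pos < i1)
    internal_evidence = int((aln.comparable & in_internal).sum())
    if internal_evidence >= th.min_internal_columns:
        return "proviral"

    # does the alignment itself reach into the internal region as N?
    internal_cols = int((in_internal & (aln.cons_col != seqs.GAP)).sum())
    if internal_cols > 0:
        n_cols = int((in_internal & (aln.copy_col == seqs.N)).sum())
        if n_cols >= th.n_flank_fraction * internal_cols:
            return "unknown"
        return "solo-LTR"

    # LTR-only alignment: look at the genomic flank where the internal
    # region would lie; an N track beginning at the junction masks it
    if arm_codes is not None and g_start is not None:
        ilen = i1 - i0
        for side in ("right", "left"):
            if side == "right":
                win = arm_codes[g_end : g_end + ilen]
            else:
                win = arm_codes[max(0, g_start - ilen) : g_start]
            if len(win) == 0:
                continue
            near = win[:100] if side == "right" else win[-100:]
            if (
                np.mean(win == seqs.N) >= th.n_flank_fraction
                and np.mean(near == seqs.N) >= th.n_flank_fraction
            ):
                return "unknown"
    return "solo-LTR"


def call_sv(
    aln: ColumnAlignment,
    family: FamilyModel,
    th: Thresholds,
) -> list[SVEvent]:
    """Indel/duplication events from maximal alignment gap runs >= 10 bp.

    Runs are left-normalized (slid to their leftmost score-equivalent
    placement, the VCF convention); this puts a tandem-duplication run onto
    the repeat boundary so its content matches the adjacent consensus.
    """
    cons = family.consensus
    copy = aln.copy_col[aln.copy_col != seqs.GAP]
    events = []
    for off, length, _cp in aln.gap_runs("copy", th.sv_min_indel):
        o = off
        while (
            o > 0
            and off - o < 2 * length + 100
            and o + length <= len(cons)
            and cons[o - 1] == cons[o + length - 1]
        ):
            o -= 1
        events.append(SVEvent("del", length, o, _ltr_flag(o, length, family)))
    for off, length, cp in aln.gap_runs("cons", th.sv_min_indel):
        u, o = cp, off
        while (
            u > 0
            and cp - u < 2 * length + 100
            and u + length <= len(copy)
            and copy[u - 1] == copy[u + length - 1]
        ):
            u -= 1
        # sliding an insertion along the copy shifts its consensus offset by
        # the same number of newly re-paired consensus bases
        o = off - (cp - u)
        kind = "ins"
        ins_seq = copy[u : u + length]
        ins_seq = ins_seq[ins_seq < 4]
        if len(ins_seq) >= 10 and _is_duplication(ins_seq, cons, o, length, th):
            kind = "dup"
        events.append(SVEvent(kind, length, max(o, 0), _ltr_flag(max(o, 0), 1, family)))
    events.sort(key=lambda e: e.offset)
    return events


def _ltr_flag(offset: int, span: int, family: FamilyModel) -> str:
    for name in ("LTR5", "LTR3"):
        s, e = family.segments[name]
        if offset < e and s < offset + span:
            return name
    return "none"


def _is_duplication(ins_seq, cons, off, length, th: Thresholds) -> bool:
    import edlib

    lo = max(0, off - th.dup_search_window - length)
    hi = min(len(cons), off + th.dup_search_window + length)
    res = edlib.align(
        seqs.decode(ins_seq), seqs.decode(cons[lo:hi]), mode="HW", task="distance"
    )
    d = res["editDistance"]
    return d >= 0 and d <= (1 - th.family_min_identity) * len(ins_seq)


def flag_partial(
    sv_events, family: FamilyModel, th: Thresholds, is_solo: bool
) -> bool:
    """Partial iff summed deletion lengths exceed 3% of the consensus length
    (strict inequality); solo-LTRs are partial by construction."""
    if is_solo:
        return True
    total_del = sum(e.size for e in sv_events if e.type == "del")
    return total_del > th.partial_del_fraction * family.length


def compute_divergence(aln: ColumnAlignment, th: Thresholds = Thresholds()) -> float | None:
    """Pairwise-deletion divergence; None when < 50 comparable columns."""
    return aln.divergence(th.min_divergence_columns)


def detect_tsd(
    arm_codes: np.ndarray, start: int, end: int, min_len: int = 4, max_len: int = 6
) -> str | None:
    """Longest exact duplicated 4–6 bp word flanking the insertion.

    Returns the motif, None if absent, and None as well when a contig edge
    truncates either flank (undetermined)."""
    if start < 10 or end + 10 > len(arm_codes):
        return None
    for L in range(max_len, min_len - 1, -1):
        left = arm_codes[start - L : start]
        right = arm_codes[end : end + L]
        if np.array_equal(left, right) and not np.any(left == seqs.N):
            return seqs.decode(left)
    return None


def classify_fragmentation(
    sv_events, aln: ColumnAlignment, reliable: bool
) -> str:
    """complete / moderately-fragmented (1–2 indels) / highly-fragmented (>=3);
    a copy without indels but with N gaps cannot be called complete."""
    if not reliable:
        return "unknown"
    n = len(sv_events)
    if n == 0:
        has_n = bool(np.any(aln.copy_col == seqs.N) or np.any(aln.cons_col == seqs.N))
        return "unknown" if has_n else "complete"
    return "moderately-fragmented" if n <= 2 else "highly-fragmented"


# ---------------------------------------------------------------------------
# driver


@dataclass
class AnnotationResult:
    copies: list
    counts: dict
    rejected: list = field(default_factory=list)

    def reconciles(self, n_candidates: int) -> bool:
        c = self.counts
        return (
            c["annotated"] + c["rejected_family"] + c["rejected_overlap"]
            == n_candidates
        )


def _overlap(a: CandidateCopy, b: CandidateCopy) -> int:
    if a.arm != b.arm:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def annotate_genome(
    genome: dict,
    library: list,
    candidates: list,
    th: Thresholds = Thresholds(),
) -> AnnotationResult:
    """Run the full classification over scanned candidates.

    Every candidate ends in exactly one of: annotated (possibly with an
    unreliable alignment, in which case SV/divergence are undetermined),
    rejected by the family rules, or rejected in competition with a
    better-supported overlapping candidate.
    """
    fams = {f.name: f for f in library}
    assessed = []
    counts = {"candidates": len(candidates), "rejected_family": 0,
              "rejected_overlap": 0, "unreliable": 0, "annotated": 0}
    rejected = []
    for cand in candidates:
        fam = fams[cand.family]
        copy_codes = genome[cand.arm][cand.start : cand.end]
        if cand.strand == "-":
            copy_codes = seqs.revcomp(copy_codes)
        aln = align_to_consensus(copy_codes, fam, cand.cons_start, cand.cons_end, cand)
        rule = assign_family(aln, fam, th)
        if rule is None:
            counts["rejected_family"] += 1
            rejected.append((cand, "family-rules"))
            continue
        weight = aln.identity() * aln.n_comparable
        assessed.append((cand, aln, rule, weight))

    # competition between overlapping accepted candidates: keep the one
    # maximizing identity x aligned length; ties break lexicographically
    assessed.sort(key=lambda t: (-t[3], t[0].family, t[0].arm, t[0].start))
    kept = []
    for cand, aln, rule, weight in assessed:
        clash = any(
            _overlap(cand, k[0]) > 0.5 * min(cand.length, k[0].length) for k in kept
        )
        if clash:
            counts["rejected_overlap"] += 1
            rejected.append((cand, "overlap"))
            continue
        kept.append((cand, aln, rule, weight))

    kept.sort(key=lambda t: (t[0].arm, t[0].start))
    copies = []
    for i, (cand, aln, rule, _w) in enumerate(kept, start=1):
        fam = fams[cand.family]
        arm_codes = genome[cand.arm]
        reliable = aln.score_ratio() >= th.reliability_floor
        counts["unreliable"] += not reliable
        condition = classify_condition(
            aln, fam, th, arm_codes, cand.start, cand.end, cand.strand
        )
        is_solo = condition == "solo-LTR"
        if reliable:
            sv_events = call_sv(aln, fam, th)
            sv_events = _with_terminal_deletions(
                sv_events, cand, aln, fam, th, arm_codes, condition
            )
            divergence = compute_divergence(aln, th)
            fragmentation = classify_fragmentation(sv_events, aln, reliable)
            partial = flag_partial(sv_events, fam, th, is_solo)
            sv_determined = True
        else:
            sv_events, divergence, sv_determined = [], None, False
            fragmentation = "unknown"
            partial = True if is_solo else None
        copies.append(
            AnnotatedCopy(
                id=f"LTRR{i:05d}",
                family=fam.name,
                lineage=fam.lineage,
                arm=cand.arm,
                start=cand.start,
                end=cand.end,
                strand=cand.strand,
                condition=condition,
                divergence=divergence,
                sv_events=sv_events,
                sv_determined=sv_determined,
                fragmentation=fragmentation,
                partial=partial,
                tsd=detect_tsd(arm_codes, cand.start, cand.end),
                rule=rule,
                reliable=reliable,
                cons_start=cand.cons_start,
                cons_end=cand.cons_end,
            )
        )
    counts["annotated"] = len(copies)
    return AnnotationResult(copies=copies, counts=counts, rejected=rejected)


def _with_terminal_deletions(
    sv_events, cand, aln, family, th, arm_codes, condition
):
    """Count consensus sequence missing at the copy ends as deletions when
    the genomic flank is determined (non-N) — i.e. the copy truly ends there.
    Solo-LTRs are exempt: their covered span is a single LTR by definition."""
    if condition == "solo-LTR":
        return sv_events
    events = list(sv_events)
    head = cand.cons_start
    tail = family.length - cand.cons_end
    left = arm_codes[max(0, cand.start - 20) : cand.start]
    right = arm_codes[cand.end : cand.end + 20]
    flank5, flank3 = (left, right) if cand.strand == "+" else (right, left)
    if head >= th.sv_min_indel and len(flank5) and np.mean(flank5 == seqs.N) < 0.5:
        events.append(SVEvent("del", head, 0, _ltr_flag(0, head, family)))
    if tail >= th.sv_min_indel and len(flank3) and np.mean(flank3 == seqs.N) < 0.5:
        events.append(
            SVEvent("del", tail, cand.cons_end, _ltr_flag(cand.cons_end, tail, family))
        )
    events.sort(key=lambda e: e.offset)
    return events
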