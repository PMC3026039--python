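"""Genomic context of annotated copies.

Chromatin compartments (PH / DIH / CIH heterochromatin, euchromatin split
into pericentromeric PE — the 3 Mb of euchromatin walked from the PH
boundary toward the telomere — and the remaining NPE), 10-kb single-linkage
clustering, gene associations within 1 kb flanks, per-region densities,
windowed density profiles, and inversion-breakpoint neighborhoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

PE_SIZE = 3_000_000
UNKNOWN_LABEL = "intermediate/unknown"


@dataclass
class CompartmentMap:
    """Ordered labeled intervals per arm (0-based half-open)."""

    arms: dict  # arm -> list[(start, end, label)]

    @classmethod
    def from_intervals(cls, intervals):
        arms = {}
        for arm, start, end, label in intervals:
            arms.setdefault(arm, []).append((int(start), int(end), label))
        for segs in arms.values():
            segs.sort()
            for (s1, e1, _), (s2, _e2, _) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ParameterError("compartment intervals overlap")
        return cls(arms=arms)

    def intervals(self):
        for arm, segs in self.arms.items():
            for s, e, label in segs:
                yield arm, s, e, label

    def arm_length(self, arm: str) -> int:
        return max(e for _s, e, _l in self.arms[arm])

    def label_at(self, arm: str, pos: int) -> str:
        for s, e, label in self.arms.get(arm, []):
            if s <= pos < e:
                return label
        return UNKNOWN_LABEL

    def regions(self, labels) -> list:
        """All (arm, start, end) intervals whose label is in ``labels``."""
        want = {labels} if isinstance(labels, str) else set(labels)
        return [
            (arm, s, e)
            for arm, segs in self.arms.items()
            for s, e, label in segs
            if label in want
        ]


def derive_pericentromeric_euchromatin(
    cmap: CompartmentMap, pe_size: int = PE_SIZE
) -> CompartmentMap:
    """Split EU into PE and NPE by walking euchromatic bp from the PH edge.

    PE accumulates euchromatin from the PH boundary toward the telomere,
    skipping non-EU blocks, until ``pe_size`` bp; every other euchromatic
    bp becomes NPE.  Arms without a PH anchor get all-NPE (with a warning);
    arms with less euchromatin than ``pe_size`` become all-PE.
    """
    out = {}
    for arm, segs in cmap.arms.items():
        ph = [(s, e) for s, e, l in segs if l == "PH"]
        eu_total = sum(e - s for s, e, l in segs if l == "EU")
        if not ph:
            warnings.warn(f"{arm}: no PH anchor; euchromatin labeled NPE")
            out[arm] = [(s, e, "NPE" if l == "EU" else l) for s, e, l in segs]
            continue
        if eu_total < pe_size:
            warnings.warn(f"{arm}: euchromatin smaller than PE size; all PE")
            out[arm] = [(s, e, "PE" if l == "EU" else l) for s, e, l in segs]
            continue
        # walk away from the PH edge bordering the larger euchromatic side
        ph_s = min(s for s, _ in ph)
        ph_e = max(e for _, e in ph)
        eu_left = sum(e - s for s, e, l in segs if l == "EU" and e <= ph_s)
        eu_right = sum(e - s for s, e, l in segs if l == "EU" and s >= ph_e)
        direction = 1 if eu_right >= eu_left else -1
        ordered = sorted(segs, key=lambda t: t[0], reverse=direction < 0)
        remaining = pe_size
        new = []
        started = False
        for s, e, label in ordered:
            if not started:
                started = label == "PH" or (
                    direction > 0 and s >= ph_e
                ) or (direction < 0 and e <= ph_s)
            if label != "EU" or not started or remaining <= 0:
                new.append((s, e, label))
                continue
            take = min(remaining, e - s)
            if direction > 0:
                new.append((s, s + take, "PE"))
                if take < e - s:
                    new.append((s + take, e, "NPE"))
            else:
                new.append((e - take, e, "PE"))
                if take < e - s:
                    new.append((s, e - take, "NPE"))
            remaining -= take
        new = [
            (s, e, "NPE" if l == "EU" else l) for s, e, l in sorted(new)
        ]
        out[arm] = new
    return CompartmentMap(arms=out)


def assign_compartment(copy, cmap: CompartmentMap) -> str:
    """Compartment of the interval midpoint; 'unplaced' for unmapped arms."""
    if copy.arm not in cmap.arms:
        return "unplaced"
    return cmap.label_at(copy.arm, (copy.start + copy.end) // 2)


# ---------------------------------------------------------------------------
# clustering


def cluster_insertions(
    copies, distance: int = 10_000, mode: str = "edge"
) -> tuple[list, int]:
    """Single-linkage clustering of insertions on one arm.

    ``mode='edge'`` links two copies when the gap between their closest
    edges is <= distance (inclusive); ``mode='start'`` measures start-to-
    start.  Returns (clusters as lists of input indices, number of
    insertions in clusters of size >= 2).
    """
    if mode not in ("edge", "start"):
        raise ParameterError(f"bad cluster mode {mode!r}")
    order = sorted(range(len(copies)), key=lambda i: (copies[i].start, copies[i].end))
    clusters = []
    current = []
    reach = None  # max end (edge mode) or last start (start mode) of cluster
    for i in order:
        c = copies[i]
        if current:
            gap = c.start - reach if mode == "edge" else c.start - reach
            if gap <= distance:
                current.append(i)
                reach = max(reach, c.end) if mode == "edge" else c.start
                continue
            clusters.append(current)
            current = []
        current = [i]
        reach = c.end if mode == "edge" else c.start
    if current:
        clusters.append(current)
    n_clustered = sum(len(cl) for cl in clusters if len(cl) >= 2)
    return clusters, n_clustered


# ---------------------------------------------------------------------------
# gene association


@dataclass(frozen=True)
class GeneAssociation:
    copy_id: str
    gene_id: str
    proximity: int  # 0 when inside the gene
    region: str  # exon | intron | 5' | 3'


def associate_genes(copies, genes, flank: int = 1000) -> list[GeneAssociation]:
    """Gene associations: inside transcription borders (exon if any exon
    overlaps, else intron), or within ``flank`` bp of either gene end —
    5' upstream of the transcription start, 3' downstream of the end
    (strand-aware).  A copy may associate with several genes."""
    out = []
    by_arm = {}
    for g in genes:
        by_arm.setdefault(g.arm, []).append(g)
    for c in copies:
        for g in by_arm.get(c.arm, []):
            if c.start < g.end and g.start < c.end:  # inside transcription borders
                exons = g.exons or ((g.start, g.end),)
                if not g.exons:
                    warnings.warn(f"gene {g.id} without exons treated as single-exon")
                hit_exon = any(c.start < e and s < c.end for s, e in exons)
                out.append(
                    GeneAssociation(c.id, g.id, 0, "exon" if hit_exon else "intron")
                )
                continue
            if c.end <= g.start:
                prox = g.start - c.end
                side = "5'" if g.strand == "+" else "3'"
            else:
                prox = c.start - g.end
                side = "3'" if g.strand == "+" else "5'"
            if prox <= flank:
                out.append(GeneAssociation(c.id, g.id, int(prox), side))
    return out


# ---------------------------------------------------------------------------
# densities


@dataclass
class RegionStats:
    label: str
    size_mb: float
    ltr_bp: int
    pct_of_region: float
    n_insertions: int
    per_mb: float
    n_proviral: int
    n_solo: int
    n_unknown: int
    pct_proviral_fragmented: float
    mean_divergence: float
    sd_divergence: float
    n_in_clusters: int
    genes_per_mb: float

    def as_row(self) -> dict:
        return {
            "region": self.label,
            "LTRr_bp": self.ltr_bp,
            "pct_of_region": round(self.pct_of_region, 2),
            "insertions": self.n_insertions,
            "insertions_per_Mb": round(self.per_mb, 2),
            "proviral": self.n_proviral,
            "solo_LTR": self.n_solo,
            "unknown": self.n_unknown,
            "pct_proviral_fragmented": round(self.pct_proviral_fragmented, 1),
            "mean_divergence_pct": round(self.mean_divergence, 2),
            "sd_divergence_pct": round(self.sd_divergence, 2),
            "in_clusters": self.n_in_clusters,
            "genes_per_Mb": round(self.genes_per_mb, 2),
            "size_Mb": round(self.size_mb, 2),
        }


def region_density(
    copies,
    regions,
    label: str = "region",
    genes=(),
    cluster_distance: int = 10_000,
    cluster_mode: str = "edge",
) -> RegionStats:
    """Census statistics of one region (a set of intervals).

    Membership uses the copy midpoint; LTRr bp tallies use overlap
    truncation, so straddling copies contribute only their inside part.
    """
    size = sum(e - s for _a, s, e in regions)
    if size == 0:
        raise ParameterError(f"region {label!r} has zero size")
    inside = []
    ltr_bp = 0
    for c in copies:
        mid = (c.start + c.end) // 2
        if any(a == c.arm and s <= mid < e for a, s, e in regions):
            inside.append(c)
        for a, s, e in regions:
            if a == c.arm:
                ltr_bp += max(0, min(c.end, e) - max(c.start, s))
    n = len(inside)
    n_prov = sum(1 for c in inside if c.condition == "proviral")
    n_solo = sum(1 for c in inside if c.condition == "solo-LTR")
    n_unk = n - n_prov - n_solo
    fragmented = sum(
        1
        for c in inside
        if c.condition == "proviral"
        and c.fragmentation in ("moderately-fragmented", "highly-fragmented")
    )
    frag_known = sum(
        1
        for c in inside
        if c.condition == "proviral" and c.fragmentation != "unknown"
    )
    divs = [c.divergence for c in inside if c.divergence is not None]
    n_genes = sum(
        1
        for g in genes
        if any(a == g.arm and s <= (g.start + g.end) // 2 < e for a, s, e in regions)
    )
    # clusters are computed within the region, per arm
    n_clustered = 0
    for arm in {a for a, _s, _e in regions}:
        arm_copies = [c for c in inside if c.arm == arm]
        if arm_copies:
            _cl, k = cluster_insertions(arm_copies, cluster_distance, cluster_mode)
            n_clustered += k
    mb = size / 1e6
    return RegionStats(
        label=label,
        size_mb=mb,
        ltr_bp=int(ltr_bp),
        pct_of_region=100.0 * ltr_bp / size,
        n_insertions=n,
        per_mb=n / mb,
        n_proviral=n_prov,
        n_solo=n_solo,
        n_unknown=n_unk,
        pct_proviral_fragmented=(100.0 * fragmented / frag_known) if frag_known else 0.0,
        mean_divergence=float(np.mean(divs)) * 100 if divs else float("nan"),
        sd_divergence=float(np.std(divs, ddof=1)) * 100 if len(divs) > 1 else 0.0,
        n_in_clusters=n_clustered,
        genes_per_mb=n_genes / mb,
    )


def windowed_density(copies, arm: str, arm_length: int, window: int) -> pd.DataFrame:
    """Non-overlapping windows tiled from the arm start.

    Reports per window both the insertion count (midpoint rule) and the
    percentage of window bp covered by copies (straddling copies split
    proportionally); the final short window is normalized by its true size.
    """
    if window <= 0:
        raise ParameterError("window must be > 0")
    edges = np.arange(0, arm_length + window, window)
    edges[-1] = min(edges[-1], arm_length)
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    n_win = len(edges) - 1
    counts = np.zeros(n_win)
    bp = np.zeros(n_win)
    for c in copies:
        if c.arm != arm:
            continue
        mid = (c.start + c.end) // 2
        w = min(int(mid // window), n_win - 1)
        counts[w] += 1
        first = max(0, min(int(c.start // window), n_win - 1))
        last = max(0, min(int((c.end - 1) // window), n_win - 1))
        for wi in range(first, last + 1):
            bp[wi] += max(0, min(c.end, edges[wi + 1]) - max(c.start, edges[wi]))
    sizes = np.diff(edges)
    return pd.DataFrame(
        {
            "start": edges[:-1] + 1,  # emitted 1-based inclusive
            "end": edges[1:],
            "count": counts.astype(int),
            "pct_bp": 100.0 * bp / sizes,
        }
    )


def breakpoint_neighborhood_density(
    copies,
    arm: str,
    eu_span: tuple,
    breakpoints: tuple,
    flank: int = 50_000,
    centered: int = 1_000_000,
) -> dict:
    """TE bp densities around an inversion: inside the rearrangement, the
    proximal and distal outside segments, each 50-kb breakpoint flank pair,
    and a window centered on the proximal breakpoint."""
    eu_s, eu_e = eu_span
    p, d = sorted(breakpoints)
    if not (eu_s <= p < d <= eu_e):
        raise ParameterError("breakpoints must lie inside the euchromatic span")
    regions = {
        "proximal_side": (eu_s, p),
        "inside": (p, d),
        "distal_side": (d, eu_e),
        "proximal_flank_out": (max(eu_s, p - flank), p),
        "proximal_flank_in": (p, min(eu_e, p + flank)),
        "distal_flank_in": (max(eu_s, d - flank), d),
        "distal_flank_out": (d, min(eu_e, d + flank)),
        "proximal_centered": (max(eu_s, p - centered // 2), min(eu_e, p + centered // 2)),
    }
    for name, (s, e) in regions.items():
        want = (
            flank
            if "flank" in name
            else centered
            if "centered" in name
            else None
        )
        if want and e - s < want:
            warnings.warn(f"{name} truncated by the arm edge")
    out = {}
    for name, (s, e) in regions.items():
        te = sum(
            max(0, min(c.end, e) - max(c.start, s)) for c in copies if c.arm == arm
        )
        cnt = sum(
            1 for c in copies if c.arm == arm and s <= (c.start + c.end) // 2 < e
        )
        out[name] = {
            "start": s,
            "end": e,
            "bp": e - s,
            "te_bp": int(te),
            "pct": 100.0 * te / (e - s) if e > s else float("nan"),
            "count": cnt,
        }
    return out
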