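"""Scoring a pipeline run against the generator's ground truth.

Simulation-mode validation: match annotated copies to planted ones by
interval overlap and measure detection recall/precision, classification
accuracy, indel recovery and divergence-estimator bias.
"""

from __future__ import annotations

import numpy as np


def match_truth(truth, copies, min_overlap: float = 0.9) -> dict:
    """Map each planted copy to the annotated copy covering >=90% of it."""
    out = {}
    by_arm = {}
    for c in copies:
        by_arm.setdefault(c.arm, []).append(c)
    for t in truth:
        for c in by_arm.get(t.arm, []):
            ov = min(t.end, c.end) - max(t.start, c.start)
            if ov >= min_overlap * (t.end - t.start):
                out[t.copy_id] = c
                break
    return out


def evaluate_run(sg, result, min_len: int = 500, max_div: float = 0.05) -> dict:
    """Detection and classification metrics of one simulate->annotate run.

    Recall/precision are restricted to planted copies >= ``min_len`` bp at
    divergence <= ``max_div``; condition/fragmentation accuracy and indel
    recovery cover every matched copy at <= ``max_div``; divergence bias is
    measured on indel-free, gap-free copies >= 1 kb.
    """
    truth = sg.truth
    copies = result.copies
    matches = match_truth(truth, copies)

    eligible = [t for t in truth if t.length >= min_len and t.true_divergence <= max_div]
    recalled = [t for t in eligible if t.copy_id in matches]

    planted_intervals = {}
    for t in truth:
        planted_intervals.setdefault(t.arm, []).append((t.start, t.end))
    true_pos = 0
    for c in copies:
        hits = planted_intervals.get(c.arm, [])
        if any(min(c.end, e) - max(c.start, s) >= 0.5 * (c.end - c.start) for s, e in hits):
            true_pos += 1

    scored = [
        (t, matches[t.copy_id])
        for t in truth
        if t.copy_id in matches and t.true_divergence <= max_div
    ]
    cond_ok = sum(1 for t, c in scored if c.condition == t.expected_condition)
    frag = [(t, c) for t, c in scored if t.expected_condition == "proviral"]
    frag_ok = sum(1 for t, c in frag if c.fragmentation == t.expected_fragmentation)

    ind_tot = ind_ok = 0
    for t, c in scored:
        for e in t.events:
            ind_tot += 1
            ind_ok += any(
                ce.type in (e.type, "dup")
                and abs(ce.size - e.size) <= 2
                and abs(ce.offset - e.offset) <= 5
                for ce in c.sv_events
            )

    div_err = [
        c.divergence - t.true_divergence
        for t in truth
        if t.copy_id in matches
        and not t.events
        and not t.has_n_gap
        and t.length >= 1000
        and (c := matches[t.copy_id]).divergence is not None
    ]

    return {
        "n_planted": len(truth),
        "n_annotated": len(copies),
        "n_eligible": len(eligible),
        "recall_pct": 100.0 * len(recalled) / len(eligible) if eligible else float("nan"),
        "precision_pct": 100.0 * true_pos / len(copies) if copies else float("nan"),
        "n_scored": len(scored),
        "condition_accuracy_pct": 100.0 * cond_ok / len(scored) if scored else float("nan"),
        "n_fragmentation_scored": len(frag),
        "fragmentation_accuracy_pct": 100.0 * frag_ok / len(frag) if frag else float("nan"),
        "n_indels_planted": ind_tot,
        "indel_recovery_pct": 100.0 * ind_ok / ind_tot if ind_tot else float("nan"),
        "n_divergence_pairs": len(div_err),
        "divergence_bias_pp": 100.0 * float(np.mean(div_err)) if div_err else float("nan"),
        "divergence_mad_pp": 100.0 * float(np.mean(np.abs(div_err))) if div_err else float("nan"),
    }
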