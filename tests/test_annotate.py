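"""Classification rules: family assignment, condition, SV, divergence, TSD."""

import numpy as np
import pytest

from conftest import overlap

from ltrscape import seqs
from ltrscape.alignment import ColumnAlignment
from ltrscape.annotate import (
    Thresholds,
    annotate_genome,
    assign_family,
    call_sv,
    classify_condition,
    classify_fragmentation,
    compute_divergence,
    detect_tsd,
    flag_partial,
)
from ltrscape.families import FamilyModel, build_family_library
from ltrscape.search import index_genome, scan
from ltrscape.simulate import ChromosomeBlueprint, InsertionPlan, synthesize_genome
from ltrscape.sv import SVEvent

TH = Thresholds()


def make_family(ltr=200, internal=5600, seed=0):
    rng = np.random.default_rng(seed)
    l = seqs.random_seq(rng, ltr, 0.5)
    return FamilyModel("Mag-T1", "Mag", l, seqs.random_seq(rng, internal, 0.5), l.copy())


def aln_over(family, cons_start, cons_end, identity=1.0, seed=0):
    """Gap-free alignment of a copy over one consensus span at a target
    identity (substitutions evenly spaced, so any window holds the rate)."""
    cons = family.consensus[cons_start:cons_end].copy()
    copy = cons.copy()
    n_sub = round((1 - identity) * len(cons))
    if n_sub:
        pos = np.linspace(0, len(cons) - 1, n_sub).astype(int)
        copy[pos] = (copy[pos] + 1) % 4
    return ColumnAlignment(copy_col=copy, cons_col=cons, cons_start=cons_start)


class TestAssignFamily:
    def test_internal_stretch_rule(self):
        fam = make_family()
        i0 = fam.segments["internal"][0]
        aln = aln_over(fam, i0 + 100, i0 + 520, identity=0.92)
        assert assign_family(aln, fam, TH) == "rule1"

    def test_half_ltr_rule(self):
        fam = make_family()
        aln = aln_over(fam, 40, 160, identity=0.91)  # 120 bp of a 200-bp LTR
        assert assign_family(aln, fam, TH) == "rule2"

    def test_both_rules_fail_at_printed_thresholds(self):
        fam = make_family()
        i0 = fam.segments["internal"][0]
        a399 = aln_over(fam, i0 + 10, i0 + 409, identity=0.95)
        assert assign_family(a399, fam, TH) is None
        a80 = aln_over(fam, 0, 80, identity=0.95)  # 80 bp of a 200-bp LTR
        assert assign_family(a80, fam, TH) is None


class TestClassifyCondition:
    def test_ltr_only_with_clean_flanks_is_solo(self):
        fam = make_family()
        aln = aln_over(fam, 0, 200)
        arm = seqs.random_seq(np.random.default_rng(1), 20_000, 0.5)
        assert classify_condition(aln, fam, TH, arm, 8000, 8200) == "solo-LTR"

    def test_internal_identity_is_proviral(self):
        fam = make_family()
        aln = aln_over(fam, 0, 2200)  # LTR5 + 2 kb of internal
        assert classify_condition(aln, fam, TH) == "proviral"

    def test_ltr_with_n_track_downstream_is_unknown(self):
        fam = make_family()
        aln = aln_over(fam, 0, 200)
        arm = seqs.random_seq(np.random.default_rng(2), 20_000, 0.5)
        arm[8200:12200] = seqs.N  # 4-kb unsequenced gap right of the LTR hit
        assert classify_condition(aln, fam, TH, arm, 8000, 8200) == "unknown"


class TestCallSv:
    def _aln_with_copy_gaps(self, fam, runs):
        cons = fam.consensus[:3000]
        copy = cons.copy()
        cols_copy, cols_cons, pos = [], [], 0
        for off, size in runs:
            cols_copy.append(copy[pos:off])
            cols_cons.append(cons[pos:off])
            cols_copy.append(np.full(size, seqs.GAP, np.uint8))
            cols_cons.append(cons[off : off + size])
            pos = off + size
        cols_copy.append(copy[pos:])
        cols_cons.append(cons[pos:])
        return ColumnAlignment(
            np.concatenate(cols_copy), np.concatenate(cols_cons), 0
        )

    def test_ten_bp_threshold_boundary(self):
        fam = make_family()
        aln = self._aln_with_copy_gaps(fam, [(300, 9), (700, 10), (1200, 250)])
        events = call_sv(aln, fam, TH)
        assert [(e.type, e.size) for e in events] == [("del", 10), ("del", 250)]

    def test_fragmentation_grades(self):
        fam = make_family()
        two = self._aln_with_copy_gaps(fam, [(300, 15), (700, 40)])
        three = self._aln_with_copy_gaps(fam, [(300, 15), (700, 40), (1500, 12)])
        assert classify_fragmentation(call_sv(two, fam, TH), two, True) == "moderately-fragmented"
        assert classify_fragmentation(call_sv(three, fam, TH), three, True) == "highly-fragmented"
        clean = aln_over(fam, 0, 3000)
        assert classify_fragmentation([], clean, True) == "complete"
        assert classify_fragmentation([], clean, False) == "unknown"

    def test_ltr_flag_on_event_in_ltr(self):
        fam = make_family()
        aln = self._aln_with_copy_gaps(fam, [(100, 50)])
        (ev,) = call_sv(aln, fam, TH)
        assert ev.ltr_flag == "LTR5"


class TestPartial:
    def test_three_percent_is_strict(self):
        fam = make_family(ltr=200, internal=4600)  # 5000-bp consensus
        over = [SVEvent("del", 100, 500), SVEvent("del", 60, 2000)]
        at = [SVEvent("del", 150, 500)]
        assert flag_partial(over, fam, TH, is_solo=False) is True  # 3.2%
        assert flag_partial(at, fam, TH, is_solo=False) is False  # exactly 3.0%
        assert flag_partial([], fam, TH, is_solo=True) is True  # any solo-LTR


class TestDivergence:
    def test_identical_alignment(self):
        fam = make_family()
        assert compute_divergence(aln_over(fam, 0, 300)) == 0.0

    def test_pairwise_deletion_denominator(self):
        # 100 columns: 5 mismatches, 8 gap columns, 2 N columns -> 5/90
        rng = np.random.default_rng(3)
        cons = seqs.random_seq(rng, 100, 0.5)
        copy = cons.copy()
        copy[:5] = (copy[:5] + 1) % 4
        copy[10:18] = seqs.GAP
        copy[20:22] = seqs.N
        aln = ColumnAlignment(copy, cons, 0)
        assert aln.divergence() == pytest.approx(5 / 90)

    def test_matches_per_column_recount(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(60, 300))
            copy = rng.integers(0, 6, n).astype(np.uint8)
            cons = rng.integers(0, 6, n).astype(np.uint8)
            keep = ~((copy == seqs.GAP) & (cons == seqs.GAP))
            copy, cons = copy[keep], cons[keep]
            aln = ColumnAlignment(copy, cons, 0)
            # independent column walk
            num = den = 0
            for a, b in zip(copy, cons):
                if a < 4 and b < 4:
                    den += 1
                    num += a != b
            expected = None if den < 50 else num / den
            assert aln.divergence() == (pytest.approx(expected) if expected is not None else None)


class TestTsd:
    def _arm_with(self, left, right):
        rng = np.random.default_rng(5)
        arm = seqs.random_seq(rng, 400, 0.5)
        arm[100 - len(left) : 100] = seqs.encode(left)
        arm[300 : 300 + len(right)] = seqs.encode(right)
        return arm

    @pytest.mark.parametrize("motif", ["CTTAT", "CTTC", "CAAG"])
    def test_duplicated_motif_found(self, motif):
        arm = self._arm_with(motif, motif)
        assert detect_tsd(arm, 100, 300) == motif

    def test_no_shared_junction_word(self):
        arm = self._arm_with("AAAAA", "CCCCC")
        assert detect_tsd(arm, 100, 300) is None

    def test_contig_edge_is_undetermined(self):
        arm = seqs.random_seq(np.random.default_rng(6), 400, 0.5)
        assert detect_tsd(arm, 4, 300) is None


class TestMosaic:
    def test_interleaved_mosaic_flags_unreliable(self):
        """A copy spliced from two families in alternating blocks chains into
        one candidate whose consensus alignment scores far below a clean
        copy, triggering the unreliable-alignment exclusion."""
        rng = np.random.default_rng(7)
        a = make_family(seed=70)
        b = make_family(seed=71)
        blocks = []
        pos = 0
        for i in range(7):
            src = a if i % 2 == 0 else b
            size = 500 if i % 2 == 0 else 250
            blocks.append(src.consensus[pos : pos + size])
            pos += size
        mosaic = np.concatenate(blocks)
        genome = {
            "m": np.concatenate(
                [seqs.random_seq(rng, 20_000, 0.5), mosaic, seqs.random_seq(rng, 20_000, 0.5)]
            )
        }
        cands = scan([a, b], genome, index=index_genome(genome))
        res = annotate_genome(genome, [a, b], cands)
        hit = [c for c in res.copies if overlap((c.start, c.end), (20_000, 20_000 + len(mosaic))) > 1000]
        assert hit and any(not c.reliable for c in hit)
        assert all(c.divergence is None and not c.sv_determined
                   for c in hit if not c.reliable)


class TestPlantedStructure:
    def test_planted_deletion_recovered_as_single_gap_run(self):
        fams = build_family_library(1, seed=81)
        bp = ChromosomeBlueprint(
            arm="chrT", length=100_000, compartment_segments=((0, 100_000, "EU"),)
        )
        i0 = fams[0].segments["internal"][0]
        plans = [
            InsertionPlan(
                fams[0].name, "chrT", 50_000, 0.01, "proviral-fragmented",
                indel_spec=(("del", 50, i0 + 400),),
            )
        ]
        sg = synthesize_genome([bp], fams, plans=plans, seed=82)
        cands = scan(fams, sg.genome, index=index_genome(sg.genome))
        res = annotate_genome(sg.genome, fams, cands)
        (copy,) = [c for c in res.copies if c.length > 2000]
        (ev,) = copy.sv_events
        assert ev.type == "del" and abs(ev.size - 50) <= 2 and abs(ev.offset - (i0 + 400)) <= 5

    def test_planted_duplication_called_dup(self):
        fams = build_family_library(1, seed=91)
        bp = ChromosomeBlueprint(
            arm="chrT", length=100_000, compartment_segments=((0, 100_000, "EU"),)
        )
        i0 = fams[0].segments["internal"][0]
        plans = [
            InsertionPlan(
                fams[0].name, "chrT", 50_000, 0.0, "proviral-fragmented",
                indel_spec=(("dup", 300, i0 + 900),),
            )
        ]
        sg = synthesize_genome([bp], fams, plans=plans, seed=92)
        cands = scan(fams, sg.genome, index=index_genome(sg.genome))
        res = annotate_genome(sg.genome, fams, cands)
        (copy,) = [c for c in res.copies if c.length > 2000]
        assert any(e.type == "dup" and abs(e.size - 300) <= 2 for e in copy.sv_events)

    def test_candidate_partition_reconciles(self, small_world):
        """Every scanned candidate ends annotated, rejected by family rules,
        or rejected in overlap competition; condition tallies add up."""
        res = small_world.result
        assert res.reconciles(len(small_world.candidates))
        n = sum(
            1
            for c in res.copies
            if c.condition in ("proviral", "solo-LTR", "unknown")
        )
        assert n == len(res.copies)
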