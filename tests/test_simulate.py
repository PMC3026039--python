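"""Synthetic-genome generator: family models, mutation, assembly, sampling."""

import numpy as np
import pytest
from scipy import stats as sps

from ltrscape import seqs
from ltrscape.alignment import ColumnAlignment
from ltrscape.errors import ParameterError, PlanningError
from ltrscape.families import build_family_library
from ltrscape.simulate import (
    ChromosomeBlueprint,
    InsertionPlan,
    SamplingParams,
    default_blueprints,
    make_solo_ltr,
    mutate_copy,
    sample_plans,
    synthesize_genome,
)


class TestFamilyLibrary:
    def test_forced_ranges_fix_lengths(self):
        (fam,) = build_family_library(1, (200, 200), (6000, 6000), 0.5, seed=1)
        assert len(fam.ltr5) == 200
        assert fam.length == 6000

    def test_deterministic_and_ltr_identity(self):
        a = build_family_library(3, seed=1)
        b = build_family_library(3, seed=1)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.consensus, fb.consensus)
            assert np.array_equal(fa.ltr5, fa.ltr3)

    def test_library_gc_matches_target(self):
        fams = build_family_library(73, (150, 400), (5000, 8000), gc=0.45, seed=7)
        assert len(fams) == 73
        joined = np.concatenate([f.consensus for f in fams])
        assert abs(seqs.gc_fraction(joined) - 0.45) <= 0.02

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_families": 0},
            {"n_families": 1, "ltr_len_range": (400, 200)},
            {"n_families": 1, "total_len_range": (8000, 5000)},
            {"n_families": 1, "gc": 1.5},
            {"n_families": 1, "ltr_len_range": (3000, 3000), "total_len_range": (5000, 5000)},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            build_family_library(**kwargs)


class TestMutateCopy:
    def test_zero_divergence_is_identity(self):
        cons = seqs.random_seq(np.random.default_rng(0), 800, 0.5)
        out, events, n = mutate_copy(cons, 0.0, (), seed=4)
        assert np.array_equal(out, cons)
        assert events == [] and n == 0

    def test_substitution_count_forced_by_rounding(self):
        cons = seqs.random_seq(np.random.default_rng(1), 5000, 0.5)
        out, _, n = mutate_copy(cons, 0.05, (), seed=4)
        assert n == 250
        assert int((out != cons).sum()) == 250

    def test_deletion_shortens_and_divergence_round_trips(self):
        cons = seqs.random_seq(np.random.default_rng(2), 1000, 0.5)
        out, events, _ = mutate_copy(cons, 0.02, (("del", 50, 400),), seed=9)
        assert len(out) == 950
        assert [(e.type, e.size, e.offset) for e in events] == [("del", 50, 400)]
        aln = ColumnAlignment.globally(out, cons)
        assert aln.divergence() == pytest.approx(0.02, abs=0.005)

    def test_overlapping_indel_spec_rejected(self):
        cons = seqs.random_seq(np.random.default_rng(3), 1000, 0.5)
        with pytest.raises(ParameterError):
            mutate_copy(cons, 0.0, (("del", 50, 100), ("ins", 20, 120)), seed=1)


class TestSoloLtr:
    @pytest.mark.parametrize("tsd", ["CTTAT", "CTTC", "CAAG"])
    def test_fragment_is_tsd_ltr_tsd(self, tsd):
        (fam,) = build_family_library(1, (200, 200), (6000, 6000), 0.5, seed=2)
        frag, _ = make_solo_ltr(fam, 0.0, tsd, seed=5)
        assert len(frag) == 200 + 2 * len(tsd)
        assert seqs.decode(frag[: len(tsd)]) == tsd
        assert seqs.decode(frag[-len(tsd) :]) == tsd
        core = frag[len(tsd) : -len(tsd)]
        # identity only over the LTR segment: the core IS the LTR and shares
        # no word with the internal region
        assert np.array_equal(core, fam.ltr5)

    def test_tsd_length_bounds(self):
        (fam,) = build_family_library(1, seed=2)
        with pytest.raises(ParameterError):
            make_solo_ltr(fam, 0.0, "CCCCCCC", seed=1)


def _one_arm_blueprint(length=120_000, label="EU"):
    return ChromosomeBlueprint(
        arm="chrT", length=length, compartment_segments=((0, length, label),)
    )


class TestSynthesizeGenome:
    def test_length_conservation_and_truth_coordinates(self):
        fams = build_family_library(3, seed=4)
        bp = _one_arm_blueprint(200_000)
        plans = [
            InsertionPlan(fams[i % 3].name, "chrT", 20_000 + 50_000 * i, 0.0,
                          "proviral-complete", tsd="CTTAT")
            for i in range(3)
        ]
        sg = synthesize_genome([bp], fams, plans=plans, seed=6)
        planted = sum(
            f.length + 2 * 5 for f in (fams[0], fams[1], fams[2])
        )
        assert len(sg.genome["chrT"]) == 200_000 + planted
        for t in sg.truth:
            fam = {f.name: f for f in fams}[t.family]
            segment = sg.genome["chrT"][t.start : t.end]
            assert np.array_equal(segment, fam.consensus)  # divergence 0, '+'

    def test_empty_plan_list_is_negative_control(self):
        from ltrscape.search import index_genome, scan

        fams = build_family_library(2, seed=5)
        sg = synthesize_genome([_one_arm_blueprint(60_000)], fams, plans=[], seed=3)
        assert sg.truth == []
        cands = scan(fams, sg.genome, index=index_genome(sg.genome))
        confident = [c for c in cands if c.length >= 400]
        assert confident == []

    def test_duplicate_sites_raise_planning_error(self):
        fams = build_family_library(1, seed=5)
        plans = [
            InsertionPlan(fams[0].name, "chrT", 30_000, 0.0, "solo-LTR"),
            InsertionPlan(fams[0].name, "chrT", 30_000, 0.0, "solo-LTR"),
        ]
        with pytest.raises(PlanningError) as err:
            synthesize_genome([_one_arm_blueprint()], fams, plans=plans, seed=1)
        assert err.value.collisions

    def test_reverse_strand_copy_is_reverse_complement(self):
        fams = build_family_library(1, seed=8)
        plans = [InsertionPlan(fams[0].name, "chrT", 40_000, 0.0,
                               "proviral-complete", strand="-")]
        sg = synthesize_genome([_one_arm_blueprint()], fams, plans=plans, seed=2)
        t = sg.truth[0]
        segment = sg.genome["chrT"][t.start : t.end]
        assert np.array_equal(seqs.revcomp(segment), fams[0].consensus)

    def test_byte_identical_for_fixed_seed(self):
        fams = build_family_library(4, seed=9)
        bps = default_blueprints(arm_length=150_000)
        a = synthesize_genome(bps, fams, params=SamplingParams(n_insertions=20), seed=12)
        b = synthesize_genome(bps, fams, params=SamplingParams(n_insertions=20), seed=12)
        for arm in a.genome:
            assert np.array_equal(a.genome[arm], b.genome[arm])
        assert a.truth_frame().equals(b.truth_frame())
        assert a.compartments == b.compartments

    def test_compartment_multipliers_drive_sampling(self):
        # half-heterochromatic arm with multipliers het:6, eu:1; the expected
        # heterochromatic share is 6/7, checked at +-4 binomial sigmas
        fams = build_family_library(4, seed=10)
        n = 600
        bp = ChromosomeBlueprint(
            arm="chrT",
            length=4_000_000,
            compartment_segments=((0, 2_000_000, "PH"), (2_000_000, 4_000_000, "EU")),
            multipliers={"PH": 6.0, "EU": 1.0},
        )
        params = SamplingParams(n_insertions=n, min_separation=50, edge_margin=500)
        plans = sample_plans([bp], fams, params, np.random.default_rng(3))
        het = sum(1 for p in plans if p.site < 2_000_000)
        p_het = 6 / 7
        sigma = np.sqrt(n * p_het * (1 - p_het))
        assert abs(het - n * p_het) <= 4 * sigma

    def test_del_ins_event_ratio_fits_two_to_one(self):
        fams = build_family_library(4, seed=11)
        bps = default_blueprints(arm_length=1_200_000, n_arms=2)
        params = SamplingParams(
            n_insertions=450, p_solo=0.0, p_complete=0.0, p_fragmented=1.0,
            p_gapped=0.0, p_masked=0.0,
        )
        plans = sample_plans(bps, fams, params, np.random.default_rng(5))
        kinds = [k for p in plans for k, _s, _o in p.indel_spec]
        n_del = kinds.count("del")
        n_ins = kinds.count("ins")
        assert n_del + n_ins >= 500
        chi2 = sps.chisquare([n_del, n_ins], f_exp=[(n_del + n_ins) * 2 / 3,
                                                   (n_del + n_ins) / 3])
        assert chi2.pvalue > 0.01

    def test_realized_divergence_within_half_point(self, bench_world):
        """Indel-free planted copies >=1 kb measured back by the annotation
        stage land within 0.5 percentage points of their target divergence."""
        pairs = [
            (t, c)
            for t, c in bench_world.matched_pairs()
            if not t.events and not t.has_n_gap and t.length >= 1000
            and c.divergence is not None
        ]
        assert len(pairs) >= 50
        for t, c in pairs:
            assert abs(c.divergence - t.true_divergence) <= 0.005
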