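"""Compartments, PE derivation, clustering, gene association, densities."""

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from ltrscape.context import (
    CompartmentMap,
    assign_compartment,
    associate_genes,
    breakpoint_neighborhood_density,
    cluster_insertions,
    derive_pericentromeric_euchromatin,
    region_density,
    windowed_density,
)
from ltrscape.errors import ParameterError
from ltrscape.simulate import Gene


@dataclass
class Iv:
    """Minimal interval record standing in for an annotated copy."""

    arm: str
    start: int
    end: int
    id: str = "x"
    condition: str = "proviral"
    fragmentation: str = "complete"
    divergence: float = 0.01


class TestPeDerivation:
    def test_x_arm_pe_matches_assembly_coordinates(self):
        # X: euchromatin from the telomere, PH proximal at the high end;
        # walking 3 Mb back from the PH boundary gives the assembly PE span
        ph_start = 19_928_574
        cmap = CompartmentMap.from_intervals(
            [("X", 0, ph_start, "EU"), ("X", ph_start, 24_393_108, "PH")]
        )
        derived = derive_pericentromeric_euchromatin(cmap)
        pe = derived.regions("PE")
        assert pe == [("X", 16_928_574, 19_928_574)]

    def test_2l_pe_walk_skips_intercalary_heterochromatin(self):
        # 2L architecture: PH, euchromatin, a DIH block, more euchromatin;
        # the 3 Mb walk spans two euchromatic segments around the DIH
        eu1_start = 2_487_769
        dih_start, dih_end = 5_042_389, 6_015_227
        cmap = CompartmentMap.from_intervals(
            [
                ("2L", 0, eu1_start, "PH"),
                ("2L", eu1_start, dih_start, "EU"),
                ("2L", dih_start, dih_end, "DIH"),
                ("2L", dih_end, 49_364_325, "EU"),
            ]
        )
        derived = derive_pericentromeric_euchromatin(cmap)
        pe = sorted(derived.regions("PE"))
        assert pe[0] == ("2L", eu1_start, dih_start)
        (arm, s, e) = pe[1]
        assert (s, e)[0] == dih_end
        total = sum(e - s for _a, s, e in pe)
        assert total == 3_000_000
        # the published two-segment span sums to ~3.0 Mb by the same walk
        assert (5_042_389 - 2_487_770 + 1) + (6_460_609 - 6_015_228 + 1) == 3_000_002

    def test_arm_without_ph_is_all_npe_with_warning(self):
        cmap = CompartmentMap.from_intervals([("A", 0, 5_000_000, "EU")])
        with pytest.warns(UserWarning):
            derived = derive_pericentromeric_euchromatin(cmap)
        assert derived.regions("PE") == []
        assert derived.regions("NPE") == [("A", 0, 5_000_000)]

    def test_small_arm_is_all_pe_with_warning(self):
        cmap = CompartmentMap.from_intervals(
            [("B", 0, 1_000_000, "PH"), ("B", 1_000_000, 2_500_000, "EU")]
        )
        with pytest.warns(UserWarning):
            derived = derive_pericentromeric_euchromatin(cmap)
        assert derived.regions("PE") == [("B", 1_000_000, 2_500_000)]


class TestAssignCompartment:
    CMAP = CompartmentMap.from_intervals(
        [("c", 0, 1000, "PH"), ("c", 1000, 3000, "EU")]
    )

    def test_midpoint_inside_ph(self):
        assert assign_compartment(Iv("c", 100, 300), self.CMAP) == "PH"

    def test_straddling_copy_takes_midpoint_side(self):
        assert assign_compartment(Iv("c", 900, 1300), self.CMAP) == "EU"
        assert assign_compartment(Iv("c", 700, 1100), self.CMAP) == "PH"

    def test_unmapped_arm_is_unplaced(self):
        assert assign_compartment(Iv("zzz", 0, 10), self.CMAP) == "unplaced"

    def test_planted_copies_recover_their_compartment(self, small_world):
        cmap = CompartmentMap.from_intervals(small_world.sg.compartments)
        for t, c in small_world.matched_pairs():
            assert assign_compartment(c, cmap) == t.compartment


class TestClustering:
    def test_single_linkage_transitivity(self):
        a = Iv("c", 0, 1000)
        b = Iv("c", 9000, 9500)  # 8 kb from a
        c = Iv("c", 17_500, 18_000  )  # 8 kb from b, 16.5 kb from a
        clusters, n = cluster_insertions([a, b, c], 10_000)
        assert [sorted(cl) for cl in clusters] == [[0, 1, 2]]
        assert n == 3

    def test_exact_boundary_is_inclusive_and_10001_is_not(self):
        a = Iv("c", 0, 1000)
        assert cluster_insertions([a, Iv("c", 11_000, 11_500)], 10_000)[1] == 2
        assert cluster_insertions([a, Iv("c", 11_001, 11_500)], 10_000)[1] == 0

    def test_matches_brute_force_connected_components(self):
        rng = np.random.default_rng(8)
        for trial in range(50):
            n = int(rng.integers(5, 45))
            starts = np.sort(rng.integers(0, 300_000, n))
            lens = rng.integers(100, 5000, n)
            copies = [Iv("c", int(s), int(s + l)) for s, l in zip(starts, lens)]
            clusters, _ = cluster_insertions(copies, 10_000)
            # quadratic union-find oracle on the edge-distance graph
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in range(n):
                for j in range(i + 1, n):
                    gap = max(
                        copies[j].start - copies[i].end,
                        copies[i].start - copies[j].end,
                    )
                    if gap <= 10_000:
                        parent[find(i)] = find(j)
            oracle = {}
            for i in range(n):
                oracle.setdefault(find(i), set()).add(i)
            assert sorted(map(sorted, clusters)) == sorted(
                map(sorted, (sorted(v) for v in oracle.values()))
            )

    def test_start_mode_switch(self):
        a = Iv("c", 0, 9000)
        b = Iv("c", 9500, 9600)  # edge gap 500, start gap 9500
        c = Iv("c", 30_000, 30_100)
        assert cluster_insertions([a, b, c], 1000, mode="edge")[1] == 2
        assert cluster_insertions([a, b, c], 1000, mode="start")[1] == 0


class TestGeneAssociation:
    GENE = Gene("G1", "c", 10_000, 18_000, "+", ((10_000, 11_000), (15_000, 18_000)))

    def test_upstream_within_flank_is_five_prime(self):
        (assoc,) = associate_genes([Iv("c", 9_000, 9_841, id="i")], [self.GENE])
        assert (assoc.proximity, assoc.region) == (159, "5'")

    def test_between_exons_is_intron_at_zero_proximity(self):
        (assoc,) = associate_genes([Iv("c", 12_000, 13_000)], [self.GENE])
        assert (assoc.proximity, assoc.region) == (0, "intron")

    def test_exon_overlap_wins(self):
        (assoc,) = associate_genes([Iv("c", 10_500, 12_000)], [self.GENE])
        assert assoc.region == "exon"

    def test_flank_boundary_excludes_1001(self):
        assert associate_genes([Iv("c", 8_000, 8_999)], [self.GENE]) == []
        assert associate_genes([Iv("c", 8_000, 9_000)], [self.GENE]) != []

    def test_minus_strand_flips_sides(self):
        gene = Gene("G2", "c", 10_000, 18_000, "-", ((10_000, 18_000),))
        (up,) = associate_genes([Iv("c", 18_200, 18_400)], [gene])
        assert up.region == "5'"
        (down,) = associate_genes([Iv("c", 9_500, 9_800)], [gene])
        assert down.region == "3'"

    def test_copy_can_hit_multiple_genes(self):
        g2 = Gene("G2", "c", 19_500, 22_000, "+", ((19_500, 22_000),))
        assocs = associate_genes([Iv("c", 18_500, 19_000)], [self.GENE, g2])
        assert {a.gene_id for a in assocs} == {"G1", "G2"}


class TestDensities:
    def test_published_density_arithmetic(self):
        copies = [Iv("r", i * 50_000, i * 50_000 + 300) for i in range(226)]
        stats = region_density(copies, [("r", 0, 12_230_000)], "PH")
        assert stats.per_mb == pytest.approx(18.48, abs=0.01)

    def test_empty_and_zero_size_regions(self):
        stats = region_density([], [("r", 0, 1_000_000)], "empty")
        assert stats.n_insertions == 0 and stats.per_mb == 0
        with pytest.raises(ParameterError):
            region_density([], [], "null")

    def test_window_bp_share(self):
        copies = [Iv("c", 10_000, 15_000)]
        df = windowed_density(copies, "c", 150_000, 50_000)
        assert df["pct_bp"].iloc[0] == pytest.approx(10.0)

    def test_straddling_copy_splits_between_windows(self):
        copies = [Iv("c", 45_000, 55_000)]
        df = windowed_density(copies, "c", 150_000, 50_000)
        assert df["pct_bp"].iloc[0] == pytest.approx(10.0)
        assert df["pct_bp"].iloc[1] == pytest.approx(10.0)

    def test_window_counts_conserve_total(self, small_world):
        copies = small_world.copies
        for arm, codes in small_world.sg.genome.items():
            df = windowed_density(copies, arm, len(codes), 50_000)
            assert df["count"].sum() == sum(1 for c in copies if c.arm == arm)


class TestBreakpoints:
    def test_copies_planted_only_in_flanks(self):
        p, d = 2_000_000, 6_000_000
        copies = [Iv("c", p - 40_000 + i * 10_000, p - 40_000 + i * 10_000 + 2000) for i in range(4)]
        copies += [Iv("c", d + 5_000 + i * 10_000, d + 5_000 + i * 10_000 + 2000) for i in range(4)]
        dens = breakpoint_neighborhood_density(copies, "c", (0, 8_000_000), (p, d))
        assert dens["proximal_flank_out"]["pct"] > 5
        assert dens["distal_flank_out"]["pct"] > 5
        inside_mid = dens["inside"]["te_bp"] - dens["distal_flank_in"]["te_bp"]
        assert inside_mid == 0

    def test_region_bp_totals_conserve_arm_span(self):
        dens = breakpoint_neighborhood_density(
            [], "c", (0, 8_000_000), (2_000_000, 6_000_000)
        )
        total = (
            dens["proximal_side"]["bp"] + dens["inside"]["bp"] + dens["distal_side"]["bp"]
        )
        assert total == 8_000_000

    def test_uniform_placement_matches_global_density(self):
        rng = np.random.default_rng(9)
        n = 500
        arm_len = 10_000_000
        starts = rng.integers(0, arm_len - 2000, n)
        copies = [Iv("c", int(s), int(s) + 1000) for s in starts]
        dens = breakpoint_neighborhood_density(
            copies, "c", (0, arm_len), (3_000_000, 7_000_000)
        )
        global_rate = n / arm_len
        for name in ("proximal_side", "inside", "distal_side", "proximal_centered"):
            r = dens[name]
            lam = global_rate * r["bp"]
            # 5-sigma binomial envelope around the expected count
            assert abs(r["count"] - lam) <= 5 * np.sqrt(lam)

    def test_breakpoints_outside_span_rejected(self):
        with pytest.raises(ParameterError):
            breakpoint_neighborhood_density([], "c", (0, 100), (50, 500))
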