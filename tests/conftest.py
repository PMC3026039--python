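"""Shared fixtures: synthetic worlds scanned and annotated once per session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from ltrscape import seqs
from ltrscape.annotate import annotate_genome
from ltrscape.families import build_family_library
from ltrscape.search import index_genome, scan
from ltrscape.simulate import SamplingParams, default_blueprints, synthesize_genome


def overlap(a, b):
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass
class World:
    """A synthetic genome with its scan/annotation results and truth match."""

    sg: object
    families: list
    candidates: list
    result: object
    matches: dict  # truth copy_id -> AnnotatedCopy (>=90% overlap of truth)

    @property
    def copies(self):
        return self.result.copies

    def matched_pairs(self):
        by_id = {t.copy_id: t for t in self.sg.truth}
        return [(by_id[cid], c) for cid, c in self.matches.items()]


def build_world(n_families, arm_length, n_insertions, seed, n_arms=2, params=None):
    families = build_family_library(n_families, seed=seed + 1)
    blueprints = default_blueprints(arm_length=arm_length, n_arms=n_arms)
    params = params or SamplingParams(n_insertions=n_insertions)
    sg = synthesize_genome(blueprints, families, params=params, seed=seed)
    candidates = scan(families, sg.genome, index=index_genome(sg.genome))
    result = annotate_genome(sg.genome, families, candidates)
    matches = {}
    for t in sg.truth:
        for c in result.copies:
            if c.arm == t.arm and overlap((t.start, t.end), (c.start, c.end)) >= 0.9 * (
                t.end - t.start
            ):
                matches[t.copy_id] = c
                break
    return World(sg, families, candidates, result, matches)


@pytest.fixture(scope="session")
def small_world():
    """~50 planted copies on two 300-kb arms; fast, used by unit tests."""
    return build_world(n_families=6, arm_length=300_000, n_insertions=50, seed=17)


@pytest.fixture(scope="session")
def bench_world():
    """Default study-scale genome: >=100 proviral copies at <=5% divergence
    and >=50 indel-free copies >=1 kb."""
    return build_world(n_families=10, arm_length=1_100_000, n_insertions=400, seed=101)


@pytest.fixture(scope="session")
def sw_oracle():
    """Exhaustive local-alignment scorer (Biopython C implementation) under
    the search scoring scheme: +1/-2, gap of length g costs 5+2g, N is 0."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    m = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGT":
        for y in "ACGT":
            m[x, y] = 1.0 if x == y else -2.0
        m[x, "N"] = 0
        m["N", x] = 0
    m["N", "N"] = 0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2

    def score(a, b):
        return float(aligner.score(seqs.decode(a), seqs.decode(b)))

    return score


def mutated_pair(rng, length, sub_rate=0.06, n_indels=2, max_indel=5, with_n=False):
    """A random sequence and a mutated relative (subs + small indels)."""
    a = seqs.random_seq(rng, length, 0.5)
    b = a.copy()
    nsub = int(sub_rate * length)
    if nsub:
        pos = rng.choice(length, nsub, replace=False)
        b[pos] = (b[pos] + rng.integers(1, 4, nsub)) % 4
    b = list(b)
    for _ in range(int(rng.integers(0, n_indels + 1))):
        off = int(rng.integers(10, max(11, len(b) - 10)))
        size = int(rng.integers(1, max_indel + 1))
        if rng.random() < 0.5:
            del b[off : off + size]
        else:
            b[off:off] = list(rng.integers(0, 4, size))
    b = np.array(b, dtype=np.uint8)
    if with_n:
        off = int(rng.integers(5, max(6, len(b) - 15)))
        b[off : off + 8] = seqs.N
    return a, b
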