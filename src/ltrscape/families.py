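"""LTR retrotransposon family models.

A family is represented by its consensus sequence segmented into LTR5,
internal region and LTR3 (the two LTRs are identical at generation time,
as they are at the moment of transposition), plus a lineage label from the
insect Ty3/gypsy lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqs
from .errors import ConfigurationError, ParameterError

#: Ty3/gypsy lineages observed in Anopheles gambiae (Osvaldo is absent).
LINEAGES = ("CsRn1", "Gypsy", "Mag", "Mdg1", "Mdg3")


@dataclass(frozen=True)
class FamilyModel:
    """Consensus model of one LTRr family with LTR/internal segmentation."""

    name: str
    lineage: str
    ltr5: np.ndarray
    internal: np.ndarray
    ltr3: np.ndarray

    def __post_init__(self):
        if self.lineage not in LINEAGES:
            raise ConfigurationError(f"unknown lineage {self.lineage!r}")
        if len(self.ltr5) < 100 or len(self.ltr3) < 100:
            raise ConfigurationError("LTR length must be >= 100 bp")

    @property
    def consensus(self) -> np.ndarray:
        return np.concatenate([self.ltr5, self.internal, self.ltr3])

    @property
    def length(self) -> int:
        return len(self.ltr5) + len(self.internal) + len(self.ltr3)

    @property
    def ltr_len(self) -> int:
        return len(self.ltr5)

    @property
    def segments(self) -> dict[str, tuple[int, int]]:
        """0-based half-open consensus spans of LTR5, internal, LTR3."""
        l5 = len(self.ltr5)
        li = len(self.internal)
        return {
            "LTR5": (0, l5),
            "internal": (l5, l5 + li),
            "LTR3": (l5 + li, self.length),
        }

    def segment_of(self, pos: int) -> str:
        for label, (s, e) in self.segments.items():
            if s <= pos < e:
                return label
        raise IndexError(pos)


def build_family_library(
    n_families: int,
    ltr_len_range: tuple[int, int] = (200, 400),
    total_len_range: tuple[int, int] = (5000, 8000),
    gc: float = 0.45,
    seed: int = 0,
) -> list[FamilyModel]:
    """Generate ``n_families`` independent random consensus models.

    LTR and total lengths are drawn uniformly from the given (inclusive)
    ranges; the internal region takes the remainder.  Within each model
    LTR5 == LTR3.  Deterministic for a fixed seed.
    """
    if n_families < 1:
        raise ParameterError("n_families must be >= 1")
    lo_l, hi_l = ltr_len_range
    lo_t, hi_t = total_len_range
    if not (100 <= lo_l <= hi_l):
        raise ParameterError(f"invalid ltr_len_range {ltr_len_range}")
    if not (0 < lo_t <= hi_t):
        raise ParameterError(f"invalid total_len_range {total_len_range}")
    if lo_t - 2 * hi_l < 0:
        raise ParameterError("total_len_range too small for two LTRs")
    if not 0 < gc < 1:
        raise ParameterError("gc must be in (0, 1)")

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_families):
        ltr_len = int(rng.integers(lo_l, hi_l + 1))
        total = int(rng.integers(max(lo_t, 2 * ltr_len), hi_t + 1))
        ltr = seqs.random_seq(rng, ltr_len, gc)
        internal = seqs.random_seq(rng, total - 2 * ltr_len, gc)
        lineage = LINEAGES[int(rng.integers(len(LINEAGES)))]
        out.append(
            FamilyModel(
                name=f"{lineage}-Ag{i + 1}",
                lineage=lineage,
                ltr5=ltr,
                internal=internal,
                ltr3=ltr.copy(),
            )
        )
    return out


def write_library(families, fasta_path, segments_path) -> None:
    """Write the consensus FASTA plus the companion segmentation table."""
    seqs.write_fasta(fasta_path, {f.name: f.consensus for f in families})
    rows = []
    for f in families:
        seg = f.segments
        rows.append(
            {
                "family": f.name,
                "lineage": f.lineage,
                # companion table is 1-based inclusive, like every emitted table
                "ltr5_start": seg["LTR5"][0] + 1,
                "ltr5_end": seg["LTR5"][1],
                "internal_start": seg["internal"][0] + 1,
                "internal_end": seg["internal"][1],
                "ltr3_start": seg["LTR3"][0] + 1,
                "ltr3_end": seg["LTR3"][1],
            }
        )
    pd.DataFrame(rows).to_csv(segments_path, sep="\t", index=False)


def read_library(fasta_path, segments_path) -> list[FamilyModel]:
    consensi = seqs.read_fasta(fasta_path)
    table = pd.read_csv(segments_path, sep="\t", comment="#")
    out = []
    for row in table.itertuples():
        cons = consensi[row.family]
        l5e = int(row.ltr5_end)
        ie = int(row.internal_end)
        out.append(
            FamilyModel(
                name=row.family,
                lineage=row.lineage,
                ltr5=cons[:l5e],
                internal=cons[l5e:ie],
                ltr3=cons[ie:],
            )
        )
    return out
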