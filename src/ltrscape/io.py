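"""Readers and writers for the pipeline's tables and annotation formats.

Conventions: every emitted table is tab-separated with '#' provenance
headers and 1-based inclusive coordinates (the census convention); BED is
the exception, 0-based half-open per that standard.  The copies table uses
the census supplementary-dataset dialect (lineage, family, coordinates,
condition, divergence in % with one decimal or 'ND', SV strings like
``del120(5′), ins45``) plus implementation columns that round-trip the full
AnnotatedCopy record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotatedCopy
from .simulate import Gene
from .sv import format_sv, parse_sv

S1_COLUMNS = [
    "lineage", "family", "scaffold", "scaffold_start", "scaffold_end",
    "chrom", "chrom_start", "chrom_end", "band", "condition", "divergence", "sv",
]
EXTRA_COLUMNS = [
    "copy_id", "strand", "fragmentation", "partial", "tsd", "rule",
    "reliable", "compartment", "cluster", "cons_start", "cons_end",
]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _fmt_div(div) -> str:
    return "ND" if div is None else f"{100 * div:.1f}"


def copies_to_frame(copies: list) -> pd.DataFrame:
    rows = []
    for c in copies:
        rows.append(
            {
                "lineage": c.lineage,
                "family": c.family,
                "scaffold": c.arm,
                "scaffold_start": c.start + 1,
                "scaffold_end": c.end,
                "chrom": c.arm,
                "chrom_start": c.start + 1,
                "chrom_end": c.end,
                "band": "NA",
                "condition": c.condition,
                "divergence": _fmt_div(c.divergence),
                "sv": format_sv(c.sv_events, c.sv_determined),
                "copy_id": c.id,
                "strand": c.strand,
                "fragmentation": c.fragmentation,
                "partial": "ND" if c.partial is None else str(bool(c.partial)),
                "tsd": c.tsd or "NA",
                "rule": c.rule,
                "reliable": c.reliable,
                "compartment": c.compartment or "NA",
                "cluster": -1 if c.cluster is None else c.cluster,
                "cons_start": c.cons_start,
                "cons_end": c.cons_end,
            }
        )
    return pd.DataFrame(rows, columns=S1_COLUMNS + EXTRA_COLUMNS)


def write_copies(copies: list, path, meta: dict | None = None) -> None:
    write_table(copies_to_frame(copies), path, meta)


def _parse_div(text) -> float | None:
    t = str(text).strip()
    if t.upper() in ("ND", "N. D.", "NAN", "NA", ""):
        return None
    return float(t) / 100.0


def frame_to_copies(df: pd.DataFrame) -> list:
    """Rebuild AnnotatedCopy records from a copies table (census dialect)."""
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        events, determined = parse_sv(d.get("sv", "ND"))
        div = _parse_div(d.get("divergence", "ND"))
        partial = d.get("partial", "ND")
        partial = None if str(partial) == "ND" else str(partial) == "True"
        cluster = d.get("cluster", -1)
        out.append(
            AnnotatedCopy(
                id=str(d.get("copy_id", f"ROW{i:05d}")),
                family=str(d["family"]),
                lineage=str(d["lineage"]),
                arm=str(d.get("chrom", d.get("scaffold"))),
                start=int(d.get("chrom_start", d.get("scaffold_start"))) - 1,
                end=int(d.get("chrom_end", d.get("scaffold_end"))),
                strand=str(d.get("strand", "+")),
                condition=str(d["condition"]),
                divergence=div,
                sv_events=events or [],
                sv_determined=determined,
                fragmentation=str(d.get("fragmentation", "unknown")),
                partial=partial,
                tsd=None if str(d.get("tsd", "NA")) == "NA" else str(d.get("tsd")),
                rule=str(d.get("rule", "imported")),
                reliable=bool(d.get("reliable", True)),
                cons_start=int(d.get("cons_start", 0)),
                cons_end=int(d.get("cons_end", 0)),
                compartment=None if str(d.get("compartment", "NA")) == "NA" else str(d.get("compartment")),
                cluster=None if int(cluster) < 0 else int(cluster),
            )
        )
    return out


def read_copies(path) -> list:
    return frame_to_copies(read_table(path))


def import_dataset_s1(path) -> list:
    """Import a census supplementary table (TSV or XLSX) of insertions.

    Expects the supplementary-dataset column layout (lineage, family,
    scaffold and chromosome coordinates, condition, divergence %, SV
    string); 'ND' fields become undetermined, malformed SV tokens downgrade
    that row's SV to undetermined with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = read_table(path)
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    return frame_to_copies(df)


# ---------------------------------------------------------------------------
# BED / GFF3


def write_bed(intervals, path, meta: dict | None = None) -> None:
    """Compartment intervals as BED (0-based half-open, label in column 4)."""
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        for arm, start, end, label in intervals:
            fh.write(f"{arm}\t{start}\t{end}\t{label}\n")


def read_bed(path) -> list:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["arm", "start", "end", "label"],
    )
    return [(r.arm, int(r.start), int(r.end), r.label) for r in df.itertuples()]


def write_gff3(genes, path, meta: dict | None = None) -> None:
    """Gene models as GFF3 (gene/mRNA/exon, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_header_lines(meta))
        for g in genes:
            attrs = f"ID={g.id}"
            fh.write(
                f"{g.arm}\tltrscape\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.id}.t1"
            fh.write(
                f"{g.arm}\tltrscape\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.id}\n"
            )
            for j, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.arm}\tltrscape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{j};Parent={mrna}\n"
                )


def read_gff3(path) -> list:
    """Genes (with exon sub-intervals) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = []
        for mrna in db.children(g, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon"):
                exons.append((ex.start - 1, ex.end))
        if not exons:
            for ex in db.children(g, featuretype="exon"):
                exons.append((ex.start - 1, ex.end))
        genes.append(
            Gene(
                id=g.id,
                arm=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                exons=tuple(sorted(exons)),
            )
        )
    genes.sort(key=lambda g: (g.arm, g.start))
    return genes


def write_json(obj, path, meta: dict | None = None) -> None:
    payload = {"meta": meta or {}, **obj} if isinstance(obj, dict) else obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(type(x))
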