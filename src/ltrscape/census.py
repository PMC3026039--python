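"""The published AgamP3 Ty3/gypsy census tables and their headline statistics.

The packaged TSVs carry the per-arm, per-heterochromatin-type and
per-euchromatin-type summaries of the 1045-copy complement of the
An. gambiae AgamP3 assembly (counts, condition splits, region sizes,
divergences).  ``headline_statistics`` recomputes the census's enrichment
tests and density figures from those tables — nothing here is a stored
result; every statistic is derived from the table counts and sizes at call
time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import chisq_2x2, chisq_gof_region, ttest_divergence


def _load(name: str) -> pd.DataFrame:
    with resources.files("ltrscape.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_arm_census() -> pd.DataFrame:
    return _load("agamp3_arms.tsv")


def load_het_census() -> pd.DataFrame:
    return _load("agamp3_heterochromatin.tsv")


def load_eu_census() -> pd.DataFrame:
    return _load("agamp3_euchromatin.tsv")


def genome_summary() -> dict:
    df = _load("agamp3_genome.tsv")
    return dict(zip(df["quantity"], df["value"]))


def _row(df: pd.DataFrame, region: str) -> pd.Series:
    return df.set_index("region").loc[region]


def headline_statistics() -> dict:
    """Recompute the census headline statistics from the packaged tables."""
    arms = load_arm_census()
    het = load_het_census()
    eu = load_eu_census()
    gen = genome_summary()

    total = _row(arms, "Total")
    x = _row(arms, "X")
    x_over = chisq_gof_region(
        int(x["insertions"]),
        int(total["insertions"] - x["insertions"]),
        float(x["size_mb"]),
        float(total["size_mb"] - x["size_mb"]),
    )

    short = arms[arms["region"].isin(["2L", "3L"])]
    long_ = arms[arms["region"].isin(["2R", "3R"])]
    short_over = chisq_gof_region(
        int(short["insertions"].sum()),
        int(long_["insertions"].sum()),
        float(short["size_mb"].sum()),
        float(long_["size_mb"].sum()),
    )

    pe = _row(eu, "Total_PE")
    npe = _row(eu, "Total_NPE")
    pe_over = chisq_gof_region(
        int(pe["insertions"]), int(npe["insertions"]),
        float(pe["size_mb"]), float(npe["size_mb"]),
    )

    ph = _row(het, "Total_PH")
    cond = chisq_2x2(
        int(ph["proviral"]), int(ph["solo"]), int(npe["proviral"]), int(npe["solo"])
    )

    het_arm_means = [
        float(_row(het, r)["mean_div"]) for r in ("2L_H", "2R_H", "3L_H", "3R_H", "X_H")
    ]
    npe_arm_means = [
        float(_row(eu, r)["mean_div"])
        for r in ("2L_NPE", "2R_NPE", "3L_NPE", "3R_NPE", "X_NPE")
    ]
    t, df, p = ttest_divergence(het_arm_means, npe_arm_means, "pooled")

    return {
        "chisq_x_overrepresentation": x_over.chi2,
        "chisq_short_arm_excess": short_over.chi2,
        "chisq_pe_enrichment": pe_over.chi2,
        "chisq_condition_ph_vs_npe": cond.chi2,
        "density_ph_per_mb": float(ph["insertions"] / ph["size_mb"]),
        "density_genome_per_mb": float(total["insertions"] / total["size_mb"]),
        "het_bp_share_pct": float(
            100.0 * _row(het, "Total_H")["ltr_bp"] / total["ltr_bp"]
        ),
        "x_insertion_share_pct": float(100.0 * x["insertions"] / total["insertions"]),
        "genome_fraction_pct": float(
            100.0 * gen["total_ltr_bp"] / gen["assembly_bp"]
        ),
        "t_het_vs_npe_divergence": t,
        "p_het_vs_npe_divergence": p,
        "n_copies_mapped": int(total["insertions"]),
    }
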