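"""Accounting helpers that turn per-location count tables into the
individual-level inputs of :func:`hybridscan.mtdna.introgression_summary`
and summarise hybrid detections.

Count tables are a lossless representation of the individual-level labels
they summarise (each individual contributes one clade and one genetic
label), so expanding them reconstructs inputs on which the full accounting
can be recomputed and cross-checked.
"""

from __future__ import annotations

import pandas as pd


def expand_mtdna_counts(
    counts: pd.DataFrame,
    hybrid_by_location: pd.DataFrame | None = None,
    hybrid_by_class: pd.DataFrame | None = None,
) -> tuple[dict, dict, pd.DataFrame, dict]:
    """Individual-level (clade, genetic label, metadata, hybrid class) maps
    from per-location counts.

    ``counts`` rows carry, per location: numbers of sequenced individuals
    genetically assigned to each species and how many of each carry the
    clade atypical for their species.  Hybrid tables carry clade counts of
    genetic hybrids by location and by genotype class.
    """
    clade: dict[str, str] = {}
    genetic: dict[str, str] = {}
    meta_rows = []
    k = 0

    def add(loc: str, ctx: str, sp: str, cl: str, n: int) -> None:
        nonlocal k
        for _ in range(int(n)):
            sid = f"ind{k}"
            k += 1
            clade[sid] = cl
            genetic[sid] = sp
            meta_rows.append({"sample_id": sid, "location": loc, "context": ctx})

    for _, r in counts.iterrows():
        loc, ctx = r["location"], r["context"]
        add(loc, ctx, "fabalis", "II", r["intro_fab_n"])
        add(loc, ctx, "fabalis", "I", r["n_fabalis"] - r["intro_fab_n"])
        add(loc, ctx, "obtusata", "I", r["intro_obt_n"])
        add(loc, ctx, "obtusata", "II", r["n_obtusata"] - r["intro_obt_n"])

    hybrid_classes: dict[str, str] = {}
    if hybrid_by_location is not None:
        for _, r in hybrid_by_location.iterrows():
            for cl, n in (("I", r["clade_I"]), ("II", r["clade_II"])):
                for _ in range(int(n)):
                    sid = f"hyb{k}"
                    k += 1
                    clade[sid] = cl
                    genetic[sid] = "hybrid"
                    meta_rows.append(
                        {"sample_id": sid, "location": r["location"], "context": "sympatric"}
                    )
    if hybrid_by_class is not None:
        for _, r in hybrid_by_class.iterrows():
            for cl, n in (("I", r["clade_I"]), ("II", r["clade_II"])):
                for _ in range(int(n)):
                    sid = f"hybc{k}"
                    k += 1
                    clade[sid] = cl
                    # a class-assigned hybrid need not be an admixture hybrid
                    genetic[sid] = "hybrid_class_only"
                    hybrid_classes[sid] = r["hybrid_class"]
                    meta_rows.append(
                        {"sample_id": sid, "location": "CLASSPOOL", "context": "sympatric"}
                    )
    return clade, genetic, pd.DataFrame(meta_rows), hybrid_classes


def summarize_hybrid_counts(counts: pd.DataFrame) -> dict:
    """Totals over a per-location hybrid-detection table.

    Returns the summed hybrid counts of the admixture analysis (global and
    local scale) and of the genotype-class analysis, the numbers of
    locations where each detected hybrids, and per-location percentages
    relative to the analysed sample sizes.
    """
    df = counts.copy()
    df["admixture_pct"] = 100.0 * df["admixture_hybrids"] / df["n_analyzed"]
    df["class_pct"] = 100.0 * df["class_hybrids"] / df["n_analyzed"]
    return {
        "n_analyzed": int(df["n_analyzed"].sum()),
        "n_assigned": int(df["n_assigned"].sum()),
        "admixture_hybrids_total": int(df["admixture_hybrids"].sum()),
        "admixture_locations_with_hybrids": int((df["admixture_hybrids"] > 0).sum()),
        "local_hybrids_total": int(df["local_hybrids"].sum()),
        "class_hybrids_total": int(df["class_hybrids"].sum()),
        "class_locations_with_hybrids": int((df["class_hybrids"] > 0).sum()),
        "per_location": df,
    }
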