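"""Multi-criterion hit calling for the in vivo screen.

A gene is a hit when, among its hairpins enriched more than ``fold_thresh``
(strictly) in at least one tumor and detected above a raw-count floor:

1. at least ``min_shrnas`` distinct hairpins are enriched (in any tumor);
2. the gene's enriched hairpins are observed in at least ``min_tumors``
   independent xenograft tumors;
3. ... and in at least ``min_lines`` different GBM lines.

Criteria 2/3 are evaluated at gene level by default; ``per_shrna=True``
requires a single hairpin to recur across tumors/lines instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError


@dataclass(frozen=True)
class HitCriteria:
    fold_thresh: float = 3.0
    min_shrnas: int = 2
    min_tumors: int = 2
    min_lines: int = 2
    detection_min_count: int = 10

    def __post_init__(self):
        if self.fold_thresh <= 0:
            raise InvalidParameterError("fold_thresh must be > 0")
        for name in ("min_shrnas", "min_tumors", "min_lines", "detection_min_count"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")


def enriched_set(table: pd.DataFrame, criteria: HitCriteria = HitCriteria()) -> pd.DataFrame:
    """Rows with fold_change strictly above the threshold and tumor count >= floor.

    The detection floor is applied before thresholding so pseudocount-driven
    fold artifacts at near-zero counts never qualify.
    """
    if len(table) == 0:
        raise InvalidParameterError("empty enrichment table")
    detected = table["tumor_count"] >= criteria.detection_min_count
    return table[detected & (table["fold_change"] > criteria.fold_thresh)].copy()


def call_hits(
    table: pd.DataFrame,
    criteria: HitCriteria = HitCriteria(),
    per_shrna: bool = False,
) -> pd.DataFrame:
    """Evaluate the three reproducibility criteria per gene.

    ``table`` is an annotated enrichment table (columns gene, shrna_id,
    tumor_sample, line_id, tumor_count, fold_change).  Returns one row per
    gene with the criterion counts, ``is_hit``, and max fold, sorted by
    n_lines, n_tumors, then max fold, all descending.  Supporting rows are
    attached as ``result.attrs["support"]``.
    """
    for col in ("gene", "shrna_id", "tumor_sample", "line_id", "tumor_count", "fold_change"):
        if col not in table.columns:
            raise InvalidParameterError(f"enrichment table missing column {col!r}")
    if table["tumor_sample"].isna().any() or table["line_id"].isna().any():
        raise InvalidParameterError("missing tumor/line annotation")
    enr = enriched_set(table, criteria)
    genes = pd.Index(sorted(table["gene"].dropna().unique()), name="gene")
    if len(enr):
        by_gene = enr.groupby("gene")
        n_shrnas = by_gene["shrna_id"].nunique()
        if per_shrna:
            per = enr.groupby(["gene", "shrna_id"]).agg(
                t=("tumor_sample", "nunique"), l=("line_id", "nunique")
            )
            n_tumors = per.groupby("gene")["t"].max()
            n_lines = per.groupby("gene")["l"].max()
        else:
            n_tumors = by_gene["tumor_sample"].nunique()
            n_lines = by_gene["line_id"].nunique()
        max_fold = by_gene["fold_change"].max()
    else:
        n_shrnas = n_tumors = n_lines = max_fold = pd.Series(dtype=float)
    out = pd.DataFrame(
        {
            "n_enriched_shrnas": n_shrnas.reindex(genes).fillna(0).astype(int),
            "n_tumors_with_enrichment": n_tumors.reindex(genes).fillna(0).astype(int),
            "n_lines_with_enrichment": n_lines.reindex(genes).fillna(0).astype(int),
            "max_fold": max_fold.reindex(genes).fillna(0.0),
        },
        index=genes,
    )
    out["is_hit"] = (
        (out["n_enriched_shrnas"] >= criteria.min_shrnas)
        & (out["n_tumors_with_enrichment"] >= criteria.min_tumors)
        & (out["n_lines_with_enrichment"] >= criteria.min_lines)
    )
    out = out.reset_index().sort_values(
        ["n_lines_with_enrichment", "n_tumors_with_enrichment", "max_fold", "gene"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out.attrs["support"] = enr[
        ["gene", "shrna_id", "tumor_sample", "line_id", "fold_change"]
    ].reset_index(drop=True)
    return out


def screen_power(
    library,
    config,
    criteria: HitCriteria = HitCriteria(),
    n_replicate_screens: int = 50,
    seed: int = 0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Monte-Carlo detection probability per gene under the screen design.

    Runs ``n_replicate_screens`` independent simulated screens and reports
    the fraction in which each gene is called a hit.  The false-positive
    rate among neutral genes (gene_effect = 0) is attached as
    ``result.attrs["false_positive_rate"]``.
    """
    import dataclasses

    from .screen_quant import annotate_genes, enrichment
    from .synthetic_data import simulate_screen

    genes = library.table.groupby("gene")["gene_effect"].first()
    hits = pd.Series(0, index=genes.index, dtype=int)
    for rep in range(n_replicate_screens):
        cfg = dataclasses.replace(config, seed=(seed + rep) % 2**31)
        control, tumors = simulate_screen(library, cfg)
        table = annotate_genes(enrichment(control, tumors, pseudocount), library)
        called = call_hits(table, criteria)
        hit_genes = called.loc[called["is_hit"], "gene"]
        hits.loc[hit_genes] += 1
    prob = (hits / n_replicate_screens).rename("detection_probability")
    out = pd.DataFrame({"gene_effect": genes, "detection_probability": prob})
    neutral = out["gene_effect"] == 0
    out.attrs["false_positive_rate"] = (
        float(out.loc[neutral, "detection_probability"].mean()) if neutral.any() else np.nan
    )
    return out.reset_index()
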