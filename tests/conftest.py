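"""Shared fixtures and reference oracles for the screenkit test suite."""

import numpy as np
import pandas as pd
import pytest

from screenkit import HitCriteria, ScreenLibrary


@pytest.fixture
def tiny_library():
    """Three genes x two hairpins with well-separated 8-mer barcodes."""
    rows = [
        ("GA.sh1", "GA", "AAAAAAAA", 0.8, 0.0),
        ("GA.sh2", "GA", "CCCCCCCC", 0.7, 0.0),
        ("GB.sh1", "GB", "GGGGGGGG", 0.9, 0.2),
        ("GB.sh2", "GB", "TTTTTTTT", 0.6, 0.2),
        ("GC.sh1", "GC", "ACGTACGT", 0.5, 0.0),
        ("GC.sh2", "GC", "TGCATGCA", 0.4, 0.0),
    ]
    return ScreenLibrary(
        pd.DataFrame(
            rows,
            columns=["shrna_id", "gene", "barcode", "knockdown_efficacy", "gene_effect"],
        )
    )


def brute_force_hits(table: pd.DataFrame, criteria: HitCriteria, per_shrna: bool = False):
    """Row-by-row reference evaluation of the three screen criteria."""
    out = {}
    for gene in sorted(table["gene"].dropna().unique()):
        rows = table[table["gene"] == gene]
        enr = []
        for _, r in rows.iterrows():
            if (
                r["tumor_count"] >= criteria.detection_min_count
                and r["fold_change"] > criteria.fold_thresh
            ):
                enr.append(r)
        shrnas = {r["shrna_id"] for r in enr}
        if per_shrna:
            tumors = lines = 0
            for s in shrnas:
                t = {r["tumor_sample"] for r in enr if r["shrna_id"] == s}
                l = {r["line_id"] for r in enr if r["shrna_id"] == s}
                tumors = max(tumors, len(t))
                lines = max(lines, len(l))
        else:
            tumors = len({r["tumor_sample"] for r in enr})
            lines = len({r["line_id"] for r in enr})
        out[gene] = (
            len(shrnas) >= criteria.min_shrnas
            and tumors >= criteria.min_tumors
            and lines >= criteria.min_lines
        )
    return out


def random_enrichment_table(rng: np.random.Generator, n_rows: int = 30) -> pd.DataFrame:
    """Small random annotated enrichment table for oracle cross-checks."""
    genes = [f"G{i}" for i in range(3)]
    lines = ["L1", "L2"]
    rows = []
    for _ in range(n_rows):
        gene = rng.choice(genes)
        shrna = f"{gene}.sh{rng.integers(1, 4)}"
        line = rng.choice(lines)
        tumor = f"{line}_T{rng.integers(1, 3)}"
        fold = float(rng.choice([0.5, 2.9, 3.0, 3.5, 8.0, 50.0]))
        count = int(rng.choice([0, 5, 10, 200]))
        rows.append((gene, shrna, tumor, line, count, fold))
    return pd.DataFrame(
        rows,
        columns=["gene", "shrna_id", "tumor_sample", "line_id", "tumor_count", "fold_change"],
    )
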