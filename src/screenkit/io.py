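"""Readers and writers for the package's plain-text interchange formats.

Matrices are genes x samples TSV with a header row of sample IDs; screen
counts are four-column TSV (shrna_id, gene, barcode, count); gene sets use
GMT (name, description, members, tab-separated); survival and LDA tables
are simple headed TSVs.  Generated tables carry ``#``-prefixed header
comments with the package version and parameters.
"""

from __future__ import annotations

import yaml
import pandas as pd

from .errors import InvalidParameterError
from .screen_quant import ScreenCounts
from .signatures import GeneSet


def _comment_header(params: dict | None) -> str:
    from . import __version__

    lines = [f"# screenkit {__version__}"]
    if params:
        for k, v in params.items():
            lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, params: dict | None = None, index: bool = False):
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_matrix(matrix: pd.DataFrame, path, params: dict | None = None):
    """Genes x samples matrix with a leading ``gene`` column."""
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        matrix.rename_axis("gene").to_csv(fh, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="gene")


def write_counts(counts: ScreenCounts, library, path, params: dict | None = None):
    meta = {"sample_id": counts.sample_id, "role": counts.role, "line_id": counts.line_id,
            "unassigned_reads": counts.unassigned_reads}
    write_table(counts.to_frame(library), path, {**(params or {}), **meta})


def read_counts(path, sample_id=None, role="tumor", line_id="NA") -> ScreenCounts:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split(":", 1)
            if len(parts) == 2:
                meta[parts[0].strip()] = parts[1].strip()
    df = read_table(path)
    if "shrna_id" not in df.columns or "count" not in df.columns:
        raise InvalidParameterError("counts TSV needs shrna_id and count columns")
    series = df.set_index("shrna_id")["count"]
    return ScreenCounts(
        sample_id or meta.get("sample_id", "sample"),
        meta.get("role", role),
        meta.get("line_id", line_id),
        series,
        int(meta.get("unassigned_reads", 0)),
    )


def write_gmt(gene_sets, path):
    """``gene_sets``: mapping name -> iterable of genes, or iterable of GeneSet."""
    if isinstance(gene_sets, dict):
        items = [(k, list(v)) for k, v in gene_sets.items()]
    else:
        items = [(gs.name, list(gs.genes)) for gs in gene_sets]
    with open(path, "w") as fh:
        for name, genes in items:
            fh.write("\t".join([name, "screenkit"] + list(genes)) + "\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InvalidParameterError(f"malformed GMT line: {line[:60]!r}")
            out[parts[0]] = GeneSet(parts[0], parts[2:])
    return out


def write_survival(table: pd.DataFrame, path, params: dict | None = None):
    cols = ["sample_id", "time_days", "event"]
    extra = [c for c in table.columns if c not in cols]
    write_table(table[cols + extra], path, params)


def write_config(config: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
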