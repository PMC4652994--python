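"""Barcode quantification for pooled shRNA screens.

Turns barcode FASTQ files or raw count tables into normalized per-shRNA
abundances and tumor-vs-control fold changes.  Abundances are expressed as
frequencies (fraction of assigned reads); a shared pseudocount keeps log2
fold changes finite when an shRNA drops out of one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InvalidParameterError, LibraryMismatchError

_BASE_TO_CODE = {c: i for i, c in enumerate("ACGTN")}


@dataclass(frozen=True)
class BarcodeMap:
    """Total mapping barcode -> shRNA -> gene for one screen library.

    Barcodes must be unique and of equal length.  ``min_hamming`` is the
    minimum pairwise Hamming distance over the map; mismatch-tolerant read
    assignment is only unambiguous when ``max_mismatch`` is below it.
    """

    table: pd.DataFrame  # columns: barcode, shrna_id, gene

    def __post_init__(self):
        t = self.table
        for col in ("barcode", "shrna_id", "gene"):
            if col not in t.columns:
                raise InvalidParameterError(f"barcode map missing column {col!r}")
        if t["barcode"].duplicated().any():
            raise InvalidParameterError("barcodes are not unique")
        if t["shrna_id"].duplicated().any():
            raise InvalidParameterError("shrna_ids are not unique")
        lengths = t["barcode"].str.len().unique()
        if len(lengths) != 1:
            raise InvalidParameterError("barcodes have unequal lengths")

    @property
    def barcode_length(self) -> int:
        return len(self.table["barcode"].iloc[0])

    @property
    def shrna_ids(self) -> pd.Index:
        return pd.Index(self.table["shrna_id"])

    def _encoded(self) -> np.ndarray:
        return np.array(
            [[_BASE_TO_CODE.get(c, 4) for c in b] for b in self.table["barcode"]],
            dtype=np.uint8,
        )

    @property
    def min_hamming(self) -> int:
        enc = self._encoded()
        n = len(enc)
        if n < 2:
            return self.barcode_length
        best = self.barcode_length
        for i in range(n - 1):
            d = (enc[i + 1 :] != enc[i]).sum(axis=1).min()
            best = min(best, int(d))
        return best

    @classmethod
    def from_tsv(cls, path) -> "BarcodeMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str, comment="#"))


@dataclass
class ScreenCounts:
    """Per-sample integer read counts keyed by the full library (zeros explicit)."""

    sample_id: str
    role: str  # "control" or "tumor"
    line_id: str
    counts: pd.Series  # index: shrna_id, values: non-negative counts
    unassigned_reads: int = 0

    def __post_init__(self):
        if self.role not in ("control", "tumor"):
            raise InvalidParameterError(f"role must be control/tumor, got {self.role!r}")
        if (np.asarray(self.counts) < 0).any():
            raise InvalidParameterError("negative read counts")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum()) + int(self.unassigned_reads)

    def to_frame(self, library=None) -> pd.DataFrame:
        df = self.counts.rename("count").rename_axis("shrna_id").reset_index()
        if library is not None:
            lib = library.table if hasattr(library, "table") else library
            df = df.merge(lib[["shrna_id", "gene", "barcode"]], on="shrna_id", how="left")
            df = df[["shrna_id", "gene", "barcode", "count"]]
        return df


def count_barcodes(
    fastq_path,
    barcode_map: BarcodeMap,
    offset: int = 0,
    max_mismatch: int = 1,
    sample_id: str = "sample",
    role: str = "tumor",
    line_id: str = "NA",
) -> ScreenCounts:
    """Assign FASTQ reads to library barcodes by Hamming distance.

    A read is assigned to the unique barcode within ``max_mismatch`` of the
    window at ``offset``; reads with no match, or two equally near matches,
    are counted as unassigned.  Exact lookup is used as a fast path.
    """
    L = barcode_map.barcode_length
    if max_mismatch < 0:
        raise InvalidParameterError("max_mismatch must be >= 0")
    exact = dict(zip(barcode_map.table["barcode"], barcode_map.table["shrna_id"]))
    enc = barcode_map._encoded()
    ids = barcode_map.table["shrna_id"].to_numpy()
    counts = {sid: 0 for sid in barcode_map.table["shrna_id"]}
    unassigned = 0
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        seq = str(rec.seq)
        if len(seq) < offset + L:
            raise InvalidParameterError(
                f"read {rec.id} shorter than offset+barcode length ({offset}+{L})"
            )
        window = seq[offset : offset + L]
        hit = exact.get(window)
        if hit is None and max_mismatch > 0:
            w = np.array([_BASE_TO_CODE.get(c, 4) for c in window], dtype=np.uint8)
            dists = (enc != w).sum(axis=1)
            d0 = dists.min()
            if d0 <= max_mismatch and (dists == d0).sum() == 1:
                hit = ids[int(dists.argmin())]
        if hit is None:
            unassigned += 1
        else:
            counts[hit] += 1
    series = pd.Series(counts, name="count").rename_axis("shrna_id")
    return ScreenCounts(sample_id, role, line_id, series, unassigned)


def normalize(counts: ScreenCounts | pd.Series, pseudocount: float = 0.5) -> pd.Series:
    """Pseudocounted frequencies: (c_i + pc) / sum_j (c_j + pc); they sum to 1."""
    c = counts.counts if isinstance(counts, ScreenCounts) else counts
    c = c.astype(float)
    if pseudocount < 0:
        raise InvalidParameterError("pseudocount must be >= 0")
    if c.sum() <= 0 and pseudocount == 0:
        raise InvalidParameterError("all-zero counts with zero pseudocount")
    shifted = c + pseudocount
    return shifted / shifted.sum()


def enrichment(
    control: ScreenCounts,
    tumors: Sequence[ScreenCounts] | ScreenCounts,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-shRNA tumor-vs-control fold changes.

    Each shRNA read count is normalized to its whole population; fold change
    is the ratio of tumor to control frequency under a shared pseudocount.
    Returns one row per shRNA x tumor with columns shrna_id, gene (if the
    control carries gene annotation via its index only, gene is omitted),
    tumor_sample, line_id, control_count, tumor_count, control_freq,
    tumor_freq, fold_change, log2fc.
    """
    if isinstance(tumors, ScreenCounts):
        tumors = [tumors]
    ctrl_freq = normalize(control, pseudocount)
    rows = []
    for t in tumors:
        if not control.counts.index.equals(t.counts.index):
            bad = control.counts.index.symmetric_difference(t.counts.index)
            raise LibraryMismatchError(
                f"sample {t.sample_id} library differs from control", bad.tolist()
            )
        t_freq = normalize(t, pseudocount)
        fold = t_freq / ctrl_freq
        rows.append(
            pd.DataFrame(
                {
                    "shrna_id": control.counts.index,
                    "tumor_sample": t.sample_id,
                    "line_id": t.line_id,
                    "control_count": control.counts.to_numpy(),
                    "tumor_count": t.counts.to_numpy(),
                    "control_freq": ctrl_freq.to_numpy(),
                    "tumor_freq": t_freq.to_numpy(),
                    "fold_change": fold.to_numpy(),
                    "log2fc": np.log2(fold.to_numpy()),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def annotate_genes(table: pd.DataFrame, library) -> pd.DataFrame:
    """Attach the gene column from a library / barcode map to an enrichment table."""
    lib = library.table if hasattr(library, "table") else library
    out = table.merge(lib[["shrna_id", "gene"]], on="shrna_id", how="left")
    cols = ["shrna_id", "gene"] + [c for c in out.columns if c not in ("shrna_id", "gene")]
    return out[cols]
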