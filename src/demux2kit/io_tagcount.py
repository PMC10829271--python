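"""Tag count matrix container and I/O.

This module owns the cells x tags UMI count matrix that every other stage
operates on, readers/writers for the common on-disk representations
(CSV/TSV matrices and MatrixMarket triplet directories with barcode and
feature sidecars), the tabulation of tag UMIs from raw paired tag-library
FASTQ reads, and the writer for per-cell classification tables.
"""

from __future__ import annotations

import gzip
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "TagCountMatrix",
    "TagReference",
    "ReadLayout",
    "FastqCountSummary",
    "count_tags_from_fastq",
    "read_tag_matrix",
    "write_tag_matrix",
    "write_results",
    "read_results",
]


@dataclass
class TagCountMatrix:
    """Cells x tags matrix of nonnegative integer UMI counts.

    ``counts`` is stored as sparse CSR; rows are cells (droplets), columns
    are tags. Labels are carried explicitly and public contracts never rely
    on positional assumptions.
    """

    counts: sp.csr_matrix
    cell_barcodes: list[str]
    tag_names: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_barcodes = [str(b) for b in self.cell_barcodes]
        self.tag_names = [str(t) for t in self.tag_names]
        n, m = self.counts.shape
        if len(self.cell_barcodes) != n:
            raise ValueError(
                f"{len(self.cell_barcodes)} barcodes for {n} matrix rows"
            )
        if len(self.tag_names) != m:
            raise ValueError(f"{len(self.tag_names)} tag names for {m} columns")
        if len(set(self.cell_barcodes)) != n:
            raise ValueError("duplicate cell barcodes")
        if len(set(self.tag_names)) != m:
            raise ValueError("duplicate tag names")
        data = self.counts.data
        if data.size:
            if not np.allclose(data, np.round(data)):
                raise ValueError("tag counts must be integers")
            if data.min() < 0:
                raise ValueError("tag counts must be nonnegative")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_tags(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-cell total UMI count over all tags (N_total)."""
        return np.asarray(self.counts.sum(axis=1)).ravel().astype(np.int64)

    def tag_column(self, tag: str) -> np.ndarray:
        j = self.tag_names.index(tag)
        return np.asarray(self.counts[:, j].todense()).ravel().astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(),
            index=pd.Index(self.cell_barcodes, name="barcode"),
            columns=self.tag_names,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TagCountMatrix":
        return cls(
            sp.csr_matrix(df.to_numpy()),
            list(map(str, df.index)),
            list(map(str, df.columns)),
        )

    def subset_cells(self, idx: np.ndarray) -> "TagCountMatrix":
        idx = np.asarray(idx)
        return TagCountMatrix(
            self.counts[idx],
            [self.cell_barcodes[i] for i in idx],
            list(self.tag_names),
        )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class TagReference:
    """Mapping of tag name -> DNA barcode sequence (common fixed length)."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        self.sequences = {str(k): str(v).upper() for k, v in self.sequences.items()}
        if not self.sequences:
            raise ValueError("empty tag reference")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"tag barcodes have mixed lengths: {sorted(lengths)}")
        names = list(self.sequences)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                d = _hamming(self.sequences[a], self.sequences[b])
                if d < 2:
                    warnings.warn(
                        f"tag barcodes {a!r} and {b!r} are within Hamming "
                        f"distance {d}; mismatch correction may be ambiguous",
                        stacklevel=2,
                    )

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def tag_names(self) -> list[str]:
        return list(self.sequences)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TagReference":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("tag reference TSV needs columns: name, sequence")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


@dataclass
class ReadLayout:
    """Where the cell barcode, UMI and tag barcode live in a read pair.

    Defaults follow the 10x 3' v3 convention: 16 bp cell barcode then
    12 bp UMI in read 1; the tag barcode read from a configurable offset
    of read 2.
    """

    cb_offset: int = 0
    cb_length: int = 16
    umi_offset: int = 16
    umi_length: int = 12
    tag_offset: int = 0
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.cb_length <= 0 or self.umi_length <= 0:
            raise ValueError("span lengths must be positive")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        cb = range(self.cb_offset, self.cb_offset + self.cb_length)
        umi = range(self.umi_offset, self.umi_offset + self.umi_length)
        if set(cb) & set(umi):
            raise ValueError("cell-barcode and UMI spans overlap in read 1")


@dataclass
class FastqCountSummary:
    """Bookkeeping from FASTQ tabulation; kept + discarded = total reads."""

    total_reads: int = 0
    kept_reads: int = 0
    discarded_tag: int = 0
    discarded_cell: int = 0
    discarded_short: int = 0
    unique_umis: int = 0

    @property
    def discarded_reads(self) -> int:
        return self.discarded_tag + self.discarded_cell + self.discarded_short


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _build_corrector(references: Sequence[str], max_mismatch: int):
    """Exact-first barcode corrector.

    A query is assigned to a reference iff exactly one reference lies
    within ``max_mismatch``; ambiguity returns None (discard).
    """
    exact = {seq: i for i, seq in enumerate(references)}

    def correct(query: str) -> int | None:
        hit = exact.get(query)
        if hit is not None:
            return hit
        if max_mismatch == 0:
            return None
        best, best_d, ties = None, max_mismatch + 1, 0
        for i, ref in enumerate(references):
            d = _hamming(query, ref)
            if d < best_d:
                best, best_d, ties = i, d, 1
            elif d == best_d:
                ties += 1
        if best is not None and best_d <= max_mismatch and ties == 1:
            return best
        return None

    return correct


def count_tags_from_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    tags: TagReference,
    whitelist: Iterable[str] | None = None,
    layout: ReadLayout | None = None,
) -> tuple[TagCountMatrix, FastqCountSummary]:
    """Tabulate tag UMI counts from a paired tag-library FASTQ run.

    Each unique (cell barcode, UMI, tag) triplet contributes exactly one
    count (UMI collapsing). Reads whose tag barcode cannot be corrected to
    exactly one reference, or whose cell barcode is not correctable to the
    whitelist (when given), are discarded and tallied in the summary.
    """
    layout = layout or ReadLayout()
    tag_names = tags.tag_names
    tag_seqs = [tags.sequences[t] for t in tag_names]
    tag_len = tags.barcode_length
    correct_tag = _build_corrector(tag_seqs, layout.max_mismatch)

    wl_list: list[str] | None = None
    correct_cb = None
    if whitelist is not None:
        wl_list = [str(b) for b in whitelist]
        correct_cb = _build_corrector(wl_list, layout.max_mismatch)

    summary = FastqCountSummary()
    # (cell index, tag index) -> set of UMI strings
    triplets: dict[tuple[int, int], set[str]] = {}
    barcode_index: dict[str, int] = (
        {b: i for i, b in enumerate(wl_list)} if wl_list is not None else {}
    )
    barcodes: list[str] = list(wl_list) if wl_list is not None else []

    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                raise ValueError("R1 and R2 have different read counts")
            summary.total_reads += 1
            seq1, seq2 = rec1[1].upper(), rec2[1].upper()
            cb_end = layout.cb_offset + layout.cb_length
            umi_end = layout.umi_offset + layout.umi_length
            tag_end = layout.tag_offset + tag_len
            if len(seq1) < max(cb_end, umi_end) or len(seq2) < tag_end:
                summary.discarded_short += 1
                continue
            cb = seq1[layout.cb_offset : cb_end]
            umi = seq1[layout.umi_offset : umi_end]
            tag_bc = seq2[layout.tag_offset : tag_end]

            j = correct_tag(tag_bc)
            if j is None:
                summary.discarded_tag += 1
                continue
            if correct_cb is not None:
                ci = correct_cb(cb)
                if ci is None:
                    summary.discarded_cell += 1
                    continue
            else:
                ci = barcode_index.get(cb)
                if ci is None:
                    ci = len(barcodes)
                    barcode_index[cb] = ci
                    barcodes.append(cb)
            summary.kept_reads += 1
            triplets.setdefault((ci, j), set()).add(umi)

    if whitelist is None:
        # drop barcodes that never received a kept read, keep first-seen order
        used = sorted({ci for ci, _ in triplets})
    else:
        used = list(range(len(barcodes)))
    remap = {ci: k for k, ci in enumerate(used)}
    rows, cols, vals = [], [], []
    for (ci, j), umis in triplets.items():
        rows.append(remap[ci])
        cols.append(j)
        vals.append(len(umis))
        summary.unique_umis += len(umis)
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(used), len(tag_names)), dtype=np.int64
    )
    return TagCountMatrix(mat, [barcodes[ci] for ci in used], tag_names), summary


def _read_mtx_dir(path: Path) -> TagCountMatrix:
    def pick(*names: str) -> Path:
        for n in names:
            p = path / n
            if p.exists():
                return p
        raise FileNotFoundError(f"none of {names} found in {path}")

    mtx = pick("matrix.mtx", "matrix.mtx.gz")
    barcodes_f = pick("barcodes.tsv", "barcodes.tsv.gz")
    features_f = pick("features.tsv", "features.tsv.gz", "genes.tsv")
    mat = sp.csr_matrix(scipy.io.mmread(str(mtx)))
    barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str).tolist()
    features = pd.read_csv(features_f, sep="\t", header=None)[0].astype(str).tolist()
    n, m = mat.shape
    if n == len(barcodes) and m == len(features):
        pass  # already cells x tags
    elif n == len(features) and m == len(barcodes):
        mat = sp.csr_matrix(mat.T)  # CellRanger convention: features x barcodes
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither sidecar orientation "
            f"({len(barcodes)} barcodes, {len(features)} features)"
        )
    return TagCountMatrix(mat, barcodes, features)


def read_tag_matrix(
    path: str | Path,
    fmt: str | None = None,
    cells_as_rows: bool | None = None,
) -> TagCountMatrix:
    """Read a tag count matrix from CSV/TSV or a MatrixMarket directory.

    Orientation is auto-detected for tabular input (the longer axis is
    assumed to be cells) unless ``cells_as_rows`` forces it.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx"
        elif path.suffix in {".tsv", ".txt"}:
            fmt = "tsv"
        else:
            fmt = "csv"
    if fmt == "mtx":
        return _read_mtx_dir(path)
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    df = pd.read_csv(path, sep=sep, index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.allclose(
        arr, np.round(arr)
    ):
        raise ValueError(f"non-integer entries in {path}")
    if cells_as_rows is None:
        cells_as_rows = df.shape[0] >= df.shape[1]
    if not cells_as_rows:
        df = df.T
    if df.index.duplicated().any():
        raise ValueError("duplicate cell barcodes in matrix file")
    return TagCountMatrix.from_frame(df)


def write_tag_matrix(
    matrix: TagCountMatrix, path: str | Path, fmt: str = "csv"
) -> Path:
    """Write a matrix as CSV/TSV (cells as rows) or a MatrixMarket directory."""
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), matrix.counts.tocoo())
        (path / "barcodes.tsv").write_text(
            "".join(b + "\n" for b in matrix.cell_barcodes)
        )
        (path / "features.tsv").write_text(
            "".join(t + "\n" for t in matrix.tag_names)
        )
        return path
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(path, sep=sep)
    return path


def write_results(result, path: str | Path) -> Path:
    """Write per-cell calls and posteriors as a TSV table.

    One row per cell in input order: barcode, call, then one posterior
    column per tag. Output is bitwise stable given fixed inputs.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = result.to_frame()
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", index_col=0)


def stable_cell_scores(seed: int, stream: str, barcodes: Sequence[str]) -> np.ndarray:
    """Deterministic pseudo-random score per barcode.

    Derived from blake2b(seed, stream, barcode), so subsampling based on
    ranking these scores is invariant to cell order and to the order in
    which streams (e.g. tags) are processed.
    """
    prefix = f"{seed}:{stream}:".encode()
    out = np.empty(len(barcodes), dtype=np.uint64)
    for i, b in enumerate(barcodes):
        h = hashlib.blake2b(prefix + str(b).encode(), digest_size=8).digest()
        out[i] = int.from_bytes(h, "big")
    return out
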