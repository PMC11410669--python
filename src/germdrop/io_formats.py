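"""On-disk formats for the germination pipeline.

Reads and writes CellRanger-style MTX bundles (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``, optionally gzipped), read-level allele
observation tables, and bulk count tables with a samplesheet.  Internal
coordinates are 0-based; MatrixMarket files on disk are 1-based per the
standard.  Barcode/feature TSVs carry no header (10x convention); allele
tables and samplesheets do.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an on-disk file violates its expected format."""


@dataclass
class CountMatrix:
    """Sparse UMI counts, barcodes x genes, with optional per-barcode metadata.

    ``meta`` maps barcode -> {"time_point_h": int, "replicate": int}; its keys
    must be a subset of ``barcodes``.
    """

    values: sp.csr_matrix
    barcodes: list[str]
    genes: list[str]
    meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")
        unknown = set(self.meta) - set(self.barcodes)
        if unknown:
            raise ValueError(f"meta keys not among barcodes: {sorted(unknown)[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_barcodes(self, keep: list[str]) -> "CountMatrix":
        idx = {b: i for i, b in enumerate(self.barcodes)}
        rows = [idx[b] for b in keep]
        return CountMatrix(
            self.values[rows, :],
            list(keep),
            list(self.genes),
            {b: self.meta[b] for b in keep if b in self.meta},
        )

    def subset_genes(self, keep_mask: np.ndarray) -> "CountMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        genes = [g for g, k in zip(self.genes, keep_mask) if k]
        return CountMatrix(self.values[:, keep_mask], list(self.barcodes), genes, dict(self.meta))


@dataclass
class SampleInfo:
    sample_id: str
    time_point_h: int
    protoplast: bool
    replicate: int


@dataclass
class BulkCounts:
    """Bulk RNA-seq counts, genes x samples, with per-sample factors."""

    values: np.ndarray
    genes: list[str]
    samples: list[SampleInfo]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset_samples(self, keep: list[int]) -> "BulkCounts":
        return BulkCounts(self.values[:, keep], list(self.genes), [self.samples[i] for i in keep])


#: Read-level allele observations: a DataFrame with columns barcode/umi/allele.
AlleleObservationTable = pd.DataFrame

_ALLELES = {"A", "B"}


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _open_auto(path: Path, mode: str = "rt") -> IO:
    """Open plain or gzipped text transparently (magic-byte detection)."""
    if _is_gzip(path):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_bundle_file(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {directory}")


def read_mtx_bundle(directory: os.PathLike | str) -> CountMatrix:
    """Read a matrix.mtx + barcodes.tsv + features.tsv bundle.

    The on-disk matrix is genes x barcodes (CellRanger convention); the
    returned :class:`CountMatrix` is transposed to barcodes x genes.
    """
    directory = Path(directory)
    mtx_path = _find_bundle_file(directory, "matrix.mtx")
    bc_path = _find_bundle_file(directory, "barcodes.tsv")
    ft_path = _find_bundle_file(directory, "features.tsv")

    try:
        with _open_auto(mtx_path, "rb") as fh:
            mat = scipy.io.mmread(io.BytesIO(fh.read()))
    except Exception as exc:  # header/triplet inconsistency, bad tokens, ...
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc

    with _open_auto(bc_path) as fh:
        barcodes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_auto(ft_path) as fh:
        genes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]

    mat = sp.csr_matrix(mat.T)
    if mat.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"matrix is {mat.T.shape} (genes x barcodes) but bundle lists "
            f"{len(genes)} features and {len(barcodes)} barcodes"
        )
    return CountMatrix(mat.astype(np.int64), barcodes, genes)


def write_mtx_bundle(matrix: CountMatrix, directory: os.PathLike | str) -> None:
    """Write ``matrix`` as a plain-text MTX bundle (genes x barcodes on disk)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.values.T)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), coo, field="integer")
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.barcodes))
    (directory / "features.tsv").write_text("".join(g + "\n" for g in matrix.genes))


def read_allele_observations(path: os.PathLike | str) -> AlleleObservationTable:
    """Read a TSV of (barcode, umi, allele) read-level records.

    Allele tokens outside {A, B} raise :class:`FormatError` naming the
    offending line (1-based, counting the header as line 1).
    """
    path = Path(path)
    with _open_auto(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    required = ["barcode", "umi", "allele"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = ~df["allele"].isin(_ALLELES)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise FormatError(
            f"{path}: invalid allele {df['allele'].iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r} "
            f"at line {line} (expected A or B)"
        )
    return df[required].reset_index(drop=True)


def write_allele_observations(table: AlleleObservationTable, path: os.PathLike | str) -> None:
    table[["barcode", "umi", "allele"]].to_csv(path, sep="\t", index=False)


def _parse_bool(token) -> bool:
    s = str(token).strip().lower()
    if s in {"yes", "true", "1"}:
        return True
    if s in {"no", "false", "0"}:
        return False
    raise FormatError(f"cannot parse boolean token {token!r}")


def read_bulk_counts(path: os.PathLike | str, samplesheet: os.PathLike | str) -> BulkCounts:
    """Read a genes x samples count TSV plus its samplesheet.

    Columns of the count table are matched to samplesheet rows by sample_id;
    a mismatch in either direction is an error listing the offenders.
    """
    with _open_auto(Path(path)) as fh:
        counts = pd.read_csv(fh, sep="\t", index_col=0)
    with _open_auto(Path(samplesheet)) as fh:
        sheet = pd.read_csv(fh, sep="\t", dtype=str)
    required = ["sample_id", "time_point_h", "protoplast", "replicate"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise FormatError(f"{samplesheet}: missing columns {missing}")

    count_ids = list(counts.columns)
    sheet_ids = list(sheet["sample_id"])
    only_counts = sorted(set(count_ids) - set(sheet_ids))
    only_sheet = sorted(set(sheet_ids) - set(count_ids))
    if only_counts or only_sheet:
        raise FormatError(
            f"sample_id mismatch: only in counts {only_counts}; only in samplesheet {only_sheet}"
        )

    samples = [
        SampleInfo(
            sample_id=row["sample_id"],
            time_point_h=int(row["time_point_h"]),
            protoplast=_parse_bool(row["protoplast"]),
            replicate=int(row["replicate"]),
        )
        for _, row in sheet.iterrows()
    ]
    values = counts[[s.sample_id for s in samples]].to_numpy()
    return BulkCounts(values, [str(g) for g in counts.index], samples)


def write_bulk_counts(bulk: BulkCounts, path: os.PathLike | str, samplesheet: os.PathLike | str) -> None:
    df = pd.DataFrame(bulk.values, index=pd.Index(bulk.genes, name="gene"), columns=bulk.sample_ids)
    df.to_csv(path, sep="\t")
    sheet = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in bulk.samples],
            "time_point_h": [s.time_point_h for s in bulk.samples],
            "protoplast": ["yes" if s.protoplast else "no" for s in bulk.samples],
            "replicate": [s.replicate for s in bulk.samples],
        }
    )
    sheet.to_csv(samplesheet, sep="\t", index=False)
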