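"""Readers and writers for the formats the pipeline touches.

Supported inputs: 10x-style MTX triplet directories (``matrix.mtx[.gz]`` +
``features.tsv``/``genes.tsv`` + ``barcodes.tsv``, optionally gzipped),
dense TSV/CSV count tables with genes as rows, per-cell annotation TSVs,
GMT gene-set files and two-column homology tables.  Trained position models
are serialized to a single self-describing archive (JSON header + raw
little-endian float64 weight blocks) whose byte content is a deterministic
function of the model, so two saves of the same model are byte-identical.
"""

from __future__ import annotations

import gzip
import json
import struct
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    CellAnnotation,
    ExpressionMatrix,
    FormatError,
    GeneSet,
    HomologyTable,
)

_MODEL_MAGIC = b"SCPOSM1\n"


def _find_member(directory: Path, stems: List[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / (stem + suffix)
            if p.exists():
                return p
    raise FormatError(f"missing triplet member {stems[0]!r} in {directory}")


def _read_tsv_column(path: Path, column: int = 0) -> List[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            out.append(fields[min(column, len(fields) - 1)])
    return out


def read_counts(path, *, genes_as_rows: bool = True) -> ExpressionMatrix:
    """Read a raw count matrix into memory as cells × genes.

    ``path`` may be a 10x-style MTX triplet directory or a dense TSV/CSV
    file.  On disk both conventions store genes as rows; the returned matrix
    is transposed to cells × genes.  Dense files with cells as rows must be
    declared with ``genes_as_rows=False`` — orientation is never guessed.
    For triplets with a multi-column features file the gene symbol column
    (second column) is used.
    """
    path = Path(path)
    if path.is_dir():
        mtx_path = _find_member(path, ["matrix.mtx"])
        features_path = _find_member(path, ["features.tsv", "genes.tsv"])
        barcodes_path = _find_member(path, ["barcodes.tsv"])
        genes = _read_tsv_column(features_path, column=1)
        cells = _read_tsv_column(barcodes_path, column=0)
        try:
            mat = scipy.io.mmread(str(mtx_path))
        except Exception as exc:  # noqa: BLE001 - re-raise as format error
            raise FormatError(f"could not parse {mtx_path}: {exc}") from exc
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        if dense.shape != (len(genes), len(cells)):
            raise FormatError(
                f"MTX header {dense.shape} does not match "
                f"{len(genes)} features × {len(cells)} barcodes"
            )
        return ExpressionMatrix(cells, genes, dense.T, layer="counts")

    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty matrix file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"matrix file has no data: {path}")
    if genes_as_rows:
        df = df.T
    return ExpressionMatrix(
        df.index.astype(str).tolist(),
        df.columns.astype(str).tolist(),
        df.to_numpy(dtype=np.float64),
        layer="counts",
    )


def write_counts_mtx(m: ExpressionMatrix, directory) -> None:
    """Write a counts matrix as a 10x-style triplet (genes × cells on disk)."""
    if m.layer != "counts":
        raise ValueError("MTX triplet output is for the counts layer")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(m.values.T.astype(np.int64))
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse, field="integer")
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in m.gene_ids)
    )
    (directory / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))


def write_dense_tsv(m: ExpressionMatrix, path) -> None:
    """Write the matrix as a dense TSV with genes as rows."""
    m.to_frame().T.to_csv(path, sep="\t")


def read_annotations(path, label_set=None) -> CellAnnotation:
    """Read a per-cell annotation TSV (first column: cell id; required column:
    ``compartment``; every other column becomes a covariate)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty annotation file: {path}") from exc
    if "compartment" not in df.columns:
        raise FormatError(f"annotation file {path} lacks a 'compartment' column")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate cell ids in {path}: {dupes[:5]}")
    covariates = {
        c: df[c].to_numpy(dtype=object) for c in df.columns if c != "compartment"
    }
    return CellAnnotation(
        df.index.astype(str).tolist(),
        df["compartment"].to_numpy(dtype=object),
        covariates,
        tuple(label_set) if label_set else (),
    )


def write_annotations(ann: CellAnnotation, path) -> None:
    ann.to_frame().to_csv(path, sep="\t", index_label="cell_id")


def read_gmt(path) -> List[GeneSet]:
    """Parse a GMT file into one GeneSet per line (provenance ``custom``).

    Duplicate symbols within a line are removed preserving first occurrence.
    """
    sets = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and ≥1 gene"
                )
            sets.append(GeneSet(fields[0], [g for g in fields[2:] if g], "custom"))
    return sets


def write_gmt(sets: List[GeneSet], path, description: str = "na") -> None:
    with open(path, "wt") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *gs.genes]) + "\n")


def read_homology_table(path) -> HomologyTable:
    """Read a two-column TSV with header ``source<TAB>target``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["source", "target"]:
        raise FormatError(
            f"homology table {path} must have header 'source\\ttarget', "
            f"got {list(df.columns[:2])}"
        )
    return HomologyTable(list(zip(df["source"], df["target"])))


def write_homology_table(table: HomologyTable, path) -> None:
    with open(path, "wt") as fh:
        fh.write("source\ttarget\n")
        for s, t in table.pairs:
            fh.write(f"{s}\t{t}\n")


# --- model archive -----------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a trained PositionModel to a deterministic single-file archive.

    Layout: magic, 8-byte little-endian header length, JSON header with
    sorted keys (metadata, gene/class order, config, array manifest), then
    the arrays as raw little-endian float64 blocks in manifest order.
    """
    arrays = [("mean", model.mean), ("sd", model.sd)]
    arrays += sorted(model.weights.items())
    header = {
        "format_version": 1,
        "gene_order": list(model.gene_order),
        "class_order": list(model.class_order),
        "config": model.config.to_dict(),
        "training_fingerprint": model.training_fingerprint,
        "arrays": [{"name": n, "shape": list(np.shape(a))} for n, a in arrays],
    }
    blob = json.dumps(header, sort_keys=True, separators=(",", ":")).encode()
    with open(path, "wb") as fh:
        fh.write(_MODEL_MAGIC)
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        for _, arr in arrays:
            fh.write(np.ascontiguousarray(arr, dtype="<f8").tobytes())


def load_model(path):
    """Load a PositionModel archive written by :func:`save_model`."""
    from .classify import PositionModel, TrainingConfig

    with open(path, "rb") as fh:
        magic = fh.read(len(_MODEL_MAGIC))
        if magic != _MODEL_MAGIC:
            raise FormatError(f"{path} is not a position-model archive")
        (header_len,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(header_len).decode())
        if header.get("format_version") != 1:
            raise FormatError(
                f"unsupported model format version {header.get('format_version')!r}"
            )
        for key in ("gene_order", "class_order", "config", "arrays"):
            if key not in header:
                raise FormatError(f"model archive missing {key!r} block")
        arrays = {}
        for entry in header["arrays"]:
            shape = tuple(entry["shape"])
            n = int(np.prod(shape)) if shape else 1
            raw = fh.read(8 * n)
            if len(raw) != 8 * n:
                raise FormatError(f"truncated model archive: array {entry['name']!r}")
            arrays[entry["name"]] = np.frombuffer(raw, dtype="<f8").reshape(shape).copy()
    mean = arrays.pop("mean")
    sd = arrays.pop("sd")
    return PositionModel(
        gene_order=list(header["gene_order"]),
        class_order=list(header["class_order"]),
        mean=mean,
        sd=sd,
        weights=arrays,
        config=TrainingConfig.from_dict(header["config"]),
        training_fingerprint=header["training_fingerprint"],
    )
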