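"""Shared file-format I/O: MTX count matrices, FASTA/FASTQ, TSV tables, JSON.

All matrices are stored genes-(or proteins)-by-columns in MatrixMarket
format with 1-based indices, accompanied by ``genes.tsv`` (feature
metadata) and ``barcodes.tsv`` (column ids). Gzip is handled
transparently for FASTQ. Every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def write_mtx(
    out_dir: str | Path,
    counts: np.ndarray | sp.spmatrix,
    genes: pd.DataFrame,
    barcodes: list[str],
) -> Path:
    """Write a genes x columns count matrix as matrix.mtx + genes.tsv + barcodes.tsv.

    ``genes`` must carry a ``gene_id`` column; any further columns
    (length, biotype, is_mito, ...) are preserved.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts)
    if mat.shape[0] != len(genes):
        raise ValueError(f"{mat.shape[0]} matrix rows but {len(genes)} gene records")
    if mat.shape[1] != len(barcodes):
        raise ValueError(f"{mat.shape[1]} matrix columns but {len(barcodes)} barcodes")
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), mat)
    genes.to_csv(out_dir / "genes.tsv", sep="\t", index=False)
    pd.Series(barcodes, name="barcode").to_csv(
        out_dir / "barcodes.tsv", sep="\t", index=False
    )
    return out_dir


def read_mtx(in_dir: str | Path) -> tuple[sp.csr_matrix, pd.DataFrame, list[str]]:
    """Read a matrix directory written by :func:`write_mtx`."""
    in_dir = Path(in_dir)
    mat = sp.csr_matrix(scipy.io.mmread(str(in_dir / "matrix.mtx")))
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t")
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", sep="\t")["barcode"].tolist()
    return mat, genes, barcodes


def write_fasta(path: str | Path, records: dict[str, str]) -> Path:
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(path: str | Path, reads: list[tuple[str, str, str]]) -> Path:
    """Write (name, sequence, quality) triples; gzipped when path ends in .gz."""
    path = Path(path)
    with _open_maybe_gzip(path, "wt") as handle:
        for name, seq, qual in reads:
            if len(seq) != len(qual):
                raise ValueError(f"record {name}: seq/qual length mismatch")
            handle.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    with _open_maybe_gzip(path, "rt") as handle:
        return [(name, seq, qual) for name, seq, qual in FastqGeneralIterator(handle)]


def iter_fastq(path: str | Path):
    """Stream (name, seq, qual) triples without materializing the file."""
    with _open_maybe_gzip(path, "rt") as handle:
        yield from FastqGeneralIterator(handle)


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_tsv(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
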