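"""Hierarchical demultiplexing of tDISCO read trios and per-cell counting.

A tDISCO library nests three barcode tiers: an Illumina index (Index2
read, pool of 50 cells), a second-strand-synthesis (SSS) barcode (pool
of 10 cells) and a cell barcode, the latter two carried on the 36-bp
Read1 together with the UMI. Read2 carries 127 bp of cDNA. This module
resolves the tiers against their whitelists with per-tier mismatch
tolerance, assigns Read2 to a transcript by k-mer voting against a toy
transcriptome, collapses UMIs into molecules, and converts molecule
counts to length-normalized TPM.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .io import iter_fastq

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"
MULTI = "MULTI"
NONE = "NONE"

READ1_LEN = 36
INDEX2_LEN = 8
READ2_LEN = 127

_BASES = "ACGT"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise InputError(f"hamming distance undefined for lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _random_whitelist(n: int, length: int, rng: np.random.Generator, min_dist: int = 3) -> list[str]:
    """Greedy rejection sampling of ``n`` barcodes pairwise >= min_dist apart."""
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        cand = "".join(rng.choice(list(_BASES), size=length))
        if all(hamming(cand, w) >= min_dist for w in out):
            out.append(cand)
        attempts += 1
        if attempts > 100_000:
            raise ConfigurationError(
                f"cannot place {n} barcodes of length {length} at distance >= {min_dist}"
            )
    return out


@dataclass
class BarcodeScheme:
    """Nested barcode layout: Illumina index -> SSS barcode -> cell barcode.

    Segment (offset, length) pairs locate the cell barcode, UMI and SSS
    barcode within Read1; the Illumina index occupies the full Index2
    read. Default layout: cell 0-10, UMI 10-18, SSS 18-26, spacer 26-36.
    """

    cell_whitelist: list[str]
    sss_whitelist: list[str]
    index_whitelist: list[str]
    cell_segment: tuple[int, int] = (0, 10)
    umi_segment: tuple[int, int] = (10, 8)
    sss_segment: tuple[int, int] = (18, 8)
    index2_len: int = INDEX2_LEN
    read2_len: int = READ2_LEN
    cells_per_sss: int = 10
    cells_per_index: int = 50

    def __post_init__(self) -> None:
        for name, wl in (
            ("cell", self.cell_whitelist),
            ("sss", self.sss_whitelist),
            ("index", self.index_whitelist),
        ):
            if len(set(wl)) != len(wl):
                raise ConfigurationError(f"duplicate entries in {name} whitelist")
            lengths = {len(w) for w in wl}
            if len(lengths) > 1:
                raise ConfigurationError(f"{name} whitelist entries differ in length")
            min_d = min(
                (hamming(a, b) for a, b in itertools.combinations(wl, 2)), default=3
            )
            if min_d < 3:
                warnings.warn(
                    f"{name} whitelist minimum pairwise Hamming distance {min_d} < 3; "
                    "single-mismatch correction may be ambiguous",
                    stacklevel=2,
                )
        spans = sorted(
            [self.cell_segment, self.umi_segment, self.sss_segment], key=lambda s: s[0]
        )
        for (o1, l1), (o2, _) in zip(spans, spans[1:]):
            if o1 + l1 > o2:
                raise ConfigurationError("Read1 segments overlap")
        last_off, last_len = spans[-1]
        if last_off + last_len > READ1_LEN:
            raise ConfigurationError("Read1 segments exceed 36 nt")
        if len(self.cell_whitelist[0]) != self.cell_segment[1]:
            raise ConfigurationError("cell whitelist length != cell segment length")
        if len(self.sss_whitelist[0]) != self.sss_segment[1]:
            raise ConfigurationError("sss whitelist length != sss segment length")
        if len(self.index_whitelist[0]) != self.index2_len:
            raise ConfigurationError("index whitelist length != index2 length")

    @property
    def capacity(self) -> int:
        """Maximum number of cells addressable by the nested pooling."""
        return len(self.index_whitelist) * self.cells_per_index

    @property
    def umi_len(self) -> int:
        return self.umi_segment[1]

    def cell_tuple(self, cell_rank: int) -> tuple[str, str, str]:
        """Barcode triple (index, sss, cell) for the cell with pooling rank ``cell_rank``."""
        if cell_rank >= self.capacity:
            raise ConfigurationError(
                f"cell rank {cell_rank} exceeds scheme capacity {self.capacity}"
            )
        idx = cell_rank // self.cells_per_index
        sss = (cell_rank % self.cells_per_index) // self.cells_per_sss
        cell = cell_rank % self.cells_per_sss
        return (
            self.index_whitelist[idx],
            self.sss_whitelist[sss],
            self.cell_whitelist[cell],
        )

    @classmethod
    def default(cls, n_cells: int = 100, seed: int = 7) -> "BarcodeScheme":
        """Deterministic default scheme sized for ``n_cells`` (ceil(n/50) indices)."""
        rng = np.random.default_rng(seed)
        n_index = max(2, -(-n_cells // 50))
        return cls(
            cell_whitelist=_random_whitelist(10, 10, rng),
            sss_whitelist=_random_whitelist(5, 8, rng),
            index_whitelist=_random_whitelist(n_index, 8, rng),
        )

    def to_dict(self) -> dict:
        return {
            "cell_whitelist": self.cell_whitelist,
            "sss_whitelist": self.sss_whitelist,
            "index_whitelist": self.index_whitelist,
            "cell_segment": list(self.cell_segment),
            "umi_segment": list(self.umi_segment),
            "sss_segment": list(self.sss_segment),
            "index2_len": self.index2_len,
            "read2_len": self.read2_len,
            "cells_per_sss": self.cells_per_sss,
            "cells_per_index": self.cells_per_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BarcodeScheme":
        d = dict(d)
        for key in ("cell_segment", "umi_segment", "sss_segment"):
            d[key] = tuple(d[key])
        return cls(**d)


def correct_barcode(observed: str, whitelist: list[str], max_mismatch: int = 1) -> str:
    """Match ``observed`` to the unique whitelist entry within ``max_mismatch``.

    Returns UNASSIGNED when no entry is close enough or when two entries
    tie at the minimal distance (never guesses).
    """
    if len(observed) != len(whitelist[0]):
        raise InputError(
            f"observed barcode length {len(observed)} != whitelist length {len(whitelist[0])}"
        )
    best, best_d, tie = None, max_mismatch + 1, False
    for entry in whitelist:
        d = hamming(observed, entry)
        if d == 0:
            return entry
        if d < best_d:
            best, best_d, tie = entry, d, False
        elif d == best_d:
            tie = True
    if best is None or tie:
        return UNASSIGNED
    return best


class _TierCorrector:
    """Whitelist matcher with an exact-hit fast path and a 1-mismatch cache."""

    def __init__(self, whitelist: list[str], max_mismatch: int):
        self.whitelist = list(whitelist)
        self.max_mismatch = max_mismatch
        self._cache: dict[str, str] = {w: w for w in whitelist}

    def __call__(self, observed: str) -> str:
        hit = self._cache.get(observed)
        if hit is not None:
            return hit
        result = correct_barcode(observed, self.whitelist, self.max_mismatch)
        self._cache[observed] = result
        return result


def _read_name(raw: str) -> str:
    return raw.split()[0]


def demultiplex(
    r1,
    i2,
    r2,
    scheme: BarcodeScheme,
    max_mismatch: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Resolve the three barcode tiers for synchronized FASTQ streams.

    ``r1``/``i2``/``r2`` may be file paths (optionally gzipped) or
    iterables of (name, seq, qual). Returns the assigned reads as a
    DataFrame (read_id, index, sss, cell, cell_id, umi, read2) and a
    rejection log with per-tier failure counts. A read is UNASSIGNED as
    soon as any tier fails; tiers are tried index -> sss -> cell so the
    log attributes each loss to the outermost failing tier.
    """
    streams = [
        iter_fastq(s) if isinstance(s, (str, Path)) else iter(s) for s in (r1, i2, r2)
    ]
    fix_index = _TierCorrector(scheme.index_whitelist, max_mismatch)
    fix_sss = _TierCorrector(scheme.sss_whitelist, max_mismatch)
    fix_cell = _TierCorrector(scheme.cell_whitelist, max_mismatch)
    co, cl = scheme.cell_segment
    uo, ul = scheme.umi_segment
    so, sl = scheme.sss_segment

    rows = []
    log = {"total": 0, "assigned": 0, "fail_index": 0, "fail_sss": 0, "fail_cell": 0}
    sentinel = object()
    for rec1, rec2, rec3 in itertools.zip_longest(*streams, fillvalue=sentinel):
        if sentinel in (rec1, rec2, rec3):
            raise InputError("FASTQ streams have unequal record counts")
        n1, s1, _ = rec1
        n2, s2, _ = rec2
        n3, s3, _ = rec3
        if not (_read_name(n1) == _read_name(n2) == _read_name(n3)):
            raise InputError(f"desynchronized FASTQ streams at read {_read_name(n1)!r}")
        log["total"] += 1
        index = fix_index(s2[: scheme.index2_len])
        if index == UNASSIGNED:
            log["fail_index"] += 1
            continue
        sss = fix_sss(s1[so : so + sl])
        if sss == UNASSIGNED:
            log["fail_sss"] += 1
            continue
        cell = fix_cell(s1[co : co + cl])
        if cell == UNASSIGNED:
            log["fail_cell"] += 1
            continue
        log["assigned"] += 1
        rows.append(
            (
                _read_name(n1),
                index,
                sss,
                cell,
                f"{index}:{sss}:{cell}",
                s1[uo : uo + ul],
                s3,
            )
        )
    assigned = pd.DataFrame(
        rows, columns=["read_id", "index", "sss", "cell", "cell_id", "umi", "read2"]
    )
    unassigned = log["fail_index"] + log["fail_sss"] + log["fail_cell"]
    assert log["assigned"] + unassigned == log["total"]
    return assigned, log


def build_kmer_index(sequences: dict[str, str], k: int = 21) -> dict:
    """k-mer -> set of gene ids containing it, plus the k used."""
    index: dict[str, set[str]] = {}
    for gene, seq in sequences.items():
        if len(seq) < 2 * k:
            raise ConfigurationError(
                f"transcript {gene} shorter than 2k = {2 * k}; k-mer voting unreliable"
            )
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(gene)
    return {"k": k, "kmers": index}


def assign_transcript(read2: str, txome_index: dict, k: int | None = None) -> str:
    """Gene whose transcript shares the most k-mers with the read.

    MULTI when the top two genes tie; NONE when the best gene covers
    fewer than half of the read's k-mers.
    """
    kmers = txome_index["kmers"]
    k = k or txome_index["k"]
    n_kmers = len(read2) - k + 1
    if n_kmers < 1:
        raise InputError(f"read shorter than k = {k}")
    votes: dict[str, int] = {}
    for i in range(n_kmers):
        for gene in kmers.get(read2[i : i + k], ()):
            votes[gene] = votes.get(gene, 0) + 1
    if not votes:
        return NONE
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return MULTI
    if ranked[0][1] < 0.5 * n_kmers:
        return NONE
    return ranked[0][0]


def _directional_collapse(umi_counts: dict[str, int]) -> int:
    """Number of molecules after directional Hamming-1 merging.

    A UMI ``b`` is absorbed by a more abundant neighbor ``a`` when
    hamming(a, b) == 1 and count(a) >= 2 * count(b) - 1, following the
    standard directional-adjacency rule.
    """
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    parent = {u: u for u in order}
    for i, a in enumerate(order):
        if parent[a] != a:
            continue
        for b in order[i + 1 :]:
            if parent[b] != b:
                continue
            if hamming(a, b) == 1 and umi_counts[a] >= 2 * umi_counts[b] - 1:
                parent[b] = a
    return sum(1 for u in parent if parent[u] == u)


def collapse_umis(
    molecules, directional: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deduplicate (cell_id, gene_id, umi) records into molecules and counts.

    ``molecules`` is an iterable of (cell_id, gene_id, umi) with one
    entry per read. Returns the molecule table (unique triples with
    read_support) and the genes x cells count matrix. Default counting
    is exact UMI dedup; ``directional=True`` additionally merges
    Hamming-1 UMI neighbors within each (cell, gene).
    """
    mol = pd.DataFrame(list(molecules), columns=["cell_id", "gene_id", "umi"])
    if mol.empty:
        return (
            mol.assign(read_support=pd.Series(dtype=int)),
            pd.DataFrame(dtype=int),
        )
    lengths = mol["umi"].str.len()
    if lengths.nunique() > 1:
        raise InputError("UMIs of non-uniform length")
    table = (
        mol.groupby(["cell_id", "gene_id", "umi"], sort=True)
        .size()
        .rename("read_support")
        .reset_index()
    )
    if directional:
        counts = (
            table.groupby(["gene_id", "cell_id"])
            .apply(
                lambda g: _directional_collapse(
                    dict(zip(g["umi"], g["read_support"]))
                ),
                include_groups=False,
            )
            .unstack(fill_value=0)
        )
    else:
        counts = (
            table.groupby(["gene_id", "cell_id"])
            .size()
            .unstack(fill_value=0)
        )
    counts.index.name = "gene_id"
    counts.columns.name = "cell_id"
    return table, counts


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: per cell, (c_g/l_g) / sum_j(c_j/l_j) * 1e6.

    ``counts`` is genes x cells; ``lengths`` maps gene_id -> transcript
    length in nt. Columns of all-zero cells stay zero (with a warning);
    all other columns sum to exactly 1e6.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise InputError(f"missing gene lengths for: {sorted(missing)[:5]}")
    lens = lengths.loc[counts.index].astype(float)
    if (lens <= 0).any():
        raise InputError("non-positive gene length")
    rate = counts.div(lens, axis=0)
    colsum = rate.sum(axis=0)
    empty = colsum == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} all-zero cells yield all-zero TPM", stacklevel=2
        )
        colsum = colsum.replace(0, 1.0)
    return rate.div(colsum, axis=1) * 1e6


def zone_for_distance(
    distance_um: float,
    zone_edges: tuple[float, ...] = (0.0, 200.0, 400.0, 600.0),
    distal_threshold: float = 1000.0,
) -> str:
    """Bin a lesion-edge distance into zones A/B/C ([lo, hi) bins) or distal D.

    Distances between the last proximal edge and the distal threshold
    are 'unzoned'.
    """
    if distance_um >= distal_threshold:
        return "D"
    names = "ABC"
    for name, lo, hi in zip(names, zone_edges, zone_edges[1:]):
        if lo <= distance_um < hi:
            return name
    return "unzoned"


def attach_metadata(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    zone_edges: tuple[float, ...] = (0.0, 200.0, 400.0, 600.0),
    distal_threshold: float = 1000.0,
) -> pd.DataFrame:
    """Align cell metadata to matrix columns, recomputing zones from distance.

    The zone column is always recomputed from ``distance_um``; a
    conflict with a provided zone raises a warning and the recomputed
    value wins. Cells falling between the proximal bins and the distal
    threshold are flagged 'unzoned' with a configuration warning.
    """
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    missing = [c for c in counts.columns if c not in meta.index]
    if missing:
        raise InputError(f"cells absent from metadata: {missing[:5]}")
    out = meta.loc[list(counts.columns)].copy()
    recomputed = out["distance_um"].map(
        lambda d: zone_for_distance(d, zone_edges, distal_threshold)
    )
    if "zone" in out.columns:
        conflict = out["zone"].notna() & (out["zone"] != recomputed)
        if conflict.any():
            warnings.warn(
                f"{int(conflict.sum())} cells had zone labels inconsistent with "
                "distance_um; recomputed zones win",
                stacklevel=2,
            )
    out["zone"] = recomputed
    if (recomputed == "unzoned").any():
        warnings.warn(
            "some cells fall between the proximal zone edges and the distal "
            "threshold; they are labeled 'unzoned'",
            stacklevel=2,
        )
    out.index.name = "cell_id"
    return out.reset_index()
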