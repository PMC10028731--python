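"""Readers and writers for the flat-text formats the pipeline exchanges.

Conventions: all in-memory coordinates are 0-based half-open. bedGraph is
natively 0-based half-open; GFF3 is converted from/to 1-based inclusive at
the boundary of this module. FASTA goes through Biopython.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")

# letter -> 0..3; anything else -> 4 (treated as ambiguous downstream)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as an int8 array (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(chrom: str, values: np.ndarray, path: str | Path) -> None:
    """Write per-base coverage as run-length-compressed 4-column bedGraph."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        if values.size == 0:
            return
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [values.size]))
        for s, e in zip(starts, ends):
            v = values[s]
            # keep integers exact, floats at full repr
            vtxt = str(int(v)) if float(v).is_integer() else repr(float(v))
            fh.write(f"{chrom}\t{s}\t{e}\t{vtxt}\n")


def read_bedgraph(path: str | Path, length: int | None = None) -> tuple[str, np.ndarray]:
    """Read a single-chromosome bedGraph into (chrom, per-base array).

    ``length`` pads the track with zeros up to the chromosome length; by
    default the maximum interval end is used.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
    )
    if df.empty:
        return "", np.zeros(length or 0)
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"expected a single chromosome per bedGraph, got {list(chroms)}")
    n = int(df["end"].max()) if length is None else int(length)
    values = np.zeros(n, dtype=np.float64)
    for s, e, v in zip(df["start"], df["end"], df["value"]):
        values[s:e] = v
    return str(chroms[0]), values


# ---------------------------------------------------------------------------
# GFF3 (CDS features only)

def write_gff3_cds(records: pd.DataFrame, path: str | Path) -> None:
    """Write CDS features from a frame with columns
    gene_id, chrom, start, end, strand (0-based half-open in memory)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in records.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tsigmascan\tCDS\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t0\tID={row.gene_id}\n"
            )


def read_gff3_cds(path: str | Path) -> pd.DataFrame:
    """Read CDS features; returns gene_id, chrom, start, end (0-based
    half-open), strand. gene_id comes from ID=, locus_tag= or Name=."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name")
            if gene_id is None:
                gene_id = f"{parts[0]}:{parts[3]}-{parts[4]}"
            rows.append(
                dict(
                    gene_id=gene_id,
                    chrom=parts[0],
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                    strand=parts[6],
                )
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# ground-truth manifest

TRUTH_COLUMNS = ["site_id", "chrom", "start", "end", "strand", "sequence"]


def write_truth_tsv(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"site_id": str, "chrom": str, "strand": str})
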