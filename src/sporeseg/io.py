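"""Readers and writers for the pipeline's plain-text formats.

FASTQ (Sanger Phred+33), FASTA + qual pairs, two-column group mappings,
lower-triangle phylip distance matrices, newick trees and TSV reports.
Every format round-trips losslessly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode

from .readqc import Read


# ---------------------------------------------------------------------------
# reads


def _sample_of(read_id: str, groups: Optional[Mapping[str, str]]) -> str:
    if groups and read_id in groups:
        return groups[read_id]
    return read_id.rsplit("_", 1)[0]


def read_fastq(path: str | Path, groups: Optional[Mapping[str, str]] = None) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(Read(
            id=rec.id,
            sequence=str(rec.seq),
            qualities=list(rec.letter_annotations["phred_quality"]),
            sample=_sample_of(rec.id, groups),
        ))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta_qual(
    fasta_path: str | Path,
    qual_path: str | Path,
    groups: Optional[Mapping[str, str]] = None,
) -> list[Read]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    quals = {rec.id: list(rec.letter_annotations["phred_quality"])
             for rec in SeqIO.parse(str(qual_path), "qual")}
    missing = set(seqs) ^ set(quals)
    if missing:
        raise ValueError(f"fasta/qual id mismatch: {sorted(missing)[:5]}")
    return [Read(id=i, sequence=s, qualities=quals[i], sample=_sample_of(i, groups))
            for i, s in seqs.items()]


def write_fasta(seqs: Mapping[str, str] | Sequence[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# group mapping


def read_groups(path: str | Path) -> dict[str, str]:
    """Two tab-separated columns: id, group."""
    mapping = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
            mapping[parts[0]] = parts[1]
    return mapping


def write_groups(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# distance matrices (lower-triangle phylip)


def write_phylip_dm(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for i, name in enumerate(dm.ids):
            row = "\t".join(f"{dm.data[i, j]:.6f}" for j in range(i))
            fh.write(f"{name}\t{row}\n" if row else f"{name}\n")


def read_phylip_dm(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise ValueError(f"{path}:1: expected a taxon count") from exc
    ids, data = [], np.zeros((n, n))
    for i, line in enumerate(lines[1:n + 1]):
        parts = line.split("\t")
        ids.append(parts[0])
        vals = [float(x) for x in parts[1:]]
        if len(vals) != i:
            raise ValueError(f"{path}:{i + 2}: expected {i} distances")
        for j, v in enumerate(vals):
            data[i, j] = data[j, i] = v
    return DistanceMatrix(data, ids)


# ---------------------------------------------------------------------------
# trees


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# tables


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
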