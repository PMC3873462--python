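"""Allele tables and variant calling.

An :class:`AlleleTable` is the samples x distinct-sequences abundance
matrix every diversity estimator and community comparison consumes.

Two variant-calling rules are provided for alignments of cloned
sequences:

* ``conventional`` — every observed SNP is taken at face value; distinct
  sequences are counted after exact collapse.
* ``conservative`` — at each alignment column, any state carried by
  exactly one sequence is treated as a likely artefact and replaced by
  the column's majority state before collapsing.

The conservative rule can only merge sequences, so its distinct count is
never larger than the conventional one, and the masking is idempotent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .readqc import Read
from .region import RegionSpec

RULE_CONVENTIONAL = "conventional"
RULE_CONSERVATIVE = "conservative"


@dataclass
class AlleleTable:
    """Distinct sequences ('alleles') x samples abundance matrix."""

    alleles: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_samples, n_alleles)
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.samples), len(self.alleles)):
            raise ValueError("counts shape must be (n_samples, n_alleles)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.alleles) and np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("all-zero allele column")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def sample_counts(self, sample: str) -> np.ndarray:
        return self.counts[self.samples.index(sample)]

    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def group_counts(self, group: str) -> np.ndarray:
        rows = [i for i, s in enumerate(self.samples) if self.group_of.get(s) == group]
        if not rows:
            raise KeyError(f"no samples in group {group!r}")
        return self.counts[rows].sum(axis=0)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            g = self.group_of.get(s)
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.T,
                            index=pd.Index(self.alleles, name="allele"),
                            columns=self.samples)


def dereplicate(
    reads: Iterable[Read] | Mapping[str, Sequence[str]],
    group_of: Optional[Mapping[str, str]] = None,
) -> AlleleTable:
    """Collapse identical sequences into alleles, tallied per sample.

    Accepts either an iterable of :class:`Read` (sample taken from the
    read) or a mapping sample -> sequences.  Alleles are ordered by total
    abundance descending, then lexicographically.
    """
    per_sample: dict[str, Counter] = {}
    if isinstance(reads, Mapping):
        for sample, seqs in reads.items():
            per_sample.setdefault(sample, Counter()).update(seqs)
    else:
        for read in reads:
            per_sample.setdefault(read.sample, Counter())[read.sequence] += 1

    samples = list(per_sample)
    total: Counter = Counter()
    for c in per_sample.values():
        total.update(c)
    alleles = sorted(total, key=lambda s: (-total[s], s))
    counts = np.zeros((len(samples), len(alleles)), dtype=int)
    index = {a: j for j, a in enumerate(alleles)}
    for i, sample in enumerate(samples):
        for seq, n in per_sample[sample].items():
            counts[i, index[seq]] = n
    return AlleleTable(alleles=alleles, samples=samples, counts=counts,
                       group_of=dict(group_of or {}))


def restrict_to_exon(table: AlleleTable, region: RegionSpec) -> AlleleTable:
    """Drop intron columns and re-collapse alleles that become identical."""
    if region.length != len(table.alleles[0]):
        raise ValueError("region span does not match the table's alignment length")
    cols = region.exon_columns
    mapping: dict[str, list[int]] = {}
    for j, allele in enumerate(table.alleles):
        key = "".join(allele[c] for c in cols)
        mapping.setdefault(key, []).append(j)
    merged = {k: table.counts[:, js].sum(axis=1) for k, js in mapping.items()}
    total = {k: int(v.sum()) for k, v in merged.items()}
    alleles = sorted(merged, key=lambda s: (-total[s], s))
    counts = np.stack([merged[a] for a in alleles], axis=1)
    return AlleleTable(alleles=alleles, samples=list(table.samples),
                       counts=counts, group_of=dict(table.group_of))


# ---------------------------------------------------------------------------
# variant calling


@dataclass
class VariantCall:
    distinct_sequences: int
    variable_sites: int
    rule: str
    collapsed: dict[str, list[int]]  # representative sequence -> input indices


def mask_singleton_states(
    seqs: Sequence[str], reference: Optional[str] = None
) -> list[str]:
    """Replace, at each column, any state carried by exactly one sequence
    with that column's majority state.

    Majority ties break toward the reference state when given, otherwise
    toward the alphabetically smallest state.  The operation is idempotent:
    a masked column is monomorphic or has no singleton states left.
    """
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must be aligned to equal length")
    rows = [list(s) for s in seqs]
    L = len(rows[0])
    for col in range(L):
        states = Counter(r[col] for r in rows)
        singles = [s for s, n in states.items() if n == 1]
        if not singles or len(states) == 1:
            continue
        non_single = {s: n for s, n in states.items() if n > 1}
        if non_single:
            best = max(non_single.values())
            cands = sorted(s for s, n in non_single.items() if n == best)
        else:  # every state is a singleton (e.g. two sequences disagreeing)
            cands = sorted(states)
        if reference is not None and reference[col] in cands:
            majority = reference[col]
        else:
            majority = cands[0]
        for r in rows:
            if states[r[col]] == 1:
                r[col] = majority
    return ["".join(r) for r in rows]


def _collapse(seqs: Sequence[str]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(s, []).append(i)
    return groups


def count_variable_sites(seqs: Sequence[str]) -> int:
    arr = np.array([list(s) for s in seqs])
    return int(sum(len(set(arr[:, j])) > 1 for j in range(arr.shape[1])))


def call_variants(
    seqs: Sequence[str],
    rule: str = RULE_CONVENTIONAL,
    reference: Optional[str] = None,
) -> VariantCall:
    """Count distinct sequences and variable sites under a calling rule."""
    if len(seqs) < 2:
        raise ValueError("variant calling needs at least 2 sequences")
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must be aligned to equal length")
    if rule not in (RULE_CONVENTIONAL, RULE_CONSERVATIVE):
        raise ValueError(f"unknown rule {rule!r}")
    work = list(seqs)
    if rule == RULE_CONSERVATIVE:
        work = mask_singleton_states(work, reference=reference)
    collapsed = _collapse(work)
    return VariantCall(
        distinct_sequences=len(collapsed),
        variable_sites=count_variable_sites(work),
        rule=rule,
        collapsed=collapsed,
    )


# ---------------------------------------------------------------------------
# translation scanning


def translate_and_scan(
    allele: str,
    region: RegionSpec,
    reference: Optional[str] = None,
) -> tuple[int, bool]:
    """Translate the exonic part of an (optionally gapped) allele and count
    stop codons; flag a frameshift when the allele's net exonic indel
    length relative to the reference is not a multiple of 3.
    """
    if len(allele) != region.length:
        raise ValueError("allele length does not match the region span")
    cols = region.exon_columns
    if len(cols) < 3:
        raise ValueError("exonic span shorter than one codon")
    exonic = "".join(allele[c] for c in cols)

    frameshift = False
    if reference is not None:
        if len(reference) != region.length:
            raise ValueError("reference length does not match the region span")
        ref_exonic = "".join(reference[c] for c in cols)
        net = ref_exonic.count("-") - exonic.count("-")
        frameshift = (net % 3) != 0

    coding = exonic.replace("-", "")
    coding = coding[region.frame_offset:]
    coding = coding[: len(coding) - (len(coding) % 3)]
    if not coding:
        return 0, frameshift
    protein = str(Seq(coding).translate())
    return protein.count("*"), frameshift


def scan_table(
    table: AlleleTable, region: RegionSpec, reference: Optional[str] = None
) -> pd.DataFrame:
    """Stop-codon / frameshift scan over every allele in a table.

    Emits both tallies the literature reports: the number of alleles with
    at least one stop codon, and the number of sequences (reads) those
    alleles represent.
    """
    ref = reference if reference is not None else table.alleles[0]
    rows = []
    pooled = table.pooled_counts()
    for j, allele in enumerate(table.alleles):
        stops, shift = translate_and_scan(allele, region, reference=ref)
        rows.append({
            "allele": allele, "n_sequences": int(pooled[j]),
            "stop_codons": stops, "frameshift": shift,
        })
    return pd.DataFrame(rows)
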