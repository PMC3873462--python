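"""Precluster near-identical amplicon sequences and screen chimeras.

Preclustering is the greedy abundance-ranked single-linkage scheme used to
absorb residual sequencing error: sequences are sorted by abundance and
each rarer sequence is merged into the first (most abundant) kept sequence
within ceil(threshold * length) differences.  A maximal contiguous gap run
counts as a single difference; terminal overhangs are ignored.

Chimera screening is reference-based: for each query the best single
reference is compared against the best two-parent model (left prefix from
one reference, right suffix from another, crossover at every column).  A
query is called chimeric when the two-parent model strictly beats the best
single parent and a column-bootstrap supports it in at least
``min_support`` of replicates; queries matching nothing above an identity
floor are flagged ``no_match`` (and removed by the pipeline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from Bio import Align


@dataclass
class UniqueSeq:
    """A dereplicated sequence with its abundance and member read ids."""

    sequence: str
    abundance: int
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = []
        if self.members and self.abundance != len(self.members):
            raise ValueError("abundance must equal number of members")


class ChimeraVerdict(str, Enum):
    OK = "ok"
    CHIMERIC = "chimeric"
    NO_MATCH = "no_match"


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -0.5
    # free terminal gaps: overhangs are not penalised and not counted
    a.open_end_gap_score = 0
    a.extend_end_gap_score = 0
    return a


_ALIGNER = _aligner()


def _diffs_aligned(a: str, b: str) -> int:
    """Differences between two equal-length (possibly gapped) sequences:
    mismatched columns count 1 each; each maximal gap run counts 1; columns
    under a terminal overhang in either sequence are ignored."""
    n = len(a)
    # trim terminal overhangs: leading/trailing columns gapped in either sequence
    start = 0
    for i in range(n):
        if a[i] == "-" or b[i] == "-":
            start = i + 1
        else:
            break
    end = n
    for i in range(n - 1, -1, -1):
        if a[i] == "-" or b[i] == "-":
            end = i
        else:
            break
    diffs = 0
    in_gap_a = in_gap_b = False
    for i in range(start, end):
        ca, cb = a[i], b[i]
        if ca == "-" and cb == "-":
            continue
        if ca == "-":
            if not in_gap_a:
                diffs += 1
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            if not in_gap_b:
                diffs += 1
            in_gap_b, in_gap_a = True, False
        else:
            in_gap_a = in_gap_b = False
            if ca != cb:
                diffs += 1
    return diffs


def pairwise_diffs(a: str, b: str) -> int:
    """Count differences between two sequences.

    Equal-length inputs are compared column-wise (gap characters allowed);
    unequal-length inputs are globally aligned first.  Each maximal gap run
    counts as one difference; terminal overhangs are free.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) == len(b):
        return _diffs_aligned(a, b)
    aln = next(iter(_ALIGNER.align(a, b)))
    sa, sb = str(aln[0]), str(aln[1])
    return _diffs_aligned(sa, sb)


def dereplicate_sequences(seqs_with_ids: Sequence[tuple[str, str]]) -> list[UniqueSeq]:
    """Collapse identical sequences; order by abundance desc, then sequence."""
    groups: dict[str, list[str]] = {}
    for rid, seq in seqs_with_ids:
        groups.setdefault(seq, []).append(rid)
    uniques = [UniqueSeq(sequence=s, abundance=len(ids), members=ids)
               for s, ids in groups.items()]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def precluster(uniques: Sequence[UniqueSeq], threshold_frac: float = 0.01) -> list[UniqueSeq]:
    """Greedy abundance-ranked single-linkage preclustering.

    Ties in abundance break lexicographically by sequence, making the
    result independent of input order.  Total abundance is conserved and
    the cluster count never exceeds the input count.
    """
    if threshold_frac < 0:
        raise ValueError("threshold_frac must be >= 0")
    if not uniques:
        raise ValueError("no sequences to precluster")
    ordered = sorted(uniques, key=lambda u: (-u.abundance, u.sequence))
    kept: list[UniqueSeq] = []
    for u in ordered:
        target = None
        for k in kept:
            length = max(len(u.sequence), len(k.sequence))
            limit = math.ceil(threshold_frac * length)
            if pairwise_diffs(u.sequence, k.sequence) <= limit:
                target = k
                break
        if target is None:
            kept.append(UniqueSeq(u.sequence, u.abundance, list(u.members)))
        else:
            target.abundance += u.abundance
            target.members.extend(u.members)
    return kept


# ---------------------------------------------------------------------------
# chimera detection


def _mismatch_profile(query: str, ref: str) -> np.ndarray:
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    return (q != r).astype(np.int64)


def detect_chimera(
    query: UniqueSeq | str,
    references: Sequence[str],
    window: int = 30,
    min_support: float = 0.90,
    min_identity: float = 0.80,
    n_boot: int = 100,
    seed: int = 0,
) -> ChimeraVerdict:
    """Reference-based two-parent chimera check.

    All references and the query must share one alignment length.  The
    best single parent (highest identity) is compared with the best
    two-parent model over every ordered reference pair and crossover
    column; support is the fraction of column-bootstrap replicates in
    which the two-parent model has strictly fewer mismatches.
    """
    seq = query.sequence if isinstance(query, UniqueSeq) else query
    if not references:
        raise ValueError("references must be non-empty")
    if window < 10:
        raise ValueError("window must be >= 10")
    if len(seq) < window:
        raise ValueError("query shorter than the support window")
    L = len(seq)
    refs = [r for r in references if len(r) == L]
    if not refs:
        raise ValueError("no reference matches the query alignment length")

    profiles = np.stack([_mismatch_profile(seq, r) for r in refs])  # (R, L)
    totals = profiles.sum(axis=1)
    best_single = int(np.argmin(totals))
    single_mm = int(totals[best_single])
    single_identity = 1.0 - single_mm / L

    # best two-parent model: prefix from A (cols < c), suffix from B (cols >= c)
    prefix = np.concatenate([np.zeros((len(refs), 1), dtype=np.int64),
                             np.cumsum(profiles, axis=1)], axis=1)  # (R, L+1)
    suffix = totals[:, None] - prefix  # mismatches in cols >= c
    best_left = prefix.min(axis=0)    # per crossover column
    best_right = suffix.min(axis=0)
    combo = best_left + best_right
    # crossovers interior to the sequence only
    c = int(np.argmin(combo[1:L]) + 1)
    chimera_mm = int(combo[c])
    if chimera_mm >= single_mm:
        # no two-parent model beats the best single parent
        if single_identity < min_identity:
            return ChimeraVerdict.NO_MATCH
        return ChimeraVerdict.OK

    a = int(np.argmin(prefix[:, c]))
    b = int(np.argmin(suffix[:, c]))
    model = np.where(np.arange(L) < c, profiles[a], profiles[b])  # chimera mismatches
    single = profiles[best_single]

    rng = np.random.default_rng(seed)
    cols = rng.integers(0, L, size=(n_boot, L))
    support = float(np.mean(model[cols].sum(axis=1) < single[cols].sum(axis=1)))
    if support >= min_support:
        return ChimeraVerdict.CHIMERIC
    if single_identity < min_identity:
        return ChimeraVerdict.NO_MATCH
    return ChimeraVerdict.OK


def screen_chimeras(
    uniques: Sequence[UniqueSeq],
    references: Sequence[str],
    window: int = 30,
    min_support: float = 0.90,
    min_identity: float = 0.80,
    seed: int = 0,
) -> tuple[list[UniqueSeq], list[tuple[str, str]]]:
    """Apply detect_chimera to every unique sequence.

    Returns (kept uniques, verdict log as (sequence-id, verdict) pairs).
    Sequences judged chimeric or matching no reference are removed.
    """
    kept, log = [], []
    for i, u in enumerate(uniques):
        v = detect_chimera(u, references, window=window, min_support=min_support,
                           min_identity=min_identity, seed=seed + i)
        name = u.members[0] if u.members else f"seq{i}"
        log.append((name, v.value))
        if v is ChimeraVerdict.OK:
            kept.append(u)
    return kept, log
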