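"""Read quality control for pyrosequencing amplicon data.

Four elimination criteria are applied per read, in a fixed order:

i.   the read does not begin with the expected MID + forward primer,
     matched exactly (and, optionally, does not end with the reverse
     adaptor);
ii.  the read contains ambiguous bases (anything outside A/C/G/T);
iii. some 50 bp sliding window has mean quality below 35;
iv.  the read contains a homopolymer run longer than 8 bp.

A read is charged to the *first* criterion it fails, so the per-class
counts in a :class:`QCReport` always sum, with the retained count, to the
raw count.  Reads are never quality-trimmed — they pass whole or are
eliminated whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

_VALID = frozenset("ACGT")

FAIL_PRIMER = "failed_primer"
FAIL_AMBIG = "failed_ambiguous"
FAIL_QUALITY = "failed_quality"
FAIL_HOMOPOLYMER = "failed_homopolymer"
FAILURE_CLASSES = (FAIL_PRIMER, FAIL_AMBIG, FAIL_QUALITY, FAIL_HOMOPOLYMER)


@dataclass
class Read:
    """One amplicon read with per-base Phred qualities and a sample label."""

    id: str
    sequence: str
    qualities: Sequence[int]
    sample: str = ""

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QCConfig:
    primer_fwd: str = ""
    primer_rev: str = ""
    mid: Optional[str] = None
    require_reverse: bool = False
    window: int = 50
    min_avg: float = 35.0
    max_homopolymer: int = 8
    check_primer: bool = True


@dataclass
class QCReport:
    """Per-sample QC accounting; counts are conserved by construction."""

    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)

    def _bucket(self, sample: str) -> dict[str, int]:
        if sample not in self.per_sample:
            self.per_sample[sample] = {"raw": 0, "retained": 0, **{c: 0 for c in FAILURE_CLASSES}}
        return self.per_sample[sample]

    def charge(self, sample: str, outcome: str) -> None:
        b = self._bucket(sample)
        b["raw"] += 1
        b[outcome] += 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.per_sample, orient="index")
        df.index.name = "sample"
        if len(df):
            df["retained_fraction"] = df["retained"] / df["raw"]
        return df


def match_and_trim(
    read: Read,
    primer_fwd: str,
    primer_rev: str = "",
    mid: Optional[str] = None,
    require_reverse: bool = False,
) -> Optional[Read]:
    """Exact MID+primer prefix match; returns the trimmed read or ``None``.

    Zero mismatches are tolerated anywhere in the matched affixes.  The
    reverse adaptor is only required when ``require_reverse`` is set (454
    reads frequently end before reaching it); when present it is trimmed.
    """
    if not primer_fwd:
        raise ValueError("forward primer must be non-empty")
    prefix = (mid or "") + primer_fwd
    if not read.sequence.startswith(prefix):
        return None
    seq = read.sequence[len(prefix):]
    qual = list(read.qualities[len(prefix):])
    if primer_rev:
        if seq.endswith(primer_rev):
            seq = seq[: -len(primer_rev)]
            qual = qual[: -len(primer_rev)]
        elif require_reverse:
            return None
    if not seq:
        return None
    return Read(id=read.id, sequence=seq, qualities=qual, sample=read.sample)


def has_ambiguous(read: Read) -> bool:
    """True iff any base falls outside A/C/G/T."""
    return any(b not in _VALID for b in read.sequence)


def window_quality_fail(read: Read, window: int = 50, min_avg: float = 35.0) -> bool:
    """True iff some sliding window of ``window`` bases has mean quality
    below ``min_avg``.  Reads shorter than the window are judged on their
    whole-read mean."""
    if window < 1:
        raise ValueError("window must be >= 1")
    q = np.asarray(read.qualities, dtype=float)
    if q.size == 0:
        return False
    if q.size < window:
        return bool(q.mean() < min_avg)
    csum = np.concatenate(([0.0], np.cumsum(q)))
    means = (csum[window:] - csum[:-window]) / window
    return bool(np.any(means < min_avg))


def longest_homopolymer(sequence: str) -> int:
    best = run = 0
    prev = None
    for b in sequence:
        run = run + 1 if b == prev else 1
        prev = b
        if run > best:
            best = run
    return best


def homopolymer_fail(read: Read, max_run: int = 8) -> bool:
    """True iff the longest single-base run strictly exceeds ``max_run``."""
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    return longest_homopolymer(read.sequence) > max_run


def classify_read(read: Read, config: QCConfig) -> tuple[str, Optional[Read]]:
    """Apply criteria i->iv; return (outcome, trimmed read or None)."""
    trimmed: Optional[Read] = read
    if config.check_primer:
        trimmed = match_and_trim(
            read,
            primer_fwd=config.primer_fwd,
            primer_rev=config.primer_rev,
            mid=config.mid,
            require_reverse=config.require_reverse,
        )
        if trimmed is None:
            return FAIL_PRIMER, None
    if has_ambiguous(trimmed):
        return FAIL_AMBIG, None
    if window_quality_fail(trimmed, window=config.window, min_avg=config.min_avg):
        return FAIL_QUALITY, None
    if config.max_homopolymer is not None and np.isfinite(config.max_homopolymer):
        if homopolymer_fail(trimmed, max_run=int(config.max_homopolymer)):
            return FAIL_HOMOPOLYMER, None
    return "retained", trimmed


def run_qc(reads: Iterable[Read], config: QCConfig) -> tuple[list[Read], QCReport]:
    """Run the four criteria over a batch of reads.

    Verdicts are per-read, so the result is independent of input order up
    to the order of the retained list itself.
    """
    report = QCReport()
    retained: list[Read] = []
    for read in reads:
        if len(read.qualities) != len(read.sequence):  # defensive: Read validates too
            raise ValueError(f"read {read.id!r}: sequence/quality length mismatch")
        outcome, trimmed = classify_read(read, config)
        report.charge(read.sample, outcome)
        if trimmed is not None:
            retained.append(trimmed)
    return retained, report
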