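"""Synthetic amplicon data with the statistical structure of a multinucleate
fungal spore experiment.

The generator builds a parent "mycelium" allele pool (one random reference
sequence plus point-mutated variants under a geometric ranked-abundance
law), samples nuclei into spores across host plants, and emits
pyrosequencing-style reads: MID + forward primer + allele insert + reverse
adaptor, with substitution errors, homopolymer length errors and optional
two-parent chimeras.  Ground truth (template, chimera flag, planted QC
failure) travels in a sidecar table keyed by read id, so every downstream
stage can be scored for sensitivity and specificity.

Defaults emulate the study design this package targets: 3 plants carrying
2-3 spores each (8 spores), a ~200 bp amplicon spanning
exon / intron / exon, a heavily skewed abundance distribution in which the
four most abundant alleles carry ~60% of the mass, and most mutations
falling in the intron.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .readqc import Read
from .region import RegionSpec, default_region

BASES = "ACGT"

PRIMER_FWD = "GAATCCTTCCCAAATTGATCAGAATACTTGTT"
PRIMER_REV = "TAATAATAAAAGCCTTTCAAAAAATCCATCAATA"
DEFAULT_MID = "ACGAGTGCGT"


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AllelePool:
    """The parent mycelium's allele complement: distinct equal-length
    sequences with strictly positive relative abundances summing to 1."""

    sequences: list[str]
    frequencies: np.ndarray
    region: RegionSpec

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.sequences) != self.frequencies.size:
            raise ValueError("sequences and frequencies must have equal length")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("pool sequences must be pairwise distinct")
        if len({len(s) for s in self.sequences}) != 1:
            raise ValueError("pool sequences must share one alignment length")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be strictly positive")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @property
    def n_alleles(self) -> int:
        return len(self.sequences)

    @property
    def amplicon_length(self) -> int:
        return len(self.sequences[0])


@dataclass
class SporeSample:
    """One spore: a multiset of nuclei, each carrying one pool allele."""

    spore_id: str
    plant_id: str
    allele_indices: np.ndarray

    def __post_init__(self) -> None:
        self.allele_indices = np.asarray(self.allele_indices, dtype=int)
        if self.allele_indices.size == 0:
            raise ValueError("spore must contain at least one nucleus")
        if np.any(self.allele_indices < 0):
            raise ValueError("negative allele index")

    @property
    def distinct_alleles(self) -> np.ndarray:
        return np.unique(self.allele_indices)

    def allele_counts(self, n_alleles: int) -> np.ndarray:
        return np.bincount(self.allele_indices, minlength=n_alleles)


@dataclass
class ReadTruth:
    read_id: str
    spore_id: str
    template: int              # pool index of the template (left parent if chimeric)
    chimera_parent: int = -1   # pool index of the right parent, -1 if not chimeric
    is_chimera: bool = False
    n_substitutions: int = 0
    n_homopolymer_errors: int = 0
    planted_failure: str = ""  # QC failure class planted on purpose, if any


# ---------------------------------------------------------------------------
# parent pool


def geometric_frequencies(n: int, dominance: float = 0.6) -> np.ndarray:
    """Ranked geometric abundances for ``n`` alleles where the top four
    alleles jointly carry ``dominance`` of the total mass.

    One decay parameter reproduces both the dominant-allele head and the
    long singleton tail seen in skewed amplicon allele distributions.
    """
    if not (0 < dominance <= 1):
        raise ValueError("dominance must lie in (0, 1]")
    if n <= 4:
        w = np.ones(n)
        return w / w.sum()
    lo, hi = 4.0 / n, 1.0
    if dominance <= lo:  # flatter than uniform is unreachable; fall back to uniform
        return np.full(n, 1.0 / n)
    if dominance >= hi - 1e-12:
        dominance = hi - 1e-9

    def top4_share(r: float) -> float:
        k = np.arange(n)
        w = r ** k
        return w[:4].sum() / w.sum()

    r = brentq(lambda r: top4_share(r) - dominance, 1e-9, 1 - 1e-9, xtol=1e-12)
    w = r ** np.arange(n)
    return w / w.sum()


def generate_parent_pool(
    n_alleles: int,
    dominance: float = 0.6,
    amplicon_length: int = 200,
    region: Optional[RegionSpec] = None,
    intron_mutation_bias: float = 0.7,
    max_mutations_per_allele: int = 4,
    seed: int = 0,
) -> AllelePool:
    """Derive ``n_alleles`` distinct sequences from one random reference by
    point mutations, placing ``intron_mutation_bias`` of mutations in intron
    columns, under a geometric ranked-abundance law.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if amplicon_length < 3:
        raise ValueError("amplicon_length must be >= 3")
    if region is None:
        region = default_region(amplicon_length)
    if region.length != amplicon_length:
        raise ValueError("region span must equal amplicon_length")
    # every (site, alternative state) pair is a possible single mutation
    if n_alleles - 1 > 3 * amplicon_length * max_mutations_per_allele:
        raise ValueError(
            f"cannot place {n_alleles} distinct alleles over "
            f"{amplicon_length} mutable sites"
        )
    rng = np.random.default_rng(seed)
    reference = "".join(rng.choice(list(BASES), size=amplicon_length))

    intron_cols = np.array(region.intron_columns, dtype=int)
    exon_cols = np.array(region.exon_columns, dtype=int)

    def draw_site() -> int:
        if intron_cols.size and (not exon_cols.size or rng.random() < intron_mutation_bias):
            return int(rng.choice(intron_cols))
        return int(rng.choice(exon_cols if exon_cols.size else intron_cols))

    sequences = [reference]
    seen = {reference}
    attempts = 0
    while len(sequences) < n_alleles:
        attempts += 1
        if attempts > 200 * n_alleles:
            raise RuntimeError("failed to generate enough distinct alleles")
        k = int(rng.integers(1, max_mutations_per_allele + 1))
        seq = list(reference)
        for _ in range(k):
            site = draw_site()
            alt = rng.choice([b for b in BASES if b != seq[site]])
            seq[site] = alt
        s = "".join(seq)
        if s not in seen:
            seen.add(s)
            sequences.append(s)

    freqs = geometric_frequencies(n_alleles, dominance)
    return AllelePool(sequences=sequences, frequencies=freqs, region=region)


# ---------------------------------------------------------------------------
# sporulation


def _spore_labels(plants: int, spores_per_plant: Sequence[int]) -> list[tuple[str, str]]:
    labels = []
    for p in range(plants):
        plant = string.ascii_uppercase[p]
        for s in range(spores_per_plant[p]):
            labels.append((plant, f"{plant}{s + 1}"))
    return labels


def sporulate(
    pool: AllelePool,
    plants: int = 3,
    spores_per_plant: Sequence[int] = (3, 3, 2),
    nuclei_per_spore: int = 1000,
    seed: int = 0,
) -> list[SporeSample]:
    """Draw each spore's nuclei independently from the pool frequencies.

    The expected number of distinct alleles per spore is
    ``sum_i 1 - (1 - p_i)**n`` for ``n`` nuclei — the sampling bottleneck
    the downstream estimators are meant to quantify.
    """
    if len(spores_per_plant) != plants:
        raise ValueError("spores_per_plant must have one entry per plant")
    if nuclei_per_spore < 1:
        raise ValueError("nuclei_per_spore must be >= 1")
    rng = np.random.default_rng(seed)
    spores = []
    for plant, label in _spore_labels(plants, spores_per_plant):
        idx = rng.choice(pool.n_alleles, size=nuclei_per_spore, p=pool.frequencies)
        spores.append(SporeSample(spore_id=label, plant_id=plant, allele_indices=idx))
    return spores


def expected_distinct(frequencies: np.ndarray, n: int) -> float:
    """Closed-form expected distinct alleles in ``n`` multinomial draws."""
    p = np.asarray(frequencies, dtype=float)
    return float(np.sum(1.0 - (1.0 - p) ** n))


# ---------------------------------------------------------------------------
# read simulation


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def _homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """(start, length) of maximal single-base runs of length >= min_len."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


@dataclass
class QualityModel:
    """Gaussian per-base qualities, truncated to [2, 40]."""

    mean: float = 38.0
    sd: float = 2.0
    low_q_frac: float = 0.0   # fraction of reads given a low-quality stretch
    low_q_mean: float = 20.0

    def draw(self, length: int, rng: np.random.Generator) -> tuple[list[int], bool]:
        q = rng.normal(self.mean, self.sd, size=length)
        planted = False
        if self.low_q_frac > 0 and rng.random() < self.low_q_frac and length >= 50:
            start = int(rng.integers(0, length - 50 + 1))
            q[start:start + 50] = rng.normal(self.low_q_mean, 1.0, size=50)
            planted = True
        q = np.clip(np.rint(q), 2, 40).astype(int)
        return q.tolist(), planted


def simulate_reads(
    spore: SporeSample,
    pool: AllelePool,
    n_reads: int,
    sub_rate: float = 0.0,
    homopolymer_err: float = 0.0,
    chimera_rate: float = 0.0,
    primer_fwd: str = PRIMER_FWD,
    primer_rev: str = PRIMER_REV,
    mid: Optional[str] = None,
    quality_model: Optional[QualityModel] = None,
    seed: int = 0,
) -> tuple[list[Read], list[ReadTruth]]:
    """Simulate error-laden amplicon reads from one spore.

    Read layout: [MID] + forward primer + insert + reverse adaptor (the
    reverse complement of the reverse primer).  Chimeras join the left
    prefix of one template to the right suffix of another at a uniform
    crossover; parents are drawn abundance-weighted and distinct.
    """
    for name, r in (("sub_rate", sub_rate), ("homopolymer_err", homopolymer_err),
                    ("chimera_rate", chimera_rate)):
        if not (0 <= r <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if pool.n_alleles == 0:
        raise ValueError("empty allele pool")

    rng = np.random.default_rng(seed)
    qm = quality_model or QualityModel()
    counts = spore.allele_counts(pool.n_alleles).astype(float)
    probs = counts / counts.sum()
    present = np.flatnonzero(counts)

    reads: list[Read] = []
    truths: list[ReadTruth] = []
    rev_adaptor = _revcomp(primer_rev) if primer_rev else ""
    for i in range(n_reads):
        rid = f"{spore.spore_id}_r{i:06d}"
        is_chimera = bool(
            chimera_rate > 0 and present.size >= 2 and rng.random() < chimera_rate
        )
        if is_chimera:
            left, right = rng.choice(pool.n_alleles, size=2, replace=False, p=probs) \
                if np.count_nonzero(probs) >= 2 else (present[0], present[0])
            cross = int(rng.integers(1, pool.amplicon_length))
            insert = pool.sequences[left][:cross] + pool.sequences[right][cross:]
            template, parent2 = int(left), int(right)
        else:
            template = int(rng.choice(pool.n_alleles, p=probs))
            parent2 = -1
            insert = pool.sequences[template]

        n_homo = 0
        if homopolymer_err > 0:
            out = []
            pos = 0
            for start, length in _homopolymer_runs(insert):
                out.append(insert[pos:start])
                run = insert[start:start + length]
                if rng.random() < homopolymer_err:
                    run = run[:-1] if rng.random() < 0.5 else run + run[0]
                    n_homo += 1
                out.append(run)
                pos = start + length
            out.append(insert[pos:])
            insert = "".join(out)

        n_sub = 0
        if sub_rate > 0:
            chars = list(insert)
            hits = np.flatnonzero(rng.random(len(chars)) < sub_rate)
            for site in hits:
                chars[site] = rng.choice([b for b in BASES if b != chars[site]])
            n_sub = hits.size
            insert = "".join(chars)

        seq = (mid or "") + primer_fwd + insert + rev_adaptor
        qual, planted_lowq = qm.draw(len(seq), rng)
        reads.append(Read(id=rid, sequence=seq, qualities=qual, sample=spore.spore_id))
        truths.append(ReadTruth(
            read_id=rid, spore_id=spore.spore_id, template=template,
            chimera_parent=parent2, is_chimera=is_chimera,
            n_substitutions=int(n_sub), n_homopolymer_errors=n_homo,
            planted_failure="failed_quality" if planted_lowq else "",
        ))
    return reads, truths


def truth_frame(truths: Sequence[ReadTruth]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truths])


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SyntheticDataset:
    pool: AllelePool
    spores: list[SporeSample]
    reads: list[Read]
    truth: pd.DataFrame
    group_of: dict[str, str]


def generate_dataset(
    n_alleles: int = 356,
    dominance: float = 0.6,
    amplicon_length: int = 200,
    plants: int = 3,
    spores_per_plant: Sequence[int] = (3, 3, 2),
    nuclei_per_spore: int = 1000,
    reads_per_spore: int = 500,
    sub_rate: float = 0.0,
    homopolymer_err: float = 0.0,
    chimera_rate: float = 0.0,
    mid: Optional[str] = None,
    quality_model: Optional[QualityModel] = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Parent pool -> spores -> reads, with ground truth and group mapping."""
    rng = np.random.default_rng(seed)
    pool = generate_parent_pool(
        n_alleles, dominance=dominance, amplicon_length=amplicon_length,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    spores = sporulate(
        pool, plants=plants, spores_per_plant=spores_per_plant,
        nuclei_per_spore=nuclei_per_spore, seed=int(rng.integers(0, 2**31 - 1)),
    )
    reads: list[Read] = []
    truths: list[ReadTruth] = []
    for spore in spores:
        r, t = simulate_reads(
            spore, pool, reads_per_spore, sub_rate=sub_rate,
            homopolymer_err=homopolymer_err, chimera_rate=chimera_rate,
            mid=mid, quality_model=quality_model,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        reads.extend(r)
        truths.extend(t)
    group_of = {s.spore_id: s.plant_id for s in spores}
    return SyntheticDataset(
        pool=pool, spores=spores, reads=reads,
        truth=truth_frame(truths), group_of=group_of,
    )
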