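"""End-to-end orchestration: synthetic data (optional) -> QC ->
precluster/chimera screen -> allele table -> diversity summary ->
community comparisons (-> segregation simulation).

A run directory receives one TSV per analysis stage plus a manifest
recording seeds, parameters and per-stage record counts, sufficient to
reproduce any run bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alleles import AlleleTable, dereplicate, restrict_to_exon, scan_table
from .compare import (amova, build_nj_tree, difference_distance_matrix, homova,
                      jclass, ks_two_sample, thetayc, unifrac)
from .denoise import dereplicate_sequences, precluster, screen_chimeras
from .diversity import diversity_summary
from .io import (read_fasta, read_fastq, read_groups, write_fasta, write_groups,
                 write_newick, write_tsv)
from .readqc import QCConfig, Read, run_qc
from .region import RegionSpec, default_region
from .simdata import PRIMER_FWD, PRIMER_REV, QualityModel, generate_dataset
from skbio import DistanceMatrix


@dataclass
class PipelineConfig:
    outdir: str = "run"
    # inputs; when fastq is None, synthetic data is generated
    fastq: Optional[str] = None
    groups: Optional[str] = None
    references: Optional[str] = None
    tree: Optional[str] = None
    # synthetic generation
    n_alleles: int = 60
    dominance: float = 0.6
    amplicon_length: int = 200
    nuclei_per_spore: int = 400
    reads_per_spore: int = 300
    sub_rate: float = 0.0
    homopolymer_err: float = 0.0
    chimera_rate: float = 0.0
    # QC
    qc_enabled: bool = True
    primer_fwd: str = PRIMER_FWD
    primer_rev: str = PRIMER_REV
    mid: Optional[str] = None
    window: int = 50
    min_avg: float = 35.0
    max_homopolymer: int = 8
    # denoise
    precluster_threshold: float = 0.01
    chimera_min_support: float = 0.90
    chimera_min_identity: float = 0.80
    # analysis
    exon_only: bool = True
    n_perms: int = 1000
    run_segsim: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> Path:
    """Execute the full chain; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }

    region = default_region(config.amplicon_length)
    references: Optional[list[str]] = None
    group_of: dict[str, str] = {}

    if config.fastq is None:
        ds = generate_dataset(
            n_alleles=config.n_alleles, dominance=config.dominance,
            amplicon_length=config.amplicon_length,
            nuclei_per_spore=config.nuclei_per_spore,
            reads_per_spore=config.reads_per_spore,
            sub_rate=config.sub_rate, homopolymer_err=config.homopolymer_err,
            chimera_rate=config.chimera_rate, mid=config.mid,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        reads = ds.reads
        group_of = ds.group_of
        region = ds.pool.region
        references = list(ds.pool.sequences)
        write_tsv(ds.truth, out / "truth.tsv")
        write_fasta({f"allele{i}": s for i, s in enumerate(ds.pool.sequences)},
                    out / "pool.fasta")
        manifest["stages"]["simdata"] = {"reads": len(reads),
                                         "pool_alleles": ds.pool.n_alleles}
    else:
        if config.groups:
            group_of = read_groups(config.groups)
        reads = read_fastq(config.fastq, groups=group_of or None)
        manifest["stages"]["input"] = {"reads": len(reads),
                                       "checksum": _checksum(Path(config.fastq))}
        if config.references:
            references = list(read_fasta(config.references).values())
    if not group_of:
        group_of = {s: s[0] for s in {r.sample for r in reads}}
    write_groups(group_of, out / "groups.tsv")

    # --- QC -----------------------------------------------------------------
    if config.qc_enabled:
        qc_cfg = QCConfig(
            primer_fwd=config.primer_fwd, primer_rev=_revcomp(config.primer_rev),
            mid=config.mid, window=config.window, min_avg=config.min_avg,
            max_homopolymer=config.max_homopolymer,
        )
        retained, report = run_qc(reads, qc_cfg)
        write_tsv(report.to_frame().reset_index(), out / "qc_report.tsv")
        manifest["stages"]["qc"] = {"raw": len(reads), "retained": len(retained)}
        assert len(reads) == sum(b["raw"] for b in report.per_sample.values())
    else:
        retained = reads
        manifest["stages"]["qc"] = {"raw": len(reads), "retained": len(reads),
                                    "disabled": True}

    # --- precluster + chimera screen, per sample ----------------------------
    per_sample_seqs: dict[str, list[str]] = {}
    removed_chimeric = 0
    for sample in sorted({r.sample for r in retained}):
        sample_reads = [r for r in retained if r.sample == sample]
        uniques = dereplicate_sequences([(r.id, r.sequence) for r in sample_reads])
        clusters = precluster(uniques, threshold_frac=config.precluster_threshold)
        if references:
            clusters, log = screen_chimeras(
                clusters, references,
                min_support=config.chimera_min_support,
                min_identity=config.chimera_min_identity,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            removed_chimeric += sum(1 for _, v in log if v != "ok")
        seqs: list[str] = []
        for c in clusters:
            seqs.extend([c.sequence] * c.abundance)
        per_sample_seqs[sample] = seqs
    manifest["stages"]["denoise"] = {
        "reads": sum(len(v) for v in per_sample_seqs.values()),
        "removed_clusters": removed_chimeric,
    }

    # --- allele table --------------------------------------------------------
    table = dereplicate(per_sample_seqs, group_of=group_of)
    full_table = table
    if config.exon_only and all(len(a) == region.length for a in table.alleles):
        table = restrict_to_exon(table, region)
    write_tsv(table.to_frame().reset_index(), out / "allele_table.tsv")
    manifest["stages"]["alleles"] = {"alleles": table.n_alleles,
                                     "alleles_full_region": full_table.n_alleles}

    # --- diversity -----------------------------------------------------------
    summary = diversity_summary(table, unit="all")
    write_tsv(summary, out / "diversity_summary.tsv")

    # --- translation scan ----------------------------------------------------
    if all(len(a) == region.length for a in full_table.alleles):
        scan = scan_table(full_table, region)
        write_tsv(scan, out / "translation_scan.tsv")

    # --- comparisons ---------------------------------------------------------
    comp = _comparisons(table, out, config, rng)
    write_tsv(comp, out / "comparisons.tsv")

    # --- optional segregation simulation -------------------------------------
    if config.run_segsim:
        from .segsim import SimConfig, simulate
        cfg = SimConfig(initial_richness=config.n_alleles,
                        retention_fraction=0.6,
                        n_generations=20, n_reps=100,
                        seed=int(rng.integers(0, 2**31 - 1)))
        traj = simulate(cfg)
        write_tsv(traj.to_frame(), out / "segsim_trajectories.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _comparisons(table: AlleleTable, out: Path, config: PipelineConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Pairwise jclass / thetaYC / UniFrac / KS between samples, plus
    AMOVA/HOMOVA across plant groups when there are enough samples."""
    rows = []
    samples = table.samples
    names = [f"a{j}" for j in range(table.n_alleles)]

    tree = None
    if table.n_alleles >= 3:
        dm_alleles = difference_distance_matrix(table.alleles, names)
        tree = build_nj_tree(dm_alleles)
        write_newick(tree, out / "allele_tree.nwk")

    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            a = table.sample_counts(samples[i])
            b = table.sample_counts(samples[j])
            pair = f"{samples[i]}-{samples[j]}"
            rows.append({"pair": pair, "method": "jclass",
                         "statistic": jclass(a, b), "p_value": np.nan})
            rows.append({"pair": pair, "method": "thetayc",
                         "statistic": thetayc(a, b), "p_value": np.nan})
            ks = ks_two_sample(a[a + b > 0], b[a + b > 0])
            rows.append({"pair": pair, "method": "ks",
                         "statistic": ks.statistic, "p_value": ks.p_value})
            if tree is not None:
                res = unifrac(tree,
                              dict(zip(names, a)), dict(zip(names, b)),
                              weighted=True, n_perms=min(config.n_perms, 200),
                              seed=int(rng.integers(0, 2**31 - 1)))
                rows.append({"pair": pair, "method": "wunifrac",
                             "statistic": res.statistic, "p_value": res.p_value})

    # AMOVA / HOMOVA across plants on a sample-level thetaYC distance matrix
    groups = [table.group_of.get(s, s[0]) for s in samples]
    counts = {g: sum(1 for x in groups if x == g) for g in set(groups)}
    if len(counts) >= 2 and all(v >= 2 for v in counts.values()):
        n = len(samples)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = thetayc(table.sample_counts(samples[i]),
                            table.sample_counts(samples[j]))
                mat[i, j] = mat[j, i] = d
        dm = DistanceMatrix(mat, samples)
        for name, fn in (("amova", amova), ("homova", homova)):
            res = fn(dm, groups, n_perms=config.n_perms,
                     seed=int(rng.integers(0, 2**31 - 1)))
            rows.append({"pair": "plants", "method": name,
                         "statistic": res.statistic, "p_value": res.p_value})
    return pd.DataFrame(rows)
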