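"""Deterministic toy datasets for tests and demonstrations.

Every fixture is small (<= 50 sites, <= 20 haplotypes), generated in
memory and written as plain text; identical seeds give identical bytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ami import vcfio
from ami.admixsim import DemographicModel, simulate_panel, type_specific_variants
from ami.panel import HaplotypePanel

KINDS = ("tiny-panel", "tiny-markers", "tiny-gwas", "sim-replicate")


def tiny_panel() -> HaplotypePanel:
    """Ten haplotypes, one 1 kb contig, a hand-checkable AMI case.

    Sites 100/400/700 carry the ALT allele on exactly haplotypes {0, 1}:
    three mutually perfect-LD target-specific variants on a 1 kb contig,
    density 3/kb, partner count 2, hence AMI = 2/3 each.  Sites 250 and
    850 are shared polymorphisms used as non-specific background.
    """
    n_hap, positions = 10, [100, 250, 400, 700, 850]
    h = np.zeros((n_hap, len(positions)), dtype=np.int8)
    for col in (0, 2, 3):  # the specific trio
        h[[0, 1], col] = 1
    h[[0, 2, 4, 6], 1] = 1  # shared variant
    h[[1, 3, 5, 7, 9], 4] = 1  # shared variant
    return HaplotypePanel(
        haplotypes=h,
        positions=np.array(positions, dtype=np.int64),
        contigs=np.array(["chrT"] * len(positions), dtype=object),
        ref=np.array(list("ACGTA"), dtype=object),
        alt=np.array(list("GTACG"), dtype=object),
        samples=[f"t{i}" for i in range(n_hap // 2)],
        contig_lengths={"chrT": 1000},
    )


def tiny_reference_panel() -> HaplotypePanel:
    """Reference panel: same sites, specific trio absent, shared sites kept."""
    n_hap, positions = 10, [100, 250, 400, 700, 850]
    h = np.zeros((n_hap, len(positions)), dtype=np.int8)
    h[[1, 3, 5], 1] = 1
    h[[0, 2], 4] = 1
    return HaplotypePanel(
        haplotypes=h,
        positions=np.array(positions, dtype=np.int64),
        contigs=np.array(["chrT"] * len(positions), dtype=object),
        ref=np.array(list("ACGTA"), dtype=object),
        alt=np.array(list("GTACG"), dtype=object),
        samples=[f"r{i}" for i in range(n_hap // 2)],
        contig_lengths={"chrT": 1000},
    )


def tiny_markers() -> pd.DataFrame:
    """The specific trio of :func:`tiny_panel` as a called marker set."""
    return pd.DataFrame(
        {
            "contig": ["chrT"] * 3,
            "pos": [100, 400, 700],
            "ref": ["A", "G", "T"],
            "alt": ["G", "A", "C"],
            "specific_allele": ["alt"] * 3,
            "marker_allele": ["G", "A", "C"],
        }
    )


def tiny_gwas() -> pd.DataFrame:
    """Two-SNP trait with mean2βf = (2·0.5·0.2 + 2·(−1)·0.5)/2 = −0.4."""
    return pd.DataFrame(
        {
            "variant_id": ["rsA", "rsB"],
            "contig": ["chrT", "chrT"],
            "pos": [100, 700],
            "effect_allele": ["G", "C"],
            "beta": [0.5, -1.0],
            "p": [1e-5, 1e-4],
        }
    )


def tiny_gwas_freqs() -> pd.DataFrame:
    """Frequencies completing the mean2βf = −0.4 hand case."""
    return pd.DataFrame(
        {
            "variant_id": ["rsA", "rsB"],
            "beta": [0.5, -1.0],
            "f": [0.2, 0.5],
        }
    )


def make_fixture(kind: str, seed: int, outdir: str | Path) -> list[Path]:
    """Write one fixture bundle; returns the created paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "tiny-panel":
        paths = [outdir / "tiny_target.vcf", outdir / "tiny_reference.vcf"]
        vcfio.write_vcf(tiny_panel(), paths[0])
        vcfio.write_vcf(tiny_reference_panel(), paths[1])
    elif kind == "tiny-markers":
        paths = [outdir / "tiny_markers.tsv"]
        vcfio.write_table(tiny_markers(), paths[0])
    elif kind == "tiny-gwas":
        paths = [outdir / "tiny_gwas.tsv", outdir / "tiny_gwas_freqs.tsv"]
        vcfio.write_table(tiny_gwas(), paths[0])
        vcfio.write_table(tiny_gwas_freqs(), paths[1])
    elif kind == "sim-replicate":
        model = DemographicModel(seq_len_bp=100_000, n_hap_per_group=20)
        sim = simulate_panel(model, seed)
        typed = type_specific_variants(sim)
        paths = [outdir / "sim_panel.vcf", outdir / "sim_truth.tsv",
                 outdir / "sim_tracts.bed"]
        vcfio.write_vcf(sim.panel, paths[0])
        vcfio.write_table(
            typed[["contig", "pos", "truth_type", "origin_time", "origin_pop"]],
            paths[1],
        )
        vcfio.write_tracts_bed(sim.tracts, sim.panel.samples, paths[2])
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
    return paths
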