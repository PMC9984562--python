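"""VCF/TSV/JSON input-output.

Reading goes through cyvcf2; writing uses a plain deterministic text
writer so simulated panels round-trip byte-identically.  Coordinates
are 1-based inclusive in all tables (VCF convention); ancestry-tract
BED output is 0-based half-open (BED convention).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ami import __version__
from ami.panel import MISSING, HaplotypePanel

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def read_haplotype_panel(path: str | Path) -> HaplotypePanel:
    """Read phased biallelic SNPs from a VCF into a panel.

    Non-biallelic or non-SNP records are skipped (counts logged).
    Missing genotypes become missing haplotype calls.  Any unphased
    heterozygote marks the whole panel unphased; haplotype-level
    operations will then refuse it while dosage-only operations accept it.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    contig_lengths: dict[str, int] = {}
    for c, ln in zip(vcf.seqnames, vcf.seqlens or []):
        contig_lengths[c] = int(ln)

    haps, positions, contigs, refs, alts = [], [], [], [], []
    n_skipped = 0
    phased = True
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        row = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a0, a1, ph = g[0], g[1], g[2]
            row[2 * i] = MISSING if a0 < 0 else a0
            row[2 * i + 1] = MISSING if a1 < 0 else a1
            if not ph and a0 >= 0 and a1 >= 0 and a0 != a1:
                phased = False
        haps.append(row)
        positions.append(var.POS)
        contigs.append(var.CHROM)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", n_skipped, path)
    if not haps:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    return HaplotypePanel(
        haplotypes=np.array(haps, dtype=np.int8).T,
        positions=np.array(positions, dtype=np.int64),
        contigs=np.array(contigs, dtype=object),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        samples=samples,
        phased=phased,
        contig_lengths=contig_lengths,
    )


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal phased VCF (deterministic bytes)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=ami {__version__}\n")
        for contig in dict.fromkeys(panel.contigs):
            length = panel.contig_lengths.get(contig)
            if length:
                fh.write(f"##contig=<ID={contig},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        sep = "|" if panel.phased else "/"
        for k in range(panel.n_sites):
            gts = []
            for i in range(panel.n_samples):
                a0, a1 = panel.haplotypes[2 * i, k], panel.haplotypes[2 * i + 1, k]
                gts.append(
                    f"{'.' if a0 < 0 else a0}{sep}{'.' if a1 < 0 else a1}"
                )
            fh.write(
                f"{panel.contigs[k]}\t{panel.positions[k]}\t.\t{panel.ref[k]}\t"
                f"{panel.alt[k]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_tracts_bed(tracts, samples: list[str], path: str | Path,
                     contig: str = "1") -> None:
    """Ancestry tracts as BED: contig, start (0-based), end, hap_id, source."""
    with Path(path).open("w") as fh:
        for hap_i, tr in enumerate(tracts):
            hap_id = f"{samples[hap_i // 2]}_h{hap_i % 2}"
            for s, e, src in tr:
                fh.write(f"{contig}\t{s}\t{e}\t{hap_id}\t{src}\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with fixed float formatting; header always written."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_json_summary(obj: dict, path: str | Path, config: dict | None = None) -> None:
    """JSON summary with a deterministic metadata block."""
    meta = {"ami_version": __version__}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str)
        meta["config"] = config
        meta["config_sha1"] = hashlib.sha1(blob.encode()).hexdigest()
    payload = {"metadata": meta, **obj}
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_gwas(path: str | Path) -> pd.DataFrame:
    """GWAS summary TSV: variant_id, contig, pos, effect_allele, beta, p."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"variant_id", "contig", "pos", "effect_allele", "beta", "p"}
    if not required.issubset(df.columns):
        raise ValueError(f"GWAS table must have columns {sorted(required)}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("GWAS p-values must lie in (0, 1]")
    return df


def read_markers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"contig", "pos", "ref", "alt", "specific_allele"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker table must have columns {sorted(required)}")
    return df


def read_groups(path: str | Path) -> dict[str, str]:
    """Two-column TSV individual -> group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]], df[cols[1]]))
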