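"""Polygenic trait comparison between ancestries: mean 2βf and D.

For a trait with GWAS effect sizes β_i at n independent SNPs, the
average polygenic contribution of a population with effect-allele
frequencies f_i is mean2βf = (Σ 2 β_i f_i) / n.  The D statistic scales
the difference of mean2βf between the two ancestral frequency sets by
the width of a permutation null in which each SNP's frequency is drawn
at random from the pair {f_J,i, f_C,i}:

    D = (mean2βf_J − mean2βf_C) / (P97.5 − P2.5 of the null).

|D| > 1 indicates an ancestry difference larger than the 95% null width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ami.markers import _r2_matrix, _specific_indicator
from ami.panel import HaplotypePanel

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def clump(
    gwas: pd.DataFrame,
    panel: HaplotypePanel,
    p_max: float,
    r2_max: float = 0.5,
    window_kb: float = 250.0,
) -> pd.DataFrame:
    """Greedy LD clumping: ascending p, keep unless in LD with a kept SNP.

    ``gwas`` needs columns variant_id, contig, pos, effect_allele, beta,
    p.  Variants absent from the panel are dropped (logged).  Returns
    the retained records sorted by ascending p.
    """
    idx = panel.site_index()
    cand = gwas[gwas["p"] <= p_max].copy()
    present = [idx.get((c, int(p))) is not None
               for c, p in zip(cand["contig"], cand["pos"])]
    n_drop = len(cand) - sum(present)
    if n_drop:
        logger.info("clump: dropped %d GWAS variants absent from the panel", n_drop)
    cand = cand[np.array(present, dtype=bool)] if len(cand) else cand
    if len(cand) == 0:
        logger.warning("clump produced an empty result")
        return cand
    cand = cand.sort_values(["p", "contig", "pos"], kind="mergesort").reset_index(drop=True)
    h = panel.haplotypes[:, [idx[(c, int(p))] for c, p in zip(cand["contig"], cand["pos"])]]
    kept: list[int] = []
    for i in range(len(cand)):
        ok = True
        for j in kept:
            if cand["contig"][i] != cand["contig"][j]:
                continue
            if abs(int(cand["pos"][i]) - int(cand["pos"][j])) > window_kb * 1000:
                continue
            r2 = _r2_matrix(h[:, [i, j]])[0, 1]
            if np.isfinite(r2) and r2 > r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
    return cand.iloc[kept].reset_index(drop=True)


def mean_2bf(betas: np.ndarray, freqs: np.ndarray) -> float:
    """(Σ 2 β_i f_i) / n over SNPs with a defined frequency.

    SNPs with missing (NaN) frequency are excluded pairwise; n counts
    the retained SNPs.  Raises when none remain.
    """
    betas = np.asarray(betas, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if betas.shape != freqs.shape:
        raise ValueError("betas and freqs must align")
    ok = np.isfinite(freqs)
    if not ok.any():
        raise ValueError("no SNPs with defined frequency")
    return float((2.0 * betas[ok] * freqs[ok]).mean())


@dataclass
class TraitScoreResult:
    """Ancestry trait divergence for one trait."""

    trait: str
    n_snps: int
    mean2bf_j: float
    mean2bf_c: float
    p2_5: float
    p97_5: float
    d: float
    seed: int
    mean2bf_sample: float | None = None


def trait_d(
    f_j: np.ndarray,
    f_c: np.ndarray,
    betas: np.ndarray,
    n_perm: int = 1000,
    seed: int = 1,
    trait: str = "trait",
    f_sample: np.ndarray | None = None,
    null_kind: str = "single",
) -> TraitScoreResult:
    """D statistic with a per-SNP frequency-switch permutation null.

    Each permutation draws every SNP's frequency independently from
    {f_J,i, f_C,i} with probability 1/2 and records one mean2βf
    (``null_kind="single"``, the default reading); with
    ``null_kind="difference"`` each permutation instead records the
    difference between the permuted assignment and its complement.
    SNPs missing either ancestral frequency are excluded up front.
    """
    f_j = np.asarray(f_j, dtype=float)
    f_c = np.asarray(f_c, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if not (len(f_j) == len(f_c) == len(betas)):
        raise ValueError("f_j, f_c and betas must align")
    ok = np.isfinite(f_j) & np.isfinite(f_c)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("trait_d: excluded %d SNPs with a missing ancestral frequency",
                    n_excluded)
    f_j, f_c, betas = f_j[ok], f_c[ok], betas[ok]
    if len(betas) == 0:
        raise ValueError("no SNPs with both ancestral frequencies defined")
    m_j = mean_2bf(betas, f_j)
    m_c = mean_2bf(betas, f_c)
    rng = np.random.default_rng(seed)
    pick = rng.random((n_perm, len(betas))) < 0.5
    f_perm = np.where(pick, f_j, f_c)
    null = (2.0 * betas * f_perm).mean(axis=1)
    if null_kind == "difference":
        comp = (2.0 * betas * np.where(pick, f_c, f_j)).mean(axis=1)
        null = null - comp
    elif null_kind != "single":
        raise ValueError(f"unknown null_kind {null_kind!r}")
    p2_5, p97_5 = np.percentile(null, [2.5, 97.5])
    width = p97_5 - p2_5
    if width == 0:
        d = 0.0 if m_j == m_c else float("nan")
        logger.warning("degenerate permutation null (zero width) for %s", trait)
    else:
        d = (m_j - m_c) / width
    return TraitScoreResult(
        trait=trait,
        n_snps=len(betas),
        mean2bf_j=m_j,
        mean2bf_c=m_c,
        p2_5=float(p2_5),
        p97_5=float(p97_5),
        d=float(d),
        seed=seed,
        mean2bf_sample=(
            mean_2bf(betas, np.asarray(f_sample, dtype=float)[ok])
            if f_sample is not None else None
        ),
    )


def align_gwas_to_freqs(gwas: pd.DataFrame, freqs: pd.DataFrame) -> pd.DataFrame:
    """Harmonize GWAS effect alleles to the frequency table's ALT allele.

    Joins on (contig, pos).  Effect allele == ALT keeps frequencies as
    they are; == REF uses 1 − f.  Strand-ambiguous A/T and C/G SNPs and
    allele mismatches are dropped with a warning.  Output columns:
    variant_id, beta, p, f_sample, f_j, f_c (effect-allele scale).
    """
    merged = gwas.merge(freqs, on=["contig", "pos"], how="inner",
                        suffixes=("", "_frq"))
    rows = []
    n_ambig = n_mismatch = 0
    for _, r in merged.iterrows():
        if (r["ref"], r["alt"]) in AMBIGUOUS_PAIRS:
            n_ambig += 1
            continue
        if r["effect_allele"] == r["alt"]:
            flip = False
        elif r["effect_allele"] == r["ref"]:
            flip = True
        else:
            n_mismatch += 1
            continue
        f = {k: (1.0 - r[k] if flip and np.isfinite(r[k]) else r[k])
             for k in ("f_sample", "f_j", "f_c")}
        rows.append((r["variant_id"], float(r["beta"]), float(r["p"]),
                     f["f_sample"], f["f_j"], f["f_c"]))
    if n_ambig:
        logger.warning("dropped %d strand-ambiguous (A/T, C/G) GWAS SNPs", n_ambig)
    if n_mismatch:
        logger.warning("dropped %d GWAS SNPs whose effect allele matches neither panel allele",
                       n_mismatch)
    return pd.DataFrame(rows, columns=["variant_id", "beta", "p",
                                       "f_sample", "f_j", "f_c"])
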