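"""Specific-variant extraction, the AMI statistic, and marker calling.

The ancestry-marker index of a target-specific variant is

    AMI = (# other specific variants with r² > cutoff within the LD window)
          / (specific-variant density per kb of the chromosome)

where r² is the squared haplotype correlation between the specific
alleles.  Variants derived from the diverged minor admixture source sit
on introgressed haplotype blocks and share LD partners; other specific
variants (lost-in-source or post-admixture de novo) do not, so high AMI
flags source-derived variants.  The calling threshold is set by ROC
analysis against simulation truth using the Youden index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from ami.panel import MISSING, HaplotypePanel

logger = logging.getLogger(__name__)

SPEC_COLUMNS = ["contig", "pos", "ref", "alt", "specific_allele", "specific_count"]


def find_specific_variants(
    target: HaplotypePanel, references: list[HaplotypePanel]
) -> pd.DataFrame:
    """Variants whose specific allele is absent from every reference panel.

    For each biallelic target site, an allele is *specific* when its
    count is zero in every reference and at least one in the target.
    A site missing from a reference's site list counts as "all
    homozygous reference" there provided the reference covers the
    position (within its per-contig site span); otherwise the variant is
    excluded as uncallable.
    """
    if not references:
        raise ValueError("at least one reference panel is required")
    ref_indexes = [r.site_index() for r in references]
    ref_counts = [r.allele_counts() for r in references]
    spans = []
    for r in references:
        span: dict[str, tuple[int, int]] = {}
        for contig in dict.fromkeys(r.contigs):
            pos = r.positions[r.contigs == contig]
            span[contig] = (int(pos.min()), int(pos.max()))
        spans.append(span)

    t_ref, t_alt = target.allele_counts()
    rows = []
    n_uncovered = n_allele_mismatch = 0
    for j in range(target.n_sites):
        contig, pos = target.contigs[j], int(target.positions[j])
        # per-reference counts of target's ref/alt alleles at this site
        ref_c, alt_c = [], []
        uncovered = mismatch = False
        for r, idx, (rc, ac), span in zip(references, ref_indexes, ref_counts, spans):
            k = idx.get((contig, pos))
            if k is None:
                lo_hi = span.get(contig)
                if lo_hi is None or not (lo_hi[0] <= pos <= lo_hi[1]):
                    uncovered = True
                    break
                ref_c.append(r.n_hap)  # implicit monomorphic reference
                alt_c.append(0)
            else:
                if r.ref[k] != target.ref[j] or r.alt[k] != target.alt[j]:
                    mismatch = True
                    break
                ref_c.append(int(rc[k]))
                alt_c.append(int(ac[k]))
        if uncovered:
            n_uncovered += 1
            continue
        if mismatch:
            n_allele_mismatch += 1
            continue
        if t_alt[j] > 0 and all(c == 0 for c in alt_c):
            rows.append((contig, pos, target.ref[j], target.alt[j], "alt", int(t_alt[j])))
        elif t_ref[j] > 0 and all(c == 0 for c in ref_c):
            rows.append((contig, pos, target.ref[j], target.alt[j], "ref", int(t_ref[j])))
    if n_uncovered:
        logger.info("excluded %d target sites outside reference coverage", n_uncovered)
    if n_allele_mismatch:
        logger.info("excluded %d target sites with mismatched alleles", n_allele_mismatch)
    return pd.DataFrame(rows, columns=SPEC_COLUMNS)


def _specific_indicator(spec: pd.DataFrame, panel: HaplotypePanel) -> np.ndarray:
    """Haplotype-by-variant 0/1 matrix of the specific allele (-1 missing)."""
    idx = panel.site_index()
    cols = []
    for contig, pos, which in zip(spec["contig"], spec["pos"], spec["specific_allele"]):
        k = idx.get((contig, int(pos)))
        if k is None:
            raise KeyError(f"specific variant {contig}:{pos} not present in panel")
        col = panel.haplotypes[:, k].astype(np.int8)
        if which == "ref":
            col = np.where(col == MISSING, MISSING, 1 - col).astype(np.int8)
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((panel.n_hap, 0), dtype=np.int8)


def _r2_matrix(h: np.ndarray) -> np.ndarray:
    """All-pairs haplotype r² for a 0/1 matrix (hap x variant).

    Monomorphic variants have undefined r² (returned as NaN).  Missing
    calls trigger a pairwise-complete fallback loop.
    """
    if (h == MISSING).any():
        n = h.shape[1]
        r2 = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1, n):
                ok = (h[:, i] != MISSING) & (h[:, j] != MISSING)
                x, y = h[ok, i].astype(float), h[ok, j].astype(float)
                vx, vy = x.var(), y.var()
                if vx == 0 or vy == 0:
                    continue
                c = ((x * y).mean() - x.mean() * y.mean())
                r2[i, j] = r2[j, i] = c * c / (vx * vy)
        return r2
    x = h.astype(np.float64)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc
    var = np.diag(cov).copy()
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, (cov / denom) ** 2, np.nan)
    np.fill_diagonal(r2, np.nan)
    return r2


def partner_counts_multi(
    spec: pd.DataFrame,
    panel: HaplotypePanel,
    r2_cuts: tuple[float, ...],
    ld_window_bp: int = 1_000_000,
    mode: str = "radius",
) -> dict[float, np.ndarray]:
    """LD partner counts at several r² cutoffs from one r² evaluation.

    ``mode="radius"`` pairs variants with |Δpos| <= window on the same
    contig; ``mode="bin"`` pairs variants inside the same fixed
    non-overlapping window-sized bin.
    """
    if not panel.phased:
        raise ValueError("haplotype r² (count_ld_partners) requires a phased panel")
    if mode not in ("radius", "bin"):
        raise ValueError(f"unknown LD pairing mode {mode!r}")
    n = len(spec)
    out = {c: np.zeros(n, dtype=np.int64) for c in r2_cuts}
    order = np.arange(n)
    for contig in dict.fromkeys(spec["contig"]):
        sel = order[(spec["contig"] == contig).to_numpy()]
        if len(sel) < 2:
            continue
        sub = spec.iloc[sel]
        h = _specific_indicator(sub, panel)
        r2 = _r2_matrix(h)
        n_mono = int(np.isnan(np.diag(r2, k=1)).sum()) if len(sel) > 1 else 0
        pos = sub["pos"].to_numpy()
        if mode == "radius":
            within = np.abs(pos[:, None] - pos[None, :]) <= ld_window_bp
        else:
            b = (pos - 1) // ld_window_bp
            within = b[:, None] == b[None, :]
        np.fill_diagonal(within, False)
        with np.errstate(invalid="ignore"):
            for c in r2_cuts:
                out[c][sel] = ((r2 > c) & within).sum(axis=1)
        if np.isnan(r2[~np.eye(len(sel), dtype=bool)]).any():
            logger.info("contig %s: pairs with undefined r² skipped (monomorphic, %d vars)",
                        contig, n_mono)
    return out


def count_ld_partners(
    spec: pd.DataFrame,
    panel: HaplotypePanel,
    ld_window_bp: int = 1_000_000,
    r2_cut: float = 0.01,
    mode: str = "radius",
) -> pd.DataFrame:
    """Append ``partner_count`` (LD partners with r² > cutoff) to ``spec``."""
    counts = partner_counts_multi(spec, panel, (r2_cut,), ld_window_bp, mode)
    out = spec.copy()
    out["partner_count"] = counts[r2_cut]
    return out


@dataclass
class DensityProfile:
    """Specific-variant density per contig with low-density bin masking."""

    contig_density: pd.DataFrame  # contig, n_variants, length_bp, density_per_kb
    bins: pd.DataFrame  # contig, bin_start, bin_end, n_variants, density_per_kb, masked
    bin_bp: int

    def density_of(self, contig: str) -> float:
        row = self.contig_density.loc[self.contig_density["contig"] == contig]
        if row.empty:
            raise KeyError(f"no density recorded for contig {contig}")
        return float(row["density_per_kb"].iloc[0])


def density_profile(
    spec: pd.DataFrame,
    contig_lengths: dict[str, int],
    bin_bp: int = 1_000_000,
) -> DensityProfile:
    """Per-contig density (variants/kb) and low-density bin mask.

    A bin is masked when its density falls strictly below the contig's
    bin-density mean minus one population (n-denominator) standard
    deviation — the sequencing-error guard applied before AMI calling.
    """
    contig_rows, bin_rows = [], []
    for contig, length in contig_lengths.items():
        pos = spec.loc[spec["contig"] == contig, "pos"].to_numpy()
        density = len(pos) / (length / 1000.0)
        contig_rows.append((contig, len(pos), length, density))
        if len(pos) == 0:
            logger.warning("contig %s has no specific variants; all bins masked", contig)
        edges = np.arange(0, length, bin_bp)
        dens = []
        for start in edges:
            end = min(start + bin_bp, length)
            n_in = int(((pos > start) & (pos <= end)).sum())
            dens.append((start, end, n_in, n_in / ((end - start) / 1000.0)))
        d = np.array([x[3] for x in dens])
        if len(pos) == 0:
            masked = np.ones(len(dens), dtype=bool)
        else:
            cutoff = d.mean() - d.std(ddof=0)
            masked = d < cutoff
        for (start, end, n_in, dd), m in zip(dens, masked):
            bin_rows.append((contig, start, end, n_in, dd, bool(m)))
    return DensityProfile(
        contig_density=pd.DataFrame(
            contig_rows, columns=["contig", "n_variants", "length_bp", "density_per_kb"]
        ),
        bins=pd.DataFrame(
            bin_rows,
            columns=["contig", "bin_start", "bin_end", "n_variants",
                     "density_per_kb", "masked"],
        ),
        bin_bp=bin_bp,
    )


def compute_ami(ld: pd.DataFrame, dens: DensityProfile) -> pd.DataFrame:
    """AMI = partner_count / contig density; masked-bin variants dropped."""
    if "partner_count" not in ld.columns:
        raise ValueError("input must carry partner_count (run count_ld_partners first)")
    dens_map = dict(
        zip(dens.contig_density["contig"], dens.contig_density["density_per_kb"])
    )
    keep_rows = []
    masked_bins = dens.bins[dens.bins["masked"]]
    for _, row in ld.iterrows():
        d = dens_map.get(row["contig"])
        if d is None or d == 0:
            continue
        in_masked = masked_bins[
            (masked_bins["contig"] == row["contig"])
            & (masked_bins["bin_start"] < row["pos"])
            & (row["pos"] <= masked_bins["bin_end"])
        ]
        if len(in_masked):
            continue
        rec = dict(row)
        rec["density_per_kb"] = d
        rec["ami"] = row["partner_count"] / d
        keep_rows.append(rec)
    n_dropped = len(ld) - len(keep_rows)
    if n_dropped:
        logger.info("dropped %d variants in masked or zero-density regions", n_dropped)
    cols = list(ld.columns) + ["density_per_kb", "ami"]
    return pd.DataFrame(keep_rows, columns=cols)


@dataclass
class ROCResult:
    """Full ROC sweep with trapezoidal AUC and the Youden-optimal cutoff."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_j: float
    youden_threshold: float


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC of scores for binary labels (positive = True/1).

    AUC is the trapezoidal area under the full threshold sweep; the
    Youden threshold is the smallest score value attaining max(TPR−FPR).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC analysis needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    area = float(_sk_auc(fpr, tpr))
    j = tpr - fpr
    best = np.where(j == j.max())[0][-1]  # thresholds descend: last tie = smallest
    return ROCResult(
        thresholds=thr,
        tpr=tpr,
        fpr=fpr,
        auc=area,
        youden_j=float(j.max()),
        youden_threshold=float(thr[best]),
    )


def call_markers(ami: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Ancestry markers: specific variants with AMI strictly above threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = ami[ami["ami"] > threshold].copy()
    out["marker_allele"] = np.where(
        out["specific_allele"] == "alt", out["alt"], out["ref"]
    )
    return out.reset_index(drop=True)
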