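"""Haplotype classification and ancestral allele-frequency estimation.

Around each focal SNP, every phased haplotype is labeled source-1
("Jomon-derived") if it carries at least one ancestry-marker allele
within a closed ±flank_bp window of the focal position, else source-2
("continental").  The source-1 allele frequency at the focal SNP is
then estimated as the allele proportion within the source-1-classified
haplotypes, and likewise for source-2.  Markers fed to this module
should be called at a strict AMI threshold (default 100 downstream),
since false-positive markers contaminate the haplotype classes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ami.markers import _specific_indicator
from ami.panel import HaplotypePanel

logger = logging.getLogger(__name__)

FREQ_COLUMNS = ["contig", "pos", "ref", "alt", "f_sample", "f_j", "f_c",
                "n_hap_j", "n_hap_c"]


def _marker_carriage(panel: HaplotypePanel, markers: pd.DataFrame, contig: str):
    """(sorted marker positions, hap x marker 0/1 carriage) for one contig."""
    sub = markers[markers["contig"] == contig].sort_values("pos").reset_index(drop=True)
    if len(sub) == 0:
        return np.empty(0, dtype=np.int64), np.empty((panel.n_hap, 0), dtype=np.int8)
    carriage = _specific_indicator(sub, panel)
    carriage = (carriage == 1).astype(np.int8)  # missing counts as not carried
    return sub["pos"].to_numpy(), carriage


def classify_window_haplotypes(
    panel: HaplotypePanel,
    markers: pd.DataFrame,
    focal_pos: int,
    contig: str,
    flank_bp: int = 10_000,
) -> np.ndarray:
    """Boolean per-haplotype label: True = source-1 derived.

    A haplotype is source-1 iff it carries >= 1 marker allele at a
    marker inside the closed window [focal_pos - flank, focal_pos +
    flank] (the focal site included when it is itself a marker).
    """
    if not panel.phased:
        raise ValueError("haplotype classification requires a phased panel")
    mpos, carriage = _marker_carriage(panel, markers, contig)
    if len(mpos) == 0:
        logger.warning("no markers on contig %s; all haplotypes labeled source-2", contig)
        return np.zeros(panel.n_hap, dtype=bool)
    lo = np.searchsorted(mpos, focal_pos - flank_bp, side="left")
    hi = np.searchsorted(mpos, focal_pos + flank_bp, side="right")
    return carriage[:, lo:hi].any(axis=1)


def ancestral_freqs(
    panel: HaplotypePanel,
    markers: pd.DataFrame,
    maf_min: float = 0.01,
    flank_bp: int = 10_000,
) -> pd.DataFrame:
    """Estimated source-1/source-2 ALT allele frequencies per SNP.

    Covers panel SNPs with minor allele frequency strictly above
    ``maf_min``.  When a haplotype class is empty at a site, its
    frequency is NaN (missing) rather than 0, to avoid biasing the
    polygenic trait statistics downstream.
    """
    if not panel.phased:
        raise ValueError("ancestral_freqs requires a phased panel")
    freq = panel.alt_freq()
    maf = np.minimum(freq, 1 - freq)
    rows = []
    for contig in dict.fromkeys(panel.contigs):
        on_contig = np.where(panel.contigs == contig)[0]
        mpos, carriage = _marker_carriage(panel, markers, contig)
        if len(mpos) == 0:
            logger.warning("no markers on contig %s; all haplotypes labeled source-2",
                           contig)
        # prefix sums over marker columns -> any-carriage within a range
        cum = np.zeros((panel.n_hap, len(mpos) + 1), dtype=np.int32)
        if len(mpos):
            np.cumsum(carriage, axis=1, out=cum[:, 1:])
        for k in on_contig:
            if not (maf[k] > maf_min):
                continue
            pos = int(panel.positions[k])
            lo = np.searchsorted(mpos, pos - flank_bp, side="left")
            hi = np.searchsorted(mpos, pos + flank_bp, side="right")
            is_j = (cum[:, hi] - cum[:, lo]) > 0
            alleles = panel.haplotypes[:, k]
            ok = alleles >= 0
            n_j = int((is_j & ok).sum())
            n_c = int((~is_j & ok).sum())
            f_j = float(alleles[is_j & ok].mean()) if n_j else np.nan
            f_c = float(alleles[~is_j & ok].mean()) if n_c else np.nan
            rows.append((contig, pos, panel.ref[k], panel.alt[k],
                         float(freq[k]), f_j, f_c, n_j, n_c))
    return pd.DataFrame(rows, columns=FREQ_COLUMNS)
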