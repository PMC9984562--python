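"""Per-individual ancestry scoring from marker genotypes (JAS).

JAS = (marker-allele count) / (2 x number of usable marker sites):
the fraction of an individual's alleles at ancestry-marker sites that
are the marker (source-1-derived) allele, a per-individual proxy for
source-1 ancestry.  The denominator counts markers non-missing for that
individual, so low-coverage genomes score on their callable sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ami.panel import MISSING, HaplotypePanel

logger = logging.getLogger(__name__)


def ld_prune(
    markers: pd.DataFrame,
    panel: HaplotypePanel,
    window_sites: int = 1000,
    step_sites: int = 200,
    r2_max: float = 0.8,
) -> pd.DataFrame:
    """Greedy sliding-window LD pruning of a marker set.

    Within each window of ``window_sites`` consecutive kept markers, any
    pair with r² > ``r2_max`` loses its later-position member; the
    window then advances by ``step_sites``.  Deterministic; the result
    is a subset of the input.
    """
    from ami.markers import _r2_matrix, _specific_indicator

    if not panel.phased:
        raise ValueError("ld_prune requires a phased panel")
    out_parts = []
    for contig in dict.fromkeys(markers["contig"]):
        sub = markers[markers["contig"] == contig].sort_values("pos").reset_index(drop=True)
        h = _specific_indicator(sub, panel)
        keep = np.ones(len(sub), dtype=bool)
        start = 0
        while True:
            live = np.where(keep)[0]
            win = live[start : start + window_sites]
            if len(win) > 1:
                r2 = _r2_matrix(h[:, win])
                changed = True
                while changed:
                    changed = False
                    active = [i for i in range(len(win)) if keep[win[i]]]
                    for a in range(len(active)):
                        for b in range(a + 1, len(active)):
                            i, j = active[a], active[b]
                            v = r2[i, j]
                            if np.isfinite(v) and v > r2_max:
                                keep[win[j]] = False  # later position removed
                                changed = True
                                break
                        if changed:
                            break
            if start + window_sites >= len(live):
                break
            start += step_sites
        out_parts.append(sub[keep])
    return pd.concat(out_parts, ignore_index=True) if out_parts else markers.iloc[0:0]


def marker_dosages(panel: HaplotypePanel, markers: pd.DataFrame) -> pd.DataFrame:
    """Diploid marker-allele dosage per individual x marker (NaN missing)."""
    idx = panel.site_index()
    dos = panel.dosages().astype(float)
    dos[dos == MISSING] = np.nan
    cols = {}
    for contig, pos, which in zip(markers["contig"], markers["pos"],
                                  markers["specific_allele"]):
        k = idx.get((contig, int(pos)))
        if k is None:
            raise KeyError(f"marker {contig}:{pos} not present in panel")
        col = dos[:, k]
        if which == "ref":
            col = 2.0 - col
        cols[f"{contig}:{pos}"] = col
    return pd.DataFrame(cols, index=panel.samples)


def jas_score(dosages: pd.DataFrame) -> pd.DataFrame:
    """JAS per individual from a marker-allele dosage table.

    Individuals with zero non-missing markers are excluded with a
    warning (no denominator exists for them).
    """
    rows = []
    for ind, row in dosages.iterrows():
        ok = row.notna()
        n_m = int(ok.sum())
        if n_m == 0:
            logger.warning("individual %s has no non-missing markers; excluded", ind)
            continue
        c = float(row[ok].sum())
        rows.append((ind, n_m, c, c / (2.0 * n_m)))
    return pd.DataFrame(rows, columns=["individual", "n_markers", "count", "jas"])


def group_summary(jas: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Arithmetic mean JAS per group; empty groups omitted with a warning."""
    missing = [i for i in jas["individual"] if i not in groups]
    if missing:
        raise KeyError(f"individuals without group mapping: {missing[:5]}")
    df = jas.copy()
    df["group"] = [groups[i] for i in df["individual"]]
    out = (
        df.groupby("group", sort=True)
        .agg(n=("jas", "size"), mean_jas=("jas", "mean"))
        .reset_index()
    )
    for g in dict.fromkeys(groups.values()):
        if g not in set(out["group"]):
            logger.warning("group %s has no scored individuals; omitted", g)
    return out


@dataclass
class CorrelationResult:
    """Pearson correlation with its two-sided t-test."""

    r: float
    df: int
    p: float


def correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson R between paired group values, two-sided t-test on df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a correlation test")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), df=len(x) - 2, p=float(res.pvalue))
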