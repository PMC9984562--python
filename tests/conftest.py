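"""Shared fixtures and independent brute-force oracles.

The heavy pooled-simulation experiment is session-scoped so the ROC
acceptance checks share one run; everything else is generated fresh and
small.  Oracles here recompute quantities by direct enumeration and are
kept independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ami.admixsim import DemographicModel, simulate_panel, type_specific_variants
from ami.fixtures import tiny_gwas, tiny_markers, tiny_panel, tiny_reference_panel
from ami.validation import run_ami_validation

R2_SWEEP = (0.0, 0.01, 0.2, 0.4, 0.8)


@pytest.fixture(scope="session")
def pooled_validation():
    """300 pooled 1 Mb replicates under the default demography."""
    return run_ami_validation(n_replicates=300, seed=1, r2_cuts=R2_SWEEP)


@pytest.fixture(scope="session")
def default_replicate():
    """One default-demography replicate with truth labels."""
    sim = simulate_panel(DemographicModel(), 11)
    return sim, type_specific_variants(sim)


@pytest.fixture
def tiny_target():
    return tiny_panel()


@pytest.fixture
def tiny_reference():
    return tiny_reference_panel()


@pytest.fixture
def tiny_marker_table():
    return tiny_markers()


@pytest.fixture
def tiny_gwas_table():
    return tiny_gwas()


# ---------------------------------------------------------------- oracles


def brute_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Haplotype r² from the textbook two-locus formula."""
    p_a, p_b = x.mean(), y.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return np.nan
    p_ab = (x * y).mean()
    return (p_ab - p_a * p_b) ** 2 / (p_a * (1 - p_a) * p_b * (1 - p_b))


def brute_partner_counts(h: np.ndarray, pos: np.ndarray, window: int,
                         cut: float) -> np.ndarray:
    """All-pairs LD partner counts by direct looping (radius pairing)."""
    n = h.shape[1]
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j or abs(int(pos[i]) - int(pos[j])) > window:
                continue
            r2 = brute_r2(h[:, i].astype(float), h[:, j].astype(float))
            if np.isfinite(r2) and r2 > cut:
                counts[i] += 1
    return counts


def brute_roc(scores: np.ndarray, labels: np.ndarray):
    """(auc, youden_threshold) by explicit threshold sweep + trapezoid."""
    thresholds = np.unique(scores)[::-1]
    pos, neg = labels.sum(), (~labels).sum()
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        call = scores >= t
        tpr.append((call & labels).sum() / pos)
        fpr.append((call & ~labels).sum() / neg)
    auc = np.trapezoid(tpr, fpr)
    j = np.array(tpr) - np.array(fpr)
    best = np.where(j == j.max())[0][-1]
    thr_axis = np.concatenate([[np.inf], thresholds])
    return float(auc), float(thr_axis[best])


def brute_sstar(dosages, positions, match_bonus=5000.0,
                mismatch_penalty=-10000.0, min_dist=10) -> float:
    """Max chain score over all ordered site subsets (exponential)."""

    def pair(i, j):
        d = positions[j] - positions[i]
        if d < min_dist:
            return -np.inf
        if dosages[i] == dosages[j]:
            return match_bonus + d
        return mismatch_penalty * abs(dosages[i] - dosages[j])

    n = len(positions)
    best = 0.0
    for size in range(2, n + 1):
        for sub in itertools.combinations(range(n), size):
            score = sum(pair(sub[k], sub[k + 1]) for k in range(size - 1))
            best = max(best, score)
    return best
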