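"""Clumping, mean 2βf, and the permutation-scaled D statistic."""

import numpy as np
import pandas as pd
import pytest

from ami import traitscore
from ami.panel import HaplotypePanel


def _panel(h, positions):
    h = np.asarray(h, dtype=np.int8)
    n = h.shape[1]
    return HaplotypePanel(
        haplotypes=h,
        positions=np.asarray(positions, dtype=np.int64),
        contigs=np.array(["c"] * n, dtype=object),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        samples=[f"s{i}" for i in range(h.shape[0] // 2)],
        contig_lengths={"c": 1_000_000},
    )


def _gwas(pos, p, beta=None):
    n = len(pos)
    return pd.DataFrame(
        {"variant_id": [f"rs{i}" for i in range(n)], "contig": ["c"] * n,
         "pos": pos, "effect_allele": ["G"] * n,
         "beta": beta if beta is not None else [0.1] * n, "p": p}
    )


class TestClump:
    def test_single_snp_below_threshold_kept(self):
        h = np.zeros((6, 1), dtype=np.int8)
        h[:2, 0] = 1
        out = traitscore.clump(_gwas([100], [1e-5]), _panel(h, [100]), p_max=0.01)
        assert len(out) == 1

    def test_perfect_ld_pair_keeps_smaller_p(self):
        h = np.zeros((6, 2), dtype=np.int8)
        h[:2, :] = 1
        out = traitscore.clump(_gwas([100, 200], [1e-4, 1e-6]),
                               _panel(h, [100, 200]), p_max=0.01)
        assert out["variant_id"].tolist() == ["rs1"]

    def test_greedy_trace_keeps_first_and_third(self):
        # p = (1e-5, 1e-4, 1e-3); r²(1,2) high, variant 3 independent
        h = np.zeros((8, 3), dtype=np.int8)
        h[:3, 0] = 1
        h[:3, 1] = 1
        h[[3, 4, 5], 2] = 1
        out = traitscore.clump(_gwas([100, 200, 300], [1e-5, 1e-4, 1e-3]),
                               _panel(h, [100, 200, 300]), p_max=0.01, r2_max=0.5)
        assert out["variant_id"].tolist() == ["rs0", "rs2"]

    def test_window_limits_ld_comparison(self):
        h = np.zeros((6, 2), dtype=np.int8)
        h[:2, :] = 1  # perfect LD but 600 kb apart > 250 kb window
        out = traitscore.clump(_gwas([100, 600_100], [1e-5, 1e-4]),
                               _panel(h, [100, 600_100]), p_max=0.01)
        assert len(out) == 2


class TestMean2bf:
    def test_hand_cases(self):
        assert traitscore.mean_2bf([1.0], [0.5]) == pytest.approx(1.0)
        assert traitscore.mean_2bf([0.3, -2.0], [0.0, 0.0]) == 0.0
        assert traitscore.mean_2bf([0.5, -1.0], [0.2, 0.5]) == pytest.approx(-0.4)

    def test_linearity_in_beta_and_freq(self):
        rng = np.random.default_rng(2)
        b, f = rng.normal(size=20), rng.random(20)
        assert traitscore.mean_2bf(3 * b, f) == pytest.approx(
            3 * traitscore.mean_2bf(b, f))
        assert traitscore.mean_2bf(b, 0.5 * f) == pytest.approx(
            0.5 * traitscore.mean_2bf(b, f))

    def test_missing_frequency_excluded_pairwise(self):
        val = traitscore.mean_2bf([0.5, -1.0, 9.9], [0.2, 0.5, np.nan])
        assert val == pytest.approx(-0.4)
        with pytest.raises(ValueError):
            traitscore.mean_2bf([1.0], [np.nan])


class TestTraitD:
    def test_identical_frequencies_give_zero(self):
        f = np.array([0.1, 0.4, 0.8])
        b = np.array([0.5, -0.2, 1.0])
        res = traitscore.trait_d(f, f, b, seed=9)
        assert res.d == 0.0

    def test_label_swap_flips_sign_exactly(self):
        rng = np.random.default_rng(4)
        f_j, f_c, b = rng.random(30), rng.random(30), rng.normal(size=30)
        a = traitscore.trait_d(f_j, f_c, b, seed=17)
        s = traitscore.trait_d(f_c, f_j, b, seed=17)
        assert s.d == pytest.approx(-a.d)
        assert (s.p97_5 - s.p2_5) == pytest.approx(a.p97_5 - a.p2_5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        f_j, f_c, b = rng.random(25), rng.random(25), rng.normal(size=25)
        assert (traitscore.trait_d(f_j, f_c, b, seed=3).d
                == traitscore.trait_d(f_j, f_c, b, seed=3).d)

    def test_null_calibration_on_exchangeable_traits(self):
        """When f_J and f_C are exchangeable, |D| > 1 is rare (~<=10%)."""
        rng = np.random.default_rng(123)
        n_exceed = 0
        n_traits = 200
        for t in range(n_traits):
            f_j = rng.random(40)
            f_c = rng.random(40)
            b = rng.normal(size=40)
            res = traitscore.trait_d(f_j, f_c, b, n_perm=300, seed=1000 + t)
            n_exceed += abs(res.d) > 1
        assert n_exceed / n_traits <= 0.15

    def test_outlier_snp_dominates_at_tight_threshold(self):
        """A single huge-effect, extreme-divergence SNP drives |D| up as
        the p threshold tightens (few SNPs left -> it dominates)."""
        rng = np.random.default_rng(6)
        n = 50
        f_j, f_c = rng.random(n), rng.random(n)
        b = rng.normal(0, 0.05, size=n)
        p = rng.uniform(1e-3, 1e-2, size=n)
        f_j[0], f_c[0], b[0], p[0] = 0.9, 0.05, 2.0, 1e-8
        loose = traitscore.trait_d(f_j[p <= 1e-2], f_c[p <= 1e-2], b[p <= 1e-2], seed=2)
        tight = traitscore.trait_d(f_j[p <= 1e-7], f_c[p <= 1e-7], b[p <= 1e-7], seed=2)
        assert abs(tight.d) > abs(loose.d)

    def test_missing_frequencies_dropped(self):
        f_j = np.array([0.2, np.nan, 0.6])
        f_c = np.array([0.1, 0.5, np.nan])
        res = traitscore.trait_d(f_j, f_c, np.array([1.0, 1.0, 1.0]), seed=5)
        assert res.n_snps == 1


class TestAlignment:
    def test_effect_allele_harmonization(self):
        gwas = pd.DataFrame(
            {"variant_id": ["r1", "r2", "r3"], "contig": ["c"] * 3,
             "pos": [1, 2, 3], "effect_allele": ["G", "A", "T"],
             "beta": [1.0, 1.0, 1.0], "p": [0.001] * 3}
        )
        freqs = pd.DataFrame(
            {"contig": ["c"] * 3, "pos": [1, 2, 3], "ref": ["A", "A", "A"],
             "alt": ["G", "G", "T"], "f_sample": [0.3, 0.3, 0.3],
             "f_j": [0.2, 0.2, 0.2], "f_c": [0.4, 0.4, 0.4]}
        )
        out = traitscore.align_gwas_to_freqs(gwas, freqs).set_index("variant_id")
        assert out.loc["r1", "f_j"] == pytest.approx(0.2)  # effect = ALT
        assert out.loc["r2", "f_j"] == pytest.approx(0.8)  # effect = REF, flipped
        assert "r3" not in out.index  # A/T ambiguous, dropped
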