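"""Specific-variant extraction, r²/partner counting, density, AMI, ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ami import markers
from ami.panel import HaplotypePanel
from conftest import brute_partner_counts, brute_r2, brute_roc


def panel_from_matrix(h, positions=None, contig="c", length=None):
    h = np.asarray(h, dtype=np.int8)
    n_hap, n_sites = h.shape
    positions = np.arange(1, n_sites + 1) * 100 if positions is None else np.asarray(positions)
    return HaplotypePanel(
        haplotypes=h,
        positions=positions,
        contigs=np.array([contig] * n_sites, dtype=object),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        samples=[f"s{i}" for i in range(n_hap // 2)],
        contig_lengths={contig: length or int(positions[-1]) + 100},
    )


class TestFindSpecificVariants:
    def test_alt_specific_when_absent_in_all_references(self, tiny_target, tiny_reference):
        spec = markers.find_specific_variants(tiny_target, [tiny_reference])
        assert spec["pos"].tolist() == [100, 400, 700]
        assert (spec["specific_allele"] == "alt").all()
        assert (spec["specific_count"] == 2).all()

    def test_single_reference_copy_disqualifies(self, tiny_target, tiny_reference):
        ref = tiny_reference
        ref.haplotypes[0, 0] = 1  # one ALT copy at pos 100 in the reference
        spec = markers.find_specific_variants(tiny_target, [ref])
        assert spec["pos"].tolist() == [400, 700]

    def test_ref_allele_can_be_specific(self):
        # REF allele present in target, absent from the reference (ALT fixed there)
        target = panel_from_matrix(np.array([[0, 0], [1, 0], [1, 0], [1, 0]]))
        ref = panel_from_matrix(np.ones((4, 2), dtype=np.int8))
        ref.haplotypes[:, 1] = [0, 1, 0, 1]
        spec = markers.find_specific_variants(target, [ref])
        assert len(spec) == 1
        assert spec["specific_allele"].iloc[0] == "ref"

    def test_uncovered_site_excluded(self, tiny_target, tiny_reference):
        # drop the last reference site: pos 850 is now outside its span
        ref = tiny_reference.take_sites(np.arange(4))
        target = tiny_target
        target.haplotypes[:, 4] = 0
        target.haplotypes[0, 4] = 1  # would be specific if judged callable
        spec = markers.find_specific_variants(target, [ref])
        assert 850 not in set(spec["pos"])


class TestLDPartners:
    def test_perfect_ld_pair_counts_both_ways(self):
        h = np.zeros((10, 2), dtype=np.int8)
        h[[0, 1], 0] = 1
        h[[0, 1], 1] = 1
        spec = pd.DataFrame(
            {"contig": ["c"] * 2, "pos": [100, 200], "ref": ["A"] * 2,
             "alt": ["G"] * 2, "specific_allele": ["alt"] * 2, "specific_count": [2] * 2}
        )
        out = markers.count_ld_partners(spec, panel_from_matrix(h))
        assert out["partner_count"].tolist() == [1, 1]

    def test_zero_r2_half_overlap_not_counted(self):
        # A on {h1,h2}, B on {h1,h3}: p_AB = p_A p_B -> r² = 0
        h = np.zeros((4, 2), dtype=np.int8)
        h[[0, 1], 0] = 1
        h[[0, 2], 1] = 1
        assert brute_r2(h[:, 0].astype(float), h[:, 1].astype(float)) == pytest.approx(0.0)
        spec = pd.DataFrame(
            {"contig": ["c"] * 2, "pos": [100, 200], "ref": ["A"] * 2,
             "alt": ["G"] * 2, "specific_allele": ["alt"] * 2, "specific_count": [2, 2]}
        )
        out = markers.count_ld_partners(spec, panel_from_matrix(h), r2_cut=0.01)
        assert out["partner_count"].tolist() == [0, 0]

    def test_window_excludes_distant_variants(self):
        h = np.zeros((6, 2), dtype=np.int8)
        h[[0, 1], 0] = 1
        h[[0, 1], 1] = 1  # perfect LD but 2 Mb apart
        spec = pd.DataFrame(
            {"contig": ["c"] * 2, "pos": [1, 2_000_001], "ref": ["A"] * 2,
             "alt": ["G"] * 2, "specific_allele": ["alt"] * 2, "specific_count": [2, 2]}
        )
        panel = panel_from_matrix(h, positions=np.array([1, 2_000_001]), length=3_000_000)
        out = markers.count_ld_partners(spec, panel, ld_window_bp=1_000_000)
        assert out["partner_count"].tolist() == [0, 0]

    def test_unphased_panel_refused(self, tiny_target, tiny_marker_table):
        tiny_target.phased = False
        spec = tiny_marker_table.assign(specific_count=2)
        with pytest.raises(ValueError, match="phased"):
            markers.count_ld_partners(spec, tiny_target)

    @settings(max_examples=25, deadline=None)
    @given(
        h=arrays(np.int8, (12, 8), elements=st.integers(0, 1)),
        cut=st.sampled_from([0.01, 0.1, 0.5]),
    )
    def test_matches_brute_force_all_pairs(self, h, cut):
        """Vectorized partner counts equal the direct all-pairs loop."""
        panel = panel_from_matrix(h)
        spec = pd.DataFrame(
            {"contig": ["c"] * 8, "pos": panel.positions, "ref": ["A"] * 8,
             "alt": ["G"] * 8, "specific_allele": ["alt"] * 8,
             "specific_count": (h == 1).sum(0)}
        )
        out = markers.count_ld_partners(spec, panel, r2_cut=cut)
        expected = brute_partner_counts(h, panel.positions, 1_000_000, cut)
        assert out["partner_count"].tolist() == expected.tolist()


class TestDensityAndAMI:
    def test_density_three_variants_on_1kb(self, tiny_target, tiny_reference):
        spec = markers.find_specific_variants(tiny_target, [tiny_reference])
        dens = markers.density_profile(spec, tiny_target.contig_lengths)
        assert dens.density_of("chrT") == pytest.approx(3.0)

    def test_equal_bins_none_masked(self):
        spec = pd.DataFrame(
            {"contig": ["c"] * 4, "pos": [500, 1500, 2500, 3500],
             "ref": ["A"] * 4, "alt": ["G"] * 4,
             "specific_allele": ["alt"] * 4, "specific_count": [1] * 4}
        )
        dens = markers.density_profile(spec, {"c": 4000}, bin_bp=1000)
        assert not dens.bins["masked"].any()

    def test_low_density_bin_masked_population_sd(self):
        # bin densities {10,10,10,0}/kb: mean 7.5, population sd 4.33 -> one bin masked
        pos = [i for start in (0, 1000, 2000) for i in range(start + 1, start + 11)]
        spec = pd.DataFrame(
            {"contig": ["c"] * 30, "pos": pos, "ref": ["A"] * 30, "alt": ["G"] * 30,
             "specific_allele": ["alt"] * 30, "specific_count": [1] * 30}
        )
        dens = markers.density_profile(spec, {"c": 4000}, bin_bp=1000)
        d = dens.bins["density_per_kb"].to_numpy()
        assert d.tolist() == [10.0, 10.0, 10.0, 0.0]
        assert d.std(ddof=0) == pytest.approx(np.sqrt(18.75))
        assert dens.bins["masked"].tolist() == [False, False, False, True]

    def test_ami_two_thirds_hand_case(self, tiny_target, tiny_reference):
        spec = markers.find_specific_variants(tiny_target, [tiny_reference])
        ld = markers.count_ld_partners(spec, tiny_target)
        dens = markers.density_profile(spec, tiny_target.contig_lengths)
        ami = markers.compute_ami(ld, dens)
        assert ami["ami"].tolist() == pytest.approx([2 / 3] * 3)

    def test_ami_scales_inversely_with_density(self, tiny_target, tiny_reference):
        spec = markers.find_specific_variants(tiny_target, [tiny_reference])
        ld = markers.count_ld_partners(spec, tiny_target)
        halved = markers.density_profile(spec, {"chrT": 2000})
        full = markers.density_profile(spec, {"chrT": 1000})
        a_half = markers.compute_ami(ld, halved)["ami"].to_numpy()
        a_full = markers.compute_ami(ld, full)["ami"].to_numpy()
        assert a_half == pytest.approx(2 * a_full)

    def test_masked_bin_variants_dropped(self):
        pos = [i for start in (0, 1000, 2000) for i in range(start + 1, start + 11)]
        pos.append(3500)
        spec = pd.DataFrame(
            {"contig": ["c"] * 31, "pos": pos, "ref": ["A"] * 31, "alt": ["G"] * 31,
             "specific_allele": ["alt"] * 31, "specific_count": [1] * 31}
        )
        ld = spec.assign(partner_count=1)
        dens = markers.density_profile(spec, {"c": 4000}, bin_bp=1000)
        ami = markers.compute_ami(ld, dens)
        assert 3500 not in set(ami["pos"])  # bin 4 density 1/kb < mean - sd


class TestROC:
    def test_perfect_separation(self):
        res = markers.roc_analysis(np.array([5.0, 6, 7, 1, 2, 3]),
                                   np.array([1, 1, 1, 0, 0, 0]))
        assert res.auc == pytest.approx(1.0)
        assert res.youden_j == pytest.approx(1.0)
        assert 3 < res.youden_threshold <= 5

    def test_uninformative_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.5
        res = markers.roc_analysis(scores, labels)
        assert abs(res.auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            markers.roc_analysis(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_matches_hand_rolled_sweep_oracle(self):
        rng = np.random.default_rng(7)
        labels = rng.random(300) < 0.4
        scores = np.round(rng.normal(size=300) + labels, 1)  # ties on purpose
        res = markers.roc_analysis(scores, labels)
        auc_o, thr_o = brute_roc(scores, labels)
        assert res.auc == pytest.approx(auc_o)
        assert res.youden_threshold == pytest.approx(thr_o)

    def test_type1_has_higher_ami_and_calls_nest(self, default_replicate):
        sim, typed = default_replicate
        adm = sim.panel.take_samples(np.arange(sim.model.n_hap_per_group // 2))
        ld = markers.count_ld_partners(typed, adm)
        dens = markers.density_profile(typed, {"1": sim.model.seq_len_bp})
        ami = markers.compute_ami(ld, dens)
        t1 = ami[ami["truth_type"] == 1]["ami"]
        rest = ami[ami["truth_type"] != 1]["ami"]
        assert t1.mean() > rest.mean()
        loose = markers.call_markers(ami, 28.0374)
        strict = markers.call_markers(ami, 100.0)
        nothing = markers.call_markers(ami, np.inf)
        loose_keys = set(zip(loose["contig"], loose["pos"]))
        strict_keys = set(zip(strict["contig"], strict["pos"]))
        assert strict_keys <= loose_keys
        assert len(nothing) == 0
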