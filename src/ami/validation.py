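"""Pooled simulation experiments validating the AMI statistic.

Runs replicate coalescent simulations, extracts truth-labeled
target-specific variants, computes AMI per replicate (per-replicate
contig density, as each 1 Mb replicate stands for a chromosome), pools
variants and evaluates ROC discrimination of type-1 (source-1-derived)
variants, optionally across several r² cutoffs from a single r²
evaluation per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ami import markers
from ami.admixsim import DemographicModel, replicate_seeds, simulate_panel, type_specific_variants
from ami.markers import ROCResult


@dataclass
class AmiValidationResult:
    """Pooled AMI scores and truth labels across simulation replicates."""

    model: DemographicModel
    seed: int
    n_replicates: int
    r2_cuts: tuple[float, ...]
    labels: np.ndarray  # True = type 1
    truth_types: np.ndarray
    ami_by_cut: dict[float, np.ndarray] = field(repr=False)

    @property
    def n_variants(self) -> int:
        return len(self.labels)

    def roc(self, r2_cut: float | None = None) -> ROCResult:
        cut = self.r2_cuts[0] if r2_cut is None else r2_cut
        return markers.roc_analysis(self.ami_by_cut[cut], self.labels)

    def auc_by_cut(self) -> dict[float, float]:
        return {c: self.roc(c).auc for c in self.r2_cuts}


@dataclass
class FreqRecoveryResult:
    """Pooled ancestral-frequency recovery measurements."""

    corr_all: float
    corr_divergent: float
    rmse_fj_divergent: float
    rmse_pooled_divergent: float
    n_sites: int
    n_divergent: int
    marker_threshold: float


def freq_recovery_experiment(
    model: DemographicModel | None = None,
    n_replicates: int = 10,
    seed: int = 1,
    marker_threshold: float = 100.0,
    flank_bp: int = 10_000,
    maf_min: float = 0.01,
    divergence_min: float = 0.2,
) -> FreqRecoveryResult:
    """Estimate f_J from marker-classified haplotypes; compare to truth.

    Truth is the derived-allele frequency in the ancient source-1 sample
    at the admixture start.  Pools sites with a defined f_J across
    replicates; the RMSE contrast is restricted to sites where the two
    ancient source samples differ by more than ``divergence_min``.
    """
    from ami import haplofreq

    model = model or DemographicModel()
    seeds = replicate_seeds(seed, n_replicates)
    fj, fs, tru, div = [], [], [], []
    for rep_seed in seeds:
        sim = simulate_panel(model, int(rep_seed))
        typed = type_specific_variants(sim)
        adm = sim.panel.take_samples(np.arange(model.n_hap_per_group // 2))
        ld = markers.count_ld_partners(typed, adm)
        dens = markers.density_profile(typed, {sim.contig: model.seq_len_bp})
        ami = markers.compute_ami(ld, dens)
        called = markers.call_markers(ami, marker_threshold)
        if len(called) == 0:
            continue
        est = haplofreq.ancestral_freqs(adm, called, maf_min=maf_min,
                                        flank_bp=flank_bp)
        true_s1 = sim.panel.alt_freq(sim.groups["source1_ancient"])
        true_s2 = sim.panel.alt_freq(sim.groups["source2_ancient"])
        idx = sim.panel.site_index()
        cols = np.array([idx[(c, int(p))] for c, p in
                         zip(est["contig"], est["pos"])])
        ok = est["f_j"].notna().to_numpy()
        fj.append(est["f_j"].to_numpy()[ok])
        fs.append(est["f_sample"].to_numpy()[ok])
        tru.append(true_s1[cols[ok]])
        div.append(np.abs(true_s1 - true_s2)[cols[ok]])
    fj, fs = np.concatenate(fj), np.concatenate(fs)
    tru, div = np.concatenate(tru), np.concatenate(div)
    d = div > divergence_min
    return FreqRecoveryResult(
        corr_all=float(np.corrcoef(fj, tru)[0, 1]),
        corr_divergent=float(np.corrcoef(fj[d], tru[d])[0, 1]),
        rmse_fj_divergent=float(np.sqrt(((fj[d] - tru[d]) ** 2).mean())),
        rmse_pooled_divergent=float(np.sqrt(((fs[d] - tru[d]) ** 2).mean())),
        n_sites=int(len(fj)),
        n_divergent=int(d.sum()),
        marker_threshold=marker_threshold,
    )


@dataclass
class JasOrderingResult:
    """JAS ranking checks on multi-chromosome simulated genomes."""

    n_genomes: int
    n_chromosomes: int
    pure_above_admixed_mean: int
    lowest_in_bottom_decile: int


def jas_ordering_experiment(
    model: DemographicModel | None = None,
    n_genomes: int = 15,
    n_chromosomes: int = 10,
    seed: int = 1,
    marker_threshold: float = 28.0374,
) -> JasOrderingResult:
    """JAS ordering on simulated genomes built from replicate chromosomes.

    Each genome concatenates independent replicates (samples are
    exchangeable across replicates, so replicate r's individual i is
    individual i's r-th chromosome).  Markers are called per chromosome;
    JAS pools all markers.  Checks per genome: (i) the ancient pure
    source-1 individuals' mean JAS exceeds the admixed mean; (ii) the
    admixed individual with the lowest true source-1 tract fraction
    ranks in the bottom JAS decile of the admixed sample.
    """
    import pandas as pd

    from ami import jas as jas_mod

    model = model or DemographicModel()
    seeds = replicate_seeds(seed, n_genomes * n_chromosomes)
    pure_above = bottom = 0
    for g in range(n_genomes):
        dos_parts, fracs = [], []
        panel = None
        for c in range(n_chromosomes):
            sim = simulate_panel(model, int(seeds[g * n_chromosomes + c]))
            panel = sim.panel
            typed = type_specific_variants(sim)
            adm = sim.panel.take_samples(np.arange(model.n_hap_per_group // 2))
            ld = markers.count_ld_partners(typed, adm)
            dens = markers.density_profile(typed, {sim.contig: model.seq_len_bp})
            ami = markers.compute_ami(ld, dens)
            called = markers.call_markers(ami, marker_threshold)
            if len(called) == 0:
                continue
            d = jas_mod.marker_dosages(sim.panel, called)
            d.columns = [f"chr{c}:{col}" for col in d.columns]
            dos_parts.append(d)
            fr = sim.source1_tract_fractions()
            fracs.append((fr[0::2] + fr[1::2]) / 2)
        scores = jas_mod.jas_score(pd.concat(dos_parts, axis=1))
        scores = scores.set_index("individual")["jas"]
        pop_of = panel.populations
        adm_scores = scores[[pop_of[i] == "admixed" for i in scores.index]]
        pure = scores[[pop_of[i] == "source1_ancient" for i in scores.index]]
        pure_above += int(pure.mean() > adm_scores.mean())
        lowest = panel.samples[int(np.mean(fracs, axis=0).argmin())]
        bottom += int(adm_scores.rank(pct=True).loc[lowest] <= 0.10)
    return JasOrderingResult(
        n_genomes=n_genomes,
        n_chromosomes=n_chromosomes,
        pure_above_admixed_mean=pure_above,
        lowest_in_bottom_decile=bottom,
    )


def run_ami_validation(
    model: DemographicModel | None = None,
    n_replicates: int = 300,
    seed: int = 1,
    r2_cuts: tuple[float, ...] = (0.01,),
    ld_window_bp: int = 1_000_000,
    mode: str = "radius",
) -> AmiValidationResult:
    """Simulate replicates and pool AMI scores with truth labels.

    Replicates with fewer than two specific variants or a single truth
    class still contribute their variants to the pool; classification
    quality is judged on the pooled set.
    """
    model = model or DemographicModel()
    seeds = replicate_seeds(seed, n_replicates)
    amis: dict[float, list[np.ndarray]] = {c: [] for c in r2_cuts}
    types: list[np.ndarray] = []
    for rep_seed in seeds:
        sim = simulate_panel(model, int(rep_seed))
        typed = type_specific_variants(sim)
        if len(typed) == 0:
            continue
        admixed = sim.panel.take_samples(np.arange(model.n_hap_per_group // 2))
        counts = markers.partner_counts_multi(
            typed, admixed, r2_cuts, ld_window_bp=ld_window_bp, mode=mode
        )
        density = len(typed) / (model.seq_len_bp / 1000.0)
        for c in r2_cuts:
            amis[c].append(counts[c] / density)
        types.append(typed["truth_type"].to_numpy())
    truth = np.concatenate(types)
    return AmiValidationResult(
        model=model,
        seed=seed,
        n_replicates=n_replicates,
        r2_cuts=tuple(r2_cuts),
        labels=truth == 1,
        truth_types=truth,
        ami_by_cut={c: np.concatenate(v) for c, v in amis.items()},
    )
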