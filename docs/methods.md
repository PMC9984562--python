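# Methods

## Demographic model and simulator

The validation engine (`ami.admixsim`) simulates a two-source admixture
with msprime. Backward in time: the admixed target population merges
into source-1 at `adm_start_gen`; between `adm_end_gen` and
`adm_start_gen` it receives one-way migration from source-2; source-1
and source-2 merge `split_gen` generations ago. Defaults (the study
conditions used throughout the tests and the acceptance script):

| parameter | default | meaning |
|---|---|---|
| `split_gen` | 1,200 | source-1/source-2 split, generations before present |
| `adm_start_gen`, `adm_end_gen` | 120, 80 | admixture window bounds |
| `target_source1_ancestry` (α) | 0.12 | final expected source-1 ancestry |
| `ne` | 5,000 | diploid effective size, every population |
| `mu`, `rho` | 1.2e-8, 1.3e-8 | mutation / recombination per bp per generation |
| `seq_len_bp` | 1,000,000 | replicate contig length |
| `n_hap_per_group` | 200 | haplotypes per sampling group |

Four groups are sampled: modern admixed, modern source-2, and both
sources at `adm_start_gen`.

**Migration calibration.** The model exposes the per-generation
replacement probability `m` solving `(1 − m)^G = α` over the G
generations of the admixture window (`m ≈ 0.0516` at the defaults).
Coalescent-time continuous migration is an exponential-rate process,
so the demography uses the backward rate `r = −ln(α) / G_eff`, which
makes the *expected realized* source-1 ancestry exactly α; `G_eff` is
the window between `adm_end_gen` and the ancestry census (below).
Calibration is verified empirically in the test suite at α ∈ {0.05,
0.12, 0.5} (unbiased within 3 standard errors over 40 replicates).

**Ancestry truth.** A census event is placed 0.01 generations below
`adm_start_gen` (migration stops at the census). Every admixed lineage
then passes through exactly one census node, and that node's population
identifies the ancestry of the underlying genomic interval: still in
the admixed population ⇒ source-1; migrated ⇒ source-2. Tracts are read
off with `tskit`'s ancestor-linking and must partition each haplotype's
contig exactly — a hard error otherwise. This recorded-ancestry truth
is exact, unlike coalescent-time heuristics.

**Variant typing.** A variant is target-specific when its derived
allele is present in the modern admixed sample and absent from the
modern source-2 sample (200 haplotypes). Its truth type comes from the
population in which the mutation arose, traced from the mutation
node's birth population plus recorded migration events at the site's
position, with time gates that make the labels independent of how
split-time lineage movements are recorded: origin at or before the
split ⇒ type 1; source-1 branch ⇒ type 1; source-2 branch ⇒ type 2;
admixed population ⇒ type 3. Sites carrying more than one mutation are
dropped (biallelic, single-origin sites only), and a missing origin is
a hard error — truth labeling must be complete.

## AMI

For each specific variant, LD partners are counted among the other
specific variants within 1 Mb (radius pairing by default; fixed 1 Mb
bins available) with haplotype r² > 0.01, where r² is the squared
Pearson correlation of the specific-allele indicators across phased
haplotypes — monomorphic pairs have undefined r² and never count.
AMI divides the partner count by the chromosome's specific-variant
density per kb (per-replicate density in simulation, where each 1 Mb
replicate stands for a chromosome). As a sequencing-error guard for
real data, 1 Mb bins whose specific-variant density falls strictly
below the chromosome's bin mean minus one population (n-denominator)
standard deviation are excluded before calling.

ROC analysis of pooled AMI scores (positive class: type 1) uses the
full threshold sweep without interpolation; AUC is trapezoidal and the
calling threshold is the smallest score maximizing TPR − FPR (Youden).
At 300 pooled replicates of the default history the AUC is ≈ 0.92 and
the Youden cutoff ≈ 26 (both recomputed by `scripts/acceptance.py`;
the cutoff is realization-dependent within the tens). The r² cutoff is
not critical: discrimination vanishes at cutoff 0 (every pair counts),
is flat over [0.01, 0.2], and decays beyond 0.2 — the test suite
reproduces this sweep.

## JAS

`JAS = (marker-allele count) / (2 × markers non-missing for that
individual)`. The per-individual denominator generalizes cleanly to
low-coverage genomes (the usable-marker set differs per individual);
an individual with no usable markers is excluded rather than scored.
Marker sets can first be LD-pruned with a greedy sliding window
(windows in site counts; within a window, the later-position member of
any pair with r² above the limit is removed — deterministic by
construction). Group means are arithmetic; correlation tests are
two-sided t-tests on df = n − 2, no multiple-testing correction.

On simulated multi-chromosome genomes, ancient pure source-1
individuals score JAS ≈ 0.05 against an admixed mean of ≈ 0.014 —
markers tag only the subset of source-1 variation that survived into
and is detectable in the admixed panel, so even a pure source-1 genome
scores far below 1; the score is a relative, not absolute, ancestry
proxy.

## Ancestral allele frequencies

Around each focal SNP with MAF > 1%, a phased haplotype is labeled
source-1 iff it carries ≥ 1 marker allele inside the closed window
±10 kb (the focal site included if it is itself a marker); f_J and f_C
are the allele proportions within the two classes, and an empty class
yields a missing value, never 0. Markers fed to this module should be
called strictly (default threshold 100): false-positive markers sit on
source-2 tracts and contaminate the source-1 class.

Known limitation, quantified on simulation: classification *precision*
at a strict threshold is high (≈ 98% of marker-allele copies lie on
true source-1 tracts), but *recall* is gated by marker spacing — with
~28 strict markers per Mb most focal windows contain no marker, and
where one exists the classified haplotypes are the descendants of the
particular founder lineage carrying it. The pooled correlation between
f_J and the true ancient source-1 frequency is therefore ≈ 0.6 at the
defaults (rising to ≈ 0.8 only if the window is widened an order of
magnitude), whereas an oracle classification from true tracts reaches
≈ 0.92 with RMSE three times smaller than the pooled sample frequency
on divergent sites. Estimates at individual SNPs should be treated as
noisy; aggregate uses (polygenic scores over many SNPs, f3 over many
sites) are the intended consumers, and the `n_hap_j` column lets users
filter on classification support.

## Trait divergence

GWAS records are LD-clumped greedily by ascending p (r² > 0.5 within
250 kb discards the later SNP; the tool the original analysis named
does the same, parameters exposed), effect alleles are harmonized to
the frequency table's ALT allele (strand-ambiguous A/T and C/G SNPs
dropped), and `mean2βf = (Σ 2 β_i f_i)/n` is computed per ancestry.
The null for D draws each SNP's frequency independently from
{f_J,i, f_C,i} with probability ½ and records one mean2βf per
permutation (1,000 permutations by default; a permuted-difference
variant is available behind `null_kind="difference"`). `D` divides the
ancestry difference by the null's 95% width; it is antisymmetric under
label swap and zero when the ancestral frequencies coincide. Under
exchangeable frequencies |D| > 1 occurs in ≲ 10% of traits — the
calibration the test suite checks.

## Outgroup f3 and S\*

f3(O; A, B) is the plain mean of (f_O − f_A)(f_O − f_B) over sites with
all three frequencies defined; no block jackknife or small-sample bias
correction is applied (point estimates only — an extension point).
Frequencies for single diploid genomes are dosages/2.

S\* chains an individual's reference-absent variants: pairs closer
than 10 bp are excluded, equal-dosage pairs score 5000 + distance,
unequal pairs −10000 per dosage unit; the chain score maximizes over
predecessors with negative prefixes floored at zero (the classic
formulation; constants configurable and recorded). The dynamic program
is verified against exhaustive subset enumeration in the tests. The
scenario contrast runs 10 replicates each of an archaic-style history
(split 40,000 generations ago, 4% admixture) and the default recent
history, groups each (individual, 50 kb window) unit by its true
source-1 haplotype count, and reports the AUC separating carriers from
non-carriers plus the Spearman correlation of per-window S\*max with
the true source-derived variant count. Under the ancient split the
groups separate completely (AUC ≈ 1.0); under the recent split the
bulk of carrier units score exactly 0 like the non-carriers (median 0
vs 0), though a minority of carriers retain signal (AUC ≈ 0.70) — the
motivating observation that a divergence of ~1,200 generations leaves
too few source-derived variants per segment for S\*.

## Numerical and I/O conventions

All user-facing tables use 1-based inclusive positions (VCF
convention); ancestry-tract BED output is 0-based half-open. Haplotype
r², window classification and pruning refuse unphased panels by name;
dosage-only operations accept them. Missing data: haplotype calls may
be missing (VCF `.`), r² falls back to pairwise-complete computation,
and JAS denominators shrink. Ties in the Youden sweep resolve to the
smallest threshold. Every stochastic operation takes an explicit seed;
replicate seeds derive from one base seed via `numpy` seed sequences,
and identical (model, seed) pairs are byte-reproducible end to end.

Problem sizes used by the shipped experiments: the ROC experiment
pools 300 replicates of 1 Mb (the original analysis used 3,000 — the
pooled variant count here, ~160k, already gives sub-0.01 Monte-Carlo
error on the AUC); the S\* contrast uses 10 replicates per scenario;
frequency recovery 10 replicates; JAS ordering 15 genomes of 10
chromosomes.
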