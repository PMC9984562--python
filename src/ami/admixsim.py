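"""Coalescent simulation of a two-source admixture with ancestry truth.

The demography mirrors the history used to validate the AMI statistic:
a minor "source-1" population (the diverged indigenous source, e.g. the
Jomon) splits from "source-2" (the continental source) ``split_gen``
generations ago; the admixed target population is founded from source-1
at ``adm_start_gen`` and receives continuous one-way migration from
source-2 until ``adm_end_gen``, calibrated so that the final expected
source-1 ancestry fraction equals ``target_source1_ancestry`` (α).

Four groups are sampled, matching the validation design: the modern
admixed population, the modern source-2 population, and both sources at
``adm_start_gen``.  Per-haplotype ancestry truth is read from a census
event placed just below ``adm_start_gen``: an admixed lineage whose
census ancestor still sits in the admixed population is source-1
ancestry; one whose ancestor migrated is source-2 ancestry.

Target-specific variants (derived allele present in the modern admixed
sample, absent from the modern source-2 sample) are classified by the
population in which the mutation arose:

* type 1 — on the source-1 branch after the split, or anywhere before
  the split (ancestral variants surviving only through source-1);
* type 2 — on the source-2 branch after the split (entered the target
  via admixture, since lost in source-2);
* type 3 — de novo in the admixed population.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd
import tskit

from ami.panel import HaplotypePanel

#: group labels, in sampling order
GROUPS = ("admixed", "source2_modern", "source1_ancient", "source2_ancient")

#: gap (generations) between the admixture start and the ancestry census
CENSUS_OFFSET = 0.01

_POP_NAMES = ("ADMIX", "SOURCE1", "SOURCE2", "ANC")
_ORIGIN_OF_POP = {"ADMIX": "admixed", "SOURCE1": "source1", "SOURCE2": "source2",
                  "ANC": "ancestral"}


@dataclass(frozen=True)
class DemographicModel:
    """Parameters of the two-source admixture history.

    Defaults are the validation conditions: split 1,200 generations ago,
    admixture between 120 and 80 generations ago, final source-1
    ancestry α = 12%, Ne = 5,000 diploids per population, μ = 1.2e-8 and
    ρ = 1.3e-8 per bp per generation, 1 Mb contigs, 200 sampled
    haplotypes per group.
    """

    split_gen: float = 1200.0
    adm_start_gen: float = 120.0
    adm_end_gen: float = 80.0
    target_source1_ancestry: float = 0.12
    ne: float = 5000.0
    mu: float = 1.2e-8
    rho: float = 1.3e-8
    seq_len_bp: int = 1_000_000
    n_hap_per_group: int = 200

    def __post_init__(self) -> None:
        a = self.target_source1_ancestry
        if not (0.0 < a <= 1.0):
            raise ValueError(f"source-1 ancestry fraction must be in (0, 1]; got {a}")
        if not (self.adm_end_gen < self.adm_start_gen < self.split_gen):
            raise ValueError(
                "need adm_end_gen < adm_start_gen < split_gen; got "
                f"{self.adm_end_gen}, {self.adm_start_gen}, {self.split_gen}"
            )
        if self.adm_end_gen < 0:
            raise ValueError("adm_end_gen must be >= 0")
        for name in ("ne", "mu", "rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_hap_per_group < 2 or self.n_hap_per_group % 2:
            raise ValueError("n_hap_per_group must be a positive even number")

    @property
    def admixture_generations(self) -> float:
        """G, the length of the migration window in generations."""
        return self.adm_start_gen - self.adm_end_gen

    @property
    def m(self) -> float:
        """Per-generation replacement probability by source-2 migrants.

        Solves (1 - m)^G = α: after G generations of forward-time
        replacement at rate m, the remaining source-1 ancestry is α.
        α = 1 gives m = 0 (no migration; the target stays pure source-1).
        """
        a = self.target_source1_ancestry
        return 1.0 - a ** (1.0 / self.admixture_generations)


def build_demography(**params) -> DemographicModel:
    """Validate raw settings and return a :class:`DemographicModel`."""
    return DemographicModel(**params)


def _msprime_inputs(model: DemographicModel):
    """Demography + sample sets for msprime.

    Continuous migration in the coalescent is an exponential-rate
    process, so the backward rate r over the effective window (census to
    adm_end) is chosen with exp(-r * G_eff) = α, making the expected
    realized source-1 ancestry exactly α.
    """
    census_t = model.adm_start_gen - CENSUS_OFFSET
    g_eff = census_t - model.adm_end_gen
    alpha = model.target_source1_ancestry
    rate = 0.0 if alpha >= 1.0 else -math.log(alpha) / g_eff

    dem = msprime.Demography()
    for name in _POP_NAMES:
        dem.add_population(name=name, initial_size=model.ne)
    if rate > 0:
        dem.add_migration_rate_change(
            time=model.adm_end_gen, rate=rate, source="ADMIX", dest="SOURCE2"
        )
        dem.add_migration_rate_change(
            time=census_t, rate=0.0, source="ADMIX", dest="SOURCE2"
        )
    dem.add_census(time=census_t)
    dem.add_population_split(time=model.adm_start_gen, derived=["ADMIX"], ancestral="SOURCE1")
    dem.add_population_split(time=model.split_gen, derived=["SOURCE1", "SOURCE2"],
                             ancestral="ANC")
    dem.sort_events()

    n_ind = model.n_hap_per_group // 2
    samples = [
        msprime.SampleSet(n_ind, population="ADMIX", time=0),
        msprime.SampleSet(n_ind, population="SOURCE2", time=0),
        msprime.SampleSet(n_ind, population="SOURCE1", time=model.adm_start_gen),
        msprime.SampleSet(n_ind, population="SOURCE2", time=model.adm_start_gen),
    ]
    return dem, samples, census_t


@dataclass
class SimPanel:
    """One simulated replicate with full ancestry truth.

    Attributes
    ----------
    panel
        all four groups' haplotypes as a :class:`HaplotypePanel`
        (biallelic single-mutation sites only).
    groups
        group label -> haplotype row indices into ``panel.haplotypes``.
    tracts
        per modern-admixed haplotype, list of ``(start, end, source)``
        0-based half-open bp intervals partitioning the contig; source
        is ``"source1"`` or ``"source2"``.
    mutations
        per retained site: position, origin population and origin time.
    """

    panel: HaplotypePanel
    groups: dict[str, np.ndarray]
    tracts: list[list[tuple[int, int, str]]]
    mutations: pd.DataFrame
    model: DemographicModel
    seed: int
    contig: str = "1"

    def source1_tract_fractions(self) -> np.ndarray:
        """Realized source-1 ancestry fraction per admixed haplotype."""
        out = np.empty(len(self.tracts))
        for i, tr in enumerate(self.tracts):
            out[i] = sum(e - s for s, e, src in tr if src == "source1")
        return out / self.model.seq_len_bp


def _ancestry_tracts(ts: tskit.TreeSequence, admixed_nodes: np.ndarray,
                     census_t: float, seq_len: int) -> list[list[tuple[int, int, str]]]:
    nodes = ts.tables.nodes
    flag = getattr(msprime, "NODE_IS_CEN_EVENT", None)
    if flag is not None:
        census = np.where(nodes.flags & flag)[0].astype(np.int32)
    else:
        census = np.where(np.isclose(nodes.time, census_t))[0].astype(np.int32)
    tables = ts.dump_tables()
    edges = tables.link_ancestors(samples=admixed_nodes.astype(np.int32), ancestors=census)
    pops = nodes.population
    per_hap: dict[int, list[tuple[int, int, str]]] = {int(n): [] for n in admixed_nodes}
    for left, right, parent, child in zip(edges.left, edges.right, edges.parent, edges.child):
        source = "source1" if pops[parent] == 0 else "source2"
        per_hap[int(child)].append((int(left), int(right), source))
    out = []
    for n in admixed_nodes:
        ivs = sorted(per_hap[int(n)])
        merged: list[tuple[int, int, str]] = []
        for s, e, src in ivs:
            if merged and merged[-1][2] == src and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e, src)
            else:
                merged.append((s, e, src))
        covered = sum(e - s for s, e, _ in merged)
        if covered != seq_len:
            raise RuntimeError(
                f"ancestry tracts cover {covered} of {seq_len} bp for haplotype {n}"
            )
        out.append(merged)
    return out


def _mutation_origins(ts: tskit.TreeSequence, site_ids: np.ndarray,
                      model: DemographicModel) -> pd.DataFrame:
    """Origin population and time for each retained (single-mutation) site.

    The lineage carrying a mutation is identified by the mutation's node;
    its population at the mutation time is the node's birth population
    updated by any recorded migrations below that time at the site's
    position.  A time gate (t >= split_gen -> ancestral side) keeps the
    labels correct regardless of how split-time lineage movements are
    recorded.
    """
    migs = ts.tables.migrations
    mig_by_node: dict[int, list[tuple[float, float, float, int]]] = {}
    for node, left, right, time, dest in zip(
        migs.node, migs.left, migs.right, migs.time, migs.dest
    ):
        mig_by_node.setdefault(int(node), []).append((time, left, right, int(dest)))
    pops = ts.tables.nodes.population
    sites = ts.tables.sites
    positions = sites.position

    rows = []
    for sid in site_ids:
        site = ts.site(int(sid))
        if len(site.mutations) != 1:
            raise RuntimeError(f"site {sid} has {len(site.mutations)} mutations; expected 1")
        mut = site.mutations[0]
        t = mut.time
        if t is None or (isinstance(t, float) and math.isnan(t)):
            raise RuntimeError(f"mutation at site {sid} has no recorded time")
        pop = int(pops[mut.node])
        best_t = -math.inf
        for mt, ml, mr, md in mig_by_node.get(int(mut.node), ()):
            if mt <= t and ml <= positions[int(sid)] < mr and mt > best_t:
                best_t, pop = mt, md
        origin = _ORIGIN_OF_POP[_POP_NAMES[pop]]
        if t >= model.split_gen:
            origin = "ancestral"
        elif t >= model.adm_start_gen and origin == "admixed":
            # lineage moved into source-1 at the admixture-start split
            origin = "source1"
        rows.append((int(sid), float(t), origin))
    return pd.DataFrame(rows, columns=["site_id", "origin_time", "origin_pop"])


def simulate_panel(model: DemographicModel, seed: int) -> SimPanel:
    """Simulate one replicate; identical (model, seed) gives identical output."""
    if seed < 1:
        raise ValueError("msprime seeds must be >= 1")
    dem, samples, census_t = _msprime_inputs(model)
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=model.seq_len_bp,
        recombination_rate=model.rho,
        record_migrations=True,
        ploidy=2,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(ts, rate=model.mu, random_seed=seed)

    # keep biallelic single-mutation sites
    keep = np.array(
        [i for i, site in enumerate(ts.sites()) if len(site.mutations) == 1],
        dtype=np.int64,
    )
    geno = ts.genotype_matrix()[keep].T.astype(np.int8)  # hap x site
    positions = ts.tables.sites.position[keep].astype(np.int64) + 1  # 1-based
    anc = [ts.site(int(i)).ancestral_state for i in keep]
    der = [ts.site(int(i)).mutations[0].derived_state for i in keep]

    n = model.n_hap_per_group
    groups = {g: np.arange(i * n, (i + 1) * n) for i, g in enumerate(GROUPS)}
    prefix = {"admixed": "adx", "source2_modern": "s2m",
              "source1_ancient": "s1a", "source2_ancient": "s2a"}
    sample_names = [
        f"{prefix[g]}{j}" for g in GROUPS for j in range(n // 2)
    ]
    panel = HaplotypePanel(
        haplotypes=geno,
        positions=positions,
        contigs=np.array(["1"] * len(keep), dtype=object),
        ref=np.array(anc, dtype=object),
        alt=np.array(der, dtype=object),
        samples=sample_names,
        phased=True,
        populations={s: g for g in GROUPS for s in
                     [f"{prefix[g]}{j}" for j in range(n // 2)]},
        contig_lengths={"1": model.seq_len_bp},
    )

    tracts = _ancestry_tracts(ts, groups["admixed"], census_t, model.seq_len_bp)
    muts = _mutation_origins(ts, keep, model)
    muts.insert(1, "pos", positions)
    return SimPanel(panel=panel, groups=groups, tracts=tracts,
                    mutations=muts, model=model, seed=seed)


def type_specific_variants(sim: SimPanel) -> pd.DataFrame:
    """Extract target-specific variants and label them type 1/2/3.

    A variant is specific when its derived allele is present in the
    modern admixed sample and absent from the modern source-2 sample.
    Raises if any specific variant lacks an origin record.
    """
    h = sim.panel.haplotypes
    dac_adm = (h[sim.groups["admixed"]] == 1).sum(axis=0)
    dac_s2 = (h[sim.groups["source2_modern"]] == 1).sum(axis=0)
    spec = np.where((dac_adm > 0) & (dac_s2 == 0))[0]

    if len(sim.mutations) != sim.panel.n_sites:
        raise RuntimeError("mutation origin records incomplete for this panel")
    model = sim.model
    rows = []
    for col in spec:
        # mutations frame rows are aligned with retained site columns
        rec = sim.mutations.iloc[col]
        t, origin = float(rec.origin_time), rec.origin_pop
        if origin == "ancestral" or t >= model.split_gen:
            typ = 1
        elif origin == "source1":
            typ = 1
        elif origin == "source2":
            typ = 2
        elif origin == "admixed":
            typ = 3
        else:
            raise RuntimeError(f"unknown mutation origin {origin!r}")
        rows.append((
            sim.contig, int(sim.panel.positions[col]), sim.panel.ref[col],
            sim.panel.alt[col], "alt", int(dac_adm[col]), col, typ, t, origin,
        ))
    df = pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt", "specific_allele", "specific_count",
                 "site_col", "truth_type", "origin_time", "origin_pop"],
    )
    return df


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """Independent msprime-safe seeds derived from one base seed."""
    rng = np.random.default_rng(np.random.SeedSequence(base_seed))
    return rng.integers(1, 2**31 - 1, size=n)
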