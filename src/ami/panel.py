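"""Phased haplotype panel container.

The panel is the in-memory exchange format between every module: a binary
haplotype-by-site matrix with 1-based positions, per-site contig ids and
REF/ALT alleles, and two haplotypes per named diploid sample (haplotypes
``2*i`` and ``2*i + 1`` belong to individual ``i``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: sentinel for a missing allele call
MISSING = -1


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for a set of diploid samples.

    Parameters
    ----------
    haplotypes
        int8 array of shape ``(n_hap, n_sites)`` with entries 0 (REF),
        1 (ALT) or :data:`MISSING`.
    positions
        1-based bp positions, int64, strictly increasing within a contig.
    contigs
        per-site contig id (sites of one contig must be contiguous).
    ref, alt
        per-site allele strings.
    samples
        individual ids; ``len(samples) * 2 == n_hap``.
    phased
        False when any heterozygote was read unphased; haplotype-level
        operations (r², window classification) refuse unphased panels.
    populations
        optional individual -> population label map.
    contig_lengths
        contig -> length in bp (from a VCF header or simulation config).
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    contigs: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    phased: bool = True
    populations: dict[str, str] | None = None
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n_hap, n_sites = self.haplotypes.shape
        if n_hap != 2 * len(self.samples):
            raise ValueError(
                f"{n_hap} haplotypes for {len(self.samples)} samples; expected 2 per sample"
            )
        for arr, name in [(self.positions, "positions"), (self.contigs, "contigs"),
                          (self.ref, "ref"), (self.alt, "alt")]:
            if len(arr) != n_sites:
                raise ValueError(f"{name} has {len(arr)} entries for {n_sites} sites")
        for contig in dict.fromkeys(self.contigs):
            pos = self.positions[self.contigs == contig]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on contig {contig}")

    # -- basic shape ---------------------------------------------------

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    # -- derived views -------------------------------------------------

    def dosages(self) -> np.ndarray:
        """Diploid ALT dosage per individual, ``(n_samples, n_sites)`` int16.

        Missing if either haplotype call is missing (entry -1).
        """
        h = self.haplotypes.astype(np.int16)
        d = h[0::2] + h[1::2]
        d[(self.haplotypes[0::2] == MISSING) | (self.haplotypes[1::2] == MISSING)] = MISSING
        return d

    def allele_counts(self, hap_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(ref_count, alt_count) per site over the given haplotypes."""
        h = self.haplotypes if hap_idx is None else self.haplotypes[hap_idx]
        alt = (h == 1).sum(axis=0)
        ref = (h == 0).sum(axis=0)
        return ref, alt

    def alt_freq(self, hap_idx: np.ndarray | None = None) -> np.ndarray:
        ref, alt = self.allele_counts(hap_idx)
        tot = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def site_index(self) -> dict[tuple[str, int], int]:
        """(contig, pos) -> column index lookup."""
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.contigs, self.positions))
        }

    # -- subsetting ----------------------------------------------------

    def take_sites(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            haplotypes=self.haplotypes[:, idx],
            positions=self.positions[idx],
            contigs=self.contigs[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            samples=list(self.samples),
            phased=self.phased,
            populations=self.populations,
            contig_lengths=dict(self.contig_lengths),
        )

    def take_samples(self, sample_idx: np.ndarray) -> "HaplotypePanel":
        sample_idx = np.asarray(sample_idx)
        hap_idx = np.empty(2 * len(sample_idx), dtype=np.int64)
        hap_idx[0::2] = 2 * sample_idx
        hap_idx[1::2] = 2 * sample_idx + 1
        return HaplotypePanel(
            haplotypes=self.haplotypes[hap_idx],
            positions=self.positions,
            contigs=self.contigs,
            ref=self.ref,
            alt=self.alt,
            samples=[self.samples[i] for i in sample_idx],
            phased=self.phased,
            populations=self.populations,
            contig_lengths=dict(self.contig_lengths),
        )
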