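"""Core domain types shared by every stage of the pipeline.

Coordinate convention: every position held in memory is 1-based inclusive
(VCF/GFF style).  BED-dialect files (the bedcov depth tables) are converted
at the I/O boundary exactly once, in :mod:`cscm_sieve.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

# Genotype codes used throughout the genotype matrix.
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GENOTYPE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with their lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    sex_chroms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(length < 1 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be >= 1")
        for sc in self.sex_chroms:
            if sc not in self.chrom_names:
                raise ValueError(f"sex chromosome {sc!r} not in build")

    def index_of(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[self.index_of(chrom)]

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.chrom_names if c not in self.sex_chroms)

    def n_windows(self, chrom: str, window_size: int) -> int:
        """Number of tiling windows; the last window may be short."""
        return -(-self.length_of(chrom) // window_size)


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV or small indel, 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    info: Mapping[str, str] = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        for allele in (self.ref, self.alt):
            if not _BASES.issuperset(allele):
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snv

    @property
    def g_label(self) -> str:
        """HGVS-like genomic label, e.g. ``Chr10:g.61284558G>T``."""
        chrom = self.chrom[3:] if self.chrom.lower().startswith("chr") else self.chrom
        return f"Chr{chrom}:g.{self.pos}{self.ref}>{self.alt}"


class CohortGenotypes:
    """Genotype matrix over biallelic sites for a multi-sample cohort.

    ``gt`` is an int8 array of shape (n_variants, n_samples) holding the
    four-state codes HOM_REF / HET / HOM_ALT / MISSING.  ``roles`` maps each
    sample id to one of ``case``, ``sire``, ``dam``, ``control``.
    """

    def __init__(
        self,
        build: GenomeBuild,
        variants: list[VariantRecord],
        samples: list[str],
        gt: np.ndarray,
        roles: Mapping[str, str] | None = None,
    ) -> None:
        gt = np.asarray(gt, dtype=np.int8)
        if gt.shape != (len(variants), len(samples)):
            raise ValueError(
                f"gt shape {gt.shape} inconsistent with "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        valid = {HOM_REF, HET, HOM_ALT, MISSING}
        if gt.size and not set(np.unique(gt)).issubset(valid):
            raise ValueError("genotype matrix contains codes outside {-1, 0, 1, 2}")
        for v in variants:
            if v.pos > build.length_of(v.chrom):
                raise ValueError(f"{v.chrom}:{v.pos} beyond chromosome end")
        self.build = build
        self.variants = list(variants)
        self.samples = list(samples)
        self.gt = gt
        self.roles = dict(roles) if roles is not None else {s: "control" for s in samples}
        self._sample_index = {s: i for i, s in enumerate(samples)}
        self._variant_index = {v.key: i for i, v in enumerate(self.variants)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def sample_indices(self, samples) -> np.ndarray:
        return np.array([self.sample_index(s) for s in samples], dtype=np.intp)

    def variant_index(self, variant: VariantRecord) -> int:
        try:
            return self._variant_index[variant.key]
        except KeyError:
            raise KeyError(f"variant {variant.key} not in cohort") from None

    def genotypes_of(self, sample: str) -> np.ndarray:
        return self.gt[:, self.sample_index(sample)]

    def is_sorted(self) -> bool:
        order = [(self.build.index_of(v.chrom), v.pos) for v in self.variants]
        return all(a <= b for a, b in zip(order, order[1:]))

    def sorted_copy(self) -> "CohortGenotypes":
        idx = sorted(
            range(self.n_variants),
            key=lambda i: (self.build.index_of(self.variants[i].chrom), self.variants[i].pos),
        )
        return CohortGenotypes(
            self.build,
            [self.variants[i] for i in idx],
            self.samples,
            self.gt[idx, :],
            self.roles,
        )

    def equal_genotypes(self, other: "CohortGenotypes") -> bool:
        return (
            [v.key for v in self.variants] == [v.key for v in other.variants]
            and self.samples == other.samples
            and np.array_equal(self.gt, other.gt)
        )
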