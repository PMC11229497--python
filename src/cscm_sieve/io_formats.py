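"""Readers and writers for the standard formats the pipeline touches.

All coordinate-convention fixes happen here, once: VCF and gene models are
1-based inclusive and stay that way internally; bedcov-style depth tables are
0-based half-open on disk and converted to 1-based inclusive on read (and
back on write).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .core import HET, HOM_ALT, HOM_REF, MISSING, CohortGenotypes, GenomeBuild, VariantRecord
from .coverage import DepthProfile

log = logging.getLogger(__name__)

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_CYVCF2_TO_CODE = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)


def read_vcf(
    path: str | Path,
    build: GenomeBuild,
    roles: dict[str, str] | None = None,
    multiallelic: str = "reject",
) -> CohortGenotypes:
    """Read a VCF 4.x file with GT fields into a :class:`CohortGenotypes`.

    Parameters
    ----------
    multiallelic:
        ``"reject"`` (default) raises on any record with more than one ALT
        allele; ``"split"`` decomposes such records into biallelic ones,
        counting each alternate allele separately.
    """
    if multiallelic not in ("reject", "split"):
        raise ValueError("multiallelic must be 'reject' or 'split'")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if rec.CHROM not in build.chrom_names:
            raise ValueError(
                f"{path}: line for {rec.CHROM}:{rec.POS}: chromosome not in genome build"
            )
        if rec.POS < 1 or rec.POS > build.length_of(rec.CHROM):
            raise ValueError(f"{path}: {rec.CHROM}:{rec.POS} outside chromosome bounds")
        info = {k: str(v) for k, v in rec.INFO}
        if len(rec.ALT) == 0:
            continue
        if len(rec.ALT) > 1:
            if multiallelic == "reject":
                raise ValueError(
                    f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}; "
                    "re-run with multiallelic='split' to decompose"
                )
            genos = rec.genotypes  # list of [a1, a2, phased]
            for ai, alt in enumerate(rec.ALT, start=1):
                codes = np.empty(len(samples), dtype=np.int8)
                for si, g in enumerate(genos):
                    alleles = [a for a in g[:-1]]
                    if any(a < 0 for a in alleles):
                        codes[si] = MISSING
                    else:
                        codes[si] = sum(1 for a in alleles if a == ai)
                variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, alt, info))
                rows.append(codes)
            continue
        variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], info))
        rows.append(_CYVCF2_TO_CODE[rec.gt_types])
    vcf.close()
    gt = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return CohortGenotypes(build, variants, samples, gt, roles)


_CODE_TO_GT = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def write_vcf(cohort: CohortGenotypes, path: str | Path) -> Path:
    """Write a cohort as an uncompressed VCF 4.2 file, sorted by build order.

    Unsorted cohorts are sorted on write (logged); the output carries one
    biallelic record per variant with GT for every sample.
    """
    if not cohort.is_sorted():
        log.info("write_vcf: input not sorted by (chrom, pos); sorting on write")
        cohort = cohort.sorted_copy()
    header = pysam.VariantHeader()
    for name, length in zip(cohort.build.chrom_names, cohort.build.chrom_lengths):
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    info_keys = sorted({k for v in cohort.variants for k in v.info})
    for k in info_keys:
        header.info.add(k, 1, "String", "pass-through annotation")
    for s in cohort.samples:
        header.add_sample(s)
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, v in enumerate(cohort.variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), filter="PASS"
            )
            for k, val in v.info.items():
                rec.info[k] = str(val)
            for j, s in enumerate(cohort.samples):
                rec.samples[s]["GT"] = _CODE_TO_GT[int(cohort.gt[i, j])]
                rec.samples[s].phased = False
            out.write(rec)
    return path


def read_depth_table(path: str | Path, window_size: int, sample: str = "") -> DepthProfile:
    """Read a bedcov-style TSV (chrom, start, end, count) into a DepthProfile.

    The on-disk table is BED-convention 0-based half-open; the returned
    profile is 1-based inclusive.  Windows must tile each chromosome left to
    right without gaps or overlaps; the last window of a chromosome may be
    shorter than ``window_size``.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "count"],
        comment="#",
        dtype={"chrom": str},
    )
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (ends <= starts).any():
            raise ValueError(f"{path}: empty or inverted window on {chrom}")
        if starts[0] != 0:
            raise ValueError(f"{path}: first window on {chrom} does not start at 0")
        if not np.array_equal(starts[1:], ends[:-1]):
            raise ValueError(f"{path}: overlapping or gapped windows on {chrom}")
        widths = ends - starts
        if (widths[:-1] != window_size).any() or widths[-1] > window_size:
            raise ValueError(f"{path}: windows on {chrom} do not match size {window_size}")
    out = df.copy()
    out["start"] = out["start"] + 1  # BED -> 1-based inclusive
    return DepthProfile(sample=sample, window_size=window_size, windows=out)


def write_depth_table(profile: DepthProfile, path: str | Path) -> Path:
    """Write a DepthProfile back to the bedcov TSV dialect (0-based half-open)."""
    df = profile.windows[["chrom", "start", "end", "count"]].copy()
    df["start"] = df["start"] - 1
    df.to_csv(path, sep="\t", header=False, index=False)
    return Path(path)


def read_case_table(path: str | Path) -> pd.DataFrame:
    """Read a case/phenotype TSV with columns case_id, breed, sex, bw_kg, ga_days."""
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str})
    required = {"case_id", "breed", "sex", "bw_kg", "ga_days"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("bw_kg", "ga_days"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() <= 0).any():
            raise ValueError(f"{path}: non-positive values in {col}")
        df[col] = vals
    return df


def read_ped(path: str | Path) -> pd.DataFrame:
    """Read a PED-style file: family, id, sire, dam, sex [, phenotype, genotype_label].

    '0' parents are mapped to NA (unknown founder parent).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 5:
        raise ValueError(f"{path}: PED needs at least 5 columns")
    names = ["family", "id", "sire", "dam", "sex", "phenotype", "genotype_label"]
    df.columns = names[: df.shape[1]]
    for col in ("sire", "dam"):
        df[col] = df[col].replace("0", pd.NA)
    return df


def write_ped(df: pd.DataFrame, path: str | Path) -> Path:
    out = df.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].fillna("0")
    out.to_csv(path, sep="\t", header=False, index=False)
    return Path(path)
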