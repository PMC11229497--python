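"""The three inheritance-scenario filtering cascades.

Each filter runs a staged funnel over the cohort genotype matrix and reports
the per-stage variant counts (the structure of a rare-disease filtering
table) plus the surviving candidate variants:

* shared recessive — homozygous alternate in ALL cases, protein-changing,
  alternate allele fully absent from the controls;
* per-case recessive — homozygous alternate in one case (each sequenced
  parent heterozygous), *private* against a first-pass control set (no
  alternate allele at all), protein-changing, and with no homozygous-
  alternate carrier in the wider global set (heterozygous carriers are
  permitted and counted);
* de novo dominant — heterozygous in one case, protein-changing, alternate
  allele absent from the parents (when sequenced) and from every control
  and global sample.

A variant must also be "callable" — non-missing genotypes in at least 90 %
of samples — replacing a manual read-alignment review step for artefact
sites.  Missing genotypes are treated conservatively: a missing case
genotype never satisfies "homozygous in the case", and a missing control
genotype never certifies absence (configurable via ``missing_excludes``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consequence import ConsequenceCall, GeneModel, annotate
from .core import HET, HOM_ALT, MISSING, CohortGenotypes, VariantRecord

CALLABLE_FRACTION = 0.9


@dataclass(frozen=True)
class CaseFamily:
    """One affected animal with its sequenced parents (if any)."""

    case: str
    sire: str | None = None
    dam: str | None = None

    @property
    def design(self) -> str:
        if self.sire is not None and self.dam is not None:
            return "trio"
        if self.sire is not None or self.dam is not None:
            return "duo"
        return "solo"

    @property
    def sequenced_parents(self) -> tuple[str, ...]:
        return tuple(p for p in (self.sire, self.dam) if p is not None)


@dataclass(frozen=True)
class CandidateVariant:
    variant: VariantRecord
    consequence: ConsequenceCall
    case: str
    scenario: str
    n_hom_alt_global: int
    n_het_global: int
    n_missing_global: int


@dataclass
class FilterFunnel:
    """Ordered (stage name, surviving count) pairs plus the final candidates."""

    scenario: str
    case: str
    stages: list[tuple[str, int]] = field(default_factory=list)
    candidates: list[CandidateVariant] = field(default_factory=list)

    def add_stage(self, name: str, count: int) -> None:
        if self.stages and count > self.stages[-1][1]:
            raise ValueError("funnel counts must be non-increasing")
        self.stages.append((name, count))

    @property
    def final_count(self) -> int:
        return self.stages[-1][1] if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_variants"]).assign(
            scenario=self.scenario, case=self.case
        )


def cohort_allele_query(
    variant: VariantRecord, cohort: CohortGenotypes, sample_ids: list[str]
) -> tuple[int, int, int]:
    """Exact genotype counts for one variant over the listed samples.

    Returns (n_hom_alt, n_het, n_missing); missing genotypes are excluded
    from the carrier counts and reported separately.
    """
    vi = cohort.variant_index(variant)
    g = cohort.gt[vi, cohort.sample_indices(sample_ids)] if sample_ids else np.array([], dtype=np.int8)
    return (
        int(np.sum(g == HOM_ALT)),
        int(np.sum(g == HET)),
        int(np.sum(g == MISSING)),
    )


def _callable_mask(cohort: CohortGenotypes) -> np.ndarray:
    if cohort.n_samples == 0:
        return np.ones(cohort.n_variants, dtype=bool)
    frac = (cohort.gt != MISSING).mean(axis=1)
    return frac >= CALLABLE_FRACTION


def _absent_mask(gt: np.ndarray, missing_excludes: bool) -> np.ndarray:
    """Sites where the alternate allele is certifiably absent in every column."""
    if gt.shape[1] == 0:
        return np.ones(gt.shape[0], dtype=bool)
    no_carrier = ~np.any((gt == HET) | (gt == HOM_ALT), axis=1)
    if missing_excludes:
        no_carrier &= ~np.any(gt == MISSING, axis=1)
    return no_carrier


def _finalize(
    funnel: FilterFunnel,
    cohort: CohortGenotypes,
    keep: np.ndarray,
    gene_models: list[GeneModel],
    global_ids: list[str],
    scenario: str,
    case_label: str,
    post_stage: str,
    post_mask_fn,
) -> FilterFunnel:
    """Annotate survivors, apply the protein-changing and final stages."""
    idx = np.flatnonzero(keep)
    calls = {int(i): annotate(gene_models, cohort.variants[i]) for i in idx}
    protein = [i for i in idx if calls[int(i)].is_protein_changing]
    funnel.add_stage("protein_changing", len(protein))
    callable_ok = _callable_mask(cohort)
    final = [i for i in protein if callable_ok[i] and post_mask_fn(i)]
    funnel.add_stage(post_stage, len(final))
    for i in final:
        v = cohort.variants[i]
        n_hom, n_het, n_miss = cohort_allele_query(v, cohort, global_ids)
        funnel.candidates.append(
            CandidateVariant(v, calls[int(i)], case_label, scenario, n_hom, n_het, n_miss)
        )
    return funnel


def filter_shared_recessive(
    cohort: CohortGenotypes,
    case_ids: list[str],
    control_ids: list[str],
    gene_models: list[GeneModel],
    missing_excludes: bool = True,
) -> FilterFunnel:
    """Scenario (i): one recessive allele common to every case."""
    if len(case_ids) < 2:
        raise ValueError("shared-recessive filtering needs at least 2 cases")
    funnel = FilterFunnel("shared_recessive", ",".join(case_ids))
    funnel.add_stage("all", cohort.n_variants)
    case_gt = cohort.gt[:, cohort.sample_indices(case_ids)]
    hom_all = np.all(case_gt == HOM_ALT, axis=1)
    funnel.add_stage("hom_alt_in_all_cases", int(hom_all.sum()))
    ctrl_gt = cohort.gt[:, cohort.sample_indices(control_ids)]
    absent = _absent_mask(ctrl_gt, missing_excludes)
    return _finalize(
        funnel,
        cohort,
        hom_all,
        gene_models,
        control_ids,
        "shared_recessive",
        ",".join(case_ids),
        "absent_in_controls",
        lambda i: bool(absent[i]),
    )


def filter_case_recessive(
    cohort: CohortGenotypes,
    family: CaseFamily,
    control_ids: list[str],
    global_ids: list[str],
    gene_models: list[GeneModel],
    missing_excludes: bool = True,
) -> FilterFunnel:
    """Scenario (ii): a recessive allele in one case considered individually.

    ``control_ids`` is the first-pass comparison set defining "private"
    (no alternate allele at all); ``global_ids`` is the wider lookup cohort
    in which heterozygous carriers are tolerated and counted but a
    homozygous-alternate animal is disqualifying.
    """
    funnel = FilterFunnel("case_recessive", family.case)
    funnel.add_stage("all", cohort.n_variants)
    case_gt = cohort.genotypes_of(family.case)
    keep = case_gt == HOM_ALT
    for parent in family.sequenced_parents:
        keep &= cohort.genotypes_of(parent) == HET
    ctrl_gt = cohort.gt[:, cohort.sample_indices(control_ids)]
    keep &= _absent_mask(ctrl_gt, missing_excludes)
    funnel.add_stage("private_hom_alt_in_case", int(keep.sum()))
    glob_gt = cohort.gt[:, cohort.sample_indices(global_ids)]
    no_hom = ~np.any(glob_gt == HOM_ALT, axis=1)
    if missing_excludes:
        no_hom &= ~np.any(glob_gt == MISSING, axis=1)
    return _finalize(
        funnel,
        cohort,
        keep,
        gene_models,
        global_ids,
        "case_recessive",
        family.case,
        "no_hom_alt_in_global",
        lambda i: bool(no_hom[i]),
    )


def filter_denovo_dominant(
    cohort: CohortGenotypes,
    family: CaseFamily,
    control_ids: list[str],
    global_ids: list[str],
    gene_models: list[GeneModel],
    missing_excludes: bool = True,
) -> FilterFunnel:
    """Scenario (iii): a dominant mutation arising de novo in one case.

    The alternate allele must be heterozygous in the case and certifiably
    absent from both parents (when sequenced), every first-pass control and
    every global sample.
    """
    funnel = FilterFunnel("denovo_dominant", family.case)
    funnel.add_stage("all", cohort.n_variants)
    keep = cohort.genotypes_of(family.case) == HET
    others = list(family.sequenced_parents) + list(control_ids)
    keep &= _absent_mask(cohort.gt[:, cohort.sample_indices(others)], missing_excludes)
    funnel.add_stage("private_het_in_case", int(keep.sum()))
    extra_global = [s for s in global_ids if s not in set(others)]
    absent_global = _absent_mask(
        cohort.gt[:, cohort.sample_indices(extra_global)], missing_excludes
    )
    return _finalize(
        funnel,
        cohort,
        keep,
        gene_models,
        global_ids,
        "denovo_dominant",
        family.case,
        "absent_in_global",
        lambda i: bool(absent_global[i]),
    )


def candidates_frame(funnels: list[FilterFunnel]) -> pd.DataFrame:
    """Candidate variants of several funnels as one report table."""
    rows = []
    for f in funnels:
        for c in f.candidates:
            cq = c.consequence
            rows.append(
                {
                    "case": c.case,
                    "scenario": c.scenario,
                    "gene": cq.transcript.rsplit("-t", 1)[0] if cq.transcript else "",
                    "chrom": c.variant.chrom,
                    "pos": c.variant.pos,
                    "ref": c.variant.ref,
                    "alt": c.variant.alt,
                    "consequence": cq.consequence,
                    "g_label": c.variant.g_label,
                    "c_label": cq.c_label or "",
                    "p_label": cq.p_label or "",
                    "hom_alt_global": c.n_hom_alt_global,
                    "het_global": c.n_het_global,
                    "missing_global": c.n_missing_global,
                    "predicted_effect": c.variant.info.get("predicted_effect", ""),
                    "pli": c.variant.info.get("pli", ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "case", "scenario", "gene", "chrom", "pos", "ref", "alt", "consequence",
            "g_label", "c_label", "p_label", "hom_alt_global", "het_global",
            "missing_global", "predicted_effect", "pli",
        ],
    )
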