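"""Synthetic cohort generator with planted events and a truth set.

Emulates the data a rare-disease WGS case series produces, at desk scale: a
control cohort with Hardy-Weinberg genotypes, trio/duo/solo case families
with Mendelian transmission, planted variant scenarios (homozygous recessive
missense, private heterozygous frameshift duplication, de novo), windowed
read-depth profiles carrying heterozygous Mb-scale deletions and a
whole-chromosome trisomy, and pedigrees with inbreeding loops and carrier
founders.  Every planted event is recorded in a :class:`TruthSet` against
which downstream recovery is scored.

The default configuration is the package's study condition: 3 chromosomes x
10 Mb, 20,000 background variants with MAF ~ U(0.1, 0.5), 50 controls (the
first 35 forming the first-pass "private variant" comparison set), one trio,
one duo and one solo family, and negative-binomial depth at 20x with
overdispersion 0.01.  Linkage structure and read-level artefacts are not
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consequence import GeneModel, map_cds_to_genomic
from .core import HET, HOM_ALT, HOM_REF, MISSING, CohortGenotypes, GenomeBuild, VariantRecord
from .coverage import DepthProfile
from .pedigree import Pedigree

DEFAULT_BUILD = GenomeBuild(("chr1", "chr2", "chr3"), (10_000_000, 10_000_000, 10_000_000))

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOP = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOP]


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = [_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons)]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    return codons


def default_gene_models() -> list[GeneModel]:
    """The fixed synthetic gene set (part of the reference, not of a simulation).

    Three candidate-gene analogs plus a decoy, all on chr1:

    * ``SHC4L``   (+): 162 bp CDS over two exons; codon 20 is GGG so that the
      canonical planted c.58G>T yields p.Gly20Trp.
    * ``WDR45BL`` (-): 702 bp CDS; codon 203 is GCT so that c.607G>A yields
      p.Ala203Thr (exercises minus-strand mapping).
    * ``DYNC1H1L`` (+): 10,860 bp CDS (3,620 codons) over three exons; codon
      3591 ends in C and codon 3592 is TCA (Ser) so that the canonical
      c.10773dupC yields p.Ser3592fs.
    * ``NOC3LL``  (+): 303 bp single-exon decoy with no planted variant.
    """
    rng = np.random.default_rng(240_817)  # fixed: the gene set is reference data

    def seq(n_codons: int, fixed: dict[int, str]) -> str:
        codons = _random_cds(rng, n_codons)
        for idx, codon in fixed.items():
            codons[idx - 1] = codon
        return "".join(codons)

    return [
        GeneModel(
            "SHC4L", "SHC4L-t1", "chr1", "+",
            ((100_001, 100_060), (100_161, 100_262)),
            seq(54, {20: "GGG"}),
        ),
        GeneModel(
            "WDR45BL", "WDR45BL-t1", "chr1", "-",
            ((200_001, 200_350), (200_451, 200_802)),
            seq(234, {203: "GCT"}),
        ),
        GeneModel(
            "DYNC1H1L", "DYNC1H1L-t1", "chr1", "+",
            ((300_001, 303_600), (304_001, 307_600), (308_001, 311_660)),
            seq(3_620, {3591: "ATC", 3592: "TCA"}),
        ),
        GeneModel("NOC3LL", "NOC3LL-t1", "chr1", "+", ((500_001, 500_303),), seq(101, {})),
    ]


def canonical_variant(model: GeneModel, scenario: str) -> VariantRecord:
    """The gene's planted-variant template for a scenario.

    Recessive scenarios plant the gene's canonical missense substitution
    (CDS 58 G>T for SHC4L, CDS 607 G>A for WDR45BL); the de novo scenario
    plants the canonical single-base duplication (c.10773dupC for DYNC1H1L).
    """
    if scenario in ("recessive_trio", "recessive_duo", "recessive_solo", "recessive"):
        cds_pos, alt_tx = {"SHC4L": (58, "T"), "WDR45BL": (607, "A")}.get(
            model.gene_id, (58, None)
        )
        if alt_tx is None:
            raise ValueError(f"no canonical recessive variant for {model.gene_id}")
        pos = map_cds_to_genomic(model, cds_pos)
        ref_tx = model.cds_seq[cds_pos - 1]
        if model.strand == "+":
            ref, alt = ref_tx, alt_tx
        else:
            ref = ref_tx.translate(_COMPLEMENT)
            alt = alt_tx.translate(_COMPLEMENT)
        return VariantRecord(model.chrom, pos, ref, alt)
    if scenario == "denovo":
        if model.gene_id != "DYNC1H1L":
            raise ValueError(f"no canonical de novo variant for {model.gene_id}")
        cds_pos = 10_773
        pos = map_cds_to_genomic(model, cds_pos)
        ref = model.cds_seq[cds_pos - 1]  # plus strand gene: genomic == transcript
        return VariantRecord(model.chrom, pos, ref, ref + ref)
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass(frozen=True)
class FamilyDesign:
    """One affected calf and which parents were sequenced."""

    index: int
    design: str  # trio | duo | solo

    def __post_init__(self) -> None:
        if self.design not in ("trio", "duo", "solo"):
            raise ValueError(f"bad family design {self.design!r}")

    @property
    def case(self) -> str:
        return f"case_{self.index}"

    @property
    def sire(self) -> str | None:
        return f"sire_{self.index}" if self.design == "trio" else None

    @property
    def dam(self) -> str | None:
        return f"dam_{self.index}" if self.design in ("trio", "duo") else None


@dataclass(frozen=True)
class PlantedEvent:
    """One planted event, also the truth-set record for recovery scoring."""

    kind: str  # recessive_snv | denovo_indel | segmental_deletion |
    #            whole_chrom_trisomy | shared_roh | carrier_allele
    case: str
    chrom: str = ""
    start: int = 0
    end: int = 0
    gene: str = ""
    variant: VariantRecord | None = None
    control_carriers: int = 0
    expected_ratio: float | None = None
    founder: str = ""


@dataclass
class TruthSet:
    events: list[PlantedEvent] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_tsv(self, path: str | Path) -> Path:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "kind": e.kind,
                    "case": e.case,
                    "chrom": e.chrom,
                    "start": e.start,
                    "end": e.end,
                    "gene": e.gene,
                    "variant": e.variant.g_label if e.variant else "",
                    "control_carriers": e.control_carriers,
                    "expected_ratio": "" if e.expected_ratio is None else e.expected_ratio,
                    "founder": e.founder,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return Path(path)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; the defaults are the package's study conditions."""

    seed: int = 0
    n_controls: int = 50
    n_first_pass: int | None = None  # default: min(35, n_controls)
    families: tuple[str, ...] = ("trio", "duo", "solo")
    n_background_variants: int = 20_000
    background_maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    mean_coverage: float = 20.0
    read_len: float = 150.0
    depth_dispersion: float = 0.01  # NB overdispersion phi; 0 -> Poisson
    window_sizes: tuple[int, ...] = (10_000, 200_000)
    build: GenomeBuild = DEFAULT_BUILD

    def __post_init__(self) -> None:
        lo, hi = self.background_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("background_maf_range must lie within (0, 0.5]")
        if self.n_first_pass is None:
            object.__setattr__(self, "n_first_pass", min(35, self.n_controls))
        if not 0 <= self.n_first_pass <= self.n_controls:
            raise ValueError("n_first_pass must be within [0, n_controls]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")


@dataclass
class SimulatedCohort:
    """A simulated cohort plus everything needed to score recovery."""

    cohort: CohortGenotypes
    pedigree: Pedigree
    truth: TruthSet
    families: list[FamilyDesign]
    gene_models: list[GeneModel]
    config: SimConfig

    @property
    def case_ids(self) -> list[str]:
        return [f.case for f in self.families]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, r in self.cohort.roles.items() if r == "control"]

    @property
    def first_pass_ids(self) -> list[str]:
        return self.control_ids[: self.config.n_first_pass]

    @property
    def global_ids(self) -> list[str]:
        return self.control_ids

    @property
    def carrier_pool(self) -> list[str]:
        """Controls outside the first-pass private-filter set."""
        return self.control_ids[self.config.n_first_pass :]


def _transmit(rng: np.random.Generator, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Mendelian transmission: one gamete per parent per site."""

    def gamete(par: np.ndarray) -> np.ndarray:
        g = (par == HOM_ALT).astype(np.int8)
        hets = par == HET
        g[hets] = rng.integers(0, 2, size=int(hets.sum()), dtype=np.int8)
        return g

    return gamete(sire) + gamete(dam)


def _genomic_ref_base(models: list[GeneModel], chrom: str, pos: int) -> str | None:
    """Plus-strand reference base at a position inside some model's CDS."""
    from .consequence import map_genomic_to_cds

    for m in models:
        if m.chrom != chrom or not m.contains(pos):
            continue
        cds = map_genomic_to_cds(m, pos)
        if cds is None:
            return None
        base = m.cds_seq[cds - 1]
        return base if m.strand == "+" else base.translate(_COMPLEMENT)
    return None


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate the cohort, pedigree and truth set for one seed.

    Background sites are drawn per-site under Hardy-Weinberg with MAF ~
    U(background_maf_range); case genotypes arise by Mendelian transmission
    from (possibly unsequenced) Hardy-Weinberg parents.  Planted scenarios
    override background at their loci; identical seeds give byte-identical
    output files.
    """
    rng = np.random.default_rng(config.seed)
    build = config.build
    models = default_gene_models()
    families = [FamilyDesign(i + 1, d) for i, d in enumerate(config.families)]

    # ---- planted variant scenarios (defaults mirror the case series) -------
    scenario_plan: list[tuple[str, FamilyDesign, GeneModel, int]] = []
    by_gene = {m.gene_id: m for m in models}
    if families:
        gene_cycle = ["SHC4L", "WDR45BL"]
        recessive_targets = [f for f in families if f.design in ("trio", "solo")][:2]
        for fam, gid in zip(recessive_targets, gene_cycle):
            k = 12 if fam.design == "trio" else 7
            scenario_plan.append((f"recessive_{fam.design}", fam, by_gene[gid], k))
        denovo_fam = next((f for f in families if f.design == "duo"), None)
        if denovo_fam is not None:
            scenario_plan.append(("denovo", denovo_fam, by_gene["DYNC1H1L"], 0))
    reserved = {
        (canonical_variant(m, s).chrom, canonical_variant(m, s).pos)
        for s, _, m, _ in scenario_plan
    }

    # ---- background sites ---------------------------------------------------
    chrom_idx = rng.integers(0, len(build.chrom_names), size=config.n_background_variants * 2)
    offsets = rng.integers(1, max(build.chrom_lengths), size=config.n_background_variants * 2)
    seen: set[tuple[str, int]] = set(reserved)
    sites: list[tuple[str, int]] = []
    for ci, off in zip(chrom_idx, offsets):
        chrom = build.chrom_names[ci]
        if off > build.chrom_lengths[ci]:
            continue
        key = (chrom, int(off))
        if key in seen:
            continue
        seen.add(key)
        sites.append(key)
        if len(sites) == config.n_background_variants:
            break
    sites.sort(key=lambda k: (build.index_of(k[0]), k[1]))
    n = len(sites)

    maf = rng.uniform(*config.background_maf_range, size=n)
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    refs = bases[ref_i]
    alts = bases[(ref_i + alt_shift) % 4]
    # inside a CDS the reference allele must match the gene model sequence
    for i, (chrom, pos) in enumerate(sites):
        model_base = _genomic_ref_base(models, chrom, pos)
        if model_base is not None:
            refs[i] = model_base
            if alts[i] == model_base:
                alts[i] = bases[(int(np.where(bases == model_base)[0][0]) + 1) % 4]

    variants = [
        VariantRecord(chrom, pos, refs[i], alts[i]) for i, (chrom, pos) in enumerate(sites)
    ]

    # ---- samples ------------------------------------------------------------
    samples: list[str] = []
    roles: dict[str, str] = {}
    for fam in families:
        for sid, role in ((fam.case, "case"), (fam.sire, "sire"), (fam.dam, "dam")):
            if sid is not None:
                samples.append(sid)
                roles[sid] = role
    control_ids = [f"ctrl_{i:02d}" for i in range(config.n_controls)]
    samples.extend(control_ids)
    roles.update({c: "control" for c in control_ids})

    gt = np.empty((n, len(samples)), dtype=np.int8)
    col = {s: j for j, s in enumerate(samples)}
    for fam in families:
        sire_gt = rng.binomial(2, maf).astype(np.int8)
        dam_gt = rng.binomial(2, maf).astype(np.int8)
        case_gt = _transmit(rng, sire_gt, dam_gt)
        gt[:, col[fam.case]] = case_gt
        if fam.sire is not None:
            gt[:, col[fam.sire]] = sire_gt
        if fam.dam is not None:
            gt[:, col[fam.dam]] = dam_gt
    for c in control_ids:
        gt[:, col[c]] = rng.binomial(2, maf).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng.random(gt.shape) < config.missing_rate
        gt[drop] = MISSING

    cohort = CohortGenotypes(build, variants, samples, gt, roles)

    # ---- plant scenarios ----------------------------------------------------
    truth = TruthSet()
    carrier_pool = control_ids[config.n_first_pass :]
    for scenario, fam, model, k in scenario_plan:
        cohort = plant_variant_scenario(cohort, scenario, fam, model, k, carrier_pool)
        variant = canonical_variant(model, scenario)
        truth.events.append(
            PlantedEvent(
                kind="denovo_indel" if scenario == "denovo" else "recessive_snv",
                case=fam.case,
                chrom=variant.chrom,
                start=variant.pos,
                end=variant.pos,
                gene=model.gene_id,
                variant=variant,
                control_carriers=k,
            )
        )

    # ---- depth events -------------------------------------------------------
    deletion_intervals = [(("chr2"), 6_133_400, 9_071_900), (("chr2"), 1_512_300, 3_524_700)]
    deletion_targets = [f for f in families if f.design in ("trio", "duo")][:2]
    for fam, (chrom, start, end) in zip(deletion_targets, deletion_intervals):
        truth.events.append(
            PlantedEvent(
                kind="segmental_deletion",
                case=fam.case,
                chrom=chrom,
                start=start,
                end=end,
                expected_ratio=0.5,
            )
        )
    trisomy_fam = next((f for f in families if f.design == "solo"), None)
    if trisomy_fam is not None:
        truth.events.append(
            PlantedEvent(
                kind="whole_chrom_trisomy",
                case=trisomy_fam.case,
                chrom="chr3",
                start=1,
                end=build.length_of("chr3"),
                expected_ratio=1.5,
            )
        )

    # ---- pedigree -----------------------------------------------------------
    pedigree = _build_pedigree(families, control_ids, cohort, truth)

    return SimulatedCohort(cohort, pedigree, truth, families, models, config)


def plant_variant_scenario(
    cohort: CohortGenotypes,
    scenario: str,
    family: FamilyDesign,
    model: GeneModel,
    control_carriers_k: int = 0,
    carrier_pool: list[str] | None = None,
) -> CohortGenotypes:
    """Insert one planted variant with the genotype pattern of a scenario.

    ``recessive_*``: case hom_alt, every sequenced parent het, exactly k het
    carriers among ``carrier_pool`` controls, no other carriers anywhere.
    ``denovo``: case het; everyone else hom_ref.  Raises when the scenario
    is incompatible with the family design (e.g. recessive_trio on a solo)
    or the planted locus collides with an existing one.
    """
    if scenario.startswith("recessive_") and scenario != "recessive":
        wanted = scenario.split("_", 1)[1]
        if wanted != family.design:
            raise ValueError(f"scenario {scenario} incompatible with a {family.design} family")
    variant = canonical_variant(model, scenario)
    if any(v.chrom == variant.chrom and v.pos == variant.pos for v in cohort.variants):
        raise ValueError(f"planted locus {variant.chrom}:{variant.pos} collides")
    if variant.chrom not in cohort.build.chrom_names:
        raise ValueError(f"planted event on unknown chromosome {variant.chrom}")
    controls = [s for s, r in cohort.roles.items() if r == "control"]
    pool = carrier_pool if carrier_pool is not None else controls
    if control_carriers_k > len(pool):
        raise ValueError("control_carriers_k exceeds the eligible control pool")

    row = np.full(cohort.n_samples, HOM_REF, dtype=np.int8)
    case_j = cohort.sample_index(family.case)
    if scenario == "denovo":
        row[case_j] = HET
    else:
        row[case_j] = HOM_ALT
        for parent in (family.sire, family.dam):
            if parent is not None:
                row[cohort.sample_index(parent)] = HET
        for carrier in pool[:control_carriers_k]:
            row[cohort.sample_index(carrier)] = HET

    order = cohort.build.index_of(variant.chrom), variant.pos
    insert_at = next(
        (
            i
            for i, v in enumerate(cohort.variants)
            if (cohort.build.index_of(v.chrom), v.pos) > order
        ),
        cohort.n_variants,
    )
    variants = cohort.variants[:insert_at] + [variant] + cohort.variants[insert_at:]
    gt = np.insert(cohort.gt, insert_at, row, axis=0)
    return CohortGenotypes(cohort.build, variants, cohort.samples, gt, cohort.roles)


def _build_pedigree(
    families: list[FamilyDesign],
    control_ids: list[str],
    cohort: CohortGenotypes,
    truth: TruthSet,
) -> Pedigree:
    """Pedigrees per family design, with carrier founders and inbreeding loops.

    Trio families descend from a carrier founder through a shared ancestor of
    both parents (plus a labeled carrier side line), solo families carry an
    inbreeding loop through a labeled carrier sire; duo parents are
    unrelated.  Founder ids are recorded in the truth set as carrier_allele
    events for the recessive scenarios.
    """
    parents: dict[str, tuple[str | None, str | None]] = {}
    sex: dict[str, str] = {}
    labels: dict[str, str] = {}
    planted_by_case = {e.case: e for e in truth.of_kind("recessive_snv")}
    for fam in families:
        i = fam.index
        case, sire, dam = fam.case, f"sire_{i}", f"dam_{i}"
        parents[case] = (sire, dam)
        sex[case] = "M"
        sex[sire] = "M"
        sex[dam] = "F"
        if fam.design == "trio":
            founder, anc, s1, d1, side = (
                f"fam{i}_founder",
                f"fam{i}_anc",
                f"fam{i}_s1",
                f"fam{i}_d1",
                f"fam{i}_side",
            )
            parents[anc] = (founder, None)
            parents[s1] = (anc, None)
            parents[d1] = (anc, None)
            parents[sire] = (s1, None)
            parents[dam] = (d1, None)
            parents[side] = (founder, None)
            parents[founder] = (None, None)
            sex.update({founder: "M", anc: "M", s1: "M", d1: "F", side: "M"})
            if case in planted_by_case:
                labels[side] = "het"
                truth.events.append(
                    PlantedEvent(
                        kind="carrier_allele",
                        case=case,
                        gene=planted_by_case[case].gene,
                        founder=founder,
                    )
                )
        elif fam.design == "solo":
            loop, p1, p2 = f"fam{i}_loop", f"fam{i}_p1", f"fam{i}_p2"
            parents[p1] = (loop, None)
            parents[p2] = (loop, None)
            parents[sire] = (p1, None)
            parents[dam] = (p2, None)
            parents[loop] = (None, None)
            sex.update({loop: "M", p1: "M", p2: "F"})
            if case in planted_by_case:
                labels[loop] = "het"
                truth.events.append(
                    PlantedEvent(
                        kind="carrier_allele",
                        case=case,
                        gene=planted_by_case[case].gene,
                        founder=loop,
                    )
                )
        else:  # duo: recorded but unrelated founder parents
            parents[sire] = (None, None)
            parents[dam] = (None, None)
    for c in control_ids:
        parents[c] = (None, None)
        sex[c] = "M" if int(c.split("_")[1]) % 2 else "F"
    # genotype labels for sequenced animals at their family's planted site
    for fam in families:
        event = planted_by_case.get(fam.case)
        if event is None:
            continue
        vi = cohort.variant_index(event.variant)
        for sid in (fam.case, fam.sire, fam.dam):
            if sid is None:
                continue
            code = int(cohort.gt[vi, cohort.sample_index(sid)])
            labels[sid] = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt"}.get(
                code, "unknown"
            )
    return Pedigree(parents, sex, labels)


def allele_pedigree(sim: SimulatedCohort, gene: str) -> Pedigree:
    """The pedigree with genotype labels restricted to one allele's carriers.

    Carrier tracing is a per-allele question: the labels of animals carrying
    a different family's allele must not constrain the founder search, so
    only the target family's sequenced animals and its labeled pedigree-only
    carriers keep their labels.
    """
    event = next(
        (e for e in sim.truth.of_kind("recessive_snv") if e.gene == gene), None
    )
    if event is None:
        raise KeyError(f"no planted recessive allele for gene {gene!r}")
    fam = next(f for f in sim.families if f.case == event.case)
    i = fam.index
    prefixes = (f"case_{i}", f"sire_{i}", f"dam_{i}", f"fam{i}_")
    labels = {
        a: l
        for a, l in sim.pedigree.genotype_labels.items()
        if any(a == p or a.startswith(p) for p in prefixes)
    }
    return Pedigree(dict(sim.pedigree.parents), dict(sim.pedigree.sex), labels)


def pedigree_to_ped(ped: Pedigree, families: list[FamilyDesign]) -> pd.DataFrame:
    fam_of = {}
    for fam in families:
        for a in (fam.case, fam.sire, fam.dam):
            if a is not None:
                fam_of[a] = f"FAM{fam.index}"
    rows = []
    for animal in ped.animals:
        sire, dam = ped.parents[animal]
        rows.append(
            {
                "family": fam_of.get(animal, "0"),
                "id": animal,
                "sire": sire,
                "dam": dam,
                "sex": {"M": "1", "F": "2"}.get(ped.sex.get(animal, ""), "0"),
                "phenotype": "2" if animal in [f.case for f in families] else "1",
                "genotype_label": ped.genotype_labels.get(animal, "unknown"),
            }
        )
    return pd.DataFrame(rows)


def simulate_depth(
    sample: str,
    cnv_events: list[PlantedEvent],
    config: SimConfig,
    window_size: int,
    rng: np.random.Generator,
) -> DepthProfile:
    """Windowed read counts for one sample under its planted copy-number state.

    Window counts are negative-binomial with mean
    ``mean_coverage * window_len * (copy_number / 2) / read_len`` and
    overdispersion ``depth_dispersion`` (0 gives Poisson); copy number is 1
    inside heterozygous deletions, 3 on trisomic chromosomes, 2 elsewhere.
    Boundary windows take the coverage-weighted mixture of the two states.
    """
    if config.mean_coverage <= 0:
        raise ValueError("mean coverage must be positive")
    for a in cnv_events:
        for b in cnv_events:
            if a is not b and a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                raise ValueError("planted depth events overlap on one chromosome")
    rows = []
    for chrom, length in zip(config.build.chrom_names, config.build.chrom_lengths):
        starts = np.arange(1, length + 1, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size - 1, length)
        widths = (ends - starts + 1).astype(np.float64)
        factor = np.ones(len(starts))
        for e in cnv_events:
            if e.chrom != chrom:
                continue
            cn = 3 if e.kind == "whole_chrom_trisomy" else 1
            ov = np.maximum(
                0, np.minimum(ends, e.end) - np.maximum(starts, e.start) + 1
            ).astype(np.float64)
            frac = ov / widths
            factor += frac * (cn / 2 - 1)
        mu = config.mean_coverage * widths * factor / config.read_len
        if config.depth_dispersion > 0:
            r = 1.0 / config.depth_dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)
        rows.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "count": counts})
        )
    df = pd.concat(rows, ignore_index=True)
    return DepthProfile(sample=sample, window_size=window_size, windows=df)


def simulate_case_depths(
    sim: SimulatedCohort, rng: np.random.Generator | None = None
) -> dict[str, dict[int, DepthProfile]]:
    """Depth profiles (every configured window size) for each case sample."""
    rng = rng if rng is not None else np.random.default_rng(sim.config.seed + 1_000_003)
    depth_kinds = ("segmental_deletion", "whole_chrom_trisomy")
    out: dict[str, dict[int, DepthProfile]] = {}
    for fam in sim.families:
        events = [e for e in sim.truth.events if e.case == fam.case and e.kind in depth_kinds]
        out[fam.case] = {
            ws: simulate_depth(fam.case, events, sim.config, ws, rng)
            for ws in sim.config.window_sizes
        }
    return out


def plant_shared_roh(
    cohort: CohortGenotypes,
    case_ids: list[str],
    chrom: str,
    start: int,
    end: int,
    rng: np.random.Generator,
) -> tuple[CohortGenotypes, PlantedEvent]:
    """Force a shared homozygous stretch in the given cases.

    Every site in [start, end] becomes homozygous in each listed case (allele
    drawn once per site by its frequency, shared across cases, emulating a
    shared autozygous haplotype).
    """
    gt = cohort.gt.copy()
    cols = cohort.sample_indices(case_ids)
    for i, v in enumerate(cohort.variants):
        if v.chrom == chrom and start <= v.pos <= end:
            called = gt[i, :] != MISSING
            freq = gt[i, called].sum() / max(1, 2 * called.sum())
            allele = HOM_ALT if rng.random() < freq else HOM_REF
            gt[i, cols] = allele
    out = CohortGenotypes(cohort.build, cohort.variants, cohort.samples, gt, cohort.roles)
    event = PlantedEvent(
        kind="shared_roh", case=",".join(case_ids), chrom=chrom, start=start, end=end
    )
    return out, event
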