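"""End-to-end orchestration: simulate -> prioritize -> associate -> karyotype
-> pedigree, plus the descriptive case-series statistics.

:func:`run_pipeline` executes every stage on a simulated cohort (or on user
data loaded through :mod:`cscm_sieve.io_formats`) and returns a
:class:`PipelineResult` whose manifest records the seed, configuration,
thresholds and per-stage funnel counts; re-running with the same seed
reproduces the manifest byte-identically.  When an output directory is
given, every stage's table is also written to disk (VCF, PED, depth TSVs,
truth TSV, candidate/funnel/segment reports, JSON manifest).
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    ROHParams,
    allelic_association,
    bonferroni_threshold,
    detect_roh,
    pairwise_relatedness,
    prune_related,
    shared_homozygosity,
)
from .coverage import AneuploidyCall, SegmentCall, call_segments, normalize_depth, refine_breakpoints
from .pedigree import common_ancestors, trace_carriers, wright_inbreeding
from .prioritize import (
    CaseFamily,
    FilterFunnel,
    candidates_frame,
    filter_case_recessive,
    filter_denovo_dominant,
    filter_shared_recessive,
)
from .synth import (
    SimConfig,
    SimulatedCohort,
    allele_pedigree,
    pedigree_to_ped,
    simulate_case_depths,
    simulate_cohort,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    manifest: dict
    candidates: pd.DataFrame
    funnels: list[FilterFunnel]
    segments: list[SegmentCall]
    aneuploidies: list[AneuploidyCall]
    association: pd.DataFrame
    shared_roh: list
    pedigree_report: dict
    sim: SimulatedCohort


def run_pipeline(config: SimConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on a freshly simulated cohort.

    Stage failures abort with the stage name; every threshold used is
    recorded in the manifest.
    """
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
        "thresholds": {
            "callable_fraction": 0.9,
            "relatedness_threshold": 0.5,
            "alpha": 0.05,
            "loss_max": 0.7,
            "gain_min": 1.3,
            "min_windows": 3,
            "roh": asdict(ROHParams()),
        },
    }
    stage = "simulate"
    try:
        sim = simulate_cohort(config)
        depths = simulate_case_depths(sim)
        manifest["stages"]["simulate"] = {
            "n_variants": sim.cohort.n_variants,
            "n_samples": sim.cohort.n_samples,
            "n_truth_events": len(sim.truth.events),
        }

        stage = "prioritize"
        families = [CaseFamily(f.case, f.sire, f.dam) for f in sim.families]
        funnels: list[FilterFunnel] = []
        if len(families) >= 2:
            funnels.append(
                filter_shared_recessive(
                    sim.cohort, [f.case for f in families], sim.first_pass_ids, sim.gene_models
                )
            )
        for fam in families:
            funnels.append(
                filter_case_recessive(
                    sim.cohort, fam, sim.first_pass_ids, sim.global_ids, sim.gene_models
                )
            )
            funnels.append(
                filter_denovo_dominant(
                    sim.cohort, fam, sim.first_pass_ids, sim.global_ids, sim.gene_models
                )
            )
        candidates = candidates_frame(funnels)
        manifest["stages"]["prioritize"] = {
            "funnels": {f"{f.scenario}:{f.case}": f.stages for f in funnels},
            "n_candidates": len(candidates),
        }

        stage = "associate"
        rel = pairwise_relatedness(sim.cohort, sim.control_ids)
        kept_controls = prune_related(rel, manifest["thresholds"]["relatedness_threshold"])
        assoc = allelic_association(sim.cohort, sim.case_ids, kept_controls)
        n_tests = int(assoc["informative"].sum())
        threshold = bonferroni_threshold(manifest["thresholds"]["alpha"], max(n_tests, 1))
        assoc["significant"] = assoc["p_value"] < threshold
        roh_sets = {c: detect_roh(sim.cohort, c) for c in sim.case_ids}
        shared = shared_homozygosity(roh_sets, min_cases=2)
        manifest["stages"]["associate"] = {
            "n_controls_retained": len(kept_controls),
            "n_tests": n_tests,
            "bonferroni_threshold": threshold,
            "n_significant": int(assoc["significant"].sum()),
            "n_roh_runs": sum(len(v) for v in roh_sets.values()),
            "n_shared_intervals": len(shared),
        }

        stage = "karyotype"
        segments: list[SegmentCall] = []
        aneuploidies: list[AneuploidyCall] = []
        seg_owner: list[str] = []
        for case, per_ws in depths.items():
            coarse = normalize_depth(per_ws[max(per_ws)], sex_chroms=config.build.sex_chroms)
            fine = normalize_depth(per_ws[min(per_ws)], sex_chroms=config.build.sex_chroms)
            segs, aneus = call_segments(coarse)
            segs = [refine_breakpoints(s, fine) for s in segs]
            segments.extend(segs)
            seg_owner.extend([case] * len(segs))
            aneuploidies.extend(aneus)
        manifest["stages"]["karyotype"] = {
            "n_segments": len(segments),
            "n_aneuploidies": len(aneuploidies),
            "segments": [
                {"case": o, "chrom": s.chrom, "start": s.start, "end": s.end,
                 "state": s.state, "size_mb": s.size_mb}
                for o, s in zip(seg_owner, segments)
            ],
            "aneuploidies": [asdict(a) for a in aneuploidies],
        }

        stage = "pedigree"
        ped_report: dict = {"cases": {}, "carrier_traces": {}}
        for fam in sim.families:
            sire, dam = sim.pedigree.parents[fam.case]
            commons = sorted(common_ancestors(sim.pedigree, sire, dam, max_gen=3))
            ped_report["cases"][fam.case] = {
                "inbreeding_loop": bool(commons),
                "common_ancestors": commons,
                "wright_F": wright_inbreeding(sim.pedigree, fam.case),
            }
        for event in sim.truth.of_kind("carrier_allele"):
            trace = trace_carriers(allele_pedigree(sim, event.gene))
            ped_report["carrier_traces"][event.gene] = {
                "candidate_founders": list(trace.candidate_founders),
                "planted_founder": event.founder,
            }
        manifest["stages"]["pedigree"] = {
            k: {"inbreeding_loop": v["inbreeding_loop"], "wright_F": v["wright_F"]}
            for k, v in ped_report["cases"].items()
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result = PipelineResult(
        manifest, candidates, funnels, segments, aneuploidies, assoc, shared, ped_report, sim
    )
    if outdir is not None:
        _write_outputs(result, depths, Path(outdir))
    return result


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["build"] = {
        "chrom_names": list(config.build.chrom_names),
        "chrom_lengths": list(config.build.chrom_lengths),
        "sex_chroms": list(config.build.sex_chroms),
    }
    return d


def _write_outputs(result: PipelineResult, depths: dict, outdir: Path) -> None:
    from .io_formats import write_depth_table, write_ped, write_vcf

    outdir.mkdir(parents=True, exist_ok=True)
    sim = result.sim
    paths = {
        "vcf": str(outdir / "cohort.vcf"),
        "ped": str(outdir / "pedigree.ped"),
        "truth": str(outdir / "truth.tsv"),
        "candidates": str(outdir / "candidates.tsv"),
        "funnels": str(outdir / "funnels.tsv"),
        "association": str(outdir / "association.tsv"),
        "segments": str(outdir / "segments.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_vcf(sim.cohort, paths["vcf"])
    write_ped(pedigree_to_ped(sim.pedigree, sim.families), paths["ped"])
    sim.truth.to_tsv(paths["truth"])
    result.candidates.to_csv(paths["candidates"], sep="\t", index=False)
    pd.concat([f.to_frame() for f in result.funnels], ignore_index=True).to_csv(
        paths["funnels"], sep="\t", index=False
    )
    result.association.to_csv(paths["association"], sep="\t", index=False)
    seg_rows = [
        {"chrom": s.chrom, "start": s.start, "end": s.end, "state": s.state,
         "mean_ratio": s.mean_ratio, "n_windows": s.n_windows, "size_mb": s.size_mb}
        for s in result.segments
    ] + [
        {"chrom": a.chrom, "start": "", "end": "", "state": a.type,
         "mean_ratio": a.median_ratio, "n_windows": "", "size_mb": ""}
        for a in result.aneuploidies
    ]
    pd.DataFrame(seg_rows).to_csv(paths["segments"], sep="\t", index=False)
    for case, per_ws in depths.items():
        for ws, profile in per_ws.items():
            p = outdir / f"depth_{case}_{ws}.tsv"
            write_depth_table(profile, p)
            paths[f"depth_{case}_{ws}"] = str(p)
    result.manifest["paths"] = paths
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# descriptive case-series statistics


def bundled_case_table() -> pd.DataFrame:
    """The transcribed case-overview fixture shipped with the package."""
    from .io_formats import read_case_table

    with importlib.resources.as_file(
        importlib.resources.files("cscm_sieve") / "data" / "table1_cases.tsv"
    ) as p:
        return read_case_table(p)


def summarize_case_table(case_table: pd.DataFrame) -> pd.DataFrame:
    """Per-breed mean, SD, min, max and n for body weight and gestation age.

    Missing values are excluded per field.  The SD is the population form
    (divisor n); means and SDs are reported to 1 decimal.  A field with no
    observations in a breed is marked unavailable (NaN, n = 0).
    """
    rows = []
    for breed, sub in case_table.groupby("breed", sort=True):
        row: dict = {"breed": breed}
        for col, label in (("bw_kg", "bw"), ("ga_days", "ga")):
            vals = sub[col].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                row.update({f"{label}_n": 0, f"{label}_mean": np.nan, f"{label}_sd": np.nan,
                            f"{label}_min": np.nan, f"{label}_max": np.nan})
                continue
            row.update(
                {
                    f"{label}_n": len(vals),
                    f"{label}_mean": round(float(vals.mean()), 1),
                    f"{label}_sd": round(float(vals.std(ddof=0)), 1),
                    f"{label}_min": float(vals.min()),
                    f"{label}_max": float(vals.max()),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
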