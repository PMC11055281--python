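"""End-to-end orchestration: simulate (or load) inputs, map, type carriers,
filter WGS variants, annotate, design the assay, and summarize phenotypes.

``run_all`` executes the discovery order of the source study design:
marker QC -> association scan -> case-shared homozygosity -> control
refinement -> haplotype extraction -> carrier tally -> WGS cascade ->
consequence/NMD annotation -> RFLP check -> phenotype statistics, writing a
deterministic report bundle (same seed, byte-identical files).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assay_rflp, consequence_annot, herdsim, io_formats, phenostats
from . import haplotype_carrier as hapmod
from . import roh_mapping as roh
from . import variant_cascade as cascade_mod
from .herdsim import Herd, SimConfig
from .io_formats import GenotypeMatrix, VariantTable
from .roh_mapping import RohParams

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RegionCall:
    assoc: roh.AssocResult
    shared: roh.SharedRegion
    refined: roh.SharedRegion


def locate_candidate_region(
    matrix: GenotypeMatrix,
    case_ids: list[str],
    control_ids: list[str],
    assoc_alpha: float = 0.01,
    top_markers: int = 20,
    refine_fraction: float = 0.45,
    refine_max_control_carriers: int | None = None,
) -> RegionCall:
    """Association scan + case-shared homozygosity + control refinement.

    The shared region holding the most of the ``top_markers`` best-associated
    markers is selected (the scan points at the region first, as in the
    study's GWA-then-homozygosity order), then refined to the sub-region
    whose control homozygote counts stay below the threshold (default
    ``ceil(refine_fraction * n_controls)``).
    """
    assoc = roh.recessive_assoc_scan(matrix, case_ids, control_ids, alpha=assoc_alpha)
    regions = roh.merge_shared_runs(
        roh.shared_case_region(matrix, case_ids), matrix, case_ids
    )
    if not regions:
        raise PipelineError("shared-region stage: no case-shared region found")
    top = assoc.table.nsmallest(top_markers, "p_value")
    def _hits(r):
        return sum(r.contains(c, int(p)) for c, p in zip(top["chrom"], top["pos"]))
    region = max(regions, key=lambda r: (_hits(r), r.n_case_homozygous_snps))
    frac, hom_counts, _ = roh.control_hom_fraction(
        matrix, case_ids, control_ids, region
    )
    threshold = (
        refine_max_control_carriers
        if refine_max_control_carriers is not None
        else math.ceil(refine_fraction * len(control_ids))
    )
    refined = roh.refine_region(region, hom_counts, threshold, fractions=frac)
    return RegionCall(assoc=assoc, shared=region, refined=refined)


@dataclass
class PipelineConfig:
    sim: SimConfig | None = field(default_factory=SimConfig)
    # real-input mode (exactly one of sim / the paths below must be active)
    ped_path: str | None = None
    map_path: str | None = None
    vcf_path: str | None = None
    cohorts_path: str | None = None
    array_case_ids: list[str] = field(default_factory=list)
    roh: RohParams = field(default_factory=RohParams)
    maf_max: float = 0.15
    max_other_homozygotes: int = 1
    max_external_heterozygotes: int = 2
    refine_max_control_carriers: int | None = None  # default: ceil(0.45*n_controls)
    region_top_markers: int = 20
    qc_maf_min: float = 0.0001
    qc_call_rate_min: float = 0.90
    assoc_alpha: float = 0.01
    out_dir: str = "autozyg_out"
    seed: int | None = None
    log_level: str = "info"

    def __post_init__(self) -> None:
        real = self.ped_path is not None
        if real and self.sim is not None:
            raise ValueError("configure either simulated or real inputs, not both")
        if not real and self.sim is None:
            raise ValueError("no inputs configured")
        if self.seed is not None and self.sim is not None:
            self.sim.seed = self.seed


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("sim", "default")
    if sim == "default":
        sim_cfg = SimConfig()
    elif sim is None:
        sim_cfg = None
    else:
        if "chromosomes" in sim:
            sim["chromosomes"] = [tuple(c) for c in sim["chromosomes"]]
        if "causal_locus" in sim:
            sim["causal_locus"] = tuple(sim["causal_locus"])
        sim_cfg = SimConfig(**sim)
    roh_cfg = RohParams(**raw.pop("roh", {}))
    return PipelineConfig(sim=sim_cfg, roh=roh_cfg, **raw)


# ---------------------------------------------------------------------------
# Genotype tally
# ---------------------------------------------------------------------------

GENOTYPE_COLUMNS = ["n_wild_type", "n_heterozygous", "n_homozygous_variant", "total"]


@dataclass
class GenotypeTally:
    table: pd.DataFrame  # one row per group plus a "Total" row

    @property
    def totals(self) -> tuple[int, int, int, int]:
        r = self.table.loc["Total"]
        return tuple(int(r[c]) for c in GENOTYPE_COLUMNS)


def tally_genotypes(calls) -> GenotypeTally:
    """Contingency counts of genotype {0,1,2} per group, plus totals.

    ``calls`` is an iterable of (animal_id, group_label, genotype).
    """
    counts: dict[str, list[int]] = {}
    for animal_id, group, genotype in calls:
        if genotype not in (0, 1, 2):
            raise ValueError(f"unknown genotype code {genotype!r} for {animal_id}")
        counts.setdefault(group, [0, 0, 0])[genotype] += 1
    rows = {}
    for group in counts:
        c = counts[group]
        rows[group] = {
            "n_wild_type": c[0],
            "n_heterozygous": c[1],
            "n_homozygous_variant": c[2],
            "total": sum(c),
        }
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if table.empty:
        table = pd.DataFrame(columns=GENOTYPE_COLUMNS, dtype=int)
    table.loc["Total"] = table.sum(axis=0).astype(int)
    table.index.name = "group"
    return GenotypeTally(table=table[GENOTYPE_COLUMNS])


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def recovery_study(
    n_replicates: int = 50,
    base_seed: int = 1,
    sim_factory=None,
) -> dict:
    """Replicate the mapping + cascade pipeline on freshly simulated herds
    and measure recovery of the planted causal variant.

    Returns rates over replicates: refined-region containment of the causal
    locus, causal survival through the full cascade, uniqueness as the final
    candidate, and the mean false-carrier rate (animals typed as carrying
    one or more copies of the suspect haplotype whose true causal-allele
    count is zero).
    """
    from . import variant_cascade as cascade_mod_
    from . import haplotype_carrier as hapmod_

    n_region = n_refined = n_cascade = n_unique = 0
    false_rates = []
    for k in range(n_replicates):
        cfg = sim_factory(base_seed + k) if sim_factory else SimConfig(seed=base_seed + k)
        herd = herdsim.simulate_herd(cfg)
        matrix, _ = roh.marker_qc(herd.array)
        cases = herd.case_ids
        controls = [a for a in matrix.animal_ids if a not in set(cases)]
        call = locate_candidate_region(matrix, cases, controls)
        cc, cp = cfg.causal_locus
        n_region += call.shared.contains(cc, cp)
        n_refined += call.refined.contains(cc, cp)
        cconfig = cascade_mod_.CascadeConfig.from_table(
            herd.wgs,
            region_of_interest=(
                call.refined.chrom,
                call.refined.envelope_start_bp,
                call.refined.envelope_end_bp,
            ),
        )
        result = cascade_mod_.run_cascade(
            herd.wgs, cconfig, evidence=herd.evidence,
            transcripts=[herd.transcript], genome=herd.genome,
        )
        surv = result.surviving.variants
        causal_in = bool(((surv["chrom"] == cc) & (surv["pos"] == cp)).any())
        n_cascade += causal_in
        n_unique += causal_in and result.surviving.n_variants == 1
        if not call.refined.is_empty:
            block = hapmod_.extract_case_haplotype(matrix, cases, call.refined)
            false_pos = n_noncarrier = 0
            for a in matrix.animal_ids:
                truth = herd.causal_genotypes[a]
                if truth != 0:
                    continue
                n_noncarrier += 1
                if hapmod_.count_haplotype_copies(matrix, a, block).copies >= 1:
                    false_pos += 1
            if n_noncarrier:
                false_rates.append(false_pos / n_noncarrier)
    return {
        "n_replicates": n_replicates,
        "region_contains_causal_rate": n_region / n_replicates,
        "refined_contains_causal_rate": n_refined / n_replicates,
        "cascade_survival_rate": n_cascade / n_replicates,
        "unique_candidate_rate": n_unique / n_replicates,
        "mean_false_carrier_rate": float(np.mean(false_rates)) if false_rates else 0.0,
    }


@dataclass
class RunResult:
    out_dir: Path
    herd: Herd | None
    shared_region: roh.SharedRegion | None
    refined_region: roh.SharedRegion | None
    carrier_tally: dict[int, int]
    cascade: cascade_mod.CascadeResult
    candidate_annotations: pd.DataFrame | None
    rflp: assay_rflp.RflpReport | None
    files: dict[str, Path]


def _write(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False),
              float_format="%.6g", **kwargs)
    return path


def run_all(config: PipelineConfig) -> RunResult:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    log_lines = [f"autozyg {__version__}"]

    # --- inputs -----------------------------------------------------------
    herd = None
    if config.sim is not None:
        herd = herdsim.simulate_herd(config.sim)
        matrix, wgs = herd.array, herd.wgs
        case_ids = herd.case_ids
        evidence = herd.evidence
        transcripts = [herd.transcript]
        genome = herd.genome
        log_lines.append(f"seed\t{config.sim.seed}")
        log_lines.append(f"gene_drop_attempts\t{herd.gene_drop_attempts}")
        herd.pedigree.to_tsv(out / "pedigree.tsv")
        _write(herd.phenotypes, out / "phenotypes.tsv")
        io_formats.write_genotype_matrix(matrix, out / "array.ped", out / "array.map")
        io_formats.write_vcf(wgs, out / "wgs.vcf")
        io_formats.write_cohorts_tsv(wgs.samples, out / "cohorts.tsv")
        io_formats.write_transcripts(transcripts, out / "transcripts.gff3")
        files.update({k: out / v for k, v in [
            ("pedigree", "pedigree.tsv"), ("phenotypes", "phenotypes.tsv"),
            ("wgs_vcf", "wgs.vcf")]})
    else:
        matrix = io_formats.read_genotype_matrix(config.ped_path, config.map_path)
        cohorts = (
            io_formats.read_cohorts_tsv(config.cohorts_path)
            if config.cohorts_path else {}
        )
        wgs = io_formats.read_vcf(config.vcf_path, cohorts) if config.vcf_path else None
        case_ids = list(config.array_case_ids)
        evidence, transcripts, genome = None, None, None
    if not case_ids:
        raise PipelineError("shared-region stage: no affected cases configured")

    # --- array analysis ---------------------------------------------------
    qc_matrix, qc_log = roh.marker_qc(
        matrix, maf_min=config.qc_maf_min, call_rate_min=config.qc_call_rate_min
    )
    files["qc_removed"] = _write(qc_log, out / "qc_removed.tsv")

    control_ids = [a for a in qc_matrix.animal_ids if a not in set(case_ids)]
    call = locate_candidate_region(
        qc_matrix,
        case_ids,
        control_ids,
        assoc_alpha=config.assoc_alpha,
        top_markers=config.region_top_markers,
        refine_max_control_carriers=config.refine_max_control_carriers,
    )
    assoc, region, refined = call.assoc, call.shared, call.refined
    files["assoc"] = _write(assoc.table, out / "assoc.tsv")
    files["manhattan"] = _write(assoc.manhattan_frame(), out / "manhattan.tsv")
    region_df = pd.DataFrame(
        [
            {
                "chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
                "envelope_start_bp": r.envelope_start_bp,
                "envelope_end_bp": r.envelope_end_bp,
                "n_snps": r.n_case_homozygous_snps,
            }
            for r in (region, refined)
        ],
        index=["shared", "refined"],
    )
    region_df.index.name = "stage"
    files["regions"] = _write(region_df, out / "regions.tsv", index=True)
    if refined.is_empty:
        raise PipelineError("refine stage: no SNP passed the control threshold")

    # anchor the haplotype on the most associated marker inside the region
    in_region = assoc.table[
        (assoc.table["chrom"] == refined.chrom)
        & assoc.table["pos"].between(refined.start_bp, refined.end_bp)
    ]
    anchor = (
        int(in_region.loc[in_region["p_value"].idxmin(), "pos"])
        if len(in_region)
        else None
    )
    block = hapmod.extract_case_haplotype(qc_matrix, case_ids, refined, anchor)
    carrier_df = hapmod.carrier_report(qc_matrix, block)
    tally = dict(
        carrier_df["copies"].value_counts().reindex([0, 1, 2], fill_value=0)
    )
    tally = {int(k): int(v) for k, v in tally.items()}
    files["carriers"] = _write(carrier_df, out / "carrier_report.tsv")

    # --- WGS cascade ------------------------------------------------------
    if wgs is None:
        raise PipelineError("cascade stage: no WGS variants supplied")
    cconfig = cascade_mod.CascadeConfig.from_table(
        wgs,
        maf_max=config.maf_max,
        max_other_homozygotes=config.max_other_homozygotes,
        max_external_heterozygotes=config.max_external_heterozygotes,
        region_of_interest=(
            refined.chrom, refined.envelope_start_bp, refined.envelope_end_bp
        ),
    )
    result = cascade_mod.run_cascade(
        wgs, cconfig, evidence=evidence, transcripts=transcripts, genome=genome
    )
    files["cascade"] = _write(result.counts_frame(), out / "cascade_counts.tsv")
    io_formats.write_vcf(result.surviving, out / "candidates.vcf")
    files["candidates"] = out / "candidates.vcf"
    ann = result.annotations
    if ann is not None and len(ann):
        files["annotations"] = _write(ann, out / "candidate_annotations.tsv")

    # --- RFLP assay for the top candidate ---------------------------------
    rflp_report = None
    if result.surviving.n_variants >= 1 and genome is not None:
        top = result.surviving.variants.iloc[0]
        if top["chrom"] in genome:
            amp_ref, amp_alt, enzyme = assay_rflp.design_causal_assay(
                genome, top["chrom"], int(top["pos"]), top["ref"], top["alt"][0]
            )
            rflp_report = assay_rflp.design_rflp_check(amp_ref, amp_alt, enzyme)
            rflp_df = pd.DataFrame(
                {
                    "allele": ["ref", "alt", "het"],
                    "fragments_bp": [
                        ",".join(map(str, rflp_report.fragments_ref)),
                        ",".join(map(str, rflp_report.fragments_alt)),
                        ",".join(map(str, rflp_report.heterozygote_pattern)),
                    ],
                    "enzyme": [enzyme.name] * 3,
                    "recognition": [enzyme.recognition] * 3,
                    "distinguishable": [rflp_report.distinguishable] * 3,
                }
            )
            files["rflp"] = _write(rflp_df, out / "rflp_report.tsv")

    # --- phenotype statistics ---------------------------------------------
    if herd is not None:
        ph = herd.phenotypes
        groups = [
            ph.loc[ph["group_label"] == g, "glycogen_mmol_per_kg"].to_numpy()
            for g in ("wild_type", "carrier", "affected")
        ]
        overall, pairwise = phenostats.anova_bonferroni(
            groups, labels=["wild_type", "carrier", "affected"]
        )
        fold = phenostats.fold_change(
            float(ph.loc[ph["affected"], "glycogen_mmol_per_kg"].mean()),
            float(ph.loc[~ph["affected"], "glycogen_mmol_per_kg"].mean()),
            decimals=1,
        )
        summary = phenostats.group_summary_table(
            ph, "glycogen_mmol_per_kg", "group_label"
        )
        files["pheno_summary"] = _write(summary, out / "phenotype_summary.tsv")
        files["pheno_pairwise"] = _write(pairwise, out / "phenotype_pairwise.tsv")
        log_lines.append(f"glycogen_anova_F\t{overall.statistic:.6g}")
        log_lines.append(f"glycogen_fold_change\t{fold}")

        tally_obj = tally_genotypes(
            (
                a,
                f"generation_{herd.pedigree[a].generation}",
                herd.causal_genotypes[a],
            )
            for a in herd.pedigree.ids
        )
        files["tally"] = _write(
            tally_obj.table, out / "genotype_tally.tsv", index=True
        )

    log_lines.append(f"carrier_tally\t{tally[0]},{tally[1]},{tally[2]}")
    log_lines.append(
        "cascade_counts\t" + ",".join(map(str, result.stage_counts))
    )
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    files["log"] = out / "run_log.txt"

    return RunResult(
        out_dir=out,
        herd=herd,
        shared_region=region,
        refined_region=refined,
        carrier_tally=tally,
        cascade=result,
        candidate_annotations=ann,
        rflp=rflp_report,
        files=files,
    )
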