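"""The WGS candidate-variant filter cascade with per-stage counts.

Stages follow the discovery order used for the herd: biallelic sites with
every sequenced case homozygous for the alternative allele; minor allele
frequency across all samples below a ceiling; at most ``max_other_hom``
non-case homozygotes; at most ``max_external_het`` external-cohort
heterozygotes; predicted protein impact; and finally absence of the
alternative allele from other breeds (user-supplied evidence).  The three
genotype-pattern filters are independent per-site predicates, so permuting
them changes intermediate counts but never the surviving set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, TranscriptModel, VariantTable
from . import consequence_annot

logger = logging.getLogger(__name__)

IMPACT_EFFECTS = {"missense", "nonsense", "stop_lost", "start_lost", "splice_region"}


@dataclass
class CascadeConfig:
    case_ids: list[str]
    herd_ids: list[str] = field(default_factory=list)
    external_ids: list[str] = field(default_factory=list)
    maf_max: float = 0.15
    max_other_homozygotes: int = 1
    max_external_heterozygotes: int = 2
    region_of_interest: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        sets = [set(self.case_ids), set(self.herd_ids), set(self.external_ids)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("case/herd/external id sets must be disjoint")
        if not 0 < self.maf_max <= 0.5:
            raise ValueError("maf_max must lie in (0, 0.5]")
        if self.max_other_homozygotes < 0 or self.max_external_heterozygotes < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_table(cls, table: VariantTable, **kwargs) -> "CascadeConfig":
        return cls(
            case_ids=table.cohort_ids("case"),
            herd_ids=table.cohort_ids("herd"),
            external_ids=table.cohort_ids("external"),
            **kwargs,
        )


@dataclass
class CascadeResult:
    stage_names: list[str]
    stage_counts: list[int]
    surviving: VariantTable
    region_fraction: float
    annotations: pd.DataFrame | None = None

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"stage": self.stage_names, "n_variants": self.stage_counts})


# ---------------------------------------------------------------------------
# Per-site genotype summaries
# ---------------------------------------------------------------------------

def _pairs(table: VariantTable, ids) -> np.ndarray:
    return table.genotypes[:, table.sample_indices(ids), :]


def _hom_alt(pairs: np.ndarray) -> np.ndarray:
    return (pairs == 1).all(axis=2)


def _het(pairs: np.ndarray) -> np.ndarray:
    called = (pairs != MISSING).all(axis=2)
    return called & (pairs[..., 0] != pairs[..., 1])


def _any_missing(pairs: np.ndarray) -> np.ndarray:
    return (pairs == MISSING).any(axis=2)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_case_hom_biallelic(table: VariantTable, case_ids: list[str]) -> VariantTable:
    """Keep biallelic sites at which every case is homozygous-alternative.

    Sites where a case genotype is missing are dropped and logged."""
    biallelic = np.array([len(a) == 1 for a in table.variants["alt"]])
    pairs = _pairs(table, case_ids)
    miss = _any_missing(pairs).any(axis=1)
    if miss.any():
        logger.info("%d sites dropped for missing case genotypes", int(miss.sum()))
    keep = biallelic & ~miss & _hom_alt(pairs).all(axis=1)
    return table.subset(keep)


def filter_maf(table: VariantTable, maf_max: float = 0.15) -> VariantTable:
    """Keep sites with minor allele frequency over all non-missing called
    genotypes (all cohorts) strictly below ``maf_max``."""
    g = table.genotypes
    called = g != MISSING
    keep = np.ones(table.n_variants, dtype=bool)
    for i in range(table.n_variants):
        alleles = g[i][called[i]]
        if alleles.size == 0:
            keep[i] = False
            continue
        counts = np.bincount(alleles)
        maf = 1.0 - counts.max() / alleles.size
        keep[i] = maf < maf_max
    return table.subset(keep)


def filter_other_homozygotes(
    table: VariantTable, case_ids: list[str], max_other_hom: int = 1
) -> VariantTable:
    """Remove sites where more than ``max_other_hom`` non-case animals are
    homozygous for the alternative allele (the case-shared allele)."""
    others = [s for s in table.sample_ids if s not in set(case_ids)]
    n_hom = _hom_alt(_pairs(table, others)).sum(axis=1)
    return table.subset(n_hom <= max_other_hom)


def filter_external_hets(
    table: VariantTable, external_ids: list[str], max_external_het: int = 2
) -> VariantTable:
    """Remove sites with more than ``max_external_het`` heterozygous animals
    in the external cohort."""
    n_het = _het(_pairs(table, external_ids)).sum(axis=1)
    return table.subset(n_het <= max_external_het)


def filter_protein_impact(
    table: VariantTable,
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
) -> tuple[VariantTable, pd.DataFrame]:
    """Keep SNVs with a predicted protein impact on any overlapping
    transcript (missense, nonsense, stop/start loss, splice-region).

    Returns the filtered table and the per-variant consequence annotations.
    """
    keep = np.zeros(table.n_variants, dtype=bool)
    ann_rows = []
    for i in range(table.n_variants):
        rec = table.variants.iloc[i]
        if len(rec["alt"]) != 1 or len(rec["ref"]) != 1 or len(rec["alt"][0]) != 1:
            continue
        for t in transcripts:
            if t.chrom != rec["chrom"] or not (t.tx_start <= rec["pos"] <= t.tx_end):
                continue
            call = consequence_annot.annotate_snv(
                (rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"][0]), t, genome
            )
            if call.effect in IMPACT_EFFECTS:
                keep[i] = True
                ann_rows.append(consequence_annot.call_to_row(call))
    ann = pd.DataFrame(ann_rows)
    return table.subset(keep), ann


def filter_external_evidence(
    table: VariantTable, evidence: pd.DataFrame | dict | None
) -> VariantTable:
    """Remove variants whose alternative allele was seen in other breeds.

    ``evidence`` maps (chrom, pos, alt) -> bool (DataFrame with those columns
    plus ``seen_in_other_breeds``, or a dict); absent variants count as not
    seen."""
    if evidence is None:
        return table.subset(np.ones(table.n_variants, dtype=bool))
    if isinstance(evidence, pd.DataFrame):
        lookup = {
            (r["chrom"], int(r["pos"]), r["alt"]): bool(r["seen_in_other_breeds"])
            for _, r in evidence.iterrows()
        }
    else:
        lookup = dict(evidence)
    keep = np.array(
        [
            not lookup.get(
                (rec["chrom"], int(rec["pos"]), rec["alt"][0]), False
            )
            for _, rec in table.variants.iterrows()
        ],
        dtype=bool,
    )
    if not keep.any() and table.n_variants:
        logger.warning("external evidence removed every candidate variant")
    return table.subset(keep)


def region_enrichment(
    table: VariantTable, region: tuple[str, int, int]
) -> float:
    """Fraction of variants inside ``region`` (chrom, start, end), bounds
    1-based inclusive.  NaN (flagged) on an empty table."""
    if table.n_variants == 0:
        logger.warning("region_enrichment on empty variant set")
        return float("nan")
    chrom, start, end = region
    inside = (
        (table.variants["chrom"] == chrom)
        & (table.variants["pos"] >= start)
        & (table.variants["pos"] <= end)
    )
    return float(inside.mean())


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_cascade(
    table: VariantTable,
    config: CascadeConfig,
    evidence: pd.DataFrame | dict | None = None,
    transcripts: list[TranscriptModel] | None = None,
    genome: dict[str, str] | None = None,
) -> CascadeResult:
    """Apply the stages in discovery order, recording per-stage counts.

    ``region_fraction`` is the fraction of post-external-het variants inside
    ``config.region_of_interest``.  The protein-impact stage runs only when
    transcript models and reference sequence are supplied.
    """
    names = ["input"]
    counts = [table.n_variants]
    annotations = None

    table = filter_case_hom_biallelic(table, config.case_ids)
    names.append("case_hom_biallelic")
    counts.append(table.n_variants)

    table = filter_maf(table, config.maf_max)
    names.append(f"maf_lt_{config.maf_max:g}")
    counts.append(table.n_variants)

    table = filter_other_homozygotes(table, config.case_ids, config.max_other_homozygotes)
    names.append(f"other_hom_le_{config.max_other_homozygotes}")
    counts.append(table.n_variants)

    table = filter_external_hets(table, config.external_ids, config.max_external_heterozygotes)
    names.append(f"external_het_le_{config.max_external_heterozygotes}")
    counts.append(table.n_variants)

    region_fraction = (
        region_enrichment(table, config.region_of_interest)
        if config.region_of_interest is not None
        else float("nan")
    )

    if transcripts is not None and genome is not None:
        table, annotations = filter_protein_impact(table, transcripts, genome)
        names.append("protein_impact")
        counts.append(table.n_variants)

    table = filter_external_evidence(table, evidence)
    names.append("not_in_other_breeds")
    counts.append(table.n_variants)

    if table.n_variants == 0:
        logger.warning("cascade left no surviving variants")
    return CascadeResult(
        stage_names=names,
        stage_counts=counts,
        surviving=table,
        region_fraction=region_fraction,
        annotations=annotations,
    )
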