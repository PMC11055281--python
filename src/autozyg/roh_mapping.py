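"""Case-shared homozygosity mapping on SNP-array dosages.

Marker QC, per-animal runs of homozygosity (ROH), the region at which every
affected animal is homozygous for the same allele, control homozygosity for
the case alleles, refinement to the low-control-homozygosity core, and a
simple exact recessive association scan.

The scan is a per-marker two-sided Fisher exact test on homozygous-for-minor
vs other by case vs control with Bonferroni control — a deliberately simple
localization tool on simulated herds, not a mixed-model GWA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class RohParams:
    """Explicit ROH thresholds (the tool defaults the study relied on are
    unpublished, so every knob is spelled out here)."""

    min_snps_per_segment: int = 15
    max_het_in_segment: int = 1
    max_missing_in_segment: int = 2
    min_length_bp: int = 500_000

    def __post_init__(self) -> None:
        if self.min_snps_per_segment < 1:
            raise ValueError("min_snps_per_segment must be >= 1")
        for name in ("max_het_in_segment", "max_missing_in_segment", "min_length_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class RohSegment:
    animal_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int


@dataclass
class SharedRegion:
    """Consecutive markers at which every case is homozygous for the same
    allele.  ``shared_alleles`` holds the case dosage (0 or 2) per marker,
    -1 where all cases were missing."""

    chrom: str
    start_bp: int
    end_bp: int
    n_case_homozygous_snps: int
    marker_indices: np.ndarray          # column indices into the source matrix
    positions_bp: np.ndarray            # per-SNP positions, parallel to indices
    shared_alleles: np.ndarray
    control_hom_fraction_per_snp: np.ndarray | None = None
    # outer envelope: the autozygous segment ends somewhere in the gap
    # before/after the boundary markers, so searches use these bounds
    envelope_start_bp: int | None = None
    envelope_end_bp: int | None = None

    def __post_init__(self) -> None:
        if self.envelope_start_bp is None:
            self.envelope_start_bp = self.start_bp
        if self.envelope_end_bp is None:
            self.envelope_end_bp = self.end_bp

    @property
    def is_empty(self) -> bool:
        return self.n_case_homozygous_snps == 0

    def contains(self, chrom: str, pos: int) -> bool:
        return (not self.is_empty and chrom == self.chrom
                and self.envelope_start_bp <= pos <= self.envelope_end_bp)


@dataclass
class AssocResult:
    table: pd.DataFrame   # marker_id, chrom, pos, counts, p_value, significant
    alpha: float
    n_tests: int

    def manhattan_frame(self) -> pd.DataFrame:
        df = self.table[["marker_id", "chrom", "pos", "p_value"]].copy()
        df["neg_log10_p"] = -np.log10(df["p_value"])
        return df


# ---------------------------------------------------------------------------
# Marker QC
# ---------------------------------------------------------------------------

def marker_qc(
    matrix: GenotypeMatrix,
    maf_min: float = 0.0001,
    call_rate_min: float = 0.90,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers with minor allele frequency below ``maf_min`` or with
    fewer than ``call_rate_min`` of animals genotyped; order preserved.

    Returns the filtered matrix and a removal log (marker_id, reason).
    """
    g = matrix.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / matrix.n_animals
    with np.errstate(invalid="ignore", divide="ignore"):
        p_b = np.where(n_called > 0, np.where(called, g, 0).sum(axis=0) / (2 * n_called), 0.0)
    maf = np.minimum(p_b, 1 - p_b)
    low_call = call_rate < call_rate_min
    low_maf = maf < maf_min
    keep = ~(low_call | low_maf)
    reasons = np.where(low_call & low_maf, "call_rate;maf",
                       np.where(low_call, "call_rate", "maf"))
    log = pd.DataFrame(
        {
            "marker_id": matrix.markers.loc[~keep, "marker_id"].to_numpy(),
            "reason": reasons[~keep],
        }
    )
    if not keep.any():
        logger.warning("marker QC removed every marker")
    return matrix.subset_markers(keep), log


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------

def call_roh(
    matrix: GenotypeMatrix, animal_id: str, params: RohParams
) -> list[RohSegment]:
    """Greedy left-to-right maximal homozygous runs for one animal.

    Within each chromosome, scan left to right; at each start take the
    longest window whose heterozygote and missing counts stay within budget;
    emit it if it meets the SNP-count and physical-span minima and continue
    after its end (so reported segments never overlap).
    """
    row = matrix.row(animal_id)
    segments: list[RohSegment] = []
    for chrom, sub in matrix.markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        g = row[idx]
        pos = sub["pos"].to_numpy()
        het = g == 1
        mis = g == MISSING
        n = len(g)
        i = 0
        while i < n:
            # longest feasible window starting at i
            j, n_het, n_mis = i, 0, 0
            while j < n:
                nh = n_het + int(het[j])
                nm = n_mis + int(mis[j])
                if nh > params.max_het_in_segment or nm > params.max_missing_in_segment:
                    break
                n_het, n_mis, j = nh, nm, j + 1
            n_snps = j - i
            if n_snps >= params.min_snps_per_segment and (
                n_snps > 0 and pos[j - 1] - pos[i] + 1 >= params.min_length_bp
            ):
                segments.append(
                    RohSegment(
                        animal_id=animal_id,
                        chrom=chrom,
                        start_bp=int(pos[i]),
                        end_bp=int(pos[j - 1]),
                        n_snps=n_snps,
                        n_het=n_het,
                        n_missing=n_mis,
                    )
                )
                i = j
            else:
                i += 1
    return segments


# ---------------------------------------------------------------------------
# Shared case region
# ---------------------------------------------------------------------------

def _case_shared_indicator(
    matrix: GenotypeMatrix, case_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per marker: are all non-missing cases homozygous for one allele?

    Returns (indicator, shared dosage 0/2, or -1 where all cases missing).
    Missing case genotypes are treated as compatible (array missingness
    should not shatter a true autozygous segment) but leave the allele
    undetermined when no case is called.
    """
    g = matrix.rows(case_ids)
    called = g != MISSING
    hom0 = g == 0
    hom2 = g == 2
    ok0 = (hom0 | ~called).all(axis=0)
    ok2 = (hom2 | ~called).all(axis=0)
    any_called = called.any(axis=0)
    indicator = (ok0 | ok2) if len(case_ids) else np.zeros(matrix.n_markers, bool)
    allele = np.full(matrix.n_markers, -1, dtype=np.int8)
    allele[ok2 & any_called] = 2
    allele[ok0 & any_called] = 0
    return indicator, allele


def shared_case_region(
    matrix: GenotypeMatrix, case_ids: list[str], min_snps: int = 1
) -> list[SharedRegion]:
    """Maximal runs of consecutive markers at which every case is homozygous
    for the same allele.  Requires at least two cases."""
    if len(case_ids) < 2:
        raise ValueError("shared_case_region needs at least 2 cases")
    indicator, allele = _case_shared_indicator(matrix, case_ids)
    regions: list[SharedRegion] = []
    for chrom, sub in matrix.markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        ind = indicator[idx]
        pos = sub["pos"].to_numpy()
        n = len(ind)
        i = 0
        while i < n:
            if not ind[i]:
                i += 1
                continue
            j = i
            while j < n and ind[j]:
                j += 1
            if j - i >= min_snps:
                regions.append(
                    SharedRegion(
                        chrom=chrom,
                        start_bp=int(pos[i]),
                        end_bp=int(pos[j - 1]),
                        n_case_homozygous_snps=j - i,
                        marker_indices=idx[i:j],
                        positions_bp=pos[i:j].copy(),
                        shared_alleles=allele[idx[i:j]],
                        envelope_start_bp=int(pos[i - 1]) + 1 if i > 0 else int(pos[i]),
                        envelope_end_bp=int(pos[j]) - 1 if j < n else int(pos[j - 1]),
                    )
                )
            i = j
    return regions


def merge_shared_runs(
    regions: list[SharedRegion],
    matrix: GenotypeMatrix,
    case_ids: list[str],
    max_gap_markers: int = 1,
    max_conflicting_cases: int = 1,
) -> list[SharedRegion]:
    """Error-tolerant merging of strict shared runs.

    Array genotyping errors in a single case shatter a true autozygous
    region into adjacent strict runs.  Runs on one chromosome separated by
    at most ``max_gap_markers`` markers, each with at most
    ``max_conflicting_cases`` cases deviating from shared homozygosity, are
    merged; the conflicted gap markers are excluded from the merged region's
    marker set (so haplotype extraction never sees them).  This mirrors the
    per-animal heterozygote allowance of standard ROH callers.
    """
    g = matrix.rows(case_ids)
    out: list[SharedRegion] = []
    by_chrom: dict[str, list[SharedRegion]] = {}
    for r in sorted(regions, key=lambda r: (r.chrom, r.start_bp)):
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, runs in by_chrom.items():
        current = runs[0]
        for nxt in runs[1:]:
            gap = np.arange(current.marker_indices[-1] + 1, nxt.marker_indices[0])
            mergeable = 0 < len(gap) <= max_gap_markers
            if mergeable:
                for m in gap:
                    col = g[:, m]
                    called = col != MISSING
                    # cases deviating from a single shared homozygous dosage
                    n_dev = min(
                        int(((col != 0) & called).sum()),
                        int(((col != 2) & called).sum()),
                    )
                    if n_dev > max_conflicting_cases:
                        mergeable = False
                        break
            if mergeable:
                current = SharedRegion(
                    chrom=chrom,
                    start_bp=current.start_bp,
                    end_bp=nxt.end_bp,
                    n_case_homozygous_snps=(
                        current.n_case_homozygous_snps + nxt.n_case_homozygous_snps
                    ),
                    marker_indices=np.concatenate(
                        [current.marker_indices, nxt.marker_indices]
                    ),
                    positions_bp=np.concatenate(
                        [current.positions_bp, nxt.positions_bp]
                    ),
                    shared_alleles=np.concatenate(
                        [current.shared_alleles, nxt.shared_alleles]
                    ),
                    envelope_start_bp=current.envelope_start_bp,
                    envelope_end_bp=nxt.envelope_end_bp,
                )
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return out


def control_hom_fraction(
    matrix: GenotypeMatrix,
    case_ids: list[str],
    control_ids: list[str],
    region: SharedRegion,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per region SNP: fraction of non-missing controls homozygous for the
    case allele.

    Returns (fractions, hom counts, non-missing counts); SNPs where every
    control is missing or the case allele is undetermined get NaN fractions
    (flagged in the log).  Also stores the fractions on the region.
    """
    g = matrix.rows(control_ids)[:, region.marker_indices]
    called = g != MISSING
    n_called = called.sum(axis=0)
    hom = np.zeros(len(region.marker_indices), dtype=int)
    for k, a in enumerate(region.shared_alleles):
        if a in (0, 2):
            hom[k] = int(((g[:, k] == a) & called[:, k]).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(
            (n_called > 0) & (region.shared_alleles >= 0),
            hom / np.maximum(n_called, 1),
            np.nan,
        )
    n_flagged = int(np.isnan(frac).sum())
    if n_flagged:
        logger.warning("%d region SNPs have undefined control fractions", n_flagged)
    region.control_hom_fraction_per_snp = frac
    return frac, hom, n_called


def refine_region(
    region: SharedRegion,
    control_hom_counts: np.ndarray,
    max_control_carriers: int,
    fractions: np.ndarray | None = None,
) -> SharedRegion:
    """Maximal sub-region whose every SNP has a control homozygote count
    strictly below ``max_control_carriers``.

    Among equally long qualifying runs the one with the smallest summed
    control fractions wins (counts stand in when fractions are absent).
    An empty result is returned as a zero-SNP region and logged.
    """
    counts = np.asarray(control_hom_counts)
    if len(counts) != len(region.marker_indices):
        raise ValueError("counts do not match region SNPs")
    qual = counts < max_control_carriers
    score = fractions if fractions is not None else counts.astype(float)
    best = None  # (length, -summed score, start, end)
    i, n = 0, len(qual)
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j < n and qual[j]:
            j += 1
        s = float(np.nansum(score[i:j]))
        key = (j - i, -s)
        if best is None or key > best[0]:
            best = (key, i, j)
        i = j
    if best is None:
        logger.warning("refine_region: no SNP qualifies below %d", max_control_carriers)
        return SharedRegion(
            chrom=region.chrom,
            start_bp=region.start_bp,
            end_bp=region.start_bp,
            n_case_homozygous_snps=0,
            marker_indices=region.marker_indices[:0],
            positions_bp=region.positions_bp[:0],
            shared_alleles=region.shared_alleles[:0],
        )
    _, i, j = best
    pos_slice = slice(i, j)
    frac = region.control_hom_fraction_per_snp
    return SharedRegion(
        chrom=region.chrom,
        start_bp=int(region.positions_bp[i]),
        end_bp=int(region.positions_bp[j - 1]),
        n_case_homozygous_snps=j - i,
        marker_indices=region.marker_indices[pos_slice],
        positions_bp=region.positions_bp[pos_slice],
        shared_alleles=region.shared_alleles[pos_slice],
        control_hom_fraction_per_snp=None if frac is None else frac[pos_slice],
        envelope_start_bp=(
            region.envelope_start_bp if i == 0 else int(region.positions_bp[i - 1]) + 1
        ),
        envelope_end_bp=(
            region.envelope_end_bp if j == n else int(region.positions_bp[j]) - 1
        ),
    )


# ---------------------------------------------------------------------------
# Recessive association scan
# ---------------------------------------------------------------------------

def recessive_assoc_scan(
    matrix: GenotypeMatrix,
    case_ids: list[str],
    control_ids: list[str],
    alpha: float = 0.01,
) -> AssocResult:
    """Per-marker two-sided Fisher exact test of homozygous-for-minor vs
    other, case vs control, with Bonferroni-adjusted significance."""
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control sets must be disjoint")
    g_case = matrix.rows(case_ids)
    g_ctrl = matrix.rows(control_ids)
    rows = []
    for m in range(matrix.n_markers):
        gc, gt = g_case[:, m], g_ctrl[:, m]
        cc, ct = gc[gc != MISSING], gt[gt != MISSING]
        if len(cc) + len(ct) == 0:
            logger.info("marker %s all-missing; skipped",
                        matrix.markers["marker_id"].iloc[m])
            continue
        pooled = np.concatenate([cc, ct])
        p_b = pooled.sum() / (2 * len(pooled))
        minor_hom = 2 if p_b <= 0.5 else 0
        a = int((cc == minor_hom).sum())
        b = len(cc) - a
        c = int((ct == minor_hom).sum())
        d = len(ct) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "marker_id": matrix.markers["marker_id"].iloc[m],
                "chrom": matrix.markers["chrom"].iloc[m],
                "pos": int(matrix.markers["pos"].iloc[m]),
                "case_hom_minor": a,
                "case_other": b,
                "control_hom_minor": c,
                "control_other": d,
                "p_value": float(min(p, 1.0)),
            }
        )
    table = pd.DataFrame(rows)
    n_tests = len(table)
    if n_tests:
        table["significant"] = table["p_value"] < alpha / n_tests
    return AssocResult(table=table, alpha=alpha, n_tests=n_tests)
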