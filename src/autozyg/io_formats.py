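"""Standard-format I/O: VCF, PED/MAP genotypes, FASTA, GFF3 transcript models.

All external coordinates are 1-based inclusive. Genotype dosages count copies
of ``allele_b`` and use ``MISSING`` (-1) for no-calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MISSING = -1

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "allele_a", "allele_b"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenotypeMatrix:
    """Animals x biallelic markers, dosages in {0, 1, 2, MISSING}.

    ``markers`` is a DataFrame with columns marker_id, chrom, pos, allele_a,
    allele_b; positions are strictly increasing within a chromosome.
    ``genotypes`` has shape (n_animals, n_markers) and counts allele_b copies.
    """

    animal_ids: list[str]
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.markers = self.markers.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        if self.genotypes.shape != (len(self.animal_ids), len(self.markers)):
            raise ValueError(
                f"genotype array {self.genotypes.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype dosages must be in {0,1,2,missing}")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError(f"marker positions not strictly increasing on {chrom}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def animal_index(self, animal_id: str) -> int:
        try:
            return self.animal_ids.index(animal_id)
        except ValueError:
            raise KeyError(f"unknown animal {animal_id!r}") from None

    def row(self, animal_id: str) -> np.ndarray:
        return self.genotypes[self.animal_index(animal_id)]

    def rows(self, animal_ids) -> np.ndarray:
        idx = [self.animal_index(a) for a in animal_ids]
        return self.genotypes[idx]

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            animal_ids=list(self.animal_ids),
            markers=self.markers.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[:, mask],
        )

    def chrom_marker_mask(self, chrom: str) -> np.ndarray:
        return (self.markers["chrom"] == chrom).to_numpy()


@dataclass
class VariantTable:
    """WGS SNV records with per-sample diploid genotypes and cohort labels.

    ``variants``: DataFrame with chrom, pos (1-based), ref, alt (tuple of alt
    alleles).  ``genotypes``: (n_variants, n_samples, 2) int8 allele indices,
    MISSING for no-call.  ``samples``: DataFrame sample_id, cohort with
    cohort in {case, herd, external}.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        if self.genotypes.shape[:2] != (len(self.variants), len(self.samples)):
            raise ValueError("genotype array shape inconsistent with table")
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must be diploid allele-index pairs")
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        for chrom, pos, ref, alt in zip(
            self.variants["chrom"], self.variants["pos"],
            self.variants["ref"], self.variants["alt"],
        ):
            if ref in alt:
                raise ValueError(f"ref == alt at {chrom}:{pos}")
        if not set(self.samples["cohort"]) <= {"case", "herd", "external"}:
            raise ValueError("cohort labels must be case/herd/external")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples["sample_id"])}
        return np.array([lookup[i] for i in ids], dtype=int)

    def cohort_ids(self, cohort: str) -> list[str]:
        return list(self.samples.loc[self.samples["cohort"] == cohort, "sample_id"])

    def subset(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            variants=self.variants.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[mask],
            samples=self.samples.copy(),
        )


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on a reference chromosome.

    ``exons`` are (start, end) 1-based inclusive pairs in transcript 5'->3'
    order (descending genomic coordinates for minus-strand transcripts).
    ``cds_start``/``cds_end`` are genomic bounds (start <= end).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 >= s2:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(f"exons of {self.transcript_id} not in transcript order")
        if not any(s <= self.cds_start <= e for s, e in self.exons) or not any(
            s <= self.cds_end <= e for s, e in self.exons
        ):
            raise ValueError("CDS bounds outside exon union")
        if self.cds_length % 3 != 0:
            raise FormatError(
                f"CDS length {self.cds_length} of {self.transcript_id} not divisible by 3"
            )

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    @property
    def tx_start(self) -> int:
        return self.exons_genomic[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons_genomic[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def cds_exon_pieces(self) -> list[tuple[int, int]]:
        """CDS-overlapping (start, end) pieces in transcript order."""
        pieces = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs <= ce:
                pieces.append((cs, ce))
        return pieces

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exon_pieces())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, cohorts: dict[str, str] | None = None) -> VariantTable:
    """Read a VCF 4.x with GT fields into a :class:`VariantTable`.

    ``cohorts`` maps sample_id -> cohort label; unlisted samples default to
    "herd".  Multiallelic records are retained (they are removed downstream
    by the cascade's biallelic filter, keeping stage counts meaningful).
    Phasing separators are accepted; phase is not retained.
    """
    cohorts = cohorts or {}
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vf.header.samples)
    rows, gts = [], []
    for rec in vf:
        alts = tuple(rec.alts or ())
        rows.append(
            {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alts}
        )
        pair_row = np.full((len(sample_ids), 2), MISSING, dtype=np.int8)
        for j, s in enumerate(sample_ids):
            gt = rec.samples[s].get("GT", (None, None))
            if gt is None:
                gt = (None, None)
            if len(gt) != 2:
                raise FormatError(
                    f"ploidy {len(gt)} != 2 at {rec.chrom}:{rec.pos} sample {s}"
                )
            pair = sorted(MISSING if a is None else a for a in gt)
            pair_row[j] = pair
        gts.append(pair_row)
    vf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    genotypes = (
        np.stack(gts) if gts else np.empty((0, len(sample_ids), 2), dtype=np.int8)
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": [cohorts.get(s, "herd") for s in sample_ids],
        }
    )
    return VariantTable(variants=variants, genotypes=genotypes, samples=samples)


def write_vcf(table: VariantTable, path, contigs: dict[str, int] | None = None) -> None:
    """Write a GT-only VCF 4.2, samples and records in stored order."""
    header = pysam.VariantHeader()
    seen = dict(contigs or {})
    for chrom in table.variants["chrom"]:
        seen.setdefault(chrom, None)
    for chrom, length in seen.items():
        if length:
            header.contigs.add(chrom, length=length)
        else:
            header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in table.sample_ids:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    for i in range(table.n_variants):
        rec = table.variants.iloc[i]
        vrec = out.new_record(
            contig=rec["chrom"],
            start=int(rec["pos"]) - 1,
            stop=int(rec["pos"]) - 1 + len(rec["ref"]),
            alleles=(rec["ref"], *rec["alt"]),
        )
        for j, s in enumerate(table.sample_ids):
            a, b = table.genotypes[i, j]
            vrec.samples[s]["GT"] = (
                None if a == MISSING else int(a),
                None if b == MISSING else int(b),
            )
        out.write(vrec)
    out.close()


def read_cohorts_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["cohort"]))


def write_cohorts_tsv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def read_genotype_matrix(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK-style text PED/MAP into a dosage matrix.

    allele_b (the counted allele) is the minor allele computed over the file,
    ties broken lexicographically; "0 0" allele pairs are missing.
    """
    markers = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos"],
        dtype={"chrom": str, "marker_id": str},
    )
    n_markers = len(markers)
    animal_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            alleles = parts[6:]
            if len(alleles) != 2 * n_markers:
                raise FormatError(
                    f"{ped_path} line {ln}: {len(alleles)} alleles, "
                    f"expected {2 * n_markers}"
                )
            animal_ids.append(parts[1])
            allele_rows.append(alleles)
    alleles = np.array(allele_rows, dtype="U8").reshape(len(animal_ids), n_markers, 2)

    allele_a = np.empty(n_markers, dtype="U8")
    allele_b = np.empty(n_markers, dtype="U8")
    genotypes = np.full((len(animal_ids), n_markers), MISSING, dtype=np.int8)
    for m in range(n_markers):
        col = alleles[:, m, :]
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise FormatError(f"marker {markers['marker_id'][m]} has >2 alleles")
        if len(uniq) == 0:
            allele_a[m], allele_b[m] = "A", "B"
            continue
        if len(uniq) == 1:
            allele_a[m], allele_b[m] = uniq[0], "0"
        else:
            order = np.lexsort((uniq, counts))  # minor first, ties lexicographic
            allele_b[m], allele_a[m] = uniq[order[0]], uniq[order[1]]
        called = (col != "0").all(axis=1)
        genotypes[called, m] = (col[called] == allele_b[m]).sum(axis=1)

    markers_df = pd.DataFrame(
        {
            "marker_id": markers["marker_id"],
            "chrom": markers["chrom"],
            "pos": markers["pos"].astype(int),
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    return GenotypeMatrix(animal_ids=animal_ids, markers=markers_df, genotypes=genotypes)


def write_genotype_matrix(matrix: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP text; missing dosage becomes the "0 0" allele pair."""
    with open(map_path, "w") as fh:
        for _, m in matrix.markers.iterrows():
            fh.write(f"{m['chrom']}\t{m['marker_id']}\t0\t{m['pos']}\n")
    a = matrix.markers["allele_a"].to_numpy()
    b = matrix.markers["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(matrix.animal_ids):
            g = matrix.genotypes[i]
            pairs = []
            for m in range(matrix.n_markers):
                if g[m] == MISSING:
                    pairs.append("0 0")
                else:
                    pairs.append(
                        f"{a[m] if g[m] < 2 else b[m]} {b[m] if g[m] > 0 else a[m]}"
                    )
            fh.write(f"FAM {animal} 0 0 0 -9 " + " ".join(pairs) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into name -> upper-case sequence; duplicate names error."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 transcripts
# ---------------------------------------------------------------------------

def read_transcripts(gff_path) -> list[TranscriptModel]:
    """Assemble :class:`TranscriptModel`s from a GFF3 with mRNA/exon/CDS rows.

    Minus-strand exon order is normalized to the transcript's 5'->3'.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", force=True
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons or not cds:
            raise FormatError(f"transcript {mrna.id} lacks exon or CDS features")
        exons = sorted(exons)
        if mrna.strand == "-":
            exons = exons[::-1]
        models.append(
            TranscriptModel(
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_start=min(s for s, _ in cds),
                cds_end=max(e for _, e in cds),
            )
        )
    return models


def write_transcripts(models: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in models:
            fh.write(
                f"{t.chrom}\t.\tmRNA\t{t.tx_start}\t{t.tx_end}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id}\n"
            )
            for s, e in t.exons_genomic:
                fh.write(
                    f"{t.chrom}\t.\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f"Parent={t.transcript_id}\n"
                )
            for s, e in t.cds_exon_pieces() if t.strand == "+" else sorted(
                t.cds_exon_pieces()
            ):
                fh.write(
                    f"{t.chrom}\t.\tCDS\t{s}\t{e}\t.\t{t.strand}\t0\t"
                    f"Parent={t.transcript_id}\n"
                )
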