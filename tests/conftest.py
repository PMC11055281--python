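import numpy as np
import pandas as pd
import pytest

from autozyg.herdsim import SimConfig, simulate_herd
from autozyg.io_formats import GenotypeMatrix, TranscriptModel, VariantTable


@pytest.fixture(scope="session")
def herd():
    """One default desk-scale simulated herd, shared across tests."""
    return simulate_herd(SimConfig(seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_matrix(genotypes, chrom="1", spacing=10_000, animal_ids=None):
    """GenotypeMatrix from a raw (animals x markers) dosage array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_animals, n_markers = g.shape
    ids = animal_ids or [f"A{i + 1}" for i in range(n_animals)]
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j + 1}" for j in range(n_markers)],
            "chrom": chrom,
            "pos": np.arange(1, n_markers + 1) * spacing,
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    return GenotypeMatrix(animal_ids=ids, markers=markers, genotypes=g)


def make_variant_table(records, samples):
    """VariantTable from [(chrom, pos, ref, alts, [gt pairs])] and
    [(sample_id, cohort)] lists."""
    variants = pd.DataFrame(
        [
            {"chrom": c, "pos": p, "ref": r, "alt": tuple(a)}
            for c, p, r, a, _ in records
        ],
        columns=["chrom", "pos", "ref", "alt"],
    )
    gts = np.array([g for *_, g in records], dtype=np.int8)
    if gts.size == 0:
        gts = np.empty((0, len(samples), 2), dtype=np.int8)
    sample_df = pd.DataFrame(samples, columns=["sample_id", "cohort"])
    return VariantTable(variants=variants, genotypes=gts, samples=sample_df)


def make_transcript(exons, strand="+", chrom="chr", transcript_id="tx",
                    cds_start=None, cds_end=None):
    genomic = sorted(exons)
    if strand == "-":
        exons = genomic[::-1]
    else:
        exons = genomic
    return TranscriptModel(
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start if cds_start is not None else genomic[0][0],
        cds_end=cds_end if cds_end is not None else genomic[-1][1],
    )


def random_coding_transcript(rng, n_exons=None, chrom="chr"):
    """Random fully-coding multi-exon transcript plus its genome dict."""
    from autozyg.herdsim import STOP_CODONS

    n_exons = n_exons or int(rng.integers(1, 6))
    codon_pool = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS and a + b + c != "ATG"
    ]
    n_codons = int(rng.integers(max(4, n_exons), 60))
    cds = "ATG" + "".join(rng.choice(codon_pool, n_codons - 2)) + str(
        rng.choice(sorted(STOP_CODONS))
    )
    # split CDS into n_exons non-empty pieces
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, len(cds)), n_exons - 1, replace=False))
    else:
        cuts = []
    pieces = np.split(np.frombuffer(cds.encode(), dtype=np.uint8), cuts)
    strand = "+" if rng.random() < 0.5 else "-"
    plus_pieces = pieces if strand == "+" else pieces[::-1]
    intron = lambda: "".join(rng.choice(list("ACGT"), int(rng.integers(20, 80))))
    seq_parts = [intron()]
    exons = []
    pos = len(seq_parts[0]) + 1
    for pc in plus_pieces:
        piece = pc.tobytes().decode()
        if strand == "-":
            from autozyg.assay_rflp import revcomp

            piece = revcomp(piece)
        exons.append((pos, pos + len(piece) - 1))
        seq_parts.append(piece)
        gap = intron()
        seq_parts.append(gap)
        pos += len(piece) + len(gap)
    genome = {chrom: "".join(seq_parts)}
    tx = make_transcript(exons, strand=strand, chrom=chrom)
    return tx, genome, cds
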