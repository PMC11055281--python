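"""Mini SNV consequence annotator on transcript models.

Classifies a single-nucleotide variant against one transcript by direct
codon comparison on the assembled CDS, emits simplified HGVS-style c./p.
labels, the truncated protein fraction for premature stops, and applies the
50-nucleotide rule for nonsense-mediated decay (NMD): a premature stop is an
NMD candidate when it lies more than 50 nt upstream of the last exon-exon
junction of the transcript.

Precedence: exonic SNVs get their coding classification; ``splice_region``
is assigned to intronic positions within 2 bp of a junction, and to exonic
positions within the 3 bp junction flank only when the coding change is
synonymous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

logger = logging.getLogger(__name__)

SPLICE_INTRON_BP = 2
SPLICE_EXON_FLANK_BP = 3

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AnnotationError(ValueError):
    pass


@dataclass
class ConsequenceCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    effect: str
    cds_position: int | None = None
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    protein_length_aa: int | None = None
    truncated_fraction: float | None = None
    nmd_candidate: bool | None = None
    exon_index: int | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None


def call_to_row(call: ConsequenceCall) -> dict:
    return {k: getattr(call, k) for k in ConsequenceCall.__dataclass_fields__}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_cds(transcript, genome: dict[str, str]) -> str:
    """Concatenated CDS in transcript orientation, validated.

    Must start with ATG, end with a stop codon, and contain no internal stop
    in the reference frame.
    """
    chrom_seq = genome[transcript.chrom]
    pieces = []
    # ascending genomic order; the whole concatenation is reverse-complemented
    # for minus-strand transcripts
    for s, e in sorted(transcript.cds_exon_pieces()):
        if e > len(chrom_seq):
            raise AnnotationError(
                f"{transcript.transcript_id}: CDS extends past reference end"
            )
        pieces.append(chrom_seq[s - 1 : e])
    cds = "".join(pieces)
    if transcript.strand == "-":
        cds = _revcomp(cds)
    if not cds.startswith("ATG"):
        raise AnnotationError(f"{transcript.transcript_id}: CDS does not start ATG")
    protein = str(Seq(cds).translate())
    if not protein.endswith("*"):
        raise AnnotationError(f"{transcript.transcript_id}: CDS lacks terminal stop")
    if "*" in protein[:-1]:
        raise AnnotationError(
            f"{transcript.transcript_id}: internal stop in reference CDS"
        )
    return cds


def _genomic_to_cds(transcript, pos: int) -> int | None:
    """1-based CDS coordinate of a genomic position, or None outside CDS."""
    offset = 0
    for s, e in transcript.cds_exon_pieces():
        if s <= pos <= e:
            within = (pos - s) if transcript.strand == "+" else (e - pos)
            return offset + within + 1
        offset += e - s + 1
    return None


def _exon_index(transcript, pos: int) -> int | None:
    for i, (s, e) in enumerate(transcript.exons, start=1):
        if s <= pos <= e:
            return i
    return None


def _intron_distance(transcript, pos: int) -> int:
    """Bases into the intron from its nearest exon boundary (1 = first
    intronic base); only meaningful for intronic positions."""
    genomic = transcript.exons_genomic
    for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
        if e1 < pos < s2:
            return min(pos - e1, s2 - pos)
    raise AnnotationError("position is not intronic")


def _in_exon_junction_flank(transcript, pos: int, flank: int) -> bool:
    """Is an exonic position within ``flank`` bases of an exon-exon
    junction edge (terminal transcript ends do not count)?"""
    genomic = transcript.exons_genomic
    for k, (s, e) in enumerate(genomic):
        if s <= pos <= e:
            near_left = k > 0 and (pos - s) < flank
            near_right = k < len(genomic) - 1 and (e - pos) < flank
            return near_left or near_right
    return False


def annotate_snv(variant, transcript, genome: dict[str, str]) -> ConsequenceCall:
    """Annotate one SNV (chrom, pos, ref, alt) against a transcript.

    The reference allele must match the genome (strand-aware checks are done
    on the plus strand, where VCF alleles live).
    """
    chrom, pos, ref, alt = variant
    if len(ref) != 1 or len(alt) != 1:
        raise AnnotationError("annotate_snv handles single-base SNVs only")
    base = ConsequenceCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        transcript_id=transcript.transcript_id, effect="intergenic",
    )
    if chrom != transcript.chrom or not (transcript.tx_start <= pos <= transcript.tx_end):
        return base
    exon_idx = _exon_index(transcript, pos)
    if exon_idx is None:  # intronic
        base.effect = (
            "splice_region"
            if _intron_distance(transcript, pos) <= SPLICE_INTRON_BP
            else "intronic"
        )
        return base
    base.exon_index = exon_idx
    cds_pos = _genomic_to_cds(transcript, pos)
    if cds_pos is None:
        base.effect = "utr"
        return base

    if genome[chrom][pos - 1] != ref:
        raise AnnotationError(
            f"reference mismatch at {chrom}:{pos}: genome has "
            f"{genome[chrom][pos - 1]}, variant says {ref}"
        )
    cds = build_cds(transcript, genome)
    ref_cds = ref if transcript.strand == "+" else _revcomp(ref)
    alt_cds = alt if transcript.strand == "+" else _revcomp(alt)
    if cds[cds_pos - 1] != ref_cds:
        raise AnnotationError("CDS/reference inconsistency")

    codon_idx = (cds_pos - 1) // 3 + 1
    within = (cds_pos - 1) % 3
    codon = cds[3 * (codon_idx - 1) : 3 * codon_idx]
    mutated = codon[:within] + alt_cds + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    protein_length = len(cds) // 3 - 1  # excluding the stop
    n_codons = len(cds) // 3

    if codon_idx == 1 and mutated != "ATG":
        effect = "start_lost"
    elif codon_idx == n_codons:  # reference stop codon
        effect = "synonymous" if alt_aa == "*" else "stop_lost"
    elif alt_aa == "*":
        effect = "nonsense"
    elif alt_aa == ref_aa:
        effect = "synonymous"
    else:
        effect = "missense"

    if effect == "synonymous" and _in_exon_junction_flank(
        transcript, pos, SPLICE_EXON_FLANK_BP
    ):
        # junction-flank synonymous changes may still perturb splicing
        effect = "splice_region"

    base.effect = effect
    base.cds_position = cds_pos
    base.codon_index = codon_idx
    base.ref_aa = ref_aa
    base.alt_aa = alt_aa
    base.protein_length_aa = protein_length
    base.hgvs_c = f"c.{cds_pos}{ref_cds}>{alt_cds}"
    aa3 = seq3(ref_aa) if ref_aa != "*" else "*"
    alt3 = "*" if alt_aa == "*" else seq3(alt_aa)
    base.hgvs_p = f"p.{aa3}{codon_idx}{alt3}"
    if effect == "nonsense":
        base.truncated_fraction = (protein_length - codon_idx + 1) / protein_length
        base.nmd_candidate = nmd_predict(base, transcript)
    return base


def nmd_predict(call: ConsequenceCall, transcript) -> bool:
    """50-nt rule: True iff the premature stop starts more than 50 nt
    upstream of the last exon-exon junction (transcript coordinates).

    Single-exon transcripts have no junction and never qualify.
    """
    if call.effect != "nonsense":
        raise ValueError("nmd_predict applies to nonsense calls")
    if transcript.n_exons < 2:
        return False
    exon_lengths = [abs(e - s) + 1 for s, e in transcript.exons]
    last_junction_tx = sum(exon_lengths[:-1])  # tx coord of junction 5' base
    # transcript coordinate of the first base of the premature stop codon
    cds_tx_offset = _cds_tx_offset(transcript)
    stop_tx = cds_tx_offset + 3 * (call.codon_index - 1) + 1
    return (last_junction_tx - stop_tx) > 50


def _cds_tx_offset(transcript) -> int:
    """Transcript-coordinate offset of the CDS start (0 for fully coding)."""
    offset = 0
    cds_first = (
        transcript.cds_start if transcript.strand == "+" else transcript.cds_end
    )
    for s, e in transcript.exons:
        gs, ge = min(s, e), max(s, e)
        if gs <= cds_first <= ge:
            offset += (cds_first - gs) if transcript.strand == "+" else (ge - cds_first)
            return offset
        offset += ge - gs + 1
    raise AnnotationError("CDS start not inside any exon")
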