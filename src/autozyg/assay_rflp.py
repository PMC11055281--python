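"""In-silico PCR and restriction-digest (RFLP) genotyping-assay design.

The assay checker answers one question: do the wild-type and variant
amplicons produce distinguishable restriction-fragment patterns under a
given enzyme?  Primer matching is exact (this is a design checker, not a
thermodynamic simulator); enzyme specifications are data, with IUPAC
recognition strings and signed cut offsets measured from the 3' end of the
recognition site, so Type IIS enzymes that cut downstream are expressible.

One top-strand cut is produced per site: plus-strand (and palindromic)
sites cut at ``3'-end + cut_offset_top``; minus-only sites cut at
``5'-boundary - cut_offset_bottom``.  With centrally-blunt offsets
(both = -len(recognition)//2) digestion is exactly strand-symmetric.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class AssayError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern:
        bases = ambiguous_dna_values.get(ch)
        if bases is None:
            raise AssayError(f"invalid IUPAC base {ch!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=(" + "".join(parts) + "))")


@dataclass
class EnzymeSpec:
    """Restriction enzyme as data: IUPAC recognition plus signed cut offsets
    from the recognition 3' end (negative = inside the site)."""

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise AssayError("recognition sequence must be non-empty")
        self.recognition = self.recognition.upper()
        _iupac_regex(self.recognition)  # validates

    @classmethod
    def blunt(cls, name: str, recognition: str) -> "EnzymeSpec":
        off = -(len(recognition) // 2)
        return cls(name, recognition, off, off)


@dataclass
class Amplicon:
    """PCR product: 1-based inclusive template coordinates; the sequence
    begins with the forward primer and ends with the reverse complement of
    the reverse primer."""

    template_name: str
    start_bp: int
    end_bp: int
    sequence: str
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        if not self.sequence.startswith(self.fwd_primer):
            raise AssayError("amplicon must begin with the forward primer")
        if not self.sequence.endswith(revcomp(self.rev_primer)):
            raise AssayError("amplicon must end with revcomp(reverse primer)")
        if len(self.sequence) != self.end_bp - self.start_bp + 1:
            raise AssayError("amplicon length inconsistent with coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


def in_silico_pcr(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    max_product: int = 5000,
    template_name: str = "template",
) -> list[Amplicon]:
    """Exact-match amplification: forward primer on the plus strand, reverse
    primer binding the minus strand (its reverse complement on the plus
    strand) downstream of it; products longer than ``max_product`` are not
    reported."""
    if len(fwd_primer) < 10 or len(rev_primer) < 10:
        raise AssayError("primers must be at least 10 bases")
    template = template.upper()
    fwd = fwd_primer.upper()
    rev_site = revcomp(rev_primer.upper())
    fwd_hits = [m.start() for m in re.finditer(f"(?={re.escape(fwd)})", template)]
    rev_hits = [m.start() for m in re.finditer(f"(?={re.escape(rev_site)})", template)]
    products = []
    for f in fwd_hits:
        for r in rev_hits:
            if r < f + len(fwd):
                continue  # reverse site must lie downstream of the forward primer
            end = r + len(rev_site)
            if end - f > max_product:
                continue
            products.append(
                Amplicon(
                    template_name=template_name,
                    start_bp=f + 1,
                    end_bp=end,
                    sequence=template[f:end],
                    fwd_primer=fwd,
                    rev_primer=rev_primer.upper(),
                )
            )
    return products


def digest(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Top-strand fragment lengths, left to right, after cutting at every
    recognition site on either strand.

    A site whose cut position falls outside the sequence is skipped with a
    warning (end-proximal site); with no site the whole sequence is one
    fragment.
    """
    seq = sequence.upper()
    n = len(seq)
    fwd_re = _iupac_regex(enzyme.recognition)
    rev_re = _iupac_regex(revcomp(enzyme.recognition))
    w = len(enzyme.recognition)
    plus = {m.start() for m in fwd_re.finditer(seq)}
    minus = {m.start() for m in rev_re.finditer(seq)}
    cuts = set()
    for s in sorted(plus):
        c = s + w + enzyme.cut_offset_top
        if 0 < c < n:
            cuts.add(c)
        else:
            logger.warning("%s site at %d cuts outside sequence; skipped",
                           enzyme.name, s + 1)
    for s in sorted(minus - plus):  # palindromic sites already handled
        c = s - enzyme.cut_offset_bottom
        if 0 < c < n:
            cuts.add(c)
        else:
            logger.warning("%s minus-strand site at %d cuts outside sequence; skipped",
                           enzyme.name, s + 1)
    bounds = [0] + sorted(cuts) + [n]
    return [b - a for a, b in zip(bounds, bounds[1:])]


@dataclass
class RflpReport:
    distinguishable: bool
    fragments_ref: list[int]
    fragments_alt: list[int]
    heterozygote_pattern: list[int]


def design_rflp_check(
    amplicon_ref: Amplicon, amplicon_alt: Amplicon, enzyme: EnzymeSpec
) -> RflpReport:
    """Do the two allelic amplicons digest into different fragment multisets?

    The predicted heterozygote pattern is the union of both multisets."""
    if amplicon_ref.sequence == amplicon_alt.sequence:
        raise AssayError("allelic amplicons are identical")
    frags_ref = digest(amplicon_ref.sequence, enzyme)
    frags_alt = digest(amplicon_alt.sequence, enzyme)
    het = sorted(frags_ref + frags_alt)
    return RflpReport(
        distinguishable=sorted(frags_ref) != sorted(frags_alt),
        fragments_ref=frags_ref,
        fragments_alt=frags_alt,
        heterozygote_pattern=het,
    )


def design_causal_assay(
    genome: dict[str, str],
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    primer_len: int = 20,
    primer_gap: int = 100,
    min_recognition: int = 6,
    max_recognition: int = 12,
) -> tuple[Amplicon, Amplicon, EnzymeSpec]:
    """Design a synthetic allele-discriminating digest around a known SNV.

    Primers are exact reference substrings flanking the variant; the enzyme
    recognizes a reference window containing the variant base, chosen (and
    widened up to ``max_recognition``) until it is unique in the amplicon
    and absent from the variant amplicon, so the alternative allele destroys
    the only site.
    """
    seq = genome[chrom]
    if seq[pos - 1] != ref:
        raise AssayError("reference does not carry the stated ref allele")
    f_start = pos - primer_gap - primer_len - 1
    r_start = pos + primer_gap
    if f_start < 0 or r_start + primer_len > len(seq):
        raise AssayError("variant too close to the template end for this design")
    fwd = seq[f_start : f_start + primer_len]
    rev = revcomp(seq[r_start : r_start + primer_len])
    products = in_silico_pcr(seq, fwd, rev, max_product=2 * (primer_gap + primer_len) + 10)
    amp_ref = next(
        (a for a in products if a.start_bp <= pos <= a.end_bp), None
    )
    if amp_ref is None:
        raise AssayError("primers do not amplify across the variant")
    alt_seq = (
        amp_ref.sequence[: pos - amp_ref.start_bp]
        + alt
        + amp_ref.sequence[pos - amp_ref.start_bp + 1 :]
    )
    amp_alt = Amplicon(
        template_name=amp_ref.template_name + "_alt",
        start_bp=amp_ref.start_bp,
        end_bp=amp_ref.end_bp,
        sequence=alt_seq,
        fwd_primer=amp_ref.fwd_primer,
        rev_primer=amp_ref.rev_primer,
    )
    var_off = pos - amp_ref.start_bp  # 0-based in amplicon
    for w in range(min_recognition, max_recognition + 1):
        for lead in range(w):
            s = var_off - lead
            if s < 0 or s + w > len(amp_ref.sequence):
                continue
            recog = amp_ref.sequence[s : s + w]
            n_ref = _count_sites(amp_ref.sequence, recog)
            n_alt = _count_sites(amp_alt.sequence, recog)
            if n_ref == 1 and n_alt == 0:
                return amp_ref, amp_alt, EnzymeSpec.blunt("synthetic_assay", recog)
    raise AssayError("no discriminating recognition window found")


def _count_sites(seq: str, recog: str) -> int:
    fwd = len(_iupac_regex(recog).findall(seq))
    if revcomp(recog) == recog:
        return fwd
    return fwd + len(_iupac_regex(revcomp(recog)).findall(seq))
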