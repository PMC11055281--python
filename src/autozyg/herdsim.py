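"""Forward simulator for a closed beef herd segregating a de novo recessive
nonsense allele.

The simulator emulates the statistical structure the mapping analysis relies
on: a single founder bull introduces the causal allele; line breeding over a
few generations puts him on both parental paths of late matings, so
homozygous (affected) calves appear; SNP-array haplotypes descend from
founder haplotypes with Haldane (Poisson, no-interference) recombination; the
causal allele rides one unique founder haplotype, creating a shared-descent
homozygous block in affected animals.  WGS variant tables add an independent
biallelic background plus the planted causal nonsense SNV, with case / herd /
external cohort labels.  Ground truth (causal genotypes, phase, haplotype
descent) is retained for tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, TranscriptModel, VariantTable

logger = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])
STOP_CODONS = {"TAA", "TAG", "TGA"}


class ConfigurationError(ValueError):
    """Raised for impossible or inconsistent simulation configurations."""


@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None
    dam: str | None
    sex: str  # 'M' or 'F'
    generation: int


@dataclass
class Pedigree:
    """Acyclic pedigree; parents precede offspring in generation order."""

    individuals: list[Individual]

    def __post_init__(self) -> None:
        self._by_id = {ind.id: ind for ind in self.individuals}
        if len(self._by_id) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        self.validate()

    def validate(self) -> None:
        for ind in self.individuals:
            for pid, want in ((ind.sire, "M"), (ind.dam, "F")):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise ValueError(f"{ind.id}: unknown parent {pid}")
                if parent.sex != want:
                    raise ValueError(f"{ind.id}: parent {pid} has wrong sex")
                if parent.generation >= ind.generation:
                    raise ValueError(f"{ind.id}: parent {pid} does not precede it")

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._by_id

    def __getitem__(self, animal_id: str) -> Individual:
        return self._by_id[animal_id]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def generation(self, g: int) -> list[Individual]:
        return [ind for ind in self.individuals if ind.generation == g]

    @property
    def n_generations(self) -> int:
        return max(ind.generation for ind in self.individuals)

    def ancestors(self, animal_id: str) -> set[str]:
        out: set[str] = set()
        stack = [animal_id]
        while stack:
            ind = self._by_id[stack.pop()]
            for pid in (ind.sire, ind.dam):
                if pid is not None and pid not in out:
                    out.add(pid)
                    stack.append(pid)
        return out

    def descendants(self, animal_id: str) -> set[str]:
        children: dict[str, list[str]] = {}
        for ind in self.individuals:
            for pid in (ind.sire, ind.dam):
                if pid is not None:
                    children.setdefault(pid, []).append(ind.id)
        out: set[str] = set()
        stack = [animal_id]
        while stack:
            for c in children.get(stack.pop(), []):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "sire": [i.sire or "0" for i in self.individuals],
                "dam": [i.dam or "0" for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "generation": [i.generation for i in self.individuals],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str)
        inds = [
            Individual(
                id=r["id"],
                sire=None if r["sire"] == "0" else r["sire"],
                dam=None if r["dam"] == "0" else r["dam"],
                sex=r.get("sex", "M"),
                generation=int(r.get("generation", 0)),
            )
            for _, r in df.iterrows()
        ]
        return cls(inds)


@dataclass
class SimConfig:
    """Desk-scale study design (scaled from 95,256 markers / 721 animals /
    147 sequenced; see docs/methods.md for the scaling rationale)."""

    n_founders: int = 40
    n_generations: int = 5
    n_matings_per_generation: int = 21
    n_offspring_per_mating: int = 2
    chromosomes: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("1", 300, 10_000_000),
            ("2", 300, 10_000_000),
            ("3", 300, 10_000_000),
        ]
    )
    causal_locus: tuple[str, int] = ("2", 5_000_000)
    founder_carrier_id: str = "F001"
    marker_freq_low: float = 0.05   # allele_b frequency ~ Uniform(low, high)
    marker_freq_high: float = 0.95
    # cM/Mb, Haldane model.  Desk chromosomes are physically compressed
    # (10 Mb standing in for ~50-100 Mb), so the rate is scaled up to keep a
    # realistic ~1 Morgan map length per chromosome and haplotype decay
    # comparable to a real herd.
    recombination_rate: float = 10.0
    genotyping_error_rate: float = 0.001
    missing_rate: float = 0.005
    n_external_samples: int = 50
    n_wgs_background_variants: int = 5000
    n_wgs_herd_controls: int = 35
    n_sequenced_cases: int = 2
    line_mating_fraction: float = 0.8
    min_affected_last_gen: int = 4
    max_gene_drop_attempts: int = 500
    low_hom_window_bp: int = 1_500_000
    # allele_b frequency of markers inside the window around the causal
    # locus; the causal haplotype carries allele_b there.  Rare-ish tag
    # alleles reproduce the low control homozygosity for case alleles that
    # characterizes the mapped region of this study design.
    causal_window_freq_low: float = 0.05
    causal_window_freq_high: float = 0.30
    multiallelic_fraction: float = 0.02
    wgs_missing_rate: float = 0.01
    external_evidence_rate: float = 0.9
    glycogen_affected_mean: float = 189.3
    glycogen_affected_sd: float = 7.4
    glycogen_unaffected_mean: float = 101.0
    glycogen_unaffected_sd: float = 6.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("genotyping_error_rate", "missing_rate", "wgs_missing_rate",
                     "multiallelic_fraction", "external_evidence_rate",
                     "line_mating_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} not in [0,1]")
        for name in ("n_founders", "n_matings_per_generation",
                     "n_offspring_per_mating", "n_external_samples",
                     "n_wgs_background_variants", "n_sequenced_cases"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        if self.n_generations > 0 and self.n_founders < 2:
            raise ConfigurationError("matings require at least 2 founders")
        if not 0 < self.marker_freq_low < self.marker_freq_high < 1:
            raise ConfigurationError("marker frequency bounds invalid")
        chroms = {c for c, _, _ in self.chromosomes}
        cc, cp = self.causal_locus
        if cc not in chroms:
            raise ConfigurationError(f"causal chromosome {cc!r} not simulated")
        length = next(l for c, _, l in self.chromosomes if c == cc)
        if not 1 <= cp <= length:
            raise ConfigurationError("causal locus outside its chromosome")

    def chrom_length(self, chrom: str) -> int:
        return next(l for c, _, l in self.chromosomes if c == chrom)


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig, seed: int | None = None) -> Pedigree:
    """Multi-generation line-bred herd descending from one founder bull.

    The designated founder sires a share of every generation-1 mating; in
    later generations a fraction ``line_mating_fraction`` of sires and dams
    are drawn from his descendants, guaranteeing matings with the founder on
    both parental paths from generation 2 onward (the topology that permits
    homozygous affected offspring).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    founders = [
        Individual(f"F{i + 1:03d}", None, None, "M" if i % 2 == 0 else "F", 0)
        for i in range(config.n_founders)
    ]
    if config.founder_carrier_id not in {f.id for f in founders}:
        raise ConfigurationError(
            f"founder_carrier_id {config.founder_carrier_id!r} not among founders"
        )
    if config.n_generations > 0:
        carrier = next(f for f in founders if f.id == config.founder_carrier_id)
        if carrier.sex != "M":
            raise ConfigurationError("founder carrier must be a male (herd bull)")

    individuals = list(founders)
    line: set[str] = {config.founder_carrier_id}

    for g in range(1, config.n_generations + 1):
        prior = [i for i in individuals if i.generation < g]
        males = [i for i in prior if i.sex == "M"]
        females = [i for i in prior if i.sex == "F"]
        if not males or not females:
            raise ConfigurationError("cannot mate: missing one sex")
        line_males = [i for i in males if i.id in line]
        line_females = [i for i in females if i.id in line]
        offspring: list[Individual] = []
        for m in range(config.n_matings_per_generation):
            use_line_sire = line_males and (
                rng.random() < config.line_mating_fraction
            )
            use_line_dam = line_females and (
                rng.random() < config.line_mating_fraction
            )
            if g >= 2 and m == 0 and line_males and line_females:
                use_line_sire = use_line_dam = True  # guarantee line x line
            sire = (
                line_males[rng.integers(len(line_males))]
                if use_line_sire
                else males[rng.integers(len(males))]
            )
            dam = (
                line_females[rng.integers(len(line_females))]
                if use_line_dam
                else females[rng.integers(len(females))]
            )
            for k in range(config.n_offspring_per_mating):
                child = Individual(
                    id=f"G{g}A{m * config.n_offspring_per_mating + k + 1:03d}",
                    sire=sire.id,
                    dam=dam.id,
                    sex="M" if rng.random() < 0.5 else "F",
                    generation=g,
                )
                offspring.append(child)
                if sire.id in line or dam.id in line:
                    line.add(child.id)
        individuals.extend(offspring)

    ped = Pedigree(individuals)
    if config.n_generations >= 2:
        found = any(
            ind.sire in line_anc and ind.dam in line_anc
            for ind in ped.individuals
            if ind.sire and ind.dam
            for line_anc in [
                ped.descendants(config.founder_carrier_id)
                | {config.founder_carrier_id}
            ]
        )
        if not found:
            raise ConfigurationError(
                "no mating with the founder on both parental paths; "
                "increase line_mating_fraction or matings per generation"
            )
    return ped


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------

def gene_drop(pedigree: Pedigree, causal_founder: str, seed: int) -> dict[str, int]:
    """Drop one causal allele from the founder through the pedigree.

    The founder is heterozygous (one copy); every other founder carries none;
    each meiosis transmits either parental allele with probability 1/2.
    Returns animal -> causal allele count in {0, 1, 2}.
    """
    return {a: g[0] + g[1] for a, g in
            _gene_drop_alleles(pedigree, causal_founder, seed).items()}


def _gene_drop_alleles(
    pedigree: Pedigree, causal_founder: str, seed: int
) -> dict[str, tuple[int, int]]:
    """Per-animal (paternal, maternal) causal allele pair."""
    if causal_founder not in pedigree:
        raise KeyError(f"unknown founder {causal_founder!r}")
    rng = np.random.default_rng(seed)
    alleles: dict[str, tuple[int, int]] = {}
    for ind in pedigree.individuals:  # generation order by construction
        if ind.sire is None and ind.dam is None:
            alleles[ind.id] = (1, 0) if ind.id == causal_founder else (0, 0)
        else:
            pat = alleles[ind.sire][rng.integers(2)] if ind.sire else 0
            mat = alleles[ind.dam][rng.integers(2)] if ind.dam else 0
            alleles[ind.id] = (pat, mat)
    return alleles


# ---------------------------------------------------------------------------
# Haplotype simulation
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeMap:
    chrom: str
    marker_ids: list[str]
    positions: np.ndarray  # 1-based bp, strictly increasing
    allele_a: np.ndarray   # letters
    allele_b: np.ndarray
    freq_b: np.ndarray     # population frequency of allele_b


@dataclass
class HaplotypeSet:
    """Phased ground truth: alleles, founder-haplotype descent, causal phase.

    ``haplotypes[chrom]``: (n_animals, 2, n_markers) int8 allele_b indicator.
    ``origins[chrom]``: same shape, index of the founder haplotype each
    marker allele descends from (haplotype 2i/2i+1 of founder i).
    ``causal_on_hap``: (n_animals, 2) bool, True where the animal's
    paternal/maternal copy of the causal chromosome carries the causal allele.
    """

    animal_ids: list[str]
    maps: dict[str, ChromosomeMap]
    haplotypes: dict[str, np.ndarray]
    origins: dict[str, np.ndarray]
    causal_chrom: str
    causal_on_hap: np.ndarray
    founder_causal_haplotype: np.ndarray  # allele_b indicator on causal chrom
    founder_causal_hap_index: int

    def animal_index(self, animal_id: str) -> int:
        return self.animal_ids.index(animal_id)


def build_marker_maps(config: SimConfig, seed: int | None = None) -> dict[str, ChromosomeMap]:
    """Evenly spaced, jittered marker maps with Uniform(low, high) allele_b
    frequencies and random (distinct) allele letters."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 11])
    )
    maps: dict[str, ChromosomeMap] = {}
    for chrom, n_markers, length in config.chromosomes:
        spacing = length / (n_markers + 1)
        base = (np.arange(1, n_markers + 1) * spacing).astype(np.int64)
        jitter = rng.integers(-int(spacing // 4), int(spacing // 4) + 1, n_markers)
        pos = np.sort(base + jitter)
        pos = np.maximum.accumulate(pos + np.arange(n_markers))  # strictly increasing
        pos = np.clip(pos, 1, length)
        # avoid colliding with the causal locus
        cc, cp = config.causal_locus
        if chrom == cc:
            pos[pos == cp] += 1
        a_idx = rng.integers(0, 4, n_markers)
        b_idx = (a_idx + rng.integers(1, 4, n_markers)) % 4
        freq_b = rng.uniform(config.marker_freq_low, config.marker_freq_high, n_markers)
        if chrom == cc:
            window = np.abs(pos - cp) <= config.low_hom_window_bp
            freq_b[window] = rng.uniform(
                config.causal_window_freq_low,
                config.causal_window_freq_high,
                int(window.sum()),
            )
        maps[chrom] = ChromosomeMap(
            chrom=chrom,
            marker_ids=[f"snp_{chrom}_{i + 1:04d}" for i in range(n_markers)],
            positions=pos,
            allele_a=BASES[a_idx],
            allele_b=BASES[b_idx],
            freq_b=freq_b,
        )
    return maps


def simulate_haplotypes(
    pedigree: Pedigree,
    config: SimConfig,
    causal_genotypes: dict[str, int],
    seed: int,
    maps: dict[str, ChromosomeMap] | None = None,
    causal_alleles: dict[str, tuple[int, int]] | None = None,
) -> HaplotypeSet:
    """Drop phased marker haplotypes through the pedigree, conditioned on the
    causal-locus transmissions implied by ``causal_genotypes``.

    Founder haplotypes are i.i.d. Bernoulli(freq_b) per marker.  The causal
    allele sits on the founder carrier's paternal haplotype; inside
    ``low_hom_window_bp`` of the causal locus that haplotype carries the
    locally minor allele (emulating the mapped region's reported low control
    homozygosity for case alleles).  Each meiosis draws a Poisson
    (Haldane) crossover count at ``recombination_rate`` with breakpoints
    uniform on the chromosome; on the causal chromosome the transmitted
    strand is anchored at the causal locus so marker descent is consistent
    with the causal-allele drop.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    maps = maps if maps is not None else build_marker_maps(config)
    ids = pedigree.ids
    index = {a: i for i, a in enumerate(ids)}
    cc, cpos = config.causal_locus

    if causal_alleles is None:
        causal_alleles = _sample_phase(pedigree, causal_genotypes, rng)
    for a in ids:
        if sum(causal_alleles[a]) != causal_genotypes[a]:
            raise ValueError(f"causal genotypes inconsistent at {a}")

    founders = [ind for ind in pedigree.individuals if ind.generation == 0]
    founder_hap_index = {f.id: (2 * i, 2 * i + 1) for i, f in enumerate(founders)}
    carrier_hap = founder_hap_index[config.founder_carrier_id][0]

    haplotypes: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] = {}
    founder_pools: dict[str, np.ndarray] = {}
    for chrom, cmap in maps.items():
        n = len(cmap.positions)
        pool = (rng.random((2 * len(founders), n)) < cmap.freq_b).astype(np.int8)
        if chrom == cc:
            # the causal haplotype carries the rare tag allele in the window
            window = np.abs(cmap.positions - cpos) <= config.low_hom_window_bp
            pool[carrier_hap, window] = 1
        founder_pools[chrom] = pool
        haplotypes[chrom] = np.zeros((len(ids), 2, n), dtype=np.int8)
        origins[chrom] = np.zeros((len(ids), 2, n), dtype=np.int16)

    causal_on_hap = np.zeros((len(ids), 2), dtype=bool)

    for ind in pedigree.individuals:
        i = index[ind.id]
        if ind.sire is None and ind.dam is None:
            h0, h1 = founder_hap_index[ind.id]
            for chrom, cmap in maps.items():
                haplotypes[chrom][i, 0] = founder_pools[chrom][h0]
                haplotypes[chrom][i, 1] = founder_pools[chrom][h1]
                origins[chrom][i, 0] = h0
                origins[chrom][i, 1] = h1
            if ind.id == config.founder_carrier_id:
                causal_on_hap[i, 0] = True
            continue
        for side, parent_id in enumerate((ind.sire, ind.dam)):
            p = index[parent_id]
            child_allele = causal_alleles[ind.id][side]
            for chrom, cmap in maps.items():
                length = config.chrom_length(chrom)
                morgans = config.recombination_rate * length / 1e8
                n_x = rng.poisson(morgans)
                breakpoints = np.sort(rng.uniform(0, length, n_x))
                parity = np.searchsorted(breakpoints, cmap.positions) % 2
                if chrom == cc:
                    parent_carries = causal_on_hap[p]
                    if parent_carries[0] != parent_carries[1]:
                        need = 0 if (parent_carries[0] == bool(child_allele)) else 1
                        causal_parity = int(np.searchsorted(breakpoints, cpos) % 2)
                        s0 = need ^ causal_parity
                    else:
                        s0 = int(rng.integers(2))
                        causal_parity = int(np.searchsorted(breakpoints, cpos) % 2)
                    strand = (parity + s0) % 2
                    haplotypes[chrom][i, side] = np.where(
                        strand == 0,
                        haplotypes[chrom][p, 0],
                        haplotypes[chrom][p, 1],
                    )
                    origins[chrom][i, side] = np.where(
                        strand == 0, origins[chrom][p, 0], origins[chrom][p, 1]
                    )
                    strand_at_causal = (causal_parity + s0) % 2
                    causal_on_hap[i, side] = bool(parent_carries[strand_at_causal])
                    if causal_on_hap[i, side] != bool(child_allele):
                        raise AssertionError("causal conditioning failed")
                else:
                    s0 = int(rng.integers(2))
                    strand = (parity + s0) % 2
                    haplotypes[chrom][i, side] = np.where(
                        strand == 0,
                        haplotypes[chrom][p, 0],
                        haplotypes[chrom][p, 1],
                    )
                    origins[chrom][i, side] = np.where(
                        strand == 0, origins[chrom][p, 0], origins[chrom][p, 1]
                    )

    return HaplotypeSet(
        animal_ids=list(ids),
        maps=maps,
        haplotypes=haplotypes,
        origins=origins,
        causal_chrom=cc,
        causal_on_hap=causal_on_hap,
        founder_causal_haplotype=founder_pools[cc][carrier_hap].copy(),
        founder_causal_hap_index=carrier_hap,
    )


def _sample_phase(
    pedigree: Pedigree, genotypes: dict[str, int], rng: np.random.Generator
) -> dict[str, tuple[int, int]]:
    """Sample per-parent causal transmissions consistent with the genotypes."""
    phase: dict[str, tuple[int, int]] = {}
    for ind in pedigree.individuals:
        g = genotypes[ind.id]
        if ind.sire is None and ind.dam is None:
            phase[ind.id] = (1, 0) if g == 1 else (g // 2, g // 2)
            continue
        g_s = genotypes[ind.sire] if ind.sire else 0
        g_d = genotypes[ind.dam] if ind.dam else 0
        options = [
            (p, m)
            for p in ({0, 1} if g_s == 1 else {g_s // 2})
            for m in ({0, 1} if g_d == 1 else {g_d // 2})
            if p + m == g
        ]
        if not options:
            raise ValueError(f"genotype {g} of {ind.id} inconsistent with parents")
        phase[ind.id] = options[rng.integers(len(options))]
    return phase


# ---------------------------------------------------------------------------
# Array genotypes
# ---------------------------------------------------------------------------

def emit_array_genotypes(
    haps: HaplotypeSet, error_rate: float, missing_rate: float, seed: int
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Collapse phased haplotypes to array dosages with genotyping noise.

    With probability ``error_rate`` a genotype is replaced by one of the
    other two dosage states (uniformly); with probability ``missing_rate`` it
    is set missing.  Returns (observed matrix, noise-free truth array).
    """
    if not 0 <= error_rate <= 1 or not 0 <= missing_rate <= 1:
        raise ValueError("rates must be in [0,1]")
    rng = np.random.default_rng(seed)
    blocks, marker_frames = [], []
    for chrom in haps.maps:
        cmap = haps.maps[chrom]
        blocks.append(haps.haplotypes[chrom].sum(axis=1, dtype=np.int8))
        marker_frames.append(
            pd.DataFrame(
                {
                    "marker_id": cmap.marker_ids,
                    "chrom": chrom,
                    "pos": cmap.positions,
                    "allele_a": cmap.allele_a,
                    "allele_b": cmap.allele_b,
                }
            )
        )
    truth = np.concatenate(blocks, axis=1)
    markers = pd.concat(marker_frames, ignore_index=True)

    observed = truth.copy()
    err = rng.random(observed.shape) < error_rate
    if err.any():
        shift = rng.integers(1, 3, size=int(err.sum()))
        observed[err] = (observed[err] + shift) % 3
    observed[rng.random(observed.shape) < missing_rate] = MISSING
    matrix = GenotypeMatrix(
        animal_ids=list(haps.animal_ids), markers=markers, genotypes=observed
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Reference sequence and gene model
# ---------------------------------------------------------------------------

# PYGM-like gene geometry: 20 exons, all coding, protein of 842 aa; the
# premature stop created by the causal SNV falls in exon 16, far enough
# upstream of the last junction to satisfy the >50-nt NMD rule.
N_EXONS = 20
PROTEIN_LENGTH = 842
CDS_EXON_LEN = 126          # exons 1..19
LAST_CDS_EXON_LEN = 3 * (PROTEIN_LENGTH + 1) - 19 * CDS_EXON_LEN
INTRON_LEN = 2000
CAUSAL_CODON = 650          # CGA -> TGA on C>T
CAUSAL_CDS_POS = 3 * (CAUSAL_CODON - 1) + 1  # 1948, the codon's first base


def _gene_start(config: SimConfig) -> int:
    # genomic offset of CDS position CAUSAL_CDS_POS from the gene start
    exon16_cds_offset = 15 * CDS_EXON_LEN        # CDS bases before exon 16
    within_exon = CAUSAL_CDS_POS - exon16_cds_offset  # 1-based in exon 16
    offset = 15 * (CDS_EXON_LEN + INTRON_LEN) + within_exon - 1
    return config.causal_locus[1] - offset


def build_gene_model(config: SimConfig) -> TranscriptModel:
    """Plus-strand, fully coding 20-exon transcript containing the causal
    locus at CDS position 1948 (codon 650) in exon 16."""
    start = _gene_start(config)
    if start < 1:
        raise ConfigurationError("causal locus too close to chromosome start")
    exons = []
    pos = start
    for i in range(N_EXONS):
        ex_len = CDS_EXON_LEN if i < N_EXONS - 1 else LAST_CDS_EXON_LEN
        exons.append((pos, pos + ex_len - 1))
        pos += ex_len + INTRON_LEN
    return TranscriptModel(
        transcript_id="PYGM_like",
        chrom=config.causal_locus[0],
        strand="+",
        exons=exons,
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
    )


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def build_reference(
    config: SimConfig, chromosomes: list[str] | None = None
) -> dict[str, str]:
    """Random reference with the designed gene embedded on the causal
    chromosome (codon 650 is CGA, so the planted C>T makes a TGA stop).

    Deterministic given ``config.seed``; each chromosome has its own seed
    stream, so restricting to ``chromosomes`` skips unneeded sequence
    without changing the rest.
    """
    wanted = (
        [c for c, _, _ in config.chromosomes] if chromosomes is None else chromosomes
    )
    genome: dict[str, str] = {}
    for k, (chrom, _, length) in enumerate(config.chromosomes):
        if chrom not in wanted:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17, k]))
        seq = _BASE_BYTES[rng.integers(0, 4, length)]
        if chrom == config.causal_locus[0]:
            _embed_gene(seq, config, rng)
        genome[chrom] = seq.tobytes().decode("ascii")
    return genome


def _embed_gene(seq: np.ndarray, config: SimConfig, rng: np.random.Generator) -> None:
    codon_pool = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS and a + b + c != "ATG"
    ]
    codons = ["ATG"]
    codons += list(rng.choice(codon_pool, PROTEIN_LENGTH - 1))
    codons[CAUSAL_CODON - 1] = "CGA"
    codons.append("TAA")
    cds = "".join(codons)
    model = build_gene_model(config)
    offset = 0
    for s, e in model.exons:
        ex_len = e - s + 1
        seq[s - 1 : e] = np.frombuffer(
            cds[offset : offset + ex_len].encode("ascii"), dtype=np.uint8
        )
        offset += ex_len
    assert offset == len(cds)


# ---------------------------------------------------------------------------
# WGS variants
# ---------------------------------------------------------------------------

def emit_wgs_variants(
    config: SimConfig,
    pedigree: Pedigree,
    causal_genotypes: dict[str, int],
    seed: int,
    case_ids: list[str] | None = None,
    genome: dict[str, str] | None = None,
) -> VariantTable:
    """WGS variant table: i.i.d. HWE biallelic background (a small fraction
    multiallelic), plus the planted causal nonsense SNV.

    Sequenced cases are homozygous-alt at the causal site, herd controls
    follow the gene drop, and the external cohort carries zero alternative
    alleles there (the de novo assumption).  Where ``genome`` covers a
    background variant the reference allele matches it.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    cc, cpos = config.causal_locus

    affected = sorted(
        a
        for a, g in causal_genotypes.items()
        if g == 2 and pedigree[a].generation == pedigree.n_generations
    )
    if case_ids is None:
        if len(affected) < config.n_sequenced_cases:
            raise ConfigurationError(
                f"need {config.n_sequenced_cases} affected final-generation "
                f"animals to sequence, found {len(affected)}"
            )
        case_ids = list(
            rng.choice(affected, config.n_sequenced_cases, replace=False)
        )
    # herd WGS controls are unaffected animals: affected calves either died,
    # were sold, or are the sequenced cases — they are not in control cohorts
    others = sorted(
        a for a in set(pedigree.ids) - set(case_ids) if causal_genotypes[a] != 2
    )
    herd_ids = list(
        rng.choice(others, min(config.n_wgs_herd_controls, len(others)), replace=False)
    )
    external_ids = [f"EXT{i + 1:03d}" for i in range(config.n_external_samples)]
    sample_ids = sorted(case_ids) + sorted(herd_ids) + external_ids
    cohorts = (
        ["case"] * len(case_ids) + ["herd"] * len(herd_ids)
        + ["external"] * len(external_ids)
    )
    n_samples = len(sample_ids)

    # background sites
    chrom_names = [c for c, _, _ in config.chromosomes]
    lengths = np.array([l for _, _, l in config.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    n_bg = config.n_wgs_background_variants
    bg_chrom = rng.choice(chrom_names, n_bg, p=probs)
    bg_pos = np.array(
        [rng.integers(1, config.chrom_length(c) + 1) for c in bg_chrom]
    )
    clash = (bg_chrom == cc) & (bg_pos == cpos)
    bg_pos[clash] += 1
    freq = rng.uniform(config.marker_freq_low, config.marker_freq_high, n_bg)
    multi = rng.random(n_bg) < config.multiallelic_fraction

    rows = []
    gt = np.empty((n_bg + 1, n_samples, 2), dtype=np.int8)
    order = np.lexsort((bg_pos, bg_chrom))
    causal_inserted = False
    out_i = 0
    causal_row, causal_gt = _causal_record(
        config, causal_genotypes, case_ids, herd_ids, external_ids, genome
    )
    for k in order:
        chrom, pos = bg_chrom[k], int(bg_pos[k])
        if not causal_inserted and (
            chrom > cc or (chrom == cc and pos > cpos)
        ):
            rows.append(causal_row)
            gt[out_i] = causal_gt
            out_i += 1
            causal_inserted = True
        ref, alts = _alleles_at(genome, chrom, pos, rng, bool(multi[k]))
        p = freq[k]
        draws = (rng.random((n_samples, 2)) < p).astype(np.int8)
        if len(alts) > 1:  # second alt at low frequency
            extra = rng.random((n_samples, 2)) < 0.02
            draws[(draws == 1) & extra] = 2
        draws.sort(axis=1)
        miss = rng.random(n_samples) < config.wgs_missing_rate
        draws[miss] = MISSING
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alts})
        gt[out_i] = draws
        out_i += 1
    if not causal_inserted:
        rows.append(causal_row)
        gt[out_i] = causal_gt
        out_i += 1

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    samples = pd.DataFrame({"sample_id": sample_ids, "cohort": cohorts})
    return VariantTable(variants=variants, genotypes=gt[:out_i], samples=samples)


def _alleles_at(genome, chrom, pos, rng, multiallelic):
    if genome is not None and chrom in genome and pos <= len(genome[chrom]):
        ref = genome[chrom][pos - 1]
    else:
        ref = str(rng.choice(BASES))
    alt_pool = [b for b in "ACGT" if b != ref]
    n_alt = 2 if multiallelic else 1
    alts = tuple(rng.choice(alt_pool, n_alt, replace=False))
    return ref, alts


def _causal_record(config, causal_genotypes, case_ids, herd_ids, external_ids, genome):
    cc, cpos = config.causal_locus
    ref, alt = "C", "T"
    if genome is not None and cc in genome:
        assert genome[cc][cpos - 1] == ref, "reference lacks planted causal base"
    gts = []
    for a in sorted(case_ids):
        assert causal_genotypes[a] == 2
        gts.append((1, 1))
    for a in sorted(herd_ids):
        g = causal_genotypes[a]
        gts.append((0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1)))
    gts.extend([(0, 0)] * len(external_ids))
    row = {"chrom": cc, "pos": cpos, "ref": ref, "alt": (alt,)}
    return row, np.array(gts, dtype=np.int8)


def emit_external_evidence(
    variants: VariantTable, config: SimConfig, seed: int
) -> pd.DataFrame:
    """Synthetic other-breed evidence: background variants are standing
    variation, seen elsewhere with probability ``external_evidence_rate``;
    the de novo causal variant is never seen."""
    rng = np.random.default_rng(seed)
    cc, cpos = config.causal_locus
    is_causal = (
        (variants.variants["chrom"] == cc) & (variants.variants["pos"] == cpos)
    ).to_numpy()
    seen = rng.random(len(is_causal)) < config.external_evidence_rate
    seen[is_causal] = False
    return pd.DataFrame(
        {
            "chrom": variants.variants["chrom"],
            "pos": variants.variants["pos"],
            "alt": [a[0] for a in variants.variants["alt"]],
            "seen_in_other_breeds": seen,
        }
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def emit_phenotypes(
    causal_genotypes: dict[str, int], seed: int, config: SimConfig | None = None
) -> pd.DataFrame:
    """Glycogen phenotypes: affected iff homozygous, per-group normal draws.

    Defaults reproduce the reported biopsy design: affected 189.3 +/- 7.4
    mmol/kg wet weight, unaffected 101.0 +/- 6.2 (the +/- treated as SD).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for a in causal_genotypes:
        g = causal_genotypes[a]
        affected = g == 2
        mean = config.glycogen_affected_mean if affected else config.glycogen_unaffected_mean
        sd = config.glycogen_affected_sd if affected else config.glycogen_unaffected_sd
        rows.append(
            {
                "animal_id": a,
                "affected": affected,
                "glycogen_mmol_per_kg": mean + sd * rng.standard_normal(),
                "group_label": ("affected" if g == 2 else
                                "carrier" if g == 1 else "wild_type"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-herd bundle
# ---------------------------------------------------------------------------

@dataclass
class Herd:
    """Everything one simulated study provides, truth included."""

    config: SimConfig
    pedigree: Pedigree
    causal_genotypes: dict[str, int]
    haplotypes: HaplotypeSet
    array: GenotypeMatrix
    array_truth: np.ndarray
    wgs: VariantTable
    evidence: pd.DataFrame
    phenotypes: pd.DataFrame
    transcript: TranscriptModel
    genome: dict[str, str] | None
    case_ids: list[str]           # affected, SNP-arrayed (final generation)
    sequenced_case_ids: list[str]
    gene_drop_attempts: int


def simulate_herd(config: SimConfig, with_reference: bool = True) -> Herd:
    """Run the full generator: pedigree, ascertained gene drop, haplotypes,
    array, WGS, evidence, phenotypes.

    The gene drop is rejection-sampled (ascertainment): draws are repeated
    with fresh streams until the final generation holds at least
    ``min_affected_last_gen`` homozygous animals — the analogue of the study
    existing only because affected calves appeared.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(6) >> 1]  # keep < 2**31
    pedigree = simulate_pedigree(config, seed=seeds[0])

    causal = None
    attempts = 0
    last_gen = pedigree.n_generations
    for attempt in range(config.max_gene_drop_attempts):
        attempts += 1
        candidate = gene_drop(pedigree, config.founder_carrier_id, seeds[1] + attempt)
        n_affected = sum(
            1
            for a, g in candidate.items()
            if g == 2 and pedigree[a].generation == last_gen
        )
        if n_affected >= config.min_affected_last_gen:
            causal = candidate
            break
    if causal is None:
        raise ConfigurationError(
            "gene drop never produced enough affected final-generation animals"
        )

    haps = simulate_haplotypes(pedigree, config, causal, seed=seeds[2])
    array, truth = emit_array_genotypes(
        haps, config.genotyping_error_rate, config.missing_rate, seed=seeds[3]
    )
    genome = (
        build_reference(config, chromosomes=[config.causal_locus[0]])
        if with_reference
        else None
    )
    wgs = emit_wgs_variants(
        config, pedigree, causal, seed=seeds[4], genome=genome
    )
    evidence = emit_external_evidence(wgs, config, seed=seeds[5])
    phenotypes = emit_phenotypes(causal, seed=seeds[5] ^ 0x5EED, config=config)
    case_ids = sorted(
        a
        for a, g in causal.items()
        if g == 2 and pedigree[a].generation == last_gen
    )
    return Herd(
        config=config,
        pedigree=pedigree,
        causal_genotypes=causal,
        haplotypes=haps,
        array=array,
        array_truth=truth,
        wgs=wgs,
        evidence=evidence,
        phenotypes=phenotypes,
        transcript=build_gene_model(config),
        genome=genome,
        case_ids=case_ids,
        sequenced_case_ids=wgs.cohort_ids("case"),
        gene_drop_attempts=attempts,
    )
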