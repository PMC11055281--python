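"""Generator correctness: pedigree topology, Mendelian gene drop, conditioned
haplotype descent, array noise, WGS planting, phenotypes, determinism."""

import numpy as np
import pytest

from autozyg import herdsim
from autozyg.herdsim import (
    ConfigurationError,
    Individual,
    Pedigree,
    SimConfig,
    build_marker_maps,
    emit_array_genotypes,
    emit_phenotypes,
    emit_wgs_variants,
    gene_drop,
    simulate_haplotypes,
    simulate_pedigree,
    simulate_herd,
)
from autozyg.io_formats import MISSING


def small_config(**kw):
    defaults = dict(
        n_founders=12,
        n_generations=3,
        n_matings_per_generation=8,
        chromosomes=[("1", 60, 2_000_000), ("2", 60, 2_000_000)],
        causal_locus=("2", 1_000_000),
        n_wgs_background_variants=200,
        n_external_samples=10,
        n_wgs_herd_controls=10,
        min_affected_last_gen=2,
        seed=5,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestPedigree:
    def test_zero_generations_yields_founders_only(self):
        ped = simulate_pedigree(small_config(n_generations=0))
        assert len(ped) == 12
        assert all(i.sire is None and i.dam is None for i in ped.individuals)

    def test_founder_reaches_both_parental_paths(self):
        cfg = SimConfig(seed=1)
        ped = simulate_pedigree(cfg)
        line = ped.descendants(cfg.founder_carrier_id) | {cfg.founder_carrier_id}
        assert any(
            ind.sire in line and ind.dam in line
            for ind in ped.individuals
            if ind.sire and ind.dam
        )

    def test_structural_invariants(self):
        ped = simulate_pedigree(small_config())
        for ind in ped.individuals:
            if ind.sire:
                assert ped[ind.sire].sex == "M"
                assert ped[ind.sire].generation < ind.generation
            if ind.dam:
                assert ped[ind.dam].sex == "F"
                assert ped[ind.dam].generation < ind.generation

    def test_fig1_like_topology_terminal_offspring(self):
        """A founder bull, carrier sires and carrier dams: terminal calves
        carry the founder in both parental ancestries."""
        inds = [Individual("BULL", None, None, "M", 0)]
        inds += [Individual(f"C{i}", None, None, "F", 0) for i in range(4)]
        sires = [Individual(f"S{i}", "BULL", f"C{i}", "M", 1) for i in range(3)]
        dams = [
            Individual(f"D{i}", "BULL", f"C{(i + 1) % 4}", "F", 1) for i in range(8)
        ]
        calves = [
            Individual(f"calf{i}", f"S{i % 3}", f"D{i}", "F", 2) for i in range(8)
        ]
        ped = Pedigree(inds + sires + dams + calves)
        for calf in calves:
            sire, dam = ped[calf.id].sire, ped[calf.id].dam
            assert "BULL" in ped.ancestors(sire) | {sire}
            assert "BULL" in ped.ancestors(dam) | {dam}

    def test_impossible_topology_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_pedigree(small_config(n_founders=1, n_generations=2))

    def test_tsv_round_trip(self, tmp_path):
        ped = simulate_pedigree(small_config())
        ped.to_tsv(tmp_path / "ped.tsv")
        back = Pedigree.from_tsv(tmp_path / "ped.tsv")
        assert back.ids == ped.ids
        assert all(back[i].sire == ped[i].sire for i in ped.ids)


class TestGeneDrop:
    def test_non_descendant_always_wild_type(self):
        cfg = small_config()
        ped = simulate_pedigree(cfg)
        line = ped.descendants(cfg.founder_carrier_id)
        for seed in range(5):
            g = gene_drop(ped, cfg.founder_carrier_id, seed)
            assert g[cfg.founder_carrier_id] == 1
            for a in ped.ids:
                if a not in line and a != cfg.founder_carrier_id:
                    assert g[a] == 0

    def test_unknown_founder_errors(self):
        ped = simulate_pedigree(small_config())
        with pytest.raises(KeyError):
            gene_drop(ped, "nobody", 0)

    def test_carrier_by_wild_type_never_homozygous_and_mendelian_ratio(self):
        # founder bull x unrelated cow: offspring are 0 or 1, each w.p. 1/2
        n = 10_000
        inds = [
            Individual("F1", None, None, "M", 0),
            Individual("F2", None, None, "F", 0),
        ] + [Individual(f"k{i}", "F1", "F2", "M", 1) for i in range(n)]
        ped = Pedigree(inds)
        g = gene_drop(ped, "F1", seed=3)
        kids = np.array([g[f"k{i}"] for i in range(n)])
        assert (kids <= 1).all()
        se = np.sqrt(0.25 / n)
        assert abs(kids.mean() - 0.5) < 3 * se

    def test_carrier_by_carrier_segregation(self):
        # F1 x (carrier daughter): conditional on the daughter carrying one
        # copy, offspring follow 1/4 : 1/2 : 1/4
        n = 10_000
        inds = [
            Individual("F1", None, None, "M", 0),
            Individual("F2", None, None, "F", 0),
            Individual("D", "F1", "F2", "F", 1),
        ] + [Individual(f"k{i}", "F1", "D", "M", 2) for i in range(n)]
        ped = Pedigree(inds)
        g = None
        for seed in range(50):  # find a drop where D is a carrier
            cand = gene_drop(ped, "F1", seed)
            if cand["D"] == 1:
                g = cand
                break
        assert g is not None
        kids = np.array([g[f"k{i}"] for i in range(n)])
        props = np.array([(kids == v).mean() for v in (0, 1, 2)])
        for p, exp in zip(props, (0.25, 0.5, 0.25)):
            assert abs(p - exp) < 3 * np.sqrt(exp * (1 - exp) / n)


class TestHaplotypes:
    def test_zero_recombination_preserves_founder_haplotype(self):
        cfg = small_config(recombination_rate=0.0)
        ped = simulate_pedigree(cfg)
        causal = gene_drop(ped, cfg.founder_carrier_id, 7)
        haps = simulate_haplotypes(ped, cfg, causal, seed=8)
        cc = cfg.causal_locus[0]
        for a in ped.ids:
            i = haps.animal_index(a)
            for side in (0, 1):
                if haps.causal_on_hap[i, side]:
                    np.testing.assert_array_equal(
                        haps.haplotypes[cc][i, side],
                        haps.founder_causal_haplotype,
                    )

    def test_mean_crossovers_matches_map_length(self):
        # founder x founder meioses; visible origin switches ~ Poisson(L)
        n = 400
        inds = [
            Individual("F1", None, None, "M", 0),
            Individual("F2", None, None, "F", 0),
        ] + [Individual(f"k{i}", "F1", "F2", "M", 1) for i in range(n)]
        ped = Pedigree(inds)
        cfg = small_config(recombination_rate=10.0, founder_carrier_id="F1")
        causal = gene_drop(ped, "F1", 1)
        haps = simulate_haplotypes(ped, cfg, causal, seed=2)
        switches = []
        for chrom in ("1", "2"):
            o = haps.origins[chrom]
            for i in range(2, 2 + n):
                for side in (0, 1):
                    switches.append(int((np.diff(o[i, side]) != 0).sum()))
        lam = 0.2
        mean = np.mean(switches)
        se = np.sqrt(lam / len(switches))
        assert abs(mean - lam) < 4 * se

    def test_affected_animals_homozygous_for_founder_block(self, herd):
        """Descent oracle: both haplotypes of every affected animal match the
        founder causal haplotype wherever they actually descend from it."""
        haps = herd.haplotypes
        cc = haps.causal_chrom
        origins = haps.origins[cc]
        for a, g in herd.causal_genotypes.items():
            if g != 2:
                continue
            i = haps.animal_index(a)
            assert haps.causal_on_hap[i].all()
            for side in (0, 1):
                ibd = origins[i, side] == haps.founder_causal_hap_index
                np.testing.assert_array_equal(
                    haps.haplotypes[cc][i, side][ibd],
                    haps.founder_causal_haplotype[ibd],
                )

    def test_inconsistent_causal_genotypes_rejected(self):
        cfg = small_config()
        ped = simulate_pedigree(cfg)
        causal = gene_drop(ped, cfg.founder_carrier_id, 7)
        bad = dict(causal)
        non_desc = next(
            a for a in ped.ids
            if a != cfg.founder_carrier_id
            and a not in ped.descendants(cfg.founder_carrier_id)
        )
        bad[non_desc] = 2
        with pytest.raises(ValueError):
            simulate_haplotypes(ped, cfg, bad, seed=1)


class TestArrayEmission:
    def test_noise_free_equals_haplotype_sums(self, herd):
        matrix, truth = emit_array_genotypes(herd.haplotypes, 0.0, 0.0, seed=1)
        np.testing.assert_array_equal(matrix.genotypes, truth)

    def test_all_missing_when_rate_one(self, herd):
        matrix, _ = emit_array_genotypes(herd.haplotypes, 0.0, 1.0, seed=1)
        assert (matrix.genotypes == MISSING).all()

    def test_error_rate_binomial_interval(self, herd):
        matrix, truth = emit_array_genotypes(herd.haplotypes, 0.01, 0.0, seed=1)
        frac = (matrix.genotypes != truth).mean()
        assert matrix.genotypes.size > 100_000
        assert 0.007 <= frac <= 0.013


class TestWgsEmission:
    def test_causal_row_genotype_pattern(self, herd):
        cc, cp = herd.config.causal_locus
        mask = (herd.wgs.variants["chrom"] == cc) & (herd.wgs.variants["pos"] == cp)
        assert mask.sum() == 1
        i = int(np.nonzero(mask.to_numpy())[0][0])
        gt = herd.wgs.genotypes[i]
        cohorts = herd.wgs.samples["cohort"].to_numpy()
        assert (gt[cohorts == "case"] == 1).all()
        assert (gt[cohorts == "external"] == 0).all()

    def test_background_frequency_spectrum(self, herd):
        g = herd.wgs.genotypes
        called = (g != MISSING).all(axis=2)
        alt = ((g == 1).sum(axis=2) * called).sum(axis=1)
        freq = alt / (2 * called.sum(axis=1))
        lo, hi = herd.config.marker_freq_low, herd.config.marker_freq_high
        # background alt frequencies should fill the configured band
        assert abs(freq.mean() - (lo + hi) / 2) < 0.03
        assert (freq > 0.6).mean() > 0.2

    def test_herd_controls_are_unaffected(self, herd):
        for a in herd.wgs.cohort_ids("herd"):
            assert herd.causal_genotypes[a] != 2


class TestPhenotypes:
    def test_affected_iff_homozygous(self, herd):
        ph = herd.phenotypes.set_index("animal_id")
        for a, g in herd.causal_genotypes.items():
            assert bool(ph.loc[a, "affected"]) == (g == 2)
            assert ph.loc[a, "group_label"] == (
                "affected" if g == 2 else "carrier" if g == 1 else "wild_type"
            )

    def test_fold_change_near_reported(self):
        genotypes = {f"a{i}": 2 for i in range(1000)}
        genotypes.update({f"u{i}": 0 for i in range(1000)})
        ph = emit_phenotypes(genotypes, seed=4)
        ratio = (
            ph.loc[ph["affected"], "glycogen_mmol_per_kg"].mean()
            / ph.loc[~ph["affected"], "glycogen_mmol_per_kg"].mean()
        )
        assert 1.8 <= ratio <= 2.0

    def test_zero_dispersion_is_exact(self):
        cfg = SimConfig(glycogen_affected_sd=0.0)
        ph = emit_phenotypes({"x": 2}, seed=0, config=cfg)
        assert ph["glycogen_mmol_per_kg"].iloc[0] == pytest.approx(189.3)


class TestDeterminism:
    def test_same_seed_identical_different_seed_differs(self):
        cfg = small_config()
        h1 = simulate_herd(cfg, with_reference=False)
        h2 = simulate_herd(small_config(), with_reference=False)
        np.testing.assert_array_equal(h1.array.genotypes, h2.array.genotypes)
        np.testing.assert_array_equal(h1.wgs.genotypes, h2.wgs.genotypes)
        assert h1.causal_genotypes == h2.causal_genotypes
        h3 = simulate_herd(small_config(seed=6), with_reference=False)
        assert not np.array_equal(h1.array.genotypes, h3.array.genotypes)

    def test_reference_carries_planted_base(self):
        cfg = small_config()
        genome = herdsim.build_reference(cfg, chromosomes=["2"])
        cc, cp = cfg.causal_locus
        assert genome[cc][cp - 1] == "C"
        assert len(genome[cc]) == cfg.chrom_length(cc)
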