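"""Marker QC, ROH calling against a brute-force oracle, shared-region logic,
control refinement, and the exact recessive association scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from autozyg import roh_mapping as roh
from autozyg.io_formats import MISSING
from autozyg.pipeline import locate_candidate_region

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Brute-force ROH oracle: greedy leftmost-maximal feasible windows, with
# feasibility re-counted directly on every candidate subrun.
# ---------------------------------------------------------------------------

def roh_oracle(genotypes, positions, params):
    g = list(genotypes)
    segments = []
    i, n = 0, len(g)
    while i < n:
        best_j = None
        for j in range(i + 1, n + 1):
            window = g[i:j]
            if (
                sum(1 for v in window if v == 1) <= params.max_het_in_segment
                and sum(1 for v in window if v == MISSING)
                <= params.max_missing_in_segment
            ):
                best_j = j
            else:
                break
        if best_j is not None:
            n_snps = best_j - i
            span = positions[best_j - 1] - positions[i] + 1
            if (
                n_snps >= params.min_snps_per_segment
                and span >= params.min_length_bp
            ):
                segments.append((i, best_j))
                i = best_j
                continue
        i += 1
    return segments


def as_tuples(segments, positions):
    out = []
    for seg in segments:
        i = int(np.searchsorted(positions, seg.start_bp))
        j = int(np.searchsorted(positions, seg.end_bp)) + 1
        out.append((i, j, seg.n_snps, seg.n_het, seg.n_missing))
    return out


class TestMarkerQc:
    def test_spec_thresholds(self):
        g = np.zeros((100, 3), dtype=np.int8)
        g[:, 1] = np.where(np.arange(100) < 89, 1, MISSING)  # 89% call rate
        g[:30, 2] = 2
        g[30:60, 2] = 1  # MAF 0.45, full call rate
        m = make_matrix(g)
        kept, log = roh.marker_qc(m, maf_min=0.0001, call_rate_min=0.90)
        assert list(kept.markers["marker_id"]) == ["m3"]
        assert set(log["marker_id"]) == {"m1", "m2"}
        assert log.set_index("marker_id").loc["m1", "reason"] == "maf"

    def test_idempotent_and_never_grows(self, herd):
        once, _ = roh.marker_qc(herd.array)
        twice, log2 = roh.marker_qc(once)
        assert once.n_markers <= herd.array.n_markers
        assert twice.n_markers == once.n_markers
        assert log2.empty


class TestCallRoh:
    def test_all_het_row_gives_nothing(self):
        m = make_matrix([[1] * 12])
        params = roh.RohParams(3, 0, 0, 1)
        assert roh.call_roh(m, "A1", params) == []

    def test_hand_enumerated_two_segments(self):
        row = [2, 2, 2, 2, 2, 1, 0, 0, 0, 0, 0]
        m = make_matrix([row])
        params = roh.RohParams(5, 0, 0, 1)
        segs = roh.call_roh(m, "A1", params)
        pos = m.markers["pos"].to_numpy()
        assert as_tuples(segs, pos) == [(0, 5, 5, 0, 0), (6, 11, 5, 0, 0)]

    @pytest.mark.parametrize("max_het,max_missing", [(0, 0), (1, 2), (2, 1)])
    def test_matches_brute_force_oracle(self, rng, max_het, max_missing):
        params = roh.RohParams(4, max_het, max_missing, 1)
        for _ in range(150):
            n = int(rng.integers(5, 60))
            row = rng.choice([0, 1, 2, MISSING], n, p=[0.4, 0.2, 0.3, 0.1])
            m = make_matrix(row[None, :])
            pos = m.markers["pos"].to_numpy()
            got = [(t[0], t[1]) for t in as_tuples(roh.call_roh(m, "A1", params), pos)]
            want = roh_oracle(row, pos, params)
            assert got == want

    def test_min_length_filter(self):
        m = make_matrix([[0, 0, 0, 0]], spacing=100)  # span 301 bp
        assert roh.call_roh(m, "A1", roh.RohParams(2, 0, 0, 1000)) == []
        assert len(roh.call_roh(m, "A1", roh.RohParams(2, 0, 0, 300))) == 1


class TestSharedRegion:
    def test_fully_heterozygous_case_gives_empty(self):
        m = make_matrix([[1] * 8, [2] * 8])
        assert roh.shared_case_region(m, ["A1", "A2"]) == []

    def test_opposite_homozygotes_break_region(self):
        g = [[2, 2, 2, 2, 2], [2, 2, 0, 2, 2]]
        regions = roh.shared_case_region(make_matrix(g), ["A1", "A2"])
        assert [(r.n_case_homozygous_snps) for r in regions] == [2, 2]

    def test_missing_case_is_compatible(self):
        g = [[2, MISSING, 2], [2, 2, 2]]
        (region,) = roh.shared_case_region(make_matrix(g), ["A1", "A2"])
        assert region.n_case_homozygous_snps == 3
        np.testing.assert_array_equal(region.shared_alleles, [2, 2, 2])

    def test_recount_oracle_on_random_matrices(self, rng):
        for _ in range(30):
            g = rng.choice([0, 1, 2, MISSING], size=(6, 40), p=[0.35, 0.2, 0.35, 0.1])
            m = make_matrix(g)
            cases = ["A1", "A2", "A3"]
            regions = roh.shared_case_region(m, cases)
            # direct recount: per-marker indicator
            sub = g[:3]
            ind = []
            for col in sub.T:
                called = col[col != MISSING]
                # all-missing markers are compatible (allele undetermined)
                ind.append((called == 0).all() or (called == 2).all())
            covered = np.zeros(40, dtype=bool)
            for r in regions:
                covered[np.searchsorted(m.markers["pos"].to_numpy(), r.positions_bp)] = True
            np.testing.assert_array_equal(covered, np.array(ind))

    def test_requires_two_cases(self):
        with pytest.raises(ValueError):
            roh.shared_case_region(make_matrix([[0, 0]]), ["A1"])

    def test_planted_block_recovered_in_simulation(self, herd):
        mat, _ = roh.marker_qc(herd.array)
        cases = herd.case_ids
        controls = [a for a in mat.animal_ids if a not in set(cases)]
        call = locate_candidate_region(mat, cases, controls)
        assert call.shared.contains(*herd.config.causal_locus)


class TestControlHomFraction:
    def test_arithmetic(self):
        g = np.zeros((22, 3), dtype=np.int8)
        g[0] = g[1] = [2, 2, 2]                   # cases
        g[2:4] = [2, 2, 2]                        # 2 of 20 controls homozygous
        m = make_matrix(g)
        (region,) = roh.shared_case_region(m, ["A1", "A2"])
        frac, counts, ncall = roh.control_hom_fraction(
            m, ["A1", "A2"], [f"A{i}" for i in range(3, 23)], region
        )
        np.testing.assert_allclose(frac, [0.1, 0.1, 0.1])
        np.testing.assert_array_equal(counts, [2, 2, 2])

    def test_no_homozygous_controls(self):
        g = np.array([[2, 2], [2, 2], [1, 0], [0, 1]], dtype=np.int8)
        m = make_matrix(g)
        (region,) = roh.shared_case_region(m, ["A1", "A2"])
        frac, counts, _ = roh.control_hom_fraction(m, ["A1", "A2"], ["A3", "A4"], region)
        np.testing.assert_allclose(frac, [0.0, 0.0])

    def test_all_controls_missing_flagged_nan(self):
        g = np.array([[2], [2], [MISSING]], dtype=np.int8)
        m = make_matrix(g)
        (region,) = roh.shared_case_region(m, ["A1", "A2"])
        frac, _, _ = roh.control_hom_fraction(m, ["A1", "A2"], ["A3"], region)
        assert np.isnan(frac[0])

    def test_recount_on_simulated_herd(self, herd):
        mat, _ = roh.marker_qc(herd.array)
        cases = herd.case_ids
        controls = [a for a in mat.animal_ids if a not in set(cases)][:50]
        regions = roh.shared_case_region(mat, cases)
        region = max(regions, key=lambda r: r.n_case_homozygous_snps)
        frac, counts, _ = roh.control_hom_fraction(mat, cases, controls, region)
        ctrl = mat.rows(controls)[:, region.marker_indices]
        for k, allele in enumerate(region.shared_alleles):
            col = ctrl[:, k]
            called = col != MISSING
            expected = ((col == allele) & called).sum()
            assert counts[k] == expected


def region_from_counts(n):
    g = np.full((2, n), 2, dtype=np.int8)
    m = make_matrix(g)
    (region,) = roh.shared_case_region(m, ["A1", "A2"])
    return region


class TestRefineRegion:
    def test_generous_threshold_keeps_region(self):
        region = region_from_counts(5)
        refined = roh.refine_region(region, np.array([3, 1, 2, 0, 4]), 100)
        assert refined.n_case_homozygous_snps == 5
        assert (refined.start_bp, refined.end_bp) == (region.start_bp, region.end_bp)

    def test_hand_enumerated_subregion(self):
        region = region_from_counts(5)
        refined = roh.refine_region(region, np.array([30, 10, 5, 8, 40]), 25)
        np.testing.assert_array_equal(
            refined.positions_bp, region.positions_bp[1:4]
        )
        assert refined.n_case_homozygous_snps == 3

    def test_tie_broken_by_smaller_fraction_sum(self):
        region = region_from_counts(5)
        counts = np.array([1, 9, 99, 1, 1])
        fracs = np.array([0.1, 0.9, 1.0, 0.01, 0.01])
        refined = roh.refine_region(region, counts, 50, fractions=fracs)
        np.testing.assert_array_equal(refined.positions_bp, region.positions_bp[3:])

    def test_no_qualifying_snp_gives_empty(self):
        region = region_from_counts(3)
        refined = roh.refine_region(region, np.array([9, 9, 9]), 2)
        assert refined.is_empty

    def test_refined_region_keeps_causal_locus(self, herd):
        mat, _ = roh.marker_qc(herd.array)
        cases = herd.case_ids
        controls = [a for a in mat.animal_ids if a not in set(cases)]
        call = locate_candidate_region(mat, cases, controls)
        assert call.refined.contains(*herd.config.causal_locus)


class TestAssocScan:
    def test_identical_distributions_p_one(self):
        g = np.tile([0, 1, 2, 1], (10, 1)).astype(np.int8)
        m = make_matrix(g)
        res = roh.recessive_assoc_scan(m, ["A1", "A2"], ["A3", "A4", "A5"])
        assert (res.table["p_value"] == 1.0).all()

    def test_hypergeometric_enumeration_oracle(self):
        # 6/6 cases homozygous-minor, 0/14 controls; two-sided Fisher p from
        # direct hypergeometric enumeration (sum of pmf(k) <= pmf(observed))
        g = np.array([[2]] * 6 + [[0]] * 10 + [[1]] * 4, dtype=np.int8)
        m = make_matrix(g)
        cases = [f"A{i}" for i in range(1, 7)]
        controls = [f"A{i}" for i in range(7, 21)]
        res = roh.recessive_assoc_scan(m, cases, controls)
        hg = stats.hypergeom(20, 6, 6)
        p_obs = hg.pmf(6)
        expected = sum(hg.pmf(k) for k in range(7) if hg.pmf(k) <= p_obs + 1e-15)
        assert res.table["p_value"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1 / math.comb(20, 6), rel=1e-9)

    def test_label_preserving_reorder_invariance(self, rng):
        g = rng.choice([0, 1, 2, MISSING], size=(12, 15), p=[0.4, 0.2, 0.3, 0.1])
        m = make_matrix(g)
        cases = ["A1", "A2", "A3"]
        controls = [f"A{i}" for i in range(4, 13)]
        res1 = roh.recessive_assoc_scan(m, cases, controls)
        res2 = roh.recessive_assoc_scan(m, cases[::-1], controls[::-1])
        np.testing.assert_allclose(
            res1.table["p_value"].to_numpy(), res2.table["p_value"].to_numpy()
        )

    def test_disjoint_sets_required(self):
        m = make_matrix([[0], [0]])
        with pytest.raises(ValueError):
            roh.recessive_assoc_scan(m, ["A1"], ["A1", "A2"])

    def test_top_marker_lands_in_causal_region(self, herd):
        mat, _ = roh.marker_qc(herd.array)
        cases = herd.case_ids
        controls = [a for a in mat.animal_ids if a not in set(cases)]
        res = roh.recessive_assoc_scan(mat, cases, controls)
        top = res.table.loc[res.table["p_value"].idxmin()]
        cc, cp = herd.config.causal_locus
        assert top["chrom"] == cc
        assert abs(top["pos"] - cp) < herd.config.low_hom_window_bp


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=4, max_size=40),
    st.integers(0, 2),
    st.integers(0, 2),
)
def test_roh_oracle_equivalence_property(row, max_het, max_missing):
    params = roh.RohParams(2, max_het, max_missing, 1)
    m = make_matrix(np.array(row, dtype=np.int8)[None, :])
    pos = m.markers["pos"].to_numpy()
    got = [(t[0], t[1]) for t in as_tuples(roh.call_roh(m, "A1", params), pos)]
    assert got == roh_oracle(row, pos, params)
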