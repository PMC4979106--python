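"""Meiosis model, crossing scheme, MAS selection and phenotype generation."""

import numpy as np
import pandas as pd
import pytest

import csslkit as ck
from csslkit import breeding_sim as bs
from csslkit.errors import ValidationError

from helpers import make_map, make_matrix


def _valid_hap(hap, length):
    ends, origins = hap
    assert len(ends) == len(origins) >= 1
    assert np.all(np.diff(ends) > 0)
    assert ends[-1] == pytest.approx(length)
    assert np.all(np.diff(origins) != 0)  # adjacent tracts alternate origin


class TestMeiosis:
    def test_zero_length_chromosome_never_recombines(self):
        gmap = make_map([0.0], length=0.0)
        parent = bs.f1(gmap)
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = bs.meiose(parent, gmap, rng)
            assert len(g["1"][0]) == 1

    def test_crossover_count_poisson_mean(self):
        """On a 100 cM chromosome the Haldane model gives a mean of 1.0
        crossovers per meiosis; check over 10,000 meioses within 3 SE."""
        gmap = make_map([50.0], length=100.0)
        parent = bs.f1(gmap)
        rng = np.random.default_rng(123)
        counts = []
        for _ in range(10_000):
            g = bs.meiose(parent, gmap, rng)
            ends, origins = g["1"]
            # the F1's haplotypes differ everywhere, so every crossover is an
            # origin switch: breakpoints count crossovers exactly
            counts.append(len(ends) - 1)
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 1.0) <= 3 * se

    def test_gamete_is_valid_tract_list(self, rice_map):
        parent = bs.f1(rice_map)
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = bs.meiose(parent, rice_map, rng)
            for c, length in rice_map.chromosomes.items():
                _valid_hap(g[c], length)
                assert set(np.asarray(g[c][1]).tolist()) <= {bs.RECURRENT, bs.DONOR}

    def test_obligate_chiasma_forces_a_crossover(self):
        gmap = make_map([5.0], length=10.0)  # 0.1 expected crossovers
        parent = bs.f1(gmap)
        rng = np.random.default_rng(5)
        for _ in range(50):
            g = bs.meiose(parent, gmap, rng, obligate_chiasma=True)
            assert len(g["1"][0]) >= 2  # at least one breakpoint

    def test_unknown_map_function_rejected(self, rice_map):
        with pytest.raises(ValidationError):
            bs.meiose(bs.f1(rice_map), rice_map, np.random.default_rng(0), map_function="morgan")


class TestBackcrossExpectations:
    def test_bc3f1_heterozygosity_and_donor_fraction(self):
        """Without selection, BC3F1 should carry donor chromatin on 6.25 %
        of the genome, all heterozygous (12.5 % of genome het), within 3 SE."""
        gmap = ck.default_rice_map()
        rec = bs.founder(gmap, bs.RECURRENT)
        hybrid = bs.f1(gmap)
        rng = np.random.default_rng(99)
        het, donor = [], []
        for _ in range(600):
            ind = hybrid
            for _ in range(3):
                ind = bs.cross(ind, rec, gmap, rng)
            het.append(bs.heterozygous_fraction(ind, gmap))
            donor.append(bs.donor_fraction(ind, gmap))
        for vals, expected in ((het, 0.125), (donor, 0.0625)):
            mean = np.mean(vals)
            se = np.std(vals) / np.sqrt(len(vals))
            assert abs(mean - expected) <= 3 * se

    def test_selfing_halves_heterozygosity(self):
        """One selfing generation halves expected heterozygosity; check the
        paired difference h_self - h_parent/2 is centred on zero."""
        gmap = ck.default_rice_map()
        rec = bs.founder(gmap, bs.RECURRENT)
        hybrid = bs.f1(gmap)
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(400):
            ind = hybrid
            for _ in range(2):
                ind = bs.cross(ind, rec, gmap, rng)
            h1 = bs.heterozygous_fraction(ind, gmap)
            selfed = bs.cross(ind, ind, gmap, rng)
            diffs.append(bs.heterozygous_fraction(selfed, gmap) - h1 / 2.0)
        mean = np.mean(diffs)
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(mean) <= 3 * se


class TestScheme:
    def test_run_scheme_deterministic(self, tiny_sim_config):
        m1, p1 = bs.run_scheme(tiny_sim_config)
        m2, p2 = bs.run_scheme(tiny_sim_config)
        pd.testing.assert_frame_equal(m1.calls, m2.calls)
        pd.testing.assert_frame_equal(p1, p2)

    def test_scheme_output_shape(self, tiny_sim_config):
        matrix, pedigree = bs.run_scheme(tiny_sim_config)
        assert matrix.n_lines == 8  # two branches of 4
        assert list(matrix.calls.columns) == tiny_sim_config.map.marker_ids
        assert set(pedigree["stage"]) >= {"F1", "BC1F1", "BC3F1-MAS"}
        assert matrix.calls.isin(["R", "D", "H"]).all().all()

    def test_mas_reduces_mean_segment_count(self, rice_map):
        """Selection on segment count must lower the population mean.

        BC1F1 plants carry many donor segments, so an exclusive threshold
        well below the population mean guarantees a strict reduction."""
        rec = bs.founder(rice_map, bs.RECURRENT)
        hybrid = bs.f1(rice_map)
        rng = np.random.default_rng(31)
        pop = {f"P{i:03d}": bs.cross(hybrid, rec, rice_map, rng) for i in range(60)}
        matrix = bs.genotype_matrix(pop, rice_map)
        summ = ck.line_summaries(ck.call_segments(matrix), matrix)
        pre_mean = summ["n_segments"].mean()
        chosen = bs.mas_select(matrix, bs.MASRule(max_segments=13, target=10))
        post_mean = summ[summ["line"].isin(chosen)]["n_segments"].mean()
        assert post_mean < pre_mean

    def test_invalid_population_size_rejected(self):
        with pytest.raises(ValidationError):
            bs.SimConfig(n_bc1=0)


class TestMASSelect:
    @pytest.fixture
    def ladder_matrix(self):
        """Four lines carrying 1, 2, 3 and 4 donor segments."""
        gmap = make_map([5, 15, 25, 35, 45, 55, 65, 75], length=80)
        return make_matrix(
            gmap,
            {
                "L1": "DRRRRRRR",
                "L2": "DRDRRRRR",
                "L3": "DRDRDRRR",
                "L4": "DRDRDRDR",
            },
        )

    def test_eligibility_threshold_is_exclusive(self, ladder_matrix):
        chosen = bs.mas_select(ladder_matrix, bs.MASRule(max_segments=3))
        assert set(chosen) == {"L1", "L2"}

    def test_identical_plants_zero_marginal_gain_still_selected(self):
        gmap = make_map([5, 15, 25], length=30)
        matrix = make_matrix(gmap, {"A": "DRR", "B": "DRR"})
        chosen = bs.mas_select(matrix, bs.MASRule(max_segments=3, target=2))
        assert sorted(chosen) == ["A", "B"]
        assert bs.mas_select(matrix, bs.MASRule(max_segments=3, target=1)) == ["A"]

    def test_greedy_matches_reference_implementation(self):
        """Lazy-heap greedy equals a plain best-first greedy on small random
        instances (ties by lowest line id)."""
        rng = np.random.default_rng(77)
        for _ in range(30):
            n_markers = 8
            gmap = make_map([5.0 * (i + 1) for i in range(n_markers)], length=45)
            n_lines = int(rng.integers(2, 9))
            calls = {
                f"L{i}": "".join(rng.choice(list("RD"), size=n_markers, p=[0.7, 0.3]))
                for i in range(n_lines)
            }
            matrix = make_matrix(gmap, calls)
            target = int(rng.integers(1, n_lines + 1))
            rule = bs.MASRule(max_segments=99, target=target)
            got = bs.mas_select(matrix, rule)

            # reference: naive greedy over merged cM interval unions
            segs = ck.call_segments(matrix)
            by_line = {lid: [(s.start_cm, s.end_cm) for s in segs if s.line == lid]
                       for lid in matrix.line_ids}
            selected, union = [], []
            remaining = sorted(matrix.line_ids)
            from csslkit.segment_calling import union_length

            while remaining and len(selected) < target:
                base = union_length(union)
                best = max(remaining, key=lambda l: (union_length(union + by_line[l]) - base, [-ord(c) for c in l]))
                selected.append(best)
                union = union + by_line[best]
                remaining.remove(best)
            assert got == selected

    def test_infeasible_target_selects_all_eligible(self, ladder_matrix, caplog):
        with caplog.at_level("WARNING"):
            chosen = bs.mas_select(ladder_matrix, bs.MASRule(max_segments=2, target=5))
        assert chosen == ["L1"]
        assert "infeasible" in caplog.text


class TestMarkerSubset:
    def test_subset_size_and_spread(self, rice_map):
        subset = bs.marker_subset(rice_map, 230)
        assert len(subset) == 230
        per_chrom = pd.Series([m.split("_")[0] for m in subset]).value_counts()
        assert len(per_chrom) == 12  # every chromosome keeps markers

    def test_target_larger_than_map_returns_all(self, rice_map):
        assert bs.marker_subset(rice_map, 1000) == rice_map.marker_ids


class TestPhenotypes:
    @pytest.fixture
    def matrix(self):
        gmap = make_map([5, 15, 25], length=30)
        return make_matrix(gmap, {"A": "DDD", "B": "RRR", "C": "HHH"})

    def test_noise_free_forward_model_is_exact(self, matrix):
        """With zero residual SD, a single QTL of effect 21.2 and intercept
        100 puts donor lines at 121.2 and recurrent lines at 78.8 exactly."""
        model = bs.TraitModel(
            name="days_to_heading", qtls=(("m2", 21.2),), intercept=100.0, residual_sd=0.0
        )
        ph = bs.simulate_phenotypes(matrix, [model], ["Nanjing"], np.random.default_rng(0))
        means = ph.groupby("line")["value"].mean()
        assert means["A"] == pytest.approx(121.2)
        assert means["B"] == pytest.approx(78.8)
        assert means["C"] == pytest.approx(100.0)  # heterozygote codes 0

    def test_fixed_seed_reproducible(self, matrix):
        model = bs.TraitModel(name="t", qtls=(("m1", 1.0),), residual_sd=2.0)
        p1 = bs.simulate_phenotypes(matrix, [model], ["S"], np.random.default_rng(11))
        p2 = bs.simulate_phenotypes(matrix, [model], ["S"], np.random.default_rng(11))
        pd.testing.assert_frame_equal(p1, p2)

    def test_unknown_qtl_marker_rejected(self, matrix):
        model = bs.TraitModel(name="t", qtls=(("nope", 1.0),))
        with pytest.raises(ValidationError, match="nope"):
            bs.simulate_phenotypes(matrix, [model], ["S"], np.random.default_rng(0))

    def test_per_site_intercepts_and_sd(self, matrix):
        model = bs.TraitModel(
            name="t", qtls=(), intercept={"N": 10.0, "S": 20.0}, residual_sd={"N": 0.0, "S": 0.0}
        )
        ph = bs.simulate_phenotypes(matrix, [model], ["N", "S"], np.random.default_rng(0))
        assert (ph[ph["site"] == "N"]["value"] == 10.0).all()
        assert (ph[ph["site"] == "S"]["value"] == 20.0).all()


def test_tract_to_marker_call_consistency(rice_map):
    """Segments called on a noiselessly reduced matrix land within half the
    local inter-marker gap of every true donor tract boundary."""
    rec = bs.founder(rice_map, bs.RECURRENT)
    hybrid = bs.f1(rice_map)
    rng = np.random.default_rng(55)
    ind = bs.cross(bs.cross(hybrid, rec, rice_map, rng), rec, rice_map, rng)
    matrix = bs.genotype_matrix({"P": ind}, rice_map)
    segs = ck.call_segments(matrix)
    for seg in segs:
        length = rice_map.chromosomes[seg.chromosome]
        pos = rice_map.positions_cm(seg.chromosome)
        gaps = np.diff(pos)
        max_half_gap = max(gaps.max() / 2, pos[0]) + 1e-9
        truth = []
        for ends, origins in ind[seg.chromosome]:
            starts = np.concatenate([[0.0], ends[:-1]])
            truth += [(s, e) for s, e, o in zip(starts, ends, origins) if o == bs.DONOR]
        # called start/end within half the local gap of a true tract boundary
        bounds = [b for iv in truth for b in iv] + [0.0, length]
        assert min(abs(seg.start_cm - b) for b in bounds) <= max_half_gap
        assert min(abs(seg.end_cm - b) for b in bounds) <= max_half_gap
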