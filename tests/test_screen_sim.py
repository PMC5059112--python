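"""Screen simulator: infection statistics, growth dynamics, sequencing."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pathscreen import (
    CellPopulation,
    Dose,
    ReadLayout,
    SampleRow,
    ScreenScenario,
    generate_screen,
    preset_scenario,
    simulate_arm,
    simulate_infection,
    simulate_sequencing,
)
from pathscreen.errors import LayoutError
from pathscreen.screen_sim import (
    DEFAULT_LAYOUT,
    make_index_set,
    subseed,
)
from pathscreen.manifest import hamming


def singleton_fraction(pop):
    total = pop.total_cells()
    single = sum(n for g, n in pop.abundance.items() if len(g) == 1)
    return single / total, total


class TestInfection:
    def test_poisson_conditional_singleton_fraction(self, manifest):
        """At MOI 0.3 the surviving pool is lam*e^-lam/(1-e^-lam) single-construct."""
        lam = 0.3
        pop = simulate_infection(200_000, lam, manifest, seed=42)
        frac, n = singleton_fraction(pop)
        expected = lam * math.exp(-lam) / (1 - math.exp(-lam))
        ci = 3 * math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < ci

    def test_low_moi_limit_all_singletons(self, manifest):
        pop = simulate_infection(10_000, 0.001, manifest, seed=1)
        frac, n = singleton_fraction(pop)
        assert n > 0 and frac == 1.0

    def test_equal_representation_chi_square(self, manifest):
        """Uniform library draw: per-construct counts consistent with uniform."""
        pop = simulate_infection(200_000, 0.3, manifest, seed=7)
        counts = pop.template_counts(manifest.construct_ids)
        res = stats.chisquare(counts)
        assert res.pvalue > 1e-3

    def test_weighted_library_skews_representation(self, manifest):
        w = np.ones(len(manifest))
        w[0] = 10.0
        pop = simulate_infection(50_000, 0.3, manifest, seed=3, weights=w)
        counts = pop.template_counts(manifest.construct_ids)
        assert counts[0] > 3 * counts[1:].mean()

    def test_bad_arguments_rejected(self, manifest):
        with pytest.raises(ValueError):
            simulate_infection(0, 0.3, manifest, seed=0)
        with pytest.raises(ValueError):
            simulate_infection(100, -1.0, manifest, seed=0)


class TestGrowth:
    @staticmethod
    def _scenario(**kw):
        defaults = dict(
            n_cells=10_000,
            doses=(Dose("d1", 0.8),),
            days=7,
            capacity=10**12,  # no passaging: deterministic expectation applies
            effects={},
            seed=0,
        )
        defaults.update(kw)
        return ScreenScenario(**defaults).validate()

    def test_zero_days_identity(self):
        pop = CellPopulation({("A",): 100, ("B",): 200})
        out = simulate_arm(pop, self._scenario(days=0), "d1", seed=1)
        assert out.abundance == pop.abundance

    def test_unknown_dose_label_rejected(self):
        pop = CellPopulation({("A",): 100})
        with pytest.raises(ValueError, match="unknown dose"):
            simulate_arm(pop, self._scenario(), "nope", seed=1)

    def test_mean_field_recurrence_oracle(self):
        """Large-population frequencies match the deterministic recurrence."""
        sc = self._scenario(effects={"R": {"d1": 0.0}})
        n0 = 50_000
        pop = CellPopulation({("R",): n0, ("S1",): n0, ("S2",): n0})
        out = simulate_arm(pop, sc, "d1", seed=5)
        # closed-form expectation: count * 2^(rate*days)
        f_resistant = 2.0 ** (1.0 * 7)
        f_sensitive = 2.0 ** ((1 - 0.8) * 7)
        expected = np.array([f_resistant, f_sensitive, f_sensitive]) * n0
        expected_freq = expected / expected.sum()
        got = np.array(
            [out.abundance.get(g, 0) for g in [("R",), ("S1",), ("S2",)]], float
        )
        got_freq = got / got.sum()
        assert np.allclose(got_freq, expected_freq, atol=0.005)

    def test_resistant_construct_enriches_in_drug_not_vehicle(self):
        sc = self._scenario(effects={"R": {"d1": 0.0}})
        pop = CellPopulation({("R",): 20_000, ("S",): 20_000})
        drug = simulate_arm(pop, sc, "d1", seed=2)
        veh = simulate_arm(pop, sc, "vehicle", seed=2)
        f = lambda p: p.abundance[("R",)] / p.total_cells()
        assert f(drug) > 0.9
        assert abs(f(veh) - 0.5) < 0.05

    def test_vehicle_growth_preserves_frequencies_under_passaging(self):
        """Splits add drift only: frequencies stay near their start values."""
        sc = self._scenario(days=10, capacity=200_000, split_fraction=0.1)
        pop = CellPopulation({("A",): 30_000, ("B",): 15_000, ("C",): 5_000})
        start = {g: n / 50_000 for g, n in pop.abundance.items()}
        out = simulate_arm(pop, sc, "vehicle", seed=9)
        total = out.total_cells()
        for g, f0 in start.items():
            assert abs(out.abundance[g] / total - f0) < 0.03

    def test_multiplet_uses_strongest_effect(self):
        """A two-construct cell grows with the min-rho (dominant) effect."""
        sc = self._scenario(effects={"R": {"d1": 0.0}}, days=5)
        pop = CellPopulation({("R", "S"): 10_000, ("S",): 10_000})
        out = simulate_arm(pop, sc, "d1", seed=3)
        f_multi = out.abundance[("R", "S")] / out.total_cells()
        assert f_multi > 0.9


class TestSequencing:
    def test_error_free_reads_round_trip(self, manifest, mini_samplesheet):
        row = mini_samplesheet.rows[0]
        pop = CellPopulation({(c,): 50 for c in manifest.construct_ids})
        sample = simulate_sequencing(
            pop, row, DEFAULT_LAYOUT, manifest, depth=2_000, error_rate=0.0, seed=1
        )
        barcode_map = manifest.barcode_map()
        assert len(sample.reads) == 2_000
        for read in sample.reads:
            assert len(read) == 27
            assert read[4:21] == DEFAULT_LAYOUT.linker_seq
            assert read[21:27] == row.index_seq
            assert read[:4] in barcode_map
        assert int(sample.template_draw.sum()) == 2_000

    def test_single_construct_population(self, manifest, mini_samplesheet):
        cid = manifest.construct_ids[0]
        pop = CellPopulation({(cid,): 10})
        sample = simulate_sequencing(
            pop, mini_samplesheet.rows[0], DEFAULT_LAYOUT, manifest,
            depth=500, error_rate=0.0, seed=2,
        )
        bc = manifest.record(cid).barcode
        assert all(r[:4] == bc for r in sample.reads)

    def test_substitution_fraction_matches_closed_form(
        self, manifest, mini_samplesheet
    ):
        """P(read has >= 1 substitution) = 1 - (1-eps)^27."""
        eps = 0.01
        row = mini_samplesheet.rows[0]
        pop = CellPopulation({(c,): 50 for c in manifest.construct_ids})
        sample = simulate_sequencing(
            pop, row, DEFAULT_LAYOUT, manifest, depth=20_000, error_rate=eps, seed=3
        )
        clean = {
            rec.barcode + DEFAULT_LAYOUT.linker_seq + row.index_seq
            for rec in manifest
        }
        frac_err = sum(r not in clean for r in sample.reads) / len(sample.reads)
        expected = 1 - (1 - eps) ** 27
        sd = math.sqrt(expected * (1 - expected) / 20_000)
        assert abs(frac_err - expected) < 4 * sd

    def test_index_length_mismatch_rejected(self, manifest):
        row = SampleRow("s", "ACGT", "vehicle", "lo")  # 4-nt index, layout wants 6
        pop = CellPopulation({(manifest.construct_ids[0],): 10})
        with pytest.raises(LayoutError):
            simulate_sequencing(
                pop, row, DEFAULT_LAYOUT, manifest, depth=10, error_rate=0, seed=0
            )

    def test_zero_depth_rejected(self, manifest, mini_samplesheet):
        pop = CellPopulation({(manifest.construct_ids[0],): 10})
        with pytest.raises(ValueError):
            simulate_sequencing(
                pop, mini_samplesheet.rows[0], DEFAULT_LAYOUT, manifest,
                depth=0, error_rate=0, seed=0,
            )


class TestLayoutAndIndices:
    def test_default_layout_is_27nt(self):
        assert DEFAULT_LAYOUT.total_len == 4 + 17 + 6 == 27
        assert DEFAULT_LAYOUT.linker_seq.endswith("ATG")

    def test_invalid_linker_rejected(self):
        with pytest.raises(LayoutError):
            ReadLayout(linker_seq="CTAGCGCCGCCACCAAA").validate()  # no ATG
        with pytest.raises(LayoutError):
            ReadLayout(linker_seq="CTAGCGCCGCCACXATG").validate()  # bad base

    def test_index_set_pairwise_distance(self):
        idx = make_index_set(20, seed=1)
        assert len(set(idx)) == 20
        for a, b in itertools.combinations(idx, 2):
            assert hamming(a, b) >= 3


class TestGenerateScreen:
    def test_seven_populations_and_outputs(self, manifest, tiny_scenario, tmp_path):
        out = generate_screen(tiny_scenario, manifest, tmp_path)
        assert len(out.populations) == 7  # t0 + 3 drug + 3 vehicle
        assert out.fastq_path.exists()
        assert out.samplesheet_path.exists()
        # truth covers every construct at every dose
        assert len(out.truth) == len(manifest) * 3
        assert set(out.truth["rho"]) == {1.0}
        n_reads = sum(1 for line in open(out.fastq_path) if line.startswith("@"))
        assert n_reads == tiny_scenario.read_depth * len(out.samplesheet)

    def test_fixed_seed_byte_identical(self, manifest, tiny_scenario, tmp_path):
        a = generate_screen(tiny_scenario, manifest, tmp_path / "a")
        b = generate_screen(tiny_scenario, manifest, tmp_path / "b")
        assert a.fastq_path.read_bytes() == b.fastq_path.read_bytes()

    def test_different_seed_differs(self, manifest, tiny_scenario, tmp_path):
        import dataclasses

        other = dataclasses.replace(tiny_scenario, seed=tiny_scenario.seed + 1)
        a = generate_screen(tiny_scenario, manifest, tmp_path / "a")
        b = generate_screen(other, manifest, tmp_path / "b")
        assert a.fastq_path.read_bytes() != b.fastq_path.read_bytes()

    def test_zero_depth_rejected(self, manifest, tiny_scenario, tmp_path):
        import dataclasses

        bad = dataclasses.replace(tiny_scenario, read_depth=0)
        with pytest.raises(ValueError):
            generate_screen(bad, manifest, tmp_path)

    def test_scenario_yaml_round_trip(self, tmp_path):
        sc = preset_scenario("uacc62-mek-planted", seed=5)
        p = tmp_path / "sc.yaml"
        sc.to_yaml(p)
        again = ScreenScenario.from_yaml(p)
        assert again == sc

    def test_subseeds_stable_and_distinct(self):
        assert subseed(1, "infection") == subseed(1, "infection")
        assert subseed(1, "infection") != subseed(1, "split")
        assert subseed(1, "infection") != subseed(2, "infection")
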