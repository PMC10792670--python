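"""Ensemble filtering, Boltzmann weighting, scaling, and broadening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iris_elucidate.constants import R_GAS
from iris_elucidate.fixtures import make_conformer_set
from iris_elucidate.theory import (
    BroadeningPolicy,
    ConformerRecord,
    EnsemblePolicy,
    boltzmann_weights,
    broaden,
    dedup_conformers,
    ensemble_spectrum,
    filter_ensemble,
    parse_frequency_output,
    scale_frequencies,
)


def conf(cid, g, site="O1", freqs=(1000.0,), intens=(100.0,), fp=None):
    return ConformerRecord(
        id=cid,
        gibbs_free_energy=g,
        frequencies=np.array(freqs),
        intensities=np.array(intens),
        ionization_site_tag=site,
        geometry_fingerprint=fp,
    )


class TestDedup:
    def test_identical_records_collapse(self):
        a = conf("a", 0.0, fp=(1.0, 2.0, 3.0))
        b = conf("b", 0.0, fp=(1.0, 2.0, 3.0))
        assert len(dedup_conformers([a, b])) == 1

    def test_energy_separated_records_kept(self):
        a = conf("a", 0.0, fp=(1.0, 2.0, 3.0))
        b = conf("b", 5.0, fp=(1.0, 2.0, 3.0))
        assert len(dedup_conformers([a, b], energy_tol=0.5)) == 2

    def test_clustered_fixture_group_count_recovered(self, rng):
        # 4 groups of 3 copies each; copies differ by tiny energy jitter
        records = []
        for g in range(4):
            fp = tuple(rng.uniform(0.5, 3.0, 3))
            for k in range(3):
                records.append(
                    conf(f"g{g}k{k}", 10.0 * g + rng.uniform(0, 0.01), fp=fp)
                )
        assert len(dedup_conformers(records)) == 4

    def test_lowest_energy_representative_survives(self):
        a = conf("hi", 0.05, fp=(1.0, 2.0, 3.0))
        b = conf("lo", 0.0, fp=(1.0, 2.0, 3.0))
        (kept,) = dedup_conformers([a, b])
        assert kept.id == "lo"


class TestFilterEnsemble:
    def test_energy_window_boundary_inclusive(self):
        records = [conf("a", 0.0), conf("b", 39.0), conf("c", 41.0), conf("d", 40.0)]
        kept = filter_ensemble(records, EnsemblePolicy())
        assert sorted(r.id for r in kept) == ["a", "b", "d"]

    def test_per_site_cap(self):
        records = [conf(f"c{i:02d}", float(i)) for i in range(25)]
        kept = filter_ensemble(records, EnsemblePolicy(per_site_cap=20))
        assert len(kept) == 20
        assert max(r.gibbs_free_energy for r in kept) == 19.0

    def test_cap_applies_per_site(self):
        records = [conf(f"a{i}", float(i), site="O1") for i in range(5)] + [
            conf(f"b{i}", float(i), site="O2") for i in range(5)
        ]
        kept = filter_ensemble(records, EnsemblePolicy(per_site_cap=3))
        assert len(kept) == 6

    def test_invalid_records_dropped_and_empty_errors(self):
        bad = conf("bad", 0.0, freqs=(-50.0,))
        assert not bad.valid
        with pytest.raises(ValueError):
            filter_ensemble([bad])


class TestBoltzmannWeights:
    def test_equal_energies_split_evenly(self):
        np.testing.assert_allclose(boltzmann_weights([3.0, 3.0]), [0.5, 0.5])

    def test_single_conformer(self):
        np.testing.assert_allclose(boltzmann_weights([12.0]), [1.0])

    def test_rt_ln2_gives_two_thirds(self):
        ddg = R_GAS * 298.15 * math.log(2) / 1000.0
        np.testing.assert_allclose(
            boltzmann_weights([0.0, ddg]), [2.0 / 3.0, 1.0 / 3.0], atol=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        energies=st.lists(
            st.floats(min_value=0, max_value=100), min_size=1, max_size=10
        ),
        shift=st.floats(min_value=-500, max_value=500),
    )
    def test_sum_to_one_and_shift_invariant(self, energies, shift):
        w = boltzmann_weights(energies)
        assert abs(w.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(
            w, boltzmann_weights([e + shift for e in energies]), atol=1e-9
        )

    def test_weights_decrease_with_energy(self):
        w = boltzmann_weights([0.0, 1.0, 2.0, 5.0])
        assert all(np.diff(w) < 0)

    def test_temperature_limits(self):
        lo = boltzmann_weights([0.0, 1.0, 2.0], temperature=1e-3)
        assert lo[0] == pytest.approx(1.0)
        hi = boltzmann_weights([0.0, 1.0, 2.0], temperature=1e9)
        np.testing.assert_allclose(hi, [1 / 3] * 3, atol=1e-6)

    def test_overflow_safe_for_huge_energies(self):
        w = boltzmann_weights([1e6, 1e6 + 1.0])
        assert np.isfinite(w).all() and abs(w.sum() - 1.0) < 1e-12


class TestScaling:
    @pytest.mark.parametrize(
        "freq,expected", [(1000.0, 975.0), (3000.0, 2865.0), (2500.0, 2387.5)]
    )
    def test_region_factors(self, freq, expected):
        assert scale_frequencies([freq])[0] == pytest.approx(expected)

    def test_s_mode_factor_overrides_fingerprint(self):
        out = scale_frequencies([1250.0, 1250.0], s_mode_flags=[True, False])
        np.testing.assert_allclose(out, [1311.25, 1218.75])

    def test_ordering_preserved_within_region(self, rng):
        freqs = np.sort(rng.uniform(600, 2400, 50))
        out = scale_frequencies(freqs)
        assert np.all(np.diff(out) > 0)


class TestBroaden:
    def test_area_conserved(self):
        policy = BroadeningPolicy(grid_start=500, grid_stop=1500, grid_step=0.5)
        spec = broaden([(1000.0, 123.0)], policy)
        area = np.trapezoid(spec.values, spec.grid)
        assert area == pytest.approx(123.0, rel=1e-3)

    def test_sigma_from_fwhm(self):
        assert BroadeningPolicy(fwhm=20.0).sigma == pytest.approx(8.4932, abs=1e-4)

    def test_empty_sticks_give_zero_spectrum(self):
        spec = broaden([])
        assert spec.values.sum() == 0.0

    def test_linearity(self):
        policy = BroadeningPolicy(grid_start=500, grid_stop=2000, grid_step=1.0)
        a = [(800.0, 10.0)]
        b = [(1200.0, 30.0), (1500.0, 5.0)]
        np.testing.assert_allclose(
            broaden(a, policy).values + broaden(b, policy).values,
            broaden(a + b, policy).values,
            atol=1e-12,
        )


class TestEnsembleSpectrum:
    def test_single_conformer_equals_own_spectrum(self):
        rec = conf("only", 0.0, freqs=(900.0, 1600.0), intens=(50.0, 200.0))
        out = ensemble_spectrum([rec])
        scaled = scale_frequencies(rec.frequencies)
        ref = broaden(list(zip(scaled, rec.intensities)))
        np.testing.assert_allclose(out.values, ref.values / ref.values.max(), atol=1e-12)

    def test_two_conformer_weighted_sum(self):
        a = conf("a", 0.0, freqs=(900.0,), intens=(100.0,), fp=(1, 1, 1))
        b = conf("b", 3.0, freqs=(1500.0,), intens=(100.0,), fp=(2, 2, 2))
        out = ensemble_spectrum([a, b])
        w = boltzmann_weights([0.0, 3.0])
        ref = w[0] * broaden([(900.0 * 0.975, 100.0)]).values + w[1] * broaden(
            [(1500.0 * 0.975, 100.0)]
        ).values
        np.testing.assert_allclose(out.values, ref / ref.max(), atol=1e-12)

    def test_input_order_invariance(self):
        records, _ = make_conformer_set(6, 12.0, seed=5)
        fwd = ensemble_spectrum(records)
        rev = ensemble_spectrum(records[::-1])
        np.testing.assert_allclose(fwd.values, rev.values, atol=1e-12)

    def test_population_recovery_from_peak_areas(self):
        """Peak-area ratios of well-separated bands match the generator's
        Boltzmann populations within 1%."""
        records, weights = make_conformer_set(
            2, 4.0, band_centers=[900.0], seed=9
        )
        # give the two conformers disjoint single bands of equal intensity
        records[0].frequencies = np.array([900.0])
        records[0].intensities = np.array([100.0])
        records[1].frequencies = np.array([2000.0])
        records[1].intensities = np.array([100.0])
        spec = ensemble_spectrum(records, dedup=False)
        mid = spec.grid < 1500.0
        a0 = np.trapezoid(spec.values[mid], spec.grid[mid])
        a1 = np.trapezoid(spec.values[~mid], spec.grid[~mid])
        ratio = a0 / (a0 + a1)
        assert ratio == pytest.approx(weights[0], abs=0.01)


class TestFrequencyParser:
    TEXT = """
 Frequencies --    800.1234   1600.5678
 IR Inten    --     10.0000     55.0000
 Sum of electronic and thermal Free Energies=            -100.000000
"""

    def test_known_block(self):
        (rec,) = parse_frequency_output(self.TEXT)
        np.testing.assert_allclose(rec.frequencies, [800.1234, 1600.5678])
        np.testing.assert_allclose(rec.intensities, [10.0, 55.0])
        assert rec.gibbs_free_energy == pytest.approx(-100.0 * 2625.4996394799)
        assert rec.valid

    def test_two_blocks(self):
        recs = parse_frequency_output(self.TEXT + self.TEXT)
        assert len(recs) == 2

    def test_empty_text_errors(self):
        with pytest.raises(ValueError):
            parse_frequency_output("")

    def test_imaginary_frequency_flagged_invalid(self):
        text = self.TEXT.replace("800.1234", "-800.1234")
        (rec,) = parse_frequency_output(text)
        assert not rec.valid
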