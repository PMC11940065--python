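"""CD spectral arithmetic: units, conversions, differences, dilutions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrkit import (
    CDSpectrum,
    GridMismatchError,
    ME,
    MILLIDEGREES,
    MRE,
    MRE_PER_ME,
    MixtureMeta,
    SampleMeta,
    UnitError,
    average_spectra,
    convert_mre_me,
    difference_spectrum,
    expected_noninteracting,
    from_mre,
    plan_dilution,
    read_spectrum,
    resample,
    subtract_blank,
    to_mre,
    to_mre_mixture,
    write_spectrum,
)


def mdeg(grid, values):
    return CDSpectrum(grid, values, MILLIDEGREES)


class TestCDSpectrum:
    def test_requires_ascending_grid(self, grid):
        with pytest.raises(ValueError, match="ascending"):
            CDSpectrum(grid[::-1], np.zeros(grid.size), MILLIDEGREES)

    def test_rejects_unknown_unit(self, grid):
        with pytest.raises(UnitError):
            CDSpectrum(grid, np.zeros(grid.size), "volts")

    def test_rejects_out_of_band_wavelengths(self):
        with pytest.raises(ValueError):
            CDSpectrum(np.array([100.0, 200.0]), np.zeros(2), MILLIDEGREES)

    def test_value_at_interpolates(self):
        spec = CDSpectrum(np.array([199.0, 201.0]), np.array([4.0, 6.0]), MRE)
        assert spec.value_at(200.0) == pytest.approx(5.0)

    def test_value_at_outside_span(self):
        spec = CDSpectrum(np.array([205.0, 250.0]), np.zeros(2), MRE)
        with pytest.raises(ValueError):
            spec.value_at(200.0)


class TestSubtractBlank:
    def test_self_subtraction_is_zero(self, grid):
        spec = mdeg(grid, np.random.default_rng(0).normal(size=grid.size))
        assert np.all(subtract_blank(spec, spec).values == 0)

    def test_pointwise_arithmetic(self, grid):
        out = subtract_blank(
            mdeg(grid, np.full(grid.size, 5.0)), mdeg(grid, np.full(grid.size, 1.5))
        )
        assert np.allclose(out.values, 3.5)

    def test_grid_mismatch_names_both_grids(self, grid):
        a = mdeg(grid, np.zeros(grid.size))
        b = mdeg(grid[5:], np.zeros(grid.size - 5))
        with pytest.raises(GridMismatchError, match="195"):
            subtract_blank(a, b)

    def test_unit_mismatch(self, grid):
        a = mdeg(grid, np.zeros(grid.size))
        b = CDSpectrum(grid, np.zeros(grid.size), MRE)
        with pytest.raises(UnitError):
            subtract_blank(a, b)


class TestToMre:
    def test_hand_evaluation(self, grid):
        # 1 mdeg / (10 * 0.1 cm * 1e-5 M * 100 bonds) = 1000 deg cm^2/dmol
        meta = SampleMeta(0.1, 1e-5, 100)
        out = to_mre(mdeg(grid, np.ones(grid.size)), meta)
        assert np.allclose(out.values, 1000.0)
        assert out.unit == MRE

    def test_linearity(self, grid, meta):
        values = np.random.default_rng(1).normal(size=grid.size)
        single = to_mre(mdeg(grid, values), meta)
        doubled = to_mre(mdeg(grid, 2 * values), meta)
        assert np.allclose(doubled.values, 2 * single.values)

    def test_round_trip_with_from_mre(self, grid, meta):
        values = np.random.default_rng(2).normal(size=grid.size)
        back = from_mre(to_mre(mdeg(grid, values), meta), meta)
        assert np.allclose(back.values, values)

    def test_invalid_meta(self):
        with pytest.raises(ValueError):
            SampleMeta(0.0, 1e-5, 100)
        with pytest.raises(ValueError):
            SampleMeta(0.1, -1e-5, 100)
        with pytest.raises(ValueError):
            SampleMeta(0.1, 1e-5, 0)


class TestMixtureMre:
    def test_paper_convention_hand_value(self, grid):
        mix = MixtureMeta(SampleMeta(0.1, 1e-5, 111), SampleMeta(0.1, 1e-5, 227))
        out = to_mre_mixture(mdeg(grid, np.full(grid.size, 2.0)), mix, "paper")
        # 2 / (10 * 0.1 * 1e-5 * (111+227)/2) = 2 / 1.69e-3
        assert np.allclose(out.values, 2.0 / (10 * 0.1 * 1e-5 * 169))

    def test_paper_convention_reduces_to_single_protein_form(self, grid):
        meta = SampleMeta(0.1, 1e-5, 150)
        mix = MixtureMeta(meta, meta)
        values = np.random.default_rng(3).normal(size=grid.size)
        via_mixture = to_mre_mixture(mdeg(grid, values), mix, "paper")
        via_single = to_mre(mdeg(grid, values), meta)
        assert np.allclose(via_mixture.values, via_single.values)

    def test_total_residue_convention_recovers_weighted_mean(self, grid):
        # Forward-simulate a strictly additive mixture and check the
        # normalisation returns the concentration-weighted component mean.
        rng = np.random.default_rng(4)
        meta_a = SampleMeta(0.1, 1e-5, 111)
        meta_b = SampleMeta(0.1, 2e-5, 227)
        mre_a, mre_b = rng.normal(size=grid.size), rng.normal(size=grid.size)
        mdeg_mix = (
            mre_a * 10 * 0.1 * meta_a.molarity * meta_a.n_peptide_bonds
            + mre_b * 10 * 0.1 * meta_b.molarity * meta_b.n_peptide_bonds
        )
        out = to_mre_mixture(
            mdeg(grid, mdeg_mix), MixtureMeta(meta_a, meta_b), "total-residue"
        )
        wa = meta_a.molarity * meta_a.n_peptide_bonds
        wb = meta_b.molarity * meta_b.n_peptide_bonds
        assert np.allclose(out.values, (wa * mre_a + wb * mre_b) / (wa + wb))

    def test_mismatched_pathlengths_rejected(self):
        with pytest.raises(ValueError, match="pathlength"):
            MixtureMeta(SampleMeta(0.1, 1e-5, 10), SampleMeta(0.2, 1e-5, 10))


class TestMreMeConversion:
    def test_constant_is_3298(self, grid):
        spec = CDSpectrum(grid, np.full(grid.size, 3298.0), MRE)
        assert np.allclose(convert_mre_me(spec, "MRE->ME").values, 1.0)

    def test_hand_values(self, grid):
        spec = CDSpectrum(grid, np.full(grid.size, -6596.0), MRE)
        assert np.allclose(convert_mre_me(spec, "MRE->ME").values, -2.0)

    def test_round_trip_is_identity_to_machine_precision(self, grid):
        values = np.random.default_rng(5).normal(scale=1e4, size=grid.size)
        spec = CDSpectrum(grid, values, MRE)
        back = convert_mre_me(convert_mre_me(spec, "MRE->ME"), "ME->MRE")
        assert np.allclose(back.values, values, rtol=1e-15, atol=0)
        ratio = spec.values / convert_mre_me(spec, "MRE->ME").values
        assert np.allclose(ratio, MRE_PER_ME, rtol=1e-15)

    def test_wrong_unit_rejected(self, grid):
        spec = CDSpectrum(grid, np.zeros(grid.size), MILLIDEGREES)
        with pytest.raises(UnitError):
            convert_mre_me(spec, "MRE->ME")


class TestAverageSpectra:
    def test_single_spectrum_identity(self, flat_mdeg):
        assert np.array_equal(average_spectra([flat_mdeg]).values, flat_mdeg.values)

    def test_idempotent_on_duplicates(self, flat_mdeg):
        out = average_spectra([flat_mdeg, flat_mdeg, flat_mdeg])
        assert np.array_equal(out.values, flat_mdeg.values)

    def test_pointwise_mean(self, grid):
        out = average_spectra(
            [mdeg(grid, np.full(grid.size, 2.0)), mdeg(grid, np.full(grid.size, 4.0))]
        )
        assert np.allclose(out.values, 3.0)

    def test_noise_reduction_scales_with_replicates(self, grid):
        rng = np.random.default_rng(6)
        n_rep = 16
        reps = [mdeg(grid, rng.normal(size=grid.size)) for _ in range(n_rep)]
        avg = average_spectra(reps)
        # variance of the mean ~ 1/n; allow generous statistical slack
        assert avg.values.var() < 3.0 / n_rep

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_spectra([])


class TestExpectedAndDifference:
    def test_arithmetic_mean(self, grid):
        a = CDSpectrum(grid, np.full(grid.size, -10000.0), MRE)
        b = CDSpectrum(grid, np.full(grid.size, -2000.0), MRE)
        assert np.allclose(expected_noninteracting(a, b).values, -6000.0)

    def test_identical_components_in_both_modes(self, grid, meta):
        a = CDSpectrum(grid, np.full(grid.size, -5000.0), MRE, meta)
        for mode in ("arithmetic", "weighted"):
            assert np.allclose(expected_noninteracting(a, a, mode).values, -5000.0)

    def test_weighted_equals_arithmetic_at_equal_weights(self, grid):
        meta = SampleMeta(0.1, 1e-5, 100)
        rng = np.random.default_rng(7)
        a = CDSpectrum(grid, rng.normal(size=grid.size), MRE, meta)
        b = CDSpectrum(grid, rng.normal(size=grid.size), MRE, meta)
        assert np.allclose(
            expected_noninteracting(a, b, "weighted").values,
            expected_noninteracting(a, b, "arithmetic").values,
        )

    def test_difference_sign_convention(self, grid):
        expected = CDSpectrum(grid, np.full(grid.size, -6000.0), MRE)
        measured = CDSpectrum(grid, np.full(grid.size, -7000.0), MRE)
        # mixture subtracted FROM the average: -6000 - (-7000) = +1000
        assert np.allclose(difference_spectrum(expected, measured).values, 1000.0)

    def test_difference_null_case(self, grid):
        spec = CDSpectrum(grid, np.random.default_rng(8).normal(size=grid.size), MRE)
        assert np.all(difference_spectrum(spec, spec).values == 0)

    def test_difference_antisymmetry(self, grid):
        rng = np.random.default_rng(9)
        a = CDSpectrum(grid, rng.normal(size=grid.size), MRE)
        b = CDSpectrum(grid, rng.normal(size=grid.size), MRE)
        assert np.allclose(
            difference_spectrum(a, b).values, -difference_spectrum(b, a).values
        )


class TestBlankThenNormalizeCommutes:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_commutation(self, seed):
        grid = np.arange(190.0, 251.0)
        rng = np.random.default_rng(seed)
        meta = SampleMeta(0.1, 1e-5, 100)
        sample = mdeg(grid, rng.normal(size=grid.size))
        blank = mdeg(grid, rng.normal(size=grid.size))
        first = to_mre(subtract_blank(sample, blank), meta)
        second_vals = to_mre(sample, meta).values - to_mre(blank, meta).values
        assert np.allclose(first.values, second_vals, rtol=1e-12)


class TestPlanDilution:
    def test_twenty_pct_tfe_recipe(self):
        plan = plan_dilution(320, 12.5, 80)
        assert plan.final_conc_um == pytest.approx(10.0)
        assert plan.additive_fraction_pct == pytest.approx(20.0)

    def test_no_additive(self):
        plan = plan_dilution(100, 7.0, 0)
        assert plan.final_conc_um == pytest.approx(7.0)
        assert plan.additive_fraction_pct == 0.0

    def test_forty_pct_tfe_recipe_gives_10_2_not_10(self):
        # The 40% co-solvent recipe dilutes 17 µM by 240/400, i.e. to
        # 10.2 µM — not the nominal 10 µM; the package reports the exact
        # arithmetic rather than the rounded nominal value.
        plan = plan_dilution(240, 17.0, 160)
        assert plan.final_conc_um == pytest.approx(10.2)
        assert plan.additive_fraction_pct == pytest.approx(40.0)

    def test_zero_total_volume_rejected(self):
        with pytest.raises(ValueError):
            plan_dilution(0, 10.0, 0)


class TestSpectralIO:
    def test_txt_round_trip(self, tmp_path, grid):
        spec = mdeg(grid, np.random.default_rng(10).normal(size=grid.size))
        path = tmp_path / "spec.txt"
        write_spectrum(path, spec)
        back = read_spectrum(path)
        assert np.allclose(back.wavelengths, spec.wavelengths)
        assert np.allclose(back.values, spec.values)

    def test_gen_dialect_stores_descending(self, tmp_path, grid):
        spec = mdeg(grid, np.arange(grid.size, dtype=float))
        path = tmp_path / "spec.gen"
        write_spectrum(path, spec)
        lines = [
            l for l in path.read_text().splitlines() if l and not l.startswith("#")
        ]
        first_wl = float(lines[0].split()[0])
        assert first_wl == grid[-1]  # on disk: descending
        back = read_spectrum(path)
        assert np.allclose(back.wavelengths, spec.wavelengths)  # in memory: ascending
        assert np.allclose(back.values, spec.values)

    def test_comments_and_header_ignored(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text("wavelength signal\n# comment\n190 1.0\n191 2.0\n")
        spec = read_spectrum(path)
        assert len(spec) == 2

    def test_resample_requires_coverage(self, grid):
        spec = mdeg(grid, np.zeros(grid.size))
        with pytest.raises(ValueError):
            resample(spec, np.arange(185.0, 251.0))
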