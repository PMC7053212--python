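"""Concentric-sphere cellular dosimetry: deposition fractions and ratios."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from augerdose.cell_micro import (
    CellGeometry,
    DepositionFractions,
    SourceDistribution,
    cell_energy_partition,
    compartment_energy_fraction,
    deposition_fractions,
    nuclear_dose_ratio,
    nuclear_volume_fraction,
    tumor_nuclear_dose,
)


class TestGeometry:
    def test_default_nuclear_volume_fraction(self, cell_geometry):
        # (18/26)^3 = 33% of the cellular volume
        assert nuclear_volume_fraction(cell_geometry) == pytest.approx(
            (18.0 / 26.0) ** 3, rel=1e-12
        )
        assert 100.0 * nuclear_volume_fraction(cell_geometry) == pytest.approx(
            33.0, abs=0.5
        )

    def test_nucleus_equal_to_cell_limit(self):
        geom = CellGeometry(cell_diameter_um=26.0, nucleus_diameter_um=25.999999)
        assert nuclear_volume_fraction(geom) == pytest.approx(1.0, rel=1e-6)

    def test_half_diameter_cube_law(self):
        geom = CellGeometry(cell_diameter_um=26.0, nucleus_diameter_um=13.0)
        assert nuclear_volume_fraction(geom) == pytest.approx(0.125)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            CellGeometry(cell_diameter_um=20.0, nucleus_diameter_um=20.0)
        with pytest.raises(ValueError):
            CellGeometry(cell_diameter_um=20.0, nucleus_diameter_um=0.0)


class TestDepositionFractions:
    def test_compartment_ordering_invariant(self, cell_geometry, spectrum):
        phi = deposition_fractions(
            cell_geometry, spectrum, histories=40_000, seed=1
        )
        assert phi.phi["perinuclear"] > phi.phi["cytoplasm"] > phi.phi["membrane"]

    def test_backends_agree_on_all_compartments(self, cell_geometry, spectrum):
        for comp in ("perinuclear", "membrane", "cytoplasm"):
            mc, _ = compartment_energy_fraction(
                cell_geometry, comp, spectrum, histories=40_000, seed=2
            )
            pk, _ = compartment_energy_fraction(
                cell_geometry, comp, spectrum, backend="point_kernel"
            )
            assert mc == pytest.approx(pk, rel=0.10)

    def test_energy_conservation_per_compartment(self, cell_geometry, spectrum):
        for comp in ("perinuclear", "membrane", "cytoplasm", "nucleus"):
            part = cell_energy_partition(
                cell_geometry, comp, spectrum, histories=20_000, seed=3
            )
            assert sum(part["phi"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_full_containment_limit(self, spectrum):
        # nucleus much larger than any electron range: nucleus-interior
        # decays deposit essentially all their energy inside
        geom = CellGeometry(cell_diameter_um=2000.2, nucleus_diameter_um=2000.0)
        phi, _ = compartment_energy_fraction(
            geom, "nucleus", spectrum, backend="point_kernel"
        )
        assert phi > 0.93

    def test_unknown_compartment_rejected(self, cell_geometry):
        with pytest.raises(ValueError):
            compartment_energy_fraction(cell_geometry, "mitochondria")

    def test_seed_reproducibility(self, cell_geometry, spectrum):
        a = compartment_energy_fraction(
            cell_geometry, "perinuclear", spectrum, histories=10_000, seed=5
        )
        b = compartment_energy_fraction(
            cell_geometry, "perinuclear", spectrum, histories=10_000, seed=5
        )
        assert a == b

    def test_phi_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            DepositionFractions(phi={"perinuclear": 1.2})


class TestNuclearDoseRatio:
    PRINTED_PHI = {"perinuclear": 0.38, "membrane": 0.05, "cytoplasm": 0.08}

    def test_printed_inputs_reproduce_35_percent(self, cell_geometry):
        ratio = nuclear_dose_ratio(
            SourceDistribution(),
            self.PRINTED_PHI,
            nuclear_volume_fraction(cell_geometry),
        )
        assert 100.0 * ratio == pytest.approx(35.0, abs=0.6)

    def test_homogeneous_deposition_gives_unity(self):
        w = 0.33
        phi = {"perinuclear": w, "membrane": w, "cytoplasm": w}
        assert nuclear_dose_ratio(SourceDistribution(), phi, w) == pytest.approx(1.0)

    def test_all_perinuclear_hand_value(self):
        dist = SourceDistribution(perinuclear=1.0, membrane=0.0, cytoplasm=0.0)
        ratio = nuclear_dose_ratio(dist, self.PRINTED_PHI, 0.33)
        assert ratio == pytest.approx(0.38 / 0.33, rel=1e-9)

    def test_zero_mass_fraction_rejected(self):
        with pytest.raises(ValueError):
            nuclear_dose_ratio(SourceDistribution(), self.PRINTED_PHI, 0.0)

    @given(st.floats(min_value=0.05, max_value=0.95))
    def test_ratio_scales_inversely_with_mass_fraction(self, w):
        r1 = nuclear_dose_ratio(SourceDistribution(), self.PRINTED_PHI, w)
        r2 = nuclear_dose_ratio(SourceDistribution(), self.PRINTED_PHI, w / 2.0)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-9)


class TestTumorNuclearDose:
    def test_printed_inputs_give_about_100_gy(self):
        assert tumor_nuclear_dose(2.6, 111.0, 0.347) == pytest.approx(100.0, abs=1.5)

    def test_zero_activity_zero_dose(self):
        assert tumor_nuclear_dose(2.6, 0.0, 0.35) == 0.0

    def test_unit_ratio_equals_average_dose(self):
        assert tumor_nuclear_dose(2.6, 111.0, 1.0) == pytest.approx(288.6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            tumor_nuclear_dose(-1.0, 111.0, 0.35)


class TestSourceDistribution:
    def test_defaults_sum_to_one(self):
        d = SourceDistribution()
        assert sum(d.as_dict().values()) == pytest.approx(1.0)

    def test_non_unit_sum_rejected(self):
        with pytest.raises(ValueError):
            SourceDistribution(0.5, 0.5, 0.5)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            SourceDistribution(-0.1, 0.6, 0.5)
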