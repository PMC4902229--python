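"""Stereological estimators: point counting, tuft area, densities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nephromorph.errors import (
    InsufficientGlomeruliError,
    InvalidParameterError,
    UndefinedResultError,
)
from nephromorph.stereology import (
    CompartmentCounts,
    areal_glomerular_density,
    fractional_areas,
    mean_tuft_area,
    point_count_section,
    volumetric_density_wicksell,
)
from nephromorph.tissue import (
    FRACTION_COLUMNS,
    LabeledSection,
    TissueParams,
    generate_tissue_section,
)


def _uniform_section(label: int = 1, n: int = 512) -> LabeledSection:
    params = TissueParams(
        compartment_fractions=tuple(1.0 if i + 1 == label else 0.0 for i in range(6)),
        sclerotic_fraction=1.0 if label == 6 else 0.5,
    )
    return LabeledSection(
        label_grid=np.full((n, n), label, dtype=np.int8),
        glomerulus_id_grid=np.zeros((n, n), dtype=np.int32),
        patency_flags={},
        resolution=2.0,
        truth=params,
    )


class TestPointCounting:
    def test_uniform_interstitium_gives_all_125_points(self):
        counts = point_count_section(_uniform_section(1), seed=0)
        assert counts.n_points == 125
        assert counts.counts["FIA"] == 125
        assert all(counts.counts[c] == 0 for c in FRACTION_COLUMNS[1:])
        assert not counts.insufficient_tissue

    def test_each_grid_contributes_25_points(self):
        counts = point_count_section(_uniform_section(3), seed=1)
        assert counts.n_grids == 5
        assert all(sum(g.values()) == 25 for g in counts.per_grid)

    def test_seed_reproducibility(self, tissue_params):
        sec = generate_tissue_section(tissue_params, "direct2d", seed=3)
        a = point_count_section(sec, seed=77)
        b = point_count_section(sec, seed=77)
        assert a.counts == b.counts and a.per_grid == b.per_grid

    def test_small_section_flagged_insufficient(self):
        sec = _uniform_section(1, n=150)  # fits one 100-cell grid, not five
        counts = point_count_section(sec, seed=0)
        assert counts.insufficient_tissue
        assert counts.n_grids < 5
        assert counts.n_points == 25 * counts.n_grids

    def test_grid_larger_than_section_is_an_error(self):
        with pytest.raises(InvalidParameterError):
            point_count_section(_uniform_section(1, n=64), seed=0)

    def test_estimator_unbiased_with_clustered_variance(self):
        """Mean point-count estimate matches the generating fraction to
        3 Monte-Carlo SE; its variance matches the binomial variance
        inflated by a glomerular-clustering design effect fitted from
        the per-grid tallies."""
        params = TissueParams(
            compartment_fractions=(0.30, 0.05, 0.45, 0.10, 0.07, 0.03)
        )
        n_seeds = 600
        est = np.empty(n_seeds)
        grid_fracs = []
        for s in range(n_seeds):
            sec = generate_tissue_section(params, "direct2d", seed=s)
            counts = point_count_section(sec, seed=500_000 + s)
            est[s] = counts.counts["FIA"] / counts.n_points
            grid_fracs.append([g["FIA"] / 25 for g in counts.per_grid])
        se = est.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(est.mean() - 0.30) <= 3 * se

        # one-way ANOVA over grids -> intraclass correlation of points
        grid_fracs = np.asarray(grid_fracs)       # sections x 5 grids
        p = est.mean()
        msb = 25 * grid_fracs.var(axis=1, ddof=1).mean()
        within_var = (grid_fracs * (1 - grid_fracs) * 25 / 24).mean()
        icc = (msb - within_var) / (msb + 24 * within_var)
        deff = 1 + 24 * max(icc, 0.0)
        expected_var = p * (1 - p) / 125 * deff
        assert est.var(ddof=1) == pytest.approx(expected_var, rel=0.20)

    def test_duplicate_stain_estimates_track_section_differences(self):
        """Independent point-count passes over the same 56 sections
        (stand-ins for PAS vs trichrome) correlate strongly when the
        cohort's between-section FIA spread is wide."""
        rng = np.random.default_rng(8)
        fia_targets = rng.uniform(0.12, 0.55, 56)
        first, second = [], []
        for i, fia in enumerate(fia_targets):
            rest = 1.0 - fia
            params = TissueParams(
                compartment_fractions=(
                    fia, 0.05 * rest / 0.95, 0.62 * rest / 0.95,
                    0.18 * rest / 0.95, 0.08 * rest / 0.95, 0.02 * rest / 0.95,
                )
            )
            sec = generate_tissue_section(params, "direct2d", seed=100 + i)
            a = fractional_areas(point_count_section(sec, seed=1000 + i, stain_tag="PAS"))
            b = fractional_areas(point_count_section(sec, seed=2000 + i, stain_tag="TRI"))
            first.append(a.FIA)
            second.append(b.FIA)
        r = np.corrcoef(first, second)[0, 1]
        assert np.std(fia_targets) >= 0.1
        assert r > 0.8


class TestFractionalAreas:
    def test_arithmetic(self):
        counts = CompartmentCounts(
            counts=dict(zip(FRACTION_COLUMNS, (40, 5, 60, 15, 4, 1))),
            n_points=125, n_grids=5,
        )
        fr = fractional_areas(counts)
        assert (fr.FIA, fr.FITA, fr.FATA) == (0.32, 0.48, 0.12)
        assert (fr.FBVA, fr.FPGA, fr.FSGA) == (0.04, 0.032, 0.008)

    @given(st.lists(st.integers(0, 200), min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fractions_sum_to_one_for_any_complete_count(self, tallies):
        n = sum(tallies)
        counts = CompartmentCounts(
            counts=dict(zip(FRACTION_COLUMNS, tallies)), n_points=n, n_grids=5
        )
        if n == 0:
            with pytest.raises(UndefinedResultError):
                fractional_areas(counts)
        else:
            fr = fractional_areas(counts)
            assert sum(fr.as_series()) == pytest.approx(1.0, abs=1e-12)


class TestTuftArea:
    def test_mean_of_single_profiles(self):
        profiles = {1: [100.0], 2: [200.0], 3: [300.0], 4: [400.0]}
        a_g, k = mean_tuft_area(profiles, seed=0)
        assert a_g == 250.0 and k == 4

    def test_fewer_than_four_glomeruli_excluded(self):
        with pytest.raises(InsufficientGlomeruliError):
            mean_tuft_area({1: [100.0], 2: [200.0], 3: [300.0]}, seed=0)

    def test_seed_invariant_when_levels_identical(self):
        profiles = {g: [50.0 * g] * 3 for g in range(1, 6)}
        values = {mean_tuft_area(profiles, seed=s)[0] for s in range(5)}
        assert len(values) == 1


class TestDensities:
    def test_patent_only_counting(self):
        n = 200
        ids = np.zeros((n, n), dtype=np.int32)
        labels = np.ones((n, n), dtype=np.int8)
        for g in range(1, 13):
            ids[g * 3, g * 3] = g
            labels[g * 3, g * 3] = 5 if g <= 10 else 6
        sec = LabeledSection(
            label_grid=labels, glomerulus_id_grid=ids,
            patency_flags={g: g <= 10 for g in range(1, 13)},
            resolution=10.0, truth=TissueParams(),
        )
        assert sec.cortical_area == pytest.approx(4.0)
        assert areal_glomerular_density(sec) == pytest.approx(2.5)

    def test_no_glomeruli_gives_zero(self):
        assert areal_glomerular_density(_uniform_section(1)) == 0.0

    def test_wicksell_closed_forms(self):
        metrics = volumetric_density_wicksell(N_A=3.5, A_G=10000.0)
        assert metrics.D == pytest.approx(np.sqrt(4 * 10000 / np.pi))
        assert metrics.D == pytest.approx(112.84, abs=0.01)
        assert metrics.N_V == pytest.approx(3.5 / 0.11284, abs=0.05)
        with pytest.raises(InvalidParameterError):
            volumetric_density_wicksell(N_A=1.0, A_G=0.0)

    @given(st.floats(500.0, 50000.0), st.floats(0.0, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_wicksell_scaling_laws(self, a_g, n_a):
        """N_V is linear in N_A and scales as A_G^(-1/2)."""
        base = volumetric_density_wicksell(n_a, a_g)
        assert volumetric_density_wicksell(2 * n_a, a_g).N_V == pytest.approx(
            2 * base.N_V
        )
        assert volumetric_density_wicksell(n_a, 2 * a_g).N_V == pytest.approx(
            base.N_V / np.sqrt(2)
        )

    def test_sphere_section_density_identity(self):
        """Monodisperse sphere sections: mean patent N_A matches
        N_V * d * (1 - sclerotic fraction) to 3 Monte-Carlo SE."""
        params = TissueParams(
            compartment_fractions=(0.30, 0.05, 0.45, 0.10, 0.07, 0.03),
            glomerular_number_density=40.0, tuft_diameter_mean=120.0,
            tuft_diameter_cv=0.0, sclerotic_fraction=0.15,
        )
        n_seeds = 400
        nas = np.empty(n_seeds)
        for s in range(n_seeds):
            sec = generate_tissue_section(params, "sphere3d", seed=s)
            nas[s] = areal_glomerular_density(sec)
        expected = 40.0 * 120e-3 * 0.85
        se = nas.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(nas.mean() - expected) <= 3 * se
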