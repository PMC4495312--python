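import itertools

import numpy as np
import pytest

from structbias import (
    ParameterError,
    PopulationSpec,
    design_grid,
    population_parameters,
    solve_validity,
    table1,
)
from structbias.population import round_half_up

# the 27 printed (k, rho2_yy, rho_xx) -> (rho2_xy, rho2_structure) pairs
PRINTED_TABLE1 = {
    (2, 0.2, 0.1): (0.11, 0.55), (2, 0.5, 0.1): (0.28, 0.55),
    (2, 0.8, 0.1): (0.44, 0.55), (2, 0.2, 0.3): (0.13, 0.65),
    (2, 0.5, 0.3): (0.33, 0.65), (2, 0.8, 0.3): (0.52, 0.65),
    (2, 0.2, 0.5): (0.15, 0.75), (2, 0.5, 0.5): (0.38, 0.75),
    (2, 0.8, 0.5): (0.60, 0.75), (4, 0.2, 0.1): (0.07, 0.33),
    (4, 0.5, 0.1): (0.16, 0.33), (4, 0.8, 0.1): (0.26, 0.33),
    (4, 0.2, 0.3): (0.10, 0.48), (4, 0.5, 0.3): (0.24, 0.48),
    (4, 0.8, 0.3): (0.38, 0.48), (4, 0.2, 0.5): (0.13, 0.63),
    (4, 0.5, 0.5): (0.31, 0.63), (4, 0.8, 0.5): (0.50, 0.63),
    (8, 0.2, 0.1): (0.04, 0.21), (8, 0.5, 0.1): (0.11, 0.21),
    (8, 0.8, 0.1): (0.17, 0.21), (8, 0.2, 0.3): (0.08, 0.39),
    (8, 0.5, 0.3): (0.19, 0.39), (8, 0.8, 0.3): (0.31, 0.39),
    (8, 0.2, 0.5): (0.11, 0.56), (8, 0.5, 0.5): (0.28, 0.56),
    (8, 0.8, 0.5): (0.45, 0.56),
}


def brute_force_validity(spec, tol=1e-12):
    """Independent oracle: bisection on R^2(r) with an explicit solve.

    R^2(r) for k equally valid predictors with common intercorrelation is
    computed directly as r' R_xx^{-1} r and is strictly increasing in
    r >= 0, so bisection on [0, 1] converges to the validity implied by
    the target rho2_yy.
    """
    k = spec.k
    R_xx = np.full((k, k), spec.rho_xx)
    np.fill_diagonal(R_xx, 1.0)

    def r2(r):
        v = np.full(k, r)
        return float(v @ np.linalg.solve(R_xx, v))

    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if r2(mid) < spec.rho2_yy:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestSolveValidity:
    @pytest.mark.parametrize(
        "k,rho2_yy,rho_xx,expected_sq",
        [
            (2, 0.2, 0.1, 0.11),
            (8, 0.8, 0.5, 0.45),
            (2, 0.5, 0.0, 0.25),  # orthogonal equal-validity split
        ],
    )
    def test_known_squared_validities(self, k, rho2_yy, rho_xx, expected_sq):
        rho = solve_validity(PopulationSpec(k=k, rho2_yy=rho2_yy, rho_xx=rho_xx))
        assert rho**2 == pytest.approx(expected_sq, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_agrees_with_bisection_oracle(self, k):
        for rho2_yy, rho_xx in itertools.product(
            (0.2, 0.5, 0.8), (0.0, 0.1, 0.3, 0.5)
        ):
            spec = PopulationSpec(k=k, rho2_yy=rho2_yy, rho_xx=rho_xx)
            assert solve_validity(spec) == pytest.approx(
                brute_force_validity(spec), abs=1e-9
            )

    def test_nonnegative_root_recovers_rho2_yy(self):
        for cell in design_grid():
            spec = cell.spec
            rho = solve_validity(spec)
            assert rho >= 0
            R_xx = np.full((spec.k, spec.k), spec.rho_xx)
            np.fill_diagonal(R_xx, 1.0)
            v = np.full(spec.k, rho)
            assert v @ np.linalg.solve(R_xx, v) == pytest.approx(
                spec.rho2_yy, abs=1e-12
            )


class TestPopulationParams:
    def test_structure_closed_form_examples(self):
        p = population_parameters(PopulationSpec(2, 0.8, 0.5))
        assert p.rho2_structure == pytest.approx(0.75)
        p = population_parameters(PopulationSpec(8, 0.5, 0.1))
        assert p.rho2_structure == pytest.approx(0.2125)
        assert round_half_up(p.rho2_structure) == 0.21
        p = population_parameters(PopulationSpec(1, 0.5))
        assert p.rho2_structure == pytest.approx(1.0)

    def test_matrix_invariants_and_r2_roundtrip(self):
        for cell in design_grid():
            p = population_parameters(cell.spec)
            corr = p.corr
            assert corr.shape == (p.k + 1, p.k + 1)
            np.testing.assert_allclose(corr, corr.T)
            np.testing.assert_allclose(np.diag(corr), 1.0)
            assert np.linalg.eigvalsh(corr)[0] > 1e-10
            r = corr[: p.k, p.k]
            r2 = r @ np.linalg.solve(corr[: p.k, : p.k], r)
            assert abs(r2 - cell.spec.rho2_yy) < 1e-12
            assert p.rho2_structure == pytest.approx(
                p.rho2_xy / cell.spec.rho2_yy
            )

    def test_structure_monotone_in_rho_xx_and_k(self):
        for k in (2, 4, 8):
            vals = [
                population_parameters(PopulationSpec(k, 0.5, r)).rho2_structure
                for r in (0.1, 0.3, 0.5)
            ]
            assert vals[0] < vals[1] < vals[2]
        for r in (0.1, 0.3, 0.5):
            vals = [
                population_parameters(PopulationSpec(k, 0.5, r)).rho2_structure
                for k in (2, 4, 8)
            ]
            assert vals[0] > vals[1] > vals[2]

    def test_near_singular_joint_matrix_rejected(self):
        # rho2_yy this close to 1 passes the spec bounds but leaves the
        # joint matrix numerically singular
        with pytest.raises(ParameterError):
            population_parameters(PopulationSpec(2, 1 - 1e-13, 0.1))


class TestSpecValidation:
    @pytest.mark.parametrize(
        "k,rho2_yy,rho_xx",
        [(0, 0.5, 0.1), (2, 1.0, 0.1), (2, -0.1, 0.1), (2, 0.5, -1.0),
         (3, 0.5, -0.6), (2, 0.5, 1.0)],
    )
    def test_invalid_specs_rejected(self, k, rho2_yy, rho_xx):
        with pytest.raises(ParameterError):
            PopulationSpec(k=k, rho2_yy=rho2_yy, rho_xx=rho_xx)

    def test_negative_equicorrelation_allowed_above_bound(self):
        # rho_xx > -1/(k-1) keeps the predictor block positive definite
        spec = PopulationSpec(k=3, rho2_yy=0.3, rho_xx=-0.4)
        assert population_parameters(spec).rho2_structure == pytest.approx(
            (1 - 2 * 0.4) / 3
        )


class TestDesignGrid:
    def test_grid_shape_and_ordering(self):
        grid = design_grid()
        assert len(grid) == 135
        assert [c.cell_id for c in grid] == list(range(135))
        keys = [
            (c.spec.k, c.spec.rho2_yy, c.spec.rho_xx, c.n) for c in grid
        ]
        assert keys == sorted(keys)
        assert len({c.spec for c in grid}) == 27
        assert all(c.n > c.spec.k + 3 for c in grid)
        # deterministic across calls
        assert design_grid() == grid


class TestTable1:
    def test_printed_parity_all_27_pairs(self):
        df = table1()
        assert len(df) == 27
        for _, row in df.iterrows():
            key = (row.k, row.rho2_yy, row.rho_xx)
            assert (row.rho2_xy_2dp, row.rho2_structure_2dp) == PRINTED_TABLE1[key]

    def test_printed_ranges(self):
        df = table1()
        assert (df.rho2_xy_2dp.min(), df.rho2_xy_2dp.max()) == (0.04, 0.60)
        assert (df.rho2_structure_2dp.min(), df.rho2_structure_2dp.max()) == (
            0.21,
            0.75,
        )


@pytest.mark.parametrize(
    "x,expected",
    [(0.275, 0.28), (0.475, 0.48), (0.2125, 0.21), (0.1125, 0.11),
     (0.065, 0.07), (0.125, 0.13)],
)
def test_round_half_up_matches_printed_convention(x, expected):
    assert round_half_up(x) == expected
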