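"""Mass-balance speciation solver: closed forms, oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuprobe import (
    BindingModel,
    ConfigurationError,
    SolutionComposition,
    free_ligand_given_free_metal,
    solve_speciation,
)

from oracles import grid_search_speciation, nested_bisection_speciation

uM = 1e-6


def random_system(rng, max_ligands=3):
    """Random composition/models: log-uniform constants 1e10-1e25, conc 1e-9-1e-3 M."""
    n_lig = rng.integers(1, max_ligands + 1)
    models, totals = [], {}
    for i in range(n_lig):
        n = int(rng.integers(1, 3))
        k = 10.0 ** rng.uniform(10, 25)
        name = f"L{i}"
        models.append(BindingModel(name, n, k))
        totals[name] = 10.0 ** rng.uniform(-9, -3)
    metal_total = 10.0 ** rng.uniform(-9, -3)
    return SolutionComposition(metal_total, totals), models


class TestBindingModel:
    def test_kd_round_trips_exactly(self):
        model = BindingModel.one_to_one_from_kd("ATX1", 5.47e-18)
        assert model.formation_constant == 1.0 / 5.47e-18
        assert model.kd == 5.47e-18
        assert BindingModel.one_to_one_from_kd("ATX1", model.kd) == model

    @pytest.mark.parametrize(
        "kwargs, exc",
        [
            (dict(ligand_name="X", ligands_per_complex=3, formation_constant=1e10), ConfigurationError),
            (dict(ligand_name="X", ligands_per_complex=1, formation_constant=-1.0), ValueError),
            (dict(ligand_name="X", ligands_per_complex=1, formation_constant=math.inf), ValueError),
            (dict(ligand_name="X", ligands_per_complex=2, formation_constant=1e17,
                  metal_per_complex=2), ConfigurationError),
        ],
    )
    def test_invalid_models_rejected(self, kwargs, exc):
        with pytest.raises(exc):
            BindingModel(**kwargs)

    def test_zero_constant_means_non_binding(self):
        model = BindingModel("mutant", 2, 0.0)
        assert free_ligand_given_free_metal(10 * uM, 1e-6, model) == 10 * uM


class TestFreeLigand:
    @pytest.mark.parametrize("n", [1, 2])
    def test_no_metal_means_no_complex(self, n):
        model = BindingModel("L", n, 1e17)
        assert free_ligand_given_free_metal(10 * uM, 0.0, model) == 10 * uM

    @pytest.mark.parametrize("n", [1, 2])
    def test_zero_ligand_total(self, n):
        model = BindingModel("L", n, 1e17)
        assert free_ligand_given_free_metal(0.0, 1e-9, model) == 0.0

    def test_negative_inputs_rejected(self):
        model = BindingModel("L", 2, 1e17)
        with pytest.raises(ValueError):
            free_ligand_given_free_metal(-1e-6, 0.0, model)
        with pytest.raises(ValueError):
            free_ligand_given_free_metal(1e-6, -1e-9, model)

    def test_matches_bisection_oracle_at_spec_point(self):
        from oracles import bisect_free_ligand

        model = BindingModel("L", 2, 1e17)
        got = free_ligand_given_free_metal(10 * uM, 1e-17, model)
        expected = bisect_free_ligand(10 * uM, 1e-17, 1e17, 2)
        assert got == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        total=st.floats(1e-9, 1e-3), log_k=st.floats(10, 25),
        log_m=st.floats(-20, -3), n=st.sampled_from([1, 2]),
    )
    def test_closed_form_satisfies_ligand_balance(self, total, log_k, log_m, n):
        model = BindingModel("L", n, 10.0**log_k)
        m = 10.0**log_m
        lig = free_ligand_given_free_metal(total, m, model)
        reconstructed = lig + n * model.formation_constant * m * lig**n
        assert reconstructed == pytest.approx(total, rel=1e-12)
        assert 0.0 <= lig <= total


class TestSolveSpeciation:
    def test_zero_metal_gives_free_ligands(self, bca_model):
        comp = SolutionComposition(0.0, {"BCA": 20 * uM})
        res = solve_speciation(comp, [bca_model])
        assert res.free_metal == 0.0
        assert res.complexes["BCA"] == 0.0
        assert res.free_ligands["BCA"] == 20 * uM

    def test_no_ligands_gives_free_metal(self):
        res = solve_speciation(SolutionComposition(5 * uM, {}), [])
        assert res.free_metal == 5 * uM

    def test_mismatched_models_rejected(self, bca_model, pls_model):
        comp = SolutionComposition(1 * uM, {"BCA": 10 * uM})
        with pytest.raises(ConfigurationError):
            solve_speciation(comp, [bca_model, pls_model])
        with pytest.raises(ConfigurationError):
            solve_speciation(comp, [])
        with pytest.raises(ConfigurationError):
            solve_speciation(comp, [bca_model, bca_model])

    def test_single_1to1_ligand_matches_quadratic_closed_form(self):
        """M + L <-> ML: free metal from the standard quadratic in [ML]."""
        k, lt, mt = 1e12, 8 * uM, 5 * uM
        comp = SolutionComposition(mt, {"L": lt})
        res = solve_speciation(comp, [BindingModel("L", 1, k)])
        # [ML] solves K*(mt-x)*(lt-x) = x; take the root in [0, min(mt, lt)]
        b = mt + lt + 1.0 / k
        x = (b - math.sqrt(b * b - 4 * mt * lt)) / 2.0
        assert res.complexes["L"] == pytest.approx(x, rel=1e-10)
        assert res.free_metal == pytest.approx(mt - x, rel=1e-9)

    def test_dominant_competitor_starves_probe(self, bca_model):
        """A vastly tighter 1:1 competitor takes nearly all metal from the probe."""
        # Effective probe affinity at 20 uM: beta2 * L^2; competitor K_A 1e4x that.
        eff_probe = bca_model.formation_constant * (20 * uM)
        competitor = BindingModel("C", 1, 1e4 * eff_probe)
        comp = SolutionComposition(10 * uM, {"BCA": 20 * uM, "C": 20 * uM})
        with_comp = solve_speciation(comp, [bca_model, competitor])
        alone = solve_speciation(
            SolutionComposition(10 * uM, {"BCA": 20 * uM}), [bca_model]
        )
        assert with_comp.complexes["BCA"] < 1e-3 * alone.complexes["BCA"]

        oracle = grid_search_speciation(
            10 * uM, [(20 * uM, bca_model.formation_constant, 2),
                      (20 * uM, competitor.formation_constant, 1)]
        )
        assert with_comp.complexes["BCA"] == pytest.approx(oracle["complexes"][0], rel=5e-4)
        assert with_comp.complexes["C"] == pytest.approx(oracle["complexes"][1], rel=5e-4)

    def test_conservation_on_random_systems(self, rng):
        """Metal and ligand balances hold to <= 1e-9 relative on random mixtures."""
        for _ in range(500):
            comp, models = random_system(rng)
            res = solve_speciation(comp, models)
            assert res.metal_balance_residual(comp.metal_total) <= 1e-9
            for m in models:
                total = comp.ligand_totals[m.ligand_name]
                back = (
                    res.free_ligands[m.ligand_name]
                    + m.ligands_per_complex * res.complexes[m.ligand_name]
                )
                assert back == pytest.approx(total, rel=1e-9)
            assert res.free_metal >= 0
            assert all(v >= 0 for v in res.free_ligands.values())
            assert all(v >= 0 for v in res.complexes.values())

    def test_agrees_with_nested_bisection_oracle(self, rng):
        """100 random small systems agree with the independent solver to 1e-6."""
        for _ in range(100):
            comp, models = random_system(rng, max_ligands=2)
            res = solve_speciation(comp, models)
            oracle = nested_bisection_speciation(
                comp.metal_total,
                [(comp.ligand_totals[m.ligand_name], m.formation_constant,
                  m.ligands_per_complex) for m in models],
            )
            assert res.free_metal == pytest.approx(oracle["free_metal"], rel=1e-6, abs=1e-30)
            for m, c_oracle in zip(models, oracle["complexes"]):
                assert res.complexes[m.ligand_name] == pytest.approx(
                    c_oracle, rel=1e-6, abs=1e-18
                )

    def test_free_metal_monotone_in_metal_total(self, bca_model, pls_model):
        comp0 = SolutionComposition(0.0, {"BCA": 10 * uM, "PLS": 14 * uM})
        frees = [
            solve_speciation(comp0.with_metal_total(mt), [bca_model, pls_model]).free_metal
            for mt in np.linspace(0, 30 * uM, 40)
        ]
        assert np.all(np.diff(frees) >= 0)

    def test_complex_monotone_in_own_constant(self, bca_model):
        comp = SolutionComposition(5 * uM, {"BCA": 10 * uM, "C": 10 * uM})
        complexes = [
            solve_speciation(comp, [bca_model, BindingModel("C", 2, 10.0**lk)]).complexes["C"]
            for lk in np.linspace(14, 22, 17)
        ]
        assert np.all(np.diff(complexes) >= 0)
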