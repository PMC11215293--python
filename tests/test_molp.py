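import numpy as np
import pytest

import _oracles
from conftest import make_pair_ecosystem
from ecoscore.ecosystem import DietSpec, apply_diet, build_ecosystem
from ecoscore.model_io import MetabolicModel, Reaction
from ecoscore.molp import (
    InfeasibleProblemError,
    ParetoFront,
    compute_pareto_front,
    pareto_front_weighted_grid,
    solve_fba,
    solve_fva,
    solve_parsimonious,
)
from ecoscore.synthetic_models import ToySpec, generate_community, generate_pair


def chain_eco(bound=10.0):
    models, _ = generate_pair(ToySpec(kind="neutralism"))
    diet = DietSpec(lumen_bounds={"s1_e": (-bound, 0.0), "s2_e": (-7.0, 0.0)})
    return apply_diet(build_ecosystem(models), diet)


def two_pathway_member():
    """Substrate convertible by two routes of unequal yield (1 vs 2)."""
    return MetabolicModel(
        model_id="twopath",
        metabolites={"s_e": "e", "s_c": "c", "x_c": "c"},
        reactions={
            "EX_s_e": Reaction("EX_s_e", {"s_e": -1.0}),
            "T_s": Reaction("T_s", {"s_e": -1.0, "s_c": 1.0}, 0.0, 1000.0),
            "LOW": Reaction("LOW", {"s_c": -1.0, "x_c": 1.0}, 0.0, 1000.0),
            "HIGH": Reaction("HIGH", {"s_c": -1.0, "x_c": 2.0}, 0.0, 1000.0),
            "BIOMASS": Reaction("BIOMASS", {"x_c": -1.0}, 0.0, 1000.0),
        },
        objective={"BIOMASS": 1.0},
        external_compartments={"e"},
    ).validate()


class TestFBA:
    def test_chain_bound_limits_objective(self):
        eco = chain_eco()
        sol = solve_fba(eco, [1.0, 0.0])
        assert sol.optimal
        assert sol.objective == pytest.approx(10.0, abs=1e-9)
        assert sol.objective_values[0] == pytest.approx(10.0, abs=1e-9)
        both = solve_fba(eco, [1.0, 1.0])
        assert both.objective_values == pytest.approx([10.0, 7.0], abs=1e-9)

    def test_two_pathway_matches_enumeration_oracle(self):
        """The LP optimum equals the brute-force basic-solution maximum."""
        eco = apply_diet(
            build_ecosystem([two_pathway_member()]),
            DietSpec(lumen_bounds={"s_e": (-10.0, 0.0)}),
        )
        sol = solve_fba(eco, [1.0])
        oracle = _oracles.enumerate_lp_max(
            eco.S.toarray(), eco.lb, eco.ub, eco.C[0]
        )
        assert sol.objective == pytest.approx(oracle, abs=1e-6)
        assert sol.objective == pytest.approx(20.0)

    def test_interior_equality_pin(self):
        eco = chain_eco()
        sol = solve_fba(eco, [1.0, 1.0], objective_pins={0: 4.0})
        assert sol.optimal
        assert sol.objective_values[0] == pytest.approx(4.0, abs=1e-9)

    def test_reaction_pin_outside_bounds_rejected(self):
        eco = chain_eco()
        rid = f"{eco.member_ids[0]}:BIOMASS"
        with pytest.raises(ValueError, match="outside bounds"):
            solve_fba(eco, [1.0, 0.0], fixed={rid: -5.0})

    def test_infeasible_status_propagated(self):
        eco = chain_eco()
        sol = solve_fba(eco, [1.0, 1.0], objective_pins={0: 50.0})
        assert sol.status == "infeasible"
        assert not sol.optimal

    def test_parsimonious_solution_hits_pins_with_less_flux(self):
        eco = apply_diet(
            build_ecosystem([two_pathway_member()]),
            DietSpec(lumen_bounds={"s_e": (-10.0, 0.0)}),
        )
        sol = solve_parsimonious(eco, {0: 10.0})
        assert sol.optimal
        assert sol.objective_values[0] == pytest.approx(10.0, abs=1e-8)
        # parsimony routes everything through the high-yield pathway
        assert sol.fluxes[eco.reaction_index("twopath:LOW")] == pytest.approx(0.0, abs=1e-8)


class TestFVA:
    def test_blocked_reaction_interval_is_zero(self):
        eco = chain_eco()
        rid = f"{eco.member_ids[0]}:T_s1_e"
        eco2 = eco.copy()
        j = eco2.reaction_index(rid)
        eco2.lb[j] = eco2.ub[j] = 0.0
        assert solve_fva(eco2, [rid])[rid] == pytest.approx((0.0, 0.0))

    def test_chain_collapses_at_pinned_maximum(self):
        eco = chain_eco()
        member = eco.member_ids[0]
        chain = [f"{member}:EX_s1_e", f"{member}:T_s1_e", f"{member}:BIOMASS"]
        fva = solve_fva(eco, chain, objective_pins={0: 10.0})
        for rid, (lo, hi) in fva.items():
            assert hi - lo == pytest.approx(0.0, abs=1e-8), rid

    def test_redundant_branches_span_zero_to_demand(self):
        """Two equal-yield branches pinned below capacity: each spans [0, demand]."""
        member = two_pathway_member()
        member.reactions["HIGH"].stoichiometry = {"s_c": -1.0, "x_c": 1.0}
        eco = apply_diet(
            build_ecosystem([member]), DietSpec(lumen_bounds={"s_e": (-10.0, 0.0)})
        )
        fva = solve_fva(eco, ["twopath:LOW", "twopath:HIGH"], objective_pins={0: 4.0})
        for rid in fva:
            assert fva[rid] == pytest.approx((0.0, 4.0), abs=1e-8)

    def test_infeasible_pin_raises(self):
        eco = chain_eco()
        with pytest.raises(InfeasibleProblemError):
            solve_fva(eco, [f"{eco.member_ids[0]}:BIOMASS"], objective_pins={0: 99.0})


class TestParetoFront:
    def test_shared_substrate_front_is_the_tradeoff_segment(self, competition_eco):
        _, _, eco = competition_eco
        front = compute_pareto_front(eco)
        assert np.allclose(front.points, [[0.0, 10.0], [10.0, 0.0]], atol=1e-7)

    def test_disjoint_substrates_single_vertex(self, neutral_eco):
        _, _, eco = neutral_eco
        front = compute_pareto_front(eco)
        assert front.points.shape == (1, 2)
        assert np.allclose(front.points, [[5.0, 7.0]], atol=1e-7)

    def test_oneway_crossfeeding_lifts_consumer_above_alone_max(self, oneway_eco):
        _, _, eco = oneway_eco
        front = compute_pareto_front(eco)
        assert front.points.shape == (1, 2)
        (point,) = front.points
        assert point[0] > 0 and point[1] > 0
        assert point[1] == pytest.approx(6.0)  # alone max is 1.0
        assert np.allclose(point, [10.0, 6.0], atol=1e-7)

    @pytest.mark.parametrize("seed", range(20))
    def test_nise_matches_epsilon_constraint_sweep(self, seed):
        """The NISE polyline equals an epsilon-constraint curve on a grid.

        Twenty randomized bi-objective toys; the oracle is a different
        algorithm (per-grid-point constrained maximization).
        """
        kinds = ("competition", "neutralism", "crossfeed_oneway", "crossfeed_mutual")
        spec = ToySpec.random(kinds[seed % 4], seed=seed)
        models, diet = generate_pair(spec)
        eco = apply_diet(build_ecosystem(models), diet)
        front = compute_pareto_front(eco)
        pts = front.points
        xs = np.linspace(pts[0, 0], pts[-1, 0], 100)
        oracle = _oracles.epsilon_constraint_curve(eco, xs)
        polyline = np.interp(xs, pts[:, 0], pts[:, 1])
        assert np.allclose(polyline, oracle, atol=1e-6)

    def test_every_vertex_is_supported_by_a_weight_vector(self, competition_eco):
        """Supporting-hyperplane check: each vertex maximizes some w >= 0."""
        _, _, eco = competition_eco
        front = compute_pareto_front(eco)
        for p in front.points:
            supported = False
            for w in ([1.0, 0.0], [0.0, 1.0], [0.5, 0.5], [0.9, 0.1], [0.1, 0.9]):
                sol = solve_fba(eco, w)
                if abs(np.dot(w, p) - sol.objective) < 1e-6:
                    supported = True
                    break
            assert supported, p

    def test_scale_equivariance_of_front(self):
        models, diet = generate_pair(ToySpec(kind="competition"))
        base = compute_pareto_front(apply_diet(build_ecosystem(models), diet))
        scaled_models = [models[0].copy(), models[1].copy()]
        scaled_models[0].objective = {"BIOMASS": 3.0}
        scaled = compute_pareto_front(
            apply_diet(build_ecosystem(scaled_models), diet)
        )
        assert np.allclose(scaled.points[:, 0], 3.0 * base.points[:, 0], atol=1e-7)
        assert np.allclose(scaled.points[:, 1], base.points[:, 1], atol=1e-7)

    def test_front_points_are_mutually_nondominated(self, mutual_eco):
        _, _, eco = mutual_eco
        pts = compute_pareto_front(eco).points
        for i, p in enumerate(pts):
            for j, q in enumerate(pts):
                if i != j:
                    assert not (np.all(q >= p - 1e-9) and np.any(q > p + 1e-7))

    def test_front_tsv_round_trip(self, tmp_path, competition_eco):
        _, _, eco = competition_eco
        front = compute_pareto_front(eco)
        front.to_tsv(tmp_path / "front.tsv")
        back = ParetoFront.from_tsv(tmp_path / "front.tsv")
        assert np.allclose(back.points, front.points)
        assert back.organism_order == front.organism_order


class TestBensonHigherDimensions:
    def test_all_neutral_community_has_single_ideal_vertex(self):
        models, diet, _ = generate_community(ToySpec(kind="neutralism", n_members=4, seed=3))
        eco = apply_diet(build_ecosystem(models), diet)
        front = compute_pareto_front(eco)
        assert front.points.shape == (1, 4)
        alone = [solve_fba(eco, np.eye(4)[i]).objective_values[i] for i in range(4)]
        assert np.allclose(front.points[0], alone, atol=1e-6)

    def test_competing_pair_inside_community_gives_segment_front(self):
        models, diet, _ = generate_community(
            ToySpec(kind="competition", n_members=3, seed=0)
        )
        eco = apply_diet(build_ecosystem(models), diet)
        front = compute_pareto_front(eco)
        pts = front.points[np.argsort(front.points[:, 0])]
        assert pts.shape == (2, 3)
        # members 0 and 1 trade the shared bound; member 2 is unaffected
        assert np.allclose(pts[:, :2], [[0.0, 10.0], [10.0, 0.0]], atol=1e-6)
        assert np.allclose(pts[:, 2], pts[0, 2], atol=1e-6)

    def test_crossfeeding_community_vertex_exceeds_alone_maxima(self):
        models, diet, _ = generate_community(
            ToySpec(kind="crossfeed_mutual", n_members=4, seed=1)
        )
        eco = apply_diet(build_ecosystem(models), diet)
        front = compute_pareto_front(eco)
        assert front.points.shape == (1, 4)
        assert front.points[0, 0] == pytest.approx(2.0, abs=1e-6)
        assert front.points[0, 1] == pytest.approx(2.0, abs=1e-6)


def test_weighted_grid_fallback_agrees_on_simple_fronts(competition_eco):
    _, _, eco = competition_eco
    exact = compute_pareto_front(eco).points
    approx = pareto_front_weighted_grid(eco, n_weights=8).points
    for p in approx:
        assert any(np.allclose(p, q, atol=1e-6) for q in exact)
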