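import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from conftest import make_pair_ecosystem
from ecoscore.ecosystem import DietSpec, apply_diet, build_ecosystem
from ecoscore.molp import ParetoFront, compute_pareto_front
from ecoscore.scoring import (
    InteractionReport,
    NormalizedFront,
    ZeroAloneGrowthError,
    auc_2d,
    classify_interaction,
    hypervolume,
    interaction_score,
    normalize_front,
    removal_analysis,
    score_ecosystem,
    score_front,
)
from ecoscore.model_io import write_model
from ecoscore.ecosystem import write_diet
from ecoscore.synthetic_models import ToySpec, generate_community, generate_pair


def synthetic_normalized_front(points):
    """NormalizedFront built directly from already-normalized points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    k = pts.shape[1]
    base = ParetoFront(k, pts, [f"m{i}" for i in range(k)])
    aug = list(base.points)
    for i in range(k):
        e = np.zeros(k)
        e[i] = 1.0
        if not any(np.allclose(p, e, atol=1e-9) for p in aug):
            aug.append(e)
    return NormalizedFront(
        base=base,
        alone_maxima=np.ones(k),
        points=base.points,
        augmented_points=np.array(aug),
        organism_order=base.organism_order,
    )


class TestAUC:
    def test_right_triangle(self):
        assert auc_2d([(0, 1), (1, 0)]) == pytest.approx(0.5)

    def test_three_point_monotone_case(self):
        assert auc_2d([(0, 1.5), (0.8, 1.0), (1, 0)]) == pytest.approx(1.1)

    def test_non_monotonic_last_point_subtracts_final_trapezoid(self):
        assert auc_2d([(0, 1), (1.3, 0.2), (1, 0)]) == pytest.approx(0.75)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError, match="two points"):
            auc_2d([(0.5, 0.5)])

    def test_interior_monotonicity_break_rejected(self):
        with pytest.raises(ValueError, match="non-monotonic"):
            auc_2d([(0, 1), (0.8, 0.5), (0.4, 0.4), (1, 0)])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 5, allow_nan=False), st.floats(0, 5, allow_nan=False)
            ),
            min_size=2,
            max_size=8,
        )
    )
    def test_monotone_curves_match_shoelace_oracle(self, raw):
        pts = sorted(set(raw))
        if len(pts) < 2:
            return
        assert auc_2d(pts) == pytest.approx(
            _oracles.shoelace_area_under(pts), abs=1e-9
        )


class TestHypervolume:
    def test_unit_square(self):
        assert hypervolume([(0, 0), (0, 1), (1, 0), (1, 1)]) == pytest.approx(1.0)

    def test_unit_simplex(self):
        pts = np.vstack([np.zeros(3), np.eye(3)])
        assert hypervolume(pts) == pytest.approx(1 / 6)

    def test_pyramid_with_all_ones_apex(self):
        pts = np.vstack([np.zeros(3), np.eye(3), np.ones(3)])
        assert hypervolume(pts) == pytest.approx(0.5)

    def test_degenerate_flat_set_is_zero(self):
        assert hypervolume([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]) == 0.0

    def test_dimension_below_two_rejected(self):
        with pytest.raises(ValueError):
            hypervolume([[1.0], [2.0]])


class TestNormalize:
    def test_competition_front_normalizes_to_unit_points(self, competition_eco):
        _, diet, eco = competition_eco
        nf = normalize_front(compute_pareto_front(eco), eco, diet)
        assert np.allclose(nf.alone_maxima, [10.0, 10.0])
        assert np.allclose(sorted(map(tuple, nf.points)), [(0, 1), (1, 0)])
        # unit vectors present exactly once in the augmentation
        assert len(nf.augmented_points) == 2

    def test_neutral_front_augments_with_unit_vectors(self, neutral_eco):
        _, diet, eco = neutral_eco
        nf = normalize_front(compute_pareto_front(eco), eco, diet)
        assert np.allclose(nf.points, [[1.0, 1.0]])
        assert len(nf.augmented_points) == 3

    def test_mutualism_doubles_normalized_coordinate(self, mutual_eco):
        _, diet, eco = mutual_eco
        nf = normalize_front(compute_pareto_front(eco), eco, diet)
        assert np.allclose(nf.alone_maxima, [1.0, 1.0])
        assert np.allclose(nf.points, [[2.0, 2.0]])

    def test_zero_alone_growth_is_an_error(self):
        models, _ = generate_pair(ToySpec(kind="competition"))
        starving = DietSpec(name="none", lumen_bounds={"s_e": (0.0, 0.0)})
        eco = apply_diet(build_ecosystem(models), starving)
        with pytest.raises(ZeroAloneGrowthError, match="zero standalone growth"):
            normalize_front(compute_pareto_front(eco), eco, starving)


class TestScore:
    def test_neutral_scores_zero(self, neutral_eco):
        _, diet, eco = neutral_eco
        report = score_front(eco, diet)
        assert report.score == pytest.approx(0.0, abs=1e-9)
        assert report.auc_ni == 1.0

    def test_pure_competition_scores_minus_half(self, competition_eco):
        _, diet, eco = competition_eco
        report = score_front(eco, diet)
        assert report.score == pytest.approx(-0.5, abs=1e-9)
        assert report.auc_p == pytest.approx(0.5, abs=1e-9)

    def test_2d_auc_score_equals_hull_based_score_on_monotone_fronts(self):
        for kind in ("competition", "neutralism"):
            _, diet, eco = make_pair_ecosystem(kind)
            nf = normalize_front(compute_pareto_front(eco), eco, diet)
            s_auc = interaction_score(nf).score
            hull_pts = np.vstack([nf.augmented_points, np.zeros(2)])
            s_hull = hypervolume(hull_pts) - 1.0
            assert s_auc == pytest.approx(s_hull, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(1.0, 1.0)], "Neutralism"),
            ([(0.0, 1.0), (1.0, 0.0)], "Competition"),
            ([(1.5, 0.4), (0.5, 1.0)], "FavorsHost"),
            ([(1.0, 1.5)], "FavorsBacteria"),
            ([(0.4, 1.3), (1.2, 0.3)], "LimitedMutualism"),
            ([(1.2, 1.3)], "Mutualism"),
            ([(0.2, 1.2), (0.5, 0.1)], "Unclassified"),  # negative S with B+
        ],
    )
    def test_type_table(self, points, expected):
        nf = synthetic_normalized_front(points)
        assert interaction_score(nf).interaction_type == expected

    def test_higher_dimension_rejected(self):
        nf = synthetic_normalized_front([(1.0, 1.0, 1.0)])
        report = interaction_score(nf)  # k >= 3: score only, no typing
        with pytest.raises(ValueError, match="two-member"):
            classify_interaction(nf, report)

    @pytest.mark.parametrize(
        "kind,expected",
        [
            ("neutralism", "Neutralism"),
            ("competition", "Competition"),
            ("crossfeed_oneway", "FavorsBacteria"),
            ("crossfeed_mutual", "Mutualism"),
        ],
    )
    def test_fixture_types(self, kind, expected):
        _, diet, eco = make_pair_ecosystem(kind)
        assert score_front(eco, diet).interaction_type == expected


class TestInvariances:
    @pytest.mark.parametrize("kind", ["competition", "crossfeed_mutual", "neutralism"])
    def test_member_permutation_leaves_score_unchanged(self, kind):
        models, diet = generate_pair(ToySpec(kind=kind))
        s_fwd = score_front(apply_diet(build_ecosystem(models), diet), diet).score
        s_rev = score_front(apply_diet(build_ecosystem(models[::-1]), diet), diet).score
        assert abs(s_fwd - s_rev) < 1e-9

    def test_three_member_permutation_leaves_score_unchanged(self):
        models, diet, _ = generate_community(ToySpec(kind="crossfeed_mutual", n_members=3, seed=7))
        orders = [models, models[::-1], [models[1], models[2], models[0]]]
        scores = [
            score_front(apply_diet(build_ecosystem(o), diet), diet).score for o in orders
        ]
        assert max(scores) - min(scores) < 1e-9

    @pytest.mark.parametrize("alpha", [0.5, 3.0])
    def test_objective_rescaling_leaves_score_and_type_unchanged(self, alpha):
        models, diet = generate_pair(ToySpec(kind="crossfeed_mutual"))
        base = score_front(apply_diet(build_ecosystem(models), diet), diet)
        scaled = [models[0].copy(), models[1]]
        scaled[0].objective = {"BIOMASS": alpha}
        rep = score_front(apply_diet(build_ecosystem(scaled), diet), diet)
        assert abs(rep.score - base.score) < 1e-9
        assert rep.interaction_type == base.interaction_type


class TestRemoval:
    def test_neutral_community_all_removal_scores_zero(self):
        models, diet, _ = generate_community(ToySpec(kind="neutralism", n_members=3, seed=2))
        eco = apply_diet(build_ecosystem(models), diet)
        scores = removal_analysis(eco, diet)
        assert all(abs(s) < 1e-9 for s in scores.values())

    def test_removing_the_crossfeeders_kills_the_positive_score(self):
        """A-B cross-feed, C independent: only C's removal keeps S > 0."""
        models, diet, _ = generate_community(
            ToySpec(kind="crossfeed_mutual", n_members=3, seed=0)
        )
        eco = apply_diet(build_ecosystem(models), diet)
        scores = removal_analysis(eco, diet)
        assert scores["org_2"] > 1e-6
        assert scores["org_0"] == pytest.approx(0.0, abs=1e-9)
        assert scores["org_1"] == pytest.approx(0.0, abs=1e-9)

    def test_two_member_ecosystem_rejected(self, competition_eco):
        _, _, eco = competition_eco
        with pytest.raises(ValueError, match="three members"):
            removal_analysis(eco)


class TestPipeline:
    def write_fixture(self, tmp_path, kind):
        models, diet = generate_pair(ToySpec(kind=kind))
        paths = []
        for m in models:
            p = tmp_path / m.model_id
            write_model(m, p, format="tabular")
            paths.append(p)
        diet_path = tmp_path / "diet.tsv"
        write_diet(diet, diet_path)
        return paths, diet_path

    def test_end_to_end_competition(self, tmp_path):
        paths, diet_path = self.write_fixture(tmp_path, "competition")
        report = score_ecosystem(paths, diet_path)
        assert report.score == pytest.approx(-0.5, abs=1e-9)
        assert report.interaction_type == "Competition"

    def test_end_to_end_is_deterministic(self, tmp_path):
        paths, diet_path = self.write_fixture(tmp_path, "crossfeed_mutual")
        a = score_ecosystem(paths, diet_path).to_dict()
        b = score_ecosystem(paths, diet_path).to_dict()
        assert a == b

    def test_single_model_rejected(self, tmp_path):
        paths, diet_path = self.write_fixture(tmp_path, "neutralism")
        with pytest.raises(ValueError, match="at least two"):
            score_ecosystem(paths[:1], diet_path)

    def test_stage_provenance_in_errors(self, tmp_path):
        with pytest.raises(RuntimeError, match=r"\[stage: read models\]"):
            score_ecosystem([tmp_path / "a.xml", tmp_path / "b.xml"])

    def test_summary_mentions_score_and_type(self, tmp_path):
        paths, diet_path = self.write_fixture(tmp_path, "neutralism")
        text = score_ecosystem(paths, diet_path).summary()
        assert "interaction score" in text and "Neutralism" in text
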