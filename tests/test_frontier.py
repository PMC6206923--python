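"""CEA-ratio arithmetic, dominance filtering and the constrained path."""

import numpy as np
import pytest

from gcea.frontier import (
    DominatedError,
    EvalResult,
    NULL_POINT,
    acer,
    budget_allocation,
    budget_allocation_from_costs,
    dominance_filter,
    dominance_filter_bruteforce,
    expansion_path,
    expansion_path_bruteforce,
    icer,
    league_table,
    programme_acer,
    round_half_up,
)


def _pt(label, cost, hly, arm="a", coverages=None):
    return EvalResult(
        label=label,
        coverages=tuple(sorted((coverages or {label: 0.95}).items())),
        cost_million=cost,
        hly=hly,
        arm=arm,
    )


class TestRatios:
    def test_acer_published_first_steps(self):
        # printed league-table rows: cost (million I$) and HLY reproduce the
        # printed average ratios exactly under half-up integer rounding
        assert acer(396, 4_541_842) == 87
        assert acer(146, 5_215_136) == 28
        assert acer(157, 1_389_662) == 113
        assert acer(136, 626_379) == 217
        assert acer(207, 870_417) == 238
        assert acer(206, 816_200) == 252
        assert acer(1056, 1_627_782) == 649

    def test_acer_edge_cases(self):
        assert acer(0, 123_456) == 0.0
        with pytest.raises(ValueError):
            acer(10, 0)
        with pytest.raises(ValueError):
            acer(10, -5)

    def test_icer_vs_null_equals_acer(self):
        nxt = _pt("x", 396, 4_541_842)
        assert icer(NULL_POINT, nxt) == acer(396, 4_541_842)

    def test_icer_published_increment(self):
        # vaccination at 80% to vaccination+VIA-screening at 80%
        prev = _pt("C1a@80", 190, 6_773_262)
        nxt = _pt("C1e@80", 1163, 30_421_065)
        assert icer(prev, nxt) == 41

    def test_icer_dominance_signal(self):
        a = _pt("a", 10, 100)
        with pytest.raises(DominatedError):
            icer(a, _pt("b", 12, 100))

    def test_round_half_up(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(1.5) == 2
        assert round_half_up(2.345, 2) == 2.35
        assert round_half_up(-0.5) == -1


class TestDominance:
    def test_single_point_is_its_own_frontier(self):
        f, d = dominance_filter([_pt("a", 5, 10)])
        assert len(f) == 1 and d == []

    def test_strictly_dominated_point_removed(self):
        a, b = _pt("a", 10, 100), _pt("b", 20, 90)
        f, d = dominance_filter([a, b])
        assert [r.label for r in f] == ["a"]
        assert [r.label for r in d] == ["b"]

    def test_extended_dominance(self):
        # b lies above the a--c segment: removed by extended dominance
        a, b, c = _pt("a", 10, 100), _pt("b", 40, 110), _pt("c", 50, 200)
        f, d = dominance_filter([a, b, c])
        assert {r.label for r in f} == {"a", "c"}
        assert {r.label for r in d} == {"b"}

    @pytest.mark.parametrize("seed", range(8))
    def test_random_clouds_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = [
            _pt(f"p{i}", float(rng.uniform(0, 100)), float(rng.uniform(1, 1000)))
            for i in range(20)
        ]
        f1, d1 = dominance_filter(pts)
        f2, d2 = dominance_filter_bruteforce(pts)
        assert {r.label for r in f1} == {r.label for r in f2}
        assert {r.label for r in d1} == {r.label for r in d2}

    def test_frontier_icers_non_decreasing(self):
        rng = np.random.default_rng(42)
        pts = [
            _pt(f"p{i}", float(rng.uniform(0, 100)), float(rng.uniform(1, 1000)))
            for i in range(25)
        ]
        f, _ = dominance_filter(pts)
        prev = NULL_POINT
        last = -np.inf
        for r in f:
            ratio = (r.cost_million - prev.cost_million) * 1e6 / (r.hly - prev.hly)
            assert ratio >= last - 1e-9
            last, prev = ratio, r


def _ladder(label, arm, costs, hlys, tech=None):
    tech = tech or label
    return [
        _pt(label, c, h, arm=arm, coverages={tech: cov})
        for c, h, cov in zip(costs, hlys, (0.5, 0.8, 0.95))
    ]


class TestExpansionPath:
    def test_single_intervention_coverage_ladder(self):
        pts = _ladder("A", "x/t", [10, 18, 25], [100, 150, 180])
        path = expansion_path({"x/t": pts})
        assert [dict(s.result.coverages)["A"] for s in path.steps] == [0.5, 0.8, 0.95]
        assert path.complete

    def test_lock_in_constraint_respected(self):
        """Once a technology is adopted, later steps keep it at >= coverage."""
        arm = "cerv/prev"
        a = _ladder("A", arm, [10, 16, 20], [100, 140, 160], tech="A")
        b = _ladder("B", arm, [30, 45, 55], [120, 170, 200], tech="B")
        ab = [
            _pt("AB", 42, 260, arm=arm, coverages={"A": 0.8, "B": 0.8}),
            _pt("AB", 52, 290, arm=arm, coverages={"A": 0.95, "B": 0.95}),
        ]
        path = expansion_path({arm: a + b + ab})
        adopted: dict[str, float] = {}
        for step in path.steps:
            cov = dict(step.result.coverages)
            for tech, lvl in adopted.items():
                assert cov.get(tech, 0.0) >= lvl
            adopted = cov

    def test_icers_non_decreasing_within_arm(self, sea_report):
        by_arm: dict[str, list[float]] = {}
        for s in sea_report.path.steps:
            by_arm.setdefault(s.result.arm, []).append(s.icer)
        for arm, icers in by_arm.items():
            assert icers == sorted(icers), arm

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        """Greedy walk equals exhaustive constrained search, <= 12 points."""
        rng = np.random.default_rng(100 + seed)
        arms = {}
        for arm in ("d1/t", "d2/t"):
            pts = []
            base_c, base_h = 0.0, 0.0
            for tech in ("P", "Q")[: rng.integers(1, 3)]:
                for cov in (0.5, 0.8, 0.95):
                    base_c += float(rng.uniform(1, 20))
                    base_h += float(rng.uniform(10, 300))
                    pts.append(
                        _pt(f"{arm}-{tech}", base_c, base_h, arm=arm, coverages={tech: cov})
                    )
            arms[arm] = pts
        p1 = expansion_path(arms)
        p2 = expansion_path_bruteforce(arms)
        seq1 = [(s.result.label, s.result.coverages) for s in p1.steps]
        seq2 = [(s.result.label, s.result.coverages) for s in p2.steps]
        assert seq1 == seq2

    def test_printed_table_fixture_ordering(self):
        """Fed the ESSA league-table cost/HLY pairs, the walk starts with
        vaccination at 50% and reaches the combination before mammography."""
        prev = [
            _pt("CVC_C1a", 146, 5_215_136, "cervical/prevention", {"C1a": 0.5}),
            _pt("CVC_C1a", 190, 6_773_262, "cervical/prevention", {"C1a": 0.8}),
            _pt("CVC_C1e", 1163, 30_421_065, "cervical/prevention", {"C1a": 0.8, "C1b": 0.8}),
            _pt("CVC_C1e", 1362, 31_554_286, "cervical/prevention", {"C1a": 0.95, "C1b": 0.95}),
        ]
        others = [
            _pt("BRC_C2a", 157, 1_389_662, "breast/treatment", {"C2a": 0.95}),
            _pt("BRC_C2b", 1307, 2_697_617, "breast/screening", {"C2b": 0.95}),
            _pt("CRC_C3a", 136, 626_379, "colorectal/treatment", {"C3a": 0.95}),
        ]
        path = expansion_path(
            {
                "cervical/prevention": prev,
                "breast/treatment": [others[0]],
                "breast/screening": [others[1]],
                "colorectal/treatment": [others[2]],
            }
        )
        labels = [s.result.label for s in path.steps]
        assert labels[0] == "CVC_C1a"
        assert dict(path.steps[0].result.coverages) == {"C1a": 0.5}
        assert labels.index("CVC_C1e") < labels.index("BRC_C2b")
        icers = [s.icer for s in path.steps]
        assert icers[0] == 28


class TestBudgetAndLeague:
    def test_published_budget_shares(self):
        sea = budget_allocation_from_costs(
            {
                "breast": 1_454_645_503,
                "cervical": 781_881_006,
                "colorectal": 364_949_796,
            }
        )
        assert sea == {"breast": 56, "cervical": 30, "colorectal": 14}
        essa = budget_allocation_from_costs(
            {
                "breast": 1_635_269_849,
                "cervical": 1_522_549_019,
                "colorectal": 248_737_875,
            }
        )
        assert essa == {"breast": 48, "cervical": 45, "colorectal": 7}

    def test_equal_costs_split_evenly(self):
        shares = budget_allocation_from_costs({"a": 1.0, "b": 1.0, "c": 1.0})
        assert set(shares.values()) == {33}
        assert 99 <= sum(shares.values()) <= 100

    def test_single_cancer_takes_everything(self):
        pts = _ladder("A", "breast/t", [10, 18, 25], [100, 150, 180])
        path = expansion_path({"breast/t": pts})
        assert budget_allocation(path) == {"breast": 100}

    def test_empty_path_league_table(self):
        from gcea.frontier import ExpansionPath

        table = league_table(ExpansionPath(steps=[]))
        assert len(table) == 0

    def test_programme_acers_from_budget_totals(self):
        assert programme_acer(2_601_476_305, 8_611_060) == 302.11
        assert programme_acer(3_406_556_743, 36_378_783) == 93.64
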