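"""Fragment planner: boundary rules, scheduling, effective RRVs."""

import math

import numpy as np
import pytest

from glycoplan.fixtures import fixture_scenario
from glycoplan.fragments import (
    Fragment,
    StrategyInfeasibleError,
    effective_rrv_of_fragment,
    fragment_search,
    schedule_connection,
    role_class_of_rrv,
)
from glycoplan.glycan import parse_glycan
from glycoplan.planner import PlanStep

from conftest import random_library, random_tree


class TestFragmentSearch:
    def test_globo_h_one_three_two_strategy(self):
        fx = fixture_scenario("globoH_132")
        plans = fragment_search(fx.tree, fx.library)
        assert len(plans) == 1
        p = plans[0]
        assert p.signature() == (1, 3, 2)
        effs = sorted(
            (effective_rrv_of_fragment(f) for f in p.fragments), reverse=True
        )
        assert effs == [72_000.0, 13.0, 0.0]
        tri = next(f for f in p.fragments if f.n_bbls == 3)
        assert tri.rrv_sequence == (4000.0, 850.0, 13.0)
        # the fucosylation site is unmasked only after the fragment one-pot
        assert any(tok == "OLev" for _, _, tok in tri.post_synthesis_deprotections)

    @pytest.mark.parametrize(
        "name,sig", [("ssea4_213", (2, 1, 3)), ("heparin_122", (1, 2, 2))]
    )
    def test_single_pot_scenarios_signatures(self, name, sig):
        fx = fixture_scenario(name)
        plans = fragment_search(fx.tree, fx.library)
        assert plans
        top = plans[0]
        assert top.signature() == sig
        assert top.n_fragments == 1

    def test_every_fragment_has_at_most_three_bbls(self, rng):
        for _ in range(20):
            t = random_tree(rng, int(rng.integers(2, 9)))
            lib = random_library(rng, t, int(rng.integers(5, 21)))
            for p in fragment_search(t, lib):
                for f in p.fragments:
                    assert 1 <= f.n_bbls <= 3

    def test_boundaries_only_at_masked_positions(self, rng):
        """A fragment break always corresponds to a precursor-masked
        attachment position on the parent-side BBL."""
        checked = 0
        fx = fixture_scenario("globoH_132")
        instances = [(fx.tree, list(fx.library))]
        for _ in range(30):
            t = random_tree(rng, int(rng.integers(3, 9)))
            instances.append((t, random_library(rng, t, int(rng.integers(5, 21)))))
        for t, lib in instances:
            for p in fragment_search(t, lib):
                frag_of = {
                    rid: i for i, f in enumerate(p.fragments)
                    for rid in f.residue_ids
                }
                for i, f in enumerate(p.fragments):
                    root_rid = next(
                        rid for rid in f.residue_ids
                        if t[rid].pid is None or t[rid].pid not in f.residue_ids
                    )
                    pid = t[root_rid].pid
                    if pid is None:
                        continue
                    parent_frag = p.fragments[frag_of[pid]]
                    masked = {
                        (rid, pos)
                        for rid, pos, _ in parent_frag.post_synthesis_deprotections
                    }
                    assert (pid, t[root_rid].parent_link_position) in masked
                    checked += 1
        assert checked >= 1

    def test_fragments_partition_residues(self, rng):
        for _ in range(15):
            t = random_tree(rng, int(rng.integers(2, 8)))
            lib = random_library(rng, t, 15)
            for p in fragment_search(t, lib):
                ids = [rid for f in p.fragments for rid in f.residue_ids]
                assert sorted(ids) == sorted(r.id for r in t.residues)

    def test_each_fragment_descends_strictly(self, rng):
        for _ in range(15):
            t = random_tree(rng, int(rng.integers(3, 8)))
            lib = random_library(rng, t, 20)
            for p in fragment_search(t, lib):
                for f in p.fragments:
                    seq = f.rrv_sequence
                    assert all(a > b for a, b in zip(seq, seq[1:]))


class TestEffectiveRRV:
    def test_defaults_to_reducing_end_bbl(self):
        fx = fixture_scenario("globoH_132")
        p = fragment_search(fx.tree, fx.library)[0]
        tri = next(f for f in p.fragments if f.n_bbls == 3)
        assert effective_rrv_of_fragment(tri) == 13.0

    def test_single_bbl_fragment(self):
        fx = fixture_scenario("globoH_132")
        p = fragment_search(fx.tree, fx.library)[0]
        fuc = next(f for f in p.fragments if f.n_bbls == 1)
        assert effective_rrv_of_fragment(fuc) == fuc.steps[0].rrv

    def test_override_wins(self):
        fx = fixture_scenario("globoH_132")
        p = fragment_search(fx.tree, fx.library)[0]
        tri = next(f for f in p.fragments if f.n_bbls == 3)
        assert effective_rrv_of_fragment(tri, override=42.0) == 42.0


def _bare_fragment(steps_rrv, state_ids, eff=None):
    """Fragment assembled directly (not via search) for scheduling tests."""
    from glycoplan.glycan import BuildingBlock, GlycanTree, Residue
    from glycoplan.matching import MatchResult

    steps = []
    for rrv, sid in zip(steps_rrv, state_ids):
        bbl = BuildingBlock(
            index=f"X{sid}", name=f"X{sid}", rrv=rrv,
            residues=GlycanTree([
                Residue(id=1, sugar_type="Gal", anomeric_form="b",
                        substituents={2: "OBz", 3: "OBn", 4: "OBn", 6: "OBn"})
            ]),
        )
        m = MatchResult("perfect", bbl.index, ((sid, 1),), ())
        steps.append(PlanStep(m, bbl, frozenset({sid}), None))
    return Fragment(
        steps=tuple(steps), fragment_yield=1.0,
        post_synthesis_deprotections=(), effective_rrv=eff,
    )


class TestScheduleConnection:
    def test_two_fragments_large_then_zero(self):
        t = parse_glycan("Gal(b1-4)Gal")
        f_top = _bare_fragment([20_000.0], [2], eff=20_000.0)
        f_root = _bare_fragment([0.0], [1], eff=0.0)
        plan = schedule_connection([f_root, f_top], t, parents=[-1, 0])
        assert plan.connection_strategy == "onepot_fragments"
        classes = [f.role_class for f in plan.fragments]
        assert classes == ["zero", "large"]
        assert plan.assembly_order == (1, 0)

    def test_four_chain_units_ordinal_classes(self):
        # linear chain of four single-residue fragments with unknown rrvs:
        # classes assigned ordinally from the non-reducing end
        t = parse_glycan("Gal(b1-4)Gal(b1-4)Gal(b1-4)Gal")
        ids = [r.id for r in t.residues]  # root first
        frags = [_bare_fragment([1.0], [rid]) for rid in ids]
        plan = schedule_connection(frags, t, parents=[-1, 0, 1, 2])
        classes = {i: f.role_class for i, f in enumerate(plan.fragments)}
        # fragment 3 is the deepest (added first)
        assert [classes[i] for i in (3, 2, 1, 0)] == [
            "large", "medium", "small", "zero"
        ]

    def test_more_than_four_chain_fragments_goes_hybrid(self):
        t = parse_glycan("Gal(b1-4)Gal(b1-4)Gal(b1-4)Gal(b1-4)Gal")
        ids = [r.id for r in t.residues]
        frags = [_bare_fragment([1.0], [rid]) for rid in ids]
        plan = schedule_connection(frags, t, parents=[-1, 0, 1, 2, 3])
        assert plan.connection_strategy == "hybrid"

    def test_unorderable_onepot_request_is_infeasible(self):
        t = parse_glycan("Gal(b1-4)Gal")
        f_top = _bare_fragment([5.0], [2], eff=5.0)
        f_root = _bare_fragment([10.0], [1], eff=10.0)  # root more reactive
        with pytest.raises(StrategyInfeasibleError):
            schedule_connection([f_root, f_top], t, parents=[-1, 0],
                                strategy="onepot_fragments")

    def test_post_order_schedule_builds_children_first(self):
        fx = fixture_scenario("globoH_132")
        p = fragment_search(fx.tree, fx.library)[0]
        order = list(p.assembly_order)
        parents = list(p.parents)
        for i, parent in enumerate(parents):
            if parent != -1:
                assert order.index(i) < order.index(parent)


class TestRoleClasses:
    @pytest.mark.parametrize(
        "rrv,cls",
        [(72_000.0, "large"), (15_001.0, "large"), (15_000.0, "medium"),
         (1462.0, "medium"), (1000.0, "small"), (13.0, "small"), (0.0, "zero")],
    )
    def test_bins(self, rrv, cls):
        assert role_class_of_rrv(rrv) == cls

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            role_class_of_rrv(-1.0)

    def test_search_plans_use_descending_classes_on_chain(self):
        fx = fixture_scenario("globoH_132")
        p = fragment_search(fx.tree, fx.library)[0]
        rank = {"large": 0, "medium": 1, "small": 2, "zero": 3}
        units = sorted(p.fragments, key=lambda f: -f.effective_rrv)
        ranks = [rank[f.role_class] for f in units]
        assert ranks == sorted(ranks)
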