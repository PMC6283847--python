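"""One-pot synthesis planning without fragmentation.

The planner tiles the query tree into connected states covered by perfectly
matched BBLs and orders them by strictly descending RRV: the most reactive
donor (non-reducing end) is added first, the RRV-0 reducing-end acceptor
last.  Every child state must be strictly more reactive than its parent
state, so the addition order is chemoselective at each coupling.

The per-coupling yield model is pluggable.  The default treats a coupling as
a competition of the donor (RRV :math:`r_d`) and the acceptor acting as a
donor (:math:`r_a`) for one equivalent of activator at equimolar loading:
with :math:`r = r_d/r_a`, integrating :math:`d[D_1]/d[D_2] = r[D_1]/[D_2]`
until the activator is consumed gives the productive fraction :math:`x`
solving :math:`x + x^r = 1`.  The limit :math:`r \\to \\infty` (or an RRV-0
acceptor, which cannot self-activate) gives yield 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from scipy.optimize import brentq

from .glycan import BuildingBlock, GlycanTree, Residue
from .matching import DEFAULT_REMOVABLE, MatchResult, match_state

__all__ = [
    "OrderingViolationError",
    "CompetingActivationYield",
    "PlanStep",
    "SynthesisPlan",
    "connected_states",
    "search_no_fragments",
    "compute_overall_yield",
]


class OrderingViolationError(ValueError):
    """Acceptor RRV >= donor RRV at a coupling."""


class CompetingActivationYield:
    """Default yield model: competing second-order activation kinetics."""

    name = "competing-activation"

    def __call__(self, rrv_donor: float, rrv_acceptor: float) -> float:
        if rrv_acceptor >= rrv_donor:
            raise OrderingViolationError(
                f"acceptor rrv {rrv_acceptor} >= donor rrv {rrv_donor}"
            )
        if rrv_acceptor == 0:
            return 1.0
        r = rrv_donor / rrv_acceptor
        return float(brentq(lambda x: x + x**r - 1.0, 0.0, 1.0, xtol=1e-12))


DEFAULT_YIELD_MODEL = CompetingActivationYield()


@dataclass(frozen=True)
class PlanStep:
    """One BBL addition: the matched state and its library record."""

    match: MatchResult
    bbl: BuildingBlock
    state_ids: frozenset[int]
    parent_state: frozenset[int] | None  # state this one glycosylates

    @property
    def rrv(self) -> float:
        return self.bbl.rrv


@dataclass(frozen=True)
class SynthesisPlan:
    """An ordered one-pot plan; steps run non-reducing end -> reducing end."""

    steps: tuple[PlanStep, ...]
    overall_yield: float

    @property
    def n_bbls(self) -> int:
        return len(self.steps)

    @property
    def rrv_sequence(self) -> tuple[float, ...]:
        return tuple(s.rrv for s in self.steps)

    @property
    def bbl_indices(self) -> tuple[str, ...]:
        return tuple(s.bbl.index for s in self.steps)

    def couplings(self) -> list[tuple[float, float]]:
        """(donor rrv, acceptor rrv) per glycosylation, donor-ordered."""
        by_state = {s.state_ids: s for s in self.steps}
        pairs = [
            (s.rrv, by_state[s.parent_state].rrv)
            for s in self.steps
            if s.parent_state is not None
        ]
        pairs.sort(key=lambda p: -p[0])
        return pairs

    def sort_key(self) -> tuple:
        return (-self.overall_yield, tuple((-s.rrv, s.bbl.index) for s in self.steps))


def connected_states(
    tree: GlycanTree, rid: int, max_size: int
) -> list[tuple[Residue, ...]]:
    """All connected residue groups containing ``rid`` that extend only into
    its subtree, up to ``max_size`` residues; deterministic order."""
    out: list[tuple[Residue, ...]] = []

    def grow(current: list[Residue], frontier: list[Residue]) -> None:
        out.append(tuple(current))
        if len(current) == max_size:
            return
        for i, nxt in enumerate(frontier):
            new_frontier = frontier[i + 1:] + list(tree.children(nxt.id))
            grow(current + [nxt], new_frontier)

    root = tree[rid]
    grow([root], list(tree.children(rid)))
    return out


def _hanging_subtrees(
    tree: GlycanTree, state: Sequence[Residue]
) -> list[tuple[Residue, Residue]]:
    """(state residue, child subtree root) pairs hanging below a state."""
    ids = {r.id for r in state}
    out = []
    for r in state:
        for k in tree.children(r.id):
            if k.id not in ids:
                out.append((r, k))
    return out


def search_no_fragments(
    tree: GlycanTree,
    library: Iterable[BuildingBlock],
    max_bbls: int = 4,
    yield_model: Callable[[float, float], float] = DEFAULT_YIELD_MODEL,
    removable: frozenset[str] = DEFAULT_REMOVABLE,
) -> list[SynthesisPlan]:
    """All one-pot plans covering the tree with perfectly matched BBLs.

    Precursor matches (masked hydroxyls) are excluded in this mode.  Returns
    plans ranked by overall yield, descending; deterministic tie-break.
    """
    if max_bbls < 1:
        raise ValueError("max_bbls must be >= 1")
    lib = list(library)

    def solve(rid: int, budget: int) -> list[tuple[PlanStep, ...]]:
        """Tilings of the subtree at rid, each as a tuple of steps whose
        parent_state is None for the state containing rid (filled by caller)."""
        results: list[tuple[PlanStep, ...]] = []
        if budget < 1:
            return results
        for state in connected_states(tree, rid, min(3, len(tree))):
            links = {
                r.id: {k.parent_link_position for k in tree.children(r.id)
                       if k.id not in {s.id for s in state}}
                for r in state
            }
            links = {k: v for k, v in links.items() if v}
            hanging = _hanging_subtrees(tree, state)
            state_ids = frozenset(r.id for r in state)
            for bbl in lib:
                if bbl.n_residues != len(state):
                    continue
                m = match_state(bbl, state, links, removable)
                if m is None or m.kind != "perfect":
                    continue
                step = PlanStep(m, bbl, state_ids, None)
                child_sets: list[list[tuple[PlanStep, ...]]] = []
                ok = True
                for _, sub_root in hanging:
                    subs = solve(sub_root.id, budget - 1)
                    # every state in the child tiling must out-react this one;
                    # the direct child state does, transitively, if each edge does
                    subs = [
                        tuple(
                            (s if s.parent_state is not None
                             else PlanStep(s.match, s.bbl, s.state_ids, state_ids))
                            for s in tiling
                        )
                        for tiling in subs
                        if all(st.rrv > bbl.rrv for st in tiling)
                    ]
                    if not subs:
                        ok = False
                        break
                    child_sets.append(subs)
                if not ok and hanging:
                    continue
                for combo in itertools.product(*child_sets):
                    steps = (step,) + tuple(s for tiling in combo for s in tiling)
                    if len(steps) <= budget:
                        results.append(steps)
        return results

    plans: list[SynthesisPlan] = []
    for steps in solve(tree.root.id, max_bbls):
        root_step = next(s for s in steps if s.parent_state is None)
        if root_step.rrv != 0:
            continue  # the final BBL must be the reducing-end acceptor
        rrvs = [s.rrv for s in steps]
        if len(set(rrvs)) != len(rrvs):
            continue  # a strict global descending order must exist
        ordered = tuple(sorted(steps, key=lambda s: -s.rrv))
        # strict descent along every state-tree edge
        by_state = {s.state_ids: s for s in steps}
        if any(
            s.parent_state is not None and s.rrv <= by_state[s.parent_state].rrv
            for s in steps
        ):
            continue
        plan = SynthesisPlan(ordered, overall_yield=1.0)
        plan = SynthesisPlan(ordered, compute_overall_yield(plan, yield_model))
        plans.append(plan)
    plans.sort(key=SynthesisPlan.sort_key)
    return plans


def compute_overall_yield(
    plan: SynthesisPlan,
    model: Callable[[float, float], float] = DEFAULT_YIELD_MODEL,
) -> float:
    """Product of per-coupling yields; a single-BBL plan has yield 1.0."""
    y = 1.0
    for donor, acceptor in plan.couplings():
        y *= model(donor, acceptor)
    return y
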