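"""Hierarchical one-pot planning: fragments of 1-3 BBLs assembled in turn.

A complex target is split into fragments, each synthesized by its own one-pot
sequence, then connected.  The split is driven by the protection state of the
matched BBLs: an attachment position carrying a free hydroxyl is coupled
inside the current fragment, while a position masked by a unique,
selectively removable protecting group defers the coupling - the sub-structure
above it becomes a separate fragment, attached after the masking group is
removed.  Fragment boundaries therefore occur exactly at precursor matches.

A completed fragment keeps the anomeric leaving group of its reducing-end BBL
and is reused as a building block; its effective RRV defaults to that BBL's
RRV (overridable by a measured value or a model prediction).  Fragments on
the target's major chain are assembled by a final one-pot whose units must
run large -> medium -> small -> zero in reactivity; with more than four
chain fragments a hybrid of one-pot assembly and distinct leaving groups is
suggested instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .glycan import BuildingBlock, GlycanTree, Residue
from .matching import DEFAULT_REMOVABLE, MatchResult, match_state
from .planner import (
    DEFAULT_YIELD_MODEL,
    OrderingViolationError,
    PlanStep,
    SynthesisPlan,
    compute_overall_yield,
    connected_states,
    _hanging_subtrees,
)

__all__ = [
    "Fragment",
    "FragmentPlan",
    "StrategyInfeasibleError",
    "fragment_search",
    "schedule_connection",
    "effective_rrv_of_fragment",
    "role_class_of_rrv",
]


class StrategyInfeasibleError(ValueError):
    """Requested connection strategy cannot order the fragments."""


def role_class_of_rrv(rrv: float) -> str:
    """Reactivity role of a fragment reused as a BBL, from the RRV bins
    (>15,000], (1,000-15,000], (0-1,000], {0}."""
    if rrv < 0:
        raise ValueError(f"rrv must be >= 0, got {rrv}")
    if rrv == 0:
        return "zero"
    if rrv > 15_000:
        return "large"
    if rrv > 1_000:
        return "medium"
    return "small"


@dataclass(frozen=True)
class Fragment:
    """A 1-3 BBL sub-assembly, independently built by one-pot synthesis."""

    steps: tuple[PlanStep, ...]  # descending rrv within the fragment
    fragment_yield: float
    post_synthesis_deprotections: tuple[tuple[int, int, str], ...]  # (residue, pos, token)
    effective_rrv: float | None
    role_class: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.steps) <= 3:
            raise ValueError("a fragment must contain 1 to 3 BBLs")
        if self.effective_rrv is not None and self.effective_rrv < 0:
            raise ValueError("effective rrv must be >= 0")

    @property
    def n_bbls(self) -> int:
        return len(self.steps)

    @property
    def n_residues(self) -> int:
        return sum(len(s.state_ids) for s in self.steps)

    @property
    def residue_ids(self) -> frozenset[int]:
        return frozenset(rid for s in self.steps for rid in s.state_ids)

    @property
    def rrv_sequence(self) -> tuple[float, ...]:
        return tuple(s.rrv for s in self.steps)

    @property
    def root_step(self) -> PlanStep:
        """The reducing-end BBL of the fragment (lowest rrv)."""
        return self.steps[-1]


def effective_rrv_of_fragment(
    fragment: Fragment, override: float | None = None
) -> float:
    """RRV of a fragment reused as a BBL.

    Defaults to the RRV of its reducing-end BBL, whose anomeric leaving group
    survives the fragment's one-pot; a measured or predicted value may be
    supplied as ``override``.
    """
    if override is not None:
        if override < 0:
            raise ValueError("override rrv must be >= 0")
        return float(override)
    if fragment.effective_rrv is not None:
        return float(fragment.effective_rrv)
    return float(fragment.root_step.rrv)


@dataclass(frozen=True)
class FragmentPlan:
    """Fragments plus the schedule for connecting them."""

    fragments: tuple[Fragment, ...]
    # parent fragment index per fragment (-1 for the reducing-end fragment)
    parents: tuple[int, ...]
    connection_strategy: str  # distinct_leaving_groups | onepot_fragments | hybrid
    assembly_order: tuple[int, ...]  # post-order over the fragment tree
    overall_yield: float

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def fragment_sizes(self) -> tuple[int, ...]:
        return tuple(f.n_residues for f in self.fragments)

    def signature(self) -> tuple[int, ...]:
        """Residue counts of the units added in the top-level one-pot,
        ordered by descending reactivity: the bracket notation of a strategy
        (e.g. [1 + 3 + 2]).  A single-fragment plan reports its BBL sizes."""
        if len(self.fragments) == 1:
            return tuple(len(s.state_ids) for s in self.fragments[0].steps)
        units = sorted(
            self.fragments, key=lambda f: -effective_rrv_of_fragment(f)
        )
        return tuple(f.n_residues for f in units)

    def sort_key(self) -> tuple:
        return (
            -self.overall_yield,
            tuple(
                tuple((-s.rrv, s.bbl.index) for s in f.steps) for f in self.fragments
            ),
        )


def _fragment_tree_edges(
    steps_by_state: Mapping[frozenset[int], PlanStep],
    frag_of_state: Mapping[frozenset[int], int],
) -> list[tuple[int, int]]:
    """(child fragment, parent fragment) pairs, from cross-fragment edges."""
    edges = set()
    for state, step in steps_by_state.items():
        if step.parent_state is None:
            continue
        a, b = frag_of_state[state], frag_of_state[step.parent_state]
        if a != b:
            edges.add((a, b))
    return sorted(edges)


def fragment_search(
    tree: GlycanTree,
    library: Iterable[BuildingBlock],
    max_bbls_per_fragment: int = 3,
    max_fragments_per_path: int = 3,
    yield_model: Callable[[float, float], float] = DEFAULT_YIELD_MODEL,
    removable: frozenset[str] = DEFAULT_REMOVABLE,
) -> list[FragmentPlan]:
    """Enumerate fragment-based plans for the target, ranked by overall yield.

    The tree is tiled by perfectly or precursor-matched BBLs; masked
    attachment positions become fragment boundaries.  Each fragment must hold
    1-3 BBLs with strictly descending RRVs, every non-reducing fragment must
    keep a positive effective RRV, and the fragment tree itself must be
    orderable by strictly descending effective RRV so the fragments can be
    assembled in one pot (or stepwise with distinct leaving groups).
    ``max_fragments_per_path`` caps boundary placements along any
    root-to-leaf path to bound the combinatorics.
    """
    lib = list(library)

    def tilings(rid: int) -> list[tuple[PlanStep, ...]]:
        results: list[tuple[PlanStep, ...]] = []
        for state in connected_states(tree, rid, min(3, len(tree))):
            sids = {r.id for r in state}
            links = {
                r.id: {k.parent_link_position for k in tree.children(r.id)
                       if k.id not in sids}
                for r in state
            }
            links = {k: v for k, v in links.items() if v}
            hanging = _hanging_subtrees(tree, state)
            state_ids = frozenset(sids)
            for bbl in lib:
                if bbl.n_residues != len(state):
                    continue
                m = match_state(bbl, state, links, removable)
                if m is None:
                    continue
                step = PlanStep(m, bbl, state_ids, None)
                child_sets = []
                for _, sub_root in hanging:
                    subs = [
                        tuple(
                            (s if s.parent_state is not None
                             else PlanStep(s.match, s.bbl, s.state_ids, state_ids))
                            for s in tiling
                        )
                        for tiling in tilings(sub_root.id)
                    ]
                    child_sets.append(subs)
                if any(not cs for cs in child_sets):
                    continue
                for combo in itertools.product(*child_sets):
                    results.append((step,) + tuple(s for t in combo for s in t))
        return results

    plans: list[FragmentPlan] = []
    seen: set = set()
    for steps in tilings(tree.root.id):
        plan = _steps_to_fragment_plan(
            tree, steps, max_bbls_per_fragment, max_fragments_per_path, yield_model
        )
        if plan is None:
            continue
        key = tuple(sorted((s.state_ids, s.bbl.index) for s in steps))
        if key in seen:
            continue
        seen.add(key)
        plans.append(plan)
    plans.sort(key=FragmentPlan.sort_key)
    return plans


def _steps_to_fragment_plan(
    tree: GlycanTree,
    steps: Sequence[PlanStep],
    max_bbls_per_fragment: int,
    max_fragments_per_path: int,
    yield_model: Callable[[float, float], float],
) -> FragmentPlan | None:
    by_state = {s.state_ids: s for s in steps}
    root_step = next(s for s in steps if s.parent_state is None)
    if root_step.rrv != 0:
        return None

    # edge classification: an edge is cross-fragment iff the attachment
    # position on the parent-side residue is masked in the parent's match
    def edge_is_masked(child: PlanStep) -> bool:
        parent = by_state[child.parent_state]
        child_root_rid = _state_root_id(tree, child.state_ids)
        q = tree[child_root_rid]
        masked = parent.match.masked_positions_of(q.pid)
        return q.parent_link_position in masked

    # group states into fragments over free (unmasked) edges
    frag_of: dict[frozenset[int], int] = {}

    def assign(state: frozenset[int], frag: int, counter: list[int]) -> None:
        frag_of[state] = frag
        for s in steps:
            if s.parent_state == state:
                if edge_is_masked(s):
                    counter[0] += 1
                    assign(s.state_ids, counter[0], counter)
                else:
                    assign(s.state_ids, frag, counter)

    counter = [0]
    assign(root_step.state_ids, 0, counter)
    n_frags = counter[0] + 1

    groups: dict[int, list[PlanStep]] = {i: [] for i in range(n_frags)}
    for s in steps:
        groups[frag_of[s.state_ids]].append(s)

    # a masked position whose edge stays inside a fragment cannot happen by
    # construction; but a precursor match may mask a position with no hanging
    # substructure only if the query genuinely attaches there - masked_links
    # are always child-link positions, so nothing to check here.

    fragments: list[Fragment] = []
    frag_parent: list[int] = []
    for i in range(n_frags):
        fsteps = groups[i]
        if not 1 <= len(fsteps) <= max_bbls_per_fragment:
            return None
        rrvs = [s.rrv for s in fsteps]
        if len(set(rrvs)) != len(rrvs):
            return None
        # strict descent along every in-fragment edge
        for s in fsteps:
            if s.parent_state is not None and frag_of[s.parent_state] == i:
                if s.rrv <= by_state[s.parent_state].rrv:
                    return None
        ordered = tuple(sorted(fsteps, key=lambda s: -s.rrv))
        root = ordered[-1]
        if i != 0 and root.rrv <= 0:
            return None  # a reused fragment must keep a reactive donor end
        deprot = tuple(
            (rid, pos, tok)
            for s in ordered
            for rid, items in s.match.masked_links
            for pos, tok in items
        )
        own_states = {s.state_ids for s in ordered}
        fy = 1.0
        for s in ordered:
            if s.parent_state in own_states:
                fy *= yield_model(s.rrv, by_state[s.parent_state].rrv)
        eff = float(root.rrv)
        fragments.append(
            Fragment(
                steps=ordered,
                fragment_yield=fy,
                post_synthesis_deprotections=deprot,
                effective_rrv=eff,
                role_class=role_class_of_rrv(eff),
            )
        )

    # fragment tree
    edges = _fragment_tree_edges(by_state, frag_of)
    parent_of = {c: p for c, p in edges}
    frag_parent = [parent_of.get(i, -1) for i in range(n_frags)]

    # descending effective rrv along the fragment tree (assembly feasibility)
    effs = [effective_rrv_of_fragment(f) for f in fragments]
    for c, p in edges:
        if effs[c] <= effs[p]:
            return None
    if len(set(effs)) != len(effs):
        return None

    # cap fragment count along any root-to-leaf path of the fragment tree
    children_of: dict[int, list[int]] = {i: [] for i in range(n_frags)}
    for c, p in edges:
        children_of[p].append(c)

    def depth(i: int) -> int:
        kids = children_of[i]
        return 1 + (max(map(depth, kids)) if kids else 0)

    if depth(0) > max_fragments_per_path:
        return None

    assembly_yield = 1.0
    for c, p in edges:
        assembly_yield *= yield_model(effs[c], effs[p])
    overall = assembly_yield
    for f in fragments:
        overall *= f.fragment_yield

    order = _post_order(children_of, 0)
    strategy = _pick_strategy(tree, fragments, effs)
    return FragmentPlan(
        fragments=tuple(fragments),
        parents=tuple(frag_parent),
        connection_strategy=strategy,
        assembly_order=tuple(order),
        overall_yield=overall,
    )


def _state_root_id(tree: GlycanTree, state_ids: frozenset[int]) -> int:
    for rid in state_ids:
        r = tree[rid]
        if r.pid is None or r.pid not in state_ids:
            return rid
    raise AssertionError("state without a root")


def _post_order(children_of: Mapping[int, list[int]], root: int) -> list[int]:
    out: list[int] = []

    def visit(i: int) -> None:
        for k in sorted(children_of[i]):
            visit(k)
        out.append(i)

    visit(root)
    return out


def _fragments_on_major_chain(
    tree: GlycanTree, fragments: Sequence[Fragment]
) -> list[int]:
    from .glycan import major_chain

    chain_ids = {r.id for r in major_chain(tree)}
    return [i for i, f in enumerate(fragments) if f.residue_ids & chain_ids]


def _pick_strategy(
    tree: GlycanTree, fragments: Sequence[Fragment], effs: Sequence[float]
) -> str:
    n_chain = len(_fragments_on_major_chain(tree, fragments))
    if n_chain > 4:
        return "hybrid"
    return "onepot_fragments"


def schedule_connection(
    fragments: Sequence[Fragment],
    tree: GlycanTree,
    parents: Sequence[int] | None = None,
    strategy: str | None = None,
) -> FragmentPlan:
    """Schedule fragment connection for an already-planned fragment set.

    ``parents`` gives the fragment tree (parent index per fragment, -1 at the
    reducing end); if omitted it is derived from residue adjacency in the
    target.  With ``strategy=None`` the one-pot assembly is chosen when at
    most four fragments lie on the major chain, falling back to
    ``distinct_leaving_groups`` when their effective RRVs cannot be ordered,
    and ``hybrid`` when the chain holds more than four fragments.  Explicitly
    requesting ``onepot_fragments`` with unorderable RRVs raises
    :class:`StrategyInfeasibleError`.
    """
    fragments = list(fragments)
    if parents is None:
        parents = _derive_parents(tree, fragments)
    parents = list(parents)
    children_of: dict[int, list[int]] = {i: [] for i in range(len(fragments))}
    root = 0
    for i, p in enumerate(parents):
        if p == -1:
            root = i
        else:
            children_of[p].append(i)
    order = _post_order(children_of, root)

    effs = [f.effective_rrv for f in fragments]
    known = all(e is not None for e in effs)
    orderable = known and all(
        effs[c] > effs[p] for p in children_of for c in children_of[p]
    )

    chain = _fragments_on_major_chain(tree, fragments)
    n_chain = len(chain) if chain else len(fragments)

    if strategy is None:
        if n_chain > 4:
            strategy = "hybrid"
        elif orderable or not known:
            strategy = "onepot_fragments"
        else:
            strategy = "distinct_leaving_groups"
    elif strategy == "onepot_fragments" and known and not orderable:
        raise StrategyInfeasibleError(
            "fragment effective RRVs cannot be ordered strictly descending "
            "toward the reducing end"
        )

    # role classes along the chain: by RRV bin when effective RRVs are known,
    # ordinal (large -> medium -> small -> zero) otherwise
    chain_or_all = chain if chain else list(range(len(fragments)))
    if known:
        classed = [
            Fragment(
                f.steps,
                f.fragment_yield,
                f.post_synthesis_deprotections,
                f.effective_rrv,
                role_class_of_rrv(f.effective_rrv),
            )
            for f in fragments
        ]
    else:
        ordinal = ["large", "medium", "small"]
        labels: dict[int, str] = {}
        # order units from non-reducing end (added first) to reducing end
        units = sorted(chain_or_all, key=lambda i: order.index(i))
        for pos, i in enumerate(units):
            if i == root:
                labels[i] = "zero"
            else:
                labels[i] = ordinal[min(pos, len(ordinal) - 1)]
        classed = [
            Fragment(
                f.steps,
                f.fragment_yield,
                f.post_synthesis_deprotections,
                f.effective_rrv,
                labels.get(i, f.role_class),
            )
            for i, f in enumerate(fragments)
        ]

    return FragmentPlan(
        fragments=tuple(classed),
        parents=tuple(parents),
        connection_strategy=strategy,
        assembly_order=tuple(order),
        overall_yield=float("nan"),
    )


def _derive_parents(tree: GlycanTree, fragments: Sequence[Fragment]) -> list[int]:
    frag_of_rid = {
        rid: i for i, f in enumerate(fragments) for rid in f.residue_ids
    }
    parents = []
    for i, f in enumerate(fragments):
        root_rid = min(
            (rid for rid in f.residue_ids
             if tree[rid].pid is None or tree[rid].pid not in f.residue_ids),
        )
        pid = tree[root_rid].pid
        parents.append(-1 if pid is None else frag_of_rid[pid])
    return parents
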