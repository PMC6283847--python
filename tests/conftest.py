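"""Shared fixtures: random glycan trees, random libraries, and brute-force
oracles kept deliberately independent of the search implementations."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from glycoplan.glycan import (
    BuildingBlock,
    GlycanTree,
    Residue,
    amine_positions,
    tracked_positions,
)
from glycoplan.matching import DEFAULT_REMOVABLE, match_state

RANDOM_SUGARS = ("Gal", "Glc", "Man", "GalNAc", "GlcNAc")
NON_REMOVABLE_PGS = ("OAc", "OBn", "OBz")
REMOVABLE_PGS = ("OLev", "OClAc", "OPMB")


def random_tree(rng: np.random.Generator, n: int) -> GlycanTree:
    """Random query tree: residue i+1 attaches at a free linkable position of
    a random earlier residue."""
    residues = [Residue(id=1, sugar_type=str(rng.choice(RANDOM_SUGARS)),
                        anomeric_form="b")]
    used: dict[int, set[int]] = {1: set()}
    for i in range(2, n + 1):
        while True:
            parent = residues[int(rng.integers(len(residues)))]
            free = [
                p for p in tracked_positions(parent.sugar_type)
                if p not in used[parent.id]
                and p not in amine_positions(parent.sugar_type)
            ]
            if free:
                break
        pos = int(rng.choice(free))
        used[parent.id].add(pos)
        r = Residue(
            id=i, pid=parent.id, parent_link_position=pos,
            sugar_type=str(rng.choice(RANDOM_SUGARS)),
            anomeric_form="a" if rng.random() < 0.4 else "b",
        )
        used[r.id] = set()
        residues.append(r)
    return GlycanTree(residues)


def connected_subsets(tree: GlycanTree, max_size: int = 3):
    """Every connected residue subset of size <= max_size (enumerative)."""
    ids = [r.id for r in tree.residues]
    for k in range(1, max_size + 1):
        for combo in itertools.combinations(ids, k):
            sub = set(combo)
            # connected iff every member except the shallowest has its parent in the set
            roots = [i for i in sub if tree[i].pid is None or tree[i].pid not in sub]
            if len(roots) == 1:
                yield tuple(sorted(sub))


def child_links_of(tree: GlycanTree, state_ids) -> dict[int, set[int]]:
    sub = set(state_ids)
    links: dict[int, set[int]] = {}
    for rid in sub:
        for k in tree.children(rid):
            if k.id not in sub:
                links.setdefault(rid, set()).add(k.parent_link_position)
    return links


def random_library(
    rng: np.random.Generator, tree: GlycanTree, n_bbls: int,
    p_oh: float = 0.4, p_removable: float = 0.2, allow_multi: bool = True,
) -> list[BuildingBlock]:
    """BBLs built from random connected states of the tree with randomized
    protection, anomeric flips, and rrvs; intentionally noisy so both
    solvable and unsolvable instances arise."""
    states = [s for s in connected_subsets(tree, 3 if allow_multi else 1)]
    lib: list[BuildingBlock] = []
    for i in range(n_bbls):
        state_ids = states[int(rng.integers(len(states)))]
        sub = set(state_ids)
        residues = []
        for rid in state_ids:
            q = tree[rid]
            internal = {
                k.parent_link_position for k in tree.children(rid) if k.id in sub
            }
            subs = {}
            for p in tracked_positions(q.sugar_type):
                if p in internal:
                    continue
                if p in amine_positions(q.sugar_type):
                    subs[p] = str(rng.choice(("NHTroc", "NPhth", "N3")))
                else:
                    u = rng.random()
                    if u < p_oh:
                        subs[p] = "OH"
                    elif u < p_oh + p_removable:
                        subs[p] = str(rng.choice(REMOVABLE_PGS))
                    else:
                        subs[p] = str(rng.choice(NON_REMOVABLE_PGS))
            anom = q.anomeric_form
            if rng.random() < 0.15:  # occasional deliberate mismatch
                anom = "a" if anom == "b" else "b"
            residues.append(
                Residue(
                    id=rid,
                    pid=q.pid if q.pid in sub else None,
                    parent_link_position=(
                        q.parent_link_position if q.pid in sub else None
                    ),
                    sugar_type=q.sugar_type,
                    anomeric_form=anom,
                    substituents=subs,
                )
            )
        is_root_state = tree.root.id in sub
        if is_root_state and rng.random() < 0.7:
            rrv = 0.0
        else:
            rrv = float(np.exp(rng.uniform(0.0, math.log(72_000.0))))
        lib.append(
            BuildingBlock(
                index=f"L{i:03d}", name=f"L{i:03d}",
                residues=GlycanTree(residues), rrv=rrv,
            )
        )
    return lib


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_onepot(tree, library, max_bbls=4, removable=DEFAULT_REMOVABLE):
    """Oracle: every tiling of the tree into connected <=3-residue blocks,
    every perfectly matching BBL assignment, filtered by the one-pot rules.
    Returns a set of canonical plan keys."""
    plans = set()
    ids = [r.id for r in tree.residues]
    for part in set_partitions(ids):
        blocks = [tuple(sorted(b)) for b in part]
        if any(len(b) > 3 for b in blocks):
            continue
        if len(blocks) > max_bbls:
            continue
        ok = True
        for b in blocks:
            sub = set(b)
            roots = [i for i in sub if tree[i].pid is None or tree[i].pid not in sub]
            if len(roots) != 1:
                ok = False
                break
        if not ok:
            continue
        block_of = {rid: b for b in blocks for rid in b}
        # candidate BBLs per block
        per_block = []
        for b in blocks:
            state = [tree[i] for i in b]
            links = child_links_of(tree, b)
            cands = []
            for bbl in library:
                if bbl.n_residues != len(b):
                    continue
                m = match_state(bbl, state, links, removable)
                if m is not None and m.kind == "perfect":
                    cands.append(bbl)
            per_block.append(cands)
        if any(not c for c in per_block):
            continue
        for assign in itertools.product(*per_block):
            rrv_of = dict(zip(blocks, (b.rrv for b in assign)))
            rrvs = list(rrv_of.values())
            if len(set(rrvs)) != len(rrvs):
                continue
            good = True
            for b in blocks:
                sub = set(b)
                root_rid = next(
                    i for i in b if tree[i].pid is None or tree[i].pid not in sub
                )
                pid = tree[root_rid].pid
                if pid is None:
                    if rrv_of[b] != 0:
                        good = False
                        break
                else:
                    if rrv_of[b] <= rrv_of[block_of[pid]]:
                        good = False
                        break
            if good:
                plans.add(
                    frozenset((b, a.index) for b, a in zip(blocks, assign))
                )
    return plans


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
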