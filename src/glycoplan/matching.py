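"""Match building blocks against the current state of a query glycan.

A *state* is a connected group of query residues whose size equals the BBL's
residue count.  ``child_links`` gives, per state residue, the positions where
the query attaches sub-structures below the state.  A *perfect* match has a
free hydroxyl at every such position and protection everywhere else; a
*precursor* match masks one or more of those positions with a protecting group
that is selectively removable and unique among the BBL's child-link positions,
so it can be unambiguously deprotected before the next coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .glycan import BuildingBlock, Residue, amine_positions, tracked_positions

__all__ = [
    "DEFAULT_REMOVABLE",
    "MatchContractError",
    "MatchResult",
    "match_state",
    "candidate_list",
]

#: protecting groups that can be selectively removed in a following step.
#: Lev deprotection is the canonical example; Fmoc appears in validated
#: virtual BBLs.  User-extensible: pass a custom set to the matchers.
DEFAULT_REMOVABLE: frozenset[str] = frozenset(
    {"OLev", "OClAc", "OPMB", "NO2Bz", "OTBDPS", "OTBS", "OTIPS", "Fmoc"}
)


class MatchContractError(ValueError):
    """State size does not equal the BBL residue count."""


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one BBL against one query state.

    ``deprotections`` lists (position, token) pairs that must be removed
    before the next coupling; it is empty iff ``kind == "perfect"``.
    ``masked_links`` records the same information keyed by query residue id,
    which disambiguates multi-residue BBLs.
    """

    kind: str  # "perfect" | "precursor"
    bbl_index: str
    residue_mapping: tuple[tuple[int, int], ...]  # (query id, bbl id)
    deprotections: tuple[tuple[int, str], ...]
    masked_links: tuple[tuple[int, tuple[tuple[int, str], ...]], ...] = ()

    def masked_positions_of(self, query_rid: int) -> dict[int, str]:
        for rid, items in self.masked_links:
            if rid == query_rid:
                return dict(items)
        return {}


def _state_root(state: Sequence[Residue]) -> Residue:
    ids = {r.id for r in state}
    roots = [r for r in state if r.pid is None or r.pid not in ids]
    if len(roots) != 1:
        raise MatchContractError(f"state is not connected: {len(roots)} internal roots")
    return roots[0]


def match_state(
    bbl: BuildingBlock,
    state: Iterable[Residue],
    child_links: Mapping[int, Iterable[int]],
    removable: frozenset[str] = DEFAULT_REMOVABLE,
) -> MatchResult | None:
    """Match one BBL against a query state; None if they are incompatible."""
    state = list(state)
    if len(state) != bbl.n_residues:
        raise MatchContractError(
            f"state has {len(state)} residues but BBL {bbl.index} has {bbl.n_residues}"
        )
    links = {rid: frozenset(ps) for rid, ps in child_links.items()}
    qroot = _state_root(state)
    by_id = {r.id: r for r in state}

    # sialic acid may only appear as the terminal unit of a multi-residue BBL
    # (it is never the first donor; the disaccharide RRV comes from the
    # reducing-end sugar), and it never carries further substructure.
    for br in bbl.residues.residues:
        if br.sugar_type == "Neu5Ac":
            if bbl.n_residues < 2 or bbl.residues.children(br.id):
                return None

    mapping: list[tuple[int, int]] = []
    masked: dict[int, dict[int, str]] = {}

    def walk(q: Residue, b: Residue) -> bool:
        if q.sugar_type != b.sugar_type or q.anomeric_form != b.anomeric_form:
            return False
        mapping.append((q.id, b.id))
        in_state_kids = {
            k.parent_link_position: k
            for k in state
            if k.pid == q.id
        }
        bbl_kids = {k.parent_link_position: k for k in bbl.residues.children(b.id)}
        if set(in_state_kids) != set(bbl_kids):
            return False  # internal linkage topology disagrees
        for pos, qk in in_state_kids.items():
            if not walk(qk, bbl_kids[pos]):
                return False
        # protection state of this residue
        internal = set(bbl_kids)
        tracked = set(tracked_positions(q.sugar_type)) - internal
        q_child = set(links.get(q.id, frozenset()))
        if not q_child <= tracked:
            return False  # query attaches where the BBL has an internal bond
        amines = amine_positions(q.sugar_type)
        for p in sorted(tracked):
            tok = b.substituents[p]
            if p in q_child:
                if p in amines:
                    return False  # an amine position cannot bear a glycosidic bond
                if tok == "OH":
                    continue
                if tok in removable:
                    masked.setdefault(q.id, {})[p] = tok
                else:
                    return False
            else:
                if tok == "OH":
                    return False  # stray free hydroxyl would compete in the pot
        return True

    if not walk(qroot, bbl.residues.root):
        return None

    # uniqueness: every masking token must occur exactly once among the BBL's
    # child-link positions, so selective deprotection is unambiguous.
    child_tokens: list[str] = []
    for q in state:
        bid = dict(mapping)[q.id]
        b = bbl.residues[bid]
        for p in links.get(q.id, frozenset()):
            child_tokens.append(b.substituents[p])
    for toks in masked.values():
        for tok in toks.values():
            if child_tokens.count(tok) != 1:
                return None

    deprotections = tuple(
        (p, tok)
        for rid in sorted(masked)
        for p, tok in sorted(masked[rid].items())
    )
    return MatchResult(
        kind="precursor" if deprotections else "perfect",
        bbl_index=bbl.index,
        residue_mapping=tuple(sorted(mapping)),
        deprotections=deprotections,
        masked_links=tuple(
            (rid, tuple(sorted(items.items()))) for rid, items in sorted(masked.items())
        ),
    )


def candidate_list(
    library: Iterable[BuildingBlock],
    state: Iterable[Residue],
    child_links: Mapping[int, Iterable[int]],
    removable: frozenset[str] = DEFAULT_REMOVABLE,
) -> list[tuple[MatchResult, BuildingBlock]]:
    """All library matches for a state: perfect first, then descending rrv,
    then index.  BBLs of the wrong size or sugar composition are pre-filtered.
    """
    state = list(state)
    want_size = len(state)
    want_sugars = tuple(sorted(r.sugar_type for r in state))
    out: list[tuple[MatchResult, BuildingBlock]] = []
    for bbl in library:
        if bbl.n_residues != want_size or bbl.sugar_multiset != want_sugars:
            continue
        m = match_state(bbl, state, child_links, removable)
        if m is not None:
            out.append((m, bbl))
    out.sort(key=lambda mb: (mb[0].kind != "perfect", -mb[1].rrv, mb[1].index))
    return out
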