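"""Glycan tree data model, text/JSON serialization, and building-block records.

A glycan is a rooted tree of monosaccharide residues with the root at the
reducing end.  Edges are glycosidic linkages written in the condensed style
``Gal(b1-4)Glc``: the donor's anomeric carbon (beta, position 1) is bonded to
position 4 of the acceptor, and the acceptor is the parent (it lies toward the
reducing end).  Branches are bracketed, e.g. ``Gal(b1-3)[Gal(b1-6)]Gal``.

Building blocks (BBLs) are protected thioglycosides of 1-3 residues with a
relative reactivity value (RRV).  Each residue records one substituent token
per trackable ring position; positions engaged in glycosidic bonds inside the
BBL carry no token.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "SUGAR_TYPES",
    "SUGAR_CLASS",
    "HEX_SUBSTITUENTS",
    "HEXNAC_AMINE",
    "GlycanError",
    "GlycanParseError",
    "GlycanStructureError",
    "Residue",
    "GlycanTree",
    "BuildingBlock",
    "tracked_positions",
    "amine_positions",
    "parse_glycan",
    "parse_glycan_json",
    "serialize_glycan",
    "glycan_to_json",
    "leaf_residues",
    "major_chain",
]

#: sugar type -> sugar class. Fuc is a 6-deoxy hexose; Neu5Ac is sialic acid,
#: whose anomeric carbon is position 2 (a2-3 / a2-6 linkages).
SUGAR_CLASS: dict[str, str] = {
    "Gal": "Hex",
    "Glc": "Hex",
    "Man": "Hex",
    "Fuc": "Hex",
    "GalNAc": "HexNAc",
    "GlcNAc": "HexNAc",
    "Neu5Ac": "SA",
}
SUGAR_TYPES: tuple[str, ...] = tuple(SUGAR_CLASS)

#: ordered protecting-group vocabulary for hydroxyl positions (11 tokens).
HEX_SUBSTITUENTS: tuple[str, ...] = (
    "OH", "OAc", "OBn", "OBz", "OClAc", "OLev",
    "NO2Bz", "OPMB", "OTBDPS", "OTBS", "OTIPS",
)
#: amine protecting groups for the 2-position of HexNAc residues.
HEXNAC_AMINE: tuple[str, ...] = ("NHTroc", "NPhth", "N3")

#: positions a glycosidic bond may use on a parent residue.
LINKABLE_POSITIONS = frozenset({2, 3, 4, 6})


class GlycanError(ValueError):
    """Base class for glycan data-model errors."""


class GlycanParseError(GlycanError):
    """Malformed glycan text; names the offending token."""


class GlycanStructureError(GlycanError):
    """Structurally invalid residue set (cycles, duplicate ids, bad links)."""


def tracked_positions(sugar_type: str) -> tuple[int, ...]:
    """Ring positions that carry a substituent token for this sugar type.

    Hexoses track 2,3,4,6; fucose (6-deoxy) tracks 2,3,4; HexNAc tracks the
    amine at 2 plus hydroxyls at 3,4,6; sialic acid tracks 4,7,8,9.
    """
    if sugar_type == "Fuc":
        return (2, 3, 4)
    if sugar_type == "Neu5Ac":
        return (4, 7, 8, 9)
    if sugar_type in SUGAR_CLASS:
        return (2, 3, 4, 6)
    raise GlycanStructureError(
        f"unknown sugar type {sugar_type!r}; allowed: {sorted(SUGAR_CLASS)}"
    )


def amine_positions(sugar_type: str) -> frozenset[int]:
    """Positions bearing a nitrogen substituent (never glycosylated)."""
    return frozenset({2}) if SUGAR_CLASS.get(sugar_type) == "HexNAc" else frozenset()


def anomeric_position(sugar_type: str) -> int:
    """Donor carbon of the glycosidic bond: 2 for sialic acid, else 1."""
    return 2 if sugar_type == "Neu5Ac" else 1


@dataclass
class Residue:
    """One monosaccharide unit of a glycan tree or building block.

    ``pid`` is None for the root (reducing end).  ``substituents`` maps ring
    position -> token; it may be empty for query glycans, where protection
    state is irrelevant.
    """

    id: int
    sugar_type: str
    anomeric_form: str  # "a" | "b"
    pid: int | None = None
    parent_link_position: int | None = None
    substituents: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sugar_type not in SUGAR_CLASS:
            raise GlycanStructureError(
                f"unknown sugar type {self.sugar_type!r}; allowed: {sorted(SUGAR_CLASS)}"
            )
        form = {"alpha": "a", "beta": "b"}.get(self.anomeric_form, self.anomeric_form)
        if form not in ("a", "b"):
            raise GlycanStructureError(
                f"anomeric form must be 'a' or 'b', got {self.anomeric_form!r}"
            )
        self.anomeric_form = form
        if (self.pid is None) != (self.parent_link_position is None):
            raise GlycanStructureError(
                f"residue {self.id}: pid and parent_link_position must both be set or both absent"
            )
        if self.parent_link_position is not None and self.parent_link_position not in LINKABLE_POSITIONS:
            raise GlycanStructureError(
                f"residue {self.id}: parent link position {self.parent_link_position} "
                f"not in {sorted(LINKABLE_POSITIONS)}"
            )
        allowed = set(tracked_positions(self.sugar_type))
        bad = set(self.substituents) - allowed
        if bad:
            raise GlycanStructureError(
                f"residue {self.id} ({self.sugar_type}): substituent positions {sorted(bad)} "
                f"outside tracked positions {sorted(allowed)}"
            )

    @property
    def sugar_class(self) -> str:
        return SUGAR_CLASS[self.sugar_type]

    @property
    def anomeric_carbon(self) -> int:
        return anomeric_position(self.sugar_type)


class GlycanTree:
    """Rooted tree of residues; root = reducing end; child order deterministic."""

    def __init__(self, residues: Iterable[Residue]):
        self._residues: dict[int, Residue] = {}
        for r in residues:
            if r.id in self._residues:
                raise GlycanStructureError(f"duplicate residue id {r.id}")
            self._residues[r.id] = r
        if not self._residues:
            raise GlycanStructureError("a glycan needs at least one residue")
        roots = [r for r in self._residues.values() if r.pid is None]
        if len(roots) != 1:
            raise GlycanStructureError(f"expected exactly one root residue, found {len(roots)}")
        self._root = roots[0]
        self._children: dict[int, list[Residue]] = {rid: [] for rid in self._residues}
        for r in self._residues.values():
            if r.pid is not None:
                if r.pid not in self._residues:
                    raise GlycanStructureError(f"residue {r.id} refers to missing parent {r.pid}")
                self._children[r.pid].append(r)
        for kids in self._children.values():
            kids.sort(key=lambda r: (r.parent_link_position, r.id))
            positions = [k.parent_link_position for k in kids]
            if len(positions) != len(set(positions)):
                raise GlycanStructureError("two children attached at the same parent position")
        # connectivity / acyclicity: every residue reachable from the root
        seen: set[int] = set()
        stack = [self._root.id]
        while stack:
            rid = stack.pop()
            if rid in seen:
                raise GlycanStructureError("cycle detected in residue graph")
            seen.add(rid)
            stack.extend(k.id for k in self._children[rid])
        if seen != set(self._residues):
            raise GlycanStructureError("residue graph is not connected")

    @property
    def root(self) -> Residue:
        return self._root

    @property
    def residues(self) -> tuple[Residue, ...]:
        """All residues in deterministic pre-order (root first)."""
        out: list[Residue] = []
        stack = [self._root]
        while stack:
            r = stack.pop()
            out.append(r)
            stack.extend(reversed(self.children(r.id)))
        return tuple(out)

    def __len__(self) -> int:
        return len(self._residues)

    def __getitem__(self, rid: int) -> Residue:
        return self._residues[rid]

    def __contains__(self, rid: int) -> bool:
        return rid in self._residues

    def children(self, rid: int) -> tuple[Residue, ...]:
        return tuple(self._children[rid])

    def renumbered(self) -> "GlycanTree":
        """Canonical copy: root id 1, then pre-order with children in link order."""
        mapping: dict[int, int] = {}
        order: list[Residue] = []
        stack = [self._root]
        while stack:
            r = stack.pop()
            mapping[r.id] = len(mapping) + 1
            order.append(r)
            stack.extend(reversed(self.children(r.id)))
        new = [
            replace(
                r,
                id=mapping[r.id],
                pid=None if r.pid is None else mapping[r.pid],
                substituents=dict(r.substituents),
            )
            for r in order
        ]
        return GlycanTree(new)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanTree):
            return NotImplemented
        a = [(r.id, r.pid, r.sugar_type, r.anomeric_form, r.parent_link_position,
              tuple(sorted(r.substituents.items()))) for r in self.renumbered().residues]
        b = [(r.id, r.pid, r.sugar_type, r.anomeric_form, r.parent_link_position,
              tuple(sorted(r.substituents.items()))) for r in other.renumbered().residues]
        return a == b

    def __repr__(self) -> str:
        return f"GlycanTree({serialize_glycan(self)!r})"


def leaf_residues(tree: GlycanTree) -> list[Residue]:
    """Residues with no children, in deterministic pre-order."""
    return [r for r in tree.residues if not tree.children(r.id)]


def major_chain(tree: GlycanTree) -> list[Residue]:
    """Longest leaf-to-root path, returned leaf first.

    Ties are broken by the smallest parent-link position at the divergence
    point, then by smallest residue id, so the result is deterministic.
    """

    def descend(r: Residue) -> list[Residue]:
        kids = tree.children(r.id)
        if not kids:
            return [r]
        best: list[Residue] | None = None
        for k in kids:  # kids already sorted by (position, id) -> first longest wins
            path = descend(k)
            if best is None or len(path) > len(best):
                best = path
        assert best is not None
        return best + [r]

    return descend(tree.root)


# ---------------------------------------------------------------------------
# Text dialect
# ---------------------------------------------------------------------------

_NAME_RE = re.compile("|".join(sorted(SUGAR_CLASS, key=len, reverse=True)))
_LINK_RE = re.compile(r"\(([ab])([12])-([0-9])\)")


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "[]":
            tokens.append((c, c))
            i += 1
            continue
        m = _NAME_RE.match(text, i)
        if m:
            tokens.append(("NAME", m.group(0)))
            i = m.end()
            continue
        m = _LINK_RE.match(text, i)
        if m:
            tokens.append(("LINK", m.group(0)))
            i = m.end()
            continue
        raise GlycanParseError(f"unexpected token at position {i}: {text[i:i + 12]!r}")
    return tokens


def parse_glycan(text: str) -> GlycanTree:
    """Parse the condensed text dialect (or, if the text starts with ``{``,
    the JSON tree dialect) into a canonical :class:`GlycanTree`.

    Grammar::

        chain  := element+            (last element is the parent-most residue)
        element:= branch* NAME LINK?  (LINK absent only on the final residue)
        branch := '[' chain-with-dangling-LINK ']'
    """
    text = text.strip()
    if text.startswith("{"):
        return parse_glycan_json(text)
    tokens = _tokenize(text)
    if not tokens:
        raise GlycanParseError("empty glycan string")

    residues: list[Residue] = []
    counter = [0]

    def new_residue(name: str, anomeric: str) -> Residue:
        counter[0] += 1
        r = Residue(id=counter[0], sugar_type=name, anomeric_form=anomeric)
        residues.append(r)
        return r

    def parse_chain(pos: int, stop_at_bracket: bool) -> tuple[int, Residue, str | None, int | None]:
        """Parse a chain; return (next_pos, parent-most residue, dangling link)."""
        pending: list[tuple[Residue, int]] = []  # (child subtree root, parent position)
        last: Residue | None = None
        dangling: tuple[str, int] | None = None
        while pos < len(tokens):
            kind, val = tokens[pos]
            if kind == "]":
                break
            if kind == "[":
                sub_pos, sub_root, sub_anom, sub_link = parse_chain(pos + 1, True)
                if sub_pos >= len(tokens) or tokens[sub_pos][0] != "]":
                    raise GlycanParseError("unterminated branch: missing ']'")
                if sub_anom is None or sub_link is None:
                    raise GlycanParseError("bracketed branch must end with a linkage")
                sub_root.anomeric_form = sub_anom
                pending.append((sub_root, sub_link))
                pos = sub_pos + 1
                continue
            if kind == "NAME":
                if last is not None and dangling is None:
                    raise GlycanParseError(f"residue {val!r} follows a residue without a linkage")
                r = new_residue(val, "b")  # anomeric set by the following link
                if last is not None:
                    assert dangling is not None
                    last.anomeric_form = dangling[0]
                    last.pid = r.id
                    last.parent_link_position = dangling[1]
                for child, p in pending:
                    child.pid = r.id
                    child.parent_link_position = p
                pending = []
                dangling = None
                pos += 1
                if pos < len(tokens) and tokens[pos][0] == "LINK":
                    m = _LINK_RE.fullmatch(tokens[pos][1])
                    assert m is not None
                    anom, donor_pos, parent_pos = m.group(1), int(m.group(2)), int(m.group(3))
                    if donor_pos != anomeric_position(val):
                        raise GlycanParseError(
                            f"{val} donates from position {anomeric_position(val)}, "
                            f"got linkage {tokens[pos][1]!r}"
                        )
                    dangling = (anom, parent_pos)
                    pos += 1
                last = r
                continue
            raise GlycanParseError(f"unexpected {val!r} in chain")
        if last is None:
            raise GlycanParseError("empty chain")
        if pending:
            raise GlycanParseError("branch group has no parent residue")
        if dangling is None:
            return pos, last, None, None
        return pos, last, dangling[0], dangling[1]

    pos, root, anom, link = parse_chain(0, False)
    if pos != len(tokens):
        raise GlycanParseError(f"unexpected {tokens[pos][1]!r} after complete glycan")
    if link is not None:
        raise GlycanParseError("glycan ends with a dangling linkage")
    # residues built with pid references both directions; validate via GlycanTree
    try:
        # re-run __post_init__ checks now that pids are final
        for r in residues:
            Residue.__post_init__(r)
        tree = GlycanTree(residues)
    except GlycanStructureError as exc:
        raise GlycanParseError(str(exc)) from exc
    return tree.renumbered()


def serialize_glycan(tree: GlycanTree) -> str:
    """Canonical condensed text: lowest-position child inline, others bracketed."""

    def link_str(r: Residue) -> str:
        return f"({r.anomeric_form}{r.anomeric_carbon}-{r.parent_link_position})"

    def render(r: Residue) -> str:
        kids = tree.children(r.id)
        if not kids:
            return r.sugar_type
        inline, *rest = kids
        parts = [render(inline) + link_str(inline)]
        for k in rest:
            parts.append("[" + render(k) + link_str(k) + "]")
        parts.append(r.sugar_type)
        return "".join(parts)

    return render(tree.root)


# ---------------------------------------------------------------------------
# JSON dialect (mirrors the per-residue record fields: ID/PID/sugar type/...)
# ---------------------------------------------------------------------------

def glycan_to_json(tree: GlycanTree) -> str:
    recs = [
        {
            "id": r.id,
            "pid": r.pid,
            "sugar_type": r.sugar_type,
            "anomeric": r.anomeric_form,
            "parent_link_position": r.parent_link_position,
            "substituents": {str(p): t for p, t in sorted(r.substituents.items())},
        }
        for r in tree.renumbered().residues
    ]
    return json.dumps({"residues": recs}, indent=2, sort_keys=True)


def parse_glycan_json(text: str) -> GlycanTree:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GlycanParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "residues" not in doc:
        raise GlycanParseError("JSON glycan must be an object with a 'residues' list")
    residues = [
        Residue(
            id=int(rec["id"]),
            pid=None if rec.get("pid") is None else int(rec["pid"]),
            sugar_type=rec["sugar_type"],
            anomeric_form=rec["anomeric"],
            parent_link_position=(
                None if rec.get("parent_link_position") is None
                else int(rec["parent_link_position"])
            ),
            substituents={int(p): t for p, t in (rec.get("substituents") or {}).items()},
        )
        for rec in doc["residues"]
    ]
    return GlycanTree(residues).renumbered()


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

@dataclass
class BuildingBlock:
    """A protected thioglycoside building block with a relative reactivity value.

    ``rrv`` is dimensionless, relative to a reference donor; the reducing-end
    acceptor of a one-pot sequence has rrv 0.  Positions engaged in internal
    glycosidic bonds carry no substituent token; every other tracked position
    must carry exactly one token.
    """

    index: str
    name: str
    residues: GlycanTree
    rrv: float
    rrv_source: str = "measured"  # "measured" | "predicted"
    leaving_group: str = "STol"

    def __post_init__(self) -> None:
        if self.rrv < 0:
            raise GlycanStructureError(f"BBL {self.index}: rrv must be >= 0, got {self.rrv}")
        n = len(self.residues)
        if not 1 <= n <= 3:
            raise GlycanStructureError(f"BBL {self.index}: must have 1-3 residues, got {n}")
        if self.rrv_source not in ("measured", "predicted"):
            raise GlycanStructureError(
                f"BBL {self.index}: rrv_source must be 'measured' or 'predicted'"
            )
        for r in self.residues.residues:
            internal = {k.parent_link_position for k in self.residues.children(r.id)}
            expected = set(tracked_positions(r.sugar_type)) - internal
            have = set(r.substituents)
            if have != expected:
                raise GlycanStructureError(
                    f"BBL {self.index} residue {r.id} ({r.sugar_type}): substituents at "
                    f"{sorted(have)} but positions {sorted(expected)} must each carry one token"
                )
            for p, tok in r.substituents.items():
                if p in amine_positions(r.sugar_type):
                    allowed = set(HEXNAC_AMINE) | {"NHAc", "Fmoc"}
                else:
                    allowed = set(HEX_SUBSTITUENTS) | {"Fmoc"}
                if tok not in allowed:
                    raise GlycanStructureError(
                        f"BBL {self.index} residue {r.id}: token {tok!r} at position {p} "
                        f"not in vocabulary {sorted(allowed)}"
                    )

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sugar_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(r.sugar_type for r in self.residues.residues))
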