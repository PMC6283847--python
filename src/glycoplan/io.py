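"""File formats: BBL libraries (CSV / nested JSON), feature tables, plans.

Library CSV is one row per residue, grouped by BBL index::

    index,name,rrv,rrv_source,leaving_group,residue_id,pid,sugar_type,
    anomeric,parent_link_position,substituents

with substituents encoded ``pos:token;pos:token`` (e.g. ``2:OLev;3:OBn``).
The JSON form nests the same residue records per BBL.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .glycan import BuildingBlock, GlycanTree, Residue

__all__ = [
    "load_library",
    "save_library",
    "load_table",
    "plan_to_dict",
    "fragment_plan_to_dict",
]

_CSV_COLUMNS = [
    "index", "name", "rrv", "rrv_source", "leaving_group",
    "residue_id", "pid", "sugar_type", "anomeric", "parent_link_position",
    "substituents",
]


def _subs_to_str(subs: dict[int, str]) -> str:
    return ";".join(f"{p}:{t}" for p, t in sorted(subs.items()))


def _subs_from_str(s: str) -> dict[int, str]:
    if not s or pd.isna(s):
        return {}
    out = {}
    for item in str(s).split(";"):
        p, t = item.split(":")
        out[int(p)] = t
    return out


def save_library(library: Iterable[BuildingBlock], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        doc = [
            {
                "index": b.index,
                "name": b.name,
                "rrv": b.rrv,
                "rrv_source": b.rrv_source,
                "leaving_group": b.leaving_group,
                "residues": [
                    {
                        "id": r.id,
                        "pid": r.pid,
                        "sugar_type": r.sugar_type,
                        "anomeric": r.anomeric_form,
                        "parent_link_position": r.parent_link_position,
                        "substituents": {str(p): t for p, t in sorted(r.substituents.items())},
                    }
                    for r in b.residues.residues
                ],
            }
            for b in library
        ]
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        return
    rows = []
    for b in library:
        for r in b.residues.residues:
            rows.append(
                {
                    "index": b.index, "name": b.name, "rrv": b.rrv,
                    "rrv_source": b.rrv_source, "leaving_group": b.leaving_group,
                    "residue_id": r.id, "pid": r.pid,
                    "sugar_type": r.sugar_type, "anomeric": r.anomeric_form,
                    "parent_link_position": r.parent_link_position,
                    "substituents": _subs_to_str(r.substituents),
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def load_library(path: str | Path) -> list[BuildingBlock]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"library file not found: {path}")
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        out = []
        for rec in doc:
            residues = [
                Residue(
                    id=int(r["id"]),
                    pid=None if r.get("pid") is None else int(r["pid"]),
                    sugar_type=r["sugar_type"],
                    anomeric_form=r["anomeric"],
                    parent_link_position=(
                        None if r.get("parent_link_position") is None
                        else int(r["parent_link_position"])
                    ),
                    substituents={int(p): t for p, t in (r.get("substituents") or {}).items()},
                )
                for r in rec["residues"]
            ]
            out.append(
                BuildingBlock(
                    index=rec["index"], name=rec.get("name", rec["index"]),
                    residues=GlycanTree(residues), rrv=float(rec["rrv"]),
                    rrv_source=rec.get("rrv_source", "measured"),
                    leaving_group=rec.get("leaving_group", "STol"),
                )
            )
        return out
    df = pd.read_csv(path)
    out = []
    for index, grp in df.groupby("index", sort=False):
        first = grp.iloc[0]
        residues = [
            Residue(
                id=int(row.residue_id),
                pid=None if pd.isna(row.pid) else int(row.pid),
                sugar_type=row.sugar_type,
                anomeric_form=row.anomeric,
                parent_link_position=(
                    None if pd.isna(row.parent_link_position)
                    else int(row.parent_link_position)
                ),
                substituents=_subs_from_str(row.substituents),
            )
            for row in grp.itertuples()
        ]
        out.append(
            BuildingBlock(
                index=str(index), name=str(first["name"]),
                residues=GlycanTree(residues), rrv=float(first.rrv),
                rrv_source=str(first.rrv_source),
                leaving_group=str(first.leaving_group),
            )
        )
    return out


def load_table(path: str | Path) -> pd.DataFrame:
    """Feature table CSV keyed by BBL index (first column)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    return pd.read_csv(path, index_col=0)


def plan_to_dict(plan) -> dict:
    return {
        "n_bbls": plan.n_bbls,
        "overall_yield": plan.overall_yield,
        "steps": [
            {
                "bbl_index": s.bbl.index,
                "bbl_name": s.bbl.name,
                "rrv": s.rrv,
                "state_residues": sorted(s.state_ids),
                "match_kind": s.match.kind,
                "deprotections": list(map(list, s.match.deprotections)),
            }
            for s in plan.steps
        ],
    }


def fragment_plan_to_dict(plan) -> dict:
    return {
        "n_fragments": plan.n_fragments,
        "connection_strategy": plan.connection_strategy,
        "assembly_order": list(plan.assembly_order),
        "signature": list(plan.signature()),
        "overall_yield": plan.overall_yield,
        "fragments": [
            {
                "n_bbls": f.n_bbls,
                "n_residues": f.n_residues,
                "effective_rrv": f.effective_rrv,
                "role_class": f.role_class,
                "fragment_yield": f.fragment_yield,
                "post_synthesis_deprotections": list(
                    map(list, f.post_synthesis_deprotections)
                ),
                "steps": [
                    {
                        "bbl_index": s.bbl.index,
                        "rrv": s.rrv,
                        "state_residues": sorted(s.state_ids),
                        "match_kind": s.match.kind,
                    }
                    for s in f.steps
                ],
            }
            for f in plan.fragments
        ],
    }
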