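"""Feature construction for the RRV regressor.

Three blocks, mirroring a QSPR setup for protected thioglycosides:

* **BP** - basic properties: sugar type (Gal/Glc/Man/GalNAc/GlcNAc), sugar
  class (Hex/HexNAc), anomeric state, and the protecting-group token at ring
  positions 2, 3, 4, 6; one-hot binarized, optionally with ordinal codes.
* **CS** - ring NMR chemical shifts: 13 slots (H1..H5, H6-1, H6-2, C1..C6) in
  ppm, ingested from a table (they come from an external shift predictor, not
  computed here); encoded as per-slot min-max normalized values, fixed-width
  bin indicators, or both.
* **MD** - a molecular-descriptor matrix (1D/2D), ingested as-is.

The regression target is ln(RRV): RRVs are roughly log-distributed over
1-72,000, and the log brings them close to normal.  Sialic-acid rows are
excluded from model datasets (their nine-carbon backbone is not comparable),
as are any sugar types outside the five-type vocabulary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .glycan import (
    HEX_SUBSTITUENTS,
    HEXNAC_AMINE,
    SUGAR_CLASS,
    BuildingBlock,
)

__all__ = [
    "MODEL_SUGAR_TYPES",
    "SHIFT_SLOTS",
    "SchemaError",
    "DataError",
    "FeatureConfig",
    "Dataset",
    "encode_basic",
    "ShiftEncoder",
    "encode_shifts",
    "assemble_dataset",
    "basic_props_of_bbl",
]

MODEL_SUGAR_TYPES: tuple[str, ...] = ("Gal", "Glc", "Man", "GalNAc", "GlcNAc")
MODEL_SUGAR_CLASSES: tuple[str, ...] = ("Hex", "HexNAc")
ANOMERIC_STATES: tuple[str, ...] = ("a", "b")
#: ring shift slots, proton then carbon, in ppm.
SHIFT_SLOTS: tuple[str, ...] = (
    "H1", "H2", "H3", "H4", "H5", "H6-1", "H6-2",
    "C1", "C2", "C3", "C4", "C5", "C6",
)
_PG_POSITIONS = (2, 3, 4, 6)
_PG2_VOCAB = tuple(HEX_SUBSTITUENTS) + tuple(HEXNAC_AMINE)


class SchemaError(ValueError):
    """A categorical token or feature name outside the schema."""


class DataError(ValueError):
    """Non-finite or otherwise unusable feature data."""


@dataclass(frozen=True)
class FeatureConfig:
    """Which blocks to build and how to encode them."""

    blocks: tuple[str, ...] = ("BP", "CS", "MD")
    bp_binarize: bool = True
    bp_ordinal: bool = False
    cs_mode: str = "both"  # normalized | binarized | both
    h_bin_width: float = 0.2  # ppm, proton slots
    c_bin_width: float = 2.0  # ppm, carbon slots

    def __post_init__(self) -> None:
        bad = set(self.blocks) - {"BP", "CS", "MD"}
        if bad:
            raise SchemaError(f"unknown feature blocks {sorted(bad)}")
        if self.cs_mode not in ("normalized", "binarized", "both"):
            raise SchemaError("cs_mode must be normalized|binarized|both")


def encode_basic(
    props: Mapping[str, str],
    binarize: bool = True,
    ordinal: bool = False,
) -> dict[str, float]:
    """One-hot (and optionally ordinal) encoding of the basic properties.

    ``props`` needs sugar_type, anomeric, and pg_2..pg_6 tokens (pg_2 holds
    the amine token for HexNAc).  sugar_class is derived.
    """
    out: dict[str, float] = {}

    def onehot(prefix: str, value: str, vocab: Sequence[str]) -> None:
        if value not in vocab:
            raise SchemaError(
                f"{prefix}: token {value!r} not in allowed {list(vocab)}"
            )
        if binarize:
            for v in vocab:
                out[f"{prefix}_{v}"] = float(v == value)
        if ordinal:
            denom = max(len(vocab) - 1, 1)
            out[f"{prefix}_ord"] = vocab.index(value) / denom

    sugar = props["sugar_type"]
    onehot("sugar_type", sugar, MODEL_SUGAR_TYPES)
    onehot("sugar_class", SUGAR_CLASS[sugar], MODEL_SUGAR_CLASSES)
    anom = {"alpha": "a", "beta": "b"}.get(props["anomeric"], props["anomeric"])
    onehot("anomeric", anom, ANOMERIC_STATES)
    for p in _PG_POSITIONS:
        vocab = _PG2_VOCAB if p == 2 else tuple(HEX_SUBSTITUENTS)
        onehot(f"pg{p}", props[f"pg_{p}"], vocab)
    return out


class ShiftEncoder:
    """Per-slot min-max normalization and fixed-width binarization of the 13
    ring chemical shifts, fitted on training data only.

    Conventions for degenerate inputs: a slot constant over the training set
    normalizes to 0 for every row and binarizes to a single always-on bin;
    missing values (NaN, e.g. H6-2 of a 6-deoxy sugar) are imputed with the
    slot's training mean and flagged with an indicator feature; out-of-range
    values at transform time are clipped into the training range.
    """

    def __init__(self, h_bin_width: float = 0.2, c_bin_width: float = 2.0):
        self.h_bin_width = h_bin_width
        self.c_bin_width = c_bin_width
        self._stats: dict[str, tuple[float, float, float]] | None = None
        self.clip_events = 0

    def fit(self, table: pd.DataFrame) -> "ShiftEncoder":
        missing = [s for s in SHIFT_SLOTS if s not in table.columns]
        if missing:
            raise DataError(f"shift table lacks slots {missing}")
        vals = table[list(SHIFT_SLOTS)].astype(float)
        if np.isinf(vals.to_numpy()).any():
            raise DataError("non-finite chemical shift in training table")
        self._stats = {}
        for s in SHIFT_SLOTS:
            col = vals[s].dropna()
            if col.empty:
                raise DataError(f"shift slot {s} has no finite training values")
            self._stats[s] = (float(col.min()), float(col.max()), float(col.mean()))
        return self

    def _width(self, slot: str) -> float:
        return self.h_bin_width if slot.startswith("H") else self.c_bin_width

    def transform(self, table: pd.DataFrame, mode: str = "both") -> pd.DataFrame:
        if self._stats is None:
            raise DataError("ShiftEncoder must be fitted before transform")
        if mode not in ("normalized", "binarized", "both"):
            raise SchemaError("mode must be normalized|binarized|both")
        cols: dict[str, np.ndarray] = {}
        n = len(table)
        for s in SHIFT_SLOTS:
            lo, hi, mean = self._stats[s]
            raw = table[s].astype(float).to_numpy()
            if np.isinf(raw).any():
                raise DataError(f"non-finite value in shift slot {s}")
            miss = np.isnan(raw)
            raw = np.where(miss, mean, raw)
            clipped = np.clip(raw, lo, hi)
            self.clip_events += int((clipped != raw).sum())
            if mode in ("normalized", "both"):
                span = hi - lo
                cols[f"cs_{s}_norm"] = (
                    (clipped - lo) / span if span > 0 else np.zeros(n)
                )
            if mode in ("binarized", "both"):
                width = self._width(s)
                n_bins = max(1, math.ceil((hi - lo) / width)) if hi > lo else 1
                idx = np.minimum(
                    ((clipped - lo) / width).astype(int) if hi > lo else np.zeros(n, int),
                    n_bins - 1,
                )
                for b in range(n_bins):
                    cols[f"cs_{s}_bin{b}"] = (idx == b).astype(float)
            cols[f"cs_{s}_missing"] = miss.astype(float)
        out = pd.DataFrame(cols, index=table.index)
        # drop all-zero missing indicators for slots never missing in training
        drop = [
            f"cs_{s}_missing" for s in SHIFT_SLOTS
            if not out[f"cs_{s}_missing"].any()
        ]
        return out.drop(columns=drop)


def encode_shifts(
    train_table: pd.DataFrame,
    mode: str = "both",
    table: pd.DataFrame | None = None,
    h_bin_width: float = 0.2,
    c_bin_width: float = 2.0,
) -> pd.DataFrame:
    """Fit a :class:`ShiftEncoder` on ``train_table`` and transform ``table``
    (default: the training table itself)."""
    enc = ShiftEncoder(h_bin_width, c_bin_width).fit(train_table)
    return enc.transform(table if table is not None else train_table, mode)


@dataclass
class Dataset:
    """Feature matrix plus RRV targets on both scales."""

    X: pd.DataFrame
    rrv: pd.Series
    ln_rrv: pd.Series
    feature_blocks: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.rrv <= 0).any():
            bad = list(self.rrv.index[self.rrv <= 0])
            raise DataError(f"rrv must be > 0 for all training rows; offending {bad}")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def basic_props_of_bbl(bbl: BuildingBlock) -> dict[str, str]:
    """Basic-property record of a monosaccharide BBL."""
    if bbl.n_residues != 1:
        raise SchemaError(
            f"BBL {bbl.index}: basic properties are defined for monosaccharide BBLs"
        )
    r = bbl.residues.root
    props = {"sugar_type": r.sugar_type, "anomeric": r.anomeric_form}
    for p in _PG_POSITIONS:
        props[f"pg_{p}"] = r.substituents.get(p, "OH")
    return props


def assemble_dataset(
    library: Iterable[BuildingBlock],
    shift_table: pd.DataFrame | None = None,
    descriptor_table: pd.DataFrame | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> Dataset:
    """Join the configured feature blocks into one model-ready dataset.

    Tables are keyed by BBL index.  Rows outside the model vocabulary
    (sialic acid, fucose, multi-residue BBLs) are dropped; a missing key in a
    required table is an error listing the absent indices.
    """
    rows = [
        b for b in library
        if b.n_residues == 1 and b.residues.root.sugar_type in MODEL_SUGAR_TYPES
    ]
    if not rows:
        raise DataError("no model-eligible BBLs in the library")
    index = [b.index for b in rows]
    rrv = pd.Series([b.rrv for b in rows], index=index, name="rrv", dtype=float)
    if (rrv <= 0).any():
        raise DataError(
            f"rrv must be > 0 to take logs; offending {list(rrv.index[rrv <= 0])}"
        )

    blocks: dict[str, pd.DataFrame] = {}
    if "BP" in config.blocks:
        bp = pd.DataFrame(
            [encode_basic(basic_props_of_bbl(b), config.bp_binarize, config.bp_ordinal)
             for b in rows],
            index=index,
        ).fillna(0.0)
        blocks["BP"] = bp
    if "CS" in config.blocks:
        if shift_table is None:
            raise DataError("CS block requested but no shift table supplied")
        absent = [i for i in index if i not in shift_table.index]
        if absent:
            raise DataError(f"shift table missing BBL indices {absent}")
        sub = shift_table.loc[index]
        blocks["CS"] = encode_shifts(
            sub, config.cs_mode,
            h_bin_width=config.h_bin_width, c_bin_width=config.c_bin_width,
        )
    if "MD" in config.blocks:
        if descriptor_table is None:
            raise DataError("MD block requested but no descriptor table supplied")
        absent = [i for i in index if i not in descriptor_table.index]
        if absent:
            raise DataError(f"descriptor table missing BBL indices {absent}")
        md = descriptor_table.loc[index].astype(float)
        if not np.isfinite(md.to_numpy()).all():
            raise DataError("non-finite molecular descriptor value")
        blocks["MD"] = md.add_prefix("md_")

    X = pd.concat(blocks.values(), axis=1)
    return Dataset(
        X=X,
        rrv=rrv,
        ln_rrv=pd.Series(np.log(rrv.to_numpy()), index=index, name="ln_rrv"),
        feature_blocks={k: list(v.columns) for k, v in blocks.items()},
    )
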