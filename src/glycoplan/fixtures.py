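"""Synthetic fixtures: worked planning scenarios and RRV datasets with known
ground truth.

The planning scenarios rebuild, with constructed protecting-group layouts,
the four published one-pot syntheses whose RRV orderings are pinned in the
literature: Globo-H ([1+3+2] with a fucose donor of RRV 72,000 and an
internal one-pot fragment of RRVs 4000/850/13), SSEA-4 ([2+1+3] led by a
sialyl disaccharide of RRV 1462), a heparin-backbone pentasaccharide
([1+2+2], RRVs 132/18.2/0; the uronic-acid sugars are represented by
Glc/GlcNAc stand-ins), and a LacNAc trisaccharide one-pot (263/51/0).

The RRV dataset generator draws protected-monosaccharide feature rows and
sets ln(RRV) as a known linear function of the encoded features plus
Gaussian noise, so regression tests can check recovery against the truth.
Defaults mirror the real training library: 117 Hex/HexNAc rows with RRVs
spanning 1-72,000, log-scale distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import (
    SHIFT_SLOTS,
    Dataset,
    FeatureConfig,
    assemble_dataset,
)
from .glycan import (
    HEX_SUBSTITUENTS,
    HEXNAC_AMINE,
    BuildingBlock,
    GlycanTree,
    Residue,
    parse_glycan,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticRRVData",
    "generate_rrv_dataset",
    "generate_linear_dataset",
    "ScenarioFixture",
    "SCENARIO_NAMES",
    "fixture_scenario",
]


# ---------------------------------------------------------------------------
# RRV dataset generator
# ---------------------------------------------------------------------------

#: additive ln(RRV) effect of each protecting-group token, reflecting the
#: usual arming/disarming trends (ethers arm, esters disarm).
_PG_EFFECTS: dict[str, float] = {
    "OH": 0.5, "OAc": -0.7, "OBn": 0.9, "OBz": -1.0, "OClAc": -1.2,
    "OLev": -0.8, "NO2Bz": -1.4, "OPMB": 1.1, "OTBDPS": 0.4, "OTBS": 0.4,
    "OTIPS": 0.3, "NHTroc": -0.9, "NPhth": -1.1, "N3": 0.2,
}
_SUGAR_EFFECTS: dict[str, float] = {
    "Gal": 0.6, "Glc": 0.0, "Man": 0.3, "GalNAc": -0.4, "GlcNAc": -0.6,
}
_ANOMERIC_EFFECTS: dict[str, float] = {"a": 0.2, "b": 0.0}

#: typical ring-shift windows (ppm) used to draw plausible values.
_SHIFT_WINDOWS: dict[str, tuple[float, float]] = {
    **{s: (3.2, 5.6) for s in ("H2", "H3", "H4", "H5", "H6-1", "H6-2")},
    "H1": (4.3, 5.9),
    "C1": (82.0, 102.0),
    **{s: (64.0, 80.0) for s in ("C2", "C3", "C4", "C5")},
    "C6": (60.0, 70.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic RRV dataset."""

    n_bbls: int = 117
    seed: int = 0
    noise_sigma: float = 0.3  # ln scale
    rrv_range: tuple[float, float] = (1.0, 72_000.0)
    intercept: float = 5.0
    shift_weight: float = 0.6  # weight scale on normalized shift features
    n_descriptors: int = 8
    n_informative_descriptors: int = 3
    descriptor_weight: float = 0.8
    sugar_mixture: tuple[tuple[str, float], ...] = (
        ("Gal", 0.30), ("Glc", 0.25), ("Man", 0.15),
        ("GalNAc", 0.15), ("GlcNAc", 0.15),
    )

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.n_bbls < 2:
            raise ValueError("need at least 2 BBLs")


@dataclass
class SyntheticRRVData:
    """Generated library + tables + assembled dataset + generating truth."""

    library: list[BuildingBlock]
    shift_table: pd.DataFrame
    descriptor_table: pd.DataFrame
    dataset: Dataset
    truth: dict


def generate_rrv_dataset(
    config: GeneratorConfig = GeneratorConfig(),
    feature_config: FeatureConfig | None = None,
) -> SyntheticRRVData:
    """Draw a synthetic protected-monosaccharide library with known ln-linear
    RRV truth: ln(RRV) = intercept + sugar/anomeric/PG effects + shift and
    descriptor terms + Normal(0, sigma) noise, clipped into the RRV range.
    """
    rng = np.random.default_rng(config.seed)
    if feature_config is None:
        feature_config = FeatureConfig(cs_mode="normalized")

    sugars, probs = zip(*config.sugar_mixture)
    probs = np.asarray(probs) / np.sum(probs)
    o_tokens = [t for t in HEX_SUBSTITUENTS]

    lib: list[BuildingBlock] = []
    shift_rows: list[dict] = []
    desc_rows: list[dict] = []
    props_rows: list[dict] = []
    for i in range(config.n_bbls):
        sugar = str(rng.choice(sugars, p=probs))
        anom = "b" if rng.random() < 0.6 else "a"
        subs: dict[int, str] = {}
        if sugar in ("GalNAc", "GlcNAc"):
            subs[2] = str(rng.choice(HEXNAC_AMINE))
        else:
            subs[2] = str(rng.choice(o_tokens))
        for p in (3, 4, 6):
            subs[p] = str(rng.choice(o_tokens))
        shifts = {
            s: float(rng.uniform(*_SHIFT_WINDOWS[s])) for s in SHIFT_SLOTS
        }
        descs = {
            f"D{j}": float(rng.normal()) for j in range(config.n_descriptors)
        }
        idx = f"S{i:03d}"
        props_rows.append({"index": idx, "sugar": sugar, "anomeric": anom, **subs})
        shift_rows.append({"index": idx, **shifts})
        desc_rows.append({"index": idx, **descs})
        tree = GlycanTree(
            [Residue(id=1, sugar_type=sugar, anomeric_form=anom, substituents=subs)]
        )
        lib.append(
            BuildingBlock(index=idx, name=f"synthetic-{sugar}-{i}", residues=tree,
                          rrv=1.0)  # placeholder; set below
        )

    shift_table = pd.DataFrame(shift_rows).set_index("index")
    descriptor_table = pd.DataFrame(desc_rows).set_index("index")

    # truth on the scale of the *encoded* features: per-slot min-max
    # normalized shifts and raw descriptors, so the target stays exactly
    # linear in what the model sees.
    shift_w = {
        s: config.shift_weight * w
        for s, w in zip(
            SHIFT_SLOTS, rng.uniform(-1.0, 1.0, size=len(SHIFT_SLOTS))
        )
    }
    desc_w = {
        f"D{j}": (config.descriptor_weight * w
                  if j < config.n_informative_descriptors else 0.0)
        for j, w in zip(
            range(config.n_descriptors),
            rng.uniform(-1.0, 1.0, size=config.n_descriptors),
        )
    }
    lo, hi = shift_table.min(), shift_table.max()
    span = (hi - lo).replace(0.0, 1.0)
    norm_shifts = (shift_table - lo) / span

    ln_lo, ln_hi = np.log(config.rrv_range[0]), np.log(config.rrv_range[1])
    clip_events = 0
    rrvs = []
    for row, (idx, srow), (_, drow) in zip(
        props_rows, norm_shifts.iterrows(), descriptor_table.iterrows()
    ):
        ln = config.intercept
        ln += _SUGAR_EFFECTS[row["sugar"]]
        ln += _ANOMERIC_EFFECTS[row["anomeric"]]
        for p in (2, 3, 4, 6):
            ln += _PG_EFFECTS[row[p]]
        ln += sum(shift_w[s] * srow[s] for s in SHIFT_SLOTS)
        ln += sum(desc_w[d] * drow[d] for d in desc_w)
        ln += rng.normal(0.0, config.noise_sigma) if config.noise_sigma > 0 else 0.0
        if ln < ln_lo or ln > ln_hi:
            clip_events += 1
            ln = min(max(ln, ln_lo), ln_hi)
        rrvs.append(float(np.exp(ln)))

    for b, r in zip(lib, rrvs):
        b.rrv = r

    dataset = assemble_dataset(lib, shift_table, descriptor_table, feature_config)
    truth = {
        "intercept": config.intercept,
        "pg_effects": dict(_PG_EFFECTS),
        "sugar_effects": dict(_SUGAR_EFFECTS),
        "anomeric_effects": dict(_ANOMERIC_EFFECTS),
        "shift_weights": shift_w,
        "descriptor_weights": desc_w,
        "noise_sigma": config.noise_sigma,
        "seed": config.seed,
        "clip_events": clip_events,
    }
    return SyntheticRRVData(lib, shift_table, descriptor_table, dataset, truth)


def generate_linear_dataset(
    n: int = 60,
    n_informative: int = 5,
    n_noise: int = 10,
    sigma: float = 0.0,
    seed: int = 0,
    duplicate_features: int = 0,
) -> tuple[Dataset, dict]:
    """Plain numeric dataset with ln(RRV) linear in the first features.

    Used for feature-selection properties: informative columns ``f00..``
    carry nonzero weights, ``noise00..`` columns carry none; optionally the
    first ``duplicate_features`` informative columns are duplicated under
    ``dup00..`` names.
    """
    rng = np.random.default_rng(seed)
    Xi = rng.uniform(0.0, 1.0, size=(n, n_informative))
    Xn = rng.uniform(0.0, 1.0, size=(n, n_noise))
    w = rng.uniform(1.0, 2.5, size=n_informative) * rng.choice([-1, 1], n_informative)
    ln = 4.0 + Xi @ w + (rng.normal(0, sigma, n) if sigma > 0 else 0.0)
    cols = {f"f{j:02d}": Xi[:, j] for j in range(n_informative)}
    cols.update({f"noise{j:02d}": Xn[:, j] for j in range(n_noise)})
    for j in range(duplicate_features):
        cols[f"dup{j:02d}"] = Xi[:, j]
    idx = [f"R{i:03d}" for i in range(n)]
    X = pd.DataFrame(cols, index=idx)
    rrv = pd.Series(np.exp(ln), index=idx, name="rrv")
    ds = Dataset(X=X, rrv=rrv, ln_rrv=pd.Series(ln, index=idx, name="ln_rrv"))
    truth = {
        "weights": {f"f{j:02d}": float(w[j]) for j in range(n_informative)},
        "informative": [f"f{j:02d}" for j in range(n_informative)],
        "noise": [f"noise{j:02d}" for j in range(n_noise)],
        "sigma": sigma,
        "seed": seed,
    }
    return ds, truth


# ---------------------------------------------------------------------------
# Planning scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioFixture:
    name: str
    tree: GlycanTree
    library: tuple[BuildingBlock, ...]
    expected_rrv_order: tuple[float, ...]  # addition order, most reactive first
    expected_signature: tuple[int, ...]  # residue counts of top-level units
    mode: str  # "onepot" | "fragments"


def _mono(index: str, sugar: str, anom: str, subs: dict[int, str],
          rrv: float, name: str | None = None) -> BuildingBlock:
    tree = GlycanTree(
        [Residue(id=1, sugar_type=sugar, anomeric_form=anom, substituents=subs)]
    )
    return BuildingBlock(index=index, name=name or index, residues=tree, rrv=rrv)


def _multi(index: str, residues: list[Residue], rrv: float,
           name: str | None = None) -> BuildingBlock:
    return BuildingBlock(index=index, name=name or index,
                         residues=GlycanTree(residues), rrv=rrv)


def _lacnac() -> ScenarioFixture:
    # trisaccharide one-pot: donor 263 -> acceptor 51 -> reducing acceptor 0
    tree = parse_glycan("Gal(b1-4)GlcNAc(b1-3)Gal")
    lib = (
        _mono("B9", "Gal", "b",
              {2: "OBz", 3: "OBn", 4: "OBn", 6: "OBn"}, 263.0, "donor-9"),
        _mono("B10", "GlcNAc", "b",
              {2: "NHTroc", 3: "OBn", 4: "OH", 6: "OBn"}, 51.0, "acceptor-10"),
        _mono("B11", "Gal", "b",
              {2: "OBz", 3: "OH", 4: "OBn", 6: "OBn"}, 0.0, "acceptor-11"),
    )
    return ScenarioFixture("lacnac_3", tree, lib, (263.0, 51.0, 0.0),
                           (1, 1, 1), "onepot")


def _heparin() -> ScenarioFixture:
    # pentasaccharide, [1 + 2 + 2]: mono 132 -> di 18.2 -> reducing di 0.
    # GlcN/uronic-acid units are represented by GlcNAc/Glc stand-ins.
    tree = parse_glycan("GlcNAc(a1-4)Glc(b1-4)GlcNAc(a1-4)Glc(b1-4)GlcNAc")
    b5 = _mono("B5", "GlcNAc", "a",
               {2: "N3", 3: "OBn", 4: "OAc", 6: "OBn"}, 132.0, "donor-5")
    b6 = _multi("B6", [
        Residue(id=1, sugar_type="GlcNAc", anomeric_form="a",
                substituents={2: "N3", 3: "OBn", 6: "OBn"}),
        Residue(id=2, pid=1, parent_link_position=4, sugar_type="Glc",
                anomeric_form="b",
                substituents={2: "OBz", 3: "OBn", 4: "OH", 6: "OBn"}),
    ], 18.2, "donor-6")
    b7 = _multi("B7", [
        Residue(id=1, sugar_type="GlcNAc", anomeric_form="b",
                substituents={2: "N3", 3: "OBn", 6: "OBn"}),
        Residue(id=2, pid=1, parent_link_position=4, sugar_type="Glc",
                anomeric_form="b",
                substituents={2: "OBz", 3: "OBn", 4: "OH", 6: "OBn"}),
    ], 0.0, "acceptor-7")
    return ScenarioFixture("heparin_122", tree, (b5, b6, b7),
                           (132.0, 18.2, 0.0), (1, 2, 2), "fragments")


def _ssea4() -> ScenarioFixture:
    # hexasaccharide, [2 + 1 + 3]: sialyl disaccharide 1462 -> mono 32 -> tri 0
    tree = parse_glycan(
        "Neu5Ac(a2-3)Gal(b1-3)GalNAc(b1-3)Gal(a1-4)Gal(b1-4)Glc"
    )
    b1 = _multi("B1", [
        Residue(id=1, sugar_type="Gal", anomeric_form="b",
                substituents={2: "OBz", 4: "OBn", 6: "OBn"}),
        Residue(id=2, pid=1, parent_link_position=3, sugar_type="Neu5Ac",
                anomeric_form="a",
                substituents={4: "OAc", 7: "OAc", 8: "OAc", 9: "OAc"}),
    ], 1462.0, "sialyl-disaccharide-1")
    b2 = _mono("B2", "GalNAc", "b",
               {2: "NHTroc", 3: "OH", 4: "OBz", 6: "OBn"}, 32.0, "donor-2")
    b3 = _multi("B3", [
        Residue(id=1, sugar_type="Glc", anomeric_form="b",
                substituents={2: "OBz", 3: "OBn", 6: "OBn"}),
        Residue(id=2, pid=1, parent_link_position=4, sugar_type="Gal",
                anomeric_form="b",
                substituents={2: "OBz", 3: "OBn", 6: "OBn"}),
        Residue(id=3, pid=2, parent_link_position=4, sugar_type="Gal",
                anomeric_form="a",
                substituents={2: "OBz", 3: "OH", 4: "OBn", 6: "OBn"}),
    ], 0.0, "acceptor-3")
    return ScenarioFixture("ssea4_213", tree, (b1, b2, b3),
                           (1462.0, 32.0, 0.0), (2, 1, 3), "fragments")


def _globoh() -> ScenarioFixture:
    # hexasaccharide, [1 + 3 + 2]: fucose fragment (72,000), an internal
    # one-pot trisaccharide fragment (4000 -> 850 -> 13) whose fucosylation
    # site is masked by Lev, and a reducing-end disaccharide acceptor whose
    # own acceptor site is masked by ClAc until fragment assembly.
    tree = parse_glycan(
        "Fuc(a1-2)Gal(b1-3)GalNAc(b1-3)Gal(a1-4)Gal(b1-4)Glc"
    )
    f1 = _mono("F1", "Fuc", "a", {2: "OBn", 3: "OBn", 4: "OBn"},
               72_000.0, "fucose-donor")
    g2 = _mono("G2", "Gal", "b",
               {2: "OLev", 3: "OBn", 4: "OBn", 6: "OBn"}, 4000.0, "gal-4000")
    g3 = _mono("G3", "GalNAc", "b",
               {2: "NHTroc", 3: "OH", 4: "OBn", 6: "OBn"}, 850.0, "galnac-850")
    g4 = _mono("G4", "Gal", "a",
               {2: "OBz", 3: "OH", 4: "OBn", 6: "OBn"}, 13.0, "gal-13")
    d5 = _multi("D5", [
        Residue(id=1, sugar_type="Glc", anomeric_form="b",
                substituents={2: "OBz", 3: "OBn", 6: "OBn"}),
        Residue(id=2, pid=1, parent_link_position=4, sugar_type="Gal",
                anomeric_form="b",
                substituents={2: "OBz", 3: "OBn", 4: "OClAc", 6: "OBn"}),
    ], 0.0, "lactoside-acceptor")
    return ScenarioFixture("globoH_132", tree, (f1, g2, g3, g4, d5),
                           (72_000.0, 13.0, 0.0), (1, 3, 2), "fragments")


_SCENARIOS = {
    "lacnac_3": _lacnac,
    "heparin_122": _heparin,
    "ssea4_213": _ssea4,
    "globoH_132": _globoh,
}
SCENARIO_NAMES: tuple[str, ...] = tuple(sorted(_SCENARIOS))


def fixture_scenario(name: str) -> ScenarioFixture:
    """A named worked scenario; unknown names raise with the available set."""
    try:
        return _SCENARIOS[name]()
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {list(SCENARIO_NAMES)}"
        ) from None
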