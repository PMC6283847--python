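"""Virtual building-block enumeration and fingerprint similarity screening.

Virtual BBLs are generated combinatorially: every hexose (Gal, Glc, Man)
with one of 11 substituent tokens at each of R2, R3, R4, R6 (3 x 11^4 =
43,923 structures), and every HexNAc (GalNAc, GlcNAc) with one of 3 amine
groups at R2 and 11 tokens at each of R3, R4, R6 (2 x 3 x 11^3 = 7,986
structures).  All carry a thio-tolyl leaving group.  Each structure can be
materialized as SMILES from a per-sugar template and screened against the
experimentally validated library by Tanimoto similarity of linear-path
fingerprints (an FP2-like scheme; the backend is pluggable and recorded,
since coverage fractions depend on the fingerprint).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .glycan import HEX_SUBSTITUENTS, HEXNAC_AMINE

__all__ = [
    "VirtualBBL",
    "HEX_SUGARS",
    "HEXNAC_SUGARS",
    "enumerate_hex",
    "enumerate_hexnac",
    "virtual_to_smiles",
    "fingerprint",
    "tanimoto",
    "tanimoto_screen",
]

HEX_SUGARS: tuple[str, ...] = ("Gal", "Glc", "Man")
HEXNAC_SUGARS: tuple[str, ...] = ("GalNAc", "GlcNAc")


@dataclass(frozen=True)
class VirtualBBL:
    """An enumerated, not-yet-synthesized protecting-group combination."""

    sugar_type: str
    substituents: tuple[tuple[int, str], ...]  # ((position, token), ...)
    amine_pg: str | None = None  # HexNAc only
    predicted_rrv: float | None = None
    similarity: float | None = None

    @property
    def key(self) -> str:
        parts = [self.sugar_type]
        if self.amine_pg is not None:
            parts.append(f"2:{self.amine_pg}")
        parts.extend(f"{p}:{t}" for p, t in self.substituents)
        return "|".join(parts)


def enumerate_hex(
    vocab: Sequence[str] = HEX_SUBSTITUENTS,
    sugar_types: Sequence[str] = HEX_SUGARS,
) -> list[VirtualBBL]:
    """All hexose virtual BBLs: |sugar_types| x |vocab|^4, deterministic order."""
    out = []
    for sugar in sugar_types:
        for r2, r3, r4, r6 in itertools.product(vocab, repeat=4):
            out.append(
                VirtualBBL(sugar, ((2, r2), (3, r3), (4, r4), (6, r6)))
            )
    return out


def enumerate_hexnac(
    vocab: Sequence[str] = HEX_SUBSTITUENTS,
    amine_vocab: Sequence[str] = HEXNAC_AMINE,
    sugar_types: Sequence[str] = HEXNAC_SUGARS,
) -> list[VirtualBBL]:
    """All HexNAc virtual BBLs: |sugar_types| x |amine| x |vocab|^3."""
    out = []
    for sugar in sugar_types:
        for amine in amine_vocab:
            for r3, r4, r6 in itertools.product(vocab, repeat=3):
                out.append(
                    VirtualBBL(sugar, ((3, r3), (4, r4), (6, r6)), amine_pg=amine)
                )
    return out


# ---------------------------------------------------------------------------
# SMILES materialization
# ---------------------------------------------------------------------------

#: attachment SMILES per substituent token (written from the ring carbon).
#: Ring-closure digits 5+ avoid clashes with the pyranose/tolyl rings.
_TOKEN_SMILES: dict[str, str] = {
    "OH": "O",
    "OAc": "OC(C)=O",
    "OBn": "OCc5ccccc5",
    "OBz": "OC(=O)c5ccccc5",
    "OClAc": "OC(=O)CCl",
    "OLev": "OC(=O)CCC(C)=O",
    "NO2Bz": "OC(=O)c5ccc(cc5)[N+](=O)[O-]",
    "OPMB": "OCc5ccc(OC)cc5",
    "OTBDPS": "O[Si](c5ccccc5)(c6ccccc6)C(C)(C)C",
    "OTBS": "O[Si](C)(C)C(C)(C)C",
    "OTIPS": "O[Si](C(C)C)(C(C)C)C(C)C",
    "Fmoc": "OC(=O)OCC5c6ccccc6-c6ccccc56",
    "NHTroc": "NC(=O)OCC(Cl)(Cl)Cl",
    "NPhth": "N5C(=O)c6ccccc6C5=O",
    "N3": "N=[N+]=[N-]",
    "NHAc": "NC(C)=O",
}

#: beta-thiotolyl pyranoside templates; ring written C1(S-tolyl)-O5-C5-C4-C3-C2.
#: Stereocenters distinguish the gal/glc/man (and their 2-amino) series.
_SUGAR_TEMPLATES: dict[str, str] = {
    "Gal": "Cc1ccc(cc1)S[C@@H]2O[C@H](C{R6})[C@H]({R4})[C@@H]({R3})[C@H]2{R2}",
    "Glc": "Cc1ccc(cc1)S[C@@H]2O[C@H](C{R6})[C@@H]({R4})[C@@H]({R3})[C@H]2{R2}",
    "Man": "Cc1ccc(cc1)S[C@@H]2O[C@H](C{R6})[C@@H]({R4})[C@@H]({R3})[C@@H]2{R2}",
    "GalNAc": "Cc1ccc(cc1)S[C@@H]2O[C@H](C{R6})[C@H]({R4})[C@@H]({R3})[C@H]2{R2}",
    "GlcNAc": "Cc1ccc(cc1)S[C@@H]2O[C@H](C{R6})[C@@H]({R4})[C@@H]({R3})[C@H]2{R2}",
}


def virtual_to_smiles(vbbl: VirtualBBL) -> str:
    """SMILES of a virtual BBL from its sugar template and substituents."""
    subs = dict(vbbl.substituents)
    r2 = vbbl.amine_pg if vbbl.amine_pg is not None else subs[2]
    try:
        frags = {
            "R2": _TOKEN_SMILES[r2],
            "R3": _TOKEN_SMILES[subs[3]],
            "R4": _TOKEN_SMILES[subs[4]],
            "R6": _TOKEN_SMILES[subs[6]],
        }
    except KeyError as exc:
        raise KeyError(f"no SMILES fragment for token {exc}") from exc
    return _SUGAR_TEMPLATES[vbbl.sugar_type].format(**frags)


# ---------------------------------------------------------------------------
# Fingerprints and Tanimoto screening
# ---------------------------------------------------------------------------

def fingerprint(smiles: str, backend: str = "rdkit-path"):
    """Linear-path (FP2-like) bit fingerprint of a SMILES string."""
    if backend != "rdkit-path":
        raise ValueError(f"unknown fingerprint backend {backend!r}")
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.RDKFingerprint(mol)


def tanimoto(fp_a, fp_b) -> float:
    from rdkit import DataStructs

    return float(DataStructs.TanimotoSimilarity(fp_a, fp_b))


def tanimoto_screen(
    virtual_smiles: Sequence[str],
    training_smiles: Sequence[str],
    thresholds: Sequence[float] = (0.75, 0.80, 0.85),
    backend: str = "rdkit-path",
) -> dict:
    """Max-similarity screen of virtual structures against the training set.

    Returns per-threshold coverage (fraction of virtual BBLs with max
    Tanimoto >= t), the per-structure max similarities, and the backend name.
    """
    if not training_smiles:
        raise ValueError("training set must not be empty")
    train_fps = [fingerprint(s, backend) for s in training_smiles]
    max_sims = []
    for s in virtual_smiles:
        fp = fingerprint(s, backend)
        max_sims.append(max(tanimoto(fp, t) for t in train_fps))
    coverage = {
        float(t): sum(m >= t for m in max_sims) / len(max_sims) if max_sims else 0.0
        for t in thresholds
    }
    return {"coverage": coverage, "max_similarity": max_sims, "backend": backend}


def attach_predicted_rrvs(
    vbbls: Iterable[VirtualBBL],
    predict_fn: Callable[[Sequence[VirtualBBL]], Sequence[float]],
) -> list[VirtualBBL]:
    """Return copies with predicted RRVs supplied by a model callback."""
    vbbls = list(vbbls)
    preds = list(predict_fn(vbbls))
    if len(preds) != len(vbbls):
        raise ValueError("predict_fn returned a mismatched number of values")
    return [
        VirtualBBL(v.sugar_type, v.substituents, v.amine_pg, float(p), v.similarity)
        for v, p in zip(vbbls, preds)
    ]
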