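# Methods

## The planning model

A glycan is a rooted tree whose root is the reducing end; an edge
`child —(anomeric, donor position → parent position)→ parent` is a glycosidic
bond pointing toward the reducing end. Hexoses donate from C1, sialic acid
from C2; acceptor positions are restricted to {2, 3, 4, 6}. Tracked
substituent positions per residue are {2,3,4,6} for hexoses, {2,3,4} for
fucose (6-deoxy), the 2-amine plus {3,4,6} for HexNAc, and {4,7,8,9} for
sialic acid.

A *state* is a connected group of query residues the size of a candidate
BBL. Matching compares sugar types, anomeric configurations, and internal
linkages residue-by-residue, then checks protection:

- every attachment position (where the query hangs sub-structure below the
  state) must carry a free OH (*perfect*) or a selectively removable
  protecting group that occurs **exactly once** among the BBL's attachment
  positions (*precursor* — unambiguous deprotection);
- every other tracked position must be protected (a stray free hydroxyl
  would compete in the pot);
- amine positions never accept a glycosidic bond;
- sialic acid only matches as the terminal unit of a multi-residue BBL
  (it is too unreactive and hindered to serve as a first donor; the
  disaccharide's RRV is set by its reducing-end sugar).

The default selectively-removable set is {OLev, OClAc, OPMB, NO2Bz, OTBDPS,
OTBS, OTIPS, Fmoc} and is user-extensible; no closed list exists, so this is
a configuration, not a claim.

**One-pot search (no fragments).** Plans tile the tree with perfectly
matched BBLs such that (i) the reducing-end state has RRV 0, (ii) RRV
strictly increases from each state to its children (so a strictly descending
global addition order exists; ties are rejected because equal reactivity
gives no chemoselectivity), and (iii) the plan has at most `max_bbls` BBLs
(default 4 — beyond three or four sequential activations, promoter side
reactions erode yields). Precursor matches are excluded in this mode: plain
one-pot runs admit no intermediate deprotection.

**Fragment search.** With precursor matches allowed, each masked attachment
position becomes a *fragment boundary*: the sub-structure above it is built
as its own fragment and coupled only after the parent fragment's one-pot is
finished and the mask removed. Fragments hold 1–3 BBLs, descend strictly in
RRV internally, and keep the anomeric leaving group of their reducing-end
BBL, whose RRV is the fragment's default *effective RRV* (overridable by a
measurement or a model prediction — the output flags the default). The
fragment tree itself must descend strictly in effective RRV toward the
reducing end. Assembly is scheduled post-order; fragments are classed
*large* (> 15,000), *medium* (1,000–15,000], *small* (0–1,000], *zero* (0)
by the same bins used for prediction categories, or ordinally when their
effective RRVs are unknown. More than four fragments on the major chain
(the longest leaf-to-root path; ties broken toward the smallest attachment
position, then smallest id) triggers a hybrid recommendation mixing one-pot
assembly with distinct leaving groups. Enumeration is bounded by a cap of 3
fragments on any root-to-leaf path (configurable).

**Yield model.** No published formula exists for per-coupling yields, so the
default is a transparent kinetic argument: donor D1 and the acceptor acting
as donor D2 compete for one equivalent of activator with second-order rate
ratio r = RRV_d / RRV_a; integrating d[D1]/d[D2] = r·[D1]/[D2] at equimolar
loading until the activator is consumed leaves a productive fraction *x*
solving `x + x^r = 1` (solved by bisection to 1e-12; an RRV-0 acceptor
cannot self-activate, so its coupling scores 1). The model is monotone in r,
tends to 1 as r → ∞, and equals 0.5 at r = 1. It is verified in the test
suite against independent numerical integration of the three-species ODE
system. The model is pluggable, and every yield figure in the output is
model-dependent: rankings are meaningful, absolute percentages are not
calibrated against experiments.

## The RRV predictor

RRVs span 1–72,000 and are roughly log-distributed, so the regression
target is ln(RRV) and predictions are back-transformed with exp. Features
come in three blocks: **BP** (one-hot sugar type over the five predictable
types Gal/Glc/Man/GalNAc/GlcNAc, sugar class, anomeric state, and the
protecting-group token at positions 2/3/4/6; ordinal codes optional),
**CS** (13 ring chemical-shift slots H1–H5, H6-1, H6-2, C1–C6 in ppm,
ingested from a table — shift prediction itself is out of scope — encoded as
per-slot min-max normalized values and/or fixed-width bin indicators,
defaults 0.2 ppm for ¹H and 2.0 ppm for ¹³C, chosen to give a handful of
occupied bins per slot over typical ring-shift windows), and **MD** (an
ingested 1D/2D molecular-descriptor matrix). Degenerate cases follow fixed
conventions: a slot constant in training normalizes to 0 and yields a single
always-on bin; missing shifts (e.g. H6-2 of 6-deoxy sugars) are imputed with
the slot training mean and flagged with an indicator; out-of-range values at
prediction time are clipped into the training range (clips counted).
Sialic-acid and fucose rows are outside the predictable vocabulary and are
excluded from model datasets.

The regressor is an epsilon-SVR (default linear kernel, C = 1, ε = 0.001 —
none are published, all exposed) behind a MinMax rescaler into [0, 1]. The
whole pipeline is refit inside every cross-validation fold, so the rescaler
never sees held-out rows; a test pins this by comparing against hand-rolled
honest and deliberately leaky LOOCV. (Bin *edges* for the CS indicators are
part of feature construction rather than the fold-local pipeline; min-max
normalization composes with the fold-local rescaler and is therefore
effectively fold-fitted.) Metrics — PCC, MAE, RAE = Σ|ŷ−y| / Σ|ȳ−y| — are
reported on both the RRV and ln scales: RRV-scale errors are the
operationally meaningful ones, but the RRV-scale PCC is dominated by the few
largest values of a log-distributed sample and is accordingly noisy, while
the ln-scale PCC measures fit quality stably. LOOCV equals k-fold with
k = n by construction. Per-category PCCs and the three-bin classification
accuracy (high > 15,000; medium 1,000–15,000; low ≤ 1,000 — both boundaries
closed downward, so 15,000 is medium and 1,000 is low) are also reported.

**Feature selection** is a backward greedy wrapper: from the full set, drop
the feature whose removal most improves (or least degrades) the pooled
5-fold cross-validated PCC (folds seeded and stratified by RRV category
where counts allow; PCC ties drop the lexicographically last name, which
also resolves duplicated columns deterministically), down to one feature.
The returned subset is the *smallest* one within `pcc_tol = 1e-4` of the
trace maximum — a parsimony rule adopted because near-duplicate subsets
score within numerical noise of each other, and it makes the noiseless
behavior (keep every informative feature, drop pure noise) exact. Features
can be pinned with `always_keep` (e.g. to retain complete sugar-type
information regardless of the optimum).

## The virtual library

Hexose virtual BBLs place one of 11 tokens (OH, OAc, OBn, OBz, OClAc, OLev,
NO2Bz, OPMB, OTBDPS, OTBS, OTIPS) at each of R2/R3/R4/R6 for Gal/Glc/Man:
3 × 11⁴ = 43,923. HexNAc virtual BBLs place one of {NHTroc, NPhth, N3} at
R2 and the 11 tokens at R3/R4/R6 for GalNAc/GlcNAc: 2 × 3 × 11³ = 7,986.
All carry a thio-tolyl leaving group. Structures are materialized as SMILES
from per-sugar-type beta-thiotolyl pyranoside templates with substituent
fragments attached; similarity screening uses RDKit's linear-path
fingerprint (an FP2-like scheme) with Tanimoto similarity, reporting for
each threshold the fraction of virtual structures whose best training-set
match reaches it. Coverage fractions are fingerprint-dependent, so the
backend name is recorded in the output; predicting RRVs for virtual
structures requires a feature provider (ingested shift/descriptor tables or
the BP-only encoding), since shifts and descriptors are not computed here.

## Synthetic fixtures: what they do and do not show

The scenario fixtures pin the published *shapes* of four syntheses — residue
composition, linkage pattern, RRVs, and strategy ([1+3+2] Globo-H with
internal fragment RRVs 4000/850/13 and a Lev-masked fucosylation site;
[2+1+3] SSEA-4 led by an RRV-1462 sialyl disaccharide; [1+2+2] heparin
backbone with 132/18.2/0; the 263/51/0 LacNAc one-pot). Their
protecting-group layouts are constructed, not transcribed from the original
synthetic schemes, and the heparin uronic-acid residues are Glc/GlcNAc
stand-ins (the data model does not carry GlcN/IdoA/GlcA). Passing these
scenarios shows the planner reproduces the published orderings given a
library containing the right blocks; it does not validate protecting-group
chemistry beyond the matching rules.

The RRV dataset generator emulates the real training library's scale (117
Hex/HexNAc monosaccharide rows, RRVs clipped into 1–72,000) with ln(RRV)
exactly linear in the encoded features: additive protecting-group effects
follow the arming/disarming trend (ethers arm, esters disarm), plus
sugar-type and anomeric offsets, weights on normalized shifts, and a sparse
descriptor signal, with Normal(0, σ) noise on the ln scale (σ = 0.3
default). Because the truth is realizable by the linear SVR, tests can make
sharp claims (noiseless near-perfect fit; weight-direction recovery with
cosine ≥ 0.95 at σ = 0.1 under C = 10, where the penalty does not shrink the
solution). Real data differ in every inconvenient way — correlated features,
non-additive protecting-group interactions, shift-prediction error,
heteroscedastic RRV measurement — so passing these tests demonstrates the
*protocol* (encoding, non-leaky CV, selection, metrics) is implemented
correctly, not that any particular accuracy is attainable on laboratory
data.

## Problem sizes and numerical choices

Exhaustive-equivalence tests compare the planner with brute-force tiling
enumeration on 500 random instances of ≤ 6 residues and ≤ 25 BBLs, a regime
where the oracle's set-partition enumeration is exact and fast; planner
correctness on larger trees follows from the same recursion. Selection
properties use 60-row, 15-feature datasets over 10 seeds. Yield equations
are solved by `brentq` to 1e-12; ODE cross-checks use `solve_ivp` at
rtol 1e-10. All randomness flows from explicit integer seeds; outputs are
written with sorted keys and no timestamps, so identical configurations
reproduce byte-identical files.

## Known limitations

- No solvent, temperature, promoter, or anomeric-selectivity modeling; the
  planner orders couplings by RRV only.
- Yield percentages are a model, uncalibrated against experiment.
- Protecting-group orthogonality across fragments is enforced only through
  the per-BBL uniqueness rule.
- The virtual-library screen depends on the fingerprint backend; absolute
  coverage numbers are not comparable across backends.
- Sialic-acid ring positions beyond {4,7,8,9} and linkages outside
  {2,3,4,6} are not representable.
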