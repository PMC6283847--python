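# glycoplan

Route planning for **programmable one-pot oligosaccharide synthesis**, for
carbohydrate chemists and glycoinformaticians.

In programmable one-pot synthesis, protected thioglycoside building blocks
(BBLs) are added sequentially to a single vessel in order of decreasing
**relative reactivity value (RRV)** — the most reactive donor first, the
RRV = 0 reducing-end acceptor last — so each activation step is
chemoselective. Planning a synthesis then becomes a search problem: tile the
target glycan tree with library BBLs whose free hydroxyls match the target's
branching pattern and whose RRVs admit a strictly descending addition order.
`glycoplan` implements:

- a **glycan tree model** (root = reducing end) with a condensed text dialect
  (`Gal(b1-4)GlcNAc(b1-3)Gal`, branches bracketed) and a JSON record dialect;
- **BBL matching**: *perfect* matches (free OH exactly at the attachment
  positions, protection everywhere else) and *precursor* matches (attachment
  positions masked by a unique, selectively removable protecting group such
  as Lev or ClAc);
- a **one-pot planner** (depth-first, in-order) returning plans ranked by a
  pluggable per-coupling yield model — the default treats each coupling as a
  competition of donor and acceptor for one equivalent of activator with rate
  ratio r = RRV_d/RRV_a, giving per-coupling yield *x* solving
  `x + x^r = 1`;
- a **hierarchical fragment planner**: complex targets are split at masked
  positions into fragments of 1–3 BBLs, each built by its own one-pot, then
  assembled (one-pot by descending effective RRV — roles *large / medium /
  small / zero* — or stepwise with distinct leaving groups);
- an **RRV predictor**: epsilon-SVR on ln(RRV) over basic properties,
  13 ring NMR chemical shifts (ingested from a table), and molecular
  descriptors, with LOOCV/k-fold evaluation (PCC, MAE,
  RAE = Σ|ŷ−y| / Σ|ȳ−y|) and backward greedy wrapper feature selection by
  5-fold CV PCC;
- a **virtual BBL library**: all 3 × 11⁴ = 43,923 hexose and
  2 × 3 × 11³ = 7,986 HexNAc protecting-group combinations (51,909 total),
  materialized as SMILES and screened against a training library by Tanimoto
  similarity of path fingerprints;
- **synthetic fixtures** reproducing four published one-pot strategies
  (Globo-H, SSEA-4, a heparin pentasaccharide backbone, oligoLacNAc) and an
  RRV dataset generator with known log-linear ground truth.

## Worked example

```python
from glycoplan import fixture_scenario, search_no_fragments
from glycoplan.fragments import fragment_search

lac = fixture_scenario("lacnac_3")          # Gal(b1-4)GlcNAc(b1-3)Gal
plan = search_no_fragments(lac.tree, lac.library)[0]
print(plan.rrv_sequence, round(plan.overall_yield, 3))

glo = fixture_scenario("globoH_132")        # Fuc(a1-2)Gal(b1-3)GalNAc(b1-3)Gal(a1-4)Gal(b1-4)Glc
top = fragment_search(glo.tree, glo.library)[0]
print(top.signature(), [f.rrv_sequence for f in top.fragments])
```

prints

```
(263.0, 51.0, 0.0) 0.759
(1, 3, 2) [(0.0,), (4000.0, 850.0, 13.0), (72000.0,)]
```

i.e. the LacNAc trisaccharide is a single one-pot — donor (RRV 263), then
acceptor (51), then the reducing-end acceptor (0) — with a model-estimated
overall yield of 76%; Globo-H is a [1 + 3 + 2] hierarchical plan: a fucose
donor fragment (RRV 72,000), an internal trisaccharide fragment built
one-pot from BBLs of RRV 4000 → 850 → 13 (its fucosylation site stays
Lev-masked until the fragment is finished), and a reducing-end disaccharide
acceptor.

The same is available from the shell:

```bash
glycoplan fixtures --scenario globoH_132 --out fx
glycoplan plan --target fx/globoH_132.glycan --library fx/globoH_132_library.csv \
    --mode fragments --out plans
glycoplan enumerate --sugar-class hex --out hex_virtual.csv   # 43,923 rows
```

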