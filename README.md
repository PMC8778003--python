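# covgen

Fragment-based generative design of covalent kinase inhibitors.

Covalent inhibitors carry a reactive "warhead" — here an N-acryloyl
piperidine Michael acceptor, as in the BTK drug ibrutinib — that bonds to
a poorly conserved cysteine near the ATP site. Designing new ones is a
constrained problem: the warhead must be kept intact while the rest of the
molecule is re-imagined to fit the binding site. `covgen` addresses this
with a matched-series strategy:

1. **Hierarchical fragmentation.** Every compound is cut twice at single
   acyclic bonds into a Key 2 core (with attachment points `[At]` for the
   Value 1 substituent and `[*:1]` for the Value 2 fragment), a Value 2
   fragment containing the warhead, and a Value 1 substituent. All
   fragmentations of a dataset are organized into SAR matrices — one shared
   core per matrix, Value 2 rows × Value 1 columns, compounds in occupied
   cells, unexplored combinations in empty ones.
2. **Three seq2seq generators** (Key 2, Value 2, Value 1) — LSTM
   encoder–decoders over SMILES tokens — are pre-trained on a large
   library's matrices and fine-tuned on a small target-focused set, then
   sampled with a temperature factor. Each emission carries a novelty
   score `s = 1 − exp(mean token log-probability)` in [0, 1]: ≈ 0 for
   fragments like the training data, → 1 for novel ones.
3. **Filters.** Generated cores must have zero rotatable bonds and fit a
   3-feature core pharmacophore; generated Value 2 fragments must contain
   the warhead SMARTS; assembled candidates are screened against a
   6-feature pharmacophore with exclusion volumes (a fully specified
   surrogate scorer — see `docs/methods.md`).
4. **Assembly.** ([Key 2 − Value 2] − Value 1) candidates are crossed into
   per-core matrices ranked by cumulative novelty score, censused against
   reference sets, and projected into ECFP6/PCA chemical space.

Because no external compound collection is required, the `fixtures` module
generates a deterministic synthetic "kinome-like" library (8 hinge-binder
scaffolds × warhead/decoy Value 2 pool × 30 substituents, ~960 compounds)
plus a 34-compound warhead-only fine-tune series standing in for a real
covalent inhibitor set.

## Worked example

The reference decomposition of ibrutinib:

```python
>>> from covgen import ibrutinib_fixture, fragment_hierarchical
>>> from covgen import assemble_key1, assemble_compound
>>> mol, key2, value2, value1 = ibrutinib_fixture()
>>> [f.key2.smiles for f in fragment_hierarchical(mol)
...  if f.key2.smiles == "Nc1ncnc2c1c([At])nn2[*:1]"]
['Nc1ncnc2c1c([At])nn2[*:1]']
>>> assemble_compound(assemble_key1(key2, value2), value1).smiles == mol.smiles
True
```

The first line recovers the amino-pyrazolopyrimidine Key 2 with both
attachment points from ibrutinib by pure bond enumeration; the second
re-assembles the three fragments back into ibrutinib exactly (canonical
SMILES identity).

A desk-scale design run from the command line:

```bash
covgen run --seed 7 --out run7/
```

prints the stage funnel, e.g.

```
sample_key2               in=  5000 out=    33      2.4s
rotatable_filter          in=    33 out=    15      0.0s
key2_pharmacophore        in=    15 out=    13      0.8s
key2_prioritized          in=    13 out=    13      0.0s
sample_value2             in=  1000 out=    91      0.4s
warhead_filter            in=    91 out=     4      0.0s
candidates                in=  1612 out=  3688      9.1s
```

read: 5,000 Key 2 emissions collapse to 33 unique valid cores, 15 are
rigid, 13 fit the core pharmacophore; of 1,000 Value 2 emissions, 4 unique
fragments contain the intact warhead; crossing the survivors yields 3,688
candidate covalent inhibitors — every one warhead-positive — written to
`run7/candidates.csv` with their cumulative novelty scores and
pharmacophore fits, alongside per-core matrices, a PCA projection and the
run manifest.

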