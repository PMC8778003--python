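# Methods

`covgen` implements a fragment-based generative workflow for designing
covalent kinase inhibitors that carry an invariant reactive warhead. This
note records the model, its assumptions, the parameters that matter, and
the design choices made where the method left them open.

## Hierarchical Key/Value fragmentation

Each compound is cut twice at single acyclic bonds:

1. **Round one** splits the molecule into a **Key 1** core and a **Value 1**
   substituent. The core keeps an `[At]` placeholder (astatine — an element
   that never occurs in drug-like molecules, so it survives SMILES
   canonicalization untouched) at the cut position; the substituent keeps a
   bare `*`.
2. **Round two** cuts the Key 1 again into a **Key 2** core and a **Value 2**
   fragment. The new cut is marked `[*:1]` on the Key 2 side and `*` on the
   Value 2 side; the round-one `[At]` is retained on the Key 2.

For ibrutinib this yields the Key 2 `Nc1ncnc2c1c([At])nn2[*:1]` (the
4-aminopyrazolo[3,4-d]pyrimidine hinge binder), the acryloylpiperidine
Value 2 and the phenoxyphenyl Value 1.

**Cut eligibility.** A bond qualifies if it is single, not in a ring, joins
two heavy atoms, touches no attachment token, and does not lie inside a
matched warhead substructure (both bond atoms in the match) — the reactive
group is treated as chemically invariant and is never dismembered. The
smaller side of a cut is the value; it must contain at most
`max_value_atoms` heavy atoms (default 13) and at most `max_value_fraction`
(default 1/2) of the parent's heavy atoms. A side that already carries
attachment tokens is always the key, because a value may carry only its own
cut point; this rule also settles the otherwise ambiguous equal-size split
of cores like ibrutinib's Key 1 (`[At]` counts as a heavy atom of its
side). Remaining exact ties are broken lexicographically on the value-form
canonical SMILES of the two sides. A Key 2 must contain at least one ring
(it is the inhibitor's scaffold); values may be acyclic.

Fragment identity is constitution-based: stereocentres are dropped when
fragments are canonicalized, and reassembly identity is checked on achiral
canonical SMILES. Cutting at ring-attachment bonds rarely preserves
stereochemical context, and series keying by constitution keeps matrices
stable under stereo-ambiguous inputs.

## SAR matrices and training pairs

All hierarchical fragmentations of a dataset are indexed by Key 2. Each
Key 2 occurring in at least `min_series_size` (default 2) distinct
compounds defines one matrix: rows are its observed Value 2 fragments,
columns its observed Value 1 fragments, occupied cells the dataset
compounds, empty cells unexplored combinations. A compound may populate
several matrices through alternative fragmentations; this is deliberate
(each decomposition is a legitimate analogue-series membership).

Three sequence-to-sequence generators learn from these matrices:

| generator | input → output | pairs harvested from |
|---|---|---|
| Key 2   | Key 2 → Key 2   | cores of matrices sharing ≥ 1 Value 1 column, both directions |
| Value 2 | Key 2 → Value 2 | occupied cells (one pair per matrix row) |
| Value 1 | Key 1 → Value 1 | occupied cells, Key 1 re-assembled from Key 2 + row |

The Key 2 pairing rule (related series = shared substituent column) is the
package's own construction; it links cores that decorate the same
substituent chemistry, which is the signal a matched-series analysis
exposes.

## Generators

Each generator is a single-layer LSTM encoder–decoder over SMILES tokens,
implemented directly in NumPy (forward pass, backpropagation through time,
Adam, global-norm gradient clipping at 5.0). Defaults follow the reference
training schedule: 256-dimensional latent state, batch size 64, a 9:1
train/validation split, pre-training epochs 30/10/30 and fine-tuning
epochs 50/500/500 for Key 2/Value 2/Value 1. The embedding width (64), the
learning rate (2e-3) and the uniform ±0.08 initialization with a +1 forget
gate bias are the package's own choices. Teacher forcing is used
throughout; there is no attention and no early stopping. Fine-tuning
resumes from the pre-trained weights and refuses out-of-vocabulary tokens.
The tokenizer treats bracket atoms (`[At]`, `[*:1]`, `[nH]`, …), `Cl`,
`Br` and `%nn` ring closures as single tokens; sequences are capped at 120
tokens.

**Sampling** draws tokens from `softmax(logits / T)` with temperature `T`
(2.0 for Key 2 and Value 2, 1.5 for Value 1 by default), terminates on the
end token, and discards emissions that fail to parse or violate the role's
attachment grammar, counting them. Duplicates (by canonical SMILES)
collapse to one. All randomness flows through a seeded generator; runs are
reproducible on one device.

**Novelty score.** Each emission is scored
`s = 1 − exp(mean per-token log-probability)` of the emitted sequence
under the model, clipped to [0, 1]: memorized sequences (probability ≈ 1)
score ≈ 0, improbable/novel ones approach 1. The score of an assembled
candidate is the arithmetic mean of its Key 2, Value 2 and Value 1 scores.
The mean (rather than a sum) was chosen to keep the cumulative score on
the same [0, 1] scale as its parts. The raw emitted string is scored, not
its canonical rewrite, since the canonical form may use tokens the model
never produces.

## Filters

* **Rotatable bonds** (applied to generated Key 2 cores): a rotatable bond
  is a single, non-ring bond between two non-terminal heavy atoms; amide
  C–N bonds are excluded by default (the common medicinal-chemistry
  convention, toggleable) and bonds to attachment tokens never count — they
  are formal, not conformational, and likewise do not anchor a neighbour
  as "non-terminal". Cores must have zero rotatable bonds.
* **Warhead** (applied to generated Value 2 fragments): substructure match
  against the warhead SMARTS. The default is `C=CC(=O)N1CCCCC1` — an
  N-acryloyl piperidine Michael acceptor, substitution-open at every ring
  carbon because SMARTS `C` atoms carry no degree constraint. Ring-size
  variants (pyrrolidine) and the saturated propanamide decoy do not match;
  the pattern is a config value for other warhead chemistries.
* **Substructure census**: the ring system of a Key 2 (attachment tokens
  removed, ring atoms plus ring-attached heteroatom substituents retained,
  every position substitution-open) is searched in named reference sets; a
  fragment found nowhere is flagged novel.

## Pharmacophore surrogate

Reference pharmacophore screens in this workflow were originally done with
commercial software whose scoring function is proprietary. `covgen` ships a
fully specified surrogate instead, and does not claim numerical equivalence
with any external tool.

A model is a set of typed features — hydrogen-bond donor/acceptor,
aromatic-ring centroid, hydrophobic centroid (connected runs of ≥ 3
carbon-only aliphatic carbons), and a residue bonding point at the
warhead's Michael-acceptor β-carbon — each with a position, a tolerance
radius (default 1.5 Å) and an optional flag, plus exclusion-volume
spheres. Feature perception is rule-based: N/O with H donate; O, and N
with a free lone pair, accept; feature directionality is ignored
(radius-only matching keeps the surrogate simple and testable; a
directional term would be a separate, flagged extension).

Candidates are embedded into up to `n` ETKDG conformers, relaxed with
MMFF (UFF fallback); Key 2 fragments are capped with hydrogen at their
attachment tokens first. For each conformer, every injective,
type-compatible assignment of candidate features to model features
(required features must be assigned; optional ones may be skipped) is
superposed onto the model by rigid-body least squares (Kabsch). A feature
is matched when its superposed partner lies within the feature radius, and

    score = (1/n_features) · Σ_matched exp(−d_i / 2 Å)

where `d_i` is the residual pair distance. Any heavy atom inside an
exclusion sphere is a clash and zeroes that pose. The best score over all
conformers and assignments is kept ("best conformation match" semantics).
A fit is declared when all required features match without clash.

The per-feature exponential was chosen over the equivalent-looking
`(matched/total) · exp(−rmsd/2)` because it coincides with it whenever the
matched distances are equal (in particular a self-fit scores ≈ 1) while
being provably monotone — per fixed conformer and assignment — under
radius widening and exclusion-volume removal, two invariants the filter's
users rely on. With the rmsd form, a far pair entering a widened radius
can lower the score discontinuously. Residual caveat: the reported best
score maximizes over assignments, and in contrived geometries a widened
radius can still shuffle which assignment wins; the panel tests probe this
empirically.

Pass thresholds for "closely matching" a model are not part of the
reference method's public description; the default cutoff (score ≥ 0.6)
and the top-18 Key 2 prioritization count are package configuration, not
reported values.

## Chemical space

Molecules are encoded as 2048-bit circular fingerprints of bond diameter
six (ECFP6, Morgan radius 3) and projected by mean-centered PCA onto the
first two components. Component signs are fixed by making each component's
largest-magnitude loading positive, so projections are deterministic.

## Synthetic library

The fixtures module generates the study data deterministically from a
seed: 8 hinge-binder-like heteroaromatic Key 2 scaffolds (pyrazolo- and
pyrrolo-pyrimidines, purine, benzimidazole, indazole, quinazoline,
7-deazahypoxanthine, thienopyrimidine), 5 Value 2 fragments (two warhead
piperidine acrylamides, a pyrrolidine near-miss, a saturated decoy, an
acyclic acrylamide) and 30 Value 1 substituents (para/meta-substituted
phenyls over 13 groups including halogens, ethers, anilines, nitriles,
plus pyridyl and aliphatic-ether members). Each scaffold's combinatorial
series is filled to exactly `round(completeness · cells)` compounds
(default 80%), giving ~960 pre-training molecules; the fine-tune subset is
34 warhead-bearing compounds drawn from the first two scaffolds, mirroring
the size relationship between a kinome-wide collection and one covalent
inhibitor series.

What the generator emulates: combinatorial analogue series with shared
cores, partial series occupancy, a reactive-group-bearing focused subset,
near-miss and decoy warheads. What it does not: bioactivity labels,
scaffold diversity beyond the hand-curated pools, stereochemistry,
tautomerism, or the long-tailed size distribution of real screening
collections. Green tests therefore certify the machinery — exact
fragmentation closure, warhead conservation, funnel consistency, score
semantics — not performance on real kinome data.

## Desk-scale run sizes

The library-scale workflow samples 50,000 Key 2, 10,000 Value 2 and 2,000
Value 1 fragments per core. The desk configuration used by the worked
examples and the reproduction script scales these by 0.1 (5,000/1,000/200),
trains compact generators (latent 96, embedding 48) with reduced epochs
(pre-train 3/2/3, fine-tune 40/150/50), caps harvested training pairs at
2,500 per stage, and fits at most 40 candidates with 8 conformers each.
These sizes keep a full run in the minutes range on a single CPU while
preserving the funnel's qualitative shape: thousands of emissions, a
handful of rigid pharmacophore-consistent cores, very few warhead-bearing
Value 2 survivors, and a candidate matrix crossing them.

## Numerical and degenerate-input choices

* Canonicalization and all identity checks go through one SMILES
  canonicalizer; fragments additionally strip stereo.
* Emissions consisting only of an attachment token, or whose attachment
  atom is multivalent, are rejected as grammar violations.
* Sampling with temperature ≤ 0.01 is numerically indistinguishable from
  greedy argmax decoding (softmax overflow is guarded by max-subtraction).
* A fine-tune corpus with tokens outside the pre-trained vocabulary raises
  an error naming the tokens rather than silently remapping.
* PCA on identical fingerprints raises a degenerate-input error; duplicate
  molecules are otherwise projected identically.
* Pharmacophore fitting with no type-compatible assignment scores 0 (not
  an error); conformer embedding failure raises.
* The pipeline derives per-stage seeds from the run seed by fixed offsets,
  so stages are independently reproducible; any stage with zero survivors
  aborts with a stage-named error carrying the partial manifest.

## Known limitations

* The NumPy LSTM is deliberately small; it memorizes desk-scale corpora
  rather than generalizing over chemical space, and validity rates at high
  temperature are low — compensated by sampling volume, as in the
  reference workflow.
* The warhead-bearing Value 2 yield at desk scale is a few per thousand
  samples; very small `scale` values can starve the funnel and abort.
* The pharmacophore surrogate ignores feature direction and partial
  charges; its absolute scores are not comparable to any published
  pharmacophore-fit values.
* Multi-site (≥ 3 cut) fragmentation, tautomer/protomer handling and
  synthetic-accessibility scoring are out of scope.
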