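# fitland

Nonlinear fitness landscapes for inverse protein folding (protein
design): given a target backbone, score candidate amino-acid sequences
so that the native sequence of a structure ranks below every competing
"decoy" sequence mounted on the same structure.

`fitland` is for structural-bioinformatics researchers who want a
global design fitness function that is cheap to evaluate, trainable
from ordinary PDB chain files, and testable end-to-end on synthetic
data without any external downloads.

## The model

A (sequence, structure) pair is represented by a 210-dimensional
contact vector `c`: the count of non-bonded nearest-neighbor residue
contacts for each unordered pair of the 20 amino-acid types.  Contacts
are edges of the Delaunay triangulation of all heavy atoms filtered at
4.5 Å, restricted to residues at sequence separation ≥ 2.  Because
total contacts grow linearly with chain length `n` (`N_c ≈ a + b·n`,
fitted by least squares on the training natives), each vector is
normalized by its predicted total before learning.

The fitness function is a reduced support vector machine with a
rectangular Gaussian kernel,

```
f(x) = Σ_j  D̄_jj ū_j K(x, ā_j) − γ,      K(x, y) = exp(−μ‖x − y‖²),
```

where `ā_j` are a small basis set Ā of m̄ contact vectors (natives and
decoys), `D̄_jj = ∓1` their class signs (natives −1, decoys +1), and
`ū, γ` are found from the quadratic program

```
min  ½‖y‖²_C + ½(ūᵀū + γ²)   s.t.   D(K(A, Āᵀ)D̄ū − eγ) + y ≥ e,  y ≥ 0
```

over the full training pool A (m rows, m ≫ m̄), with class-weighted
costs C so that errors on the scarce natives outweigh errors on
decoys.  The 2-norm slack makes the program an unconstrained strongly
convex piecewise quadratic in only m̄+1 variables, which a generalized
Newton iteration with LU solves and an Armijo line search minimizes in
a handful of steps — the m × m kernel matrix is never formed.

Training data comes from two decoy generators (gapless threading of
longer sequences through shorter structures, and composition-preserving
random residue swaps), and the pool/basis are rebuilt iteratively by
hard-example mining: Strategy 1 refills the pool with the
least-violating *misclassified* decoys, Strategy 2 with the hardest
*correctly classified* decoys and natives.  Discrimination is
summarized by the F<sub>β</sub> score with β = 10 (natives are the
positive minority class) and by per-native design-rank success: the
native must score strictly lowest among itself and all its decoys.

## Worked example

Train and evaluate on a synthetic cohort (no downloads needed):

```sh
fitland synth --n-natives 32 --decoys-per-native 20 --seed 7 \
    --train-out train.tsv --test-out test.tsv
fitland train --vectors train.tsv --strategy 2 --seed 7 \
    --model-out model --reports-out rounds.jsonl
fitland evaluate --model model --vectors test.tsv -o metrics.json
```

The round reports show the hard-example mining at work — the first
round trains on one decoy per native (pool 48), the second on the ten
hardest decoys per native (pool 264):

```
{"round": 0, "strategy": 2, "misclassified_natives": 0, "misclassified_decoys": 1, "pool_size": 48,  "basis_size": 24,  "solver_converged": true, "notes": []}
{"round": 1, "strategy": 2, "misclassified_natives": 0, "misclassified_decoys": 0, "pool_size": 264, "basis_size": 110, "solver_converged": true, "notes": []}
```

and `metrics.json` reports the held-out universe (8 natives, 160
decoys):

```
{"n_natives": 8, "n_decoys": 160,
 "misclassified_natives": 0, "misclassified_decoys": 0,
 "fbeta": 1.0, "beta": 10.0, "design_success_rate": 1.0, ...}
```

`misclassified_natives` counts natives with positive fitness,
`misclassified_decoys` decoys with negative fitness, and
`design_success_rate` the fraction of held-out natives that score
strictly below all of their own decoys — here the landscape separates
the classes perfectly.

Real structures go through the same pipeline: `fitland contacts
*.pdb --chain A -o vectors.tsv` extracts contact vectors, and `fitland
decoys thread|swap` generates decoy universes from chain pairs.

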