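# Methods

## The modelling problem

`pairqsar` builds multiple-linear-regression QSAR models that relate a
compound's inhibitory potency (pEC50, the negative base-10 logarithm of
the molar EC50) to distance-constrained pharmacophore-pair descriptors
computed from its molecular graph. The workflow follows the OECD-style
recipe used in regulatory QSAR practice: curate the activity table,
compute a large descriptor pool, prune it blindly (objective feature
selection), split into training and prediction sets, search descriptor
subsets with a genetic algorithm scored by leave-one-out
cross-validation, and subject the final model to a full internal /
external / chance-correlation / applicability-domain battery.

## Molecular graphs and atom typing

Structures are parsed from SMILES (or SDF) with RDKit; hydrogens are
made explicit and all-pairs shortest-path distances are computed in
bond counts over the explicit-hydrogen graph. Topological ("nB")
descriptors use these bond counts; geometric ("nA") descriptors use 3D
coordinates, taken from SDF input when present and otherwise generated
deterministically (ETKDGv3 with a fixed seed, then MMFF94
minimisation).

The descriptor grammar needs pharmacophoric atom classes that standard
toolkits do not define uniformly, so the typing table is explicit and
config-overridable:

| flag        | rule                                                |
|-------------|-----------------------------------------------------|
| `donor`     | N or O bearing ≥ 1 hydrogen                          |
| `amide_N`   | N single-bonded to a carbon that is double-bonded to O |
| `lipophilic`| C with no N/O neighbour; plus S and halogens (switchable) |
| `sp2_O`     | O participating in a double bond                     |
| `nonring_O` | O outside any ring                                   |
| `ring_C`, `ring_S` | ring-membership carbon / sulfur               |
| `sp3_C`     | sp3-hybridised carbon                                |

Whether sulfur and the halogens belong to the lipophilic class is a
genuine interpretation choice in this descriptor family; both switches
default to "included" and can be turned off in `TypingRules`.

Partial charges are Gasteiger–Marsili iterative partial equalization
charges (8 iterations), the de-facto fast topological charge model.
The charge backend is a single function boundary, so another model can
be swapped in; charges over a neutral molecule sum to zero to 1e-6 by
construction of the transfer scheme.

## Descriptor grammar

Four families cover the descriptors the models use:

* `f<center><target><n>B` — the number of ordered (center, target)
  atom pairs exactly *n* bonds apart, e.g. `fNringC6B` (ring carbons
  exactly six bonds from a nitrogen) or `fringCH3B` (hydrogens three
  bonds from a ring carbon). Ordered-pair counting reproduces the
  "frequency of occurrence" semantics when several centers see the
  same target; the alternative (distinct targets) is a one-line change.
* `<class>_<center>_<n>Bc` — summed partial charge of a class of atoms
  within 1..n bonds of any center, each contributing atom counted
  once, e.g. `lipo_ringS_8Bc`.
* `com_<target>_<n>A` — the number of target atoms within *n* Å of the
  molecular center of mass (mass-weighted), e.g. `com_sp2O_4A`. The
  center-of-mass reading of `com_` is an interpretation; it is isolated
  in one evaluator.
* `avg_molweight` — molecular weight divided by the explicit-hydrogen
  atom count. The alternative reading (mean mass over heavy atoms
  only) is numerically distinguishable but not resolvable from printed
  data; the definition used here is stated in the docstring and tested.

"Within n bonds" always means shortest-path distance 1..n, excluding
the center atom itself. Unknown descriptor names fail loudly rather
than evaluating to zero. The combinatorial default pool (all ordered
token pairs × distances 1–9, charge sums at radii 2/4/6/8, geometric
counts at 4 Å) yields ~1600 descriptors, the scale of a contracted
topological pool.

## Curation and the activity transform

EC50 values are converted to molar and transformed as
pEC50 = −log10 EC50(M); the transform is exactly invertible and
strictly decreasing. Curation flags, in input order: unparsable
structures (kept in the table, never fatal), disconnected SMILES
(salts/mixtures), qualifiers other than `=` (imprecise), and records
whose canonical structure (stereo ignored) repeats an earlier kept
record (first occurrence wins). Stored pEC50s are taken as given and
never reconciled against stored EC50s, so inconsistent source pairs
survive inspection. The train/prediction split is random without
replacement with train size = floor(fraction × n) — 67/17 for 84
compounds at 80% — under a recorded seed, and the partition is written
into the run output.

## Objective feature selection

Activity-blind pruning removes, in order: constant columns;
near-constant columns (most frequent value covering > 95% of rows, a
common QSAR default, configurable); and the later member of any column
pair with |Pearson r| > 0.90, scanning pairs in fixed input order.
Keeping the earlier column is deterministic and auditable;
higher-variance-wins is available through configuration. The removal
log names every dropped column exactly once, with the retained partner
for correlation drops.

## GA-MLR subset search

Candidate models are fixed-size descriptor index sets scored by
Q²_LOO of the OLS fit (computed through the hat-matrix deletion
identity; rank-deficient candidates score −∞). The GA uses tournament
selection (size 2), one-point crossover on sorted index lists with
duplicate repair by random resampling, single-gene point mutation, and
elitism, all under one recorded seed; elite fitness is monotone
non-decreasing by construction. The best subset is polished by a
deterministic greedy 1-swap hill climb (best improving swap, scanned
in index order, until a local optimum), which makes the search exact
on small pools — on every enumerable instance tested the GA matches
exhaustive search.

Defaults: population 50, 150 generations, crossover 0.9, mutation 0.2,
elitism 2. These are reproducibility choices, not tuned constants; the
original tooling in this model family does not report its GA settings,
so results are compared at the level of model-quality statistics, not
subset identity.

Model size is chosen by an explicit breaking-point rule on the
Q²_LOO-vs-k curve: the smallest k whose marginal gain falls below
ε = 0.02 (the knee that is usually read off a plot). A curve that
never plateaus returns k_max with a warning.

## Validation battery

* **Internal:** Q²_LOO = 1 − PRESS/TSS via the deletion identity
  e_i/(1−h_i) (equal to brute-force n-refit LOO to 1e-10 and cheaper);
  Q²_LMO over seeded random deletion groups (default leave 30%, 1000
  iterations), each group scored about the retained rows' mean — the
  exhaustive leave-one mode reproduces Q²_LOO exactly; RMSE/MAE on
  deletion residuals; Lin's CCC with n-denominator moments.
  PRESS ≥ RSS always (deletion residuals dominate), hence
  Q²_LOO < R² whenever the fit is non-trivial.
* **External:** R²_ext, Q²_F1 (error scaled by external TSS about the
  *training* mean), Q²_F2 (about the external mean), Q²_F3 (per-compound
  MSE against training variance), CCC_ext, Roy's r²m computed in both
  regression directions (reported as the average and the absolute
  difference, with acceptance read as average > 0.5 and Δ < 0.2), and
  the Golbraikh–Tropsha checklist (Q²_LOO > 0.5, R²_ext > 0.6,
  (r²−r²₀)/r² < 0.1 in either direction, through-origin slope within
  0.85–1.15).
* **Chance correlation:** Y-randomization — the response is permuted
  (2000 iterations by default), the model refit on the same
  descriptors, and the scrambled R²/Q²_LOO distribution summarized by
  mean and max.
* **QUIK rule:** Todeschini's multivariate K correlation index
  K = Σ|λ_j/Σλ − 1/m| / (2(m−1)/m) over the eigenvalues of the column
  correlation matrix; the model passes iff K_xxy − K_xx ≥ 0.05.  The
  intercept column cannot enter K (a constant has no defined
  correlation), and because Pearson correlation is scale-invariant the
  raw- and standardized-response variants of K_xxy coincide; one
  variant is therefore exposed.
* **Applicability domain:** Williams-plot data with leverage
  h_i = x_i(XᵀX)⁻¹x_iᵀ (intercept column included), warning leverage
  h* = 3(p+1)/n, internally studentized training residuals with cutoff
  ±3 (2.5 is a config away). Labels: `X_outlier` (h > h*), `Y_outlier`
  (|standardized residual| > 3, co-occurrence reported as
  `XY_outlier`), and `model_outlier` for compounds inside both margins
  whose deletion residual exceeds 3 × RMSE_cv — an operationalization
  of the "visible only once the model exists" outlier class, documented
  as an interpretation.

Degenerate inputs are handled explicitly: zero response variance makes
R²/F zero by convention in the fit and raises for cross-validated
statistics; constant prediction vectors yield NaN correlation-based
metrics and a failed (not crashed) Golbraikh–Tropsha verdict; singular
designs raise an error naming the collinear columns.

## Synthetic data: what it emulates and what it does not

`make_planted` draws an iid standard-normal descriptor matrix with a
planted k-column linear signal: unit-magnitude coefficients with
random signs (the canonical planted-signal benchmark in the variable
selection literature; varied magnitudes via `beta_range`), intercept
7.0 (a typical pEC50 level), and noise σ solved from the population
identity R² = Σβ²/(Σβ² + σ²). Planted columns are redrawn until
mutually |r| < 0.5, so the signal survives correlation pruning by
construction; a decoy mode correlates chosen noise columns with
planted ones (default ρ 0.6) to stress the GA the way collinear real
pools do. Regeneration under the same seed is bit-identical.

The benchmark regime mirrors the reference study's statistics — 84
compounds split 67/17, ~200 post-filter descriptors, k = 5, target
R² = 0.83 — and at desk scale reproduces its characteristic ordering
R² > Q²_LOO ≥ Q²_LMO with PRESS ≥ RSS and near-zero scrambled R².
What passing these tests does **not** show: real descriptor columns
are integer-valued, sparse, and heavily collinear rather than
Gaussian; real activity noise is not homoscedastic; and exact-subset
recovery rates on Gaussian pools overstate what any selector can do on
a strongly redundant chemical pool. The toy-molecule suite (16 small
molecules covering every atom flag, with golden values regenerated on
demand by an independent networkx-BFS/double-loop oracle) covers the
chemistry side at unit scale; it does not exercise conformational
variability or tautomerism, which are out of scope.

## Problem sizes used by the shipped experiments

The planted-regime benchmark runs 100 seeded pipeline repeats (OFS →
split → GA at k = 5 → validation) with Q²_LMO at 1000 iterations per
run and one 2000-iteration Y-randomization on the first run's model —
the scrambled-R² level is a property of the regime, not of a
particular draw. Parameter-recovery coverage uses 100 replicates of
the n = 67, k = 5 design, counting per-coefficient events
|estimate − truth| ≤ 2 SE. The analysis drivers use 25 repeats for the
desk benchmark and a 16-molecule toy set for the end-to-end pipeline
demo (whose 12-compound training set supports at most k = 2, hence the
plateau warning in its output).

## Known limitations

* The descriptor grammar implements the four families the models use,
  applied combinatorially — not a general descriptor compiler.
* Gasteiger charges are a topological approximation; descriptor values
  that depend on charges will not match tools using other charge
  models, and matching a specific historical tool's numbers would
  require that tool's charges.
* Geometric descriptors depend on the embedded conformer; a single
  minimized conformer is used, not an ensemble.
* Tautomers, protonation states and stereochemistry-aware descriptors
  are out of scope; duplicate detection deliberately ignores stereo.
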