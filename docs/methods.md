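# Methods

## Problem and model

Absolute retention time (RT) in liquid chromatography is platform-dependent,
but retention *order* on similar C18 reversed-phase systems is largely
conserved. `retorder` therefore learns to predict the elution order of
compound pairs rather than their absolute RTs, which lets heterogeneous
corpora — small-molecule RT collections and peptide RTs from proteomics runs
— train a single model that can be applied to peptides with
non-proteinogenic amino acids (PNPAs), for which almost no reference RT data
exist.

The pipeline is:

1. **Counting fingerprints.** Each structure (largest covalent fragment,
   stereochemistry stripped) is profiled by four substructure families:
   166-key MACCS, hashed linear-path features with bond orders ("extended"),
   the same paths ignoring bond order ("graph"), and circular Morgan
   environments ("circular", ECFP6-like). Counting mode records occurrence
   multiplicities instead of presence bits; the MIX fingerprint is the fixed
   concatenation `[maccs | extended | graph | circular]`.
2. **Principal component fingerprints (PCF).** Counting fingerprints are
   massively multicollinear (VIF ≫ 10). Covariance PCA on the training
   matrix (constant slots dropped, columns mean-centered, no unit-variance
   scaling — counting magnitudes are meaningful) yields decorrelated scores.
   The fitted transform is serialized and reused verbatim on every query,
   reference compound and database candidate; it is never refit.
3. **Ranking SVM.** All non-tied compound pairs within a subset become
   training examples (δ = x_a − x_b, label +1 iff a elutes first). The
   linear model minimizes ½‖w‖² + C·Σ hinge(1 − y⟨w, δ⟩); having no
   intercept, its decision is exactly antisymmetric. C is chosen by
   leave-one-subset-out cross-validation on held-out pairwise accuracy.
4. **Order-agreement scoring.** A query is placed relative to a panel of n
   reference compounds: measured relations m_i = sign(rt_query − rt_i)
   (ties → "after"), predicted relations p_i from the model. The accuracy
   S = (1/n)Σδ(m_i, p_i) takes values k/n. The same statistic between a
   measured feature and a *database candidate's* predicted relations is the
   match score S′ used for annotation.
5. **Candidate search.** A structure database is filtered by adduct m/z
   (default [M+H]+ = neutral monoisotopic mass + 1.007276 Da) within a
   tolerance window (default ±0.5), duplicates collapsed on canonical
   SMILES; survivors are ranked by S′ and shortlisted at S′ ≥ 0.9. The two
   stages commute — the mass filter never sees the model and the ranking
   never sees the masses.
6. **Interpretation.** For the linear model the Shapley value of component j
   on input x is exactly w_j·(x_j − E[x_j]) under independent features;
   attributions add up to f(x) − E[f] to machine precision. Components
   ranked by mean |contribution| are traced to substructures via the MACCS
   block of the PCF loadings.

## Numerical choices

* **RankSVM solver.** The primal objective is minimized with L-BFGS using a
  quadratically smoothed hinge (band width γ = 0.01 margin units; the exact
  hinge is the γ → 0 limit). The problem is solved in globally rescaled
  coordinates δ/s (s = median pair norm, C·s² compensating) and the
  objective is normalized by C_eff·n so stopping tolerances are per-pair
  quantities; a solve that stops at the iteration limit is accepted only if
  the per-pair gradient is below 1e−3. This formulation is deterministic and
  converges at every C on both separable and noisy pair sets, where dual
  coordinate-descent solvers stall. The RBF variant trains a standard SVC on
  the symmetrized pair set and predicts through the antisymmetrized score
  (f(δ) − f(−δ))/2.
* **C grid.** PCF scores of counting fingerprints carry variances of order
  1e2–1e4, so pair difference vectors are large and the informative part of
  the regularization path lies at small C. The default grid is
  {1e−5, 1e−4, 1e−3, 1e−2, 0.1}; ties in mean held-out accuracy resolve to
  the smaller C. The grid is a parameter everywhere.
* **Tie-breaks.** RT ties while sorting are broken by input order (stable
  sort); equal-RT pairs are excluded from training (order information only);
  a zero ranking score predicts "+1, a before b"; an exact RT tie with a
  reference resolves to "after". All are arbitrary but fixed and tested.
* **PCA sign convention.** Each component's largest-|loading| entry is made
  positive, so scores and loadings are reproducible across linear-algebra
  backends.
* **VIF.** VIF_j = 1/(1 − R²_j) with an intercept-included least-squares
  regression of slot j on the remaining slots; perfect collinearity reports
  +inf. Exact VIF needs n_samples > n_features; wider matrices are scored on
  a seeded random column subsample with a warning (NaN elsewhere).
* **MACCS semantics.** Counting = number of distinct SMARTS matches
  (unique atom tuples); binary = indicator(count > 0). The handful of MACCS
  keys defined with a count threshold ("more than one …") follow the
  indicator convention here so that binary(x) = 1 ⇔ counting(x) > 0 holds
  for every family; the placeholder keys RDKit stores as `?` are always 0.
* **Hashed families.** Paths are canonicalized (lexicographic min of the two
  directions), atoms typed by element/aromaticity/ring membership, and
  hashed with BLAKE2b into a power-of-two-length vector (default 1024,
  depth 6 bonds, radius 3). Counting mode lets hash collisions add.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| hashed length | 1024 per family | fingerprint resolution vs collision rate |
| path depth / radius | 6 bonds / 3 | substructure context size |
| PCF components k | 200 | filter-style truncation by explained variance |
| C grid | {1e−5 … 0.1} | soft-margin regularization path |
| m/z tolerance | ±0.5 Th | mass-filter window |
| adduct | [M+H]+ | ionization assumed for positive-mode peptides |
| S′ threshold | 0.9 | shortlisting cut for candidate annotation |

## Synthetic data: what it emulates and what it does not

Real training corpora cannot ship with the package, so the generator builds
libraries from a fragment grammar: small molecules as linear/branched
assemblies of alkyl, aromatic, hydroxyl, carboxyl, amine, amide, halogen and
N-methyl fragments, and peptide-like chains of 5–12 residues over 8 residue
types including an N-methylated and a halogenated "non-proteinogenic"
residue. RT follows a reversed-phase-flavored linear law —

    rt = a0 + a1·#aliphatic_C + a2·#aromatic_rings + a3·#CH3
            − a4·(#HBD + #HBA) + N(0, σ),  clipped at 0

with defaults (1.0, 0.12, 0.6, 0.4, 0.1) minutes chosen to span roughly
1–15 min like a long C18 gradient, and independent Gaussian noise (default
σ = 0.5 min) as the simplest model in which pairwise label noise is
controlled by ΔRT/σ. Because the RT-generating counts are themselves
substructure features, noise-free libraries are ground-truth cases where the
order is exactly learnable — tests on them verify the machinery, not
chemistry. What the generator does **not** emulate: real RT nonlinearity and
column chemistry, isomer-resolution effects, RT distribution shapes of real
corpora, or measurement drift. Passing tests therefore demonstrate correct
recovery of a known generative law at realistic sizes, nothing more.

The study-scale checks use 300 molecules, 5 round-robin subsets and 200 PCF
components (seed 1) — sizes chosen so a complete leave-one-subset-out grid
search runs on a laptop-class single core in about a minute.

## Design choices on genuinely open points

* PCA is fit on the concatenated MIX matrix (a per-family mode exists but is
  not the default), on training molecules plus the reference panel.
* Component selection ranks by explained variance — the natural filter
  criterion when no wrapper search is affordable.
* Reference-panel pairs join the training side of *every* CV fold and are
  never scored.
* Cross-dataset pairs are never generated; ordering information is only
  assumed comparable within a subset.
* SHAP background = the model's training inputs (pair differences), whose
  mean is ≈ 0 after centering, so contributions reduce to w_j·x_j.
* The packaged 22-compound reference panel carries measured RTs
  (1.74–9.95 min) with hand-curated SMILES; structure identity of those
  SMILES is best-effort and not asserted by any test.

## Known limitations

* The linear RankSVM cannot express non-monotone structure–retention
  relationships; the RBF variant can but loses exact SHAP and JSON
  serialization.
* S′-based annotation degrades when candidates are structural near-isomers
  with genuinely similar retention behavior — the mass filter and order
  filter are then both uninformative, and MS/MS evidence is required.
* VIF on matrices with more slots than samples is estimated on a column
  subsample; it is a diagnostic, not an exact quantity, in that regime.
* Hash collisions in the path families can merge unrelated substructures;
  lengths are configurable if that matters.
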