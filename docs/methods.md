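# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `neofit`, module by module, and documents what the synthetic
data generators do and do not emulate.

## Neoantigen quality

Quality is the product Q = R × D of a recognition term and a
self-discrimination term, both dimensionless.

**Recognition potential R.** For a mutant peptide p^MT and an epitope set
{e}, alignment scores s_e are the best gapless window: every full-containment
offset of the shorter sequence against the longer is scored by summing
BLOSUM62 residue scores, and the maximum is kept. R aggregates them as

    R = Z⁻¹ Σ_e exp(−k (a − s_e)),   Z = 1 + Σ_e exp(−k (a − s_e)),

evaluated stably as `expit(logsumexp(k (s − a)))`, which is algebraically
identical. `a` (score units) displaces and `k` (inverse score units) steepens
the logistic. R ∈ [0, 1), is monotone in every s_e, and is 0 for an empty
epitope set (with a warning). The aggregation sums over all epitopes rather
than taking only the best hit; the best-aligned epitope id is reported for
interpretation.

**Self discrimination D.** D = (1 − w)·log A + w·log C with the MHC amplitude
A = Kd^WT/Kd^MT and the cross-reactivity distance C = EC50^MT/EC50^WT.
Natural logarithms are used throughout (they pair with the exponential clone
propagation below); a log10 option exists for display only. D is linear in
w ∈ [0, 1]: w = 0 uses only differential MHC presentation, w = 1 only
differential T cell reactivity.

**Parameter selection.** (w, a, k) are cohort-level tuning parameters with no
universal default; the package deliberately ships none as truth. They are
selected on a survival cohort by grid search maximising the two-sided
log-rank statistic of the split at the cohort median of a per-patient quality
summary (maximum Q by default, mean available). Degenerate splits score −∞;
exact ties are broken toward the lexicographically smallest (w, a, k).
Alignment scores, log A and log C do not depend on (w, a, k), so they are
precomputed once per record and the grid sweep only re-evaluates the logistic
and the split.

## Dose–response fitting and cross-reactivity

**Hill fits.** Activation curves are fitted as
response = baseline + emax / (1 + (ec50/c)^h) by bounded least squares in
log10-concentration, with h ∈ [0.5, 5], ec50 constrained to the tested range
×/÷ 100, and three EC50 initialisations across the tested range with best-RSS
selection (sigmoid fits on sparse grids are initialisation-sensitive). Fits
are invariant to uniform rescaling of response units. A curve with zero
response range, a failed fit, or (when a same-TCR wild-type reference is
available) a fitted emax below 0.1 × the reference emax is *censored*:
non-activating within the tested range. Censored peptides receive
EC50 = (highest tested concentration) × 10, so their log C is finite but
capped — poorly cross-reactive substitutions still inform the substitution
matrix. A censored wild-type reference is an error: C has no denominator.

**Product decomposition.** Observed log C values pooled across TCRs (equal
weight) are decomposed as log C(i, a→b) ≈ w_i · M[a][b] by alternating least
squares: closed-form per-cell updates of M given w, then per-position updates
of w given M, iterated until the relative RSS change falls below 1e-8 (at
most 200 sweeps; exact-recovery checks use more because convergence near the
fixed point is geometric, not superlinear). Identity cells are pinned to 0. M
is directional (EC50 ratios are directional); residue clustering symmetrises
it as (M + Mᵀ)/2 and applies average-linkage agglomerative clustering to the
Euclidean distances between rows, with residues entered alphabetically so
tie-breaking is deterministic. The w·M ↔ (cw)·(M/c) scale degeneracy is fixed
by normalising the mean of the interior-position weights (positions 2..L−1)
to 1.

**Identifiability of the decomposition.** Positions are coupled only through
shared wild-type residues: a scan of one arbitrary reference peptide
partitions positions into disconnected residue classes whose relative scales
the data cannot fix, and no estimator can recover the true matrix from such a
design. The synthetic scan generator therefore defaults to scanning a
reference peptide together with its cyclic shift, which chains every position
to its neighbour and leaves only the single global scale that the profile
normalisation removes. Real scan designs achieve partial coupling through
repeated residues; users combining scans should check coverage via the
recorded per-cell support.

**Imputation.** Cells never observed are imputed with the mean of observed
cells whose wild-type and mutant residues fall in the same biochemical
families (aliphatic AVLIM, aromatic FWY, positive KRH, negative DE, polar
STNQC, special GP), falling back to the global off-diagonal mean; their
support is recorded as 0 so downstream users can filter. Peptides of lengths
other than the training length map positions by linear interpolation of the
profile over the normalised position (0 = N terminus, 1 = C terminus).
Multi-substitution pairs sum per-substitution terms — an extension beyond the
single-substitution data the model is trained on.

## Clone fitness and selection inference

Clone genotypes are unions of own mutations along the root path of the clone
tree; per-sample frequencies may sum to <1 (tumour purity), and all model
computations renormalise over clones. The immune cost F_I of a clone is the
maximum Q over neoantigens in its genotype (0 if none); the oncogenic term
F_P counts missense mutations in KRAS, TP53, CDKN2A and SMAD4 in the
genotype. Fitness is F = −σ_I F_I + σ_P F_P with σ_I, σ_P ≥ 0, and
propagation x̂_rec ∝ x_prim exp(F) is computed in log space (constant fitness
short-circuits to the renormalised primary fractions exactly).

**Likelihood.** The fitting objective is a multinomial log-likelihood over
observed recurrent fractions, L = n_eff Σ_α x_rec^α log x̂_rec^α, with an
effective sampling depth n_eff (default 100) standing in for the unknown
read-level evidence; it is isolated behind a small interface so a
least-squares-on-log-ratios variant can be swapped in. Clones without primary
support are excluded (the propagation equation only moves primary clones
forward; clones new in the recurrent tumour are handled by the cohort
metrics) and both fraction vectors are renormalised over the remaining
clones. Optimisation is bounded L-BFGS-B multi-started from {0, 1, 10} per
axis with tight tolerances (ftol 1e-15), which recovers noiseless optima to
~1e-6. BIC = κ·ln(n_clones) − 2·L̂ compares the full model (κ = 2), the
oncogene-only model (κ = 1) and the neutral model (κ = 0); n_clones is the
number of clones entering the likelihood and is reported. `fit_params_pooled`
fits one (σ_I, σ_P) jointly across several tumour pairs (per-tumour
normalisation, summed likelihood) — the appropriate estimator for
cohort-level statements and the one used by the acceptance script.

**Frequency-change evaluation.** Observed and fitted ratios x_rec/x_prim are
evaluated for clones with primary frequency above 3%; frequencies below that
sampling threshold are replaced by a pseudocount (default threshold/2 =
0.015) before forming ratios. The summary reports the direction-agreement
fraction (clones whose observed or fitted log-ratio is exactly 0 count as
"unchanged" and leave the denominator) and the two-tailed Spearman rank
correlation of the log-ratios.

## Cohort metrics and repertoire analysis

Shannon entropy of clone frequencies is reported in nats (log2 display
option), with 0·log 0 = 0 and renormalisation built in. A clone is "present"
in a sample above a 1% frequency threshold (sampling-noise floor — distinct
from the 3% prediction threshold above). TMB counts non-synonymous mutations
on present lineages; neoantigen counts keep records with Kd^MT below the
conventional 500 nM MHC-I binder cutoff (configurable, since published
pipelines differ). The mean immune cost of a tumour is the
clone-frequency-weighted mean of F_I over present clones; an unweighted
variant is available because either reading of "averaging over clones" is
defensible. Paired primary→recurrent deltas are recurrent − primary; new
clones are present in the recurrent but not the primary sample, and the
percentage of new neoantigens is the share of recurrent binder neoantigens
whose clone of origin is new (defined as 0, flagged, when the recurrent
tumour has none). Depletion analyses compare empirical CDFs of log C and D
between groups with two-sided Kolmogorov–Smirnov tests; substitution-spectrum
regressions are ordinary least squares of substitution proportions on matrix
distance with two-tailed Pearson statistics; group comparisons use two-tailed
Mann–Whitney U.

The TCR dissimilarity index takes the k (default 10; "most expanded" is not
standardised) most frequent CDR3β clonotypes — ties broken lexicographically,
so the index is invariant to uniform count scaling — and averages pairwise
length-normalised distances. The default metric is a cost-minimising global
alignment with residue cost max(BLOSUM62 self-score) − pair score (0 for
identity) and gap cost equal to the maximum residue cost, normalised by mean
pair length; a plain normalised edit distance is available behind the same
interface. The index is 0 iff the top clonotypes are identical, and its
correlation with tumour immune cost (two-tailed Pearson plus linear slope) is
the convergent-expansion readout.

## Synthetic data

The generators are pure functions of (config, seed); per-patient streams are
spawned from one root seed, so extending a cohort never perturbs existing
patients. Defaults encode the study conditions the analyses target:

* **Peptides**: 9-mers; epitope sets of 20 random 9-mers. The generator
  quality parameters (w, a, k) = (0.5, 4.0, 0.5) centre `a` on the measured
  best-alignment score of a random 9-mer against such a set (median ~3,
  IQR 0–7), so recognition potentials span (0, 1) as they do against a
  curated epitope database rather than collapsing to a constant.
* **Scans**: reference peptide + cyclic shift (see identifiability above),
  3 TCRs per peptide; two 9-mer epitopes give the canonical 1,026
  TCR–variant pairs, plus one neopeptide × 1 TCR for 1,197. Titrations are
  12 log-spaced points over a 10,000-fold range (~2.8-fold serial dilutions,
  one plate row) with duplicate wells averaged and per-well Gaussian response
  noise of sd 0.05 on a unit emax; responses are clipped at 0. On this
  design the median EC50 recovery error at sd 0.05 is ~7–10%; sparser or
  wider grids degrade it (the information about EC50 sits in the transition
  region).
* **True cross-reactivity structure**: the ground-truth matrix draws small
  within-family and larger cross-family distances; the true profile is
  terminal-permissive (lower weight at positions 1 and L).
* **Cohorts**: 10 patients; clone trees grow by uniform attachment with
  8–15 clones; primary fractions are symmetric Dirichlet; 0–6 neoantigens
  and 1–5 passenger mutations per clone (tens of neoantigens per tumour,
  the burden scale of a low-mutated cancer); Kd^MT log-uniform on 10–500 nM
  (predicted binders), Kd^WT on 10–10,000 nM. Two driver missense mutations
  (KRAS, TP53) are clonal at the root — oncogenic drivers are early events —
  and each non-root clone acquires an additional subclonal driver
  (CDKN2A/SMAD4) with probability 0.35. The subclonal component is a
  deliberate generator choice: with strictly clonal drivers F_P is constant
  across clones, the oncogenic amplitude cancels against the normalisation Z,
  and σ_P is structurally unidentifiable; clone-level variance in F_P is what
  makes the recovery experiments meaningful. Recurrent fractions follow the
  propagation model at the configured (σ_I, σ_P) = (1.0, 0.5) and are
  multinomially sampled at depth n_eff = 200 (n_eff = None gives the
  noiseless limit). Survival times are exponential with hazard
  0.05·exp(β·maxQ), β default 1 (3 in the parameter-selection experiments,
  where the signal must separate grid cells).
* **Repertoires**: top clonotypes are copies of one seed CDR3β mutated
  per-residue with probability 1 − convergence; counts are geometric.

What the generators do **not** emulate: mutational signatures and codon
structure (substitutions are uniform over residues), linkage between
neoantigen load and TMB beyond shared clone assignment, purity below 1,
read-level sampling of clone frequencies (the multinomial depth is an
abstraction), HLA restriction (a single allele string), and repertoire V/J
gene usage. Passing recovery tests on these data therefore demonstrates
correctness of the estimators under the model's own assumptions, not
robustness to the full messiness of patient data.

## Problem sizes and numerical conventions

The test suite and acceptance script use the sizes above: 50 cohorts per
recovery experiment, 100 seeds for EC50 noise ensembles, 1,000 random
parameter points for conservation checks, 15 replicates × 50 patients for the
log-rank grid-recovery experiment (a scaled version of the same design,
asserted against a chance level of 1/27). Frequencies are conserved to 1e-12
by construction (log-space propagation); statistic implementations are
checked against independent brute-force oracles to 1e-12. Substitution
positions are 1-based; Kd is stored in nM; concentrations in molar units;
all logarithms natural unless a display option says otherwise.

## Known limitations

* The recognition-potential aggregation (sum over epitopes) and the
  multinomial likelihood with fixed n_eff are declared conventions; both are
  isolated behind interfaces for variants.
* The cross-reactivity model is trained on single substitutions; its additive
  extension to multi-substitution pairs is unvalidated.
* Censored (non-activating) variants enter the matrix at a capped log C; the
  cap (censor factor 10) is a convention, and heavily censored scans will
  compress the top of the distance scale.
* The fitness model propagates primary clones only; clones arising after the
  primary sample are described by the cohort metrics but not predicted.
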