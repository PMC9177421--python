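# neofit

Neoantigen quality scoring and clone-fitness modelling of tumour
immunoediting.

When the immune system surveils a growing tumour, T cells preferentially kill
cancer cell clones that carry immunogenic mutations (neoantigens), so less
immunogenic clones come to dominate — immunoediting. `neofit` implements the
quantitative machinery needed to detect and predict this process in paired
primary/recurrent tumours: a neoantigen quality model, a TCR cross-reactivity
model learned from dose–response substitution scans, a clone-fitness model
that propagates clone frequencies from the primary to the recurrent tumour,
maximum-likelihood inference of the selection pressures with model comparison,
and the cohort-level statistics (entropy, burden deltas, depletion tests, TCR
repertoire convergence) used to read out editing. It is aimed at
computational cancer-immunology groups working with clone trees, neoantigen
tables and TCR repertoires.

## The model

**Neoantigen quality.** A neoantigen — a wild-type/mutant peptide pair
(p^WT, p^MT) with MHC dissociation constants Kd^WT, Kd^MT — is scored as

    Q = R × D

* **R (recognition potential)** aggregates gapless BLOSUM62 alignment scores
  s_e of p^MT against a set of known immunogenic epitopes through a logistic
  sum, R = Σ_e exp(−k(a − s_e)) / (1 + Σ_e exp(−k(a − s_e))) — a proxy for
  the mutant peptide lying inside the recognition space of the TCR
  repertoire.
* **D (self discrimination)** measures the antigenic distance from self:
  D = (1 − w)·log(Kd^WT / Kd^MT) + w·log C, combining the MHC amplitude
  A = Kd^WT/Kd^MT with the cross-reactivity distance
  C = EC50^MT / EC50^WT — the fold increase in peptide concentration a T cell
  needs to activate on the mutant versus the wild type.

**Cross-reactivity model.** EC50 values come from Hill fits of TCR activation
titrations. Pooled over substitution scans, the observed log C of a
substitution a→b at peptide position i is decomposed as
log C ≈ w_i · M[a][b]: a 20×20 directional residue matrix M times a
position-weight profile, fitted by alternating least squares. Agglomerative
clustering of the learned M recovers biochemical residue families; the profile
captures the permissiveness of peptide termini.

**Clone fitness and propagation.** Each clone α of a multisample clone tree
has fitness

    F^α = −σ_I · max_{p^MT ∈ α} Q(p^MT) + σ_P · F_P^α

where F_P^α counts missense mutations in the canonical PDAC driver genes
(KRAS, TP53, CDKN2A, SMAD4) in the clone genotype. Recurrent-tumour clone
fractions are predicted from primary fractions by

    x̂_rec^α = x_prim^α · exp(F^α) / Z .

The amplitudes (σ_I, σ_P) ≥ 0 are fitted by maximising a multinomial
log-likelihood over observed recurrent fractions and compared by BIC against
an oncogene-only model (σ_I = 0) and a neutral model (no selection).

## Worked example

All inputs can be generated synthetically, so the full pipeline runs without
any external data:

```bash
neofit simulate --seed 7 --out demo --patients 2
neofit quality --neoantigens demo/neoantigens.tsv --epitopes demo/epitopes.fasta \
    --model demo/xreact_model.json --w 0.5 --a 4.0 --k 0.5 --out demo/quality.tsv
neofit fit-fitness --tree demo/trees/P000.json --qualities demo/quality.tsv \
    --mutations demo/mutations.tsv --primary P000_prim --recurrent P000_rec \
    --n-eff 200 --out demo/fit.json
```

`demo/quality.tsv` holds one row per neoantigen; the first data row reads

```
patient_id tumor_id  clone_id p_wt      p_mt      ...  R       logA   logC   D      Q
P000       P000_prim P000_c0  DGASQWWCK DGASQWWHK ...  0.6825  3.225  1.504  2.365  1.614
```

i.e. this C→H substitution is epitope-like (R = 0.68), better presented than
its wild type (logA = 3.2) and poorly cross-reactive (logC = 1.5), giving a
high quality Q = 1.61 — a clone carrying it pays a large immune fitness cost.
`demo/fit.json` then reports the selection amplitudes fitted on patient P000
(simulated under true σ_I = 1.0, σ_P = 0.5):

```json
{"sigma_i": 1.137, "sigma_p": 0.699, "preferred_model": "full",
 "bic": {"full": 809.4, "oncogenic_only": 896.5, "neutral": 899.4}, ...}
```

The full model is BIC-preferred over both the oncogene-only and the neutral
alternative: the recurrent tumour's clonal composition is best explained by
immune selection against high-quality neoantigens.

Other subcommands: `fit-curves` (Hill fits of dose–response CSVs),
`build-xreact` (learn the substitution model from a scan), `predict`
(propagate clone frequencies at given σ), `metrics` (per-tumour entropy, TMB,
neoantigen counts, immune cost), `tcr` (CDR3β dissimilarity index). Every run
writes a `run_manifest.json` with input hashes for reproducibility.

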