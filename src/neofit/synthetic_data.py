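"""Seeded generators for every input class the pipeline consumes.

These generators are the testing ground of the package: substitution scans
with known position-profile x substitution-matrix structure, cohorts of clone
trees evolved from primary to recurrent tumours under known selection
amplitudes (the generative inversion of the propagation model), and TCR
repertoires with tunable convergence. All generators are pure functions of
(config, seed): per-patient random streams are spawned from a single root
seed so adding patients never perturbs earlier patients' data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .clonal_fitness import (
    Clone,
    CloneTree,
    clone_covariates,
    predict_recurrent,
)
from .cross_reactivity import (
    BIOCHEMICAL_FAMILIES,
    CrossReactModel,
    PositionProfile,
    SubstitutionMatrix,
    _FAMILY_OF,
)
from .data_model import (
    AA_ALPHABET,
    DoseResponseCurve,
    EpitopeSet,
    MutationRecord,
    NeoantigenRecord,
    TcrRepertoire,
    write_clone_tree,
    write_dose_response_csv,
    write_epitope_fasta,
    write_mutation_table,
    write_neoantigen_table,
    write_airr_repertoire,
)
from .quality import QualityParams, quality


@dataclass
class SimConfig:
    """Study conditions for all generators.

    The defaults mirror the design the analyses are meant to operate on:
    9-mer peptides, 8-15 clones per tumour, a handful of neoantigens per clone
    (tens per tumour), selection amplitudes (sigma_I, sigma_P) = (1.0, 0.5),
    multinomial sampling depth n_eff = 200 and dose-response readout noise
    sd = 0.05 (fraction of a unit emax).
    """

    seed: int
    n_patients: int = 10
    clones_per_tumor: tuple[int, int] = (8, 15)
    peptide_length: int = 9
    n_epitopes: int = 20
    sigma_i: float = 1.0
    sigma_p: float = 0.5
    n_eff: Optional[float] = 200.0
    noise_sd: float = 0.05
    logc_noise_sd: float = 0.0
    neoantigens_per_clone: tuple[int, int] = (0, 6)
    passengers_per_clone: tuple[int, int] = (1, 5)
    subclonal_driver_prob: float = 0.35
    kd_wt_range_nm: tuple[float, float] = (10.0, 10000.0)
    kd_mt_range_nm: tuple[float, float] = (10.0, 500.0)
    concentration_range_molar: tuple[float, float] = (1e-11, 1e-7)
    n_concentrations: int = 12
    replicates: int = 2
    survival_beta: float = 1.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("clones_per_tumor", "neoantigens_per_clone", "passengers_per_clone"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name}: empty range")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


# ---------------------------------------------------------------------------
# ground-truth cross-reactivity structure
# ---------------------------------------------------------------------------


def default_true_profile(length: int = 9) -> PositionProfile:
    """Terminal-permissive position profile (termini more cross-reactive)."""
    t = np.linspace(0.0, 1.0, length)
    w = 0.45 + 0.75 * np.sin(math.pi * t) ** 0.5
    interior = w[1:-1] if length > 2 else w
    return PositionProfile(weights=w / interior.mean(), length=length)


def default_true_matrix(seed: int = 0) -> SubstitutionMatrix:
    """Random directional matrix with biochemical-family block structure.

    Within-family substitutions draw small distances, cross-family larger
    ones, emulating the observation that cross-reactivity is preserved inside
    families of similar size and hydrophobicity.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(901,)))
    m = np.zeros((20, 20))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            if i == j:
                continue
            same = _FAMILY_OF[a] == _FAMILY_OF[b]
            m[i, j] = rng.gamma(2.0, 0.3) if same else 1.0 + rng.gamma(2.0, 0.75)
    return SubstitutionMatrix(entries=m, support=np.ones((20, 20), dtype=int))


def default_reference_peptides(rng: np.random.Generator, length: int) -> list[str]:
    """A reference peptide plus its cyclic shift.

    In a substitution scan, positions are only tied together through shared
    wild-type residues; scanning a peptide together with its cyclic shift
    chains every position to its neighbour, making the position-profile x
    matrix decomposition identifiable up to the single global scale.
    """
    p = _random_peptide(rng, length)
    return [p, p[1:] + p[0]]


def simulate_logc_observations(
    config: SimConfig,
    true_profile: PositionProfile,
    true_matrix: SubstitutionMatrix,
    reference_peptides: Optional[Sequence[str]] = None,
    tcrs_per_peptide: int = 3,
) -> list[dict]:
    """Noisy (tcr, position, wt, mt, log_c) observations from the product model.

    Each reference peptide is scanned with every substitution at every
    position for each of its TCRs; log C = w[pos] * M[wt][mt] + Gaussian noise
    of sd ``config.logc_noise_sd``.
    """
    rng = _rng(config, 11)
    L = config.peptide_length
    if reference_peptides is None:
        reference_peptides = default_reference_peptides(rng, L)
    obs = []
    for p_idx, pep in enumerate(reference_peptides):
        for t in range(tcrs_per_peptide):
            tcr_id = f"pep{p_idx}_tcr{t}"
            for pos in range(1, len(pep) + 1):
                wt = pep[pos - 1]
                for mt in AA_ALPHABET:
                    if mt == wt:
                        continue
                    logc = true_profile.weight_at(pos, len(pep)) * true_matrix[wt, mt]
                    if config.logc_noise_sd > 0:
                        logc += rng.normal(0.0, config.logc_noise_sd)
                    obs.append(
                        {
                            "tcr_id": tcr_id,
                            "position": pos,
                            "wt_residue": wt,
                            "mt_residue": mt,
                            "log_c": logc,
                            "censored": False,
                        }
                    )
    return obs


def simulate_substitution_scan(
    config: SimConfig,
    true_profile: PositionProfile,
    true_matrix: SubstitutionMatrix,
    reference_peptides: Optional[Sequence[str]] = None,
    tcrs_per_peptide: int = 3,
) -> tuple[list[DoseResponseCurve], list[dict]]:
    """Full dose-response substitution scan.

    For each reference peptide x TCR: one reference curve plus all
    19 x length single-substitution variant curves (two 9-mers x 3 TCRs give
    the canonical 1,026 variant pairs; one more 9-mer x 1 TCR brings the total
    to 1,197). The titration emulates a 12-point serial-dilution row over a
    10,000-fold concentration range with duplicate wells: per-well Gaussian
    noise of sd ``config.noise_sd`` is averaged over ``config.replicates``
    wells and responses are clipped at 0. Returns (curves, true
    observations); deterministic under a fixed seed.
    """
    rng = _rng(config, 12)
    L = config.peptide_length
    if reference_peptides is None:
        reference_peptides = default_reference_peptides(rng, L)
    concs = np.logspace(
        math.log10(config.concentration_range_molar[0]),
        math.log10(config.concentration_range_molar[1]),
        config.n_concentrations,
    )

    def hill(ec50, h=1.0, emax=1.0, baseline=0.0):
        resp = baseline + emax / (1.0 + (ec50 / concs) ** h)
        if config.noise_sd > 0:
            wells = rng.normal(0.0, config.noise_sd, size=(config.replicates, len(concs)))
            resp = resp + wells.mean(axis=0)
        return np.clip(resp, 0.0, None)

    curves, truth = [], []
    for p_idx, pep in enumerate(reference_peptides):
        for t in range(tcrs_per_peptide):
            tcr_id = f"pep{p_idx}_tcr{t}"
            ec50_wt = 10.0 ** rng.uniform(-10.0, -8.0)
            curves.append(
                DoseResponseCurve(
                    tcr_id=tcr_id,
                    peptide=pep,
                    position=None,
                    points=list(zip(concs, hill(ec50_wt))),
                )
            )
            for pos in range(1, len(pep) + 1):
                wt = pep[pos - 1]
                for mt in AA_ALPHABET:
                    if mt == wt:
                        continue
                    logc = true_profile.weight_at(pos, len(pep)) * true_matrix[wt, mt]
                    if config.logc_noise_sd > 0:
                        logc += rng.normal(0.0, config.logc_noise_sd)
                    variant = pep[: pos - 1] + mt + pep[pos:]
                    curves.append(
                        DoseResponseCurve(
                            tcr_id=tcr_id,
                            peptide=variant,
                            position=pos,
                            wt_residue=wt,
                            mt_residue=mt,
                            points=list(zip(concs, hill(ec50_wt * math.exp(logc)))),
                        )
                    )
                    truth.append(
                        {
                            "tcr_id": tcr_id,
                            "position": pos,
                            "wt_residue": wt,
                            "mt_residue": mt,
                            "log_c": logc,
                            "censored": False,
                        }
                    )
    return curves, truth


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


def default_epitope_set(config: SimConfig) -> EpitopeSet:
    rng = _rng(config, 13)
    return EpitopeSet(
        entries=[
            (f"EPI{i:03d}", _random_peptide(rng, config.peptide_length))
            for i in range(config.n_epitopes)
        ]
    )


def default_quality_params(config: SimConfig, w: float = 0.5, a: float = 4.0, k: float = 0.5):
    """Quality parameters paired with a random epitope set.

    The displacement ``a`` is centred on the best gapless BLOSUM62 score a
    random 9-mer reaches against a random epitope set (median ~3-4, spread
    ~±7), so recognition potentials span the unit interval the way they do
    against a curated epitope database, rather than collapsing to 0 or 1.
    """
    return QualityParams(w=w, a=a, k=k, epitope_set=default_epitope_set(config))


DRIVER_GENE_ORDER = ("KRAS", "TP53", "CDKN2A", "SMAD4")


@dataclass
class SimulatedPatient:
    patient_id: str
    tree: CloneTree
    neoantigens: list[NeoantigenRecord]
    mutations: list[MutationRecord]
    qualities: dict[str, list[float]]
    survival_time: float
    survival_event: bool
    true_x_rec_expected: np.ndarray
    f_i: np.ndarray
    f_p: np.ndarray


@dataclass
class Cohort:
    config: SimConfig
    patients: list[SimulatedPatient]
    params: QualityParams
    model: CrossReactModel


def _simulate_patient(
    pid: str,
    rng: np.random.Generator,
    config: SimConfig,
    params: QualityParams,
    model: CrossReactModel,
) -> SimulatedPatient:
    n_clones = int(rng.integers(config.clones_per_tumor[0], config.clones_per_tumor[1] + 1))
    clone_ids = [f"{pid}_c{i}" for i in range(n_clones)]
    parents = [None] + [clone_ids[int(rng.integers(0, i))] for i in range(1, n_clones)]

    mutations: list[MutationRecord] = []
    neoantigens: list[NeoantigenRecord] = []
    prim, rec = f"{pid}_prim", f"{pid}_rec"
    mut_counter = 0
    own_mutations: dict[str, set] = {cid: set() for cid in clone_ids}

    def add_mutation(cid, gene, effect, generates=False):
        nonlocal mut_counter
        mid = f"{pid}_m{mut_counter}"
        mut_counter += 1
        own_mutations[cid].add(mid)
        mutations.append(
            MutationRecord(
                patient_id=pid,
                tumor_id=prim,
                clone_id=cid,
                gene=gene,
                effect=effect,
                generates_neoantigen=generates,
            )
        )
        return mid

    # oncogenic drivers: two clonal driver missense at the root (drivers are
    # early events), plus occasional subclonal driver hits that give the
    # likelihood clone-level variance in F_P
    add_mutation(clone_ids[0], "KRAS", "missense")
    add_mutation(clone_ids[0], "TP53", "missense")
    for cid in clone_ids[1:]:
        if rng.random() < config.subclonal_driver_prob:
            gene = DRIVER_GENE_ORDER[int(rng.integers(2, 4))]
            add_mutation(cid, gene, "missense")

    # passengers (for burden metrics) and neoantigens
    effects = ("missense", "synonymous", "nonsense")
    for cid in clone_ids:
        for _ in range(int(rng.integers(config.passengers_per_clone[0], config.passengers_per_clone[1] + 1))):
            add_mutation(cid, f"GENE{int(rng.integers(0, 5000)):04d}", effects[int(rng.choice(3, p=[0.7, 0.2, 0.1]))])
        n_na = int(rng.integers(config.neoantigens_per_clone[0], config.neoantigens_per_clone[1] + 1))
        for _ in range(n_na):
            p_wt = _random_peptide(rng, config.peptide_length)
            pos = int(rng.integers(1, config.peptide_length + 1))
            mt = rng.choice([a for a in AA_ALPHABET if a != p_wt[pos - 1]])
            p_mt = p_wt[: pos - 1] + mt + p_wt[pos:]
            lo, hi = config.kd_wt_range_nm
            kd_wt = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))
            lo, hi = config.kd_mt_range_nm
            kd_mt = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))
            gene = f"GENE{int(rng.integers(0, 5000)):04d}"
            add_mutation(cid, gene, "missense", generates=True)
            neoantigens.append(
                NeoantigenRecord(
                    patient_id=pid,
                    tumor_id=prim,
                    clone_id=cid,
                    p_wt=p_wt,
                    p_mt=p_mt,
                    hla="HLA-A*02:01",
                    kd_wt=kd_wt,
                    kd_mt=kd_mt,
                    gene=gene,
                )
            )

    qualities: dict[str, list[float]] = {}
    for rec_na in neoantigens:
        qualities.setdefault(rec_na.clone_id, []).append(quality(rec_na, params, model).Q)

    x_prim = rng.dirichlet(np.ones(n_clones))
    clones = [
        Clone(
            clone_id=cid,
            parent_id=parents[i],
            own_mutations=frozenset(own_mutations[cid]),
            frequencies={prim: float(x_prim[i])},
        )
        for i, cid in enumerate(clone_ids)
    ]
    tree = CloneTree(clones, sample_roles={prim: "primary", rec: "recurrent"})
    cov = clone_covariates(tree, qualities, mutations)
    f_i = cov["F_I"].to_numpy()
    f_p = cov["F_P"].to_numpy()
    fitness = -config.sigma_i * f_i + config.sigma_p * f_p
    x_hat = predict_recurrent(x_prim, fitness)
    if config.n_eff:
        counts = rng.multinomial(int(config.n_eff), x_hat)
        x_rec = counts / counts.sum()
    else:
        x_rec = x_hat
    for i, c in enumerate(tree.clones):
        c.frequencies[rec] = float(x_rec[i])

    max_q = max((q for qs in qualities.values() for q in qs), default=0.0)
    hazard = 0.05 * math.exp(config.survival_beta * max(max_q, 0.0))
    survival_time = float(rng.exponential(1.0 / hazard))
    survival_event = bool(rng.random() < 0.8)

    return SimulatedPatient(
        patient_id=pid,
        tree=tree,
        neoantigens=neoantigens,
        mutations=mutations,
        qualities=qualities,
        survival_time=survival_time,
        survival_event=survival_event,
        true_x_rec_expected=x_hat,
        f_i=f_i,
        f_p=f_p,
    )


def simulate_cohort(
    config: SimConfig, params: QualityParams, model: CrossReactModel
) -> Cohort:
    """Cohort of paired primary/recurrent tumours evolved under known selection.

    Clone trees grow by uniform attachment; primary fractions are symmetric
    Dirichlet; recurrent fractions follow the exponential propagation of the
    fitness model at (config.sigma_i, config.sigma_p) and are multinomially
    sampled at depth n_eff (set ``n_eff=None`` for the noiseless limit).
    Survival times are exponential with hazard increasing in the patient's
    maximum neoantigen quality.
    """
    root = np.random.SeedSequence(entropy=config.seed, spawn_key=(20,))
    children = root.spawn(config.n_patients)
    patients = [
        _simulate_patient(f"P{i:03d}", np.random.default_rng(children[i]), config, params, model)
        for i in range(config.n_patients)
    ]
    return Cohort(config=config, patients=patients, params=params, model=model)


# ---------------------------------------------------------------------------
# repertoires and fixture bundles
# ---------------------------------------------------------------------------


def simulate_repertoire(
    config: SimConfig,
    convergence: float,
    sample_id: str = "sample",
    n_clonotypes: int = 30,
    seed_cdr3: str = "CASSLAPGATNEKLFF",
    stream: int = 31,
) -> TcrRepertoire:
    """Repertoire whose top clonotypes are mutated copies of one seed CDR3beta.

    Each residue of the seed mutates with probability (1 - convergence);
    convergence 1 gives identical top clonotypes (dissimilarity 0). Counts are
    geometric, so expanded clones dominate.
    """
    if not 0.0 <= convergence <= 1.0:
        raise ValueError("convergence must lie in [0, 1]")
    rng = _rng(config, stream)
    p_mut = 1.0 - convergence
    clonotypes = []
    counts = np.sort(rng.geometric(0.05, size=n_clonotypes))[::-1]
    for i in range(n_clonotypes):
        seq = "".join(
            rng.choice([a for a in AA_ALPHABET if a != c]) if rng.random() < p_mut else c
            for c in seed_cdr3
        )
        clonotypes.append((seq, int(counts[i])))
    return TcrRepertoire(sample_id=sample_id, clonotypes=clonotypes)


def make_fixture_bundle(outdir, config: SimConfig, force: bool = False) -> dict:
    """Write one coherent mini-cohort in every supported format.

    Produces epitopes.fasta, xreact_model.json, neoantigens.tsv,
    mutations.tsv, trees/<patient>.json, dose_response.csv (a one-TCR scan),
    repertoires/<sample>.tsv and a config.yaml naming everything. Regeneration
    with the same seed is byte-identical. Refuses a non-empty directory unless
    ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True)")
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    (outdir / "repertoires").mkdir(exist_ok=True)

    params = default_quality_params(config)
    profile = default_true_profile(config.peptide_length)
    matrix = default_true_matrix(config.seed)
    model = CrossReactModel(matrix=matrix, profile=profile)
    cohort = simulate_cohort(config, params, model)

    write_epitope_fasta(params.epitope_set, outdir / "epitopes.fasta")
    model.to_json(outdir / "xreact_model.json")

    neo, muts = [], []
    tree_paths = {}
    for p in cohort.patients:
        neo.extend(p.neoantigens)
        muts.extend(p.mutations)
        path = outdir / "trees" / f"{p.patient_id}.json"
        write_clone_tree(p.tree, path)
        tree_paths[p.patient_id] = str(path.relative_to(outdir))
    write_neoantigen_table(neo, outdir / "neoantigens.tsv")
    write_mutation_table(muts, outdir / "mutations.tsv")

    scan_cfg = SimConfig(seed=config.seed, peptide_length=config.peptide_length,
                         noise_sd=config.noise_sd)
    curves, _ = simulate_substitution_scan(scan_cfg, profile, matrix, tcrs_per_peptide=1,
                                           reference_peptides=None)
    write_dose_response_csv(curves, outdir / "dose_response.csv")

    rep_paths = {}
    for i, p in enumerate(cohort.patients):
        sample = f"{p.patient_id}_rec"
        rep = simulate_repertoire(config, convergence=0.5, sample_id=sample, stream=40 + i)
        rpath = outdir / "repertoires" / f"{sample}.tsv"
        write_airr_repertoire(rep, rpath)
        rep_paths[sample] = str(rpath.relative_to(outdir))

    manifest = {
        "seed": config.seed,
        "epitopes": "epitopes.fasta",
        "xreact_model": "xreact_model.json",
        "neoantigens": "neoantigens.tsv",
        "mutations": "mutations.tsv",
        "trees": tree_paths,
        "repertoires": rep_paths,
        "dose_response": "dose_response.csv",
        "quality_params": {"w": params.w, "a": params.a, "k": params.k},
        "sigma_i": config.sigma_i,
        "sigma_p": config.sigma_p,
        "n_eff": config.n_eff,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
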