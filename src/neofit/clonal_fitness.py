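"""Clone-tree fitness model and maximum-likelihood inference of selection.

Each tumour clone alpha carries an immune fitness cost F_I (the maximum
neoantigen quality Q over the clone's genotype) and an oncogenic fitness gain
F_P (the count of missense mutations in canonical PDAC driver genes KRAS,
TP53, CDKN2A, SMAD4 in the genotype). The composite fitness is

    F = -sigma_I * F_I + sigma_P * F_P

and the clonal composition of the recurrent tumour is predicted from the
primary tumour by exponential propagation

    x_rec_hat = x_prim * exp(F) / Z,    Z = sum_beta x_prim_beta * exp(F_beta)

The selection amplitudes (sigma_I, sigma_P) >= 0 are fitted by maximising a
multinomial log-likelihood over observed recurrent clone fractions with an
effective sampling depth n_eff, and the full model is compared against an
oncogene-only model (sigma_I = 0) and a neutral model (no selection) with the
Bayesian information criterion BIC = kappa * ln(n_clones) - 2 * lnL.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import spearmanr

from .data_model import MutationRecord, NeoantigenRecord

DEFAULT_DRIVER_GENES = frozenset({"KRAS", "TP53", "CDKN2A", "SMAD4"})


@dataclass
class Clone:
    """One tumour clone: its private mutations and per-sample frequencies."""

    clone_id: str
    parent_id: Optional[str]
    own_mutations: frozenset = frozenset()
    frequencies: dict = field(default_factory=dict)

    def __post_init__(self):
        for sample, x in self.frequencies.items():
            if x < 0:
                raise ValueError(f"clone {self.clone_id}: negative frequency in {sample}")


class CloneTree:
    """Multisample clone hierarchy with per-sample frequencies.

    Genotypes are unions of ``own_mutations`` along the path from the root.
    Per-sample frequencies may sum to <1 (tumour purity); sums above 1 + 1e-6
    are rejected. ``sample_roles`` maps sample ids to "primary"/"recurrent".
    """

    _SUM_TOL = 1e-6

    def __init__(self, clones: Sequence[Clone], sample_roles: Optional[Mapping[str, str]] = None):
        self.clones = list(clones)
        self.sample_roles = dict(sample_roles or {})
        self._by_id = {c.clone_id: c for c in self.clones}
        if len(self._by_id) != len(self.clones):
            raise ValueError("duplicate clone ids")
        roots = [c for c in self.clones if c.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root clone, found {len(roots)}")
        self.root = roots[0]
        for c in self.clones:
            if c.parent_id is not None and c.parent_id not in self._by_id:
                raise ValueError(f"clone {c.clone_id}: orphan parent id {c.parent_id!r}")
        self._check_acyclic()
        sums: dict[str, float] = {}
        for c in self.clones:
            for sample, x in c.frequencies.items():
                sums[sample] = sums.get(sample, 0.0) + x
        for sample, s in sums.items():
            if s > 1.0 + self._SUM_TOL:
                raise ValueError(f"sample {sample!r}: clone frequencies sum to {s} > 1")
        self.samples = sorted(sums)

    def _check_acyclic(self):
        for c in self.clones:
            seen = set()
            cur = c
            while cur.parent_id is not None:
                if cur.clone_id in seen:
                    raise ValueError(f"cycle detected at clone {cur.clone_id}")
                seen.add(cur.clone_id)
                cur = self._by_id[cur.parent_id]

    def __getitem__(self, clone_id: str) -> Clone:
        return self._by_id[clone_id]

    def lineage(self, clone_id: str) -> list[str]:
        """Clone ids on the root -> clone path (inclusive)."""
        path = []
        cur = self._by_id[clone_id]
        while True:
            path.append(cur.clone_id)
            if cur.parent_id is None:
                break
            cur = self._by_id[cur.parent_id]
        return path[::-1]

    def genotype(self, clone_id: str) -> frozenset:
        out: set = set()
        for cid in self.lineage(clone_id):
            out |= self._by_id[cid].own_mutations
        return frozenset(out)

    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    def frequencies(self, sample: str, renormalize: bool = False) -> np.ndarray:
        x = np.array([c.frequencies.get(sample, 0.0) for c in self.clones], dtype=float)
        if renormalize:
            s = x.sum()
            if s <= 0:
                raise ValueError(f"sample {sample!r}: all clone frequencies are zero")
            x = x / s
        return x


# ---------------------------------------------------------------------------
# per-clone fitness components
# ---------------------------------------------------------------------------


def driver_fitness(
    tree: CloneTree,
    clone_id: str,
    mutations: Sequence[MutationRecord],
    driver_genes=DEFAULT_DRIVER_GENES,
) -> int:
    """F_P: missense mutations in driver genes within the clone genotype.

    Mutations are attributed to clones by their clone of origin; a clone
    inherits everything on its root path. Only missense events count.
    """
    lineage = set(tree.lineage(clone_id))
    return sum(
        1
        for m in mutations
        if m.clone_id in lineage and m.effect == "missense" and m.gene in driver_genes
    )


def immune_fitness_cost(
    tree: CloneTree, clone_id: str, qualities: Mapping[str, Sequence[float]]
) -> float:
    """F_I: maximum neoantigen quality Q over the clone genotype (0 if none).

    ``qualities`` maps a clone id (of origin) to the Q values of neoantigens
    arising in that clone.
    """
    qs = [q for cid in tree.lineage(clone_id) for q in qualities.get(cid, ())]
    return max(qs) if qs else 0.0


def clone_covariates(
    tree: CloneTree,
    qualities: Mapping[str, Sequence[float]],
    mutations: Sequence[MutationRecord],
    driver_genes=DEFAULT_DRIVER_GENES,
) -> pd.DataFrame:
    """Per-clone F_I and F_P in tree clone order."""
    rows = [
        {
            "clone_id": c.clone_id,
            "F_I": immune_fitness_cost(tree, c.clone_id, qualities),
            "F_P": driver_fitness(tree, c.clone_id, mutations, driver_genes),
        }
        for c in tree.clones
    ]
    return pd.DataFrame(rows)


@dataclass
class FitnessParams:
    """Selection amplitudes: immune cost sigma_I and oncogenic gain sigma_P (>= 0)."""

    sigma_i: float
    sigma_p: float
    driver_genes: frozenset = DEFAULT_DRIVER_GENES

    def __post_init__(self):
        if self.sigma_i < 0 or self.sigma_p < 0:
            raise ValueError("selection amplitudes must be non-negative")


def clone_fitness(f_i: float, f_p: float, params: FitnessParams) -> float:
    """F = -sigma_I * F_I + sigma_P * F_P."""
    return -params.sigma_i * f_i + params.sigma_p * f_p


def predict_recurrent(x_prim: np.ndarray, fitness: np.ndarray) -> np.ndarray:
    """Exponential propagation of primary clone fractions under fitness F.

    ``x_prim`` is renormalised over clones; the output sums to 1 (to 1e-12).
    Computed in log space so large |F| cannot overflow.
    """
    x = np.asarray(x_prim, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative primary frequencies")
    s = x.sum()
    if s <= 0:
        raise ValueError("all primary frequencies are zero")
    x = x / s
    f = np.asarray(fitness, dtype=float)
    if np.all(f == f[0]):  # constant fitness cancels exactly against Z
        return x
    with np.errstate(divide="ignore"):
        logw = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)) + f, -np.inf)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def predict_recurrent_frequencies(
    tree: CloneTree,
    params: FitnessParams,
    qualities: Mapping[str, Sequence[float]],
    mutations: Sequence[MutationRecord],
    primary_sample: str,
) -> dict[str, float]:
    """Predicted recurrent fraction per clone from one primary sample."""
    cov = clone_covariates(tree, qualities, mutations, params.driver_genes)
    f = -params.sigma_i * cov["F_I"].to_numpy() + params.sigma_p * cov["F_P"].to_numpy()
    x_prim = tree.frequencies(primary_sample)
    x_hat = predict_recurrent(x_prim, f)
    return dict(zip(tree.clone_ids(), x_hat))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting and model comparison
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Fitting configuration.

    n_eff: effective multinomial sampling depth of the likelihood.
    sampling_threshold: clones with primary frequency at or below this are
        excluded from the likelihood (new clones in the recurrent tumour are
        always excluded: Eq. 3 only propagates primary clones).
    starts: per-axis multi-start grid for the bounded quasi-Newton optimiser.
    """

    n_eff: float = 100.0
    sampling_threshold: float = 0.0
    starts: tuple[float, ...] = (0.0, 1.0, 10.0)


@dataclass
class FitResult:
    params: FitnessParams
    log_likelihood: float
    bic_full: float
    bic_oncogenic_only: float
    bic_neutral: float
    preferred_model: str
    n_clones_used: int
    sigma_p_oncogenic_only: float = 0.0

    @property
    def bics(self) -> dict[str, float]:
        return {
            "full": self.bic_full,
            "oncogenic_only": self.bic_oncogenic_only,
            "neutral": self.bic_neutral,
        }


def _multinomial_loglik(sigma: np.ndarray, x_prim, x_rec, f_i, f_p, n_eff) -> float:
    f = -sigma[0] * f_i + sigma[1] * f_p
    x_hat = predict_recurrent(x_prim, f)
    mask = x_rec > 0
    if np.any(x_hat[mask] <= 0):
        return -1e15  # finite sentinel keeps numerical gradients defined
    return float(n_eff * np.sum(x_rec[mask] * np.log(x_hat[mask])))


def fit_params(
    x_prim: np.ndarray,
    x_rec: np.ndarray,
    f_i: np.ndarray,
    f_p: np.ndarray,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Maximum-likelihood (sigma_I, sigma_P) with BIC model comparison.

    ``x_prim``/``x_rec`` are per-clone fractions in the primary and recurrent
    samples (same clone order as ``f_i``/``f_p``). Clones without primary
    support are dropped and both fraction vectors renormalised before fitting.
    """
    cfg = config or FitConfig()
    x_prim = np.asarray(x_prim, dtype=float)
    x_rec = np.asarray(x_rec, dtype=float)
    f_i = np.asarray(f_i, dtype=float)
    f_p = np.asarray(f_p, dtype=float)
    keep = x_prim > cfg.sampling_threshold
    n = int(keep.sum())
    if n < 2:
        warnings.warn("fewer than 2 usable clones: likelihood is flat, returning neutral", stacklevel=2)
        return FitResult(
            params=FitnessParams(0.0, 0.0),
            log_likelihood=0.0,
            bic_full=math.inf,
            bic_oncogenic_only=math.inf,
            bic_neutral=0.0,
            preferred_model="neutral",
            n_clones_used=n,
        )
    x_prim = x_prim[keep] / x_prim[keep].sum()
    xr = x_rec[keep]
    if xr.sum() <= 0:
        raise ValueError("no recurrent mass on propagated clones")
    xr = xr / xr.sum()
    fi, fp = f_i[keep], f_p[keep]

    def neg(sigma, mask=(True, True)):
        s = np.array([sigma[0] if mask[0] else 0.0, sigma[-1] if mask[1] else 0.0])
        return -_multinomial_loglik(s, x_prim, xr, fi, fp, cfg.n_eff)

    def optimize(mask):
        ndim = sum(mask)
        best = None
        for start in itertools.product(cfg.starts, repeat=ndim):
            res = minimize(
                lambda s: neg(s, mask),
                np.array(start, dtype=float),
                method="L-BFGS-B",
                bounds=[(0.0, None)] * ndim,
                options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    full = optimize((True, True))
    onco = optimize((False, True))
    ll_full = -float(full.fun)
    ll_onco = -float(onco.fun)
    ll_neutral = _multinomial_loglik(np.zeros(2), x_prim, xr, fi, fp, cfg.n_eff)

    logn = math.log(n)
    bics = {
        "full": 2 * logn - 2 * ll_full,
        "oncogenic_only": 1 * logn - 2 * ll_onco,
        "neutral": 0.0 - 2 * ll_neutral,
    }
    preferred = min(bics, key=lambda k: (bics[k], ("full", "oncogenic_only", "neutral").index(k)))
    return FitResult(
        params=FitnessParams(sigma_i=float(full.x[0]), sigma_p=float(full.x[1])),
        log_likelihood=ll_full,
        bic_full=bics["full"],
        bic_oncogenic_only=bics["oncogenic_only"],
        bic_neutral=bics["neutral"],
        preferred_model=preferred,
        n_clones_used=n,
        sigma_p_oncogenic_only=float(onco.x[0]),
    )


def fit_params_pooled(
    datasets: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Joint maximum likelihood over several primary -> recurrent tumour pairs.

    The selection amplitudes are shared across tumours while each tumour keeps
    its own normalisation Z; the log-likelihood is the sum of per-tumour
    multinomial terms. ``datasets`` holds (x_prim, x_rec, f_i, f_p) per
    tumour. BIC uses the total clone count entering the likelihood.
    """
    cfg = config or FitConfig()
    prepared = []
    for x_prim, x_rec, f_i, f_p in datasets:
        x_prim = np.asarray(x_prim, dtype=float)
        keep = x_prim > cfg.sampling_threshold
        if keep.sum() < 2:
            continue
        xp = x_prim[keep] / x_prim[keep].sum()
        xr = np.asarray(x_rec, dtype=float)[keep]
        if xr.sum() <= 0:
            continue
        prepared.append((xp, xr / xr.sum(), np.asarray(f_i)[keep], np.asarray(f_p)[keep]))
    if not prepared:
        raise ValueError("no usable tumour pairs")
    n = sum(len(d[0]) for d in prepared)

    def loglik(sigma):
        return sum(_multinomial_loglik(sigma, *d, cfg.n_eff) for d in prepared)

    def optimize(mask):
        ndim = sum(mask)
        best = None
        for start in itertools.product(cfg.starts, repeat=ndim):
            res = minimize(
                lambda s: -loglik(
                    np.array([s[0] if mask[0] else 0.0, s[-1] if mask[1] else 0.0])
                ),
                np.array(start, dtype=float),
                method="L-BFGS-B",
                bounds=[(0.0, None)] * ndim,
                options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    full = optimize((True, True))
    onco = optimize((False, True))
    ll_full, ll_onco = -float(full.fun), -float(onco.fun)
    ll_neutral = loglik(np.zeros(2))
    logn = math.log(n)
    bics = {
        "full": 2 * logn - 2 * ll_full,
        "oncogenic_only": 1 * logn - 2 * ll_onco,
        "neutral": 0.0 - 2 * ll_neutral,
    }
    preferred = min(bics, key=lambda k: (bics[k], ("full", "oncogenic_only", "neutral").index(k)))
    return FitResult(
        params=FitnessParams(sigma_i=float(full.x[0]), sigma_p=float(full.x[1])),
        log_likelihood=ll_full,
        bic_full=bics["full"],
        bic_oncogenic_only=bics["oncogenic_only"],
        bic_neutral=bics["neutral"],
        preferred_model=preferred,
        n_clones_used=n,
        sigma_p_oncogenic_only=float(onco.x[0]),
    )


def fit_tree(
    tree: CloneTree,
    qualities: Mapping[str, Sequence[float]],
    mutations: Sequence[MutationRecord],
    primary_sample: str,
    recurrent_sample: str,
    config: Optional[FitConfig] = None,
    driver_genes=DEFAULT_DRIVER_GENES,
) -> FitResult:
    """Fit selection amplitudes on one primary -> recurrent tumour pair."""
    cov = clone_covariates(tree, qualities, mutations, driver_genes)
    return fit_params(
        tree.frequencies(primary_sample),
        tree.frequencies(recurrent_sample),
        cov["F_I"].to_numpy(),
        cov["F_P"].to_numpy(),
        config,
    )


def evaluate_frequency_changes(
    x_prim: np.ndarray,
    x_rec: np.ndarray,
    x_rec_hat: np.ndarray,
    clone_ids: Optional[Sequence[str]] = None,
    threshold: float = 0.03,
    pseudocount: Optional[float] = None,
):
    """Observed vs fitted clone frequency changes above the sampling threshold.

    Restricted to clones with primary frequency above ``threshold`` (default
    3%). Frequencies below the threshold are replaced by ``pseudocount``
    (default threshold/2) before forming the ratios x_rec/x_prim and
    x_rec_hat/x_prim. Returns a per-clone table plus a summary with the
    direction-agreement fraction (clones whose observed or fitted log-ratio is
    exactly 0 count as "unchanged" and leave the denominator) and the
    two-tailed Spearman rank correlation of the log-ratios.
    """
    if pseudocount is None:
        pseudocount = threshold / 2.0
    x_prim = np.asarray(x_prim, dtype=float)
    x_rec = np.asarray(x_rec, dtype=float)
    x_rec_hat = np.asarray(x_rec_hat, dtype=float)
    keep = x_prim > threshold
    if not keep.any():
        raise ValueError(f"no clones above the {threshold} primary-frequency threshold")
    ids = list(np.asarray(clone_ids)[keep]) if clone_ids is not None else [
        str(i) for i in np.where(keep)[0]
    ]

    def ratio(x_num, x_den):
        num = np.where(x_num < threshold, pseudocount, x_num)
        return num / x_den

    obs = ratio(x_rec[keep], x_prim[keep])
    fit = ratio(x_rec_hat[keep], x_prim[keep])
    log_obs = np.log(obs)
    log_fit = np.log(fit)
    table = pd.DataFrame(
        {
            "clone_id": ids,
            "x_prim": x_prim[keep],
            "x_rec": x_rec[keep],
            "x_rec_hat": x_rec_hat[keep],
            "log_ratio_obs": log_obs,
            "log_ratio_fit": log_fit,
        }
    )
    decided = (log_obs != 0) & (log_fit != 0)
    if decided.any():
        agreement = float(np.mean(np.sign(log_obs[decided]) == np.sign(log_fit[decided])))
    else:
        agreement = math.nan
    if len(log_obs) > 1 and np.ptp(log_obs) > 0 and np.ptp(log_fit) > 0:
        rho, pval = spearmanr(log_obs, log_fit)
    else:
        rho, pval = math.nan, math.nan
    summary = {
        "n_clones": int(keep.sum()),
        "n_directional": int(decided.sum()),
        "direction_agreement": agreement,
        "spearman_rho": float(rho) if rho == rho else math.nan,
        "spearman_p": float(pval) if pval == pval else math.nan,
    }
    return table, summary
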