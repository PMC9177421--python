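"""Tumour- and cohort-level immunoediting statistics.

Per-tumour summaries (clonal Shannon entropy, tumour mutational burden,
neoantigen counts, frequency-weighted mean immune fitness cost), paired
primary -> recurrent deltas including new-clone metrics, depletion analyses
(empirical CDFs with two-sided Kolmogorov-Smirnov tests) and the regression of
observed amino-acid substitution frequencies on matrix-defined substitution
distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clonal_fitness import CloneTree, immune_fitness_cost
from .cross_reactivity import SubstitutionMatrix
from .data_model import MutationRecord, NeoantigenRecord

#: clone counted as present in a sample above this frequency
DEFAULT_PRESENCE_THRESHOLD = 0.01
#: conventional MHC-I binder cutoff on Kd (nM)
DEFAULT_BINDER_THRESHOLD_NM = 500.0


def shannon_entropy(frequencies, base: Optional[float] = None) -> float:
    """Shannon entropy of clone frequencies in nats (0 log 0 = 0).

    Frequencies are renormalised to sum to 1. ``base=2`` gives bits for
    display.
    """
    x = np.asarray(frequencies, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative frequencies")
    s = x.sum()
    if s <= 0:
        raise ValueError("all-zero frequency vector")
    x = x[x > 0] / s
    h = float(-(x * np.log(x)).sum())
    if base is not None:
        h /= math.log(base)
    return h


@dataclass
class TumorSummary:
    tumor_id: str
    role: str
    shannon_entropy: float
    tmb: int
    na_count: int
    na_mut_count: int
    mean_immune_cost: float


def summarize_tumor(
    sample_id: str,
    tree: CloneTree,
    mutations: Sequence[MutationRecord],
    neoantigens: Sequence[NeoantigenRecord],
    qualities: Mapping[str, Sequence[float]],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    binder_threshold_nm: float = DEFAULT_BINDER_THRESHOLD_NM,
    weighted_immune_cost: bool = True,
) -> TumorSummary:
    """Per-tumour summary statistics for one sample of a clone tree.

    TMB counts non-synonymous mutations whose clone of origin lies on the
    lineage of any clone present in the sample (frequency > presence
    threshold). Neoantigen counts keep records with kd_mt below the binder
    threshold in present clones; ``na_mut_count`` collapses them to distinct
    (gene, peptide pair) mutations. The mean immune cost is the
    clone-frequency-weighted mean of F_I over present clones (unweighted
    available via ``weighted_immune_cost=False``).
    """
    if sample_id not in tree.samples:
        raise ValueError(f"sample {sample_id!r} not present in clone tree")
    x = tree.frequencies(sample_id)
    present = {
        cid for cid, xi in zip(tree.clone_ids(), x) if xi > presence_threshold
    }
    present_lineage: set[str] = set()
    for cid in present:
        present_lineage.update(tree.lineage(cid))

    tmb = sum(
        1 for m in mutations if m.effect != "synonymous" and m.clone_id in present_lineage
    )
    binders = [
        r
        for r in neoantigens
        if r.clone_id in present_lineage and r.kd_mt < binder_threshold_nm
    ]
    na_count = len(binders)
    na_mut_count = len({(r.gene, r.p_wt, r.p_mt) for r in binders})

    costs = np.array(
        [immune_fitness_cost(tree, c.clone_id, qualities) for c in tree.clones]
    )
    mask = x > presence_threshold
    if not mask.any():
        mean_cost = 0.0
    elif weighted_immune_cost:
        mean_cost = float((x[mask] * costs[mask]).sum() / x[mask].sum())
    else:
        mean_cost = float(costs[mask].mean())

    return TumorSummary(
        tumor_id=sample_id,
        role=tree.sample_roles.get(sample_id, "unknown"),
        shannon_entropy=shannon_entropy(x),
        tmb=tmb,
        na_count=na_count,
        na_mut_count=na_mut_count,
        mean_immune_cost=mean_cost,
    )


@dataclass
class PairedDelta:
    """Recurrent-minus-primary differences for one patient."""

    patient_id: str
    delta_entropy: float
    delta_tmb: int
    delta_na: int
    delta_na_mut: int
    pct_new_neoantigens: float
    new_clone_mean_immune_cost: float
    n_new_clones: int
    pct_new_defined: bool = True


def paired_deltas(
    patient_id: str,
    tree: CloneTree,
    primary_summary: TumorSummary,
    recurrent_summary: TumorSummary,
    neoantigens: Sequence[NeoantigenRecord],
    qualities: Mapping[str, Sequence[float]],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    binder_threshold_nm: float = DEFAULT_BINDER_THRESHOLD_NM,
) -> PairedDelta:
    """Paired primary -> recurrent deltas on a joint clone tree.

    New clones are present in the recurrent sample (frequency > threshold) but
    not in the primary. ``pct_new_neoantigens`` is the share of recurrent
    binder neoantigens private to new clones, in percent; with no recurrent
    neoantigens it is defined as 0 and flagged.
    """
    prim, rec = primary_summary.tumor_id, recurrent_summary.tumor_id
    x_prim = dict(zip(tree.clone_ids(), tree.frequencies(prim)))
    x_rec = dict(zip(tree.clone_ids(), tree.frequencies(rec)))
    new_clones = {
        cid
        for cid in tree.clone_ids()
        if x_rec[cid] > presence_threshold and x_prim[cid] <= presence_threshold
    }

    rec_present = {cid for cid in tree.clone_ids() if x_rec[cid] > presence_threshold}
    rec_lineage: set[str] = set()
    for cid in rec_present:
        rec_lineage.update(tree.lineage(cid))
    rec_binders = [
        r for r in neoantigens if r.clone_id in rec_lineage and r.kd_mt < binder_threshold_nm
    ]
    # neoantigens private to new clones: origin clone is new (not on any
    # primary-present lineage)
    new_private = [r for r in rec_binders if r.clone_id in new_clones]
    if rec_binders:
        pct_new = 100.0 * len(new_private) / len(rec_binders)
        pct_defined = True
    else:
        pct_new, pct_defined = 0.0, False

    if new_clones:
        new_cost = float(
            np.mean([immune_fitness_cost(tree, cid, qualities) for cid in sorted(new_clones)])
        )
    else:
        new_cost = 0.0

    return PairedDelta(
        patient_id=patient_id,
        delta_entropy=recurrent_summary.shannon_entropy - primary_summary.shannon_entropy,
        delta_tmb=recurrent_summary.tmb - primary_summary.tmb,
        delta_na=recurrent_summary.na_count - primary_summary.na_count,
        delta_na_mut=recurrent_summary.na_mut_count - primary_summary.na_mut_count,
        pct_new_neoantigens=pct_new,
        new_clone_mean_immune_cost=new_cost,
        n_new_clones=len(new_clones),
        pct_new_defined=pct_defined,
    )


# ---------------------------------------------------------------------------
# depletion statistics
# ---------------------------------------------------------------------------


def ecdf(values: np.ndarray) -> pd.DataFrame:
    """Empirical CDF as a (value, cumulative_probability) table."""
    v = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"value": v, "cdf": np.arange(1, len(v) + 1) / len(v)})


def depletion_analysis(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    statistics: Sequence[str] = ("logC", "D"),
) -> dict[str, dict]:
    """Compare score distributions of two neoantigen groups.

    For each named column, returns both groups' empirical CDFs and the
    two-sided Kolmogorov-Smirnov statistic/p-value. Used to test whether one
    cohort depletes high-distance (less self) neoantigens more than another.
    """
    out = {}
    for stat in statistics:
        for name, df in (("A", scores_a), ("B", scores_b)):
            if stat not in df.columns or df[stat].dropna().size < 2:
                raise ValueError(f"group {name}: fewer than 2 values for statistic {stat!r}")
        a = scores_a[stat].dropna().to_numpy()
        b = scores_b[stat].dropna().to_numpy()
        ks = stats.ks_2samp(a, b, alternative="two-sided")
        out[stat] = {
            "ecdf_a": ecdf(a),
            "ecdf_b": ecdf(b),
            "ks_statistic": float(ks.statistic),
            "p_value": float(ks.pvalue),
        }
    return out


def substitution_frequency_regression(
    substitution_counts: Mapping[tuple[str, str], float], matrix: SubstitutionMatrix
) -> dict[str, float]:
    """Regress observed substitution proportions on matrix distance.

    ``substitution_counts`` maps (wt_residue, mt_residue) to observed counts
    in a cohort. Counts are normalised to proportions and regressed linearly
    on the matrix-defined distance; returns slope, intercept, two-tailed
    Pearson r and p.
    """
    pairs = [(a, b) for (a, b) in substitution_counts if a != b]
    if len(pairs) < 3:
        raise ValueError("need at least 3 distinct substitution types")
    counts = np.array([substitution_counts[p] for p in pairs], dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all substitution counts are zero")
    prop = counts / total
    dist = np.array([matrix[a, b] for a, b in pairs])
    res = stats.linregress(dist, prop)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "pearson_r": float(res.rvalue),
        "p_value": float(res.pvalue),
        "n": len(pairs),
    }


def group_comparison(values_a, values_b) -> dict[str, float]:
    """Two-tailed Mann-Whitney U comparison of two tumour groups."""
    res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return {"u_statistic": float(res.statistic), "p_value": float(res.pvalue)}
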