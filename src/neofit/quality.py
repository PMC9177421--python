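"""Neoantigen quality Q = R x D.

R (recognition potential) scores how similar the mutant peptide is to known
immunogenic epitopes — a proxy for lying inside the recognition space of the
TCR repertoire. It aggregates gapless alignment scores s_e of the mutant
peptide against every epitope e through a logistic-saturated sum:

    R = Z**-1 * sum_e exp(-k * (a - s_e)),   Z = 1 + sum_e exp(-k * (a - s_e))

with displacement ``a`` (alignment-score units) and steepness ``k``.

D (self discrimination) measures the antigenic distance of the mutant from its
wild-type peptide — a proxy for escaping the toleration space:

    D = (1 - w) * log(Kd_WT / Kd_MT) + w * log C(p_WT, p_MT)

combining the MHC amplitude A = Kd_WT/Kd_MT with the TCR cross-reactivity
distance C predicted by a :class:`~neofit.cross_reactivity.CrossReactModel`.
Natural logarithms throughout. Quality is the product Q = R * D.

Model parameters (w, a, k) are selected on a survival cohort by maximising the
log-rank test score of the split at the cohort median of a per-patient quality
summary.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from lifelines.statistics import logrank_test
from scipy.special import expit, logsumexp

from .cross_reactivity import CrossReactModel, predict_logC
from .data_model import EpitopeSet, NeoantigenRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gapless_alignment_score(a: str, b: str) -> float:
    """Best ungapped window score of the shorter sequence against the longer.

    All full-containment offsets of the shorter sequence are scored by summing
    BLOSUM62 residue scores; the maximum is returned.
    """
    if len(a) > len(b):
        a, b = b, a
    n, m = len(a), len(b)
    best = -math.inf
    for off in range(m - n + 1):
        s = sum(BLOSUM62[a[i], b[off + i]] for i in range(n))
        if s > best:
            best = s
    return float(best)


@dataclass
class QualityParams:
    """Recognition-potential parameters and the amplitude/cross-reactivity weight.

    ``w`` in [0, 1] interpolates D between pure MHC amplitude (w=0) and pure
    cross-reactivity (w=1). ``a`` displaces and ``k`` (>0) steepens the
    recognition logistic. Fitted values are cohort-specific and must be
    supplied by the user; there is no universal default.
    """

    w: float
    a: float
    k: float
    epitope_set: EpitopeSet = field(default_factory=EpitopeSet)

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass(frozen=True)
class QualityScore:
    R: float
    logA: float
    logC: float
    D: float
    Q: float
    best_epitope_id: Optional[str] = None


def _epitope_scores(p_mt: str, epitopes: EpitopeSet) -> np.ndarray:
    return np.array([gapless_alignment_score(p_mt, seq) for seq in epitopes.sequences()])


def recognition_potential(p_mt: str, params: QualityParams) -> tuple[float, Optional[str]]:
    """R of a mutant peptide and the id of its best-aligned epitope.

    Computed stably as expit(logsumexp(k * (s_e - a))), identical to the
    defining sum/(1 + sum) form.
    """
    if len(params.epitope_set) == 0:
        warnings.warn("empty epitope set: recognition potential is 0", stacklevel=2)
        return 0.0, None
    scores = _epitope_scores(p_mt, params.epitope_set)
    r = float(expit(logsumexp(params.k * (scores - params.a))))
    best = params.epitope_set.ids()[int(np.argmax(scores))]
    return r, best


def self_discrimination(
    record: NeoantigenRecord, model: CrossReactModel, w: float
) -> tuple[float, float, float]:
    """(logA, logC, D) for one neoantigen under Eq. D = (1-w) logA + w logC."""
    log_a = math.log(record.kd_wt / record.kd_mt)
    log_c = predict_logC(record.p_wt, record.p_mt, model)
    return log_a, log_c, (1.0 - w) * log_a + w * log_c


def quality(
    record: NeoantigenRecord, params: QualityParams, model: CrossReactModel
) -> QualityScore:
    """Full quality score Q = R x D with all components recorded."""
    r, best = recognition_potential(record.p_mt, params)
    log_a, log_c, d = self_discrimination(record, model, params.w)
    return QualityScore(R=r, logA=log_a, logC=log_c, D=d, Q=r * d, best_epitope_id=best)


def quality_table(
    records: Sequence[NeoantigenRecord], params: QualityParams, model: CrossReactModel
) -> pd.DataFrame:
    """One row per neoantigen with all quality components."""
    rows = []
    for rec in records:
        s = quality(rec, params, model)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "tumor_id": rec.tumor_id,
                "clone_id": rec.clone_id,
                "p_wt": rec.p_wt,
                "p_mt": rec.p_mt,
                "hla": rec.hla,
                "R": s.R,
                "logA": s.logA,
                "logC": s.logC,
                "D": s.D,
                "Q": s.Q,
                "best_epitope_id": s.best_epitope_id,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PatientSurvival:
    """One patient's neoantigens with overall-survival follow-up."""

    patient_id: str
    time: float
    event: bool
    records: list[NeoantigenRecord] = field(default_factory=list)


def select_params_by_logrank(
    patients: Sequence[PatientSurvival],
    epitope_set: EpitopeSet,
    model: CrossReactModel,
    grid: Iterable[tuple[float, float, float]],
    summary: str = "max",
):
    """Grid search (w, a, k) maximising the log-rank statistic of the median split.

    For each grid point the per-patient summary quality (``max`` or ``mean``
    of Q over the patient's neoantigens; 0 for patients with none) splits the
    cohort at its median; the two-sided log-rank test statistic scores the
    point. Degenerate splits (an empty arm) score -inf. Ties are broken by the
    lexicographically smallest (w, a, k). Returns ``(best_params,
    score_table)``.
    """
    grid = sorted(set(tuple(map(float, g)) for g in grid))
    if not grid:
        raise ValueError("empty parameter grid")
    if not any(p.event for p in patients):
        raise ValueError("all-censored cohort: log-rank score undefined")
    if summary not in ("max", "mean"):
        raise ValueError("summary must be 'max' or 'mean'")

    # alignment scores and (logA, logC) do not depend on (w, a, k): precompute
    pre = []
    for p in patients:
        recs = []
        for rec in p.records:
            scores = _epitope_scores(rec.p_mt, epitope_set) if len(epitope_set) else np.array([])
            log_a = math.log(rec.kd_wt / rec.kd_mt)
            log_c = predict_logC(rec.p_wt, rec.p_mt, model)
            recs.append((scores, log_a, log_c))
        pre.append(recs)

    times = np.array([p.time for p in patients], dtype=float)
    events = np.array([bool(p.event) for p in patients])

    rows = []
    best = None
    agg = np.max if summary == "max" else np.mean
    for w, a, k in grid:
        summaries = np.empty(len(patients))
        for idx, recs in enumerate(pre):
            if not recs:
                summaries[idx] = 0.0
                continue
            qs = []
            for scores, log_a, log_c in recs:
                r = float(expit(logsumexp(k * (scores - a)))) if scores.size else 0.0
                qs.append(r * ((1.0 - w) * log_a + w * log_c))
            summaries[idx] = agg(qs)
        median = float(np.median(summaries))
        high = summaries > median
        if high.all() or (~high).all():
            score = -math.inf
        else:
            res = logrank_test(times[~high], times[high], events[~high], events[high])
            score = float(res.test_statistic)
        rows.append({"w": w, "a": a, "k": k, "score": score})
        if best is None or score > best[0]:
            best = (score, (w, a, k))

    table = pd.DataFrame(rows)
    w, a, k = best[1]
    return QualityParams(w=w, a=a, k=k, epitope_set=epitope_set), table


def make_grid(ws, as_, ks):
    """Cartesian (w, a, k) grid from per-parameter value lists."""
    return list(itertools.product(ws, as_, ks))
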