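"""Hill curve fitting of TCR activation titrations and EC50 cross-reactivity ratios.

T cell activation against a titrated peptide is modelled as an increasing
four-parameter Hill curve

    response(c) = baseline + emax / (1 + (ec50 / c) ** h)

fitted in log10-concentration space. The cross-reactivity distance between a
mutant and its wild-type peptide for one TCR is C = EC50_MT / EC50_WT; this
module returns log C (natural log). Peptides that never activate within the
tested range are censored: their EC50 is pinned to the highest tested
concentration times ``censor_factor`` so that log C stays finite but capped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .data_model import DoseResponseCurve


@dataclass
class HillConfig:
    """Fitting configuration.

    bound_factor: EC50 is constrained to the tested range x/÷ this factor.
    censor_factor: censored EC50 = max tested concentration x this factor.
    activation_floor: fraction of the reference (same-TCR wild type) emax
        below which a fitted curve is classified as non-activating.
    n_starts: number of EC50 initialisations spread across the tested range.
    """

    bound_factor: float = 100.0
    censor_factor: float = 10.0
    activation_floor: float = 0.1
    n_starts: int = 3
    h_bounds: tuple[float, float] = (0.5, 5.0)


@dataclass
class HillFit:
    ec50: float  # molar
    hill_coefficient: float
    emax: float
    baseline: float
    censored: bool
    rss: float
    n_points: int


def _hill(log10_conc: np.ndarray, baseline: float, emax: float, log10_ec50: float, h: float):
    return baseline + emax / (1.0 + 10.0 ** (h * (log10_ec50 - log10_conc)))


def fit_hill(
    curve: DoseResponseCurve,
    config: Optional[HillConfig] = None,
    reference_emax: Optional[float] = None,
) -> HillFit:
    """Least-squares Hill fit of one titration curve.

    Multi-start over EC50 initial values with best-RSS selection. When
    ``reference_emax`` (the same-TCR wild-type emax) is given, fits with
    emax below ``activation_floor * reference_emax`` are censored; a flat
    curve or a failed fit is always censored.
    """
    cfg = config or HillConfig()
    conc = np.asarray(curve.concentrations, dtype=float)
    resp = np.asarray(curve.responses, dtype=float)
    n = len(conc)
    x = np.log10(conc)
    cmax = conc[-1]
    span = resp.max() - resp.min()

    lo = np.array([resp.min() - max(span, 1e-12), 0.0, np.log10(conc[0] / cfg.bound_factor), cfg.h_bounds[0]])
    hi = np.array(
        [resp.max() + max(span, 1e-12), 10.0 * max(span, abs(resp).max(), 1e-12),
         np.log10(cmax * cfg.bound_factor), cfg.h_bounds[1]]
    )

    best = None
    if span > 0:
        starts = np.quantile(x, np.linspace(0.2, 0.8, cfg.n_starts))
        for le0 in starts:
            p0 = np.array([resp.min(), span, le0, 1.0])
            p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)
            try:
                sol = least_squares(
                    lambda p: _hill(x, *p) - resp, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
                )
            except Exception:  # numerical failure on a pathological start
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)

    if best is None:  # flat or unfittable curve
        baseline = float(resp.mean())
        return HillFit(
            ec50=cmax * cfg.censor_factor,
            hill_coefficient=1.0,
            emax=0.0,
            baseline=baseline,
            censored=True,
            rss=float(np.sum((resp - baseline) ** 2)),
            n_points=n,
        )

    rss, (baseline, emax, log10_ec50, h) = best
    censored = reference_emax is not None and emax < cfg.activation_floor * reference_emax
    ec50 = cmax * cfg.censor_factor if censored else float(10.0**log10_ec50)
    return HillFit(
        ec50=ec50,
        hill_coefficient=float(h),
        emax=float(emax),
        baseline=float(baseline),
        censored=bool(censored),
        rss=float(rss),
        n_points=n,
    )


@dataclass(frozen=True)
class CrossReactivityRatio:
    """log C = log(EC50_MT / EC50_WT), natural log, with censoring flag."""

    log_c: float
    censored: bool


def cross_reactivity_ratio(fit_mt: HillFit, fit_wt: HillFit) -> CrossReactivityRatio:
    """Observed cross-reactivity distance of one mutant peptide for one TCR.

    Both fits must come from the same TCR. A censored mutant fit returns the
    capped value implied by the censoring rule; a censored wild-type fit is an
    error because C has no reference.
    """
    if fit_wt.censored:
        raise ValueError("reference epitope non-activating for this TCR")
    return CrossReactivityRatio(
        log_c=math.log(fit_mt.ec50 / fit_wt.ec50), censored=fit_mt.censored
    )


def fit_scan(curves: Sequence[DoseResponseCurve], config: Optional[HillConfig] = None):
    """Fit a whole substitution scan and extract per-variant observed log C.

    For each TCR the curve with ``position is None`` is the reference
    (wild-type) peptide. Returns a list of observation dicts
    (tcr_id, position, wt_residue, mt_residue, log_c, censored) suitable for
    :func:`neofit.cross_reactivity.build_model`, plus the per-curve fits.
    """
    cfg = config or HillConfig()
    by_tcr: dict[str, list[DoseResponseCurve]] = {}
    for c in curves:
        by_tcr.setdefault(c.tcr_id, []).append(c)
    observations = []
    fits = []
    for tcr_id in sorted(by_tcr):
        group = by_tcr[tcr_id]
        refs = [c for c in group if c.position is None]
        if len(refs) != 1:
            raise ValueError(f"TCR {tcr_id!r}: expected exactly one reference curve, got {len(refs)}")
        ref_fit = fit_hill(refs[0], cfg)
        fits.append((refs[0], ref_fit))
        if ref_fit.censored:
            raise ValueError(f"reference epitope non-activating for TCR {tcr_id!r}")
        for c in group:
            if c.position is None:
                continue
            f = fit_hill(c, cfg, reference_emax=ref_fit.emax)
            fits.append((c, f))
            ratio = cross_reactivity_ratio(f, ref_fit)
            observations.append(
                {
                    "tcr_id": tcr_id,
                    "position": c.position,
                    "wt_residue": c.wt_residue,
                    "mt_residue": c.mt_residue,
                    "log_c": ratio.log_c,
                    "censored": ratio.censored,
                }
            )
    return observations, fits
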