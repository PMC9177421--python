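"""Substitution-matrix model of TCR cross-reactivity distance.

The observed log cross-reactivity distance of a single amino-acid
substitution a -> b at peptide position i is decomposed multiplicatively:

    log C(i, a -> b)  ~  w_i * M[a][b]

where ``M`` is a 20 x 20 directional residue-substitution matrix (identity
cells pinned to 0) and ``w`` a per-position weight profile. Both are learned
from pooled EC50 substitution scans by alternating least squares. The scale
degeneracy (w*M vs (cw)*(M/c)) is resolved by normalising the mean of the
interior-position weights to 1.

Residue clustering of the learned matrix (average-linkage agglomerative
clustering of the symmetrised matrix rows) groups residues with similar
cross-reactivity behaviour, typically recovering biochemical families.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .data_model import AA_ALPHABET

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: coarse biochemical families used to impute unobserved matrix cells
BIOCHEMICAL_FAMILIES = {
    "aliphatic": "AVLIM",
    "aromatic": "FWY",
    "positive": "KRH",
    "negative": "DE",
    "polar": "STNQC",
    "special": "GP",
}
_FAMILY_OF = {a: name for name, members in BIOCHEMICAL_FAMILIES.items() for a in members}


@dataclass
class SubstitutionMatrix:
    """20x20 grid of directional log-distance values M[wt][mt] with support counts."""

    entries: np.ndarray  # (20, 20) float
    support: np.ndarray  # (20, 20) int, observations per cell

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if self.entries.shape != (20, 20) or self.support.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("matrix entries must be finite")
        if np.any(np.diag(self.entries) != 0):
            raise ValueError("identity substitutions must have distance 0")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.entries[_AA_INDEX[a], _AA_INDEX[b]])


@dataclass
class PositionProfile:
    """Per-position cross-reactivity multipliers, interior mean normalised to 1."""

    weights: np.ndarray
    length: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != self.length:
            raise ValueError("profile length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("profile weights must be non-negative")

    def weight_at(self, position: int, peptide_length: Optional[int] = None) -> float:
        """Weight for a 1-based position of a peptide of ``peptide_length``.

        Lengths differing from the training length are handled by linear
        interpolation over the normalised position (0 = N terminus,
        1 = C terminus).
        """
        L = peptide_length or self.length
        if not 1 <= position <= L:
            raise ValueError(f"position {position} outside peptide of length {L}")
        if L == self.length:
            return float(self.weights[position - 1])
        if self.length == 1:
            return float(self.weights[0])
        t = 0.5 if L == 1 else (position - 1) / (L - 1)
        grid = np.linspace(0.0, 1.0, self.length)
        return float(np.interp(t, grid, self.weights))


def _normalize_profile(w: np.ndarray) -> tuple[np.ndarray, float]:
    interior = w[1:-1] if len(w) > 2 else w
    scale = interior.mean()
    if scale <= 0:
        return w, 1.0
    return w / scale, scale


@dataclass
class CrossReactModel:
    """Learned cross-reactivity model: substitution matrix x position profile."""

    matrix: SubstitutionMatrix
    profile: PositionProfile
    combiner: str = "multiplicative"

    def to_json(self, path) -> None:
        payload = {
            "combiner": self.combiner,
            "residues": AA_ALPHABET,
            "matrix": self.matrix.entries.tolist(),
            "support": self.matrix.support.tolist(),
            "profile_weights": self.profile.weights.tolist(),
            "profile_length": self.profile.length,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CrossReactModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("residues") != AA_ALPHABET:
            raise ValueError("model residue order does not match expected alphabet")
        return cls(
            matrix=SubstitutionMatrix(
                entries=np.array(payload["matrix"]), support=np.array(payload["support"])
            ),
            profile=PositionProfile(
                weights=np.array(payload["profile_weights"]), length=payload["profile_length"]
            ),
            combiner=payload.get("combiner", "multiplicative"),
        )


def build_model(
    observations: Iterable[Mapping],
    peptide_length: Optional[int] = None,
    include_censored: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> CrossReactModel:
    """Fit matrix and profile to pooled (tcr, position, wt, mt, log_c) observations.

    Alternating least squares on ``log_c ~ w[position] * M[wt][mt]`` until the
    relative RSS change drops below ``tol`` (or ``max_iter`` sweeps).
    Observations are pooled across TCRs with equal weight. Cells never
    observed are imputed from same-biochemical-family observed cells (falling
    back to the global off-diagonal mean) and carry support 0.
    """
    obs = [o for o in observations if include_censored or not o.get("censored", False)]
    if not obs:
        raise ValueError("no observations")
    pos = np.array([int(o["position"]) for o in obs])
    ai = np.array([_AA_INDEX[o["wt_residue"]] for o in obs])
    bi = np.array([_AA_INDEX[o["mt_residue"]] for o in obs])
    y = np.array([float(o["log_c"]) for o in obs])
    if not np.all(np.isfinite(y)):
        raise ValueError("log_c observations must be finite")
    if np.any(ai == bi):
        raise ValueError("identity substitutions are not observations (log C pinned to 0)")
    L = int(peptide_length or pos.max())
    if pos.min() < 1 or pos.max() > L:
        raise ValueError("positions outside peptide length")
    pi = pos - 1

    n_positions = len(np.unique(pi))
    M = np.zeros((20, 20))
    support = np.zeros((20, 20), dtype=int)
    np.add.at(support, (ai, bi), 1)

    w = np.ones(L)
    degenerate_profile = n_positions < 2 or len({(a, b) for a, b in zip(ai, bi)}) < 2
    if degenerate_profile:
        warnings.warn("degenerate scan design: position profile fixed to all-ones", stacklevel=2)

    prev_rss = np.inf
    for _ in range(max_iter):
        # matrix update: M[a,b] = sum(w_i * y) / sum(w_i^2) per cell
        num = np.zeros((20, 20))
        den = np.zeros((20, 20))
        np.add.at(num, (ai, bi), w[pi] * y)
        np.add.at(den, (ai, bi), w[pi] ** 2)
        mask = den > 0
        M[mask] = num[mask] / den[mask]
        np.fill_diagonal(M, 0.0)

        if not degenerate_profile:
            m = M[ai, bi]
            num_w = np.zeros(L)
            den_w = np.zeros(L)
            np.add.at(num_w, pi, m * y)
            np.add.at(den_w, pi, m**2)
            w = np.where(den_w > 0, np.divide(num_w, den_w, out=np.ones(L), where=den_w > 0), w)
            w = np.clip(w, 0.0, None)
            w, scale = _normalize_profile(w)
            M = M * scale

        rss = float(np.sum((w[pi] * M[ai, bi] - y) ** 2))
        if np.isfinite(prev_rss) and abs(prev_rss - rss) <= tol * max(rss, 1e-300):
            break
        prev_rss = rss

    # positions never scanned inherit the nearest observed weight
    observed_pos = np.unique(pi)
    if len(observed_pos) < L:
        grid = np.arange(L)
        w = np.interp(grid, observed_pos, w[observed_pos])
        w, _ = _normalize_profile(w)

    _impute_unobserved(M, support)
    return CrossReactModel(
        matrix=SubstitutionMatrix(entries=M, support=support),
        profile=PositionProfile(weights=w, length=L),
    )


def _impute_unobserved(M: np.ndarray, support: np.ndarray) -> None:
    off = ~np.eye(20, dtype=bool)
    observed = (support > 0) & off
    if not observed.any():
        return
    global_mean = M[observed].mean()
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            if i == j or support[i, j] > 0:
                continue
            fam_mask = np.zeros((20, 20), dtype=bool)
            for ii, aa in enumerate(AA_ALPHABET):
                if _FAMILY_OF[aa] != _FAMILY_OF[a]:
                    continue
                for jj, bb in enumerate(AA_ALPHABET):
                    if _FAMILY_OF[bb] == _FAMILY_OF[b]:
                        fam_mask[ii, jj] = True
            fam_obs = fam_mask & observed
            M[i, j] = M[fam_obs].mean() if fam_obs.any() else global_mean


def cluster_residues(matrix: SubstitutionMatrix):
    """Average-linkage clustering of residues on symmetrised matrix rows.

    Returns ``(linkage_matrix, leaf_order)`` where ``leaf_order`` is the list
    of one-letter residues in dendrogram order. Residues enter in alphabetical
    order, which makes tie-breaking deterministic.
    """
    sym = (matrix.entries + matrix.entries.T) / 2.0
    dist = pdist(sym, metric="euclidean")
    Z = linkage(dist, method="average")
    order = [AA_ALPHABET[i] for i in leaves_list(Z)]
    return Z, order


def predict_logC(p_wt: str, p_mt: str, model: CrossReactModel) -> float:
    """Predicted log cross-reactivity distance for a peptide pair.

    Identity pairs return 0. Multi-substitution pairs return the sum of
    per-substitution terms (an extension beyond single substitutions).
    """
    if len(p_wt) != len(p_mt):
        raise ValueError("peptides must have equal length")
    total = 0.0
    L = len(p_wt)
    for i, (a, b) in enumerate(zip(p_wt, p_mt), start=1):
        if a == b:
            continue
        total += model.profile.weight_at(i, L) * model.matrix[a, b]
    return total


def matrix_to_tsv(matrix: SubstitutionMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(matrix.entries, index=list(AA_ALPHABET), columns=list(AA_ALPHABET)).to_csv(
        path, sep="\t"
    )
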