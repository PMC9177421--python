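"""Domain types and file I/O for neoantigen, epitope, clone-tree and repertoire data.

All peptide/CDR3 sequences use the 20-letter amino-acid alphabet, uppercase.
Substitution positions are 1-based over the peptide, inclusive. Dissociation
constants (Kd) are stored in nM; readers can convert from other units.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AA_ALPHABET)

#: accepted Kd input units, as multipliers to nM
_KD_UNIT_TO_NM = {"nM": 1.0, "pM": 1e-3, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}

MUTATION_EFFECTS = ("missense", "nonsense", "synonymous", "other")


def _check_peptide(seq: str, what: str = "peptide") -> str:
    seq = str(seq).strip().upper()
    if not seq:
        raise ValueError(f"empty {what}")
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(f"{what} {seq!r} contains non-amino-acid characters {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Substitution:
    """Single amino-acid substitution at a 1-based peptide position."""

    position: int
    wt_residue: str
    mt_residue: str


@dataclass(frozen=True)
class NeoantigenRecord:
    """A wild-type/mutant peptide pair with MHC binding affinities.

    ``kd_wt``/``kd_mt`` are peptide-MHC dissociation constants in nM (>0);
    lower Kd means stronger binding. ``clone_id`` is the tumour clone in which
    the underlying mutation arose.
    """

    patient_id: str
    tumor_id: str
    clone_id: str
    p_wt: str
    p_mt: str
    hla: str
    kd_wt: float
    kd_mt: float
    gene: str = ""
    substitution: Optional[Substitution] = None

    def __post_init__(self):
        object.__setattr__(self, "p_wt", _check_peptide(self.p_wt, "p_wt"))
        object.__setattr__(self, "p_mt", _check_peptide(self.p_mt, "p_mt"))
        if len(self.p_wt) != len(self.p_mt):
            raise ValueError(
                f"p_wt and p_mt have different lengths ({len(self.p_wt)} vs {len(self.p_mt)})"
            )
        if not (self.kd_wt > 0 and self.kd_mt > 0):
            raise ValueError("kd_wt and kd_mt must be positive")
        if self.substitution is None:
            object.__setattr__(self, "substitution", infer_substitution(self.p_wt, self.p_mt))
        sub = self.substitution
        i = sub.position - 1
        if not (0 <= i < len(self.p_wt)):
            raise ValueError(f"substitution position {sub.position} outside peptide")
        if self.p_wt[i] != sub.wt_residue or self.p_mt[i] != sub.mt_residue:
            raise ValueError("substitution does not match peptide pair")


def infer_substitution(p_wt: str, p_mt: str) -> Substitution:
    """Locate the single differing position of a peptide pair (1-based)."""
    diffs = [i for i, (a, b) in enumerate(zip(p_wt, p_mt)) if a != b]
    if len(diffs) == 0:
        raise ValueError("p_wt and p_mt are identical: zero substitutions")
    if len(diffs) > 1:
        raise ValueError(f"expected a single substitution, found {len(diffs)}")
    i = diffs[0]
    return Substitution(position=i + 1, wt_residue=p_wt[i], mt_residue=p_mt[i])


@dataclass
class EpitopeSet:
    """A reference set of known immunogenic epitopes (id, sequence)."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate epitope ids")
        self.entries = [(i, _check_peptide(s, f"epitope {i}")) for i, s in self.entries]

    def __len__(self):
        return len(self.entries)

    def sequences(self) -> list[str]:
        return [s for _, s in self.entries]

    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]


@dataclass(frozen=True)
class MutationRecord:
    """A somatic mutation with its coding effect and clone of origin."""

    patient_id: str
    tumor_id: str
    clone_id: str
    gene: str
    effect: str
    generates_neoantigen: bool = False

    def __post_init__(self):
        if self.effect not in MUTATION_EFFECTS:
            raise ValueError(f"effect {self.effect!r} not one of {MUTATION_EFFECTS}")


@dataclass
class DoseResponseCurve:
    """One TCR x peptide activation titration.

    ``points`` are (concentration in M on a log-spaced grid, response)
    pairs with strictly increasing concentrations. ``position`` is None for
    the unsubstituted reference peptide.
    """

    tcr_id: str
    peptide: str
    points: list[tuple[float, float]]
    position: Optional[int] = None
    wt_residue: Optional[str] = None
    mt_residue: Optional[str] = None

    def __post_init__(self):
        self.peptide = _check_peptide(self.peptide)
        if len(self.points) < 4:
            raise ValueError("dose-response curve needs >= 4 points")
        concs = [c for c, _ in self.points]
        if any(c2 <= c1 for c1, c2 in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly increasing")
        import math

        if any(not math.isfinite(r) or r < 0 for _, r in self.points):
            raise ValueError("responses must be finite and non-negative")

    @property
    def concentrations(self):
        return [c for c, _ in self.points]

    @property
    def responses(self):
        return [r for _, r in self.points]


@dataclass
class TcrRepertoire:
    """CDR3beta clonotypes of one sample, aggregated with read counts."""

    sample_id: str
    clonotypes: list[tuple[str, int]]

    def __post_init__(self):
        for cdr3, count in self.clonotypes:
            _check_peptide(cdr3, "cdr3b")
            if count < 1:
                raise ValueError("clonotype counts must be >= 1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


_NEO_COLUMNS = ["patient_id", "tumor_id", "clone_id", "p_wt", "p_mt", "hla", "kd_wt", "kd_mt"]


def read_neoantigen_table(path, kd_unit: str = "nM") -> list[NeoantigenRecord]:
    """Read a neoantigen TSV into validated records.

    The table must carry a header naming at least the columns
    ``patient_id tumor_id clone_id p_wt p_mt hla kd_wt kd_mt`` (``gene``
    optional). Invalid rows raise ValueError carrying the 1-based data row
    number. Kd values are converted from ``kd_unit`` to nM.
    """
    if kd_unit not in _KD_UNIT_TO_NM:
        raise ValueError(f"unknown kd unit {kd_unit!r}; expected one of {sorted(_KD_UNIT_TO_NM)}")
    factor = _KD_UNIT_TO_NM[kd_unit]
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _NEO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"neoantigen table missing columns {missing}; found {list(df.columns)}")
    records = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 1
        try:
            records.append(
                NeoantigenRecord(
                    patient_id=row["patient_id"],
                    tumor_id=row["tumor_id"],
                    clone_id=row["clone_id"],
                    p_wt=row["p_wt"],
                    p_mt=row["p_mt"],
                    hla=row["hla"],
                    kd_wt=float(row["kd_wt"]) * factor,
                    kd_mt=float(row["kd_mt"]) * factor,
                    gene=row.get("gene", "") if isinstance(row.get("gene", ""), str) else "",
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
    return records


def write_neoantigen_table(records: Sequence[NeoantigenRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "tumor_id": r.tumor_id,
            "clone_id": r.clone_id,
            "p_wt": r.p_wt,
            "p_mt": r.p_mt,
            "hla": r.hla,
            "kd_wt": r.kd_wt,
            "kd_mt": r.kd_mt,
            "gene": r.gene,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_NEO_COLUMNS + ["gene"]).to_csv(path, sep="\t", index=False)


def read_epitope_fasta(path) -> EpitopeSet:
    """Read a FASTA of reference epitopes; sequences are uppercased."""
    entries = []
    seen = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate epitope id {rec.id!r}")
            seen.add(rec.id)
            try:
                seq = _check_peptide(str(rec.seq))
            except ValueError as exc:
                raise ValueError(f"epitope {rec.id!r}: {exc}") from exc
            entries.append((rec.id, seq))
    if not entries:
        warnings.warn(f"epitope FASTA {path} is empty", stacklevel=2)
    return EpitopeSet(entries=entries)


def write_epitope_fasta(epitopes: EpitopeSet, path) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in epitopes.entries]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


_MUT_COLUMNS = ["patient_id", "tumor_id", "clone_id", "gene", "effect", "generates_neoantigen"]


def read_mutation_table(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns {missing}; found {list(df.columns)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                MutationRecord(
                    patient_id=row["patient_id"],
                    tumor_id=row["tumor_id"],
                    clone_id=row["clone_id"],
                    gene=row["gene"],
                    effect=row["effect"],
                    generates_neoantigen=str(row["generates_neoantigen"]).lower()
                    in ("true", "1", "yes"),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {int(idx) + 1}: {exc}") from exc
    return records


def write_mutation_table(records: Sequence[MutationRecord], path) -> None:
    rows = [
        {
            "patient_id": m.patient_id,
            "tumor_id": m.tumor_id,
            "clone_id": m.clone_id,
            "gene": m.gene,
            "effect": m.effect,
            "generates_neoantigen": m.generates_neoantigen,
        }
        for m in records
    ]
    pd.DataFrame(rows, columns=_MUT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clone_tree(path):
    """Read a clone tree JSON into a validated :class:`~neofit.clonal_fitness.CloneTree`.

    Schema: ``{"sample_roles": {sample: "primary"|"recurrent"}, "clones":
    [{"clone_id", "parent_id" (null for root), "mutations": [...],
    "frequencies": {sample: fraction}}]}``. Per-sample frequencies may sum to
    <1 (residual mass = normal cells); sums above 1 + 1e-6 are rejected.
    """
    from .clonal_fitness import Clone, CloneTree  # local import: CloneTree lives there

    with _open_text(path) as fh:
        payload = json.load(fh)
    clones = [
        Clone(
            clone_id=node["clone_id"],
            parent_id=node.get("parent_id"),
            own_mutations=frozenset(node.get("mutations", [])),
            frequencies=dict(node.get("frequencies", {})),
        )
        for node in payload["clones"]
    ]
    return CloneTree(clones=clones, sample_roles=payload.get("sample_roles", {}))


def write_clone_tree(tree, path) -> None:
    payload = {
        "sample_roles": dict(tree.sample_roles),
        "clones": [
            {
                "clone_id": c.clone_id,
                "parent_id": c.parent_id,
                "mutations": sorted(c.own_mutations),
                "frequencies": dict(c.frequencies),
            }
            for c in tree.clones
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_airr_repertoire(
    path,
    sample_id: Optional[str] = None,
    cdr3_column: str = "junction_aa",
    count_column: str = "duplicate_count",
) -> TcrRepertoire:
    """Read an AIRR-style TSV into a repertoire, aggregating identical CDR3beta.

    Rows whose CDR3 contains non-standard characters (``*``, ``_``, ``X``...)
    are dropped with a warning, since sequence distances are defined only over
    the 20-letter alphabet.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (cdr3_column, count_column):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}; found header {list(df.columns)}")
    counts: dict[str, int] = {}
    n_dropped = 0
    for idx, row in df.iterrows():
        cdr3 = str(row[cdr3_column]).strip().upper()
        if not cdr3 or set(cdr3) - _AA_SET:
            n_dropped += 1
            logger.warning("row %d: dropping CDR3 %r with non-standard characters", int(idx) + 1, cdr3)
            continue
        counts[cdr3] = counts.get(cdr3, 0) + int(float(row[count_column]))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} CDR3 rows with non-standard characters", stacklevel=2)
    if not counts:
        raise ValueError("no clonotypes in repertoire table")
    if sample_id is None:
        sample_id = Path(path).stem
    clonotypes = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return TcrRepertoire(sample_id=sample_id, clonotypes=clonotypes)


def write_airr_repertoire(rep: TcrRepertoire, path) -> None:
    pd.DataFrame(
        [{"junction_aa": c, "duplicate_count": n} for c, n in rep.clonotypes]
    ).to_csv(path, sep="\t", index=False)


_DR_COLUMNS = [
    "tcr_id",
    "peptide",
    "position",
    "wt_residue",
    "mt_residue",
    "concentration_molar",
    "response",
]


def read_dose_response_csv(path) -> list[DoseResponseCurve]:
    """Read the long-format dose-response CSV into per-(TCR, peptide) curves."""
    df = pd.read_csv(path)
    missing = [c for c in _DR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response CSV missing columns {missing}")
    curves = []
    for (tcr, pep, pos, wt, mt), grp in df.groupby(
        ["tcr_id", "peptide", "position", "wt_residue", "mt_residue"], dropna=False, sort=True
    ):
        grp = grp.sort_values("concentration_molar")
        curves.append(
            DoseResponseCurve(
                tcr_id=str(tcr),
                peptide=str(pep),
                position=None if pd.isna(pos) else int(pos),
                wt_residue=None if pd.isna(wt) else str(wt),
                mt_residue=None if pd.isna(mt) else str(mt),
                points=list(zip(grp["concentration_molar"].astype(float), grp["response"].astype(float))),
            )
        )
    return curves


def write_dose_response_csv(curves: Iterable[DoseResponseCurve], path) -> None:
    rows = []
    for c in curves:
        for conc, resp in c.points:
            rows.append(
                {
                    "tcr_id": c.tcr_id,
                    "peptide": c.peptide,
                    "position": c.position,
                    "wt_residue": c.wt_residue,
                    "mt_residue": c.mt_residue,
                    "concentration_molar": conc,
                    "response": resp,
                }
            )
    pd.DataFrame(rows, columns=_DR_COLUMNS).to_csv(path, index=False)
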