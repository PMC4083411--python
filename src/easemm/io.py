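"""Dataset records, file formats, and curation rules.

A stability measurement is a single amino-acid substitution with the change
in unfolding free energy ddGu = dGu(mutant) - dGu(wild-type) in kcal/mol.
Curation collapses replicate measurements (same experimental conditions are
averaged; across conditions the measurement closest to physiological pH 7
is kept), labels each record stabilising (ddGu >= 0) or destabilising
(ddGu < 0), and removes redundant substitutions within homology clusters.

File formats are deliberately plain: whitespace-delimited mutation tables,
FASTA sequences, PSI-BLAST ASCII PSSMs, tab-separated provider tables
(secondary-structure probabilities, relative accessible surface area,
disorder, SIFT scores, exposed/buried categories), and a two-column
protein-to-cluster map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import AMINO_ACIDS

logger = logging.getLogger(__name__)

STABILISING = "stabilising"
DESTABILISING = "destabilising"

#: Column order of a PSI-BLAST ASCII PSSM.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: pH/temperature equality tolerance for "same experimental conditions".
CONDITION_TOL = 0.05


@dataclass(frozen=True)
class RawMeasurement:
    """One experimental stability-change measurement, as read from a table."""

    protein_id: str
    wt_aa: str
    position: int  # 1-based
    mut_aa: str
    ddg: float  # kcal/mol, ddGu
    ph: Optional[float] = None
    temperature: Optional[float] = None  # deg C; carried, never used in rules
    source_tag: str = ""

    def __post_init__(self):
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"{self.protein_id}: wild-type equals mutant ({self.wt_aa})")
        if self.position < 1:
            raise ValueError(f"{self.protein_id}: position must be >= 1")

    @property
    def key(self) -> Tuple[str, str, int, str]:
        return (self.protein_id, self.wt_aa, self.position, self.mut_aa)

    @property
    def mutation(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class StabilityRecord:
    """A curated, labelled measurement attached to a homology cluster."""

    protein_id: str
    wt_aa: str
    position: int
    mut_aa: str
    ddg: float
    label: str
    cluster_id: str
    ph: Optional[float] = None
    temperature: Optional[float] = None
    source_tag: str = ""

    @property
    def key(self) -> Tuple[str, str, int, str]:
        return (self.protein_id, self.wt_aa, self.position, self.mut_aa)

    @property
    def mutation(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def is_stabilising(self) -> bool:
        return self.label == STABILISING


ClusterMap = Dict[str, str]  # protein_id -> cluster_id


@dataclass
class PSSMatrix:
    """Position-specific scoring matrix: L x 20 log-odds scores.

    Columns follow :data:`PSSM_ALPHABET`; scores are the log-odds block of a
    PSI-BLAST ASCII PSSM (``-out_ascii_pssm``).
    """

    protein_id: str
    sequence: str
    scores: np.ndarray  # (L, 20) float (integers in real PSSMs)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sequence), 20):
            raise ValueError(
                f"{self.protein_id}: PSSM shape {self.scores.shape} does not "
                f"match sequence length {len(self.sequence)}"
            )

    def score(self, position: int, aa: str) -> float:
        """Log-odds score at a 1-based position for residue ``aa``."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        col = PSSM_ALPHABET.find(aa)
        if col < 0:
            raise KeyError(f"unknown amino acid {aa!r}")
        return float(self.scores[position - 1, col])


class ProviderError(KeyError):
    """A provider table does not cover a requested site."""


class ProviderTable:
    """Per-site predictions from external providers, ingested as tables.

    Holds secondary-structure probabilities (helix, sheet, coil; renormalised
    to sum to 1 on load), relative accessible surface area, disorder
    probability, per-substitution SIFT scores, and exposed/buried categories.
    """

    def __init__(self):
        self.ss_probs: Dict[Tuple[str, int], np.ndarray] = {}
        self.rasa: Dict[Tuple[str, int], float] = {}
        self.disorder: Dict[Tuple[str, int], float] = {}
        self.sift: Dict[Tuple[str, int, str], float] = {}
        self.exposure: Dict[Tuple[str, int], str] = {}

    def _get(self, store, key, name):
        try:
            return store[key]
        except KeyError:
            raise ProviderError(f"{name} provider has no entry for {key}") from None

    def get_ss_probs(self, protein_id: str, position: int) -> np.ndarray:
        return self._get(self.ss_probs, (protein_id, position), "secondary-structure")

    def get_rasa(self, protein_id: str, position: int) -> float:
        return self._get(self.rasa, (protein_id, position), "rASA")

    def get_disorder(self, protein_id: str, position: int) -> float:
        return self._get(self.disorder, (protein_id, position), "disorder")

    def get_sift(self, protein_id: str, position: int, mut_aa: str) -> float:
        return self._get(self.sift, (protein_id, position, mut_aa), "SIFT")

    def get_exposure(self, protein_id: str, position: int) -> str:
        return self._get(self.exposure, (protein_id, position), "exposure")

    def set_structure(self, protein_id, position, ss_probs, rasa, disorder):
        p = np.asarray(ss_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0):
            raise ValueError("ss_probs must be 3 non-negative reals")
        total = p.sum()
        if total <= 0:
            raise ValueError("ss_probs sum to zero")
        self.ss_probs[(protein_id, position)] = p / total
        self.rasa[(protein_id, position)] = float(rasa)
        self.disorder[(protein_id, position)] = float(disorder)

    def set_sift(self, protein_id, position, mut_aa, score):
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"SIFT score {score} outside [0, 1]")
        self.sift[(protein_id, position, mut_aa)] = float(score)

    def set_exposure(self, protein_id, position, category):
        if category not in ("exposed", "buried"):
            raise ValueError(f"unknown exposure category {category!r}")
        self.exposure[(protein_id, position)] = category


# ---------------------------------------------------------------------------
# Curation operations
# ---------------------------------------------------------------------------

def assign_label(ddg: float) -> str:
    """Stabilising iff ddGu >= 0 (zero counts as stabilising)."""
    if not math.isfinite(ddg):
        raise ValueError(f"non-finite ddG {ddg}")
    return STABILISING if ddg >= 0 else DESTABILISING


def _cond_equal(a: Optional[float], b: Optional[float], tol: float) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return abs(a - b) <= tol


def merge_same_conditions(
    records: Sequence[RawMeasurement], tol: float = CONDITION_TOL
) -> List[RawMeasurement]:
    """Average measurements taken under the same (pH, temperature) conditions.

    Records must all describe the same substitution.  Conditions are "the
    same" when both pH and temperature agree within ``tol`` absolutely
    (missing matches missing).  Each condition group collapses to a single
    entry whose ddG is the arithmetic mean; the group's first record (in
    input order) supplies the other fields.
    """
    if not records:
        return []
    keys = {r.key for r in records}
    if len(keys) > 1:
        raise ValueError(f"records describe multiple substitutions: {sorted(keys)}")
    groups: List[List[RawMeasurement]] = []
    for rec in records:
        for grp in groups:
            if _cond_equal(rec.ph, grp[0].ph, tol) and _cond_equal(
                rec.temperature, grp[0].temperature, tol
            ):
                grp.append(rec)
                break
        else:
            groups.append([rec])
    out = []
    for grp in groups:
        if len(grp) == 1:
            out.append(grp[0])
        else:
            mean_ddg = float(np.mean([r.ddg for r in grp]))
            out.append(replace(grp[0], ddg=mean_ddg))
    return out


def _ph_sort_key(rec) -> Tuple[float, float]:
    # distance to physiological pH 7; ties broken by the lower pH
    if rec.ph is None:
        return (math.inf, math.inf)
    return (abs(rec.ph - 7.0), rec.ph)


def select_physiological(records: Sequence[RawMeasurement]) -> RawMeasurement:
    """Keep the measurement closest to physiological pH 7.

    Ties at equal ``|pH - 7|`` keep the lower pH.  Missing pH counts as
    infinitely far; if every pH is missing the first record is kept.
    """
    if not records:
        raise ValueError("select_physiological on empty input")
    return min(records, key=_ph_sort_key)


def cluster_dedupe(
    records: Sequence[StabilityRecord], clusters: ClusterMap
) -> List[StabilityRecord]:
    """Within each homology cluster keep one record per substitution key.

    The substitution key is (wt_aa, position, mut_aa) in each protein's own
    numbering; among duplicates the record closest to pH 7 is kept (same tie
    rule as :func:`select_physiological`).
    """
    for rec in records:
        if rec.protein_id not in clusters:
            raise KeyError(f"protein {rec.protein_id!r} missing from cluster map")
    best: Dict[Tuple[str, str, int, str], StabilityRecord] = {}
    for rec in records:
        k = (clusters[rec.protein_id], rec.wt_aa, rec.position, rec.mut_aa)
        if k not in best or _ph_sort_key(rec) < _ph_sort_key(best[k]):
            best[k] = rec
    return list(best.values())


@dataclass
class CurationLog:
    """Counts of records dropped or merged at each curation step."""

    n_input: int = 0
    n_nonfinite: int = 0
    n_merged_same_conditions: int = 0
    n_dropped_cross_conditions: int = 0
    n_dropped_cluster_dedupe: int = 0
    n_output: int = 0
    messages: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict[str, int]:
        return {
            "input": self.n_input,
            "nonfinite_ddg": self.n_nonfinite,
            "merged_same_conditions": self.n_merged_same_conditions,
            "dropped_cross_conditions": self.n_dropped_cross_conditions,
            "dropped_cluster_dedupe": self.n_dropped_cluster_dedupe,
            "output": self.n_output,
        }


def curate(
    raw: Sequence[RawMeasurement],
    clusters: ClusterMap,
    tol: float = CONDITION_TOL,
) -> Tuple[List[StabilityRecord], CurationLog]:
    """Full curation pipeline: merge, pH-select, label, cluster-dedupe.

    Order-insensitive and idempotent: the output record set is a pure
    function of the input record *set*.  Records are sorted internally so
    that all within-group "first record" choices are deterministic.
    """
    log = CurationLog(n_input=len(raw))
    finite = []
    for rec in raw:
        if math.isfinite(rec.ddg):
            finite.append(rec)
        else:
            log.n_nonfinite += 1
            log.messages.append(f"dropped non-finite ddG: {rec.protein_id} {rec.mutation}")
    finite.sort(
        key=lambda r: (
            r.key,
            r.ph if r.ph is not None else math.inf,
            r.temperature if r.temperature is not None else math.inf,
            r.ddg,
            r.source_tag,
        )
    )
    by_key: Dict[Tuple, List[RawMeasurement]] = {}
    for rec in finite:
        by_key.setdefault(rec.key, []).append(rec)

    labelled: List[StabilityRecord] = []
    for key in sorted(by_key):
        merged = merge_same_conditions(by_key[key], tol=tol)
        log.n_merged_same_conditions += len(by_key[key]) - len(merged)
        kept = select_physiological(merged)
        log.n_dropped_cross_conditions += len(merged) - 1
        labelled.append(
            StabilityRecord(
                protein_id=kept.protein_id,
                wt_aa=kept.wt_aa,
                position=kept.position,
                mut_aa=kept.mut_aa,
                ddg=kept.ddg,
                label=assign_label(kept.ddg),
                cluster_id=clusters.get(kept.protein_id, ""),
                ph=kept.ph,
                temperature=kept.temperature,
                source_tag=kept.source_tag,
            )
        )
    for rec in labelled:
        if rec.protein_id not in clusters:
            raise KeyError(f"protein {rec.protein_id!r} missing from cluster map")
    deduped = cluster_dedupe(labelled, clusters)
    log.n_dropped_cluster_dedupe = len(labelled) - len(deduped)
    deduped.sort(key=lambda r: r.key)
    log.n_output = len(deduped)
    return deduped, log


def check_against_sequences(
    records: Sequence[StabilityRecord], sequences: Dict[str, str]
) -> None:
    """Verify each record's wild-type letter matches its sequence."""
    for rec in records:
        seq = sequences.get(rec.protein_id)
        if seq is None:
            raise KeyError(f"no sequence for protein {rec.protein_id!r}")
        if not 1 <= rec.position <= len(seq):
            raise ValueError(
                f"{rec.protein_id} {rec.mutation}: position outside sequence"
            )
        if seq[rec.position - 1] != rec.wt_aa:
            raise ValueError(
                f"{rec.protein_id} {rec.mutation}: sequence has "
                f"{seq[rec.position - 1]!r} at position {rec.position}"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_optional(token: str) -> Optional[float]:
    if token in ("-", "NA", "na", "nan", "None"):
        return None
    return float(token)


def read_mutation_table(path) -> List[RawMeasurement]:
    """Read a whitespace-delimited mutation/stability table.

    One record per line: ``protein_id wt_aa position mut_aa ddG pH temp``;
    pH and temperature may be ``-`` for missing and may be omitted entirely.
    ``#`` starts a comment; a header line is detected and skipped.  Rows with
    letters outside the 20-residue alphabet are rejected and logged.
    """
    records: List[RawMeasurement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 fields, got {len(parts)}")
            try:
                position = int(parts[2])
            except ValueError:
                if lineno == 1 or not records:
                    continue  # header line
                raise ValueError(f"{path}:{lineno}: position {parts[2]!r} not an integer")
            wt, mut = parts[1], parts[3]
            if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
                logger.warning("%s:%d: rejected row with unknown amino acid (%s/%s)",
                               path, lineno, wt, mut)
                continue
            try:
                ddg = float(parts[4])
                ph = _parse_optional(parts[5]) if len(parts) > 5 else None
                temp = _parse_optional(parts[6]) if len(parts) > 6 else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            records.append(
                RawMeasurement(parts[0], wt, position, mut, ddg, ph, temp)
            )
    return records


def write_mutation_table(records: Iterable, path) -> None:
    """Write records (raw or curated) in the mutation-table dialect.

    ddG is written to 2 decimal places (kcal/mol); missing pH/temperature
    as ``-``.
    """
    def fmt(x):
        return "-" if x is None else f"{x:g}"

    with open(path, "w") as fh:
        fh.write("# protein_id wt position mut ddG pH temperature\n")
        for r in records:
            fh.write(
                f"{r.protein_id} {r.wt_aa} {r.position} {r.mut_aa} "
                f"{r.ddg:.2f} {fmt(r.ph)} {fmt(r.temperature)}\n"
            )


def read_fasta(path) -> Dict[str, str]:
    """Read sequences into a dict id -> string (ids match protein_id)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=pid, description="") for pid, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_pssm(path, protein_id: Optional[str] = None) -> PSSMatrix:
    """Parse the log-odds block of a PSI-BLAST ASCII PSSM.

    Rows start with the 1-based position and the query residue, followed by
    20 integer log-odds scores (further columns — the percentage block and
    information content — are ignored).
    """
    sequence: List[str] = []
    rows: List[List[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 22:
                continue
            try:
                pos = int(parts[0])
            except ValueError:
                continue  # header with the 20-letter alphabet, or footer
            aa = parts[1]
            if aa not in AMINO_ACIDS or pos != len(rows) + 1:
                raise ValueError(f"{path}:{lineno}: malformed PSSM row")
            try:
                scores = [float(v) for v in parts[2:22]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric PSSM score") from None
            sequence.append(aa)
            rows.append(scores)
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    pid = protein_id if protein_id is not None else str(path)
    return PSSMatrix(pid, "".join(sequence), np.array(rows))


def write_pssm(pssm: PSSMatrix, path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect (log-odds block only)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(PSSM_ALPHABET) + "\n")
        for i, aa in enumerate(pssm.sequence):
            scores = "  ".join(f"{int(round(v)):3d}" for v in pssm.scores[i])
            fh.write(f"{i + 1:5d} {aa}  {scores}\n")


def read_structure_table(path, providers: Optional[ProviderTable] = None) -> ProviderTable:
    """Read the SS-probability / rASA / disorder provider table (TSV).

    Columns: protein_id, position, H, E, C, rasa, disorder.
    """
    providers = providers or ProviderTable()
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "position", "H", "E", "C", "rasa", "disorder"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for row in df.itertuples(index=False):
        providers.set_structure(
            str(row.protein_id), int(row.position),
            (row.H, row.E, row.C), row.rasa, row.disorder,
        )
    return providers


def read_sift_table(path, providers: Optional[ProviderTable] = None) -> ProviderTable:
    """Read the SIFT provider table (TSV): protein_id, position, mut_aa, sift."""
    providers = providers or ProviderTable()
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "position", "mut_aa", "sift"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for row in df.itertuples(index=False):
        providers.set_sift(str(row.protein_id), int(row.position),
                           str(row.mut_aa), float(row.sift))
    return providers


def read_exposure_table(path, providers: Optional[ProviderTable] = None) -> ProviderTable:
    """Read the exposed/buried provider table (TSV): protein_id, position, acc_cat."""
    providers = providers or ProviderTable()
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "position", "acc_cat"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for row in df.itertuples(index=False):
        providers.set_exposure(str(row.protein_id), int(row.position), str(row.acc_cat))
    return providers


def write_provider_tables(providers: ProviderTable, structure_path, sift_path,
                          exposure_path) -> None:
    struct_rows = []
    for (pid, pos), probs in sorted(providers.ss_probs.items()):
        struct_rows.append({
            "protein_id": pid, "position": pos,
            "H": probs[0], "E": probs[1], "C": probs[2],
            "rasa": providers.rasa[(pid, pos)],
            "disorder": providers.disorder[(pid, pos)],
        })
    pd.DataFrame(struct_rows).to_csv(structure_path, sep="\t", index=False,
                                     float_format="%.6f")
    sift_rows = [
        {"protein_id": pid, "position": pos, "mut_aa": mut, "sift": val}
        for (pid, pos, mut), val in sorted(providers.sift.items())
    ]
    pd.DataFrame(sift_rows).to_csv(sift_path, sep="\t", index=False,
                                   float_format="%.6f")
    exp_rows = [
        {"protein_id": pid, "position": pos, "acc_cat": cat}
        for (pid, pos), cat in sorted(providers.exposure.items())
    ]
    pd.DataFrame(exp_rows).to_csv(exposure_path, sep="\t", index=False)


def read_cluster_map(path) -> ClusterMap:
    """Read a two-column protein_id -> cluster_id map."""
    clusters: ClusterMap = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pid, cid = parts
            if pid in clusters and clusters[pid] != cid:
                raise ValueError(f"{path}:{lineno}: protein {pid!r} in two clusters")
            clusters[pid] = cid
    return clusters


def write_cluster_map(clusters: ClusterMap, path) -> None:
    with open(path, "w") as fh:
        for pid, cid in sorted(clusters.items()):
            fh.write(f"{pid} {cid}\n")


def read_true_category_table(path) -> Dict[Tuple[str, int], Dict[str, object]]:
    """Read a per-site true-structure table (TSV): protein_id, position, ss, rasa.

    This is the interface for e.g. DSSP-derived categories used only in
    evaluation breakdowns, never in routing.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "position", "ss", "rasa"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out: Dict[Tuple[str, int], Dict[str, object]] = {}
    for row in df.itertuples(index=False):
        out[(str(row.protein_id), int(row.position))] = {
            "ss": str(row.ss), "rasa": float(row.rasa),
        }
    return out


def write_true_category_table(table: Dict[Tuple[str, int], Dict[str, object]],
                              path) -> None:
    rows = [
        {"protein_id": pid, "position": pos, "ss": v["ss"], "rasa": v["rasa"]}
        for (pid, pos), v in sorted(table.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
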