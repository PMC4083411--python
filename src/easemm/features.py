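"""Feature encodings for a single amino-acid substitution.

A mutation is encoded from four information sources:

* evolutionary — the SIFT tolerance score of the substitution, and dM, the
  difference of PSSM log-odds scores of the introduced and deleted residue
  divided by 10;
* amino-acid parameters — for each of 11 normalised scales, the difference
  ``value(mut) - value(wt)`` (delta features) and the mean/min/max of the
  scale over a window of six neighbouring residues (three on each side of
  the site, the site itself excluded, truncated at the termini);
* predicted structure — the three secondary-structure probabilities, the
  relative accessible surface area, and the disorder probability.

Features are grouped into selectable units (descriptors): a window trio or
the SS-probability triple is selected or dropped as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import PSSMatrix, ProviderTable, StabilityRecord
from .scales import AAParameterTable, SCALE_NAMES


@dataclass(frozen=True, order=True)
class FeatureDescriptor:
    """A selectable feature group: a group name plus an optional scale."""

    group: str  # sift_score | delta_M | delta | window | ss_probs | rasa | disorder
    scale: Optional[str] = None

    @property
    def name(self) -> str:
        return self.group if self.scale is None else f"{self.group}:{self.scale}"

    @property
    def arity(self) -> int:
        return {"window": 3, "ss_probs": 3}.get(self.group, 1)

    def value_names(self) -> List[str]:
        if self.group == "window":
            return [f"{self.name}:{s}" for s in ("mean", "min", "max")]
        if self.group == "ss_probs":
            return ["ss_probs:H", "ss_probs:E", "ss_probs:C"]
        return [self.name]

    @classmethod
    def parse(cls, name: str) -> "FeatureDescriptor":
        if ":" in name:
            group, scale = name.split(":", 1)
            return cls(group, scale)
        return cls(name)


def all_descriptors() -> List[FeatureDescriptor]:
    """All 27 descriptors in canonical order (51 feature values)."""
    out = [FeatureDescriptor("sift_score"), FeatureDescriptor("delta_M")]
    out += [FeatureDescriptor("delta", s) for s in SCALE_NAMES]
    out += [FeatureDescriptor("window", s) for s in SCALE_NAMES]
    out += [FeatureDescriptor("ss_probs"), FeatureDescriptor("rasa"),
            FeatureDescriptor("disorder")]
    return out


def canonical_order(wanted: Sequence[FeatureDescriptor]) -> List[FeatureDescriptor]:
    """Stable canonical ordering of a descriptor subset."""
    rank = {d: i for i, d in enumerate(all_descriptors())}
    unknown = [d for d in wanted if d not in rank]
    if unknown:
        raise ValueError(f"unknown descriptors: {[d.name for d in unknown]}")
    return sorted(set(wanted), key=rank.__getitem__)


@dataclass
class FeatureVector:
    """Ordered feature values for one mutation, keyed by descriptor."""

    descriptors: Tuple[FeatureDescriptor, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = sum(d.arity for d in self.descriptors)
        if self.values.shape != (n,):
            raise ValueError(f"expected {n} values, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def names(self) -> List[str]:
        return [n for d in self.descriptors for n in d.value_names()]

    def subset(self, wanted: Sequence[FeatureDescriptor]) -> np.ndarray:
        """Values of a descriptor subset, in this vector's order."""
        slices: Dict[FeatureDescriptor, slice] = {}
        off = 0
        for d in self.descriptors:
            slices[d] = slice(off, off + d.arity)
            off += d.arity
        out = []
        for d in canonical_order(wanted):
            if d not in slices:
                raise KeyError(f"descriptor {d.name} not in vector")
            out.append(self.values[slices[d]])
        return np.concatenate(out) if out else np.empty(0)


def delta_param(table: AAParameterTable, scale: str, wt_aa: str, mut_aa: str) -> float:
    """Difference of a normalised parameter: introduced minus deleted residue."""
    return table.value(scale, mut_aa) - table.value(scale, wt_aa)


def window_stats(
    sequence: str,
    position: int,
    table: AAParameterTable,
    scale: str,
    half_width: int = 3,
) -> Tuple[float, float, float]:
    """(mean, min, max) of a scale over the site's sequence neighbourhood.

    The window covers up to ``half_width`` residues on each side of the
    1-based ``position``; the mutated site itself is excluded and the window
    truncates at the termini.
    """
    L = len(sequence)
    if not 1 <= position <= L:
        raise IndexError(f"position {position} outside 1..{L}")
    lo = max(1, position - half_width)
    hi = min(L, position + half_width)
    neighbours = [sequence[i - 1] for i in range(lo, hi + 1) if i != position]
    if not neighbours:
        raise ValueError("no neighbouring residues (length-1 sequence)")
    vals = np.array([table.value(scale, aa) for aa in neighbours])
    return float(vals.mean()), float(vals.min()), float(vals.max())


def delta_M(pssm: PSSMatrix, position: int, wt_aa: str, mut_aa: str) -> float:
    """PSSM log-odds difference (introduced minus deleted), divided by 10."""
    return (pssm.score(position, mut_aa) - pssm.score(position, wt_aa)) / 10.0


def encode(
    record: StabilityRecord,
    sequence: str,
    pssm: PSSMatrix,
    providers: ProviderTable,
    table: AAParameterTable,
    wanted: Optional[Sequence[FeatureDescriptor]] = None,
    half_width: int = 3,
) -> FeatureVector:
    """Encode one mutation into its feature vector.

    Only the requested descriptors are computed; output order is the fixed
    canonical order, independent of provider-file row order.  A site not
    covered by a provider raises an error naming the provider — values are
    never silently imputed.
    """
    if sequence[record.position - 1] != record.wt_aa:
        raise ValueError(
            f"{record.protein_id} {record.mutation}: sequence has "
            f"{sequence[record.position - 1]!r} at the site"
        )
    wanted = canonical_order(wanted if wanted is not None else all_descriptors())
    pid, pos = record.protein_id, record.position
    values: List[float] = []
    for d in wanted:
        if d.group == "sift_score":
            values.append(providers.get_sift(pid, pos, record.mut_aa))
        elif d.group == "delta_M":
            values.append(delta_M(pssm, pos, record.wt_aa, record.mut_aa))
        elif d.group == "delta":
            values.append(delta_param(table, d.scale, record.wt_aa, record.mut_aa))
        elif d.group == "window":
            values.extend(window_stats(sequence, pos, table, d.scale, half_width))
        elif d.group == "ss_probs":
            values.extend(providers.get_ss_probs(pid, pos))
        elif d.group == "rasa":
            values.append(providers.get_rasa(pid, pos))
        elif d.group == "disorder":
            values.append(providers.get_disorder(pid, pos))
        else:  # pragma: no cover - canonical_order already rejects these
            raise ValueError(f"unknown feature group {d.group!r}")
    return FeatureVector(tuple(wanted), np.array(values))


def feature_matrix(
    records: Sequence[StabilityRecord],
    sequences: Dict[str, str],
    pssms: Dict[str, PSSMatrix],
    providers: ProviderTable,
    table: AAParameterTable,
    wanted: Optional[Sequence[FeatureDescriptor]] = None,
) -> Tuple[np.ndarray, List[FeatureDescriptor]]:
    """Stack encodings of many records into an (n, p) matrix."""
    wanted = canonical_order(wanted if wanted is not None else all_descriptors())
    rows = [
        encode(r, sequences[r.protein_id], pssms[r.protein_id], providers,
               table, wanted).values
        for r in records
    ]
    return np.array(rows, dtype=float), wanted


def descriptor_columns(
    descriptors: Sequence[FeatureDescriptor],
) -> Dict[FeatureDescriptor, List[int]]:
    """Column indices of each descriptor inside a stacked feature matrix."""
    cols: Dict[FeatureDescriptor, List[int]] = {}
    off = 0
    for d in descriptors:
        cols[d] = list(range(off, off + d.arity))
        off += d.arity
    return cols


def write_feature_table(vectors: Sequence[FeatureVector], records, path) -> None:
    """Export feature vectors as TSV with canonical descriptor-value names."""
    if not vectors:
        raise ValueError("nothing to write")
    names = vectors[0].names
    with open(path, "w") as fh:
        fh.write("protein_id\tmutation\t" + "\t".join(names) + "\n")
        for rec, vec in zip(records, vectors):
            if vec.names != names:
                raise ValueError("inconsistent descriptor sets across vectors")
            vals = "\t".join(f"{v:.6f}" for v in vec.values)
            fh.write(f"{rec.protein_id}\t{rec.mutation}\t{vals}\n")
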