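"""Seed-reproducible synthetic datasets with planted feature-label structure.

The generator emits a full input bundle — sequences, a mutation/stability
table, PSSMs, provider tables, a homology-cluster map, and a true-category
table — in exactly the formats the readers consume, so synthetic fixtures
and real supplementary files are interchangeable.

The statistical model is deliberately simple test scaffolding, not protein
energetics: class labels are Bernoulli draws (default 28% stabilising,
mirroring the 72%-destabilising composition of real mutation datasets), and
for each mutation the informative descriptor of its structural category is
shifted between classes (Gaussian class-conditional means separated by
``effect_size`` noise standard deviations) while every other feature input
is exchangeable noise.  Provider tables are internally consistent by
construction: the exposure category agrees with rASA vs the 25% threshold,
and the secondary-structure argmax agrees with the true SS category.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import io as eio
from .features import FeatureDescriptor
from .scales import AMINO_ACIDS, AAParameterTable, default_table

#: Noise sd of each plantable descriptor's underlying input.
BASE_SD = {
    "sift_score": 0.15,
    "disorder": 0.15,
    "delta_M": 0.30,
    "delta": 0.35,  # any delta:<scale>
}

CATEGORY_VALUES = ("exposed", "buried", "helix", "sheet", "coil")


def _base_sd(descriptor: str) -> float:
    group = descriptor.split(":", 1)[0]
    if group not in BASE_SD:
        raise ValueError(f"descriptor {descriptor!r} is not plantable")
    return BASE_SD[group]


@dataclass
class SyntheticSpec:
    """The stated world of one synthetic dataset.

    Defaults mirror the composition of the real development data: 28% of
    mutations stabilising and ~24 mutations per protein, with homology
    clusters of one to three proteins.
    """

    n_proteins: int = 70
    length_range: Tuple[int, int] = (80, 200)
    mutations_per_protein: int = 24
    max_cluster_size: int = 3
    positive_fraction: float = 0.28
    effects: Dict[str, Tuple[str, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    n_same_condition_duplicates: int = 0
    n_cross_condition_duplicates: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.n_proteins < 1 or self.mutations_per_protein < 1:
            raise ValueError("need at least one protein and one mutation")
        if not 1 <= self.max_cluster_size:
            raise ValueError("max_cluster_size must be >= 1")
        # strided positions per cluster member must still fit the budget
        need = self.mutations_per_protein * self.max_cluster_size + self.max_cluster_size
        if self.length_range[0] < need:
            raise ValueError(
                f"minimum length {self.length_range[0]} too short for "
                f"{self.mutations_per_protein} mutations at cluster size "
                f"{self.max_cluster_size} (need >= {need})"
            )
        for cat, (desc, size) in self.effects.items():
            if cat not in CATEGORY_VALUES:
                raise ValueError(f"unknown category {cat!r}")
            if desc.split(":", 1)[0] == "rasa":
                raise ValueError("planting on rasa would confound routing")
            _base_sd(desc)
            if not np.isfinite(size):
                raise ValueError("effect size must be finite")


def heterogeneous_effects(effect_size: float = 1.0) -> Dict[str, Tuple[str, float]]:
    """Category-specific informative descriptors, one per category, mirroring
    the kind of feature relevance seen in real stability data (substitution
    tolerance for exposed sites, hydrophobicity change for buried ones,
    secondary-structure propensity changes for helix/sheet, disorder for
    coil)."""
    return {
        "exposed": ("sift_score", effect_size),
        "buried": ("delta:hydrophobicity", effect_size),
        "helix": ("delta:helix_tendency", effect_size),
        "sheet": ("delta:sheet_tendency", effect_size),
        "coil": ("disorder", effect_size),
    }


def homogeneous_effects(descriptor: str, effect_size: float) -> Dict[str, Tuple[str, float]]:
    """One globally informative descriptor (planted via both ASA categories,
    which together cover every mutation)."""
    return {"exposed": (descriptor, effect_size), "buried": (descriptor, effect_size)}


@dataclass
class Bundle:
    """An in-memory synthetic dataset plus its on-disk serialisation."""

    spec: SyntheticSpec
    sequences: Dict[str, str]
    pssms: Dict[str, eio.PSSMatrix]
    providers: eio.ProviderTable
    clusters: eio.ClusterMap
    raw_records: List[eio.RawMeasurement]
    true_categories: Dict[Tuple[str, int], Dict[str, object]]

    def write(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "pssm").mkdir(exist_ok=True)
        paths = {
            "fasta": out / "sequences.fasta",
            "mutations": out / "mutations.txt",
            "structure": out / "structure.tsv",
            "sift": out / "sift.tsv",
            "exposure": out / "exposure.tsv",
            "clusters": out / "clusters.txt",
            "true_categories": out / "true_categories.tsv",
            "pssm_dir": out / "pssm",
        }
        eio.write_fasta(self.sequences, paths["fasta"])
        eio.write_mutation_table(self.raw_records, paths["mutations"])
        eio.write_provider_tables(self.providers, paths["structure"],
                                  paths["sift"], paths["exposure"])
        eio.write_cluster_map(self.clusters, paths["clusters"])
        eio.write_true_category_table(self.true_categories, paths["true_categories"])
        for pid, pssm in self.pssms.items():
            eio.write_pssm(pssm, paths["pssm_dir"] / f"{pid}.pssm")
        return paths

    def curated(self) -> Tuple[List[eio.StabilityRecord], eio.CurationLog]:
        return eio.curate(self.raw_records, self.clusters)

    def design_matrix(self, wanted: Optional[List[FeatureDescriptor]] = None,
                      table: Optional[AAParameterTable] = None):
        """Curate, encode and route every record.

        Returns (records, X, descriptors, y, asa_cats, ss_cats, clusters).
        """
        from .features import feature_matrix
        from .models import route_asa, route_ss

        table = table or default_table()
        records, _ = self.curated()
        X, descriptors = feature_matrix(records, self.sequences, self.pssms,
                                        self.providers, table, wanted)
        y = np.array([r.is_stabilising for r in records], dtype=int)
        asa = np.array([route_asa(self.providers, r.protein_id, r.position)
                        for r in records])
        ss = np.array([route_ss(self.providers, r.protein_id, r.position)
                       for r in records])
        clusters = np.array([r.cluster_id for r in records])
        return records, X, descriptors, y, asa, ss, clusters


def _plant_mut_letter(table: AAParameterTable, wt: str,
                      targets: Dict[str, float]) -> str:
    """Pick the mutant letter whose scale deltas best match the targets."""
    best, best_cost = None, np.inf
    for aa in AMINO_ACIDS:
        if aa == wt:
            continue
        cost = sum(
            (table.value(scale, wt) + d - table.value(scale, aa)) ** 2
            for scale, d in targets.items()
        )
        if cost < best_cost:
            best, best_cost = aa, cost
    return best


def generate(spec: SyntheticSpec) -> Bundle:
    """Generate one bundle according to the spec; byte-identical per seed."""
    rng = np.random.default_rng(spec.seed)
    table = default_table()

    # clusters of 1..max_cluster_size proteins
    clusters: eio.ClusterMap = {}
    members: Dict[str, List[str]] = {}
    pid_i, cid_i = 0, 0
    while pid_i < spec.n_proteins:
        size = int(rng.integers(1, spec.max_cluster_size + 1))
        size = min(size, spec.n_proteins - pid_i)
        cid = f"C{cid_i:03d}"
        members[cid] = []
        for _ in range(size):
            pid = f"P{pid_i:03d}"
            clusters[pid] = cid
            members[cid].append(pid)
            pid_i += 1
        cid_i += 1

    sequences: Dict[str, str] = {}
    pssms: Dict[str, eio.PSSMatrix] = {}
    providers = eio.ProviderTable()
    raw_records: List[eio.RawMeasurement] = []
    true_categories: Dict[Tuple[str, int], Dict[str, object]] = {}

    exposed_frac = 0.47  # roughly balanced exposure, as in real data

    for cid in sorted(members):
        size = len(members[cid])
        for j, pid in enumerate(members[cid]):
            L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
            seq_list = list(seq)
            base_scores = np.round(rng.normal(0.0, 3.0, size=(L, 20)))
            # cluster members use disjoint strided positions so no two
            # homologs ever share a substitution key by accident
            candidates = np.arange(j + 1, L + 1, size)
            positions = rng.choice(candidates, size=spec.mutations_per_protein,
                                   replace=False)
            for pos in sorted(int(p) for p in positions):
                ss_cat = str(rng.choice(["helix", "sheet", "coil"],
                                        p=[0.35, 0.25, 0.40]))
                if rng.random() < exposed_frac:
                    rasa = float(rng.uniform(0.2501, 0.95))
                    asa_cat = "exposed"
                else:
                    rasa = float(rng.uniform(0.0, 0.25))
                    asa_cat = "buried"
                # SS probabilities with the argmax at the true category
                probs = np.sort(rng.dirichlet([1.5, 1.5, 1.5]))[::-1]
                ss_index = {"helix": 0, "sheet": 1, "coil": 2}[ss_cat]
                others = [i for i in range(3) if i != ss_index]
                rng.shuffle(others)
                p3 = np.empty(3)
                p3[ss_index] = probs[0]
                p3[others[0]], p3[others[1]] = probs[1], probs[2]

                y = bool(rng.random() < spec.positive_fraction)
                if y:
                    ddg = round(abs(rng.normal(0.8, 0.6)), 2)
                else:
                    ddg = -round(abs(rng.normal(1.2, 0.9)) + 0.05, 2)

                # accumulate planted shifts from this record's two categories
                pairs = {spec.effects[c] for c in (asa_cat, ss_cat)
                         if c in spec.effects}
                shifts: Dict[str, float] = {}
                for desc, size_eff in pairs:
                    sep = size_eff * _base_sd(desc) * spec.noise_sd
                    shifts[desc] = shifts.get(desc, 0.0) + (sep / 2 if y else -sep / 2)

                wt = seq_list[pos - 1]
                delta_targets = {
                    d.split(":", 1)[1]: rng.normal(shift, BASE_SD["delta"] * spec.noise_sd)
                    for d, shift in shifts.items() if d.startswith("delta:")
                }
                if delta_targets:
                    mut = _plant_mut_letter(table, wt, delta_targets)
                else:
                    choices = [a for a in AMINO_ACIDS if a != wt]
                    mut = str(rng.choice(choices))

                sift_shift = shifts.get("sift_score", 0.0)
                sift = float(np.clip(rng.normal(0.5 + sift_shift,
                                                BASE_SD["sift_score"] * spec.noise_sd),
                                     0.0, 1.0))
                dis_shift = shifts.get("disorder", 0.0)
                disorder = float(np.clip(rng.normal(0.35 + dis_shift,
                                                    BASE_SD["disorder"] * spec.noise_sd),
                                         0.0, 1.0))
                if "delta_M" in shifts:
                    d = rng.normal(shifts["delta_M"], BASE_SD["delta_M"] * spec.noise_sd)
                    wt_col = eio.PSSM_ALPHABET.index(wt)
                    mut_col = eio.PSSM_ALPHABET.index(mut)
                    base_scores[pos - 1, mut_col] = (
                        base_scores[pos - 1, wt_col] + round(10 * d)
                    )

                ph = round(float(rng.uniform(5.5, 8.0)), 1)
                providers.set_structure(pid, pos, p3, rasa, disorder)
                providers.set_sift(pid, pos, mut, sift)
                providers.set_exposure(pid, pos, asa_cat)
                true_categories[(pid, pos)] = {"ss": ss_cat, "rasa": rasa}
                raw_records.append(eio.RawMeasurement(
                    pid, wt, pos, mut, float(ddg), ph, 25.0
                ))
            sequences[pid] = seq
            pssms[pid] = eio.PSSMatrix(pid, seq, base_scores)

    # duplicate injection: same-condition copies vanish in the averaging
    # step, cross-condition copies in the pH-7 selection step
    n_same = min(spec.n_same_condition_duplicates, len(raw_records))
    n_cross = min(spec.n_cross_condition_duplicates, len(raw_records))
    dup_idx = rng.choice(len(raw_records), size=n_same + n_cross, replace=False)
    for i in dup_idx[:n_same]:
        r = raw_records[i]
        raw_records.append(replace(r, ddg=r.ddg * 1.1 if r.ddg != 0 else 0.1))
    for i in dup_idx[n_same:]:
        r = raw_records[i]
        raw_records.append(replace(r, ph=3.0, ddg=r.ddg))

    bundle = Bundle(spec, sequences, pssms, providers, clusters,
                    raw_records, true_categories)
    _check_consistency(bundle)
    return bundle


def generate_heterogeneous(spec: SyntheticSpec) -> Bundle:
    """As :func:`generate`, but require genuinely heterogeneous structure:
    at least two distinct informative descriptors, and no descriptor
    informative in every category — the regime where multiple specialised
    models should beat one pooled model."""
    descs = {desc for desc, _ in spec.effects.values()}
    if len(descs) < 2:
        raise ValueError("heterogeneous spec needs >= 2 distinct informative descriptors")
    for d in descs:
        cats = [c for c, (dd, _) in spec.effects.items() if dd == d]
        if set(cats) >= set(CATEGORY_VALUES):
            raise ValueError(f"descriptor {d!r} is informative in every category")
    return generate(spec)


def _check_consistency(bundle: Bundle) -> None:
    """Internal-consistency invariants, asserted on every generated bundle."""
    for (pid, pos), cat in bundle.providers.exposure.items():
        rasa = bundle.providers.rasa[(pid, pos)]
        assert cat == ("exposed" if rasa > 0.25 else "buried"), (pid, pos)
    ss_index = {"helix": 0, "sheet": 1, "coil": 2}
    for (pid, pos), info in bundle.true_categories.items():
        probs = bundle.providers.ss_probs[(pid, pos)]
        assert int(np.argmax(probs)) == ss_index[info["ss"]], (pid, pos)
    for rec in bundle.raw_records:
        assert bundle.sequences[rec.protein_id][rec.position - 1] == rec.wt_aa


def load_bundle(directory) -> Bundle:
    """Read a written bundle back through the standard readers."""
    d = Path(directory)
    sequences = eio.read_fasta(d / "sequences.fasta")
    providers = eio.read_structure_table(d / "structure.tsv")
    eio.read_sift_table(d / "sift.tsv", providers)
    eio.read_exposure_table(d / "exposure.tsv", providers)
    pssms = {
        p.stem: eio.read_pssm(p, protein_id=p.stem)
        for p in sorted((d / "pssm").glob("*.pssm"))
    }
    return Bundle(
        spec=SyntheticSpec(),
        sequences=sequences,
        pssms=pssms,
        providers=providers,
        clusters=eio.read_cluster_map(d / "clusters.txt"),
        raw_records=eio.read_mutation_table(d / "mutations.txt"),
        true_categories=eio.read_true_category_table(d / "true_categories.tsv"),
    )
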