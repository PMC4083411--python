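"""Amino-acid parameter scales and their min-max normalisation.

Eleven literature scales are shipped raw and normalised into [-0.9, 0.9]
before any feature is computed from them.  The normalisation is an affine
map per scale, so every scale attains both endpoints exactly.
"""

from __future__ import annotations

from typing import Dict, Iterable

import numpy as np

#: Canonical one-letter amino-acid alphabet (alphabetical order); every
#: 20-wide structure in the package uses this order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

NORM_LO = -0.9
NORM_HI = 0.9

# Raw literature values, keyed scale -> one-letter residue -> value.
# hydrophobicity: Kyte & Doolittle (1982) hydropathy index
# volume: Zamyatnin (1972) residue volume, A^3
# polarisability: Charton & Charton (1982)
# isoelectric_point: Zimmerman et al. (1968)
# helix_tendency / sheet_tendency: Chou & Fasman conformational propensities
# steric_parameter: graph shape index
# flexibility: Bhaskaran & Ponnuswamy (1988) average flexibility
# compressibility / bulkiness / equilibrium_constant_COOH: physico-chemical
#   property compilations (partial specific compressibility, Zimmerman
#   bulkiness, alpha-COOH ionisation constant pK1)
RAW_SCALES: Dict[str, Dict[str, float]] = {
    "hydrophobicity": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    },
    "volume": {
        "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
        "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
        "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
        "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
    },
    "polarisability": {
        "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128,
        "Q": 0.180, "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186,
        "L": 0.186, "K": 0.219, "M": 0.221, "F": 0.290, "P": 0.131,
        "S": 0.062, "T": 0.108, "W": 0.409, "Y": 0.298, "V": 0.140,
    },
    "isoelectric_point": {
        "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.05,
        "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02,
        "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.30,
        "S": 5.68, "T": 5.66, "W": 5.89, "Y": 5.66, "V": 5.96,
    },
    "helix_tendency": {
        "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
        "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
        "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
        "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
    },
    "sheet_tendency": {
        "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
        "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
        "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
        "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
    },
    "steric_parameter": {
        "A": 1.28, "R": 2.34, "N": 1.60, "D": 1.60, "C": 1.77,
        "Q": 1.56, "E": 1.56, "G": 0.00, "H": 2.99, "I": 4.19,
        "L": 2.59, "K": 1.89, "M": 2.35, "F": 2.94, "P": 2.67,
        "S": 1.31, "T": 3.03, "W": 3.21, "Y": 2.94, "V": 3.67,
    },
    "flexibility": {
        "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346,
        "Q": 0.493, "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462,
        "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314, "P": 0.509,
        "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.420, "V": 0.386,
    },
    "compressibility": {
        "A": -25.5, "R": -26.7, "N": -22.8, "D": -33.1, "C": -32.8,
        "Q": -23.8, "E": -36.6, "G": -27.0, "H": -31.1, "I": -31.8,
        "L": -28.3, "K": -22.2, "M": -31.0, "F": -29.4, "P": -23.7,
        "S": -27.5, "T": -25.4, "W": -30.2, "Y": -28.5, "V": -30.7,
    },
    "bulkiness": {
        "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
        "Q": 14.45, "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40,
        "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
        "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57,
    },
    "equilibrium_constant_COOH": {
        "A": 2.34, "R": 2.17, "N": 2.02, "D": 1.88, "C": 1.96,
        "Q": 2.17, "E": 2.19, "G": 2.34, "H": 1.82, "I": 2.36,
        "L": 2.36, "K": 2.18, "M": 2.28, "F": 1.83, "P": 1.99,
        "S": 2.21, "T": 2.09, "W": 2.38, "Y": 2.20, "V": 2.32,
    },
}

SCALE_NAMES = tuple(RAW_SCALES)  # fixed canonical scale order


def normalize_scale(raw: Iterable[float]) -> np.ndarray:
    """Min-max normalise 20 raw values into [-0.9, 0.9].

    The map is affine: ``x -> -0.9 + 1.8 * (x - min) / (max - min)``, so the
    raw minimum maps to -0.9 and the raw maximum to 0.9 exactly.

    Raises
    ------
    ValueError
        If there are not exactly 20 finite values or the scale is constant.
    """
    x = np.asarray(list(raw), dtype=float)
    if x.shape != (20,):
        raise ValueError(f"expected 20 values, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("scale contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant scale cannot be normalised")
    return NORM_LO + (NORM_HI - NORM_LO) * (x - lo) / (hi - lo)


class AAParameterTable:
    """Normalised amino-acid parameter table: 11 scales x 20 residues.

    Values always lie in [-0.9, 0.9] and each scale attains both endpoints.
    """

    def __init__(self, raw: Dict[str, Dict[str, float]] | None = None):
        raw = RAW_SCALES if raw is None else raw
        self.scales = tuple(raw)
        self._values: Dict[str, np.ndarray] = {}
        for scale, table in raw.items():
            missing = set(AMINO_ACIDS) - set(table)
            if missing:
                raise ValueError(f"scale {scale!r} missing residues {sorted(missing)}")
            self._values[scale] = normalize_scale(table[aa] for aa in AMINO_ACIDS)

    def value(self, scale: str, aa: str) -> float:
        if scale not in self._values:
            raise KeyError(f"unknown scale {scale!r}")
        idx = AMINO_ACIDS.find(aa)
        if idx < 0:
            raise KeyError(f"unknown amino acid {aa!r}")
        return float(self._values[scale][idx])

    def values(self, scale: str) -> np.ndarray:
        """All 20 normalised values of one scale, in canonical residue order."""
        if scale not in self._values:
            raise KeyError(f"unknown scale {scale!r}")
        return self._values[scale].copy()

    # -- serialisation: whitespace-delimited, rows = residues, cols = scales

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("aa " + " ".join(self.scales) + "\n")
            for i, aa in enumerate(AMINO_ACIDS):
                vals = " ".join(f"{self._values[s][i]:.6f}" for s in self.scales)
                fh.write(f"{aa} {vals}\n")

    @classmethod
    def read(cls, path) -> "AAParameterTable":
        with open(path) as fh:
            header = fh.readline().split()
            if not header or header[0] != "aa":
                raise ValueError(f"{path}: malformed scale-table header")
            scales = header[1:]
            table: Dict[str, Dict[str, float]] = {s: {} for s in scales}
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                aa, vals = parts[0], parts[1:]
                if len(vals) != len(scales):
                    raise ValueError(f"{path}: row {aa!r} has {len(vals)} values")
                for s, v in zip(scales, vals):
                    table[s][aa] = float(v)
        obj = cls.__new__(cls)
        obj.scales = tuple(scales)
        obj._values = {
            s: np.array([table[s][aa] for aa in AMINO_ACIDS], dtype=float)
            for s in scales
        }
        return obj


def default_table() -> AAParameterTable:
    """The package's built-in normalised 11-scale table."""
    return AAParameterTable()
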