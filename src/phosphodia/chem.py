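"""Monoisotopic mass constants and averagine isotope envelopes.

Masses follow the usual proteomics conventions: residue masses are the
monoisotopic masses of the amino-acid residues (i.e. the amino acid minus
water), a peptide's neutral mass adds one water, and an ion of charge z adds
z protons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics import mass as _pmass

PROTON = 1.007276
WATER = 18.010565
PHOSPHO = 79.96633          # HPO3 addition on S/T/Y
H3PO4_LOSS = -97.976896     # neutral loss of phosphoric acid
CARBAMIDOMETHYL = 57.02146  # fixed Cys modification
OXIDATION = 15.994915       # variable Met modification, treated as inert delta

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASSES: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

PHOSPHO_RESIDUES = frozenset("STY")

# Averagine model peptide: average elemental composition per 111.1254 Da of
# peptide mass (Senko's averagine), used to approximate isotope envelopes
# when the exact composition is unknown.
_AVERAGINE_MASS = 111.1254
_AVERAGINE_COMPOSITION = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}

# Isotope abundance vectors indexed by extra neutron count.
_ISOTOPES = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0, 0.0001]),
}

NEUTRON = 1.0033548


def residue_mass(residue: str) -> float:
    try:
        return RESIDUE_MASSES[residue]
    except KeyError:
        raise ValueError(f"unknown residue: {residue!r}") from None


def peptide_neutral_mass(sequence: str, mod_deltas: float = 0.0) -> float:
    """Monoisotopic neutral mass of a peptide plus any modification deltas."""
    return sum(residue_mass(aa) for aa in sequence) + WATER + mod_deltas


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return neutral_mass / charge + PROTON


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Relative abundances of the M+0..M+3 isotopologues of one ion."""

    base_mz: float
    charge: int
    relative_abundances: tuple[float, ...]

    def peak_mzs(self) -> np.ndarray:
        k = np.arange(len(self.relative_abundances))
        return self.base_mz + k * NEUTRON / self.charge


def _element_distribution(abundances: np.ndarray, n_atoms: int, n_peaks: int) -> np.ndarray:
    """Isotope distribution of n_atoms of one element, truncated to n_peaks."""
    out = np.zeros(n_peaks)
    out[0] = 1.0
    base = abundances[:n_peaks].copy()
    power = n_atoms
    while power:
        if power & 1:
            out = np.convolve(out, base)[:n_peaks]
        base = np.convolve(base, base)[:n_peaks]
        power >>= 1
    return out


def isotope_envelope(mass: float, charge: int, n_peaks: int = 4) -> IsotopeEnvelope:
    """Averagine-approximation isotope envelope for an ion of given neutral mass.

    The elemental composition is scaled from the averagine model peptide;
    abundances are normalized to sum to one over the first ``n_peaks``
    isotopologues (M+0..M+3 by default).
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if charge <= 0:
        raise ValueError("charge must be positive")
    scale = mass / _AVERAGINE_MASS
    dist = np.ones(1)
    for element, per_unit in _AVERAGINE_COMPOSITION.items():
        n_atoms = max(int(round(per_unit * scale)), 0)
        if n_atoms:
            dist = np.convolve(dist, _element_distribution(_ISOTOPES[element], n_atoms, n_peaks))[:n_peaks]
    dist = np.pad(dist, (0, n_peaks - len(dist)))
    dist = dist / dist.sum()
    return IsotopeEnvelope(base_mz=mz_from_neutral(mass, charge), charge=charge,
                           relative_abundances=tuple(dist))
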