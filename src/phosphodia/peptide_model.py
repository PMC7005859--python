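"""Modified peptides, positional-isomer candidates and theoretical fragments.

A phosphopeptide with ``p`` phospho groups and more than ``p`` S/T/Y residues
is ambiguous: the phospho groups can sit on any combination of the acceptor
residues. Each concrete placement is a :class:`SiteCandidate` (a positional
isomer). Fragments whose mass differs between candidates are
*site-determining*; :func:`site_determining_fragment_sets` annotates, per
candidate, every unique fragment mass as confirming, refuting or neutral —
the evidence vocabulary the localization scorer consumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import chem
from .chem import (H3PO4_LOSS, PHOSPHO, PHOSPHO_RESIDUES, PROTON, WATER,
                   IsotopeEnvelope, isotope_envelope, residue_mass)

__all__ = [
    "ModifiedPeptide",
    "SiteCandidate",
    "FragmentIon",
    "IsotopeEnvelope",
    "enumerate_site_candidates",
    "theoretical_fragments",
    "site_determining_fragment_sets",
    "UniqueMass",
    "isotope_envelope",
]

MASS_DEDUP_TOL = 1e-4  # Da; below instrument resolution, above float noise


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with fixed modifications and ``p`` mobile phosphos.

    Parameters
    ----------
    sequence
        Uppercase amino-acid string (standard 20 letters).
    variable_phospho_count
        Number of phospho groups to place on S/T/Y residues.
    fixed_mods
        ``(position, mass_delta)`` pairs, 1-based; position-locked deltas such
        as carbamidomethyl-C or oxidized M.
    """

    sequence: str
    variable_phospho_count: int = 0
    fixed_mods: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        for aa in self.sequence:
            if aa not in chem.RESIDUE_MASSES:
                raise ValueError(f"unknown residue: {aa!r}")
        for pos, _ in self.fixed_mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"fixed_mod position {pos} outside peptide")
        if self.variable_phospho_count < 0:
            raise ValueError("phospho count must be >= 0")

    @property
    def candidate_residues(self) -> tuple[int, ...]:
        """1-based positions of phospho-acceptor residues (S/T/Y)."""
        return tuple(i + 1 for i, aa in enumerate(self.sequence) if aa in PHOSPHO_RESIDUES)

    def neutral_mass(self) -> float:
        deltas = sum(d for _, d in self.fixed_mods) + self.variable_phospho_count * PHOSPHO
        return chem.peptide_neutral_mass(self.sequence, deltas)

    def mz(self, charge: int) -> float:
        return chem.mz_from_neutral(self.neutral_mass(), charge)


@dataclass(frozen=True)
class SiteCandidate:
    """One concrete placement of the parent's phospho groups."""

    parent: ModifiedPeptide
    phospho_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        acceptors = set(self.parent.candidate_residues)
        if len(self.phospho_positions) != self.parent.variable_phospho_count:
            raise ValueError("candidate must place exactly p phospho groups")
        if not set(self.phospho_positions) <= acceptors:
            raise ValueError("phospho position on a non-S/T/Y residue")

    def localized_string(self, probabilities: dict[int, float] | None = None) -> str:
        """Render e.g. ``AAS(0.75)LS(0.25)K``; bare positions get 1.0."""
        probs = probabilities or {p: 1.0 for p in self.phospho_positions}
        out = []
        for i, aa in enumerate(self.parent.sequence, start=1):
            out.append(aa)
            if i in probs:
                out.append(f"({probs[i]:g})")
        return "".join(out)


@dataclass(frozen=True)
class FragmentIon:
    series: str                # 'b' or 'y'
    index: int                 # 1..len-1
    charge: int
    mz: float
    carries_phospho_count: int
    neutral_loss: str = "none"  # 'none' or 'H3PO4'

    @property
    def label(self) -> str:
        loss = "-H3PO4" if self.neutral_loss == "H3PO4" else ""
        return f"{self.series}{self.index}{loss}^{self.charge}"


def enumerate_site_candidates(peptide: ModifiedPeptide) -> list[SiteCandidate]:
    """All C(n_acceptors, p) phospho placements, lexicographic by position tuple."""
    p = peptide.variable_phospho_count
    acceptors = peptide.candidate_residues
    if p == 0:
        raise ValueError("nothing to localize: peptide carries no variable phospho")
    if p > len(acceptors):
        raise ValueError(
            f"no valid site combination: {p} phospho groups but only "
            f"{len(acceptors)} acceptor residues in {peptide.sequence!r}")
    return [SiteCandidate(peptide, combo)
            for combo in itertools.combinations(acceptors, p)]


def theoretical_fragments(candidate: SiteCandidate, charges: tuple[int, ...] = (1, 2),
                          neutral_losses: bool = False) -> list[FragmentIon]:
    """All b/y ions of one candidate at the requested charges.

    Phospho mass is added to every fragment spanning a phospho position; with
    ``neutral_losses`` each phospho-bearing fragment gains a -H3PO4 twin.
    b1 ions are generated: the b1 of an N-terminal phospho-residue is
    maximally site-determining.
    """
    seq = candidate.parent.sequence
    n = len(seq)
    fixed = dict(candidate.parent.fixed_mods)
    phospho = set(candidate.phospho_positions)

    # cumulative residue + fixed-mod masses, positions 1..n
    cum = np.zeros(n + 1)
    for i, aa in enumerate(seq, start=1):
        cum[i] = cum[i - 1] + residue_mass(aa) + fixed.get(i, 0.0)

    ions: list[FragmentIon] = []
    for idx in range(1, n):
        nb = sum(1 for p in phospho if p <= idx)        # phosphos on b_idx
        ny = len(phospho) - nb                          # phosphos on y_(n-idx)
        b_neutral = cum[idx] + nb * PHOSPHO
        y_neutral = (cum[n] - cum[idx]) + WATER + ny * PHOSPHO
        for series, frag_idx, neutral, np_ in (("b", idx, b_neutral, nb),
                                               ("y", n - idx, y_neutral, ny)):
            for z in sorted(charges):
                ions.append(FragmentIon(series, frag_idx, z,
                                        neutral / z + PROTON, np_))
                if neutral_losses and np_ > 0:
                    ions.append(FragmentIon(series, frag_idx, z,
                                            (neutral + H3PO4_LOSS) / z + PROTON,
                                            np_, neutral_loss="H3PO4"))
    return ions


@dataclass
class UniqueMass:
    """One deduplicated fragment m/z with its per-candidate evidence role."""

    mz: float
    #: representative ion labels (one per candidate whose set contains the mass)
    labels: tuple[str, ...]
    #: role per candidate index: 'confirming' | 'refuting' | 'neutral'
    roles: tuple[str, ...] = field(default=())

    @property
    def is_site_determining(self) -> bool:
        return any(r != "neutral" for r in self.roles)


def site_determining_fragment_sets(candidates: list[SiteCandidate],
                                   charges: tuple[int, ...] = (1, 2),
                                   neutral_losses: bool = False,
                                   tol: float = MASS_DEDUP_TOL) -> list[UniqueMass]:
    """Union of all candidates' fragment m/z, deduplicated and role-annotated.

    A unique mass is *confirming* for a candidate if it lies in that
    candidate's theoretical set but not in every candidate's set, *refuting*
    if it lies in at least one other candidate's set but not this one's, and
    *neutral* if all candidates share it.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    parent = candidates[0].parent
    if any(c.parent != parent for c in candidates):
        raise ValueError("candidates must share one parent peptide")

    per_candidate = [theoretical_fragments(c, charges, neutral_losses) for c in candidates]
    flat = [(ion.mz, ci, ion.label) for ci, ions in enumerate(per_candidate) for ion in ions]
    flat.sort(key=lambda t: t[0])

    n_cand = len(candidates)
    out: list[UniqueMass] = []
    cluster: list[tuple[float, int, str]] = []

    def _flush() -> None:
        if not cluster:
            return
        members = {ci for _, ci, _ in cluster}
        roles = tuple("neutral" if len(members) == n_cand
                      else ("confirming" if ci in members else "refuting")
                      for ci in range(n_cand))
        out.append(UniqueMass(mz=float(np.mean([m for m, _, _ in cluster])),
                              labels=tuple(sorted({lab for _, _, lab in cluster})),
                              roles=roles))

    for item in flat:
        if cluster and item[0] - cluster[-1][0] > tol:
            _flush()
            cluster = []
        cluster.append(item)
    _flush()
    return out
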