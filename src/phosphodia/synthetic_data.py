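"""Ground-truth generators for the three benchmark designs.

Three simulations with known truth make every pipeline stage testable:

* :func:`simulate_dia_run` — a DIA map (MS1 + windowed MS2 scans) containing
  phosphopeptides whose positional isomers co-elute at controlled mixing
  ratios inside 14-Da isolation windows, with Gaussian elution profiles,
  log-normal intensity noise and random interference peaks; the analog of
  spiking synthetic phosphopeptides into a constant background.
* :func:`simulate_species_mix` — the mixed-species ratio design: a constant
  background population plus a regulated subpopulation scaled by condition
  ratios 0.25/0.5/1.5/2 against a 1:1 reference.
* :func:`simulate_stoichiometry_benchmark` — phospho / counterpart / protein
  intensity triplets at fixed occupancies {1, 10, 50, 90, 99}%.

All generators are deterministic given their seed, and each returns a truth
table sufficient to score any downstream estimate without the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .dia_extraction import (IsolationWindow, SpectrumRecord, assign_windows,
                             build_window_scheme)
from .peptide_model import (ModifiedPeptide, SiteCandidate, theoretical_fragments)

__all__ = [
    "RosterEntry", "SynthDIAConfig", "simulate_dia_run", "random_roster",
    "simulate_species_mix", "simulate_stoichiometry_benchmark",
    "RATIO_CONDITIONS", "OCCUPANCY_CONDITIONS",
]

#: Regulated-subpopulation mixing ratios of the ratio benchmark (vs 1:1 reference).
RATIO_CONDITIONS = (0.25, 0.5, 1.5, 2.0)
#: Occupancy grid of the stoichiometry benchmark.
OCCUPANCY_CONDITIONS = (0.01, 0.10, 0.50, 0.90, 0.99)


@dataclass
class RosterEntry:
    """One precursor in a simulated DIA run.

    ``isomer_ratios`` maps a phospho-position tuple to its mixing fraction;
    fractions must sum to 1. All isomers share the apex by default (the
    hardest localization case); per-isomer rt offsets are configurable.
    """

    sequence: str
    charge: int = 2
    isomer_ratios: dict[tuple[int, ...], float] = field(default_factory=dict)
    abundance: float = 1e6
    apex_rt: float = 60.0
    rt_offsets: dict[tuple[int, ...], float] = field(default_factory=dict)

    @property
    def phospho_count(self) -> int:
        return len(next(iter(self.isomer_ratios)))

    @property
    def peptide(self) -> ModifiedPeptide:
        return ModifiedPeptide(self.sequence, self.phospho_count)

    def __post_init__(self) -> None:
        if not self.isomer_ratios:
            raise ValueError("roster entry needs at least one isomer")
        total = sum(self.isomer_ratios.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isomer mixing ratios must sum to 1, got {total}")


@dataclass
class SynthDIAConfig:
    roster: list[RosterEntry]
    window_start: float = 350.0
    window_width: float = 14.0
    window_overlap: float = 1.0
    window_count: int = 48
    gradient_seconds: float = 120.0
    cycle_seconds: float = 3.0
    elution_sigma: float = 5.0
    snr: float = 50.0                  # multiplicative noise cv = 1/snr; inf -> noiseless
    interference_density: float = 0.0  # expected interference peaks per MS2 scan
    fragment_charges: tuple[int, ...] = (1,)
    uniform_fragment_intensities: bool = False
    isotope_peaks: int = 2             # M+0..M+(k-1) emitted per fragment
    seed: int = 0

    def scheme(self) -> list[IsolationWindow]:
        return build_window_scheme(self.window_start, self.window_width,
                                   self.window_overlap, self.window_count)


def _gaussian(rt: np.ndarray, apex: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((rt - apex) / sigma) ** 2)


def simulate_dia_run(config: SynthDIAConfig
                     ) -> tuple[list[SpectrumRecord], pd.DataFrame, dict]:
    """Forward-simulate a DIA run.

    Returns ``(run, truth, library)`` where ``run`` is the time-ordered scan
    list, ``truth`` one row per precursor (sequence, charge, true isomer
    positions and ratios, apex rt, abundance, window), and ``library`` maps
    ``(sequence, charge)`` to the fragment-label -> relative-intensity dict
    of the mixed isomer population (what a project-specific spectral library
    would contain).
    """
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme()
    cycle_rts = np.arange(0.0, config.gradient_seconds, config.cycle_seconds)
    noise_cv = 0.0 if np.isinf(config.snr) else 1.0 / config.snr
    noise_sigma = np.sqrt(np.log1p(noise_cv ** 2))

    # precompute per-precursor fragment ions and relative intensities
    precursors = []
    truth_rows = []
    library: dict = {}
    for entry in config.roster:
        peptide = entry.peptide
        mz = peptide.mz(entry.charge)
        windows = sorted(assign_windows(mz, scheme))
        if not windows:
            raise ValueError(
                f"precursor {entry.sequence}/{entry.charge} m/z {mz:.3f} "
                f"outside window scheme")
        isomers = []
        lib_intensities: dict[str, float] = {}
        for positions, fraction in sorted(entry.isomer_ratios.items()):
            cand = SiteCandidate(peptide, tuple(sorted(positions)))
            ions = theoretical_fragments(cand, charges=config.fragment_charges)
            if config.uniform_fragment_intensities:
                rel = np.ones(len(ions))
            else:
                rel = rng.lognormal(0.0, 0.6, size=len(ions))
            rel = rel / rel.max()
            envs = []
            for ion in ions:
                if config.isotope_peaks > 0:
                    env = chem.isotope_envelope(
                        (ion.mz - chem.PROTON) * ion.charge, ion.charge,
                        n_peaks=config.isotope_peaks + 1)
                    envs.append(tuple(ab / env.relative_abundances[0]
                                      for ab in env.relative_abundances))
                else:
                    envs.append((1.0,))
            isomers.append((positions, fraction, ions, rel, envs))
            for ion, r in zip(ions, rel):
                lib_intensities[ion.label] = lib_intensities.get(ion.label, 0.0) + fraction * r
        library[(entry.sequence, entry.charge)] = lib_intensities
        ms1_env = chem.isotope_envelope((mz - chem.PROTON) * entry.charge,
                                        entry.charge, n_peaks=config.isotope_peaks + 1)
        precursors.append((entry, mz, windows, isomers, ms1_env))
        truth_rows.append({
            "sequence": entry.sequence, "charge": entry.charge,
            "phospho_count": entry.phospho_count,
            "true_positions": ";".join(
                ",".join(map(str, pos)) for pos in sorted(entry.isomer_ratios)),
            "mixing_ratios": ";".join(
                f"{entry.isomer_ratios[pos]:g}" for pos in sorted(entry.isomer_ratios)),
            "apex_rt": entry.apex_rt, "abundance": entry.abundance,
            "precursor_mz": mz, "window_index": windows[0],
        })

    def _noisy(x: np.ndarray | float) -> np.ndarray | float:
        if noise_sigma == 0:
            return x
        return x * rng.lognormal(-0.5 * noise_sigma ** 2, noise_sigma,
                                 size=np.shape(x) or None)

    run: list[SpectrumRecord] = []
    frag_lo, frag_hi = 100.0, 1500.0
    for rt in cycle_rts:
        # MS1 scan: precursor isotope envelopes
        mzs, intens = [], []
        for entry, mz, windows, isomers, ms1_env in precursors:
            elut = entry.abundance * float(np.exp(
                -0.5 * ((rt - entry.apex_rt) / config.elution_sigma) ** 2))
            if elut <= entry.abundance * 1e-6:
                continue
            for k, ab in enumerate(ms1_env.relative_abundances):
                mzs.append(mz + k * chem.NEUTRON / entry.charge)
                intens.append(float(_noisy(elut * ab)))
        run.append(SpectrumRecord(1, float(rt), np.array(mzs), np.array(intens)))

        # one MS2 scan per window
        for window in scheme:
            mzs, intens = [], []
            for entry, mz, windows, isomers, _ms1_env in precursors:
                if window.index not in windows:
                    continue
                for positions, fraction, ions, rel, envs in isomers:
                    apex = entry.apex_rt + entry.rt_offsets.get(positions, 0.0)
                    elut = entry.abundance * fraction * float(np.exp(
                        -0.5 * ((rt - apex) / config.elution_sigma) ** 2))
                    if elut <= entry.abundance * 1e-6:
                        continue
                    for ion, r, env in zip(ions, rel, envs):
                        base = float(_noisy(elut * r))
                        if base <= 0:
                            continue
                        for k, ab in enumerate(env):
                            mzs.append(ion.mz + k * chem.NEUTRON / ion.charge)
                            intens.append(base * ab)
            n_interference = rng.poisson(config.interference_density)
            for _ in range(n_interference):
                mzs.append(float(rng.uniform(frag_lo, frag_hi)))
                intens.append(float(rng.lognormal(np.log(1e4), 1.0)))
            mz_arr = np.array(mzs)
            inten_arr = np.array(intens)
            # merge coincident centroids
            if mz_arr.size:
                order = np.argsort(mz_arr)
                mz_arr, inten_arr = mz_arr[order], inten_arr[order]
                keep_mz, keep_int = [mz_arr[0]], [inten_arr[0]]
                for m, i in zip(mz_arr[1:], inten_arr[1:]):
                    if m - keep_mz[-1] < 1e-6:
                        keep_int[-1] += i
                    else:
                        keep_mz.append(m)
                        keep_int.append(i)
                mz_arr, inten_arr = np.array(keep_mz), np.array(keep_int)
            run.append(SpectrumRecord(2, float(rt), mz_arr, inten_arr, window=window))

    truth = pd.DataFrame(truth_rows)
    return run, truth, library


_ROSTER_RESIDUES = "ACDEFGHILMNPQVW"  # non-acceptor, non-K/R body residues


def random_roster(n: int, rng: np.random.Generator, scheme_range=(350.0, 975.0),
                  charge: int = 2, abundance: float = 1e6,
                  gradient_seconds: float = 120.0) -> list[RosterEntry]:
    """Random tryptic-like singly phosphorylated peptides with >= 2 acceptor
    residues each (so localization is never trivial), one true site per
    peptide, precursor m/z constrained to the window scheme."""
    roster: list[RosterEntry] = []
    attempts = 0
    while len(roster) < n and attempts < 100 * n:
        attempts += 1
        length = int(rng.integers(8, 15))
        body = list(rng.choice(list(_ROSTER_RESIDUES), size=length - 1))
        n_sty = int(rng.integers(2, 4))
        positions = rng.choice(length - 1, size=n_sty, replace=False)
        for pos in positions:
            body[pos] = str(rng.choice(list("STY")))
        seq = "".join(body) + str(rng.choice(["K", "R"]))
        peptide = ModifiedPeptide(seq, 1)
        mz = peptide.mz(charge)
        if not scheme_range[0] + 0.5 <= mz <= scheme_range[1] - 0.5:
            continue
        acceptors = peptide.candidate_residues
        true_site = int(rng.choice(acceptors))
        apex = float(rng.uniform(0.25, 0.75) * gradient_seconds)
        roster.append(RosterEntry(
            sequence=seq, charge=charge, isomer_ratios={(true_site,): 1.0},
            abundance=abundance * float(rng.lognormal(0, 0.3)), apex_rt=apex))
    if len(roster) < n:
        raise RuntimeError("could not generate enough in-range peptides")
    return roster


def simulate_species_mix(n_background: int = 1000, n_regulated: int = 200,
                         ratios: tuple[float, ...] = RATIO_CONDITIONS,
                         cv: float = 0.10, replicates: int = 3,
                         seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mixed-species ratio benchmark quant table.

    Background features (the constant-species pool) keep their abundance in
    every condition; regulated features (the spiked species) are scaled by
    the condition ratio relative to the 1:1 reference. Intensities are
    log-normal with multiplicative replicate noise at the given CV.

    Returns ``(quant, truth)``: quant has one row per feature and one column
    per ``(condition, replicate)`` (reference condition labelled 1.0), truth
    gives each feature's class and per-condition expected ratio.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    rng = np.random.default_rng(seed)
    n = n_background + n_regulated
    base = rng.lognormal(np.log(1e6), 1.0, size=n)
    is_regulated = np.zeros(n, dtype=bool)
    is_regulated[n_background:] = True
    conditions = (1.0,) + tuple(ratios)
    sigma = np.sqrt(np.log1p(cv ** 2))

    cols = {}
    for cond in conditions:
        scale = np.where(is_regulated, cond, 1.0)
        for rep in range(1, replicates + 1):
            noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=n) if sigma > 0 else 1.0
            cols[(cond, rep)] = base * scale * noise
    quant = pd.DataFrame(cols)
    quant.columns = pd.MultiIndex.from_tuples(quant.columns,
                                              names=["condition", "replicate"])
    quant.index.name = "feature"
    truth = pd.DataFrame({
        "feature": np.arange(n), "regulated": is_regulated,
        "base_intensity": base,
    }).set_index("feature")
    for cond in conditions:
        truth[f"expected_ratio_{cond:g}"] = np.where(is_regulated, cond, 1.0)
    return quant, truth


def simulate_stoichiometry_benchmark(occupancies: tuple[float, ...] = OCCUPANCY_CONDITIONS,
                                     n_sites: int = 500, cv: float = 0.10,
                                     replicates: int = 3, alpha: float = 1.0,
                                     beta: float = 1.0, seed: int = 0
                                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stoichiometry benchmark: (P, N, Q, truth) tables.

    Per site, protein abundance is log-normal; each condition fixes the true
    occupancy ``a`` and every replicate observes P = a*Q0/alpha' noise and
    N = (1-a)*Q0/beta' noise with independent log-normal noise at the given
    CV (``alpha``/``beta`` are the generative response factors, both 1 by
    default so the observed protein satisfies Q = alpha*P + beta*N in
    expectation). Conditions follow the benchmark's occupancy grid
    {1, 10, 50, 90, 99}%.

    P, N, Q have one row per site and a (condition, replicate) MultiIndex
    column per measurement; truth has one row per site x condition.
    """
    for a in occupancies:
        if not 0.0 < a < 1.0:
            raise ValueError(f"occupancy {a} is degenerate; must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv ** 2))
    q0 = rng.lognormal(np.log(1e7), 1.0, size=n_sites)

    def noise() -> np.ndarray:
        if sigma == 0:
            return np.ones(n_sites)
        return rng.lognormal(-0.5 * sigma ** 2, sigma, size=n_sites)

    P_cols, N_cols, Q_cols, truth_rows = {}, {}, {}, []
    for a in occupancies:
        for rep in range(1, replicates + 1):
            P_cols[(a, rep)] = (a * q0 / alpha) * noise()
            N_cols[(a, rep)] = ((1.0 - a) * q0 / beta) * noise()
            Q_cols[(a, rep)] = q0 * noise()
        truth_rows.append({"condition": a, "true_occupancy": a})

    def frame(cols: dict) -> pd.DataFrame:
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(df.columns,
                                               names=["condition", "replicate"])
        df.index.name = "site"
        return df

    truth = pd.DataFrame(truth_rows)
    return frame(P_cols), frame(N_cols), frame(Q_cols), truth
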