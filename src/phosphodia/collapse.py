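"""Precursor-report collapse: peptide-level and MaxQuant-like site tables.

Input is a long-format precursor report emulating a Spectronaut "normal
report". Expected columns (Spectronaut equivalents in parentheses):

==========================  =================================
run                         R.FileName
modified_sequence           EG.ModifiedSequence
charge                      FG.Charge
protein                     PG.ProteinAccessions
peptide_start               PEP.PeptidePosition (1-based)
localization_probabilities  EG.PTMLocalizationProbabilities
assay_probability           EG.PTMAssayProbability
quantity                    FG.Quantity
normalization_factor        EG.NormalizationFactor
==========================  =================================

Collapse sums charge states in linear intensity space and log2-transforms
afterwards; missing values stay missing, never zero. Site-level collapse
explodes each localized phospho position at or above the probability cutoff
into a (protein, protein position, multiplicity) site key, MaxQuant style,
where multiplicity is the phospho count of the contributing peptide.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

__all__ = [
    "parse_localization_string", "collapse_to_modified_peptides",
    "collapse_to_sites", "denormalize_and_requantile",
]

_LOC_TOKEN = re.compile(r"([A-Z])(\(([0-9.eE+-]+)\))?")

REQUIRED_COLUMNS = ("run", "modified_sequence", "charge", "quantity")


def parse_localization_string(s: str) -> dict[int, float]:
    """Parse ``"AAS(0.75)LS(0.25)K"`` into {1-based position: probability}."""
    if not isinstance(s, str) or not s:
        raise ValueError(f"malformed localization string: {s!r}")
    probs: dict[int, float] = {}
    pos = 0
    cursor = 0
    for m in _LOC_TOKEN.finditer(s):
        if m.start() != cursor:
            raise ValueError(f"malformed localization string at offset {cursor}: {s!r}")
        cursor = m.end()
        pos += 1
        if m.group(3) is not None:
            p = float(m.group(3))
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"probability {p} outside [0, 1] at position {pos} in {s!r}")
            probs[pos] = p
    if cursor != len(s):
        raise ValueError(f"malformed localization string at offset {cursor}: {s!r}")
    return probs


def _check_columns(df: pd.DataFrame, extra: tuple[str, ...] = ()) -> None:
    missing = [c for c in (*REQUIRED_COLUMNS, *extra) if c not in df.columns]
    if missing:
        raise ValueError(f"missing column: {', '.join(missing)}")


def collapse_to_modified_peptides(report: pd.DataFrame,
                                  grouping: str = "assay_probability",
                                  cutoff: float = 0.0,
                                  log2: bool = True) -> pd.DataFrame:
    """Collapse a precursor report to modification-specific peptide level.

    Rows sharing (modified_sequence, run) — i.e. charge states — are summed
    in linear intensity space; log2 is applied afterwards. Groups whose best
    value in the grouping column falls below ``cutoff`` are dropped (the
    peptide-level dilution benchmark uses the assay probability column with
    cutoff 0, so nothing is dropped there).

    Returns a wide table: one row per modified sequence, one quantity column
    per run.
    """
    _check_columns(report)
    if grouping not in ("assay_probability", "localized_sequence"):
        raise ValueError(f"unknown grouping column: {grouping}")
    df = report.copy()
    if grouping == "assay_probability":
        if "assay_probability" not in df.columns:
            raise ValueError("missing column: assay_probability")
        gate = df.groupby("modified_sequence")["assay_probability"].max()
    else:
        if "localization_probabilities" not in df.columns:
            raise ValueError("missing column: localization_probabilities")
        # a precursor is localized if its worst site probability clears the
        # cutoff; the group passes on its best-localized precursor
        worst = df["localization_probabilities"].map(
            lambda s: min(parse_localization_string(s).values(), default=1.0))
        gate = worst.groupby(df["modified_sequence"]).max()
    keep = gate[gate >= cutoff].index
    df = df[df["modified_sequence"].isin(keep)]

    summed = (df.groupby(["modified_sequence", "run"], sort=True)["quantity"]
              .sum().unstack("run"))
    if log2:
        summed = np.log2(summed.where(summed > 0))
    return summed


def collapse_to_sites(report: pd.DataFrame, cutoff: float = 0.75,
                      log2: bool = False) -> pd.DataFrame:
    """Collapse a precursor report to MaxQuant-like phosphosite level.

    Every phospho position whose localization probability reaches ``cutoff``
    becomes a site keyed by (protein, 1-based protein position,
    multiplicity); quantities of all contributing precursors are summed per
    run and the best probability per site is retained. Multiplicity — the
    number of phospho groups on the contributing peptide — is part of the
    key, so singly and doubly phosphorylated evidence stays in separate rows.
    """
    _check_columns(report, ("protein", "peptide_start", "localization_probabilities"))
    if report["peptide_start"].isna().any():
        bad = report.loc[report["peptide_start"].isna(), "modified_sequence"].unique()
        raise ValueError(f"peptide_start missing for sequences: {', '.join(map(str, bad))}")

    records = []
    for row in report.itertuples(index=False):
        probs = parse_localization_string(row.localization_probabilities)
        multiplicity = int(round(sum(probs.values())))
        protein = str(row.protein).split(";")[0]
        for pep_pos, p in probs.items():
            if p < cutoff:
                continue
            records.append({
                "protein": protein,
                "position": int(row.peptide_start) + pep_pos - 1,
                "multiplicity": multiplicity,
                "run": row.run,
                "quantity": row.quantity,
                "probability": p,
            })
    if not records:
        return pd.DataFrame(columns=["quantity"]).rename_axis(
            ["protein", "position", "multiplicity", "run"])
    long = pd.DataFrame.from_records(records)
    agg = (long.groupby(["protein", "position", "multiplicity", "run"])
           .agg(quantity=("quantity", "sum"), best_probability=("probability", "max")))
    wide = agg["quantity"].unstack("run")
    if log2:
        wide = np.log2(wide.where(wide > 0))
    best = agg["best_probability"].groupby(["protein", "position", "multiplicity"]).max()
    wide.insert(0, "best_probability", best)
    return wide


def denormalize_and_requantile(table: pd.DataFrame,
                               factors: pd.Series | dict | None = None,
                               mode: str = "denormalize") -> pd.DataFrame:
    """Undo run-wise normalization or quantile-normalize intensity columns.

    mode='denormalize' divides each run column by its normalization factor
    (recovering raw intensities from a locally normalized report);
    mode='quantile' maps every column onto the mean sorted profile so all
    columns share identical sorted values afterwards. Missing entries keep
    their rank semantics and stay missing.
    """
    if mode == "denormalize":
        if factors is None:
            raise ValueError("denormalize mode requires normalization factors")
        factors = pd.Series(factors)
        if (factors <= 0).any():
            bad = factors[factors <= 0].index.tolist()
            raise ValueError(f"non-positive normalization factor for runs: {bad}")
        out = table.copy()
        for run, f in factors.items():
            if run in out.columns:
                out[run] = out[run] / f
        return out
    if mode == "quantile":
        num = table.select_dtypes(include=[np.number])
        ranks = num.rank(method="first")
        sorted_cols = {c: np.sort(num[c].dropna().values) for c in num.columns}
        n_ref = max((len(v) for v in sorted_cols.values()), default=0)
        if n_ref == 0:
            return table.copy()
        grid = np.linspace(0, 1, n_ref)
        interped = [np.interp(grid, np.linspace(0, 1, len(v)), v)
                    for v in sorted_cols.values() if len(v) > 0]
        reference = np.mean(interped, axis=0)
        out = table.copy()
        for c in num.columns:
            valid = num[c].notna()
            k = int(valid.sum())
            if k == 0:
                continue
            target = np.interp(np.linspace(0, 1, k), grid, reference)
            out.loc[valid, c] = target[(ranks.loc[valid, c].astype(int) - 1).values]
        return out
    raise ValueError(f"unknown mode: {mode}")
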