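"""Phosphosite occupancy (fractional stoichiometry) from label-free data.

The model: if a protein pool of abundance Q carries a site phosphorylated at
occupancy a, the phosphopeptide reports P proportional to a*Q and its
non-phosphorylated counterpart reports N proportional to (1-a)*Q, each with
its own response factor:

    Q_i = alpha * P_i + beta * N_i        (plane through the origin)

Fitting (alpha, beta) by nonnegative least squares over every condition x
replicate point — the 3D multiple-regression model — gives the occupancy of
condition i as

    a_i = alpha * P_i / (alpha * P_i + beta * N_i)

which is invariant to a common rescaling of (alpha, beta). The classical
two-condition closed form (from the SILAC occupancy literature) is kept as
:func:`occupancy_two_condition`; with exactly two noiseless conditions the
regression reproduces it.

Missing P or N entries can first be filled by linear-behavior extrapolation:
peptide forms of the same group (charge states, missed cleavages) scale
together, so a missing entry is predicted from the best-correlated donor
form by a least-squares line in log-intensity space.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

__all__ = [
    "occupancy_two_condition", "extrapolate_missing", "fit_3dmm",
    "StoichiometryModel", "OccupancyFit",
]


def occupancy_two_condition(x: float, y: float, z: float,
                            clip: bool = True) -> tuple[float, float, bool]:
    """Closed-form occupancies from A/B ratios of phosphopeptide (x),
    counterpart peptide (y) and protein (z).

    Returns (a_A, a_B, clipped_flag). The pair solves
    a_B = (z - y)/(x - y) and a_A = x*(z - y)/(z*(x - y)).
    """
    if x <= 0 or y <= 0 or z <= 0:
        raise ValueError("ratios must be positive")
    if x == y:
        raise ValueError("indeterminate occupancy: phospho and counterpart ratios equal")
    a_b = (z - y) / (x - y)
    a_a = x * (z - y) / (z * (x - y))
    clipped = not (0.0 <= a_a <= 1.0 and 0.0 <= a_b <= 1.0)
    if clip:
        a_a, a_b = float(np.clip(a_a, 0, 1)), float(np.clip(a_b, 0, 1))
    return a_a, a_b, clipped


def extrapolate_missing(matrix: pd.DataFrame, min_shared: int = 2
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing entries of peptide forms from their best-correlated donor.

    ``matrix`` holds one row per peptide form of a single group and one
    column per sample, linear intensities. For each row with missing entries
    the donor row with the highest Pearson correlation over >= ``min_shared``
    shared log-intensity observations is selected; a least-squares line in
    log space predicts the missing values. Entries with no eligible donor
    stay missing.

    Returns (filled matrix, boolean imputed mask).
    """
    log = np.log(matrix.where(matrix > 0))
    filled = matrix.copy().astype(float)
    imputed = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
    for target in matrix.index:
        trow = log.loc[target]
        missing = trow[trow.isna()].index
        if len(missing) == 0:
            continue
        best_r, best_donor = -np.inf, None
        for donor in matrix.index:
            if donor == target:
                continue
            drow = log.loc[donor]
            shared = trow.notna() & drow.notna()
            if shared.sum() < min_shared:
                continue
            if shared.sum() == 2:
                r = 1.0  # a line fits two points exactly; correlation undefined
            else:
                r = pearsonr(drow[shared], trow[shared])[0]
            if r > best_r:
                best_r, best_donor = r, donor
        if best_donor is None:
            continue
        drow = log.loc[best_donor]
        shared = trow.notna() & drow.notna()
        slope, intercept = np.polyfit(drow[shared], trow[shared], 1)
        for col in missing:
            if np.isnan(drow[col]):
                continue
            filled.loc[target, col] = float(np.exp(slope * drow[col] + intercept))
            imputed.loc[target, col] = True
    return filled, imputed


@dataclass
class OccupancyFit:
    """Results of a 3DMM occupancy fit for one site.

    alpha and beta are the nonnegative response factors of the phospho and
    counterpart peptide; occupancies are per condition on replicate means.
    """

    alpha: float
    beta: float
    conditions: list
    occupancies: np.ndarray
    clipped: np.ndarray
    degenerate: bool
    residual: float
    n_points: int
    model: "StoichiometryModel | None" = field(default=None, repr=False)

    def occupancy(self, condition) -> float:
        return float(self.occupancies[self.conditions.index(condition)])

    def summary(self) -> str:
        buf = io.StringIO()
        print("3DMM phosphosite occupancy fit", file=buf)
        print("=" * 46, file=buf)
        print(f"points: {self.n_points}    residual norm: {self.residual:.4g}", file=buf)
        print(f"alpha (phospho response):     {self.alpha:.6g}", file=buf)
        print(f"beta (counterpart response):  {self.beta:.6g}", file=buf)
        if self.degenerate:
            print("WARNING: degenerate fit (a response factor is zero)", file=buf)
        print("-" * 46, file=buf)
        print(f"{'condition':>12} {'occupancy':>12} {'clipped':>8}", file=buf)
        for c, a, cl in zip(self.conditions, self.occupancies, self.clipped):
            print(f"{str(c):>12} {a:12.4f} {str(bool(cl)):>8}", file=buf)
        return buf.getvalue()


class StoichiometryModel:
    """Label-free 3D multiple-regression occupancy model for one site.

    Parameters
    ----------
    P, N, Q
        DataFrames (condition x replicate) or 2-D arrays of linear-scale
        phosphopeptide, counterpart-peptide and protein intensities.
        Conditions are rows; NaN marks missing replicates.
    """

    def __init__(self, P, N, Q, conditions=None):
        self.P = self._as_frame(P, conditions)
        self.N = self._as_frame(N, conditions)
        self.Q = self._as_frame(Q, conditions)
        if not (self.P.shape == self.N.shape == self.Q.shape):
            raise ValueError("P, N, Q must share shape (conditions x replicates)")
        self.conditions = list(self.P.index)

    @staticmethod
    def _as_frame(x, conditions) -> pd.DataFrame:
        if isinstance(x, pd.DataFrame):
            return x.astype(float)
        arr = np.atleast_2d(np.asarray(x, dtype=float))
        idx = conditions if conditions is not None else list(range(arr.shape[0]))
        return pd.DataFrame(arr, index=idx)

    @classmethod
    def from_tables(cls, sites: pd.DataFrame, counterparts: pd.DataFrame,
                    proteins: pd.DataFrame, site_key, peptide_key, protein_key,
                    condition_of: dict) -> "StoichiometryModel":
        """Assemble one site's triplet from collapse-style wide tables.

        ``condition_of`` maps run column -> condition label; replicates are
        the runs of each condition in column order.
        """
        def pivot(row: pd.Series) -> pd.DataFrame:
            groups: dict = {}
            for run, value in row.items():
                cond = condition_of.get(run)
                if cond is None:
                    continue
                groups.setdefault(cond, []).append(value)
            width = max(len(v) for v in groups.values())
            data = {c: v + [np.nan] * (width - len(v)) for c, v in groups.items()}
            return pd.DataFrame.from_dict(data, orient="index")

        return cls(pivot(sites.loc[site_key]), pivot(counterparts.loc[peptide_key]),
                   pivot(proteins.loc[protein_key]))

    def fit(self, extrapolate: bool = False) -> OccupancyFit:
        """Nonnegative least squares for (alpha, beta), then per-condition
        occupancy on replicate means. Requires >= 2 conditions with complete
        (P, N, Q) triplets."""
        P, N, Q = self.P, self.N, self.Q
        if extrapolate:
            P, _ = extrapolate_missing(P)
            N, _ = extrapolate_missing(N)
        mask = P.notna() & N.notna() & Q.notna()
        complete_conditions = mask.any(axis=1)
        if complete_conditions.sum() < 2:
            raise ValueError("insufficient conditions: need >= 2 with complete triplets")
        p = P.values[mask.values]
        n = N.values[mask.values]
        q = Q.values[mask.values]
        coef, residual = nnls(np.column_stack([p, n]), q)
        alpha, beta = float(coef[0]), float(coef[1])
        degenerate = bool(alpha == 0.0 or beta == 0.0)

        p_mean = P.mean(axis=1, skipna=True).values
        n_mean = N.mean(axis=1, skipna=True).values
        denom = alpha * p_mean + beta * n_mean
        with np.errstate(invalid="ignore", divide="ignore"):
            occ = np.where(denom > 0, alpha * p_mean / denom, np.nan)
        if np.all(np.nan_to_num(n_mean) == 0):
            occ = np.where(np.isnan(occ), 1.0, occ)
            degenerate = True
        clipped = (occ < 0) | (occ > 1)
        occ = np.clip(occ, 0.0, 1.0)
        return OccupancyFit(alpha=alpha, beta=beta, conditions=self.conditions,
                            occupancies=occ, clipped=clipped, degenerate=degenerate,
                            residual=float(residual), n_points=int(mask.values.sum()),
                            model=self)


def fit_3dmm(P, N, Q, conditions=None, extrapolate: bool = False) -> OccupancyFit:
    """Functional wrapper: build a :class:`StoichiometryModel` and fit it."""
    return StoichiometryModel(P, N, Q, conditions=conditions).fit(extrapolate=extrapolate)
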