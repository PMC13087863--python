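"""Composition-thermostability analysis.

After a campaign, the evaluated sequences form a dataset linking residue
composition to melting temperature.  Two analyses are provided:

* Spearman rank screens of Tm against simple composition descriptors
  (number of charged residues, number of hydrophobic residues, and the
  count of each individual residue);
* a linear residue-count regression ``Tm_hat = c + sum_i alpha_i C_i``
  where ``C_i`` is the count of residue type ``i`` over the four variable
  hexamer positions.  The counts always sum to four, so the design matrix
  is exactly collinear with the intercept and the coefficients are
  identifiable only up to that null space; the minimum-norm least-squares
  solution is used, which leaves the predictions, RMSE and rank
  correlation well defined.

A small packaged table of published Tm / denaturation free-energy pairs
for thirteen reference sequences supports the Tm-vs-deltaF concordance
analysis (the natural-collagen control is excluded from the rank
correlation as a kinetically trapped outlier).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantInput, DegenerateDesign, LengthMismatch
from .palette import composition_vector

__all__ = [
    "CompositionModel", "spearman", "fit_composition_model",
    "composition_screens", "stability_table", "tm_deltaF_concordance",
]


@dataclass
class CompositionModel:
    intercept: float                 # K
    coefficients: dict               # residue code -> K per count
    rmse: float                      # K, in-sample
    spearman_fit: float              # rank corr of predicted vs observed Tm
    residue_order: list

    def predict(self, sequences) -> np.ndarray:
        X = _count_matrix(sequences, self.residue_order)
        alpha = np.array([self.coefficients[r] for r in self.residue_order])
        return self.intercept + X @ alpha


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value comes from the large-sample t approximation.  Raises
    :class:`ConstantInput` when either series is constant (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise LengthMismatch(f"lengths differ: {x.size} vs {y.size}")
    if x.size < 3:
        raise LengthMismatch("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInput("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _codes(sequences) -> list[str]:
    return [s if isinstance(s, str) else s.hexamer_code for s in sequences]


def _count_matrix(sequences, residue_order) -> np.ndarray:
    rows = []
    for code in _codes(sequences):
        cv = composition_vector(code)
        rows.append([cv.counts.get(r, 0) for r in residue_order])
    return np.asarray(rows, dtype=float)


def fit_composition_model(sequences, tm_values) -> CompositionModel:
    """Minimum-norm least squares of Tm on residue counts (plus intercept)."""
    codes = _codes(sequences)
    y = np.asarray(tm_values, dtype=float)
    if len(codes) != y.size:
        raise LengthMismatch("sequences and Tm values differ in length")
    residues = sorted({r for c in codes for r in composition_vector(c).counts})
    X = _count_matrix(codes, residues)
    if len({tuple(row) for row in X.tolist()}) < 2:
        raise DegenerateDesign("all composition rows identical")
    design = np.hstack([np.ones((X.shape[0], 1)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        # degenerate rank correlation: a perfect constant fit counts as 1
        rho = 1.0 if rmse == 0 else 0.0
    else:
        rho, _ = spearman(pred, y)
    return CompositionModel(
        intercept=float(coef[0]),
        coefficients={r: float(a) for r, a in zip(residues, coef[1:])},
        rmse=rmse,
        spearman_fit=rho,
        residue_order=residues,
    )


def composition_screens(sequences, tm_values) -> pd.DataFrame:
    """Spearman of Tm against n_charged, n_hydrophobic and each residue count.

    Residues absent from every sequence are omitted; descriptors constant
    across the dataset are reported with NaN rho/p rather than raised, so a
    single table covers heterogeneous campaigns.
    """
    codes = _codes(sequences)
    y = np.asarray(tm_values, dtype=float)
    if len(codes) != y.size:
        raise LengthMismatch("sequences and Tm values differ in length")
    cvs = [composition_vector(c) for c in codes]
    residues = sorted({r for cv in cvs for r in cv.counts})
    screens = {
        "n_charged": [cv.n_charged for cv in cvs],
        "n_hydrophobic": [cv.n_hydrophobic for cv in cvs],
    }
    for r in residues:
        screens[f"count_{r}"] = [cv.counts.get(r, 0) for cv in cvs]
    rows = []
    for name, x in screens.items():
        try:
            rho, p = spearman(x, y)
        except ConstantInput:
            rho, p = np.nan, np.nan
        rows.append({"descriptor": name, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published stability table and Tm / deltaF concordance
# ---------------------------------------------------------------------------

def stability_table() -> pd.DataFrame:
    """The packaged 13-sequence Tm / deltaF reference table."""
    with resources.files("cmphelix.data").joinpath("stability_table.csv").open() as fh:
        return pd.read_csv(fh)


def tm_deltaF_concordance(table: pd.DataFrame | None = None) -> dict:
    """Concordance between ramp Tm and equilibrium deltaF stability measures.

    Returns the Spearman correlation over the non-collagen rows (the
    natural-collagen control is excluded as a kinetic-trapping outlier),
    and the free-energy advantage over the collagen reference of the best
    screened and best engineered sequences, in kcal/mol and as a fraction
    of the collagen deltaF.
    """
    t = stability_table() if table is None else table
    non_collagen = t[t["class"] != "collagen"]
    rho, p = spearman(non_collagen["tm_K"], non_collagen["deltaF_kcal_mol"])
    collagen_dF = float(t.loc[t["class"] == "collagen", "deltaF_kcal_mol"].iloc[0])
    best_screen = float(t.loc[t["class"] == "screen", "deltaF_kcal_mol"].max())
    best_eng = float(t.loc[t["class"] == "engineered", "deltaF_kcal_mol"].max())
    return {
        "spearman_rho": rho,
        "spearman_p": p,
        "n": int(len(non_collagen)),
        "collagen_deltaF": collagen_dF,
        "screen_advantage_kcal_mol": best_screen - collagen_dF,
        "engineered_advantage_kcal_mol": best_eng - collagen_dF,
        "engineered_advantage_relative": (best_eng - collagen_dF) / collagen_dF,
    }
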