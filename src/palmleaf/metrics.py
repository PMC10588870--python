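"""Evaluation metrics for comparing per-plant total leaf-area vectors.

Two estimation methods are compared plant-by-plant: ``est`` is the method
under evaluation (M_o) and ``bench`` the benchmark (M_b).  The benchmark is
always the *second* argument and supplies the denominator of the mean
relative error, so the argument order matters for MRE.

RMSE  = sqrt( mean_i (est_i - bench_i)^2 )
MAE   =       mean_i |est_i - bench_i|
MRE   =       mean_i |est_i - bench_i| / bench_i
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rmse", "mae", "mre", "pearson_r", "evaluate_methods", "EvaluationReport"]


def _as_pair(est, bench) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(est, dtype=float).ravel()
    b = np.asarray(bench, dtype=float).ravel()
    if e.size != b.size:
        raise ValueError(f"length mismatch: {e.size} vs {b.size}")
    if e.size == 0:
        raise ValueError("empty input")
    return e, b


def rmse(est, bench) -> float:
    """Root mean square difference between two equal-length vectors."""
    e, b = _as_pair(est, bench)
    return float(np.sqrt(np.mean((e - b) ** 2)))


def mae(est, bench) -> float:
    """Mean absolute difference between two equal-length vectors."""
    e, b = _as_pair(est, bench)
    return float(np.mean(np.abs(e - b)))


def mre(est, bench) -> float:
    """Mean relative absolute error, with ``bench`` as the denominator."""
    e, b = _as_pair(est, bench)
    if np.any(b == 0):
        raise ValueError("benchmark vector contains zero entries")
    return float(np.mean(np.abs(e - b) / np.abs(b)))


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    a, b = _as_pair(x, y)
    if a.size < 2:
        raise ValueError("need at least two points for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class EvaluationReport:
    """Bundle of error metrics comparing an estimate against a benchmark.

    ``r`` is ``nan`` (with ``r_defined = False``) when either vector has
    zero variance, e.g. when the two methods agree exactly.
    ``per_plant_residuals`` holds |est - bench| keyed by plant id.
    """

    n: int
    rmse: float
    mae: float
    mre: float
    r: float
    r_defined: bool
    per_plant_residuals: pd.Series = field(repr=False)

    def rounded(self) -> dict:
        """Display-precision view: 2 decimals for errors, 4 for r."""
        return {
            "n": self.n,
            "RMSE": round(self.rmse, 2),
            "MAE": round(self.mae, 2),
            "MRE": round(self.mre, 2),
            "r": round(self.r, 4) if self.r_defined else None,
        }

    def to_frame(self) -> pd.DataFrame:
        df = self.per_plant_residuals.rename("abs_residual").to_frame()
        return df


def evaluate_methods(est, bench) -> EvaluationReport:
    """Compare two per-plant total-LA vectors.

    Parameters
    ----------
    est, bench
        Per-plant totals.  When both are :class:`pandas.Series` they are
        matched by plant id (and must share exactly the same ids); plain
        arrays are matched by position.
    """
    if isinstance(est, pd.Series) and isinstance(bench, pd.Series):
        if set(est.index) != set(bench.index):
            raise ValueError(
                f"unmatched plant ids: {sorted(set(est.index) ^ set(bench.index))}"
            )
        bench = bench.reindex(est.index)
        index = est.index
    else:
        e = np.asarray(est, dtype=float).ravel()
        index = pd.RangeIndex(e.size)
    e, b = _as_pair(np.asarray(est, dtype=float), np.asarray(bench, dtype=float))
    # identical vectors: the methods agree exactly and a correlation of a
    # vector with itself carries no information — flag r as undefined
    if np.array_equal(e, b):
        r, r_defined = float("nan"), False
    else:
        try:
            r, r_defined = pearson_r(e, b), True
        except ValueError:
            r, r_defined = float("nan"), False
    return EvaluationReport(
        n=e.size,
        rmse=rmse(e, b),
        mae=mae(e, b),
        mre=mre(e, b),
        r=r,
        r_defined=r_defined,
        per_plant_residuals=pd.Series(np.abs(e - b), index=index),
    )
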