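"""Global sensitivity of steady-state SP cell count via PRCC.

The partial rank correlation coefficient (PRCC) of a parameter against the
model output is the Pearson correlation between the residuals of the
parameter's ranks and of the output's ranks, after both are linearly
regressed on the ranks of all other parameters.  It captures monotone
(not necessarily linear) influence while discounting correlations induced
through the other sampled parameters.

A "dummy" parameter — drawn independently and absent from the model —
serves as a negative control: a real parameter is called significant only
if its p-value clears alpha *and* its |PRCC| exceeds the dummy's.
Monotonicity diagnostics (a numerical stand-in for the usual scatter-plot
inspection) should be checked before trusting PRCC magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from scipy.stats import t as t_dist

from .homeostasis import PARAM_NAMES
from .screening import ScreenOutcome

__all__ = ["SensitivitySample", "PRCCResult", "prcc", "monotonicity_diagnostics"]


@dataclass(frozen=True)
class SensitivitySample:
    """Parameter matrix and matching scalar output vector."""

    X: np.ndarray
    names: tuple[str, ...]
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be (n, k) and y length n")
        if X.shape[1] != len(self.names):
            raise ValueError("one name per column required")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("sample contains non-finite values")

    @classmethod
    def from_screen(cls, outcome: ScreenOutcome,
                    output: str = "sp") -> "SensitivitySample":
        """Build a sample from the plausible sets of a screen.

        ``output`` selects the steady-state readout: "sp" (SP4+SP8, the
        default thymic-function proxy), or one of "t_dn", "t_dp", "t_sp4",
        "t_sp8".
        """
        ok = outcome.results["plausible"]
        X = outcome.results.loc[ok, list(PARAM_NAMES)].to_numpy(dtype=float)
        if output == "sp":
            y = (outcome.results.loc[ok, "t_sp4"]
                 + outcome.results.loc[ok, "t_sp8"]).to_numpy(dtype=float)
        else:
            y = outcome.results.loc[ok, output].to_numpy(dtype=float)
        return cls(X, tuple(PARAM_NAMES), y)


@dataclass(frozen=True)
class PRCCResult:
    """Per-parameter PRCC with significance against a dummy threshold."""

    table: pd.DataFrame          # index: parameter; columns: prcc, p_value, significant
    dummy_prcc: float | None
    dummy_p: float | None
    alpha: float

    def __getitem__(self, name: str) -> float:
        return float(self.table.loc[name, "prcc"])


def _partial_rank_corr(R: np.ndarray, ry: np.ndarray, j: int) -> float:
    """PRCC of column j: correlation of rank-regression residuals."""
    others = np.delete(R, j, axis=1)
    A = np.column_stack([np.ones(R.shape[0]), others])
    bx, *_ = np.linalg.lstsq(A, R[:, j], rcond=None)
    by, *_ = np.linalg.lstsq(A, ry, rcond=None)
    res_x = R[:, j] - A @ bx
    res_y = ry - A @ by
    sx = np.linalg.norm(res_x)
    sy = np.linalg.norm(res_y)
    if sx == 0 or sy == 0:
        raise np.linalg.LinAlgError("rank-deficient design: zero residual variance")
    return float(res_x @ res_y / (sx * sy))


def prcc(sample: SensitivitySample, add_dummy: bool = True,
         seed: int | None = None, alpha: float = 0.05) -> PRCCResult:
    """Partial rank correlation of every parameter against the output.

    Requires at least three more rows than columns.  P-values use the
    t approximation with n - 2 - (k-1) degrees of freedom, where k-1
    parameters are controlled for.  With ``add_dummy``, an independent
    uniform column is appended and significance additionally requires
    |PRCC| > |dummy PRCC|.
    """
    X, names = sample.X, list(sample.names)
    n = X.shape[0]
    if add_dummy:
        rng = np.random.default_rng(seed)
        X = np.column_stack([X, rng.uniform(0.0, 1.0, size=n)])
        names = names + ["dummy"]
    k = X.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} rows for {k} columns, got {n}")

    R = np.column_stack([rankdata(X[:, j]) for j in range(k)])
    ry = rankdata(sample.y)
    df = n - 2 - (k - 1)
    coefs, pvals = [], []
    for j in range(k):
        r = _partial_rank_corr(R, ry, j)
        r = float(np.clip(r, -1.0, 1.0))
        with np.errstate(divide="ignore", over="ignore"):
            t_stat = r * np.sqrt(df / max(1.0 - r * r, np.finfo(float).tiny))
        p = 2.0 * t_dist.sf(abs(t_stat), df)
        coefs.append(r)
        pvals.append(float(p))

    dummy_r = coefs[-1] if add_dummy else None
    dummy_p = pvals[-1] if add_dummy else None
    thr = abs(dummy_r) if add_dummy else 0.0
    rows = {}
    for nm, r, p in zip(names[: len(sample.names)], coefs, pvals):
        rows[nm] = {"prcc": r, "p_value": p,
                    "significant": bool(p < alpha and abs(r) > thr)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return PRCCResult(table, dummy_r, dummy_p, alpha)


def monotonicity_diagnostics(sample: SensitivitySample) -> pd.DataFrame:
    """Numerical monotonicity check per parameter.

    Reports the Spearman rank correlation with the output, plus Spearman
    coefficients on the lower and upper halves of the parameter's sampled
    range.  The relation is flagged non-monotone when the two halves show
    significantly opposite-signed correlations (each |rho| > 2/sqrt(n_half))
    — e.g. a parabola centered in the range; pure noise stays unflagged.
    """
    rows = {}
    for j, nm in enumerate(sample.names):
        x = sample.X[:, j]
        rho = spearmanr(x, sample.y).statistic if x.std() > 0 else 0.0
        med = np.median(x)
        lo_mask, hi_mask = x <= med, x > med
        rho_lo = rho_hi = 0.0
        if lo_mask.sum() > 2 and np.std(x[lo_mask]) > 0:
            rho_lo = spearmanr(x[lo_mask], sample.y[lo_mask]).statistic
        if hi_mask.sum() > 2 and np.std(x[hi_mask]) > 0:
            rho_hi = spearmanr(x[hi_mask], sample.y[hi_mask]).statistic
        thr_lo = 2.0 / np.sqrt(max(lo_mask.sum(), 1))
        thr_hi = 2.0 / np.sqrt(max(hi_mask.sum(), 1))
        opposite = (rho_lo * rho_hi < 0
                    and abs(rho_lo) > thr_lo and abs(rho_hi) > thr_hi)
        rows[nm] = {"spearman": float(np.nan_to_num(rho)),
                    "spearman_low_half": float(np.nan_to_num(rho_lo)),
                    "spearman_high_half": float(np.nan_to_num(rho_hi)),
                    "monotone": not opposite}
    return pd.DataFrame.from_dict(rows, orient="index")
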