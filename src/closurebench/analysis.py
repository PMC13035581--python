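"""Statistical pipeline: regression on closure scores, per-size t-tests on
configural-effect scores, the removal-percentage scale, and summary verdicts.

The similarity route fits an ordinary-least-squares model

    closure ~ edge_length + C(theta_global) + C(background)
              + C(center) + C(theta_local)

with edge length continuous and every other factor nominal (dummy-coded,
first level as reference — the edge-length slope is invariant to that
choice).  A model is said to show closure when the edge-length slope is
significantly positive; effect size is graded by adjusted R²
(> .40 moderate-to-large, < .30 small, between: small-to-moderate).

The configural-effect route runs a one-sample t-test of the CE scores
against 0 at each edge length (n = 32 per level on the full grid,
alternative 'greater' by default); closure is present when any level is
significantly positive, and the verdict carries the *removal fraction* —
the portion of each square side left uncovered by the two adjacent arms,
(side - 2*edge) / side — at the smallest significant edge length, i.e.
the largest removal at which the effect survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

EXP2_SIDE = 95.0
EXP1_SIDE = 116.0   # triangle side, for removal fractions on triangle grids

ADJ_R2_MODERATE = 0.40
ADJ_R2_SMALL = 0.30

NOMINAL_PREDICTORS = ("theta_global", "background", "center", "theta_local")


@dataclass
class RegressionReport:
    coefficients: Dict[str, Tuple[float, float, float]]  # term -> (est, se, p)
    edge_length_slope: float
    edge_length_p: float
    r_squared: float
    adjusted_r_squared: float
    model_p: float
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = {k: list(v) for k, v in self.coefficients.items()}
        return d


@dataclass
class TTestReport:
    edge_length: float
    n: int
    mean: float
    t: float
    df: int
    p: float
    alternative: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Verdict:
    method: str                      # "similarity" | "CE"
    present: str                     # "yes_strong" | "yes_small" | "no"
    effect_size_label: Optional[str] = None
    r_threshold: Optional[float] = None
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)


def _design_matrix(records: pd.DataFrame):
    """Continuous edge length plus dummy-coded nominal factors."""
    df = records.copy()
    df["center"] = list(zip(df["center_x"], df["center_y"]))
    X = pd.DataFrame({"edge_length": df["edge_length"].astype(float)})
    for col in NOMINAL_PREDICTORS:
        levels = sorted(df[col].astype(str).unique())
        for lev in levels[1:]:  # first level is the reference
            X[f"{col}[{lev}]"] = (df[col].astype(str) == lev).astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_closure_regression(records: pd.DataFrame) -> RegressionReport:
    """OLS of the closure score on edge length and the nominal covariates."""
    if records["edge_length"].nunique() < 2:
        raise ValueError("need at least 2 distinct edge lengths")
    X = _design_matrix(records)
    y = records["value"].astype(float).to_numpy()

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by incremental rank growth
        bad, cols = [], []
        for name in X.columns:
            cols.append(name)
            if np.linalg.matrix_rank(X[cols].to_numpy()) < len(cols):
                bad.append(name)
                cols.pop()
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")

    if float(np.var(y)) == 0.0:
        coeffs = {c: (0.0, 0.0, float("nan")) for c in X.columns}
        coeffs["const"] = (float(y[0]) if len(y) else 0.0, 0.0, float("nan"))
        return RegressionReport(
            coefficients=coeffs, edge_length_slope=0.0,
            edge_length_p=float("nan"), r_squared=0.0,
            adjusted_r_squared=0.0, model_p=float("nan"),
            n=len(y), degenerate=True)

    res = sm.OLS(y, X).fit()
    coeffs = {name: (float(res.params[name]), float(res.bse[name]),
                     float(res.pvalues[name]))
              for name in X.columns}
    return RegressionReport(
        coefficients=coeffs,
        edge_length_slope=float(res.params["edge_length"]),
        edge_length_p=float(res.pvalues["edge_length"]),
        r_squared=float(res.rsquared),
        adjusted_r_squared=float(res.rsquared_adj),
        model_p=float(res.f_pvalue),
        n=int(res.nobs),
    )


def t_tests_by_edge_length(records: pd.DataFrame,
                           alternative: str = "greater") -> List[TTestReport]:
    """One-sample t-test of the CE scores against 0 at each edge length."""
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    reports = []
    for el, grp in records.groupby("edge_length", sort=True):
        vals = grp["value"].astype(float).to_numpy()
        if len(vals) < 2:
            raise ValueError(f"edge length {el}: need >= 2 records")
        if float(np.var(vals)) == 0.0:
            raise ValueError(f"edge length {el}: zero variance, t-test undefined")
        res = scipy.stats.ttest_1samp(vals, popmean=0.0, alternative=alternative)
        reports.append(TTestReport(
            edge_length=float(el), n=len(vals), mean=float(vals.mean()),
            t=float(res.statistic), df=len(vals) - 1, p=float(res.pvalue),
            alternative=alternative))
    return reports


def removal_fraction(side: float, edge_length: float) -> float:
    """Fraction of each square side not covered by the two adjacent arms.

    Two corner fragments contribute one arm of ``edge_length`` each to a
    side, so the uncovered middle portion is (side - 2*edge) / side.  Over
    the side-95 grid this reproduces the scale 0.9, 0.8, ..., 0.1 at one
    decimal.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    if 2.0 * edge_length >= side:
        raise ValueError(
            f"2*edge_length = {2 * edge_length} >= side = {side}: no gap remains")
    return (side - 2.0 * edge_length) / side


def _strength_label(adj_r2: float) -> str:
    if adj_r2 > ADJ_R2_MODERATE:
        return "moderate_or_large"
    if adj_r2 < ADJ_R2_SMALL:
        return "small"
    return "small_to_moderate"


def table1_verdict(reg: Optional[RegressionReport] = None,
                   tests: Optional[List[TTestReport]] = None,
                   method: str = "similarity",
                   alpha: float = 0.05,
                   side: float = EXP2_SIDE,
                   per_edge_tests: Optional[List[TTestReport]] = None) -> Verdict:
    """Summary verdict for one model/dataset cell.

    similarity: present iff the edge-length slope is positive and
    significant; strength from adjusted R².  If per-edge t-tests of the
    closure scores are supplied, the removal threshold is attached the
    same way as for the CE route.

    CE: present iff some edge length has a significantly positive mean;
    r_threshold is the removal fraction at the smallest such edge length.
    """
    if method == "similarity":
        if reg is None:
            raise ValueError("similarity verdict requires a RegressionReport")
        significant = (not reg.degenerate
                       and reg.edge_length_p < alpha
                       and reg.edge_length_slope > 0)
        if not significant:
            return Verdict("similarity", "no", alpha=alpha)
        label = _strength_label(reg.adjusted_r_squared)
        present = "yes_strong" if label == "moderate_or_large" else "yes_small"
        r_thr = _r_threshold(per_edge_tests, alpha, side) if per_edge_tests else None
        return Verdict("similarity", present, label, r_thr, alpha)

    if method == "CE":
        if tests is None:
            raise ValueError("CE verdict requires t-test reports")
        r_thr = _r_threshold(tests, alpha, side)
        if r_thr is None:
            return Verdict("CE", "no", alpha=alpha)
        sig_means = [t.mean for t in tests if t.p < alpha and t.mean > 0]
        label = "moderate_or_large" if max(sig_means) >= 0.1 else "small"
        present = "yes_strong" if label == "moderate_or_large" else "yes_small"
        return Verdict("CE", present, label, r_thr, alpha)

    raise ValueError("method must be 'similarity' or 'CE'")


def _r_threshold(tests: List[TTestReport], alpha: float,
                 side: float) -> Optional[float]:
    sig = [t.edge_length for t in tests if t.p < alpha and t.mean > 0]
    if not sig:
        return None
    return round(removal_fraction(side, min(sig)), 1)
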