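"""Economic-value derivation by mediator-corrected multiple regression.

Net return per cow-year is regressed on the nominal trait level, the
trait's mediator variables (realized levels of correlated breeding-goal
traits) and the within-scenario realized deviation of the trait itself:

    net_return = mu + beta_a * x + sum_k beta_bk * m_k + beta_c * x_diff + eps

``beta_a`` is the economic value: the marginal effect of the trait on
profit with the mediated (double-counted) pathways held fixed. For rate
traits, 100 x |beta_a| is the total cost per case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import RegressionError

#: Mediator variables per trait (realized-level column names). Traits
#: not listed are fitted without mediators. "ecm" stands for milk
#: yield; "ho_cows" is the realized insemination-per-detected-oestrus
#: rate standing in for the cow insemination rate.
_MEDIATORS = {
    "mastitis": ["ecm", "cow_mortality"],
    "metritis": ["ecm", "ketosis", "cr_cows", "ho_cows"],
    "ketosis": ["ecm", "cr_cows"],
    "milk_fever": ["ecm", "metritis", "mastitis", "dystocia"],
    "lameness": ["ecm", "cr_cows", "cow_mortality"],
    "dystocia": ["stillbirth", "cow_mortality"],
}

_RATE_TRAITS = frozenset(
    {
        "mastitis",
        "lameness",
        "ketosis",
        "milk_fever",
        "metritis",
        "dystocia",
        "stillbirth",
        "early_calf_mortality",
        "late_calf_mortality",
        "cow_mortality",
        "cr_cows",
        "cr_heifers",
        "ho_cows",
        "ho_heifers",
    }
)


def mediator_map(trait: str) -> list[str]:
    """Mediator variable names for a trait (empty for traits fitted
    without correction)."""
    from .scenarios import TRAITS

    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    return list(_MEDIATORS.get(trait, []))


def per_case_cost(ev: float, trait: str = "mastitis") -> float:
    """Total cost per case: 100 x |EV| (rate traits only)."""
    if trait not in _RATE_TRAITS:
        raise ValueError(f"per-case cost is undefined for trait {trait!r}")
    return 100.0 * abs(float(ev))


@dataclass(frozen=True)
class RegressionSpec:
    """What to fit: the trait column, its mediators, and whether to
    include the within-scenario realized deviation."""

    trait: str
    mediators: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    include_x_diff: bool = True

    def __post_init__(self):
        mediators = self.mediators
        if mediators is None:
            mediators = tuple(mediator_map(self.trait))
        mediators = tuple(mediators)
        if len(set(mediators)) != len(mediators):
            raise ValueError("mediators must be distinct")
        if self.trait in mediators:
            raise ValueError("a trait cannot mediate itself")
        object.__setattr__(self, "mediators", mediators)


@dataclass(frozen=True)
class EVEstimate:
    """Fitted economic value and its regression context."""

    trait: str
    breed: str
    ev: float
    standard_error: float
    confidence_interval_95: tuple[float, float]
    intercept: float
    mediator_coefficients: dict
    x_diff_coefficient: float | None
    n_rows: int
    per_case_cost: float | None

    def __post_init__(self):
        lo, hi = self.confidence_interval_95
        if not lo <= self.ev <= hi:
            raise ValueError("confidence interval must contain the estimate")


def derive_ev(data: pd.DataFrame, spec: RegressionSpec, breed: str = "") -> EVEstimate:
    """Ordinary least squares fit of net return on
    [1, x, mediators, x_diff]; the coefficient on x is the EV.

    Mediators are centered on their pooled means (conditioning only —
    beta_a is unchanged). Raises :class:`RegressionError` for
    rank-deficient or undersized designs.
    """
    required = ["net_return", "x"] + list(spec.mediators)
    if spec.include_x_diff:
        required.append("x_diff")
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise RegressionError(f"data is missing columns: {missing}")
    if data["x"].nunique() < 2:
        raise RegressionError("need at least 2 distinct nominal x levels")

    cols = ["x"] + list(spec.mediators) + (["x_diff"] if spec.include_x_diff else [])
    X = data[cols].astype(float).copy()
    for m in spec.mediators:
        X[m] = X[m] - X[m].mean()
    X = sm.add_constant(X, prepend=True, has_constant="add")
    y = data["net_return"].astype(float)
    if len(data) < X.shape[1]:
        raise RegressionError(
            f"fewer rows ({len(data)}) than design columns ({X.shape[1]})"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise RegressionError(f"design matrix is rank-deficient; collinear columns: {bad}")

    fit = sm.OLS(y, X).fit()
    ev = float(fit.params["x"])
    if fit.df_resid > 0 and np.isfinite(fit.bse["x"]):
        ci_row = fit.conf_int(alpha=0.05).loc["x"]
        se, ci = float(fit.bse["x"]), (float(ci_row[0]), float(ci_row[1]))
    else:  # saturated fit: the estimate is exact, no residual variance
        se, ci = 0.0, (ev, ev)
    return EVEstimate(
        trait=spec.trait,
        breed=breed,
        ev=ev,
        standard_error=se,
        confidence_interval_95=ci,
        intercept=float(fit.params["const"]),
        mediator_coefficients={m: float(fit.params[m]) for m in spec.mediators},
        x_diff_coefficient=(
            float(fit.params["x_diff"]) if spec.include_x_diff else None
        ),
        n_rows=int(len(data)),
        per_case_cost=(per_case_cost(ev, spec.trait) if spec.trait in _RATE_TRAITS else None),
    )
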