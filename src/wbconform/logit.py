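"""Binary logistic regression for woody-breast detection.

Maximum-likelihood logistic regression fitted by iteratively reweighted
least squares (Newton–Raphson on the log-likelihood), with Wald chi-square
inference and odds ratios — the quantities reported by classical binary
logistic platforms.  The modelled event is the positive woody-breast status
(tactile score >= 2.0), so coefficient signs follow the convention of the
published tables.

The six candidate predictor subsets studied for carcass grading are exposed
as :data:`MODEL_SPECS`:

========  =================
model1    M1, M2, M3
model2    M1, M2, M4
model3    M1, M2, M6
model4    M9, M11
model5    M1, M9
model6    M3, M11
========  =================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "BinaryLogit",
    "BinaryLogitResults",
    "OddsRatioStatement",
    "odds_ratio",
    "SeparationWarning",
]


class SeparationWarning(UserWarning):
    """Raised as a warning when the likelihood has no finite maximiser."""


@dataclass(frozen=True)
class ModelSpec:
    """Named ordered subset of conformational predictors."""

    name: str
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("a model spec needs at least one predictor")


MODEL_SPECS: dict[str, ModelSpec] = {
    "model1": ModelSpec("model1", ("M1", "M2", "M3")),
    "model2": ModelSpec("model2", ("M1", "M2", "M4")),
    "model3": ModelSpec("model3", ("M1", "M2", "M6")),
    "model4": ModelSpec("model4", ("M9", "M11")),
    "model5": ModelSpec("model5", ("M1", "M9")),
    "model6": ModelSpec("model6", ("M3", "M11")),
}

_MAX_COND = 1e12


class BinaryLogit:
    """Binary logistic regression model.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Binary response; 1 is the modelled (positive) event.
    exog : 2-D array-like
        Design matrix.  No intercept column is added implicitly; use
        :meth:`from_dataframe` to prepend one.
    exog_names : sequence of str, optional
        Column names for reporting; defaults to ``x0, x1, ...``.
    """

    def __init__(self, endog, exog, exog_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if y.shape[0] != X.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("endog must be coded 0/1")
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("both response classes must be present")
        # a constant predictor next to the intercept is unidentifiable;
        # a single constant column (the intercept itself) is fine
        ptp = X.max(axis=0) - X.min(axis=0)
        if int(np.sum(ptp == 0)) > 1:
            raise ValueError(
                "constant predictor column: collinear with the intercept"
            )
        self.endog = y
        self.exog = X
        if exog_names is None:
            exog_names = [f"x{i}" for i in range(X.shape[1])]
        if len(exog_names) != X.shape[1]:
            raise ValueError("exog_names length mismatch")
        self.exog_names = list(exog_names)
        self.spec: ModelSpec | None = None

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, spec: ModelSpec, response: str = "wb_binary"
    ) -> "BinaryLogit":
        """Build the model for ``spec`` from a cohort table.

        Prepends an intercept column named ``const``; the response column
        must already be coded 0/1 (see :func:`wbconform.io.read_cohort`).
        """
        missing = [p for p in spec.predictors if p not in data.columns]
        if missing:
            raise ValueError(f"data lacks predictor column(s) {missing}")
        X = np.column_stack(
            [np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in spec.predictors]
        )
        model = cls(
            data[response].to_numpy(dtype=float), X, ["const", *spec.predictors]
        )
        model.spec = spec
        return model

    # -- likelihood pieces -------------------------------------------------
    def loglike(self, params: np.ndarray) -> float:
        eta = self.exog @ params
        # log(1+exp(eta)) evaluated stably
        return float(self.endog @ eta - np.logaddexp(0.0, eta).sum())

    def score(self, params: np.ndarray) -> np.ndarray:
        p = expit(self.exog @ params)
        return self.exog.T @ (self.endog - p)

    def information(self, params: np.ndarray) -> np.ndarray:
        p = expit(self.exog @ params)
        w = p * (1.0 - p)
        return (self.exog * w[:, None]).T @ self.exog

    def loglike_null(self) -> float:
        n1 = self.endog.sum()
        n = len(self.endog)
        pbar = n1 / n
        return float(n1 * np.log(pbar) + (n - n1) * np.log(1.0 - pbar))

    # -- fitting -----------------------------------------------------------
    def fit(
        self, start_params=None, maxiter: int = 50, tol: float = 1e-10
    ) -> "BinaryLogitResults":
        """Fit by IRLS until the relative log-likelihood change is < ``tol``.

        Complete or quasi-complete separation is reported through the
        ``converged``/``separation`` flags rather than silently penalised.
        """
        beta = (
            np.zeros(self.exog.shape[1])
            if start_params is None
            else np.asarray(start_params, dtype=float)
        )
        ll = self.loglike(beta)
        converged = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            info = self.information(beta)
            if not np.isfinite(info).all() or np.linalg.cond(info) > _MAX_COND:
                raise ValueError(
                    "singular information matrix: predictors are collinear "
                    "(or the fit has fully saturated)"
                )
            step = np.linalg.solve(info, self.score(beta))
            # step-halving keeps Newton monotone on awkward starts
            factor = 1.0
            for _ in range(30):
                trial = beta + factor * step
                ll_new = self.loglike(trial)
                if ll_new >= ll - 1e-13:
                    break
                factor *= 0.5
            beta, ll_prev, ll = trial, ll, ll_new
            if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
                converged = True
                break
        # complete separation: the likelihood saturates (every observation
        # perfectly classified with extreme linear predictor) or the Newton
        # iterates diverge without meeting the tolerance
        eta = self.exog @ beta
        perfectly = bool(((eta > 0) == (self.endog == 1)).all())
        separation = (perfectly and float(np.abs(eta).min()) > 7.0) or bool(
            not converged and np.abs(beta).max() > 10.0
        )
        if separation:
            converged = False
        if separation:
            warnings.warn(
                "coefficients diverging: data appear separated, the ML "
                "estimate does not exist",
                SeparationWarning,
                stacklevel=2,
            )
        info = self.information(beta)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:  # saturated weights
            cov = np.full_like(info, np.nan)
        names = pd.Index(self.exog_names)
        return BinaryLogitResults(
            spec=self.spec,
            params=pd.Series(beta, index=names),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            llf=ll,
            llnull=self.loglike_null(),
            nobs=len(self.endog),
            converged=converged,
            iterations=n_iter,
            separation=separation,
            model=self,
        )


@dataclass
class BinaryLogitResults:
    """Fitted binary logistic model: estimates, inference and prediction."""

    spec: ModelSpec | None
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    llnull: float
    nobs: int
    converged: bool
    iterations: int
    separation: bool = False
    model: BinaryLogit | None = None

    # -- inference ---------------------------------------------------------
    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def wald_chi2(self) -> pd.Series:
        return (self.params / self.bse) ** 2

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(chi2.sf(self.wald_chi2, df=1), index=self.params.index)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def predictor_names(self) -> list[str]:
        return [n for n in self.params.index if n != "const"]

    # -- prediction --------------------------------------------------------
    def linear_predictor(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame) or isinstance(data, pd.Series):
            if isinstance(data, pd.Series):
                data = data.to_frame().T
            missing = [p for p in self.predictor_names if p not in data.columns]
            if missing:
                raise ValueError(f"missing predictor(s) {missing}")
            eta = np.full(len(data), self.params.get("const", 0.0), dtype=float)
            for name in self.predictor_names:
                eta += self.params[name] * data[name].to_numpy(dtype=float)
            return eta
        if isinstance(data, dict):
            return self.linear_predictor(pd.DataFrame([data]))
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] == len(self.params) - 1:
            # slope columns only: the leading parameter is the intercept
            X = np.column_stack([np.ones(len(X)), X])
        elif X.shape[1] != len(self.params):
            raise ValueError(
                f"expected {len(self.params)} (or {len(self.params) - 1}) "
                f"columns, got {X.shape[1]}"
            )
        return X @ self.params.to_numpy()

    def predict(self, data) -> np.ndarray:
        """Predicted probability of the positive class, saturating in (0,1)
        without overflow for extreme linear predictors."""
        return expit(self.linear_predictor(data))

    def classify(self, data, threshold: float = 0.5) -> np.ndarray:
        """Most-likely class at the given threshold (default 0.5)."""
        return self.predict(data) >= threshold

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        name = self.spec.name if self.spec is not None else "binary logit"
        lines = [
            f"Binary logistic regression ({name})",
            f"  n = {self.nobs}, log-likelihood = {self.llf:.4f} "
            f"(null {self.llnull:.4f})",
            f"  converged: {self.converged} in {self.iterations} iterations"
            + ("  [separation]" if self.separation else ""),
            "",
            f"  {'Parameter':<10}{'Estimate':>12}{'Std. Error':>12}"
            f"{'Wald chi2':>12}{'Pr > chi2':>12}{'OR':>12}",
        ]
        bse, wald, pval, ors = self.bse, self.wald_chi2, self.pvalues, self.odds_ratios
        for nm in self.params.index:
            ortxt = f"{ors[nm]:>12.4g}" if nm != "const" else f"{'':>12}"
            lines.append(
                f"  {nm:<10}{self.params[nm]:>12.4f}{bse[nm]:>12.4f}"
                f"{wald[nm]:>12.2f}{pval[nm]:>12.4g}{ortxt}"
            )
        return "\n".join(lines)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spec": None
            if self.spec is None
            else {"name": self.spec.name, "predictors": list(self.spec.predictors)},
            "param_names": list(self.params.index),
            "params": [float(v) for v in self.params],
            "cov_params": [[float(v) for v in row] for row in self.cov_params.to_numpy()],
            "llf": float(self.llf),
            "llnull": float(self.llnull),
            "nobs": int(self.nobs),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "separation": bool(self.separation),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinaryLogitResults":
        names = pd.Index(d["param_names"])
        spec = d.get("spec")
        return cls(
            spec=None
            if spec is None
            else ModelSpec(spec["name"], tuple(spec["predictors"])),
            params=pd.Series(d["params"], index=names, dtype=float),
            cov_params=pd.DataFrame(d["cov_params"], index=names, columns=names),
            llf=d["llf"],
            llnull=d["llnull"],
            nobs=d["nobs"],
            converged=d["converged"],
            iterations=d["iterations"],
            separation=d.get("separation", False),
        )


@dataclass(frozen=True)
class OddsRatioStatement:
    """Odds ratio for a coefficient with its percent-change reading."""

    beta: float
    odds_ratio: float
    percent_change: float
    direction: str  # "increase" | "reduction" | "no change"

    @property
    def statement(self) -> str:
        if self.direction == "no change":
            return "odds unchanged (OR = 1)"
        if self.direction == "increase":
            return (
                f"odds {self.odds_ratio:.2f} times higher "
                f"({self.percent_change:.2f}% increase) per unit increase"
            )
        return f"odds {self.percent_change:.2f}% smaller per unit increase"


def odds_ratio(beta: float) -> OddsRatioStatement:
    """OR = exp(beta) with the matching percent-change statement.

    For beta > 0 the percent increase is 100*(exp(beta)-1); for beta < 0
    the percent reduction is 100*(1-exp(beta)).
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    or_ = float(np.exp(beta))
    if beta > 0:
        return OddsRatioStatement(beta, or_, 100.0 * (or_ - 1.0), "increase")
    if beta < 0:
        return OddsRatioStatement(beta, or_, 100.0 * (1.0 - or_), "reduction")
    return OddsRatioStatement(beta, 1.0, 0.0, "no change")
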