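"""Binomial regression models for coverage and barcode-gap presence.

The country-level taxonomic-coverage analysis treats each country as a
binomial experiment — of the ``n`` catalogue species of a country, ``y`` are
covered in the database — and models the covered proportion with a
logit-link binomial GLM, optionally with a biogeographic-region random
intercept (GLMM).  The species-level barcode-gap analysis is a Bernoulli
GLM on gap presence.  Candidate predictors are screened for
multicollinearity with variance inflation factors, and models over all
additive predictor subsets are ranked by AIC, treating differences under 2
as equally plausible.

The GLM is fitted by IRLS (via statsmodels) with Wald standard errors.  The
random-intercept GLMM is fitted by Laplace-approximated maximum likelihood:
for each candidate (beta, sigma) the group-wise integrals over the random
intercept are approximated at their mode (inner Newton iteration per group)
and the approximate marginal log-likelihood is maximised by L-BFGS-B.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
import statsmodels.api as sm

__all__ = [
    "compute_vif",
    "PredictorTransform",
    "BinomialGLM",
    "BinomialGLMResults",
    "BinomialGLMM",
    "BinomialGLMMResults",
    "fit_binomial_glm",
    "fit_binomial_glmm",
    "select_models",
    "ModelSelectionTable",
]


# ---------------------------------------------------------------------------
# multicollinearity screening
# ---------------------------------------------------------------------------

def compute_vif(X: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor per predictor.

    ``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` comes from the least-squares
    regression of predictor ``j`` on all other predictors plus an intercept.
    Exact collinearity is reported as ``inf`` with a warning.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("VIF needs at least p + 2 observations")
    arr = X.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(X.columns):
        y = arr[:, j]
        others = np.column_stack(
            [np.ones(len(y)), np.delete(arr, j, axis=1)]
        )
        resid = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        sst = np.sum((y - y.mean()) ** 2)
        sse = np.sum(resid**2)
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        if 1.0 - r2 < 1e-12:
            warnings.warn(
                f"predictor {name!r} is exactly collinear with the others",
                UserWarning,
                stacklevel=2,
            )
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# predictor transform
# ---------------------------------------------------------------------------

@dataclass
class PredictorTransform:
    """log(x+1) followed by z-scoring, the scaling applied to count
    predictors before model fitting.  The fitted centres/scales are stored
    so the transform is recorded alongside any fit that used it."""

    log1p: bool = True
    means_: pd.Series | None = None
    scales_: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "PredictorTransform":
        Z = np.log1p(X) if self.log1p else X.astype(float)
        self.means_ = Z.mean()
        sd = Z.std(ddof=0)
        self.scales_ = sd.where(sd > 0, 1.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.means_ is None:
            raise ValueError("transform not fitted")
        Z = np.log1p(X) if self.log1p else X.astype(float)
        return (Z - self.means_) / self.scales_

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# shared results machinery
# ---------------------------------------------------------------------------

def _add_intercept(X: pd.DataFrame) -> pd.DataFrame:
    if "Intercept" in X.columns:
        return X
    out = X.copy()
    out.insert(0, "Intercept", 1.0)
    return out


@dataclass
class _ResultsBase:
    params: pd.Series
    bse: pd.Series
    llf: float
    k: int
    converged: bool

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("odds_ratio")

    def conf_int_or(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald CI on the odds-ratio scale: exp(beta +/- z * SE)."""
        z = special.ndtri(1.0 - alpha / 2.0)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"or_lower": lo, "or_upper": hi})

    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(
            2.0 * special.ndtr(-np.abs(z)), index=self.params.index, name="p"
        )

    def _rows(self) -> pd.DataFrame:
        ci = self.conf_int_or()
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": self.bse,
                "odds_ratio": self.odds_ratios,
                "ci95": [
                    f"{lo:.2f}-{hi:.2f}"
                    for lo, hi in zip(ci["or_lower"], ci["or_upper"])
                ],
                "p_value": self.pvalues(),
            }
        )


@dataclass
class BinomialGLMResults(_ResultsBase):
    """Fitted binomial GLM: coefficients, Wald SEs, odds ratios and AIC."""

    transform: PredictorTransform | None = None

    def summary(self) -> str:
        head = (
            f"Binomial GLM (logit link)  llf={self.llf:.3f}  "
            f"k={self.k}  AIC={self.aic:.1f}  converged={self.converged}"
        )
        return head + "\n" + self._rows().to_string(float_format="%.4f")


class BinomialGLM:
    """Logit-link binomial GLM.

    Parameters
    ----------
    successes, trials
        Per-observation success counts and trial counts.  Bernoulli data is
        the special case ``trials = 1``.
    exog
        Predictor DataFrame; an intercept column is added automatically.
    """

    def __init__(
        self,
        successes: Sequence[float],
        trials: Sequence[float],
        exog: pd.DataFrame,
        transform: PredictorTransform | None = None,
    ) -> None:
        successes = np.asarray(successes, dtype=float)
        trials = np.asarray(trials, dtype=float)
        if np.any(successes < 0) or np.any(trials < successes):
            raise ValueError("need 0 <= successes <= trials")
        self.successes = successes
        self.trials = trials
        self.exog = _add_intercept(pd.DataFrame(exog))
        self.transform = transform

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        predictors: Sequence[str],
        trials: str | None = None,
        transform: PredictorTransform | None = None,
    ) -> "BinomialGLM":
        X = data[list(predictors)].astype(float)
        if transform is not None:
            X = transform.fit_transform(X)
        n = data[trials].to_numpy(float) if trials else np.ones(len(data))
        return cls(data[response].to_numpy(float), n, X, transform=transform)

    def fit(self) -> BinomialGLMResults:
        endog = np.column_stack([self.successes, self.trials - self.successes])
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = sm.GLM(endog, self.exog, family=sm.families.Binomial())
            res = model.fit(maxiter=100, tol=1e-8)
        for w in caught:
            if "separat" in str(w.message).lower():
                converged = False
        converged = converged and bool(res.converged) and np.all(
            np.isfinite(res.bse)
        ) and np.all(res.bse < 1e4)
        return BinomialGLMResults(
            params=pd.Series(res.params, index=self.exog.columns),
            bse=pd.Series(res.bse, index=self.exog.columns),
            llf=float(res.llf),
            k=self.exog.shape[1],
            converged=converged,
            transform=self.transform,
        )


def fit_binomial_glm(
    successes, trials, X: pd.DataFrame, transform: PredictorTransform | None = None
) -> BinomialGLMResults:
    """Functional wrapper over :class:`BinomialGLM`."""
    if transform is not None:
        X = transform.fit_transform(pd.DataFrame(X))
    return BinomialGLM(successes, trials, X, transform=transform).fit()


# ---------------------------------------------------------------------------
# random-intercept binomial GLMM (Laplace ML)
# ---------------------------------------------------------------------------

def _group_loglik_parts(y, n, eta):
    """Binomial log-likelihood (without the constant binomial coefficient,
    which cancels in all comparisons of interest... kept for exact AIC) and
    its first two derivatives in the shared intercept direction."""
    p = special.expit(eta)
    ll = np.sum(y * eta - n * np.logaddexp(0.0, eta))
    d1 = np.sum(y - n * p)
    d2 = -np.sum(n * p * (1.0 - p))
    return ll, d1, d2


def _laplace_loglik(beta, sigma, y, n, Xmat, group_idx, n_groups,
                    return_modes=False):
    """Laplace-approximated marginal log-likelihood of the random-intercept
    model, profiling nothing: modes found by per-group Newton iteration."""
    base_eta = Xmat @ beta
    total = 0.0
    modes = np.zeros(n_groups)
    for g in range(n_groups):
        idx = group_idx == g
        yg, ng, eg = y[idx], n[idx], base_eta[idx]
        if sigma < 1e-8:
            ll, _, _ = _group_loglik_parts(yg, ng, eg)
            total += ll
            continue
        u = 0.0
        for _ in range(50):
            ll, d1, d2 = _group_loglik_parts(yg, ng, eg + u)
            g1 = d1 - u / sigma**2
            g2 = d2 - 1.0 / sigma**2
            step = g1 / g2
            u -= step
            if abs(step) < 1e-10:
                break
        ll, d1, d2 = _group_loglik_parts(yg, ng, eg + u)
        modes[g] = u
        # log integral ~ loglik(u*) - u*^2/(2 s^2) - 0.5 log(1 + s^2 * I)
        total += ll - u**2 / (2.0 * sigma**2) - 0.5 * np.log1p(sigma**2 * (-d2))
    if return_modes:
        return total, modes
    return total


def _binom_logcoef(y, n):
    return np.sum(
        special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    )


@dataclass
class BinomialGLMMResults(_ResultsBase):
    """Fitted random-intercept binomial GLMM (Laplace ML)."""

    sigma_group: float = 0.0
    group_labels: Sequence[str] = field(default_factory=list)
    random_effects: pd.Series | None = None
    boundary: bool = False
    transform: PredictorTransform | None = None

    @property
    def sigma2_group(self) -> float:
        return self.sigma_group**2

    def summary(self) -> str:
        head = (
            f"Binomial GLMM (logit link, random intercept)  "
            f"llf={self.llf:.3f}  k={self.k}  AIC={self.aic:.1f}  "
            f"sigma_group={self.sigma_group:.4f}"
            f"{'  [boundary]' if self.boundary else ''}  "
            f"converged={self.converged}"
        )
        return head + "\n" + self._rows().to_string(float_format="%.4f")


class BinomialGLMM:
    """Random-intercept binomial GLMM, Laplace-approximated ML.

    One Gaussian random intercept per group (here: biogeographic region);
    the intercept SD counts as one parameter in the AIC.
    """

    def __init__(
        self,
        successes: Sequence[float],
        trials: Sequence[float],
        exog: pd.DataFrame,
        groups: Sequence,
        transform: PredictorTransform | None = None,
    ) -> None:
        self.successes = np.asarray(successes, dtype=float)
        self.trials = np.asarray(trials, dtype=float)
        if np.any(self.successes < 0) or np.any(self.trials < self.successes):
            raise ValueError("need 0 <= successes <= trials")
        self.exog = _add_intercept(pd.DataFrame(exog))
        labels, idx = np.unique(np.asarray(groups), return_inverse=True)
        if len(labels) < 2:
            raise ValueError("GLMM needs at least 2 groups")
        self.group_labels = [str(x) for x in labels]
        self.group_idx = idx
        self.transform = transform

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        predictors: Sequence[str],
        group: str,
        trials: str | None = None,
        transform: PredictorTransform | None = None,
    ) -> "BinomialGLMM":
        X = data[list(predictors)].astype(float)
        if transform is not None:
            X = transform.fit_transform(X)
        n = data[trials].to_numpy(float) if trials else np.ones(len(data))
        return cls(data[response].to_numpy(float), n, X, data[group],
                   transform=transform)

    def fit(self, start_sigma: float = 0.5) -> BinomialGLMMResults:
        y, n = self.successes, self.trials
        Xmat = self.exog.to_numpy(float)
        gidx = self.group_idx
        n_groups = len(self.group_labels)
        p = Xmat.shape[1]

        # warm start from the fixed-effects GLM
        glm = BinomialGLM(y, n, self.exog.drop(columns="Intercept")).fit()
        theta0 = np.append(glm.params.to_numpy(), start_sigma)

        def negll(theta):
            beta, sigma = theta[:-1], theta[-1]
            return -_laplace_loglik(beta, sigma, y, n, Xmat, gidx, n_groups)

        res = optimize.minimize(
            negll,
            theta0,
            method="L-BFGS-B",
            bounds=[(None, None)] * p + [(0.0, None)],
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        beta_hat, sigma_hat = res.x[:-1], res.x[-1]
        llf_kernel, modes = _laplace_loglik(
            beta_hat, sigma_hat, y, n, Xmat, gidx, n_groups, return_modes=True
        )
        llf = llf_kernel + _binom_logcoef(y, n)
        boundary = sigma_hat < 1e-4

        # Wald SEs for the fixed effects from the numerical Hessian of the
        # Laplace log-likelihood at the optimum
        bse = np.full(p, np.nan)
        try:
            H = _numerical_hessian(negll, res.x)
            use = H[: p + 1, : p + 1] if not boundary else H[:p, :p]
            cov = np.linalg.inv(use)
            bse = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
        except np.linalg.LinAlgError:
            pass

        return BinomialGLMMResults(
            params=pd.Series(beta_hat, index=self.exog.columns),
            bse=pd.Series(bse, index=self.exog.columns),
            llf=float(llf),
            k=p + 1,  # fixed effects + intercept SD
            converged=bool(res.success),
            sigma_group=float(sigma_hat),
            group_labels=self.group_labels,
            random_effects=pd.Series(modes, index=self.group_labels),
            boundary=boundary,
            transform=self.transform,
        )


def _numerical_hessian(f, x, eps=1e-4):
    m = len(x)
    H = np.empty((m, m))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = steps[i]
            ej = np.zeros(m); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    # guard: symmetrise against round-off
    _ = f0
    return H


def fit_binomial_glmm(
    successes, trials, X: pd.DataFrame, groups,
    transform: PredictorTransform | None = None,
) -> BinomialGLMMResults:
    """Functional wrapper over :class:`BinomialGLMM`."""
    if transform is not None:
        X = transform.fit_transform(pd.DataFrame(X))
    return BinomialGLMM(successes, trials, X, groups, transform=transform).fit()


# ---------------------------------------------------------------------------
# all-subsets AIC model selection
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionTable:
    """All additive predictor subsets ranked by AIC."""

    table: pd.DataFrame
    fits: Mapping[tuple[str, ...], _ResultsBase]

    @property
    def best(self) -> tuple[str, ...]:
        ok = self.table[self.table["converged"]]
        return tuple(ok.iloc[0]["predictors"])

    @property
    def best_fit(self) -> _ResultsBase:
        return self.fits[self.best]

    def __str__(self) -> str:
        df = self.table.copy()
        df["predictors"] = df["predictors"].map(
            lambda t: " + ".join(t) if t else "(intercept only)"
        )
        return df.to_string(index=False, float_format="%.2f")


def select_models(
    successes,
    trials,
    X: pd.DataFrame,
    groups=None,
    transform: PredictorTransform | None = None,
    delta_aic_plausible: float = 2.0,
) -> ModelSelectionTable:
    """Fit every additive subset of the candidate predictors (the
    intercept-only model included), rank by AIC and flag models with
    ``delta AIC < 2`` as equally plausible.

    With ``groups`` given, every subset is fitted as a random-intercept
    GLMM; otherwise as a plain GLM.  AIC ties are broken toward the smaller
    model.  Subsets that fail to converge keep their row but are excluded
    from ``best``.
    """
    X = pd.DataFrame(X)
    if X.shape[1] > 12:
        raise ValueError("all-subsets enumeration capped at 12 predictors")
    if transform is not None:
        X = transform.fit_transform(X)

    names = list(X.columns)
    fits: dict[tuple[str, ...], _ResultsBase] = {}
    rows = []
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            Xs = X[list(subset)]
            if groups is None:
                fit = BinomialGLM(successes, trials, Xs).fit()
            else:
                fit = BinomialGLMM(successes, trials, Xs, groups).fit()
            fits[subset] = fit
            rows.append(
                {
                    "predictors": subset,
                    "n_predictors": len(subset),
                    "k": fit.k,
                    "llf": fit.llf,
                    "aic": fit.aic,
                    "converged": fit.converged,
                }
            )
    df = pd.DataFrame(rows).sort_values(
        ["aic", "n_predictors", "predictors"], kind="mergesort"
    ).reset_index(drop=True)
    best_aic = df.loc[df["converged"], "aic"].min()
    df["delta_aic"] = df["aic"] - best_aic
    df["plausible"] = df["delta_aic"] < delta_aic_plausible
    return ModelSelectionTable(table=df, fits=fits)
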