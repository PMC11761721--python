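"""Proportional-odds (cumulative logit) regression.

Model: for a 5-level ordinal outcome Y and predictor vector x,

    P(Y <= k | x) = F(kappa_k - eta),   eta = sum_j b_j x_j,   k = 1..4,

with F the standard logistic CDF and kappa_1 < ... < kappa_4 the cutpoints.
There is no separate intercept; the cutpoints absorb it.  Under this sign
convention a positive b_j means higher item scores shift satisfaction upward.
Item responses enter as continuous 1-5 scores (one coefficient per item).

Estimation maximizes the exact log-likelihood with an analytic score:
quasi-Newton (BFGS) iterations from a deterministic start (b = 0, cutpoints at
the logits of the cumulative outcome proportions), with cutpoint ordering
enforced through an increasing log-gap reparameterization, followed by Newton
polishing on the original parameters.  Standard errors come from the inverse
observed information at the optimum; coefficient p-values are two-sided Wald.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, ndtr

from .codebook import SATISFACTION_ITEM
from .errors import DomainError, FitError
from .reference import REGRESSION_ESTIMATES
from .survey_data import SurveyDataset, listwise_complete

N_CATEGORIES = 5
N_CUTPOINTS = N_CATEGORIES - 1


# -- likelihood core (array level) ----------------------------------------


def category_probs(kappa: np.ndarray, eta) -> np.ndarray:
    """Category probabilities p_k = F(kappa_k - eta) - F(kappa_{k-1} - eta).

    ``kappa`` holds K-1 increasing cutpoints for a K-level outcome (K = 5 for
    the standard satisfaction scale).  ``eta`` may be a scalar or a length-n
    vector; returns shape (K,) or (n, K).
    """
    kappa = np.atleast_1d(np.asarray(kappa, float))
    if kappa.ndim != 1 or len(kappa) < 1:
        raise DomainError("kappa must be a nonempty 1-D cutpoint vector")
    if not np.all(np.diff(kappa) > 0):
        raise DomainError("cutpoints must be strictly increasing")
    eta_arr = np.atleast_1d(np.asarray(eta, float))
    cum = expit(kappa[None, :] - eta_arr[:, None])
    probs = np.diff(np.concatenate([np.zeros((len(eta_arr), 1)), cum, np.ones((len(eta_arr), 1))], axis=1))
    return probs[0] if np.isscalar(eta) or np.ndim(eta) == 0 else probs


def _loglik_terms(b: np.ndarray, kappa: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Per-record probability P_i plus the densities at the two bracketing cutpoints."""
    eta = X @ b if X.size else np.zeros(len(y))
    # A_i = kappa_{y_i} - eta_i (upper), B_i = kappa_{y_i - 1} - eta_i (lower)
    n_cat = len(kappa) + 1
    kap_pad = np.concatenate([[-np.inf], kappa, [np.inf]])
    A = kap_pad[y] - eta
    B = kap_pad[y - 1] - eta
    FA = expit(A)
    FB = expit(B)
    # P = F(A) - F(B), computed stably at the open ends
    P = np.where(y == n_cat, expit(-B), np.where(y == 1, FA, FA - FB))
    fA = np.where(np.isinf(A), 0.0, FA * (1.0 - FA))
    fB = np.where(np.isinf(B), 0.0, FB * (1.0 - FB))
    return P, fA, fB, eta


def _loglik_grad(b: np.ndarray, kappa: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Log-likelihood and its gradient with respect to (b, kappa)."""
    P, fA, fB, _ = _loglik_terms(b, kappa, X, y)
    ll = float(np.log(P).sum())
    n_cut = len(kappa)
    g_eta = -(fA - fB) / P
    grad_b = X.T @ g_eta if X.size else np.zeros(0)
    grad_k = np.zeros(n_cut)
    # d/dkappa_k: +f(A)/P where y == k, -f(B)/P where y == k + 1
    np.add.at(grad_k, np.clip(y - 1, 0, n_cut - 1), np.where(y <= n_cut, fA / P, 0.0))
    np.add.at(grad_k, np.clip(y - 2, 0, n_cut - 1), np.where(y >= 2, -fB / P, 0.0))
    return ll, np.concatenate([grad_b, grad_k])


def loglik(
    b: Sequence[float],
    kappa: Sequence[float],
    data: SurveyDataset,
    outcome: str = SATISFACTION_ITEM,
    predictors: Sequence[str] | None = None,
) -> float:
    """Cumulative-logit log-likelihood of ``data`` at the given parameters."""
    predictors = list(predictors) if predictors is not None else []
    kappa = np.asarray(kappa, float)
    if kappa.shape != (N_CUTPOINTS,) or not np.all(np.diff(kappa) > 0):
        raise DomainError("kappa must be 4 strictly increasing cutpoints")
    ds = listwise_complete(data, [outcome, *predictors])
    if ds.n == 0:
        raise DomainError("no complete records for the requested variables")
    y = ds.frame[outcome].to_numpy(int)
    X = ds.frame[predictors].to_numpy(float) if predictors else np.zeros((ds.n, 0))
    b = np.asarray(b, float)
    if b.shape != (len(predictors),):
        raise DomainError(f"expected {len(predictors)} coefficients, got {b.shape}")
    ll, _ = _loglik_grad(b, kappa, X, y)
    return ll


# -- fit result ------------------------------------------------------------


@dataclass
class OrdinalFit:
    """Estimated proportional-odds model for one stratum.

    ``categories`` lists the outcome levels the cutpoints separate; the
    standard satisfaction scale is (1, 2, 3, 4, 5).  A shorter tuple arises
    when unobserved extreme levels were explicitly collapsed before fitting
    (:func:`fit_collapsed_proportional_odds`).
    """

    item_ids: tuple[str, ...]
    b: np.ndarray
    kappa: np.ndarray
    se: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    cov: np.ndarray | None = None
    loglik: float | None = None
    n: int | None = None
    converged: bool = True
    gradient_norm: float | None = None
    stratum: str | None = None
    categories: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, float)
        self.kappa = np.asarray(self.kappa, float)
        self.categories = tuple(int(c) for c in self.categories)
        if len(self.b) != len(self.item_ids):
            raise DomainError("one coefficient per item required")
        n_cut = len(self.categories) - 1
        if n_cut < 1:
            raise DomainError("at least two outcome categories required")
        if self.kappa.shape != (n_cut,) or not np.all(np.diff(self.kappa) > 0):
            raise DomainError(f"kappa must be {n_cut} strictly increasing cutpoints")
        if self.se is not None:
            self.se = np.asarray(self.se, float)
            if self.se.shape != (len(self.b) + n_cut,):
                raise DomainError("se must cover coefficients plus cutpoints")
            if not np.all(self.se > 0):
                raise DomainError("standard errors must be positive")

    @property
    def se_b(self) -> np.ndarray | None:
        return None if self.se is None else self.se[: len(self.b)]

    @property
    def se_kappa(self) -> np.ndarray | None:
        return None if self.se is None else self.se[len(self.b):]

    def coefficient(self, item_id: str) -> float:
        return float(self.b[self.item_ids.index(item_id)])

    def to_frame(self) -> pd.DataFrame:
        """Regression table: one row per item then per cutpoint (b, SE, p)."""
        rows = []
        for j, item in enumerate(self.item_ids):
            rows.append(
                {
                    "term": item,
                    "b": self.b[j],
                    "se": None if self.se is None else self.se[j],
                    "p": None if self.pvalues is None else self.pvalues[j],
                }
            )
        for k in range(len(self.kappa)):
            rows.append(
                {
                    "term": f"cut{k + 1}",
                    "b": self.kappa[k],
                    "se": None if self.se is None else self.se[len(self.b) + k],
                    "p": None,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "item_ids": list(self.item_ids),
            "b": self.b.tolist(),
            "kappa": self.kappa.tolist(),
            "se": None if self.se is None else self.se.tolist(),
            "pvalues": None if self.pvalues is None else np.asarray(self.pvalues).tolist(),
            "cov": None if self.cov is None else np.asarray(self.cov).tolist(),
            "loglik": self.loglik,
            "n": self.n,
            "converged": bool(self.converged),
            "gradient_norm": self.gradient_norm,
            "stratum": self.stratum,
            "categories": list(self.categories),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrdinalFit":
        return cls(
            item_ids=tuple(d["item_ids"]),
            b=np.asarray(d["b"], float),
            kappa=np.asarray(d["kappa"], float),
            se=None if d.get("se") is None else np.asarray(d["se"], float),
            pvalues=None if d.get("pvalues") is None else np.asarray(d["pvalues"], float),
            cov=None if d.get("cov") is None else np.asarray(d["cov"], float),
            loglik=d.get("loglik"),
            n=d.get("n"),
            converged=d.get("converged", True),
            gradient_norm=d.get("gradient_norm"),
            stratum=d.get("stratum"),
            categories=tuple(d.get("categories", (1, 2, 3, 4, 5))),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "OrdinalFit":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_published(cls, area: str) -> "OrdinalFit":
        """Fit object carrying the published per-area estimates."""
        est = REGRESSION_ESTIMATES[area]
        items = tuple(est["coefficients"])
        b = np.array([est["coefficients"][i][0] for i in items])
        se = np.array(
            [est["coefficients"][i][1] for i in items] + list(est["cutpoint_se"])
        )
        p = np.array([est["coefficients"][i][2] for i in items])
        return cls(
            item_ids=items,
            b=b,
            kappa=np.asarray(est["cutpoints"], float),
            se=se,
            pvalues=p,
            loglik=est["log_likelihood"],
            n=est["n"],
            stratum=area,
        )


# -- fitting ---------------------------------------------------------------


def _theta_from_phi(phi: np.ndarray, J: int) -> tuple[np.ndarray, np.ndarray]:
    b = phi[:J]
    kappa = phi[J] + np.concatenate([[0.0], np.cumsum(np.exp(phi[J + 1:]))])
    return b, kappa


def _phi_objective(phi: np.ndarray, J: int, X: np.ndarray, y: np.ndarray):
    b, kappa = _theta_from_phi(phi, J)
    ll, grad = _loglik_grad(b, kappa, X, y)
    # chain rule: dkappa_m/dphi_{J} = 1; dkappa_m/dphi_{J+l} = e^{phi_{J+l}} for m >= l
    gk = grad[J:]
    gphi = np.empty_like(phi)
    gphi[:J] = grad[:J]
    gphi[J] = gk.sum()
    for l in range(1, len(phi) - J):
        gphi[J + l] = np.exp(phi[J + l]) * gk[l:].sum()
    return -ll, -gphi


def _observed_hessian(theta: np.ndarray, J: int, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Hessian of the log-likelihood by central differences of the analytic score."""
    dim = len(theta)
    H = np.zeros((dim, dim))
    for j in range(dim):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _loglik_grad(tp[:J], tp[J:], X, y)
        _, gm = _loglik_grad(tm[:J], tm[J:], X, y)
        H[j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_proportional_odds(
    data: SurveyDataset,
    outcome: str = SATISFACTION_ITEM,
    predictors: Sequence[str] | None = None,
    stratum: str | None = None,
    gtol: float = 1e-6,
    max_iter: int = 200,
    categories: Sequence[int] = (1, 2, 3, 4, 5),
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit on the complete cases.

    Deterministic: the start point is b = 0 with cutpoints at the logits of the
    cumulative outcome proportions, so repeated fits are bit-identical without
    any seed.  ``converged`` requires the score norm at the optimum < ``gtol``.

    Every level in ``categories`` must be observed at least once; an empty
    level raises :class:`FitError` advising an explicit collapse (coefficients
    are invariant under merging adjacent categories, so dropping an unobserved
    extreme level via :func:`fit_collapsed_proportional_odds` leaves the item
    effects comparable).
    """
    if predictors is None:
        predictors = [
            i for i in data.codebook.experience_ids if i in data.frame.columns
        ]
    predictors = list(predictors)
    categories = tuple(sorted(int(c) for c in categories))
    n_cut = len(categories) - 1
    if n_cut < 1:
        raise FitError("at least two outcome categories required")
    ds = data.for_stratum(stratum) if stratum is not None else data
    ds = listwise_complete(ds, [outcome, *predictors])
    n, J = ds.n, len(predictors)
    if n <= J + n_cut:
        raise FitError(f"n = {n} complete cases cannot identify {J + n_cut} parameters")
    y_raw = ds.frame[outcome].to_numpy(int)
    outside = np.setdiff1d(np.unique(y_raw), categories)
    if outside.size:
        raise FitError(f"outcome values {outside.tolist()} not among categories {categories}")
    # map levels to ranks 1..K
    y = np.searchsorted(categories, y_raw) + 1
    X = ds.frame[predictors].to_numpy(float) if J else np.zeros((n, 0))

    counts = np.bincount(y, minlength=len(categories) + 1)[1:]
    if (counts == 0).any():
        empty = [categories[k] for k in np.flatnonzero(counts == 0)]
        raise FitError(
            f"outcome categories {empty} unobserved; collapse adjacent categories "
            "explicitly before fitting"
        )

    cum_props = np.cumsum(counts)[:n_cut] / n
    kappa0 = logit(cum_props)
    phi0 = np.concatenate([np.zeros(J), [kappa0[0]], np.log(np.diff(kappa0))])

    res = optimize.minimize(
        _phi_objective,
        phi0,
        args=(J, X, y),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": max_iter},
    )
    b, kappa = _theta_from_phi(res.x, J)
    theta = np.concatenate([b, kappa])

    # Newton polish on the original parameters (interior optimum)
    ll, grad = _loglik_grad(theta[:J], theta[J:], X, y)
    H = None
    for _ in range(20):
        if np.linalg.norm(grad) < gtol * 1e-2:
            break
        H = _observed_hessian(theta, J, X, y)
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            if np.all(np.diff(cand[J:]) > 0):
                ll_new, grad_new = _loglik_grad(cand[:J], cand[J:], X, y)
                if ll_new >= ll - 1e-10:
                    theta, ll, grad = cand, ll_new, grad_new
                    break
            scale *= 0.5
        else:
            break
    if H is None:
        H = _observed_hessian(theta, J, X, y)

    grad_norm = float(np.linalg.norm(grad))
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se = np.where(se > 0, se, np.nan)
    z = theta[:J] / se[:J] if J else np.zeros(0)
    pvalues = 2.0 * (1.0 - ndtr(np.abs(z)))

    return OrdinalFit(
        item_ids=tuple(predictors),
        b=theta[:J],
        kappa=theta[J:],
        se=se,
        pvalues=pvalues,
        cov=cov,
        loglik=ll,
        n=n,
        converged=grad_norm < gtol,
        gradient_norm=grad_norm,
        stratum=stratum,
        categories=categories,
    )


def fit_collapsed_proportional_odds(
    data: SurveyDataset,
    outcome: str = SATISFACTION_ITEM,
    predictors: Sequence[str] | None = None,
    stratum: str | None = None,
    **kwargs,
) -> OrdinalFit:
    """Proportional-odds fit restricted to the outcome levels actually observed.

    Heavily top-skewed satisfaction data can leave the bottom of the 1-5 scale
    empty in a given sample; the cutpoint for an unobserved extreme level is
    not identified.  This helper performs the collapse explicitly — it fits on
    the observed level set (logging which levels were dropped) — rather than
    silently inside :func:`fit_proportional_odds`.  Item coefficients are
    unaffected by merging adjacent outcome categories under proportional odds.
    """
    import logging

    ds = data.for_stratum(stratum) if stratum is not None else data
    preds = predictors
    if preds is None:
        preds = [i for i in data.codebook.experience_ids if i in data.frame.columns]
    complete = listwise_complete(ds, [outcome, *list(preds)])
    if complete.n == 0:
        raise FitError("no complete records for the requested variables")
    observed = tuple(int(v) for v in np.unique(complete.frame[outcome].to_numpy(int)))
    dropped = sorted(set(range(1, N_CATEGORIES + 1)) - set(observed))
    if dropped:
        logging.getLogger(__name__).warning(
            "outcome levels %s unobserved%s; fitting on collapsed scale %s",
            dropped,
            "" if stratum is None else f" in stratum {stratum!r}",
            observed,
        )
    return fit_proportional_odds(
        data, outcome, predictors, stratum=stratum, categories=observed, **kwargs
    )


# -- prediction ------------------------------------------------------------


def predict_category_probs(fit: OrdinalFit, x: Sequence[float]) -> np.ndarray:
    """Probability vector over the 5 outcome categories at predictor values ``x``."""
    x = np.asarray(x, float)
    if x.shape != (len(fit.item_ids),):
        raise DomainError(f"expected {len(fit.item_ids)} predictor values, got {x.shape}")
    eta = float(fit.b @ x)
    return category_probs(fit.kappa, eta)


def expected_satisfaction(fit: OrdinalFit, x: Sequence[float]) -> float:
    """Expected outcome score sum_k k p_k on the 1-5 scale."""
    probs = predict_category_probs(fit, x)
    return float(probs @ np.asarray(fit.categories, float))
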