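"""Synthetic survey generator with the statistical structure the analysis assumes.

Real inpatient PREM data are confidential, so every downstream stage is
exercised on simulated surveys that emulate the documented features of the real
ones: strongly top-skewed 1–5 item distributions (means around 4.2–4.8),
inter-item correlation, an overall-satisfaction outcome generated by a
proportional-odds model with published per-stratum coefficients and cutpoints,
and monotone questionnaire drop-off (respondents quit and never return).

Item responses are discretized latent Gaussian traits with an equicorrelation
structure; per-item discretization thresholds are calibrated analytically so
each item hits its target mean exactly in expectation.  Satisfaction is then
drawn from P(Y <= k | x) = logistic(kappa_k - sum_j b_j x_j) at the realized
item scores, which makes the generator exactly model-consistent with
:mod:`premopt.ordinal_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr

from .codebook import SATISFACTION_ITEM, ItemCodebook, default_codebook
from .errors import ConfigurationError
from .reference import REGRESSION_ESTIMATES
from .survey_data import SurveyDataset

#: spacing of the latent discretization cuts (latent-SD units); the shared
#: shift is calibrated per item to match its target mean.
_CUT_GAP = 0.8
_BASE_CUTS = np.arange(4) * _CUT_GAP


@dataclass(frozen=True)
class StratumScenario:
    """Generative specification for one stratum (departmental area)."""

    label: str
    n: int
    item_means: Mapping[str, float]
    coefficients: Mapping[str, float]
    cutpoints: tuple[float, float, float, float]
    item_corr: float = 0.4
    dropout_rate: float = 0.0
    #: probability that a respondent who quit early also skips the
    #: satisfaction item (it closes the questionnaire, hence default 1).
    satisfaction_dropout_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigurationError("n must be positive")
        if tuple(self.item_means) != tuple(self.coefficients):
            raise ConfigurationError("item_means and coefficients must list the same items in order")
        for item, m in self.item_means.items():
            if not 1.0 < m < 5.0:
                raise ConfigurationError(f"item {item!r}: target mean {m} not in (1, 5)")
        if not all(a < b for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ConfigurationError("cutpoints must be strictly increasing")
        if not 0.0 <= self.item_corr < 1.0:
            raise ConfigurationError("item_corr must be in [0, 1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.item_means)


@dataclass(frozen=True)
class SimScenario:
    """Full generative specification: one or more strata plus the master seed."""

    strata: tuple[StratumScenario, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("stratum labels must be unique")


def default_scenario(
    area: str,
    seed: int = 0,
    n: int | None = None,
    item_corr: float = 0.4,
    dropout_rate: float = 0.0,
) -> SimScenario:
    """Single-stratum scenario parameterized by the published per-area estimates.

    Coefficients and cutpoints equal the published regression values for
    ``area``; ``n`` defaults to that regression's (complete-case) sample size.
    Item-level means are not published, so baselines are drawn deterministically
    from ``seed``, uniform on [4.2, 4.8] — the top-skewed range PREM surveys
    report.
    """
    if area not in REGRESSION_ESTIMATES:
        raise ConfigurationError(
            f"unknown area {area!r}; expected one of {sorted(REGRESSION_ESTIMATES)}"
        )
    est = REGRESSION_ESTIMATES[area]
    items = list(est["coefficients"])
    rng = np.random.default_rng(seed)
    means = rng.uniform(4.2, 4.8, size=len(items))
    stratum = StratumScenario(
        label=area,
        n=int(n if n is not None else est["n"]),
        item_means=dict(zip(items, means.tolist())),
        coefficients={k: v[0] for k, v in est["coefficients"].items()},
        cutpoints=tuple(est["cutpoints"]),
        item_corr=item_corr,
        dropout_rate=dropout_rate,
    )
    return SimScenario(strata=(stratum,), seed=seed)


def two_area_scenario(seed: int = 0, n: Mapping[str, int] | None = None, **kwargs) -> SimScenario:
    """Convenience scenario with both published areas (surgical + medical)."""
    strata = []
    for area in REGRESSION_ESTIMATES:
        sc = default_scenario(area, seed=seed, n=(n or {}).get(area), **kwargs)
        strata.append(sc.strata[0])
    return SimScenario(strata=tuple(strata), seed=seed)


def calibrate_thresholds(target_mean: float) -> np.ndarray:
    """Latent cut vector whose discretized standard normal has the target mean.

    With cuts c_1<...<c_4, the discretized score X = 1 + #{k : z > c_k} has
    E[X] = 1 + sum_k (1 - Phi(c_k)); the shared shift of an equally spaced cut
    vector is a strictly monotone handle on that mean, solved by root finding.
    """
    if not 1.0 < target_mean < 5.0:
        raise ConfigurationError(f"target mean {target_mean} not calibratable on a 1-5 scale")

    def mean_minus_target(shift: float) -> float:
        return 1.0 + float((1.0 - ndtr(_BASE_CUTS + shift)).sum()) - target_mean

    shift = brentq(mean_minus_target, -30.0, 30.0, xtol=1e-12)
    return _BASE_CUTS + shift


def expected_item_correlation(mean_i: float, mean_j: float, item_corr: float) -> float:
    """Analytic Pearson correlation of two discretized items.

    Discretizing the latent traits attenuates their correlation; this computes
    the exact correlation of the 1-5 scores implied by latent equicorrelation
    ``item_corr`` and the calibrated per-item thresholds, via bivariate normal
    orthant probabilities.
    """
    from scipy.stats import multivariate_normal

    ci, cj = calibrate_thresholds(mean_i), calibrate_thresholds(mean_j)
    mv = multivariate_normal([0.0, 0.0], [[1.0, item_corr], [item_corr, 1.0]])
    cov = 0.0
    for a in ci:
        for b in cj:
            joint = 1.0 - ndtr(a) - ndtr(b) + mv.cdf(np.array([a, b]))
            cov += joint - (1.0 - ndtr(a)) * (1.0 - ndtr(b))

    def _var(cuts: np.ndarray) -> float:
        p = np.diff(np.concatenate([[0.0], ndtr(cuts), [1.0]]))
        k = np.arange(1, 6)
        return float((p * k * k).sum() - ((p * k).sum()) ** 2)

    return float(cov / np.sqrt(_var(ci) * _var(cj)))


def _simulate_stratum(stratum: StratumScenario, rng: np.random.Generator) -> pd.DataFrame:
    n, items = stratum.n, list(stratum.item_ids)
    J = len(items)
    cuts = np.array([calibrate_thresholds(stratum.item_means[i]) for i in items])  # (J, 4)

    rho = stratum.item_corr
    common = rng.standard_normal(n)
    idio = rng.standard_normal((n, J))
    z = np.sqrt(rho) * common[:, None] + np.sqrt(1.0 - rho) * idio
    x = 1 + (z[:, :, None] > cuts[None, :, :]).sum(axis=2)  # (n, J) in 1..5

    b = np.array([stratum.coefficients[i] for i in items])
    eta = x @ b
    cum = expit(np.asarray(stratum.cutpoints)[None, :] - eta[:, None])  # P(Y <= k)
    u = rng.random(n)
    y = 1 + (u[:, None] > cum).sum(axis=1)

    item_data = x.astype(float)
    sat = y.astype(float)
    if stratum.dropout_rate > 0.0:
        quit_draw = rng.random((n, J)) < stratum.dropout_rate
        any_quit = quit_draw.any(axis=1)
        first = np.where(any_quit, quit_draw.argmax(axis=1), J)
        item_data[np.arange(J)[None, :] >= first[:, None]] = np.nan
        sat_missing = any_quit & (rng.random(n) < stratum.satisfaction_dropout_prob)
        sat[sat_missing] = np.nan

    df = pd.DataFrame(
        {
            "respondent_id": [f"{stratum.label}-{i:06d}" for i in range(n)],
            "stratum": stratum.label,
        }
    )
    for j, item in enumerate(items):
        df[item] = pd.array(item_data[:, j], dtype="Float64").astype("Int64")
    df[SATISFACTION_ITEM] = pd.array(sat, dtype="Float64").astype("Int64")
    return df


def generate_survey(scenario: SimScenario, codebook: ItemCodebook | None = None) -> SurveyDataset:
    """Simulate a survey; deterministic given ``scenario.seed``."""
    codebook = codebook or default_codebook()
    for st in scenario.strata:
        missing = [i for i in st.item_ids if i not in codebook.item_ids]
        if missing:
            raise ConfigurationError(f"scenario items not in codebook: {missing}")
    frames = []
    for si, st in enumerate(scenario.strata):
        rng = np.random.default_rng([int(scenario.seed), si])
        frames.append(_simulate_stratum(st, rng))
    frame = pd.concat(frames, ignore_index=True)
    return SurveyDataset(codebook, frame)


def with_coefficients(
    scenario: SimScenario, label: str, coefficients: Mapping[str, float]
) -> SimScenario:
    """Copy of ``scenario`` with one stratum's coefficients replaced.

    Because the generator draws the latent traits and the satisfaction uniform
    in a fixed order, two scenarios differing only in coefficients share common
    random numbers — useful for monotonicity checks.
    """
    strata = tuple(
        replace(st, coefficients=dict(coefficients)) if st.label == label else st
        for st in scenario.strata
    )
    return replace(scenario, strata=strata)
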