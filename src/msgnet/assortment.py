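"""Assortative mixing: does similarity in lion-prey susceptibility or in diet
predict the strength of pairwise associations?

The response is the Dice index w_ij of every species pair, modelled with a
logit link on two pair-level similarity covariates: the negated absolute
difference in Jacobs' index (lion prey preference) and in the dietary monocot
proportion, so larger values mean more similar species.  Because the
responses are fractions in [0, 1], the model is a fractional (quasi-binomial)
logit: the point estimates coincide with the binomial-logit estimates, and
all inference comes from node-label permutation — the species -> attribute
assignment is shuffled, the covariates recomputed and the model refitted; a
coefficient is significant when the observed value is among the largest of
the permutation distribution (one-tailed, add-one estimator).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ValidationError, slugify
from .networks import AssociationNetwork

__all__ = [
    "AssortmentResult",
    "similarity_covariates",
    "fractional_logit",
    "fit_assortment",
]


@dataclass(frozen=True)
class AssortmentResult:
    network: str
    coef_prey: float
    p_prey: float
    coef_diet: float
    p_diet: float
    intercept: float
    n_pairs: int
    n_perms: int


def similarity_covariates(
    attrs: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Per-pair similarity covariates from the species attribute table.

    sim_prey = -|J_i - J_j| (range [-2, 0]); sim_diet = -|m_i - m_j|
    (range [-1, 0]).  Zero means identical attributes (maximal similarity).
    Pairs with a species missing from ``attrs`` are dropped with a warning.
    """
    rows, dropped = [], []
    for a, b in pairs:
        a, b = slugify(a), slugify(b)
        if a not in attrs.index or b not in attrs.index:
            dropped.append((a, b))
            continue
        rows.append(
            {
                "species_a": a,
                "species_b": b,
                "sim_prey": -abs(attrs.at[a, "jacobs_index"] - attrs.at[b, "jacobs_index"]),
                "sim_diet": -abs(attrs.at[a, "monocot_prop"] - attrs.at[b, "monocot_prop"]),
            }
        )
    if dropped:
        warnings.warn(f"dropping pairs lacking attributes: {dropped}")
    return pd.DataFrame(rows)


def fractional_logit(
    y: np.ndarray, X: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> np.ndarray:
    """Logit-link fit for fractional responses y in [0, 1] by IRLS.

    Maximises the Bernoulli-form quasi-likelihood sum y*log(mu) +
    (1-y)*log(1-mu); for 0/1 responses this is ordinary logistic regression.
    Returns the coefficient vector; raises on non-convergence.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValidationError("fractional responses must lie in [0, 1]")
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        # Newton step via weighted least squares on the working response
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        try:
            step = np.linalg.solve(X.T @ wx, X.T @ (w * z)) - beta
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"singular design in fractional logit: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta
    raise ValidationError("fractional logit did not converge")


def fit_assortment(
    net: AssociationNetwork,
    attrs: pd.DataFrame,
    n_perms: int = 10_000,
    seed: int = 0,
    covariates: Sequence[str] = ("sim_prey", "sim_diet"),
    max_failure_rate: float = 0.01,
) -> AssortmentResult:
    """Fit the assortment model on a network and assess significance by
    node-label permutation.

    Pairs with w_ij = 0 are retained (zeros are informative).  One-tailed
    p-values: p = (1 + #{permuted coef >= observed}) / (n_perms + 1).  The
    observed coefficients are deterministic; only the p-values carry
    Monte-Carlo error.  More than ``max_failure_rate`` non-converging
    permutation fits aborts with diagnostics.
    """
    species = [s for s in net.species if s in attrs.index]
    if len(species) < 3:
        raise ValidationError(
            f"need >= 3 species with attributes, have {len(species)}"
        )
    pairs = list(itertools.combinations(species, 2))
    idx = {s: i for i, s in enumerate(net.species)}
    y = np.array([net.weights[idx[a], idx[b]] for a, b in pairs])

    jac = attrs.loc[species, "jacobs_index"].to_numpy(dtype=float)
    mono = attrs.loc[species, "monocot_prop"].to_numpy(dtype=float)
    ia = np.array([species.index(a) for a, _ in pairs])
    ib = np.array([species.index(b) for _, b in pairs])

    def design(j: np.ndarray, m: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(pairs))]
        if "sim_prey" in covariates:
            cols.append(-np.abs(j[ia] - j[ib]))
        if "sim_diet" in covariates:
            cols.append(-np.abs(m[ia] - m[ib]))
        return np.column_stack(cols)

    beta_obs = fractional_logit(y, design(jac, mono))

    rng = np.random.default_rng(seed)
    n_coef = len(beta_obs)
    exceed = np.zeros(n_coef)
    failures = 0
    for _ in range(n_perms):
        perm = rng.permutation(len(species))
        try:
            beta_p = fractional_logit(y, design(jac[perm], mono[perm]))
        except ValidationError:
            failures += 1
            if failures > max_failure_rate * n_perms:
                raise ValidationError(
                    f"{failures} of {n_perms} permutation fits failed to converge"
                )
            continue
        exceed += beta_p >= beta_obs
    n_ok = n_perms - failures
    p = (1.0 + exceed) / (n_ok + 1.0)

    k = 1
    coef_prey = p_prey = float("nan")
    if "sim_prey" in covariates:
        coef_prey, p_prey = float(beta_obs[k]), float(p[k])
        k += 1
    coef_diet = p_diet = float("nan")
    if "sim_diet" in covariates:
        coef_diet, p_diet = float(beta_obs[k]), float(p[k])
    return AssortmentResult(
        network=net.scenario,
        coef_prey=coef_prey,
        p_prey=p_prey,
        coef_diet=coef_diet,
        p_diet=p_diet,
        intercept=float(beta_obs[0]),
        n_pairs=len(pairs),
        n_perms=n_ok,
    )
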