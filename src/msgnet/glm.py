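"""Logistic regression of MSG occurrence on scenario covariates (H1-H4) and
the Cramér's V collinearity screen.

The response is group type (1 = mixed-species, 0 = single-species); the
explanatory factors are habitat structure, NDVI tertile, lion-home-range
membership and the core/edge human-activity zone.  Effects are reported as
odds ratios with Wald 95% confidence intervals against fixed reference
levels: habitat *bushland*, NDVI *medium*, *outside* the LHR, *edge* zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .data import AnimalGroup, ValidationError, slugify

__all__ = ["OrResult", "fit_msg_model", "or_table", "cramers_v", "SeparationError"]

#: factor -> (levels in contrast order, reference level)
_FACTORS: dict[str, tuple[tuple[str, ...], str]] = {
    "habitat": (("grassland", "open_bushland", "bushland", "riverine"), "bushland"),
    "ndvi_class": (("small", "medium", "large"), "medium"),
    "in_lhr": (("inside", "outside"), "outside"),
    "zone": (("core", "edge"), "edge"),
}

DEFAULT_TERMS: tuple[str, ...] = ("habitat", "ndvi_class", "in_lhr", "zone")
#: species-specific models drop the zone term (community-level null result);
#: pass terms explicitly to restore it
SPECIES_TERMS: tuple[str, ...] = ("habitat", "ndvi_class", "in_lhr")


class SeparationError(ValidationError):
    """The likelihood is degenerate (separation or a constant predictor)."""


@dataclass(frozen=True)
class OrResult:
    """One factor contrast: odds ratio with Wald 95% CI and p-value."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def _design(groups: Sequence[AnimalGroup], terms: Sequence[str]) -> pd.DataFrame:
    rows = []
    for g in groups:
        row: dict[str, object] = {"is_msg": int(g.is_msg)}
        for t in terms:
            if t == "habitat":
                row[t] = g.habitat
            elif t == "ndvi_class":
                if g.ndvi_class is None:
                    raise ValidationError(f"group {g.group_id}: ndvi_class unset")
                row[t] = g.ndvi_class
            elif t == "in_lhr":
                if g.in_lhr is None:
                    raise ValidationError(f"group {g.group_id}: in_lhr unset")
                row[t] = "inside" if g.in_lhr else "outside"
            elif t == "zone":
                if g.zone is None:
                    raise ValidationError(f"group {g.group_id}: zone unset")
                row[t] = g.zone
            else:
                raise ValidationError(f"unknown model term {t!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def fit_msg_model(
    groups: Sequence[AnimalGroup],
    terms: Sequence[str] = DEFAULT_TERMS,
    subset_species: str | None = None,
    tol: float = 1e-8,
) -> list[OrResult]:
    """Fit the MSG-occurrence logit model and return odds-ratio contrasts.

    With ``subset_species`` the analysis units are the groups containing that
    species and the response is whether such a group is mixed.  Factor levels
    absent from the data are dropped from the design; a factor left with a
    single level (zero variance) or showing complete separation raises
    :class:`SeparationError` naming the term.
    """
    if subset_species is not None:
        sp = slugify(subset_species)
        groups = [g for g in groups if sp in g.species]
        if not groups:
            raise ValidationError(f"no groups contain species {sp!r}")
    df = _design(groups, terms)
    n = len(df)
    n_msg = int(df["is_msg"].sum())
    if n_msg < 2 or n - n_msg < 2:
        raise ValidationError(
            f"need >= 2 groups in each response class (have {n_msg} MSG / {n - n_msg} single)"
        )

    X_parts = [pd.Series(1.0, index=df.index, name="intercept")]
    labels: list[str] = ["intercept"]
    for t in terms:
        levels, ref = _FACTORS[t]
        observed = [lv for lv in levels if (df[t] == lv).any()]
        if len(observed) < 2:
            raise SeparationError(
                f"term {t!r} has a single observed level ({observed}); zero variance"
            )
        for lv in observed:
            if lv == ref:
                continue
            X_parts.append((df[t] == lv).astype(float).rename(f"{t}[{lv}]"))
            labels.append(f"{t}[{lv}]")
    X = pd.concat(X_parts, axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(df["is_msg"].to_numpy(), X.to_numpy()).fit(
                disp=0, method="newton", tol=tol, maxiter=200
            )
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(f"logit fit failed: {exc}") from exc
    params, bse = np.asarray(fit.params), np.asarray(fit.bse)
    if not np.all(np.isfinite(bse)) or np.any(np.abs(params[1:]) > 30):
        bad = [labels[i] for i in range(len(labels)) if not np.isfinite(bse[i]) or (i > 0 and abs(params[i]) > 30)]
        raise SeparationError(f"separation/degeneracy detected for term(s) {bad}")

    z = stats.norm.ppf(0.975)
    out = []
    for i, lab in enumerate(labels):
        if lab == "intercept":
            continue
        out.append(
            OrResult(
                term=lab,
                odds_ratio=float(np.exp(params[i])),
                ci_low=float(np.exp(params[i] - z * bse[i])),
                ci_high=float(np.exp(params[i] + z * bse[i])),
                p_value=float(2 * stats.norm.sf(abs(params[i] / bse[i]))),
                n=n,
            )
        )
    return out


def or_table(results: Sequence[OrResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "n": r.n,
            }
            for r in results
        ]
    )


def cramers_v(x: Sequence, y: Sequence) -> float:
    """Cramér's V between two categorical vectors.

    V = sqrt(chi2 / (n * (min(r, c) - 1))) from the Pearson chi-square of the
    contingency table, without continuity correction.  Levels with a zero
    margin are dropped (with a warning).
    """
    x = pd.Series(list(x)).astype(str)
    y = pd.Series(list(y)).astype(str)
    if len(x) != len(y):
        raise ValidationError("cramers_v: vectors must have equal length")
    table = pd.crosstab(x, y)
    empty_rows = table.index[(table.sum(axis=1) == 0)]
    empty_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(empty_rows) or len(empty_cols):
        warnings.warn(
            f"dropping zero-margin levels rows={list(empty_rows)} cols={list(empty_cols)}"
        )
        table = table.drop(index=empty_rows, columns=empty_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("cramers_v: need >= 2 levels in each vector")
    chi2 = stats.chi2_contingency(table.to_numpy(), correction=False)[0]
    n = table.to_numpy().sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))
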