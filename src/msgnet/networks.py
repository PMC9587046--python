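"""Dice-weighted species association networks and scenario comparisons.

Edges carry Dice's index w_ij = 2 N_ij / (N_i + N_j), where N_i, N_j and
N_ij count the groups holding species i, species j, and both.  Scenario
networks are compared through three node measures — strength, the Y-measure
(disparity) and a weighted clustering coefficient — aggregated over the focal
species in subsampled replicates and tested with Welch's t on the logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import AnimalGroup, FOCAL_SPECIES, OccurrenceMatrix, ValidationError, slugify

__all__ = [
    "AssociationNetwork",
    "dice_network",
    "network_from_matrix",
    "node_measures",
    "MEASURES",
    "subsample_replicates",
    "match_sample_size",
    "aggregated_measures",
    "compare_networks",
    "WelchResult",
    "welch_log_test",
    "export_dot",
]

MEASURES: tuple[str, ...] = ("strength", "y_measure", "wcc")


@dataclass
class AssociationNetwork:
    """Symmetric Dice-weighted species graph for one scenario."""

    species: list[str]
    weights: np.ndarray  # (S, S) symmetric, zero diagonal, values in [0, 1]
    occurrences: np.ndarray  # N_j per species
    cooccurrences: np.ndarray  # N_ij per pair
    scenario: str = ""
    n_groups: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValidationError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValidationError("weight diagonal must be zero")
        if w.size and (w.min() < 0 or w.max() > 1):
            raise ValidationError("Dice weights must lie in [0, 1]")
        self.weights = w

    def weight(self, a: str, b: str) -> float:
        ia, ib = self.species.index(slugify(a)), self.species.index(slugify(b))
        return float(self.weights[ia, ib])

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.species)):
            for j in range(i + 1, len(self.species)):
                rows.append(
                    {
                        "species_a": self.species[i],
                        "species_b": self.species[j],
                        "dice": self.weights[i, j],
                        "n_cooccur": int(self.cooccurrences[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _network_from_counts(
    n: np.ndarray, nij: np.ndarray, species: Sequence[str], scenario: str, n_groups: int
) -> AssociationNetwork:
    denom = n[:, None] + n[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, 2.0 * nij / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(w, 0.0)
    return AssociationNetwork(
        species=list(species),
        weights=w,
        occurrences=n.astype(int),
        cooccurrences=nij.astype(int),
        scenario=scenario,
        n_groups=n_groups,
    )


def dice_network(
    groups: Sequence[AnimalGroup],
    species: Sequence[str],
    scenario: str = "",
) -> AssociationNetwork:
    """Build the Dice association network over ``groups`` on a fixed node set."""
    species = [slugify(s) for s in species]
    if not species:
        raise ValidationError("species set must be nonempty")
    idx = {s: j for j, s in enumerate(species)}
    m = np.zeros((len(groups), len(species)), dtype=np.int8)
    for i, g in enumerate(groups):
        for s in g.species:
            j = idx.get(s)
            if j is not None:
                m[i, j] = 1
    n = m.sum(axis=0)
    nij = (m.T @ m).astype(float)
    return _network_from_counts(n.astype(float), nij, species, scenario, len(groups))


def network_from_matrix(
    matrix: OccurrenceMatrix | np.ndarray,
    species: Sequence[str] | None = None,
    scenario: str = "",
) -> AssociationNetwork:
    """Dice network from a binary occurrence matrix (rows = groups)."""
    if isinstance(matrix, OccurrenceMatrix):
        data, species = matrix.data, matrix.species
    else:
        data = np.asarray(matrix)
        if species is None:
            species = [f"sp{j}" for j in range(data.shape[1])]
    n = data.sum(axis=0).astype(float)
    nij = (data.T.astype(int) @ data.astype(int)).astype(float)
    return _network_from_counts(n, nij, list(species), scenario, data.shape[0])


# ---------------------------------------------------------------------------
# Node measures
# ---------------------------------------------------------------------------


def node_measures(
    net: AssociationNetwork, variant: Literal["barrat", "geometric"] = "barrat"
) -> pd.DataFrame:
    """Per-node strength, Y-measure and weighted clustering coefficient.

    * strength  s_i = sum_j w_ij
    * Y-measure Y_i = sum_j (w_ij / s_i)^2, the disparity of i's associations
      (1/k_i when all incident weights are equal, 1 when one edge dominates)
    * wcc: triangle closure among i's neighbours.  The default ``barrat``
      variant averages the two adjacent edge weights of each closed triplet,
      c_i = [1/(s_i (k_i - 1))] * sum_{j != h} ((w_ij + w_ih)/2) a_ij a_ih a_jh;
      ``geometric`` uses the geometric mean of the adjacent weights over all
      triplets (closed-triplet value / total-triplet value).

    Isolated nodes (s_i = 0) get NaN for Y and wcc; nodes with a single
    neighbour get NaN for wcc.
    """
    w = net.weights
    a = (w > 0).astype(float)
    s = w.sum(axis=1)
    k = a.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(s > 0, w / np.where(s > 0, s, 1)[:, None], 0.0)
        y = np.where(s > 0, (norm**2).sum(axis=1), np.nan)

    if variant == "barrat":
        closed = ((w * a) @ a * a).sum(axis=1)  # ordered pairs (j, h)
        denom = s * (k - 1)
        wcc = np.where(denom > 0, closed / np.where(denom > 0, denom, 1), np.nan)
    elif variant == "geometric":
        r = np.sqrt(w)
        tri = ((r @ a) * r).sum(axis=1)  # closed triplets, ordered (j, h)
        allt = r.sum(axis=1) ** 2 - (r**2).sum(axis=1)  # all triplets at i
        wcc = np.where(allt > 0, tri / np.where(allt > 0, allt, 1), np.nan)
    else:
        raise ValidationError(f"unknown clustering variant {variant!r}")
    wcc = np.where(k >= 2, wcc, np.nan)

    return pd.DataFrame(
        {
            "species": net.species,
            "strength": s,
            "y_measure": y,
            "wcc": wcc,
            "degree": k.astype(int),
        }
    ).set_index("species")


# ---------------------------------------------------------------------------
# Subsampling and scenario comparison
# ---------------------------------------------------------------------------


def subsample_replicates(
    groups: Sequence[AnimalGroup], k: int = 3, seed: int | np.random.Generator = 0
) -> list[list[AnimalGroup]]:
    """Seeded uniform random partition into k disjoint, exhaustive subsets
    whose sizes differ by at most one."""
    if k < 2:
        raise ValidationError(f"need k >= 2 replicates, got {k}")
    if len(groups) < k:
        raise ValidationError(f"cannot split {len(groups)} groups into {k} replicates")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(groups))
    return [[groups[i] for i in chunk] for chunk in np.array_split(perm, k)]


def match_sample_size(
    groups_a: Sequence[AnimalGroup],
    groups_b: Sequence[AnimalGroup],
    seed: int | np.random.Generator = 0,
) -> list[AnimalGroup]:
    """Uniform random subset of ``groups_b`` matching ``len(groups_a)``."""
    if len(groups_b) < len(groups_a):
        raise ValidationError(
            f"cannot downsample {len(groups_b)} groups to {len(groups_a)}"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(len(groups_b), size=len(groups_a), replace=False)
    return [groups_b[i] for i in sorted(take)]


def aggregated_measures(
    replicates: Sequence[Sequence[AnimalGroup]],
    species: Sequence[str],
    focal_species: Sequence[str] = FOCAL_SPECIES,
    variant: str = "barrat",
    scenario: str = "",
) -> pd.DataFrame:
    """One aggregated value per replicate per measure: the mean of the focal
    species' node measures in that replicate's Dice network."""
    focal = [slugify(s) for s in focal_species]
    rows = []
    for r, rep in enumerate(replicates):
        net = dice_network(rep, species, scenario=scenario)
        nm = node_measures(net, variant=variant)
        present = [s for s in focal if s in nm.index]
        if not present:
            raise ValidationError(f"replicate {r}: no focal species measured")
        agg = nm.loc[present, list(MEASURES)].mean(skipna=True)
        rows.append({"replicate": r, **agg.to_dict()})
    return pd.DataFrame(rows).set_index("replicate")


@dataclass(frozen=True)
class WelchResult:
    measure: str
    t: float
    df: float
    p: float
    mean_log_a: float
    mean_log_b: float


def welch_log_test(a: np.ndarray, b: np.ndarray, measure: str = "") -> WelchResult:
    """Two-tailed Welch two-sample t-test on natural logs."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    for name, v in (("a", a), ("b", b)):
        if (v <= 0).any():
            bad = np.flatnonzero(v <= 0).tolist()
            raise ValidationError(
                f"log undefined: non-positive aggregated {measure} values in sample "
                f"{name} at replicate(s) {bad}"
            )
    la, lb = np.log(a), np.log(b)
    if la.shape == lb.shape and np.array_equal(la, lb):
        # identical samples: no evidence of difference by convention
        return WelchResult(measure, 0.0, float(len(la) + len(lb) - 2), 1.0,
                           float(la.mean()), float(lb.mean()))
    res = stats.ttest_ind(la, lb, equal_var=False)
    return WelchResult(
        measure=measure,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_log_a=float(la.mean()),
        mean_log_b=float(lb.mean()),
    )


def compare_networks(
    groups_a: Sequence[AnimalGroup],
    groups_b: Sequence[AnimalGroup],
    species: Sequence[str],
    focal_species: Sequence[str] = FOCAL_SPECIES,
    k: int = 3,
    seed: int = 0,
    match: bool = True,
    variant: str = "barrat",
) -> dict[str, WelchResult]:
    """Compare two scenarios on the three aggregated node measures.

    The larger scenario is first downsampled to the size of the smaller
    (when ``match``), both are split into ``k`` disjoint replicates, each
    replicate yields the focal-species mean of every measure, and the k-vs-k
    values are tested with Welch's t on natural logs.
    """
    rng = np.random.default_rng(seed)
    if match:
        if len(groups_b) > len(groups_a):
            groups_b = match_sample_size(groups_a, groups_b, rng)
        elif len(groups_a) > len(groups_b):
            groups_a = match_sample_size(groups_b, groups_a, rng)
    # the same child seed partitions both sides, so identical inputs yield
    # identical replicates (and a null comparison: t = 0, p = 1)
    part_seed = int(rng.integers(0, 2**31 - 1))
    reps_a = subsample_replicates(groups_a, k=k, seed=part_seed)
    reps_b = subsample_replicates(groups_b, k=k, seed=part_seed)
    agg_a = aggregated_measures(reps_a, species, focal_species, variant)
    agg_b = aggregated_measures(reps_b, species, focal_species, variant)
    return {
        m: welch_log_test(agg_a[m].to_numpy(), agg_b[m].to_numpy(), measure=m)
        for m in MEASURES
    }


# ---------------------------------------------------------------------------
# DOT export (display filtering only; analysis always uses the full network)
# ---------------------------------------------------------------------------


def export_dot(
    net: AssociationNetwork,
    min_weight: float = 0.05,
    min_cooccur: int = 2,
    highlight: Mapping[frozenset, str] | None = None,
    focal_species: Sequence[str] = FOCAL_SPECIES,
) -> str:
    """Render the network as Graphviz DOT text.

    An edge is drawn only when its Dice weight is >= ``min_weight`` and the
    pair co-occurred at least ``min_cooccur`` times; node area is
    proportional to the species' occurrence count.  ``highlight`` maps pairs
    (frozensets of two slugs) to a style: ``"significant"`` (thick black) or
    ``"habitat"`` (thick grey, significance explainable by shared habitat
    preference).  Filtering affects display only.
    """
    highlight = {frozenset(map(slugify, k)): v for k, v in (highlight or {}).items()}
    focal = {slugify(s) for s in focal_species}
    nmax = max(1, int(net.occurrences.max()) if len(net.occurrences) else 1)
    lines = ["graph associations {", "  layout=neato;", "  node [shape=circle];"]
    for s, n in zip(net.species, net.occurrences):
        width = 0.3 + 0.9 * math.sqrt(n / nmax)  # node area ~ occurrences
        fill = "grey80" if s in focal else "white"
        lines.append(
            f'  "{s}" [width={width:.2f}, fixedsize=true, style=filled, '
            f'fillcolor={fill}, label="{s}\\n{int(n)}"];'
        )
    for i in range(len(net.species)):
        for j in range(i + 1, len(net.species)):
            w = net.weights[i, j]
            if w < min_weight or net.cooccurrences[i, j] < min_cooccur:
                continue
            style = highlight.get(frozenset((net.species[i], net.species[j])))
            attrs = [f'label="{w:.2f}"', f"len={1.0 / max(w, 0.05):.2f}"]
            if style == "significant":
                attrs += ["penwidth=3", "color=black"]
            elif style == "habitat":
                attrs += ["penwidth=3", "color=grey60"]
            else:
                attrs += ["penwidth=1", "color=grey30"]
            lines.append(
                f'  "{net.species[i]}" -- "{net.species[j]}" [{", ".join(attrs)}];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"
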