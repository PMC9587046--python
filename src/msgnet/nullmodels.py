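"""Fixed-margin randomisation of the occurrence matrix and dyadic tests.

The null model treats every binary groups x species matrix with the observed
row and column sums as equally likely; the habitat-stratified variant
additionally fixes each species' number of occurrences per habitat type.
The space is explored with checkerboard swaps (2x2 submatrix exchanges, the
classic Monte-Carlo move for presence/absence matrices); a "step" is one swap
*attempt*, and the realised acceptance rate is reported so users can gauge
effective mixing.  Because the randomisation preserves every species' total
N_j, the co-occurrence count N_ij is an equivalent test statistic to Dice's
index, and the upper tail probes pairs that co-occur more often than chance.

For guard-sized matrices an exact depth-first enumeration of the null space
serves as the oracle against which the Monte-Carlo chain is validated.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import AnimalGroup, OccurrenceMatrix, ValidationError, slugify, summarize_species

__all__ = [
    "RandomisationPlan",
    "NullSamples",
    "DyadResult",
    "checkerboard_swap",
    "sample_null",
    "enumerate_null",
    "EnumerationGuardError",
    "dyad_test",
    "dyad_tests",
]


@dataclass(frozen=True)
class RandomisationPlan:
    """Chain schedule for the fixed-margin sampler.

    ``n_steps`` (total swap attempts) is ``burn_in + n_samples * thin``; the
    defaults give ~1.01e7 attempts, the scale used for the field analysis.
    ``serial`` switches to the serial scheme in which the observed matrix
    itself counts as the first sample and no burn-in is discarded.
    """

    n_samples: int = 10_000
    burn_in: int = 100_000
    thin: int = 1_000
    stratified: bool = False
    seed: int = 0
    serial: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.thin < 1 or self.burn_in < 0:
            raise ValidationError("invalid plan: need n_samples >= 1, thin >= 1, burn_in >= 0")

    @property
    def n_steps(self) -> int:
        return self.burn_in + self.n_samples * self.thin

    def scaled(self, factor: float) -> "RandomisationPlan":
        """A cheaper copy with n_samples/burn_in scaled down (thin kept)."""
        return RandomisationPlan(
            n_samples=max(100, int(self.n_samples * factor)),
            burn_in=max(100, int(self.burn_in * factor)),
            thin=self.thin,
            stratified=self.stratified,
            seed=self.seed,
            serial=self.serial,
        )


@dataclass
class NullSamples:
    """Sampled co-occurrence statistics for tracked pairs under the null."""

    pairs: list[tuple[str, str]]
    observed: np.ndarray  # (n_pairs,)
    samples: np.ndarray  # (n_samples, n_pairs)
    acceptance_rate: float
    stratified: bool
    frozen: bool  # no successful swap during burn-in

    def p_upper(self) -> np.ndarray:
        """Add-one upper-tail p-value per pair (never exactly 0)."""
        n = self.samples.shape[0]
        exceed = (self.samples >= self.observed[None, :]).sum(axis=0)
        return (1.0 + exceed) / (n + 1.0)


def checkerboard_swap(
    matrix: OccurrenceMatrix | np.ndarray,
    rng: np.random.Generator,
    stratified: bool = False,
) -> bool:
    """One swap attempt in place; returns True when a swap happened.

    Picks two distinct rows and two distinct columns uniformly; if the 2x2
    submatrix is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]) it is
    flipped, otherwise nothing changes.  Margins are preserved either way.
    In stratified mode rows from different habitat strata are rejected, which
    additionally preserves per-stratum column sums.
    """
    if isinstance(matrix, OccurrenceMatrix):
        data, strata = matrix.data, matrix.row_stratum
    else:
        data, strata = np.asarray(matrix), None
    n_rows, n_cols = data.shape
    if n_rows < 2 or n_cols < 2:
        return False
    r1, r2 = rng.choice(n_rows, size=2, replace=False)
    c1, c2 = rng.choice(n_cols, size=2, replace=False)
    if stratified:
        if strata is None:
            raise ValidationError("stratified swap requires row strata")
        if strata[r1] != strata[r2]:
            return False
    a, b = data[r1, c1], data[r1, c2]
    c, d = data[r2, c1], data[r2, c2]
    if a == d and b == c and a != b:
        data[r1, c1], data[r1, c2] = b, a
        data[r2, c1], data[r2, c2] = d, c
        return True
    return False


def _run_chain(
    data: np.ndarray,
    strata_codes: np.ndarray | None,
    pair_idx: Sequence[tuple[int, int]],
    plan: RandomisationPlan,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, bool]:
    """Hot loop: flat-list matrix, pre-drawn proposals, incremental statistics."""
    n_rows, n_cols = data.shape
    flat = data.ravel().astype(int).tolist()
    codes = strata_codes.tolist() if strata_codes is not None else None

    # current co-occurrence per tracked pair, updated incrementally
    cols = data.astype(np.int64)
    stat = [int((cols[:, a] * cols[:, b]).sum()) for a, b in pair_idx]
    # column -> [(pair position, partner column), ...]
    touching: dict[int, list[tuple[int, int]]] = {}
    for k, (a, b) in enumerate(pair_idx):
        touching.setdefault(a, []).append((k, b))
        touching.setdefault(b, []).append((k, a))

    n_samples, burn_in, thin = plan.n_samples, plan.burn_in, plan.thin
    total = burn_in + n_samples * thin if not plan.serial else (n_samples - 1) * thin
    samples = np.empty((n_samples, len(pair_idx)), dtype=np.int64)
    if plan.serial:
        samples[0] = stat
    out_i = 1 if plan.serial else 0
    accepted = 0
    burn_accepted = 0
    attempt = 0
    batch = 1 << 16
    next_record = (burn_in + thin) if not plan.serial else thin
    while attempt < total:
        m = min(batch, total - attempt)
        rr1 = rng.integers(0, n_rows, size=m).tolist()
        rr2 = rng.integers(0, n_rows - 1, size=m).tolist()
        cc1 = rng.integers(0, n_cols, size=m).tolist()
        cc2 = rng.integers(0, n_cols - 1, size=m).tolist()
        for t in range(m):
            attempt += 1
            r1 = rr1[t]
            r2 = rr2[t]
            if r2 >= r1:
                r2 += 1
            ok = True
            if codes is not None and codes[r1] != codes[r2]:
                ok = False
            if ok:
                c1 = cc1[t]
                c2 = cc2[t]
                if c2 >= c1:
                    c2 += 1
                i11 = r1 * n_cols + c1
                i12 = r1 * n_cols + c2
                i21 = r2 * n_cols + c1
                i22 = r2 * n_cols + c2
                a = flat[i11]
                d = flat[i22]
                if a == d and flat[i12] == flat[i21] and a != flat[i12]:
                    # flip the checkerboard, one cell at a time, keeping the
                    # tracked products consistent with the current state
                    for idx, row, col in (
                        (i11, r1, c1),
                        (i12, r1, c2),
                        (i21, r2, c1),
                        (i22, r2, c2),
                    ):
                        new = 1 - flat[idx]
                        delta = new - flat[idx]
                        for k, partner in touching.get(col, ()):
                            stat[k] += delta * flat[row * n_cols + partner]
                        flat[idx] = new
                    accepted += 1
                    if attempt <= burn_in:
                        burn_accepted += 1
            if attempt == next_record:
                samples[out_i] = stat
                out_i += 1
                next_record += thin
    acc_rate = accepted / total if total else 0.0
    frozen = burn_accepted == 0 and burn_in > 0
    data[...] = np.asarray(flat, dtype=data.dtype).reshape(n_rows, n_cols)
    return samples, acc_rate, frozen


def sample_null(
    matrix: OccurrenceMatrix,
    plan: RandomisationPlan,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> NullSamples:
    """Run the swap chain from the observed matrix and sample co-occurrence
    counts for the given species pairs.

    The input matrix is not modified (the chain runs on a copy).  A warning
    is emitted when no swap succeeds during burn-in (frozen matrix: every
    sample equals the observed statistic and all p-values are 1).
    """
    if pairs is None:
        pairs = list(itertools.combinations(matrix.species, 2))
    pairs = [(slugify(a), slugify(b)) for a, b in pairs]
    col = {s: j for j, s in enumerate(matrix.species)}
    try:
        pair_idx = [(col[a], col[b]) for a, b in pairs]
    except KeyError as exc:
        raise ValidationError(f"pair species not in matrix: {exc}") from exc

    work = matrix.data.copy()
    strata_codes = None
    if plan.stratified:
        _, strata_codes = np.unique(matrix.row_stratum.astype(str), return_inverse=True)
    observed = np.array(
        [int((matrix.data[:, a].astype(int) * matrix.data[:, b]).sum()) for a, b in pair_idx]
    )
    rng = np.random.default_rng(plan.seed)
    samples, acc, frozen = _run_chain(work, strata_codes, pair_idx, plan, rng)
    if frozen:
        warnings.warn(
            "no successful swap during burn-in: matrix is (effectively) frozen, "
            "all null samples equal the observed statistic",
            stacklevel=2,
        )
    # margins are invariant by construction; verify cheaply
    assert (work.sum(axis=0) == matrix.data.sum(axis=0)).all()
    assert (work.sum(axis=1) == matrix.data.sum(axis=1)).all()
    return NullSamples(
        pairs=pairs,
        observed=observed,
        samples=samples,
        acceptance_rate=acc,
        stratified=plan.stratified,
        frozen=frozen,
    )


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------


class EnumerationGuardError(ValidationError):
    """The instance is too large for exhaustive enumeration; use the chain."""


_MAX_CELLS = 20
_MAX_MATRICES = 5000


def _enumerate_block(
    row_sums: Sequence[int],
    col_sums: Sequence[int],
    ja: int,
    jb: int,
    cap: list[int],
    limit: int | None,
) -> Counter:
    """Distribution of the (ja, jb) co-occurrence count over all 0/1 matrices
    with the given margins, by row-wise DFS with feasibility pruning."""
    n_cols = len(col_sums)
    counts: Counter = Counter()

    def rec(i: int, remaining: tuple[int, ...], acc: int) -> None:
        if i == len(row_sums):
            if all(r == 0 for r in remaining):
                counts[acc] += 1
                cap[0] += 1
                if limit is not None and cap[0] > limit:
                    raise EnumerationGuardError(
                        f"more than {limit} matrices with these margins; "
                        "use the Monte-Carlo sampler"
                    )
            return
        rows_left = len(row_sums) - i - 1
        avail = [j for j in range(n_cols) if remaining[j] > 0]
        if len(avail) < row_sums[i]:
            return
        for chosen in itertools.combinations(avail, row_sums[i]):
            rem = list(remaining)
            for j in chosen:
                rem[j] -= 1
            if any(r > rows_left for r in rem):
                continue
            rec(i + 1, tuple(rem), acc + (ja in chosen and jb in chosen))

    rec(0, tuple(col_sums), 0)
    return counts


def enumerate_null(
    matrix: OccurrenceMatrix,
    pair: tuple[str, str],
    stratified: bool = False,
) -> dict[int, float]:
    """Exact null distribution of the pair's co-occurrence count.

    Enumerates every binary matrix with the observed margins (per habitat
    stratum when ``stratified``: the strata are independent blocks whose
    statistic distributions convolve).  Guarded to <= 20 cells or <= 5000
    matrices; larger instances raise :class:`EnumerationGuardError`.
    """
    ja = matrix.species.index(slugify(pair[0]))
    jb = matrix.species.index(slugify(pair[1]))
    n_rows, n_cols = matrix.shape
    # instances with <= 20 cells are always enumerable; larger ones only up
    # to the matrix-count cap
    limit = None if n_rows * n_cols <= _MAX_CELLS else _MAX_MATRICES
    cap = [0]

    if stratified:
        dists = []
        for h in dict.fromkeys(matrix.row_stratum):
            sub = matrix.data[matrix.row_stratum == h]
            dists.append(
                _enumerate_block(
                    sub.sum(axis=1).tolist(), sub.sum(axis=0).tolist(), ja, jb, cap, limit
                )
            )
        combined = dists[0]
        for d in dists[1:]:
            nxt: Counter = Counter()
            for v1, c1 in combined.items():
                for v2, c2 in d.items():
                    nxt[v1 + v2] += c1 * c2
            combined = nxt
        counts = combined
    else:
        counts = _enumerate_block(
            matrix.row_sums().tolist(), matrix.col_sums().tolist(), ja, jb, cap, limit
        )
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no matrix satisfies the margins (inconsistent input)")
    return {v: c / total for v, c in sorted(counts.items())}


def count_matrices(matrix: OccurrenceMatrix, stratified: bool = False) -> int:
    """Number of binary matrices sharing the observed margins (guarded)."""
    if len(matrix.species) < 2:
        raise ValidationError("need >= 2 species")
    cap = [0]
    limit = None if matrix.shape[0] * matrix.shape[1] <= _MAX_CELLS else _MAX_MATRICES
    a, b = matrix.species[0], matrix.species[1]
    ja, jb = 0, 1
    if stratified:
        total = 1
        for h in dict.fromkeys(matrix.row_stratum):
            sub = matrix.data[matrix.row_stratum == h]
            total *= sum(
                _enumerate_block(
                    sub.sum(axis=1).tolist(), sub.sum(axis=0).tolist(), ja, jb, cap, limit
                ).values()
            )
        return total
    return sum(
        _enumerate_block(
            matrix.row_sums().tolist(), matrix.col_sums().tolist(), ja, jb, cap, limit
        ).values()
    )


def exact_p_upper(dist: dict[int, float], observed: int) -> float:
    """Exact upper-tail probability P(statistic >= observed)."""
    return sum(p for v, p in dist.items() if v >= observed)


# ---------------------------------------------------------------------------
# Dyadic tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DyadResult:
    pair: tuple[str, str]
    dice: float
    n_cooccur: int
    p_unstratified: float
    p_stratified: float
    acceptance_unstratified: float
    acceptance_stratified: float


MIN_COOCCUR_TESTED = 2  # pairs must co-occur more than this to be tested


def dyad_tests(
    groups: Sequence[AnimalGroup],
    plan: RandomisationPlan,
    pairs: Sequence[tuple[str, str]] | None = None,
    species: Sequence[str] | None = None,
    top: int = 10,
) -> list[DyadResult]:
    """Randomisation tests for dyadic associations over a set of groups.

    By default all pairs among the ``top`` most frequently encountered
    species are considered; pairs co-occurring <= 2 times are skipped.  Both
    the unstratified and the habitat-stratified null are run (one chain
    each, all pairs tracked simultaneously); p-values are add-one upper-tail
    estimates, so significance means the pair co-occurred more often than
    the fixed-margin null explains.
    """
    matrix = OccurrenceMatrix.from_groups(groups, species=species)
    if pairs is None:
        summary = summarize_species(groups)
        common = [
            s for s in summary["species"].head(top) if s in matrix.species
        ]
        pairs = list(itertools.combinations(sorted(common), 2))
    pairs = [(slugify(a), slugify(b)) for a, b in pairs]
    tested = [p for p in pairs if matrix.cooccurrence(*p) > MIN_COOCCUR_TESTED]
    if not tested:
        return []
    res_u = sample_null(
        matrix,
        RandomisationPlan(
            n_samples=plan.n_samples,
            burn_in=plan.burn_in,
            thin=plan.thin,
            stratified=False,
            seed=plan.seed,
            serial=plan.serial,
        ),
        pairs=tested,
    )
    res_s = sample_null(
        matrix,
        RandomisationPlan(
            n_samples=plan.n_samples,
            burn_in=plan.burn_in,
            thin=plan.thin,
            stratified=True,
            seed=plan.seed + 1,
            serial=plan.serial,
        ),
        pairs=tested,
    )
    p_u, p_s = res_u.p_upper(), res_s.p_upper()
    out = []
    for k, (a, b) in enumerate(tested):
        na = int(matrix.col_sums()[matrix.species.index(a)])
        nb = int(matrix.col_sums()[matrix.species.index(b)])
        nab = int(res_u.observed[k])
        dice = 2.0 * nab / (na + nb) if na + nb else 0.0
        out.append(
            DyadResult(
                pair=(a, b),
                dice=dice,
                n_cooccur=nab,
                p_unstratified=float(p_u[k]),
                p_stratified=float(p_s[k]),
                acceptance_unstratified=res_u.acceptance_rate,
                acceptance_stratified=res_s.acceptance_rate,
            )
        )
    return out


def dyad_test(
    groups: Sequence[AnimalGroup],
    pair: tuple[str, str],
    plan: RandomisationPlan,
    species: Sequence[str] | None = None,
) -> DyadResult | None:
    """Randomisation test for one pair; ``None`` when the pair co-occurred
    too rarely (<= 2 times) to be tested."""
    res = dyad_tests(groups, plan, pairs=[pair], species=species)
    return res[0] if res else None


def dyad_table(results: Iterable[DyadResult]) -> pd.DataFrame:
    rows = [
        {
            "species_a": r.pair[0],
            "species_b": r.pair[1],
            "dice": r.dice,
            "n_cooccur": r.n_cooccur,
            "p_unstratified": r.p_unstratified,
            "p_stratified": r.p_stratified,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
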