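"""Fisher exact tests for the cohort-composition comparisons.

Two-sided p-values use the minimum-likelihood definition: the sum of the
probabilities of all margin-preserving tables whose point probability does
not exceed the observed table's (with a 1e-7 relative tolerance for
floating-point ties, the convention of most statistical software). The
2x2 case goes through scipy; the general r x c case enumerates all tables
with the observed margins, or estimates the tail by seeded Monte-Carlo
sampling of margin-preserving tables when enumeration is infeasible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .records import ClinicalRecord

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "fisher_2x2",
    "fisher_rxc",
    "compare_cohort_composition",
]

_REL_TOL = 1e-7


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")


@dataclass
class FisherResult:
    p_value: float
    method: str                      # "exact_enumeration" or "monte_carlo"
    standard_error: float | None = None
    n_tables: int | None = None      # tables enumerated (exact) or reps (MC)

    def __float__(self) -> float:
        return self.p_value


def _effective(table: np.ndarray) -> np.ndarray:
    """Drop all-zero rows and columns (they carry no information)."""
    t = np.asarray(table, dtype=int)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0] if t.size else t
    return t


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    A table with a zero margin is uninformative and returns p = 1 with a
    warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("table has a zero margin; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _log_table_prob(table: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray,
                    total: int) -> float:
    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(total + 1)
        - gammaln(table + 1).sum()
    )


def _enumeration_bound(row_sums: np.ndarray, n_cols: int) -> float:
    """Upper bound on the number of margin-preserving tables: the product
    over free rows of the number of compositions of the row sum."""
    bound = 1.0
    for r in row_sums[:-1]:
        bound *= math.comb(int(r) + n_cols - 1, n_cols - 1)
        if bound > 1e18:
            break
    return bound


def fisher_rxc(
    table,
    method: str = "exact_enumeration",
    reps: int = 10000,
    seed: int | None = None,
    max_tables: float = 1e7,
) -> FisherResult:
    """Two-sided Fisher exact test for an r x c table.

    ``exact_enumeration`` walks every table with the observed margins
    (refusing when the enumeration bound exceeds ``max_tables`` — use
    ``monte_carlo`` then); ``monte_carlo`` samples ``reps`` tables with the
    observed margins (Patefield sampler, seeded) and reports the estimated
    p with its binomial standard error.
    """
    t = _effective(np.asarray(table, dtype=int))
    if t.size == 0 or t.shape[0] < 2 or t.shape[1] < 2:
        return FisherResult(p_value=1.0, method=method)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    total = int(t.sum())
    logp_obs = _log_table_prob(t, row_sums, col_sums, total)
    cut = logp_obs + math.log1p(_REL_TOL)

    if method == "exact_enumeration":
        if _enumeration_bound(row_sums, t.shape[1]) > max_tables:
            raise ValueError(
                "enumeration bound exceeded; rerun with method='monte_carlo'"
            )
        p, count = _enumerate_tables(row_sums, col_sums, total, cut)
        return FisherResult(p_value=min(p, 1.0), method=method, n_tables=count)
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(row_sums, col_sums)
        draws = sampler.rvs(size=reps, random_state=rng)
        logps = (
            gammaln(row_sums + 1).sum()
            + gammaln(col_sums + 1).sum()
            - gammaln(total + 1)
            - gammaln(draws + 1).sum(axis=(1, 2))
        )
        hits = int((logps <= cut).sum())
        # add-one estimate keeps p in (0, 1]
        p = (hits + 1) / (reps + 1)
        se = math.sqrt(p * (1 - p) / reps)
        return FisherResult(p_value=p, method=method, standard_error=se, n_tables=reps)
    raise ValueError(f"unknown method {method!r}")


def _enumerate_tables(
    row_sums: np.ndarray, col_sums: np.ndarray, total: int, log_cut: float
) -> tuple[float, int]:
    """Depth-first enumeration of all tables with the given margins,
    accumulating the probability of those at least as extreme (point
    probability <= observed) as the observed table."""
    r, c = len(row_sums), len(col_sums)
    const = float(gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum()
                  - gammaln(total + 1))
    p_sum = 0.0
    count = 0
    table = np.zeros((r, c), dtype=int)

    def fill_row(i: int, remaining_cols: np.ndarray, log_acc: float) -> None:
        nonlocal p_sum, count
        if i == r - 1:
            # last row forced by the column margins
            if np.all(remaining_cols >= 0):
                logp = const + log_acc - float(gammaln(remaining_cols + 1).sum())
                count += 1
                if logp <= log_cut:
                    p_sum += math.exp(logp)
            return
        for comp in _compositions(int(row_sums[i]), c, remaining_cols):
            row = np.array(comp, dtype=int)
            fill_row(i + 1, remaining_cols - row,
                     log_acc - float(gammaln(row + 1).sum()))

    def _compositions(s: int, k: int, caps: np.ndarray):
        """All ways to split s into k non-negative parts with part j <= caps[j]."""
        if k == 1:
            if 0 <= s <= caps[0]:
                yield (s,)
            return
        hi = min(s, int(caps[0]))
        lo = max(0, s - int(caps[1:].sum()))
        for x in range(lo, hi + 1):
            for rest in _compositions(s - x, k - 1, caps[1:]):
                yield (x,) + rest

    fill_row(0, col_sums.copy(), 0.0)
    return p_sum, count


def compare_cohort_composition(
    records: Iterable[ClinicalRecord],
    variable: str,
    by: str = "country",
    values: Mapping[str, object] | None = None,
    method: str = "exact_enumeration",
    seed: int | None = None,
) -> tuple[ContingencyTable, float]:
    """Cross-tabulate a categorical variable against a grouping variable
    (default: country) and test independence with Fisher's exact test.

    ``variable`` names a :class:`ClinicalRecord` attribute, or, when
    ``values`` is given, ``values[sample_id]`` supplies the category
    (e.g. a Schell class or an MSI status computed upstream). Records with
    a missing category are excluded from the table.
    """
    counts: dict[tuple[str, str], int] = {}
    rows: set[str] = set()
    cols: set[str] = set()
    for rec in records:
        group = getattr(rec, by)
        cat = values.get(rec.sample_id) if values is not None else getattr(rec, variable)
        if cat is None or group is None:
            continue
        cat, group = str(cat), str(group)
        rows.add(cat)
        cols.add(group)
        counts[(cat, group)] = counts.get((cat, group), 0) + 1
    if len(rows) < 1 or len(cols) < 2:
        raise ValueError(
            f"need at least 2 groups and 1 category to compare "
            f"({len(rows)} categories x {len(cols)} groups observed)"
        )
    row_labels = sorted(rows)
    col_labels = sorted(cols)
    mat = np.array(
        [[counts.get((r, c), 0) for c in col_labels] for r in row_labels], dtype=int
    )
    table = ContingencyTable(row_labels=row_labels, col_labels=col_labels, counts=mat)
    if mat.shape == (2, 2):
        p = fisher_2x2(mat)
    else:
        p = fisher_rxc(mat, method=method, seed=seed).p_value
    return table, p
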