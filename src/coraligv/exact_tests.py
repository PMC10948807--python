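"""Fisher exact test of independence for r x c contingency tables.

The two-sided p-value is the total conditional probability, given the
margins, of all tables whose probability does not exceed that of the
observed table (the standard definition, matching the 2x2 case and R's
implementation for general tables).  Tables are enumerated exactly when the
lattice is small enough; otherwise a seeded Monte-Carlo sample of tables
with the observed margins is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

_REL_TOL = 1e-7


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str        # "exact" or "monte-carlo"
    n_tables: int      # tables enumerated, or Monte-Carlo draws

    def __float__(self) -> float:
        return self.p_value


def _log_table_prob(table: np.ndarray, lgr: float) -> float:
    # P(T) = prod r_i! prod c_j! / (n! prod n_ij!); lgr carries the constant part
    return lgr - gammaln(table + 1.0).sum()


def fisher_exact_rxc(table, max_tables: int = 10_000_000, n_mc: int = 1_000_000,
                     seed: int = 0) -> FisherResult:
    """Two-sided Fisher exact test on an r x c table of counts."""
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (obs < 0).any():
        raise ValueError("table counts must be non-negative")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        import warnings
        warnings.warn("dropping empty rows/columns from the contingency table")
        obs = obs[row_ok][:, col_ok]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping empty margins")

    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = int(obs.sum())
    lgr = (gammaln(rows + 1.0).sum() + gammaln(cols + 1.0).sum() - gammaln(n + 1.0))
    log_p_obs = _log_table_prob(obs, lgr)
    cutoff = log_p_obs + abs(log_p_obs) * _REL_TOL + 1e-12

    n_rows, n_cols = obs.shape
    counter = {"n": 0}
    total = 0.0

    def _enumerate(row: int, remaining_cols: np.ndarray, acc_lognum: float) -> float:
        """Sum P(T) over completions from `row` on, for tables with P <= cutoff."""
        nonlocal_counter = counter
        if row == n_rows - 1:
            nonlocal_counter["n"] += 1
            if nonlocal_counter["n"] > max_tables:
                raise _TooManyTables
            log_p = lgr - (acc_lognum + gammaln(remaining_cols + 1.0).sum())
            return float(np.exp(log_p)) if log_p <= cutoff else 0.0
        total_here = 0.0
        r = int(rows[row])
        cell = np.zeros(n_cols, dtype=np.int64)

        def _fill(col: int, left: int, lognum: float) -> None:
            nonlocal total_here
            if col == n_cols - 1:
                if left > remaining_cols[col]:
                    return
                cell[col] = left
                new_rem = remaining_cols - cell
                total2 = _enumerate(row + 1, new_rem,
                                    acc_lognum + lognum + gammaln(left + 1.0))
                total_here += total2
                return
            for v in range(min(left, int(remaining_cols[col])) + 1):
                cell[col] = v
                _fill(col + 1, left - v, lognum + gammaln(v + 1.0))
            cell[col] = 0

        _fill(0, r, 0.0)
        return total_here

    class _TooManyTables(Exception):
        pass

    try:
        total = _enumerate(0, cols.copy(), 0.0)
        return FisherResult(p_value=min(1.0, total), method="exact",
                            n_tables=counter["n"])
    except _TooManyTables:
        pass

    # Monte-Carlo: sample tables with the observed margins by permuting labels
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(n_rows), rows)
    col_labels = np.repeat(np.arange(n_cols), cols)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        t = np.zeros((n_rows, n_cols), dtype=np.int64)
        np.add.at(t, (row_labels, perm), 1)
        if _log_table_prob(t, lgr) <= cutoff:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    return FisherResult(p_value=min(1.0, p), method="monte-carlo", n_tables=n_mc)
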