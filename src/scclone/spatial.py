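"""Exact contingency-table tests and the two-region heterogeneity report.

Clone- and event-level differences between the two sampled tumour regions
are assessed with two-sided Fisher exact tests (the "probability mass at
or below the observed table" convention, as in R's ``fisher.test``):
a fast 2x2 path, and a general r x c test by full enumeration of tables
with fixed margins (with a seeded Monte-Carlo fallback for tables too
large to enumerate).  p-values are adjusted per tumour and per test
family with the Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

REL_TOL = 1e-7
ALPHA = 0.05


class DegenerateTableError(ValueError):
    """A margin of the contingency table is zero (p defined as 1)."""


@dataclass
class SpatialTestResult:
    test_id: str
    unit: str  # "clone" | "cnv" | "composition"
    table: np.ndarray
    p: float
    q: float = float("nan")
    region_specific: bool = False

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    @property
    def q_significant(self) -> bool:
        return self.q < ALPHA


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's (within
    relative tolerance 1e-7).  Zero margins make the table degenerate and
    p is 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _log_table_prob(table: np.ndarray, lgamma=math.lgamma) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = (
        sum(lgamma(r + 1) for r in rows)
        + sum(lgamma(c + 1) for c in cols)
        - lgamma(n + 1)
        - sum(lgamma(v + 1) for v in table.ravel())
    )
    return lp


def fisher_exact_rxc(
    table,
    max_tables: int = 2_000_000,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided exact conditional test for an r x c table.

    Enumerates every table with the observed margins recursively, summing
    the probabilities of tables no more probable than the observed one
    (relative tolerance 1e-7).  If the enumeration would visit more than
    ``max_tables`` partial states, a seeded Monte-Carlo estimate over
    ``mc_draws`` margin-preserving random tables is used instead.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be 2-D with non-negative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    t = t[rows > 0][:, cols > 0]
    if t.size == 0 or t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    obs_lp = _log_table_prob(t)
    cutoff = obs_lp + math.log1p(REL_TOL)

    nr, nc = t.shape
    lgamma = math.lgamma
    log_row_fact = sum(lgamma(r + 1) for r in rows)
    log_col_fact = sum(lgamma(c + 1) for c in cols)
    log_n_fact = lgamma(rows.sum() + 1)
    const = log_row_fact + log_col_fact - log_n_fact

    counter = [0]
    total_p = [0.0]

    cols_list = cols.tolist()
    rows_list = rows.tolist()

    def recurse(ri: int, rem_cols: list[int], acc_log_cell_fact: float) -> None:
        if counter[0] > max_tables:
            raise _TooLarge()
        if ri == nr - 1:
            lp = const - acc_log_cell_fact - sum(
                lgamma(c + 1) for c in rem_cols
            )
            counter[0] += 1
            if lp <= cutoff:
                total_p[0] += math.exp(lp)
            return
        r = rows_list[ri]

        def fill(ci: int, remaining: int, acc: float, rem: list[int]) -> None:
            if counter[0] > max_tables:
                raise _TooLarge()
            counter[0] += 1
            if ci == nc - 1:
                if remaining <= rem[ci]:
                    rem2 = rem.copy()
                    rem2[ci] -= remaining
                    recurse(ri + 1, rem2, acc + lgamma(remaining + 1))
                return
            lo = max(0, remaining - sum(rem[ci + 1 :]))
            hi = min(remaining, rem[ci])
            for v in range(lo, hi + 1):
                rem2 = rem.copy()
                rem2[ci] -= v
                fill(ci + 1, remaining - v, acc + lgamma(v + 1), rem2)

        fill(0, r, acc_log_cell_fact, rem_cols)

    class _TooLarge(Exception):
        pass

    try:
        recurse(0, cols_list, 0.0)
        return float(min(total_p[0], 1.0))
    except _TooLarge:
        pass

    # Monte-Carlo fallback: margin-preserving random tables (Patefield)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(rows, cols)
    draws = sampler.rvs(mc_draws, random_state=rng)
    lps = np.array([_log_table_prob(d.astype(np.int64)) for d in draws])
    exceed = int(np.sum(lps <= cutoff))
    return float((exceed + 1) / (mc_draws + 1))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spatial_report(
    clones,
    events,
    cell_regions: dict[str, str],
    regions: tuple[str, str] = ("r1", "r2"),
) -> list[SpatialTestResult]:
    """Two-region heterogeneity tests for one tumour.

    * composition: clones x regions r x c exact test (all clones,
      including any normal cluster, using member-cell region counts);
    * per clone: 2x2 in-clone vs rest x region;
    * per CNV event: 2x2 supporters vs non-supporters x region.

    BH-FDR is applied within the clone family and within the CNV family
    separately.  Clones whose members all fall in one region are flagged
    region-specific.
    """
    r1, r2 = regions
    region_cells = {
        r: [c for c, reg in cell_regions.items() if reg == r] for r in regions
    }
    n1, n2 = len(region_cells[r1]), len(region_cells[r2])
    if n1 == 0 or n2 == 0:
        raise DegenerateTableError(
            "spatial analysis needs cells in both regions"
        )
    results: list[SpatialTestResult] = []

    comp = np.array(
        [
            [c.region_counts.get(r1, 0), c.region_counts.get(r2, 0)]
            for c in clones
        ],
        dtype=np.int64,
    )
    results.append(
        SpatialTestResult(
            test_id="composition",
            unit="composition",
            table=comp,
            p=fisher_exact_rxc(comp),
        )
    )

    clone_results = []
    for c in clones:
        a1 = c.region_counts.get(r1, 0)
        a2 = c.region_counts.get(r2, 0)
        table = np.array([[a1, n1 - a1], [a2, n2 - a2]], dtype=np.int64)
        res = SpatialTestResult(
            test_id=f"clone:{c.clone_id}",
            unit="clone",
            table=table,
            p=fisher_exact_2x2(table),
            region_specific=(a1 + a2 > 0) and (a1 == 0 or a2 == 0),
        )
        clone_results.append(res)
    for res, q in zip(clone_results, bh_fdr([r.p for r in clone_results])):
        res.q = float(q)
    results.extend(clone_results)

    cnv_results = []
    for ev in events:
        s1 = sum(1 for cell in ev.cells if cell_regions.get(cell) == r1)
        s2 = sum(1 for cell in ev.cells if cell_regions.get(cell) == r2)
        table = np.array([[s1, n1 - s1], [s2, n2 - s2]], dtype=np.int64)
        res = SpatialTestResult(
            test_id=f"cnv:{ev.chrom}:{ev.start_bp}-{ev.end_bp}:{ev.direction}",
            unit="cnv",
            table=table,
            p=fisher_exact_2x2(table),
            region_specific=(s1 + s2 > 0) and (s1 == 0 or s2 == 0),
        )
        cnv_results.append(res)
    for res, q in zip(cnv_results, bh_fdr([r.p for r in cnv_results])):
        res.q = float(q)
    results.extend(cnv_results)
    return results
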