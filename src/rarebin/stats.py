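"""Per-bin burden testing: Wilcoxon rank-sum, Bonferroni, ranking.

The burden tables are integer-valued and heavily tied, so the rank-sum
test uses midranks throughout.  Small samples are handled by exact
enumeration of the permutation distribution of the rank sum (valid under
ties); larger samples use the tie-corrected normal approximation with a
continuity correction, the same recipe as R's default two-sample
``wilcox.test``.  The test is two-sided: a bin accumulates risk variants
(higher burden in cases) as well as potentially protective ones, and
either direction is of interest.

Multiple testing is a plain Bonferroni correction with m equal to the
number of bins tested in the current run.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binning import BinMatrix
from .variants import PhenotypeAssignment

# exact enumeration is used when the smaller group is at most this size
# and the number of arrangements stays enumerable
EXACT_GROUP_CUTOFF = 8
EXACT_MAX_ARRANGEMENTS = 200_000


class StatsError(Exception):
    pass


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank sum of the first sample (midranks)
    pvalue: float
    method: str       # "exact" | "normal"
    degenerate: bool  # all values identical in the pooled sample


@dataclass
class BinTestResult:
    bin_id: str
    feature_type: str
    n_loci: int
    case_burdens: np.ndarray
    control_burdens: np.ndarray
    statistic: float
    p_unadjusted: float
    p_adjusted: float
    significant: bool
    rank: int
    degenerate: bool = False


def wilcoxon_rank_sum(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon 2-sample rank-sum test with midranks for ties.

    Exact permutation enumeration when ``min(n1, n2) <= 8`` and at most
    2e5 arrangements; otherwise normal approximation with tie-corrected
    variance and continuity correction.  Pooled samples with zero
    variance return p = 1 with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if np.all(pooled == pooled[0]):
        return WilcoxonResult(statistic=w, pvalue=1.0, method="degenerate",
                              degenerate=True)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    if min(n1, n2) <= EXACT_GROUP_CUTOFF and comb(n, n1) <= EXACT_MAX_ARRANGEMENTS:
        obs_dev = abs(w - mu)
        hits = 0
        total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= obs_dev - 1e-9:
                hits += 1
        return WilcoxonResult(statistic=w, pvalue=hits / total,
                              method="exact", degenerate=False)
    # tie-corrected normal approximation with continuity correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return WilcoxonResult(statistic=w, pvalue=1.0, method="degenerate",
                              degenerate=True)
    dev = w - mu
    z = (abs(dev) - 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return WilcoxonResult(statistic=w, pvalue=p, method="normal",
                          degenerate=False)


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, p * m)."""
    if m < 1:
        raise StatsError("number of tests m must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise StatsError(f"p-value {p} outside [0, 1]")
    return min(1.0, p * m)


def test_all_bins(bin_matrix: BinMatrix, phen: PhenotypeAssignment,
                  alpha: float = 0.05) -> list:
    """Wilcoxon test per bin, Bonferroni over the bins tested, ranked.

    Results are sorted by ascending unadjusted p (ties broken by bin_id
    for determinism) and ranked 1..m.  Zero-variance bins are kept with
    p = 1 so that m stays interpretable.
    """
    if not 0.0 < alpha <= 1.0:
        raise StatsError("alpha must lie in (0, 1]")
    codes = np.array([1 if phen.group_of(s) == "case"
                      else 0 if phen.group_of(s) == "control" else -1
                      for s in bin_matrix.sample_ids], dtype=np.int8)
    if not (codes == 1).any() or not (codes == 0).any():
        raise StatsError("both phenotype groups must be non-empty")
    m = len(bin_matrix.bins)
    results = []
    for b, row in zip(bin_matrix.bins, bin_matrix.values):
        case_vals = row[codes == 1]
        ctrl_vals = row[codes == 0]
        res = wilcoxon_rank_sum(case_vals, ctrl_vals)
        p_adj = bonferroni_adjust(res.pvalue, m)
        results.append(BinTestResult(
            bin_id=b.bin_id, feature_type=b.feature_type, n_loci=b.n_loci,
            case_burdens=case_vals, control_burdens=ctrl_vals,
            statistic=res.statistic, p_unadjusted=res.pvalue,
            p_adjusted=p_adj, significant=(p_adj < alpha or alpha >= 1.0),
            rank=0,
            degenerate=res.degenerate))
    results.sort(key=lambda r: (r.p_unadjusted, r.bin_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def results_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "bin_id": r.bin_id,
        "feature_type": r.feature_type,
        "n_loci": r.n_loci,
        "case_mean_burden": float(np.mean(r.case_burdens)),
        "control_mean_burden": float(np.mean(r.control_burdens)),
        "statistic": r.statistic,
        "p_unadjusted": r.p_unadjusted,
        "p_adjusted": r.p_adjusted,
        "significant": int(r.significant),
        "rank": r.rank,
    } for r in results])


def write_results_tsv(results: list, path,
                      metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        results_frame(results).to_csv(fh, sep="\t", index=False)
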