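"""Expression-based confidence for regulatory edges.

Given a genes x samples expression matrix, each regulatory edge whose
endpoints are both measured gains the Pearson correlation of the two
genes and a qualitative confidence band on |r|; directional support
can be probed with a median-split rank-sum test (samples split at one
gene's median, the other gene's values compared between the high and
low groups, exactly for small n).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd

from litreg.graph import REGULATORY_PREDICATES, RegulatoryGraph

#: |r| thresholds for the qualitative bands: weak < .3 <= moderate < .6 <= strong
DEFAULT_BANDS = (0.3, 0.6)


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x samples.

    The loader does not transform values; log-normalisation is the
    caller's responsibility.
    """

    data: pd.DataFrame  # index = gene symbols, columns = sample ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ExpressionError(f"duplicate gene symbols: {list(dupes)[:5]}")
        if self.data.shape[1] < 3:
            raise ExpressionError("need at least 3 samples")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ExpressionError("non-finite expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, gene: str) -> np.ndarray:
        if gene not in self.data.index:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self.data.loc[gene].to_numpy(dtype=float)

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        """TSV dialect: first column gene symbol, header row sample ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


def pearson(x, y) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ExpressionError("inputs must be equal-length vectors")
    if x.size < 3:
        raise ExpressionError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        raise ExpressionError("zero variance: correlation undefined")
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def _u_statistic(low: np.ndarray, high: np.ndarray) -> float:
    """Mann–Whitney U counting (low > high) pairs, ties as 1/2."""
    diff = low[:, None] - high[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_two_sided_p(low_n: int, pooled: np.ndarray, u_obs: float) -> float:
    """Enumerate all equal-content group assignments of the pooled values.

    Two-sided: mass of assignments at least as extreme as ``u_obs`` in
    either tail of the (symmetric-support) permutation distribution of
    U, capped at 1.
    """
    n = pooled.size
    m = low_n * (n - low_n)
    lo_tail = min(u_obs, m - u_obs)
    hi_tail = max(u_obs, m - u_obs)
    idx = np.arange(n)
    count = 0
    total = comb(n, low_n)
    for low_idx in combinations(idx, low_n):
        mask = np.zeros(n, dtype=bool)
        mask[list(low_idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if u <= lo_tail + 1e-12 or u >= hi_tail - 1e-12:
            count += 1
    return min(1.0, count / total)


def median_split_ranksum(
    matrix: ExpressionMatrix,
    split_gene: str,
    test_gene: str,
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """(U, two-sided p) for the test gene across the split gene's median.

    Samples at or below the split gene's median form the low group
    (ties to low, deterministic for even n). U counts (low > high)
    pairs with ties as 1/2. The p-value is exact by full enumeration
    of group assignments when the combined n <= ``exact_max_n``, else
    a tie-corrected normal approximation with continuity correction.
    """
    sv = matrix.values_for(split_gene)
    tv = matrix.values_for(test_gene)
    med = float(np.median(sv))
    low_mask = sv <= med
    n_low = int(low_mask.sum())
    n_high = int((~low_mask).sum())
    if n_low < 2 or n_high < 2:
        raise ExpressionError(
            f"degenerate split on {split_gene!r}: groups {n_low}/{n_high}"
        )
    low, high = tv[low_mask], tv[~low_mask]
    u = _u_statistic(low, high)
    n = n_low + n_high
    if n <= exact_max_n:
        p = _exact_two_sided_p(n_low, tv.copy(), u)
        return u, p
    # tie-corrected normal approximation with continuity correction
    m = n_low * n_high
    _, tie_counts = np.unique(tv, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = m / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - m / 2.0) - 0.5) / sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
    return u, min(1.0, p)


def band(r: float, thresholds: tuple[float, float] = DEFAULT_BANDS) -> str:
    a = abs(r)
    if a < thresholds[0]:
        return "weak"
    if a < thresholds[1]:
        return "moderate"
    return "strong"


def attach_confidence(
    graph: RegulatoryGraph,
    matrix: ExpressionMatrix,
    thresholds: tuple[float, float] = DEFAULT_BANDS,
) -> RegulatoryGraph:
    """Annotate regulatory edges with Pearson r and a confidence band.

    Non-regulatory edges and edges with an endpoint missing from the
    matrix receive ``confidence: "no-data"``. Returns an annotated
    copy; the input graph is unmodified. The graph-level flag
    ``confidence_annotated`` marks the pass even when nothing matched.
    """
    out = graph.copy()
    genes = set(matrix.genes)
    for u, k, v, d in out.edges():
        if k not in REGULATORY_PREDICATES or u not in genes or v not in genes:
            d["confidence"] = "no-data"
            continue
        try:
            r = pearson(matrix.values_for(u), matrix.values_for(v))
        except ExpressionError:
            d["confidence"] = "no-data"
            continue
        d["r"] = r
        d["confidence"] = band(r, thresholds)
    out.g.graph["confidence_annotated"] = True
    return out
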