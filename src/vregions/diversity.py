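"""Richness, alpha-diversity and beta-diversity statistics on ASV count tables.

All estimators are implemented at the formula level:

* Hurlbert rarefaction  E[S] = sum_i (1 - C(N - N_i, n) / C(N, n))
* Chao1 (bias-corrected by default)  S_obs + F1 (F1 - 1) / (2 (F2 + 1))
* Shannon  H = -sum p_i ln p_i      (natural log by default)
* Simpson, reported as Gini-Simpson 1 - sum p_i^2 by default
* Fisher's alpha, the root of  S = alpha ln(1 + N / alpha)
* Bray-Curtis  sum|x - y| / sum(x + y)   and presence/absence Jaccard distance
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln


@dataclasses.dataclass
class CountTable:
    """ASV-by-sample matrix of non-negative integer counts."""

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray  # shape (n_asvs, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match id lists")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.asv_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.columns), list(df.index), df.to_numpy())

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="asv_id")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances; every column sums to 1."""
    sums = table.counts.sum(axis=0)
    for sid, s in zip(table.sample_ids, sums):
        if s == 0:
            raise ValueError(f"sample {sid!r} has zero total count")
    return pd.DataFrame(
        table.counts / sums, index=table.asv_ids, columns=table.sample_ids
    )


def _clean(counts: Sequence[int]) -> np.ndarray:
    x = np.asarray(counts, dtype=np.int64)
    if np.any(x < 0):
        raise ValueError("negative counts")
    return x[x > 0]


def rarefy_expected_richness(sample_counts: Sequence[int], n: int) -> float:
    """Expected richness in a random subsample of n individuals (Hurlbert).

    Computed with log-gamma for numerical stability; ``n == N`` returns the
    observed richness exactly.
    """
    x = _clean(sample_counts)
    total = int(x.sum())
    if not 1 <= n <= total:
        raise ValueError(f"subsample size must be in [1, {total}], got {n}")
    if n == total:
        return float(len(x))

    def log_choose(a: np.ndarray, b: int) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    keep = x <= total - n  # C(N - N_i, n) = 0 otherwise
    probs = np.zeros(len(x))
    if np.any(keep):
        probs[keep] = np.exp(log_choose(total - x[keep], n) - log_choose(np.array(total), n))
    return float(np.sum(1.0 - probs))


def chao1(sample_counts: Sequence[int], bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts."""
    x = _clean(sample_counts)
    if len(x) == 0:
        raise ValueError("empty sample")
    s_obs = len(x)
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        # classic form is undefined at F2 = 0; standard fallback correction
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(sample_counts: Sequence[int], base: float = math.e) -> float:
    """Shannon entropy H = -sum p ln p (natural log unless ``base`` given)."""
    x = _clean(sample_counts)
    if x.sum() == 0:
        raise ValueError("empty sample")
    p = x / x.sum()
    return float(-(p * (np.log(p) / math.log(base))).sum())


def simpson(sample_counts: Sequence[int], variant: str = "gini") -> float:
    """Simpson's index: ``gini`` = 1 - D (default), ``dominance`` = D,
    ``inverse`` = 1/D, with D = sum p_i^2."""
    x = _clean(sample_counts)
    if x.sum() == 0:
        raise ValueError("empty sample")
    p = x / x.sum()
    d = float((p**2).sum())
    if variant == "gini":
        return 1.0 - d
    if variant == "dominance":
        return d
    if variant == "inverse":
        return 1.0 / d
    raise ValueError(f"unknown Simpson variant {variant!r}")


def fisher_alpha(sample_counts: Sequence[int], tol: float = 1e-10) -> float:
    """Fisher's alpha: the root of S = alpha ln(1 + N / alpha).

    The defining function is increasing in alpha with supremum N, so a root
    exists for 1 <= S < N; S == N (all singletons) diverges and returns inf
    with a warning, as does the degenerate single-species sample S == 1.
    """
    x = _clean(sample_counts)
    s, n = len(x), int(x.sum())
    if s == 0 or n == 0:
        raise ValueError("empty sample")
    if s == n:
        warnings.warn("fisher_alpha: all species are singletons (S == N); alpha -> inf")
        return math.inf
    if s == 1:
        warnings.warn("fisher_alpha: single-species sample; estimate is degenerate")

    def f(alpha: float) -> float:
        return alpha * math.log1p(n / alpha) - s

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("fisher_alpha failed to bracket root")
    return float(brentq(f, lo, hi, xtol=tol))


def bray_curtis(x: Sequence[int], y: Sequence[int]) -> float | None:
    """Bray-Curtis dissimilarity; None when both vectors are all-zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors differ in length")
    denom = float((x + y).sum())
    if denom == 0:
        warnings.warn("bray_curtis undefined for two empty samples")
        return None
    return float(np.abs(x - y).sum() / denom)


def jaccard_distance(x: Sequence[int], y: Sequence[int]) -> float | None:
    """Presence/absence Jaccard distance; None when both vectors are all-zero."""
    x = np.asarray(x) > 0
    y = np.asarray(y) > 0
    if x.shape != y.shape:
        raise ValueError("count vectors differ in length")
    union = int((x | y).sum())
    if union == 0:
        warnings.warn("jaccard_distance undefined for two empty samples")
        return None
    return 1.0 - int((x & y).sum()) / union


def beta_diversity_matrix(table: CountTable, metric: str = "bray_curtis") -> pd.DataFrame:
    """Square sample-by-sample dissimilarity matrix (Bray-Curtis or Jaccard)."""
    fn = {"bray_curtis": bray_curtis, "jaccard": jaccard_distance}.get(metric)
    if fn is None:
        raise ValueError(f"unknown beta-diversity metric {metric!r}")
    n = len(table.sample_ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = fn(table.counts[:, i], table.counts[:, j])
            out[i, j] = out[j, i] = np.nan if v is None else v
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


def alpha_diversity_table(
    table: CountTable,
    *,
    rarefy_to: int | None = None,
    chao1_bias_corrected: bool = True,
    simpson_variant: str = "gini",
) -> pd.DataFrame:
    """Per-sample richness and alpha-diversity summary."""
    rows = {}
    for sid in table.sample_ids:
        counts = table.sample(sid)
        present = counts[counts > 0]
        row = {
            "n_reads": int(counts.sum()),
            "observed_richness": int(len(present)),
            "chao1": chao1(present, bias_corrected=chao1_bias_corrected),
            "shannon": shannon(present),
            "simpson": simpson(present, variant=simpson_variant),
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["fisher_alpha"] = fisher_alpha(present)
        if rarefy_to is not None:
            row["rarefied_richness"] = rarefy_expected_richness(present, rarefy_to)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefy_subsample(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Deterministic for a fixed seed. Raises if any sample holds fewer than
    ``depth`` reads.
    """
    sums = table.counts.sum(axis=0)
    for sid, s in zip(table.sample_ids, sums):
        if s < depth:
            raise ValueError(f"sample {sid!r} has only {s} reads (< depth {depth})")
    rng = np.random.default_rng(seed)
    cols = [
        rng.multivariate_hypergeometric(table.counts[:, j], depth)
        for j in range(len(table.sample_ids))
    ]
    return CountTable(
        list(table.sample_ids), list(table.asv_ids), np.column_stack(cols)
    )
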