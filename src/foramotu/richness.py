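"""Sample-based rarefaction and first-order jackknife richness.

Occurrences of MOTUs across sampling stations form an incidence matrix;
the expected richness at reduced sampling depth follows the
hypergeometric rarefaction formula and total richness is estimated with
the first-order jackknife

    S_e = S_o + f1 * (n - 1) / n,

where f1 counts taxa present in exactly one sample.  The variance uses
the Heltshe-Forrester form over f_j, the number of samples holding
exactly j unique taxa, and the 95% interval is 1.96 * sqrt(var).  The
coverage test asks whether the observed richness falls inside the
interval; the reported interval width can be read as a full width
(test against +/- CI/2, the default) or as a half width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "IncidenceMatrix",
    "RichnessEstimate",
    "build_incidence",
    "rarefaction",
    "jackknife1",
    "coverage_test",
]


@dataclass
class IncidenceMatrix:
    """Presence/absence of taxa (rows) across samples (columns)."""

    data: pd.DataFrame  # bool, taxa x samples

    def __post_init__(self):
        self.data = self.data.astype(bool)
        if self.data.shape[1] < 1:
            raise ValueError("need at least one sample")
        empty = self.data.index[~self.data.any(axis=1)]
        if len(empty):
            raise ValueError(f"empty taxon rows: {list(empty)}")

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @property
    def s_obs(self) -> int:
        return self.data.shape[0]


@dataclass
class RichnessEstimate:
    S_o: int
    f_1: int
    f_j: dict[int, int]  # j -> number of samples with exactly j uniques
    S_e: float
    variance: float
    CI_95: float
    n: int


def build_incidence(
    occurrences: pd.DataFrame,
    taxon_col: str = "taxon",
    sample_col: str = "station_id",
) -> IncidenceMatrix:
    """Incidence matrix from a long occurrence table."""
    table = pd.crosstab(occurrences[taxon_col], occurrences[sample_col]) > 0
    return IncidenceMatrix(table)


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction(
    incidence: IncidenceMatrix,
    depths=None,
    mode: str = "analytic",
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected richness at reduced numbers of samples.

    Analytic mode evaluates E[S_k] = sum_i (1 - C(n - n_i, k) / C(n, k));
    resample mode averages richness over random k-subsets of samples and
    reports the Monte-Carlo standard error.
    """
    n = incidence.n
    if depths is None:
        depths = range(1, n + 1)
    depths = list(depths)
    if any(k < 1 or k > n for k in depths):
        raise ValueError(f"depths must lie in [1, {n}]")
    counts = incidence.data.sum(axis=1).to_numpy()  # n_i per taxon
    rows = []
    if mode == "analytic":
        for k in depths:
            # P(taxon i absent from k samples) = C(n - n_i, k) / C(n, k)
            with np.errstate(divide="ignore"):
                mask = (n - counts) >= k
                p_absent = np.zeros(counts.size)
                p_absent[mask] = np.exp(
                    _log_comb(n - counts[mask], k) - _log_comb(n, k)
                )
            rows.append({"depth": k,
                         "expected_richness": float((1 - p_absent).sum()),
                         "se": 0.0})
    elif mode == "resample":
        rng = np.random.default_rng(seed)
        mat = incidence.data.to_numpy()
        for k in depths:
            vals = np.empty(reps)
            for r in range(reps):
                cols = rng.choice(n, size=k, replace=False)
                vals[r] = mat[:, cols].any(axis=1).sum()
            rows.append({"depth": k,
                         "expected_richness": float(vals.mean()),
                         "se": float(vals.std(ddof=1) / np.sqrt(reps))})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def jackknife1(incidence: IncidenceMatrix) -> RichnessEstimate:
    """First-order jackknife estimate of total richness.

    S_e = S_o + f1 (n-1)/n with variance
    ((n-1)/n) * (sum_j j^2 f_j - f1^2 / n) and CI_95 = 1.96 sqrt(var).
    """
    n = incidence.n
    if n < 2:
        raise ValueError("jackknife1 requires at least 2 samples")
    mat = incidence.data.to_numpy()
    counts = mat.sum(axis=1)
    unique_taxa = counts == 1  # taxa found in exactly one sample
    f1 = int(unique_taxa.sum())
    uniques_per_sample = mat[unique_taxa].sum(axis=0)
    f_j = {
        int(j): int((uniques_per_sample == j).sum())
        for j in np.unique(uniques_per_sample) if j > 0
    }
    S_o = incidence.s_obs
    S_e = S_o + f1 * (n - 1) / n
    var = ((n - 1) / n) * (
        sum(j * j * c for j, c in f_j.items()) - f1 * f1 / n
    )
    return RichnessEstimate(
        S_o=S_o, f_1=f1, f_j=f_j, S_e=S_e, variance=var,
        CI_95=1.96 * np.sqrt(var), n=n,
    )


def coverage_test(
    estimate: RichnessEstimate, interval_convention: str = "half_width"
) -> bool:
    """Whether S_o falls inside the 95% interval around S_e.

    ``half_width`` treats the reported CI_95 as a full interval width
    (S_o in S_e +/- CI_95 / 2); ``full_width`` uses S_e +/- CI_95.
    """
    if interval_convention == "half_width":
        half = estimate.CI_95 / 2.0
    elif interval_convention == "full_width":
        half = estimate.CI_95
    else:
        raise ValueError(f"unknown convention {interval_convention!r}")
    return bool(
        (estimate.S_e - half) <= estimate.S_o <= (estimate.S_e + half)
    )
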