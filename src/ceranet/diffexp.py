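"""Differential expression without replicates.

One sequenced sample per condition gives no within-group variance estimate,
so significance is assessed with a conditional exact test on the pair of
counts: both counts are rescaled to the geometric-mean library size, and the
split of the rescaled total between the two libraries is compared with its
null distribution under two equal-mean negative-binomial halves with a fixed,
user-supplied dispersion.  With dispersion 0 the null reduces to
Binomial(total, 1/2).  A feature is called differentially expressed when the
linear fold change of its pseudocounted CPM exceeds the fold-change threshold
AND the exact-test p-value is at or below the p threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT = 0.5  # added to counts before CPM / log-ratio to avoid zeros


class DiffExpError(ValueError):
    pass


@dataclass(frozen=True)
class DEThresholds:
    """Significance thresholds for one contrast.

    fc_threshold is applied on the linear scale, strictly greater-than;
    p_threshold is inclusive.  dispersion is the negative-binomial phi
    (variance = mu + phi * mu^2) assumed by the exact test.
    """

    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    dispersion: float = 0.16

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise DiffExpError("fc_threshold must exceed 1")
        if not (0 < self.p_threshold <= 1):
            raise DiffExpError("p_threshold must be in (0, 1]")
        if self.dispersion < 0:
            raise DiffExpError("dispersion must be >= 0")


@dataclass
class ExpressionMatrix:
    """Integer count table, features x samples, with per-feature biotype."""

    counts: pd.DataFrame
    biotype: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise DiffExpError("duplicate feature ids in count matrix")
        if not self.counts.index.equals(self.biotype.index):
            self.biotype = self.biotype.reindex(self.counts.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()].tolist()[:5]
            raise DiffExpError(f"missing biotype for features {missing}")

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset(self, biotype: str) -> "ExpressionMatrix":
        mask = self.biotype == biotype
        return ExpressionMatrix(self.counts.loc[mask], self.biotype.loc[mask])


@dataclass
class ScaledMatrix:
    """Counts-per-million table plus the raw library sizes it was scaled by."""

    cpm: pd.DataFrame
    library_sizes: pd.Series


@dataclass
class DEProfile:
    """Significant features for one sample-vs-reference contrast.

    ``table`` holds only the features passing both thresholds, with columns
    feature_id (index), biotype, log2fc, p, direction.
    """

    contrast: Tuple[str, str]
    table: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.table)

    def features(self, biotype: str | None = None) -> pd.DataFrame:
        if biotype is None:
            return self.table
        return self.table[self.table["biotype"] == biotype]


def normalize_libsize(matrix: ExpressionMatrix) -> ScaledMatrix:
    """Counts-per-million with a 0.5 pseudocount added before scaling.

    The pseudocount enters both numerator and denominator:
    CPM[f, s] = (count[f, s] + 0.5) / sum_f (count[f, s] + 0.5) * 1e6,
    so each CPM column sums to exactly 1e6.  The raw (un-pseudocounted)
    column sums are preserved as metadata for the exact test.
    """
    if matrix.counts.empty:
        raise DiffExpError("empty count matrix")
    libs = matrix.library_sizes()
    if (libs <= 0).any():
        raise DiffExpError("all library sizes must be positive")
    pseudo = matrix.counts + PSEUDOCOUNT
    cpm = pseudo.div(pseudo.sum(axis=0), axis=1) * 1e6
    return ScaledMatrix(cpm=cpm, library_sizes=libs)


def _split_logpmf(s: int, dispersion: float) -> np.ndarray:
    """Unnormalized log-probability of each split (x, s-x) of total s under
    equal-mean halves: NB(mu=s/2, phi) x NB(mu=s/2, phi), or Binomial(s, 1/2)
    at phi=0 (the Poisson-halves limit)."""
    x = np.arange(s + 1)
    if dispersion == 0:
        return stats.binom.logpmf(x, s, 0.5)
    r = 1.0 / dispersion
    mu = s / 2.0
    p = r / (r + mu)
    return stats.nbinom.logpmf(x, r, p) + stats.nbinom.logpmf(s - x, r, p)


def nb_exact_test(
    count_a: int,
    count_b: int,
    lib_a: float,
    lib_b: float,
    dispersion: float,
) -> float:
    """Two-sided conditional exact p-value for one count per condition.

    Counts are rescaled to the geometric-mean library size and rounded; the
    p-value is the total conditional probability of all splits of the rescaled
    total whose probability does not exceed that of the observed split.

    Returns a probability in (0, 1].
    """
    if count_a < 0 or count_b < 0:
        raise DiffExpError("counts must be non-negative")
    if lib_a <= 0 or lib_b <= 0:
        raise DiffExpError("library sizes must be positive")
    if dispersion < 0:
        raise DiffExpError("dispersion must be >= 0")
    geo = math.sqrt(lib_a * lib_b)
    a = int(round(count_a * geo / lib_a))
    b = int(round(count_b * geo / lib_b))
    s = a + b
    if s == 0:
        return 1.0
    logw = _split_logpmf(s, dispersion)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    obs = w[a]
    p = float(w[w <= obs * (1.0 + 1e-12)].sum())
    return min(max(p, np.finfo(float).tiny), 1.0)


def call_de(
    matrix: ExpressionMatrix,
    sample: str,
    reference: str,
    thresholds: DEThresholds | None = None,
) -> DEProfile:
    """Call DE features for ``sample`` vs ``reference``.

    log2 fold change comes from pseudocounted CPM; the p-value from
    :func:`nb_exact_test` on the raw counts.  A feature is retained iff
    linear |FC| > fc_threshold and p <= p_threshold.
    """
    thresholds = thresholds or DEThresholds()
    for sid in (sample, reference):
        if sid not in matrix.counts.columns:
            raise DiffExpError(f"unknown sample id {sid!r}")
    scaled = normalize_libsize(matrix)
    cpm_s = scaled.cpm[sample]
    cpm_r = scaled.cpm[reference]
    log2fc = np.log2(cpm_s / cpm_r)
    lib_s = float(scaled.library_sizes[sample])
    lib_r = float(scaled.library_sizes[reference])
    pvals = np.array(
        [
            nb_exact_test(int(a), int(b), lib_s, lib_r, thresholds.dispersion)
            for a, b in zip(matrix.counts[sample], matrix.counts[reference])
        ]
    )
    linear_fc = np.maximum(2.0 ** log2fc, 2.0 ** (-log2fc))
    keep = (linear_fc > thresholds.fc_threshold) & (pvals <= thresholds.p_threshold)
    table = pd.DataFrame(
        {
            "biotype": matrix.biotype,
            "log2fc": log2fc,
            "p": pvals,
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=matrix.counts.index,
    ).loc[keep]
    # deterministic output order regardless of input row order
    table = table.sort_index()
    return DEProfile(contrast=(sample, reference), table=table)
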