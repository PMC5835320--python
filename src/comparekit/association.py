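"""Sensitivity partition and cluster-vs-sensitivity chi-square test.

Cell lines are labelled sensitive (log10 IC50 below the threshold) or
resistant (at or above it); the default threshold is the sample median, and
a fixed log10 molar value (the panel-scale -5.45, for instance) can be
passed instead.  The k x 2 cluster-by-label contingency table is tested
with Pearson's chi-square without continuity correction; expected counts
below 5 trigger a warning plus an optional Monte-Carlo permutation p-value
reported alongside (never replacing) the asymptotic one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clustering import ClusterAssignment
from .io_formats import ResponseVector, ValidationError

log = logging.getLogger("comparekit")

SENSITIVE = "sensitive"
RESISTANT = "resistant"


@dataclass
class SensitivityLabels:
    """Cell-line id -> sensitive/resistant, plus the threshold used."""

    labels: dict[str, str]
    threshold: float

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {SENSITIVE, RESISTANT}
        if bad:
            raise ValidationError(f"unknown sensitivity labels {sorted(bad)}")

    def counts(self) -> tuple[int, int]:
        vals = list(self.labels.values())
        return vals.count(SENSITIVE), vals.count(RESISTANT)


@dataclass
class ContingencyTable:
    """k x 2 counts: clusters (rows) by sensitive/resistant (columns)."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValidationError("contingency counts must be 2-D")
        if np.any(self.counts < 0):
            raise ValidationError("negative contingency counts")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("contingency labels do not match counts shape")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    expected_below_5: bool = False
    p_monte_carlo: float | None = None

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0.0 <= self.p <= 1.0:
            raise ValidationError("invalid chi-square result")


def partition_by_threshold(
    resp: ResponseVector, threshold: float | str = "median"
) -> SensitivityLabels:
    """Label lines sensitive (< threshold) or resistant (>= threshold).

    A value exactly at the threshold counts as resistant (documented tie
    rule).  ``threshold='median'`` resolves to the sample median of the
    response.
    """
    if len(resp) == 0:
        raise ValidationError("empty response vector")
    thr = float(np.median(resp.log10_ic50)) if threshold == "median" \
        else float(threshold)
    labels = {
        cid: (SENSITIVE if v < thr else RESISTANT)
        for cid, v in zip(resp.cellline_ids, resp.log10_ic50)
    }
    return SensitivityLabels(labels=labels, threshold=thr)


def build_contingency(
    clusters: ClusterAssignment, labels: SensitivityLabels
) -> ContingencyTable:
    """Count lines per (cluster, sensitivity label)."""
    ids_c, ids_l = set(clusters.labels), set(labels.labels)
    if ids_c != ids_l:
        raise ValidationError(
            "cluster/label id mismatch; symmetric difference: "
            f"{sorted(ids_c ^ ids_l)}"
        )
    counts = np.zeros((clusters.k, 2), dtype=int)
    for cid, cluster in clusters.labels.items():
        col = 0 if labels.labels[cid] == SENSITIVE else 1
        counts[cluster - 1, col] += 1
    return ContingencyTable(
        counts=counts,
        row_labels=[f"Cluster {i}" for i in range(1, clusters.k + 1)],
        col_labels=["Sensitive", "Resistant"],
    )


def chi_square_test(
    table: ContingencyTable,
    n_permutations: int = 0,
    seed: int | None = None,
) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    ``n_permutations > 0`` additionally estimates a Monte-Carlo p-value by
    permuting column labels across observations (useful when expected counts
    fall below 5, which only warns).  Zero row or column marginals are an
    error.
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("need >= 2 rows and >= 2 columns")
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValidationError("zero row/column marginal in contingency table")

    statistic, p, df, expected = stats.chi2_contingency(counts, correction=False)
    below = bool(np.any(expected < 5))
    if below:
        log.warning(
            "%d expected count(s) below 5; asymptotic chi-square p may be "
            "unreliable (consider n_permutations > 0)",
            int(np.sum(expected < 5)),
        )

    p_mc = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        rows = np.repeat(np.arange(counts.shape[0]), counts.sum(axis=1))
        cols = np.repeat(np.arange(counts.shape[1]), counts.sum(axis=0))
        n_extreme = 0
        for _ in range(n_permutations):
            perm = rng.permutation(cols)
            t = np.zeros_like(counts)
            np.add.at(t, (rows, perm), 1)
            s = stats.chi2_contingency(t, correction=False)[0] \
                if t.sum(axis=0).all() and t.sum(axis=1).all() else 0.0
            if s >= statistic - 1e-12:
                n_extreme += 1
        p_mc = (n_extreme + 1) / (n_permutations + 1)

    return ChiSquareResult(
        statistic=float(statistic), df=int(df), p=float(p),
        expected_below_5=below, p_monte_carlo=p_mc,
    )
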