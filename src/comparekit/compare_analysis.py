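"""COMPARE-style correlation ranking of genes against a response profile.

Every gene's expression profile across the cell-line panel is correlated
(Pearson by default, Spearman behind a flag) with the per-line log10 IC50
response.  Genes are returned sorted by the correlation coefficient R:
positively correlated genes (higher expression in resistant lines) head the
standard list; negatively correlated genes (higher expression in sensitive
lines) head the reverse list.  The top k of each side form the signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, ResponseVector, ValidationError

log = logging.getLogger("comparekit")


@dataclass
class Signature:
    """Ordered top-k gene lists: resistance- and sensitivity-associated."""

    positive: list[str]  # r > 0, descending r
    negative: list[str]  # r < 0, ascending r
    k_pos: int
    k_neg: int

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValidationError("signature lists overlap")
        if len(self.positive) > self.k_pos or len(self.negative) > self.k_neg:
            raise ValidationError("signature lists exceed requested k")

    @property
    def genes(self) -> list[str]:
        return [*self.positive, *self.negative]

    def __len__(self) -> int:
        return len(self.positive) + len(self.negative)


def compare_correlate(
    expr: ExpressionMatrix,
    resp: ResponseVector,
    method: str = "pearson",
    fdr: bool = False,
) -> pd.DataFrame:
    """Correlate every gene's expression with the response profile.

    Missing expression values are handled pairwise-complete per gene; genes
    with fewer than 3 complete pairs or zero variance are excluded with a
    logged warning.  Returns a DataFrame with columns ``gene_id``, ``r``,
    ``p`` (two-sided, from the t distribution with n_used - 2 df),
    ``n_used`` and ``rank`` (1..n by descending r, ties broken by gene id);
    ``fdr=True`` appends a Benjamini-Hochberg ``q`` column (an extension —
    the ranking itself uses raw R values only).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    shared = [c for c in expr.cellline_ids if c in set(resp.cellline_ids)]
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared cell lines between expression and "
            "response; need >= 3"
        )
    if len(shared) < len(expr.cellline_ids) or len(shared) < len(resp):
        log.info("using %d shared cell lines", len(shared))

    frame = expr.to_frame()[shared]
    y_full = resp.to_series()[shared].to_numpy()
    X = frame.to_numpy()

    excluded_few, excluded_const = [], []
    rows = []
    for gene_id, x in zip(expr.gene_ids, X):
        mask = ~np.isnan(x)
        n_used = int(mask.sum())
        if n_used < 3:
            excluded_few.append(gene_id)
            continue
        xv, yv = x[mask], y_full[mask]
        if method == "spearman":
            xv = stats.rankdata(xv)
            yv = stats.rankdata(yv)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            excluded_const.append(gene_id)
            continue
        xc = xv - xv.mean()
        yc = yv - yv.mean()
        r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
        r = max(-1.0, min(1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n_used - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n_used - 2))
        rows.append((gene_id, r, p, n_used))

    if excluded_few:
        log.warning(
            "excluded %d gene(s) with < 3 pairwise-complete values: %s",
            len(excluded_few), ", ".join(excluded_few[:10]),
        )
    if excluded_const:
        log.warning(
            "excluded %d zero-variance gene(s): %s",
            len(excluded_const), ", ".join(excluded_const[:10]),
        )
    if not rows:
        raise ValidationError("no gene passed the correlation prerequisites")

    result = pd.DataFrame(rows, columns=["gene_id", "r", "p", "n_used"])
    result = result.sort_values(
        ["r", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    result["rank"] = np.arange(1, len(result) + 1)
    if fdr:
        result["q"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
    return result


def select_signature(
    results: pd.DataFrame, k_pos: int = 20, k_neg: int = 20
) -> Signature:
    """Pick the top positively and negatively correlated genes.

    Standard COMPARE side: top ``k_pos`` genes with r > 0 (descending r).
    Reverse side: top ``k_neg`` genes with r < 0 (ascending r).  Ties at the
    k-th slot go to the lexicographically smaller gene id.  If fewer genes
    qualify on a side, the shorter list is returned with a warning.
    """
    if k_pos <= 0 or k_neg <= 0:
        raise ValidationError("k_pos and k_neg must be positive")
    if results.empty:
        raise ValidationError("empty COMPARE results")

    pos_pool = results[results["r"] > 0].sort_values(
        ["r", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    neg_pool = results[results["r"] < 0].sort_values(
        ["r", "gene_id"], ascending=[True, True], kind="mergesort"
    )
    positive = pos_pool["gene_id"].head(k_pos).tolist()
    negative = neg_pool["gene_id"].head(k_neg).tolist()
    if len(positive) < k_pos:
        log.warning(
            "only %d gene(s) with r > 0 available for k_pos=%d",
            len(positive), k_pos,
        )
    if len(negative) < k_neg:
        log.warning(
            "only %d gene(s) with r < 0 available for k_neg=%d",
            len(negative), k_neg,
        )
    return Signature(positive=positive, negative=negative,
                     k_pos=k_pos, k_neg=k_neg)
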