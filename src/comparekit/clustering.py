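"""Ward hierarchical clustering of the signature matrix and CIM rendering.

Cell lines (or genes) are clustered by agglomerative Ward linkage on
Euclidean distances over per-gene z-scored expression.  Merge heights are
reported as the Ward cost, i.e. the increase in total within-cluster sum of
squared Euclidean distances caused by the merge.  (SciPy's ``ward`` linkage
reports ``h = sqrt(2 * cost)``; the conversion ``cost = h**2 / 2`` is
applied so oracle tests against a direct SSE computation line up.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy

from .compare_analysis import Signature
from .io_formats import ExpressionMatrix, ValidationError

log = logging.getLogger("comparekit")


@dataclass
class Dendrogram:
    """Agglomeration history over ``leaf_ids``.

    ``merges`` has one row per merge: (node_a, node_b, ward_cost, size)
    where node indices < n refer to leaves and >= n to prior merges, as in a
    SciPy linkage matrix.
    """

    merges: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise ValidationError(
                f"expected {n - 1} merges for {n} leaves, got {self.merges.shape}"
            )
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValidationError("merge heights are not non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        """Ward cost (delta within-cluster SSE) of each merge."""
        return self.merges[:, 2]

    def to_scipy_linkage(self) -> np.ndarray:
        """Linkage matrix with SciPy's Euclidean ward heights sqrt(2*cost)."""
        Z = self.merges.copy()
        Z[:, 2] = np.sqrt(2.0 * np.maximum(Z[:, 2], 0.0))
        return Z

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.to_scipy_linkage())
        return [self.leaf_ids[i] for i in order]

    def to_newick(self) -> str:
        """Newick export with branch lengths on the Ward-cost height scale."""
        Z = self.merges
        n = self.n_leaves

        def height(node: int) -> float:
            return 0.0 if node < n else float(Z[node - n, 2])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < n:
                return f"{self.leaf_ids[node]}:{bl:g}"
            a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
            h = height(node)
            return f"({render(a, h)},{render(b, h)}):{bl:g}"

        root = 2 * n - 2
        a, b = int(Z[-1, 0]), int(Z[-1, 1])
        h = height(root)
        return f"({render(a, h)},{render(b, h)});"


@dataclass
class ClusterAssignment:
    """Cell-line id -> cluster label in 1..k, numbered by leaf-order appearance."""

    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        found = set(self.labels.values())
        if found != set(range(1, self.k + 1)):
            raise ValidationError(
                f"labels must be contiguous 1..{self.k}, got {sorted(found)}"
            )

    def members(self, label: int) -> list[str]:
        return [obj for obj, lab in self.labels.items() if lab == label]


def standardize_signature_matrix(
    expr: ExpressionMatrix, sig: Signature
) -> ExpressionMatrix:
    """Subset to the signature genes and z-score each gene row.

    Rows are centred and scaled to unit variance (population sd); a
    zero-variance row becomes all zeros with a warning.  Missing values are
    z-scored against the observed cells and then imputed at 0 (the row mean)
    so Euclidean distances downstream are defined.
    """
    missing = [g for g in sig.genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValidationError(f"signature genes absent from matrix: {missing}")
    frame = expr.to_frame().loc[sig.genes]
    values = frame.to_numpy()

    out = np.empty_like(values)
    for i, gene in enumerate(frame.index):
        row = values[i]
        mask = ~np.isnan(row)
        mu = row[mask].mean()
        sd = row[mask].std(ddof=0)
        if sd == 0:
            log.warning("zero-variance signature gene %s: z-scores set to 0", gene)
            out[i] = 0.0
            continue
        out[i] = np.where(mask, (row - mu) / sd, 0.0)
        if not mask.all():
            log.warning(
                "gene %s: %d missing value(s) imputed at the row mean",
                gene, int((~mask).sum()),
            )
    return ExpressionMatrix(
        gene_ids=list(frame.index),
        cellline_ids=expr.cellline_ids,
        values=out,
    )


def ward_cluster(matrix: ExpressionMatrix, axis: str = "lines") -> Dendrogram:
    """Ward linkage on Euclidean distances over the chosen axis.

    ``axis='lines'`` clusters cell lines (columns as observations, genes as
    features); ``axis='genes'`` clusters genes.  Deterministic given input
    order; SciPy's nearest-neighbour chain resolves exact merge-cost ties by
    the smaller object index.
    """
    if axis not in ("lines", "genes"):
        raise ValueError(f"axis must be 'lines' or 'genes', got {axis!r}")
    if axis == "lines":
        data = matrix.values.T
        ids = list(matrix.cellline_ids)
    else:
        data = matrix.values
        ids = list(matrix.gene_ids)
    if len(ids) < 2:
        raise ValidationError(f"need >= 2 objects on axis {axis!r}")
    if np.isnan(data).any():
        raise ValidationError("matrix contains missing values; standardize first")
    Z = hierarchy.linkage(data, method="ward")
    merges = Z.copy()
    merges[:, 2] = Z[:, 2] ** 2 / 2.0  # Euclidean ward height -> Ward cost
    return Dendrogram(merges=merges, leaf_ids=ids)


def cut_tree(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into exactly k clusters.

    Cluster labels 1..k are assigned by first appearance in the dendrogram's
    leaf order (so cluster 1 is the leftmost cluster of the display).
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range 1..{n}")
    Z = dend.to_scipy_linkage()
    raw = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    order = hierarchy.leaves_list(Z)
    relabel: dict[int, int] = {}
    for leaf in order:
        if raw[leaf] not in relabel:
            relabel[raw[leaf]] = len(relabel) + 1
    labels = {dend.leaf_ids[i]: relabel[raw[i]] for i in range(n)}
    return ClusterAssignment(labels=labels, k=k)


def render_cim(
    matrix: ExpressionMatrix,
    row_dend: Dendrogram,
    col_dend: Dendrogram,
    annotations: dict[str, str] | None = None,
    path: str | Path = "cim.svg",
    cmap: str = "RdBu_r",
):
    """Render a clustered image map: heat map plus both dendrograms.

    ``row_dend`` must be over the matrix's genes and ``col_dend`` over its
    cell lines; ``annotations`` (cell line -> category, e.g.
    sensitive/resistant) draws a colour bar under the columns.  SVG output
    is byte-stable across re-renders (fixed hash salt, no timestamps).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    if set(row_dend.leaf_ids) != set(matrix.gene_ids):
        raise ValidationError("row dendrogram does not match matrix genes")
    if set(col_dend.leaf_ids) != set(matrix.cellline_ids):
        raise ValidationError("column dendrogram does not match matrix lines")

    row_order = row_dend.leaf_order()
    col_order = col_dend.leaf_order()
    frame = matrix.to_frame().loc[row_order, col_order]

    with matplotlib.rc_context({"svg.hashsalt": "comparekit"}):
        fig = plt.figure(figsize=(10, 8))
        gs = fig.add_gridspec(
            2, 2, width_ratios=[1, 5], height_ratios=[1, 5],
            wspace=0.02, hspace=0.02,
        )
        ax_col = fig.add_subplot(gs[0, 1])
        ax_row = fig.add_subplot(gs[1, 0])
        ax_heat = fig.add_subplot(gs[1, 1])

        hierarchy.dendrogram(
            col_dend.to_scipy_linkage(), ax=ax_col, no_labels=True,
            color_threshold=0, above_threshold_color="k",
        )
        hierarchy.dendrogram(
            row_dend.to_scipy_linkage(), ax=ax_row, no_labels=True,
            orientation="left", color_threshold=0, above_threshold_color="k",
        )
        ax_col.axis("off")
        ax_row.axis("off")
        ax_row.invert_yaxis()  # match imshow row direction

        vmax = np.nanmax(np.abs(frame.to_numpy())) or 1.0
        ax_heat.imshow(
            frame.to_numpy(), aspect="auto", cmap=cmap,
            vmin=-vmax, vmax=vmax, interpolation="nearest",
        )
        ax_heat.set_yticks([])
        ax_heat.set_xticks(range(len(col_order)))
        ax_heat.set_xticklabels(col_order, rotation=90, fontsize=4)

        if annotations:
            categories = sorted(set(annotations.values()))
            palette = {c: plt.get_cmap("Set1")(i) for i, c in enumerate(categories)}
            for j, line in enumerate(col_order):
                cat = annotations.get(line)
                if cat is not None:
                    ax_heat.add_patch(plt.Rectangle(
                        (j - 0.5, -0.5), 1, 0.5, clip_on=False,
                        transform=ax_heat.transData, color=palette[cat],
                    ))
            fig.legend(
                handles=[Patch(color=palette[c], label=c) for c in categories],
                loc="upper left", fontsize=6,
            )

        path = Path(path)
        fig.savefig(
            path, format=path.suffix.lstrip("."),
            metadata={"Date": None} if path.suffix == ".svg" else None,
        )
        plt.close(fig)
    return path
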