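"""Functional-group classification, gene-set over-representation and
curated network assembly.

An open substitute for closed commercial pathway suites: enrichment runs
against user-supplied GMT collections with Fisher's right-tailed exact
test and the conventional -log10 p cutoff of 1.3 (p = 0.05); the packaged
functional-group table assigns known determinants of arsenic-trioxide
responsiveness (oxidative stress response, drug transport, DNA repair,
cell cycle/proliferation, tumor suppressors/oncogenes, signal
transduction, metabolic pathways, cytoskeleton, apoptosis) to one primary
group each; curated interaction edges (direct/indirect, with provenance)
assemble into a networkx graph exportable as edge-list TSV and GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import FormatError, GeneSetCollection, ValidationError

log = logging.getLogger("comparekit")

DEFAULT_CUTOFF_NEG_LOG10_P = 1.3
UNCLASSIFIED = "unclassified"

FUNCTIONAL_GROUPS = (
    "oxidative stress response",
    "drug transport",
    "DNA repair",
    "cell cycle/proliferation",
    "tumor suppressors/oncogenes",
    "signal transduction",
    "metabolic pathways",
    "cytoskeleton",
    "apoptosis",
)


@dataclass
class FunctionalGroupTable:
    """Curated gene/protein -> primary functional group mapping."""

    entries: pd.DataFrame  # columns: symbol, group, aliases, provenance

    def __post_init__(self) -> None:
        needed = {"symbol", "group", "aliases", "provenance"}
        if not needed <= set(self.entries.columns):
            raise ValidationError(f"functional group table needs {sorted(needed)}")
        if self.entries["symbol"].duplicated().any():
            raise ValidationError("duplicate symbols in functional group table")
        self._index: dict[str, str] = {}
        for _, row in self.entries.iterrows():
            keys = [str(row["symbol"])]
            if pd.notna(row["aliases"]) and str(row["aliases"]):
                keys += str(row["aliases"]).split(",")
            for key in keys:
                self._index.setdefault(key.strip().upper(), str(row["group"]))

    def lookup(self, gene: str) -> str:
        return self._index.get(gene.strip().upper(), UNCLASSIFIED)

    @property
    def symbols(self) -> list[str]:
        return self.entries["symbol"].astype(str).tolist()

    def __len__(self) -> int:
        return len(self.entries)


def load_functional_groups(path: str | Path | None = None) -> FunctionalGroupTable:
    """Load the packaged curated table (or a user table of the same shape)."""
    if path is None:
        source = resources.files("comparekit") / "data" / "functional_groups.tsv"
        with resources.as_file(source) as p:
            entries = pd.read_csv(p, sep="\t", keep_default_na=False)
    else:
        entries = pd.read_csv(path, sep="\t", keep_default_na=False)
    return FunctionalGroupTable(entries=entries)


def classify_functional_groups(
    genes: Iterable[str], table: FunctionalGroupTable | None = None
) -> dict[str, str]:
    """Map each query gene to its primary functional group.

    Matching is case-insensitive over symbols and aliases; genes not in the
    table map to ``"unclassified"``.
    """
    if table is None:
        table = load_functional_groups()
    return {g: table.lookup(g) for g in genes}


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    neg_log10_p: float
    passes_cutoff: bool
    q: float  # Benjamini-Hochberg FDR, reported alongside raw p

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.query_size):
            raise ValidationError("overlap exceeds set/query size")


def ora_fisher(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    cutoff_neg_log10_p: float = DEFAULT_CUTOFF_NEG_LOG10_P,
) -> list[EnrichmentResult]:
    """Fisher right-tailed over-representation of the query in each gene set.

    Each set is intersected with the universe before testing; the 2x2 table
    is (in set / out of set) x (in query / out of query) and the p-value is
    the hypergeometric right tail P(overlap >= observed).  Results are
    sorted by p ascending; ``passes_cutoff`` applies the -log10 p threshold
    (>= comparison, so exactly 1.3 passes) to the raw p; a BH-FDR ``q`` is
    reported alongside.
    """
    universe_set = {str(g) for g in universe}
    query_set = {str(g) for g in query}
    if not universe_set or not query_set:
        raise ValidationError("universe and query must be non-empty")
    outside = query_set - universe_set
    if outside:
        raise ValidationError(
            f"query gene(s) outside the universe: {sorted(outside)[:10]}"
        )
    M, n = len(universe_set), len(query_set)

    rows = []
    for name in sets.names():
        members = {str(g) for g in sets.members(name)} & universe_set
        K = len(members)
        k = len(members & query_set)
        # right tail: P(X >= k) for X ~ Hypergeom(M, K, n)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, k, K, p))

    pvals = [r[3] for r in rows]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            set_name=name, overlap=k, set_size=K, query_size=n,
            universe_size=M, p=p, neg_log10_p=float(-np.log10(p)) if p > 0 else np.inf,
            passes_cutoff=bool((-np.log10(p) if p > 0 else np.inf)
                               >= cutoff_neg_log10_p),
            q=float(q),
        )
        for (name, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "neg_log10_p": [r.neg_log10_p for r in results],
            "passes_cutoff": [r.passes_cutoff for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Curated network assembly
# ---------------------------------------------------------------------------

EDGE_TYPES = ("direct", "indirect")


def read_edge_table(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Read a curated edge TSV: a, b, interaction type, provenance."""
    edges = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["a", "b"]:
                continue
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 4 fields "
                    f"(a, b, type, provenance), got {len(fields)}"
                )
            a, b, etype, prov = fields[:4]
            if etype not in EDGE_TYPES:
                raise FormatError(
                    f"{path}: line {lineno}: interaction type must be one of "
                    f"{EDGE_TYPES}, got {etype!r}"
                )
            edges.append((a, b, etype, prov))
    return edges


def assemble_network(
    genes: Sequence[str],
    groups: FunctionalGroupTable | None = None,
    edges: str | Path | Sequence[tuple[str, str, str, str]] = (),
) -> nx.Graph:
    """Build a group-labelled interaction network over a gene list.

    Nodes carry a ``group`` attribute from the functional-group table;
    edges carry ``interaction`` (direct/indirect) and ``provenance``.
    Edges touching genes outside the list, and self-loops, are dropped
    with a warning.
    """
    if isinstance(edges, (str, Path)):
        edges = read_edge_table(edges)
    grouping = classify_functional_groups(genes, groups)

    net = nx.Graph()
    for gene in genes:
        net.add_node(gene, group=grouping[gene])
    known = set(genes)
    for a, b, etype, prov in edges:
        if a == b:
            log.warning("dropping self-loop edge on %s", a)
            continue
        if a not in known or b not in known:
            log.warning("dropping edge (%s, %s): endpoint(s) not in gene list", a, b)
            continue
        net.add_edge(a, b, interaction=etype, provenance=prov)
    return net


def write_network(
    net: nx.Graph,
    edge_tsv: str | Path | None = None,
    graphml: str | Path | None = None,
) -> None:
    """Export the network as edge-list TSV and/or GraphML XML."""
    if edge_tsv is not None:
        with open(edge_tsv, "w") as handle:
            handle.write("a\tb\ttype\tprovenance\n")
            for a, b, data in net.edges(data=True):
                handle.write(
                    f"{a}\t{b}\t{data.get('interaction', 'direct')}\t"
                    f"{data.get('provenance', '')}\n"
                )
    if graphml is not None:
        nx.write_graphml(net, graphml)
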