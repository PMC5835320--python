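"""End-to-end orchestration: compare -> signature -> cluster -> associate ->
(optional) motif enrichment -> (optional) ORA / curated network.

Every run writes per-stage outputs, the resolved configuration and a JSON
manifest (stage status, output checksums, key metrics, seed, version) into
the output directory; re-running with the same inputs and seed reproduces
the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .association import (
    build_contingency, chi_square_test, partition_by_threshold,
)
from .clustering import (
    cut_tree, render_cim, standardize_signature_matrix, ward_cluster,
)
from .compare_analysis import compare_correlate, select_signature
from .io_formats import (
    parse_jaspar, read_expression_matrix, read_gmt, read_response,
)
from .motif_enrichment import enrich_motifs, enrichment_table, extract_promoters
from .pathway_network import (
    assemble_network, enrichment_frame, load_functional_groups, ora_fisher,
    write_network,
)

log = logging.getLogger("comparekit")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs and parameters of a full run; defaults follow the reference
    analysis where it states a choice (20+20 signature, 4 clusters, 50 kb
    promoter window, -log10 p cutoff 1.3)."""

    expr_path: str
    response_path: str
    out_dir: str
    k_pos: int = 20
    k_neg: int = 20
    cluster_k: int = 4
    threshold: float | str = "median"
    annotation_path: str | None = None
    genome_path: str | None = None
    pwm_path: str | None = None
    motif_window: int = 50_000
    n_shuffles: int = 100
    gmt_path: str | None = None
    edge_path: str | None = None
    ora_cutoff: float = 1.3
    correlation_method: str = "pearson"
    seed: int = 0
    render_heatmap: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class _Stage:
    name: str
    status: str = "ok"
    outputs: dict[str, str] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    required = {"expression": config.expr_path, "response": config.response_path}
    optional = {
        "annotation": config.annotation_path, "genome": config.genome_path,
        "pwms": config.pwm_path, "gene sets": config.gmt_path,
        "edges": config.edge_path,
    }
    missing = [
        f"{label} ({p})" for label, p in required.items() if not Path(p).exists()
    ] + [
        f"{label} ({p})" for label, p in optional.items()
        if p is not None and not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(
            "missing input path(s) before any computation: " + "; ".join(missing)
        )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[_Stage] = []

    def record(stage: _Stage, *paths: Path) -> None:
        for p in paths:
            stage.outputs[p.name] = _sha256(p)
        stages.append(stage)

    def run_stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # --- compare ---------------------------------------------------------
    def _compare():
        expr = read_expression_matrix(config.expr_path)
        resp = read_response(config.response_path)
        results = compare_correlate(
            expr, resp, method=config.correlation_method, fdr=True
        )
        path = out / "compare_results.tsv"
        results.to_csv(path, sep="\t", index=False)
        st = _Stage("compare", metrics={
            "n_genes": len(results), "n_lines": int(results["n_used"].max()),
        })
        record(st, path)
        return expr, resp, results

    expr, resp, results = run_stage("compare", _compare)

    # --- signature -------------------------------------------------------
    def _signature():
        sig = select_signature(results, config.k_pos, config.k_neg)
        path = out / "signature.tsv"
        with open(path, "w") as handle:
            handle.write("gene_id\tside\n")
            for g in sig.positive:
                handle.write(f"{g}\tpositive\n")
            for g in sig.negative:
                handle.write(f"{g}\tnegative\n")
        st = _Stage("signature", metrics={"size": len(sig)})
        record(st, path)
        return sig

    sig = run_stage("signature", _signature)

    # --- cluster ---------------------------------------------------------
    def _cluster():
        standardized = standardize_signature_matrix(expr, sig)
        line_dend = ward_cluster(standardized, axis="lines")
        gene_dend = ward_cluster(standardized, axis="genes")
        assignment = cut_tree(line_dend, config.cluster_k)
        cpath = out / "clusters.tsv"
        with open(cpath, "w") as handle:
            handle.write("cellline\tcluster\n")
            for cid in standardized.cellline_ids:
                handle.write(f"{cid}\t{assignment.labels[cid]}\n")
        npath = out / "dendrogram_lines.nwk"
        npath.write_text(line_dend.to_newick() + "\n")
        outputs = [cpath, npath]
        labels = partition_by_threshold(resp, config.threshold)
        if config.render_heatmap:
            hpath = out / "cim.svg"
            render_cim(standardized, gene_dend, line_dend,
                       annotations=labels.labels, path=hpath)
            outputs.append(hpath)
        st = _Stage("cluster", metrics={"k": config.cluster_k})
        record(st, *outputs)
        return assignment, labels

    assignment, labels = run_stage("cluster", _cluster)

    # --- associate -------------------------------------------------------
    def _associate():
        table = build_contingency(assignment, labels)
        result = chi_square_test(table)
        tpath = out / "contingency.tsv"
        with open(tpath, "w") as handle:
            handle.write("cluster\t" + "\t".join(table.col_labels) + "\n")
            for lab, row in zip(table.row_labels, table.counts):
                handle.write(lab + "\t" + "\t".join(map(str, row)) + "\n")
        jpath = out / "association.json"
        jpath.write_text(json.dumps({
            "statistic": result.statistic, "df": result.df, "p": result.p,
            "expected_below_5": result.expected_below_5,
            "threshold_log10_molar": labels.threshold,
            "threshold_rule": "value < threshold -> sensitive; ties resistant",
        }, indent=2) + "\n")
        st = _Stage("associate", metrics={"p": result.p,
                                          "statistic": result.statistic})
        record(st, tpath, jpath)
        return result

    association_result = run_stage("associate", _associate)

    # --- motifs (optional) ----------------------------------------------
    motif_inputs = (config.annotation_path, config.genome_path, config.pwm_path)
    if all(p is not None for p in motif_inputs):
        def _motifs():
            proms = extract_promoters(
                sig.genes, config.annotation_path, config.genome_path,
                window_bp=config.motif_window,
                bed_out=out / "promoters.bed",
            )
            pwms = parse_jaspar(config.pwm_path)
            results_m = enrich_motifs(
                proms, pwms, n_shuffles=config.n_shuffles, seed=config.seed
            )
            mpath = out / "motifs.tsv"
            enrichment_table(results_m).to_csv(mpath, sep="\t", index=False)
            st = _Stage("motifs", metrics={
                "n_promoters": len(proms), "n_motifs": len(pwms),
                "top_motif": results_m[0].motif_id,
            })
            record(st, mpath, out / "promoters.bed")

        run_stage("motifs", _motifs)
    else:
        stages.append(_Stage("motifs", status="skipped"))
        log.info("motif stage skipped (annotation/genome/PWM inputs not given)")

    # --- enrichment / network (optional) ---------------------------------
    if config.gmt_path is not None:
        def _enrich():
            sets = read_gmt(config.gmt_path)
            ora = ora_fisher(
                sig.genes, sets, universe=expr.gene_ids,
                cutoff_neg_log10_p=config.ora_cutoff,
            )
            epath = out / "ora.tsv"
            enrichment_frame(ora).to_csv(epath, sep="\t", index=False)
            outputs = [epath]
            groups = load_functional_groups()
            net = assemble_network(
                sig.genes, groups,
                edges=config.edge_path if config.edge_path else (),
            )
            gpath = out / "network.graphml"
            tpath2 = out / "network_edges.tsv"
            write_network(net, edge_tsv=tpath2, graphml=gpath)
            outputs += [gpath, tpath2]
            st = _Stage("enrich", metrics={
                "n_sets": len(sets),
                "n_passing": int(sum(r.passes_cutoff for r in ora)),
            })
            record(st, *outputs)

        run_stage("enrich", _enrich)
    else:
        stages.append(_Stage("enrich", status="skipped"))
        log.info("enrichment stage skipped (no gene-set collection given)")

    # --- manifest --------------------------------------------------------
    resolved = out / "config.yaml"
    with open(resolved, "w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "association_p": association_result.p,
        "stages": [dataclasses.asdict(s) for s in stages],
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
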