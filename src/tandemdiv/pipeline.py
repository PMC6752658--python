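"""End-to-end orchestration: detect → classify → divergence → summary.

The run is driven by one declarative YAML config naming the input files
and every analysis threshold (all published constants live in
``AnalysisConfig`` and can be overridden there, so thresholds are data,
not code). Outputs are deterministic: re-running an identical config over
identical inputs reproduces byte-identical TSV/JSON files.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import (
    assign_gene_types,
    classify_tandem_genes,
    find_focal_clusters,
    nearest_outgroup_orthologs,
    outgroup_tandem_evidence,
    summarize_labels,
    write_labels_tsv,
)
from .exprdiv import (
    call_expression,
    ddct_fold_change,
    pair_correlation,
    summarize_class_statistics,
)
from .io import (
    AnalysisConfig,
    ParseError,
    parse_expression_table,
    parse_gene_tree,
    parse_gff_genes,
    read_fasta,
    read_qpcr_table,
    read_species_map,
)
from .seqdiv import backtranslate_alignment, ng86_ka_ks, write_divergence_tsv
from .structdiv import pair_structure_summary, read_motif_table
from .tandem import detect_tandem_repeats, write_repeats_tsv

log = logging.getLogger("tandemdiv")

REQUIRED_INPUTS = ("focal_gff", "family_ids", "tree", "species_map")
OPTIONAL_INPUTS = ("expression", "motifs", "outgroup_gff", "cds", "proteins", "qpcr")


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    version: str
    rng_seed: int
    config: dict
    input_checksums: dict[str, str]
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, status: str, **info) -> None:
        self.stages.append({"name": name, "status": status, **info})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None) -> RunManifest:
    """Execute all stages named by the config; see module docstring.

    Raises :class:`ParseError` before any stage runs when a required input
    is missing; a stage failure is recorded in the manifest and re-raised.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text()) or {}
    inputs = cfg.get("inputs", {})
    missing = [k for k in REQUIRED_INPUTS if k not in inputs]
    absent = [
        k for k, v in inputs.items() if not Path(v).exists()
    ]
    problems = [f"missing config key inputs.{k}" for k in missing] + [
        f"input file not found: {inputs[k]}" for k in absent
    ]
    if problems:
        raise ParseError("; ".join(problems))

    analysis = AnalysisConfig(**cfg.get("analysis", {}))
    out = Path(outdir or cfg.get("output_dir", "tandemdiv_out"))
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        version=__version__,
        rng_seed=analysis.rng_seed,
        config=cfg,
        input_checksums={k: _sha256(Path(v)) for k, v in sorted(inputs.items())},
    )

    family_ids = {
        line.strip()
        for line in Path(inputs["family_ids"]).read_text().splitlines()
        if line.strip()
    }

    # --- detect ------------------------------------------------------------
    genes = parse_gff_genes(inputs["focal_gff"], family_ids)
    repeats = detect_tandem_repeats(genes, analysis)
    write_repeats_tsv(repeats, out / "repeats.tsv")
    n_family = sum(g.is_family_member for g in genes)
    log.info("detect: %d genes in (%d family), %d repeats out",
             len(genes), n_family, len(repeats))
    manifest.record(
        "detect", "ok", n_genes=len(genes), n_family=n_family,
        n_repeats=len(repeats), output=str(out / "repeats.tsv"),
    )

    # --- classify ----------------------------------------------------------
    tree = parse_gene_tree(inputs["tree"], read_species_map(inputs["species_map"]))
    clusters = find_focal_clusters(tree)
    types = assign_gene_types(tree, clusters)
    evidence = {}
    if "outgroup_gff" in inputs:
        out_genes = parse_gff_genes(inputs["outgroup_gff"], set(tree.outgroup_tips()))
        ortho = nearest_outgroup_orthologs(tree)
        for rep in repeats:
            for g1, g2 in itertools.combinations(rep.members, 2):
                evidence[(g1, g2)] = outgroup_tandem_evidence(
                    (g1, g2), ortho, out_genes, analysis
                )
    labels = classify_tandem_genes(repeats, clusters, types, evidence)
    write_labels_tsv(labels, out / "labels.tsv")
    label_summary = summarize_labels(labels)
    log.info("classify: %d clusters, labels %s", len(clusters), label_summary)
    manifest.record(
        "classify", "ok", n_clusters=len(clusters), **label_summary,
        output=str(out / "labels.tsv"),
    )

    # pair universe: all within-repeat pairs, classed by shared cluster
    cluster_of = {}
    for c in clusters:
        for g in c.members:
            cluster_of[g] = c.members
    pairs: list[tuple[str, str]] = []
    pair_classes: dict[tuple[str, str], str] = {}
    for rep in repeats:
        for g1, g2 in itertools.combinations(rep.members, 2):
            pairs.append((g1, g2))
            same = cluster_of.get(g1) is not None and cluster_of.get(g1) == cluster_of.get(g2)
            pair_classes[(g1, g2)] = "lineage_specific" if same else "ancestral"

    report: dict = {
        "labels": label_summary,
        "n_clusters": len(clusters),
        "n_repeats": len(repeats),
        "repeat_sizes": [len(r) for r in repeats],
        "pair_classes": {f"{a}|{b}": c for (a, b), c in sorted(pair_classes.items())},
    }

    # --- sequence divergence ----------------------------------------------
    if "cds" in inputs:
        try:
            cds = read_fasta(inputs["cds"])
            proteins = (
                read_fasta(inputs["proteins"]) if "proteins" in inputs else None
            )
            results = []
            for g1, g2 in pairs:
                if g1 not in cds or g2 not in cds:
                    log.warning("seqdiv: missing CDS for pair (%s,%s)", g1, g2)
                    continue
                if proteins is not None and len(proteins[g1]) == len(proteins[g2]):
                    aln = backtranslate_alignment(
                        {g1: proteins[g1], g2: proteins[g2]}, cds
                    )
                    row1, row2 = aln.rows
                elif len(cds[g1]) == len(cds[g2]):
                    row1, row2 = cds[g1], cds[g2]
                else:
                    log.warning(
                        "seqdiv: unalignable pair (%s,%s) of unequal length", g1, g2
                    )
                    continue
                results.append(ng86_ka_ks(row1, row2, g1, g2))
            write_divergence_tsv(results, out / "divergence.tsv")
            by_class: dict[str, dict[str, list[float]]] = {}
            for r in results:
                cls = pair_classes[(r.gene1, r.gene2)]
                d = by_class.setdefault(cls, {"pi": [], "ka": [], "ks": [], "ka_ks": []})
                for key, v in (("pi", r.pi), ("ka", r.ka), ("ks", r.ks), ("ka_ks", r.ka_ks)):
                    if v is not None:
                        d[key].append(v)
            report["divergence_by_class"] = {
                cls: {k: (sum(v) / len(v) if v else None) for k, v in d.items()}
                for cls, d in by_class.items()
            }
            manifest.record(
                "seqdiv", "ok", n_pairs=len(results),
                output=str(out / "divergence.tsv"),
            )
        except Exception as exc:
            manifest.record("seqdiv", "failed", error=str(exc))
            raise

    # --- structural divergence ----------------------------------------------
    by_id = {g.gene_id: g for g in genes}
    archs = read_motif_table(inputs["motifs"]) if "motifs" in inputs else None
    struct_pairs = [
        (by_id[g1], by_id[g2]) for g1, g2 in pairs if g1 in by_id and g2 in by_id
    ]
    struct_by_class = {}
    for cls in ("lineage_specific", "ancestral"):
        sel = [
            (by_id[g1], by_id[g2])
            for g1, g2 in pairs
            if pair_classes[(g1, g2)] == cls and g1 in by_id and g2 in by_id
        ]
        struct_by_class[cls] = pair_structure_summary(sel, archs)
    report["structure"] = {
        "all_pairs": pair_structure_summary(struct_pairs, archs),
        "by_class": struct_by_class,
    }
    manifest.record("structdiv", "ok", n_pairs=len(struct_pairs))

    # --- expression divergence ----------------------------------------------
    if "expression" in inputs:
        matrix = parse_expression_table(inputs["expression"])
        calls = call_expression(matrix, analysis)
        pair_results = [
            pair_correlation(matrix, g1, g2, analysis)
            for g1, g2 in pairs
            if g1 in matrix.values.index and g2 in matrix.values.index
        ]
        with open(out / "expression_pairs.tsv", "w") as fh:
            fh.write("gene1\tgene2\tn_shared_stages\tr\tcorrelated\n")
            for p in pair_results:
                r = "NA" if p.r is None else f"{p.r:.4f}"
                fh.write(
                    f"{p.gene1}\t{p.gene2}\t{p.n_shared_stages}\t{r}\t{p.correlated}\n"
                )
        report["expression"] = summarize_class_statistics(
            labels, calls, pair_results, pair_classes
        )
        manifest.record(
            "exprdiv", "ok", n_pairs=len(pair_results),
            output=str(out / "expression_pairs.tsv"),
        )

    if "qpcr" in inputs:
        records = read_qpcr_table(inputs["qpcr"])
        control = cfg.get("control_condition")
        if control is None:
            raise ParseError("qpcr input given but no control_condition in config")
        ddct = ddct_fold_change(records, control)
        with open(out / "qpcr_fold_changes.tsv", "w") as fh:
            fh.write(
                "gene_id\tcondition\ttimepoint\tn_replicates\tddct\tfold_change\tp_value\n"
            )
            for r in ddct:
                p = "NA" if r.p_value is None else f"{r.p_value:.4g}"
                fh.write(
                    f"{r.gene_id}\t{r.condition}\t{r.timepoint}\t{r.n_replicates}\t"
                    f"{r.ddct:.4f}\t{r.fold_change:.4f}\t{p}\n"
                )
        manifest.record("qpcr", "ok", n_results=len(ddct))

    # --- consolidated report -------------------------------------------------
    (out / "summary.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "summary.txt").write_text(render_summary(report))
    (out / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=1, sort_keys=True)
    )
    manifest.record("summarize", "ok", output=str(out / "summary.json"))
    return manifest


def _pct(n: int | None, d: int | None) -> str:
    from .exprdiv import format_percent

    if n is None or d is None:
        return "NA"
    return format_percent(n, d)


def render_summary(report: dict) -> str:
    """Human-readable tables over the consolidated report dict."""
    lines = ["tandemdiv summary", "================="]
    lab = report.get("labels", {})
    if lab:
        n = lab.get("n_genes", 0)
        lines += [
            f"focal family genes: {n}",
            f"  type I (clustered): {lab.get('n_type_I')}"
            f"  type II: {lab.get('n_type_II')}",
            f"  tandem: {lab.get('n_tandem')} ({_pct(lab.get('n_tandem'), n)})",
            f"  lineage-specific tandem: {lab.get('n_lineage_specific')}"
            f" ({_pct(lab.get('n_lineage_specific'), n)})",
            f"  ancestral tandem: {lab.get('n_ancestral')}"
            f" ({_pct(lab.get('n_ancestral'), n)})",
            f"  in both classes: {lab.get('n_both')}",
            f"repeats: {report.get('n_repeats')} "
            f"(sizes {report.get('repeat_sizes')})",
            f"clusters: {report.get('n_clusters')}",
        ]
    div = report.get("divergence_by_class")
    if div:
        lines.append("mean divergence by pair class:")
        for cls, d in sorted(div.items()):
            vals = ", ".join(
                f"{k}={d[k]:.4f}" if d[k] is not None else f"{k}=NA"
                for k in ("pi", "ka", "ks", "ka_ks")
            )
            lines.append(f"  {cls}: {vals}")
    struct = report.get("structure", {}).get("by_class")
    if struct:
        lines.append("structure divergence by pair class:")
        for cls, d in sorted(struct.items()):
            mid = d.get("mean_intron_difference")
            mmd = d.get("mean_motif_difference")
            lines.append(
                f"  {cls}: pairs={d['n_pairs']}"
                f" mean_intron_diff={'NA' if mid is None else f'{mid:.2f}'}"
                f" mean_motif_diff={'NA' if mmd is None else f'{mmd:.2f}'}"
            )
    expr = report.get("expression")
    if expr:
        tc, other = expr["tandem_or_clustered"], expr["other_genes"]
        lines += [
            "expression:",
            f"  low expression among tandem/clustered: "
            f"{tc['n_low']}/{tc['n']} ({_pct(tc['n_low'], tc['n'])})",
            f"  low expression among others: "
            f"{other['n_low']}/{other['n']} ({_pct(other['n_low'], other['n'])})",
            f"  fold ratio: {expr.get('low_expression_fold_ratio')}",
        ]
        if "pairs" in expr:
            p = expr["pairs"]
            lines.append(
                f"  correlated tandem pairs: {p['n_correlated']}/{p['n_pairs']}"
                f" ({_pct(p['n_correlated'], p['n_pairs'])})"
            )
    return "\n".join(lines) + "\n"
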