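"""Ancestral vs lineage-specific classification of tandem duplicates.

Family genes of the focal species fall into two types read off the
two-species gene tree: type I genes sit inside a focal-species-only clade
with at least one other focal gene (a lineage-specific expansion cluster),
type II genes do not. A tandem gene is then

* lineage_specific when at least one of its tandem-repeat partners belongs
  to its own focal cluster (the pair arose by duplication after the split),
* ancestral when it is a type II gene inside a repeat, or when it is
  arrayed in tandem with a gene outside its cluster (the array predates the
  split),
* both when the two conditions hold simultaneously.

Trees are used as topologies only; support values are carried along but not
filtered on. Orthologs of a focal gene are the outgroup tips of the
smallest clade above it that contains any outgroup tip; tandem arrangement
of those orthologs in the outgroup genome is corroborating evidence for an
ancestral call, not a requirement (observed non-tandem orthologs can simply
reflect outgroup genome rearrangement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import FOCAL, AnalysisConfig, GeneRecord, GeneTree
from .tandem import TandemRepeat, is_tandem_pair

log = logging.getLogger("tandemdiv")

LINEAGE_SPECIFIC = "lineage_specific"
ANCESTRAL = "ancestral"
BOTH = "both"
NONE = "none"


@dataclass(frozen=True)
class FocalCluster:
    """A maximal focal-only clade with >= 2 focal tips."""

    members: frozenset[str]
    support: float | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DuplicateLabel:
    gene_id: str
    gene_type: str  # "I" or "II"
    tandem_class: str  # lineage_specific | ancestral | both | none
    evidence: list[str] = field(default_factory=list)


def find_focal_clusters(tree: GeneTree) -> list[FocalCluster]:
    """Return every maximal focal-only clade holding >= 2 focal tips.

    Maximality means the parent clade contains at least one outgroup tip
    (or the clade is the root). A polytomy mixing focal and outgroup tips is
    not a cluster, but its all-focal child clades can be.
    """
    focal = set(tree.focal_tips())
    if not focal:
        raise ValueError("tree has no focal-species tips")

    clusters: list[FocalCluster] = []

    def walk(clade) -> None:
        tips = [t.name for t in clade.get_terminals()]
        if all(t in focal for t in tips):
            if len(tips) >= 2:
                support = getattr(clade, "confidence", None)
                clusters.append(
                    FocalCluster(members=frozenset(tips), support=support)
                )
            return  # maximal: do not descend into sub-clusters
        for child in clade.clades:
            walk(child)

    walk(tree.tree.root)
    clusters.sort(key=lambda c: sorted(c.members))
    return clusters


def assign_gene_types(
    tree: GeneTree, clusters: Sequence[FocalCluster]
) -> dict[str, str]:
    """Map every focal gene to type I (in a cluster) or type II."""
    in_cluster = set().union(*(c.members for c in clusters)) if clusters else set()
    return {
        g: ("I" if g in in_cluster else "II") for g in tree.focal_tips()
    }


def nearest_outgroup_orthologs(tree: GeneTree) -> dict[str, set[str]]:
    """For each focal tip, the outgroup tips of the smallest enclosing clade
    that contains any outgroup tip."""
    outgroup = set(tree.outgroup_tips())
    root = tree.tree.root
    parents: dict = {}
    for clade in tree.tree.find_clades(order="level"):
        for child in clade.clades:
            parents[child] = clade
    result: dict[str, set[str]] = {}
    for tip in tree.tree.get_terminals():
        if tree.species_of[tip.name] != FOCAL:
            continue
        node = tip
        orthos: set[str] = set()
        while True:
            tips = {t.name for t in node.get_terminals()}
            orthos = tips & outgroup
            if orthos or node is root:
                break
            node = parents[node]
        result[tip.name] = orthos
    return result


def outgroup_tandem_evidence(
    focal_pair: tuple[str, str],
    ortholog_map: Mapping[str, set[str]],
    outgroup_genes: Sequence[GeneRecord],
    config: AnalysisConfig | None = None,
) -> bool:
    """True when some ortholog of each focal gene forms a tandem pair in the
    outgroup genome under the same pair rule."""
    config = config or AnalysisConfig()
    g1, g2 = focal_pair
    orth1 = ortholog_map.get(g1, set())
    orth2 = ortholog_map.get(g2, set())
    if not orth1 or not orth2:
        log.info("no outgroup orthologs for pair (%s, %s)", g1, g2)
        return False
    by_id = {g.gene_id: g for g in outgroup_genes}
    for a in orth1:
        for b in orth2:
            if a == b or a not in by_id or b not in by_id:
                continue
            if is_tandem_pair(by_id[a], by_id[b], outgroup_genes, config):
                return True
    return False


def classify_tandem_genes(
    repeats: Sequence[TandemRepeat],
    clusters: Sequence[FocalCluster],
    types: Mapping[str, str],
    evidence: Mapping[tuple[str, str], bool] | None = None,
) -> list[DuplicateLabel]:
    """Label every focal gene with its tandem class.

    ``evidence`` optionally carries outgroup tandem-arrangement flags per
    focal pair; it annotates the labels but never changes a call.
    """
    evidence = evidence or {}
    cluster_of: dict[str, frozenset[str]] = {}
    for c in clusters:
        for g in c.members:
            cluster_of[g] = c.members
    repeat_of: dict[str, TandemRepeat] = {}
    for r in repeats:
        for g in r.members:
            repeat_of[g] = r

    missing = [g for g in repeat_of if g not in types]
    if missing:
        raise ValueError(
            "genes in tandem repeats but absent from tree: " + ", ".join(sorted(missing))
        )

    labels: list[DuplicateLabel] = []
    for gene_id, gtype in sorted(types.items()):
        rep = repeat_of.get(gene_id)
        if rep is None:
            labels.append(DuplicateLabel(gene_id, gtype, NONE))
            continue
        partners = [m for m in rep.members if m != gene_id]
        own_cluster = cluster_of.get(gene_id, frozenset())
        ls_partners = [p for p in partners if p in own_cluster]
        ext_partners = [p for p in partners if p not in own_cluster]
        is_ls = bool(ls_partners)
        is_anc = gtype == "II" or bool(ext_partners)
        if is_ls and is_anc:
            tclass = BOTH
        elif is_ls:
            tclass = LINEAGE_SPECIFIC
        else:
            tclass = ANCESTRAL
        notes = []
        if ls_partners:
            notes.append("cluster partners in repeat: " + ",".join(sorted(ls_partners)))
        if ext_partners:
            notes.append(
                "non-cluster partners in repeat: " + ",".join(sorted(ext_partners))
            )
        for p in partners:
            key = (gene_id, p) if (gene_id, p) in evidence else (p, gene_id)
            if key in evidence:
                notes.append(
                    f"outgroup orthologs of ({key[0]},{key[1]}) tandem: {evidence[key]}"
                )
        labels.append(DuplicateLabel(gene_id, gtype, tclass, notes))
    return labels


def summarize_labels(labels: Sequence[DuplicateLabel]) -> dict:
    """Gene-level tallies plus the inclusion-exclusion identity."""
    ls = sum(1 for l in labels if l.tandem_class in (LINEAGE_SPECIFIC, BOTH))
    anc = sum(1 for l in labels if l.tandem_class in (ANCESTRAL, BOTH))
    both = sum(1 for l in labels if l.tandem_class == BOTH)
    tandem = sum(1 for l in labels if l.tandem_class != NONE)
    return {
        "n_genes": len(labels),
        "n_type_I": sum(1 for l in labels if l.gene_type == "I"),
        "n_type_II": sum(1 for l in labels if l.gene_type == "II"),
        "n_tandem": tandem,
        "n_lineage_specific": ls,
        "n_ancestral": anc,
        "n_both": both,
        "inclusion_exclusion_ok": ls + anc - both == tandem,
    }


def write_labels_tsv(labels: Sequence[DuplicateLabel], path) -> None:
    from pathlib import Path

    lines = ["gene_id\tgene_type\ttandem_class\tevidence"]
    for l in labels:
        lines.append(
            f"{l.gene_id}\t{l.gene_type}\t{l.tandem_class}\t" + "; ".join(l.evidence)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels_tsv(path) -> list[DuplicateLabel]:
    from pathlib import Path

    labels = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        gene_id, gtype, tclass, ev = (line.split("\t") + [""])[:4]
        labels.append(
            DuplicateLabel(gene_id, gtype, tclass, ev.split("; ") if ev else [])
        )
    return labels
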