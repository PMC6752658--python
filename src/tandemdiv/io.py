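"""Core domain types and readers/writers for the formats the pipeline touches.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive on
both ends. Unanchored scaffolds are ingested exactly like chromosomes.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import Phylo

log = logging.getLogger("tandemdiv")

FOCAL = "focal"
OUTGROUP = "outgroup"


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _source_text(source) -> str:
    """Accept a path, raw text, or an open handle; return the text."""
    if hasattr(source, "read"):
        return source.read()
    s = str(source)
    if "\n" not in s and len(s) < 4000:
        try:
            p = Path(s)
            if p.exists():
                return p.read_text()
        except OSError:
            pass
    return s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One gene model: coordinates, strand, exons and family membership.

    ``start``/``end`` are 1-based inclusive base-pair positions; ``exons``
    is an ordered list of (start, end) pairs lying within the gene span.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    exons: tuple[tuple[int, int], ...] = ()
    is_family_member: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon start {s} > end {e}")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene span"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons unsorted or overlapping"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class GeneTree:
    """A rooted gene tree whose tips carry a gene id and a species role.

    ``species_of`` maps every tip gene id to ``"focal"`` or ``"outgroup"``.
    The underlying topology is a :class:`Bio.Phylo.BaseTree.Tree`.
    """

    def __init__(self, tree, species_of: Mapping[str, str]):
        self.tree = tree
        self.species_of = dict(species_of)
        tips = [t.name for t in tree.get_terminals()]
        if len(tips) != len(set(tips)):
            raise ValueError("duplicate tip gene_ids in tree")
        missing = [t for t in tips if t not in self.species_of]
        if missing:
            raise ParseError(
                "tips absent from species map: " + ", ".join(sorted(missing))
            )
        bad = {s for s in self.species_of.values()} - {FOCAL, OUTGROUP}
        if bad:
            raise ParseError(f"species labels must be focal/outgroup, got {bad}")

    @property
    def tip_ids(self) -> list[str]:
        return [t.name for t in self.tree.get_terminals()]

    def focal_tips(self) -> list[str]:
        return [t for t in self.tip_ids if self.species_of[t] == FOCAL]

    def outgroup_tips(self) -> list[str]:
        return [t for t in self.tip_ids if self.species_of[t] == OUTGROUP]


class ExpressionMatrix:
    """Genes x stages matrix of non-negative RPKM values."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene_id(s): {dups}")
        if values.columns.has_duplicates:
            raise ParseError("duplicate stage labels")
        if values.isna().any().any():
            raise ParseError("missing cells in expression matrix")
        if (values.to_numpy() < 0).any():
            raise ParseError("negative RPKM value in expression matrix")
        self.values = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_stages(self) -> int:
        return self.values.shape[1]

    def profile(self, gene_id: str):
        return self.values.loc[gene_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.values.equals(
            other.values
        )


@dataclass
class AnalysisConfig:
    """Analysis thresholds; defaults are the study's published constants.

    max_pair_distance_bp / max_intervening define the tandem pair rule
    ("within 100 kb", "no more than 10 non-homologous intervening genes");
    detection_threshold is the RPKM expressed/not-expressed cutoff (0.3);
    low_expr_threshold/low_expr_fraction define low expression (RPKM < 1 in
    at least two thirds of stages); corr_threshold is the correlated-pair
    rule (r > 0.5).
    """

    max_pair_distance_bp: int = 100_000
    max_intervening: int = 10
    detection_threshold: float = 0.3
    min_expressed_stages: int = 2
    low_expr_threshold: float = 1.0
    low_expr_fraction: float = 2.0 / 3.0
    corr_threshold: float = 0.5
    min_shared_stages: int = 3
    distance_mode: str = "gap"  # "gap" (inner gap) or "start" (anchor-to-anchor)
    correlation_method: str = "pearson"  # or "spearman"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_pair_distance_bp",
            "detection_threshold",
            "low_expr_threshold",
            "corr_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")
        if not 0 < self.low_expr_fraction <= 1:
            raise ValueError("low_expr_fraction must be in (0, 1]")
        if self.distance_mode not in {"gap", "start"}:
            raise ValueError("distance_mode must be 'gap' or 'start'")
        if self.correlation_method not in {"pearson", "spearman"}:
            raise ValueError("correlation_method must be pearson or spearman")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: target and reference-gene Ct for a replicate."""

    sample_id: str
    condition: str
    timepoint: str
    gene_id: str
    ct_target: float
    ct_reference: float
    replicate: int

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(
                    f"sample {self.sample_id}: Ct values must be positive finite"
                )


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------


def _validate_gff_lines(text: str) -> None:
    # gffutils reports structural problems but not coordinate sanity with
    # line numbers, which the parse contract requires.
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 9:
            raise ParseError(
                f"line {lineno}: expected 9 GFF3 columns, got {len(parts)}"
            )
        try:
            start, end = int(parts[3]), int(parts[4])
        except ValueError:
            raise ParseError(f"line {lineno}: non-integer coordinates") from None
        if start > end:
            raise ParseError(
                f"line {lineno}: start {start} > end {end} ({parts[2]} on {parts[0]})"
            )


def parse_gff_genes(
    source: str | Path | _io.TextIOBase, family_ids: Iterable[str] = ()
) -> list[GeneRecord]:
    """Read gene and exon features from GFF3 into :class:`GeneRecord` s.

    ``family_ids`` marks which genes belong to the studied family; all other
    genes are retained as potential intervening genes. Records come back
    sorted by (chromosome, start, gene_id).

    Exons attach to genes through their ``Parent`` attribute, directly or
    via an intermediate mRNA feature.
    """
    import gffutils

    text = _source_text(source)
    family = set(family_ids)
    _validate_gff_lines(text)
    try:
        db = gffutils.create_db(
            text, ":memory:", from_string=True,
            merge_strategy="error", keep_order=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed GFF3: {exc}") from exc

    gene_ids = {f.id for f in db.features_of_type("gene")}
    gene_exons: dict[str, set[tuple[int, int]]] = {gid: set() for gid in gene_ids}

    def _resolve_gene(parent: str) -> str | None:
        if parent in gene_ids:
            return parent
        try:
            mid = db[parent]
        except gffutils.FeatureNotFoundError:
            raise ParseError(
                f"exon Parent {parent!r} does not resolve to a feature"
            ) from None
        for p in mid.attributes.get("Parent", []):
            if p in gene_ids:
                return p
        return None

    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents:
            raise ParseError(f"exon at {exon.seqid}:{exon.start} has no Parent")
        resolved = [_resolve_gene(p) for p in parents]
        hits = [g for g in resolved if g is not None]
        if not hits:
            raise ParseError(
                f"exon at {exon.seqid}:{exon.start} has no resolvable gene parent"
            )
        for gid in hits:
            gene_exons[gid].add((exon.start, exon.end))

    records = [
        GeneRecord(
            gene_id=gene.id,
            chromosome=gene.seqid,
            start=gene.start,
            end=gene.end,
            strand=gene.strand if gene.strand in "+-" else ".",
            exons=tuple(sorted(gene_exons[gene.id])),
            is_family_member=gene.id in family,
        )
        for gene in db.features_of_type("gene")
    ]
    records.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return records


def write_gff_genes(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene + exon features; inverse of :func:`parse_gff_genes`."""
    lines = ["##gff-version 3"]
    for g in sorted(records, key=lambda r: (r.chromosome, r.start, r.gene_id)):
        lines.append(
            f"{g.chromosome}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        for s, e in g.exons:
            lines.append(
                f"{g.chromosome}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_species_map(source: str | Path | _io.TextIOBase) -> dict[str, str]:
    """Read the two-column gene_id → focal/outgroup sidecar TSV."""
    text = _source_text(source)
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError(f"species map line {lineno}: need gene_id<TAB>species")
        mapping[parts[0]] = parts[1]
    return mapping


def parse_gene_tree(
    newick: str | Path | _io.TextIOBase, species_map: Mapping[str, str]
) -> GeneTree:
    """Parse a Newick gene tree and annotate each tip focal/outgroup.

    A basal polytomy is taken to mean the input is unrooted; the tree is
    then rooted at its midpoint and a warning is logged.
    """
    handle = _io.StringIO(_source_text(newick))
    tree = Phylo.read(handle, "newick")
    if len(tree.root.clades) > 2:
        log.warning("input tree is unrooted (basal polytomy); midpoint rooting")
        for cl in tree.find_clades():
            if cl.branch_length is None:
                cl.branch_length = 1.0
        tree.root_at_midpoint()
    return GeneTree(tree, species_map)


def parse_expression_table(source: str | Path | _io.TextIOBase) -> ExpressionMatrix:
    """Read a genes x stages TSV of RPKM values (header row = stage labels)."""
    handle = _io.StringIO(_source_text(source))
    try:
        df = pd.read_csv(handle, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read expression table: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError("expression table has no stage columns")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        raise ParseError(f"non-numeric expression columns: {list(non_numeric)}")
    return ExpressionMatrix(df)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_qpcr_table(source: str | Path | _io.TextIOBase) -> list[QpcrRecord]:
    """Read qPCR Ct measurements from TSV with columns
    sample_id, condition, timepoint, gene_id, ct_target, ct_reference, replicate.
    """
    handle = _io.StringIO(_source_text(source))
    df = pd.read_csv(handle, sep="\t")
    required = {
        "sample_id", "condition", "timepoint", "gene_id",
        "ct_target", "ct_reference", "replicate",
    }
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"qPCR table missing columns: {sorted(missing)}")
    return [
        QpcrRecord(
            sample_id=str(r.sample_id),
            condition=str(r.condition),
            timepoint=str(r.timepoint),
            gene_id=str(r.gene_id),
            ct_target=float(r.ct_target),
            ct_reference=float(r.ct_reference),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def read_fasta(source: str | Path | _io.TextIOBase) -> dict[str, str]:
    """Whole-file FASTA read into an id → sequence dict."""
    from Bio import SeqIO

    handle = _io.StringIO(_source_text(source))
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA id {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
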