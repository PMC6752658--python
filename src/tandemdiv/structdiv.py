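"""Exon/intron and motif-architecture divergence within duplicate pairs.

Motif discovery is out of scope: architectures (ordered motif identifiers
with protein start offsets) are inputs. Arrangement differences are scored
as the symmetric difference of the motif-id multisets, so copy-number
changes count but pure re-ordering does not; an edit-distance alternative
over the motif sequences is available for callers who want order to count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import GeneRecord, ParseError, _source_text


@dataclass(frozen=True)
class MotifArchitecture:
    """Ordered motif identifiers of one protein, with start offsets."""

    gene_id: str
    motifs: tuple[str, ...]
    starts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.starts:
            if len(self.starts) != len(self.motifs):
                raise ValueError(f"{self.gene_id}: offsets do not match motifs")
            if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
                raise ValueError(f"{self.gene_id}: offsets not strictly increasing")


def intron_count(g: GeneRecord) -> int:
    """Introns are the gaps between annotated exons: len(exons) - 1."""
    if not g.exons:
        raise ValueError(f"{g.gene_id}: no exon annotation")
    return len(g.exons) - 1


def pair_intron_difference(g1: GeneRecord, g2: GeneRecord) -> int:
    """Absolute intron-count difference; > 0 marks a structure-divergent pair."""
    return abs(intron_count(g1) - intron_count(g2))


def motif_difference(
    a1: MotifArchitecture,
    a2: MotifArchitecture,
    motif_set: Iterable[str] | None = None,
    method: str = "multiset",
) -> int:
    """Architecture difference between two proteins.

    ``multiset`` (default) counts the symmetric difference of motif-id
    multisets; ``edit`` computes Levenshtein distance over the ordered
    motif sequences.
    """
    if motif_set is not None:
        known = set(motif_set)
        unknown = (set(a1.motifs) | set(a2.motifs)) - known
        if unknown:
            raise ValueError(f"unknown motif id(s): {sorted(unknown)}")
    if method == "multiset":
        c1, c2 = Counter(a1.motifs), Counter(a2.motifs)
        return sum((c1 - c2).values()) + sum((c2 - c1).values())
    if method == "edit":
        return _levenshtein(a1.motifs, a2.motifs)
    raise ValueError(f"unknown method {method!r}")


def _levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def read_motif_table(source) -> dict[str, MotifArchitecture]:
    """Read the gene_id / motif_id / start TSV into architectures."""
    text = _source_text(source)
    rows: dict[str, list[tuple[int, str]]] = {}
    lines = text.splitlines()
    start_idx = 1 if lines and lines[0].startswith("gene_id") else 0
    for lineno, line in enumerate(lines[start_idx:], start_idx + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"motif table line {lineno}: need gene_id/motif_id/start")
        gene_id, motif_id, start_s = parts[0], parts[1], parts[2]
        try:
            start = int(start_s)
        except ValueError:
            raise ParseError(f"motif table line {lineno}: bad start {start_s!r}") from None
        rows.setdefault(gene_id, []).append((start, motif_id))
    out = {}
    for gene_id, entries in rows.items():
        entries.sort()
        out[gene_id] = MotifArchitecture(
            gene_id=gene_id,
            motifs=tuple(m for _, m in entries),
            starts=tuple(s for s, _ in entries),
        )
    return out


def write_motif_table(archs: Mapping[str, MotifArchitecture], path) -> None:
    lines = ["gene_id\tmotif_id\tstart"]
    for arch in archs.values():
        starts = arch.starts or tuple(range(len(arch.motifs)))
        for s, m in zip(starts, arch.motifs):
            lines.append(f"{arch.gene_id}\t{m}\t{s}")
    Path(path).write_text("\n".join(lines) + "\n")


def pair_structure_summary(
    pairs: Sequence[tuple[GeneRecord, GeneRecord]],
    archs: Mapping[str, MotifArchitecture] | None = None,
) -> dict:
    """Mean intron and motif differences over duplicate pairs."""
    intron_diffs = [pair_intron_difference(a, b) for a, b in pairs]
    result = {
        "n_pairs": len(pairs),
        "intron_differences": intron_diffs,
        "n_structure_divergent": sum(1 for d in intron_diffs if d > 0),
        "mean_intron_difference": (
            sum(intron_diffs) / len(intron_diffs) if intron_diffs else None
        ),
    }
    if archs is not None:
        motif_diffs = [
            motif_difference(archs[a.gene_id], archs[b.gene_id]) for a, b in pairs
        ]
        result["motif_differences"] = motif_diffs
        result["mean_motif_difference"] = (
            sum(motif_diffs) / len(motif_diffs) if motif_diffs else None
        )
    return result
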