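"""Tandem duplicate detection.

A pair of family genes is tandem when both lie on the same chromosome,
within 100 kb of each other, and are separated by no more than 10
non-homologous (non-family) intervening genes. Qualifying pairs are chained
by single linkage into maximal tandem repeats, so a six-gene array whose
consecutive gaps all qualify is reported as one repeat.

Distance is measured as the inner gap between gene spans by default (0 for
overlapping genes); anchor start-to-start distance can be selected through
``AnalysisConfig.distance_mode``. Strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import AnalysisConfig, GeneRecord


@dataclass(frozen=True)
class TandemRepeat:
    """A maximal single-linkage chain of tandem family genes."""

    chromosome: str
    members: tuple[str, ...]  # gene ids ordered by start coordinate
    span: tuple[int, int]  # (min start, max end), bp

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a tandem repeat needs at least 2 members")

    def __len__(self) -> int:
        return len(self.members)


def count_intervening(
    g1: GeneRecord, g2: GeneRecord, all_genes: Sequence[GeneRecord]
) -> int:
    """Number of non-family genes lying strictly between ``g1`` and ``g2``.

    A gene counts only when its whole span falls inside the open interval
    (g1.end, g2.start); family members in between are never counted.
    """
    if g1.chromosome != g2.chromosome:
        raise ValueError(
            f"{g1.gene_id} and {g2.gene_id} are on different chromosomes"
        )
    if g1.start > g2.start:
        g1, g2 = g2, g1
    return sum(
        1
        for g in all_genes
        if g.chromosome == g1.chromosome
        and not g.is_family_member
        and g.start > g1.end
        and g.end < g2.start
    )


def pair_distance(g1: GeneRecord, g2: GeneRecord, mode: str = "gap") -> int:
    """Distance between two genes: inner gap (default) or start-to-start."""
    if g1.start > g2.start:
        g1, g2 = g2, g1
    if mode == "start":
        return g2.start - g1.start
    return max(0, g2.start - g1.end)


def is_tandem_pair(
    g1: GeneRecord,
    g2: GeneRecord,
    all_genes: Sequence[GeneRecord],
    config: AnalysisConfig | None = None,
) -> bool:
    """Apply the tandem pair rule to two family genes."""
    config = config or AnalysisConfig()
    for g in (g1, g2):
        if not g.is_family_member:
            raise ValueError(f"{g.gene_id} is not a family member")
    if g1.chromosome != g2.chromosome:
        return False
    if pair_distance(g1, g2, config.distance_mode) > config.max_pair_distance_bp:
        return False
    return count_intervening(g1, g2, all_genes) <= config.max_intervening


def detect_tandem_repeats(
    genes: Sequence[GeneRecord], config: AnalysisConfig | None = None
) -> list[TandemRepeat]:
    """Chain qualifying family pairs into maximal tandem repeats.

    The pair rule is evaluated between all family pairs on each chromosome
    and components of the resulting graph (single linkage) with >= 2 genes
    become repeats. Output order is (chromosome, span start) and does not
    depend on input order.
    """
    config = config or AnalysisConfig()
    genes = sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.is_family_member:
            by_chrom.setdefault(g.chromosome, []).append(g)

    repeats: list[TandemRepeat] = []
    for chrom, fam in by_chrom.items():
        parent = list(range(len(fam)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                # sorted by start: genes further right can only grow the gap,
                # but intervening counts are not monotone, so test every pair
                if pair_distance(fam[i], fam[j], config.distance_mode) > (
                    config.max_pair_distance_bp
                ):
                    continue
                if is_tandem_pair(fam[i], fam[j], genes, config):
                    parent[find(i)] = find(j)

        groups: dict[int, list[GeneRecord]] = {}
        for i, g in enumerate(fam):
            groups.setdefault(find(i), []).append(g)
        for members in groups.values():
            if len(members) < 2:
                continue
            members.sort(key=lambda g: (g.start, g.gene_id))
            repeats.append(
                TandemRepeat(
                    chromosome=chrom,
                    members=tuple(g.gene_id for g in members),
                    span=(
                        min(g.start for g in members),
                        max(g.end for g in members),
                    ),
                )
            )
    repeats.sort(key=lambda r: (r.chromosome, r.span[0]))
    return repeats


def write_repeats_tsv(repeats: Sequence[TandemRepeat], path) -> None:
    lines = ["repeat_id\tchromosome\tspan_start\tspan_end\tmembers"]
    for i, r in enumerate(repeats, 1):
        lines.append(
            f"TR{i:03d}\t{r.chromosome}\t{r.span[0]}\t{r.span[1]}\t"
            + ",".join(r.members)
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def read_repeats_tsv(path) -> list[TandemRepeat]:
    from pathlib import Path

    repeats = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        _, chrom, s, e, members = line.split("\t")
        repeats.append(
            TandemRepeat(
                chromosome=chrom,
                members=tuple(members.split(",")),
                span=(int(s), int(e)),
            )
        )
    return repeats
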