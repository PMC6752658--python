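"""Codon-aware back-translation and pairwise Pi / Ka / Ks estimation.

Ka/Ks follows Nei & Gojobori's (1986) counting method: fractional
synonymous and nonsynonymous site counts per codon, observed differences
resolved by averaging over all minimal mutational pathways with equal
weights (pathways through stop codons excluded), and a Jukes–Cantor
multiple-hit correction d = -(3/4) ln(1 - 4p/3) applied to the proportions.
Single-nucleotide changes that would create a stop codon count as
nonsynonymous in the site tally. A proportion at or past the p = 3/4
saturation point yields NA for the corresponding rate.

Pi is the raw proportion of differing nucleotides among gap-free aligned
sites.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

log = logging.getLogger("tandemdiv")

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, stripping one terminal stop."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        pos = protein.index("*")
        raise ValueError(f"internal stop codon at codon {pos + 1}")
    return protein


# ---------------------------------------------------------------------------
# Codon alignment (back-translation)
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Aligned CDS rows over {A,C,G,T,-}; gaps occur in whole-codon units."""

    gene_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length not divisible by 3")

    def pair(self, id1: str, id2: str) -> tuple[str, str]:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        return self.rows[idx[id1]], self.rows[idx[id2]]


def backtranslate_alignment(
    protein_alignment: Mapping[str, str], cds_map: Mapping[str, str]
) -> CodonAlignment:
    """Thread each unaligned CDS onto its aligned protein row.

    Every amino-acid column becomes one codon column; protein gaps become
    ``---``. The translated CDS must equal the ungapped protein row;
    a mismatch is reported with the gene and the offending position.
    """
    gene_ids, rows = [], []
    for gene_id, prot_row in protein_alignment.items():
        if gene_id not in cds_map:
            raise ValueError(f"no CDS for {gene_id}")
        cds = cds_map[gene_id].upper()
        if len(cds) % 3:
            raise ValueError(f"{gene_id}: CDS length {len(cds)} not a multiple of 3")
        # strip one terminal stop codon if present
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        ungapped = prot_row.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{gene_id}: CDS length {len(cds)} does not match "
                f"{len(ungapped)} aligned residues"
            )
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for pos, (aa, codon) in enumerate(zip(ungapped, codons), 1):
            if codon in STOP_CODONS:
                raise ValueError(f"{gene_id}: internal stop codon at position {pos}")
            trans = CODON_TO_AA.get(codon, "X")
            if trans != aa.upper():
                raise ValueError(
                    f"{gene_id}: translation mismatch at position {pos}: "
                    f"codon {codon} -> {trans}, protein has {aa}"
                )
        out, k = [], 0
        for aa in prot_row:
            if aa == "-":
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        gene_ids.append(gene_id)
        rows.append("".join(out))
    return CodonAlignment(gene_ids, rows)


# ---------------------------------------------------------------------------
# Pi
# ---------------------------------------------------------------------------


def pairwise_pi(row1: str, row2: str) -> float | None:
    """Proportion of differing nucleotides among sites where neither row is
    gapped; None when no site is comparable."""
    if len(row1) != len(row2):
        raise ValueError("aligned rows have unequal lengths")
    compared = diffs = 0
    for a, b in zip(row1.upper(), row2.upper()):
        if a == "-" or b == "-":
            continue
        compared += 1
        if a != b:
            diffs += 1
    if compared == 0:
        return None
    return diffs / compared


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that preserve the amino acid; changes creating a stop codon are
    nonsynonymous. The two counts always add to 3.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOP_CODONS and CODON_TO_AA[mut] == aa:
                n_syn += 1
        syn += n_syn / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over all minimal mutational pathways with equal weights.

    Pathways passing through a stop codon are dropped and the remaining
    ones reweighted; None when every pathway passes through a stop.
    """
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if len(c) != 3 or any(b not in BASES for b in c):
            raise ValueError(f"invalid codon {c!r}")
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_syn = total_nonsyn = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps: list[tuple[str, str]] = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append((cur, nxt))
            cur = nxt
        if blocked:
            continue
        n_paths += 1
        for a, b in steps:
            if CODON_TO_AA[a] == CODON_TO_AA[b]:
                total_syn += 1
            else:
                total_nonsyn += 1
    if n_paths == 0:
        return None
    return total_syn / n_paths, total_nonsyn / n_paths


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None at or beyond the p = 3/4 saturation point."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DivergenceResult:
    """Pairwise divergence statistics and the counts behind them.

    ``ks``/``ka`` are None at Jukes–Cantor saturation; ``ka_ks`` is None
    whenever ks is 0 or undefined.
    """

    gene1: str
    gene2: str
    pi: float | None
    S: float
    N: float
    Sd: float
    Nd: float
    ks: float | None
    ka: float | None
    ka_ks: float | None
    n_codons: int


def ng86_ka_ks(
    row1: str, row2: str, gene1: str = "seq1", gene2: str = "seq2"
) -> DivergenceResult:
    """Nei–Gojobori Ka/Ks for one aligned CDS pair.

    Codon columns containing a gap or an ambiguity character are skipped
    pairwise; site counts are averaged over the two sequences.
    """
    if len(row1) != len(row2):
        raise ValueError("aligned rows have unequal lengths")
    if len(row1) % 3:
        raise ValueError("alignment length not divisible by 3")
    row1, row2 = row1.upper(), row2.upper()

    S1 = S2 = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(row1), 3):
        c1, c2 = row1[i : i + 3], row2[i : i + 3]
        if any(b not in BASES for b in c1) or any(b not in BASES for b in c2):
            continue  # gap or ambiguity in this codon column
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        diffs = codon_pair_differences(c1, c2)
        if diffs is None:
            log.info(
                "codon pair (%s,%s) at column %d: all pathways pass a stop; skipped",
                c1, c2, i // 3,
            )
            continue
        s1, _ = ng86_sites(c1)
        s2, _ = ng86_sites(c2)
        S1 += s1
        S2 += s2
        Sd += diffs[0]
        Nd += diffs[1]
        n_codons += 1
    if n_codons < 1:
        raise ValueError(f"({gene1},{gene2}): no comparable codons")

    S = (S1 + S2) / 2.0
    N = 3.0 * n_codons - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    ka_ks = (ka / ks) if (ks is not None and ka is not None and ks > 0) else None
    return DivergenceResult(
        gene1=gene1,
        gene2=gene2,
        pi=pairwise_pi(row1, row2),
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        ks=ks,
        ka=ka,
        ka_ks=ka_ks,
        n_codons=n_codons,
    )


def divergence_for_pairs(
    alignment: CodonAlignment, pairs: Sequence[tuple[str, str]]
) -> list[DivergenceResult]:
    """NG86 + Pi for each requested gene pair of a codon alignment."""
    return [
        ng86_ka_ks(*alignment.pair(g1, g2), gene1=g1, gene2=g2) for g1, g2 in pairs
    ]


def write_divergence_tsv(results: Sequence[DivergenceResult], path) -> None:
    from pathlib import Path

    def fmt(x):
        return "NA" if x is None else f"{x:.6g}"

    lines = ["gene1\tgene2\tpi\tS\tN\tSd\tNd\tks\tka\tka_ks\tn_codons"]
    for r in results:
        lines.append(
            "\t".join(
                [
                    r.gene1, r.gene2, fmt(r.pi),
                    f"{r.S:.4f}", f"{r.N:.4f}", f"{r.Sd:.4f}", f"{r.Nd:.4f}",
                    fmt(r.ks), fmt(r.ka), fmt(r.ka_ks), str(r.n_codons),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
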