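"""Forward simulation of a two-species gene family with tandem duplications.

The generator plays the inferred history forward: a set of ancestral genes
may duplicate in tandem before the speciation split (ancestral tandem
arrays, inherited by the focal and outgroup genomes), and focal-lineage
copies may duplicate in tandem again after the split (lineage-specific
arrays) or disperse to another chromosome. Codon sequences evolve under a
proposal process calibrated to a target synonymous divergence (Ks) with
nonsynonymous proposals accepted at probability ω, duplicate expression
profiles are generated at controlled pair correlation over 13 stages, and
every event is recorded as ground truth so the detection, classification,
divergence and expression modules can be validated end to end.

Tandem duplicates are inserted immediately downstream of their template
with a gap drawn from [200, 20000] bp and 0–3 non-family filler genes, so
the pair rule holds at the default thresholds; distinct loci are separated
by >100 kb so arrays never merge.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    FOCAL,
    OUTGROUP,
    ExpressionMatrix,
    GeneRecord,
    write_expression_table,
    write_fasta,
    write_gff_genes,
)
from .seqdiv import BASES, CODON_TO_AA, STOP_CODONS, translate_cds
from .structdiv import MotifArchitecture, write_motif_table

_NONSTOP_CODONS = sorted(set(CODON_TO_AA))


@dataclass
class SimulationParams:
    """Knobs of the family history and of the data layered on top of it.

    Rates are per ancestral gene (duplication) or per gene copy (loss);
    Ks targets are total expected pairwise synonymous divergence
    contributed by each event class, split evenly over the two branches.
    """

    n_ancestral_genes: int = 20
    p_tandem_before_speciation: float = 0.3
    p_tandem_after_speciation: float = 0.3
    p_dispersed_after_speciation: float = 0.1
    gene_loss_rate: float = 0.0
    n_chromosomes: int = 3
    chromosome_length_bp: int = 30_000_000
    intervening_per_10kb: float = 0.25
    n_codons: int = 300
    ks_lineage_specific: float = 0.1
    ks_ancestral_duplication: float = 0.4
    ks_speciation: float = 0.8
    omega_lineage_specific: float = 0.25
    omega_ancestral: float = 0.15
    n_stages: int = 13
    corr_lineage_specific: float = 0.5
    corr_ancestral: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_tandem_before_speciation",
            "p_tandem_after_speciation",
            "p_dispersed_after_speciation",
            "gene_loss_rate",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.n_ancestral_genes < 1 or self.n_codons < 1:
            raise ValueError("counts and lengths must be positive")


@dataclass
class SyntheticTruth:
    """Everything the simulator knows that the pipeline must recover."""

    gene_type: dict[str, str]  # focal family gene -> I/II
    tandem_class: dict[str, str]  # focal family gene -> class
    clusters: list[list[str]]  # true focal-only expansion clades
    arrays_focal: list[list[str]]  # planted tandem arrays (>=2 survivors)
    arrays_outgroup: list[list[str]]
    pair_ks: dict[str, float]  # "g1|g2" -> expected Ks
    pair_omega: dict[str, float]
    pair_class: dict[str, str]  # "g1|g2" -> lineage_specific/ancestral
    pair_expr_r: dict[str, float]
    n_focal_genes: int
    n_outgroup_genes: int


@dataclass
class SimulatedFamily:
    params: SimulationParams
    focal_genes: list[GeneRecord]
    outgroup_genes: list[GeneRecord]
    cds: dict[str, str]
    proteins: dict[str, str]
    newick: str
    species_map: dict[str, str]
    expression: ExpressionMatrix
    motifs: dict[str, MotifArchitecture]
    truth: SyntheticTruth

    @property
    def family_ids(self) -> set[str]:
        return set(self.species_map)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every artifact as plain-text files; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "focal_gff": out / "focal.gff3",
            "outgroup_gff": out / "outgroup.gff3",
            "cds": out / "cds.fasta",
            "proteins": out / "proteins.fasta",
            "tree": out / "tree.nwk",
            "species_map": out / "species_map.tsv",
            "expression": out / "expression.tsv",
            "motifs": out / "motifs.tsv",
            "family_ids": out / "family_ids.txt",
            "truth": out / "truth.json",
        }
        write_gff_genes(self.focal_genes, paths["focal_gff"])
        write_gff_genes(self.outgroup_genes, paths["outgroup_gff"])
        write_fasta(self.cds, paths["cds"])
        write_fasta(self.proteins, paths["proteins"])
        paths["tree"].write_text(self.newick + "\n")
        paths["species_map"].write_text(
            "".join(f"{g}\t{s}\n" for g, s in sorted(self.species_map.items()))
        )
        write_expression_table(self.expression, paths["expression"])
        write_motif_table(self.motifs, paths["motifs"])
        paths["family_ids"].write_text(
            "".join(f"{g}\n" for g in sorted(self.family_ids))
        )
        paths["truth"].write_text(json.dumps(asdict(self.truth), indent=1))
        return paths


# ---------------------------------------------------------------------------
# Codon sequence evolution
# ---------------------------------------------------------------------------


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Uniform random CDS over the 61 sense codons, starting with ATG."""
    codons = ["ATG"] + list(rng.choice(_NONSTOP_CODONS, size=n_codons - 1))
    return "".join(codons)


def evolve_codon_sequence(
    seq: str, target_ks: float, omega: float, seed: int | np.random.Generator
) -> str:
    """Evolve a CDS to an expected synonymous divergence of ``target_ks``.

    Single-nucleotide changes are proposed uniformly; synonymous proposals
    are always accepted, nonsynonymous ones with probability ``omega``, and
    proposals creating a stop codon are rejected. The number of proposals
    is Poisson with mean 3 x codons x target_ks, which makes the expected
    number of accepted synonymous events per synonymous site equal
    ``target_ks`` (the NG86 + Jukes-Cantor estimand).
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("CDS length not a multiple of 3")
    translate_cds(seq)  # validates: no internal stops
    if target_ks == 0:
        return seq
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chars = list(seq)
    n_prop = rng.poisson(3.0 * (len(seq) / 3) * target_ks)
    for _ in range(n_prop):
        pos = int(rng.integers(len(chars)))
        old = chars[pos]
        alt = BASES[int(rng.integers(4))]
        while alt == old:
            alt = BASES[int(rng.integers(4))]
        c0 = pos - pos % 3
        codon = "".join(chars[c0 : c0 + 3])
        mutated = codon[: pos - c0] + alt + codon[pos - c0 + 1 :]
        if mutated in STOP_CODONS:
            continue
        if CODON_TO_AA[mutated] != CODON_TO_AA[codon] and rng.random() >= omega:
            continue
        chars[pos] = alt
    return "".join(chars)


# ---------------------------------------------------------------------------
# Expression profiles
# ---------------------------------------------------------------------------


def simulate_expression_pair(
    base_profile: Sequence[float],
    target_r: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a duplicate partner profile at a target Pearson correlation.

    On the log2 scale the partner mixes the base profile's stage deviations
    (weight ``target_r``) with independent Gaussian noise of equal variance
    (weight sqrt(1 - r^2)), so the expected log-scale correlation is
    ``target_r``; target_r = 1 returns an identical profile.
    """
    if not 0 <= target_r <= 1:
        raise ValueError("target_r must be in [0, 1]")
    base = np.asarray(base_profile, dtype=float)
    if not np.all(np.isfinite(base)) or np.any(base <= 0):
        raise ValueError("base profile must be finite and positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.log2(base)
    dev = z - z.mean()
    sd = dev.std()
    if target_r == 1.0:
        return base.copy(), base.copy()
    noise = rng.normal(0.0, sd if sd > 0 else 1e-12, size=len(z))
    z2 = z.mean() + target_r * dev + math.sqrt(1.0 - target_r**2) * noise
    return base.copy(), np.power(2.0, z2)


def _base_profile(
    n_stages: int, rng: np.random.Generator, mean_log2: float, sd_log2: float = 0.6
) -> np.ndarray:
    return np.power(2.0, mean_log2 + rng.normal(0.0, sd_log2, size=n_stages))


# ---------------------------------------------------------------------------
# Family history
# ---------------------------------------------------------------------------


@dataclass
class _Copy:
    """One ancestral-copy lineage within a locus."""

    name: str
    focal_tips: list[str] = field(default_factory=list)  # surviving focal genes
    ls_pair: tuple[str, str] | None = None  # post-speciation tandem pair
    dispersed: str | None = None
    outgroup_tip: str | None = None
    focal_order: list[str] = field(default_factory=list)  # array placement order


def _pair_key(g1: str, g2: str) -> str:
    return "|".join(sorted((g1, g2)))


def simulate_family(params: SimulationParams | None = None) -> SimulatedFamily:
    """Run the forward simulation; deterministic under ``params.rng_seed``."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.rng_seed)

    # --- history -----------------------------------------------------------
    loci: list[list[_Copy]] = []
    truth_clusters: list[list[str]] = []
    gene_type: dict[str, str] = {}
    pair_ks: dict[str, float] = {}
    pair_omega: dict[str, float] = {}
    pair_class: dict[str, str] = {}

    for locus_idx in range(params.n_ancestral_genes):
        pre_dup = rng.random() < params.p_tandem_before_speciation
        copies = []
        for copy_idx in range(2 if pre_dup else 1):
            cname = f"L{locus_idx:02d}{'ab'[copy_idx]}"
            copy = _Copy(name=cname)
            # outgroup descendant
            if rng.random() >= params.gene_loss_rate:
                copy.outgroup_tip = f"og_{cname}"
            # focal descendants
            post_dup = rng.random() < params.p_tandem_after_speciation
            dispersed = rng.random() < params.p_dispersed_after_speciation
            focal_base = f"fv_{cname}"
            if post_dup:
                tips = [f"{focal_base}1", f"{focal_base}2"]
                copy.ls_pair = (tips[0], tips[1])
            else:
                tips = [focal_base]
            if dispersed:
                copy.dispersed = f"{focal_base}d"
                tips.append(copy.dispersed)
            survivors = [t for t in tips if rng.random() >= params.gene_loss_rate]
            copy.focal_tips = survivors
            copy.focal_order = [t for t in survivors if t != copy.dispersed]
            copies.append(copy)
        loci.append(copies)

    all_focal = [t for copies in loci for c in copies for t in c.focal_tips]
    all_outgroup = [
        c.outgroup_tip for copies in loci for c in copies if c.outgroup_tip
    ]
    if not all_focal or not all_outgroup:
        raise ValueError(
            "parameter combination produced no surviving family genes in one species"
        )

    # --- true clusters and gene types -------------------------------------
    for copies in loci:
        for c in copies:
            if len(c.focal_tips) >= 2:
                truth_clusters.append(sorted(c.focal_tips))
    in_cluster = {g for cl in truth_clusters for g in cl}
    for g in all_focal:
        gene_type[g] = "I" if g in in_cluster else "II"

    # --- placement: focal and outgroup genomes ----------------------------
    focal_arrays: list[list[str]] = []
    outgroup_arrays: list[list[str]] = []
    focal_slots: list[tuple[list[str], str]] = []  # (adjacent genes, kind)
    outgroup_slots: list[list[str]] = []
    for copies in loci:
        focal_array = []
        out_array = []
        for c in copies:
            focal_array.extend(c.focal_order)
            if c.outgroup_tip:
                out_array.append(c.outgroup_tip)
        if focal_array:
            focal_slots.append((focal_array, "array"))
            if len(focal_array) >= 2:
                focal_arrays.append(list(focal_array))
        if out_array:
            outgroup_slots.append(out_array)
            if len(out_array) >= 2:
                outgroup_arrays.append(list(out_array))
        for c in copies:
            if c.dispersed and c.dispersed in c.focal_tips:
                focal_slots.append(([c.dispersed], "dispersed"))

    # --- true tandem classes ----------------------------------------------
    cluster_of: dict[str, set[str]] = {}
    for cl in truth_clusters:
        for g in cl:
            cluster_of[g] = set(cl)
    array_of: dict[str, list[str]] = {}
    for arr in focal_arrays:
        for g in arr:
            array_of[g] = arr
    tandem_class: dict[str, str] = {}
    for g in all_focal:
        arr = array_of.get(g)
        if arr is None:
            tandem_class[g] = "none"
            continue
        partners = [p for p in arr if p != g]
        own = cluster_of.get(g, set())
        is_ls = any(p in own for p in partners)
        is_anc = gene_type[g] == "II" or any(p not in own for p in partners)
        tandem_class[g] = (
            "both" if (is_ls and is_anc) else "lineage_specific" if is_ls else "ancestral"
        )

    # --- sequences along the true tree -------------------------------------
    cds: dict[str, str] = {}
    newick_loci: list[str] = []
    for copies in loci:
        root_seq = random_cds(params.n_codons, rng)
        copy_subtrees = []
        for c in copies:
            branch_anc = params.ks_ancestral_duplication / 2 if len(copies) == 2 else 0.0
            copy_seq = evolve_codon_sequence(
                root_seq, branch_anc, params.omega_ancestral, rng
            )
            if c.outgroup_tip:
                cds[c.outgroup_tip] = evolve_codon_sequence(
                    copy_seq, params.ks_speciation / 2, params.omega_ancestral, rng
                )
            focal_base_seq = evolve_codon_sequence(
                copy_seq, params.ks_speciation / 2, params.omega_ancestral, rng
            )
            tip_nodes = []
            if c.ls_pair:
                pair_nodes = []
                for tip in c.ls_pair:
                    seq = evolve_codon_sequence(
                        focal_base_seq,
                        params.ks_lineage_specific / 2,
                        params.omega_lineage_specific,
                        rng,
                    )
                    if tip in c.focal_tips:
                        cds[tip] = seq
                        pair_nodes.append(
                            f"{tip}:{params.ks_lineage_specific / 2:.4f}"
                        )
                if len(pair_nodes) == 2:
                    tip_nodes.append(f"({pair_nodes[0]},{pair_nodes[1]}):0.01")
                else:
                    tip_nodes.extend(pair_nodes)
            else:
                base_tip = f"fv_{c.name}"
                if base_tip in c.focal_tips:
                    cds[base_tip] = focal_base_seq
                    tip_nodes.append(f"{base_tip}:0.01")
            if c.dispersed:
                seq = evolve_codon_sequence(
                    focal_base_seq,
                    params.ks_lineage_specific / 2,
                    params.omega_lineage_specific,
                    rng,
                )
                if c.dispersed in c.focal_tips:
                    cds[c.dispersed] = seq
                    tip_nodes.append(
                        f"{c.dispersed}:{params.ks_lineage_specific / 2:.4f}"
                    )
            # focal clade node
            if len(tip_nodes) > 1:
                focal_node = f"({','.join(tip_nodes)}):{params.ks_speciation / 2:.4f}"
            elif len(tip_nodes) == 1:
                focal_node = _extend_branch(tip_nodes[0], params.ks_speciation / 2)
            else:
                focal_node = None
            out_node = (
                f"{c.outgroup_tip}:{params.ks_speciation / 2:.4f}"
                if c.outgroup_tip
                else None
            )
            kids = [n for n in (focal_node, out_node) if n]
            if not kids:
                continue
            if len(kids) == 2:
                copy_subtrees.append(
                    f"({kids[0]},{kids[1]}):{params.ks_ancestral_duplication / 2:.4f}"
                )
            else:
                copy_subtrees.append(
                    _extend_branch(kids[0], params.ks_ancestral_duplication / 2)
                )
        if len(copy_subtrees) == 2:
            newick_loci.append(f"({copy_subtrees[0]},{copy_subtrees[1]}):0.5")
        elif len(copy_subtrees) == 1:
            newick_loci.append(_extend_branch(copy_subtrees[0], 0.5))

    # caterpillar backbone over loci
    tree = newick_loci[0]
    for sub in newick_loci[1:]:
        tree = f"({tree},{sub}):0.3"
    newick = tree.rsplit(":", 1)[0] + ";"

    proteins = {g: translate_cds(s) for g, s in cds.items()}

    # --- truth pair statistics ---------------------------------------------
    for copies in loci:
        for c in copies:
            if c.ls_pair and all(t in c.focal_tips for t in c.ls_pair):
                k = _pair_key(*c.ls_pair)
                pair_ks[k] = params.ks_lineage_specific
                pair_omega[k] = params.omega_lineage_specific
                pair_class[k] = "lineage_specific"
        if len(copies) == 2:
            for g1 in copies[0].focal_order:
                for g2 in copies[1].focal_order:
                    k = _pair_key(g1, g2)
                    pair_ks[k] = (
                        params.ks_ancestral_duplication + params.ks_speciation
                    )
                    pair_omega[k] = params.omega_ancestral
                    pair_class[k] = "ancestral"

    # --- genome layout ------------------------------------------------------
    focal_records = _layout_genome(
        focal_slots, params, rng, chrom_prefix="fc", filler_prefix="fvfill",
        cds=cds,
    )
    outgroup_records = _layout_genome(
        [(arr, "array") for arr in outgroup_slots],
        params, rng, chrom_prefix="oc", filler_prefix="ogfill", cds=cds,
    )

    # --- expression ---------------------------------------------------------
    profiles: dict[str, np.ndarray] = {}
    pair_expr_r: dict[str, float] = {}
    for copies in loci:
        locus_anchor: str | None = None
        for c in copies:
            members = [
                t
                for t in c.focal_order + ([c.dispersed] if c.dispersed else [])
                if t in c.focal_tips
            ]
            if not members:
                continue
            low = bool(c.ls_pair)  # recent duplicates tend to low expression
            anchor = members[0]
            if locus_anchor is None:
                mean_log2 = rng.uniform(-2.0, 0.5) if low else rng.uniform(2.0, 6.0)
                profiles[anchor] = _base_profile(params.n_stages, rng, mean_log2)
                locus_anchor = anchor
            else:
                # second ancestral copy: correlate with the first at the
                # ancestral target
                _, p2 = simulate_expression_pair(
                    profiles[locus_anchor], params.corr_ancestral, rng
                )
                profiles[anchor] = p2
                pair_expr_r[_pair_key(locus_anchor, anchor)] = params.corr_ancestral
            for tip in members[1:]:
                _, p2 = simulate_expression_pair(
                    profiles[anchor], params.corr_lineage_specific, rng
                )
                profiles[tip] = p2
                pair_expr_r[_pair_key(anchor, tip)] = params.corr_lineage_specific
    expression = ExpressionMatrix(
        pd.DataFrame(
            {f"stage{i + 1:02d}": [profiles[g][i] for g in sorted(profiles)]
             for i in range(params.n_stages)},
            index=sorted(profiles),
        )
    )

    # --- motif architectures -------------------------------------------------
    motifs: dict[str, MotifArchitecture] = {}
    motif_pool = [f"m{i}" for i in range(5, 16)]
    for copies in loci:
        core = ["m1", "m2", "m3", "m4"]
        extra = [m for m in motif_pool if rng.random() < 0.35]
        base_arch = core + extra
        for c in copies:
            copy_arch = _perturb_motifs(
                base_arch, rng, n_changes=int(rng.integers(0, 4)), pool=motif_pool
            ) if len(copies) == 2 else list(base_arch)
            for tip in c.focal_tips:
                if c.ls_pair and tip in c.ls_pair and tip != c.ls_pair[0]:
                    arch = _perturb_motifs(
                        copy_arch, rng,
                        n_changes=int(rng.choice([0, 1, 2], p=[0.5, 0.3, 0.2])),
                        pool=motif_pool,
                    )
                else:
                    arch = list(copy_arch)
                motifs[tip] = MotifArchitecture(
                    gene_id=tip,
                    motifs=tuple(arch),
                    starts=tuple(10 + 55 * i for i in range(len(arch))),
                )

    species_map = {g: FOCAL for g in all_focal}
    species_map.update({g: OUTGROUP for g in all_outgroup})

    truth = SyntheticTruth(
        gene_type=gene_type,
        tandem_class=tandem_class,
        clusters=sorted(truth_clusters),
        arrays_focal=sorted(focal_arrays),
        arrays_outgroup=sorted(outgroup_arrays),
        pair_ks=pair_ks,
        pair_omega=pair_omega,
        pair_class=pair_class,
        pair_expr_r=pair_expr_r,
        n_focal_genes=len(all_focal),
        n_outgroup_genes=len(all_outgroup),
    )
    return SimulatedFamily(
        params=params,
        focal_genes=focal_records,
        outgroup_genes=outgroup_records,
        cds=cds,
        proteins=proteins,
        newick=newick,
        species_map=species_map,
        expression=expression,
        motifs=motifs,
        truth=truth,
    )


def _extend_branch(node: str, extra: float) -> str:
    """Lengthen the root branch of a newick fragment (unary-node collapse)."""
    head, length = node.rsplit(":", 1)
    return f"{head}:{float(length) + extra:.4f}"


def _perturb_motifs(
    arch: list[str], rng: np.random.Generator, n_changes: int, pool: list[str]
) -> list[str]:
    out = list(arch)
    for _ in range(n_changes):
        removable = [m for m in out if m not in ("m1", "m2", "m3", "m4")]
        addable = [m for m in pool if m not in out]
        if removable and (not addable or rng.random() < 0.5):
            out.remove(removable[int(rng.integers(len(removable)))])
        elif addable:
            out.append(addable[int(rng.integers(len(addable)))])
    order = {f"m{i}": i for i in range(1, 16)}
    out.sort(key=lambda m: order[m])
    return out


def _layout_genome(
    slots: list[tuple[list[str], str]],
    params: SimulationParams,
    rng: np.random.Generator,
    chrom_prefix: str,
    filler_prefix: str,
    cds: dict[str, str],
) -> list[GeneRecord]:
    """Place family arrays and filler genes along chromosomes.

    Arrays occupy consecutive positions with 200–20000 bp gaps and 0–3
    fillers between adjacent members; slots are separated by >100 kb of
    filler-populated spacer so the tandem pair rule never bridges them.
    """
    cursors = {f"{chrom_prefix}{i + 1}": 50_000 for i in range(params.n_chromosomes)}
    chroms = sorted(cursors)
    records: list[GeneRecord] = []
    filler_count = 0

    def add_filler(chrom: str, start: int) -> int:
        nonlocal filler_count
        filler_count += 1
        length = int(rng.integers(500, 3000))
        records.append(
            GeneRecord(
                gene_id=f"{filler_prefix}{filler_count:05d}",
                chromosome=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                exons=((start, start + length),),
                is_family_member=False,
            )
        )
        return start + length

    def add_family_gene(gene_id: str, chrom: str, start: int) -> int:
        cds_len = len(cds[gene_id])
        if rng.random() < 0.25:
            n_introns = int(rng.integers(1, 4))
        else:
            n_introns = 0
        cuts = sorted(rng.choice(range(30, cds_len - 30), size=n_introns, replace=False)) if n_introns else []
        exons = []
        pos = start
        prev = 0
        for cut in list(cuts) + [cds_len]:
            exon_len = cut - prev
            exons.append((pos, pos + exon_len - 1))
            pos += exon_len + (int(rng.integers(100, 1000)) if cut != cds_len else 0)
            prev = cut
        end = exons[-1][1]
        records.append(
            GeneRecord(
                gene_id=gene_id,
                chromosome=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons),
                is_family_member=True,
            )
        )
        return end

    for slot_idx, (members, _kind) in enumerate(slots):
        chrom = chroms[slot_idx % len(chroms)]
        pos = cursors[chrom]
        for i, gene_id in enumerate(members):
            if i > 0:
                gap = int(rng.integers(200, 20_001))
                n_fill = int(rng.integers(0, 4))
                seg = gap // (n_fill + 1)
                for _ in range(n_fill):
                    fill_start = pos + max(50, seg // 4)
                    fill_end = add_filler(chrom, fill_start)
                    pos = fill_end
                pos = pos + max(100, gap // (n_fill + 1))
            end = add_family_gene(gene_id, chrom, pos)
            pos = end + 1
        # inter-slot spacer: far larger than the pair-rule distance
        spacing = int(rng.integers(150_000, 300_000))
        n_fill = rng.poisson(params.intervening_per_10kb * spacing / 10_000)
        for _ in range(int(n_fill)):
            fill_start = pos + int(rng.integers(2_000, max(3_000, spacing // max(1, n_fill))))
            pos = add_filler(chrom, fill_start)
        cursors[chrom] = pos + spacing
    records.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return records
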