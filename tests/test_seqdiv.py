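import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from tandemdiv.seqdiv import (
    BASES,
    STOP_CODONS,
    backtranslate_alignment,
    codon_pair_differences,
    jukes_cantor,
    ng86_ka_ks,
    ng86_sites,
    pairwise_pi,
)
from tandemdiv.simulate import evolve_codon_sequence, random_cds

SENSE_CODONS = [
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
]


def _aa(codon):
    return str(Seq(codon).translate())


# --- independent oracles ----------------------------------------------------


def oracle_sites(codon):
    """Enumerate all 9 single-nucleotide changes; stops are nonsynonymous."""
    syn = 0.0
    for pos, b in itertools.product(range(3), BASES):
        if b == codon[pos]:
            continue
        mut = codon[:pos] + b + codon[pos + 1 :]
        if mut not in STOP_CODONS and _aa(mut) == _aa(codon):
            syn += 1 / 3
    return syn, 3 - syn


def oracle_pathways(c1, c2):
    """Exhaustive pathway enumeration for Sd/Nd of one codon pair."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return None
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


# --- tests -------------------------------------------------------------------


class TestBacktranslate:
    def test_gap_becomes_triple_dash(self):
        aln = backtranslate_alignment({"g": "M-K"}, {"g": "ATGAAA"})
        assert aln.rows == ["ATG---AAA"]

    def test_terminal_stop_stripped(self):
        aln = backtranslate_alignment({"g": "MK"}, {"g": "ATGAAATGA"})
        assert aln.rows == ["ATGAAA"]

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            backtranslate_alignment({"g": "M*K"}, {"g": "ATGTAAAAA"})

    def test_mismatch_names_gene_and_position(self):
        with pytest.raises(ValueError, match="g1.*position 2"):
            backtranslate_alignment({"g1": "MW"}, {"g1": "ATGAAA"})

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            backtranslate_alignment({"g": "MKK"}, {"g": "ATGAAA"})

    def test_simulated_round_trip(self, sim_family):
        prot = sim_family.proteins
        aln = backtranslate_alignment(prot, sim_family.cds)
        for gene_id, row in zip(aln.gene_ids, aln.rows):
            assert str(Seq(row.replace("-", "")).translate()) == prot[gene_id]


class TestPairwisePi:
    def test_identical_rows_zero(self):
        assert pairwise_pi("ATGAAA", "ATGAAA") == 0.0

    def test_single_difference(self):
        assert pairwise_pi("ATGAAA", "ATGAAG") == pytest.approx(1 / 6)

    def test_gapped_sites_excluded(self):
        assert pairwise_pi("ATG---AAA", "ATGCCCAAG") == pytest.approx(1 / 6)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            pairwise_pi("ATG", "ATGAAA")

    def test_matches_per_site_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            r1 = "".join(rng.choice(list(BASES), n))
            r2 = "".join(rng.choice(list(BASES), n))
            expected = sum(a != b for a, b in zip(r1, r2)) / n
            assert pairwise_pi(r1, r2) == pytest.approx(expected)


class TestNg86Sites:
    def test_phenylalanine_codon(self):
        assert ng86_sites("TTT") == pytest.approx((1 / 3, 8 / 3))

    def test_methionine_codon(self):
        assert ng86_sites("ATG") == pytest.approx((0.0, 3.0))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_sites("TAA")

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_conservation_and_oracle(self, codon):
        syn, nonsyn = ng86_sites(codon)
        assert syn + nonsyn == pytest.approx(3.0, abs=1e-12)
        assert (syn, nonsyn) == pytest.approx(oracle_sites(codon))


class TestCodonPairDifferences:
    def test_matches_pathway_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            c1, c2 = rng.choice(SENSE_CODONS, 2)
            assert codon_pair_differences(c1, c2) == (
                pytest.approx(oracle_pathways(c1, c2))
                if oracle_pathways(c1, c2) is not None
                else None
            )

    def test_stop_blocked_pathways_reweighted(self):
        # TTA (Leu) <-> TAT (Tyr): path through TAA (stop) is excluded,
        # leaving the single pathway TTA -> TTT? no: positions 2,3 differ;
        # orders: pos2 first gives TAA (stop, blocked); pos3 first gives
        # TTT (Phe) then TAT -> both steps nonsynonymous.
        assert codon_pair_differences("TTA", "TAT") == pytest.approx((0.0, 2.0))


class TestNg86KaKs:
    def test_identical_sequences(self):
        seq = "ATGAAATTTGGG"
        r = ng86_ka_ks(seq, seq)
        assert (r.ka, r.ks) == (0.0, 0.0)
        assert r.ka_ks is None

    def test_single_synonymous_change(self):
        rng = np.random.default_rng(1)
        seq = random_cds(100, rng)
        # synonymous third-position change: GGx family (Gly) is fourfold
        mutated = None
        for i in range(0, 300, 3):
            codon = seq[i : i + 3]
            if codon[:2] in {"GG", "CC", "TC", "AC", "GC", "GT", "CG", "CT"}:
                alt = "A" if codon[2] != "A" else "G"
                mutated = seq[:i] + codon[:2] + alt + seq[i + 3 :]
                break
        assert mutated is not None
        r = ng86_ka_ks(seq, mutated)
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        assert r.ka == 0.0
        assert r.ks > 0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = random_cds(50, rng)
        b = evolve_codon_sequence(a, 0.4, 0.5, rng)
        r1, r2 = ng86_ka_ks(a, b), ng86_ka_ks(b, a)
        for attr in ("pi", "S", "N", "Sd", "Nd", "ks", "ka", "ka_ks"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr))

    def test_site_conservation(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = random_cds(60, rng)
            b = evolve_codon_sequence(a, 0.3, 0.3, rng)
            r = ng86_ka_ks(a, b)
            assert r.S + r.N == pytest.approx(3 * r.n_codons, abs=1e-9)

    def test_gapped_codons_pairwise_deleted(self):
        r = ng86_ka_ks("ATG---AAA", "ATGCCCAAA")
        assert r.n_codons == 2

    def test_no_comparable_codons_error(self):
        with pytest.raises(ValueError, match="comparable"):
            ng86_ka_ks("---", "ATG")

    def test_saturation_returns_na(self):
        assert jukes_cantor(0.8) is None
        assert jukes_cantor(0.1) == pytest.approx(
            -0.75 * math.log(1 - 0.4 / 3)
        )

    def test_agrees_with_biopython_reference(self):
        """Independent cross-check against Bio.codonalign's NG86."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(9)
        for _ in range(5):
            a = random_cds(200, rng)
            b = evolve_codon_sequence(a, 0.2, 0.3, rng)
            mine = ng86_ka_ks(a, b)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert mine.ka == pytest.approx(dn, abs=2e-3)
            assert mine.ks == pytest.approx(ds, abs=2e-3)


class TestParameterRecovery:
    def test_ks_monotone_in_divergence_time(self):
        rng = np.random.default_rng(23)
        means = []
        for ks_target in (0.05, 0.2, 0.5):
            vals = []
            for _ in range(30):
                a = random_cds(300, rng)
                b = evolve_codon_sequence(a, ks_target, 0.3, rng)
                vals.append(ng86_ka_ks(a, b).ks)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
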