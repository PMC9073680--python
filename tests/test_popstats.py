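"""Degeneracy classes, effect annotation, pN/pS, pi and Tajima's D."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hornscan import polarize as pol
from hornscan.containers import GeneModel, revcomp
from hornscan.popstats import (
    FOUR_FOLD,
    MISSENSE,
    NON_CODING,
    OTHER,
    STOP_GAIN,
    STOP_LOSS,
    SYNONYMOUS,
    ZERO_FOLD,
    annotate_effect,
    classify_degeneracy,
    codon_degeneracy,
    degeneracy_map,
    gene_polymorphism,
    pi_and_tajimas_d,
    tajima_constants,
    translate_codon,
)

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


class TestCodonDegeneracy:
    def test_forced_examples(self):
        assert codon_degeneracy("GGG", 2) == FOUR_FOLD
        for p in range(3):
            assert codon_degeneracy("ATG", p) == ZERO_FOLD

    def test_thirty_two_codons_have_fourfold_third_position(self):
        """Enumeration of the standard table: exactly 32 of 64 codons are
        4-fold degenerate at the third position."""
        codons = ["".join(c) for c in itertools.product(BASES, repeat=3)]
        n4 = sum(codon_degeneracy(c, 2) == FOUR_FOLD for c in codons)
        assert n4 == 32

    def test_degeneracy_against_translation_oracle(self):
        """Class of every codon position agrees with direct counting of
        amino-acid-changing substitutions."""
        for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
            for p in range(3):
                aa = translate_codon(codon)
                changed = sum(
                    translate_codon(codon[:p] + b + codon[p + 1 :]) != aa
                    for b in BASES
                    if b != codon[p]
                )
                expected = (
                    FOUR_FOLD if changed == 0 else
                    ZERO_FOLD if changed == 3 else OTHER
                )
                assert codon_degeneracy(codon, p) == expected


def _make_gene_reference(cds, strand="+", pad=10):
    """Place a CDS (given in mRNA orientation) on a padded scaffold."""
    insert = cds if strand == "+" else revcomp(cds)
    seq = "A" * pad + insert + "A" * pad
    gene = GeneModel("g1", "s", strand, ((pad, pad + len(cds)),))
    return gene, {"s": seq}


class TestClassifyDegeneracy:
    def test_minus_strand_matches_plus_strand_classes(self):
        cds = "ATGGGGCCTTAA"
        plus_gene, plus_ref = _make_gene_reference(cds, "+")
        minus_gene, minus_ref = _make_gene_reference(cds, "-")
        dplus, _ = classify_degeneracy([plus_gene], plus_ref)
        dminus, _ = classify_degeneracy([minus_gene], minus_ref)
        # compare in translation order (plus: ascending; minus: descending)
        key = ["codon", "codon_pos", "degeneracy"]
        assert dplus.sort_values(["pos"])[key].to_numpy().tolist() == (
            dminus.sort_values("pos", ascending=False)[key].to_numpy().tolist()
        )

    def test_invalid_cds_flagged_and_excluded(self):
        bad_len, ref1 = _make_gene_reference("ATGGGTA")  # not divisible by 3
        internal_stop, ref2 = _make_gene_reference("ATGTAAGGGTAA")
        df, flagged = classify_degeneracy([bad_len], ref1)
        assert flagged == ["g1"] and df.empty
        df, flagged = classify_degeneracy([internal_stop], ref2)
        assert flagged == ["g1"] and df.empty

    def test_conflicting_overlaps_collapse_to_other(self):
        # two genes sharing positions in different reading frames
        g1 = GeneModel("a", "s", "+", ((10, 22),))
        g2 = GeneModel("b", "s", "+", ((14, 26),))
        ref = {"s": "A" * 10 + "ATGGGGGGGGGGTAAA" + "A" * 10}
        per_gene, flagged = classify_degeneracy([g1, g2], ref)
        assert flagged == []
        site_map = degeneracy_map(per_gene)
        dup = per_gene.groupby(["scaffold", "pos"])["degeneracy"].nunique()
        conflict_pos = dup[dup > 1].index
        assert len(conflict_pos) > 0
        merged = site_map.set_index(["scaffold", "pos"])
        for key in conflict_pos:
            assert merged.loc[key, "degeneracy"] == OTHER


class TestAnnotateEffect:
    def test_stop_loss_at_terminal_stop(self):
        gene, ref = _make_gene_reference("ATGGGGTAA")
        ann = annotate_effect("s", 18, "A", "C", [gene], ref)[0]
        assert ann.effect == STOP_LOSS
        assert (ann.codon_ref, ann.codon_alt) == ("TAA", "TCA")

    def test_synonymous_change(self):
        gene, ref = _make_gene_reference("ATGGGATAA")
        # GGA -> GGG at codon 2, third position (pos 16, 1-based)
        ann = annotate_effect("s", 16, "A", "G", [gene], ref)[0]
        assert ann.effect == SYNONYMOUS

    def test_outside_gene_is_non_coding(self):
        gene, ref = _make_gene_reference("ATGGGATAA")
        ann = annotate_effect("s", 2, "A", "C", [gene], ref)[0]
        assert ann.effect == NON_CODING and ann.gene_id is None

    def test_reference_mismatch_rejected(self):
        gene, ref = _make_gene_reference("ATGGGATAA")
        with pytest.raises(ValueError, match="reference base"):
            annotate_effect("s", 11, "C", "G", [gene], ref)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_full_enumeration_matches_translate_oracle(self, rng, strand):
        """Every possible SNP in a random toy gene annotates identically to
        a brute-force translate-and-compare oracle."""
        sense = [
            c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
            if c not in STOPS
        ]
        body = "".join(rng.choice(sense, size=40))
        cds = "ATG" + body + "TAA"
        gene, ref = _make_gene_reference(cds, strand)
        start = gene.exons[0][0]
        for offset in range(len(cds)):
            pos = start + offset + 1  # genomic 1-based
            ref_base = ref["s"][pos - 1]
            for alt in BASES:
                if alt == ref_base:
                    continue
                ann = annotate_effect("s", pos, ref_base, alt, [gene], ref)[0]
                # oracle: substitute in the genome, retranslate the CDS
                mutated = dict(ref)
                mutated["s"] = ref["s"][: pos - 1] + alt + ref["s"][pos:]
                before = gene.cds_sequence(ref)
                after = gene.cds_sequence(mutated)
                aa_before = [translate_codon(before[i:i+3]) for i in range(0, len(before), 3)]
                aa_after = [translate_codon(after[i:i+3]) for i in range(0, len(after), 3)]
                diffs = [
                    (a, b) for a, b in zip(aa_before, aa_after) if a != b
                ]
                if not diffs:
                    expected = SYNONYMOUS
                elif diffs[0][1] == "*":
                    expected = STOP_GAIN
                elif diffs[0][0] == "*":
                    expected = STOP_LOSS
                else:
                    expected = MISSENSE
                assert ann.effect == expected, (offset, ref_base, alt)


class TestGenePolymorphism:
    def _degeneracy(self, gene_id, n_zero, n_four):
        rows = [(gene_id, "s", i + 1, "+", "NNN", 0, ZERO_FOLD) for i in range(n_zero)]
        rows += [
            (gene_id, "s", 1000 + i, "+", "NNN", 2, FOUR_FOLD)
            for i in range(n_four)
        ]
        return pd.DataFrame(
            rows,
            columns=["gene_id", "scaffold", "pos", "strand", "codon",
                     "codon_pos", "degeneracy"],
        )

    def _effects(self, gene_id, n_nonsyn, n_syn):
        rows = [("s", i + 1, gene_id, MISSENSE, None, None) for i in range(n_nonsyn)]
        rows += [
            ("s", 1000 + i, gene_id, SYNONYMOUS, None, None) for i in range(n_syn)
        ]
        return pd.DataFrame(
            rows,
            columns=["scaffold", "pos", "gene_id", "effect", "codon_ref",
                     "codon_alt"],
        )

    def test_gene_without_snps_is_zero(self):
        out = gene_polymorphism(
            self._effects("g", 0, 0), self._degeneracy("g", 100, 40)
        )
        assert out.loc[0, "pN"] == 0.0 and out.loc[0, "pS"] == 0.0
        assert np.isnan(out.loc[0, "pn_ps"])

    def test_toy_counts_match_hand_tally(self):
        """6 nonsynonymous and 10 synonymous SNPs over 300 zero-fold and
        120 four-fold positions."""
        out = gene_polymorphism(
            self._effects("g", 6, 10), self._degeneracy("g", 300, 120)
        )
        assert out.loc[0, "pN"] == pytest.approx(6 / 300)
        assert out.loc[0, "pS"] == pytest.approx(10 / 120)
        assert out.loc[0, "pn_ps"] == pytest.approx((6 / 300) / (10 / 120))

    def test_doubling_snps_doubles_rates(self):
        deg = self._degeneracy("g", 300, 120)
        single = gene_polymorphism(self._effects("g", 6, 10), deg)
        double = gene_polymorphism(self._effects("g", 12, 20), deg)
        assert double.loc[0, "pN"] == pytest.approx(2 * single.loc[0, "pN"])
        assert double.loc[0, "pS"] == pytest.approx(2 * single.loc[0, "pS"])


class TestEffectDegeneracyConsistency:
    def test_zero_fold_snps_nonsynonymous_four_fold_synonymous(self, rng):
        """Mutual consistency on a random gene: every SNP at a 0-fold site
        changes the protein; every SNP at a 4-fold site does not."""
        sense = [
            c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
            if c not in STOPS
        ]
        cds = "ATG" + "".join(rng.choice(sense, size=30)) + "TAA"
        gene, ref = _make_gene_reference(cds)
        per_gene, _ = classify_degeneracy([gene], ref)
        for row in per_gene.itertuples(index=False):
            ref_base = ref["s"][row.pos - 1]
            for alt in BASES:
                if alt == ref_base:
                    continue
                eff = annotate_effect("s", row.pos, ref_base, alt, [gene], ref)[0]
                if row.degeneracy == ZERO_FOLD:
                    assert eff.effect in {MISSENSE, STOP_GAIN, STOP_LOSS}
                elif row.degeneracy == FOUR_FOLD:
                    assert eff.effect == SYNONYMOUS


class TestPiAndTajimasD:
    def test_no_segregation_reports_zero(self):
        pi, s, d = pi_and_tajimas_d(np.array([0.0, 1.0, 0.0]), n=16)
        assert (pi, s, d) == (0.0, 0, 0.0)

    def test_single_site_heterozygosity(self):
        # p = 0.5, n = 16: per-site pi = 0.5 * 16/15
        pi, s, _ = pi_and_tajimas_d(np.array([0.5]), n=16)
        assert s == 1
        assert pi == pytest.approx(0.5 * 16 / 15)

    def test_pi_invariant_to_allele_relabeling(self, rng):
        freqs = rng.uniform(0, 1, 50)
        pi1, _, _ = pi_and_tajimas_d(freqs, n=20)
        pi2, _, _ = pi_and_tajimas_d(1 - freqs, n=20)
        assert pi1 == pytest.approx(pi2)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pi_and_tajimas_d(np.array([0.5]), n=3)

    def test_constants_match_direct_sums(self):
        n = 10
        c = tajima_constants(n)
        assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, n)))
        assert c["b1"] == pytest.approx((n + 1) / (3 * (n - 1)))

    def test_null_mean_near_zero(self, rng):
        """Monte-Carlo under the neutral frequency spectrum (site counts
        proportional to 1/k): mean D over 200 replicates within +/-0.15."""
        n, s_sites, reps = 16, 60, 200
        weights = 1 / np.arange(1, n)
        weights /= weights.sum()
        ds = []
        for _ in range(reps):
            ks = rng.choice(np.arange(1, n), size=s_sites, p=weights)
            _, _, d = pi_and_tajimas_d(ks / n, n)
            ds.append(d)
        assert abs(np.mean(ds)) <= 0.15


class TestDirectionalSelectionSignal:
    def _summary(self, suppression, seed=3):
        from hornscan.containers import Scaffold
        from hornscan.popstats import population_summary
        from hornscan.simulate import (
            GenePlacement,
            PopulationSpec,
            SimConfig,
            simulate_dataset,
        )

        genes = [
            GenePlacement(f"g{i}", "s1", 10_000 + 12_000 * i,
                          "+" if i % 2 == 0 else "-", 3000)
            for i in range(30)
        ]
        cfg = SimConfig(
            populations=[PopulationSpec("A", 10, 10, 0)],
            scaffolds=[Scaffold("s1", 400_000, "1", False)],
            background_fst={},
            n_snps_per_scaffold=3000,
            inversions=[], genes=genes, pseudogene=None, seed=seed,
            zero_fold_suppression=suppression,
        )
        res = simulate_dataset(cfg)
        dec = pol.polarize_table(res.table, res.outgroup)
        return population_summary(res.table, dec, res.genes, res.reference, "A")

    def test_drift_only_pi0_matches_pi4(self):
        s = self._summary(suppression=1.0)
        assert s["pi_0"] == pytest.approx(s["pi_4"], rel=0.15)

    def test_frequency_suppression_depresses_pi0(self):
        s = self._summary(suppression=0.25)
        assert s["pi_0"] < 0.75 * s["pi_4"]
        assert s["tajimas_d_0"] < s["tajimas_d_4"]
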