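"""Variant-effect annotation, substitution classes, summaries and GO weighting."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from coraligv.annotation import load_annotation
from coraligv.effects import (
    annotate_effect,
    differing_snps,
    effect_table,
    go_weighting,
    occurrence_spectrum,
    substitution_type,
    summarise_effects,
)
from coraligv.genotypes import MISSING

from conftest import make_gm

# one plus-strand gene: M G Y *  (CDS 11..22)
FIXTURE_CDS = "ATGGGATACTAA"


@pytest.fixture(scope="module")
def tiny_ann(tmp_path_factory):
    d = tmp_path_factory.mktemp("eff")
    seq = "T" * 10 + FIXTURE_CDS + "G" * 10 + "C" * 8
    (d / "r.fa").write_text(">c\n" + seq + "\n")
    (d / "g.gff3").write_text(
        "##gff-version 3\n"
        "c\tt\tgene\t6\t27\t.\t+\t.\tID=g1\n"
        "c\tt\tmRNA\t6\t27\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        "c\tt\tCDS\t11\t22\t.\t+\t0\tID=g1.cds;Parent=g1.t1\n")
    return load_annotation(str(d / "g.gff3"), str(d / "r.fa"))


class TestSubstitutionType:
    @pytest.mark.parametrize("ref, alt, expected", [
        ("A", "G", "transition"), ("G", "A", "transition"),
        ("C", "T", "transition"), ("A", "C", "transversion"),
        ("G", "T", "transversion"), ("C", "G", "transversion"),
    ])
    def test_classes(self, ref, alt, expected):
        assert substitution_type(ref, alt) == expected

    def test_ratio_counting(self):
        subs = [("A", "G"), ("C", "T"), ("A", "C")]
        kinds = [substitution_type(*s) for s in subs]
        assert kinds.count("transition") == 2 and kinds.count("transversion") == 1

    @pytest.mark.parametrize("ref, alt", [("N", "A"), ("A", "A"), ("AG", "A")])
    def test_invalid_alleles_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            substitution_type(ref, alt)


class TestAnnotateEffect:
    def test_silent_third_position(self, tiny_ann):
        # codon GGA (pos 14..16) -> GGG, Gly -> Gly
        eff = annotate_effect(("c", 16), ("A", "G"), tiny_ann)
        assert eff.location == "coding" and eff.codon_position == 3
        assert eff.ref_codon == "GGA" and eff.alt_codon == "GGG"
        assert eff.effect == "silent"

    def test_nonsense_from_tyrosine(self, tiny_ann):
        # codon TAC (17..19) -> TAA, Tyr -> stop
        eff = annotate_effect(("c", 19), ("C", "A"), tiny_ann)
        assert eff.effect == "nonsense" and eff.codon_position == 3

    def test_missense_first_position(self, tiny_ann):
        # GGA -> AGA, Gly -> Arg
        eff = annotate_effect(("c", 14), ("G", "A"), tiny_ann)
        assert eff.effect == "missense" and eff.codon_position == 1

    def test_stop_loss_flagged_missense(self, tiny_ann):
        # stop codon TAA (20..22) -> TAT? position 22 A->T gives TAT (Tyr)
        eff = annotate_effect(("c", 22), ("A", "T"), tiny_ann)
        assert eff.effect == "missense" and eff.stop_loss

    def test_intergenic_site_has_no_effect(self, tiny_ann):
        eff = annotate_effect(("c", 3), ("T", "C"), tiny_ann)
        assert eff.location == "intergenic"
        assert eff.effect is None and eff.codon_position is None

    def test_genic_noncoding(self, tiny_ann):
        eff = annotate_effect(("c", 8), ("T", "G"), tiny_ann)
        assert eff.location == "genic_noncoding" and eff.gene_id == "g1"


class TestFullTranscriptOracle:
    def test_agrees_on_every_coding_site_both_strands(self, dataset):
        """Per-codon annotation equals mutating the whole transcript and
        translating the full protein, for every coding site on both strands."""
        ann = dataset.annotation
        contig = dataset.truth.sites["chrom"].iloc[0]
        seq = dataset.seqs[contig]
        strands = set()
        n_checked = 0
        for _, row in dataset.genotypes.sites.iterrows():
            pos, ref, alt = int(row["pos"]), row["ref"], row["alt"]
            eff = annotate_effect((contig, pos), (ref, alt), ann)
            if eff.location != "coding":
                continue
            sa = ann.classify(contig, pos)
            tr = ann.transcripts[sa.transcript_id]
            strands.add(tr.strand)
            mutseq = seq[:pos - 1] + alt + seq[pos:]

            def _protein(s):
                sp = "".join(s[a - 1:b] for a, b, _ in tr.segments)
                if tr.strand == "-":
                    sp = str(Seq(sp).reverse_complement())
                return str(Seq(sp[tr.phase0:]).translate())

            p_ref, p_alt = _protein(seq), _protein(mutseq)
            changed = [(a, b) for a, b in zip(p_ref, p_alt) if a != b]
            if not changed:
                expected = "silent"
            elif changed[0][1] == "*" and changed[0][0] != "*":
                expected = "nonsense"
            else:
                expected = "missense"
            assert eff.effect == expected, (pos, tr.strand)
            n_checked += 1
        assert n_checked > 100 and strands == {"+", "-"}


class TestDifferingSNPs:
    def _pairs(self, *pairs):
        return pd.DataFrame([{"colony_id": c, "sample_a": a, "sample_b": b,
                              "pair_type": t} for c, a, b, t in pairs])

    def test_single_allele_difference_detected(self):
        gm = make_gm([[0, 1], [0, 0], [2, MISSING]])
        diffs = differing_snps(gm, self._pairs(("C1", "S1", "S2", "mosaic")))
        assert len(diffs) == 1
        assert diffs["site_index"].iloc[0] == 0
        assert bool(diffs["single_allele_difference"].iloc[0])

    def test_occurrence_counts_distinct_colonies(self):
        gm = make_gm([[0, 1, 0, 1, 0, 1]],
                     sample_ids=["A1", "A2", "B1", "B2", "C1", "C2"])
        pairs = self._pairs(("CA", "A1", "A2", "chimeric"),
                            ("CB", "B1", "B2", "chimeric"),
                            ("CC", "C1", "C2", "chimeric"))
        occ = occurrence_spectrum(differing_snps(gm, pairs))
        assert occ["occurrence"].iloc[0] == 3

    def test_no_variation_no_differences(self):
        gm = make_gm([[1, 1], [0, 0]])
        diffs = differing_snps(gm, self._pairs(("C1", "S1", "S2", "mosaic")))
        assert diffs.empty

    def test_missing_genotype_not_a_difference(self):
        gm = make_gm([[MISSING, 2]])
        diffs = differing_snps(gm, self._pairs(("C1", "S1", "S2", "mosaic")))
        assert diffs.empty


class TestSummaries:
    def test_hand_built_five_snp_summary(self, tiny_ann):
        effects = pd.DataFrame({
            "site_index": range(5),
            "location": ["coding", "coding", "coding", "genic_noncoding", "intergenic"],
            "gene_id": ["g1", "g1", "g1", "g1", None],
            "substitution": ["transition"] * 4 + ["transversion"],
            "codon_position": [3, 3, 1, None, None],
            "effect": ["silent", "silent", "missense", None, None],
            "stop_loss": False,
            "n_differences": [4, 2, 2, 1, 1],
            "n_colonies": 1,
            "n_single_allele": [4, 2, 2, 1, 1],
        })
        s = summarise_effects(effects)
        assert s["n_snps"] == 5 and s["n_differences"] == 10
        assert s["coding_snp_fraction"] == pytest.approx(0.6)
        assert s["effect_by_snp"]["silent"]["percent"] == pytest.approx(100 * 2 / 3)
        assert s["effect_by_difference"]["silent"]["count"] == 6
        assert s["codon_position_by_difference"]["3"]["count"] == 6

    def test_conservation_of_coding_counts(self, dataset, filtered):
        """silent+missense+nonsense equals the coding SNP count, and the
        codon-position tally sums to the same total."""
        from coraligv.igv import enumerate_intra_colonial_pairs
        from coraligv.toy import toy_colony_structure  # noqa: F401 (structure below)

        pairs = []
        for colony, grp in dataset.meta.drop_duplicates("nubbin_id").groupby("colony_id"):
            s = sorted(grp["sample_id"])
            for i in range(len(s)):
                for j in range(i + 1, len(s)):
                    pairs.append({"colony_id": colony, "sample_a": s[i],
                                  "sample_b": s[j], "pair_type": "mosaic"})
        diffs = differing_snps(filtered, pd.DataFrame(pairs))
        effs = effect_table(filtered, diffs, dataset.annotation)
        coding = effs[effs["location"] == "coding"]
        assert len(coding) > 0
        assert coding["effect"].isin(["silent", "missense", "nonsense"]).all()
        assert coding["effect"].notna().all()
        assert coding["codon_position"].isin([1, 2, 3]).all()
        s = summarise_effects(effs)
        eff_total = sum(v["count"] for v in s["effect_by_snp"].values())
        pos_total = sum(v["count"] for v in s["codon_position_by_snp"].values())
        assert eff_total == pos_total == len(coding)

    def test_third_position_enriched_for_silent(self, dataset, filtered):
        """Codon degeneracy: random substitutions at third positions are
        silent more often than at first/second positions."""
        ann = dataset.annotation
        rates = {}
        for cpos in (1, 2, 3):
            n = silent = 0
            for _, row in dataset.genotypes.sites.iterrows():
                eff = annotate_effect((row["chrom"], int(row["pos"])),
                                      (row["ref"], row["alt"]), ann)
                if eff.location == "coding" and eff.codon_position == cpos:
                    n += 1
                    silent += eff.effect == "silent"
            rates[cpos] = silent / n
        assert rates[3] > rates[1] and rates[3] > rates[2]


class TestGOWeighting:
    def _effects(self, gene_counts):
        rows = []
        for i, (gene, n) in enumerate(gene_counts):
            rows.append({"site_index": i, "location": "coding", "gene_id": gene,
                         "effect": "missense", "n_differences": n,
                         "n_colonies": 1, "n_single_allele": n,
                         "substitution": "transition", "codon_position": 1,
                         "stop_loss": False})
        return pd.DataFrame(rows)

    def test_term_retained_at_min_count(self):
        g2g = pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:1"]})
        out = go_weighting(self._effects([("g1", 60)]), g2g, min_count=50)
        assert out.loc[0, "weight"] == 60 and bool(out.loc[0, "retained"])

    def test_term_filtered_below_min_count(self):
        g2g = pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:1"]})
        out = go_weighting(self._effects([("g1", 49)]), g2g, min_count=50)
        assert not bool(out.loc[0, "retained"])

    def test_shared_term_weights_add(self):
        g2g = pd.DataFrame({"gene_id": ["g1", "g2"], "go_id": ["GO:1", "GO:1"]})
        out = go_weighting(self._effects([("g1", 30), ("g2", 30)]), g2g)
        assert out.loc[0, "weight"] == 60 and out.loc[0, "n_genes"] == 2

    def test_silent_differences_do_not_count(self):
        effs = self._effects([("g1", 60)])
        effs.loc[0, "effect"] = "silent"
        g2g = pd.DataFrame({"gene_id": ["g1"], "go_id": ["GO:1"]})
        assert go_weighting(effs, g2g).empty

    def test_unannotated_genes_reported(self):
        g2g = pd.DataFrame({"gene_id": ["other"], "go_id": ["GO:1"]})
        out = go_weighting(self._effects([("g1", 10)]), g2g)
        assert out.attrs["unannotated_genes"] == ["g1"]
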