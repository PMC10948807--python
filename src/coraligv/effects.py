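"""Characterisation of SNPs that differ within colonies.

Each differing SNP is located against the annotation (intergenic /
genic-noncoding / coding), and coding SNPs are classified by codon position
and effect: the alternate base (strand-corrected) is substituted into the
reference codon and both codons are translated with the standard genetic
code.  Silent keeps the amino acid, nonsense turns a sense codon into a
stop, everything else is missense (a reference stop turning into a sense
codon — stop-loss — is counted missense and flagged).  Substitutions are
tallied as transitions (A<->G, C<->T) or transversions.  GO terms are
weighted by the non-silent allelic differences hitting their genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import Annotation
from .dissimilarity import DissimilarityMatrix  # noqa: F401  (typing context)
from .genotypes import MISSING, GenotypeMatrix

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class VariantEffect:
    """Effect annotation of one biallelic SNP."""

    chrom: str
    pos: int
    ref: str
    alt: str
    location: str                     # intergenic | genic_noncoding | coding
    gene_id: str | None
    substitution: str                 # transition | transversion
    codon_position: int | None = None  # 1..3, coding only
    effect: str | None = None          # silent | missense | nonsense, coding only
    ref_codon: str | None = None
    alt_codon: str | None = None
    stop_loss: bool = False


def substitution_type(ref: str, alt: str) -> str:
    """"transition" when both alleles are purines or both pyrimidines."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"alleles must be single bases in ACGT, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("REF and ALT must differ")
    same_class = ({ref, alt} <= _PURINES) or ({ref, alt} <= _PYRIMIDINES)
    return "transition" if same_class else "transversion"


def annotate_effect(site: tuple[str, int], alleles: tuple[str, str],
                    annotation: Annotation) -> VariantEffect:
    """Annotate one biallelic SNP (REF, ALT on the forward genomic strand)."""
    chrom, pos = site
    ref, alt = alleles
    sub = substitution_type(ref, alt)
    sa = annotation.classify(chrom, pos)
    if sa.location != "coding":
        return VariantEffect(chrom=chrom, pos=pos, ref=ref, alt=alt,
                             location=sa.location, gene_id=sa.gene_id,
                             substitution=sub)
    codon = sa.codon
    alt_base = alt.upper() if sa.strand == "+" else alt.upper().translate(_COMPLEMENT)
    idx = sa.codon_position - 1
    alt_codon = codon[:idx] + alt_base + codon[idx + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    stop_loss = False
    if aa_ref == aa_alt:
        effect = "silent"
    elif aa_alt == "*":
        effect = "nonsense"
    else:
        effect = "missense"
        stop_loss = aa_ref == "*"
    return VariantEffect(chrom=chrom, pos=pos, ref=ref, alt=alt, location="coding",
                         gene_id=sa.gene_id, substitution=sub,
                         codon_position=sa.codon_position, effect=effect,
                         ref_codon=codon, alt_codon=alt_codon, stop_loss=stop_loss)


def differing_snps(gm: GenotypeMatrix, pairs: pd.DataFrame) -> pd.DataFrame:
    """Sites with different allelic states within pairs of samples.

    ``pairs`` needs columns colony_id, sample_a, sample_b (and optionally
    pair_type).  A site differs for a pair when both genotypes are present
    and their dosages differ.  Returns a long frame with one row per
    (pair, differing site): colony_id, pair_type, sample_a, sample_b,
    site_index, n_allele_diff (1 or 2), single_allele_difference.
    """
    if pairs.empty:
        return pd.DataFrame(columns=["colony_id", "pair_type", "sample_a", "sample_b",
                                     "site_index", "n_allele_diff",
                                     "single_allele_difference"])
    idx = {s: i for i, s in enumerate(gm.sample_ids)}
    rows = []
    for _, pr in pairs.iterrows():
        ia, ib = idx[pr["sample_a"]], idx[pr["sample_b"]]
        ga, gb = gm.gt[:, ia], gm.gt[:, ib]
        both = (ga != MISSING) & (gb != MISSING)
        d = np.abs(ga.astype(np.int16) - gb.astype(np.int16))
        hits = np.flatnonzero(both & (d > 0))
        ptype = pr.get("pair_type", "unspecified")
        for s in hits:
            nd = int(d[s])
            rows.append((pr["colony_id"], ptype, pr["sample_a"], pr["sample_b"],
                         int(s), nd, nd == 1))
    return pd.DataFrame(rows, columns=["colony_id", "pair_type", "sample_a", "sample_b",
                                       "site_index", "n_allele_diff",
                                       "single_allele_difference"])


def occurrence_spectrum(diffs: pd.DataFrame) -> pd.DataFrame:
    """Per-site occurrence: distinct colonies in which the site differs."""
    if diffs.empty:
        return pd.DataFrame(columns=["site_index", "occurrence", "n_pairs"])
    g = diffs.groupby("site_index")
    out = pd.DataFrame({
        "occurrence": g["colony_id"].nunique(),
        "n_pairs": g.size(),
    }).reset_index()
    return out


def effect_table(gm: GenotypeMatrix, diffs: pd.DataFrame,
                 annotation: Annotation) -> pd.DataFrame:
    """Annotate every distinct differing site and merge per-site difference counts."""
    if diffs.empty:
        return pd.DataFrame()
    site_counts = (diffs.groupby("site_index")
                        .agg(n_differences=("site_index", "size"),
                             n_colonies=("colony_id", "nunique"),
                             n_single_allele=("single_allele_difference", "sum"))
                        .reset_index())
    recs = []
    for s in site_counts["site_index"]:
        row = gm.sites.iloc[int(s)]
        eff = annotate_effect((row["chrom"], int(row["pos"])),
                              (row["ref"], row["alt"]), annotation)
        recs.append({
            "site_index": int(s), "chrom": eff.chrom, "pos": eff.pos,
            "ref": eff.ref, "alt": eff.alt, "location": eff.location,
            "gene_id": eff.gene_id, "substitution": eff.substitution,
            "codon_position": eff.codon_position, "effect": eff.effect,
            "stop_loss": eff.stop_loss,
        })
    return pd.DataFrame(recs).merge(site_counts, on="site_index")


def summarise_effects(effects: pd.DataFrame) -> dict:
    """Summary of an effect table: location, codon position and effect spectra.

    Counts are reported both per SNP (distinct sites) and per allelic
    difference (each site weighted by the number of pairs in which it
    differs).
    """
    if effects.empty:
        return {"n_snps": 0, "n_differences": 0}

    def _spectrum(frame: pd.DataFrame, column: str, weights: str | None):
        if weights is None:
            counts = frame[column].value_counts()
        else:
            counts = frame.groupby(column)[weights].sum()
        total = counts.sum()

        def _key(k):
            if isinstance(k, float) and k.is_integer():
                return str(int(k))
            return str(k)

        return {_key(k): {"count": int(v), "percent": 100.0 * v / total}
                for k, v in counts.items()}

    coding = effects[effects["location"] == "coding"]
    n_snps = len(effects)
    n_diffs = int(effects["n_differences"].sum())
    out = {
        "n_snps": n_snps,
        "n_differences": n_diffs,
        "genic_snp_fraction": float((effects["location"] != "intergenic").mean()),
        "coding_snp_fraction": float((effects["location"] == "coding").mean()),
        "single_allele_fraction": float(effects["n_single_allele"].sum()
                                        / max(n_diffs, 1)),
        "location_by_snp": _spectrum(effects, "location", None),
        "location_by_difference": _spectrum(effects, "location", "n_differences"),
        "substitution_by_snp": _spectrum(effects, "substitution", None),
    }
    if not coding.empty:
        out["codon_position_by_snp"] = _spectrum(coding, "codon_position", None)
        out["codon_position_by_difference"] = _spectrum(coding, "codon_position",
                                                        "n_differences")
        out["effect_by_snp"] = _spectrum(coding, "effect", None)
        out["effect_by_difference"] = _spectrum(coding, "effect", "n_differences")
    return out


def go_weighting(effects: pd.DataFrame, gene2go: pd.DataFrame,
                 min_count: int = 50) -> pd.DataFrame:
    """Weight GO terms by the non-silent allelic differences in their genes.

    ``gene2go`` has columns gene_id, go_id.  Genes carrying non-silent
    differences but absent from the mapping are tallied as unannotated
    (reported in the frame's ``attrs``).  Returns go_id, n_genes, weight,
    retained (weight >= min_count), sorted by descending weight.
    """
    non_silent = effects[(effects["location"] == "coding")
                         & (effects["effect"] != "silent")]
    per_gene = non_silent.groupby("gene_id")["n_differences"].sum()
    merged = (per_gene.rename("weight").reset_index()
              .merge(gene2go, on="gene_id", how="left"))
    unannotated = merged[merged["go_id"].isna()]["gene_id"].tolist()
    annotated = merged.dropna(subset=["go_id"])
    out = (annotated.groupby("go_id")
           .agg(n_genes=("gene_id", "nunique"), weight=("weight", "sum"))
           .reset_index())
    out["weight"] = out["weight"].astype(int)
    out["retained"] = out["weight"] >= min_count
    out = out.sort_values(["weight", "go_id"], ascending=[False, True]).reset_index(drop=True)
    out.attrs["unannotated_genes"] = unannotated
    return out
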