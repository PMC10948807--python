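"""Genotype matrix container, VCF I/O and site/genotype-level filtering.

Genotypes are unordered diploid allele pairs at biallelic SNPs, stored as
ALT-allele dosage (0 = REF/REF, 1 = REF/ALT, 2 = ALT/ALT, -1 = missing).
Phase is ignored everywhere.  VCF and the internal site table are both
1-based; the readers own the convention so nothing downstream converts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

META_COLUMNS = [
    "sample_id", "nubbin_id", "colony_id", "site_label", "replicate_of",
    "surface_length_cm", "surface_width_cm", "species_group",
]


class VCFParseError(ValueError):
    pass


class NoSitesRetainedError(ValueError):
    """All sites were removed by filtering."""


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid genotype calls with per-genotype DP/SP.

    ``sites`` columns: chrom, pos (1-based), ref, alt, qual, biallelic.
    ``gt``, ``dp``, ``sp`` are (n_sites, n_samples) arrays.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray
    sp: np.ndarray
    filter_report: dict = field(default_factory=dict, compare=False)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __post_init__(self) -> None:
        n_sites, n_samples = self.gt.shape
        if len(self.sites) != n_sites or len(self.sample_ids) != n_samples:
            raise ValueError("inconsistent GenotypeMatrix dimensions")
        for name in ("dp", "sp"):
            if getattr(self, name).shape != (n_sites, n_samples):
                raise ValueError(f"{name} array shape mismatch")

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return GenotypeMatrix(
            sample_ids=list(keep),
            sites=self.sites.copy(),
            gt=self.gt[:, idx].copy(),
            dp=self.dp[:, idx].copy(),
            sp=self.sp[:, idx].copy(),
        )

    def equal_genotypes(self, other: "GenotypeMatrix") -> bool:
        a = self.sites[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
        b = other.sites[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.gt, other.gt)
            and a.equals(b)
        )


def load_vcf(path: str) -> GenotypeMatrix:
    """Read a multi-sample VCF (v4.2, FORMAT GT[:DP][:SP]) into a GenotypeMatrix.

    Multi-allelic records are loaded with ``biallelic=False`` (removed later
    by :func:`apply_filters`); their dosage counts any non-reference allele.
    Absent DP is stored as 0 reads, absent SP as 0 (treated as passing).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    biallelic: list[bool] = []
    gt_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    sp_rows: list[np.ndarray] = []

    record_no = 0
    try:
        for variant in vcf:
            record_no += 1
            chroms.append(variant.CHROM)
            poss.append(variant.POS)
            refs.append(variant.REF)
            alts.append(",".join(variant.ALT) if variant.ALT else ".")
            quals.append(float(variant.QUAL) if variant.QUAL is not None else np.nan)
            biallelic.append(len(variant.ALT) == 1)
            # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            g = variant.gt_types.astype(np.int8)
            g[g == 3] = MISSING
            gt_rows.append(g)
            dp = variant.format("DP")
            if dp is None:
                dp_rows.append(np.zeros(n, dtype=np.int32))
            else:
                d = dp.astype(np.int32).reshape(-1)
                d[d < 0] = 0
                dp_rows.append(d)
            sp = variant.format("SP")
            if sp is None:
                sp_rows.append(np.zeros(n, dtype=np.float32))
            else:
                s = sp.astype(np.float32).reshape(-1)
                s[~np.isfinite(s)] = 0.0
                sp_rows.append(s)
    except VCFParseError:
        raise
    except Exception as exc:
        raise VCFParseError(
            f"malformed VCF {path} at record {record_no + 1}: {exc}"
        ) from exc

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts,
         "qual": quals, "biallelic": biallelic}
    )
    shape = (len(sites), n)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        sites=sites,
        gt=np.vstack(gt_rows) if gt_rows else np.empty(shape, dtype=np.int8),
        dp=np.vstack(dp_rows) if dp_rows else np.empty(shape, dtype=np.int32),
        sp=np.vstack(sp_rows) if sp_rows else np.empty(shape, dtype=np.float32),
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 with GT:DP:SP."""
    contigs = list(dict.fromkeys(gm.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coraligv\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=SP,Number=1,Type=Integer,Description='
                 '"Phred-scaled strand bias P-value">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        sites = gm.sites
        for i in range(gm.n_sites):
            row = sites.iloc[i]
            qual = "." if np.isnan(row["qual"]) else f"{row['qual']:.6g}"
            cells = [
                f"{_GT_STR[int(g)]}:{int(d)}:{int(round(float(s)))}"
                for g, d, s in zip(gm.gt[i], gm.dp[i], gm.sp[i])
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\t.\t.\tGT:DP:SP\t" + "\t".join(cells) + "\n"
            )


def apply_filters(gm: GenotypeMatrix, fc, report: dict | None = None) -> GenotypeMatrix:
    """Apply the filter cascade: QUAL -> biallelic -> genotype DP/SP -> %NA -> MAF.

    Sites failing QUAL or biallelicity are removed.  Genotypes with
    DP < min_dp or SP > max_sp are set missing (the site is retained).
    Then, when configured, sites whose missing fraction is >= max_na_fraction
    are removed (strict "< x" retention) and sites with MAF < min_maf are
    removed (ties at the threshold retained).  MAF counts two alleles per
    non-missing genotype after the masking step.

    Raises :class:`NoSitesRetainedError` if nothing survives.
    """
    fc.validate()
    rep: dict = {} if report is None else report

    keep = gm.sites["qual"].to_numpy() >= fc.min_qual
    rep["removed_qual"] = int((~keep).sum())
    if fc.biallelic_only:
        bi = gm.sites["biallelic"].to_numpy().astype(bool)
        rep["removed_multiallelic"] = int((keep & ~bi).sum())
        keep &= bi

    gt = gm.gt[keep].copy()
    dp = gm.dp[keep].copy()
    sp = gm.sp[keep].copy()
    sites = gm.sites.loc[keep].reset_index(drop=True)

    mask = (dp < fc.min_dp) | (sp > fc.max_sp)
    rep["masked_genotypes"] = int((mask & (gt != MISSING)).sum())
    gt[mask] = MISSING

    if fc.max_na_fraction is not None and len(sites):
        na_frac = (gt == MISSING).mean(axis=1)
        keep2 = na_frac < fc.max_na_fraction
        rep["removed_na"] = int((~keep2).sum())
        gt, dp, sp = gt[keep2], dp[keep2], sp[keep2]
        sites = sites.loc[keep2].reset_index(drop=True)
    else:
        rep["removed_na"] = 0

    if fc.min_maf is not None and len(sites):
        nonmiss = gt != MISSING
        n_alleles = 2 * nonmiss.sum(axis=1)
        alt_count = np.where(nonmiss, gt, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            af = np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), 0.0)
        maf = np.minimum(af, 1.0 - af)
        keep3 = maf >= fc.min_maf
        rep["removed_maf"] = int((~keep3).sum())
        gt, dp, sp = gt[keep3], dp[keep3], sp[keep3]
        sites = sites.loc[keep3].reset_index(drop=True)
    else:
        rep["removed_maf"] = 0

    rep["retained_sites"] = len(sites)
    if len(sites) == 0:
        raise NoSitesRetainedError(f"no sites retained under {fc.label()}")

    out = GenotypeMatrix(sample_ids=list(gm.sample_ids), sites=sites,
                         gt=gt, dp=dp, sp=sp)
    out.filter_report = rep
    return out


def load_meta(path: str) -> pd.DataFrame:
    """Read the sample metadata TSV and validate its required columns."""
    meta = pd.read_csv(path, sep="\t", dtype={"replicate_of": str}, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table lacks columns: {missing}")
    meta["replicate_of"] = meta["replicate_of"].replace({"": None, "NA": None})
    known = set(meta["nubbin_id"])
    bad = [r for r in meta["replicate_of"] if r is not None and r not in known]
    if bad:
        raise ValueError(f"replicate_of points to unknown nubbins: {sorted(set(bad))[:5]}")
    return meta


def write_meta(meta: pd.DataFrame, path: str) -> None:
    out = meta.copy()
    out["replicate_of"] = out["replicate_of"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def collapse_replicates(meta: pd.DataFrame) -> pd.DataFrame:
    """Keep one sample per nubbin (first by sample_id), dropping resequencings."""
    return (meta.sort_values("sample_id")
                .drop_duplicates("nubbin_id", keep="first")
                .sort_index()
                .reset_index(drop=True))
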