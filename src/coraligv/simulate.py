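"""Synthetic colony-genotype datasets with known ground truth.

The generator emulates a triplicate-sampled colony survey: clonal founder
lineages partitioned into sympatric species groups, colonies drawn from
those lineages, chimeric colonies carrying one nubbin from a foreign
lineage, mosaic colonies carrying somatic single-allele changes in one
nubbin, per-allele genotyping errors (optionally inflated at low read
depth), negative-binomial read depths, strand-bias scores, per-site quality
scores and independent per-genotype missingness.  Pairwise dissimilarities
of the resulting samples are trimodal: an error mode, a chimeric
(inter-lineage) mode and an inter-group mode, with the somatic-mutation
mode sitting just above the error mode.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimulationConfig.seed``, so a fixed config yields byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, _Transcript
from .config import SimulationConfig
from .genotypes import MISSING, GenotypeMatrix, load_vcf, load_meta, write_meta, write_vcf

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
     if a + b + c not in _STOPS]
)


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``nubbins``: nubbin_id, colony_id, lineage, species_group,
    n_somatic_mutations.  ``colonies``: colony_id, category.  ``mutations``:
    nubbin_id, site_index, chrom, pos.  ``sites``: site_index, chrom, pos,
    location, gene_id.
    """

    nubbins: pd.DataFrame
    colonies: pd.DataFrame
    mutations: pd.DataFrame
    sites: pd.DataFrame

    def category_counts(self) -> dict[str, int]:
        counts = self.colonies["category"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("invariable", "mosaic", "chimeric")}


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    genotypes: GenotypeMatrix
    meta: pd.DataFrame
    annotation: Annotation
    truth: TruthTable
    config: SimulationConfig
    features: pd.DataFrame = field(repr=False)   # GFF3 feature table
    seqs: dict = field(repr=False)               # contig -> sequence
    gene2go: pd.DataFrame = field(repr=False)
    true_gt: np.ndarray = field(repr=False)      # pre-error dosages per sample


# ---------------------------------------------------------------------------
# genome construction


def _build_genome(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay out one contig of non-overlapping genes and pick SNP positions.

    Region lengths are sized at ~4 bp per requested site so positions can be
    sampled without replacement from each class pool.  Each gene is
    UTR + contiguous CDS (sense codons + terminal stop) + UTR, phase 0,
    strands alternating.
    """
    n = cfg.n_sites_total
    n_coding = int(round(n * cfg.gene_fraction * cfg.coding_fraction))
    n_gnc = int(round(n * cfg.gene_fraction * (1 - cfg.coding_fraction)))
    n_inter = n - n_coding - n_gnc

    n_genes = max(2, int(np.ceil(n_coding / 30.0)))
    codons_per_gene = max(12, int(np.ceil(4.0 * n_coding / 3.0 / n_genes)))
    utr_len = max(24, int(np.ceil(4.0 * n_gnc / (2.0 * n_genes))))
    spacer_len = max(60, int(np.ceil(4.0 * max(n_inter, 1) / (n_genes + 1.0))))

    seq_parts: list[str] = []
    features = []  # (type, start, end, strand, phase, feat_id, parent)
    coding_pool: list[np.ndarray] = []
    gnc_pool: list[np.ndarray] = []
    inter_pool: list[np.ndarray] = []
    pos = 0  # running 0-based length

    def _random_seq(length: int) -> str:
        return "".join(rng.choice(_BASES, size=length))

    for g in range(n_genes + 1):
        seq_parts.append(_random_seq(spacer_len))
        inter_pool.append(np.arange(pos + 1, pos + spacer_len + 1))
        pos += spacer_len
        if g == n_genes:
            break
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"gene{g + 1:04d}"
        gene_start = pos + 1
        # UTR - CDS - UTR in genomic order; biology flips with strand but the
        # genomic layout is what the coordinates see.
        seq_parts.append(_random_seq(utr_len))
        gnc_pool.append(np.arange(pos + 1, pos + utr_len + 1))
        pos += utr_len
        cds = "".join(rng.choice(_SENSE_CODONS, size=codons_per_gene - 1))
        stop = _STOPS[rng.integers(len(_STOPS))]
        cds_fwd = cds + stop
        cds_len = 3 * codons_per_gene
        if strand == "-":
            from Bio.Seq import Seq
            cds_genomic = str(Seq(cds_fwd).reverse_complement())
        else:
            cds_genomic = cds_fwd
        cds_start = pos + 1
        seq_parts.append(cds_genomic)
        # exclude the stop codon from the site pool to keep effect classes
        # on substitutions within the protein
        if strand == "+":
            pool = np.arange(cds_start, cds_start + cds_len - 3)
        else:
            pool = np.arange(cds_start + 3, cds_start + cds_len)
        coding_pool.append(pool)
        pos += cds_len
        seq_parts.append(_random_seq(utr_len))
        gnc_pool.append(np.arange(pos + 1, pos + utr_len + 1))
        pos += utr_len
        gene_end = pos
        tid = f"{gene_id}.t1"
        features.append(("gene", gene_start, gene_end, strand, ".", gene_id, None))
        features.append(("mRNA", gene_start, gene_end, strand, ".", tid, gene_id))
        features.append(("CDS", cds_start, cds_start + cds_len - 1, strand, "0", f"{tid}.cds", tid))

    contig = "contig1"
    seq = "".join(seq_parts)
    feat_df = pd.DataFrame(features, columns=["type", "start", "end", "strand",
                                              "phase", "feat_id", "parent"])
    feat_df.insert(0, "contig", contig)

    def _sample(pools: list[np.ndarray], k: int) -> np.ndarray:
        all_pos = np.concatenate(pools) if pools else np.empty(0, dtype=int)
        if k > len(all_pos):
            raise ValueError("site pool smaller than requested site count")
        return rng.choice(all_pos, size=k, replace=False)

    positions = np.concatenate([
        _sample(coding_pool, n_coding),
        _sample(gnc_pool, n_gnc),
        _sample(inter_pool, n_inter),
    ])
    order = np.argsort(positions)
    positions = positions[order]
    return contig, seq, feat_df, positions


def _build_annotation(seqs: dict[str, str], feat_df: pd.DataFrame) -> Annotation:
    ann = Annotation(seqs)
    genes = feat_df[feat_df["type"] == "gene"]
    for _, row in genes.iterrows():
        ann.add_gene(row["feat_id"], row["contig"], row["start"], row["end"], row["strand"])
    mrnas = feat_df[feat_df["type"] == "mRNA"].set_index("feat_id")
    cds = feat_df[feat_df["type"] == "CDS"]
    for tid, group in cds.groupby("parent"):
        segs = [(int(r["start"]), int(r["end"]), int(r["phase"])) for _, r in group.iterrows()]
        mrna = mrnas.loc[tid]
        tr = _Transcript(tid, mrna["parent"], mrna["strand"], segs, seqs[mrna["contig"]])
        ann.add_transcript(tr, mrna["contig"])
    return ann


# ---------------------------------------------------------------------------
# genotype processes


def _lineage_genotypes(cfg: SimulationConfig, rng: np.random.Generator,
                       lineage_group: np.ndarray) -> np.ndarray:
    n, L = cfg.n_sites_total, cfg.n_lineages
    G = cfg.n_species_groups
    u = rng.random(n)
    gt = np.zeros((n, L), dtype=np.int8)

    group_sites = u < cfg.inter_group_divergence
    lineage_sites = (~group_sites) & (u < cfg.inter_group_divergence + cfg.intra_group_divergence)
    shared_sites = ~(group_sites | lineage_sites)

    # group-differentiating: fixed opposite homozygotes between groups
    n_gs = int(group_sites.sum())
    if n_gs:
        bits = rng.integers(0, 2, size=(n_gs, G))
        all_same = bits.min(axis=1) == bits.max(axis=1)
        if all_same.any():
            flip_group = rng.integers(0, G, size=int(all_same.sum()))
            rows = np.flatnonzero(all_same)
            bits[rows, flip_group] ^= 1
        gt[group_sites] = (2 * bits[:, lineage_group]).astype(np.int8)

    # lineage-differentiating: independent dosage per lineage
    n_ls = int(lineage_sites.sum())
    if n_ls:
        gt[lineage_sites] = rng.choice(
            np.array([0, 1, 2], dtype=np.int8), size=(n_ls, L), p=[0.25, 0.5, 0.25])

    # shared polymorphism: one dosage for everybody
    n_ss = int(shared_sites.sum())
    if n_ss:
        common = rng.choice(np.array([0, 1, 2], dtype=np.int8), size=n_ss,
                            p=[0.55, 0.30, 0.15])
        gt[shared_sites] = common[:, None]
    return gt


def _apply_errors(true_gt: np.ndarray, eps: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Flip each of the two allele calls independently with probability eps."""
    a1 = (true_gt == 2).astype(np.int8)
    a2 = (true_gt >= 1).astype(np.int8)
    f1 = rng.random(true_gt.shape) < eps
    f2 = rng.random(true_gt.shape) < eps
    return ((a1 ^ f1) + (a2 ^ f2)).astype(np.int8)


# ---------------------------------------------------------------------------
# main entry points


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset (genotypes, metadata, annotation, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    contig, seq, feat_df, positions = _build_genome(cfg, rng)
    seqs = {contig: seq}
    ann = _build_annotation(seqs, feat_df)

    n_sites = cfg.n_sites_total
    ref = np.array([seq[p - 1] for p in positions])
    is_ts = rng.random(n_sites) < cfg.transition_prob
    alt = np.empty(n_sites, dtype="<U1")
    for i, (r, t) in enumerate(zip(ref, is_ts)):
        if t:
            alt[i] = _TRANSITION[r]
        else:
            tv = [b for b in "ACGT" if b != r and b != _TRANSITION[r]]
            alt[i] = tv[rng.integers(2)]

    # lineages and species groups
    G = cfg.n_species_groups
    lineage_group = np.empty(cfg.n_lineages, dtype=int)
    lineage_group[:G] = np.arange(G)
    if cfg.n_lineages > G:
        p = np.array([0.78, 0.22]) if G == 2 else np.full(G, 1.0 / G)
        lineage_group[G:] = rng.choice(G, size=cfg.n_lineages - G, p=p)
    lineage_gt = _lineage_genotypes(cfg, rng, lineage_group)

    # colonies
    lineage_weights = rng.dirichlet(np.full(cfg.n_lineages, 0.6))
    u = rng.random(cfg.n_colonies)
    categories = np.where(u < cfg.p_chimera_colony, "chimeric",
                          np.where(u < cfg.p_chimera_colony + cfg.p_mosaic_colony,
                                   "mosaic", "invariable"))
    colony_lineage = rng.choice(cfg.n_lineages, size=cfg.n_colonies, p=lineage_weights)
    site_labels = [cfg.site_labels[i % len(cfg.site_labels)] for i in range(cfg.n_colonies)]

    nubbin_rows = []
    mutation_rows = []
    nubbin_true_cols: list[np.ndarray] = []
    colony_ids = [f"C{i + 1:03d}" for i in range(cfg.n_colonies)]
    for ci, colony_id in enumerate(colony_ids):
        lin = int(colony_lineage[ci])
        lineages = [lin] * cfg.nubbins_per_colony
        category = categories[ci]
        mutated_nubbin = -1
        if category == "chimeric":
            foreign = int(rng.choice([l for l in range(cfg.n_lineages) if l != lin]))
            lineages[int(rng.integers(cfg.nubbins_per_colony))] = foreign
        elif category == "mosaic":
            mutated_nubbin = int(rng.integers(cfg.nubbins_per_colony))
        for ni in range(cfg.nubbins_per_colony):
            nubbin_id = f"{colony_id}N{ni + 1}"
            g = lineage_gt[:, lineages[ni]].copy()
            n_mut = 0
            if ni == mutated_nubbin:
                n_mut = 1 + rng.poisson(max(cfg.mosaic_mutation_count - 1.0, 0.0))
                mut_sites = rng.choice(n_sites, size=min(n_mut, n_sites), replace=False)
                for s in mut_sites:
                    d = g[s]
                    if d == 0 or d == 2:
                        g[s] = 1
                    else:
                        g[s] = 0 if rng.random() < 0.5 else 2
                    mutation_rows.append((nubbin_id, int(s), contig, int(positions[s])))
                n_mut = len(mut_sites)
            nubbin_rows.append((nubbin_id, colony_id, lineages[ni],
                                int(lineage_group[lineages[ni]]), n_mut))
            nubbin_true_cols.append(g)

    nubbins = pd.DataFrame(nubbin_rows, columns=["nubbin_id", "colony_id", "lineage",
                                                 "species_group", "n_somatic_mutations"])

    # replicated nubbins: the first nubbin of the first colony of each site label
    replicated: list[str] = []
    for label in cfg.site_labels:
        if len(replicated) >= cfg.n_replicated_nubbins:
            break
        ci = next((i for i, s in enumerate(site_labels) if s == label), None)
        if ci is not None:
            replicated.append(f"{colony_ids[ci]}N1")
    i = 0
    while len(replicated) < cfg.n_replicated_nubbins and i < len(nubbins):
        cand = nubbins["nubbin_id"].iloc[i]
        if cand not in replicated:
            replicated.append(cand)
        i += 1

    sample_rows = []
    sample_true: list[np.ndarray] = []
    nubbin_index = {nid: k for k, nid in enumerate(nubbins["nubbin_id"])}
    colony_site = dict(zip(colony_ids, site_labels))
    length = np.round(rng.lognormal(np.log(20.0), 0.35, size=cfg.n_colonies), 1)
    width = np.round(length * rng.uniform(0.5, 0.9, size=cfg.n_colonies), 1)
    colony_dims = {cid: (length[i], width[i]) for i, cid in enumerate(colony_ids)}
    for _, nub in nubbins.iterrows():
        nid = nub["nubbin_id"]
        n_copies = 3 if nid in replicated else 1
        for r in range(n_copies):
            sid = nid if n_copies == 1 else f"{nid}_R{r + 1}"
            sample_rows.append({
                "sample_id": sid,
                "nubbin_id": nid,
                "colony_id": nub["colony_id"],
                "site_label": colony_site[nub["colony_id"]],
                "replicate_of": nid if r > 0 else None,
                "surface_length_cm": colony_dims[nub["colony_id"]][0],
                "surface_width_cm": colony_dims[nub["colony_id"]][1],
                "species_group": f"GSH{nub['species_group'] + 1}",
            })
            sample_true.append(nubbin_true_cols[nubbin_index[nid]])
    meta = pd.DataFrame(sample_rows)
    true_gt = np.column_stack(sample_true)  # (n_sites, n_samples)
    n_samples = true_gt.shape[1]

    # depth, errors, strand bias, missingness
    dm = cfg.depth_model
    p_nb = dm.shape / (dm.shape + dm.mean)
    dp = rng.negative_binomial(dm.shape, p_nb, size=true_gt.shape).astype(np.int32)
    eps_sample = cfg.per_allele_error_rate * np.ones(n_samples)
    if cfg.error_rate_sample_cv > 0:
        cv2 = cfg.error_rate_sample_cv ** 2
        eps_sample *= rng.gamma(1.0 / cv2, cv2, size=n_samples)
    eps = np.broadcast_to(eps_sample, true_gt.shape).copy()
    if cfg.low_dp_error_multiplier > 1.0:
        eps[dp < cfg.low_dp_threshold] *= cfg.low_dp_error_multiplier
    np.clip(eps, 0.0, 0.5, out=eps)
    gt = _apply_errors(true_gt, eps, rng)
    sp = rng.exponential(4.0, size=true_gt.shape).astype(np.float32)
    if cfg.missing_rate > 0:
        gt[rng.random(true_gt.shape) < cfg.missing_rate] = MISSING

    qual = rng.gamma(4.0, 60.0, size=n_sites)
    low = rng.random(n_sites) < cfg.qual_low_fraction
    qual[low] = rng.uniform(2.0, 19.5, size=int(low.sum()))

    sites = pd.DataFrame({
        "chrom": contig, "pos": positions.astype(int), "ref": ref, "alt": alt,
        "qual": qual, "biallelic": True,
    })
    gm = GenotypeMatrix(sample_ids=list(meta["sample_id"]), sites=sites,
                        gt=gt, dp=dp, sp=sp.astype(np.float32))

    site_truth_rows = []
    for i, p in enumerate(positions):
        sa = ann.classify(contig, int(p))
        site_truth_rows.append((i, contig, int(p), sa.location, sa.gene_id or ""))
    truth_sites = pd.DataFrame(site_truth_rows,
                               columns=["site_index", "chrom", "pos", "location", "gene_id"])

    truth = TruthTable(
        nubbins=nubbins,
        colonies=pd.DataFrame({"colony_id": colony_ids, "category": categories,
                               "lineage": colony_lineage,
                               "site_label": site_labels}),
        mutations=pd.DataFrame(mutation_rows,
                               columns=["nubbin_id", "site_index", "chrom", "pos"]),
        sites=truth_sites,
    )

    # synthetic GO annotation: 1-4 terms per gene from a shared pool
    gene_ids = feat_df.loc[feat_df["type"] == "gene", "feat_id"].tolist()
    n_terms = max(20, len(gene_ids) // 2)
    term_pool = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    g2g_rows = []
    for gid in gene_ids:
        k = int(rng.integers(1, 5))
        for t in rng.choice(n_terms, size=min(k, n_terms), replace=False):
            g2g_rows.append((gid, term_pool[int(t)]))
    gene2go = pd.DataFrame(g2g_rows, columns=["gene_id", "go_id"])

    return SimulatedDataset(genotypes=gm, meta=meta, annotation=ann, truth=truth,
                            config=cfg, features=feat_df, seqs=seqs,
                            gene2go=gene2go, true_gt=true_gt)


def write_dataset(dataset: SimulatedDataset, out_dir: str) -> dict[str, str]:
    """Write VCF, FASTA, GFF3, metadata and truth tables; return the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "fasta": os.path.join(out_dir, "reference.fa"),
        "gff3": os.path.join(out_dir, "annotation.gff3"),
        "meta": os.path.join(out_dir, "meta.tsv"),
        "gene2go": os.path.join(out_dir, "gene2go.tsv"),
        "truth_nubbins": os.path.join(out_dir, "truth_nubbins.tsv"),
        "truth_colonies": os.path.join(out_dir, "truth_colonies.tsv"),
        "truth_mutations": os.path.join(out_dir, "truth_mutations.tsv"),
        "truth_sites": os.path.join(out_dir, "truth_sites.tsv"),
    }
    write_vcf(dataset.genotypes, paths["vcf"])
    with open(paths["fasta"], "w") as fh:
        for contig, seq in dataset.seqs.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for _, f in dataset.features.iterrows():
            attrs = f"ID={f['feat_id']}"
            if f["parent"]:
                attrs += f";Parent={f['parent']}"
            fh.write(f"{f['contig']}\tcoraligv\t{f['type']}\t{f['start']}\t{f['end']}"
                     f"\t.\t{f['strand']}\t{f['phase']}\t{attrs}\n")
    write_meta(dataset.meta, paths["meta"])
    dataset.gene2go.to_csv(paths["gene2go"], sep="\t", index=False)
    dataset.truth.nubbins.to_csv(paths["truth_nubbins"], sep="\t", index=False)
    dataset.truth.colonies.to_csv(paths["truth_colonies"], sep="\t", index=False)
    dataset.truth.mutations.to_csv(paths["truth_mutations"], sep="\t", index=False)
    dataset.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    return paths


def load_dataset(out_dir: str):
    """Load a written dataset back as (GenotypeMatrix, meta, Annotation)."""
    from .annotation import load_annotation

    gm = load_vcf(os.path.join(out_dir, "genotypes.vcf"))
    meta = load_meta(os.path.join(out_dir, "meta.tsv"))
    ann = load_annotation(os.path.join(out_dir, "annotation.gff3"),
                          os.path.join(out_dir, "reference.fa"))
    return gm, meta, ann
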