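"""Configuration objects for the simulator and the genotype filters."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    """Raised when a configuration field is out of its valid range."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid field '{name}': {msg}")


@dataclass
class DepthModel:
    """Negative-binomial model for per-genotype read depth.

    ``mean`` is the expected depth; ``shape`` is the gamma shape of the
    gamma-Poisson mixture (smaller = more overdispersed, more low-depth
    genotypes for the depth filter to act on).
    """

    mean: float = 46.0
    shape: float = 1.2

    def validate(self) -> None:
        _check(self.mean > 0, "depth_model.mean", "must be positive")
        _check(self.shape > 0, "depth_model.shape", "must be positive")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic colony-genotype generator.

    Defaults emulate a triplicate-sampled survey of 93 coral colonies on
    three reefs, genotyped at ~6e4 biallelic SNPs: two sympatric species
    groups (~25% of sites carrying fixed differences between groups),
    15 clonal lineages, a genotyping-error mode near 0.85% pairwise
    dissimilarity, a somatic-mutation (mosaic) mode just above it, and
    chimeric colonies assembled from nubbins of different lineages.
    """

    n_colonies: int = 93
    nubbins_per_colony: int = 3
    n_sites_total: int = 60_000
    n_lineages: int = 15
    n_species_groups: int = 2
    inter_group_divergence: float = 0.25
    intra_group_divergence: float = 0.08
    mosaic_mutation_count: float = 600.0
    p_mosaic_colony: float = 0.075
    p_chimera_colony: float = 0.12
    per_allele_error_rate: float = 0.004
    missing_rate: float = 0.40
    depth_model: DepthModel = field(default_factory=DepthModel)
    n_replicated_nubbins: int = 3
    gene_fraction: float = 0.76
    coding_fraction: float = 0.25
    seed: int = 0
    # Optional knobs
    error_rate_sample_cv: float = 0.05   # per-sample spread of the error rate
    low_dp_error_multiplier: float = 1.0  # >1 inflates errors where DP < low_dp_threshold
    low_dp_threshold: int = 12
    site_labels: tuple[str, ...] = ("REU2", "REU3", "REU4")
    qual_low_fraction: float = 0.05      # fraction of sites drawn with QUAL < 20
    transition_prob: float = 0.64        # P(ALT is a transition of REF)

    def validate(self) -> None:
        for name in ("n_colonies", "nubbins_per_colony", "n_sites_total",
                     "n_lineages", "n_species_groups"):
            _check(getattr(self, name) > 0, name, "must be a positive count")
        for name in ("p_mosaic_colony", "p_chimera_colony",
                     "per_allele_error_rate", "missing_rate",
                     "gene_fraction", "coding_fraction", "inter_group_divergence",
                     "intra_group_divergence", "qual_low_fraction", "transition_prob"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, "must lie in [0, 1]")
        _check(self.p_mosaic_colony + self.p_chimera_colony <= 1.0,
               "p_mosaic_colony", "p_mosaic_colony + p_chimera_colony must be <= 1")
        _check(self.inter_group_divergence > self.intra_group_divergence,
               "inter_group_divergence", "must exceed intra_group_divergence")
        _check(self.inter_group_divergence + self.intra_group_divergence < 1.0,
               "inter_group_divergence", "divergence fractions must sum below 1")
        _check(self.mosaic_mutation_count >= 0, "mosaic_mutation_count", "must be >= 0")
        _check(self.n_replicated_nubbins >= 0, "n_replicated_nubbins", "must be >= 0")
        _check(self.n_replicated_nubbins <= self.n_colonies,
               "n_replicated_nubbins", "cannot exceed n_colonies")
        _check(self.n_lineages >= self.n_species_groups,
               "n_lineages", "need at least one lineage per species group")
        _check(self.low_dp_error_multiplier >= 1.0,
               "low_dp_error_multiplier", "must be >= 1")
        _check(self.error_rate_sample_cv >= 0, "error_rate_sample_cv", "must be >= 0")
        _check(len(self.site_labels) > 0, "site_labels", "need at least one site label")
        self.depth_model.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "depth_model" in d and isinstance(d["depth_model"], dict):
            d["depth_model"] = DepthModel(**d["depth_model"])
        if "site_labels" in d:
            d["site_labels"] = tuple(d["site_labels"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class FilterConfig:
    """Site- and genotype-level filter thresholds.

    QUAL acts on sites, DP/SP on individual genotypes (failing genotypes are
    set missing, the site is retained), %NA and MAF act on sites after the
    genotype-level masking.  ``max_na_fraction=None`` / ``min_maf=None``
    disable those filters.  Order is fixed: QUAL -> biallelic -> DP/SP ->
    %NA -> MAF.
    """

    min_qual: float = 20.0
    min_dp: int = 12
    max_sp: float = 13.0
    max_na_fraction: float | None = None
    min_maf: float | None = None
    biallelic_only: bool = True

    def validate(self) -> None:
        _check(self.min_qual >= 0, "min_qual", "must be non-negative")
        _check(self.min_dp >= 0, "min_dp", "must be non-negative")
        _check(self.max_sp >= 0, "max_sp", "must be non-negative")
        if self.max_na_fraction is not None:
            _check(0.0 <= self.max_na_fraction <= 1.0, "max_na_fraction", "must lie in [0, 1]")
        if self.min_maf is not None:
            _check(0.0 <= self.min_maf <= 1.0, "min_maf", "must lie in [0, 1]")

    def label(self) -> str:
        parts = [f"QUAL>={self.min_qual:g}", f"DP>={self.min_dp}", f"SP<={self.max_sp:g}"]
        if self.max_na_fraction is not None:
            parts.append(f"%NA<{100 * self.max_na_fraction:g}%")
        if self.min_maf is not None:
            parts.append(f"MAF>={self.min_maf:g}")
        return " & ".join(parts)
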