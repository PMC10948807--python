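"""Detection of intra-colonial genetic variability (IGV).

Per-colony maximum dissimilarity, the threshold-sweep curve and its T50
summary, the two-component Gaussian mixture separating genotyping error
from somatic mutation, the analytic density-curve intersection used as the
IGV threshold, the mosaic/chimera antimode gap, colony classification,
intra-colonial pair enumeration, and the association/correlation tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import FilterConfig
from .dissimilarity import (
    AntimodeGap,
    DissimilarityMatrix,
    NoAntimodeError,
    detect_antimode,
    pairwise_dissimilarity,
    replicate_dissimilarity,
)
from .exact_tests import FisherResult, fisher_exact_rxc
from .genotypes import GenotypeMatrix, NoSitesRetainedError, apply_filters, collapse_replicates


class DegenerateFitError(RuntimeError):
    """EM collapsed to a zero-variance component in every restart."""


class NoIntersectionError(RuntimeError):
    """The two weighted Gaussian densities never cross."""


# ---------------------------------------------------------------------------
# colony maxima and the IGV curve


def colony_max_distance(D: DissimilarityMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Maximum intra-colonial dissimilarity per colony.

    Sequencing replicates are collapsed to one representative per nubbin
    first.  Colonies with fewer than two usable nubbins are flagged
    unclassifiable (``max_percent_diff`` NaN).
    """
    collapsed = collapse_replicates(meta)
    rows = []
    for colony, group in collapsed.groupby("colony_id", sort=True):
        samples = [s for s in group["sample_id"] if s in D.sample_ids]
        if not samples:
            raise KeyError(f"colony {colony} absent from the dissimilarity matrix")
        if len(samples) < 2:
            rows.append((colony, np.nan, len(samples), False))
            continue
        sub = D.subset(samples)
        iu = np.triu_indices(len(samples), k=1)
        vals = sub.percent[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append((colony, np.nan, len(samples), False))
        else:
            rows.append((colony, float(vals.max()), len(samples), True))
    return pd.DataFrame(rows, columns=["colony_id", "max_percent_diff",
                                       "n_nubbins", "classifiable"])


@dataclass
class IGVCurve:
    """Fraction of IGV colonies as a function of the dissimilarity threshold."""

    thresholds: np.ndarray
    fraction_igv: np.ndarray
    t50: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fraction_igv": self.fraction_igv})


def igv_curve(colony_maxima, thresholds=None) -> IGVCurve:
    """IGV-vs-threshold curve; a colony is IGV when its max exceeds the threshold.

    T50 is the median of the per-colony maxima (midpoint convention for even
    counts), which is where the curve crosses 50%.
    """
    maxima = np.asarray(list(colony_maxima), dtype=float)
    maxima = maxima[np.isfinite(maxima)]
    if maxima.size == 0:
        raise ValueError("need at least one classifiable colony")
    if thresholds is None:
        hi = max(maxima.max(), 1.0)
        thresholds = np.linspace(0.0, hi, 201)
    thresholds = np.asarray(thresholds, dtype=float)
    frac = (maxima[None, :] > thresholds[:, None]).mean(axis=1)
    return IGVCurve(thresholds=thresholds, fraction_igv=frac,
                    t50=float(np.median(maxima)))


# ---------------------------------------------------------------------------
# Gaussian mixture and its intersection threshold


@dataclass
class GMMFit:
    """Two-component univariate normal mixture, components mean-ordered."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float = np.nan
    n_points: int = 0
    fit_range: tuple[float, float] = (np.nan, np.nan)
    intersection: float | None = None
    intersection_between_means: bool | None = None

    def density(self, x):
        x = np.asarray(x, dtype=float)
        return (self.weights[0] * stats.norm.pdf(x, self.means[0], self.sds[0])
                + self.weights[1] * stats.norm.pdf(x, self.means[1], self.sds[1]))


def _em_univariate(x: np.ndarray, w, mu, sd, max_iter: int, tol: float):
    """Plain EM for a 2-component univariate normal mixture."""
    n = x.size
    ll_old = -np.inf
    for _ in range(max_iter):
        log_comp = np.stack([
            np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in (0, 1)
        ])
        log_norm = np.logaddexp(log_comp[0], log_comp[1])
        ll = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm)
        nk = resp.sum(axis=1)
        if nk.min() < 1e-10:
            return None
        w = nk / n
        mu = (resp @ x) / nk
        var = np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in (0, 1)])
        sd = np.sqrt(var)
        if sd.min() < 1e-6:
            return None
        if ll - ll_old < tol and ll >= ll_old:
            break
        ll_old = ll
    return w, mu, sd, ll


def fit_gmm_2(values, fit_upper_bound: float | None = None, seed: int = 0,
              n_restarts: int = 10, max_iter: int = 500, tol: float = 1e-8) -> GMMFit:
    """Maximum-likelihood 2-component normal mixture of values below a bound.

    EM with ``n_restarts`` seeded initialisations (the first quantile-based,
    the rest random); convergence when the log-likelihood improves by less
    than ``tol``.  Restarts collapsing to a near-zero standard deviation are
    discarded; if every restart collapses a :class:`DegenerateFitError` is
    raised.  Components are reported mean-ordered.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if fit_upper_bound is not None:
        x = x[x < fit_upper_bound]
    if x.size < 20:
        raise ValueError(f"need at least 20 values below the fit bound, got {x.size}")
    rng = np.random.default_rng(seed)
    best = None
    spread = x.std()
    for r in range(n_restarts):
        if r == 0:
            mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
        else:
            mu = np.sort(rng.choice(x, size=2, replace=False).astype(float))
            mu = mu + rng.normal(0.0, max(spread, 1e-6) * 0.05, size=2)
        sd0 = max(spread / 2, 1e-4)
        result = _em_univariate(x, np.array([0.5, 0.5]), mu.copy(),
                                np.array([sd0, sd0]), max_iter, tol)
        if result is None:
            continue
        w, mu, sd, ll = result
        if best is None or ll > best[3]:
            best = (w, mu, sd, ll)
    if best is None:
        raise DegenerateFitError("every EM restart collapsed to a degenerate component")
    w, mu, sd, ll = best
    order = np.argsort(mu)
    fit = GMMFit(weights=(float(w[order[0]]), float(w[order[1]])),
                 means=(float(mu[order[0]]), float(mu[order[1]])),
                 sds=(float(sd[order[0]]), float(sd[order[1]])),
                 log_likelihood=ll, n_points=int(x.size),
                 fit_range=(float(x.min()),
                            float(fit_upper_bound) if fit_upper_bound is not None
                            else float(x.max())))
    try:
        fit.intersection, fit.intersection_between_means = _intersection(fit)
    except NoIntersectionError:
        fit.intersection = None
        fit.intersection_between_means = None
    return fit


def _intersection(fit: GMMFit) -> tuple[float, bool]:
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    if min(s1, s2) <= 0:
        raise ValueError("standard deviations must be positive")
    if s1 == s2:
        if m1 == m2:
            raise NoIntersectionError("identical components have no crossing")
        x = 0.5 * (m1 + m2) + s1 ** 2 * math.log(w1 / w2) / (m2 - m1)
        roots = [x]
    else:
        # w1 phi(x; m1, s1) = w2 phi(x; m2, s2)  <=>  A x^2 + B x + C = 0
        a1, a2 = 1.0 / (2 * s1 ** 2), 1.0 / (2 * s2 ** 2)
        A = a2 - a1
        B = 2 * (a1 * m1 - a2 * m2)
        C = a2 * m2 ** 2 - a1 * m1 ** 2 + math.log(w1 / s1) - math.log(w2 / s2)
        disc = B * B - 4 * A * C
        if disc < 0:
            raise NoIntersectionError("densities do not cross (negative discriminant)")
        sq = math.sqrt(disc)
        roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    lo, hi = min(m1, m2), max(m1, m2)
    inside = [r for r in roots if lo < r < hi]
    if inside:
        return float(inside[0]), True
    above = sorted([r for r in roots if r > lo], key=lambda r: abs(r - hi))
    if above:
        return float(above[0]), False
    raise NoIntersectionError("no crossing at or above the lower component mean")


def gaussian_intersection(fit: GMMFit) -> float:
    """Crossing point of the two weighted component densities, in percent.

    Returns the root strictly between the two means when one exists, else
    the root above the lower mean closest to the upper mean (the fit's
    ``intersection_between_means`` flag records which case occurred).
    """
    x, between = _intersection(fit)
    fit.intersection = x
    fit.intersection_between_means = between
    return x


def _is_bimodal(fit: GMMFit) -> bool:
    """True when the fitted mixture density dips between the component means."""
    m1, m2 = fit.means
    if m2 <= m1:
        return False
    x = np.linspace(m1, m2, 512)
    d = fit.density(x)
    interior = d[1:-1].min()
    return interior < 0.99 * min(d[0], d[-1])


def detect_igv_threshold(values, bin_width: float = 0.25, seed: int = 0):
    """Locate the error threshold T_err from all pairwise dissimilarities.

    The first antimode gap of the distribution bounds the error+mutation
    mass from above; a two-component mixture is fitted below it and T_err is
    the intersection of the weighted component densities.  The intersection
    is only trusted when the fitted mixture is genuinely bimodal (its
    density dips between the component means — an encrypted antimode);
    otherwise — a split of a single error mode, or one component buried
    under the other — there is no evidence of a distinct mutation mode and
    T_err falls back to the lower edge of the gap, so the whole low-value
    mass counts as error.

    Returns ``(t_err, fit, gap)``.
    """
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    gap = detect_antimode(vals, bin_width=bin_width, which="first")
    fit = fit_gmm_2(vals, fit_upper_bound=gap.lower, seed=seed)
    if not _is_bimodal(fit):
        warnings.warn("fitted mixture is unimodal: no distinct mutation mode; "
                      "using the antimode gap edge as the error threshold")
        return gap.lower, fit, gap
    try:
        t_err = gaussian_intersection(fit)
    except NoIntersectionError:
        warnings.warn("component densities never cross; using the antimode gap "
                      "edge as the error threshold")
        t_err = gap.lower
    return t_err, fit, gap


# ---------------------------------------------------------------------------
# classification


@dataclass
class ColonyClassification:
    """Per-colony IGV category with the thresholds used."""

    table: pd.DataFrame  # colony_id, max_percent_diff, category, ambiguous
    t_err: float
    chimera_gap: AntimodeGap | None

    def counts(self) -> dict[str, int]:
        c = self.table["category"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("invariable", "mosaic", "chimeric")}

    def category_of(self, colony_id: str) -> str:
        row = self.table[self.table["colony_id"] == colony_id]
        if row.empty:
            raise KeyError(colony_id)
        return row["category"].iloc[0]


def classify_colonies(colony_maxima: pd.DataFrame, t_err: float,
                      pairwise_values=None, chimera_gap: AntimodeGap | None = None,
                      bin_width: float = 0.25) -> ColonyClassification:
    """Classify colonies as invariable / mosaic / chimeric.

    ``colony_maxima`` is the frame from :func:`colony_max_distance`.  A colony
    is invariable when its maximum intra-colonial dissimilarity is <= the
    error threshold ``t_err``.  Among IGV colonies, the mosaic/chimera
    boundary is the first antimode gap of the pairwise values above ``t_err``
    (passed precomputed via ``chimera_gap`` or located here from
    ``pairwise_values``): chimeric at or above the gap's upper edge, mosaic
    at or below its lower edge, and in-gap maxima split at the gap midpoint
    and flagged ambiguous.  If no gap exists all IGV colonies are labelled
    mosaic with a warning.
    """
    if chimera_gap is None and pairwise_values is not None:
        vals = np.asarray(list(pairwise_values), dtype=float)
        vals = vals[np.isfinite(vals) & (vals > t_err)]
        # anchor the histogram at t_err so a gap immediately above the error
        # threshold (no mosaic mass at all) is still the first antimode
        anchored = np.concatenate([[t_err], vals])
        try:
            chimera_gap = detect_antimode(anchored, bin_width=bin_width, which="first")
        except NoAntimodeError:
            chimera_gap = None
    if chimera_gap is None:
        warnings.warn("no antimode gap above t_err: all IGV colonies labelled mosaic")

    rows = []
    for _, r in colony_maxima.iterrows():
        m = r["max_percent_diff"]
        if not r.get("classifiable", True) or not np.isfinite(m):
            rows.append((r["colony_id"], m, "unclassifiable", False))
            continue
        if m <= t_err:
            cat, amb = "invariable", False
        elif chimera_gap is None:
            cat, amb = "mosaic", False
        elif m >= chimera_gap.upper:
            cat, amb = "chimeric", False
        elif m <= chimera_gap.lower:
            cat, amb = "mosaic", False
        else:
            # in-gap maxima: the study design expects none; flagged for review
            cat = "chimeric" if m > chimera_gap.midpoint else "mosaic"
            amb = True
        rows.append((r["colony_id"], m, cat, amb))
    table = pd.DataFrame(rows, columns=["colony_id", "max_percent_diff",
                                        "category", "ambiguous"])
    return ColonyClassification(table=table, t_err=t_err, chimera_gap=chimera_gap)


def enumerate_intra_colonial_pairs(classifications: ColonyClassification,
                                   D: DissimilarityMatrix,
                                   meta: pd.DataFrame) -> pd.DataFrame:
    """Split intra-colonial nubbin pairs into chimeric and mosaic-candidate pairs.

    In a chimeric colony the most distant nubbin (largest mean dissimilarity
    to its colony-mates) pairs chimerically with each of the others, and the
    remaining nubbins pair as mosaic candidates among themselves.  Every
    intra-colonial pair of a non-chimeric colony is a mosaic-candidate pair.
    Colonies with a single nubbin are skipped with a warning.

    Returns a frame with columns colony_id, sample_a, sample_b, pair_type.
    """
    collapsed = collapse_replicates(meta)
    collapsed = collapsed[collapsed["sample_id"].isin(D.sample_ids)]
    cat = dict(zip(classifications.table["colony_id"], classifications.table["category"]))
    rows = []
    for colony, group in collapsed.groupby("colony_id", sort=True):
        samples = sorted(group["sample_id"])
        if len(samples) < 2:
            warnings.warn(f"colony {colony} has a single usable nubbin; skipped")
            continue
        if cat.get(colony) == "chimeric":
            sub = D.subset(samples)
            mask = np.ones_like(sub.percent, dtype=bool)
            np.fill_diagonal(mask, False)
            mean_to_mates = np.nanmean(np.where(mask, sub.percent, np.nan), axis=1)
            distant = samples[int(np.nanargmax(mean_to_mates))]
            others = [s for s in samples if s != distant]
            for s in others:
                rows.append((colony, *sorted((distant, s)), "chimeric"))
            for i in range(len(others)):
                for j in range(i + 1, len(others)):
                    rows.append((colony, others[i], others[j], "mosaic"))
        else:
            for i in range(len(samples)):
                for j in range(i + 1, len(samples)):
                    rows.append((colony, samples[i], samples[j], "mosaic"))
    return pd.DataFrame(rows, columns=["colony_id", "sample_a", "sample_b", "pair_type"])


# ---------------------------------------------------------------------------
# association and correlation tests


def association_test(classifications: ColonyClassification, meta: pd.DataFrame,
                     grouping: str, seed: int = 0) -> FisherResult:
    """Fisher exact test of colony category against a metadata grouping.

    ``grouping`` is a per-colony metadata column (``site_label`` or
    ``species_group``).  The contingency table is groups x categories in the
    order invariable, mosaic, chimeric.
    """
    per_colony = meta.drop_duplicates("colony_id")[["colony_id", grouping]]
    merged = classifications.table.merge(per_colony, on="colony_id")
    merged = merged[merged["category"] != "unclassifiable"]
    table = pd.crosstab(merged[grouping], merged["category"])
    order = [c for c in ("invariable", "mosaic", "chimeric") if c in table.columns]
    table = table[order]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least two groups and two categories")
    return fisher_exact_rxc(table.to_numpy(), seed=seed)


def surface_correlation(meta: pd.DataFrame, D: DissimilarityMatrix,
                        pair_set: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of colony surface area vs mean pair dissimilarity.

    Surface area is length x width.  Returns (R^2, two-sided p).
    """
    if pair_set.empty:
        raise ValueError("empty pair set")
    vals = []
    for _, r in pair_set.iterrows():
        vals.append((r["colony_id"], D.value(r["sample_a"], r["sample_b"])))
    per_colony = (pd.DataFrame(vals, columns=["colony_id", "percent_diff"])
                  .groupby("colony_id")["percent_diff"].mean())
    dims = meta.drop_duplicates("colony_id").set_index("colony_id")
    area = (dims["surface_length_cm"] * dims["surface_width_cm"]).reindex(per_colony.index)
    ok = area.notna() & per_colony.notna()
    x, y = area[ok].to_numpy(float), per_colony[ok].to_numpy(float)
    if x.size < 3:
        raise ValueError("need at least three colonies with surface measurements")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r ** 2), float(p)


# ---------------------------------------------------------------------------
# filter grid


def evaluate_filter_grid(gm: GenotypeMatrix, meta: pd.DataFrame,
                         grid: list[FilterConfig],
                         drop_chimeric_nubbins: list[str] | None = None) -> pd.DataFrame:
    """Sweep filter configurations, reporting N_SNP, T50 and delta_rep per row.

    ``drop_chimeric_nubbins``: pre-identified multi-lineage colonies; for each,
    the nubbin most distant from its colony-mates is removed before colony
    maxima are taken (their variability is not in question and would mask the
    filter effects).  Rows whose filters retain no site are recorded with
    N_SNP = 0 and NaN metrics.
    """
    if not grid:
        raise ValueError("empty filter grid")
    rows = []
    for fc in grid:
        try:
            filtered = apply_filters(gm, fc)
        except NoSitesRetainedError:
            rows.append({"label": fc.label(), "n_snp": 0, "t50": np.nan,
                         "delta_rep": np.nan, "delta_rep_se": np.nan})
            continue
        D = pairwise_dissimilarity(filtered)
        try:
            rep = replicate_dissimilarity(D, meta)
            delta_rep, delta_se = rep.delta_rep, rep.se
        except Exception:
            delta_rep, delta_se = np.nan, np.nan

        use_meta = collapse_replicates(meta)
        if drop_chimeric_nubbins:
            drop = set()
            for colony in drop_chimeric_nubbins:
                samples = sorted(use_meta.loc[use_meta["colony_id"] == colony, "sample_id"])
                samples = [s for s in samples if s in D.sample_ids]
                if len(samples) < 3:
                    continue
                sub = D.subset(samples)
                mask = np.ones_like(sub.percent, dtype=bool)
                np.fill_diagonal(mask, False)
                mean_to_mates = np.nanmean(np.where(mask, sub.percent, np.nan), axis=1)
                drop.add(samples[int(np.nanargmax(mean_to_mates))])
            use_meta = use_meta[~use_meta["sample_id"].isin(drop)]
        maxima = colony_max_distance(D, use_meta)
        curve = igv_curve(maxima["max_percent_diff"])
        rows.append({"label": fc.label(), "n_snp": filtered.n_sites, "t50": curve.t50,
                     "delta_rep": delta_rep, "delta_rep_se": delta_se})
    return pd.DataFrame(rows)
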