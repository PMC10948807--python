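"""Pairwise percent-different-alleles, clone calling and replicate error.

The dissimilarity between two samples is the number of allele differences
summed over comparable sites (sites genotyped in both), divided by twice the
number of comparable sites, as a percentage: identical genotypes everywhere
give 0, opposite homozygotes everywhere give 100.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotypes import MISSING, GenotypeMatrix


class NoAntimodeError(ValueError):
    """The histogram has no empty interior bin."""


class NoReplicatesError(ValueError):
    """The metadata contains no replicated nubbin."""


def allele_differences(g1, g2) -> int:
    """Number of differing alleles between two unordered diploid genotypes.

    Genotypes are 2-tuples of allele labels, e.g. ``("A", "T")``.  Returns
    2 minus the size of the maximal multiset intersection, i.e. 0, 1 or 2.
    Missing genotypes (``None`` or containing ``None``) violate the contract:
    callers must skip them.
    """
    if g1 is None or g2 is None or None in g1 or None in g2:
        raise ValueError("allele_differences requires non-missing genotypes")
    c1, c2 = Counter(g1), Counter(g2)
    shared = sum((c1 & c2).values())
    return 2 - shared


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise percent-different-alleles over comparable sites.

    ``percent`` is NaN for pairs with zero comparable sites (flagged in
    ``incomparable_pairs``), 0 on the diagonal.
    """

    sample_ids: list[str]
    percent: np.ndarray
    n_comparable: np.ndarray
    n_allele_diffs: np.ndarray
    incomparable_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def value(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.percent[i, j])

    def to_long(self) -> pd.DataFrame:
        """Long-format table of unordered pairs."""
        rows = []
        n = self.n_samples
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.sample_ids[i], self.sample_ids[j],
                             self.percent[i, j], int(self.n_comparable[i, j]),
                             int(self.n_allele_diffs[i, j])))
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "percent_diff",
                                           "n_comparable", "n_allele_diffs"])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major order (scipy 'condensed' layout)."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.percent[iu]

    def subset(self, keep: list[str]) -> "DissimilarityMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        ix = np.ix_(idx, idx)
        kept = set(keep)
        return DissimilarityMatrix(
            sample_ids=list(keep),
            percent=self.percent[ix].copy(),
            n_comparable=self.n_comparable[ix].copy(),
            n_allele_diffs=self.n_allele_diffs[ix].copy(),
            incomparable_pairs=[p for p in self.incomparable_pairs
                                if p[0] in kept and p[1] in kept],
        )


def pairwise_dissimilarity(gm: GenotypeMatrix) -> DissimilarityMatrix:
    """Exhaustive pairwise dissimilarity over all unordered sample pairs.

    Computed through one-hot dosage indicator products, which reproduces the
    per-site sum of absolute dosage differences exactly.
    """
    gt = gm.gt
    present = (gt != MISSING)
    x0 = ((gt == 0) & present).astype(np.float32)
    x1 = (gt == 1).astype(np.float32)
    x2 = (gt == 2).astype(np.float32)
    m = present.astype(np.float32)

    n_comp = (m.T @ m).round().astype(np.int64)
    one = x0.T @ x1 + x1.T @ x2
    one = one + one.T
    two = x0.T @ x2
    diffs = (one + 2.0 * (two + two.T)).round().astype(np.int64)

    with np.errstate(divide="ignore", invalid="ignore"):
        percent = np.where(n_comp > 0, 100.0 * diffs / (2.0 * np.maximum(n_comp, 1)), np.nan)
    np.fill_diagonal(percent, 0.0)

    incomparable = []
    n = gm.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            if n_comp[i, j] == 0:
                incomparable.append((gm.sample_ids[i], gm.sample_ids[j]))
    if incomparable:
        warnings.warn(f"{len(incomparable)} sample pair(s) share no comparable site")
    return DissimilarityMatrix(sample_ids=list(gm.sample_ids), percent=percent,
                               n_comparable=n_comp, n_allele_diffs=diffs,
                               incomparable_pairs=incomparable)


@dataclass(frozen=True)
class AntimodeGap:
    """An empty interval of the dissimilarity histogram."""

    lower: float
    upper: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower


def detect_antimode(values, bin_width: float = 0.1, which: str = "widest") -> AntimodeGap:
    """Locate an empty gap in the histogram of dissimilarity values.

    Bins of ``bin_width`` are anchored at 0.  ``which="widest"`` returns the
    widest maximal run of empty bins strictly between the first and last
    occupied bins (ties broken towards lower values); ``which="first"``
    returns the lowest such run, which is the relevant one when several gaps
    exist and the threshold sought is the first antimode.

    Raises :class:`NoAntimodeError` when no interior bin is empty.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise NoAntimodeError("need at least two values")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil((v.max() + 1e-12) / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    occupied = np.flatnonzero(counts > 0)
    if occupied.size < 2:
        raise NoAntimodeError("all values fall in a single bin")
    first, last = occupied[0], occupied[-1]

    runs = []  # (length, start_bin, end_bin) of empty runs strictly inside
    i = first + 1
    while i < last:
        if counts[i] == 0:
            j = i
            while counts[j + 1] == 0:
                j += 1
            runs.append((j - i + 1, i, j))
            i = j + 1
        i += 1
    if not runs:
        raise NoAntimodeError("no empty interior bin: no antimode found")
    if which == "widest":
        run = max(runs, key=lambda r: (r[0], -r[1]))
    elif which == "first":
        run = runs[0]
    else:
        raise ValueError("which must be 'widest' or 'first'")
    _, start, end = run
    return AntimodeGap(lower=float(edges[start]), upper=float(edges[end + 1]))


def call_clonal_lineages(D: DissimilarityMatrix, threshold: float) -> pd.Series:
    """Group samples into clonal lineages by single-linkage at ``threshold``.

    Lineages are connected components of the graph linking pairs with
    ``percent_diff < threshold``.  Components whose internal pairs exceed the
    threshold (transitivity violations) are reported as warnings.
    Returns a Series mapping sample_id to an integer lineage label (labelled
    in order of first appearance).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    adj = np.nan_to_num(D.percent, nan=np.inf) < threshold
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    # relabel in order of first appearance for determinism
    order: dict[int, int] = {}
    relabelled = []
    for lab in labels:
        order.setdefault(lab, len(order))
        relabelled.append(order[lab])
    labels = np.array(relabelled)

    for comp in np.unique(labels):
        idx = np.flatnonzero(labels == comp)
        if idx.size > 1:
            sub = D.percent[np.ix_(idx, idx)]
            iu = np.triu_indices(idx.size, k=1)
            bad = np.nan_to_num(sub[iu], nan=0.0) >= threshold
            if bad.any():
                warnings.warn(
                    f"lineage {comp}: {int(bad.sum())} within-lineage pair(s) exceed "
                    f"the {threshold}% threshold (single-linkage chaining)")
    return pd.Series(labels, index=D.sample_ids, name="lineage")


@dataclass
class ReplicateStats:
    """Dissimilarity among sequencing replicates of the same nubbins."""

    per_nubbin: dict[str, list[float]]
    delta_rep: float
    se: float
    n_pairs: int

    def __str__(self) -> str:
        return f"delta_rep = {self.delta_rep:.2f} +/- {self.se:.2f}% ({self.n_pairs} pairs)"


def replicate_dissimilarity(D: DissimilarityMatrix, meta: pd.DataFrame) -> ReplicateStats:
    """Mean (+/- s.e.) dissimilarity between sequencing replicates of a nubbin."""
    groups = meta.groupby("nubbin_id")["sample_id"].apply(list)
    per_nubbin: dict[str, list[float]] = {}
    all_vals: list[float] = []
    for nubbin, samples in groups.items():
        samples = [s for s in samples if s in D.sample_ids]
        if len(samples) < 2:
            continue
        vals = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                vals.append(D.value(samples[i], samples[j]))
        per_nubbin[nubbin] = vals
        all_vals.extend(vals)
    if not all_vals:
        raise NoReplicatesError("no replicated nubbin in the metadata")
    arr = np.array(all_vals)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return ReplicateStats(per_nubbin=per_nubbin, delta_rep=float(arr.mean()),
                          se=se, n_pairs=int(arr.size))
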