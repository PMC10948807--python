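"""Detect IGV: mixture threshold, colony classification, association tests.

Fits the two-component Gaussian mixture to the low-value pairwise
dissimilarities, takes the density intersection as the error threshold,
classifies every colony as invariable / mosaic / chimeric against the
mosaic-chimera antimode, and runs the site and species-group association
tests plus the surface-area correlations.
"""

import warnings

import numpy as np
import pandas as pd

from common import SURVEY, results_path
from coraligv.config import FilterConfig
from coraligv.dissimilarity import pairwise_dissimilarity
from coraligv.genotypes import apply_filters, collapse_replicates
from coraligv.igv import (
    association_test,
    classify_colonies,
    colony_max_distance,
    detect_igv_threshold,
    enumerate_intra_colonial_pairs,
    igv_curve,
    surface_correlation,
)
from coraligv.simulate import simulate_dataset


def main() -> None:
    ds = simulate_dataset(SURVEY)
    filtered = apply_filters(ds.genotypes, FilterConfig())
    D = pairwise_dissimilarity(filtered)
    collapsed = collapse_replicates(ds.meta)
    Dc = D.subset([s for s in D.sample_ids if s in set(collapsed["sample_id"])])
    vals = Dc.condensed()
    vals = vals[np.isfinite(vals)]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_err, fit, gap = detect_igv_threshold(vals, seed=SURVEY.seed)
    print(f"GMM on {fit.n_points} low-value pairs: "
          f"weights ({fit.weights[0]:.3f}, {fit.weights[1]:.3f}), "
          f"means ({fit.means[0]:.3f}, {fit.means[1]:.3f})%, "
          f"sds ({fit.sds[0]:.3f}, {fit.sds[1]:.3f})%")
    print(f"density intersection -> error threshold T_err = {t_err:.2f}%")

    maxima = colony_max_distance(D, ds.meta)
    curve = igv_curve(maxima["max_percent_diff"])
    curve.as_frame().to_csv(results_path("04_igv_curve.tsv"), sep="\t",
                            index=False, float_format="%.4f")
    print(f"T50 (median colony maximum) = {curve.t50:.2f}%")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cls = classify_colonies(maxima, t_err, pairwise_values=vals)
    cls.table.to_csv(results_path("04_classification.tsv"), sep="\t",
                     index=False, float_format="%.4f")
    counts = cls.counts()
    truth = ds.truth.category_counts()
    chim_gap = cls.chimera_gap
    print(f"mosaic/chimera antimode: ({chim_gap.lower:.2f}, {chim_gap.upper:.2f})%")
    print(f"called: {counts}   truth: {truth}")
    agree = (cls.table.set_index("colony_id")["category"]
             == ds.truth.colonies.set_index("colony_id")["category"]).mean()
    print(f"classification agrees with truth for {100 * agree:.1f}% of colonies")

    pairs = enumerate_intra_colonial_pairs(cls, D, ds.meta)
    pairs.to_csv(results_path("04_pair_enumeration.tsv"), sep="\t", index=False)
    print(f"intra-colonial pairs: "
          f"{(pairs['pair_type'] == 'chimeric').sum()} chimeric, "
          f"{(pairs['pair_type'] == 'mosaic').sum()} mosaic-candidate")

    rows = []
    for grouping in ("site_label", "species_group"):
        res = association_test(cls, ds.meta, grouping, seed=SURVEY.seed)
        rows.append((f"fisher_{grouping}", res.p_value, res.method))
        print(f"Fisher exact ({grouping}): p = {res.p_value:.3f} [{res.method}]")
    for ptype in ("chimeric", "mosaic"):
        sub = pairs[pairs["pair_type"] == ptype]
        try:
            r2, p = surface_correlation(ds.meta, D, sub)
            rows.append((f"surface_{ptype}_r2", r2, f"p={p:.3g}"))
            print(f"surface area vs {ptype} dissimilarity: R^2 = {r2:.3f}, p = {p:.3f}")
        except ValueError as exc:
            rows.append((f"surface_{ptype}_r2", np.nan, str(exc)))
    pd.DataFrame(rows, columns=["test", "value", "detail"]).to_csv(
        results_path("04_tests.tsv"), sep="\t", index=False, float_format="%.4f")


if __name__ == "__main__":
    main()
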