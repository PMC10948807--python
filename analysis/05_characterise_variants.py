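"""Characterise the SNPs that differ within colonies.

Splits intra-colonial pairs into chimeric and mosaic-candidate sets,
identifies the sites with different allelic states in each, annotates them
against the reference (genic / coding, codon position, silent / missense /
nonsense, transition / transversion) and weights GO terms by the non-silent
allelic differences hitting their genes.
"""

import json
import warnings

import numpy as np
import pandas as pd

from common import SURVEY, results_path
from coraligv.config import FilterConfig
from coraligv.dissimilarity import pairwise_dissimilarity
from coraligv.effects import (
    differing_snps,
    effect_table,
    go_weighting,
    occurrence_spectrum,
    summarise_effects,
)
from coraligv.genotypes import apply_filters, collapse_replicates
from coraligv.igv import (
    classify_colonies,
    colony_max_distance,
    detect_igv_threshold,
    enumerate_intra_colonial_pairs,
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
        t_err, _, _ = detect_igv_threshold(vals, seed=SURVEY.seed)
        cls = classify_colonies(colony_max_distance(D, ds.meta), t_err,
                                pairwise_values=vals)
        pairs = enumerate_intra_colonial_pairs(cls, D, ds.meta)

    summaries = {}
    for ptype in ("chimeric", "mosaic"):
        sub = pairs[pairs["pair_type"] == ptype]
        diffs = differing_snps(filtered, sub)
        effs = effect_table(filtered, diffs, ds.annotation)
        occ = occurrence_spectrum(diffs)
        (occ["occurrence"].value_counts().sort_index()
            .rename("n_snps").rename_axis("n_colonies").reset_index()
            .to_csv(results_path(f"05_occurrence_hist_{ptype}.tsv"),
                    sep="\t", index=False))
        s = summarise_effects(effs)
        summaries[ptype] = s
        print(f"\n{ptype}: {len(sub)} pairs, {s['n_snps']} differing SNPs, "
              f"{s['n_differences']} allelic differences")
        if s["n_snps"]:
            print(f"  genic {100 * s['genic_snp_fraction']:.1f}%, "
                  f"coding {100 * s['coding_snp_fraction']:.1f}%, "
                  f"single-allele {100 * s['single_allele_fraction']:.1f}%")
        if "effect_by_snp" in s:
            eff = {k: f"{v['percent']:.1f}%" for k, v in s["effect_by_snp"].items()}
            pos = {k: f"{v['percent']:.1f}%"
                   for k, v in s["codon_position_by_snp"].items()}
            print(f"  effects (by SNP): {eff}")
            print(f"  codon positions (by SNP): {pos}")
        ts = s["substitution_by_snp"].get("transition", {"count": 0})["count"]
        tv = s["substitution_by_snp"].get("transversion", {"count": 0})["count"]
        if tv:
            print(f"  transition:transversion = {ts}:{tv} ({ts / tv:.2f})")

        if not effs.empty:
            go = go_weighting(effs, ds.gene2go, min_count=50)
            go.to_csv(results_path(f"05_go_weights_{ptype}.tsv"), sep="\t",
                      index=False)
            kept = go[go["retained"]]
            print(f"  GO terms with >=50 non-silent differences: {len(kept)}")

    with open(results_path("05_effect_summaries.json"), "w") as fh:
        json.dump(summaries, fh, indent=2)


if __name__ == "__main__":
    main()
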