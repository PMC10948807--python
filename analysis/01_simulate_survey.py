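"""Generate the synthetic colony survey and summarise its composition.

Writes the full dataset (VCF/FASTA/GFF3/metadata/truth) under scratch/ and
a small overview table under results/.
"""

import pandas as pd

from common import SURVEY, results_path, scratch_path
from coraligv.genotypes import MISSING
from coraligv.simulate import simulate_dataset, write_dataset


def main() -> None:
    ds = simulate_dataset(SURVEY)
    write_dataset(ds, scratch_path("dataset"))

    gm = ds.genotypes
    truth = ds.truth.category_counts()
    site_classes = ds.truth.sites["location"].value_counts()
    overview = pd.DataFrame([
        ("samples", gm.n_samples),
        ("nubbins", ds.meta["nubbin_id"].nunique()),
        ("colonies", ds.meta["colony_id"].nunique()),
        ("replicated_nubbins", (ds.meta.groupby("nubbin_id").size() == 3).sum()),
        ("candidate_sites", gm.n_sites),
        ("missing_fraction", round(float((gm.gt == MISSING).mean()), 4)),
        ("true_invariable", truth["invariable"]),
        ("true_mosaic", truth["mosaic"]),
        ("true_chimeric", truth["chimeric"]),
        ("coding_sites", int(site_classes.get("coding", 0))),
        ("genic_noncoding_sites", int(site_classes.get("genic_noncoding", 0))),
        ("intergenic_sites", int(site_classes.get("intergenic", 0))),
    ], columns=["quantity", "value"])
    overview.to_csv(results_path("01_survey_overview.tsv"), sep="\t", index=False)

    print(f"survey: {gm.n_samples} samples ({ds.meta['colony_id'].nunique()} colonies) "
          f"x {gm.n_sites} sites")
    print(f"true colony categories: {truth}")
    print(f"site classes: {site_classes.to_dict()}")
    print(f"dataset written to {scratch_path('dataset')}")


if __name__ == "__main__":
    main()
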