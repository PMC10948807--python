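"""Shared configuration of the synthetic colony survey analysed by the
numbered scripts.

The survey mirrors a triplicate-sampled field design: 93 colonies on three
reefs, three nubbins each, three nubbins re-sequenced in triplicate, two
sympatric species groups, 15 clonal lineages.  The site count is scaled to
30,000 (half the full panel) to keep each script in seconds while leaving
the per-pair dissimilarity noise small against the 0.5-percentage-point
somatic-mutation offset; depth-dependent genotyping errors are switched on
so the depth filter has something to remove.
"""

import os

from coraligv.config import SimulationConfig

SEED = 20240318

SURVEY = SimulationConfig(
    n_colonies=93,
    n_sites_total=30_000,
    n_lineages=15,
    mosaic_mutation_count=300,   # keeps the default 0.5-pp mosaic offset at 30k sites
    missing_rate=0.30,
    low_dp_error_multiplier=8.0,
    seed=SEED,
)

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)


def scratch_path(name: str) -> str:
    os.makedirs(SCRATCH, exist_ok=True)
    return os.path.join(SCRATCH, name)
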