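"""Hand-specified synthetic colony structures for worked examples.

These builders construct small dissimilarity matrices and metadata tables
with a prescribed colony composition (how many chimeric / non-chimeric
colonies, how many nubbins each), so the classification and
pair-enumeration rules can be exercised against known bookkeeping without a
full simulated dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dissimilarity import AntimodeGap, DissimilarityMatrix
from .genotypes import META_COLUMNS
from .igv import ColonyClassification, classify_colonies, colony_max_distance


def toy_colony_structure(n_chimeric_3: int, n_chimeric_2: int,
                         n_other_3: int, n_other_2: int,
                         seed: int = 0,
                         t_err: float = 1.0,
                         gap: AntimodeGap = AntimodeGap(1.3, 8.4)):
    """Build (classification, D, meta) for a prescribed colony composition.

    Chimeric colonies get one distant nubbin (dissimilarity drawn inside the
    chimeric band above the gap) and an error-level close pair; other
    colonies get error-level pairs only.  Values are jittered with ``seed``
    but stay inside their bands, so the derived classification is exact.
    """
    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    meta_rows = []
    colonies: list[tuple[str, bool, int]] = []
    c = 0
    for n_nub, chimeric in ((3, True),) * n_chimeric_3 + ((2, True),) * n_chimeric_2 \
            + ((3, False),) * n_other_3 + ((2, False),) * n_other_2:
        c += 1
        colony = f"C{c:03d}"
        colonies.append((colony, chimeric, n_nub))
        for k in range(n_nub):
            sid = f"{colony}N{k + 1}"
            sample_ids.append(sid)
            meta_rows.append({
                "sample_id": sid, "nubbin_id": sid, "colony_id": colony,
                "site_label": "S1", "replicate_of": None,
                "surface_length_cm": 20.0, "surface_width_cm": 15.0,
                "species_group": "GSH1",
            })
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)

    n = len(sample_ids)
    idx = {s: i for i, s in enumerate(sample_ids)}
    percent = np.full((n, n), 25.0)  # inter-colony filler, never used downstream
    np.fill_diagonal(percent, 0.0)

    def _set(a: str, b: str, v: float) -> None:
        i, j = idx[a], idx[b]
        percent[i, j] = percent[j, i] = v

    for colony, chimeric, n_nub in colonies:
        members = [f"{colony}N{k + 1}" for k in range(n_nub)]
        low = rng.uniform(0.2, 0.6, size=4)
        if chimeric:
            high = rng.uniform(gap.upper + 0.2, gap.upper + 2.0)
            # N1 is the distant (foreign) nubbin
            for k, other in enumerate(members[1:]):
                _set(members[0], other, high + 0.05 * k)
            if n_nub == 3:
                _set(members[1], members[2], low[0])
        else:
            for i in range(n_nub):
                for j in range(i + 1, n_nub):
                    _set(members[i], members[j], low[i + j])

    n_comp = np.full((n, n), 1000, dtype=np.int64)
    diffs = np.round(percent / 100.0 * 2 * 1000).astype(np.int64)
    D = DissimilarityMatrix(sample_ids=sample_ids, percent=percent,
                            n_comparable=n_comp, n_allele_diffs=diffs)
    maxima = colony_max_distance(D, meta)
    classification: ColonyClassification = classify_colonies(
        maxima, t_err=t_err, chimera_gap=gap)
    return classification, D, meta
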