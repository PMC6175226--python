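"""Small-study-effect selection filter (publication-bias proxy).

Ranks studies jointly on size and true exposure effect and removes the
lowest-ranked fraction before analysis, inducing an upward selection on the
surviving effects.  Deterministic: no randomness is used.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.stats import rankdata

from .simulate import IPDDataset

__all__ = ["FilterError", "apply_small_study_filter"]


class FilterError(ValueError):
    """Raised when the filter would leave fewer than 2 studies."""


def apply_small_study_filter(dataset: IPDDataset, fraction: float) -> IPDDataset:
    """Drop the floor(fraction * k) studies ranked lowest on size and effect.

    Each study receives an ascending rank on ``n_patients`` and on its TRUE
    exposure effect beta1j (average ranks on ties); the composite score is
    the rank sum.  The studies with the smallest composite are removed, ties
    broken by smaller study id.  Survivors are re-indexed 1..k'; the
    original ids of dropped studies are recorded on the returned dataset.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0.0:
        return dataset

    k = dataset.n_studies
    n_drop = math.floor(fraction * k)
    if n_drop < 1:
        return dataset
    if k - n_drop < 2:
        raise FilterError(
            f"dropping {n_drop} of {k} studies would leave fewer than 2"
        )

    sizes = dataset.study_sizes().astype(float)
    effects = dataset.true_beta1()
    composite = rankdata(sizes, method="average") + rankdata(effects, method="average")
    study_ids = np.array([r.study_id for r in dataset.realizations])

    order = np.lexsort((study_ids, composite))  # composite asc, then id asc
    dropped = set(study_ids[order[:n_drop]].tolist())

    survivors = [r for r in dataset.realizations if r.study_id not in dropped]
    id_map = {r.study_id: new_id for new_id, r in enumerate(survivors, start=1)}

    data = dataset.data[~dataset.data["study_id"].isin(dropped)].copy()
    data["study_id"] = data["study_id"].map(id_map).astype(np.int64)
    data = data.reset_index(drop=True)

    new_reals = tuple(
        replace(r, study_id=id_map[r.study_id]) for r in survivors
    )
    return IPDDataset(
        data=data,
        spec=dataset.spec,
        realizations=new_reals,
        dropped_study_ids=tuple(sorted(dropped)),
    )
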