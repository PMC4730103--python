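"""Consensus enrichment across independent studies of the same contrast.

When several cohorts test the same disease-vs-control contrast, each study's
bootstrap run yields a replicates x groups null matrix and a per-group target
gamma.  Pooling sums the null matrices element-wise (replicate j of every
study is aligned by index) and sums the target gammas, then computes p, fold
and z from the sums exactly as for a single study.  Merging a study with
itself, or with a degenerate all-zero study, therefore reproduces the
single-study p and fold exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core_specificity import EwceError
from .bootstrap_enrichment import (
    BootstrapSampleMatrix,
    EnrichmentResult,
    bootstrap_test,
)


def merge_bootstrap(
    per_study_targets: Sequence[pd.Series],
    per_study_nulls: Sequence[BootstrapSampleMatrix],
    correction: str | None = None,
    continuity: bool = True,
) -> EnrichmentResult:
    """Sum per-study targets and null matrices, then test the consensus.

    All studies must share an identical group set and replicate count;
    mismatches are rejected with a listing rather than resampled.
    """
    if len(per_study_targets) != len(per_study_nulls) or not per_study_nulls:
        raise EwceError("need one target gamma vector per null matrix (>= 1 study)")
    ref = per_study_nulls[0]
    groups = list(ref.groups)
    problems = []
    for i, null in enumerate(per_study_nulls):
        if list(null.groups) != groups:
            problems.append(f"study {i}: groups {list(null.groups)} != {groups}")
        if null.n_replicates != ref.n_replicates:
            problems.append(
                f"study {i}: {null.n_replicates} replicates != {ref.n_replicates}"
            )
    for i, tg in enumerate(per_study_targets):
        if set(tg.index) != set(groups):
            problems.append(f"study {i}: target groups {list(tg.index)} != {groups}")
    if problems:
        raise EwceError("cannot merge studies:\n  " + "\n  ".join(problems))

    consensus_null = BootstrapSampleMatrix(
        values=np.sum([null.values for null in per_study_nulls], axis=0),
        groups=groups,
        n_replicates=ref.n_replicates,
        list_length=sum(null.list_length for null in per_study_nulls),
        mode="+".join(dict.fromkeys(null.mode for null in per_study_nulls)),
        seed=ref.seed,
    )
    consensus_target = sum(tg.loc[groups] for tg in per_study_targets)
    result = bootstrap_test(
        consensus_target, consensus_null, correction=correction, continuity=continuity
    )
    result.list_length = consensus_null.list_length
    return result
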