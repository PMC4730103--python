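"""The expression-weighted enrichment statistic and its bootstrap null.

The test statistic for a gene list ``X`` and group ``c`` is the summed
specificity

    gamma(X, c) = sum_{g in X} e[g, c]

i.e. ``n`` times the average specificity of the list.  Its null distribution
is estimated by drawing many random gene lists of the same length ``n`` from
the background set -- without replacement within a list -- and recording
their gamma in every group.  For each group the report gives

* ``p``      -- fraction of null lists whose gamma is at least the target's
               (ties count against the target); by default the positively
               biased estimator ``(count + 1) / (reps + 1)``, which cannot be
               zero under a finite bootstrap,
* ``fold``   -- target gamma over the mean null gamma,
* ``z``      -- standard deviations (sample SD, ddof=1) separating the target
               gamma from the null mean.

In controlled mode, position ``i`` of every null list is drawn from the
transcript-length/GC decile-grid cell of target gene ``i``, so the null
matches the target's gene-property profile position by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_specificity import EwceError, SpecificityMatrix
from .gene_universe import BackgroundSet, DecileGrid

logger = logging.getLogger("ewce")

DEFAULT_REPLICATES = 100_000
_BATCH = 2048          # replicates per vectorized sampling batch
_MAX_REDRAWS = 200     # rejection rounds for within-list uniqueness


@dataclass
class BootstrapSampleMatrix:
    """Replicates x groups matrix of null summed specificities.

    Entry ``(j, c)`` is gamma of the j-th random list in group ``c``.  The
    sampled gene identities are not retained; the gamma matrix is the
    reusable null, and is the exchange format for multi-study merging.
    """

    values: np.ndarray
    groups: list[str]
    n_replicates: int
    list_length: int
    mode: str              # "uncontrolled" | "controlled"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_replicates, len(self.groups)):
            raise EwceError("null matrix shape disagrees with its metadata")
        if (self.values < 0).any():
            raise EwceError("null summed specificities must be non-negative")


@dataclass
class EnrichmentResult:
    """Per-group enrichment statistics plus run provenance."""

    table: pd.DataFrame   # index group; columns gamma, p, p_adj, fold, z
    genes_used: list[str]
    genes_excluded: list[str]
    n_replicates: int
    seed: int | None
    correction_method: str | None
    mode: str
    list_length: int = 0

    def __post_init__(self) -> None:
        if self.list_length == 0:
            self.list_length = len(self.genes_used)


def summed_specificity(genes: Sequence[str], spec: SpecificityMatrix) -> pd.Series:
    """gamma(X, c): the exact sum of the listed genes' specificity rows.

    Every gene must be present in the matrix; filtering unknown symbols is
    the caller's explicit job so that exclusions stay auditable.
    """
    idx = spec.values.index
    unknown = [g for g in genes if g not in idx]
    if unknown:
        raise EwceError(f"genes absent from the specificity matrix: {unknown[:10]}")
    if len(genes) == 0:
        return pd.Series(0.0, index=spec.values.columns)
    return spec.values.loc[list(genes)].sum(axis=0)


def _null_from_indices(S: np.ndarray, idx: np.ndarray) -> np.ndarray:
    # S: background-genes x groups; idx: batch x n -> batch x groups
    return S[idx].sum(axis=1)


def sample_random_lists(
    background: BackgroundSet,
    spec: SpecificityMatrix,
    n: int,
    reps: int = DEFAULT_REPLICATES,
    seed: int | None = None,
) -> BootstrapSampleMatrix:
    """Draw ``reps`` uniform random lists of ``n`` distinct background genes.

    Each replicate is an unordered simple random sample (without replacement)
    from the background; replicates are independent and the whole matrix is
    deterministic given ``seed``.
    """
    genes = [g for g in background.genes if g in set(spec.genes)]
    if len(genes) < len(background.genes):
        raise EwceError("background contains genes absent from the specificity matrix")
    N = len(genes)
    if n < 1 or reps < 1:
        raise EwceError("list length and replicate count must be positive")
    if n > N:
        raise EwceError(f"cannot draw {n} distinct genes from a background of {N}")
    S = spec.values.loc[genes].to_numpy(float)
    rng = np.random.default_rng(seed)
    out = np.empty((reps, S.shape[1]), dtype=float)
    done = 0
    while done < reps:
        b = min(_BATCH, reps - done)
        # uniform random keys; the n smallest per row form a uniform n-subset
        keys = rng.random((b, N))
        if n == N:
            idx = np.broadcast_to(np.arange(N), (b, N))
        else:
            idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        out[done : done + b] = _null_from_indices(S, idx)
        done += b
    return BootstrapSampleMatrix(
        values=out, groups=list(spec.values.columns),
        n_replicates=reps, list_length=n, mode="uncontrolled", seed=seed,
    )


def sample_controlled_lists(
    target: Sequence[str],
    grid: DecileGrid,
    spec: SpecificityMatrix,
    reps: int = DEFAULT_REPLICATES,
    seed: int | None = None,
) -> BootstrapSampleMatrix:
    """Draw property-matched null lists from the decile grid.

    Position ``i`` of every replicate is uniform over the grid cell of target
    gene ``i``.  Within a replicate, duplicate genes are re-drawn (rejection)
    so each list has ``n`` distinct members; when the combined cell membership
    cannot supply ``n`` distinct genes the replicate keeps its duplicates and
    a single warning is logged.
    """
    target = list(target)
    n = len(target)
    if n < 1 or reps < 1:
        raise EwceError("list length and replicate count must be positive")
    gene_pos = {g: i for i, g in enumerate(spec.genes)}
    cell_members: list[np.ndarray] = []
    for g in target:
        cell = grid.cell_assignment.get(g)
        if cell is None:
            raise EwceError(f"target gene {g!r} has no decile-grid cell")
        members = [m for m in grid.members[cell] if m in gene_pos]
        if not members:
            raise EwceError(
                f"decile-grid cell {cell} of target gene {g!r} has no members "
                "in the specificity matrix"
            )
        cell_members.append(np.array([gene_pos[m] for m in members], dtype=np.int64))
    distinct_pool = len(set(np.concatenate(cell_members).tolist()))
    enforce_unique = distinct_pool >= n
    if not enforce_unique:
        logger.warning(
            "combined grid-cell membership (%d distinct genes) cannot fill "
            "lists of length %d without duplicates; allowing duplicates",
            distinct_pool, n,
        )
    rng = np.random.default_rng(seed)
    S = spec.values.to_numpy(float)
    out = np.empty((reps, S.shape[1]), dtype=float)
    done = 0
    warned_stuck = False
    while done < reps:
        b = min(_BATCH, reps - done)
        draws = np.empty((b, n), dtype=np.int64)
        for i, members in enumerate(cell_members):
            draws[:, i] = members[rng.integers(0, len(members), size=b)]
        if enforce_unique and n > 1:
            for _ in range(_MAX_REDRAWS):
                srt = np.sort(draws, axis=1)
                bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
                if not bad.any():
                    break
                for row in np.flatnonzero(bad):
                    seen: set[int] = set()
                    for i in range(n):
                        v = int(draws[row, i])
                        if v in seen:
                            members = cell_members[i]
                            draws[row, i] = members[rng.integers(0, len(members))]
                        else:
                            seen.add(v)
            else:
                if not warned_stuck:
                    logger.warning(
                        "within-list uniqueness not achieved after %d redraw "
                        "rounds for some replicates; keeping duplicates",
                        _MAX_REDRAWS,
                    )
                    warned_stuck = True
        out[done : done + b] = _null_from_indices(S, draws)
        done += b
    return BootstrapSampleMatrix(
        values=out, groups=list(spec.values.columns),
        n_replicates=reps, list_length=n, mode="controlled", seed=seed,
    )


def bootstrap_test(
    target_gamma: pd.Series,
    null: BootstrapSampleMatrix,
    genes_used: Sequence[str] = (),
    genes_excluded: Sequence[str] = (),
    correction: str | None = None,
    continuity: bool = True,
) -> EnrichmentResult:
    """Compare a target's summed specificities with a bootstrap null.

    ``p`` counts null replicates whose gamma is >= the target's (a large
    target gamma gives a small p; ties count against the target).  With
    ``continuity`` (default) the count and the denominator are both shifted
    by one so a finite bootstrap never reports p = 0; with
    ``continuity=False`` the raw fraction ``count / reps`` is returned and a
    zero is to be read as "p < 1/reps".
    """
    groups = list(null.groups)
    if list(target_gamma.index) != groups:
        if set(target_gamma.index) != set(groups):
            raise EwceError("target and null cover different group sets")
        target_gamma = target_gamma.loc[groups]
    t = target_gamma.to_numpy(float)
    vals = null.values
    reps = null.n_replicates
    count = (vals >= t[None, :]).sum(axis=0)
    if continuity:
        p = (count + 1) / (reps + 1)
    else:
        p = count / reps
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if reps > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean > 0, t / mean, np.nan)
        z = np.where(sd > 0, (t - mean) / sd, np.nan)
    if (sd == 0).any():
        logger.warning(
            "zero bootstrap SD in %d groups; z reported as NaN there",
            int((sd == 0).sum()),
        )
    table = pd.DataFrame(
        {"gamma": t, "p": p, "fold": fold, "z": z}, index=pd.Index(groups, name="group")
    )
    if correction is not None:
        table["p_adj"] = correct_pvalues(table["p"], method=correction)
    else:
        table["p_adj"] = np.nan
    table = table[["gamma", "p", "p_adj", "fold", "z"]]
    return EnrichmentResult(
        table=table,
        genes_used=list(genes_used),
        genes_excluded=list(genes_excluded),
        n_replicates=reps,
        seed=null.seed,
        correction_method=correction,
        mode=null.mode,
        list_length=null.list_length,
    )


def correct_pvalues(p_values, method: str = "bonferroni"):
    """Adjust a family of p-values by Bonferroni or Benjamini-Hochberg.

    The family should be every (list x group x direction) test of one
    analysis, corrected in a single invocation.
    """
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return type(p_values)([]) if isinstance(p_values, list) else arr
    if ((arr <= 0) | (arr > 1)).any():
        raise EwceError("p-values must lie in (0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh", "fdr_bh": "fdr_bh"}.get(
        str(method).lower()
    )
    if key is None:
        raise EwceError(f"unknown correction method {method!r}")
    adj = multipletests(arr, method=key)[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index)
    if isinstance(p_values, list):
        return list(adj)
    return adj


def bootstrap_enrichment(
    target: Sequence[str],
    spec: SpecificityMatrix,
    background: BackgroundSet,
    reps: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    controlled: bool = False,
    grid: DecileGrid | None = None,
    correction: str | None = "bonferroni",
    continuity: bool = True,
) -> EnrichmentResult:
    """End-to-end enrichment test for one gene list.

    Filters the target to genes present in the specificity matrix (reporting
    exclusions), computes its summed specificity, draws the null (uncontrolled
    or decile-grid controlled), and returns per-group statistics.
    """
    target = list(dict.fromkeys(target))
    present = set(spec.genes)
    used = [g for g in target if g in present]
    excluded = [g for g in target if g not in present]
    if controlled and grid is not None:
        in_grid = [g for g in used if g in grid.cell_assignment]
        excluded += [g for g in used if g not in grid.cell_assignment]
        if len(in_grid) < len(used):
            logger.warning(
                "%d target genes lack grid properties and are excluded from "
                "the controlled analysis", len(used) - len(in_grid),
            )
        used = in_grid
    if not used:
        raise EwceError("no usable target genes after filtering")
    gamma = summed_specificity(used, spec)
    if controlled:
        if grid is None:
            raise EwceError("controlled mode requires a decile grid")
        null = sample_controlled_lists(used, grid, spec, reps=reps, seed=seed)
    else:
        null = sample_random_lists(background, spec, len(used), reps=reps, seed=seed)
    return bootstrap_test(
        gamma, null, genes_used=used, genes_excluded=excluded,
        correction=correction, continuity=continuity,
    )
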