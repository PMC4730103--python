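"""Enrichment of the extreme tails of a differential-expression ranking.

For a disease-vs-control transcriptome study the input is a table of
(probe, gene, t-statistic) rows.  Probes are ranked by t; the ``k`` most
positive form the up-regulated set and the ``k`` most negative the
down-regulated set (``k`` = 250 by default).  Where several of the selected
probes target the same gene, the duplicates are dropped *after* selection,
keeping the most extreme probe, and the null lists are drawn with the length
of the resulting unique-gene list.

The null for each direction is equivalent to re-ranking the detected genes
at random: uniform lists drawn from the background restricted to genes
detected in the study and present in the specificity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_specificity import EwceError, SpecificityMatrix
from .gene_universe import BackgroundSet
from .bootstrap_enrichment import (
    DEFAULT_REPLICATES,
    EnrichmentResult,
    bootstrap_test,
    correct_pvalues,
    sample_random_lists,
    summed_specificity,
)

logger = logging.getLogger("ewce")

DEFAULT_TAIL_SIZE = 250
MIN_UNIQUE_GENES = 10


@dataclass
class RankedDETable:
    """Differential-expression results: probe, gene, t-statistic.

    Probe ids are unique; a gene may appear under several probes.
    """

    frame: pd.DataFrame
    study_id: str = ""
    region: str | None = None

    def __post_init__(self) -> None:
        f = self.frame
        if not {"probe", "gene", "t"} <= set(f.columns):
            raise EwceError("DE table needs columns 'probe', 'gene', 't'")
        if f["probe"].duplicated().any():
            dups = f.loc[f["probe"].duplicated(), "probe"].unique().tolist()
            raise EwceError(f"duplicate probe ids: {dups[:10]}")
        if not np.isfinite(f["t"].to_numpy(float)).all():
            raise EwceError("t-statistics must be finite")
        self.frame = f.reset_index(drop=True)


def select_extreme_genes(
    table: RankedDETable,
    k: int = DEFAULT_TAIL_SIZE,
    direction: str = "up",
) -> list[str]:
    """Pick the ``k`` most extreme probes, then deduplicate gene symbols.

    ``direction="up"`` takes the largest t-statistics, ``"down"`` the most
    negative.  Ties at the k-th boundary are broken by stable input order
    (and logged).  Genes hit by more than one selected probe are kept once,
    at their most extreme probe, so the returned list may be shorter than
    ``k`` -- its length is what the null lists must match.
    """
    if direction not in ("up", "down"):
        raise EwceError("direction must be 'up' or 'down'")
    f = table.frame
    if len(f) < k:
        raise EwceError(f"DE table has {len(f)} probes; k={k} requested")
    t = f["t"].to_numpy(float)
    key = -t if direction == "up" else t
    order = np.argsort(key, kind="stable")
    boundary = key[order[k - 1]]
    if k < len(f) and key[order[k]] == boundary:
        logger.info(
            "t-statistic tie at the k=%d boundary (%s direction); broken by "
            "stable input order", k, direction,
        )
    chosen = order[:k]
    genes: list[str] = []
    seen: set[str] = set()
    for i in chosen:  # most-extreme-first, so dedup keeps the extreme probe
        g = str(f["gene"].iloc[i])
        if g not in seen:
            seen.add(g)
            genes.append(g)
    if len(genes) < k:
        logger.info(
            "%d duplicate-gene probes dropped after selection; list length %d",
            k - len(genes), len(genes),
        )
    return genes


def transcriptome_ewce(
    table: RankedDETable,
    spec: SpecificityMatrix,
    universe: BackgroundSet,
    reps: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    k: int = DEFAULT_TAIL_SIZE,
    correction: str = "bh",
    continuity: bool = True,
) -> dict[str, EnrichmentResult]:
    """Run the enrichment test on both tails of a DE ranking.

    ``universe`` must already be restricted to genes detected in the study
    and present in the specificity matrix (see
    :func:`ewce.gene_universe.build_background`).  Multiple-testing
    correction (Benjamini-Hochberg by default) is applied across both
    directions and all groups in one family.

    Both directions draw their null with the same seed, so negating every
    t-statistic swaps the up and down results exactly.
    """
    present = set(spec.genes)
    bg_set = set(universe.genes)
    results: dict[str, EnrichmentResult] = {}
    for direction in ("up", "down"):
        selected = select_extreme_genes(table, k=k, direction=direction)
        used = [g for g in selected if g in present and g in bg_set]
        excluded = [g for g in selected if g not in present or g not in bg_set]
        if len(used) < MIN_UNIQUE_GENES:
            raise EwceError(
                f"only {len(used)} usable unique genes in the {direction} tail "
                f"(minimum {MIN_UNIQUE_GENES})"
            )
        gamma = summed_specificity(used, spec)
        null = sample_random_lists(universe, spec, len(used), reps=reps, seed=seed)
        results[direction] = bootstrap_test(
            gamma, null, genes_used=used, genes_excluded=excluded,
            correction=None, continuity=continuity,
        )
    family = pd.concat(
        [results["up"].table["p"], results["down"].table["p"]],
        keys=["up", "down"],
    )
    adj = correct_pvalues(family, method=correction)
    for direction in ("up", "down"):
        res = results[direction]
        res.table["p_adj"] = adj.loc[direction].to_numpy()
        res.correction_method = correction
    return results
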