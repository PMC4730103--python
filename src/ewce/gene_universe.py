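"""Background gene universes, ortholog mapping, and the length/GC decile grid.

Null gene lists are drawn from a *background set*: the genes quantified in the
single-cell reference (post filtering), optionally further restricted to genes
detected in a disease study, and always including the (mapped) target genes
that survive those restrictions.

Enrichment statistics on gene lists from genetic studies are known to be
biased by gene properties such as transcript length and GC content.  The
controlled bootstrap removes this bias by sampling each null gene from the
same cell of a 10 x 10 grid -- deciles of mean transcript length crossed with
deciles of GC fraction, both computed empirically over the background set --
as the corresponding target gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_specificity import EwceError, SpecificityMatrix

logger = logging.getLogger("ewce")

N_DECILES = 10


@dataclass
class OrthologTable:
    """One-to-one gene symbol pairs between a source and a reference species.

    Built via :meth:`from_pairs`, which drops every symbol involved in a
    many-to-one or one-to-many relation (ambiguous mappings would let one
    specificity row stand in for several source genes).
    """

    source_to_reference: dict[str, str]
    dropped_ambiguous: list[str] = field(default_factory=list)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologTable":
        df = pd.DataFrame(pairs, columns=["source", "reference"])
        df["source"] = df["source"].astype(str).str.strip()
        df["reference"] = df["reference"].astype(str).str.strip()
        if (df["source"] == "").any() or (df["reference"] == "").any():
            raise EwceError("ortholog table contains empty symbols")
        df = df.drop_duplicates()
        multi_src = df["source"].duplicated(keep=False)
        multi_ref = df["reference"].duplicated(keep=False)
        ambiguous = multi_src | multi_ref
        dropped = sorted(df.loc[ambiguous, "source"].unique())
        if dropped:
            logger.warning(
                "dropped %d source symbols with non-1:1 ortholog relations", len(dropped)
            )
        kept = df.loc[~ambiguous]
        return cls(
            source_to_reference=dict(zip(kept["source"], kept["reference"])),
            dropped_ambiguous=dropped,
        )


def map_orthologs(
    symbols: Sequence[str], table: OrthologTable
) -> tuple[list[str], list[str]]:
    """Translate symbols through a 1:1 ortholog table.

    Returns ``(mapped, unmapped)``: mapped preserves input order and drops
    duplicates after translation; every input symbol without a 1:1 partner is
    reported in ``unmapped``.
    """
    mapped: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for s in symbols:
        s = str(s).strip()
        ref = table.source_to_reference.get(s)
        if ref is None:
            unmapped.append(s)
        elif ref not in seen:
            seen.add(ref)
            mapped.append(ref)
    return mapped, unmapped


@dataclass
class GeneProperties:
    """Per-gene mean transcript length (bp) and GC fraction."""

    table: pd.DataFrame  # index gene; columns transcript_length, gc_content

    def __post_init__(self) -> None:
        t = self.table
        if not {"transcript_length", "gc_content"} <= set(t.columns):
            raise EwceError(
                "gene properties need 'transcript_length' and 'gc_content' columns"
            )
        if (t["transcript_length"] <= 0).any():
            raise EwceError("transcript lengths must be positive")
        gc = t["gc_content"]
        if ((gc < 0) | (gc > 1)).any():
            raise EwceError("gc_content must be a fraction in [0, 1]")
        if t.index.duplicated().any():
            raise EwceError("duplicate genes in the property table")


@dataclass
class BackgroundSet:
    """The gene universe null lists are drawn from."""

    genes: list[str]
    excluded_targets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = list(dict.fromkeys(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def build_background(
    spec: SpecificityMatrix,
    target: Sequence[str],
    detected_in_study: set[str] | None = None,
) -> BackgroundSet:
    """Assemble the background: reference genes, optionally study-restricted.

    The background is the set of genes in the specificity matrix, intersected
    with ``detected_in_study`` when given, plus any target genes present in
    the specificity matrix (targets are always eligible for sampling).  Target
    genes absent from the specificity matrix are reported as excluded, never
    silently dropped.
    """
    spec_genes = list(spec.genes)
    spec_set = set(spec_genes)
    target = list(dict.fromkeys(target))
    excluded = [g for g in target if g not in spec_set]
    if excluded:
        logger.warning(
            "%d target genes absent from the specificity matrix are excluded: %s%s",
            len(excluded), excluded[:8], "..." if len(excluded) > 8 else "",
        )
    usable_target = [g for g in target if g in spec_set]
    if detected_in_study is None:
        genes = spec_genes
    else:
        keep = set(detected_in_study) | set(usable_target)
        genes = [g for g in spec_genes if g in keep]
    if len(genes) < len(usable_target):
        raise EwceError("background smaller than the usable target list")
    return BackgroundSet(genes=genes, excluded_targets=excluded)


@dataclass
class DecileGrid:
    """Assignment of background genes to a length-decile x GC-decile grid.

    Decile boundaries are the empirical 10%, 20%, ... 90% quantiles over the
    background genes that have properties.  Bins are right-closed: a gene
    whose value equals a boundary falls in the lower bin.  Axes with fewer
    distinct values than bins collapse to fewer bins.
    """

    length_boundaries: np.ndarray
    gc_boundaries: np.ndarray
    cell_assignment: dict[str, tuple[int, int]]   # gene -> (1-based bins)
    members: dict[tuple[int, int], list[str]]
    missing_properties: list[str] = field(default_factory=list)

    def n_bins(self) -> tuple[int, int]:
        return len(self.length_boundaries) + 1, len(self.gc_boundaries) + 1


def _axis_boundaries(values: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(values, np.arange(1, n_bins) / n_bins)
    qs = np.unique(qs)
    # a boundary at (or above) the maximum would leave the top bin empty
    qs = qs[qs < values.max()]
    if len(qs) < n_bins - 1:
        logger.warning(
            "tied property values collapse a grid axis to %d bins", len(qs) + 1
        )
    return qs


def _bin_of(value: float, boundaries: np.ndarray) -> int:
    # right-closed: value == boundary -> lower bin; 1-based index
    return int(np.searchsorted(boundaries, value, side="left")) + 1


def build_decile_grid(
    background: BackgroundSet,
    props: GeneProperties,
    n_bins: int = N_DECILES,
) -> DecileGrid:
    """Place every background gene with properties into the decile grid."""
    genes = [g for g in background.genes if g in props.table.index]
    missing = [g for g in background.genes if g not in props.table.index]
    if missing:
        logger.warning(
            "%d background genes lack length/GC properties and are excluded "
            "from controlled sampling", len(missing),
        )
    if not genes:
        raise EwceError("no background gene has length/GC properties")
    sub = props.table.loc[genes]
    lb = _axis_boundaries(sub["transcript_length"].to_numpy(float), n_bins)
    gb = _axis_boundaries(sub["gc_content"].to_numpy(float), n_bins)
    li = np.searchsorted(lb, sub["transcript_length"].to_numpy(float), side="left") + 1
    gi = np.searchsorted(gb, sub["gc_content"].to_numpy(float), side="left") + 1
    assignment = {g: (int(a), int(b)) for g, a, b in zip(genes, li, gi)}
    members: dict[tuple[int, int], list[str]] = {}
    for g, cell in assignment.items():
        members.setdefault(cell, []).append(g)
    return DecileGrid(
        length_boundaries=lb,
        gc_boundaries=gb,
        cell_assignment=assignment,
        members=members,
        missing_properties=missing,
    )


def grid_cell_of(gene: str, grid: DecileGrid) -> tuple[int, int]:
    """Look up a gene's (length-decile, gc-decile) cell."""
    try:
        return grid.cell_assignment[gene]
    except KeyError:
        raise EwceError(f"gene {gene!r} is not assigned to the decile grid") from None
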