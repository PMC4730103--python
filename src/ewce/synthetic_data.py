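"""Synthetic references, gene lists, property and DE tables with known truth.

Every stage of the pipeline is testable without downloads: this module plants
marker structure in a simulated single-cell reference and generates gene
lists, differential-expression tables, gene-property tables and ortholog
tables consistent with that truth.

The generative model is deliberately simple.  Each sub-cell type owns a
disjoint set of marker genes; a marker's mean expression is
``baseline_mean * marker_effect`` in its own sub-cell type and
``baseline_mean`` everywhere else; non-markers sit at ``baseline_mean`` in
every cell.  Counts are Poisson or negative-binomial (gamma-Poisson) around
those means.  With ``marker_effect = 1`` all genes are exchangeable and the
downstream p-values must be uniform; with a Poisson noise model and effect
``f`` over ``k`` sub-cell types a planted marker's expected specificity in
its own sub-cell type is ``f / (f + k - 1)``.

Gene-property simulation can correlate transcript length and GC content with
marker status, recreating the confounding that the decile-grid controlled
bootstrap exists to remove: a property-biased "null" list is then covertly
marker-enriched, so the uncontrolled test over-rejects while the controlled
test stays calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_specificity import EwceError, SingleCellDataset
from .gene_universe import GeneProperties, OrthologTable
from .transcriptome_mode import RankedDETable


@dataclass
class SimulationConfig:
    """Conditions for a planted-marker single-cell reference.

    Defaults give a desk-scale reference: 1,000 genes, six sub-cell types
    grouped two-per-cell-type into three cell types, 25 cells per sub-cell
    type, 5% of genes planted as markers of each sub-cell type, five-fold
    marker elevation over a baseline mean of 1 count, negative-binomial noise
    with dispersion 0.5 (UMI-like overdispersion; Poisson is available for
    closed-form checks).
    """

    n_genes: int = 1000
    n_subtypes: int = 6
    celltype_partition: dict[str, str] | None = None  # subtype -> celltype
    cells_per_subtype: int = 25
    marker_fraction: float = 0.05
    marker_effect: float = 5.0
    baseline_mean: float = 1.0
    noise_model: str = "negative-binomial"   # or "poisson"
    dispersion: float = 0.5                  # NB: var = mu + dispersion * mu^2
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_subtypes, self.cells_per_subtype) < 1:
            raise EwceError("all simulation counts must be positive")
        if not (0 <= self.marker_fraction <= 1):
            raise EwceError("marker_fraction must lie in [0, 1]")
        if self.marker_effect <= 0 or self.baseline_mean <= 0:
            raise EwceError("marker_effect and baseline_mean must be positive")
        if self.noise_model not in ("poisson", "negative-binomial"):
            raise EwceError("noise_model must be 'poisson' or 'negative-binomial'")
        if self.celltype_partition is None:
            # pair consecutive subtypes into cell types: (S1,S2)->C1, ...
            self.celltype_partition = {
                f"S{i + 1}": f"C{i // 2 + 1}" for i in range(self.n_subtypes)
            }
        subtypes = [f"S{i + 1}" for i in range(self.n_subtypes)]
        if set(self.celltype_partition) != set(subtypes):
            raise EwceError("celltype_partition must cover exactly the sub-cell types")
        n_markers = int(round(self.marker_fraction * self.n_genes)) * self.n_subtypes
        if n_markers > self.n_genes:
            raise EwceError(
                "marker allocation infeasible: disjoint marker sets need "
                f"{n_markers} genes but only {self.n_genes} exist"
            )

    @property
    def subtypes(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_subtypes)]

    @property
    def markers_per_subtype(self) -> int:
        return int(round(self.marker_fraction * self.n_genes))


@dataclass
class MarkerTruth:
    """Ground truth of a simulation: which genes mark which sub-cell type."""

    markers: dict[str, list[str]]            # subtype -> marker symbols
    genes: list[str] = field(default_factory=list)

    def marker_set(self, group: str | None = None) -> set[str]:
        if group is not None:
            return set(self.markers.get(group, []))
        return {g for ms in self.markers.values() for g in ms}

    def non_markers(self) -> list[str]:
        all_markers = self.marker_set()
        return [g for g in self.genes if g not in all_markers]


def _gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def simulate_sct(config: SimulationConfig) -> tuple[SingleCellDataset, MarkerTruth]:
    """Draw a planted-marker single-cell reference from the generative model."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_symbols(config.n_genes)
    subtypes = config.subtypes
    m = config.markers_per_subtype
    markers: dict[str, list[str]] = {}
    cursor = 0
    for s in subtypes:
        markers[s] = genes[cursor : cursor + m]
        cursor += m

    n_cells = config.n_subtypes * config.cells_per_subtype
    mu = np.full((config.n_genes, n_cells), config.baseline_mean, dtype=float)
    labels = np.repeat(subtypes, config.cells_per_subtype)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for s in subtypes:
        cols = np.flatnonzero(labels == s)
        rows = [gene_pos[g] for g in markers[s]]
        if rows:
            mu[np.ix_(rows, cols)] = config.baseline_mean * config.marker_effect

    if config.noise_model == "poisson":
        counts = rng.poisson(mu)
    else:
        # gamma-Poisson with var = mu + dispersion * mu^2
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)

    cell_ids = [f"cell{j + 1:04d}" for j in range(n_cells)]
    dataset = SingleCellDataset(
        expression=pd.DataFrame(counts, index=genes, columns=cell_ids),
        subtype_of_cell=pd.Series(labels, index=cell_ids),
        celltype_of_subtype=dict(config.celltype_partition),
    )
    return dataset, MarkerTruth(markers=markers, genes=genes)


def simulate_gene_list(
    truth: MarkerTruth,
    group: str,
    n: int,
    purity: float = 1.0,
    seed: int | None = None,
) -> list[str]:
    """A target list: ``ceil(purity * n)`` markers of ``group``, rest non-markers."""
    if not (0 <= purity <= 1):
        raise EwceError("purity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    group_markers = truth.markers.get(group)
    if group_markers is None:
        raise EwceError(f"unknown group {group!r}")
    n_markers = int(np.ceil(purity * n))
    if n_markers > len(group_markers):
        raise EwceError(f"group {group!r} has only {len(group_markers)} markers")
    pool = truth.non_markers()
    if n - n_markers > len(pool):
        raise EwceError("not enough non-marker genes for the requested list")
    chosen = list(rng.choice(group_markers, size=n_markers, replace=False))
    chosen += list(rng.choice(pool, size=n - n_markers, replace=False))
    return chosen


def simulate_de_table(
    truth: MarkerTruth,
    group: str,
    effect: float,
    n_probes_per_gene: int = 1,
    seed: int | None = None,
    study_id: str = "sim",
) -> RankedDETable:
    """A DE table: t ~ N(0,1), shifted by ``effect`` for the group's markers.

    ``n_probes_per_gene > 1`` duplicates every gene across probes (with
    independent noise) to exercise the post-selection deduplication.
    """
    if n_probes_per_gene < 1:
        raise EwceError("n_probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    group_markers = truth.marker_set(group)
    rows = []
    probe = 0
    for g in truth.genes:
        shift = effect if g in group_markers else 0.0
        for _ in range(n_probes_per_gene):
            probe += 1
            rows.append((f"p{probe:06d}", g, rng.normal(shift, 1.0)))
    frame = pd.DataFrame(rows, columns=["probe", "gene", "t"])
    return RankedDETable(frame=frame, study_id=study_id)


def simulate_gene_properties(
    genes: Sequence[str],
    marker_genes: Sequence[str] = (),
    correlation_with_marker_status: float = 0.0,
    seed: int | None = None,
) -> GeneProperties:
    """Transcript lengths (log-normal) and GC fractions (beta) per gene.

    ``correlation_with_marker_status`` shifts the marker genes' log-lengths
    upward by that many baseline standard deviations (and nudges their GC
    draws), creating the length/GC confounding the controlled bootstrap
    corrects.  Zero leaves properties independent of marker status.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    is_marker = np.array([g in set(marker_genes) for g in genes])
    c = float(correlation_with_marker_status)
    log_mu, log_sigma = 7.6, 0.7          # median length ~ 2 kb
    loglen = rng.normal(log_mu, log_sigma, len(genes))
    loglen[is_marker] += c * log_sigma
    lengths = np.exp(loglen)
    gc = rng.beta(18, 22, len(genes))     # mean 0.45
    gc[is_marker] = np.clip(gc[is_marker] + 0.02 * c, 0.01, 0.99)
    return GeneProperties(
        table=pd.DataFrame(
            {"transcript_length": lengths, "gc_content": gc},
            index=pd.Index(genes, name="gene"),
        )
    )


def simulate_property_biased_list(
    genes: Sequence[str],
    props: GeneProperties,
    n: int,
    bias: float = 2.0,
    seed: int | None = None,
) -> list[str]:
    """A "null" list drawn with probability proportional to length-decile^bias.

    Emulates the selection bias of genetic studies toward long genes,
    operating on coarse length classes: a gene's sampling weight is its
    empirical length-decile index (1-10) raised to ``bias``, uniform within
    a decile.  With properties correlated to marker status, such lists are
    covertly marker-enriched even though no marker information is used.
    """
    rng = np.random.default_rng(seed)
    genes = [g for g in genes if g in props.table.index]
    if n > len(genes):
        raise EwceError("not enough genes with properties for the requested list")
    lengths = props.table.loc[genes, "transcript_length"].to_numpy(float)
    boundaries = np.quantile(lengths, np.arange(1, 10) / 10)
    decile = np.searchsorted(np.unique(boundaries), lengths, side="left") + 1
    w = decile.astype(float) ** bias
    w = w / w.sum()
    return list(rng.choice(genes, size=n, replace=False, p=w))


def simulate_ortholog_table(
    genes: Sequence[str],
    dropout: float = 0.0,
    prefix: str = "HS_",
    seed: int | None = None,
) -> OrthologTable:
    """Symbol-to-symbol ortholog fixture, dropping a ``dropout`` fraction."""
    if not (0 <= dropout < 1):
        raise EwceError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(genes)) >= dropout
    pairs = [(prefix + g, g) for g, k in zip(genes, keep) if k]
    return OrthologTable.from_pairs(pairs)
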