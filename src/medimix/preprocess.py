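"""Count-table preprocessing, the log-proportion mediator transform, and
genus-level alpha diversity.

The filtering chain reproduces the standard amplicon workflow for this kind
of cohort: drop non-bacterial domains, aggregate OTUs to genus, drop
low-depth samples (< 1,000 reads), keep prevalent genera (> 3 counts in at
least 5% of samples), and drop patients represented by a single sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable, logger as _io_logger

logger = logging.getLogger("medimix")

DEFAULT_EXCLUDED_DOMAINS = frozenset({"Archaea", "Eukarya"})


@dataclass
class FilterReport:
    """Per-step record of taxa/sample attrition along the filter chain."""

    steps: list = field(default_factory=list)

    def record(self, step, n_taxa_in, n_taxa_out, n_samples_in, n_samples_out):
        if n_taxa_out > n_taxa_in or n_samples_out > n_samples_in:
            raise ValueError("filter step increased taxa or sample count")
        self.steps.append(
            dict(
                step=step,
                n_taxa_in=n_taxa_in,
                n_taxa_out=n_taxa_out,
                n_samples_in=n_samples_in,
                n_samples_out=n_samples_out,
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps,
            columns=["step", "n_taxa_in", "n_taxa_out", "n_samples_in", "n_samples_out"],
        )

    def write(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def exclude_domains(table: CountTable, excluded=DEFAULT_EXCLUDED_DOMAINS) -> CountTable:
    """Remove taxa whose lineage domain is in ``excluded``.

    Taxa with an empty/unparseable domain rank are retained (conservative)
    and logged.
    """
    excluded = {str(d).lower() for d in excluded}
    domains = table.rank_values("domain")
    n_blank = sum(1 for d in domains if not d)
    if n_blank:
        logger.warning("exclude_domains: %d taxa with missing domain rank retained", n_blank)
    keep = [d.lower() not in excluded for d in domains]
    out = table.select_taxa(keep)
    logger.info("exclude_domains: %d -> %d taxa", table.n_taxa, out.n_taxa)
    return out


def aggregate_genus(table: CountTable) -> CountTable:
    """Sum counts over taxa sharing a genus; empty genus pools to 'unclassified'.

    Column sums (sample depths) are preserved exactly.
    """
    genera = [g if g else "unclassified" for g in table.rank_values("genus")]
    order: list = []
    index: dict = {}
    for g in genera:
        if g not in index:
            index[g] = len(order)
            order.append(g)
    counts = np.zeros((len(order), table.n_samples), dtype=np.int64)
    lineages = [None] * len(order)
    for row, g in enumerate(genera):
        i = index[g]
        counts[i] += table.counts[row]
        if lineages[i] is None:
            lin = list(table.lineages[row])
            lin[-1] = g
            lineages[i] = tuple(lin)
    return CountTable(counts, order, lineages, list(table.sample_ids))


def filter_sample_depth(table: CountTable, min_reads: int = 1000) -> CountTable:
    """Drop samples whose total read count is below ``min_reads``.

    A depth of exactly ``min_reads`` is retained.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    depths = table.depths
    keep = depths >= min_reads
    if not keep.any():
        raise ValueError(f"all samples below the {min_reads}-read depth threshold")
    if not keep.all():
        logger.info(
            "filter_sample_depth: removed %d/%d samples below %d reads",
            int((~keep).sum()), table.n_samples, min_reads,
        )
    ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return table.select_samples(ids)


def prevalence_filter(
    table: CountTable, min_count: int = 3, min_fraction: float = 0.05
) -> CountTable:
    """Keep taxa with more than ``min_count`` reads in at least
    ``min_fraction`` of samples.

    The count threshold is strict (``> min_count``); the fraction threshold
    is inclusive (``>= min_fraction``).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    qualifying = (table.counts > min_count).sum(axis=1)
    keep = qualifying / table.n_samples >= min_fraction
    if not keep.any():
        raise ValueError("prevalence filter removed every taxon")
    if not keep.all():
        logger.info(
            "prevalence_filter: removed %d/%d taxa (<=%d counts in <%.1f%% of samples)",
            int((~keep).sum()), table.n_taxa, min_count, 100 * min_fraction,
        )
    return table.select_taxa(keep)


def drop_singleton_clusters(meta: pd.DataFrame) -> pd.DataFrame:
    """Drop patients (clusters) contributing exactly one sample."""
    sizes = meta.groupby("cluster_id")["cluster_id"].transform("size")
    keep = sizes >= 2
    if not keep.any():
        raise ValueError("every cluster is a singleton; nothing left to analyze")
    dropped = meta.loc[~keep, "cluster_id"].nunique()
    if dropped:
        logger.info("drop_singleton_clusters: removed %d single-sample patient(s)", dropped)
    return meta.loc[keep]


def preprocess_counts(
    table: CountTable,
    excluded_domains=DEFAULT_EXCLUDED_DOMAINS,
    min_reads: int = 1000,
    min_count: int = 3,
    min_fraction: float = 0.05,
):
    """Run the fixed filter chain and return (table, FilterReport).

    Order: exclude_domains -> aggregate_genus -> filter_sample_depth ->
    prevalence_filter.  The chain is idempotent.
    """
    report = FilterReport()
    stages = [
        ("exclude_domains", lambda t: exclude_domains(t, excluded_domains)),
        ("aggregate_genus", aggregate_genus),
        ("filter_sample_depth", lambda t: filter_sample_depth(t, min_reads)),
        ("prevalence_filter", lambda t: prevalence_filter(t, min_count, min_fraction)),
    ]
    for name, fn in stages:
        nt, ns = table.n_taxa, table.n_samples
        table = fn(table)
        report.record(name, nt, table.n_taxa, ns, table.n_samples)
    return table, report


# ---------------------------------------------------------------------------
# mediator transform
# ---------------------------------------------------------------------------

def lognorm_transform(table: CountTable, pseudo: float = 0.5, placement: str = "count") -> pd.DataFrame:
    """Log10 proportion transform with a pseudo-count, samples x taxa.

    With ``placement='count'`` (default) the pseudo-count is added to the
    numerator read count and divided by the unmodified sample depth:
    ``log10((M + 0.5) / D)``, which is finite at zero counts.  The
    alternative ``placement='proportion'`` adds the pseudo-count to the
    proportion itself: ``log10(M/D + 0.5)``.
    """
    depths = table.depths.astype(float)
    if (depths <= 0).any():
        bad = [s for s, d in zip(table.sample_ids, depths) if d <= 0]
        raise ValueError(f"zero-depth sample(s): {bad}")
    counts = table.counts.T.astype(float)  # samples x taxa
    if placement == "count":
        vals = np.log10((counts + pseudo) / depths[:, None])
    elif placement == "proportion":
        vals = np.log10(counts / depths[:, None] + pseudo)
    else:
        raise ValueError(f"unknown pseudo-count placement: {placement!r}")
    return pd.DataFrame(vals, index=table.sample_ids, columns=table.taxon_ids)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: CountTable, index: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity at the table's taxonomic level.

    observed: count of taxa with nonzero reads.
    shannon:  -sum p ln p  (natural log; 0 ln 0 := 0).
    simpson:  Gini-Simpson 1 - sum p^2.
    inverse_simpson: 1 / sum p^2.
    """
    depths = table.depths.astype(float)
    if (depths <= 0).any():
        bad = [s for s, d in zip(table.sample_ids, depths) if d <= 0]
        raise ValueError(f"zero-depth sample(s): {bad}")
    counts = table.counts.astype(float)
    p = counts / depths[None, :]
    if index == "observed":
        vals = (counts > 0).sum(axis=0).astype(float)
    elif index == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        vals = -plogp.sum(axis=0)
    elif index == "simpson":
        vals = 1.0 - (p**2).sum(axis=0)
    elif index == "inverse_simpson":
        vals = 1.0 / (p**2).sum(axis=0)
    else:
        raise ValueError(f"unknown alpha-diversity index: {index!r}")
    return pd.Series(vals, index=table.sample_ids, name=index)
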