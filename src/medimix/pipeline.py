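"""End-to-end orchestration of the two analysis modes.

taxa mode:      align -> exclude_domains -> aggregate_genus ->
                filter_sample_depth -> prevalence_filter ->
                drop_singleton_clusters -> log-proportion transform ->
                contrast subset -> cluster bootstrap of the debiased-lasso
                mediation -> effect table.

community mode: same preprocessing through drop_singleton_clusters, then a
                genus-level alpha-diversity index as the single mediator
                (entering the models untransformed) and the REML
                single-mediator mediation under the same bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import preprocess as prep
from .bootstrap import bootstrap_mediation
from .io import CountTable, align
from .mediation import Contrast, subset_contrast

logger = logging.getLogger("medimix")


@dataclass
class RunConfig:
    """Configuration for one pipeline invocation."""

    mode: str = "taxa"                       # "taxa" or "community"
    exposure: str = "clinical_state"
    reference: str = "baseline"
    comparison: str = "exacerbation"
    index: str = "shannon"                   # community mode only
    covariates: tuple = ("age",)
    min_reads: int = 1000
    prev_count: int = 3
    prev_fraction: float = 0.05
    excluded_domains: tuple = ("Archaea", "Eukarya")
    pseudo_placement: str = "count"
    n_boot: int = 3000
    seed: int = 0
    threads: int = 1
    ci_level: float = 0.95
    a: object = "cv"
    lam: object = "cv"
    cv_folds: int = 5

    def contrast(self) -> Contrast:
        return Contrast(self.exposure, self.reference, self.comparison)

    def to_dict(self) -> dict:
        return asdict(self)


def _prepare(counts: CountTable, meta: pd.DataFrame, config: RunConfig):
    """Shared preprocessing: align, filter chain, singleton-cluster drop."""
    counts, meta = align(counts, meta)
    counts, report = prep.preprocess_counts(
        counts,
        excluded_domains=set(config.excluded_domains),
        min_reads=config.min_reads,
        min_count=config.prev_count,
        min_fraction=config.prev_fraction,
    )
    meta = meta.loc[counts.sample_ids]
    n_before = counts.n_samples
    meta = prep.drop_singleton_clusters(meta)
    counts = counts.select_samples(list(meta.index))
    report.record(
        "drop_singleton_clusters", counts.n_taxa, counts.n_taxa,
        n_before, counts.n_samples,
    )
    return counts, meta, report


def run_taxa_mediation(config: RunConfig, counts: CountTable, meta: pd.DataFrame):
    """Taxa-level mediation for one contrast.

    Returns (effect_table, filter_report, bootstrap_result).
    """
    try:
        counts, meta, report = _prepare(counts, meta, config)
        mlog = prep.lognorm_transform(counts, placement=config.pseudo_placement)
        frame = subset_contrast(mlog, meta, config.contrast(), config.covariates)
    except Exception as exc:
        raise RuntimeError(f"[preprocessing] {exc}") from exc
    boot = bootstrap_mediation(
        frame, mode="taxa", B=config.n_boot, seed=config.seed,
        n_jobs=config.threads, level=config.ci_level,
        analysis_params=dict(a=config.a, lam=config.lam, cv=config.cv_folds,
                             random_state=config.seed),
    )
    return boot.to_effect_table(config.contrast().name), report, boot


def run_community_mediation(config: RunConfig, counts: CountTable, meta: pd.DataFrame):
    """Community-level (alpha-diversity) mediation for one contrast.

    The diversity index is computed at genus level on the filtered counts
    and enters the outcome model untransformed.
    """
    try:
        counts, meta, report = _prepare(counts, meta, config)
        diversity = prep.alpha_diversity(counts, config.index)
        mediator = diversity.to_frame()
        frame = subset_contrast(mediator, meta, config.contrast(), config.covariates)
    except Exception as exc:
        raise RuntimeError(f"[preprocessing] {exc}") from exc
    boot = bootstrap_mediation(
        frame, mode="community", B=config.n_boot, seed=config.seed,
        n_jobs=config.threads, level=config.ci_level,
    )
    return boot.to_effect_table(config.contrast().name), report, boot
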