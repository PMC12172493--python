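"""Contrast construction and direct/indirect/total effect composition.

Two analysis modes share the same structural logic:

* taxa mode — the outcome model is the high-dimensional debiased lasso LMM
  over all genus-level mediators jointly, and each mediator gets its own
  REML random-intercept model for the exposure -> mediator path;
* community mode — a single continuous mediator (an alpha-diversity
  index), with both linked models fitted by REML (no penalization needed).

In both, the indirect effect of mediator t is the product of coefficients
delta_T^t * beta_{M_t}, and the total effect is direct + sum of indirects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .hdlmm import DebiasedLassoLMM
from .io import AGGRESSIVENESS_LEVELS, CLINICAL_STATES
from .lmm import RandomInterceptLMM, fit_mediator_model

logger = logging.getLogger("medimix")


@dataclass(frozen=True)
class Contrast:
    """A two-level exposure comparison (reference -> comparison)."""

    exposure: str  # "clinical_state" or "aggressiveness"
    reference: str
    comparison: str

    def __post_init__(self):
        allowed = {
            "clinical_state": set(CLINICAL_STATES),
            "aggressiveness": set(AGGRESSIVENESS_LEVELS),
        }
        if self.exposure not in allowed:
            raise ValueError(f"unknown exposure variable: {self.exposure!r}")
        for level in (self.reference, self.comparison):
            if level not in allowed[self.exposure]:
                raise ValueError(
                    f"unknown {self.exposure} level {level!r}; "
                    f"allowed: {sorted(allowed[self.exposure])}"
                )
        if self.reference == self.comparison:
            raise ValueError("contrast levels must differ")

    @property
    def name(self) -> str:
        return f"{self.reference}-{self.comparison}"


#: the six pairwise clinical-state contrasts plus the phenotype contrast
ALL_CONTRASTS = tuple(
    [
        Contrast("clinical_state", a, b)
        for i, a in enumerate(CLINICAL_STATES)
        for b in CLINICAL_STATES[i + 1 :]
    ]
    + [Contrast("aggressiveness", "mild", "moderate_severe")]
)


@dataclass
class StudyFrame:
    """Aligned per-sample arrays consumed by every model.

    Rows are cluster-contiguous (patient blocks in first-appearance order).
    """

    Y: np.ndarray
    T: np.ndarray
    C: np.ndarray                      # N x c covariates (possibly 0 columns)
    Mlog: np.ndarray                   # N x H mediators
    cluster_ids: np.ndarray
    mediator_names: list = field(default_factory=list)
    covariate_names: list = field(default_factory=list)

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.T = np.asarray(self.T, dtype=float).ravel()
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim == 1:
            self.C = self.C[:, None]
        self.Mlog = np.asarray(self.Mlog, dtype=float)
        if self.Mlog.ndim == 1:
            self.Mlog = self.Mlog[:, None]
        self.cluster_ids = np.asarray(self.cluster_ids)
        N = len(self.Y)
        for name, arr in (("T", self.T), ("C", self.C), ("Mlog", self.Mlog),
                          ("cluster_ids", self.cluster_ids)):
            if len(arr) != N:
                raise ValueError(f"{name} row count {len(arr)} != N={N}")
        if not np.isfinite(self.Mlog).all():
            raise ValueError("Mlog contains missing/non-finite values")
        if not set(np.unique(self.T)) <= {0.0, 1.0}:
            raise ValueError("T must be binary 0/1")
        if not self.mediator_names:
            self.mediator_names = [f"M{t}" for t in range(self.Mlog.shape[1])]
        if not self.covariate_names:
            self.covariate_names = [f"C{j}" for j in range(self.C.shape[1])]
        self._sort_clusters()

    def _sort_clusters(self):
        g = self.cluster_ids
        _, first = np.unique(g, return_index=True)
        rank = {g[i]: r for r, i in enumerate(np.sort(first))}
        order = np.argsort([rank[v] for v in g], kind="stable")
        for name in ("Y", "T", "C", "Mlog", "cluster_ids"):
            setattr(self, name, getattr(self, name)[order])

    @property
    def n_obs(self) -> int:
        return len(self.Y)

    @property
    def n_mediators(self) -> int:
        return self.Mlog.shape[1]

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster_ids))

    @property
    def cluster_sizes(self) -> np.ndarray:
        g = self.cluster_ids
        starts = np.flatnonzero(np.concatenate([[True], g[1:] != g[:-1]]))
        return np.diff(np.concatenate([starts, [len(g)]]))

    def take_clusters(self, labels, relabel=None):
        """Rows of the given clusters concatenated in the given order.

        ``relabel`` supplies replacement cluster ids (needed when a
        bootstrap resample repeats a cluster).
        """
        g = self.cluster_ids
        blocks = {lab: np.flatnonzero(g == lab) for lab in set(labels)}
        rows, new_ids = [], []
        for k, lab in enumerate(labels):
            idx = blocks[lab]
            rows.append(idx)
            new_ids.extend([relabel[k] if relabel is not None else lab] * len(idx))
        rows = np.concatenate(rows)
        return StudyFrame(
            Y=self.Y[rows], T=self.T[rows], C=self.C[rows], Mlog=self.Mlog[rows],
            cluster_ids=np.asarray(new_ids),
            mediator_names=list(self.mediator_names),
            covariate_names=list(self.covariate_names),
        )


def build_study_frame(
    Mlog: pd.DataFrame, meta: pd.DataFrame, contrast: Contrast, covariates=("age",)
) -> StudyFrame:
    """Assemble a :class:`StudyFrame` for one contrast (see subset_contrast)."""
    return subset_contrast(Mlog, meta, contrast, covariates)


def subset_contrast(
    Mlog: pd.DataFrame, meta: pd.DataFrame, contrast: Contrast, covariates=("age",)
) -> StudyFrame:
    """Restrict to the contrast's two exposure levels and binarize T.

    T = 1 for the comparison level, 0 for the reference.  Clusters losing
    every sample are dropped; clusters reduced to one sample are retained
    (the random intercept absorbs them).
    """
    meta = meta.loc[Mlog.index]
    col = meta[contrast.exposure]
    for level in (contrast.reference, contrast.comparison):
        if not (col == level).any():
            raise ValueError(
                f"contrast level {level!r} has zero samples for {contrast.exposure}"
            )
    keep = col.isin([contrast.reference, contrast.comparison])
    meta_sub = meta.loc[keep]
    return StudyFrame(
        Y=meta_sub["fev1_pct"].to_numpy(dtype=float),
        T=(meta_sub[contrast.exposure] == contrast.comparison).to_numpy(dtype=float),
        C=meta_sub[list(covariates)].to_numpy(dtype=float)
        if covariates else np.empty((keep.sum(), 0)),
        Mlog=Mlog.loc[keep].to_numpy(dtype=float),
        cluster_ids=meta_sub["cluster_id"].to_numpy(),
        mediator_names=list(Mlog.columns),
        covariate_names=list(covariates),
    )


# ---------------------------------------------------------------------------
# effects
# ---------------------------------------------------------------------------

@dataclass
class MediationEffects:
    """Direct, per-mediator indirect, and total effect for one contrast.

    The identity total = direct + sum(indirect) holds by construction;
    failed mediator fits appear as NaN indirect effects and are excluded
    from the total (with a warning already logged at fit time).
    """

    direct: float
    indirect: dict
    mediator_names: list

    @property
    def total(self) -> float:
        vals = [v for v in self.indirect.values() if np.isfinite(v)]
        return self.direct + float(np.sum(vals))

    def as_vector(self) -> np.ndarray:
        """(direct, total, indirect...) in a fixed order for bootstrapping."""
        return np.concatenate(
            [[self.direct, self.total], [self.indirect[m] for m in self.mediator_names]]
        )

    @staticmethod
    def effect_labels(mediator_names) -> list:
        return ["direct", "total"] + [f"indirect:{m}" for m in mediator_names]


def compose_effects(direct: float, mediator_deltas: dict, beta_M: dict) -> MediationEffects:
    """Product-of-coefficients composition: indirect_t = delta_T^t * beta_M_t."""
    if set(mediator_deltas) != set(beta_M):
        raise ValueError(
            "mediator name mismatch between exposure->mediator and "
            "mediator->outcome coefficients"
        )
    names = list(mediator_deltas)
    indirect = {m: float(mediator_deltas[m]) * float(beta_M[m]) for m in names}
    return MediationEffects(direct=float(direct), indirect=indirect, mediator_names=names)


# ---------------------------------------------------------------------------
# model orchestration
# ---------------------------------------------------------------------------

def fit_taxa_outcome(frame: StudyFrame, **tuning) -> DebiasedLassoLMM:
    """Debiased-lasso outcome model on X = [intercept | T | C | Mlog]."""
    if frame.n_mediators < 1:
        raise ValueError("taxa outcome model requires at least one mediator")
    X = np.column_stack([frame.T, frame.C, frame.Mlog])
    est = DebiasedLassoLMM(**tuning)
    est.fit(X, frame.Y, frame.cluster_ids)
    est.coord_names_ = (
        ["T"] + list(frame.covariate_names) + list(frame.mediator_names)
    )
    return est


def fit_all_mediator_models(frame: StudyFrame):
    """One REML random-intercept fit per mediator; returns {name: delta_T}.

    A mediator whose fit fails is recorded as NaN (missing indirect
    effect), never silently zero.
    """
    deltas, failures = {}, []
    C = frame.C if frame.C.shape[1] else None
    for t, name in enumerate(frame.mediator_names):
        try:
            fit = fit_mediator_model(frame.Mlog[:, t], frame.T, C, frame.cluster_ids)
            deltas[name] = float(fit.coef_[0])
        except Exception as exc:  # noqa: BLE001 - surfaced, not swallowed
            failures.append((name, str(exc)))
            deltas[name] = np.nan
    if failures:
        logger.warning(
            "fit_all_mediator_models: %d mediator fit(s) failed and will be "
            "missing from the total effect: %s", len(failures), failures[:5],
        )
    return deltas


class TaxaMediation(BaseEstimator):
    """High-dimensional (taxa-level) mediation analysis for one contrast.

    fit(frame) runs the debiased-lasso outcome model and the per-mediator
    REML models and composes effects; fitted attributes:

    effects_ : MediationEffects
    outcome_fit_ : DebiasedLassoLMM
    mediator_deltas_ : dict mediator -> delta_T
    """

    def __init__(self, a="cv", lam="cv", cv=5, random_state=0,
                 a_candidates=None, multipliers=None):
        self.a = a
        self.lam = lam
        self.cv = cv
        self.random_state = random_state
        self.a_candidates = a_candidates
        self.multipliers = multipliers

    def fit(self, frame: StudyFrame):
        tuning = dict(a=self.a, lam=self.lam, cv=self.cv,
                      random_state=self.random_state)
        if self.a_candidates is not None:
            tuning["a_candidates"] = self.a_candidates
        if self.multipliers is not None:
            tuning["multipliers"] = self.multipliers
        outcome = fit_taxa_outcome(frame, **tuning)
        names = outcome.coord_names_
        beta_db = dict(zip(names, outcome.coef_db_))
        deltas = fit_all_mediator_models(frame)
        beta_M = {m: beta_db[m] for m in frame.mediator_names}
        self.effects_ = compose_effects(beta_db["T"], deltas, beta_M)
        self.outcome_fit_ = outcome
        self.mediator_deltas_ = deltas
        return self


class CommunityMediation(BaseEstimator):
    """Single-mediator (alpha-diversity) mediation, both models by REML.

    Outcome: Y ~ T + M + C + intercept + patient intercept.
    Mediator: M ~ T + C + intercept + patient intercept.
    """

    def fit(self, frame: StudyFrame):
        if frame.n_mediators != 1:
            raise ValueError(
                f"community mode requires exactly one mediator, got {frame.n_mediators}"
            )
        M = frame.Mlog[:, 0]
        C = frame.C if frame.C.shape[1] else None
        constant_mediator = np.ptp(M) == 0.0
        cols = [frame.T] + ([] if constant_mediator else [M])
        if C is not None:
            cols.append(C)
        X = np.column_stack(cols)
        outcome = RandomInterceptLMM(fit_intercept=True).fit(X, frame.Y, frame.cluster_ids)
        name = frame.mediator_names[0]
        if constant_mediator:
            # a constant mediator cannot transmit any effect; its outcome
            # coefficient is unidentified (collinear with the intercept)
            logger.warning("community mediator %r is constant; indirect effect is 0", name)
            mediator_delta, beta_M = 0.0, 0.0
            mediator = None
        else:
            mediator = fit_mediator_model(M, frame.T, C, frame.cluster_ids)
            mediator_delta, beta_M = mediator.coef_[0], outcome.coef_[1]
        self.effects_ = compose_effects(
            direct=outcome.coef_[0],
            mediator_deltas={name: mediator_delta},
            beta_M={name: beta_M},
        )
        self.outcome_fit_ = outcome
        self.mediator_fit_ = mediator
        return self


def community_mediation(frame: StudyFrame) -> MediationEffects:
    """Functional wrapper over :class:`CommunityMediation`."""
    return CommunityMediation().fit(frame).effects_


def taxa_mediation(frame: StudyFrame, **params) -> MediationEffects:
    """Functional wrapper over :class:`TaxaMediation`."""
    return TaxaMediation(**params).fit(frame).effects_
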