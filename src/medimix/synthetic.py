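"""Synthetic longitudinal, clustered, compositional datasets with known
direct and indirect effects.

The generator emulates the structure of a repeated-measures sputum
microbiome cohort: patients (clusters) contribute variable numbers of
samples; a binary exposure (clinical state, varying within patient, or a
patient-level phenotype) shifts the latent log-abundance of a sparse set
of genera; counts are drawn multinomially at a realistic sequencing depth;
and a lung-function-like outcome is a linear function of the exposure, the
true log-proportions, age, a patient random intercept, and noise.

Because the outcome is generated from the *true* log-proportions (not the
pseudo-counted transform), estimation error introduced by the pseudo-count
is a measured property of the pipeline rather than baked into the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable, validate_metadata
from .mediation import StudyFrame


@dataclass
class SyntheticConfig:
    """Study-scale defaults mimic the cohort the pipeline targets:
    ~89 patients with 2-24 samples each, 47 genera, an FEV1%-like outcome
    (intercept 58, residual SD 8), and ages 6-54 years."""

    n: int = 89                      # clusters (patients)
    cluster_size_range: tuple = (2, 24)
    H: int = 47                      # mediators (genera)
    s: int = 5                       # truly active mediators
    beta_T: float = -5.0             # direct exposure -> outcome effect
    beta_M: float | np.ndarray = 1.5      # mediator -> outcome (sparse)
    delta_T: float | np.ndarray = 0.5     # exposure -> mediator (log10 scale)
    psi: float = 100.0               # outcome random-intercept variance
    sigma_e: float = 8.0             # outcome residual SD
    psi_m: float = 0.25              # mediator random-intercept variance
    sigma_m: float = 0.5             # mediator residual SD (log10 scale)
    age_effect: float = -0.2         # covariate effect on the outcome
    age_range: tuple = (6.0, 54.0)
    intercept: float = 58.0
    baseline_sd: float = 1.2         # spread of genus baseline log10 abundances
    active_abundance: tuple = (0.5, 0.5)  # baseline mean/sd of active mediators
    depth_range: tuple = (2000, 20000)
    exposure_mode: str = "within_cluster"   # or "between_cluster"
    exposure_levels: tuple = ("baseline", "exacerbation")
    overdispersion: float = 0.0      # Dirichlet layer; 0 = plain multinomial
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 clusters")
        if not 0 <= self.s <= self.H:
            raise ValueError("need H >= s >= 0")
        if self.psi < 0 or self.psi_m < 0:
            raise ValueError("random-intercept variances must be >= 0")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be > 0")
        if self.depth_range[0] < 1:
            raise ValueError("depths must be >= 1")
        if self.exposure_mode not in ("within_cluster", "between_cluster"):
            raise ValueError(f"unknown exposure_mode: {self.exposure_mode!r}")

    def _sparse(self, value, rng=None) -> np.ndarray:
        """Expand a scalar magnitude into a length-H sparse vector with
        alternating signs on the first s coordinates."""
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            out = np.zeros(self.H)
            signs = np.resize([1.0, -1.0], self.s)
            out[: self.s] = float(arr) * signs
            return out
        if arr.shape != (self.H,):
            raise ValueError(f"effect vector must have length H={self.H}")
        return arr


@dataclass
class SyntheticTruth:
    """Ground-truth effects and latent states for one generated dataset."""

    direct: float
    indirect: dict
    delta_T: np.ndarray
    beta_M: np.ndarray
    Mlog_true: pd.DataFrame
    active: np.ndarray

    @property
    def total(self) -> float:
        return self.direct + float(np.sum(list(self.indirect.values())))


def _cluster_layout(cfg: SyntheticConfig, rng):
    m = rng.integers(cfg.cluster_size_range[0], cfg.cluster_size_range[1] + 1, cfg.n)
    cluster_ids = np.repeat([f"P{i:03d}" for i in range(cfg.n)], m)
    ages = np.repeat(rng.uniform(*cfg.age_range, cfg.n), m)
    if cfg.exposure_mode == "within_cluster":
        T = rng.integers(0, 2, m.sum()).astype(float)
        # guarantee both levels appear somewhere
        if T.min() == T.max():
            T[0] = 1.0 - T[0]
    else:
        T = np.repeat(rng.integers(0, 2, cfg.n).astype(float), m)
        if T.min() == T.max():
            T[: m[0]] = 1.0 - T[: m[0]]
    return m, cluster_ids, ages, T


def generate(cfg: SyntheticConfig):
    """Generate (CountTable, metadata, SyntheticTruth) for taxa-mode runs."""
    rng = np.random.default_rng(cfg.seed)
    m, cluster_ids, ages, T = _cluster_layout(cfg, rng)
    N = int(m.sum())
    delta = cfg._sparse(cfg.delta_T)
    beta_M = cfg._sparse(cfg.beta_M)

    genera = [f"Genus_{t:03d}" for t in range(cfg.H)]
    baseline = rng.normal(0.0, cfg.baseline_sd, cfg.H)
    # active mediators are common genera: mediation through a taxon whose
    # counts are mostly zero is unidentifiable at finite sequencing depth
    if cfg.s:
        baseline[: cfg.s] = rng.normal(*cfg.active_abundance, cfg.s)
    b_med = np.repeat(rng.normal(0.0, np.sqrt(cfg.psi_m), (cfg.n, cfg.H)), m, axis=0)
    latent = (
        baseline[None, :]
        + delta[None, :] * T[:, None]
        + b_med
        + rng.normal(0.0, cfg.sigma_m, (N, cfg.H))
    )  # log10 latent abundances
    if cfg.H:
        logw = latent * np.log(10.0)
        probs = np.exp(logw - logw.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
    else:
        probs = np.zeros((N, 0))

    depths = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1, N)
    counts = np.zeros((N, cfg.H), dtype=np.int64)
    for k in range(N):
        if cfg.H == 0:
            break
        p = probs[k]
        if cfg.overdispersion > 0:
            p = rng.dirichlet(p / cfg.overdispersion)
        counts[k] = rng.multinomial(depths[k], p)

    with np.errstate(divide="ignore"):
        Mlog_true = np.log10(probs) if cfg.H else np.zeros((N, 0))
    gamma = np.repeat(rng.normal(0.0, np.sqrt(cfg.psi), cfg.n), m)
    Y = (
        cfg.intercept
        + cfg.beta_T * T
        + Mlog_true @ beta_M
        + cfg.age_effect * ages
        + gamma
        + rng.normal(0.0, cfg.sigma_e, N)
    )
    Y = np.maximum(Y, 1.0)  # FEV1% is strictly positive

    sample_ids = [f"S{k:04d}" for k in range(N)]
    lineages = [("Bacteria", "", "", "", "", g) for g in genera]
    table = CountTable(counts.T, genera, lineages, sample_ids)

    if cfg.exposure_mode == "between_cluster":
        state = np.full(N, "baseline")
        aggr = np.where(T > 0, "moderate_severe", "mild")
    else:
        state = np.where(T > 0, cfg.exposure_levels[1], cfg.exposure_levels[0])
        aggr = np.repeat(
            np.where(rng.random(cfg.n) < 0.5, "mild", "moderate_severe"), m
        )
    meta = validate_metadata(
        pd.DataFrame(
            dict(
                sample_id=sample_ids,
                cluster_id=cluster_ids,
                clinical_state=state,
                aggressiveness=aggr,
                age=ages,
                fev1_pct=Y,
            )
        )
    )
    truth = SyntheticTruth(
        direct=cfg.beta_T,
        indirect={g: float(delta[t] * beta_M[t]) for t, g in enumerate(genera)},
        delta_T=delta,
        beta_M=beta_M,
        Mlog_true=pd.DataFrame(Mlog_true, index=sample_ids, columns=genera),
        active=np.flatnonzero((delta != 0) & (beta_M != 0)),
    )
    return table, meta, truth


@dataclass
class CommunityConfig:
    """Single continuous mediator (alpha-diversity-like) generator.

    Default effects are a strong mediated pathway: the exposure raises the
    mediator by delta_T = 1, each mediator unit lowers the outcome by 2,
    and the direct effect is -3, so the true indirect effect is -2 and the
    true total is -5.
    """

    n: int = 89
    cluster_size_range: tuple = (2, 24)
    delta_T: float = 1.0
    beta_M: float = -2.0
    beta_T: float = -3.0
    psi: float = 25.0
    sigma_e: float = 8.0
    psi_m: float = 0.25
    sigma_m: float = 0.5
    mediator_mean: float = 3.0
    age_effect: float = -0.2
    age_range: tuple = (6.0, 54.0)
    intercept: float = 58.0
    exposure_mode: str = "within_cluster"
    exposure_levels: tuple = ("baseline", "exacerbation")
    seed: int = 0


def generate_community(cfg: CommunityConfig):
    """Generate (StudyFrame, SyntheticTruth) with one Gaussian mediator."""
    base = SyntheticConfig(
        n=cfg.n, cluster_size_range=cfg.cluster_size_range,
        exposure_mode=cfg.exposure_mode, seed=cfg.seed,
    )
    rng = np.random.default_rng(cfg.seed)
    m, cluster_ids, ages, T = _cluster_layout(base, rng)
    N = int(m.sum())
    b_med = np.repeat(rng.normal(0.0, np.sqrt(cfg.psi_m), cfg.n), m)
    M = cfg.mediator_mean + cfg.delta_T * T + b_med + rng.normal(0.0, cfg.sigma_m, N)
    gamma = np.repeat(rng.normal(0.0, np.sqrt(cfg.psi), cfg.n), m)
    Y = (
        cfg.intercept
        + cfg.beta_T * T
        + cfg.beta_M * M
        + cfg.age_effect * ages
        + gamma
        + rng.normal(0.0, cfg.sigma_e, N)
    )
    frame = StudyFrame(
        Y=Y, T=T, C=ages[:, None], Mlog=M[:, None], cluster_ids=cluster_ids,
        mediator_names=["diversity"], covariate_names=["age"],
    )
    truth = SyntheticTruth(
        direct=cfg.beta_T,
        indirect={"diversity": cfg.delta_T * cfg.beta_M},
        delta_T=np.array([cfg.delta_T]),
        beta_M=np.array([cfg.beta_M]),
        Mlog_true=pd.DataFrame({"diversity": M}),
        active=np.array([0] if cfg.delta_T * cfg.beta_M != 0 else [], dtype=int),
    )
    return frame, truth


def generate_lmm_regression(
    n=50, cluster_size_range=(4, 10), p=100, s=5, beta_scale=1.0,
    psi=1.0, sigma_e=1.0, seed=0,
):
    """Plain high-dimensional random-intercept regression data.

    X is iid standard normal; the first s coefficients are +/- beta_scale
    with alternating signs.  Returns (X, y, groups, beta_true).
    """
    rng = np.random.default_rng(seed)
    m = rng.integers(cluster_size_range[0], cluster_size_range[1] + 1, n)
    N = int(m.sum())
    groups = np.repeat(np.arange(n), m)
    X = rng.normal(size=(N, p))
    beta = np.zeros(p)
    beta[:s] = beta_scale * np.resize([1.0, -1.0], s)
    gamma = np.repeat(rng.normal(0.0, np.sqrt(psi), n), m)
    y = X @ beta + gamma + rng.normal(0.0, sigma_e, N)
    return X, y, groups, beta
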