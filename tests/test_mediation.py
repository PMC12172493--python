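import numpy as np
import pandas as pd
import pytest

from medimix import (
    CommunityMediation,
    Contrast,
    StudyFrame,
    TaxaMediation,
    community_mediation,
    compose_effects,
    fit_all_mediator_models,
    fit_mediator_model,
    fit_taxa_outcome,
    lognorm_transform,
    subset_contrast,
)
from medimix.synthetic import CommunityConfig, SyntheticConfig, generate, \
    generate_community


class TestContrast:
    def test_name(self):
        c = Contrast("clinical_state", "baseline", "exacerbation")
        assert c.name == "baseline-exacerbation"

    def test_identical_levels_error(self):
        with pytest.raises(ValueError, match="differ"):
            Contrast("clinical_state", "baseline", "baseline")

    def test_unknown_level_error(self):
        with pytest.raises(ValueError, match="level"):
            Contrast("clinical_state", "baseline", "remission")

    def test_unknown_exposure_error(self):
        with pytest.raises(ValueError, match="exposure"):
            Contrast("smoking", "no", "yes")


class TestSubsetContrast:
    def _mlog(self, meta):
        rng = np.random.default_rng(0)
        return pd.DataFrame(rng.normal(size=(len(meta), 3)), index=meta.index,
                            columns=["g1", "g2", "g3"])

    def test_two_state_restriction(self, toy_metadata):
        frame = subset_contrast(
            self._mlog(toy_metadata), toy_metadata,
            Contrast("clinical_state", "baseline", "exacerbation"),
        )
        assert frame.n_obs == 8  # 4 baseline + 4 exacerbation
        assert set(np.unique(frame.T)) == {0.0, 1.0}
        assert frame.T.sum() == 4

    def test_patient_level_exposure_constant_within_cluster(self, toy_metadata):
        frame = subset_contrast(
            self._mlog(toy_metadata), toy_metadata,
            Contrast("aggressiveness", "mild", "moderate_severe"),
        )
        for cid in np.unique(frame.cluster_ids):
            assert len(np.unique(frame.T[frame.cluster_ids == cid])) == 1

    def test_missing_level_errors(self, toy_metadata):
        with pytest.raises(ValueError, match="zero samples"):
            subset_contrast(
                self._mlog(toy_metadata), toy_metadata,
                Contrast("clinical_state", "baseline", "recovery"),
            )


class TestStudyFrame:
    def test_non_binary_T_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            StudyFrame(Y=[1.0, 2.0], T=[0.0, 2.0], C=np.zeros((2, 0)),
                       Mlog=np.zeros((2, 1)), cluster_ids=["a", "b"])

    def test_missing_mediator_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            StudyFrame(Y=[1.0, 2.0], T=[0.0, 1.0], C=np.zeros((2, 0)),
                       Mlog=np.array([[np.nan], [0.0]]), cluster_ids=["a", "b"])

    def test_cluster_blocks_contiguized(self):
        f = StudyFrame(Y=[1.0, 2, 3, 4], T=[0.0, 1, 0, 1], C=np.zeros((4, 0)),
                       Mlog=np.zeros((4, 1)), cluster_ids=["a", "b", "a", "b"])
        assert list(f.cluster_ids) == ["a", "a", "b", "b"]
        assert list(f.Y) == [1.0, 3.0, 2.0, 4.0]


class TestComposeEffects:
    def test_arithmetic(self):
        eff = compose_effects(2.0, {"m1": 0.5, "m2": -1.0}, {"m1": 1.0, "m2": 0.5})
        assert eff.indirect == {"m1": 0.5, "m2": -0.5}
        assert eff.total == pytest.approx(2.0)

    def test_zero_deltas(self):
        eff = compose_effects(1.5, {"m": 0.0}, {"m": 3.0})
        assert eff.total == eff.direct

    def test_zero_beta_m(self):
        eff = compose_effects(1.5, {"m": 2.0}, {"m": 0.0})
        assert eff.indirect["m"] == 0.0

    def test_name_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            compose_effects(1.0, {"a": 1.0}, {"b": 1.0})

    def test_missing_mediator_excluded_from_total(self):
        eff = compose_effects(1.0, {"a": np.nan, "b": 2.0}, {"a": 1.0, "b": 0.5})
        assert eff.total == pytest.approx(2.0)


class TestMediatorModels:
    def test_single_mediator_consistency(self):
        frame, _ = generate_community(CommunityConfig(n=20, cluster_size_range=(2, 4),
                                                      seed=0))
        deltas = fit_all_mediator_models(frame)
        direct = fit_mediator_model(frame.Mlog[:, 0], frame.T, frame.C,
                                    frame.cluster_ids)
        assert deltas["diversity"] == pytest.approx(direct.coef_[0], abs=1e-12)

    def test_null_mediators_centered(self):
        est = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, m = 40, 3
            groups = np.repeat(np.arange(n), m)
            T = rng.integers(0, 2, n * m).astype(float)
            frame = StudyFrame(
                Y=rng.normal(size=n * m), T=T, C=np.zeros((n * m, 0)),
                Mlog=rng.normal(size=(n * m, 3)), cluster_ids=groups,
            )
            est.append(list(fit_all_mediator_models(frame).values()))
        means = np.mean(est, axis=0)
        assert np.abs(means).max() < 0.08

    def test_constructed_mediator_recovery(self):
        rng = np.random.default_rng(3)
        n, m = 60, 4
        groups = np.repeat(np.arange(n), m)
        T = rng.integers(0, 2, n * m).astype(float)
        mlog = 0.8 * T + rng.normal(0, 0.3, n * m)
        frame = StudyFrame(Y=rng.normal(size=n * m), T=T, C=np.zeros((n * m, 0)),
                           Mlog=mlog[:, None], cluster_ids=groups,
                           mediator_names=["g"])
        deltas = fit_all_mediator_models(frame)
        assert deltas["g"] == pytest.approx(0.8, abs=0.15)


class TestCommunityMediation:
    def test_recovery_sanity(self):
        vals = []
        for seed in range(10):
            frame, truth = generate_community(CommunityConfig(seed=seed))
            eff = community_mediation(frame)
            vals.append([eff.direct, eff.indirect["diversity"], eff.total])
        m = np.mean(vals, axis=0)
        assert m[0] == pytest.approx(-3.0, abs=0.6)
        assert m[1] == pytest.approx(-2.0, abs=0.6)

    def test_decomposition_identity(self):
        frame, _ = generate_community(CommunityConfig(n=25, cluster_size_range=(2, 5),
                                                      seed=1))
        eff = community_mediation(frame)
        assert abs(eff.total - eff.direct - sum(eff.indirect.values())) < 1e-12

    def test_sign_flip_on_level_swap(self):
        frame, _ = generate_community(CommunityConfig(n=30, cluster_size_range=(2, 5),
                                                      seed=2))
        eff = community_mediation(frame)
        flipped = StudyFrame(
            Y=frame.Y, T=1.0 - frame.T, C=frame.C, Mlog=frame.Mlog,
            cluster_ids=frame.cluster_ids, mediator_names=frame.mediator_names,
        )
        eff2 = community_mediation(flipped)
        # limited only by the REML 1-D optimizer's float path
        assert eff2.direct == pytest.approx(-eff.direct, rel=1e-6, abs=1e-6)
        assert eff2.indirect["diversity"] == pytest.approx(
            -eff.indirect["diversity"], rel=1e-6, abs=1e-6
        )
        assert eff2.total == pytest.approx(-eff.total, rel=1e-6, abs=1e-6)

    def test_requires_single_mediator(self):
        frame, _ = generate_community(CommunityConfig(n=10, cluster_size_range=(2, 3),
                                                      seed=0))
        wide = StudyFrame(Y=frame.Y, T=frame.T, C=frame.C,
                          Mlog=np.column_stack([frame.Mlog, frame.Mlog]),
                          cluster_ids=frame.cluster_ids)
        with pytest.raises(ValueError, match="exactly one mediator"):
            CommunityMediation().fit(wide)

    def test_constant_mediator_gives_zero_indirect(self):
        frame, _ = generate_community(CommunityConfig(n=10, cluster_size_range=(2, 3),
                                                      seed=0))
        const = StudyFrame(Y=frame.Y, T=frame.T, C=frame.C,
                           Mlog=np.full_like(frame.Mlog, 2.0),
                           cluster_ids=frame.cluster_ids,
                           mediator_names=["observed"])
        eff = CommunityMediation().fit(const).effects_
        assert eff.indirect["observed"] == 0.0
        assert eff.total == eff.direct


@pytest.fixture(scope="module")
def small_frame():
    cfg = SyntheticConfig(n=15, cluster_size_range=(3, 5), H=6, s=2,
                          depth_range=(1500, 4000), seed=7)
    table, meta, truth = generate(cfg)
    mlog = lognorm_transform(table)
    frame = subset_contrast(
        mlog, meta, Contrast("clinical_state", "baseline", "exacerbation")
    )
    return frame, truth


class TestTaxaMediation:
    def test_requires_mediators(self, small_frame):
        frame, _ = small_frame
        empty = StudyFrame(Y=frame.Y, T=frame.T, C=frame.C,
                           Mlog=np.zeros((frame.n_obs, 0)),
                           cluster_ids=frame.cluster_ids)
        with pytest.raises(ValueError, match="at least one mediator"):
            fit_taxa_outcome(empty)

    def test_decomposition_identity_and_structure(self, small_frame):
        frame, _ = small_frame
        fit = TaxaMediation(a=1.0, random_state=0).fit(frame)
        eff = fit.effects_
        assert set(eff.indirect) == set(frame.mediator_names)
        assert abs(eff.total - eff.direct - sum(eff.indirect.values())) < 1e-12

    def test_outcome_fit_exposes_named_coordinates(self, small_frame):
        frame, _ = small_frame
        fit = fit_taxa_outcome(frame, a=1.0, random_state=0)
        assert fit.coord_names_[0] == "T"
        assert len(fit.coord_names_) == 1 + frame.C.shape[1] + frame.n_mediators
        assert np.isfinite(fit.coef_db_).all()
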