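import logging

import numpy as np
import pandas as pd
import pytest

from recurph import RecurrencePH, make_labeled_cohort
from recurph.model import PipelineConfig
from recurph.simulate import ChuaParams, simulate_chua
from recurph.sweep import SweepResult, beta_sweep, regime_segments


@pytest.fixture(scope="module")
def small_cohort():
    return make_labeled_cohort({"sine": 6, "logistic": 6}, length=120, seed=4)


@pytest.fixture(scope="module")
def fitted(small_cohort):
    return RecurrencePH(small_cohort, rank=2, seed=0).fit()


class TestRecurrencePH:
    def test_one_feature_row_per_series(self, fitted, small_cohort):
        assert fitted.features.shape[0] == len(small_cohort)
        assert fitted.features.shape[1] == fitted.grid.n_cells
        assert fitted.scores.shape == (len(small_cohort), 2)

    def test_determinism_bitwise(self, small_cohort):
        a = RecurrencePH(small_cohort, rank=2, seed=1).fit()
        b = RecurrencePH(small_cohort, rank=2, seed=1).fit()
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.scores, b.scores)

    def test_classes_separable_by_one_component(self, fitted):
        y = np.array([lab == "logistic" for lab in fitted.labels], int)
        metrics = [fitted.evaluate("logistic", component=c) for c in range(2)]
        assert max(m["accuracy"] for m in metrics) == 1.0

    def test_single_series_forces_rank_one(self, small_cohort, caplog):
        with caplog.at_level(logging.WARNING, logger="recurph"):
            res = RecurrencePH(small_cohort[:1], rank=2).fit()
        assert res.scores.shape == (1, 1)
        assert any("rank" in r.message for r in caplog.records)

    def test_mixed_lengths_warn_but_run(self, caplog):
        cohort = [np.sin(np.arange(80) / 3.0), np.sin(np.arange(60) / 3.0)]
        with caplog.at_level(logging.WARNING, logger="recurph"):
            res = RecurrencePH(cohort, rank=1).fit()
        assert res.features.shape[0] == 2
        assert any("lengths" in r.message for r in caplog.records)

    def test_train_test_split_scores_test_rows(self, small_cohort):
        res = RecurrencePH(small_cohort, rank=2, seed=0).fit(train_idx=range(8))
        assert res.test_idx.tolist() == [8, 9, 10, 11]
        assert np.all(res.scores >= 0)
        # transform of a training series lands close to its fitted score row
        again = res.transform([small_cohort[0]])
        denom = np.linalg.norm(res.scores[0]) or 1.0
        assert np.linalg.norm(again[0] - res.scores[0]) / denom < 0.05

    def test_shared_grid_across_cohort(self, fitted):
        assert fitted.features.shape[1] == fitted.grid.n_cells  # single grid object

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            RecurrencePH([])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            RecurrencePH([[1.0, 2.0]], k=3)

    def test_from_dataframe(self):
        df = pd.DataFrame(np.sin(np.arange(200).reshape(4, 50) / 2.0))
        df.insert(0, "target", ["a", "a", "b", "b"])
        model = RecurrencePH.from_dataframe(df, label_col="target", rank=2)
        assert [ts.label for ts in model.cohort] == ["a", "a", "b", "b"]
        assert len(model.cohort[0]) == 50

    def test_summary_mentions_fit_facts(self, fitted):
        text = fitted.summary()
        assert "rank=2" in text and "NMF1" in text and "k=3" in text

    def test_save_writes_provenance(self, fitted, tmp_path):
        fitted.save(tmp_path / "run")
        for name in ["features.tsv", "features.tsv.meta.yaml", "scores.tsv", "config.yaml", "samples.tsv"]:
            assert (tmp_path / "run" / name).exists()


class TestPipelineConfig:
    def test_yaml_round_trip_exact(self, tmp_path):
        cfg = PipelineConfig(k=4, tau=2, resolution=(32, 48), sigma_scale=0.07, rank=3, seed=11)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert PipelineConfig.from_yaml(path) == cfg


class TestBetaSweep:
    def test_single_beta_matches_direct_pipeline(self):
        cfg = PipelineConfig(rank=4, seed=0)
        res = beta_sweep(31.0, 31.0, 0.1, series_length=150, config=cfg)
        assert res.score_matrix.shape[0] == 1
        direct = RecurrencePH(
            [simulate_chua(ChuaParams(beta=31.0, n_samples=150))], config=cfg
        ).fit()
        assert np.array_equal(res.score_matrix, direct.scores)

    def test_same_regime_more_similar_than_cross_regime(self):
        """Score rows of two nearby periodic-window betas resemble each
        other more than a periodic/chaotic pair."""
        series = [
            simulate_chua(ChuaParams(beta=b, n_samples=300)) for b in (30.35, 30.40, 31.8)
        ]
        res = RecurrencePH(series, rank=3, seed=0).fit()
        s = res.scores

        def cosine(u, v):
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

        assert cosine(s[0], s[1]) > cosine(s[0], s[2])

    def test_segments_partition_the_grid(self):
        scores = np.array([[1.0, 0.0], [0.9, 0.1], [0.2, 0.8], [0.1, 0.9], [0.7, 0.3]])
        res = SweepResult(
            beta_grid=np.array([30.0, 30.1, 30.2, 30.3, 30.4]),
            score_matrix=scores,
            basis=np.zeros((2, 4)),
            grid=None,
            config=PipelineConfig(),
        )
        segs = regime_segments(res)
        assert segs == [(30.0, 30.1, 0), (30.2, 30.3, 1), (30.4, 30.4, 0)]

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            beta_sweep(30.0, 31.0, step=0.0)
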