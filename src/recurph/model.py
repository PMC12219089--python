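"""The end-to-end model: cohort of series -> topological scores.

:class:`RecurrencePH` wires the four pipeline stages together in the
fashion of a statsmodels model object: it is constructed from data (a
cohort of univariate series) plus configuration, ``fit()`` runs

    delay embedding -> recurrence distance matrix -> 0-dim sublevel
    persistence -> persistence image on one cohort-wide grid -> NMF

and returns a :class:`RecurrencePHResults` carrying the per-sample
scores, the basis, the diagrams and full provenance.  When a training
subset is given, the NMF basis is fitted on the training rows only and
test rows are scored against the fixed basis, matching the
train/transfer protocol used for held-out classification.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .cubical import PersistenceDiagram, persistence_h0
from .embedding import TimeSeries, delay_embed, recurrence_distance_matrix
from .evaluate import auc as _auc, best_threshold_accuracy, roc_curve
from .nmf import NMFModel, nmf_fit, nmf_transform
from .pimage import PIGridSpec, grid_from_diagrams, persistence_image

logger = logging.getLogger("recurph")

__all__ = ["PipelineConfig", "RecurrencePH", "RecurrencePHResults"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, with documented defaults.

    k, tau — embedding dimension and delay (samples); resolution —
    persistence-image grid (nb, nd); sigma_scale — kernel bandwidth as
    a fraction of the cohort's death range; weight_mode — "grid"
    (squared lifetime at the grid location) or "point"; rank — NMF
    rank; seed/max_iter/tol — NMF convergence controls;
    cap_essential — substitute death = max pixel value for essential
    classes instead of excluding them from the image.
    """

    k: int = 3
    tau: int = 1
    resolution: Tuple[int, int] = (64, 64)
    sigma_scale: float = 0.05
    weight_mode: str = "grid"
    rank: int = 2
    seed: int = 0
    max_iter: int = 2000
    tol: float = 1e-6
    cap_essential: bool = False

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["resolution"] = list(d["resolution"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["resolution"] = tuple(d["resolution"])
        return cls(**d)


def _coerce_cohort(series, labels) -> List[TimeSeries]:
    cohort: List[TimeSeries] = []
    for i, s in enumerate(series):
        label = labels[i] if labels is not None else getattr(s, "label", None)
        if isinstance(s, TimeSeries):
            cohort.append(TimeSeries(s.values, label=label, id=s.id or f"sample{i}"))
        else:
            cohort.append(TimeSeries(np.asarray(s, float), label=label, id=f"sample{i}"))
    return cohort


class RecurrencePH:
    """Topological feature model for a cohort of univariate time series.

    Parameters
    ----------
    series : sequence of TimeSeries or 1-D arrays
        The cohort; series may differ in length (diagrams and images
        are length-agnostic), though a warning is logged.
    labels : sequence, optional
        Per-sample class labels; overrides labels carried by the
        series objects.
    config : PipelineConfig, optional
        Defaults are used where not given; keyword overrides accepted.

    Examples
    --------
    >>> from recurph import RecurrencePH, make_labeled_cohort
    >>> cohort = make_labeled_cohort({"sine": 5, "logistic": 5}, length=100, seed=0)
    >>> res = RecurrencePH(cohort, rank=2).fit()
    >>> res.scores.shape
    (10, 2)
    """

    def __init__(self, series, labels=None, config: Optional[PipelineConfig] = None, **overrides):
        self.cohort = _coerce_cohort(series, labels)
        if len(self.cohort) == 0:
            raise ValueError("empty cohort")
        cfg = config or PipelineConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self.config = cfg
        lengths = {len(ts) for ts in self.cohort}
        if len(lengths) > 1:
            logger.warning("cohort mixes series lengths %s; PDs/PIs are length-agnostic", sorted(lengths))
        min_len = (cfg.k - 1) * cfg.tau + 1
        for ts in self.cohort:
            if len(ts) < min_len:
                raise ValueError(
                    f"series {ts.id!r} too short: T={len(ts)} < {(cfg.k - 1) * cfg.tau + 1} "
                    f"required for k={cfg.k}, tau={cfg.tau}"
                )

    @classmethod
    def from_dataframe(cls, df, label_col=None, **kwargs) -> "RecurrencePH":
        """Build from a DataFrame with one series per row.

        ``label_col`` names the column holding class labels; all other
        columns are taken as the ordered signal.
        """
        labels = None
        values = df
        if label_col is not None:
            labels = df[label_col].astype(str).tolist()
            values = df.drop(columns=[label_col])
        series = [np.asarray(row, float) for _, row in values.iterrows()]
        return cls(series, labels=labels, **kwargs)

    # -- pipeline stages ---------------------------------------------------

    def diagrams(self) -> List[PersistenceDiagram]:
        """Persistence diagram of each series' recurrence plot."""
        cfg = self.config
        out = []
        for ts in self.cohort:
            t0 = time.perf_counter()
            traj = delay_embed(ts, cfg.k, cfg.tau)
            dmat = recurrence_distance_matrix(traj)
            diagram = persistence_h0(dmat.entries)
            if cfg.cap_essential:
                cap = float(dmat.entries.max())
                from .cubical import PersistencePair

                diagram = PersistenceDiagram(
                    finite_pairs=diagram.finite_pairs
                    + [PersistencePair(b, cap) for b in diagram.essential_births if cap > b],
                    essential_births=[],
                )
            logger.info("ph sample=%s n=%d pairs=%d %.3fs", ts.id, dmat.n, len(diagram), time.perf_counter() - t0)
            out.append(diagram)
        return out

    def fit(self, train_idx: Optional[Sequence[int]] = None) -> "RecurrencePHResults":
        """Run the full pipeline and fit the NMF basis.

        If ``train_idx`` is given, the shared persistence-image grid
        and the NMF basis are computed from the training rows only;
        the remaining rows are scored against the fixed basis.
        """
        cfg = self.config
        n = len(self.cohort)
        rank = cfg.rank
        if rank > n:
            logger.warning("rank %d exceeds cohort size %d; forcing rank=%d", rank, n, n)
            rank = n
        diagrams = self.diagrams()
        idx_train = np.arange(n) if train_idx is None else np.asarray(train_idx, int)
        idx_test = np.setdiff1d(np.arange(n), idx_train)

        grid = grid_from_diagrams(
            [diagrams[i] for i in idx_train],
            resolution=cfg.resolution,
            sigma_rule=lambda lo, hi: cfg.sigma_scale * (hi - lo),
            weight_mode=cfg.weight_mode,
        )
        features = np.vstack([persistence_image(dg, grid) for dg in diagrams])
        model = nmf_fit(
            features[idx_train], rank, seed=cfg.seed, max_iter=cfg.max_iter, tol=cfg.tol
        )
        scores = np.zeros((n, rank))
        scores[idx_train] = model.P
        if idx_test.size:
            scores[idx_test] = nmf_transform(
                features[idx_test], model, seed=cfg.seed, max_iter=cfg.max_iter, tol=cfg.tol
            )
        return RecurrencePHResults(
            model=self,
            diagrams=diagrams,
            grid=grid,
            features=features,
            nmf=model,
            scores=scores,
            train_idx=idx_train,
            test_idx=idx_test,
        )


@dataclass
class RecurrencePHResults:
    """Fitted pipeline output: scores, basis, diagrams, provenance."""

    model: RecurrencePH
    diagrams: List[PersistenceDiagram]
    grid: PIGridSpec
    features: np.ndarray
    nmf: NMFModel
    scores: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def labels(self) -> List[Optional[str]]:
        return [ts.label for ts in self.model.cohort]

    @property
    def basis(self) -> np.ndarray:
        """NMF basis rows, each reshapeable to the PI grid resolution."""
        return self.nmf.Q

    def transform(self, series, labels=None) -> np.ndarray:
        """Score new series against the fitted grid and basis."""
        new_model = RecurrencePH(series, labels=labels, config=self.model.config)
        feats = np.vstack([persistence_image(dg, self.grid) for dg in new_model.diagrams()])
        cfg = self.model.config
        return nmf_transform(feats, self.nmf, seed=cfg.seed, max_iter=cfg.max_iter, tol=cfg.tol)

    def evaluate(self, positive_label, component: int = 0, subset: str = "all") -> Dict[str, float]:
        """ROC/AUC and best-threshold accuracy of one score component.

        ``subset`` is "all", "train" or "test".  The binary target is
        ``label == positive_label``.
        """
        idx = {
            "all": np.arange(len(self.model.cohort)),
            "train": self.train_idx,
            "test": self.test_idx,
        }[subset]
        y = np.array([self.labels[i] == positive_label for i in idx], dtype=int)
        s = self.scores[idx, component]
        thr, acc = best_threshold_accuracy(s, y)
        return {
            "auc": _auc(s, y),
            "accuracy": acc,
            "threshold": thr,
            "roc": roc_curve(s, y),
        }

    def summary(self) -> str:
        """Human-readable fit report."""
        cfg = self.model.config
        n = len(self.model.cohort)
        lines = [
            "Recurrence-plot persistent homology / NMF results",
            "=" * 52,
            f"samples: {n} (train {self.train_idx.size}, test {self.test_idx.size})",
            f"embedding: k={cfg.k}, tau={cfg.tau}",
            f"PI grid: {self.grid.resolution[0]}x{self.grid.resolution[1]}, "
            f"sigma={self.grid.sigma:.4g}, weight={self.grid.weight_name}/{self.grid.weight_mode}",
            f"birth/death range: [{self.grid.birth_range[0]:.4g}, {self.grid.birth_range[1]:.4g}]",
            f"NMF: rank={self.nmf.rank}, iterations={self.nmf.n_iter}, "
            f"final ||V-PQ||={self.nmf.reconstruction_error:.6g}",
            "",
            "component   Q row-norm   mean score   max score",
        ]
        qn = np.linalg.norm(self.nmf.Q, axis=1)
        for j in range(self.nmf.rank):
            lines.append(
                f"NMF{j + 1:<9d} {qn[j]:>10.4g} {self.scores[:, j].mean():>12.4g} "
                f"{self.scores[:, j].max():>11.4g}"
            )
        mean_pairs = np.mean([len(dg) for dg in self.diagrams])
        lines += ["", f"mean finite pairs per diagram: {mean_pairs:.1f}"]
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_basis(self, component: int = 0, ax=None):
        """Heatmap of one NMF basis row on the (birth, death) grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        nb, nd = self.grid.resolution
        img = self.nmf.Q[component].reshape(nb, nd)
        b0, b1 = self.grid.birth_range
        d0, d1 = self.grid.death_range
        # birth on x, death on y, origin at lower left
        ax.imshow(img.T, origin="lower", extent=(b0, b1, d0, d1), aspect="auto")
        ax.set_xlabel("birth")
        ax.set_ylabel("death")
        ax.set_title(f"NMF{component + 1} basis")
        return ax

    def plot_scores(self, x: int = 0, y: int = 1, ax=None):
        """Scatter of two score components, coloured by label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = np.array([str(l) for l in self.labels])
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(self.scores[m, x], self.scores[m, y], label=lab, s=18)
        ax.set_xlabel(f"NMF{x + 1}")
        ax.set_ylabel(f"NMF{y + 1}")
        ax.legend()
        return ax

    def save(self, directory) -> None:
        """Write features, factors, scores and config for bit-identical re-runs."""
        import os

        from .io import save_nmf_model, write_feature_matrix, write_matrix

        os.makedirs(directory, exist_ok=True)
        write_feature_matrix(self.features, self.grid, os.path.join(directory, "features.tsv"))
        write_matrix(self.scores, os.path.join(directory, "scores.tsv"))
        save_nmf_model(self.nmf, os.path.join(directory, "nmf"))
        self.model.config.to_yaml(os.path.join(directory, "config.yaml"))
        with open(os.path.join(directory, "samples.tsv"), "w") as fh:
            fh.write("id\tlabel\tsplit\n")
            train = set(self.train_idx.tolist())
            for i, ts in enumerate(self.model.cohort):
                fh.write(f"{ts.id}\t{ts.label}\t{'train' if i in train else 'test'}\n")
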