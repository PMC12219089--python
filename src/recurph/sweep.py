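"""Parameter sweep over the Chua oscillator's bifurcation parameter.

Simulates the oscillator on a grid of beta values, runs every series
through the topological pipeline, and fits ONE NMF across the whole
sweep so that component scores are comparable along beta.  Reading the
dominant component per beta then segments the axis into dynamical
regimes: the periodic windows and chaotic bands appear as contiguous
stretches dominated by different basis components, with transitions
near the known regime boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .model import PipelineConfig, RecurrencePH
from .pimage import PIGridSpec
from .simulate import ChuaParams, simulate_chua

__all__ = ["SweepResult", "beta_sweep", "regime_segments"]


@dataclass
class SweepResult:
    """Per-beta NMF scores and the shared basis."""

    beta_grid: np.ndarray
    score_matrix: np.ndarray  # (n_beta, rank)
    basis: np.ndarray  # (rank, D)
    grid: PIGridSpec
    config: PipelineConfig

    def dominant_component(self) -> np.ndarray:
        """Index of the largest score at each beta."""
        return np.argmax(self.score_matrix, axis=1)


def beta_sweep(
    beta_min: float = 30.0,
    beta_max: float = 32.0,
    step: float = 0.1,
    series_length: int = 500,
    config: Optional[PipelineConfig] = None,
    chua: Optional[ChuaParams] = None,
) -> SweepResult:
    """Sweep beta, pipeline each trajectory, fit one rank-4 NMF.

    Deterministic given the configuration seed.  Integration
    instability at any beta is re-raised naming the offending value.
    """
    if beta_min > beta_max + 1e-12:
        raise ValueError(f"beta_min ({beta_min}) must not exceed beta_max ({beta_max})")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    cfg = config or PipelineConfig(rank=4)
    base = chua or ChuaParams()
    n_beta = int(round((beta_max - beta_min) / step)) + 1
    betas = beta_min + step * np.arange(n_beta)
    series = []
    for b in betas:
        params = replace(base, beta=float(b), n_samples=series_length)
        try:
            series.append(simulate_chua(params))
        except RuntimeError as exc:
            raise RuntimeError(f"integration failed at beta={b:g}: {exc}") from exc
    res = RecurrencePH(series, config=cfg).fit()
    return SweepResult(
        beta_grid=betas,
        score_matrix=res.scores,
        basis=res.nmf.Q,
        grid=res.grid,
        config=cfg,
    )


def regime_segments(result: SweepResult) -> List[Tuple[float, float, int]]:
    """Contiguous stretches of beta dominated by one NMF component.

    Returns ``(beta_start, beta_end, component)`` triples in order; a
    change of dominant component marks a candidate regime boundary.
    """
    dom = result.dominant_component()
    betas = result.beta_grid
    segments: List[Tuple[float, float, int]] = []
    start = 0
    for i in range(1, len(dom) + 1):
        if i == len(dom) or dom[i] != dom[start]:
            segments.append((float(betas[start]), float(betas[i - 1]), int(dom[start])))
            start = i
    return segments
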