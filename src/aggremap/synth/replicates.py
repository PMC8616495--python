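"""Replicate-level noisy aggregation curves for condition comparisons."""

from __future__ import annotations

import numpy as np

from .model import AcquisitionGeometry, KineticsModel

__all__ = ["simulate_replicate_curves"]


def simulate_replicate_curves(
    model: KineticsModel,
    geometry: AcquisitionGeometry,
    n_replicates: int,
    seed: int = 0,
    *,
    a_inf_sd: float = 0.04,
    k_rel_sd: float = 0.15,
    obs_sd: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample noisy per-well normalized-area curves around one model.

    Each replicate jitters the plateau (``a_inf_sd``, additive, clipped to
    (0, 1]) and the rate (``k_rel_sd``, multiplicative log-normal), then
    adds frame-level observation noise (``obs_sd``). The first sample of
    every curve is forced to 1 (normalization convention).

    Returns ``(times, curves)`` with ``curves`` of shape
    ``(n_replicates, n_frames)``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    times = geometry.times()
    curves = np.empty((n_replicates, len(times)))
    for i in range(n_replicates):
        a = float(np.clip(model.a_inf + rng.normal(0.0, a_inf_sd), 1e-3, 1.0))
        k = model.k * float(np.exp(rng.normal(0.0, k_rel_sd)))
        rep = KineticsModel(a_inf=a, k=k, lag=model.lag)
        vals = rep(times) + rng.normal(0.0, obs_sd, len(times))
        vals = np.clip(vals, 1e-6, None)
        vals[0] = 1.0
        curves[i] = vals
    return times, curves
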