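"""Topology incongruence tests from site-wise log-likelihoods.

Both tests use RELL resampling (resampling estimated log-likelihoods): site
indices are bootstrapped, per-site log-likelihood vectors are re-summed,
and no branch lengths are re-optimized per replicate. The SH test compares
every candidate topology against the maximum-likelihood one simultaneously
and is deliberately conservative; the KH test is the two-topology,
two-sided special case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np

__all__ = ["SiteLnLMatrix", "TopoTestResult", "sh_test", "kh_test"]


@dataclass(frozen=True)
class SiteLnLMatrix:
    """Per-site log-likelihood vectors for a set of candidate topologies."""

    topology_ids: tuple[str, ...]
    values: np.ndarray  # (n_topologies, n_sites)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2 or vals.shape[0] != len(self.topology_ids):
            raise ValueError("values must be (n_topologies, n_sites)")
        if vals.shape[1] < 1:
            raise ValueError("need at least one site")
        if not np.isfinite(vals).all():
            raise ValueError("site log-likelihoods must be finite")
        if len(set(self.topology_ids)) != len(self.topology_ids):
            raise ValueError("topology ids must be unique")


@dataclass(frozen=True)
class TopoTestResult:
    topology_id: str
    lnL: float
    delta: float  # lnL_best - lnL, >= 0
    p_value: float
    n_resamples: int

    def __post_init__(self):
        if self.delta < -1e-9:
            raise ValueError("delta must be non-negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _resample_sums(values: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """(n_topologies, B) bootstrap totals of per-site lnL vectors."""
    n_topo, n_sites = values.shape
    out = np.empty((n_topo, B))
    # one shared site resampling per replicate (the RELL bootstrap)
    for b in range(B):
        idx = rng.integers(0, n_sites, size=n_sites)
        out[:, b] = values[:, idx].sum(axis=1)
    return out


def _check_B(B: int) -> None:
    if B < 1:
        raise ValueError("need at least one RELL resample")
    if B < 100:
        warnings.warn(
            f"B={B} RELL resamples is very small; p-values will be coarse",
            stacklevel=3,
        )


def sh_test(matrix: SiteLnLMatrix, B: int = 10000, seed: int = 0) -> list[TopoTestResult]:
    """Shimodaira–Hasegawa test over >= 2 topologies.

    Null resampling: per replicate, the bootstrap totals are centered by
    their per-topology replicate means; the null statistic for topology i
    is max_j(centered_j) - centered_i, and p_i is the fraction of
    replicates where it reaches the observed delta_i. The ML topology has
    delta 0 and hence p exactly 1.
    """
    if len(matrix.topology_ids) < 2:
        raise ValueError("SH test needs at least two topologies")
    _check_B(B)
    rng = np.random.default_rng(seed)
    totals = matrix.values.sum(axis=1)
    best = totals.max()
    deltas = best - totals
    sums = _resample_sums(matrix.values, B, rng)
    centered = sums - sums.mean(axis=1, keepdims=True)
    null_stat = centered.max(axis=0, keepdims=True) - centered  # (n_topo, B)
    results = []
    for i, tid in enumerate(matrix.topology_ids):
        p = float((null_stat[i] >= deltas[i] - 1e-12).mean())
        results.append(
            TopoTestResult(
                topology_id=tid,
                lnL=float(totals[i]),
                delta=float(deltas[i]),
                p_value=p,
                n_resamples=B,
            )
        )
    return results


def kh_test(matrix: SiteLnLMatrix, B: int = 10000, seed: int = 0) -> list[TopoTestResult]:
    """Kishino–Hasegawa two-sided RELL test for exactly two topologies."""
    if len(matrix.topology_ids) != 2:
        raise ValueError("KH test requires exactly two topologies")
    _check_B(B)
    rng = np.random.default_rng(seed)
    diff = matrix.values[0] - matrix.values[1]
    observed = float(diff.sum())
    n_sites = diff.size
    reps = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n_sites, size=n_sites)
        reps[b] = diff[idx].sum()
    centered = reps - reps.mean()
    p = float((np.abs(centered) >= abs(observed) - 1e-12).mean())
    totals = matrix.values.sum(axis=1)
    best = totals.max()
    return [
        TopoTestResult(
            topology_id=tid,
            lnL=float(totals[i]),
            delta=float(best - totals[i]),
            p_value=p,
            n_resamples=B,
        )
        for i, tid in enumerate(matrix.topology_ids)
    ]
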