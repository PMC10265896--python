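"""Shared numerical helpers: seeded substreams and two-sided normal P values."""

from __future__ import annotations

import zlib

import numpy as np
from scipy import stats


def rng_for_stage(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator whose stream depends on (seed, stage name).

    Stage-level reruns then reproduce the same draws regardless of which
    other stages ran before them.
    """
    tag = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def two_sided_p(z) -> np.ndarray | float:
    """P value of a two-sided normal test, 2*Psi(-|z|)."""
    return 2.0 * stats.norm.sf(np.abs(z))


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted P values.

    Adjusted value for the i-th order statistic is min over j >= i of
    p_(j) * m / j, capped at 1; output is returned in the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of P values")
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
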