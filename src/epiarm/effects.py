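"""Additive-product vs interaction BLUP correlations (the rho statistic).

For an arm pair (i, i') with a non-zero interaction variance, rho is the
Pearson correlation across lines between the elementwise product of the two
arms' additive BLUPs and the interaction BLUP.  A negative rho indicates a
less-than-additive (redundancy-like) architecture; a positive rho a
greater-than-additive one.  When only one additive variance is non-zero the
single remaining additive BLUP is correlated with the interaction BLUP
instead, and when both additive variances sit on the boundary the statistic
is undefined and reported as 0 with p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reml import MixedModelFit

__all__ = ["CorrelationResult", "additive_interaction_correlation", "significance_stars"]


@dataclass
class CorrelationResult:
    rho: float
    p: float
    mode: str  # "product" | "single_arm" | "undefined"
    n: int


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with p from the t-transform on n-2 df."""
    n = a.size
    if n < 3 or np.std(a) == 0 or np.std(b) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def additive_interaction_correlation(
    fit: MixedModelFit,
    arm_i: str,
    arm_j: str,
    interaction: str | None = None,
    prefix: str = "A:",
) -> CorrelationResult:
    """Correlate additive arm BLUPs (or their product) with the interaction BLUP.

    Requires the interaction variance to be off the boundary; callers should
    not request rho for a zero interaction component.
    """
    name_i, name_j = f"{prefix}{arm_i}", f"{prefix}{arm_j}"
    int_name = interaction if interaction is not None else f"AxA:{arm_i}:{arm_j}"
    for t in (name_i, name_j, int_name):
        if t not in fit.blups:
            raise KeyError(f"missing BLUP term {t!r} (have {sorted(fit.blups)})")
    if fit.boundary_flags.get(int_name, False):
        raise ValueError(
            f"interaction component {int_name!r} is on the boundary; rho is undefined"
        )
    g_int = fit.blups[int_name]
    n = g_int.size
    on_i = fit.boundary_flags.get(name_i, False)
    on_j = fit.boundary_flags.get(name_j, False)
    if on_i and on_j:
        return CorrelationResult(rho=0.0, p=1.0, mode="undefined", n=n)
    if on_i or on_j:
        g_add = fit.blups[name_j] if on_i else fit.blups[name_i]
        r, p = _pearson(g_add, g_int)
        return CorrelationResult(rho=r, p=p, mode="single_arm", n=n)
    r, p = _pearson(fit.blups[name_i] * fit.blups[name_j], g_int)
    return CorrelationResult(rho=r, p=p, mode="product", n=n)


def significance_stars(p: float, bonferroni: float = 0.05 / 42) -> str:
    """Three-level star convention: 0.05, 0.01, and the Bonferroni level."""
    if p < bonferroni:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
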