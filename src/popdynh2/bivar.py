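"""Bivariate heritability: the share of a phenotypic correlation explained by genetics.

The statistic is ``h2_AB = rg * sqrt(h2_A * h2_B) / r_p``.  It is a ratio
whose numerator is not nested within the denominator, so values above one
are mathematically legal — and diagnostically useful: they indicate that
the univariate heritabilities or the genetic correlation were likely
inflated, or that the phenotypic correlation was suppressed by non-genetic
(e.g. negatively confounded) pathways.

Standard errors are Monte-Carlo: each input is drawn independently from a
normal centred on its point estimate with SD equal to its SE, the statistic
is evaluated per draw, and the SD of the draws is the SE.  Independence of
the inputs makes this conservative when the inputs are positively
correlated (as they are when fitted on shared data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DataError

__all__ = ["BivariateH2", "bivariate_h2", "mc_standard_error", "flag_inflation"]

#: draws whose |r_p| falls below this are rejected as numerically undefined
RP_EPS = 1e-3


@dataclass
class BivariateH2:
    h2_ab: float
    se_h2_ab: float
    inputs: dict
    n_draws: int
    rejected_fraction: float = 0.0

    @property
    def exceeds_one_margin(self) -> float:
        """(h2_ab - 1) in units of its SE; inf if the SE is zero."""
        if self.se_h2_ab == 0:
            return np.inf if self.h2_ab > 1 else -np.inf
        return (self.h2_ab - 1.0) / self.se_h2_ab

    @property
    def exceeds_one(self) -> bool:
        return self.h2_ab > 1.0


def bivariate_h2(rg: float, h2_A: float, h2_B: float, r_p: float) -> float:
    """Point estimate ``rg * sqrt(h2_A * h2_B) / r_p``."""
    if h2_A < 0 or h2_B < 0:
        raise DataError("heritabilities must be non-negative")
    if r_p == 0:
        raise DataError("bivariate heritability undefined at r_p = 0")
    return rg * np.sqrt(h2_A * h2_B) / r_p


def mc_standard_error(
    rg: float, se_rg: float,
    h2_A: float, se_A: float,
    h2_B: float, se_B: float,
    r_p: float, se_rp: float,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> BivariateH2:
    """Monte-Carlo SE of the bivariate heritability.

    Inputs are drawn as independent normals (point estimate, SE).  Negative
    heritability draws are truncated at zero; draws with ``|r_p|`` below
    ``RP_EPS`` are rejected and the rejected fraction reported.  All-zero
    SEs short-circuit to an SE of exactly 0.
    """
    for s in (se_rg, se_A, se_B, se_rp):
        if s < 0:
            raise DataError("standard errors must be non-negative")
    point = bivariate_h2(rg, h2_A, h2_B, r_p)
    inputs = dict(rg=rg, se_rg=se_rg, h2_A=h2_A, se_A=se_A,
                  h2_B=h2_B, se_B=se_B, r_p=r_p, se_rp=se_rp)
    if se_rg == se_A == se_B == se_rp == 0:
        return BivariateH2(h2_ab=point, se_h2_ab=0.0, inputs=inputs, n_draws=0)
    if n_draws < 1000:
        raise ConfigError("n_draws below 1000 gives unstable SEs; refusing")
    rng = np.random.default_rng(seed)
    d_rg = rng.normal(rg, se_rg, n_draws)
    d_hA = np.maximum(rng.normal(h2_A, se_A, n_draws), 0.0)
    d_hB = np.maximum(rng.normal(h2_B, se_B, n_draws), 0.0)
    d_rp = rng.normal(r_p, se_rp, n_draws)
    ok = np.abs(d_rp) >= RP_EPS
    vals = d_rg[ok] * np.sqrt(d_hA[ok] * d_hB[ok]) / d_rp[ok]
    return BivariateH2(
        h2_ab=point,
        se_h2_ab=float(np.std(vals)),
        inputs=inputs,
        n_draws=n_draws,
        rejected_fraction=float(1.0 - ok.mean()),
    )


def flag_inflation(est: BivariateH2) -> str:
    """Qualitative verdict on whether the statistic exceeds one.

    The verdict is phrased as an indicator of possible bias in the inputs,
    never as a causal conclusion.
    """
    margin = est.exceeds_one_margin
    if margin <= 0:
        return (
            "consistent: bivariate heritability does not exceed 1; "
            "no indicator of possible bias from this statistic"
        )
    if margin < 2:
        return (
            "exceeds_one_weak: point estimate above 1 but within 2 SEs; "
            "weak indicator of possible bias in the univariate heritabilities, "
            "genetic correlation, or phenotypic correlation"
        )
    return (
        "exceeds_one_strong: estimate above 1 by more than 2 SEs; "
        "strong indicator of possible bias in the input estimates "
        "(inflated genetic parameters or suppressed phenotypic correlation)"
    )
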