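"""Compiled kernel for the Albert-Chib truncated-normal latent update.

The Gibbs sweep redraws one latent ``w ~ N(eta, 1)`` truncated to the
half-line matching each binary response, for every subject-voxel pair; at
realistic sizes this is millions of inverse-CDF evaluations per iteration and
dominates the chain cost, so it is compiled.  The inverse normal CDF uses
Acklam's rational approximation (relative error < 1.2e-9, far below the
Monte-Carlo resolution of any chain) with the normal CDF from ``erfc``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["latent_update"]

_SQRT1_2 = 1.0 / math.sqrt(2.0)


@njit(fastmath=True, cache=True)
def _ndtri_acklam(p: float) -> float:
    if p < 0.02425:
        q = math.sqrt(-2.0 * math.log(p))
        return (
            ((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
               - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
             + 4.374664141464968e+00) * q + 2.938163982698783e+00
        ) / (
            (((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
              + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0
        )
    elif p <= 0.97575:
        q = p - 0.5
        r = q * q
        return (
            ((((-3.969683028665376e+01 * r + 2.209460984245205e+02) * r
               - 2.759285104469687e+02) * r + 1.383577518672690e+02) * r
             - 3.066479806614716e+01) * r + 2.506628277459239e+00
        ) * q / (
            ((((-5.447609879822406e+01 * r + 1.615858368580409e+02) * r
               - 1.556989798598866e+02) * r + 6.680131188771972e+01) * r
             - 1.328068155288572e+01) * r + 1.0
        )
    else:
        q = math.sqrt(-2.0 * math.log1p(-p))
        return -(
            ((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
               - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
             + 4.374664141464968e+00) * q + 2.938163982698783e+00
        ) / (
            (((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
              + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0
        )


@njit(fastmath=True, cache=True)
def latent_update(eta, sgn, u, out) -> None:
    """``out = eta - sgn * ndtri(u * ndtr(sgn * eta))`` elementwise.

    With ``sgn = +1`` (response 1) this draws N(eta, 1) truncated to
    (0, inf) by inversion through the reflection identity; ``sgn = -1``
    (response 0) gives the (-inf, 0] branch.  All arrays share one shape;
    arithmetic is double internally regardless of input dtype.
    """
    ef = eta.ravel()
    sf = sgn.ravel()
    uf = u.ravel()
    of = out.ravel()
    for i in range(ef.size):
        e = float(ef[i])
        s = float(sf[i])
        p = 0.5 * math.erfc(-s * e * _SQRT1_2)
        arg = float(uf[i]) * p
        if arg < 1e-300:
            arg = 1e-300
        of[i] = e - s * _ndtri_acklam(arg)
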