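"""Forward simulation of three external psychophysical tasks.

Given a fitted observer parameter set, predict performance on:

1. the dichoptic letter-chart **balance point** — the amblyopic-eye
   contrast fraction x at which the two eyes' perceived contrasts are
   equal under the constraint that the two contrasts sum to 1;
2. the **cyclopean phase-combination balance** — for a set of fixed
   amblyopic-eye contrasts, the fellow-eye contrast producing equal
   per-eye perceived contrast, reported as the AE/FE contrast ratio;
3. **dichoptic masking threshold elevation** — the dB elevation of the
   amblyopic eye's contrast threshold when the fellow eye views a mask,
   TE = 20*log10(Thr_mask / Thr_no-mask).

"Equal perceived contrast across both eyes" is interpreted as equality
of the model's per-eye normalized outputs. All solvers use bracketed
root-finding on a monotone residual; closed forms exist for (2) and
(3) and serve as independent cross-checks in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import DegenerateParameterError
from .model import ObserverParams

__all__ = [
    "BalancePointResult",
    "CyclopeanResult",
    "MaskingResult",
    "DING_CONTRASTS",
    "simulate_letter_balance",
    "simulate_cyclopean_balance",
    "simulate_masking_te",
]

_XTOL = 1e-9

#: Fixed non-dominant-eye contrasts used in the cyclopean phase task
#: (the experimental values for that paradigm span this range).
DING_CONTRASTS = (0.0075, 0.015, 0.03, 0.06, 0.12, 0.24, 0.48, 0.96)


@dataclass
class BalancePointResult:
    """``bp``: AE contrast fraction at equal per-eye perceived contrast
    under the sum-to-1 constraint; 0.5 for a symmetric observer."""

    bp: float


@dataclass
class CyclopeanResult:
    fixed_contrasts: np.ndarray
    fellow_contrasts: np.ndarray
    ratios: np.ndarray  #: fixed (AE) / solved (FE) contrast


@dataclass
class MaskingResult:
    thr_no_mask: float
    thr_mask: float
    te_db: float
    saturated: bool = False  #: the required AE contrast exceeded 1


def _percepts(params: ObserverParams, c_ae: float, c_fe: float) -> tuple[float, float]:
    a_ae = params.k_ae * c_ae
    return (
        a_ae / (params.mu_ae * c_fe + params.sigma),
        c_fe / (params.mu_fe * a_ae + params.sigma),
    )


def simulate_letter_balance(params: ObserverParams) -> BalancePointResult:
    """Solve for the balance point under the sum-to-1 constraint.

    Finds x in (0, 1) with ``Chat_AE(x, 1-x) = Chat_FE(x, 1-x)`` by
    bracketed root-finding; the residual is strictly monotone in x.
    """

    def residual(x: float) -> float:
        p_ae, p_fe = _percepts(params, x, 1.0 - x)
        return p_ae - p_fe

    lo, hi = 1e-12, 1.0 - 1e-12
    if residual(lo) >= 0 or residual(hi) <= 0:
        raise DegenerateParameterError(
            "no balance point in (0, 1) for these parameters"
        )
    bp = brentq(residual, lo, hi, xtol=_XTOL)
    return BalancePointResult(bp=float(bp))


def simulate_cyclopean_balance(
    params: ObserverParams, fixed_contrasts=DING_CONTRASTS
) -> CyclopeanResult:
    """For each fixed amblyopic-eye contrast, solve for the fellow-eye
    contrast giving equal per-eye perceived contrast.

    As the fixed contrast tends to 0 the ratio tends to 1/k_ae (both
    normalization denominators tend to sigma).
    """
    fixed = np.asarray(fixed_contrasts, dtype=float)
    if fixed.size == 0 or np.any(fixed <= 0) or np.any(fixed > 1):
        raise ValueError("fixed contrasts must lie in (0, 1]")
    fellow = np.empty_like(fixed)
    for i, c in enumerate(fixed):

        def residual(y: float, c: float = c) -> float:
            p_ae, p_fe = _percepts(params, c, y)
            return p_ae - p_fe

        # residual is positive at y ~ 0 and strictly decreasing in y
        lo = 1e-12
        if residual(lo) <= 0:
            raise DegenerateParameterError(
                f"no positive fellow-eye solution at fixed contrast {c}"
            )
        hi = 1.0
        while residual(hi) > 0:
            hi *= 2.0
            if hi > 1e6:
                raise DegenerateParameterError(
                    f"fellow-eye solution diverges at fixed contrast {c}"
                )
        fellow[i] = brentq(residual, lo, hi, xtol=_XTOL)
    return CyclopeanResult(
        fixed_contrasts=fixed, fellow_contrasts=fellow, ratios=fixed / fellow
    )


def simulate_masking_te(
    params: ObserverParams, thr_no_mask: float, mask_contrast: float
) -> MaskingResult:
    """Threshold elevation of the amblyopic eye under a fellow-eye mask.

    The perceived-contrast threshold is the model's AE output at the
    unmasked threshold with the fellow eye blank; the masked threshold
    is the AE contrast whose output reaches that same level with the
    fellow eye fixed at ``mask_contrast``. If that would require more
    than 100% contrast the result is flagged ``saturated`` and reports
    the boundary value.
    """
    if not 0.0 < thr_no_mask < 1.0:
        raise ValueError("thr_no_mask must be in (0, 1)")
    if not 0.0 <= mask_contrast <= 1.0:
        raise ValueError("mask_contrast must be in [0, 1]")
    tau = _percepts(params, thr_no_mask, 0.0)[0]

    def residual(x: float) -> float:
        return _percepts(params, x, mask_contrast)[0] - tau

    if residual(1.0) < 0:
        thr_mask, saturated = 1.0, True
    elif residual(1.0) == 0:
        thr_mask, saturated = 1.0, False
    else:
        thr_mask = brentq(residual, 1e-12, 1.0, xtol=_XTOL)
        saturated = False
    te_db = 20.0 * np.log10(thr_mask / thr_no_mask)
    return MaskingResult(
        thr_no_mask=float(thr_no_mask),
        thr_mask=float(thr_mask),
        te_db=float(te_db),
        saturated=saturated,
    )
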