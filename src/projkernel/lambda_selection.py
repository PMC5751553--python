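"""Closed-form selection of the projection strength lam.

Minimising the Bregman divergence between the projected kernel and the
original over lam gives, for the Mahalanobis, Frobenius and von-Neumann
generators, the degenerate answer lam = 0 (no perturbation at all, hence no
rectification).  The LogDet generator yields a usable stationarity condition

    -m / (1 - lam) - sum_{i<=m} d_i tr(K^+ p_i p_i') = 0
    =>  lam_opt = 1 + m / sum_{i<=m} d_i t_i

with pseudo-inverse traces t_i, and the perturbed von-Neumann objective gives

    lam_opt1 = (sum_{i=1}^n d_i t_i - 0.5) / (sum_{i<=m} d_i t_i).

On a kernel of full numerical rank d_i t_i = 1 for every retained eigenvalue,
so lam_opt = 2 exactly and lam_opt1 = (n - 0.5) / m.  When the denominator
vanishes (tiny negatives truncated by the pseudo-inverse) the selected value
is clamped: 1 for a -inf limit, 100 for +inf, and any finite value outside
[1, 100] is clamped into that interval with the raw value preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .divergences import pinv_traces
from .spectral import SpectralDecomposition

__all__ = [
    "LambdaSelection",
    "lambda_closed_form",
    "lambda_opt_logdet",
    "lambda_opt_pvn",
    "stationarity_residual",
    "LAMBDA_MIN",
    "LAMBDA_MAX",
]

LAMBDA_MIN = 1.0
LAMBDA_MAX = 100.0
_DENOM_EPS = 1e-12

_CLOSED_FORM_ZERO = ("mahalanobis", "frobenius", "von_neumann")


@dataclass(frozen=True)
class LambdaSelection:
    """A selected projection strength with clamping provenance.

    ``raw_lam`` is the pre-clamp value (may be ``inf``/``-inf`` when the
    denominator vanished); ``denominator`` is the diagnostic
    sum_{i<=m} d_i t_i; ``note`` records why clamping fired, if it did.
    """

    divergence: str
    lam: float
    clamped: bool
    raw_lam: float
    denominator: float
    note: str = ""


def lambda_closed_form(divergence_name: str) -> LambdaSelection:
    """lam = 0 minimisers for the three dismissed generators.

    The Mahalanobis and Frobenius objectives are monotone in lam >= 0 with
    minimum at 0; the von-Neumann objective's derivative
    ``-sum_{i<=m} d_i log(1 - lam)`` has its unique stationary point at
    lam = 0.  A zero strength leaves the kernel unperturbed — the reason
    these three rules are rejected for rectification — so callers should
    treat the result as a warning, not apply it silently.
    """
    name = divergence_name.replace("-", "_").lower()
    if name not in _CLOSED_FORM_ZERO:
        raise ValueError(
            f"no lam=0 closed form for {divergence_name!r}; use lambda_opt_logdet "
            "or lambda_opt_pvn for the logdet / perturbed von-Neumann rules"
        )
    return LambdaSelection(
        divergence=name,
        lam=0.0,
        clamped=False,
        raw_lam=0.0,
        denominator=float("nan"),
        note="lam=0 leaves the kernel unperturbed (no rectification)",
    )


def _clamp(divergence: str, raw: float, denom: float, note: str = "") -> LambdaSelection:
    if raw < LAMBDA_MIN:
        return LambdaSelection(divergence, LAMBDA_MIN, True, raw, denom,
                               note or f"raw value {raw:g} clamped to {LAMBDA_MIN:g}")
    if raw > LAMBDA_MAX:
        return LambdaSelection(divergence, LAMBDA_MAX, True, raw, denom,
                               note or f"raw value {raw:g} clamped to {LAMBDA_MAX:g}")
    return LambdaSelection(divergence, float(raw), False, float(raw), denom, note)


def _denominator(decomp: SpectralDecomposition, pinv_tol: float) -> float:
    d = decomp.eigenvalues
    m = decomp.neg_index
    t = pinv_traces(decomp, pinv_tol=pinv_tol)
    return float(np.sum(d[:m] * t[:m]))


def _degenerate(divergence: str, denom: float) -> LambdaSelection:
    # limit convention: denominator -> 0+ gives +inf (clamp 100), 0- gives -inf (clamp 1)
    if denom >= 0:
        return LambdaSelection(divergence, LAMBDA_MAX, True, float("inf"), denom,
                               "denominator ~ 0, +inf limit clamped to 100")
    return LambdaSelection(divergence, LAMBDA_MIN, True, float("-inf"), denom,
                           "denominator ~ 0, -inf limit clamped to 1")


def lambda_opt_logdet(
    decomp: SpectralDecomposition, pinv_tol: float = 1e-8
) -> LambdaSelection:
    """LogDet-divergence optimum: lam = 1 + m / sum_{i<=m} d_i t_i.

    Total function: PSD input returns the identity projection lam = 1;
    a vanishing denominator follows the +/-inf clamping convention; finite
    values are clamped into [1, 100] with the raw value preserved.
    """
    m = decomp.neg_index
    if m == 0:
        return LambdaSelection("logdet", LAMBDA_MIN, True, LAMBDA_MIN, 0.0,
                               "PSD input: projection is the identity at lam=1")
    denom = _denominator(decomp, pinv_tol)
    if abs(denom) < _DENOM_EPS:
        return _degenerate("logdet", denom)
    return _clamp("logdet", 1.0 + m / denom, denom)


def lambda_opt_pvn(
    decomp: SpectralDecomposition, pinv_tol: float = 1e-8
) -> LambdaSelection:
    """Perturbed von-Neumann optimum: lam = (sum_i d_i t_i - 0.5) / sum_{i<=m} d_i t_i."""
    m = decomp.neg_index
    if m == 0:
        return LambdaSelection("perturbed_von_neumann", LAMBDA_MIN, True, LAMBDA_MIN, 0.0,
                               "PSD input: projection is the identity at lam=1")
    denom = _denominator(decomp, pinv_tol)
    d = decomp.eigenvalues
    t = pinv_traces(decomp, pinv_tol=pinv_tol)
    numer = float(np.sum(d * t)) - 0.5
    if abs(denom) < _DENOM_EPS:
        return _degenerate("perturbed_von_neumann", denom)
    return _clamp("perturbed_von_neumann", numer / denom, denom)


def stationarity_residual(
    decomp: SpectralDecomposition, lam: float, pinv_tol: float = 1e-8
) -> float:
    """-m / (1 - lam) - sum_{i<=m} d_i t_i, the LogDet stationarity condition.

    Zero exactly at the unclamped LogDet optimum; diagnostic only.
    """
    if lam == 1.0:
        raise ValueError("stationarity residual has a pole at lam = 1")
    m = decomp.neg_index
    return -m / (1.0 - lam) - _denominator(decomp, pinv_tol)
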