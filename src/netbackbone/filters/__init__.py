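"""The seven statistical edge-significance filters.

Each filter scores every edge of a weighted network with a p-value under
its own null model of weight formation:

========  =====================================================
``df``    disparity filter (uniform split of node strength)
``pf``    Pólya-urn filter (beta-binomial reinforcement null)
``mlf``   marginal likelihood filter (binomial, n = T)
``nc``    noise-corrected filter (binomial approximation, n = 2T)
``ecm``   enhanced configuration model (degree+strength ensemble)
``gloss`` global statistical significance (weight shuffling)
``lans``  locally adaptive sparsification (per-node empirical CDF)
========  =====================================================
"""

from __future__ import annotations

from ..graph import WeightedNetwork
from ._base import EdgePValues, FilterError
from ._binomial import mlf_pvalues, nc_pvalues
from ._ecm import (
    ECMConvergenceError,
    ECMParameters,
    ecm_fit,
    ecm_pvalues,
    ecm_sample_weights,
)
from ._gloss import gloss_pvalues
from ._local import disparity_pvalues, lans_pvalues
from ._polya import beta_binomial_survival, polya_pvalues

__all__ = [
    "EdgePValues",
    "FilterError",
    "ECMParameters",
    "ECMConvergenceError",
    "disparity_pvalues",
    "polya_pvalues",
    "mlf_pvalues",
    "nc_pvalues",
    "ecm_fit",
    "ecm_pvalues",
    "ecm_sample_weights",
    "gloss_pvalues",
    "lans_pvalues",
    "beta_binomial_survival",
    "compute_pvalues",
]


def compute_pvalues(
    net: WeightedNetwork, method: str, **params: object
) -> EdgePValues:
    """Dispatch to a filter by its canonical short name.

    Recognized ``params``: ``a`` (pf reinforcement, default 1), ``mode``
    (gloss, default ``"conditional"``), ``tol``/``max_iter`` (ecm solver).
    """
    if method == "df":
        return disparity_pvalues(net)
    if method == "pf":
        return polya_pvalues(net, a=float(params.get("a", 1.0)))
    if method == "mlf":
        return mlf_pvalues(net)
    if method == "nc":
        return nc_pvalues(net)
    if method == "ecm":
        return ecm_pvalues(
            net,
            tol=float(params.get("tol", 1e-6)),
            max_iter=int(params.get("max_iter", 5000)),
        )
    if method == "gloss":
        return gloss_pvalues(net, mode=str(params.get("mode", "conditional")))
    if method == "lans":
        return lans_pvalues(net)
    raise ValueError(f"unknown method {method!r}")
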