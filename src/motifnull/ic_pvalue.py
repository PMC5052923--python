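"""Tail probabilities of motif information content under the uniform null.

The p-value of an IC value I for N x L motifs is the fraction of all
4^(NL) motifs with IC(M) > I (strict; ties sit on measure-zero class
boundaries).  Writing the tilted MaxEnt distribution in IC form,
Q(M) = exp(lambda IC(M)) / Z_Q with lambda tuned so the mean IC under Q is
I, the p-value is an importance-sampling expectation

    p = (Z_Q / Z_P) < [IC(M) > I] exp(-lambda IC(M)) >_Q,   Z_P = 4^(NL),

which yields three estimators, all computed entirely on the log10 scale so
they remain finite past p ~ 1e-100:

  * an analytic upper bound (Z_Q/Z_P) * (1/2) exp(-lambda I) — the 1/2
    assumes the tilted IC distribution is symmetric about its mean;
  * a moment-matching estimate: the bound times erfcx(lambda sigma/sqrt 2),
    treating IC under Q as approximately normal with exactly computed
    variance sigma^2;
  * a Monte Carlo importance-sampling estimate with a delta-method
    standard error.

log(Z_Q/Z_P) = 2 lambda L + L log Z_c(lambda) - N L log 4, since the IC
tilt differs from the entropy tilt by the constant exp(2 lambda L).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx, logsumexp

from . import count_classes as cc
from .errors import EmptyInputError, ParameterError
from .maxent import MaxEntModel, fit_lambda, sample_maxent_ics

_LN10 = math.log(10.0)
SKEW_FLAG_THRESHOLD = 1.0


@dataclass
class PValueResult:
    """Log-scale IC p-value estimates with the tilt they were computed at."""

    log10_bound: float
    log10_moment: float
    log10_is: float
    is_se_log10: float
    n_is: int
    lam: float
    sigma2: float  # variance of IC under Q, bits^2
    skewness: float  # skewness of IC under Q
    symmetric_halving_heuristic: bool  # True when |skewness| exceeds threshold


def _tilted_model(N: int, L: int, I: float, table=None) -> MaxEntModel:
    return fit_lambda(N, L, I, table=table)


def log_zq_over_zp(model: MaxEntModel) -> float:
    """Natural log of Z_Q / Z_P for the IC-form tilt at the model's lambda."""
    logzc = cc.log_partition_column(model.class_table, model.lam)
    return (
        2.0 * model.lam * model.L
        + model.L * logzc
        - model.N * model.L * math.log(4.0)
    )


def ic_sigma2(model: MaxEntModel) -> float:
    """Exact variance of motif IC under Q (equals the entropy variance)."""
    _, var_h = cc.tilted_moments(model.class_table, model.lam)
    return model.L * var_h


def ic_skewness(model: MaxEntModel) -> float:
    """Exact skewness of motif IC under Q (sign-flipped entropy skewness)."""
    m3 = cc.tilted_central_moment(model.class_table, model.lam, 3)
    var = ic_sigma2(model)
    if var == 0:
        return 0.0
    return -model.L * m3 / var**1.5


def pvalue_bound(N: int, L: int, I: float, model: MaxEntModel | None = None) -> float:
    """log10 of the analytic upper bound (Z_Q/Z_P) * (1/2) e^{-lambda I}.

    The integrand [IC > I] e^{-lambda IC} never exceeds e^{-lambda I} for
    lambda >= 0; the further halving assumes symmetry of IC about I and is
    therefore heuristic (see PValueResult.symmetric_halving_heuristic).
    """
    if model is None:
        model = _tilted_model(N, L, I)
    if model.lam < 0:
        warnings.warn(
            "lambda < 0 (I below the uniform mean IC): the e^{-lambda I} "
            "envelope is not a bound in this regime",
            RuntimeWarning,
            stacklevel=2,
        )
    return (log_zq_over_zp(model) - model.lam * I + math.log(0.5)) / _LN10


def pvalue_moment(N: int, L: int, I: float, model: MaxEntModel | None = None) -> float:
    """log10 moment-matching estimate: the bound times erfcx(lambda sigma/sqrt 2)."""
    if model is None:
        model = _tilted_model(N, L, I)
    sigma = math.sqrt(ic_sigma2(model))
    factor = erfcx(model.lam * sigma / math.sqrt(2.0))
    return pvalue_bound(N, L, I, model) + math.log(factor) / _LN10


def pvalue_importance(
    N: int, L: int, I: float, n: int = 10_000, seed=None,
    model: MaxEntModel | None = None,
) -> tuple[float, float]:
    """Importance-sampling log10 p-value and its delta-method SE.

    Draws n motif ICs from Q and averages [IC > I] e^{-lambda IC} in
    log space.  Returns (-inf, inf) with a warning if no draw lands in the
    tail (increase n).
    """
    if n < 100:
        raise ParameterError("importance sampling needs n >= 100")
    if model is None:
        model = _tilted_model(N, L, I)
    ics = sample_maxent_ics(model, n, seed=seed)
    tail = ics[ics > I]
    if tail.size == 0:
        warnings.warn(
            "no importance samples exceeded I; increase n", RuntimeWarning,
            stacklevel=2,
        )
        return -math.inf, math.inf
    a = -model.lam * tail
    ls1 = logsumexp(a)
    ls2 = logsumexp(2.0 * a)
    log_mean = ls1 - math.log(n)
    log10_p = (log_zq_over_zp(model) + log_mean) / _LN10
    # SE(log10 p) = (SE of mean)/(mean * ln 10); n*S2/S1^2 - 1 is computed
    # in log space to avoid underflow.
    rel_var = math.exp(ls2 + math.log(n) - 2.0 * ls1) - 1.0
    se_log10 = math.sqrt(max(rel_var, 0.0) / n) / _LN10
    return log10_p, se_log10


def estimate_pvalues(
    N: int, L: int, I: float, n_is: int = 10_000, seed=None, table=None
) -> PValueResult:
    """All three estimators at once, sharing a single tuned tilt."""
    model = _tilted_model(N, L, I, table=table)
    skew = ic_skewness(model)
    log10_is, se = pvalue_importance(N, L, I, n=n_is, seed=seed, model=model)
    return PValueResult(
        log10_bound=pvalue_bound(N, L, I, model),
        log10_moment=pvalue_moment(N, L, I, model),
        log10_is=log10_is,
        is_se_log10=se,
        n_is=n_is,
        lam=model.lam,
        sigma2=ic_sigma2(model),
        skewness=skew,
        symmetric_halving_heuristic=abs(skew) > SKEW_FLAG_THRESHOLD,
    )


def evalue_oops(log10_p: float, sequence_lengths, L: int) -> float:
    """Convert a log10 p-value to a log10 E-value under the OOPS model.

    One occurrence per sequence: the number of possible alignments is
    prod_i (m_i - L + 1), so log10 E = log10 p + sum_i log10(m_i - L + 1).
    """
    lengths = list(sequence_lengths)
    if not lengths:
        raise EmptyInputError("sequence_lengths must be nonempty")
    total = 0.0
    for m in lengths:
        if m < L:
            raise ParameterError(f"sequence length {m} is shorter than motif width {L}")
        total += math.log10(m - L + 1)
    return log10_p + total
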