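"""Method-of-moments net diversification estimators.

Closed-form estimators of the net diversification rate r = lambda - mu
(species/Myr) from a clade's extant species richness n and its age t,
under an assumed relative extinction fraction epsilon = mu/lambda.
Epsilon is a fixed assumption, never estimated; standard runs use
epsilon in {0, 0.5, 0.9} (zero, intermediate, and high extinction
relative to speciation).

The stem-group estimator inverts the expected richness of a clade that
starts from a single lineage at its stem age; the crown-group estimator
starts from the two daughter lineages at the crown age, conditioning on
the survival of both.  A post-processing helper for branch-specific
speciation-rate summaries (ClaDS-style output) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def _check_inputs(t: float, epsilon: float) -> None:
    if t <= 0:
        raise ValueError(f"clade age must be positive, got {t}")
    if not (0 <= epsilon < 1):
        raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")


def ms_stem_rate(n: float, t_stem: float, epsilon: float = 0.5) -> float:
    """Stem-group method-of-moments net diversification rate.

    r = ln(n (1 - eps) + eps) / t_stem

    With epsilon = 0 this reduces to ln(n) / t.  Defined for n >= 1
    (a single surviving species gives r = 0).
    """
    _check_inputs(t_stem, epsilon)
    if n < 1:
        raise ValueError(f"stem estimator requires richness >= 1, got {n}")
    return math.log(n * (1.0 - epsilon) + epsilon) / t_stem


def ms_crown_rate(n: float, t_crown: float, epsilon: float = 0.5) -> float:
    """Crown-group method-of-moments net diversification rate.

    r = (1/t) * { ln[ n(1-eps^2)/2 + 2 eps
                      + (1-eps)/2 * sqrt( n (n eps^2 - 8 eps + 2 n eps + n) ) ]
                  - ln 2 }

    With epsilon = 0 this reduces to ln(n/2) / t, and at n = 2 the
    bracketed term equals 2 identically, giving r = 0 for every epsilon.
    Requires n >= 2 (a crown group has at least two extant species).
    """
    _check_inputs(t_crown, epsilon)
    if n < 2:
        raise ValueError(f"crown estimator requires richness >= 2, got {n}")
    # inner square root grouped exactly as written to avoid cancellation
    disc = n * (n * epsilon * epsilon - 8.0 * epsilon + 2.0 * n * epsilon + n)
    if disc < 0:  # cannot occur for n >= 2, eps in [0,1); guard anyway
        raise ValueError(
            f"negative discriminant ({disc}) for n={n}, epsilon={epsilon}"
        )
    inner = (
        0.5 * n * (1.0 - epsilon * epsilon)
        + 2.0 * epsilon
        + 0.5 * (1.0 - epsilon) * math.sqrt(disc)
    )
    return (math.log(inner) - math.log(2.0)) / t_crown


def clads_diversification(lambda_imean: float, epsilon: float) -> float:
    """Net diversification from a mean branch-specific speciation rate.

    Given clade-wide turnover epsilon = mu/lambda and the mean
    branch-specific speciation rate lambda_imean, the clade's mean
    branch-specific diversification rate is (1 - epsilon) * lambda_imean.
    """
    if lambda_imean < 0:
        raise ValueError(f"lambda_imean must be >= 0, got {lambda_imean}")
    if not (0 <= epsilon < 1):
        raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")
    return (1.0 - epsilon) * lambda_imean


@dataclass
class CladsSummary:
    """Posterior summaries from a branch-heterogeneous speciation model.

    epsilon: clade-wide turnover mu/lambda.
    lambda_imean: mean speciation rate over all branches (/Myr).
    lambda_tipmean: mean speciation rate over terminal branches (/Myr).
    """

    epsilon: float
    lambda_imean: float
    lambda_tipmean: float

    def diversification_rate(self) -> float:
        return clads_diversification(self.lambda_imean, self.epsilon)


def fill_rates(records, age_basis: str = "crown", epsilon=0.5):
    """Fill the diversification-rate field of clade records in place.

    ``epsilon`` may be a scalar or an iterable; every value is stored in
    ``record.rates[(basis, eps)]`` and the scalar (or first) value also
    populates ``record.rate``.  Records whose relevant age is zero are
    flagged ``zero_crown`` and receive no rate (the estimator is undefined
    at t = 0).  Returns the records.
    """
    if age_basis not in ("crown", "stem"):
        raise ValueError("age_basis must be 'crown' or 'stem'")
    eps_list = [epsilon] if isinstance(epsilon, (int, float)) else list(epsilon)
    est = ms_crown_rate if age_basis == "crown" else ms_stem_rate
    for rec in records:
        t = rec.crown_age if age_basis == "crown" else rec.stem_age
        if t <= 0:
            rec.zero_crown = True
            rec.rate = None
            continue
        for eps in eps_list:
            rec.rates[(age_basis, eps)] = est(rec.richness, t, eps)
        rec.rate = rec.rates[(age_basis, eps_list[0])]
    return records
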