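"""How many single EVs are enough: rare-event detection power.

Tumor-derived EVs are a ~1e-6 to 1e-3 fraction of the plasma pool, and the
rarest informative cargo (mutant mRNAs) occurs at roughly one copy per
100,000 EVs.  When ``n`` single EVs are drawn at random from a mixed sample,
the number of positives is Binomial(n, p) — sampling with replacement is
exact enough because n is always many orders of magnitude below the ~1e10
EVs per ml of blood.  This module answers the two inverse questions: the
probability of seeing at least ``m`` positives at a given ``n``, and the
smallest ``n`` achieving a target confidence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "SamplingScenario",
    "detection_probability",
    "required_sample_size",
    "cargo_positive_probability",
    "power_table",
]

# Below this per-EV probability the Poisson tail is used in place of the
# binomial one.  The Barbour-Hall bound gives total-variation distance
# <= (1 - e^-np) * p <= p between Binomial(n, p) and Poisson(np), so at this
# boundary the two tails agree to better than 1e-6 absolute for every n, m.
POISSON_SWITCHOVER_P: float = 1e-6


@dataclass(frozen=True)
class SamplingScenario:
    """A single-EV assay: tEV fraction, cargo abundance, and sample size."""

    tev_fraction: float
    copies_per_ev: float = 0.0
    n_sampled: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.tev_fraction <= 1.0:
            raise ValueError(f"tEV fraction must lie in [0, 1], got {self.tev_fraction}")
        if self.copies_per_ev < 0:
            raise ValueError(f"copies per EV must be >= 0, got {self.copies_per_ev}")
        if self.n_sampled < 1:
            raise ValueError(f"must sample at least one EV, got {self.n_sampled}")


def cargo_positive_probability(copies_per_ev: float, model: str = "bernoulli") -> float:
    """Per-EV probability of carrying at least one biomarker copy.

    ``"bernoulli"`` treats the expected copy number directly as a presence
    probability (valid for the sub-one copy numbers typical of mutant
    transcripts; rejects values above 1).  ``"poisson"`` uses
    ``1 - exp(-copies)`` and handles any copy number.
    """
    if copies_per_ev < 0:
        raise ValueError(f"copies per EV must be >= 0, got {copies_per_ev}")
    if model == "bernoulli":
        if copies_per_ev > 1.0:
            raise ValueError(
                "bernoulli cargo model requires copies per EV <= 1; use model='poisson'"
            )
        return copies_per_ev
    if model == "poisson":
        return 1.0 - math.exp(-copies_per_ev)
    raise ValueError(f"model must be 'bernoulli' or 'poisson', got {model!r}")


def _tail_probability(n: int, p: float, min_positives: int) -> float:
    if p < POISSON_SWITCHOVER_P:
        return float(stats.poisson.sf(min_positives - 1, n * p))
    return float(stats.binom.sf(min_positives - 1, n, p))


def detection_probability(
    scenario: SamplingScenario | None = None,
    min_positives: int = 1,
    *,
    p: float | None = None,
    n: int | None = None,
    target: str = "tev",
    cargo_model: str = "bernoulli",
) -> float:
    """P(at least ``min_positives`` positive EVs among those analyzed).

    Either pass a :class:`SamplingScenario` (with ``target`` choosing whether
    a positive means a tumor EV or a cargo-bearing EV), or ``p`` and ``n``
    directly.  Returns ``P(X >= min_positives)`` for ``X ~ Binomial(n, p)``,
    with a Poisson tail below the documented small-``p`` switch-over.
    """
    if min_positives < 1:
        raise ValueError(f"min_positives must be >= 1, got {min_positives}")
    if scenario is not None:
        n = scenario.n_sampled
        if target == "tev":
            p = scenario.tev_fraction
        elif target == "cargo":
            p = cargo_positive_probability(scenario.copies_per_ev, cargo_model)
        else:
            raise ValueError(f"target must be 'tev' or 'cargo', got {target!r}")
    if p is None or n is None:
        raise ValueError("provide either a scenario or both p and n")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if min_positives > n:
        warnings.warn(
            f"cannot see {min_positives} positives among {n} EVs; probability is 0",
            stacklevel=2,
        )
        return 0.0
    return _tail_probability(n, p, min_positives)


def required_sample_size(p: float, confidence: float, min_positives: int = 1) -> int:
    """Smallest n with ``detection_probability(p, n) >= confidence``.

    Starts from the analytic guess ``-ln(1 - confidence) / p`` (exact for
    ``min_positives = 1`` under the Poisson tail), brackets by doubling, and
    finishes with integer bisection — so the returned n is tight:
    ``n`` meets the confidence and ``n - 1`` does not.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1); p = {p} makes detection impossible or trivial")
    if not 0.0 <= confidence < 1.0:
        raise ValueError(f"confidence must lie in [0, 1), got {confidence}")
    if min_positives < 1:
        raise ValueError(f"min_positives must be >= 1, got {min_positives}")
    if confidence == 0.0:
        return 1

    def prob(n: int) -> float:
        if n < min_positives:
            return 0.0
        return _tail_probability(n, p, min_positives)

    lo = 1
    hi = max(min_positives, int(-math.log(1.0 - confidence) / p * (1 + 0.5 * min_positives)), 2)
    while prob(hi) < confidence:
        lo = hi
        hi *= 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if prob(mid) >= confidence:
            hi = mid
        else:
            lo = mid
    return hi if prob(lo) < confidence else lo


def power_table(
    p: float,
    sample_sizes: list[int],
    min_positives: int = 1,
) -> "list[tuple[int, float]]":
    """(n, P(detect)) pairs for a set of candidate sample sizes."""
    return [(n, detection_probability(p=p, n=n, min_positives=min_positives)) for n in sample_sizes]
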