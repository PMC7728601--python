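"""Closed-form rate and time conversions.

Three exact conversions recur throughout comparative studies of hybrid crops:
the per-year substitution rate implied by an interspecific distance and a
divergence date, the insertion age of an LTR retrotransposon from the
divergence of its twin LTRs, and the rescaling of coalescent (PSMC-style)
output into years and individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "mutation_rate",
    "ltr_insertion_age",
    "ltr_divergence_from_age",
    "scale_demography",
    "ScaledDemography",
]


def mutation_rate(D: float, T: float) -> float:
    """Per-site, per-year substitution rate from distance and split time.

    Two lineages separated ``T`` years ago accumulate divergence on both
    branches, hence ``mu = D / (2 T)``.

    Parameters
    ----------
    D : evolutionary distance between the two species (substitutions/site).
    T : divergence time in years.
    """
    if T <= 0:
        raise ValueError(f"divergence time must be positive, got {T}")
    if D < 0:
        raise ValueError(f"distance must be non-negative, got {D}")
    return D / (2.0 * T)


def ltr_insertion_age(d: float, mu: float) -> float:
    """Age of an LTR-RT insertion from the divergence of its two LTRs.

    The LTRs are identical on insertion and diverge along two branches at
    rate ``mu`` each, so ``age = d / (2 mu)`` years.
    """
    if mu <= 0:
        raise ValueError(f"mutation rate must be positive, got {mu}")
    if not 0 <= d < 0.75:
        raise ValueError(f"LTR divergence must lie in [0, 0.75), got {d}")
    return d / (2.0 * mu)


def ltr_divergence_from_age(age: float, mu: float) -> float:
    """Inverse of :func:`ltr_insertion_age` (exact round trip)."""
    if mu <= 0:
        raise ValueError(f"mutation rate must be positive, got {mu}")
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return 2.0 * mu * age


@dataclass(frozen=True)
class ScaledDemography:
    """Coalescent output rescaled to natural units.

    Attributes
    ----------
    N0 : baseline effective population size, ``theta0 / (4 mu s)``.
    years : time of each interval left boundary, in years before present.
    Ne : effective population size per interval, ``N0 * lambda_k``.
    """

    N0: float
    years: np.ndarray
    Ne: np.ndarray


def scale_demography(
    theta0: float,
    times: np.ndarray,
    lambdas: np.ndarray,
    mu: float,
    s: float = 100.0,
    g: float = 7.5,
) -> ScaledDemography:
    """Scale PSMC-style output into years and individuals.

    Parameters
    ----------
    theta0 : scaled mutation parameter per ``s``-bp bin.
    times : scaled interval times ``t_k`` (in units of 2 N0 generations).
    lambdas : relative population sizes ``lambda_k``.
    mu : mutation rate per site per year.
    s : bin size in bp used when producing the scaled output.
    g : generation time in years (default 7.5, typical of apples).

    Returns
    -------
    ScaledDemography with ``N0 = theta0/(4 mu s)``, ``years_k = 2 N0 g t_k``
    and ``Ne_k = N0 lambda_k``.
    """
    if theta0 <= 0 or mu <= 0 or s <= 0 or g <= 0:
        raise ValueError("theta0, mu, s and g must all be positive")
    times = np.asarray(times, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    if times.shape != lambdas.shape:
        raise ValueError("times and lambdas must have matching shapes")
    N0 = theta0 / (4.0 * mu * s)
    years = 2.0 * N0 * g * times
    Ne = N0 * lambdas
    return ScaledDemography(N0=N0, years=years, Ne=Ne)
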