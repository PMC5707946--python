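"""Synthetic series generators for property and parameter-recovery tests.

``generate_exact`` instantiates the GM(1,1) data-generating process itself:
x(1) = C and x(k) = (1 - e^a)(C - b/a) e^(-a(k-1)) for k >= 2, so a refit
must recover (a, b) to round-off and the initial-condition optimizer must
recover C. ``generate_noisy`` multiplies the exact series by independent
(1 + eps) factors with eps ~ Normal(0, noise_sd) — relative noise, matching
the relative-error objective and keeping the diagnostics' scale invariance
meaningful. Draws producing non-positive values are rejection-resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NonPositiveGenerated
from .model import restored_values
from .sequences import AnnualSeries

__all__ = ["SyntheticSpec", "generate_exact", "generate_noisy"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic GM(1,1) data-generating process.

    Attributes
    ----------
    a_true : float
        Development coefficient; small |a| (|a| < 0.3, say) mimics the
        slow annual trends the model targets.
    b_true : float
        Grey action quantity, in observation units.
    C_true : float
        Initial condition; the first generated observation.
    n : int
        Series length, >= 4.
    noise_sd : float
        Relative-noise standard deviation (0 for exact series).
    seed : int
        RNG seed; generation is deterministic given the spec.
    start_year : int
        Calendar year of the first observation.
    label : str
    """

    a_true: float
    b_true: float
    C_true: float
    n: int = 7
    noise_sd: float = 0.0
    seed: int = 0
    start_year: int = 2008
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"n must be >= 4, got {self.n}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_exact(spec: SyntheticSpec) -> AnnualSeries:
    """Noise-free series drawn exactly from the restored-model formula."""
    k = np.arange(2, spec.n + 1)
    values = np.concatenate(
        [[spec.C_true], restored_values(spec.a_true, spec.b_true, spec.C_true, k)]
    )
    if np.any(values <= 0):
        raise NonPositiveGenerated(
            f"spec {spec} yields non-positive values {values.tolist()}"
        )
    return AnnualSeries(
        label=spec.label, start_year=spec.start_year, values=values
    )


def generate_noisy(spec: SyntheticSpec, max_tries: int = 100) -> AnnualSeries:
    """Exact series perturbed by multiplicative Gaussian relative noise.

    Each observation is scaled by an independent (1 + eps) factor,
    eps ~ Normal(0, noise_sd); whole draws with any non-positive result are
    rejected and resampled (bounded by ``max_tries``).
    """
    exact = generate_exact(spec)
    if spec.noise_sd == 0:
        return exact
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_tries):
        factors = 1.0 + rng.normal(0.0, spec.noise_sd, size=spec.n)
        values = exact.values * factors
        if np.all(values > 0):
            return AnnualSeries(
                label=spec.label, start_year=spec.start_year, values=values
            )
    raise NonPositiveGenerated(
        f"could not draw a positive series in {max_tries} tries (noise_sd="
        f"{spec.noise_sd}); reduce the noise level"
    )
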