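"""Two-sample t-test power and sample-size analysis (exact noncentral t).

Given a detectable log2 effect ``delta`` and residual SD ``sigma``, the
standardized effect is d = delta/sigma and the power of a two-sample t
test at per-group size n uses the noncentral t distribution with
noncentrality d·sqrt(n/2) and 2n-2 degrees of freedom.  ``sample_size``
inverts this exactly for a fractional n (the study-design convention:
9.4 means "at least 10 in practice").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError

__all__ = ["PowerSpec", "power_at_n", "sample_size"]


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of the power analysis.

    ``delta`` is the group difference on the log2 scale (default
    log2 1.5 ≈ 0.585), ``sigma`` the residual log2 SD (default 0.208),
    ``alpha`` the significance level and ``target_power`` the power to
    reach; ``sides`` selects a one- or two-sided test.
    """

    delta: float = 0.585
    sigma: float = 0.208
    alpha: float = 0.0001
    target_power: float = 0.8
    sides: str = "two"

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ConfigurationError("delta must be nonzero")
        if self.sigma <= 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.target_power < 1:
            raise ConfigurationError(
                f"target_power must be in (0, 1), got {self.target_power}"
            )
        if self.sides not in ("one", "two"):
            raise ConfigurationError(f"sides must be 'one' or 'two', got {self.sides!r}")

    @property
    def effect_size(self) -> float:
        return abs(self.delta) / self.sigma


def power_at_n(n: float, spec: PowerSpec) -> float:
    """Exact power of the two-sample t test at fractional per-group size n."""
    if n <= 1:
        return 0.0
    df = 2.0 * n - 2.0
    nc = spec.effect_size * np.sqrt(n / 2.0)
    if spec.sides == "two":
        tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        upper = stats.nct.sf(tcrit, df, nc)
        lower = stats.nct.cdf(-tcrit, df, nc)
        # scipy's nct can NaN in extreme tails; fall back to the Normal
        # limit for the main tail and to 0 for the vanishing one
        if not np.isfinite(upper):
            upper = float(stats.norm.sf(tcrit - nc)) if np.isfinite(tcrit) else 0.0
        lower = 0.0 if not np.isfinite(lower) else lower
        return float(upper + lower)
    tcrit = stats.t.ppf(1.0 - spec.alpha, df)
    p = stats.nct.sf(tcrit, df, nc)
    if not np.isfinite(p):
        p = float(stats.norm.sf(tcrit - nc)) if np.isfinite(tcrit) else 0.0
    return float(p)


def sample_size(spec: PowerSpec, n_max: float = 1e6) -> float:
    """Fractional per-group n at which the exact power equals the target.

    Solved by bracketing + Brent's method to |power - target| < 1e-8.
    Report ceil(n) for a practical design.
    """
    f = lambda n: power_at_n(n, spec) - spec.target_power
    # below ~1.1 per group the t test has <0.2 df and the power function
    # is not monotone; such designs are not meaningful sample sizes
    lo = 1.1
    if f(lo) >= 0:
        raise ConfigurationError(
            "target power is already reached at n <= 1.1; effect size too "
            "large for a meaningful sample-size calculation"
        )
    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > n_max:
            raise ConfigurationError(
                f"target power {spec.target_power} unattainable below n={n_max:g}"
            )
    n = optimize.brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16)
    assert abs(power_at_n(n, spec) - spec.target_power) < 1e-8
    return float(n)
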