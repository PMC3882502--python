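"""Domain types shared across the package.

The program model: an inexhaustible supply of candidate treatments with
independent standardized effects mu_i ~ N(m0, v0^2) is screened in cycles.
Each cycle runs a (K+1)-arm screening trial (K experimental arms plus a
shared control, n1 patients per arm, responses N(mu_i, 1), control effect
fixed at 0).  A progression rule decides which treatments, if any, move to
a confirmatory (phase III) trial powered for the clinically relevant
standardized difference delta.  Cycles repeat with fresh treatments until
the first confirmatory success; the planning criterion is the expected
total number of patients recruited up to and including that success (ESS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

TOP_TREATMENT = "top-treatment"
ALL_INTERESTING = "all-interesting"


@dataclass(frozen=True)
class PriorSpec:
    """Exchangeable normal prior N(m0, v0^2) on standardized treatment effects.

    Parameters
    ----------
    m0 : prior mean of a treatment's standardized effect.
    v0 : prior standard deviation (>= 0; 0 collapses every effect to m0).
    """

    m0: float
    v0: float

    def __post_init__(self):
        if self.v0 < 0:
            raise ValueError(f"prior standard deviation v0 must be >= 0, got {self.v0}")


@dataclass(frozen=True)
class ScreeningDesign:
    """Decision variables of a screening trial.

    K experimental arms plus one control, n1 patients per arm, and the
    threshold c1 on the screening z-statistics Z_i (treatment i vs the
    shared control, variance standardized).  n1 may be non-integer while
    a design is being optimized; c1 may be negative.
    """

    K: int
    n1: float
    c1: float

    def __post_init__(self):
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.n1 < 1:
            raise ValueError(f"n1 must be >= 1, got {self.n1}")

    @property
    def screening_ss(self) -> float:
        """Patients recruited per screening trial, (K+1) * n1."""
        return (self.K + 1) * self.n1


@dataclass(frozen=True)
class ConfirmatorySpec:
    """Requirements for confirmatory trials.

    delta : standardized clinically relevant difference used for powering.
    alpha : one-sided type-I error rate (family-wise when multi-arm).
    beta  : 1 - power at delta.
    J     : number of analyses (1 = single-stage).
    rule  : progression rule, "top-treatment" or "all-interesting".
    """

    delta: float
    alpha: float = 0.025
    beta: float = 0.1
    J: int = 1
    rule: str = TOP_TREATMENT

    def __post_init__(self):
        if not 0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not 0 < self.beta < 0.5:
            raise ValueError(f"beta must be in (0, 0.5), got {self.beta}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.J < 1:
            raise ValueError(f"J must be >= 1, got {self.J}")
        if self.rule not in (TOP_TREATMENT, ALL_INTERESTING):
            raise ValueError(f"unknown progression rule {self.rule!r}")


@dataclass(frozen=True)
class ConfirmatoryDesign:
    """Derived confirmatory design, per possible number of experimental arms.

    n2_by_arms[i] is the per-arm sample size and c2_by_arms[i] the final
    critical value (z scale) of a confirmatory trial testing i experimental
    arms against one control with family-wise error alpha and marginal
    power 1-beta.  ``boundaries`` holds per-stage group-sequential bounds
    when J > 1 and is empty for single-stage designs.
    """

    n2_by_arms: dict
    c2_by_arms: dict
    boundaries: dict = field(default_factory=dict)
    n2_integer: bool = False

    def __post_init__(self):
        for i, n2 in self.n2_by_arms.items():
            if n2 <= 0:
                raise ValueError(f"n2({i}) must be > 0, got {n2}")
        cs = [self.c2_by_arms[i] for i in sorted(self.c2_by_arms)]
        if any(b <= a for a, b in zip(cs, cs[1:])):
            raise ValueError("c2(i) must be strictly increasing in i")


@dataclass
class ProgramResult:
    """Operating characteristics of one screening-design point.

    ess        : expected patients until the first phase III success.
    p_conduct  : prior-predictive probability a cycle triggers a
                 confirmatory trial (E[P1]).
    p_success  : prior-predictive probability a cycle ends in a phase III
                 success (E[P2]).
    fwer       : screening family-wise error rate (all effects zero).
    power      : screening power (one effect delta, the rest zero).
    diagnostics: integration / Monte-Carlo error estimates.
    """

    ess: float
    p_conduct: float
    p_success: float
    fwer: float | None = None
    power: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.p_success <= self.p_conduct + 1e-12:
            raise ValueError(
                f"need 0 <= p_success <= p_conduct, got "
                f"{self.p_success}, {self.p_conduct}"
            )
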