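"""Stable-isotope and elemental mass-balance computations.

Composted maize (a C4 plant, isotopically heavy) incubated in a C3
forest soil acquires new fungal carbon that is isotopically lighter.
A two-pool delta-13C mixing model therefore quantifies how much of the
carbon remaining in a mesh bag is still maize-derived, the
one-compartment exponential model turns initial/final C contents into a
decay constant, and simple C/N bookkeeping partitions the observed rise
of the C/N ratio into a fungal-biomass contribution, an
inorganic-N-leaching contribution and an unexplained remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import fmean

# Default end-members (per mil vs VPDB): the maize-compost source and
# in-grown mycelial carbon from comparable forest mesh bags.
DELTA13C_C4_DEFAULT = -13.36
DELTA13C_NEW_DEFAULT = -25.82

#: Incubation time: bags placed July 2011, harvested after 17 months.
T_YEARS_DEFAULT = 17.0 / 12.0


@dataclass(frozen=True)
class MixingEndMembers:
    """delta-13C end-members of the two-pool mixing model (per mil)."""

    delta13c_c4: float = DELTA13C_C4_DEFAULT
    delta13c_new: float = DELTA13C_NEW_DEFAULT

    def __post_init__(self) -> None:
        if abs(self.delta13c_c4 - self.delta13c_new) < 1.0:
            raise ValueError(
                "end-members differ by < 1 per mil: mixing fraction ill-conditioned"
            )


@dataclass(frozen=True)
class SampleChemistry:
    """One mesh-bag composite's chemistry with design metadata."""

    C: float            # g kg^-1
    N: float            # g kg^-1
    delta13C: float     # per mil vs VPDB
    pH: float | None = None
    horizon: str = "humus"        # humus | mineral
    treatment: str = "control"    # control | fertilized
    plot: str = ""

    def __post_init__(self) -> None:
        if self.C <= 0 or self.N <= 0:
            raise ValueError("C and N must be positive")

    @property
    def cn(self) -> float:
        return self.C / self.N


@dataclass(frozen=True)
class CNPartition:
    """Decomposition of a C/N-ratio increase into attributed shares (%)."""

    total_increase_pct: float
    fungal_contribution_pct: float
    leaching_contribution_pct: float
    unexplained_pct: float
    convention: str

    def __post_init__(self) -> None:
        total = (self.fungal_contribution_pct + self.leaching_contribution_pct
                 + self.unexplained_pct)
        if abs(total - 100.0) > 1e-6:
            raise ValueError("partition contributions must sum to 100%")


def delta13c_from_ratio(r_sample: float, r_standard: float) -> float:
    """delta-13C (per mil) = (R_sample/R_standard - 1) * 1000."""
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("molar 13C/12C ratios must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def c4_fraction(delta_sample: float,
                em: MixingEndMembers = MixingEndMembers()) -> tuple[float, bool]:
    """Fraction of C4 (maize-derived) carbon from the two-pool mixing model.

    f = (delta_sample - delta_new) / (delta_c4 - delta_new).  Values
    outside [0, 1] are returned unclamped together with ``in_range=False``
    so that end-member misspecification is visible downstream.

    Returns
    -------
    (fraction, in_range)
    """
    f = (delta_sample - em.delta13c_new) / (em.delta13c_c4 - em.delta13c_new)
    return f, 0.0 <= f <= 1.0


def new_carbon(c_total: float, f_c4: float) -> float:
    """New (non-C4) carbon: c_total * (1 - f_c4); same units as c_total."""
    if not 0.0 <= f_c4 <= 1.0:
        raise ValueError("f_c4 must be within [0, 1]")
    return c_total * (1.0 - f_c4)


def decay_constant(c_initial: float, c_final: float, t: float) -> tuple[float, bool]:
    """One-compartment decay constant k (yr^-1) from C_final = C_initial*e^(-kt).

    A negative k (carbon gain) is allowed but flagged.

    Returns
    -------
    (k, is_loss) where ``is_loss`` is False when k < 0.
    """
    if t <= 0:
        raise ValueError("incubation time must be positive")
    if c_initial <= 0 or c_final <= 0:
        raise ValueError("carbon contents must be positive")
    k = math.log(c_initial / c_final) / t
    return k, k >= 0


def cn_increase_percent(cn_initial: float, cn_values: list[float]) -> float:
    """Percent increase of the mean incubated C/N over the initial C/N."""
    if not cn_values:
        raise ValueError("no incubated C/N values supplied")
    if cn_initial <= 0 or any(v <= 0 for v in cn_values):
        raise ValueError("C/N ratios must be positive")
    return 100.0 * (fmean(cn_values) / cn_initial - 1.0)


PARTITION_CONVENTION = (
    "counterfactual-removal: fungal share = (CN_final - CN_without_fungal_pool)"
    " / (CN_final - CN_initial); leaching share = (CN_final - CN_with_N_restored)"
    " / (CN_final - CN_initial); remainder unexplained"
)


def partition_cn_increase(initial: SampleChemistry, final: SampleChemistry,
                          fungal_cn: float, new_c_frac: float,
                          inorganic_n: float) -> CNPartition:
    """Partition the C/N-ratio increase into fungal and leaching shares.

    Convention (recorded in the result): the fungal pool is
    ``new_c_frac`` of the final C at C/N = ``fungal_cn``; removing it
    from both final C and final N gives a counterfactual C/N whose
    shortfall relative to the observed final C/N is the fungal share of
    the total increase.  Adding the initially present inorganic N (taken
    as leached during incubation) back to final N gives the leaching
    counterfactual.  The remainder of the increase is unexplained.
    """
    if fungal_cn <= 0:
        raise ValueError("fungal C/N must be positive")
    if not 0.0 <= new_c_frac <= 1.0:
        raise ValueError("new_c_frac must be within [0, 1]")
    if inorganic_n < 0 or inorganic_n >= initial.N:
        raise ValueError("inorganic N must be non-negative and below initial N")

    cn_initial = initial.cn
    cn_final = final.cn
    delta_total = cn_final - cn_initial
    if delta_total == 0:
        raise ValueError("no C/N change to partition")

    c_fungal = new_c_frac * final.C
    n_fungal = c_fungal / fungal_cn
    c_rem = final.C - c_fungal
    n_rem = final.N - n_fungal
    if c_rem <= 0 or n_rem <= 0:
        raise ValueError("fungal pool exceeds the final C or N pool")
    delta_fungal = cn_final - c_rem / n_rem
    delta_leach = cn_final - final.C / (final.N + inorganic_n)

    fungal_pct = 100.0 * delta_fungal / delta_total
    leach_pct = 100.0 * delta_leach / delta_total
    return CNPartition(
        total_increase_pct=100.0 * delta_total / cn_initial,
        fungal_contribution_pct=fungal_pct,
        leaching_contribution_pct=leach_pct,
        unexplained_pct=100.0 - fungal_pct - leach_pct,
        convention=PARTITION_CONVENTION,
    )
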