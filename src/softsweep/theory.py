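"""Closed-form sweep theory for a multi-site resistance locus.

Quantities describing how a panmictic diploid Wright-Fisher population of
effective size ``N_e`` adapts at a single locus once the environment flips a
formerly deleterious allele (selection coefficient ``s_d < 0``, maintained in
mutation-selection balance) to beneficial (``s > 0``, multiplicative fitness,
heterozygote fitness ``1 + s``):

* the stationary frequency density of the deleterious allele and the
  probability that any copy is present at all (mutation-selection balance);
* the probability of successful adaptation from standing genetic variation;
* establishment and sweep times for de novo adaptive mutations, and the
  overall waiting time until the allele is common;
* the minimal selection strength needed to meet an adaptation deadline;
* for a hard sweep, the chance that mutation or recombination during the
  sweep puts the adaptive allele onto a second, distinguishable haplotype
  that itself reaches a minor frequency ``d``.

Resistance can arise by one of three possible nucleotide changes per site, so
the adaptive mutation rate per site is ``theta_u = theta / 3``.

All waiting times are in generations.  Invalid or out-of-asymptotic-range
inputs produce sentinel values and ``valid`` flags rather than exceptions, so
parameter sweeps never abort mid-grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "PopulationParams",
    "SelectionParams",
    "HardSweepParams",
    "RootResult",
    "theta_from_popsize",
    "popsize_from_theta",
    "msb_density",
    "msb_presence_probability",
    "p_standing_variation",
    "establishment_time",
    "logistic_trajectory",
    "sweep_time",
    "waiting_time",
    "required_selection",
    "locus_event_rate",
    "second_haplotype_window",
    "p_distinct_haplotypes",
]

#: Per-site per-generation point mutation rate for D. melanogaster.
DEFAULT_MU = 2.5e-9
#: Locus length in bp (the sequenced Ace region).
DEFAULT_L = 1500
#: Local recombination rate in cM/Mbp.
DEFAULT_RHO = 0.15
#: cM/Mbp -> crossover probability per bp per generation.
CM_PER_MBP_TO_PER_BP = 1e-8

_INF = math.inf


def theta_from_popsize(n_e: float, mu: float) -> float:
    """Per-site population mutation parameter theta = 4*N_e*mu.

    Parameters
    ----------
    n_e : diploid effective population size.
    mu : per-site per-generation mutation rate.
    """
    if n_e < 0 or mu < 0:
        raise ValueError("N_e and mu must be non-negative")
    return 4.0 * n_e * mu


def popsize_from_theta(theta: float, mu: float) -> float:
    """Diploid N_e implied by a per-site theta: N_e = theta / (4*mu)."""
    if theta < 0 or mu < 0:
        raise ValueError("theta and mu must be non-negative")
    if mu == 0:
        if theta == 0:
            return 0.0
        raise ValueError("theta > 0 with mu = 0 leaves N_e undefined")
    return theta / (4.0 * mu)


@dataclass(frozen=True)
class PopulationParams:
    """Neutral-parameter bundle for one panmictic deme.

    ``theta`` (= 4*N_e*mu per site) and ``theta_u`` (= theta/3, the adaptive
    analogue: one of three possible changes at a resistance site confers
    resistance) are derived on construction.
    """

    n_e: float
    mu: float = DEFAULT_MU
    L: int = DEFAULT_L
    rho_cM_per_Mbp: float = DEFAULT_RHO
    theta: float = field(init=False)
    theta_u: float = field(init=False)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("locus length must be >= 1 bp")
        if self.rho_cM_per_Mbp < 0:
            raise ValueError("recombination rate must be >= 0")
        object.__setattr__(self, "theta", theta_from_popsize(self.n_e, self.mu))
        object.__setattr__(self, "theta_u", self.theta / 3.0)

    @classmethod
    def from_theta(
        cls,
        theta: float,
        mu: float = DEFAULT_MU,
        L: int = DEFAULT_L,
        rho_cM_per_Mbp: float = DEFAULT_RHO,
    ) -> "PopulationParams":
        return cls(popsize_from_theta(theta, mu), mu, L, rho_cM_per_Mbp)

    @property
    def locus_event_rate(self) -> float:
        return locus_event_rate(self.mu, self.rho_cM_per_Mbp, self.L)


@dataclass(frozen=True)
class SelectionParams:
    """Selection regime around the environmental shift.

    ``s_d`` is the (negative) coefficient of a resistant haplotype before
    pesticides; ``s`` the (positive) coefficient afterwards.
    """

    s_d: float
    s: float

    def __post_init__(self) -> None:
        if not (self.s_d < 0 <= self.s):
            raise ValueError("require s_d < 0 <= s")

    def establishment_frequency(self, n_e: float) -> float:
        """x0 ~ 1/(4*N_e*s): above this, loss by drift is unlikely."""
        if 4.0 * n_e * self.s <= 1.0:
            raise ValueError("4*N_e*s <= 1: no deterministic sweep phase")
        return 1.0 / (4.0 * n_e * self.s)


# ---------------------------------------------------------------------------
# Mutation-selection balance (pre-pesticide standing variation)
# ---------------------------------------------------------------------------


def msb_density(
    x: np.ndarray | float, params: PopulationParams, s_d: float
) -> np.ndarray | float:
    """Stationary density g(x) of the resistant-allele frequency.

    Wright's stationary distribution for genic selection with two-way
    mutation (forward rate theta_u; back-mutation rate theta, since every
    one of the three changes away from the resistant nucleotide restores
    sensitivity)::

        g(x) = C * x**(theta_u - 1) * (1 - x)**(theta - 1) * exp(4*N_e*s_d*x)

    normalized to integrate to 1 over (0, 1).  Valid for deleterious balance
    only (``s_d < 0``).
    """
    if s_d >= 0:
        raise ValueError("mutation-selection balance requires s_d < 0")
    tu = params.theta_u
    if tu == 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    norm = _msb_norm(params, s_d)
    xa = np.asarray(x, dtype=float)
    out = _msb_kernel(xa, tu, params.theta, 4.0 * params.n_e * s_d) / norm
    return out if out.ndim else float(out)


def _msb_kernel(x: np.ndarray, tu: float, theta: float, alpha: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logk = (tu - 1.0) * np.log(x) + (theta - 1.0) * np.log1p(-x) + alpha * x
    return np.exp(logk)


def _msb_norm(params: PopulationParams, s_d: float) -> float:
    tu, theta = params.theta_u, params.theta
    alpha = 4.0 * params.n_e * s_d
    # x**(tu-1) is integrable but sharply peaked at 0: integrate on log x.
    val, _ = integrate.quad(
        lambda u: _msb_kernel(np.exp(u), tu, theta, alpha) * np.exp(u),
        -200.0,
        -1e-12,
        epsabs=1e-10,
        limit=400,
    )
    return val


def msb_presence_probability(params: PopulationParams, s_d: float) -> float:
    """P(at least one resistant copy): integral of g over [1/(2N_e), 1].

    Small for theta ~ 0.01 and strong purifying selection — the population
    is usually empty of resistant alleles before pesticides.
    """
    if s_d >= 0:
        raise ValueError("mutation-selection balance requires s_d < 0")
    if params.theta_u == 0:
        return 0.0
    lo = 1.0 / (2.0 * params.n_e)
    tu, theta = params.theta_u, params.theta
    alpha = 4.0 * params.n_e * s_d
    val, _ = integrate.quad(
        lambda u: _msb_kernel(np.exp(u), tu, theta, alpha) * np.exp(u),
        math.log(lo),
        -1e-12,
        epsabs=1e-10,
        limit=400,
    )
    return float(np.clip(val / _msb_norm(params, s_d), 0.0, 1.0))


def p_standing_variation(theta_u: float, s_d: float, s: float) -> float:
    """Probability of successful adaptation from standing genetic variation.

    ``P_sgv = 1 - (1 + s/|s_d|)**(-theta_u)``: with theta ~ 0.01 this stays
    near 1% even for s ~ 100%, so rescue from the standing pool is unlikely
    and adaptation must wait for de novo mutations.
    """
    if theta_u < 0:
        raise ValueError("theta_u must be >= 0")
    if s_d >= 0:
        raise ValueError("require s_d < 0")
    if s <= 0:
        raise ValueError("require s > 0")
    if theta_u == 0:
        return 0.0
    p = 1.0 - (1.0 + s / abs(s_d)) ** (-theta_u)
    return float(np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# De novo adaptation: establishment, sweep, overall waiting time
# ---------------------------------------------------------------------------


def establishment_time(theta_u: float, s: float) -> float:
    """Expected generations until a de novo adaptive mutation establishes.

    New adaptive copies enter at 2*N_e*mu_u = theta_u/2 per generation and
    each escapes initial stochastic loss with probability ~2s, giving
    ``T_e ~ 1 / (theta_u * s)``.  Zero arguments yield +inf (no crash: grid
    sweeps include degenerate corners).
    """
    if theta_u < 0 or s < 0:
        raise ValueError("theta_u and s must be >= 0")
    if theta_u == 0 or s == 0:
        return _INF
    return 1.0 / (theta_u * s)


def logistic_trajectory(x0: float, s: float, t: np.ndarray | float) -> np.ndarray | float:
    """Deterministic post-establishment frequency trajectory.

    ``x(t) = x0 / (x0 + (1 - x0) * exp(-s t))`` — logistic growth from the
    establishment frequency x0 ~ 1/(4*N_e*s).
    """
    if not (0.0 < x0 < 1.0):
        raise ValueError("x0 must lie in (0, 1)")
    if s <= 0:
        raise ValueError("s must be > 0")
    ta = np.asarray(t, dtype=float)
    if np.any(ta < 0):
        raise ValueError("t must be >= 0")
    out = x0 / (x0 + (1.0 - x0) * np.exp(-s * ta))
    return out if out.ndim else float(out)


def sweep_time(n_e: float, s: float) -> float:
    """Generations from establishment to intermediate (~50%) frequency.

    ``T_f ~ ln(4*N_e*s) / s`` — the deterministic logistic rise from
    x0 = 1/(4*N_e*s) to 1/2.
    """
    if s <= 0:
        raise ValueError("s must be > 0")
    if 4.0 * n_e * s <= 1.0:
        raise ValueError("4*N_e*s <= 1: establishment frequency >= 1")
    return math.log(4.0 * n_e * s) / s


def waiting_time(theta: float, n_e: float, s: float) -> float:
    """Overall expected wait for a de novo adaptive allele to become common.

    ``T_w = T_e + T_f = 1/(theta_u * s) + ln(4*N_e*s)/s`` with
    theta_u = theta/3.  Dominated by the establishment term when theta is
    small: rapid adaptation demands strong selection.
    """
    return establishment_time(theta / 3.0, s) + sweep_time(n_e, s)


@dataclass(frozen=True)
class RootResult:
    """Result of a bracketing search, with an explicit no-solution flag."""

    value: float
    valid: bool
    message: str = ""


def required_selection(
    theta: float,
    n_e: float,
    deadline: float,
    s_max: float = 10.0,
    rtol: float = 1e-6,
) -> RootResult:
    """Smallest s with waiting_time(theta, N_e, s) <= deadline.

    Bracketing plus Brent root-finding on ``T_w(s) - deadline``; T_w is
    strictly decreasing in s on the relevant range, so the first crossing is
    the minimum.  Returns an invalid RootResult if even ``s_max`` misses the
    deadline.
    """
    if deadline <= 0:
        raise ValueError("deadline must be > 0")

    def f(s: float) -> float:
        if 4.0 * n_e * s <= 1.0:
            return _INF
        return waiting_time(theta, n_e, s) - deadline

    if f(s_max) > 0:
        return RootResult(_INF, False, f"no s <= {s_max} meets the deadline")
    lo = max(1.0 / (4.0 * n_e) * 1.0001, 1e-12)
    # grow the lower bracket edge until T_w exceeds the deadline
    while f(lo) < 0:
        lo /= 2.0
        if lo < 1e-15:
            return RootResult(lo, True, "deadline met for arbitrarily small s")
    root = optimize.brentq(f, lo, s_max, rtol=rtol)
    return RootResult(float(root), True)


# ---------------------------------------------------------------------------
# Hard sweep: probability of a second distinguishable haplotype
# ---------------------------------------------------------------------------


def locus_event_rate(mu: float, rho_cM_per_Mbp: float, L: float) -> float:
    """Total per-individual per-generation mutation + recombination rate R.

    ``R = L*mu + L*rho*1e-8`` (cM/Mbp converts to per-bp crossover
    probability by the factor 1e-8).  For the 1.5-kb locus with
    mu = 2.5e-9 and rho = 0.15 cM/Mbp this is 6e-6.
    """
    if mu < 0 or rho_cM_per_Mbp < 0 or L < 0:
        raise ValueError("rates and length must be >= 0")
    return L * mu + L * rho_cM_per_Mbp * CM_PER_MBP_TO_PER_BP


@dataclass(frozen=True)
class HardSweepParams:
    """Inputs for the two-haplotype hard-sweep calculation.

    ``R`` is the locus event rate; ``d`` the minor-haplotype population
    frequency that must be reached for the second haplotype to be
    observable.  The closed forms assume ``N_e*s*d >> 1``; ``asymptotics_ok``
    reports whether N_e*s*d >= 10.
    """

    R: float
    d: float
    s: float
    n_e: float

    def __post_init__(self) -> None:
        if not (0.0 < self.d < 1.0):
            raise ValueError("d must lie in (0, 1)")
        if self.R < 0:
            raise ValueError("R must be >= 0")
        if self.s <= 0:
            raise ValueError("s must be > 0")

    @property
    def asymptotics_ok(self) -> bool:
        return self.n_e * self.s * self.d >= 10.0


@dataclass(frozen=True)
class WindowResult:
    """A waiting-time or probability with its asymptotic-validity flag."""

    value: float
    asymptotics_ok: bool


def second_haplotype_window(s: float, d: float, n_e: float) -> WindowResult:
    """Generations T_d within which a second haplotype must establish.

    A variant haplotype establishing later than ``T_d = ln((1-d)/d)/s`` can
    never reach minor frequency d: both haplotypes share fitness, so their
    ratio is frozen at establishment.  Asymptotic in N_e*s*d >> 1
    (``asymptotics_ok`` is N_e*s*d >= 10).
    """
    if not (0.0 < d < 1.0):
        raise ValueError("d must lie in (0, 1)")
    if s <= 0:
        raise ValueError("s must be > 0")
    return WindowResult(math.log((1.0 - d) / d) / s, n_e * s * d >= 10.0)


def p_distinct_haplotypes(R: float, s: float, d: float, n_e: float) -> WindowResult:
    """Probability P_d that a hard sweep shows two distinct haplotypes.

    New variants of the sweeping haplotype establish at rate
    ``lambda(t) = 2*N_e*x1(t) * R * 2s``; integrating over the window
    [0, T_d] with the early-exponential x1(t) = exp(s t)/(4*N_e*s) gives::

        P_d = 1 - exp(-(R/s) * (1 - d)/d)

    independent of theta (and of N_e, under the asymptotics).  Clipped to
    [0, 1]; ``asymptotics_ok`` flags N_e*s*d >= 10.
    """
    if R < 0:
        raise ValueError("R must be >= 0")
    if not (0.0 < d < 1.0):
        raise ValueError("d must lie in (0, 1)")
    if s <= 0:
        raise ValueError("s must be > 0")
    p = 1.0 - math.exp(-(R / s) * (1.0 - d) / d)
    return WindowResult(float(np.clip(p, 0.0, 1.0)), n_e * s * d >= 10.0)
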