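"""Ensemble summary statistics for resistance-adaptation simulations.

Four per-scenario probabilities describe what a replicate ensemble shows:

* ``P_1m`` — a single-mutation resistant configuration (100, 010 or 001)
  was ever present in more than 10% of the population;
* ``P_3m`` — the complex triple-mutant configuration (111) ever reached at
  least 10%;
* ``P_ss`` — a soft-sweep signature: at some generation, two independently
  drawn alleles had more than 10% probability of carrying the same
  single-mutation configuration on *different* haplotype classes;
* ``P_c`` — the empirical conjunction of the 3m and soft-sweep events
  within the same run (never the product of marginals).

The soft-sweep signatures are additionally attributed to their origin:
whether the runner-up haplotype class at the first flagging generation
descends from an independent de novo mutation or from a recombination
event (an approximate, bookkeeping-level attribution).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "detect_resistance",
    "pair_probability",
    "detect_soft_sweep",
    "ProbabilityEstimates",
    "estimate_probabilities",
    "OriginAttribution",
    "attribute_ss_origin",
]

ONE_M_CONFIGS = (0b001, 0b010, 0b100)
THREE_M_CONFIG = 0b111


def detect_resistance(
    config_freq: np.ndarray, threshold: float = 0.10
) -> tuple[bool, bool]:
    """Resistance flags from a (generations, 8) configuration-frequency matrix.

    ``one_m`` is true iff any single-mutation configuration ever exceeds the
    threshold (strictly more than 10%); ``three_m`` iff the 111
    configuration ever reaches at least 10% (non-strict) — the two
    thresholds follow their respective definitions to the letter.
    """
    config_freq = np.asarray(config_freq)
    if config_freq.size == 0:
        return False, False
    one_m = bool((config_freq[:, list(ONE_M_CONFIGS)] > threshold).any())
    three_m = bool((config_freq[:, THREE_M_CONFIG] >= threshold).any())
    return one_m, three_m


def pair_probability(configs: Sequence[int], freqs: Sequence[float]) -> float:
    """P(two independent draws share a 1m config but differ in class).

    Draws are with replacement; for each single-mutation configuration c the
    contribution is ``(sum_h x_h)^2 - sum_h x_h^2`` over classes h of
    configuration c (all ordered distinct-class pairs), summed over the
    three configurations.
    """
    configs = np.asarray(configs)
    freqs = np.asarray(freqs, dtype=float)
    p = 0.0
    for cfg in ONE_M_CONFIGS:
        x = freqs[configs == cfg]
        if x.size >= 2:
            t = x.sum()
            p += t * t - np.dot(x, x)
    return float(p)


def detect_soft_sweep(
    per_generation: Iterable[tuple[Sequence[int], Sequence[float]]]
    | np.ndarray,
    threshold: float = 0.10,
) -> bool:
    """True iff the same-config distinct-class pair probability ever exceeds
    the threshold.

    Accepts either the per-generation series of pair probabilities (1-d
    array) or an iterable of per-generation ``(configs, class_frequencies)``
    pairs.
    """
    if isinstance(per_generation, np.ndarray) and per_generation.ndim == 1:
        return bool((per_generation > threshold).any())
    return any(
        pair_probability(cfgs, freqs) > threshold for cfgs, freqs in per_generation
    )


@dataclass(frozen=True)
class ProbabilityEstimates:
    """Ensemble proportions with binomial standard errors."""

    p_1m: float
    p_3m: float
    p_ss: float
    p_c: float
    se_1m: float
    se_3m: float
    se_ss: float
    se_c: float
    n_replicates: int

    def as_dict(self) -> dict:
        return {
            "P_1m": self.p_1m, "P_3m": self.p_3m,
            "P_ss": self.p_ss, "P_c": self.p_c,
            "SE_1m": self.se_1m, "SE_3m": self.se_3m,
            "SE_ss": self.se_ss, "SE_c": self.se_c,
            "replicates": self.n_replicates,
        }


def _prop(flags: np.ndarray) -> tuple[float, float]:
    n = len(flags)
    p = flags.mean()
    return float(p), float(np.sqrt(p * (1 - p) / n))


def estimate_probabilities(run_summaries: Sequence) -> ProbabilityEstimates:
    """(P_1m, P_3m, P_ss, P_c) with binomial SEs over an ensemble.

    P_c is the conjunction frequency computed within runs.
    """
    if len(run_summaries) == 0:
        raise ValueError("need at least one replicate")
    flags = np.array([r.flags for r in run_summaries], dtype=bool)
    (p1, e1), (p3, e3) = _prop(flags[:, 0]), _prop(flags[:, 1])
    (ps, es), (pc, ec) = _prop(flags[:, 2]), _prop(flags[:, 3])
    return ProbabilityEstimates(p1, p3, ps, pc, e1, e3, es, ec, len(run_summaries))


@dataclass(frozen=True)
class OriginAttribution:
    """Partition of soft-sweep-flagged runs by runner-up haplotype origin."""

    n_ss: int
    mutation_fraction: float
    recombination_fraction: float


def attribute_ss_origin(run_summaries: Sequence) -> OriginAttribution:
    """Partition soft-sweep runs by whether the runner-up class at the first
    flagging generation descends from a recombination event.

    A run counts toward the recombination partition if any event in the
    runner-up class's origin chain is a recombination; otherwise its
    co-segregating haplotype traces to an independent de novo mutation.
    """
    ss_runs = [r for r in run_summaries if r.ss]
    if any(r.ss_second_from_recombination is None for r in ss_runs):
        raise ValueError("origin records missing for a soft-sweep run")
    n = len(ss_runs)
    if n == 0:
        return OriginAttribution(0, 0.0, 0.0)
    rec = sum(bool(r.ss_second_from_recombination) for r in ss_runs)
    return OriginAttribution(n, (n - rec) / n, rec / n)
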