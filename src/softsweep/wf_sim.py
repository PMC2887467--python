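"""Forward Wright-Fisher simulation of haplotype classes at a short locus.

The model follows the adaptive dynamics of a ~1.5-kb locus carrying three
resistance sites.  Resistant haplotypes are tracked as *classes* under an
infinite alleles model scoped to the classes the statistics distinguish:
every event that changes the adaptive configuration creates a new class
with a fresh integer ID, as does every event on a single-mutation (1m)
background — the haplotype diversity of 1m alleles is what defines the
soft-sweep signature.  Configuration-preserving events on other
backgrounds stay in their class: fully sensitive haplotypes form one
canonical class, and 2m/3m classes are distinguished only by independent
origin.  Only the 3-bit adaptive configuration (which resistance sites
carry the resistant nucleotide) is modelled explicitly; population state
per deme is a sparse id -> count table, which keeps runs with deme sizes
up to 1e8-1e9 tractable.

Each generation applies, in order: mutation, recombination, migration, and
multinomial Wright-Fisher resampling with selection.  A run starts from the
sensitive class at 100% in every deme, burns in to mutation-selection
balance (all resistant classes deleterious at -s_1m), then switches to the
post-pesticide selection scheme (s_1m, s_2m, s_3m by number of resistant
alleles) for the adaptive epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .theory import CM_PER_MBP_TO_PER_BP, DEFAULT_L, DEFAULT_MU, DEFAULT_RHO

__all__ = [
    "SelectionScheme",
    "ScenarioConfig",
    "Deme",
    "RunSummary",
    "mutate_step",
    "recombine_step",
    "migrate_step",
    "resample_step",
    "run_scenario",
    "run_ensemble",
    "replicate_rng",
]

N_SITES = 3
SENSITIVE_ID = 0
#: number of resistant alleles per 3-bit configuration 0b000..0b111
CONFIG_WEIGHT = np.array([bin(c).count("1") for c in range(8)], dtype=np.int8)
ONE_M_CONFIGS = (0b001, 0b010, 0b100)
THREE_M_CONFIG = 0b111

FOUNDER, MUTATION, RECOMBINATION = 0, 1, 2
_EVENT_NAMES = {FOUNDER: "founder", MUTATION: "mutation", RECOMBINATION: "recombination"}


@dataclass(frozen=True)
class SelectionScheme:
    """Selection coefficients keyed by number of resistant alleles.

    Post-pesticide, a haplotype with k resistant alleles has fitness
    1 + s_km; pre-pesticide every resistant haplotype is deleterious with
    coefficient -s_1m.
    """

    s_1m: float
    s_2m: float
    s_3m: float

    def coefficients(self, pesticide: bool) -> np.ndarray:
        """Length-8 array of s(config), indexed by the 3-bit configuration."""
        if pesticide:
            by_k = np.array([0.0, self.s_1m, self.s_2m, self.s_3m])
        else:
            by_k = np.array([0.0, -self.s_1m, -self.s_1m, -self.s_1m])
        s = by_k[CONFIG_WEIGHT]
        if np.any(1.0 + s <= 0.0):
            raise ValueError("selection coefficients give non-positive fitness")
        return s


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulation scenario.

    Either ``N`` (diploid size per deme) or ``theta`` (with ``mu``) must be
    given; ``theta = 4*N*mu``.  ``M`` is the expected number of migrating
    individuals per generation for each ordered deme pair.  Adaptive-site
    coordinates default to the relative positions of the three resistance
    codons within the locus.
    """

    N: int | None = None
    theta: float | None = None
    mu: float = DEFAULT_MU
    L: int = DEFAULT_L
    rho_cM_per_Mbp: float = DEFAULT_RHO
    n_subpops: int = 1
    M: float = 0.0
    scheme: SelectionScheme = field(default_factory=lambda: SelectionScheme(0.05, 0.1, 0.2))
    burn_in: int = 1000
    epoch: int = 1500
    site_positions: tuple[int, ...] | None = None
    seed: int = 0
    report_threshold: float = 0.02

    def __post_init__(self) -> None:
        if self.N is None:
            if self.theta is None:
                raise ValueError("give either N or theta")
            self.N = int(round(self.theta / (4.0 * self.mu)))
        self.theta = 4.0 * self.N * self.mu
        if self.site_positions is None:
            # codons 161, 265, 330 at their approximate relative offsets
            self.site_positions = (
                int(0.35 * self.L),
                int(0.60 * self.L),
                int(0.75 * self.L),
            )
        pos = self.site_positions
        if len(pos) != N_SITES or any(not 1 <= p <= self.L for p in pos):
            raise ValueError("need 3 adaptive sites within [1, L]")
        if list(pos) != sorted(pos) or len(set(pos)) != N_SITES:
            raise ValueError("adaptive sites must be strictly increasing")
        if self.burn_in < 0 or self.epoch < 0:
            raise ValueError("burn_in and epoch must be >= 0")
        if self.M < 0:
            raise ValueError("M must be >= 0")

    @property
    def mutation_mean(self) -> float:
        """Poisson mean of mutation events per deme per generation."""
        return self.mu * self.L * 2 * self.N

    @property
    def recombination_mean(self) -> float:
        """Poisson mean of recombination events per deme per generation."""
        return self.rho_cM_per_Mbp * CM_PER_MBP_TO_PER_BP * self.L * 2 * self.N

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "mu": self.mu,
            "L": self.L,
            "rho_cM_per_Mbp": self.rho_cM_per_Mbp,
            "n_subpops": self.n_subpops,
            "M": self.M,
            "scheme": {
                "s_1m": self.scheme.s_1m,
                "s_2m": self.scheme.s_2m,
                "s_3m": self.scheme.s_3m,
            },
            "burn_in": self.burn_in,
            "epoch": self.epoch,
            "site_positions": list(self.site_positions),
            "seed": self.seed,
            "report_threshold": self.report_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "scheme" in d:
            d["scheme"] = SelectionScheme(**d["scheme"])
        if d.get("site_positions") is not None:
            d["site_positions"] = tuple(d["site_positions"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


class _OriginLog:
    """Append-only genealogy of haplotype classes.

    IDs are issued in blocks (vectorized); per-id records are materialized
    on demand for chain walks.  ID 0 is the canonical sensitive class.
    """

    def __init__(self) -> None:
        self.n = 1
        self._chunks: list[tuple[int, np.ndarray, np.ndarray, int, int]] = []
        self._arrays: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None

    def ensure_above(self, max_existing_id: int) -> None:
        """IDs are never reused: skip past externally constructed classes."""
        self.n = max(self.n, int(max_existing_id) + 1)

    def new_ids(
        self,
        parents: np.ndarray,
        event: int,
        generation: int,
        parents_b: np.ndarray | None = None,
    ) -> np.ndarray:
        k = len(parents)
        if k == 0:
            return np.empty(0, dtype=np.int64)
        if parents_b is None:
            parents_b = np.full(k, -1, dtype=np.int64)
        self._chunks.append(
            (self.n, np.asarray(parents, dtype=np.int64),
             np.asarray(parents_b, dtype=np.int64), event, generation)
        )
        ids = np.arange(self.n, self.n + k, dtype=np.int64)
        self.n += k
        self._arrays = None
        return ids

    def _materialize(self):
        if self._arrays is None:
            parent = np.full(self.n, -1, dtype=np.int64)
            parent_b = np.full(self.n, -1, dtype=np.int64)
            event = np.full(self.n, FOUNDER, dtype=np.int8)
            gen = np.zeros(self.n, dtype=np.int64)
            for start, pa, pb, ev, g in self._chunks:
                sl = slice(start, start + len(pa))
                parent[sl] = pa
                parent_b[sl] = pb
                event[sl] = ev
                gen[sl] = g
            self._arrays = (parent, parent_b, event, gen)
        return self._arrays

    def chain_has_recombination(self, class_id: int) -> bool:
        """Walk the primary-parent chain back to the sensitive founder."""
        parent, _, event, _ = self._materialize()
        i = class_id
        while i > 0:
            if event[i] == RECOMBINATION:
                return True
            i = parent[i]
        return False

    def record(self, class_id: int) -> dict:
        parent, parent_b, event, gen = self._materialize()
        return {
            "id": int(class_id),
            "parent": int(parent[class_id]),
            "parent_b": int(parent_b[class_id]),
            "event": _EVENT_NAMES[int(event[class_id])],
            "generation": int(gen[class_id]),
        }


class Deme:
    """Sparse haplotype-class state of one panmictic subpopulation."""

    __slots__ = ("ids", "configs", "counts", "N")

    def __init__(self, ids: np.ndarray, configs: np.ndarray, counts: np.ndarray, N: int):
        self.ids = ids
        self.configs = configs
        self.counts = counts
        self.N = N

    @classmethod
    def founder(cls, N: int) -> "Deme":
        return cls(
            np.array([SENSITIVE_ID], dtype=np.int64),
            np.array([0], dtype=np.int8),
            np.array([2 * N], dtype=np.int64),
            N,
        )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def prune(self) -> None:
        keep = self.counts > 0
        if not keep.all():
            self.ids = self.ids[keep]
            self.configs = self.configs[keep]
            self.counts = self.counts[keep]

    def append_singletons(self, ids: np.ndarray, configs: np.ndarray) -> None:
        if len(ids) == 0:
            return
        self.ids = np.concatenate([self.ids, ids])
        self.configs = np.concatenate([self.configs, configs.astype(np.int8)])
        self.counts = np.concatenate(
            [self.counts, np.ones(len(ids), dtype=np.int64)]
        )

    def add_sensitive(self, k: int) -> None:
        """Merge k copies into the canonical sensitive class (id 0)."""
        if k == 0:
            return
        idx = np.flatnonzero(self.ids == SENSITIVE_ID)
        if idx.size:
            self.counts[idx[0]] += k
        else:
            self.ids = np.concatenate(
                [self.ids, np.array([SENSITIVE_ID], dtype=np.int64)]
            )
            self.configs = np.concatenate([self.configs, np.zeros(1, dtype=np.int8)])
            self.counts = np.concatenate(
                [self.counts, np.array([k], dtype=np.int64)]
            )


def _weighted_copy_draw(counts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of k copies drawn without replacement, class-count weighted."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    hits = rng.multivariate_hypergeometric(counts, k, method="marginals")
    return np.repeat(np.arange(len(counts)), hits)


def mutate_step(
    deme: Deme, config: ScenarioConfig, rng: np.random.Generator,
    origins: _OriginLog | None = None, generation: int = 0,
) -> None:
    """Apply one generation of mutation.

    Event count ~ Poisson(mu*L*2N); each event picks a uniform copy and a
    uniform position.  A hit on a sensitive adaptive site becomes resistant
    with probability 1/3 (one of three nucleotide changes); a hit on a
    resistant adaptive site always reverts it.  Configuration-changing
    products, and any product of an event on a 1m background, form a new
    class of count 1; configuration-preserving products elsewhere stay in
    their source class (their identity is never measured).
    """
    total = deme.total
    if total == 0:
        return
    k = rng.poisson(config.mutation_mean)
    if k == 0:
        return
    k = min(k, total)
    if origins is None:
        origins = _OriginLog()
    origins.ensure_above(int(deme.ids.max()))
    src = _weighted_copy_draw(deme.counts, k, rng)
    positions = rng.integers(1, config.L + 1, size=k)
    src_cfg = deme.configs[src].astype(np.int64)
    new_cfg = src_cfg.copy()
    for i, p in enumerate(config.site_positions):
        at_site = positions == p
        if not at_site.any():
            continue
        bit = (src_cfg >> i) & 1
        # resistant -> sensitive always; sensitive -> resistant w.p. 1/3
        gain = at_site & (bit == 0) & (rng.random(k) < 1.0 / 3.0)
        lose = at_site & (bit == 1)
        new_cfg[gain] |= 1 << i
        new_cfg[lose] &= ~(1 << i)
    # fresh classes for configuration changes and for events on 1m
    # backgrounds (whose haplotype diversity defines the soft-sweep
    # signature); config-preserving events elsewhere stay in their class
    tracked = (new_cfg != src_cfg) | (CONFIG_WEIGHT[src_cfg] == 1)
    if not tracked.any():
        return
    src, new_cfg = src[tracked], new_cfg[tracked]
    np.subtract.at(deme.counts, src, 1)
    resistant = new_cfg != 0
    deme.add_sensitive(int((~resistant).sum()))
    ids = origins.new_ids(deme.ids[src[resistant]], MUTATION, generation)
    deme.append_singletons(ids, new_cfg[resistant])
    deme.prune()


def recombine_step(
    deme: Deme, config: ScenarioConfig, rng: np.random.Generator,
    origins: _OriginLog | None = None, generation: int = 0,
) -> None:
    """Apply one generation of recombination.

    Event count ~ Poisson(rho*1e-8*L*2N); each event draws two copies and a
    uniform breakpoint in [1, L-1].  The single recombinant product carries
    adaptive bits from parent A at sites <= breakpoint and from parent B
    above it, and replaces one parent-A copy.  Products whose configuration
    differs from parent A's, or whose parent A is a 1m haplotype, are new
    classes; other products merge back into the parent-A class.
    """
    total = deme.total
    if total < 2:
        return
    k = rng.poisson(config.recombination_mean)
    if k == 0:
        return
    k = min(k, total // 2)
    if origins is None:
        origins = _OriginLog()
    origins.ensure_above(int(deme.ids.max()))
    pa = _weighted_copy_draw(deme.counts, k, rng)
    pb = _weighted_copy_draw(deme.counts, k, rng)
    breakpoints = rng.integers(1, config.L, size=k)
    cfg_a = deme.configs[pa].astype(np.int64)
    cfg_b = deme.configs[pb].astype(np.int64)
    site_pos = np.asarray(config.site_positions)
    # bit mask of sites inherited from parent A (position <= breakpoint)
    from_a = (site_pos[None, :] <= breakpoints[:, None]).astype(np.int64)
    mask_a = (from_a * (1 << np.arange(N_SITES))[None, :]).sum(axis=1)
    new_cfg = (cfg_a & mask_a) | (cfg_b & ~mask_a)
    tracked = (new_cfg != cfg_a) | (CONFIG_WEIGHT[cfg_a] == 1)
    if not tracked.any():
        return
    pa, pb, new_cfg = pa[tracked], pb[tracked], new_cfg[tracked]
    np.subtract.at(deme.counts, pa, 1)
    resistant = new_cfg != 0
    deme.add_sensitive(int((~resistant).sum()))
    ids = origins.new_ids(
        deme.ids[pa[resistant]], RECOMBINATION, generation,
        parents_b=deme.ids[pb[resistant]],
    )
    deme.append_singletons(ids, new_cfg[resistant])
    deme.prune()


def migrate_step(
    demes: list[Deme], config: ScenarioConfig, rng: np.random.Generator
) -> None:
    """Copy migrant haplotypes between every ordered deme pair.

    Migrant individuals per pair ~ Poisson(M); each contributes two
    count-weighted haplotype copies from the source, added to the
    destination (sources unchanged; deme sizes are restored by the next
    resampling step).  Class identity is preserved across demes.
    """
    if len(demes) < 2 or config.M == 0:
        return
    # snapshot source states so simultaneous migration is order-independent
    snapshots = [(d.ids.copy(), d.configs.copy(), d.counts.copy()) for d in demes]
    for j, dest in enumerate(demes):
        add: dict[int, tuple[int, int]] = {}
        for i, (ids, cfgs, counts) in enumerate(snapshots):
            if i == j:
                continue
            migrants = rng.poisson(config.M)
            ncopies = min(2 * migrants, int(counts.sum()))
            if ncopies == 0:
                continue
            picked = _weighted_copy_draw(counts, ncopies, rng)
            for idx in picked:
                cid = int(ids[idx])
                cnt, cfg = add.get(cid, (0, int(cfgs[idx])))
                add[cid] = (cnt + 1, cfg)
        if not add:
            continue
        pos = {int(cid): p for p, cid in enumerate(dest.ids)}
        new_ids, new_cfgs, new_counts = [], [], []
        for cid, (cnt, cfg) in add.items():
            if cid in pos:
                dest.counts[pos[cid]] += cnt
            else:
                new_ids.append(cid)
                new_cfgs.append(cfg)
                new_counts.append(cnt)
        if new_ids:
            dest.ids = np.concatenate([dest.ids, np.asarray(new_ids, dtype=np.int64)])
            dest.configs = np.concatenate(
                [dest.configs, np.asarray(new_cfgs, dtype=np.int8)]
            )
            dest.counts = np.concatenate(
                [dest.counts, np.asarray(new_counts, dtype=np.int64)]
            )


def resample_step(
    deme: Deme, coeffs: np.ndarray, rng: np.random.Generator
) -> None:
    """Multinomial Wright-Fisher resampling with selection.

    Sampling probabilities p_h = x_h (1 + s_h) / w_bar with
    w_bar = sum x_h (1 + s_h); the next generation is multinomial(2N, p).
    Restores the deme to exactly 2N copies and prunes extinct classes.
    """
    total = deme.total
    if total == 0:
        raise ValueError("cannot resample an empty deme")
    fitness = 1.0 + coeffs[deme.configs]
    weights = deme.counts * fitness
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("mean fitness <= 0: selection scheme too severe")
    deme.counts = rng.multinomial(2 * deme.N, weights / wsum).astype(np.int64)
    deme.prune()


@dataclass
class RunSummary:
    """Per-replicate record of one scenario run.

    Time series cover the post-pesticide epoch (generation 0 = first
    generation after the switch).  ``generations_run`` may be shorter than
    the configured epoch when all detection flags were already set (they
    are monotone, so continuing cannot change them).
    """

    config: ScenarioConfig
    config_freq: np.ndarray  # (generations_run, 8) global config frequencies
    ss_pair_prob: np.ndarray  # (generations_run,)
    one_m: bool
    three_m: bool
    ss: bool
    c: bool
    ss_first_gen: int  # -1 if never flagged
    ss_second_class: dict | None  # origin record of the runner-up class
    ss_second_from_recombination: bool | None
    class_trajectories: dict[int, list[tuple[int, float]]]
    burnin_occupancy: float  # fraction of burn-in generations with >=1 resistant copy
    burnin_resistant_freq: float  # mean per-site resistant-allele freq, late burn-in
    n_classes_created: int
    generations_run: int

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.one_m, self.three_m, self.ss, self.c)


def replicate_rng(base_seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate generator: SeedSequence(base, spawn_key=(r,))."""
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(replicate,)))


def _pair_probability(configs: np.ndarray, freqs: np.ndarray) -> float:
    """P(two independent draws share a 1m config but are distinct classes)."""
    p = 0.0
    for cfg in ONE_M_CONFIGS:
        x = freqs[configs == cfg]
        if x.size >= 2:
            t = x.sum()
            p += t * t - np.dot(x, x)
    return float(p)


def run_scenario(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    ss_threshold: float = 0.10,
    detect_threshold: float = 0.10,
    early_stop: bool = True,
) -> RunSummary:
    """Run one replicate: burn-in, selection switch, adaptive epoch.

    Returns a :class:`RunSummary` holding global configuration-frequency
    trajectories, the per-generation soft-sweep pair probability, detection
    flags, and the origin attribution of the runner-up haplotype at the
    first soft-sweep generation.  With ``early_stop`` the epoch ends as
    soon as all three (monotone) detection flags are set.
    """
    from . import summaries  # deferred: summaries is the flag authority

    if rng is None:
        rng = replicate_rng(config.seed, 0)
    origins = _OriginLog()
    demes = [Deme.founder(config.N) for _ in range(config.n_subpops)]
    pre = config.scheme.coefficients(pesticide=False)
    post = config.scheme.coefficients(pesticide=True)
    total_copies = 2 * config.N * config.n_subpops

    occupied = 0
    late_freqs: list[float] = []
    late_window = max(1, config.burn_in // 5)

    for gen in range(config.burn_in):
        _one_generation(demes, config, rng, origins, gen, pre)
        res = _resistant_site_frequency(demes, total_copies)
        if res > 0:
            occupied += 1
        if gen >= config.burn_in - late_window:
            late_freqs.append(res)

    epoch = config.epoch
    config_freq = np.zeros((epoch, 8))
    ss_series = np.zeros(epoch)
    ss_first = -1
    ss_second: dict | None = None
    ss_recomb: bool | None = None
    trajectories: dict[int, list[tuple[int, float]]] = {}
    one_m = three_m = False
    gens_run = 0

    for gen in range(epoch):
        _one_generation(demes, config, rng, origins, config.burn_in + gen, post)
        gens_run = gen + 1
        ids, configs, freqs = _global_state(demes, total_copies)
        np.add.at(config_freq[gen], configs, freqs)
        ss_series[gen] = _pair_probability(configs, freqs)
        if not one_m or not three_m:
            g1, g3 = summaries.detect_resistance(
                config_freq[gen : gen + 1], threshold=detect_threshold
            )
            one_m, three_m = one_m or g1, three_m or g3
        if ss_first < 0 and ss_series[gen] > ss_threshold:
            ss_first = gen
            second = _runner_up_class(ids, configs, freqs)
            if second is not None:
                ss_second = origins.record(second)
                ss_recomb = origins.chain_has_recombination(second)
        big = freqs >= config.report_threshold
        for cid, f in zip(ids[big], freqs[big]):
            trajectories.setdefault(int(cid), []).append((gen, float(f)))
        if early_stop and one_m and three_m and ss_first >= 0:
            break

    ss = ss_first >= 0
    return RunSummary(
        config=config,
        config_freq=config_freq[:gens_run],
        ss_pair_prob=ss_series[:gens_run],
        one_m=one_m,
        three_m=three_m,
        ss=ss,
        c=three_m and ss,
        ss_first_gen=ss_first,
        ss_second_class=ss_second,
        ss_second_from_recombination=ss_recomb,
        class_trajectories=trajectories,
        burnin_occupancy=occupied / config.burn_in if config.burn_in else 0.0,
        burnin_resistant_freq=float(np.mean(late_freqs)) if late_freqs else 0.0,
        n_classes_created=origins.n,
        generations_run=gens_run,
    )


def run_ensemble(
    config: ScenarioConfig, replicates: int, progress: bool = False, **kw
) -> list[RunSummary]:
    """Independent replicates with per-replicate derived seeds."""
    out = []
    for r in range(replicates):
        out.append(run_scenario(config, replicate_rng(config.seed, r), **kw))
        if progress and (r + 1) % 20 == 0:
            print(f"  replicate {r + 1}/{replicates}", flush=True)
    return out


# -- internals --------------------------------------------------------------


def _one_generation(
    demes: list[Deme],
    config: ScenarioConfig,
    rng: np.random.Generator,
    origins: _OriginLog,
    generation: int,
    coeffs: np.ndarray,
) -> None:
    for deme in demes:
        mutate_step(deme, config, rng, origins, generation)
        recombine_step(deme, config, rng, origins, generation)
    migrate_step(demes, config, rng)
    for deme in demes:
        resample_step(deme, coeffs, rng)


def _resistant_site_frequency(demes: list[Deme], total_copies: int) -> float:
    """Mean per-site resistant-allele frequency across the whole population."""
    alleles = 0
    for d in demes:
        alleles += int((d.counts * CONFIG_WEIGHT[d.configs]).sum())
    return alleles / (N_SITES * total_copies)


def _global_state(demes: list[Deme], total_copies: int):
    """Pooled (ids, configs, frequencies) across demes, classes merged by id."""
    if len(demes) == 1:
        d = demes[0]
        return d.ids, d.configs, d.counts / total_copies
    ids = np.concatenate([d.ids for d in demes])
    configs = np.concatenate([d.configs for d in demes])
    counts = np.concatenate([d.counts for d in demes])
    uids, inv = np.unique(ids, return_inverse=True)
    ucounts = np.zeros(len(uids), dtype=np.int64)
    np.add.at(ucounts, inv, counts)
    ucfg = np.zeros(len(uids), dtype=np.int8)
    ucfg[inv] = configs
    return uids, ucfg, ucounts / total_copies


def _runner_up_class(ids, configs, freqs):
    """Second-most-frequent class of the config driving the pair probability."""
    best_cfg, best_p = None, 0.0
    for cfg in ONE_M_CONFIGS:
        x = freqs[configs == cfg]
        if x.size >= 2:
            t = x.sum()
            p = t * t - np.dot(x, x)
            if p > best_p:
                best_p, best_cfg = p, cfg
    if best_cfg is None:
        return None
    mask = configs == best_cfg
    order = np.argsort(freqs[mask])[::-1]
    return int(ids[mask][order[1]])
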