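"""Synthetic inputs: neutral alignments, resistance panels, scenario suites.

Everything the other modules consume can be generated here, seeded and
reproducible:

* neutral haplotype alignments at a target per-site diversity (sequences
  are dropped onto a coalescent genealogy, emulating a Sanger panel from a
  natural population);
* panels of sensitive/resistant haplotypes in which chosen resistance
  configurations are planted on a chosen number of distinct neutral
  backgrounds — the knob that creates (or withholds) a soft-sweep-like
  structure of one adaptive mutation on several haplotypes;
* scenario-configuration files spanning the selection/recombination/
  demography grid for the forward simulator.

The ancestral sequence is uniform-random over nucleotides; each resistance
site is held at a fixed sensitive state ('A') with 'G' as its resistant
state, so that genotyping is unambiguous by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import neutral_coalescent as nc
from .seq_stats import HaplotypePanel, ResistanceSite, DEFAULT_SITE_NAMES
from .theory import DEFAULT_L, DEFAULT_MU
from .wf_sim import ScenarioConfig, SelectionScheme

__all__ = [
    "PanelSpec",
    "default_sites",
    "gen_neutral_panel",
    "gen_resistance_panel",
    "gen_scenario_suite",
    "write_fasta",
]

SENSITIVE_STATE = b"A"
RESISTANT_STATE = "G"
_NUCS = np.frombuffer(b"ACGT", dtype="S1")


def default_sites(L: int = DEFAULT_L) -> tuple[ResistanceSite, ...]:
    """Four resistance sites at the relative codon offsets of the real locus."""
    rel = (0.35, 0.60, 0.75, 0.90)
    return tuple(
        ResistanceSite(name, max(1, int(r * L)), RESISTANT_STATE)
        for name, r in zip(DEFAULT_SITE_NAMES, rel)
    )


@dataclass
class PanelSpec:
    """Specification of a synthetic haplotype panel.

    ``assignments`` maps each strain to a 4-bit resistance configuration and
    a background index; strains sharing a background are identical outside
    the resistance sites.  ``n_backgrounds`` is the number of distinct
    backgrounds (coalescent draws) available.
    """

    n: int
    L: int = DEFAULT_L
    theta: float = 0.008
    sites: tuple[ResistanceSite, ...] = ()
    assignments: list[tuple[tuple[int, int, int, int], int]] = field(default_factory=list)
    n_backgrounds: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            self.sites = default_sites(self.L)
        if not self.assignments:
            self.assignments = [((0, 0, 0, 0), i) for i in range(self.n)]
            self.n_backgrounds = self.n
        if len(self.assignments) != self.n:
            raise ValueError("need one assignment per strain")
        if self.n_backgrounds < 1:
            raise ValueError("need at least one background")
        if self.n_backgrounds > self.n:
            raise ValueError("more backgrounds than strains")
        if any(b >= self.n_backgrounds for _, b in self.assignments):
            raise ValueError("background index out of range")

    @classmethod
    def resistant_panel(
        cls,
        n: int,
        n_resistant: int,
        config: tuple[int, int, int, int] = (1, 0, 0, 0),
        n_resistant_backgrounds: int = 1,
        L: int = DEFAULT_L,
        theta: float = 0.008,
        seed: int = 0,
    ) -> "PanelSpec":
        """Panel where `n_resistant` strains share `config`, spread over
        `n_resistant_backgrounds` distinct backgrounds; sensitive strains
        each get their own background."""
        if n_resistant > n:
            raise ValueError("more resistant strains than strains")
        if n_resistant == 0:
            n_resistant_backgrounds = 0
        n_sens = n - n_resistant
        assignments: list[tuple[tuple[int, int, int, int], int]] = []
        for i in range(n_sens):
            assignments.append(((0, 0, 0, 0), i))
        for i in range(n_resistant):
            assignments.append((config, n_sens + i % n_resistant_backgrounds))
        return cls(
            n=n,
            L=L,
            theta=theta,
            assignments=assignments,
            n_backgrounds=n_sens + n_resistant_backgrounds,
            seed=seed,
        )


def _background_sequences(
    n_bg: int, L: int, theta: float, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_bg, L) sequences from one coalescent genealogy at per-site theta."""
    ancestral = _NUCS[rng.integers(0, 4, size=L)]
    seqs = np.tile(ancestral, (n_bg, 1))
    if n_bg >= 2 and theta > 0:
        model = nc.DemographicModel(
            sizes=(theta / (4.0 * mu),), sample_size=n_bg, mu=mu, L=L
        )
        g = nc.simulate_genealogy(model, rng)
        for mask, m in zip(g.branch_leafsets, g.branch_mutations):
            for _ in range(int(m)):
                pos = rng.integers(0, L)
                current = seqs[np.flatnonzero(mask)[0], pos]
                choices = _NUCS[_NUCS != current]
                seqs[mask, pos] = choices[rng.integers(0, 3)]
    return seqs


def gen_neutral_panel(
    n: int,
    L: int = DEFAULT_L,
    theta: float = 0.008,
    seed: int = 0,
    mu: float = DEFAULT_MU,
) -> HaplotypePanel:
    """Aligned neutral FASTA-ready panel at a target per-site theta.

    Sequences descend from a uniform-random ancestral sequence along one
    coalescent genealogy; expected pairwise diversity per site equals theta
    and expected segregating sites theta*L*a_{n-1}.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    seqs = _background_sequences(n, L, theta, mu, rng)
    labels = [f"strain_{i:03d}" for i in range(n)]
    return HaplotypePanel(labels, seqs, default_sites(L))


def gen_resistance_panel(spec: PanelSpec) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Panel with planted resistance configurations, plus its truth table.

    Backgrounds are neutral coalescent draws with every resistance site
    forced to the sensitive state; each strain then receives the resistant
    state at exactly the sites its configuration requests.  The truth table
    (strain, configuration, background) round-trips through genotyping.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,)))
    bg = _background_sequences(spec.n_backgrounds, spec.L, spec.theta, DEFAULT_MU, rng)
    for site in spec.sites:
        bg[:, site.position - 1] = SENSITIVE_STATE
    labels, rows, seqs = [], [], []
    for i, (config, bg_id) in enumerate(spec.assignments):
        seq = bg[bg_id].copy()
        for bit, site in zip(config, spec.sites):
            if bit:
                seq[site.position - 1] = site.resistant_state.encode()
        label = f"strain_{i:03d}"
        labels.append(label)
        seqs.append(seq)
        rows.append(
            {"strain": label, "configuration": "".join(map(str, config)), "background": bg_id}
        )
    panel = HaplotypePanel(labels, np.array(seqs), spec.sites)
    return panel, pd.DataFrame(rows)


def write_fasta(panel: HaplotypePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, row in zip(panel.labels, panel.sequences):
            fh.write(f">{label}\n{row.tobytes().decode()}\n")


def gen_scenario_suite(
    out_dir: str | Path,
    full: bool = False,
    seed: int = 0,
) -> list[Path]:
    """Write the scenario grid as YAML files consumable by the simulator.

    The default (desk-scale) grid keeps the key contrast — theta in
    {0.01, 0.1, 1} under the reference selection scheme (0.05, 0.1, 0.2),
    recombination on/off, and one structured-population case — at the true
    theta<->N mapping (mu = 2.5e-9); desk scale here means a >=200-replicate
    ensemble per scenario rather than 1e5.  With ``full=True`` the complete
    published grid is emitted instead (s = 2.5%..500%, rho = 0..10 cM/Mbp,
    1..100 subpopulations, M = 0.01..10).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = {"s_1m": 0.05, "s_2m": 0.1, "s_3m": 0.2}
    written: list[Path] = []

    if full:
        thetas = [0.01, 0.1, 1.0]
        schemes = [
            {"s_1m": s1, "s_2m": 2 * s1, "s_3m": 4 * s1}
            for s1 in (0.025, 0.05, 0.125, 0.25, 0.5, 1.25)
        ]
        rhos = [0.0, 0.15, 1.0, 10.0]
        demes = [(1, 0.0), (10, 0.01), (10, 1.0), (100, 0.01), (100, 10.0)]
        mu = DEFAULT_MU
        grid = itertools.product(thetas, schemes, rhos, demes)
    else:
        mu = DEFAULT_MU
        grid = [
            (th, scheme, rho, dm)
            for th in (0.01, 0.1, 1.0)
            for rho in (0.0, 0.15)
            for dm in [(1, 0.0)]
        ] + [(1.0, scheme, 0.15, (5, 1.0))]

    for i, (theta, sch, rho, (n_sub, M)) in enumerate(grid):
        cfg = ScenarioConfig(
            theta=theta,
            mu=mu,
            rho_cM_per_Mbp=rho,
            n_subpops=n_sub,
            M=M,
            scheme=SelectionScheme(**sch),
            seed=seed + i,
        )
        name = (
            f"scenario_theta{theta}_s{sch['s_1m']}_rho{rho}"
            f"_demes{n_sub}_M{M}.yaml"
        )
        path = out / name
        cfg.to_file(path)
        written.append(path)
    return written
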