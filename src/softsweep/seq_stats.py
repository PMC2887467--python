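"""Diversity estimators and resistance genotyping for haplotype alignments.

Operates on aligned panels of ~1.5-kb haplotype sequences (the sequenced
resistance-locus region).  Provides:

* per-strain resistance genotyping against a user-supplied table of
  resistance sites (1-based coordinate + resistant nucleotide), yielding a
  4-bit configuration per strain (sites I161V, G265A, F330Y, G368A);
* nucleotide diversity theta_pi (mean pairwise differences per site) and
  Watterson's theta_w (S / (a_{n-1} L));
* a segregating-site table (position, consensus state, per-strain alleles).

Columns containing gaps or IUPAC ambiguity codes are excluded listwise by
default (the behaviour of standard polymorphism software); a
pairwise-deletion mode is available for theta_pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ResistanceSite",
    "HaplotypePanel",
    "GenotypeResult",
    "DiversityResult",
    "genotype_resistance",
    "diversity",
    "DEFAULT_SITE_NAMES",
]

DEFAULT_SITE_NAMES = ("I161V", "G265A", "F330Y", "G368A")
_VALID_ARR = np.frombuffer(b"ACGT", dtype="S1")
_VALID = frozenset(_VALID_ARR.tolist())


@dataclass(frozen=True)
class ResistanceSite:
    """One resistance site: 1-based position and its resistant nucleotide."""

    name: str
    position: int
    resistant_state: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based")
        if self.resistant_state.upper() not in "ACGT":
            raise ValueError("resistant state must be a single unambiguous base")


@dataclass
class HaplotypePanel:
    """An aligned panel of equal-length haplotype sequences.

    ``populations`` optionally tags each strain with its source population.
    ``reference`` names the strain whose sequence is used as the consensus
    row of the segregating-site table; by default the first sequence.
    """

    labels: list[str]
    sequences: np.ndarray  # (n, L) bytes ('S1')
    sites: tuple[ResistanceSite, ...] = ()
    populations: dict[str, str] = field(default_factory=dict)
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.sequences.ndim != 2:
            raise ValueError("sequences must be a (n, L) array")
        if len(self.labels) != self.sequences.shape[0]:
            raise ValueError("one label per sequence")
        for s in self.sites:
            if s.position > self.L:
                raise ValueError(f"site {s.name} beyond alignment length")

    @property
    def n(self) -> int:
        return self.sequences.shape[0]

    @property
    def L(self) -> int:
        return self.sequences.shape[1]

    @classmethod
    def from_sequences(
        cls,
        records: Sequence[tuple[str, str]],
        sites: Sequence[ResistanceSite] = (),
        **kw,
    ) -> "HaplotypePanel":
        labels = [r[0] for r in records]
        lens = {len(r[1]) for r in records}
        if len(lens) != 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        arr = np.array(
            [list(r[1].upper().encode()) for r in records], dtype=np.uint8
        ).view("S1")
        return cls(labels, arr, tuple(sites), **kw)

    @classmethod
    def from_fasta(
        cls, path: str | Path, sites: Sequence[ResistanceSite] = (), **kw
    ) -> "HaplotypePanel":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(records, sites, **kw)

    def subset(self, labels: Sequence[str]) -> "HaplotypePanel":
        idx = [self.labels.index(l) for l in labels]
        return HaplotypePanel(
            [self.labels[i] for i in idx],
            self.sequences[idx],
            self.sites,
            self.populations,
            self.reference,
        )

    def reference_index(self) -> int:
        return self.labels.index(self.reference) if self.reference else 0


@dataclass(frozen=True)
class GenotypeResult:
    """Per-strain resistance configurations and the panel-level fraction."""

    configurations: dict[str, tuple[int, ...]]  # strain -> bit per site
    flagged: tuple[str, ...]  # strains with ambiguous bases at a site
    resistant_fraction: float  # of unflagged strains, >=1 resistant site

    def n_resistant_sites(self, strain: str) -> int:
        return sum(self.configurations[strain])


def genotype_resistance(panel: HaplotypePanel) -> GenotypeResult:
    """Call each strain's resistance configuration at the panel's sites.

    A strain with a gap or ambiguity code at any resistance site is flagged
    and excluded from the resistant-fraction denominator.
    """
    if not panel.sites:
        raise ValueError("panel defines no resistance sites")
    configs: dict[str, tuple[int, ...]] = {}
    flagged: list[str] = []
    n_resistant = 0
    n_ok = 0
    for i, label in enumerate(panel.labels):
        bits = []
        ok = True
        for site in panel.sites:
            base = panel.sequences[i, site.position - 1]
            if base not in _VALID:
                ok = False
                bits.append(0)
            else:
                bits.append(int(base == site.resistant_state.upper().encode()))
        configs[label] = tuple(bits)
        if ok:
            n_ok += 1
            n_resistant += any(bits)
        else:
            flagged.append(label)
    frac = n_resistant / n_ok if n_ok else 0.0
    return GenotypeResult(configs, tuple(flagged), frac)


@dataclass(frozen=True)
class DiversityResult:
    theta_pi: float
    theta_w: float
    segregating_sites: int
    table: pd.DataFrame
    excluded_columns: int
    n: int
    L: int


def diversity(
    panel: HaplotypePanel,
    subset: Sequence[str] | None = None,
    pairwise_deletion: bool = False,
) -> DiversityResult:
    """theta_pi, Watterson's theta_w and the segregating-site table.

    theta_pi is the mean number of pairwise differences divided by L;
    theta_w = S / (a_{n-1} * L) with a_{n-1} = sum_{i<n} 1/i.  Columns with
    any gap/ambiguity are dropped listwise (the count is reported); with
    ``pairwise_deletion`` theta_pi instead uses all columns valid within
    each pair.  L is the full alignment length in either mode.
    """
    p = panel.subset(subset) if subset is not None else panel
    if p.n < 2:
        raise ValueError("need at least 2 sequences")
    seqs = p.sequences
    n, L = p.n, p.L
    valid_cols = np.all(np.isin(seqs, _VALID_ARR), axis=0)
    excluded = int(L - valid_cols.sum())

    if pairwise_deletion:
        total_diff = 0.0
        npairs = 0
        ok = np.isin(seqs, _VALID_ARR)
        for i in range(n):
            for j in range(i + 1, n):
                both = ok[i] & ok[j]
                total_diff += int(((seqs[i] != seqs[j]) & both).sum())
                npairs += 1
        theta_pi = total_diff / npairs / L
    else:
        vs = seqs[:, valid_cols]
        total = 0
        for i in range(n):
            total += (vs[i + 1 :] != vs[i]).sum()
        theta_pi = total / (n * (n - 1) / 2) / L

    vs = seqs[:, valid_cols]
    seg_mask = (vs != vs[0]).any(axis=0) if vs.shape[1] else np.zeros(0, dtype=bool)
    S = int(seg_mask.sum())
    a_n = sum(1.0 / i for i in range(1, n))
    theta_w = S / (a_n * L)

    positions = np.flatnonzero(valid_cols)[seg_mask] + 1  # 1-based
    ref = p.reference_index()
    rows = {}
    cons = [seqs[ref, pos - 1].decode() for pos in positions]
    rows["consensus"] = cons
    for i, label in enumerate(p.labels):
        rows[label] = [
            "." if seqs[i, pos - 1] == seqs[ref, pos - 1] else seqs[i, pos - 1].decode()
            for pos in positions
        ]
    table = pd.DataFrame(rows, index=pd.Index(positions, name="position")).T
    return DiversityResult(float(theta_pi), float(theta_w), S, table, excluded, n, L)
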