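"""Synthetic benchmark generators with planted ground truth.

Real regulon data (curated TF-target interactions, start-codon coordinates,
promoter sequences) cannot ship with the package, so every analysis input
is emulated here with controlled ground truth:

* periodic feature sets — a planted lattice of spacing P0 with Gaussian
  positional jitter, drowned in a uniform background, optionally confined
  to one genomic sub-region (for region-mapping benchmarks);
* uniform null feature sets — the null model of the period scan;
* labelled regulons — target promoters carrying planted PWM motif
  instances while the targets also sit on a positional lattice, with an
  optional *negative* coupling regime in which a strong binding site buys a
  gene off the lattice (the anti-correlated division of labour probed by
  the CCA interplay analysis).

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import ALPHABET, FeatureSet, MotifMatrix
from .boosting import LabeledGene

__all__ = [
    "PlantedConfig",
    "generate_periodic_positions",
    "generate_null_positions",
    "generate_regulon_dataset",
    "random_sequence",
    "sample_motif_site",
]


@dataclass(frozen=True)
class PlantedConfig:
    """Ground truth of a planted periodic feature set.

    ``n_lattice`` sites sit at offset + k*P0 (jittered, wrapped into the
    genome); ``n_background`` sites are uniform.  ``region`` confines both
    the lattice and the background to a (start, end) interval.
    """

    genome_length: int
    period: float
    n_lattice: int
    jitter_sd: float = 0.0
    n_background: int = 0
    region: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        span = (
            self.genome_length
            if self.region is None
            else self.region[1] - self.region[0] + 1
        )
        if self.n_lattice * self.period > span + self.period:
            raise ValueError(
                f"{self.n_lattice} lattice sites at period {self.period} do not fit "
                f"in {span} bp"
            )


def _dedupe(positions: list[int], genome_length: int) -> list[int]:
    """Resolve position collisions by +1 bp shifts (wrapping at G)."""
    taken: set[int] = set()
    out = []
    for p in positions:
        while p in taken:
            p = p % genome_length + 1
        taken.add(p)
        out.append(p)
    return out


def generate_periodic_positions(cfg: PlantedConfig) -> tuple[FeatureSet, np.ndarray]:
    """A planted-lattice feature set and its truth labels.

    Returns the sorted FeatureSet plus a boolean array aligned with it:
    True marks lattice members (names also encode the truth: ``lat*`` vs
    ``bg*``).  The lattice offset is drawn uniformly per seed so the phase
    of the planted signal is never special.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.genome_length
    lo, hi = cfg.region if cfg.region is not None else (1, G)
    span = hi - lo + 1
    offset = rng.uniform(0.0, cfg.period)
    lattice = []
    for k in range(cfg.n_lattice):
        p = lo + (offset + k * cfg.period + rng.normal(0.0, cfg.jitter_sd)) % span
        lattice.append(int(round(p - 1)) % G + 1)
    background = [
        int(p) for p in rng.integers(lo, hi + 1, size=cfg.n_background)
    ]
    positions = _dedupe(lattice + background, G)
    names = [f"lat{i+1:04d}" for i in range(cfg.n_lattice)] + [
        f"bg{i+1:04d}" for i in range(cfg.n_background)
    ]
    fs = FeatureSet.from_positions(positions, G, circular=True, names=names)
    truth = np.array([f.name.startswith("lat") for f in fs])
    return fs, truth


def generate_null_positions(n: int, genome_length: int, seed: int = 0) -> FeatureSet:
    """n positions drawn uniformly on [1, G] — the period scan's null model."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    positions = _dedupe([int(p) for p in rng.integers(1, genome_length + 1, size=n)], genome_length)
    return FeatureSet.from_positions(positions, genome_length)


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """i.i.d. background nucleotides with adjustable GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(ALPHABET), size=length, p=p))


def sample_motif_site(motif: MotifMatrix, rng: np.random.Generator) -> str:
    """Draw one site from the motif's per-column nucleotide distributions."""
    return "".join(
        rng.choice(list(ALPHABET), p=motif.probabilities[j] / motif.probabilities[j].sum())
        for j in range(motif.width)
    )


def generate_regulon_dataset(
    n_targets: int,
    n_nontargets: int,
    motif: MotifMatrix,
    implant_prob: float = 1.0,
    seq_len: int = 200,
    genome_length: int = 4_641_652,
    period: float = 93_000.0,
    jitter_sd: float = 2_000.0,
    coupling: str = "independent",
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[list[LabeledGene], FeatureSet]:
    """A labelled synthetic regulon for the multi-view classifier.

    Targets receive a motif instance (sampled from the matrix) implanted at
    a uniform offset with probability ``implant_prob`` and sit on a planted
    positional lattice of spacing ``period`` with Gaussian jitter;
    non-targets get pure background promoters and uniform positions.

    ``coupling="negative"`` creates the anti-correlated regime: each target
    draws a sequence-strength variable s ~ U(0,1); strong-sequence targets
    (s > 1/2) get the motif implanted but a *uniform* (off-lattice)
    position, weak-sequence targets keep their lattice position but no
    implanted motif.  Motif score and positional score are then negatively
    correlated among targets by construction.
    """
    if not (0.0 <= implant_prob <= 1.0):
        raise ValueError("implant_prob must be in [0, 1]")
    if motif.width > seq_len:
        raise ValueError("motif wider than the promoter sequences")
    if coupling not in ("independent", "negative"):
        raise ValueError(f"unknown coupling {coupling!r}")
    rng = np.random.default_rng(seed)
    G = genome_length
    offset = rng.uniform(0.0, period)

    def implant(seq: str) -> str:
        site = sample_motif_site(motif, rng)
        at = int(rng.integers(0, len(seq) - len(site) + 1))
        return seq[:at] + site + seq[at + len(site) :]

    genes: list[LabeledGene] = []
    positions: list[int] = []
    for i in range(n_targets):
        seq = random_sequence(seq_len, rng, gc)
        lattice_pos = int(round(offset + i * period + rng.normal(0.0, jitter_sd))) % G + 1
        if coupling == "negative":
            strong_seq = rng.uniform() > 0.5
            if strong_seq:
                seq = implant(seq)
                pos = int(rng.integers(1, G + 1))  # off the lattice
            else:
                pos = lattice_pos  # on the lattice, no implanted site
        else:
            if rng.uniform() < implant_prob:
                seq = implant(seq)
            pos = lattice_pos
        genes.append(LabeledGene(f"tgt{i+1:04d}", pos, seq, +1))
        positions.append(pos)
    for i in range(n_nontargets):
        seq = random_sequence(seq_len, rng, gc)
        pos = int(rng.integers(1, G + 1))
        genes.append(LabeledGene(f"non{i+1:04d}", pos, seq, -1))
        positions.append(pos)
    positions = _dedupe(positions, G)
    genes = [
        LabeledGene(g.name, p, g.regulatory_sequence, g.label)
        for g, p in zip(genes, positions)
    ]
    fs = FeatureSet.from_positions(
        positions, G, circular=True, names=[g.name for g in genes]
    )
    return genes, fs
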