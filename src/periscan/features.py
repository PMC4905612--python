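"""Genomic feature sets and binding-motif matrices.

This module holds the two containers the rest of the package works on:

* :class:`FeatureSet` — named genomic features (genes, operons, sites) with
  1-based positions on a single chromosome of known length, optionally
  circular.  Features are the *reference points* of whatever is being
  analysed; for genes this is conventionally the start codon coordinate.
* :class:`MotifMatrix` — a position weight matrix (PWM) for a transcription
  factor binding site, stored as per-column nucleotide probabilities plus a
  background model, exposing log-odds scores.

Readers accept plain TSV (name, position), BED and GFF3 for features, and
JASPAR-style plain count matrices or aligned FASTA sites for motifs.
Interval formats are reduced to the strand-aware 5' end so that every
feature enters the analysis as a single 1-based coordinate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicFeature",
    "FeatureSet",
    "MotifMatrix",
    "ParseError",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "remove_proximal",
    "read_motif",
    "motif_variants",
]

ALPHABET = "ACGT"
STRANDS = ("+", "-", ".")  # '.' = unknown


class ParseError(ValueError):
    """A file did not parse under the requested dialect."""


class ValidationError(ValueError):
    """Parsed content violates a FeatureSet/MotifMatrix invariant."""


@dataclass(frozen=True)
class GenomicFeature:
    """One named feature: a 1-based reference coordinate and a strand."""

    name: str
    position: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("feature name must be non-empty")
        if self.strand not in STRANDS:
            raise ValidationError(
                f"feature {self.name!r}: strand must be one of {STRANDS}, got {self.strand!r}"
            )
        if self.position < 1:
            raise ValidationError(
                f"feature {self.name!r}: position must be >= 1, got {self.position}"
            )


@dataclass(frozen=True)
class FeatureSet:
    """An ordered, validated collection of features on one chromosome.

    Features are sorted by position (ties broken by name) on construction.
    ``genome_length`` is the chromosome length G in bp; ``circular`` marks a
    circular chromosome (bacterial style), which affects proximity filtering
    and window wrapping downstream.
    """

    features: tuple[GenomicFeature, ...]
    genome_length: int
    circular: bool = False

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValidationError(f"genome_length must be > 0, got {self.genome_length}")
        feats = tuple(sorted(self.features, key=lambda f: (f.position, f.name)))
        object.__setattr__(self, "features", feats)
        seen: set[str] = set()
        for f in feats:
            if f.name in seen:
                raise ValidationError(f"duplicate feature name {f.name!r}")
            seen.add(f.name)
            if f.position > self.genome_length:
                raise ValidationError(
                    f"feature {f.name!r}: position {f.position} exceeds genome length "
                    f"{self.genome_length}"
                )

    @classmethod
    def from_positions(
        cls,
        positions: Sequence[int],
        genome_length: int,
        circular: bool = False,
        names: Sequence[str] | None = None,
        strands: Sequence[str] | None = None,
    ) -> "FeatureSet":
        """Build a set from bare positions, auto-naming features if needed."""
        n = len(positions)
        if names is None:
            width = max(1, len(str(n)))
            names = [f"f{str(i + 1).zfill(width)}" for i in range(n)]
        if strands is None:
            strands = ["."] * n
        feats = tuple(
            GenomicFeature(str(nm), int(p), s) for nm, p, s in zip(names, positions, strands)
        )
        return cls(feats, int(genome_length), circular)

    @property
    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features], dtype=np.int64)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GenomicFeature]:
        return iter(self.features)


# ---------------------------------------------------------------------------
# feature-table reading / writing
# ---------------------------------------------------------------------------


def _five_prime(start1: int, end1: int, strand: str) -> int:
    """5' end of a 1-based closed interval with respect to strand."""
    return end1 if strand == "-" else start1


def _iter_data_lines(path: Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_feature_table(
    path: str | Path,
    format: str = "tsv",
    *,
    genome_length: int,
    circular: bool = False,
) -> FeatureSet:
    """Read a feature table into a validated :class:`FeatureSet`.

    Parameters
    ----------
    format
        ``tsv`` — two columns (name, position), positions taken verbatim as
        1-based reference points; header row and ``#`` comments allowed.
        ``bed`` — ≥4 columns; 0-based half-open intervals reduced to the
        strand-aware 5' end, converted to 1-based.
        ``gff3`` — 1-based closed intervals reduced to the 5' end; the
        feature name is the ``Name=`` attribute, falling back to ``ID=``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    feats: list[GenomicFeature] = []
    if format == "tsv":
        first = True
        for lineno, line in _iter_data_lines(path):
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns (name, position)")
            name, pos_s = parts[0].strip(), parts[1].strip()
            try:
                pos = int(pos_s)
            except ValueError:
                if first:  # tolerate a single header row
                    first = False
                    continue
                raise ParseError(
                    f"{path}:{lineno}: position {pos_s!r} is not an integer"
                ) from None
            first = False
            feats.append(GenomicFeature(name, pos))
    elif format == "bed":
        for lineno, line in _iter_data_lines(path):
            if line.startswith(("track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs >= 4 columns for a name")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: BED start/end not integers") from None
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            pos = _five_prime(start0 + 1, end0, strand)
            feats.append(GenomicFeature(parts[3], pos, strand))
    elif format == "gff3":
        for lineno, line in _iter_data_lines(path):
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: GFF3 needs 9 tab-separated columns")
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: GFF3 start/end not integers") from None
            strand = parts[6] if parts[6] in ("+", "-") else "."
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID")
            if not name:
                raise ParseError(f"{path}:{lineno}: no Name= or ID= attribute")
            feats.append(GenomicFeature(name.strip(), _five_prime(start1, end1, strand), strand))
    else:
        raise ValueError(f"unknown feature-table format {format!r}")
    return FeatureSet(tuple(feats), int(genome_length), circular)


def write_feature_table(fs: FeatureSet, path: str | Path) -> None:
    """Write a FeatureSet as two-column TSV (name, position); round-trips."""
    with open(path, "w") as fh:
        fh.write("# name\tposition\n")
        for f in fs:
            fh.write(f"{f.name}\t{f.position}\n")


def remove_proximal(fs: FeatureSet, threshold: int) -> FeatureSet:
    """Drop features closer than ``threshold`` bp to the last kept feature.

    A greedy keep-first scan in coordinate order: a feature is removed when
    its distance to the most recently *kept* feature is below the threshold.
    Tightly packed genes otherwise inflate the periodicity score (many
    near-identical phases), bloating p-values with false positives.  On a
    circular chromosome the wrap distance between the last and first kept
    features is also enforced, dropping the later-coordinate one.
    Idempotent; the output is an ordered subset of the input.
    """
    if threshold < 0:
        raise ValueError(f"proximity threshold must be >= 0, got {threshold}")
    if threshold == 0 or len(fs) == 0:
        return fs
    kept: list[GenomicFeature] = []
    for f in fs:
        if not kept or f.position - kept[-1].position >= threshold:
            kept.append(f)
    if fs.circular:
        while len(kept) >= 2:
            wrap = fs.genome_length - (kept[-1].position - kept[0].position)
            if wrap >= threshold:
                break
            kept.pop()  # the later-coordinate member of the wrapping pair
    return FeatureSet(tuple(kept), fs.genome_length, fs.circular)


# ---------------------------------------------------------------------------
# motif matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifMatrix:
    """A PWM: per-position nucleotide probabilities over (A, C, G, T).

    ``log_odds`` are log2(p / background); columns where every base matches
    the background contribute nothing to a match score.
    """

    probabilities: np.ndarray  # shape (w, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # shape (4,)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValidationError(f"probabilities must be (w, 4) with w >= 1, got {p.shape}")
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValidationError("background must be 4 positive probabilities summing to 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probabilities / self.background)

    @property
    def information_content(self) -> np.ndarray:
        """Per-column relative entropy vs background, in bits."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / self.background), 0.0)
        return terms.sum(axis=1)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probabilities.argmax(axis=1))

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: Sequence[float] | None = None,
    ) -> "MotifMatrix":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValidationError("motif counts must be non-negative")
        probs = counts + pseudocount
        totals = probs.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValidationError("motif column with zero total count and zero pseudocount")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(probs / totals, bg)


def _counts_from_sites(sites: list[str]) -> np.ndarray:
    width = len(sites[0])
    counts = np.zeros((width, 4))
    for s in sites:
        if len(s) != width:
            raise ParseError(
                f"ragged alignment: site length {len(s)} != {width}"
            )
        for j, base in enumerate(s.upper()):
            if base in ALPHABET:
                counts[j, ALPHABET.index(base)] += 1
    return counts


def read_motif(
    path: str | Path,
    format: str = "jaspar_pfm",
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
) -> MotifMatrix:
    """Read a binding motif from a JASPAR-style matrix or aligned FASTA sites.

    ``jaspar_pfm`` accepts both the bracketed JASPAR layout and the plain
    4-row count matrix; rows are (A, C, G, T).  ``aligned_fasta`` requires
    all sites to share one length.  Counts plus ``pseudocount`` become
    column probabilities, then log-odds against the background.
    """
    from Bio import SeqIO, motifs as bio_motifs

    path = Path(path)
    if format == "jaspar_pfm":
        counts = None
        for fmt in ("jaspar", "pfm"):
            try:
                with open(path) as fh:
                    m = bio_motifs.read(fh, fmt)
                counts = np.array([m.counts[b] for b in ALPHABET], dtype=float).T
                break
            except Exception:
                continue
        if counts is None:
            raise ParseError(f"{path}: could not parse as a JASPAR/pfm matrix")
    elif format == "aligned_fasta":
        sites = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
        if not sites:
            raise ParseError(f"{path}: no sites in aligned FASTA")
        counts = _counts_from_sites(sites)
    else:
        raise ValueError(f"unknown motif format {format!r}")
    motif = MotifMatrix.from_counts(counts, pseudocount, background)
    if np.allclose(motif.log_odds, 0.0, atol=1e-12):
        warnings.warn("motif carries zero information (matches background everywhere)")
    return motif


def motif_variants(motif: MotifMatrix, max_trim: int = 4, min_width: int = 4) -> dict[str, MotifMatrix]:
    """Full matrix plus progressively flank-trimmed versions.

    Each trim removes the flanking column (left or right) with the lower
    information content, producing the "set of consensus sequences" used as
    sequence-view weak-classifier generators.
    """
    variants = {"full": motif}
    probs = motif.probabilities
    lo, hi = 0, probs.shape[0]
    for k in range(1, max_trim + 1):
        if hi - lo <= min_width:
            break
        sub = MotifMatrix(probs[lo:hi], motif.background)
        ic = sub.information_content
        if ic[0] <= ic[-1]:
            lo += 1
        else:
            hi -= 1
        variants[f"trim{k}"] = MotifMatrix(probs[lo:hi], motif.background)
    return variants
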