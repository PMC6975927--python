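"""Differential CRISPR-screen scores and sgRNA off-target scanning.

A pooled knockout screen yields one fitness score per gene (negative
means the guides targeting that gene depleted from the population).  To
remove genotype-independent fitness effects, the scores of each
experimental screen are compared against the average of control
screens: differential = experimental - mean(controls).  Genes missing
from any table are dropped and reported rather than imputed, since a
differential is only meaningful on shared genes.

The off-target scan compares a 20-mer guide against candidate genomic
sites by Hamming distance (mismatch count at aligned positions); sites
within the mismatch budget are reported sorted by mismatch count.
Candidate-site enumeration from a genome is out of scope — the scan
operates on a provided site list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

__all__ = [
    "GeneScoreTable",
    "DifferentialResult",
    "differential_scores",
    "OffTargetHit",
    "hamming_distance",
    "offtarget_scan",
]

_ALPHABET = set("ACGT")


@dataclass
class GeneScoreTable:
    """Mapping gene -> fitness score for one screen."""

    scores: dict[str, float]
    label: str = ""

    def __post_init__(self):
        if len(self.scores) == 0:
            raise ValidationError("score table is empty")
        arr = np.asarray(list(self.scores.values()), dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("scores must be finite")
        self.scores = {str(g): float(s) for g, s in self.scores.items()}

    @classmethod
    def from_series(cls, s: pd.Series, label: str = "") -> "GeneScoreTable":
        if s.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers")
        return cls(dict(s), label=label)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, name=self.label or "score")

    @property
    def genes(self) -> set[str]:
        return set(self.scores)


@dataclass
class DifferentialResult:
    """Differential scores plus the genes dropped for being unshared."""

    table: GeneScoreTable
    dropped_genes: list[str] = field(default_factory=list)

    def ranked(self, ascending: bool = True) -> pd.Series:
        """Scores sorted most-depleted first (ascending=True)."""
        return self.table.to_series().sort_values(ascending=ascending)


def differential_scores(
    experimental: GeneScoreTable, controls
) -> DifferentialResult:
    """Per-gene differential = experimental - mean(control scores).

    Only genes present in the experimental table and every control are
    scored; the rest are returned as ``dropped_genes``.
    """
    if isinstance(controls, GeneScoreTable):
        controls = [controls]
    controls = list(controls)
    if not controls:
        raise ValidationError("at least one control table is required")
    shared = experimental.genes.intersection(*(c.genes for c in controls))
    if not shared:
        raise ValidationError("no genes shared between experimental and controls")
    all_genes = experimental.genes.union(*(c.genes for c in controls))
    dropped = sorted(all_genes - shared)
    diff = {
        g: experimental.scores[g]
        - float(np.mean([c.scores[g] for c in controls]))
        for g in sorted(shared)
    }
    label = f"{experimental.label or 'experimental'} - mean(controls)"
    return DifferentialResult(
        table=GeneScoreTable(diff, label=label), dropped_genes=dropped
    )


def _check_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    if not set(seq) <= _ALPHABET:
        raise ValidationError(f"{name} contains characters outside ACGT")
    return seq


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatched positions between equal-length ACGT strings."""
    a = _check_sequence(a, "first sequence")
    b = _check_sequence(b, "second sequence")
    if len(a) != len(b):
        raise ValidationError(
            f"sequences differ in length ({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class OffTargetHit:
    """A candidate site within the mismatch budget of a guide."""

    guide: str
    site: str
    mismatch_count: int
    position: str = ""

    def __post_init__(self):
        if len(self.guide) != len(self.site):
            raise ValidationError("guide and site must have equal length")
        if not 0 <= self.mismatch_count <= len(self.guide):
            raise ValidationError("mismatch_count out of range")


def offtarget_scan(
    guide: str, candidate_sites, max_mismatch: int = 2,
    labels=None,
) -> list[OffTargetHit]:
    """All candidate sites within ``max_mismatch`` of the guide.

    Hits are sorted by mismatch count, ties kept in input order.
    ``labels`` optionally names each candidate (same length as the list).
    """
    guide = _check_sequence(guide, "guide")
    candidate_sites = list(candidate_sites)
    if labels is None:
        labels = [f"site_{i}" for i in range(len(candidate_sites))]
    hits = []
    for i, site in enumerate(candidate_sites):
        d = hamming_distance(guide, site)
        if d <= max_mismatch:
            hits.append(OffTargetHit(
                guide=guide, site=site.upper(), mismatch_count=d,
                position=str(labels[i]),
            ))
    hits.sort(key=lambda h: h.mismatch_count)  # stable: input order on ties
    return hits
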