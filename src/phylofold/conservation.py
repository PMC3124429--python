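"""Per-column conservation annotation of a protein alignment.

Three measures, following the annotation style popularized by alignment
viewers in the AMAS lineage:

* **consensus** — the most frequent non-gap residue in the column and its
  frequency as a percentage of all rows (gaps count in the denominator).
* **conservation** — the number (0-10) of physicochemical property classes
  whose status (shared by every residue, or absent from every residue) is
  uniform down the column, using the Livingstone-Barton ten-class scheme;
  a column made of a single residue with no gaps additionally carries an
  identity flag.
* **quality** — a BLOSUM62-based score of how conservative the observed
  substitutions are: each ordered pair of differing residues contributes the
  ratio of its (shifted) BLOSUM62 score to the larger of the two diagonal
  scores; a fully conserved column scores 1, the worst possible column 0.

BLOSUM62 scores are shifted by +4 (the negated minimum entry) before the
ratio so that all ratios are well-defined and lie in [0, 1].
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd
from Bio.Align import substitution_matrices

from .family_io import Alignment, AMINO_ACIDS, GAP

__all__ = [
    "PROPERTY_TABLE",
    "PROPERTY_NAMES",
    "ColumnAnnotation",
    "consensus",
    "conservation_score",
    "quality_score",
    "annotate_alignment",
]

# Livingstone-Barton ten-class physicochemical property table (version 1993,
# as used by the AMAS family of conservation methods).  Membership only; every
# amino acid has a defined (possibly empty) property vector.
PROPERTY_TABLE: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ILVCAGMFYWHKT"),
    "polar": frozenset("YWHKREQDNSTC"),
    "small": frozenset("VCAGDNSTP"),
    "proline": frozenset("P"),
    "tiny": frozenset("AGS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("HFWY"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "charged": frozenset("HKRDE"),
}
PROPERTY_NAMES = tuple(PROPERTY_TABLE)

_B62 = substitution_matrices.load("BLOSUM62")
_B62_SHIFT = 4.0  # -min(BLOSUM62); makes every score non-negative

DEFAULT_QUALITY_SCALE = 215.0


def _b62(a: str, b: str) -> float:
    return float(_B62[a, b]) + _B62_SHIFT


@dataclass(frozen=True)
class ColumnAnnotation:
    column: int  # 1-based
    consensus_residue: str
    consensus_percent: float  # of all rows, gaps included in denominator
    conservation: int  # 0..10 conserved property classes
    identity: bool
    quality_norm: float  # in [0, 1]
    quality_scaled: float


def consensus(aln: Alignment) -> list[tuple[str, float]]:
    """Per-column (most frequent non-gap residue, percent of all rows).

    Ties break alphabetically; an all-gap column reports ('-', 0.0).
    """
    out = []
    n_rows = len(aln)
    for c in range(1, aln.n_columns + 1):
        counts = Counter(s for s in aln.column(c) if s != GAP)
        if not counts:
            out.append((GAP, 0.0))
            continue
        best = min(counts, key=lambda r: (-counts[r], r))
        out.append((best, 100.0 * counts[best] / n_rows))
    return out


def conservation_score(
    aln: Alignment, gap_policy: Literal["exclude", "penalize"] = "exclude"
) -> list[tuple[int, bool]]:
    """Per-column (number of uniformly conserved properties, identity flag).

    A property counts as conserved when it is present in every residue of the
    column or absent from every residue.  Under ``exclude`` gaps are ignored;
    under ``penalize`` a gap behaves as a residue with no properties, so any
    gap defeats every "present in all" property.
    """
    out = []
    for c in range(1, aln.n_columns + 1):
        col = aln.column(c)
        residues = [s for s in col if s != GAP]
        has_gap = len(residues) < len(col)
        if not residues:
            out.append((0, False))
            continue
        if gap_policy == "penalize" and has_gap:
            # gap = property-less residue: only "absent in all" can hold
            score = sum(
                1
                for members in PROPERTY_TABLE.values()
                if all(r not in members for r in residues)
            )
        else:
            score = sum(
                1
                for members in PROPERTY_TABLE.values()
                if all(r in members for r in residues)
                or all(r not in members for r in residues)
            )
        identity = len(set(residues)) == 1 and not has_gap and residues[0] != "X"
        out.append((score, identity))
    return out


def quality_score(
    aln: Alignment, scale: float = DEFAULT_QUALITY_SCALE
) -> list[tuple[float, float]]:
    """Per-column (quality_norm in [0,1], quality_norm x scale).

    Over all ordered pairs of rows carrying different residues, each pair
    (a, b) contributes a penalty 1 - B'(a,b)/max(B'(a,a), B'(b,b)) where B' is
    BLOSUM62 shifted to non-negative; the mean penalty over all ordered
    non-gap row pairs is subtracted from 1.  Columns with fewer than two
    non-gap residues score 1 (nothing varies); an all-gap column scores 0.
    """
    out = []
    for c in range(1, aln.n_columns + 1):
        counts = Counter(s for s in aln.column(c) if s != GAP and s != "X")
        n = sum(counts.values())
        if n == 0:
            out.append((0.0, 0.0))
            continue
        if n == 1:
            out.append((1.0, scale))
            continue
        penalty = 0.0
        items = list(counts.items())
        for i, (a, na) in enumerate(items):
            for b, nb in items[i + 1 :]:
                ratio = _b62(a, b) / max(_b62(a, a), _b62(b, b))
                penalty += 2 * na * nb * (1.0 - ratio)  # ordered pairs
        norm = 1.0 - penalty / (n * (n - 1))
        out.append((norm, norm * scale))
    return out


def annotate_alignment(
    aln: Alignment,
    gap_policy: Literal["exclude", "penalize"] = "exclude",
    scale: float = DEFAULT_QUALITY_SCALE,
) -> list[ColumnAnnotation]:
    cons = consensus(aln)
    scores = conservation_score(aln, gap_policy)
    quals = quality_score(aln, scale)
    return [
        ColumnAnnotation(
            column=c,
            consensus_residue=cons[c - 1][0],
            consensus_percent=cons[c - 1][1],
            conservation=scores[c - 1][0],
            identity=scores[c - 1][1],
            quality_norm=quals[c - 1][0],
            quality_scaled=quals[c - 1][1],
        )
        for c in range(1, aln.n_columns + 1)
    ]


def annotation_table(annotations: Iterable[ColumnAnnotation]) -> pd.DataFrame:
    """Tabular report; percent shown rounded, unrounded value retained."""
    rows = [
        {
            "column": a.column,
            "consensus": a.consensus_residue,
            "percent": a.consensus_percent,
            "percent_display": round(a.consensus_percent),
            "conservation": a.conservation,
            "identity": int(a.identity),
            "quality_norm": a.quality_norm,
            "quality_scaled": a.quality_scaled,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows)


def write_annotation_tsv(annotations: Iterable[ColumnAnnotation], path) -> None:
    annotation_table(annotations).to_csv(path, sep="\t", index=False, float_format="%.6g")
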