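"""Alignment I/O, species-level curation and residue/column coordinate mapping.

A protein family arrives as a multiple alignment whose sequence identifiers
follow the UniProt entry-name convention (``B2MG_HUMAN``): the token after the
last underscore names the species.  Curation keeps a single representative
sequence per species — preferring full-length entries over fragments, then the
sequence most similar on average to the other species — so that downstream
tree building sees one tip per species.

Positions of interest (e.g. the two tryptophans of mature beta-2-microglobulin)
are given in the residue numbering of a reference sequence; :func:`map_position`
translates them into alignment columns and back.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Align import MultipleSeqAlignment

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
_ALLOWED = set(AMINO_ACIDS) | {GAP, "X"}

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "SequenceRecord",
    "Alignment",
    "PositionMap",
    "read_alignment",
    "write_alignment",
    "read_species_map",
    "select_species_representatives",
    "map_position",
    "column_to_mature",
    "extract_column_states",
    "percent_identity",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned protein sequence.

    ``residues`` is the gapped row: the 20 amino-acid letters, ``-`` for a
    gap and ``X`` for an unknown residue.
    """

    id: str
    residues: str
    species: str = ""
    is_fragment: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        bad = [(i, c) for i, c in enumerate(self.residues) if c not in _ALLOWED]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"record {self.id!r}: unknown symbol {c!r} at position {i + 1}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class Alignment:
    """An ordered collection of equal-length :class:`SequenceRecord` rows."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("alignment needs at least one record")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup}")
        n = len(self.records[0].residues)
        for r in self.records:
            if len(r.residues) != n:
                raise ValueError(
                    f"ragged alignment: record {r.id!r} has length "
                    f"{len(r.residues)}, expected {n}"
                )
        for c in range(n):
            if all(r.residues[c] == GAP for r in self.records):
                warnings.warn(f"column {c + 1} is all gaps", stacklevel=2)
                break

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rid: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, column: int) -> str:
        """1-based column as a string over rows (row order preserved)."""
        if not 1 <= column <= self.n_columns:
            raise IndexError(
                f"column {column} out of range 1..{self.n_columns}"
            )
        return "".join(r.residues[column - 1] for r in self.records)


@dataclass(frozen=True)
class PositionMap:
    """Correspondence between a reference row's ungapped numbering and columns.

    Both coordinates are 1-based; ``pairs`` is strictly increasing in both.
    """

    ref_id: str
    pairs: tuple[tuple[int, int], ...]

    def to_column(self, mature_index: int) -> int:
        for m, c in self.pairs:
            if m == mature_index:
                return c
        raise IndexError(f"mature index {mature_index} out of range for {self.ref_id}")

    def to_mature(self, column: int) -> int:
        for m, c in self.pairs:
            if c == column:
                return m
        raise IndexError(f"column {column} holds a gap in {self.ref_id}")


_FRAGMENT_RE = re.compile(r"\bfragment\b", re.IGNORECASE)


def _species_from_id(seq_id: str) -> str:
    """UniProt entry-name convention: species mnemonic after the last '_'."""
    if "_" in seq_id:
        return seq_id.rsplit("_", 1)[1]
    return ""


def read_alignment(
    path: str | Path,
    fmt: str = "fasta",
    species_map: Mapping[str, str] | None = None,
) -> Alignment:
    """Read an aligned FASTA or Clustal file.

    Species labels come from an explicit ``species_map`` when given, else from
    the suffix after the last underscore of the id.  A record whose
    description contains the token "Fragment" (any case) is flagged as a
    fragment; an explicit map read by :func:`read_species_map` can also carry
    the flag.
    """
    path = Path(path)
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as e:
        # Distinguish ragged input from empty input with a clearer message.
        if fmt == "fasta":
            seqs = list(SeqIO.parse(str(path), "fasta"))
            if not seqs:
                raise ValueError(f"{path}: empty alignment file") from e
            lengths = {len(s.seq) for s in seqs}
            if len(lengths) > 1:
                ref = len(seqs[0].seq)
                for s in seqs:
                    if len(s.seq) != ref:
                        raise ValueError(
                            f"{path}: ragged alignment: record {s.id!r} has "
                            f"length {len(s.seq)}, expected {ref}"
                        ) from e
        raise
    records = []
    frag_flags: Mapping[str, bool] = getattr(species_map, "fragment_flags", {})
    for rec in msa:
        if species_map is not None and rec.id in species_map:
            sp = species_map[rec.id]
        else:
            sp = _species_from_id(rec.id)
        desc = rec.description or ""
        is_frag = bool(_FRAGMENT_RE.search(desc)) or frag_flags.get(rec.id, False)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper().replace(".", GAP),
                species=sp,
                is_fragment=is_frag,
                description=desc,
            )
        )
    return Alignment(records)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write aligned FASTA; round-trips sequence content byte-identically."""
    bio = MultipleSeqAlignment(
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in aln.records
    )
    with open(path, "w") as fh:
        AlignIO.write(bio, fh, "fasta")


class SpeciesMap(dict):
    """id -> species mapping with optional per-id fragment flags."""

    def __init__(self, mapping: Mapping[str, str], fragment_flags=None):
        super().__init__(mapping)
        self.fragment_flags: dict[str, bool] = dict(fragment_flags or {})


def read_species_map(path: str | Path) -> SpeciesMap:
    """Read a TSV with columns id, species[, is_fragment (0/1)]."""
    mapping: dict[str, str] = {}
    flags: dict[str, bool] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if line_no == 1 and parts[0].lower() in ("id", "tip", "gene"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected at least 2 columns")
            mapping[parts[0]] = parts[1]
            if len(parts) >= 3 and parts[2].strip():
                flags[parts[0]] = parts[2].strip() not in ("0", "false", "False")
    return SpeciesMap(mapping, flags)


def percent_identity(a: str, b: str) -> float:
    """Percent identity over columns where both rows are non-gap.

    Pairs with zero overlap score 0 (deterministic convention).
    """
    same = 0
    total = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            total += 1
            if x == y:
                same += 1
    return 100.0 * same / total if total else 0.0


def select_species_representatives(aln: Alignment) -> Alignment:
    """Keep one record per species.

    Non-fragments beat fragments; among the remaining candidates the record
    with the highest mean pairwise percent identity to all records of *other*
    species wins; ties break on lexicographic id.  Idempotent.
    """
    by_species: dict[str, list[SequenceRecord]] = {}
    for r in aln.records:
        if not r.species:
            raise ValueError(f"record {r.id!r} has no species label")
        by_species.setdefault(r.species, []).append(r)

    keep: set[str] = set()
    for sp, group in by_species.items():
        if len(group) == 1:
            keep.add(group[0].id)
            continue
        candidates = [r for r in group if not r.is_fragment] or group
        others = [r for r in aln.records if r.species != sp]

        def mean_ident(r: SequenceRecord) -> float:
            if not others:
                return 0.0
            return sum(percent_identity(r.residues, o.residues) for o in others) / len(
                others
            )

        best = min(candidates, key=lambda r: (-mean_ident(r), r.id))
        keep.add(best.id)
    return Alignment([r for r in aln.records if r.id in keep])


def build_position_map(aln: Alignment, ref_id: str) -> PositionMap:
    row = aln[ref_id].residues
    pairs = []
    m = 0
    for c, sym in enumerate(row, start=1):
        if sym != GAP:
            m += 1
            pairs.append((m, c))
    return PositionMap(ref_id=ref_id, pairs=tuple(pairs))


def map_position(aln: Alignment, ref_id: str, mature_index: int) -> int:
    """Column (1-based) holding the ``mature_index``-th non-gap residue of
    the reference row."""
    return build_position_map(aln, ref_id).to_column(mature_index)


def column_to_mature(aln: Alignment, ref_id: str, column: int) -> int:
    """Inverse of :func:`map_position`; errors if the reference has a gap."""
    return build_position_map(aln, ref_id).to_mature(column)


def extract_column_states(aln: Alignment, column: int) -> dict[str, str]:
    """Mapping id -> one-letter state at a 1-based column (gap allowed)."""
    col = aln.column(column)
    return {r.id: s for r, s in zip(aln.records, col)}
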