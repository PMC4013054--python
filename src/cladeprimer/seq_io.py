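"""Sequence records, alignments, FASTA I/O and the IUPAC degenerate alphabet.

All downstream stages (distances, word models, primer matching) operate on the
types defined here.  Residues are upper-case IUPAC DNA codes plus ``-`` for an
alignment gap; ``U`` is normalised to ``T`` on input.  Degenerate codes are
represented internally as 4-bit base sets (A=1, C=2, G=4, T=8), which makes
set-intersection matching and reverse complementation table lookups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "IUPAC_SETS",
    "SequenceRecord",
    "Alignment",
    "SeqIOError",
    "read_fasta",
    "write_fasta",
    "read_taxonomy_tsv",
    "apply_taxonomy",
    "length_filter",
    "degap",
    "revcomp",
    "iupac_match",
    "encode_bits",
]

# IUPAC nucleotide codes as base sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
#: 4-bit encoding of every IUPAC code (union of its base bits); gap encodes to 0.
IUPAC_BITS: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()
}
IUPAC_BITS["-"] = 0

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

ALPHABET = frozenset(IUPAC_SETS) | {"-"}
CONCRETE = frozenset("ACGT")

# Byte lookup table: ASCII ord -> bitmask, 255 for invalid.
_BIT_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _v in IUPAC_BITS.items():
    _BIT_LUT[ord(_c)] = _v


class SeqIOError(ValueError):
    """Malformed sequence input (bad residues, ragged alignment, empty file)."""


def _normalise(residues: str, where: str = "") -> str:
    s = residues.upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        raise SeqIOError(f"invalid residue(s) {sorted(bad)}{where}")
    if not s:
        raise SeqIOError(f"empty residue string{where}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A labelled IUPAC DNA sequence, optionally gapped.

    ``taxon_label`` is a hierarchical label, ``phylum`` or ``phylum/subgroup``.
    """

    id: str
    residues: str
    description: str = ""
    taxon_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalise(self.residues, f" in record {self.id!r}"))
        if not self.id:
            raise SeqIOError("record id must be non-empty")

    @property
    def degapped(self) -> str:
        return self.residues.replace("-", "")

    @property
    def degapped_length(self) -> int:
        return len(self.degapped)

    @property
    def phylum(self) -> str | None:
        return self.taxon_label.split("/")[0] if self.taxon_label else None

    @property
    def subgroup(self) -> str | None:
        if self.taxon_label and "/" in self.taxon_label:
            return self.taxon_label.split("/", 1)[1]
        return None

    def with_label(self, label: str | None) -> "SequenceRecord":
        return replace(self, taxon_label=label)


@dataclass(frozen=True)
class Alignment:
    """Column-aligned sequence records (identical residue-string lengths)."""

    records: tuple[SequenceRecord, ...]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        if not recs:
            raise SeqIOError("alignment must contain at least one record")
        n = len(recs[0].residues)
        for r in recs:
            if len(r.residues) != n:
                raise SeqIOError(
                    f"ragged alignment: record {r.id!r} has length "
                    f"{len(r.residues)}, expected {n}"
                )
        _check_unique(recs)
        object.__setattr__(self, "records", recs)
        object.__setattr__(self, "n_columns", n)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, ids: Iterable[str]) -> "Alignment":
        keep = set(ids)
        return Alignment(tuple(r for r in self.records if r.id in keep))

    def bit_matrix(self) -> np.ndarray:
        """(n_records, n_columns) uint8 matrix of 4-bit base codes."""
        buf = np.frombuffer(
            "".join(r.residues for r in self.records).encode("ascii"), dtype=np.uint8
        )
        return _BIT_LUT[buf].reshape(len(self.records), self.n_columns)


def _check_unique(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise SeqIOError(f"duplicate record id {r.id!r}")
        seen.add(r.id)


def _parse_label(description: str, key: str) -> str | None:
    for token in description.split():
        if token.startswith(key + "="):
            return token[len(key) + 1 :]
    return None


def read_fasta(
    path: str | Path,
    aligned: bool = False,
    taxon_key: str = "taxon",
) -> Alignment | list[SequenceRecord]:
    """Read (optionally aligned) FASTA; taxon labels parsed from ``taxon=...``
    tokens in the description line."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        desc = bio.description
        try:
            records.append(
                SequenceRecord(
                    id=bio.id,
                    residues=str(bio.seq),
                    description=desc,
                    taxon_label=_parse_label(desc, taxon_key),
                )
            )
        except SeqIOError as exc:
            raise SeqIOError(f"{path}: {exc}") from exc
    if not records:
        raise SeqIOError(f"{path}: no FASTA records found")
    _check_unique(records)
    if aligned:
        return Alignment(tuple(records))
    return records


def write_fasta(
    records: Alignment | Iterable[SequenceRecord],
    path: str | Path,
    taxon_key: str = "taxon",
) -> None:
    recs = records.records if isinstance(records, Alignment) else tuple(records)
    bio = []
    for r in recs:
        desc = r.description
        if r.taxon_label and f"{taxon_key}=" not in desc:
            desc = (desc + " " if desc else "") + f"{taxon_key}={r.taxon_label}"
        bio.append(_BioRecord(Seq(r.residues), id=r.id, description=desc))
    SeqIO.write(bio, str(path), "fasta")


def read_taxonomy_tsv(path: str | Path) -> dict[str, str]:
    """Two-column ``id<TAB>phylum[/subgroup]`` taxonomy map."""
    out: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise SeqIOError(f"{path}:{line_no}: expected 2 tab-separated columns")
        out[parts[0]] = parts[1]
    return out


def apply_taxonomy(
    records: Iterable[SequenceRecord], taxonomy: dict[str, str]
) -> list[SequenceRecord]:
    return [r.with_label(taxonomy.get(r.id, r.taxon_label)) for r in records]


def length_filter(
    records: Iterable[SequenceRecord], min_length: int = 1200
) -> list[SequenceRecord]:
    """Keep records whose degapped length is >= ``min_length`` (inclusive),
    preserving order.  The near-full-length screen for 16S data uses 1200 nt."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    return [r for r in records if r.degapped_length >= min_length]


def degap(residues: str) -> str:
    return residues.replace("-", "")


def revcomp(residues: str) -> str:
    """IUPAC-aware reverse complement; rejects gapped input."""
    if "-" in residues:
        raise SeqIOError("cannot reverse-complement a gapped sequence")
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(residues.upper().replace("U", "T")))
    except KeyError as exc:
        raise SeqIOError(f"invalid residue {exc.args[0]!r}") from exc


def iupac_match(primer_base: str, subject_base: str, mode: str = "intersect") -> bool:
    """Whether a primer base can pair with a subject base.

    For a concrete subject base, true iff the primer's base set contains it.
    For a degenerate subject, ``intersect`` mode (default) requires the two
    base sets to overlap; ``subset`` mode requires the subject set to be
    contained in the primer set.
    """
    try:
        p = IUPAC_SETS[primer_base.upper()]
        s = IUPAC_SETS[subject_base.upper()]
    except KeyError as exc:
        raise SeqIOError(f"invalid IUPAC code {exc.args[0]!r}") from exc
    if mode == "intersect":
        return bool(p & s)
    if mode == "subset":
        return s <= p
    raise ValueError(f"unknown mode {mode!r}")


def encode_bits(residues: str) -> np.ndarray:
    """Encode an IUPAC string as a uint8 bitmask array (gap -> 0)."""
    arr = _BIT_LUT[np.frombuffer(residues.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = residues[int(np.argmax(arr == 255))]
        raise SeqIOError(f"invalid residue {bad!r}")
    return arr


def random_iupac_string(rng: np.random.Generator, length: int, concrete_only: bool = True) -> str:
    codes = sorted(CONCRETE if concrete_only else set(IUPAC_SETS))
    return "".join(rng.choice(codes, size=length))
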