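"""Consensus construction, primer candidates, physical properties, and the
coverage/tolerance specificity framework.

Coverage is the percentage of sequences in the primer's intended target taxon
containing a site matched by the primer; tolerance is the same percentage for
sequences outside the target.  Matching is IUPAC-aware (a primer base matches
a concrete subject base contained in its base set; degenerate subject bases
use set intersection by default), searches both strands, and defaults to zero
mismatches.  Group percentages are computed over ALL records of the group,
including records that do not span the primer locus.

Thermodynamics use the unified nearest-neighbour parameter set (Allawi &
SantaLucia 1997/1998 duplex stacks) with the 0.368 ln[Na+] entropic salt
correction; hairpin and self-dimer propensities are scored as the sum of
stack free energies over perfectly paired stretches found by exhaustive
enumeration (stem >= 3 bp with loop >= 3 nt, and ungapped antiparallel
self-alignments with >= 3 contiguous pairs).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .seq_io import (
    IUPAC_SETS,
    SequenceRecord,
    SeqIOError,
    encode_bits,
    revcomp,
)

__all__ = [
    "Primer",
    "PrimerProperties",
    "primer_properties",
    "gc_percent",
    "degenerate_count",
    "TmResult",
    "tm_nearest_neighbor",
    "self_structure_dg",
    "Consensus",
    "consensus_majority",
    "match_sites",
    "SpecificityResult",
    "coverage_tolerance",
    "pair_coverage",
    "Candidate",
    "enumerate_candidates",
    "MappedSite",
    "map_to_reference",
    "specificity_table",
    "round_half_up",
]

_CONCRETE = frozenset("ACGT")
_CODE_OF_SET = {bases: code for code, bases in IUPAC_SETS.items()}
_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as in the reports."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Primer:
    """A named oligonucleotide, written 5'->3', with its intended target."""

    name: str
    residues: str
    target: str = ""
    role: str = "forward"

    def __post_init__(self) -> None:
        s = self.residues.upper().replace("U", "T")
        if "-" in s:
            raise SeqIOError(f"primer {self.name!r} contains a gap")
        bad = set(s) - set(IUPAC_SETS)
        if bad:
            raise SeqIOError(f"primer {self.name!r}: invalid residues {sorted(bad)}")
        if len(s) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")
        if self.role not in ("forward", "reverse"):
            raise ValueError("role must be 'forward' or 'reverse'")
        object.__setattr__(self, "residues", s)

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# physical properties
# ---------------------------------------------------------------------------


def gc_percent(primer: Primer | str) -> float:
    """%GC over non-degenerate positions only (degenerate positions are
    excluded from both numerator and denominator)."""
    s = primer.residues if isinstance(primer, Primer) else primer.upper()
    concrete = [c for c in s if c in _CONCRETE]
    if not concrete:
        raise ValueError("all positions degenerate: %GC undefined")
    gc = sum(1 for c in concrete if c in "GC")
    return 100.0 * gc / len(concrete)


def degenerate_count(primer: Primer | str) -> int:
    """Number of positions carrying a non-A/C/G/T code."""
    s = primer.residues if isinstance(primer, Primer) else primer.upper()
    return sum(1 for c in s if c not in _CONCRETE)


# Unified nearest-neighbour duplex parameters (dH kcal/mol, dS cal/mol/K),
# keyed by the top-strand dinucleotide 5'->3'; complements share parameters.
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
for _d in list(_NN):
    _rc = _WC[_d[1]] + _WC[_d[0]]
    _NN.setdefault(_rc, _NN[_d])
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_R_GAS = 1.987  # cal / (mol K)


def _nn_sums(seq: str) -> tuple[float, float]:
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    for term in (seq[0], seq[-1]):
        h, s = _INIT_GC if term in "GC" else _INIT_AT
        dh += h
        ds += s
    return dh, ds


@dataclass(frozen=True)
class TmResult:
    celsius: float
    na_mM: float
    primer_nM: float
    parameter_set: str = "unified nearest-neighbor (Allawi & SantaLucia)"

    def __float__(self) -> float:
        return self.celsius


def tm_nearest_neighbor(
    primer: Primer | str, na_mM: float = 50.0, primer_nM: float = 250.0
) -> TmResult:
    """Nearest-neighbour melting temperature with entropic salt correction.

    Tm = 1000 dH / (dS + 0.368 (N-1) ln[Na+] + R ln(C_T/4)) - 273.15.
    Degenerate primers are evaluated on their most stable (highest-Tm)
    expansion.
    """
    s = primer.residues if isinstance(primer, Primer) else primer.upper()
    if len(s) < 8:
        raise ValueError("Tm estimation requires a primer of >= 8 nt")
    sets = [sorted(IUPAC_SETS[c]) for c in s]
    n_exp = math.prod(len(x) for x in sets)
    if n_exp > 4096:
        raise ValueError("too many degenerate expansions for Tm estimation")
    ct = primer_nM * 1e-9
    best = -math.inf
    for combo in itertools.product(*sets):
        dh, ds = _nn_sums("".join(combo))
        ds_corr = ds + 0.368 * (len(s) - 1) * math.log(na_mM / 1000.0)
        tm = 1000.0 * dh / (ds_corr + _R_GAS * math.log(ct / 4.0)) - 273.15
        best = max(best, tm)
    return TmResult(celsius=best, na_mM=na_mM, primer_nM=primer_nM)


def _stack_dg(dinuc: str) -> float:
    dh, ds = _NN[dinuc]
    return dh - 310.15 * ds / 1000.0


def self_structure_dg(primer: Primer | str) -> tuple[float, float]:
    """(hairpin dG, dimer dG) in kcal/mol; 0.0 when no qualifying structure.

    Hairpin: perfectly self-complementary stems of >= 3 bp with a loop of
    >= 3 nt; score = sum of stack free energies along the stem; the most
    negative arrangement is reported.  Dimer: ungapped antiparallel self-
    alignments; every complementary stretch of >= 3 contiguous pairs
    contributes its stack sum; the most negative offset is reported.
    Degenerate positions do not pair.
    """
    s = primer.residues if isinstance(primer, Primer) else primer.upper()
    L = len(s)

    def paired(a: str, b: str) -> bool:
        return _WC.get(a) == b

    hairpin = 0.0
    for stem in range(3, L // 2 + 1):
        for i in range(0, L - 2 * stem - 3 + 1):
            for j in range(i + stem + 3, L - stem + 1):
                if all(paired(s[i + t], s[j + stem - 1 - t]) for t in range(stem)):
                    dg = sum(_stack_dg(s[i + t : i + t + 2]) for t in range(stem - 1))
                    hairpin = min(hairpin, dg)

    dimer = 0.0
    for off in range(2 * L - 1):
        # strand copies antiparallel: position i pairs with position off - i
        dg_off = 0.0
        run = 0
        run_start = 0
        for i in range(max(0, off - L + 1), min(L, off + 1) + 1):
            ok = i <= min(L - 1, off) and paired(s[i], s[off - i])
            if ok:
                if run == 0:
                    run_start = i
                run += 1
            else:
                if run >= 3:
                    dg_off += sum(
                        _stack_dg(s[t : t + 2]) for t in range(run_start, run_start + run - 1)
                    )
                run = 0
        if dg_off < dimer:
            dimer = dg_off
    return hairpin, dimer


@dataclass(frozen=True)
class PrimerProperties:
    length: int
    percent_gc: float
    degenerate_sites: int
    tm: float
    hairpin_dg: float
    dimer_dg: float


def primer_properties(
    primer: Primer, na_mM: float = 50.0, primer_nM: float = 250.0
) -> PrimerProperties:
    hp, dim = self_structure_dg(primer)
    return PrimerProperties(
        length=len(primer),
        percent_gc=gc_percent(primer),
        degenerate_sites=degenerate_count(primer),
        tm=tm_nearest_neighbor(primer, na_mM, primer_nM).celsius,
        hairpin_dg=hp,
        dimer_dg=dim,
    )


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Consensus:
    """Majority-rule consensus with per-column concrete-base frequencies."""

    residues: str
    base_counts: np.ndarray  # (n_columns, 4) counts of A, C, G, T
    gap_fraction: np.ndarray


def consensus_majority(alignment) -> Consensus:
    """Per column: the most frequent concrete base wins (plurality over
    A/C/G/T); ties become the IUPAC code of the tied set; columns with gap
    frequency > 50% are marked '-' (excluded from candidate windows); columns
    with no concrete bases at all become 'N'."""
    bits = alignment.bit_matrix()
    n, L = bits.shape
    counts = np.stack([(bits == b).sum(axis=0) for b in (1, 2, 4, 8)], axis=1)
    gap_frac = (bits == 0).sum(axis=0) / n
    bases = "ACGT"
    out = []
    for col in range(L):
        if gap_frac[col] > 0.5:
            out.append("-")
            continue
        c = counts[col]
        top = c.max()
        if top == 0:
            out.append("N")
            continue
        tied = frozenset(bases[k] for k in range(4) if c[k] == top)
        out.append(_CODE_OF_SET[tied])
    return Consensus(residues="".join(out), base_counts=counts, gap_fraction=gap_frac)


# ---------------------------------------------------------------------------
# site matching
# ---------------------------------------------------------------------------


def _mismatch_profile(pat: np.ndarray, subj: np.ndarray, mode: str) -> np.ndarray:
    k = len(pat)
    if len(subj) < k:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(subj, k)
    if mode == "intersect":
        ok = (win & pat) != 0
    elif mode == "subset":
        ok = (win & ~pat & 0x0F) == 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (~ok).sum(axis=1)


def match_sites(
    primer: Primer | str,
    subject: str,
    max_mismatch: int = 0,
    mode: str = "intersect",
    both_strands: bool = True,
) -> list[tuple[int, str]]:
    """Primer binding sites on a degapped subject, both strands by default.

    Positions are 1-based starts on the forward subject; strand '-' means the
    primer anneals to the reverse complement at that locus.
    """
    p = primer.residues if isinstance(primer, Primer) else primer.upper()
    subj = subject.upper().replace("-", "")
    sbits = encode_bits(subj)
    hits: list[tuple[int, str]] = []
    fwd = _mismatch_profile(encode_bits(p), sbits, mode)
    hits.extend((int(i) + 1, "+") for i in np.flatnonzero(fwd <= max_mismatch))
    if both_strands:
        rev = _mismatch_profile(encode_bits(revcomp(p)), sbits, mode)
        hits.extend((int(i) + 1, "-") for i in np.flatnonzero(rev <= max_mismatch))
    return sorted(hits)


# ---------------------------------------------------------------------------
# coverage / tolerance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupRow:
    group: str
    size: int
    matched: int
    is_target: bool

    @property
    def percent(self) -> float:
        return 100.0 * self.matched / self.size


@dataclass(frozen=True)
class SpecificityResult:
    """Per-group matched counts for one primer (or pair); coverage rows are
    the target groups, tolerance rows the rest."""

    primer_name: str
    target: str
    rows: tuple[GroupRow, ...]

    def coverage(self, group: str | None = None) -> float:
        rows = [r for r in self.rows if r.is_target]
        if group is not None:
            rows = [r for r in rows if r.group == group]
        if not rows:
            raise KeyError("no matching target group")
        if group is not None:
            return rows[0].percent
        top = [r for r in rows if "/" not in r.group] or rows
        matched = sum(r.matched for r in top)
        size = sum(r.size for r in top)
        return 100.0 * matched / size

    def max_tolerance(self) -> float:
        tol = [r.percent for r in self.rows if not r.is_target and r.size > 0]
        return max(tol) if tol else 0.0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [r.group for r in self.rows],
                "n": [r.size for r in self.rows],
                "matched": [r.matched for r in self.rows],
                "percent": [round_half_up(r.percent) for r in self.rows],
                "role": ["coverage" if r.is_target else "tolerance" for r in self.rows],
            }
        )


def _group_records(
    records: Sequence[SequenceRecord], target: str
) -> list[tuple[str, list[SequenceRecord], bool]]:
    """Phylum-level groups (sorted), expanded with subgroup rows for the
    target phylum, Table-5 style."""
    target_phylum = target.split("/")[0]
    phyla: dict[str, list[SequenceRecord]] = {}
    subs: dict[str, list[SequenceRecord]] = {}
    for r in records:
        ph = r.phylum or "unlabeled"
        phyla.setdefault(ph, []).append(r)
        if ph == target_phylum and r.subgroup:
            subs.setdefault(r.taxon_label, []).append(r)

    def is_target(name: str) -> bool:
        return name == target or name.startswith(target + "/")

    out = []
    for ph in sorted(phyla):
        out.append((ph, phyla[ph], is_target(ph)))
        if ph == target_phylum:
            for sg in sorted(subs):
                out.append((sg, subs[sg], is_target(sg)))
    return out


def _record_matched(
    primer_str: str, rec: SequenceRecord, max_mismatch: int, mode: str
) -> bool:
    subj = rec.degapped
    if max_mismatch == 0 and set(primer_str) <= _CONCRETE and set(subj) <= _CONCRETE:
        return primer_str in subj or revcomp(primer_str) in subj
    sbits = encode_bits(subj)
    prof = _mismatch_profile(encode_bits(primer_str), sbits, mode)
    if len(prof) and prof.min() <= max_mismatch:
        return True
    prof = _mismatch_profile(encode_bits(revcomp(primer_str)), sbits, mode)
    return bool(len(prof) and prof.min() <= max_mismatch)


def coverage_tolerance(
    primer: Primer,
    database: Sequence[SequenceRecord],
    target: str | None = None,
    max_mismatch: int = 0,
    mode: str = "intersect",
) -> SpecificityResult:
    """Per-group percentage of database records containing a primer site."""
    tgt = target if target is not None else primer.target
    rows = []
    for name, recs, is_tgt in _group_records(database, tgt):
        matched = sum(
            _record_matched(primer.residues, r, max_mismatch, mode) for r in recs
        )
        rows.append(GroupRow(group=name, size=len(recs), matched=matched, is_target=is_tgt))
    return SpecificityResult(primer_name=primer.name, target=tgt, rows=tuple(rows))


def _pair_matched(
    fwd: str, rev: str, rec: SequenceRecord, min_amplicon: int, max_mismatch: int, mode: str
) -> bool:
    subj = rec.degapped
    sbits = encode_bits(subj)
    fprof = _mismatch_profile(encode_bits(fwd), sbits, mode)
    fstarts = np.flatnonzero(fprof <= max_mismatch)
    if not len(fstarts):
        return False
    rprof = _mismatch_profile(encode_bits(revcomp(rev)), sbits, mode)
    rstarts = np.flatnonzero(rprof <= max_mismatch)
    if not len(rstarts):
        return False
    rends = rstarts + len(rev) - 1
    # amplicon inclusive of both primer footprints, 3' ends facing inward
    for f in fstarts:
        ok = rends[(rstarts >= f) & (rends - f + 1 > min_amplicon)]
        if len(ok):
            return True
    return False


def pair_coverage(
    forward: Primer,
    reverse: Primer,
    database: Sequence[SequenceRecord],
    target: str | None = None,
    min_amplicon: int = 400,
    max_mismatch: int = 0,
    mode: str = "intersect",
) -> SpecificityResult:
    """Per-group percentage of records amplifiable by a primer pair: a
    forward-strand site of the forward primer and a downstream reverse-strand
    site of the reverse primer with an implied amplicon (inclusive of both
    primer footprints) longer than ``min_amplicon``."""
    tgt = target if target is not None else forward.target
    rows = []
    for name, recs, is_tgt in _group_records(database, tgt):
        matched = sum(
            _pair_matched(
                forward.residues, reverse.residues, r, min_amplicon, max_mismatch, mode
            )
            for r in recs
        )
        rows.append(GroupRow(group=name, size=len(recs), matched=matched, is_target=is_tgt))
    return SpecificityResult(
        primer_name=f"{forward.name}-{reverse.name}", target=tgt, rows=tuple(rows)
    )


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    position: int  # 1-based start on the consensus
    residues: str
    coverage: float
    max_tolerance: float
    structure_violations: int

    @property
    def score(self) -> float:
        return self.coverage - self.max_tolerance


def enumerate_candidates(
    consensus: Consensus | str,
    database: Sequence[SequenceRecord],
    target: str,
    length_range: tuple[int, int] = (15, 25),
    max_mismatch: int = 0,
    mode: str = "intersect",
) -> list[Candidate]:
    """All gap-free, ambiguity-free consensus windows in the length range,
    scored by target coverage minus maximum non-target tolerance and ranked by
    (score desc, fewer self-structure violations, 5' position asc).

    No candidate may contain a degenerate code, so only fully resolved
    consensus stretches yield candidates.
    """
    cons = consensus.residues if isinstance(consensus, Consensus) else consensus.upper()
    lo, hi = length_range
    groups = _group_records(database, target)
    windows: list[tuple[int, str]] = []
    for k in range(lo, hi + 1):
        for i in range(len(cons) - k + 1):
            w = cons[i : i + k]
            if set(w) <= _CONCRETE:
                windows.append((i + 1, w))
    if not windows:
        warnings.warn("no admissible candidate windows in consensus")
        return []

    candidates = []
    for pos, w in windows:
        t_matched = t_size = 0
        max_tol = 0.0
        for name, recs, is_tgt in groups:
            if "/" in name:
                continue  # score at phylum level
            m = sum(_record_matched(w, r, max_mismatch, mode) for r in recs)
            if is_tgt:
                t_matched += m
                t_size += len(recs)
            elif recs:
                max_tol = max(max_tol, 100.0 * m / len(recs))
        cov = 100.0 * t_matched / t_size if t_size else 0.0
        hp, dim = self_structure_dg(w)
        violations = int(hp < 0.0) + int(dim < 0.0)
        candidates.append(
            Candidate(
                position=pos,
                residues=w,
                coverage=cov,
                max_tolerance=max_tol,
                structure_violations=violations,
            )
        )
    candidates.sort(key=lambda c: (-c.score, c.structure_violations, c.position))
    return candidates


# ---------------------------------------------------------------------------
# reference mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MappedSite:
    start: int  # 1-based inclusive on the forward reference
    end: int
    strand: str
    mismatches: int


def map_to_reference(
    primer: Primer | str,
    reference: str,
    max_mismatch: int = 5,
    mode: str = "intersect",
) -> MappedSite | None:
    """Best primer site on a reference (fewest mismatches; ties -> leftmost,
    forward strand preferred).  ``None`` when nothing within the ceiling."""
    p = primer.residues if isinstance(primer, Primer) else primer.upper()
    subj = reference.upper().replace("-", "")
    sbits = encode_bits(subj)
    best: MappedSite | None = None
    for strand, pat in (("+", p), ("-", revcomp(p))):
        prof = _mismatch_profile(encode_bits(pat), sbits, mode)
        if not len(prof):
            continue
        i = int(np.argmin(prof))
        mm = int(prof[i])
        if mm > max_mismatch:
            continue
        site = MappedSite(start=i + 1, end=i + len(p), strand=strand, mismatches=mm)
        if (
            best is None
            or mm < best.mismatches
            or (mm == best.mismatches and site.start < best.start)
        ):
            best = site
    return best


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def specificity_table(
    items: Sequence[Primer | tuple[Primer, Primer]],
    database: Sequence[SequenceRecord],
    min_amplicon: int = 400,
    max_mismatch: int = 0,
    mode: str = "intersect",
) -> pd.DataFrame:
    """One row per group, one percentage column per primer (or pair), to one
    decimal (half-up); an ``n`` column gives the group sizes."""
    results: list[SpecificityResult] = []
    for item in items:
        if isinstance(item, Primer):
            results.append(
                coverage_tolerance(item, database, max_mismatch=max_mismatch, mode=mode)
            )
        else:
            fwd, rev = item
            results.append(
                pair_coverage(
                    fwd, rev, database,
                    min_amplicon=min_amplicon, max_mismatch=max_mismatch, mode=mode,
                )
            )
    if not results:
        raise ValueError("no primers or pairs given")
    groups = [r.group for r in results[0].rows]
    data: dict[str, list] = {
        "group": groups,
        "n": [r.size for r in results[0].rows],
    }
    for res in results:
        by_group = {r.group: r for r in res.rows}
        data[res.primer_name] = [
            round_half_up(by_group[g].percent) if by_group[g].size else float("nan")
            for g in groups
        ]
    return pd.DataFrame(data)
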