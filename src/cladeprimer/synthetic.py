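"""Synthetic 16S-like sequence pools with known clade structure.

The generator emulates the landscape the analysis stages were built for: a
mixed pool of phylum-level clades whose intra-clade divergence (~0.08
substitutions/site by default) and inter-clade divergence (~0.28) mirror the
scales measured for archaeal 16S data, a designated target clade carrying
planted conserved primer windows, a distant outgroup, and a fraction of
partial-length records.  Evolution is independent-site Jukes-Cantor along a
random bifurcating tree per clade (branch lengths rescaled so the expected
pairwise intra-clade distance hits the configured value), with no indels
except terminal truncation — matching the distance model used downstream so
divergence targets are exact in expectation.  Fixed seeds give byte-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seq_io import Alignment, SequenceRecord

__all__ = [
    "PlantedWindow",
    "GeneratorConfig",
    "SyntheticTruth",
    "simulate_pool",
    "RecoveryMetrics",
    "score_collection",
    "score_partition",
    "score_classification",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedWindow:
    """A conserved motif planted at fixed alignment columns.

    The motif is copied verbatim into sequences of the in-scope clades with
    the given retention probability; every other sequence gets uniformly
    random bases across the window instead.
    """

    start: int  # 0-based column
    length: int
    clades: tuple[str, ...]
    retention: Mapping[str, float]  # clade -> probability; missing -> 0.0
    motif: str | None = None  # drawn from the seed when None


@dataclass(frozen=True)
class GeneratorConfig:
    clade_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "CladeA": 60, "CladeB": 45, "CladeC": 45, "CladeD": 40, "CladeE": 40
        }
    )
    target_clade: str = "CladeA"
    alignment_length: int = 1400
    intra_divergence: float = 0.08
    inter_divergence: float = 0.28
    windows: tuple[PlantedWindow, ...] = ()
    partial_fraction: float = 0.0
    #: partial records keep a uniformly drawn fraction of their length in this range
    truncation_keep: tuple[float, float] = (0.5, 0.9)
    include_outgroup: bool = True
    outgroup_divergence: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.intra_divergence < 0.75:
            raise ValueError("intra_divergence must be in [0, 0.75)")
        if not 0 <= self.inter_divergence < 0.75:
            raise ValueError("inter_divergence must be in [0, 0.75)")
        if self.inter_divergence < self.intra_divergence:
            raise ValueError("inter-clade divergence must be >= intra-clade")
        if self.target_clade not in self.clade_sizes:
            raise ValueError(f"target clade {self.target_clade!r} not in clade_sizes")
        for w in self.windows:
            if w.start < 0 or w.start + w.length > self.alignment_length:
                raise ValueError("planted window outside alignment bounds")
            if not 0 < w.length:
                raise ValueError("planted window length must be positive")
            if any(not 0 <= p <= 1 for p in w.retention.values()):
                raise ValueError("retention probabilities must be in [0, 1]")
        if not 0 <= self.partial_fraction <= 1:
            raise ValueError("partial_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for every emitted record."""

    clade_of: dict[str, str]
    window_retained: tuple[dict[str, bool], ...]
    window_motifs: tuple[str, ...]
    phylotype_of: dict[str, str]  # planted phylotype = generating clade
    tree_newick: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "clade_of": self.clade_of,
                "window_retained": list(self.window_retained),
                "window_motifs": list(self.window_motifs),
                "phylotype_of": self.phylotype_of,
                "tree_newick": self.tree_newick,
            }
        )


def _random_topology(n: int, rng: np.random.Generator):
    """Random bifurcating tree over n tips by sequential random joins;
    exponential branch lengths.  Returns (children, lengths, root) arrays."""
    total = 2 * n - 1
    lengths = rng.exponential(1.0, size=total)
    children: list[tuple[int, int] | None] = [None] * total
    avail = list(range(n))
    nxt = n
    while len(avail) > 1:
        i = int(rng.integers(len(avail)))
        a = avail.pop(i)
        j = int(rng.integers(len(avail)))
        b = avail.pop(j)
        children[nxt] = (a, b)
        avail.append(nxt)
        nxt += 1
    root = avail[0]
    lengths[root] = 0.0
    return children, lengths, root


def _tip_depths_and_mean_path(children, lengths, root, n):
    depth = np.zeros(len(lengths))
    order = [root]
    for node in order:
        if children[node] is not None:
            for c in children[node]:
                depth[c] = depth[node] + lengths[c]
                order.append(c)
    # mean pairwise tip path length via per-node tip aggregation
    tips_below: dict[int, list[int]] = {}
    total_path, n_pairs = 0.0, 0
    for node in reversed(order):
        if children[node] is None:
            tips_below[node] = [node]
            continue
        a, b = children[node]
        ta, tb = tips_below.pop(a), tips_below.pop(b)
        for x in ta:
            for y in tb:
                total_path += depth[x] + depth[y] - 2 * depth[node]
                n_pairs += 1
        tips_below[node] = ta + tb
    mean_path = total_path / n_pairs if n_pairs else 0.0
    return depth, order, mean_path


def _evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One JC step along a branch of expected length t substitutions/site."""
    if t <= 0:
        return seq.copy()
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    hit = rng.random(len(seq)) < p_diff
    out = seq.copy()
    # replacement uniform over the three other bases
    out[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def simulate_pool(config: GeneratorConfig) -> tuple[Alignment, SyntheticTruth]:
    """Generate a labelled pool of clades plus ground truth.

    Clade roots sit at distance (inter - intra) / 2 from a shared ancestor so
    that expected tip-to-tip distances are ~intra within and ~inter between
    clades; planted windows are then overwritten; finally a configured
    fraction of records is truncated (as leading/trailing alignment gaps).
    """
    rng = np.random.default_rng(config.rng_seed)
    L = config.alignment_length
    ancestor = rng.integers(0, 4, size=L)

    # resolve window motifs up front so they are stable for a given seed
    windows = []
    for w in config.windows:
        motif = w.motif or "".join(_BASES[rng.integers(0, 4, size=w.length)])
        if len(motif) != w.length:
            raise ValueError("window motif length mismatch")
        windows.append((w, motif.upper()))

    root_branch = max((config.inter_divergence - config.intra_divergence) / 2.0, 0.0)
    records: list[SequenceRecord] = []
    clade_of: dict[str, str] = {}
    retained: list[dict[str, bool]] = [dict() for _ in windows]
    newick_parts = []

    for clade in sorted(config.clade_sizes):
        size = config.clade_sizes[clade]
        if size < 1:
            raise ValueError(f"clade {clade!r} must have >= 1 sequence")
        clade_root_seq = _evolve(ancestor, root_branch, rng)
        ids = [f"{clade}_{i:03d}" for i in range(size)]
        if size == 1:
            seqs = {0: _evolve(clade_root_seq, config.intra_divergence / 2, rng)}
        else:
            children, lengths, root = _random_topology(size, rng)
            _, order, mean_path = _tip_depths_and_mean_path(
                children, lengths, root, size
            )
            scale = (config.intra_divergence / mean_path) if mean_path > 0 else 0.0
            node_seq: dict[int, np.ndarray] = {root: clade_root_seq}
            for node in order:
                if children[node] is None:
                    continue
                for c in children[node]:
                    node_seq[c] = _evolve(node_seq[node], lengths[c] * scale, rng)
            seqs = {t: node_seq[t] for t in range(size)}
        newick_parts.append(
            "(" + ",".join(f"{i}:{config.intra_divergence / 2:.4f}" for i in ids) + f"):{root_branch:.4f}"
        )
        for t, rid in enumerate(ids):
            arr = seqs[t]
            flags = []
            for k, (w, motif) in enumerate(windows):
                keep = (
                    clade in w.clades
                    and rng.random() < w.retention.get(clade, 0.0)
                )
                if keep:
                    arr[w.start : w.start + w.length] = [
                        "ACGT".index(c) for c in motif
                    ]
                else:
                    arr[w.start : w.start + w.length] = rng.integers(
                        0, 4, size=w.length
                    )
                flags.append(keep)
            residues = "".join(_BASES[arr])
            if rng.random() < config.partial_fraction:
                keep_frac = rng.uniform(*config.truncation_keep)
                keep_len = max(int(round(L * keep_frac)), 1)
                start = int(rng.integers(0, L - keep_len + 1))
                residues = (
                    "-" * start
                    + residues[start : start + keep_len]
                    + "-" * (L - start - keep_len)
                )
            records.append(
                SequenceRecord(id=rid, residues=residues, taxon_label=clade)
            )
            clade_of[rid] = clade
            for k, f in enumerate(flags):
                retained[k][rid] = f

    if config.include_outgroup:
        og = _evolve(ancestor, config.outgroup_divergence, rng)
        records.append(
            SequenceRecord(
                id="OUTGROUP", residues="".join(_BASES[og]), taxon_label="Outgroup"
            )
        )
        clade_of["OUTGROUP"] = "Outgroup"
        newick_parts.append(f"OUTGROUP:{config.outgroup_divergence:.4f}")

    truth = SyntheticTruth(
        clade_of=clade_of,
        window_retained=tuple(retained),
        window_motifs=tuple(m for _, m in windows),
        phylotype_of={
            rid: cl for rid, cl in clade_of.items() if cl != "Outgroup"
        },
        tree_newick="(" + ",".join(newick_parts) + ");",
    )
    return Alignment(tuple(records)), truth


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: float
    specificity: float
    false_collection_rate: float
    misassigned: dict[str, int]


def score_collection(
    truth: SyntheticTruth,
    collected_ids: Sequence[str] | frozenset[str],
    query_ids: Sequence[str],
    target_clade: str,
) -> RecoveryMetrics:
    """Sensitivity/specificity of a collection run over the query set."""
    unknown = set(query_ids) - set(truth.clade_of)
    if unknown:
        raise KeyError(f"unknown query id(s): {sorted(unknown)[:5]}")
    collected = set(collected_ids)
    pos = [q for q in query_ids if truth.clade_of[q] == target_clade]
    neg = [q for q in query_ids if truth.clade_of[q] != target_clade]
    tp = sum(q in collected for q in pos)
    fp = sum(q in collected for q in neg)
    mis: dict[str, int] = {}
    for q in neg:
        if q in collected:
            mis[truth.clade_of[q]] = mis.get(truth.clade_of[q], 0) + 1
    return RecoveryMetrics(
        sensitivity=tp / len(pos) if pos else float("nan"),
        specificity=1.0 - (fp / len(neg)) if neg else float("nan"),
        false_collection_rate=fp / len(neg) if neg else 0.0,
        misassigned=mis,
    )


def score_partition(truth: SyntheticTruth, assignment: Mapping[str, int]) -> float:
    """Adjusted Rand index between planted and inferred phylotype partitions."""
    from sklearn.metrics import adjusted_rand_score

    ids = sorted(set(assignment) & set(truth.phylotype_of))
    if not ids:
        raise KeyError("no shared ids between truth and assignment")
    planted = [truth.phylotype_of[i] for i in ids]
    inferred = [assignment[i] for i in ids]
    return float(adjusted_rand_score(planted, inferred))


def score_classification(
    truth: SyntheticTruth, labels: Mapping[str, str]
) -> tuple[float, dict[tuple[str, str], int]]:
    """Accuracy and confusion counts of predicted clade labels."""
    unknown = set(labels) - set(truth.clade_of)
    if unknown:
        raise KeyError(f"unknown id(s): {sorted(unknown)[:5]}")
    confusion: dict[tuple[str, str], int] = {}
    correct = 0
    for rid, pred in labels.items():
        actual = truth.clade_of[rid]
        confusion[(actual, pred)] = confusion.get((actual, pred), 0) + 1
        correct += actual == pred
    return correct / len(labels), confusion
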