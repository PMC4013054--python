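"""Phylotype (OTU) clustering, group distance statistics, and rarefaction.

Phylotypes are defined by cutting a UPGMA dendrogram of JC distances at a
cophenetic threshold.  The default threshold corresponds to 98% sequence
identity — the species-level 16S criterion — expressed on the JC scale:
-(3/4) ln(1 - (4/3)*0.02) ~= 0.0203 substitutions/site.  Merge heights are
recorded on the distance scale (two sequences merging at distance d have
cophenetic distance d), so thresholds compare directly to JC distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.special import gammaln
from scipy import stats

from .phylo import DistanceMatrix, jc_distance
from .seq_io import SequenceRecord

__all__ = [
    "identity_threshold",
    "Dendrogram",
    "PhylotypeSet",
    "upgma",
    "cut_phylotypes",
    "GroupDistanceStats",
    "group_distance_stats",
    "compare_distances_ttest",
    "RarefactionCurve",
    "rarefaction_curve",
]

#: JC distance corresponding to 98% sequence identity (species-level cutoff)
DEFAULT_PHYLOTYPE_THRESHOLD = jc_distance(0.02)


def identity_threshold(identity: float = 0.98) -> float:
    """JC distance threshold equivalent to a fractional sequence identity."""
    return jc_distance(1.0 - identity)


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge structure (scipy linkage matrix) over record ids."""

    labels: tuple[str, ...]
    linkage: np.ndarray

    def cophenetic_matrix(self) -> np.ndarray:
        if len(self.labels) == 1:
            return np.zeros((1, 1))
        from scipy.spatial.distance import squareform

        return squareform(hierarchy.cophenet(self.linkage))

    def root_height(self) -> float:
        return float(self.linkage[-1, 2]) if len(self.linkage) else 0.0


@dataclass(frozen=True)
class PhylotypeSet:
    """Disjoint, exhaustive partition of ids into phylotypes at a threshold."""

    threshold: float
    clusters: tuple[tuple[str, ...], ...]
    representatives: tuple[str, ...]

    @property
    def n_phylotypes(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def assignment(self) -> dict[str, int]:
        return {rid: k for k, cl in enumerate(self.clusters) for rid in cl}

    def membership_tsv(self) -> str:
        lines = ["id\tphylotype\trepresentative"]
        for k, cl in enumerate(self.clusters):
            for rid in cl:
                rep = 1 if rid == self.representatives[k] else 0
                lines.append(f"{rid}\t{k}\t{rep}")
        return "\n".join(lines) + "\n"


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Merge height equals the average inter-cluster distance; scipy breaks ties
    deterministically toward the earliest-formed pair.
    """
    if len(dm) == 1:
        return Dendrogram(dm.labels, np.empty((0, 4)))
    Z = hierarchy.linkage(dm.condensed(), method="average")
    return Dendrogram(dm.labels, Z)


def cut_phylotypes(
    dendrogram: Dendrogram,
    threshold: float = DEFAULT_PHYLOTYPE_THRESHOLD,
    dm: DistanceMatrix | None = None,
    records: Mapping[str, SequenceRecord] | None = None,
) -> PhylotypeSet:
    """Phylotypes = connected components after removing merges above threshold.

    The representative of each cluster is its medoid (minimum mean distance to
    the other members, requires ``dm``); ties go to the longest degapped
    sequence (when ``records`` given), then the lexicographically first id.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    labels = dendrogram.labels
    if len(labels) == 1:
        flat = np.array([1])
    else:
        flat = hierarchy.fcluster(dendrogram.linkage, t=threshold, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for lab, k in zip(labels, flat):
        clusters.setdefault(int(k), []).append(lab)
    ordered = sorted(clusters.values(), key=lambda c: min(labels.index(x) for x in c))

    reps: list[str] = []
    for cl in ordered:
        if dm is not None and len(cl) > 1:
            idx = [dm.labels.index(x) for x in cl]
            sub = dm.d[np.ix_(idx, idx)]
            mean_d = sub.sum(axis=1) / (len(cl) - 1)
            best = mean_d.min()
            tied = [cl[i] for i in range(len(cl)) if math.isclose(mean_d[i], best)]
        else:
            tied = list(cl)
        if records is not None and len(tied) > 1:
            longest = max(records[t].degapped_length for t in tied)
            tied = [t for t in tied if records[t].degapped_length == longest]
        reps.append(min(tied))
    return PhylotypeSet(
        threshold=threshold,
        clusters=tuple(tuple(sorted(c)) for c in ordered),
        representatives=tuple(reps),
    )


@dataclass(frozen=True)
class GroupDistanceStats:
    """Intra-group and inter-group pairwise distance summaries.

    ``intra[g] = (mean, sd, n_pairs)`` and ``inter[(g1, g2)]`` likewise; the
    SD is ``None`` when fewer than 2 pairs were available, and a singleton
    group has no intra entry.
    """

    intra: dict[str, tuple[float, float | None, int]]
    inter: dict[tuple[str, str], tuple[float, float | None, int]]

    def matrix_tsv(self, ndigits: int = 3) -> str:
        """Lower half = mean, upper half = SD (the paper-style layout)."""
        groups = sorted(set(self.intra) | {g for pair in self.inter for g in pair})
        header = "taxa\t" + "\t".join(groups)
        lines = [header]
        for i, gi in enumerate(groups):
            row = [gi]
            for j, gj in enumerate(groups):
                if i == j:
                    row.append("")
                elif i > j:
                    m = self.inter.get((gj, gi), (None,) * 3)[0]
                    row.append("" if m is None else f"{m:.{ndigits}f}")
                else:
                    s = self.inter.get((gi, gj), (None,) * 3)[1]
                    row.append("" if s is None else f"{s:.{ndigits}f}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def _mean_sd(values: np.ndarray) -> tuple[float, float | None, int]:
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n >= 2 else None
    return mean, sd, n


def group_distance_stats(
    dm: DistanceMatrix, groups: Mapping[str, Sequence[str]]
) -> GroupDistanceStats:
    """Mean +/- SD of pairwise distances within and between labelled groups."""
    if not groups:
        raise ValueError("groups must be non-empty")
    index = {lab: i for i, lab in enumerate(dm.labels)}
    intra: dict[str, tuple[float, float | None, int]] = {}
    inter: dict[tuple[str, str], tuple[float, float | None, int]] = {}
    names = sorted(groups)
    for g in names:
        idx = [index[x] for x in groups[g]]
        if len(idx) >= 2:
            iu = np.triu_indices(len(idx), 1)
            intra[g] = _mean_sd(dm.d[np.ix_(idx, idx)][iu])
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ia = [index[x] for x in groups[names[a]]]
            ib = [index[x] for x in groups[names[b]]]
            vals = dm.d[np.ix_(ia, ib)].ravel()
            inter[(names[a], names[b])] = _mean_sd(vals)
    return GroupDistanceStats(intra=intra, inter=inter)


def compare_distances_ttest(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Welch two-sample t-test on two sets of distances.

    Returns ``(t, p_value, reject)`` with ``reject`` at the given alpha.
    """
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), bool(p < alpha)


@dataclass(frozen=True)
class RarefactionCurve:
    """Expected phylotype richness E[S_n] at each subsample size n."""

    n: np.ndarray
    expected_richness: np.ndarray
    s_obs: int

    def tsv(self) -> str:
        lines = ["n\texpected_richness"]
        for ni, ei in zip(self.n, self.expected_richness):
            lines.append(f"{int(ni)}\t{ei:.4f}")
        return "\n".join(lines) + "\n"


def rarefaction_curve(
    phylotype_sizes: Sequence[int], eval_points: Iterable[int] | None = None
) -> RarefactionCurve:
    """Analytic individual-based rarefaction.

    E[S_n] = S_obs - sum_i C(N - N_i, n) / C(N, n), evaluated in log space
    (gammaln) for numerical stability; N_i are the per-phylotype abundances.
    """
    sizes = np.asarray(list(phylotype_sizes), dtype=np.int64)
    if len(sizes) == 0 or (sizes < 1).any():
        raise ValueError("phylotype sizes must all be >= 1")
    N = int(sizes.sum())
    s_obs = len(sizes)
    pts = np.asarray(
        sorted(eval_points) if eval_points is not None else range(1, N + 1),
        dtype=np.int64,
    )
    if (pts < 1).any() or (pts > N).any():
        raise ValueError(f"evaluation points must lie in [1, {N}]")

    def log_choose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    expected = np.empty(len(pts), dtype=float)
    log_cNn = log_choose(np.float64(N), pts.astype(np.float64))
    for k, n in enumerate(pts):
        rem = N - sizes
        ok = rem >= n
        terms = np.exp(log_choose(rem[ok].astype(np.float64), np.float64(n)) - log_cNn[k])
        expected[k] = s_obs - terms.sum()
    return RarefactionCurve(n=pts, expected_richness=expected, s_obs=s_obs)
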