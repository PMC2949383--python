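"""Band-pattern heterogeneity among individuals of an isogenic strain.

Individuals of an isogenic strain should show identical Southern band
patterns for a quiescent TE family; new transposition shows up as bands
present in some individuals and absent in others.  This module formalizes
the visual lane-to-lane comparison:

1. all band sizes across lanes are clustered (single linkage on a log2 size
   scale) into bins that absorb run-to-run gel variation;
2. each lane becomes a presence/absence vector over bins;
3. lanes are compared by Dice dissimilarity of their present-bin sets, and a
   group of individuals is called *stable* iff its maximum pairwise
   dissimilarity does not exceed a threshold (default 0: any difference
   counts);
4. groups (sublines) are compared through consensus band sets (bins present
   in at least half of a group's lanes), robust to one aberrant lane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .vsouthern import Ladder

__all__ = [
    "BandMatrix",
    "GroupCall",
    "GroupPairCall",
    "InstabilityReport",
    "DEFAULT_BIN_TOL",
    "bin_bands",
    "pairwise_dissimilarity",
    "set_dissimilarity",
    "classify",
]

#: Default binning tolerance, in log2 units, absorbing run-to-run gel
#: variation in size estimates (≈1.4% size ratio).
DEFAULT_BIN_TOL = 0.02


@dataclass
class BandMatrix:
    """Presence/absence of binned band sizes across samples.

    ``presence[i, j]`` is True iff sample i contributed at least one band to
    bin j.  ``bin_centers`` are geometric means of bin members, in kb,
    ascending.
    """

    bin_centers: list[float]
    samples: list[str]
    presence: np.ndarray
    groups: dict[str, str] = field(default_factory=dict)

    def present_bins(self, sample: str) -> frozenset[int]:
        i = self.samples.index(sample)
        return frozenset(np.flatnonzero(self.presence[i]).tolist())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence,
            index=self.samples,
            columns=[f"{c:.3f}" for c in self.bin_centers],
        )


def bin_bands(ladders: Sequence[Ladder], rel_tol: float = DEFAULT_BIN_TOL) -> BandMatrix:
    """Cluster all band sizes into bins and build the presence matrix.

    Sizes are compared on a log2 scale: two bands merge into one bin when
    single-linkage chaining connects them at distance <= ``rel_tol`` log2
    units.  Bin center is the geometric mean of member sizes.  Every input
    band maps to exactly one bin (the bins partition the bands).
    """
    if not ladders:
        raise ValueError("need at least one ladder")
    samples = [lad.sample_id for lad in ladders]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids among ladders")
    groups = {lad.sample_id: lad.group for lad in ladders if lad.group is not None}

    sizes: list[float] = []
    owners: list[int] = []
    for i, lad in enumerate(ladders):
        for b in lad.bands:
            sizes.append(b.size_estimate)
            owners.append(i)

    if not sizes:
        return BandMatrix([], samples, np.zeros((len(samples), 0), dtype=bool), groups)

    log_sizes = np.log2(np.asarray(sizes, dtype=float))
    if len(sizes) == 1:
        labels = np.array([1])
    else:
        Z = linkage(log_sizes.reshape(-1, 1), method="single")
        labels = fcluster(Z, t=rel_tol, criterion="distance")

    centers: dict[int, float] = {}
    for lab in np.unique(labels):
        centers[int(lab)] = float(2 ** log_sizes[labels == lab].mean())
    order = sorted(centers, key=centers.get)
    col = {lab: j for j, lab in enumerate(order)}

    presence = np.zeros((len(samples), len(order)), dtype=bool)
    for owner, lab in zip(owners, labels):
        presence[owner, col[int(lab)]] = True
    return BandMatrix([centers[lab] for lab in order], samples, presence, groups)


def set_dissimilarity(a: frozenset, b: frozenset, metric: str = "dice") -> float:
    """Dice (default) or Jaccard dissimilarity of two bin sets; 0 when both empty."""
    if not a and not b:
        return 0.0
    inter = len(a & b)
    if metric == "dice":
        return 1.0 - 2.0 * inter / (len(a) + len(b))
    if metric == "jaccard":
        return 1.0 - inter / len(a | b)
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_dissimilarity(
    matrix: BandMatrix, s1: str, s2: str, metric: str = "dice"
) -> float:
    """Dissimilarity of two samples' present-bin sets."""
    return set_dissimilarity(matrix.present_bins(s1), matrix.present_bins(s2), metric)


@dataclass(frozen=True)
class GroupCall:
    group: str
    n_samples: int
    max_pairwise_dissimilarity: float | None
    classification: str  # stable | heterogeneous | undetermined


@dataclass(frozen=True)
class GroupPairCall:
    group_a: str
    group_b: str
    consensus_dissimilarity: float
    classification: str  # identical | diverged


@dataclass
class InstabilityReport:
    family: str
    group_calls: list[GroupCall]
    pair_calls: list[GroupPairCall]
    threshold: float
    metric: str

    def call(self, group: str) -> str:
        for gc in self.group_calls:
            if gc.group == group:
                return gc.classification
        raise KeyError(group)

    def pair_call(self, a: str, b: str) -> str:
        key = frozenset((a, b))
        for pc in self.pair_calls:
            if frozenset((pc.group_a, pc.group_b)) == key:
                return pc.classification
        raise KeyError((a, b))


def _consensus(matrix: BandMatrix, members: list[str], frac: float) -> frozenset[int]:
    idx = [matrix.samples.index(s) for s in members]
    counts = matrix.presence[idx].sum(axis=0)
    return frozenset(np.flatnonzero(counts >= frac * len(idx)).tolist())


def classify(
    matrix: BandMatrix,
    threshold: float = 0.0,
    metric: str = "dice",
    family: str = "",
    consensus_frac: float = 0.5,
) -> InstabilityReport:
    """Classify within-group stability and between-group divergence.

    A group is *stable* iff its maximum pairwise Dice dissimilarity is
    <= ``threshold`` (default 0); a single-sample group is *undetermined*.
    Two groups are *identical* iff the dissimilarity of their consensus band
    sets (bins present in >= ``consensus_frac`` of a group's samples) is
    <= ``threshold``, else *diverged*.  The result does not depend on sample
    order or on the order of bands within lanes.
    """
    by_group: dict[str, list[str]] = {}
    for s in matrix.samples:
        by_group.setdefault(matrix.groups.get(s, "all"), []).append(s)

    group_calls = []
    for group in sorted(by_group):
        members = by_group[group]
        if len(members) < 2:
            group_calls.append(GroupCall(group, len(members), None, "undetermined"))
            continue
        dmax = max(
            pairwise_dissimilarity(matrix, a, b, metric)
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        )
        cls = "stable" if dmax <= threshold else "heterogeneous"
        group_calls.append(GroupCall(group, len(members), dmax, cls))

    pair_calls = []
    names = sorted(by_group)
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            d = set_dissimilarity(
                _consensus(matrix, by_group[ga], consensus_frac),
                _consensus(matrix, by_group[gb], consensus_frac),
                metric,
            )
            pair_calls.append(
                GroupPairCall(ga, gb, d, "identical" if d <= threshold else "diverged")
            )
    return InstabilityReport(family, group_calls, pair_calls, threshold, metric)
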