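"""Virtual Southern blots: predicted band ladders and observed-ladder matching.

Combining a complete digest with a probe-homology map predicts the ladder a
Southern filter would show: a restriction fragment produces a band iff a
probe hit overlaps it by at least ``min_overlap`` bp.  Observed gel ladders
(size estimates in kb, read off against markers) are then paired one-to-one
with predicted fragment sizes within a relative tolerance.

Matching is greedy best-first on relative error by default.  A
maximum-cardinality assignment (Hungarian) is available behind a flag; on
real blot-vs-digest comparisons the greedy pairing reproduces the pattern an
experimentalist reads off a gel — closest sizes pair first, and an observed
band with no close predicted size stays unexplained ("nd") even when a
contorted global assignment could absorb it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .probemap import DEFAULT_MIN_OVERLAP, ProbeHit
from .seqres import RestrictionFragment

__all__ = [
    "PredictedBand",
    "ObservedBand",
    "Ladder",
    "MatchedPair",
    "LadderMatch",
    "DEFAULT_REL_TOL",
    "predict_bands",
    "match_ladders",
    "table_report",
    "read_ladders_tsv",
]

#: Default relative tolerance when pairing gel estimates with exact digest sizes.
DEFAULT_REL_TOL = 0.05


@dataclass(frozen=True)
class PredictedBand:
    """A predicted gel band: exact size in bp plus its source fragment(s).

    Co-migrating fragments of identical exact size collapse into one band;
    ``fragment_refs`` lists (seq_id, ordinal) of every contributing fragment.
    """

    size: int
    fragment_refs: tuple[tuple[str, int], ...]
    probe_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("band size must be positive")
        if not self.fragment_refs:
            raise ValueError("a predicted band needs at least one source fragment")

    @property
    def size_kb(self) -> float:
        return self.size / 1000.0


@dataclass(frozen=True)
class ObservedBand:
    """A band read off a gel: size estimate in kb, optional intensity."""

    size_estimate: float
    sample_id: str
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.size_estimate <= 0:
            raise ValueError("observed band size must be positive")


@dataclass
class Ladder:
    """One lane: the observed bands of one sample for one probe/family label."""

    sample_id: str
    label: str
    bands: list[ObservedBand] = field(default_factory=list)
    group: str | None = None

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands, key=lambda b: -b.size_estimate)

    @property
    def sizes_kb(self) -> list[float]:
        return [b.size_estimate for b in self.bands]


@dataclass(frozen=True)
class MatchedPair:
    observed: ObservedBand
    predicted: PredictedBand
    relative_error: float


@dataclass
class LadderMatch:
    """One-to-one pairing of observed and predicted bands within tolerance."""

    pairs: list[MatchedPair]
    unmatched_observed: list[ObservedBand]
    unmatched_predicted: list[PredictedBand]
    tolerance: float

    @property
    def matched_fraction(self) -> float:
        n_obs = len(self.pairs) + len(self.unmatched_observed)
        return len(self.pairs) / n_obs if n_obs else 0.0

    @property
    def total_error(self) -> float:
        return sum(p.relative_error for p in self.pairs)


def predict_bands(
    fragments: Sequence[RestrictionFragment],
    hits: Iterable[ProbeHit],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[PredictedBand]:
    """Predicted ladder from digest fragments and probe hits.

    A fragment produces a band iff some single hit overlaps it by
    >= ``min_overlap`` bp; a hit spanning a cut site may light both flanking
    fragments when each side's overlap clears the threshold.  Bands carry
    exact fragment sizes and are sorted descending by size.
    """
    trees: dict[str, IntervalTree] = {}
    frag_by_ref: dict[tuple[str, int], RestrictionFragment] = {}
    for frag in fragments:
        iv = frag.interval
        trees.setdefault(iv.seq_id, IntervalTree()).addi(iv.start, iv.end, frag)
        frag_by_ref[(iv.seq_id, frag.ordinal)] = frag

    lit: dict[tuple[str, int], set[str]] = {}
    for hit in hits:
        g = hit.genomic
        tree = trees.get(g.seq_id)
        if tree is None:
            continue
        for node in tree.overlap(g.start, g.end):
            overlap = min(node.end, g.end) - max(node.begin, g.start)
            if overlap >= min_overlap:
                frag = node.data
                lit.setdefault((g.seq_id, frag.ordinal), set()).add(hit.probe_id)

    by_size: dict[int, tuple[list[tuple[str, int]], set[str]]] = {}
    for ref, probe_ids in lit.items():
        size = frag_by_ref[ref].size
        refs, probes = by_size.setdefault(size, ([], set()))
        refs.append(ref)
        probes |= probe_ids
    bands = [
        PredictedBand(size=size, fragment_refs=tuple(sorted(refs)), probe_ids=frozenset(probes))
        for size, (refs, probes) in by_size.items()
    ]
    bands.sort(key=lambda b: -b.size)
    return bands


def _candidate_pairs(
    observed: Sequence[ObservedBand],
    predicted: Sequence[PredictedBand],
    rel_tol: float,
) -> list[tuple[float, int, int]]:
    """Feasible (relative_error, obs_index, pred_index) triples within tolerance."""
    out = []
    for i, obs in enumerate(observed):
        obs_bp = obs.size_estimate * 1000.0
        for j, pred in enumerate(predicted):
            err = abs(obs_bp - pred.size) / pred.size
            if err <= rel_tol:
                out.append((err, i, j))
    return out


def match_ladders(
    observed: Ladder,
    predicted: Sequence[PredictedBand],
    rel_tol: float = DEFAULT_REL_TOL,
    method: str = "greedy",
) -> LadderMatch:
    """Pair observed gel bands with predicted digest fragments one-to-one.

    Relative error is |obs - pred| / pred (the prediction is exact; the gel
    estimate carries the error); comparison is done in bp.  ``greedy``
    accepts candidate pairs in ascending error order (ties: larger predicted
    size first, then input order); ``optimal`` computes a maximum-cardinality
    minimum-total-error assignment via the Hungarian algorithm.
    An empty observed ladder yields a match with every prediction unmatched.
    """
    if not 0 < rel_tol <= 0.2:
        raise ValueError("rel_tol must lie in (0, 0.2]")
    if method not in ("greedy", "optimal"):
        raise ValueError(f"unknown matching method {method!r}")

    obs = observed.bands
    cands = _candidate_pairs(obs, predicted, rel_tol)

    chosen: list[tuple[float, int, int]] = []
    if method == "greedy":
        cands.sort(key=lambda t: (t[0], -predicted[t[2]].size, t[1], t[2]))
        used_obs: set[int] = set()
        used_pred: set[int] = set()
        for err, i, j in cands:
            if i in used_obs or j in used_pred:
                continue
            used_obs.add(i)
            used_pred.add(j)
            chosen.append((err, i, j))
    elif cands:
        # pad infeasible cells so the assignment first maximizes cardinality,
        # then minimizes total relative error
        big = 1e6
        cost = np.full((len(obs), len(predicted)), big)
        for err, i, j in cands:
            cost[i, j] = err
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < big:
                chosen.append((float(cost[i, j]), int(i), int(j)))

    matched_obs = {i for _, i, _ in chosen}
    matched_pred = {j for _, _, j in chosen}
    pairs = [
        MatchedPair(observed=obs[i], predicted=predicted[j], relative_error=err)
        for err, i, j in sorted(chosen, key=lambda t: -predicted[t[2]].size)
    ]
    return LadderMatch(
        pairs=pairs,
        unmatched_observed=[b for i, b in enumerate(obs) if i not in matched_obs],
        unmatched_predicted=[p for j, p in enumerate(predicted) if j not in matched_pred],
        tolerance=rel_tol,
    )


def table_report(match: LadderMatch) -> pd.DataFrame:
    """Side-by-side comparison table of a ladder match.

    One row per band, sorted descending by size, with columns
    (observed_kb, predicted_kb, relative_error); a band absent from one side
    prints as "nd" (not detected) there.
    """
    rows: list[tuple[float, object, object, object]] = []
    for p in match.pairs:
        rows.append(
            (p.predicted.size_kb, p.observed.size_estimate, round(p.predicted.size_kb, 3),
             round(p.relative_error, 4))
        )
    for b in match.unmatched_observed:
        rows.append((b.size_estimate, b.size_estimate, "nd", ""))
    for p in match.unmatched_predicted:
        rows.append((p.size_kb, "nd", round(p.size_kb, 3), ""))
    rows.sort(key=lambda r: -r[0])
    return pd.DataFrame(
        [r[1:] for r in rows],
        columns=["observed_kb", "predicted_kb", "relative_error"],
    )


def read_ladders_tsv(path) -> list[Ladder]:
    """Read observed ladders from TSV (sample_id, family, size_kb[, intensity[, group]]).

    Returns one Ladder per (sample_id, family); an optional ``group`` column
    is preserved as an attribute on each ladder for grouped analyses.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "family", "size_kb"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ladder TSV missing columns: {sorted(missing)}")
    ladders = []
    for (sample, family), sub in df.groupby(["sample_id", "family"], sort=True):
        bands = [
            ObservedBand(
                size_estimate=float(r.size_kb),
                sample_id=str(sample),
                intensity=float(r.intensity) if "intensity" in df.columns and pd.notna(r.intensity) else None,
            )
            for r in sub.itertuples(index=False)
        ]
        group = str(sub["group"].iloc[0]) if "group" in df.columns else None
        ladders.append(
            Ladder(sample_id=str(sample), label=str(family), bands=bands, group=group)
        )
    return ladders
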