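"""Independent brute-force oracles used to validate the fast implementations.

Each oracle here is deliberately naive — full scans, exhaustive enumeration —
and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

from dataclasses import dataclass


def naive_site_scan(residues: str, recognition: str, cut_offset: int) -> list[int]:
    """Scan every index for the recognition sequence; O(n*m)."""
    m = len(recognition)
    return [
        i + cut_offset
        for i in range(len(residues) - m + 1)
        if residues[i : i + m] == recognition
    ]


def naive_split(residues: str, cuts: list[int]) -> list[str]:
    """Split a residue string at cut positions."""
    bounds = [0] + list(cuts) + [len(residues)]
    return [residues[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def naive_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass
class Assignment:
    n_pairs: int
    total_error: float
    pairs: frozenset  # of (obs_index, pred_index)


def exhaustive_assignments(
    obs_sizes_bp: list[float], pred_sizes_bp: list[float], rel_tol: float
) -> dict[int, Assignment]:
    """Best (minimum total relative error) one-to-one assignment per cardinality.

    Enumerates every feasible one-to-one assignment of observed to predicted
    bands with relative error |obs - pred| / pred <= rel_tol, by backtracking
    over observed bands.  Returns {cardinality: best assignment}.
    """
    candidates: list[list[tuple[int, float]]] = []
    for o in obs_sizes_bp:
        row = []
        for j, p in enumerate(pred_sizes_bp):
            err = abs(o - p) / p
            if err <= rel_tol:
                row.append((j, err))
        candidates.append(row)

    best: dict[int, Assignment] = {}

    def search(i: int, used: frozenset, pairs: frozenset, toterr: float) -> None:
        if i == len(obs_sizes_bp):
            cur = best.get(len(pairs))
            if cur is None or toterr < cur.total_error:
                best[len(pairs)] = Assignment(len(pairs), toterr, pairs)
            return
        search(i + 1, used, pairs, toterr)
        for j, err in candidates[i]:
            if j not in used:
                search(i + 1, used | {j}, pairs | {(i, j)}, toterr + err)

    search(0, frozenset(), frozenset(), 0.0)
    return best


def max_cardinality(obs_sizes_bp, pred_sizes_bp, rel_tol) -> int:
    best = exhaustive_assignments(obs_sizes_bp, pred_sizes_bp, rel_tol)
    return max(best) if best else 0
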