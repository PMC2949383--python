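"""Orchestration of the two study workflows and consolidated reporting.

* **identity check**: digest a genome, map probes, predict the ladder and
  match it against an observed ladder; the sample is declared identical to
  the sequenced reference when a sufficient fraction of its observed bands
  match predictions (the "fingerprint" argument: a stable family's band
  pattern identifies a subline as the sequenced strain).
* **instability study**: per family, bin all individuals' bands and
  classify each group as stable or heterogeneous and each pair of groups as
  identical or diverged.

Report generation is pure: the same inputs and seed yield byte-identical
JSON (no timestamps).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .instability import DEFAULT_BIN_TOL, InstabilityReport, bin_bands, classify
from .probemap import DEFAULT_MIN_OVERLAP, Probe, TEInsertion, annotation_hits
from .seqres import HINDIII, RestrictionEnzyme, SequenceRecord, digest_genome
from .vsouthern import (
    DEFAULT_REL_TOL,
    Ladder,
    LadderMatch,
    match_ladders,
    predict_bands,
)

__all__ = [
    "IDENTITY_THRESHOLD",
    "run_identity_check",
    "identity_from_match",
    "run_instability_study",
    "build_study_report",
    "report_to_json",
]

#: Minimum matched fraction of observed bands for "identity supported".
IDENTITY_THRESHOLD = 0.85


def identity_from_match(match: LadderMatch, threshold: float = IDENTITY_THRESHOLD) -> dict:
    """Identity verdict from an existing ladder match."""
    frac = match.matched_fraction
    return {
        "matched_fraction": frac,
        "n_pairs": len(match.pairs),
        "n_observed": len(match.pairs) + len(match.unmatched_observed),
        "n_predicted": len(match.pairs) + len(match.unmatched_predicted),
        "threshold": threshold,
        "identity_supported": bool(frac >= threshold),
    }


def run_identity_check(
    records: Sequence[SequenceRecord],
    insertions: Sequence[TEInsertion],
    probes: Sequence[Probe],
    observed: Ladder,
    enzyme: RestrictionEnzyme = HINDIII,
    rel_tol: float = DEFAULT_REL_TOL,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    threshold: float = IDENTITY_THRESHOLD,
) -> dict:
    """Digest -> probe map -> predict -> match, then the identity verdict."""
    try:
        fragments = digest_genome(records, enzyme)
    except Exception as exc:
        raise RuntimeError(f"digest stage failed: {exc}") from exc
    hits = []
    for probe in probes:
        hits.extend(annotation_hits(insertions, probe, min_overlap))
    predicted = predict_bands(fragments, hits, min_overlap)
    match = match_ladders(observed, predicted, rel_tol)
    out = identity_from_match(match, threshold)
    out["sample_id"] = observed.sample_id
    out["label"] = observed.label
    return out


def run_instability_study(
    ladders: Sequence[Ladder],
    bin_tol: float = DEFAULT_BIN_TOL,
    threshold: float = 0.0,
    metric: str = "dice",
) -> dict[str, InstabilityReport]:
    """Per-family band binning and stability classification.

    ``ladders`` carry a family label and a group; every group needs at
    least 2 individuals for a within-group call (single-sample groups are
    reported as undetermined).
    """
    by_family: dict[str, list[Ladder]] = {}
    for lad in ladders:
        by_family.setdefault(lad.label, []).append(lad)
    reports: dict[str, InstabilityReport] = {}
    for family in sorted(by_family):
        matrix = bin_bands(by_family[family], bin_tol)
        reports[family] = classify(matrix, threshold, metric, family=family)
    return reports


def instability_table(reports: dict[str, InstabilityReport]) -> pd.DataFrame:
    """Families x groups classification table (the multi-filter readout)."""
    rows = {}
    for family, rep in sorted(reports.items()):
        rows[family] = {gc.group: gc.classification for gc in rep.group_calls}
    return pd.DataFrame(rows).T.sort_index()


def build_study_report(
    identity_sections: Iterable[dict] = (),
    instability: dict[str, InstabilityReport] | None = None,
    site_comparison=None,
    relative_quantities: Iterable = (),
    provenance: dict | None = None,
) -> dict:
    """Consolidated study report; every section is JSON-serializable."""
    report: dict = {
        "tool": {"name": "tefp", "version": __version__},
        "provenance": provenance or {},
    }
    identity = list(identity_sections)
    if identity:
        report["identity_checks"] = identity
    if instability:
        report["instability"] = {
            fam: asdict(rep) for fam, rep in sorted(instability.items())
        }
    if site_comparison is not None:
        report["fish_sites"] = {
            "rule": site_comparison.rule,
            "totals": site_comparison.totals,
            "category_counts": site_comparison.category_counts,
            "pairwise_shared": {
                " & ".join(k): v for k, v in site_comparison.pairwise_shared.items()
            },
            "kway_shared": site_comparison.kway_shared,
        }
    rqs = [asdict(rq) if hasattr(rq, "__dataclass_fields__") else rq
           for rq in relative_quantities]
    if rqs:
        report["relative_quantities"] = rqs
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    return json.dumps(report, indent=2, sort_keys=True, default=str)
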