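"""Polytene cytological site labels and multi-strain site-list comparison.

FISH on D. melanogaster polytene chromosomes localizes TE copies to
cytological addresses of the Bridges map: a numbered division (1-102, laid
out along the arms X, 2L, 2R, 3L, 3R, 4), an optional band letter A-F, and
an optional numeric subdivision — e.g. ``98B2``.  Site lists from different
strains (or from genome annotation) are compared as sets under a configurable
matching rule, because FISH calls and annotation rarely agree in resolution:
``ignore_subdivision`` (default) treats 98B2 and 98B as the same site.

Each site may carry a probe category — whether it hybridized the 5' probe,
the 3' probe, or both.  A site seen only with the 3' probe is the signature
of a 5'-truncated retrocopy, i.e. of recent retrotransposition.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "CytoSite",
    "SiteList",
    "SiteComparison",
    "ARM_DIVISIONS",
    "MATCH_RULES",
    "parse_site",
    "format_site",
    "count_sites",
    "shared_sites",
    "read_site_lists",
]

#: Division ranges of the Bridges polytene map by chromosome arm.
ARM_DIVISIONS: dict[str, tuple[int, int]] = {
    "X": (1, 20),
    "2L": (21, 40),
    "2R": (41, 60),
    "3L": (61, 80),
    "3R": (81, 100),
    "4": (101, 102),
}

CATEGORIES = ("five_prime_only", "three_prime_only", "both", "unspecified")
MATCH_RULES = ("exact", "ignore_subdivision", "letter_adjacent")

_SITE_RE = re.compile(r"^(\d{1,3})([A-Z])?(\d+)?(\*)?$")


@dataclass(frozen=True)
class CytoSite:
    """A cytological address, e.g. 98B2: division 98, letter B, subdivision 2."""

    arm: str
    division: int
    band_letter: str | None = None
    subdivision: int | None = None
    category: str = "unspecified"
    shared_flag: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ARM_DIVISIONS:
            raise ValueError(f"unknown chromosome arm {self.arm!r}")
        lo, hi = ARM_DIVISIONS[self.arm]
        if not lo <= self.division <= hi:
            raise ValueError(
                f"division {self.division} outside range {lo}-{hi} of arm {self.arm}"
            )
        if self.band_letter is not None and self.band_letter not in "ABCDEF":
            raise ValueError(f"band letter {self.band_letter!r} beyond F")
        if self.subdivision is not None and self.band_letter is None:
            raise ValueError("a subdivision requires a band letter")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _arm_of_division(division: int) -> str:
    for arm, (lo, hi) in ARM_DIVISIONS.items():
        if lo <= division <= hi:
            return arm
    raise ValueError(f"division {division} outside the polytene map (1-102)")


def parse_site(label: str, category: str = "unspecified") -> CytoSite:
    """Parse a label like ``98B2`` or ``102A*`` into a CytoSite.

    A trailing ``*`` is recorded as a shared-site annotation (it is stored
    but never used in computation — shared sets are always recomputed).
    The chromosome arm is inferred from the division number.
    """
    m = _SITE_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse cytological site label {label!r}")
    division = int(m.group(1))
    letter = m.group(2)
    subdivision = int(m.group(3)) if m.group(3) else None
    return CytoSite(
        arm=_arm_of_division(division),
        division=division,
        band_letter=letter,
        subdivision=subdivision,
        category=category,
        shared_flag=m.group(4) == "*",
    )


def format_site(site: CytoSite) -> str:
    """Inverse of parse_site, minus the asterisk: format(parse(x)) == x.rstrip('*')."""
    out = str(site.division)
    if site.band_letter:
        out += site.band_letter
    if site.subdivision is not None:
        out += str(site.subdivision)
    return out


def site_key(site: CytoSite, rule: str) -> tuple:
    """Equivalence key of a site under a matching rule."""
    if rule == "exact":
        return (site.arm, site.division, site.band_letter, site.subdivision)
    if rule == "ignore_subdivision":
        return (site.arm, site.division, site.band_letter)
    if rule == "letter_adjacent":
        # handled pairwise; key used only for canonical ordering
        return (site.arm, site.division)
    raise ValueError(f"unknown matching rule {rule!r}")


def _sites_match(a: CytoSite, b: CytoSite, rule: str) -> bool:
    if rule == "letter_adjacent":
        if (a.arm, a.division) != (b.arm, b.division):
            return False
        if a.band_letter is None or b.band_letter is None:
            return True
        return abs(ord(a.band_letter) - ord(b.band_letter)) <= 1
    return site_key(a, rule) == site_key(b, rule)


@dataclass
class SiteList:
    """FISH (or annotation-derived) site list of one strain."""

    strain_id: str
    sites: list[CytoSite] = field(default_factory=list)

    def deduplicated(self, rule: str = "ignore_subdivision") -> "SiteList":
        """Collapse duplicate sites under ``rule`` (warns when any are dropped)."""
        kept: list[CytoSite] = []
        for site in self.sites:
            if any(_sites_match(site, k, rule) for k in kept):
                warnings.warn(
                    f"{self.strain_id}: duplicate site {format_site(site)} collapsed",
                    stacklevel=2,
                )
                continue
            kept.append(site)
        return SiteList(self.strain_id, kept)

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for s in self.sites:
            out[s.category] += 1
        return out


def count_sites(site_list: SiteList, rule: str = "exact") -> int:
    """Number of distinct sites under the active matching rule.

    Counting defaults to ``exact`` (every printed site counts once) even
    though set comparison defaults to ``ignore_subdivision``: an annotation
    may legitimately resolve two subdivisions (98B2 and 98B8) that a FISH
    signal cannot, and both are real sites.
    """
    return len(site_list.deduplicated(rule).sites)


@dataclass
class SiteComparison:
    """Totals, category counts and shared sets for k strains under one rule."""

    rule: str
    totals: dict[str, int]
    category_counts: dict[str, dict[str, int]]
    pairwise_shared: dict[tuple[str, str], list[str]]
    kway_shared: list[str]


def _shared_labels(a: Sequence[CytoSite], b: Sequence[CytoSite], rule: str) -> list[CytoSite]:
    return [sa for sa in a if any(_sites_match(sa, sb, rule) for sb in b)]


def shared_sites(lists: Sequence[SiteList], rule: str = "ignore_subdivision") -> SiteComparison:
    """Pairwise and k-way shared site sets among >= 2 strains.

    The k-way shared set is computed by successive intersection (sites of
    the first strain matched by every other strain), so it is contained in
    every pairwise shared set.  Output ordering is deterministic: sites sort
    by (arm order on the map, division, letter, subdivision).
    """
    if len(lists) < 2:
        raise ValueError("need at least two site lists to compare")
    deduped = [sl.deduplicated(rule if rule != "letter_adjacent" else "ignore_subdivision")
               for sl in lists]

    arm_order = list(ARM_DIVISIONS)

    def sort_key(s: CytoSite):
        return (arm_order.index(s.arm), s.division, s.band_letter or "", s.subdivision or 0)

    def labels(sites: Iterable[CytoSite]) -> list[str]:
        uniq: dict[tuple, CytoSite] = {}
        for s in sites:
            uniq.setdefault(site_key(s, "ignore_subdivision"), s)
        return [format_site(s) for s in sorted(uniq.values(), key=sort_key)]

    pairwise: dict[tuple[str, str], list[str]] = {}
    for i, sa in enumerate(deduped):
        for sb in deduped[i + 1 :]:
            pairwise[(sa.strain_id, sb.strain_id)] = labels(
                _shared_labels(sa.sites, sb.sites, rule)
            )

    kway = list(deduped[0].sites)
    for other in deduped[1:]:
        kway = _shared_labels(kway, other.sites, rule)

    return SiteComparison(
        rule=rule,
        totals={sl.strain_id: count_sites(sl) for sl in lists},
        category_counts={sl.strain_id: sl.category_counts() for sl in lists},
        pairwise_shared=pairwise,
        kway_shared=labels(kway),
    )


def read_site_lists(path: Union[str, Path]) -> list[SiteList]:
    """Read site lists from TSV (strain, site_label[, category])."""
    df = pd.read_csv(path, sep="\t")
    if not {"strain", "site_label"} <= set(df.columns):
        raise ValueError("site-list TSV needs columns: strain, site_label")
    out = []
    for strain, sub in df.groupby("strain", sort=True):
        sites = [
            parse_site(
                str(r.site_label),
                category=str(r.category) if "category" in df.columns and pd.notna(r.category) else "unspecified",
            )
            for r in sub.itertuples(index=False)
        ]
        out.append(SiteList(strain_id=str(strain), sites=sites))
    return out
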