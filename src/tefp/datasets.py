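"""Packaged reference datasets.

Two small reference tables from the Southern/FISH survey of I-element and
jockey copies in sublines of the sequenced *y; cn bw sp* isogenic strain of
D. melanogaster ship with the package:

* the jockey HindIII comparison — fragment sizes detected on a Southern
  filter in individual flies (kb, gel estimates) side by side with the
  fragment sizes of an in silico HindIII digest of the sequenced genome.
  The printed genomic coordinates are retained as metadata only: most rows
  span the 1,620 bp probe-homology segment rather than the fragment, and
  one row spans 97 kb (an apparent typo), so only the size columns are
  load-bearing.
* the I-element FISH site lists — cytological addresses of I-element
  hybridization sites on polytene chromosomes of the Seattle and
  Montpellier sublines and of the annotated genome ("FlyBase"), plus the
  per-strain counts of sites seen only with the 3' probe.

These fixtures let the matching, counting and comparison stages be
exercised against real published-scale data without any download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cytosites import SiteList, read_site_lists
from .vsouthern import Ladder, ObservedBand, PredictedBand

__all__ = [
    "jockey_hindiii_table",
    "jockey_observed_ladder",
    "jockey_predicted_bands",
    "fish_site_lists",
    "fish_three_prime_only_counts",
]


def _data_path(name: str):
    return resources.files("tefp.data").joinpath(name)


def jockey_hindiii_table() -> pd.DataFrame:
    """The full jockey HindIII comparison table ('ND' = not detected)."""
    with resources.as_file(_data_path("jockey_hindiii_fragments.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def jockey_observed_ladder() -> Ladder:
    """The 18 observed jockey band sizes (kb) as a single-lane ladder."""
    df = jockey_hindiii_table()
    bands = [
        ObservedBand(size_estimate=float(v), sample_id="ycnbwsp")
        for v in df["observed_kb"]
        if v != "ND"
    ]
    return Ladder(sample_id="ycnbwsp", label="jockey", bands=bands)


def jockey_predicted_bands() -> list[PredictedBand]:
    """The 18 in silico jockey fragment sizes as predicted bands (exact bp)."""
    df = jockey_hindiii_table()
    bands = []
    for i, v in enumerate(df["insilico_kb"]):
        if v == "ND":
            continue
        chrom = df["chrom"].iloc[i]
        bands.append(
            PredictedBand(
                size=round(float(v) * 1000),
                fragment_refs=((chrom if chrom != "ND" else "?", i),),
                probe_ids=frozenset({"jockey"}),
            )
        )
    bands.sort(key=lambda b: -b.size)
    return bands


def fish_site_lists() -> list[SiteList]:
    """I-element FISH site lists for Seattle, Montpellier and the annotation."""
    with resources.as_file(_data_path("i_element_fish_sites.tsv")) as p:
        return read_site_lists(p)


def fish_three_prime_only_counts() -> dict[str, int]:
    """Per-strain counts of sites seen only with the 3' probe."""
    with resources.as_file(_data_path("i_element_fish_3prime_only.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["strain"], df["three_prime_only"].astype(int)))
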