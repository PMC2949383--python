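"""Relative transcript quantification.

Two estimators of relative transcript abundance, both normalized to an
internal reference gene (G6PD in the motivating experiments) and expressed
relative to a calibrator sample:

* ``densitometry_relative`` — semi-quantitative RT-PCR in the exponential
  regime: the ethidium-bromide band area of the target amplicon is divided
  by the reference-gene area in the same lane, then by the same ratio in
  the calibrator lane.
* ``delta_delta_ct`` — the Livak 2^-ΔΔCt method for real-time PCR:
  ΔCt = mean Ct(target) - mean Ct(reference) per sample,
  ΔΔCt = ΔCt(sample) - ΔCt(calibrator), RQ = 2^-ΔΔCt, with an error range
  from the combined replicate standard deviation
  s = sqrt(sd_target^2 + sd_ref^2) as [2^-(ΔΔCt+s), 2^-(ΔΔCt-s)].
  Amplification efficiency is fixed at 100% (the exponent base 2).

Replicate Cts are averaged *before* differencing (standard Livak practice;
deterministic under unbalanced replication).

``amplicon_length`` follows the end - start convention in which a fragment
spanning primer positions 4761-5112 is 351 bp; note this is one less than
inclusive base counting would give.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "DensitometryMeasurement",
    "CtMeasurement",
    "RelativeQuantity",
    "Amplicon",
    "amplicon_length",
    "densitometry_relative",
    "delta_delta_ct",
    "read_ct_tsv",
    "read_densitometry_tsv",
]


@dataclass(frozen=True)
class Amplicon:
    """A PCR product located by its primer coordinates on a consensus."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"amplicon {self.name}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def amplicon_length(start: int, end: int) -> int:
    """Length of an amplicon spanning primer positions (end - start convention)."""
    if end <= start:
        raise ValueError(f"end ({end}) must exceed start ({start})")
    return end - start


@dataclass(frozen=True)
class DensitometryMeasurement:
    sample_id: str
    gene: str
    band_area: float

    def __post_init__(self) -> None:
        if self.band_area < 0:
            raise ValueError("band area must be non-negative")


@dataclass(frozen=True)
class CtMeasurement:
    sample_id: str
    gene: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("Ct must be positive")


@dataclass(frozen=True)
class RelativeQuantity:
    """2^-ΔΔCt output for one sample/target."""

    sample_id: str
    target: str
    rq: float
    rq_low: float
    rq_high: float
    calibrator_id: str
    delta_delta_ct: float

    def __post_init__(self) -> None:
        if self.rq <= 0:
            raise ValueError("RQ must be positive")
        if not self.rq_low <= self.rq <= self.rq_high:
            raise ValueError("RQ error range must bracket the RQ")


def _as_frame(
    measurements: Union[pd.DataFrame, Iterable], columns: Sequence[str]
) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements
    rows = [vars(m) if hasattr(m, "__dataclass_fields__") else m for m in measurements]
    if not rows:
        return pd.DataFrame(columns=list(columns))
    return pd.DataFrame(rows)[list(columns)]


def densitometry_relative(
    measurements: Union[pd.DataFrame, Iterable[DensitometryMeasurement]],
    calibrator_id: str,
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> dict[str, float]:
    """Reference-normalized band areas relative to a calibrator sample.

    rel(s) = (area_target(s)/area_ref(s)) / (area_target(cal)/area_ref(cal));
    the calibrator maps to exactly 1.0.  A zero reference area is an error
    naming the sample; the result is invariant to lane-wide multiplicative
    factors (loading differences).
    """
    df = _as_frame(measurements, ["sample_id", "gene", "band_area"])
    areas: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        areas[(str(row.sample_id), str(row.gene))] = float(row.band_area)

    samples = sorted({s for s, _ in areas})
    if calibrator_id not in samples:
        raise ValueError(f"calibrator sample {calibrator_id!r} not in measurements")

    def ratio(sample: str) -> float:
        try:
            t = areas[(sample, target_gene)]
            r = areas[(sample, reference_gene)]
        except KeyError as exc:
            raise ValueError(f"sample {sample!r} missing gene {exc.args[0][1]!r}") from None
        if r == 0:
            raise ValueError(f"zero reference area for sample {sample!r}")
        return t / r

    cal = ratio(calibrator_id)
    if cal == 0:
        raise ValueError(f"calibrator {calibrator_id!r} has zero target signal")
    out = {s: ratio(s) / cal for s in samples}
    out[calibrator_id] = 1.0
    return out


def delta_delta_ct(
    cts: Union[pd.DataFrame, Iterable[CtMeasurement]],
    target_gene: str,
    ref_gene: str,
    calibrator_id: str,
) -> list[RelativeQuantity]:
    """Livak relative quantification of one target against one reference gene.

    Requires >= 1 replicate per (sample, gene); single-replicate groups get
    sd 0.  Samples whose target was undetected (NaN Ct in every replicate)
    are omitted.  A sample missing the reference gene is an error.
    """
    df = _as_frame(cts, ["sample_id", "gene", "replicate", "ct"])
    df = df[df["gene"].isin([target_gene, ref_gene])]
    df = df.dropna(subset=["ct"])

    stats: dict[tuple[str, str], tuple[float, float]] = {}
    for (sample, gene), sub in df.groupby(["sample_id", "gene"]):
        vals = sub["ct"].astype(float).to_numpy()
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        stats[(str(sample), str(gene))] = (float(vals.mean()), sd)

    samples = sorted({s for s, _ in stats})
    for s in samples:
        if (s, ref_gene) not in stats:
            raise ValueError(f"sample {s!r} has no reference-gene ({ref_gene!r}) Ct")
    if (calibrator_id, target_gene) not in stats:
        raise ValueError(f"calibrator {calibrator_id!r} has no target Ct")

    def dct(sample: str) -> float:
        return stats[(sample, target_gene)][0] - stats[(sample, ref_gene)][0]

    dct_cal = dct(calibrator_id)
    out: list[RelativeQuantity] = []
    for s in samples:
        if (s, target_gene) not in stats:
            continue  # target undetected in this sample
        ddct = dct(s) - dct_cal
        sd = math.sqrt(stats[(s, target_gene)][1] ** 2 + stats[(s, ref_gene)][1] ** 2)
        out.append(
            RelativeQuantity(
                sample_id=s,
                target=target_gene,
                rq=2.0 ** -ddct,
                rq_low=2.0 ** -(ddct + sd),
                rq_high=2.0 ** -(ddct - sd),
                calibrator_id=calibrator_id,
                delta_delta_ct=ddct,
            )
        )
    return out


def read_ct_tsv(path) -> pd.DataFrame:
    """Read a Ct table (sample_id, gene, replicate, ct); 'ND' parses as NaN."""
    df = pd.read_csv(path, sep="\t", na_values=["ND", "nd", "undetected"])
    missing = {"sample_id", "gene", "replicate", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct TSV missing columns: {sorted(missing)}")
    return df


def read_densitometry_tsv(path) -> pd.DataFrame:
    """Read a densitometry table (sample_id, gene, band_area)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "gene", "band_area"} - set(df.columns)
    if missing:
        raise ValueError(f"densitometry TSV missing columns: {sorted(missing)}")
    return df
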