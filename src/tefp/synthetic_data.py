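"""Synthetic genomes, subline evolution, gel ladders and expression tables.

Everything the analysis stages read can be generated here with known ground
truth: a founder genome with planted multi-copy TE families, subline
individuals evolved from that founder under per-family transposition and
excision rates, noisy Southern ladders simulated from each individual's
realized genome, and densitometry / Ct tables whose relative levels encode
preset truths.

The model mirrors the biology of the motivating system:

* new retroelement (LINE) insertions are full-length with probability
  ``p_full`` and otherwise 5'-truncated — the product of incomplete
  target-primed reverse transcription — with the truncation point uniform
  and at least ``min_tail`` bp of the 3' end always retained; retroelement
  copies are never excised;
* DNA transposons (hobo-like families) can both insert and excise;
* every individual of a subline evolves independently from the same founder
  annotation, so a mobilized family produces lane-to-lane band differences
  while a quiescent family leaves the founder fingerprint untouched.

Gel noise is decomposed into a per-gel multiplicative size-calibration error
(lognormal, sd ``gel_sd``, shared by all lanes run on one filter) and a much
smaller per-band lane jitter (sd ``lane_sd``): comparisons of lanes on the
same filter are far more reproducible than absolute size estimates read
against a marker, which is exactly why individual flies are compared side by
side on one filter.

Determinism: every operation takes the scenario's master seed and derives
independent streams as ``default_rng([seed, stream, ...])``; the stream
constants are fixed (0 genome, 1 evolution, 2 gels, 3 expression), so the
same seed always reproduces the same scenario end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .probemap import Probe, TEInsertion, annotation_hits
from .seqres import (
    HINDIII,
    GenomicInterval,
    RestrictionEnzyme,
    SequenceRecord,
    digest_genome,
)
from .vsouthern import Ladder, ObservedBand, predict_bands

__all__ = [
    "FamilyModel",
    "GroupConfig",
    "ScenarioConfig",
    "SyntheticGenome",
    "PlantedCopy",
    "make_genome",
    "evolve_individuals",
    "realize",
    "default_probes",
    "simulate_ladders",
    "simulate_scenario_ladders",
    "simulate_expression",
    "three_subline_scenario",
    "ADULT_FEMALE_LEVELS",
    "GONAD_LEVELS",
    "EXPRESSION_PRESETS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FamilyModel:
    """Transposition model of one TE family.

    Rates are events per genome per generation.  ``p_full`` is the
    probability that a new copy is full-length; otherwise its 5' end is
    truncated at a uniform consensus position in [1, L - min_tail].
    Only ``excisable`` (DNA-transposon) families ever lose copies.
    """

    name: str
    consensus_length: int
    insertion_rate: float = 0.0
    excision_rate: float = 0.0
    p_full: float = 1.0
    min_tail: int = 500
    excisable: bool = False

    def __post_init__(self) -> None:
        if self.insertion_rate < 0 or self.excision_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.p_full <= 1.0:
            raise ValueError("p_full must lie in [0, 1]")
        if self.min_tail >= self.consensus_length:
            raise ValueError("min_tail must be smaller than the consensus length")


@dataclass(frozen=True)
class GroupConfig:
    """One subline: its size and per-family rate overrides."""

    name: str
    n_individuals: int = 5
    insertion_rates: dict[str, float] = field(default_factory=dict)
    excision_rates: dict[str, float] = field(default_factory=dict)


@dataclass
class ScenarioConfig:
    """Full description of a simulated study; reproducible under ``seed``."""

    chrom_lengths: dict[str, int]
    families: list[FamilyModel]
    planted_copies: dict[str, int]
    groups: list[GroupConfig]
    generations: int = 10
    gc: float = 0.42
    enzyme: RestrictionEnzyme = HINDIII
    gel_sd: float = 0.02
    lane_sd: float = 0.002
    detection_window: tuple[float, float] = (1.5, 12.0)
    min_copy_spacing: int = 13_000
    seed: int = 0

    def family(self, name: str) -> FamilyModel:
        for f in self.families:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass(frozen=True)
class PlantedCopy:
    """One TE copy, located by its insertion point in background coordinates."""

    copy_id: str
    chrom: str
    bg_pos: int
    family: str
    consensus_span: tuple[int, int]
    strand: str
    seq: str

    @property
    def completeness(self) -> str:
        return "full" if self.consensus_span[0] == 0 else "five_prime_truncated"


@dataclass
class SyntheticGenome:
    """Background chromosomes plus founder TE copies and family consensi."""

    background: dict[str, str]
    consensi: dict[str, str]
    founder_copies: list[PlantedCopy]
    config: ScenarioConfig


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode("ascii")


def _place_positions(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n: int,
    taken: dict[str, list[int]],
    min_gap: int,
    max_retries: int = 1000,
) -> list[tuple[str, int]]:
    """Uniform insertion points keeping ``min_gap`` bp from existing points.

    The spacing (default just above the gel detection limit) guarantees that
    no two TE copies can share a *visible* restriction fragment, so that a
    scaled-down genome does not manufacture fragment linkage between
    families that would be vanishingly rare at real genome scale.
    """
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[tuple[str, int]] = []
    for _ in range(n):
        for attempt in range(max_retries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            pos = int(rng.integers(0, chrom_lengths[chrom]))
            if all(abs(pos - q) >= min_gap for q in taken.get(chrom, [])):
                taken.setdefault(chrom, []).append(pos)
                out.append((chrom, pos))
                break
        else:
            raise RuntimeError(
                f"could not place a TE copy without overlap after {max_retries} retries"
            )
    return out


def _new_copy(
    rng: np.random.Generator,
    family: FamilyModel,
    consensus: str,
    copy_id: str,
    chrom: str,
    pos: int,
    force_full: bool = False,
) -> PlantedCopy:
    L = family.consensus_length
    if force_full or rng.random() < family.p_full:
        span = (0, L)
    else:
        start = int(rng.integers(1, L - family.min_tail + 1))
        span = (start, L)
    strand = "+" if rng.random() < 0.5 else "-"
    seg = consensus[span[0] : span[1]]
    return PlantedCopy(
        copy_id=copy_id,
        chrom=chrom,
        bg_pos=pos,
        family=family.name,
        consensus_span=span,
        strand=strand,
        seq=seg if strand == "+" else _revcomp(seg),
    )


def make_genome(config: ScenarioConfig) -> SyntheticGenome:
    """Random background with planted full-length founder copies.

    The background must be at least 10x the total planted TE length; copies
    are placed without overlap (bounded retries, then error) and the
    annotation records family, consensus span and completeness.
    """
    rng = np.random.default_rng([config.seed, 0])
    consensi = {
        f.name: _random_dna(rng, f.consensus_length, config.gc)
        for f in config.families
    }
    total_te = sum(
        config.planted_copies.get(f.name, 0) * f.consensus_length
        for f in config.families
    )
    genome_len = sum(config.chrom_lengths.values())
    if total_te and genome_len < 10 * total_te:
        raise ValueError(
            f"genome length {genome_len} < 10x total planted TE length {total_te}"
        )
    background = {
        name: _random_dna(rng, length, config.gc)
        for name, length in config.chrom_lengths.items()
    }
    taken: dict[str, list[int]] = {}
    copies: list[PlantedCopy] = []
    for fam in config.families:
        n = config.planted_copies.get(fam.name, 0)
        for k, (chrom, pos) in enumerate(
            _place_positions(rng, config.chrom_lengths, n, taken, config.min_copy_spacing)
        ):
            copies.append(
                _new_copy(
                    rng, fam, consensi[fam.name],
                    copy_id=f"{fam.name}_f{k}", chrom=chrom, pos=pos,
                    force_full=True,
                )
            )
    return SyntheticGenome(background, consensi, copies, config)


def realize(
    genome: SyntheticGenome, copies: Sequence[PlantedCopy]
) -> tuple[list[SequenceRecord], list[TEInsertion]]:
    """Splice TE copies into the background and return sequence + annotation.

    Copies are inserted at their background positions; final genomic
    coordinates account for all insertions upstream on the same chromosome.
    """
    records: list[SequenceRecord] = []
    insertions: list[TEInsertion] = []
    by_chrom: dict[str, list[PlantedCopy]] = {}
    for c in copies:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, bg in genome.background.items():
        parts: list[str] = []
        cursor = 0
        offset = 0
        for copy in sorted(by_chrom.get(chrom, []), key=lambda c: (c.bg_pos, c.copy_id)):
            parts.append(bg[cursor : copy.bg_pos])
            start = copy.bg_pos + offset
            parts.append(copy.seq)
            insertions.append(
                TEInsertion(
                    family=copy.family,
                    genomic=GenomicInterval(chrom, start, start + len(copy.seq), copy.strand),
                    consensus_span=copy.consensus_span,
                    completeness=copy.completeness,
                )
            )
            offset += len(copy.seq)
            cursor = copy.bg_pos
        parts.append(bg[cursor:])
        records.append(SequenceRecord(id=chrom, residues="".join(parts)))
    return records, insertions


def evolve_individuals(
    genome: SyntheticGenome, config: ScenarioConfig | None = None
) -> dict[str, list[list[PlantedCopy]]]:
    """Evolve each group's individuals independently from the founder.

    Per generation and mobilized family, a Poisson number of new insertions
    lands uniformly on the background (full-length with probability
    ``p_full``, else 5'-truncated) and, for excisable families, a Poisson
    number of existing copies excises.  Deterministic under the seed.
    """
    config = config or genome.config
    out: dict[str, list[list[PlantedCopy]]] = {}
    for g_idx, group in enumerate(config.groups):
        individuals: list[list[PlantedCopy]] = []
        for i in range(group.n_individuals):
            rng = np.random.default_rng([config.seed, 1, g_idx, i])
            copies = list(genome.founder_copies)
            taken = {c.chrom: [c.bg_pos] for c in copies}
            for c in copies:
                taken.setdefault(c.chrom, [])
                if c.bg_pos not in taken[c.chrom]:
                    taken[c.chrom].append(c.bg_pos)
            n_new = 0
            for gen in range(config.generations):
                for fam in config.families:
                    ins_rate = group.insertion_rates.get(fam.name, fam.insertion_rate)
                    exc_rate = group.excision_rates.get(fam.name, fam.excision_rate)
                    for _ in range(rng.poisson(ins_rate)):
                        (chrom, pos), = _place_positions(
                            rng, config.chrom_lengths, 1, taken,
                            config.min_copy_spacing,
                        )
                        copies.append(
                            _new_copy(
                                rng, fam, genome.consensi[fam.name],
                                copy_id=f"{fam.name}_{group.name}{i}_n{n_new}",
                                chrom=chrom, pos=pos,
                            )
                        )
                        n_new += 1
                    if fam.excisable and exc_rate > 0:
                        for _ in range(rng.poisson(exc_rate)):
                            idx = [k for k, c in enumerate(copies) if c.family == fam.name]
                            if idx:
                                copies.pop(idx[int(rng.integers(len(idx)))])
            individuals.append(copies)
        out[group.name] = individuals
    return out


def default_probes(genome: SyntheticGenome) -> dict[str, list[Probe]]:
    """Per-family probe sets.

    The I-element-like family (any family named 'I') gets separate 5'
    (consensus 0-1800) and 3' (consensus 3600-end) probes — the pair whose
    disagreement flags 5'-truncated copies; every other family gets one
    internal probe spanning most of its consensus.
    """
    probes: dict[str, list[Probe]] = {}
    for fam, consensus in genome.consensi.items():
        L = len(consensus)
        if fam == "I":
            probes[fam] = [
                Probe("I_5p", fam, (0, min(1800, L)), consensus[0 : min(1800, L)]),
                Probe("I_3p", fam, (max(0, 3600), L), consensus[3600:L]),
            ]
        else:
            lo, hi = min(200, L // 10), L - min(200, L // 10)
            probes[fam] = [Probe(f"{fam}_int", fam, (lo, hi), consensus[lo:hi])]
    return probes


def simulate_ladders(
    genome: SyntheticGenome,
    copies: Sequence[PlantedCopy],
    sample_id: str,
    group: str | None = None,
    probes: dict[str, list[Probe]] | None = None,
    rng: np.random.Generator | None = None,
    gel_factors: dict[str, float] | None = None,
) -> list[Ladder]:
    """Simulated observed ladders (one per family) for one individual.

    Runs the real pipeline — digest, annotation probe mapping, band
    prediction — on the realized genome, then applies multiplicative noise
    (per-gel calibration factor x per-band lane jitter), drops bands outside
    the detection window, and rounds to 2 decimals in kb.
    """
    cfg = genome.config
    probes = probes or default_probes(genome)
    rng = rng if rng is not None else np.random.default_rng([cfg.seed, 2])
    gel_factors = gel_factors if gel_factors is not None else {f: 1.0 for f in probes}
    records, insertions = realize(genome, copies)
    fragments = digest_genome(records, cfg.enzyme)
    lo, hi = cfg.detection_window
    ladders: list[Ladder] = []
    for family in sorted(probes):
        hits = []
        for probe in probes[family]:
            hits.extend(annotation_hits(insertions, probe))
        bands = predict_bands(fragments, hits)
        observed: list[ObservedBand] = []
        for band in bands:
            # the detection window acts on the band's mobility on the shared
            # filter (gel-calibrated size), so all lanes agree on visibility
            filter_kb = band.size / 1000.0 * gel_factors[family]
            if not lo <= filter_kb <= hi:
                continue
            jitter = float(np.exp(rng.normal(0.0, cfg.lane_sd))) if cfg.lane_sd else 1.0
            size_kb = round(filter_kb * jitter, 2)
            observed.append(ObservedBand(size_estimate=size_kb, sample_id=sample_id))
        ladders.append(Ladder(sample_id=sample_id, label=family, bands=observed, group=group))
    return ladders


def simulate_scenario_ladders(
    genome: SyntheticGenome, config: ScenarioConfig | None = None
) -> pd.DataFrame:
    """Evolve all individuals and simulate every lane; tidy ladder table.

    One gel (filter) per family: all individuals share that family's
    calibration factor, as they would on a single filter.  Columns:
    sample_id, group, family, size_kb.
    """
    config = config or genome.config
    probes = default_probes(genome)
    gel_rng = np.random.default_rng([config.seed, 2])
    gel_factors = {
        f: float(np.exp(gel_rng.normal(0.0, config.gel_sd))) if config.gel_sd else 1.0
        for f in sorted(probes)
    }
    evolved = evolve_individuals(genome, config)
    rows = []
    for g_idx, group in enumerate(config.groups):
        for i, copies in enumerate(evolved[group.name]):
            sample = f"{group.name}{i + 1}"
            lane_rng = np.random.default_rng([config.seed, 2, 1, g_idx, i])
            for ladder in simulate_ladders(
                genome, copies, sample, group.name, probes, lane_rng, gel_factors
            ):
                for band in ladder.bands:
                    rows.append((sample, group.name, ladder.label, band.size_estimate))
    return pd.DataFrame(rows, columns=["sample_id", "group", "family", "size_kb"])


def three_subline_scenario(seed: int = 0) -> ScenarioConfig:
    """The three-subline study scenario.

    Three groups of 5 individuals emulate the Bari/Seattle/Montpellier
    sublines of an isogenic inducer strain: jockey is quiescent everywhere,
    the I element mobilizes only in group M (new copies mostly
    5'-truncated), and the DNA transposon hobo inserts and excises in all
    three groups.  Transposition rates are arbitrary, chosen only so that
    within-group heterogeneity is detectable with 5 individuals over 10
    generations.
    """
    families = [
        FamilyModel("jockey", 5019),
        FamilyModel("I", 5371, insertion_rate=0.0, p_full=0.2),
        FamilyModel("hobo", 2959, insertion_rate=0.3, excision_rate=0.15, excisable=True),
    ]
    groups = [
        GroupConfig("B", 5),
        GroupConfig("S", 5),
        GroupConfig("M", 5, insertion_rates={"I": 0.6}),
    ]
    return ScenarioConfig(
        chrom_lengths={"chr2L": 700_000, "chr2R": 700_000, "chr3L": 600_000},
        families=families,
        planted_copies={"jockey": 6, "I": 8, "hobo": 4},
        groups=groups,
        generations=10,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# expression presets

#: Relative transcript levels in adult females (semi-quantitative RT-PCR):
#: Montpellier defines 1.0; the reactive JA strain has no 5' or internal
#: I transcripts (its copies lost those portions) but retains some 3' signal.
ADULT_FEMALE_LEVELS: dict[str, dict[str, float]] = {
    "I5": {"Montpellier": 1.0, "Seattle": 0.30, "JA": 0.0},
    "Im": {"Montpellier": 1.0, "Seattle": 0.40, "JA": 0.0},
    "I3": {"Montpellier": 1.0, "Seattle": 0.50, "JA": 0.20},
}

#: Relative transcript levels in gonads (real-time PCR), calibrated to Bari:
#: Montpellier highest for both ends; dysgenic crosses intermediate, with the
#: I3 ratio of the Montpellier-sired to the Seattle-sired dysgenic gonads
#: fixed at 2.5; the reactive JA strain and the non-dysgenic cross lowest.
GONAD_LEVELS: dict[str, dict[str, float]] = {
    "I5": {
        "Bari_gonads": 1.0,
        "Seattle_gonads": 1.0,
        "Montpellier_gonads": 8.0,
        "JA_gonads": 0.1,
        "nondysgenic_gonads": 0.1,
        "dysgenic_S_gonads": 2.0,
        "dysgenic_M_gonads": 3.0,
    },
    "I3": {
        "Bari_gonads": 1.0,
        "Seattle_gonads": 0.8,
        "Montpellier_gonads": 6.0,
        "JA_gonads": 0.05,
        "nondysgenic_gonads": 0.2,
        "dysgenic_S_gonads": 1.2,
        "dysgenic_M_gonads": 3.0,
    },
}

EXPRESSION_PRESETS: dict[str, dict[str, dict[str, float]]] = {
    "adult_females": ADULT_FEMALE_LEVELS,
    "gonads": GONAD_LEVELS,
}

REFERENCE_GENE = "G6PD"
_CT_BASE_TARGET = 24.0
_CT_BASE_REF = 18.0


def simulate_expression(
    preset: str = "gonads",
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    dens_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct and densitometry tables whose relative levels encode a preset truth.

    Ct(sample, target) = base - log2(level) + Normal(0, ct_noise_sd), with
    the reference gene flat across samples; a zero-level target is emitted
    as an undetected (NaN) Ct.  Densitometry band areas are proportional to
    level x a per-sample lane loading factor (x lognormal noise when
    ``dens_noise_sd`` > 0), so reference-normalized ratios recover the
    preset levels exactly at zero noise.
    """
    if preset not in EXPRESSION_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; known: {sorted(EXPRESSION_PRESETS)}")
    levels = EXPRESSION_PRESETS[preset]
    rng = np.random.default_rng([seed, 3])
    samples = sorted({s for gene_levels in levels.values() for s in gene_levels})

    ct_rows = []
    for sample in samples:
        for rep in range(n_replicates):
            ct_rows.append(
                (sample, REFERENCE_GENE, rep,
                 _CT_BASE_REF + rng.normal(0.0, ct_noise_sd))
            )
        for gene in sorted(levels):
            level = levels[gene].get(sample)
            if level is None:
                continue
            for rep in range(n_replicates):
                if level == 0.0:
                    ct_rows.append((sample, gene, rep, np.nan))
                else:
                    ct_rows.append(
                        (sample, gene, rep,
                         _CT_BASE_TARGET - np.log2(level) + rng.normal(0.0, ct_noise_sd))
                    )
    ct_df = pd.DataFrame(ct_rows, columns=["sample_id", "gene", "replicate", "ct"])

    dens_rows = []
    for sample in samples:
        lane = float(rng.uniform(0.8, 1.25))
        noise = float(np.exp(rng.normal(0.0, dens_noise_sd))) if dens_noise_sd else 1.0
        dens_rows.append((sample, REFERENCE_GENE, 100.0 * lane * noise))
        for gene in sorted(levels):
            level = levels[gene].get(sample)
            if level is None:
                continue
            noise = float(np.exp(rng.normal(0.0, dens_noise_sd))) if dens_noise_sd else 1.0
            dens_rows.append((sample, gene, 100.0 * level * lane * noise))
    dens_df = pd.DataFrame(dens_rows, columns=["sample_id", "gene", "band_area"])
    return ct_df, dens_df
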