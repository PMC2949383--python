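"""Locate probe-homologous segments of a genome.

A Southern probe lights up a restriction fragment only if the fragment
carries enough sequence homologous to the probe.  This module finds those
homologous segments in two ways:

* **annotation mode** (`annotation_hits`): from a transposable-element
  insertion annotation in which every copy records which slice of the family
  consensus it retains (its ``consensus_span``).  A probe defined as an
  interval on the same consensus hits a copy iff the two intervals overlap
  by at least ``min_overlap``.  This is the mode the synthetic-genome
  pipeline uses, and it makes 5'-truncation directly consequential: a copy
  missing the consensus 5' end is invisible to a 5' probe.

* **sequence mode** (`sequence_hits`): by direct ungapped k-mer seeded
  search of the probe sequence against the genome, both strands, for use
  when no annotation exists.

The I element of D. melanogaster is the motivating family: full copies are
~5.4 kb and retrotransposition generates 5'-truncated copies, so 5' and 3'
probes of the same element can disagree — the signature this package
quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .seqres import GenomicInterval, SequenceRecord

__all__ = [
    "Probe",
    "TEInsertion",
    "ProbeHit",
    "DEFAULT_MIN_OVERLAP",
    "load_insertions",
    "write_insertions_bed",
    "load_probes",
    "annotation_hits",
    "sequence_hits",
    "write_hits_bed",
]

#: Minimum probe/target duplex, in bp, for a hybridization signal.
DEFAULT_MIN_OVERLAP = 100

COMPLETENESS_VALUES = ("full", "five_prime_truncated", "internal_deleted")


@dataclass(frozen=True)
class Probe:
    """A hybridization probe defined on a TE family consensus.

    ``consensus_interval`` is the 0-based half-open slice of the family
    consensus the probe covers; ``sequence`` is optional and only needed for
    sequence-mode search.
    """

    probe_id: str
    family: str
    consensus_interval: tuple[int, int]
    sequence: str | None = None

    def __post_init__(self) -> None:
        s, e = self.consensus_interval
        if not 0 <= s < e:
            raise ValueError(f"invalid consensus interval ({s}, {e}) for {self.probe_id}")


@dataclass(frozen=True)
class TEInsertion:
    """One genomic copy of a TE family.

    ``consensus_span`` records which part of the family consensus the copy
    retains; a 5'-truncated copy has span start > 0.
    """

    family: str
    genomic: GenomicInterval
    consensus_span: tuple[int, int]
    completeness: str = "full"

    def __post_init__(self) -> None:
        s, e = self.consensus_span
        if not 0 <= s < e:
            raise ValueError(f"invalid consensus span ({s}, {e})")
        if self.completeness not in COMPLETENESS_VALUES:
            raise ValueError(f"invalid completeness {self.completeness!r}")
        if self.completeness == "five_prime_truncated" and s == 0:
            raise ValueError("a 5'-truncated insertion must have consensus span start > 0")


@dataclass(frozen=True)
class ProbeHit:
    """A probe-homologous genomic segment."""

    probe_id: str
    genomic: GenomicInterval
    matched_length: int
    identity: float

    def __post_init__(self) -> None:
        if self.matched_length > self.genomic.length:
            raise ValueError("matched_length exceeds hit interval length")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")


# ---------------------------------------------------------------------------
# annotation I/O


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def load_insertions(
    path: Union[str, Path],
    fmt: str | None = None,
    family_field: str = "family",
) -> list[TEInsertion]:
    """Read TE insertions from BED or GFF3, normalized to 0-based half-open.

    BED dialect (native 0-based half-open), tab-separated::

        chrom  start  end  family  [score  strand  cons_start  cons_end  completeness]

    GFF3 records are converted from 1-based inclusive; the family and
    optional consensus span / completeness are read from the attribute keys
    ``family_field``, ``consensus_start``, ``consensus_end``, ``completeness``.

    Records missing a consensus span get span ``(0, genomic length)`` with
    completeness ``full``.  Malformed records raise with their line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    insertions: list[TEInsertion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    ins = _insertion_from_bed(fields)
                else:
                    ins = _insertion_from_gff3(fields, family_field)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
            insertions.append(ins)
    return insertions


def _insertion_from_bed(fields: Sequence[str]) -> TEInsertion:
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    family = fields[3] if len(fields) > 3 else "unknown"
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
    genomic = GenomicInterval(chrom, start, end, strand)
    if len(fields) > 7:
        span = (int(fields[6]), int(fields[7]))
        completeness = fields[8] if len(fields) > 8 else (
            "five_prime_truncated" if span[0] > 0 else "full"
        )
    else:
        span = (0, genomic.length)
        completeness = "full"
    return TEInsertion(family=family, genomic=genomic, consensus_span=span, completeness=completeness)


def _insertion_from_gff3(fields: Sequence[str], family_field: str) -> TEInsertion:
    if len(fields) < 9:
        raise ValueError(f"expected 9 GFF3 columns, got {len(fields)}")
    chrom = fields[0]
    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
    end = int(fields[4])
    strand = fields[6] if fields[6] in "+-" else "."
    attrs = _parse_gff3_attributes(fields[8])
    family = attrs.get(family_field) or attrs.get("Name") or fields[2]
    genomic = GenomicInterval(chrom, start, end, strand)
    if "consensus_start" in attrs and "consensus_end" in attrs:
        span = (int(attrs["consensus_start"]), int(attrs["consensus_end"]))
        completeness = attrs.get(
            "completeness", "five_prime_truncated" if span[0] > 0 else "full"
        )
    else:
        span = (0, genomic.length)
        completeness = "full"
    return TEInsertion(family=family, genomic=genomic, consensus_span=span, completeness=completeness)


def write_insertions_bed(insertions: Iterable[TEInsertion], path: Union[str, Path]) -> None:
    """Write insertions in the package's BED dialect (9 columns)."""
    with open(path, "w") as fh:
        for ins in insertions:
            g = ins.genomic
            fh.write(
                f"{g.seq_id}\t{g.start}\t{g.end}\t{ins.family}\t0\t{g.strand}"
                f"\t{ins.consensus_span[0]}\t{ins.consensus_span[1]}\t{ins.completeness}\n"
            )


def load_probes(tsv_path: Union[str, Path], fasta_path: Union[str, Path] | None = None) -> list[Probe]:
    """Read probe definitions from TSV (probe_id, family, consensus_start, consensus_end).

    If ``fasta_path`` is given, sequences with matching ids are attached.
    """
    df = pd.read_csv(tsv_path, sep="\t")
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        from Bio import SeqIO

        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    probes = []
    for row in df.itertuples(index=False):
        probes.append(
            Probe(
                probe_id=str(row.probe_id),
                family=str(row.family),
                consensus_interval=(int(row.consensus_start), int(row.consensus_end)),
                sequence=seqs.get(str(row.probe_id)),
            )
        )
    return probes


# ---------------------------------------------------------------------------
# annotation mode


def annotation_hits(
    insertions: Iterable[TEInsertion],
    probe: Probe,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[ProbeHit]:
    """Probe hits derived from an insertion annotation.

    An insertion yields a hit iff its consensus span overlaps the probe's
    consensus interval by >= ``min_overlap`` bp.  The hit's genomic interval
    is the insertion's genomic sub-interval corresponding to the overlapped
    consensus segment (linear mapping, strand-aware); identity is 1.0 in
    annotation mode.
    """
    ps, pe = probe.consensus_interval
    hits: list[ProbeHit] = []
    for ins in insertions:
        if ins.family != probe.family:
            continue
        cs, ce = ins.consensus_span
        lo, hi = max(cs, ps), min(ce, pe)
        if hi - lo < min_overlap:
            continue
        g = ins.genomic
        scale = g.length / (ce - cs)
        if g.strand == "-":
            gstart = g.end - round((hi - cs) * scale)
            gend = g.end - round((lo - cs) * scale)
        else:
            gstart = g.start + round((lo - cs) * scale)
            gend = g.start + round((hi - cs) * scale)
        hits.append(
            ProbeHit(
                probe_id=probe.probe_id,
                genomic=GenomicInterval(g.seq_id, gstart, gend, g.strand),
                matched_length=hi - lo,
                identity=1.0,
            )
        )
    hits.sort(key=lambda h: (h.genomic.seq_id, h.genomic.start))
    return hits


# ---------------------------------------------------------------------------
# sequence mode

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def sequence_hits(
    genome: Iterable[SequenceRecord],
    probe: Probe,
    k: int = 12,
    min_len: int = 50,
    min_identity: float = 0.85,
) -> list[ProbeHit]:
    """Ungapped k-mer seeded search of the probe sequence against both strands.

    Exact k-mer seeds anchor diagonals; each diagonal is scored by aligning
    the full probe ungapped at that offset, then trimmed of terminal
    mismatches.  Overlapping candidates are resolved by keeping the longer,
    then the leftmost.  Hits shorter than ``min_len`` or below
    ``min_identity`` are dropped; output is sorted by (seq_id, start).
    """
    if probe.sequence is None:
        raise ValueError(f"probe {probe.probe_id} has no sequence for sequence mode")
    pseq = probe.sequence.upper()
    if len(pseq) < min_len:
        raise ValueError("probe sequence shorter than min_len")

    # index probe k-mers
    kmer_pos: dict[str, list[int]] = {}
    for i in range(len(pseq) - k + 1):
        kmer_pos.setdefault(pseq[i : i + k], []).append(i)

    candidates: list[ProbeHit] = []
    for rec in genome:
        for strand in ("+", "-"):
            target = rec.residues if strand == "+" else _revcomp(rec.residues)
            seen_diagonals: set[int] = set()
            for j in range(len(target) - k + 1):
                positions = kmer_pos.get(target[j : j + k])
                if not positions:
                    continue
                for qi in positions:
                    diag = j - qi  # genome offset of probe position 0
                    if diag in seen_diagonals:
                        continue
                    seen_diagonals.add(diag)
                    hit = _score_diagonal(
                        probe.probe_id, rec.id, target, pseq, diag, strand,
                        min_len, min_identity,
                    )
                    if hit is not None:
                        candidates.append(hit)

    # overlap resolution: longer wins, then leftmost
    candidates.sort(key=lambda h: (-h.genomic.length, h.genomic.seq_id, h.genomic.start))
    accepted: list[ProbeHit] = []
    for cand in candidates:
        if all(cand.genomic.overlap(a.genomic) == 0 for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda h: (h.genomic.seq_id, h.genomic.start))
    return accepted


def _score_diagonal(
    probe_id: str,
    seq_id: str,
    target: str,
    pseq: str,
    diag: int,
    strand: str,
    min_len: int,
    min_identity: float,
) -> ProbeHit | None:
    g0 = max(diag, 0)
    g1 = min(diag + len(pseq), len(target))
    if g1 - g0 < min_len:
        return None
    matches = [target[g] == pseq[g - diag] for g in range(g0, g1)]
    # trim terminal mismatches
    lo, hi = 0, len(matches)
    while lo < hi and not matches[lo]:
        lo += 1
    while hi > lo and not matches[hi - 1]:
        hi -= 1
    length = hi - lo
    if length < min_len:
        return None
    n_match = sum(matches[lo:hi])
    identity = n_match / length
    if identity < min_identity:
        return None
    start, end = g0 + lo, g0 + hi
    if strand == "-":
        start, end = len(target) - end, len(target) - start
    return ProbeHit(
        probe_id=probe_id,
        genomic=GenomicInterval(seq_id, start, end, strand),
        matched_length=length,
        identity=identity,
    )


def write_hits_bed(hits: Iterable[ProbeHit], path: Union[str, Path]) -> None:
    """Write probe hits as BED with the probe id in the name column."""
    with open(path, "w") as fh:
        for h in hits:
            g = h.genomic
            fh.write(
                f"{g.seq_id}\t{g.start}\t{g.end}\t{h.probe_id}\t"
                f"{h.identity:.3f}\t{g.strand}\n"
            )
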