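"""3'READS-style poly(A)-site calling with the internal-priming filter.

Reverse transcription through the poly(A) tail leaves a 5' T-stretch on
the R1 read.  The pipeline counts and trims those Ts, maps the next
17 bases exactly and uniquely to the genome (either strand), and keeps a
read only when its T count exceeds the number of genomically encoded As
immediately downstream of the mapped position — otherwise the "tail"
could be templated by the genome (internal priming).  Retained reads
accumulate into single-nucleotide poly(A) site counts at the last
templated base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio import SeqIO

from .annotations_io import GenomeSequence, SiteKey, revcomp
from .synthetic_data import downstream_a_run

logger = logging.getLogger(__name__)

KMER = 17


@dataclass(frozen=True)
class TTrimmedRead:
    """An R1 read after 5' T counting and trimming."""

    read_id: str  # original id with ":T<t_count>" appended
    t_count: int
    seq: str      # trimmed sequence; first 17 nt are used for mapping

    def __post_init__(self) -> None:
        if self.t_count < 1:
            raise ValueError("t_count must be >= 1 (read began with T)")


@dataclass(frozen=True)
class MappedPolyARead:
    read: TTrimmedRead
    chrom: str
    strand: str          # transcript sense strand
    pos: int             # genomic coordinate of the last templated base
    downstream_a_run: int

    @property
    def retained(self) -> bool:
        """True if the T-stretch cannot be fully genome-templated."""
        return self.read.t_count > self.downstream_a_run


def count_leading_t(seq: str) -> int:
    n = 0
    for ch in seq:
        if ch != "T":
            break
        n += 1
    return n


def preprocess_3reads(
    records: Iterable[Tuple[str, str]] | str | Path,
) -> Tuple[List[TTrimmedRead], Dict[str, int]]:
    """Count/trim 5' Ts from R1 reads.

    Accepts a FASTQ path or an iterable of (id, sequence) pairs.  Reads
    that do not begin with T, or that retain fewer than 17 nt after
    trimming, are discarded; the returned stats report both counts.
    """
    if isinstance(records, (str, Path)):
        records = (
            (rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(records), "fastq")
        )
    out: List[TTrimmedRead] = []
    stats = {"kept": 0, "no_leading_t": 0, "too_short": 0}
    for rid, seq in records:
        t = count_leading_t(seq)
        if t == 0:
            stats["no_leading_t"] += 1
            continue
        trimmed = seq[t:]
        if len(trimmed) < KMER:
            stats["too_short"] += 1
            continue
        out.append(TTrimmedRead(read_id=f"{rid}:T{t}", t_count=t, seq=trimmed))
        stats["kept"] += 1
    return out, stats


class KmerIndex:
    """Exact-match index of all genomic 17-mers (top strand positions).

    Stands in for a short-read aligner run with zero mismatches and
    unique-hit filtering; adequate for the synthetic genomes this package
    targets.  Matches on both strands are found by also looking up the
    reverse complement of the query.
    """

    def __init__(self, genome: GenomeSequence, k: int = KMER) -> None:
        self.k = k
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in genome.seqs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def lookup(self, kmer: str) -> List[Tuple[str, int]]:
        return self._index.get(kmer, [])


def map_17mer(
    read: TTrimmedRead,
    genome: GenomeSequence,
    index: KmerIndex | None = None,
) -> MappedPolyARead | None:
    """Map the first 17 trimmed bases; None unless exactly one genome hit.

    The read is the reverse complement of the transcript's 3' end, so its
    reverse complement is matched against the top strand (plus-strand
    transcripts) and the read itself against the top strand (minus-strand
    transcripts).  The mapped position is the transcript-sense 3'-most
    templated base.
    """
    if len(read.seq) < KMER:
        return None
    if index is None:
        index = KmerIndex(genome)
    query = read.seq[:KMER]
    sense = revcomp(query)
    plus_hits = index.lookup(sense)       # sense 17-mer on top strand
    minus_hits = index.lookup(query)      # revcomp(sense) on top strand
    n_hits = len(plus_hits) + len(minus_hits)
    if n_hits != 1:
        return None
    if plus_hits:
        chrom, start = plus_hits[0]
        strand, pos = "+", start + KMER - 1
    else:
        chrom, start = minus_hits[0]
        strand, pos = "-", start
    return MappedPolyARead(
        read=read, chrom=chrom, strand=strand, pos=pos,
        downstream_a_run=downstream_a_run(genome, chrom, strand, pos),
    )


def map_reads(
    reads: Sequence[TTrimmedRead], genome: GenomeSequence
) -> Tuple[List[MappedPolyARead], int]:
    """Map many reads against one shared index; returns (mapped, unmapped count)."""
    index = KmerIndex(genome)
    mapped: List[MappedPolyARead] = []
    unmapped = 0
    for read in reads:
        m = map_17mer(read, genome, index)
        if m is None:
            unmapped += 1
        else:
            mapped.append(m)
    return mapped, unmapped


def call_polya_sites(
    mapped_reads: Iterable[MappedPolyARead],
) -> Tuple[Dict[SiteKey, int], Dict[str, int]]:
    """Accumulate retained reads into per-nucleotide site counts.

    A read is retained iff t_count strictly exceeds the genomic A-run
    immediately downstream of its mapped position; retained reads add to
    the count at (chrom, strand, last templated base).
    """
    sites: Dict[SiteKey, int] = {}
    stats = {"retained": 0, "internal_priming": 0}
    for m in mapped_reads:
        if m.retained:
            key = (m.chrom, m.strand, m.pos)
            sites[key] = sites.get(key, 0) + 1
            stats["retained"] += 1
        else:
            stats["internal_priming"] += 1
    return sites, stats
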