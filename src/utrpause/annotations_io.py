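"""Genomes, transcription units, coverage tracks and poly(A) profiles.

One coordinate convention is used throughout the package:

* genomic coordinates are 0-based half-open, as in BED;
* transcript-relative positions are 0-based with position 0 being the
  first nucleotide downstream of the stop codon, increasing in the
  direction of transcription (so on the minus strand, increasing relative
  position means decreasing genomic coordinate);
* "upstream"/"downstream" always refer to the direction of transcription.

Figures rendered from these data that count "1 to 400 nt downstream"
correspond to relative positions 0..399 with a +1 display offset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# IUPAC ambiguity codes other than N are collapsed to N on load.
_IUPAC_AMBIG = set("RYSWKMBDHV")
_VALID_BASES = set("ACGTN")

Strand = str  # "+" or "-"
SiteKey = Tuple[str, Strand, int]  # (chrom, strand, 0-based position)


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """In-memory genome: chromosome name -> upper-case sequence string."""

    seqs: Mapping[str, str]

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(s) for name, s in self.seqs.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: Strand = "+") -> str:
        """Sequence of [start, end); minus strand returns the reverse complement."""
        seq = self.seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"interval [{start}, {end}) outside {chrom} [0, {len(seq)})"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub

    def base(self, chrom: str, pos: int, strand: Strand = "+") -> str:
        return self.fetch(chrom, pos, pos + 1, strand)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_genome(fasta_path: str | Path) -> GenomeSequence:
    """Read a FASTA genome, upper-casing bases and validating the alphabet.

    Duplicate record names and non-IUPAC characters raise ``ValueError``.
    IUPAC ambiguity codes other than N are stored as N.
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r}")
        bad = set(seq) - _VALID_BASES - _IUPAC_AMBIG
        if bad:
            raise ValueError(f"non-IUPAC characters {sorted(bad)} in {rec.id!r}")
        if set(seq) & _IUPAC_AMBIG:
            seq = re.sub(f"[{''.join(_IUPAC_AMBIG)}]", "N", seq)
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return GenomeSequence(seqs)


@dataclass(frozen=True)
class TranscriptionUnit:
    """A stranded gene interval with a stop-codon anchor and a 3'UTR window.

    ``stop_codon_ref`` is stored as the half-open boundary between the gene
    body and the 3'UTR window: on the plus strand it is the genomic
    coordinate of relative position 0; on the minus strand relative
    position 0 is ``stop_codon_ref - 1``.
    """

    id: str
    chrom: str
    strand: Strand
    tu_start: int
    tu_end: int
    stop_codon_ref: int
    utr3_len: int = 400

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tu_start < self.tu_end:
            raise ValueError(f"{self.id}: tu_start must be < tu_end")
        if self.utr3_len <= 0:
            raise ValueError("utr3_len must be positive")

    def utr3_interval(self) -> Tuple[int, int]:
        """Genomic half-open interval of the 3'UTR window."""
        if self.strand == "+":
            return self.stop_codon_ref, self.stop_codon_ref + self.utr3_len
        return self.stop_codon_ref - self.utr3_len, self.stop_codon_ref

    def span(self) -> Tuple[int, int]:
        """Genomic half-open interval covering the unit and its window."""
        ws, we = self.utr3_interval()
        return min(self.tu_start, ws), max(self.tu_end, we)

    def rel_to_genomic(self, rel: int) -> int:
        """Map a transcript-relative position to its genomic coordinate.

        Relative position 0 is the first nt downstream of the stop codon;
        negative values walk upstream into the gene body.
        """
        if self.strand == "+":
            return self.stop_codon_ref + rel
        return self.stop_codon_ref - 1 - rel

    def genomic_to_rel(self, pos: int) -> int:
        if self.strand == "+":
            return pos - self.stop_codon_ref
        return self.stop_codon_ref - 1 - pos

    def region_of(self, rel: int) -> str:
        return "utr3" if 0 <= rel < self.utr3_len else "body"


def load_units(
    path: str | Path,
    utr3_len: int = 400,
    chrom_lengths: Mapping[str, int] | None = None,
    fmt: str | None = None,
) -> List[TranscriptionUnit]:
    """Load transcription units from BED6 or GFF3 and attach 3'UTR windows.

    ``fmt`` may be "bed" or "gff"; by default it is inferred from the file
    extension.  Units whose 3'UTR window would run past a chromosome end
    (when ``chrom_lengths`` is supplied) are excluded with a warning, not
    truncated, so that all windows have uniform length.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff" if path.suffix.lower() in {".gff", ".gff3", ".gtf"} else "bed"
    if fmt == "bed":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
        records = df.to_dict("records")
    elif fmt == "gff":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "source", "type", "start", "end",
                   "score", "strand", "frame", "attributes"],
        )
        records = []
        for i, row in df.iterrows():
            m = re.search(r"ID=([^;]+)", str(row["attributes"]))
            records.append(
                {
                    "chrom": row["chrom"],
                    "start": int(row["start"]) - 1,  # GFF is 1-based closed
                    "end": int(row["end"]),
                    "name": m.group(1) if m else f"unit{i}",
                    "strand": row["strand"],
                }
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")

    units: List[TranscriptionUnit] = []
    for rec in records:
        strand = str(rec["strand"])
        if strand not in ("+", "-"):
            raise ValueError(f"unit {rec['name']!r} has no valid strand")
        start, end = int(rec["start"]), int(rec["end"])
        stop_ref = end if strand == "+" else start
        unit = TranscriptionUnit(
            id=str(rec["name"]), chrom=str(rec["chrom"]), strand=strand,
            tu_start=start, tu_end=end, stop_codon_ref=stop_ref,
            utr3_len=utr3_len,
        )
        ws, we = unit.utr3_interval()
        if ws < 0 or (
            chrom_lengths is not None
            and (unit.chrom not in chrom_lengths or we > chrom_lengths[unit.chrom])
        ):
            logger.warning(
                "unit %s excluded: 3'UTR window [%d, %d) outside chromosome bounds",
                unit.id, ws, we,
            )
            continue
        units.append(unit)
    return units


def write_units_bed(units: Iterable[TranscriptionUnit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for u in units:
            fh.write(f"{u.chrom}\t{u.tu_start}\t{u.tu_end}\t{u.id}\t0\t{u.strand}\n")


class CoverageTrack:
    """Per-strand, per-nucleotide integer 3'-end read counts (sparse)."""

    def __init__(self) -> None:
        self._data: Dict[Tuple[str, Strand], Dict[int, int]] = {}

    def _chunk(self, chrom: str, strand: Strand) -> Dict[int, int]:
        return self._data.setdefault((chrom, strand), {})

    def get(self, chrom: str, strand: Strand, pos: int) -> int:
        return self._data.get((chrom, strand), {}).get(pos, 0)

    def set_count(self, chrom: str, strand: Strand, pos: int, count: int) -> None:
        if count < 0 or int(count) != count:
            raise ValueError("counts must be nonnegative integers")
        chunk = self._chunk(chrom, strand)
        if count == 0:
            chunk.pop(pos, None)
        else:
            chunk[pos] = int(count)

    def add_count(self, chrom: str, strand: Strand, pos: int, count: int = 1) -> None:
        self.set_count(chrom, strand, pos, self.get(chrom, strand, pos) + count)

    def total(self) -> int:
        return sum(sum(chunk.values()) for chunk in self._data.values())

    def window(self, chrom: str, strand: Strand, start: int, end: int) -> np.ndarray:
        """Dense integer array of counts over genomic [start, end)."""
        out = np.zeros(end - start, dtype=np.int64)
        chunk = self._data.get((chrom, strand))
        if chunk:
            for pos, c in chunk.items():
                if start <= pos < end:
                    out[pos - start] = c
        return out

    def unit_array(self, unit: TranscriptionUnit) -> np.ndarray:
        """Counts over the unit span, ordered in transcription direction."""
        s, e = unit.span()
        arr = self.window(unit.chrom, unit.strand, s, e)
        return arr if unit.strand == "+" else arr[::-1]

    def positions(self, chrom: str, strand: Strand) -> List[int]:
        return sorted(self._data.get((chrom, strand), {}))

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        out = CoverageTrack()
        for track in (self, other):
            for (chrom, strand), chunk in track._data.items():
                for pos, c in chunk.items():
                    out.add_count(chrom, strand, pos, c)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        keys = set(self._data) | set(other._data)
        return all(
            self._data.get(k, {}) == other._data.get(k, {}) for k in keys
        )

    # ---- bedGraph I/O ---------------------------------------------------

    @staticmethod
    def _read_bedgraph(path: str | Path, strand: Strand, track: "CoverageTrack") -> None:
        try:
            df = pd.read_csv(
                path, sep=r"\s+", header=None, comment="#",
                names=["chrom", "start", "end", "value"],
            )
        except pd.errors.EmptyDataError:
            return
        if df.empty:
            return
        if (df["value"] < 0).any():
            raise ValueError(f"{path}: negative coverage values")
        vals = df["value"].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"{path}: non-integer coverage values (counts must be integral)")
        df = df.sort_values(["chrom", "start"])
        for chrom, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"{path}: overlapping intervals on {chrom}")
            for start, end, value in zip(grp["start"], grp["end"], grp["value"]):
                v = int(round(value))
                if v == 0:
                    continue
                for pos in range(int(start), int(end)):
                    track.set_count(str(chrom), strand, pos, v)

    @classmethod
    def from_bedgraphs(
        cls, bedgraph_plus: str | Path, bedgraph_minus: str | Path
    ) -> "CoverageTrack":
        track = cls()
        cls._read_bedgraph(bedgraph_plus, "+", track)
        cls._read_bedgraph(bedgraph_minus, "-", track)
        return track

    def _write_bedgraph(self, path: str | Path, strand: Strand) -> None:
        with open(path, "w") as fh:
            chroms = sorted({c for (c, s) in self._data if s == strand})
            for chrom in chroms:
                chunk = self._data[(chrom, strand)]
                run_start = run_end = None
                run_val = 0
                for pos in sorted(chunk):
                    val = chunk[pos]
                    if run_start is not None and pos == run_end and val == run_val:
                        run_end += 1
                        continue
                    if run_start is not None:
                        fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val}\n")
                    run_start, run_end, run_val = pos, pos + 1, val
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val}\n")

    def to_bedgraphs(self, bedgraph_plus: str | Path, bedgraph_minus: str | Path) -> None:
        self._write_bedgraph(bedgraph_plus, "+")
        self._write_bedgraph(bedgraph_minus, "-")


def load_coverage(bedgraph_plus: str | Path, bedgraph_minus: str | Path) -> CoverageTrack:
    """Load a strand pair of bedGraph files into one :class:`CoverageTrack`."""
    return CoverageTrack.from_bedgraphs(bedgraph_plus, bedgraph_minus)


@dataclass
class PolyAProfile:
    """Per-unit poly(A)-supporting read counts at transcript-relative positions.

    ``counts[unit_id][rel_pos]`` is the number of retained poly(A) reads whose
    last templated base maps ``rel_pos`` nt downstream of the stop codon.
    Positions outside [0, utr3_len) are rejected unless ``allow_outside``.
    """

    utr3_len: int = 400
    counts: Dict[str, Dict[int, int]] = field(default_factory=dict)

    def add(self, unit_id: str, rel_pos: int, count: int, allow_outside: bool = False) -> None:
        if count < 0:
            raise ValueError("poly(A) read counts must be >= 0")
        if not allow_outside and not (0 <= rel_pos < self.utr3_len):
            raise ValueError(
                f"relative position {rel_pos} outside [0, {self.utr3_len})"
            )
        if count == 0:
            return
        unit = self.counts.setdefault(unit_id, {})
        unit[rel_pos] = unit.get(rel_pos, 0) + int(count)

    def site_positions(self, unit_id: str) -> List[int]:
        """Sorted relative positions with at least one supporting read."""
        return sorted(self.counts.get(unit_id, {}))

    def total_reads(self) -> int:
        return sum(sum(d.values()) for d in self.counts.values())

    def n_sites(self) -> int:
        return sum(len(d) for d in self.counts.values())

    @classmethod
    def from_genomic_sites(
        cls,
        sites: Mapping[SiteKey, int],
        units: Iterable[TranscriptionUnit],
        utr3_len: int = 400,
    ) -> "PolyAProfile":
        """Project genomic (chrom, strand, pos) -> count onto unit windows."""
        prof = cls(utr3_len=utr3_len)
        for unit in units:
            for (chrom, strand, pos), count in sites.items():
                if chrom != unit.chrom or strand != unit.strand:
                    continue
                rel = unit.genomic_to_rel(pos)
                if 0 <= rel < utr3_len:
                    prof.add(unit.id, rel, count)
        return prof


def write_polya_sites(
    sites: Mapping[SiteKey, int], path: str | Path
) -> None:
    """Write genomic poly(A) site counts as TSV: chrom, pos0, strand, count."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos0\tstrand\tcount\n")
        for (chrom, strand, pos), count in sorted(sites.items()):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{count}\n")


def read_polya_sites(path: str | Path) -> Dict[SiteKey, int]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[SiteKey, int] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chrom), str(row.strand), int(row.pos0))
        out[key] = out.get(key, 0) + int(row.count)
    return out
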