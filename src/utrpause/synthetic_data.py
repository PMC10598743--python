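"""Synthetic NET-seq / 3'READS data with planted ground truth.

The generator emulates the data shapes the downstream analyses assume:

* background 3'-end coverage drawn i.i.d. per nucleotide from a negative
  binomial (mean, size) — the marginal model the pause caller fits locally;
* rare planted pause spikes at ``pause_fold`` times the background mean;
* per-unit poly(A) read-count profiles that are either uniform over the
  3'UTR window or coupled a fixed offset range upstream of planted pauses;
* raw 3'READS R1 reads carrying a 5' T-stretch, with a configurable
  fraction of internally-primed reads anchored at genomic A-runs;
* per-position genomic feature tracks (Gaussian noise plus a smoothed,
  scaled pause indicator) with tunable signal-to-noise per category.

All simulators are deterministic functions of (config, seed); each draws
from an independent stream derived from the seed so that, e.g., changing
the poly(A) settings does not perturb the coverage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .annotations_io import (
    CoverageTrack,
    GenomeSequence,
    PolyAProfile,
    TranscriptionUnit,
    revcomp,
)

logger = logging.getLogger(__name__)

FEATURE_CATEGORIES = ("dna_shape", "chromatin", "ctd")

# Independent RNG streams per simulator, mixed with the user seed.
_STREAM_GENOME = 11
_STREAM_COVERAGE = 12
_STREAM_POLYA = 13
_STREAM_READS = 14
_STREAM_TRACKS = 15


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the conditions exercised throughout the analyses:
    NB(mean 4) background with moderate overdispersion, 20-fold pause
    spikes, 400-nt 3'UTR windows, and poly(A) sites coupled 5-45 nt
    upstream of pauses.
    """

    seed: int = 0
    n_units: int = 50
    unit_len: int = 1000          # gene-body length, nt
    utr3_len: int = 400           # 3'UTR window length, nt
    gap_len: int = 100            # intergenic spacer, nt
    nb_mean: float = 4.0          # background reads/nt
    nb_dispersion: float = 10.0   # NB size parameter; variance = m + m^2/size
    pause_rate: float = 5.0       # planted pauses per kb of unit span
    pause_fold: float = 20.0      # pause count = round(fold * nb_mean)
    polya_coupling: str = "coupled"          # {"coupled", "uniform"}
    coupling_offset_range: Tuple[int, int] = (5, 45)  # nt upstream, inclusive
    polya_read_mean: float = 5.0  # mean supporting reads per site (>= 1)
    uniform_sites_per_unit: int = 2
    tail_len_dist: Tuple[int, int] = (4, 15)  # 5' T-stretch length, inclusive
    internal_priming_frac: float = 0.0
    feature_snr: Dict[str, float] = field(
        default_factory=lambda: {"dna_shape": 2.0, "chromatin": 2.0, "ctd": 0.5}
    )
    feature_smooth_sd: float = 0.5  # nt, width of the pause-indicator kernel

    def __post_init__(self) -> None:
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be > 0")
        if self.pause_rate < 0:
            raise ValueError("pause_rate must be >= 0")
        if self.pause_fold <= 1:
            raise ValueError("pause_fold must exceed 1 (pauses must exceed background)")
        if self.polya_coupling not in ("coupled", "uniform"):
            raise ValueError("polya_coupling must be 'coupled' or 'uniform'")
        lo, hi = self.coupling_offset_range
        if not (0 <= lo <= hi < self.utr3_len):
            raise ValueError("coupling_offset_range must lie within [0, utr3_len)")
        if not (0.0 <= self.internal_priming_frac <= 1.0):
            raise ValueError("internal_priming_frac must be in [0, 1]")
        if self.polya_read_mean < 1:
            raise ValueError("polya_read_mean must be >= 1")
        for name, snr in self.feature_snr.items():
            if name not in FEATURE_CATEGORIES:
                raise ValueError(f"unknown feature category {name!r}")
            if snr < 0:
                raise ValueError("feature_snr values must be >= 0")


class NetSeqSim(NamedTuple):
    genome: GenomeSequence
    units: List[TranscriptionUnit]
    coverage: CoverageTrack
    truth_pauses: pd.DataFrame  # unit, chrom, strand, pos0, rel_pos, count


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _layout_units(config: SimulationConfig, rng: np.random.Generator
                  ) -> Tuple[int, List[TranscriptionUnit]]:
    """Lay units end to end on one chromosome, random strand per unit."""
    slot = config.unit_len + config.utr3_len + config.gap_len
    units: List[TranscriptionUnit] = []
    cursor = config.gap_len
    for i in range(config.n_units):
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tu_start = cursor
            tu_end = cursor + config.unit_len
            stop_ref = tu_end
        else:
            # 3'UTR window occupies the low-coordinate side of the slot
            tu_start = cursor + config.utr3_len
            tu_end = tu_start + config.unit_len
            stop_ref = tu_start
        units.append(
            TranscriptionUnit(
                id=f"unit{i:04d}", chrom="chr1", strand=strand,
                tu_start=tu_start, tu_end=tu_end, stop_codon_ref=stop_ref,
                utr3_len=config.utr3_len,
            )
        )
        cursor += slot
    genome_len = cursor + config.gap_len
    return genome_len, units


def simulate_netseq(config: SimulationConfig, seed: int | None = None) -> NetSeqSim:
    """Random genome, units, NB background coverage and planted pause truth.

    Background counts are i.i.d. NB(nb_mean, nb_dispersion) at every
    nucleotide of each unit span on the unit's strand; planted pauses are
    drawn uniformly within unit spans at ``pause_rate`` per kb and their
    count is overwritten with round(pause_fold * nb_mean).
    """
    seed = config.seed if seed is None else seed
    grng = _rng(seed, _STREAM_GENOME)
    genome_len, units = _layout_units(config, grng)
    seq = "".join(grng.choice(list("ACGT"), size=genome_len))
    genome = GenomeSequence({"chr1": seq})

    crng = _rng(seed, _STREAM_COVERAGE)
    p = config.nb_dispersion / (config.nb_dispersion + config.nb_mean)
    coverage = CoverageTrack()
    truth_rows = []
    pause_count = int(round(config.pause_fold * config.nb_mean))
    for unit in units:
        s, e = unit.span()
        counts = crng.negative_binomial(config.nb_dispersion, p, size=e - s)
        n_pauses = crng.poisson(config.pause_rate * (e - s) / 1000.0)
        pause_pos = (
            crng.choice(e - s, size=min(n_pauses, e - s), replace=False)
            if n_pauses > 0 else np.array([], dtype=int)
        )
        counts[pause_pos] = pause_count
        nz = np.nonzero(counts)[0]
        for off in nz:
            coverage.set_count(unit.chrom, unit.strand, s + int(off), int(counts[off]))
        for off in sorted(int(x) for x in pause_pos):
            pos = s + off
            truth_rows.append(
                {
                    "unit": unit.id, "chrom": unit.chrom, "strand": unit.strand,
                    "pos0": pos, "rel_pos": unit.genomic_to_rel(pos),
                    "count": pause_count,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["unit", "chrom", "strand", "pos0", "rel_pos", "count"],
    )
    return NetSeqSim(genome, units, coverage, truth)


def simulate_polya(
    units: Sequence[TranscriptionUnit],
    truth_pauses: pd.DataFrame,
    config: SimulationConfig,
    genome: GenomeSequence | None = None,
    seed: int | None = None,
) -> Tuple[PolyAProfile, pd.DataFrame]:
    """Per-unit poly(A) profiles, coupled upstream of pauses or uniform.

    Coupled mode: every truth pause lying in a 3'UTR window spawns one
    site at ``rel_pos - U(coupling_offset_range)``; sites pushed below
    relative position 0 are dropped with a log message.  Uniform mode:
    ``uniform_sites_per_unit`` sites per unit, uniform over the window.
    When ``genome`` is supplied, a site landing on a sense-strand A is
    nudged upstream to the nearest non-A base (the last templated base of
    a cleaved transcript is identifiable only at a non-A position, since
    templated As are absorbed into the tail).  Returns the profile and a
    truth table (unit, rel_pos, pos0, count).
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _STREAM_POLYA)
    unit_by_id = {u.id: u for u in units}
    profile = PolyAProfile(utr3_len=config.utr3_len)
    rows = []

    def _emit(unit: TranscriptionUnit, rel: int) -> None:
        if genome is not None:
            while rel >= 0 and genome.base(
                unit.chrom, unit.rel_to_genomic(rel), unit.strand
            ) == "A":
                rel -= 1
            if rel < 0:
                logger.debug("site in %s dropped: no non-A base upstream", unit.id)
                return
        count = int(rng.poisson(config.polya_read_mean - 1.0)) + 1
        profile.add(unit.id, rel, count)
        rows.append(
            {"unit": unit.id, "rel_pos": rel,
             "pos0": unit.rel_to_genomic(rel), "count": count}
        )

    if config.polya_coupling == "coupled":
        if truth_pauses.empty:
            logger.info("coupled poly(A) simulation with no pauses: empty profile")
            return profile, pd.DataFrame(columns=["unit", "rel_pos", "pos0", "count"])
        lo, hi = config.coupling_offset_range
        utr = truth_pauses[
            (truth_pauses["rel_pos"] >= 0)
            & (truth_pauses["rel_pos"] < config.utr3_len)
        ]
        for row in utr.itertuples(index=False):
            offset = int(rng.integers(lo, hi + 1))
            rel = int(row.rel_pos) - offset
            if rel < 0:
                logger.debug("site for pause at +%d dropped (offset %d)", row.rel_pos, offset)
                continue
            _emit(unit_by_id[row.unit], rel)
    else:
        for unit in units:
            k = min(config.uniform_sites_per_unit, config.utr3_len)
            for rel in rng.choice(config.utr3_len, size=k, replace=False):
                _emit(unit, int(rel))

    truth_sites = pd.DataFrame(rows, columns=["unit", "rel_pos", "pos0", "count"])
    return profile, truth_sites


def _sense_a_runs(genome: GenomeSequence, unit: TranscriptionUnit
                  ) -> List[Tuple[int, int]]:
    """(last templated base c, run length) for sense-strand A-runs in the window.

    ``c`` is the genomic position of the base immediately upstream
    (transcript sense) of a maximal A-run within the unit's 3'UTR window.
    """
    ws, we = unit.utr3_interval()
    seq = genome.fetch(unit.chrom, ws, we)  # top strand
    runs = []
    if unit.strand == "+":
        for m in re.finditer(r"A+", seq):
            c = ws + m.start() - 1
            if c >= ws:
                runs.append((c, m.end() - m.start()))
    else:
        for m in re.finditer(r"T+", seq):  # genomic T = sense A on minus strand
            c = ws + m.end()
            if c < we:
                runs.append((c, m.end() - m.start()))
    return runs


def downstream_a_run(genome: GenomeSequence, chrom: str, strand: str, pos: int) -> int:
    """Length of the maximal sense-strand A-run starting just downstream of pos."""
    seq = genome.seqs[chrom]
    n = 0
    if strand == "+":
        i = pos + 1
        while i < len(seq) and seq[i] == "A":
            n += 1
            i += 1
    else:
        i = pos - 1
        while i >= 0 and seq[i] == "T":
            n += 1
            i -= 1
    return n


def simulate_3reads_raw(
    profile: PolyAProfile,
    units: Sequence[TranscriptionUnit],
    genome: GenomeSequence,
    config: SimulationConfig,
    seed: int | None = None,
) -> List[Tuple[str, str, str]]:
    """Raw 3'READS R1 reads: (id, sequence, quality) triples.

    Each read is ``T^k`` followed by the reverse complement of the 17
    sense-strand nucleotides ending at the site.  Genuine reads draw
    ``k = downstream_A_run + U(tail_len_dist)`` so the T-stretch always
    exceeds what the genome could template; with probability
    ``internal_priming_frac`` the read is instead anchored immediately
    upstream of a genomic A-run with ``k <= run length``, emulating
    internal priming.  Sites with fewer than 17 templated nt upstream
    within the unit are skipped with a log message.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _STREAM_READS)
    lo, hi = config.tail_len_dist
    unit_by_id = {u.id: u for u in units}
    reads: List[Tuple[str, str, str]] = []
    a_run_cache: Dict[str, List[Tuple[int, int]]] = {}

    def _sense17(unit: TranscriptionUnit, c: int) -> str | None:
        if unit.strand == "+":
            start = c - 16
            if start < unit.tu_start:
                return None
            return genome.fetch(unit.chrom, start, c + 1)
        end = c + 17
        if end > unit.tu_end:
            return None
        return genome.fetch(unit.chrom, c, end, strand="-")

    serial = 0
    for unit_id in sorted(profile.counts):
        unit = unit_by_id[unit_id]
        for rel in sorted(profile.counts[unit_id]):
            count = profile.counts[unit_id][rel]
            if count <= 0:
                raise ValueError(f"{unit_id}:+{rel}: site count must be > 0")
            c = unit.rel_to_genomic(rel)
            for _ in range(count):
                primed = rng.random() < config.internal_priming_frac
                if primed:
                    runs = a_run_cache.get(unit_id)
                    if runs is None:
                        runs = _sense_a_runs(genome, unit)
                        a_run_cache[unit_id] = runs
                    if not runs:
                        logger.debug("%s: no A-runs for internal priming", unit_id)
                        continue
                    cp, run_len = runs[int(rng.integers(len(runs)))]
                    k = int(rng.integers(1, run_len + 1))
                    sense = _sense17(unit, cp)
                    origin = "primed"
                else:
                    k = downstream_a_run(genome, unit.chrom, unit.strand, c) + int(
                        rng.integers(lo, hi + 1)
                    )
                    sense = _sense17(unit, c)
                    origin = "polya"
                if sense is None:
                    logger.debug("%s:+%d: site within 17 nt of unit 5' edge, skipped",
                                 unit_id, rel)
                    continue
                seq = "T" * k + revcomp(sense)
                reads.append((f"read{serial}:{unit_id}:{rel}:{origin}", seq, "I" * len(seq)))
                serial += 1
    return reads


def write_fastq(reads: Iterable[Tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_feature_tracks(
    truth_pauses: pd.DataFrame,
    units: Sequence[TranscriptionUnit],
    genome: GenomeSequence,
    config: SimulationConfig,
    seed: int | None = None,
    categories: Sequence[str] | None = None,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-position genomic tracks: N(0,1) noise + snr x smoothed pause indicator.

    The pause indicator is smoothed with a Gaussian kernel
    (sd = ``feature_smooth_sd`` nt) and rescaled so an isolated pause
    contributes a peak of height 1; at snr 0 the track is pure noise.
    The association is kept essentially nucleotide-resolution (narrow
    kernel) because downstream consumers read the track value at the
    exact candidate position.  Returns {category: {chrom: array}}.
    """
    seed = config.seed if seed is None else seed
    categories = tuple(categories) if categories is not None else tuple(config.feature_snr)
    for cat in categories:
        if cat not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature category {cat!r}")
    lengths = genome.lengths
    indicator = {chrom: np.zeros(n) for chrom, n in lengths.items()}
    for row in truth_pauses.itertuples(index=False):
        indicator[row.chrom][int(row.pos0)] = 1.0
    peak = 1.0 / (config.feature_smooth_sd * np.sqrt(2 * np.pi))
    smoothed = {
        chrom: gaussian_filter1d(arr, sigma=config.feature_smooth_sd) / peak
        for chrom, arr in indicator.items()
    }
    tracks: Dict[str, Dict[str, np.ndarray]] = {}
    for i, cat in enumerate(categories):
        snr = config.feature_snr.get(cat, 0.0)
        rng = _rng(seed, _STREAM_TRACKS + 100 * (i + 1))
        tracks[cat] = {
            chrom: rng.standard_normal(n) + snr * smoothed[chrom]
            for chrom, n in lengths.items()
        }
    return tracks


def write_truth_tsv(
    truth_pauses: pd.DataFrame, truth_sites: pd.DataFrame, path: str | Path
) -> None:
    """Planted-truth table: unit, rel_pos, kind in {pause, polya}."""
    rows = [
        {"unit": r.unit, "rel_pos": int(r.rel_pos), "kind": "pause"}
        for r in truth_pauses.itertuples(index=False)
    ] + [
        {"unit": r.unit, "rel_pos": int(r.rel_pos), "kind": "polya"}
        for r in truth_sites.itertuples(index=False)
    ]
    pd.DataFrame(rows, columns=["unit", "rel_pos", "kind"]).to_csv(
        path, sep="\t", index=False
    )
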