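"""Negative-binomial local pause calling and shuffled-null generation.

A Pol II pause is a nucleotide whose 3'-end read count both reaches a
minimum absolute count and strictly exceeds ``mean + z * sd`` of the
surrounding window (200 nt by default, the focal nucleotide excluded),
where mean and sd come from a method-of-moments negative-binomial fit with
the variance floored at the mean (an NB cannot be underdispersed).
Calling is restricted to transcription units passing a mean-coverage
filter, with replicate tracks summed beforehand.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotations_io import CoverageTrack, SiteKey, TranscriptionUnit

logger = logging.getLogger(__name__)

PAUSE_COLUMNS = [
    "unit", "chrom", "strand", "pos0", "rel_pos",
    "count", "local_mean", "local_sd", "region",
]


@dataclass
class PauseCallParams:
    min_gene_coverage: float = 2.0  # mean reads/nt over unit + 3'UTR window
    local_halfwidth: int = 100      # nt each side: "the surrounding 200 nt"
    z_threshold: float = 3.0        # SDs above the local mean
    min_pause_reads: int = 2        # absolute count floor
    min_window: int = 50            # smallest usable background window, nt

    def __post_init__(self) -> None:
        if self.local_halfwidth < 10:
            raise ValueError("local_halfwidth must be >= 10")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")


@dataclass
class PauseSet:
    """Called (or shuffled) pauses with their local background statistics."""

    df: pd.DataFrame
    provenance: str = "real"   # {"real", "shuffled"}
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in PAUSE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"pause table missing columns {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def positions(self) -> Set[SiteKey]:
        return {
            (r.chrom, r.strand, int(r.pos0)) for r in self.df.itertuples(index=False)
        }

    def subset_region(self, region: str) -> "PauseSet":
        return PauseSet(
            self.df[self.df["region"] == region].reset_index(drop=True),
            provenance=self.provenance, seed=self.seed,
        )

    def by_unit(self, region: str | None = None) -> dict:
        """unit id -> list of transcript-relative positions."""
        df = self.df if region is None else self.df[self.df["region"] == region]
        out: dict = {}
        for r in df.itertuples(index=False):
            out.setdefault(r.unit, []).append(int(r.rel_pos))
        return out

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["provenance"] = self.provenance
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PauseSet":
        df = pd.read_csv(path, sep="\t")
        provenance = "real"
        if "provenance" in df.columns and len(df):
            provenance = str(df["provenance"].iloc[0])
        return cls(df[PAUSE_COLUMNS].copy(), provenance=provenance)


def unit_mean_coverage(track: CoverageTrack, unit: TranscriptionUnit) -> float:
    """Mean reads/nt over the union of the unit interval and its 3'UTR window."""
    arr = track.unit_array(unit)
    return float(arr.sum()) / len(arr)


def filter_units_by_coverage(
    track: CoverageTrack,
    units: Sequence[TranscriptionUnit],
    params: PauseCallParams | None = None,
) -> List[TranscriptionUnit]:
    """Units whose mean coverage reaches ``min_gene_coverage`` (inclusive)."""
    if not units:
        raise ValueError("empty unit list")
    params = params or PauseCallParams()
    return [
        u for u in units
        if unit_mean_coverage(track, u) >= params.min_gene_coverage
    ]


def _window_stats(arr: np.ndarray, params: PauseCallParams
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized local (mean, sd, n) at every index, focal excluded.

    The window is up to ``local_halfwidth`` nt each side, clipped to the
    unit; sd is sqrt(max(sample variance, mean)) — the NB moment fit with
    a Poisson variance floor.  Positions whose clipped window holds fewer
    than ``min_window`` nt get n = 0 (not callable).
    """
    x = arr.astype(np.float64)
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csumsq = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(n)
    lo = np.maximum(idx - params.local_halfwidth, 0)
    hi = np.minimum(idx + params.local_halfwidth + 1, n)
    wn = (hi - lo - 1).astype(np.float64)  # focal excluded
    wsum = csum[hi] - csum[lo] - x
    wsumsq = csumsq[hi] - csumsq[lo] - x * x
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(wn > 0, wsum / wn, 0.0)
        var = np.where(wn > 1, (wsumsq - wn * mean**2) / (wn - 1), 0.0)
    var = np.maximum(var, 0.0)  # guard tiny negative round-off
    var = np.maximum(var, mean)  # Poisson floor: NB requires var >= mean
    sd = np.sqrt(var)
    usable = wn >= params.min_window
    wn = np.where(usable, wn, 0.0)
    return mean, sd, wn


def fit_local_background(
    track: CoverageTrack,
    unit: TranscriptionUnit,
    pos: int,
    params: PauseCallParams | None = None,
) -> Tuple[float, float]:
    """(mean, sd) of the NB moment fit around one genomic position.

    The window covers up to ``local_halfwidth`` nt on each side of the
    position within the unit span, excluding the focal nucleotide; an
    all-zero window returns (0, 0).
    """
    params = params or PauseCallParams()
    s, e = unit.span()
    if not s <= pos < e:
        raise ValueError(f"position {pos} outside unit span [{s}, {e})")
    arr = track.unit_array(unit)
    i = pos - s if unit.strand == "+" else e - 1 - pos
    mean, sd, _ = _window_stats(arr, params)
    return float(mean[i]), float(sd[i])


def call_pauses(
    track: CoverageTrack,
    units: Sequence[TranscriptionUnit],
    params: PauseCallParams | None = None,
) -> PauseSet:
    """Call pauses over pre-filtered units.

    A nucleotide is a pause iff its count is at least ``min_pause_reads``
    and strictly exceeds ``local mean + z * local sd``.  Each call is
    annotated with its transcript-relative position and region
    (body / utr3).  Callers should pass units that already passed
    :func:`filter_units_by_coverage` and sum replicate tracks beforehand.
    """
    params = params or PauseCallParams()
    rows = []
    for unit in units:
        s, e = unit.span()
        arr = track.unit_array(unit)  # transcript orientation
        mean, sd, wn = _window_stats(arr, params)
        called = (
            (wn > 0)
            & (arr >= params.min_pause_reads)
            & (arr > mean + params.z_threshold * sd)
        )
        for i in np.nonzero(called)[0]:
            pos = s + int(i) if unit.strand == "+" else e - 1 - int(i)
            rel = unit.genomic_to_rel(pos)
            rows.append(
                {
                    "unit": unit.id, "chrom": unit.chrom, "strand": unit.strand,
                    "pos0": pos, "rel_pos": rel, "count": int(arr[i]),
                    "local_mean": float(mean[i]), "local_sd": float(sd[i]),
                    "region": unit.region_of(rel),
                }
            )
    return PauseSet(pd.DataFrame(rows, columns=PAUSE_COLUMNS), provenance="real")


def sample_positions_in_units(
    units: Sequence[TranscriptionUnit],
    n_per_unit: dict | int,
    seed: int,
    region: str | None = None,
) -> pd.DataFrame:
    """Uniform random positions within unit spans (optionally one region).

    ``n_per_unit`` is either a mapping unit id -> count or a single count
    applied to every unit.  Draws are without replacement per unit; if a
    unit/region has fewer positions than requested the draw falls back to
    replacement with a warning.  This is the primitive behind shuffled
    pause sets.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for unit in units:
        n = n_per_unit if isinstance(n_per_unit, int) else n_per_unit.get(unit.id, 0)
        if n <= 0:
            continue
        if region == "utr3":
            rel_positions = np.arange(unit.utr3_len)
        elif region == "body":
            s, e = unit.span()
            ws, we = unit.utr3_interval()
            body_len = (e - s) - (we - ws)
            rel_positions = np.arange(-body_len, 0)
        else:
            s, e = unit.span()
            ws, we = unit.utr3_interval()
            body_len = (e - s) - (we - ws)
            rel_positions = np.arange(-body_len, unit.utr3_len)
        replace = n > len(rel_positions)
        if replace:
            logger.warning(
                "unit %s: %d draws from %d positions, sampling with replacement",
                unit.id, n, len(rel_positions),
            )
        picked = rng.choice(rel_positions, size=n, replace=replace)
        for rel in picked:
            rel = int(rel)
            pos = unit.rel_to_genomic(rel)
            rows.append(
                {
                    "unit": unit.id, "chrom": unit.chrom, "strand": unit.strand,
                    "pos0": pos, "rel_pos": rel, "region": unit.region_of(rel),
                }
            )
    return pd.DataFrame(
        rows, columns=["unit", "chrom", "strand", "pos0", "rel_pos", "region"]
    )


def shuffle_pauses(
    pauses: PauseSet,
    units: Sequence[TranscriptionUnit],
    seed: int,
    stratify_region: bool = False,
) -> PauseSet:
    """Size-matched null: per unit, redraw pause positions uniformly.

    The shuffled set holds, for each unit (and region when
    ``stratify_region``), exactly as many positions as the source set,
    drawn uniformly without replacement within that unit (or region) span.
    Read counts are copied from the source records in order so that
    read-weighted statistics remain comparable.
    """
    if not len(pauses):
        raise ValueError("cannot shuffle an empty pause set")
    unit_by_id = {u.id: u for u in units}
    src = pauses.df
    parts = []
    group_cols = ["unit", "region"] if stratify_region else ["unit"]
    for key, grp in src.groupby(group_cols, sort=True):
        unit_id = key[0] if isinstance(key, tuple) else key
        region = key[1] if stratify_region else None
        unit = unit_by_id[unit_id]
        # crc32 gives a process-independent per-unit stream
        sub_seed = np.random.SeedSequence(
            [int(seed), zlib.crc32(str(unit_id).encode()), 0 if region != "utr3" else 1]
        ).generate_state(1)[0] % (2**31)
        drawn = sample_positions_in_units(
            [unit], len(grp), int(sub_seed), region=region
        )
        drawn["count"] = grp["count"].to_numpy()
        drawn["local_mean"] = np.nan
        drawn["local_sd"] = np.nan
        parts.append(drawn[PAUSE_COLUMNS])
    df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=PAUSE_COLUMNS)
    return PauseSet(df, provenance="shuffled", seed=seed)


def pause_overlap(set_a: PauseSet, set_b: PauseSet) -> float:
    """Percentage of maximal overlap: 100 * |A n B| / min(|A|, |B|)."""
    a, b = set_a.positions(), set_b.positions()
    if not a or not b:
        raise ValueError("pause overlap undefined for empty sets")
    return 100.0 * len(a & b) / min(len(a), len(b))


def replicate_correlations(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    units: Sequence[TranscriptionUnit],
    level: str = "gene",
    params: PauseCallParams | None = None,
) -> float:
    """Pearson r between two tracks at gene (RPKM) or nucleotide level.

    Gene level: per-unit RPKM = reads * 1e9 / (unit length * total mapped
    reads), over all units.  Nucleotide level: raw per-position counts over
    units passing the coverage filter in *both* tracks.
    """
    params = params or PauseCallParams()
    if level == "gene":
        tot_a, tot_b = track_a.total(), track_b.total()
        xs, ys = [], []
        for unit in units:
            s, e = unit.span()
            length = e - s
            xs.append(track_a.unit_array(unit).sum() * 1e9 / (length * tot_a))
            ys.append(track_b.unit_array(unit).sum() * 1e9 / (length * tot_b))
    elif level == "nucleotide":
        passing = [
            u for u in units
            if unit_mean_coverage(track_a, u) >= params.min_gene_coverage
            and unit_mean_coverage(track_b, u) >= params.min_gene_coverage
        ]
        xs = np.concatenate([track_a.unit_array(u) for u in passing]) if passing else []
        ys = np.concatenate([track_b.unit_array(u) for u in passing]) if passing else []
    else:
        raise ValueError("level must be 'gene' or 'nucleotide'")
    if len(xs) < 3:
        raise ValueError("fewer than 3 paired observations")
    return float(stats.pearsonr(np.asarray(xs, float), np.asarray(ys, float))[0])


def pause_density(
    pauses: PauseSet, units: Sequence[TranscriptionUnit]
) -> pd.Series:
    """Per-unit 3'UTR pause density, pauses per kilobase of window."""
    utr = pauses.df[pauses.df["region"] == "utr3"]
    counts = utr.groupby("unit").size()
    return pd.Series(
        {u.id: 1000.0 * counts.get(u.id, 0) / u.utr3_len for u in units},
        name="pauses_per_kb",
    )
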