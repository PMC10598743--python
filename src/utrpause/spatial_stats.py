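"""Positional summaries and pause <-> poly(A) coupling statistics.

All positions here are transcript-relative (0 = first nt downstream of
the stop codon).  "Upstream" distance from a pause to a poly(A) site is
``d = pause_rel - site_rel`` with d >= 0; co-located events (d = 0) fall
in the first 10-nt bin and bins are half-open, so d = 50 is excluded
from the 0-50 nt window.
"""

from __future__ import annotations

from typing import Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotations_io import PolyAProfile, TranscriptionUnit

BIN_WIDTH = 10
N_BINS = 5
BIN_COLUMNS = [f"bin_{i * BIN_WIDTH}_{(i + 1) * BIN_WIDTH}" for i in range(N_BINS)]


def weighted_average_position(
    positions: Sequence[int], reads: Sequence[int]
) -> float:
    """Read-weighted mean position: sum(pos * reads) / sum(reads)."""
    pos = np.asarray(positions, dtype=float)
    w = np.asarray(reads, dtype=float)
    if pos.size == 0 or w.sum() <= 0:
        raise ValueError("need at least one record with positive reads")
    return float((pos * w).sum() / w.sum())


def weighted_average_by_unit(
    events_by_unit: Mapping[str, Sequence[Tuple[int, int]]]
) -> pd.Series:
    """Per-unit weighted average of (rel_pos, reads) records."""
    return pd.Series(
        {
            uid: weighted_average_position([p for p, _ in recs], [r for _, r in recs])
            for uid, recs in events_by_unit.items()
            if recs and sum(r for _, r in recs) > 0
        },
        name="weighted_avg_pos",
    )


def metagene_profile(
    events_by_unit: Mapping[str, Iterable[int]],
    units: Sequence[TranscriptionUnit],
    utr3_len: int = 400,
) -> np.ndarray:
    """Percent of units with an event at each relative position 0..utr3_len-1.

    ``events_by_unit`` maps unit id -> relative positions (a unit counts
    once per position regardless of multiplicity); units absent from the
    mapping contribute zeros.  Every value lies in [0, 100].
    """
    if not units:
        raise ValueError("no units")
    prof = np.zeros(utr3_len)
    ids = {u.id for u in units}
    for uid, positions in events_by_unit.items():
        if uid not in ids:
            continue
        for p in set(int(x) for x in positions):
            if 0 <= p < utr3_len:
                prof[p] += 1
    return 100.0 * prof / len(units)


def upstream_bin_counts(
    pauses_by_unit: Mapping[str, Sequence[int]],
    profile: PolyAProfile,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per pause, poly(A) site counts in 10-nt bins 0-50 nt upstream.

    A site at distance d upstream of a pause (d = pause - site, d >= 0)
    falls in bin floor(d/10) for d in [0, 50); downstream sites and
    d >= 50 are ignored.  By default a site counts once if it has any
    retained read; ``weighted`` counts reads instead.
    """
    rows = []
    for uid, pause_positions in pauses_by_unit.items():
        site_counts = profile.counts.get(uid, {})
        for p in pause_positions:
            bins = [0] * N_BINS
            for s, c in site_counts.items():
                d = p - s
                if 0 <= d < N_BINS * BIN_WIDTH:
                    bins[d // BIN_WIDTH] += c if weighted else 1
            rows.append({"unit": uid, "pause_rel": int(p),
                         **dict(zip(BIN_COLUMNS, bins))})
    return pd.DataFrame(rows, columns=["unit", "pause_rel", *BIN_COLUMNS])


def ks_real_vs_shuffled(
    real_bins: pd.DataFrame, shuffled_bins: pd.DataFrame, bin_index: int
) -> Tuple[float, float]:
    """Two-sample two-sided KS test on per-pause counts for one bin.

    ``bin_index`` selects the 10-nt bin (0 = 0-10 nt upstream);
    ``bin_index=None`` is not supported here — sum columns beforehand to
    pool bins.  Returns (D, p).
    """
    col = BIN_COLUMNS[bin_index]
    x = real_bins[col].to_numpy(dtype=float)
    y = shuffled_bins[col].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample for KS test")
    # per-pause counts are small integers; heavy ties defeat the exact
    # two-sample computation, so the asymptotic p-value is used outright
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def nearest_upstream_distances(
    pauses_by_unit: Mapping[str, Sequence[int]], profile: PolyAProfile
) -> List[int]:
    """Distance from each pause to its nearest upstream site, in nt.

    Pauses with no site at or upstream of them (within the window) are
    excluded; co-located sites give distance 0.
    """
    out: List[int] = []
    for uid, pause_positions in pauses_by_unit.items():
        sites = np.asarray(profile.site_positions(uid))
        if sites.size == 0:
            continue
        for p in pause_positions:
            upstream = sites[sites <= p]
            if upstream.size:
                out.append(int(p - upstream.max()))
    return out


def distance_ratio(
    real_by_unit: Mapping[str, Sequence[int]],
    shuffled_by_unit: Mapping[str, Sequence[int]],
    profile: PolyAProfile,
) -> Tuple[float, float]:
    """Mean nearest-upstream-site distance, real over shuffled, with SE.

    Pauses lacking an upstream site are excluded symmetrically from both
    sets.  The standard error of the ratio is propagated from the two
    means by the delta method:
    SE(r) = r * sqrt(SE_real^2/mean_real^2 + SE_shuf^2/mean_shuf^2).
    """
    d_real = np.asarray(nearest_upstream_distances(real_by_unit, profile), float)
    d_shuf = np.asarray(nearest_upstream_distances(shuffled_by_unit, profile), float)
    if d_real.size == 0 or d_shuf.size == 0:
        raise ValueError("no contributing pauses in one of the sets")
    m_r, m_s = d_real.mean(), d_shuf.mean()
    if m_s == 0:
        raise ValueError("shuffled mean distance is zero")
    se_r = d_real.std(ddof=1) / np.sqrt(d_real.size) if d_real.size > 1 else 0.0
    se_s = d_shuf.std(ddof=1) / np.sqrt(d_shuf.size) if d_shuf.size > 1 else 0.0
    ratio = m_r / m_s
    se = ratio * np.sqrt(
        (se_r / m_r) ** 2 + (se_s / m_s) ** 2
    ) if m_r > 0 else ratio * (se_s / m_s)
    return float(ratio), float(se)
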