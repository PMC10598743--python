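"""Trinucleotide pause-preference scores normalized by shuffled controls.

The trinucleotide at a pause is read on the transcribed (sense) strand at
a contiguous offset triple relative to the pause nucleotide (offset 0):
(-1, 0, +1) by default, with the downstream windows (+1..+3) and
(+2..+4) also supported.  The normalized preference for a trinucleotide
is the real pause count divided by the shuffled pause count (after a
configurable pseudocount), and its log2 is what heatmaps display.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotations_io import GenomeSequence
from .pause_calling import PauseSet

TRINUCLEOTIDES = ["".join(t) for t in product("ACGT", repeat=3)]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _validate_offsets(offsets: Sequence[int]) -> Tuple[int, int, int]:
    offs = tuple(int(o) for o in offsets)
    if len(offs) != 3 or offs[1] != offs[0] + 1 or offs[2] != offs[0] + 2:
        raise ValueError(f"offsets must be a contiguous triple, got {offs}")
    if not -4 <= offs[0] <= 2:
        raise ValueError(f"first offset must be in [-4, 2], got {offs[0]}")
    return offs


def sense_context(
    genome: GenomeSequence, chrom: str, strand: str, pos: int, offsets: Sequence[int]
) -> str | None:
    """Sense-strand bases at the given offsets around a pause, or None.

    Offsets count in the direction of transcription; on the minus strand
    offset +1 is the genomic position pos-1, complemented.  Returns None
    when the context runs off the chromosome or contains N.
    """
    seq = genome.seqs[chrom]
    out = []
    for off in offsets:
        g = pos + off if strand == "+" else pos - off
        if not 0 <= g < len(seq):
            return None
        base = seq[g] if strand == "+" else _COMP[seq[g]]
        if base == "N":
            return None
        out.append(base)
    return "".join(out)


def trinuc_counts(
    pauses: PauseSet,
    genome: GenomeSequence,
    offsets: Sequence[int] = (-1, 0, 1),
) -> Tuple[pd.Series, int]:
    """Count pauses per trinucleotide at the given offsets.

    Returns (64-entry Series indexed by trinucleotide, number skipped);
    a pause is skipped when its context includes N or leaves the
    chromosome.  Counts sum to len(pauses) - skipped.
    """
    offs = _validate_offsets(offsets)
    counts: Dict[str, int] = {t: 0 for t in TRINUCLEOTIDES}
    skipped = 0
    for r in pauses.df.itertuples(index=False):
        ctx = sense_context(genome, r.chrom, r.strand, int(r.pos0), offs)
        if ctx is None:
            skipped += 1
        else:
            counts[ctx] += 1
    return pd.Series(counts, name="count"), skipped


def preference_table(
    real_pauses: PauseSet,
    shuffled_pauses: PauseSet,
    genome: GenomeSequence,
    offsets: Sequence[int] = (-1, 0, 1),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Normalized trinucleotide preference: real / shuffled counts.

    The ratio is (real + pseudocount) / (shuffled + pseudocount); with
    pseudocount 0 a zero shuffled count yields an undefined (NaN) entry,
    flagged in the ``defined`` column rather than dropped.
    """
    if not len(real_pauses) or not len(shuffled_pauses):
        raise ValueError("both pause sets must be nonempty")
    offs = _validate_offsets(offsets)
    real, _ = trinuc_counts(real_pauses, genome, offs)
    shuf, _ = trinuc_counts(shuffled_pauses, genome, offs)
    num = real.astype(float) + pseudocount
    den = shuf.astype(float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.nan)
        log2 = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)), np.nan)
    table = pd.DataFrame(
        {
            "real": real,
            "shuffled": shuf,
            "ratio": ratio,
            "log2": log2,
            "defined": ~np.isnan(ratio),
        },
        index=real.index,
    )
    table.attrs["offsets"] = offs
    table.attrs["pseudocount"] = pseudocount
    return table


def region_delta(body_table: pd.DataFrame, utr_table: pd.DataFrame) -> pd.Series:
    """Per-trinucleotide body ratio minus 3'UTR ratio (raw ratios, not logs).

    Positive values mark trinucleotides more favored for pausing in the
    gene body than in the 3'UTR.
    """
    bo = body_table.attrs.get("offsets")
    uo = utr_table.attrs.get("offsets")
    if bo is not None and uo is not None and bo != uo:
        raise ValueError(f"offset mismatch: body {bo} vs utr {uo}")
    return (body_table["ratio"] - utr_table["ratio"]).rename("delta")


def preference_correlation_matrix(
    tables: Sequence[pd.DataFrame], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation of normalized ratios across conditions.

    Each pair is correlated over the trinucleotides where both tables are
    defined; fewer than 3 shared defined entries is an error.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 preference tables")
    offs = {t.attrs.get("offsets") for t in tables if t.attrs.get("offsets")}
    if len(offs) > 1:
        raise ValueError(f"tables computed at different offsets: {offs}")
    labels = list(labels) if labels is not None else [f"set{i}" for i in range(len(tables))]
    n = len(tables)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = tables[i]["ratio"], tables[j]["ratio"]
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                raise ValueError("fewer than 3 jointly defined trinucleotides")
            r = stats.pearsonr(x[ok], y[ok])[0]
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=labels, columns=labels)
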