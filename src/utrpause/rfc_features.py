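"""Random-forest discrimination of real vs shuffled pauses from genomic features.

Each candidate position (a real or shuffled pause in a 3'UTR window)
becomes a feature vector grouped into named categories:

* ``distance_to_polya`` — distance to the nearest upstream poly(A) site
  (sentinel ``utr3_len`` when none) and site counts in the five 10-nt
  bins 0-50 nt upstream;
* ``sequence_context`` — one-hot sense-strand nucleotides at offsets
  -4..+4 around the position;
* ``dna_shape`` / ``chromatin`` / ``ctd`` — values of per-position
  genomic tracks at the position.

A random forest (mtry features per split, ntrees trees) is trained on a
stratified 75% split and scored by ROC AUC on the held-out 25%; 0.5 is
random classification.  Cross-condition matrices train on all rows of
one condition and test on another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .annotations_io import GenomeSequence, PolyAProfile, TranscriptionUnit
from .spatial_stats import BIN_COLUMNS, BIN_WIDTH

TRACK_CATEGORIES = ("dna_shape", "chromatin", "ctd")
SEQ_OFFSETS = tuple(range(-4, 5))
BASES = "ACGT"


@dataclass
class RFCConfig:
    mtry: int = 5            # features tried per split
    ntrees: int = 2000       # forest size
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mtry < 1 or self.ntrees < 1:
            raise ValueError("mtry and ntrees must be >= 1")


@dataclass
class FeatureMatrix:
    """Labeled per-candidate feature vectors with named column categories."""

    X: pd.DataFrame
    y: np.ndarray                       # binary labels, e.g. real/shuffled
    categories: Dict[str, List[str]]    # category -> column names

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        cols = [c for cat in self.categories.values() for c in cat]
        if len(cols) != len(set(cols)):
            raise ValueError("category column sets must be disjoint")

    def columns_for(self, category: str) -> List[str]:
        if category == "all":
            return list(self.X.columns)
        if category not in self.categories:
            raise KeyError(f"unknown category {category!r}")
        return self.categories[category]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _sense_base(
    genome: GenomeSequence, chrom: str, strand: str, pos: int, off: int
) -> str | None:
    """Sense-strand base at a transcript-direction offset; None if N/out of range."""
    g = pos + off if strand == "+" else pos - off
    seq = genome.seqs[chrom]
    if not 0 <= g < len(seq):
        return None
    base = seq[g] if strand == "+" else _COMP[seq[g]]
    return None if base == "N" else base


def _distance_features(
    rel_pos: int, site_positions: np.ndarray, site_counts: Mapping[int, int],
    utr3_len: int,
) -> Dict[str, float]:
    upstream = site_positions[site_positions <= rel_pos]
    dist = float(rel_pos - upstream.max()) if upstream.size else float(utr3_len)
    feats = {"dist_upstream_polya": dist}
    for i, col in enumerate(BIN_COLUMNS):
        lo, hi = i * BIN_WIDTH, (i + 1) * BIN_WIDTH
        feats[col] = float(
            sum(1 for s in site_counts if lo <= rel_pos - s < hi)
        )
    return feats


def extract_features(
    candidates: pd.DataFrame,
    profile: PolyAProfile,
    genome: GenomeSequence,
    tracks: Mapping[str, Mapping[str, np.ndarray]],
    units: Sequence[TranscriptionUnit],
    utr3_len: int = 400,
    label_col: str = "label",
) -> FeatureMatrix:
    """Build the feature matrix for labeled candidate positions.

    ``candidates`` needs columns unit, rel_pos and ``label_col``; rows
    should be 3'UTR positions of units passing coverage.  Candidates with
    no upstream poly(A) site get the sentinel distance ``utr3_len``.
    One-hot sequence context uses the sense strand; offsets falling on N
    or outside the chromosome leave that offset all-zero.
    """
    unit_by_id = {u.id: u for u in units}
    track_names = list(tracks)
    for name in track_names:
        if name not in TRACK_CATEGORIES:
            raise KeyError(f"unknown track category {name!r}")
    rows = []
    for r in candidates.itertuples(index=False):
        unit = unit_by_id[r.unit]
        rel = int(r.rel_pos)
        pos = unit.rel_to_genomic(rel)
        site_counts = profile.counts.get(unit.id, {})
        sites = np.asarray(sorted(site_counts))
        feats = _distance_features(rel, sites, site_counts, utr3_len)
        for off in SEQ_OFFSETS:
            base = _sense_base(genome, unit.chrom, unit.strand, pos, off)
            for b in BASES:
                feats[f"seq_{off:+d}_{b}"] = float(base == b)
        for name in track_names:
            feats[f"track_{name}"] = float(tracks[name][unit.chrom][pos])
        feats["_label"] = getattr(r, label_col)
        rows.append(feats)
    df = pd.DataFrame(rows)
    y = df.pop("_label").to_numpy()
    categories = {
        "distance_to_polya": ["dist_upstream_polya", *BIN_COLUMNS],
        "sequence_context": [f"seq_{o:+d}_{b}" for o in SEQ_OFFSETS for b in BASES],
    }
    for name in track_names:
        categories[name] = [f"track_{name}"]
    return FeatureMatrix(X=df, y=y, categories=categories)


def _fit_forest(
    X: np.ndarray, y: np.ndarray, config: RFCConfig
) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=config.ntrees,
        max_features=min(config.mtry, X.shape[1]),
        random_state=config.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def _auc(clf: RandomForestClassifier, X: np.ndarray, y: np.ndarray) -> float:
    pos = clf.classes_[1]
    scores = clf.predict_proba(X)[:, 1]
    return float(roc_auc_score((y == pos).astype(int), scores))


def train_eval_rfc(
    matrix: FeatureMatrix, category: str = "all", config: RFCConfig | None = None
) -> float:
    """Held-out ROC AUC of a forest on one feature category (or all).

    Stratified ``train_fraction`` split, deterministic given the config
    seed.  Raises on single-class input.
    """
    config = config or RFCConfig()
    if len(np.unique(matrix.y)) != 2:
        raise ValueError("need exactly two classes")
    cols = matrix.columns_for(category)
    X = matrix.X[cols].to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, matrix.y,
        train_size=config.train_fraction,
        stratify=matrix.y,
        random_state=config.seed,
    )
    clf = _fit_forest(X_tr, y_tr, config)
    return _auc(clf, X_te, y_te)


def cross_strain_auc(
    matrices: Mapping[str, FeatureMatrix],
    category: str = "all",
    config: RFCConfig | None = None,
) -> pd.DataFrame:
    """AUC matrix: train on condition i (rows), test on condition j (cols).

    Off-diagonal cells train on all rows of i and test on all rows of j;
    diagonal cells use the within-condition stratified split.
    """
    config = config or RFCConfig()
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least 2 conditions")
    cols = matrices[names[0]].columns_for(category)
    for name in names[1:]:
        if matrices[name].columns_for(category) != cols:
            raise ValueError("feature columns differ between conditions")
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i in names:
        mi = matrices[i]
        Xi = mi.X[cols].to_numpy(dtype=float)
        clf_full = _fit_forest(Xi, mi.y, config)
        for j in names:
            if i == j:
                out.loc[i, j] = train_eval_rfc(mi, category, config)
            else:
                mj = matrices[j]
                out.loc[i, j] = _auc(clf_full, mj.X[cols].to_numpy(dtype=float), mj.y)
    return out


def pca_strains(
    pause_sets: Mapping[str, Sequence[Tuple[str, int]]]
) -> Tuple[pd.DataFrame, np.ndarray, bool]:
    """Strain coordinates on the first two PCs of binary pause profiles.

    Each strain is encoded as a presence/absence vector over the union of
    (unit, relative position) pause sites; vectors are centered and
    projected.  Returns (coords with columns PC1/PC2, explained-variance
    fractions, degenerate flag).  Identical strains (zero variance) give
    all-zero coordinates with the flag set.
    """
    names = list(pause_sets)
    if len(names) < 3:
        raise ValueError("need at least 3 strains")
    universe = sorted({site for s in pause_sets.values() for site in s})
    mat = np.zeros((len(names), len(universe)))
    col = {site: k for k, site in enumerate(universe)}
    for i, name in enumerate(names):
        for site in pause_sets[name]:
            mat[i, col[site]] = 1.0
    centered = mat - mat.mean(axis=0)
    if not np.any(centered):
        coords = pd.DataFrame(0.0, index=names, columns=["PC1", "PC2"])
        return coords, np.zeros(2), True
    pca = PCA(n_components=2, random_state=0)
    xy = pca.fit_transform(centered)
    coords = pd.DataFrame(xy, index=names, columns=["PC1", "PC2"])
    return coords, pca.explained_variance_ratio_, False
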