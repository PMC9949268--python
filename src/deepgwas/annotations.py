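"""Interval annotations, score tracks, eQTL filtering, Jaccard clustering,
and assembly of the 33-feature matrix.

Interval tracks are 0-based half-open (BED); a variant at 1-based position
p overlaps an interval [start, end) iff start < p ≤ end. Tracks are merged
to disjoint sorted form on construction, which makes membership, base-pair
intersection, and the Jaccard index simple sweeps over sorted arrays.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from deepgwas.data_io import ConfigError
from deepgwas.schema import DEFAULT_SCHEMA, STAT_FEATURES

logger = logging.getLogger(__name__)

NEGLOG10_P_CAP = 320.0


@dataclass
class IntervalAnnotation:
    """A named set of genomic intervals, stored merged and sorted per chromosome."""

    name: str
    intervals: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, name: str, triples) -> "IntervalAnnotation":
        """Build from an iterable of (chrom, start, end), merging overlaps."""
        by_chrom: dict[str, list] = {}
        for chrom, start, end in triples:
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"{name}: degenerate interval [{start}, {end})")
            by_chrom.setdefault(str(chrom), []).append((start, end))
        merged = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts, ends = [], []
            for s, e in ivs:
                if ends and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            merged[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
        return cls(name=name, intervals=merged)

    @classmethod
    def read_bed(cls, path: str | os.PathLike, name: str | None = None) -> "IntervalAnnotation":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
                         names=["chrom", "start", "end"], dtype={0: str})
        track_name = name or os.path.splitext(os.path.basename(str(path)))[0]
        return cls.from_intervals(track_name, df.itertuples(index=False))

    def to_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                starts, ends = self.intervals[chrom]
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def total_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in self.intervals.values()))

    def contains(self, chrom: str, pos_1based: np.ndarray) -> np.ndarray:
        """Membership for 1-based positions on one chromosome."""
        pos0 = np.asarray(pos_1based, dtype=np.int64) - 1
        if chrom not in self.intervals:
            return np.zeros(len(pos0), dtype=np.uint8)
        starts, ends = self.intervals[chrom]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        hit = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        return hit.astype(np.uint8)


@dataclass
class ScoreTrack:
    """Per-variant continuous scores keyed by variant ID or canonical key."""

    name: str
    values: pd.Series  # index: variant_id or key

    @classmethod
    def read_tsv(cls, path: str | os.PathLike, name: str | None = None,
                 id_col: str = "variant_id", score_col: str = "score") -> "ScoreTrack":
        df = pd.read_csv(path, sep="\t", dtype={id_col: str})
        track_name = name or os.path.splitext(os.path.basename(str(path)))[0]
        return cls(track_name, pd.Series(df[score_col].to_numpy(), index=df[id_col]))


def overlap_indicator(variants: pd.DataFrame, track: IntervalAnnotation) -> np.ndarray:
    """Binary membership of each variant (columns chrom, pos) in the track.

    Chromosomes absent from the track yield 0 with one aggregated warning.
    """
    out = np.zeros(len(variants), dtype=np.uint8)
    unknown = []
    for chrom, idx in variants.groupby("chrom", sort=False).indices.items():
        chrom = str(chrom)
        if chrom not in track.intervals:
            unknown.append(chrom)
            continue
        out[idx] = track.contains(chrom, variants["pos"].to_numpy()[idx])
    if unknown and track.intervals:
        warnings.warn(
            f"track {track.name!r}: {len(unknown)} chromosome(s) absent from track "
            f"({', '.join(sorted(unknown)[:5])})",
            stacklevel=2,
        )
    return out


def score_lookup(
    variants: pd.DataFrame, track: ScoreTrack, fill: str = "zero"
) -> tuple[np.ndarray, int]:
    """Per-variant scores with missing entries filled per policy.

    ``fill`` is "zero" or "median" (median of the track's own values).
    Returns the vector and the number of filled entries. Lookup tries the
    ``variant_id`` column first, then the canonical ``key``.
    """
    if fill not in ("zero", "median"):
        raise ConfigError(f"unknown fill policy {fill!r}; use 'zero' or 'median'")
    by_id = variants["variant_id"].map(track.values) if "variant_id" in variants else None
    vals = by_id if by_id is not None else pd.Series(np.nan, index=variants.index)
    if "key" in variants:
        vals = vals.fillna(variants["key"].map(track.values))
    missing = vals.isna()
    fill_value = 0.0 if fill == "zero" else float(np.nanmedian(track.values.to_numpy()))
    vals = vals.fillna(fill_value)
    return vals.to_numpy(dtype=float), int(missing.sum())


def filter_eqtls(eqtl_table: pd.DataFrame, p_max: float = 1e-6) -> set[str]:
    """Variant keys with any eQTL association at nominal p strictly below p_max.

    Set semantics: a variant significant for several genes or in several
    sources appears once. The table needs columns ``key`` and ``p``.
    """
    keep = eqtl_table["p"] < p_max
    return set(eqtl_table.loc[keep, "key"])


def _intersect_bp(a: IntervalAnnotation, b: IntervalAnnotation) -> int:
    total = 0
    for chrom in a.intervals.keys() & b.intervals.keys():
        sa, ea = a.intervals[chrom]
        sb, eb = b.intervals[chrom]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return total


def jaccard_index(a: IntervalAnnotation, b: IntervalAnnotation) -> float:
    """Base-pair Jaccard similarity: |intersection| / |union|; 0 if union empty."""
    inter = _intersect_bp(a, b)
    union = a.total_bp() + b.total_bp() - inter
    return inter / union if union else 0.0


def union_tracks(name: str, tracks: list[IntervalAnnotation]) -> IntervalAnnotation:
    triples = [
        (chrom, s, e)
        for t in tracks
        for chrom, (starts, ends) in t.intervals.items()
        for s, e in zip(starts, ends)
    ]
    return IntervalAnnotation.from_intervals(name, triples)


def cluster_annotations(
    tracks: list[IntervalAnnotation], n_groups: int = 11
) -> list[IntervalAnnotation]:
    """Group similar tracks into meta-annotations by Jaccard similarity.

    Average-linkage hierarchical clustering on distance 1 − Jaccard, cut at
    ``n_groups`` clusters; each meta-annotation is the base-pair union of
    its members. Tracks are sorted by name first, so the result is
    deterministic and invariant to input order.
    """
    if n_groups > len(tracks):
        raise ConfigError(
            f"n_groups={n_groups} exceeds the {len(tracks)} available tracks"
        )
    tracks = sorted(tracks, key=lambda t: t.name)
    m = len(tracks)
    if n_groups == m:
        labels = np.arange(1, m + 1)
    else:
        dist = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                d = 1.0 - jaccard_index(tracks[i], tracks[j])
                dist[i, j] = dist[j, i] = d
        link = sch.linkage(squareform(dist, checks=False), method="average")
        labels = sch.fcluster(link, t=n_groups, criterion="maxclust")
    metas = []
    order = {}
    for lab in labels:  # clusters numbered by first (name-sorted) member
        if lab not in order:
            order[lab] = len(order) + 1
    for lab in sorted(order, key=order.get):
        members = [t for t, l in zip(tracks, labels) if l == lab]
        metas.append(union_tracks(f"meta_{order[lab]:02d}", members))
    return metas


def assemble_features(
    stats: pd.DataFrame,
    maf: np.ndarray,
    ld_overall: np.ndarray,
    ld_known: np.ndarray,
    indicator_tracks: dict[str, IntervalAnnotation],
    score_tracks: dict[str, ScoreTrack],
    eqtl_keys: set[str],
    schema: list[str] | None = None,
    neglog10_cap: float = NEGLOG10_P_CAP,
    score_fill: str = "zero",
    extra_columns: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble the n × |schema| feature matrix, columns in schema order.

    The five statistics columns (−log10 p capped at ``neglog10_cap``, OR,
    MAF, and the two LD scores) come from the aligned arrays; every other
    schema name must resolve to an indicator track, a score track, "eqtl",
    or an entry of ``extra_columns`` ("user_slot" defaults to zeros).
    """
    schema = list(schema or DEFAULT_SCHEMA)
    if len(set(schema)) != len(schema):
        raise ConfigError("feature schema contains duplicate names")
    extra_columns = extra_columns or {}
    n = len(stats)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(stats["p_value"].to_numpy(dtype=float))
    n_capped = int((neglog > neglog10_cap).sum())
    if n_capped:
        logger.warning("assemble_features: capped −log10(p) at %.0f for %d variants",
                       neglog10_cap, n_capped)
    neglog = np.minimum(neglog, neglog10_cap)

    stat_values = {
        "neglog10_p": neglog,
        "odds_ratio": stats["odds_ratio"].to_numpy(dtype=float),
        "maf": np.asarray(maf, dtype=float),
        "ld_score_overall": np.asarray(ld_overall, dtype=float),
        "ld_score_known": np.asarray(ld_known, dtype=float),
    }
    columns = {}
    for name in schema:
        if name in stat_values:
            col = stat_values[name]
        elif name in indicator_tracks:
            col = overlap_indicator(stats, indicator_tracks[name]).astype(float)
        elif name in score_tracks:
            col, _ = score_lookup(stats, score_tracks[name], fill=score_fill)
        elif name == "eqtl":
            col = stats["key"].isin(eqtl_keys).to_numpy(dtype=float)
        elif name in extra_columns:
            col = np.asarray(extra_columns[name], dtype=float)
        elif name == "user_slot":
            col = np.zeros(n)
        else:
            candidates = sorted(
                list(stat_values) + list(indicator_tracks) + list(score_tracks)
                + ["eqtl", "user_slot"] + list(extra_columns)
            )
            raise ConfigError(
                f"schema feature {name!r} is not resolvable; candidates: {candidates}"
            )
        if len(col) != n:
            raise ConfigError(f"feature {name!r}: length {len(col)} != {n} variants")
        columns[name] = col
    X = pd.DataFrame(columns, index=stats["key"].to_numpy())[schema]
    if not np.isfinite(X.to_numpy()).all():
        bad = X.columns[~np.isfinite(X.to_numpy()).all(axis=0)].tolist()
        raise ValueError(f"non-finite entries in features {bad}")
    return X


__all__ = [
    "IntervalAnnotation",
    "ScoreTrack",
    "overlap_indicator",
    "score_lookup",
    "filter_eqtls",
    "jaccard_index",
    "union_tracks",
    "cluster_annotations",
    "assemble_features",
    "STAT_FEATURES",
    "NEGLOG10_P_CAP",
]
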