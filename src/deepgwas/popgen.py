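"""MAF and LD-score features computed from a genotype reference panel.

Two LD scores are produced per target variant, both over a 1 Mb window:
the overall LD score (self term + sum of r² with every panel variant in
the window) and the LD score with known variants (the sum restricted to
the input GWAS's genome-wide-significant set, self term included iff the
target itself is significant). r² is the squared Pearson correlation of
allele-count vectors, so phased haplotypes are not required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_BP_DEFAULT = 1_000_000


class MonomorphicVariantError(ValueError):
    """r² or MAF requested for a variant with no variation (or all-missing)."""


@dataclass
class GenotypePanel:
    """Reference panel: a variant index plus an individuals × variants dosage matrix.

    Entries are alternate-allele counts in {0, 1, 2} (fractional dosages in
    [0, 2] permitted); NaN marks missing. Variants are kept sorted by
    (chrom, pos).
    """

    variants: pd.DataFrame  # columns: chrom, pos, variant_id, ref, alt, key
    genotypes: np.ndarray  # shape (n_individuals, n_variants)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.genotypes.shape[0] < 2:
            raise ValueError("panel needs at least 2 individuals")
        if self.genotypes.shape[1] != len(self.variants):
            raise ValueError("genotype matrix / variant table length mismatch")
        order = np.lexsort(
            (self.variants["pos"].to_numpy(), self.variants["chrom"].to_numpy())
        )
        if not np.array_equal(order, np.arange(len(order))):
            self.variants = self.variants.iloc[order].reset_index(drop=True)
            self.genotypes = self.genotypes[:, order]
        self.genotypes = np.asarray(self.genotypes, dtype=np.float64)
        self._index = {k: i for i, k in enumerate(self.variants["key"])}

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def loc(self, key: str) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"variant {key!r} not in panel") from None

    def column(self, key: str) -> np.ndarray:
        return self.genotypes[:, self.loc(key)]


def compute_maf(panel: GenotypePanel, key: str) -> float:
    """Minor allele frequency min(f, 1−f) over non-missing individuals."""
    g = panel.column(key)
    ok = ~np.isnan(g)
    if not ok.any():
        raise MonomorphicVariantError(f"{key}: all genotypes missing, MAF undefined")
    f = g[ok].mean() / 2.0
    return float(min(f, 1.0 - f))


def maf_vector(panel: GenotypePanel) -> np.ndarray:
    """MAF for every panel variant (NaN where all genotypes are missing)."""
    with np.errstate(invalid="ignore"):
        f = np.nanmean(panel.genotypes, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def pairwise_r2(panel: GenotypePanel, key_i: str, key_j: str) -> float:
    """Squared Pearson correlation of two allele-count vectors.

    Uses individuals with both genotypes non-missing. Raises
    :class:`MonomorphicVariantError` if either variant has zero variance
    over that set (callers treating this as a 0 contribution should catch
    it; the LD-score functions do).
    """
    if key_i == key_j:
        return 1.0
    gi, gj = panel.column(key_i), panel.column(key_j)
    ok = ~np.isnan(gi) & ~np.isnan(gj)
    xi, xj = gi[ok], gj[ok]
    if len(xi) < 2 or xi.std() == 0 or xj.std() == 0:
        raise MonomorphicVariantError(
            f"r² undefined for pair ({key_i}, {key_j}): monomorphic or too few complete pairs"
        )
    r = np.corrcoef(xi, xj)[0, 1]
    return float(r * r)


def _r2_or_zero(panel, key_i, key_j) -> float:
    try:
        return pairwise_r2(panel, key_i, key_j)
    except MonomorphicVariantError:
        logger.debug("treating undefined r² (%s, %s) as 0", key_i, key_j)
        return 0.0


def _window_keys(panel: GenotypePanel, target: str, window_bp: int) -> list[str]:
    i = panel.loc(target)
    v = panel.variants
    chrom, pos = v.at[i, "chrom"], v.at[i, "pos"]
    same = v[(v["chrom"] == chrom) & ((v["pos"] - pos).abs() <= window_bp)]
    return [k for k in same["key"] if k != target]


def ld_score_overall(
    panel: GenotypePanel,
    target: str,
    window_bp: int = WINDOW_BP_DEFAULT,
    include_self: bool = True,
) -> float:
    """Self term (if configured) + Σ r²(target, v) over window neighbours."""
    total = 1.0 if include_self else 0.0
    for k in _window_keys(panel, target, window_bp):
        total += _r2_or_zero(panel, target, k)
    return total


def ld_score_known(
    panel: GenotypePanel,
    target: str,
    known: set[str],
    window_bp: int = WINDOW_BP_DEFAULT,
    include_self: bool = True,
) -> float:
    """Σ r²(target, v) over known (input-GWAS-significant) window neighbours.

    The self term counts iff the target itself is in the known set (and the
    self-term convention is enabled), so "known = all panel variants"
    reproduces the overall LD score exactly.
    """
    total = 1.0 if (include_self and target in known) else 0.0
    for k in _window_keys(panel, target, window_bp):
        if k in known:
            total += _r2_or_zero(panel, target, k)
    return total


def ld_scores(
    panel: GenotypePanel,
    known_masks: dict[str, np.ndarray] | None = None,
    window_bp: int = WINDOW_BP_DEFAULT,
    include_self: bool = True,
    chunk: int = 512,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Vectorised LD scores for every panel variant in one pass.

    ``known_masks`` maps a label (e.g. a study name) to a boolean mask over
    panel variants marking that study's significant set; the matching
    restricted LD scores come back under the same label. Assumes missing
    genotypes are rare (mean-imputed here; the per-variant functions use
    pairwise-complete individuals — identical on complete panels).
    """
    known_masks = known_masks or {}
    n_var = panel.n_variants
    G = panel.genotypes
    mu = np.nanmean(G, axis=0)
    Z = G - mu[None, :]
    Z[np.isnan(Z)] = 0.0
    norms = np.sqrt((Z**2).sum(axis=0))
    safe = np.where(norms == 0, 1.0, norms)
    U = Z / safe[None, :]
    U[:, norms == 0] = 0.0  # monomorphic: zero contribution everywhere

    overall = np.zeros(n_var)
    known = {name: np.zeros(n_var) for name in known_masks}
    pos_all = panel.variants["pos"].to_numpy()
    chroms = panel.variants["chrom"].to_numpy()

    start = 0
    while start < n_var:
        stop = start
        while stop < n_var and chroms[stop] == chroms[start]:
            stop += 1
        pos = pos_all[start:stop]
        for s in range(start, stop, chunk):
            e = min(s + chunk, stop)
            ws = start + int(np.searchsorted(pos, pos_all[s] - window_bp, side="left"))
            we = start + int(np.searchsorted(pos, pos_all[e - 1] + window_bp, side="right"))
            r2 = (U[:, s:e].T @ U[:, ws:we]) ** 2
            in_win = (
                np.abs(pos_all[s:e][:, None] - pos_all[ws:we][None, :]) <= window_bp
            )
            r2 = np.where(in_win, r2, 0.0)
            rows = np.arange(e - s)
            r2[rows, np.arange(s, e) - ws] = 0.0  # drop self column
            overall[s:e] = r2.sum(axis=1) + (1.0 if include_self else 0.0)
            for name, mask in known_masks.items():
                vals = r2 @ mask[ws:we].astype(float)
                if include_self:
                    vals = vals + mask[s:e].astype(float)
                known[name][s:e] = vals
        start = stop
    return overall, known
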