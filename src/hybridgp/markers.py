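"""Marker quality control for biallelic SNP panels of inbred lines.

Genotypes are coded per line and marker as -1 (homozygous reference),
0 (heterozygous) and +1 (homozygous alternate), with NaN for missing calls.
QC removes markers with low minor-allele frequency or high missingness, and a
naive per-marker mode imputer fills the surviving gaps so that downstream
design-matrix and kinship computations see a complete matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

VALID_CODES = (-1.0, 0.0, 1.0)


@dataclass
class GenotypeMatrix:
    """Lines x markers genotype codes with a physical marker map.

    Parameters
    ----------
    lines
        Line identifiers (rows).
    markers
        Marker identifiers (columns), unique.
    codes
        Float array of shape ``(n_lines, n_markers)`` with values in
        {-1, 0, +1} and NaN for missing calls.
    marker_map
        DataFrame indexed by marker ID with columns ``chrom``, ``pos``,
        ``ref``, ``alt``.
    """

    lines: list[str]
    markers: list[str]
    codes: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker IDs")
        if not self.marker_map.index.equals(pd.Index(self.markers)):
            raise ValueError("marker_map index must equal the marker ID list")
        if (self.marker_map["pos"] < 0).any():
            raise ValueError("marker positions must be non-negative")
        finite = self.codes[~np.isnan(self.codes)]
        if finite.size and not np.isin(finite, VALID_CODES).all():
            bad = sorted(set(finite) - set(VALID_CODES))
            raise ValueError(f"genotype codes outside {{-1, 0, +1}}: {bad}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a copy keeping markers where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        keep = [m for m, k in zip(self.markers, mask) if k]
        return GenotypeMatrix(
            lines=list(self.lines),
            markers=keep,
            codes=self.codes[:, mask].copy(),
            marker_map=self.marker_map.loc[keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.lines, columns=self.markers)


@dataclass
class MarkerStats:
    """Per-marker QC statistics and per-chromosome marker counts."""

    maf: pd.Series
    missing_rate: pd.Series
    chrom_counts: pd.Series

    def __post_init__(self) -> None:
        if ((self.maf < 0) | (self.maf > 0.5)).any():
            raise ValueError("MAF outside [0, 0.5]")
        if ((self.missing_rate < 0) | (self.missing_rate > 1)).any():
            raise ValueError("missing rate outside [0, 1]")
        if int(self.chrom_counts.sum()) != len(self.maf):
            raise ValueError("chromosome counts do not sum to the marker total")


@dataclass
class FilterResult:
    """Filtered genotypes plus a retention report."""

    genotypes: GenotypeMatrix
    retained_mask: np.ndarray
    n_input: int
    n_retained: int
    n_removed_maf: int
    n_removed_missing: int

    @property
    def report(self) -> pd.Series:
        return pd.Series(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "n_removed_maf": self.n_removed_maf,
                "n_removed_missing": self.n_removed_missing,
            }
        )


def compute_marker_stats(genotypes: GenotypeMatrix) -> MarkerStats:
    """Minor-allele frequency, missing rate and chromosome counts per marker.

    Allele counting treats each homozygous line (+1 or -1) as carrying two
    copies of one allele and a heterozygous line (0) as one copy of each;
    frequencies use non-missing calls only.  An all-missing marker is an
    error because its MAF is undefined.
    """
    codes = genotypes.codes
    missing = np.isnan(codes)
    n_obs = (~missing).sum(axis=0)
    if (n_obs == 0).any():
        bad = [m for m, n in zip(genotypes.markers, n_obs) if n == 0]
        raise ValueError(f"all calls missing for marker(s): {bad[:5]}")
    # alt-allele copies: code c contributes c + 1 copies of the alt allele
    alt_copies = np.nansum(codes + 1.0, axis=0)
    alt_freq = alt_copies / (2.0 * n_obs)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    missing_rate = missing.sum(axis=0) / genotypes.n_lines
    chrom_counts = (
        genotypes.marker_map["chrom"].value_counts(sort=False).sort_index()
    )
    idx = pd.Index(genotypes.markers)
    return MarkerStats(
        maf=pd.Series(maf, index=idx, name="maf"),
        missing_rate=pd.Series(missing_rate, index=idx, name="missing_rate"),
        chrom_counts=chrom_counts,
    )


def filter_markers(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.20,
) -> FilterResult:
    """Remove markers with MAF below ``maf_min`` or missingness above
    ``missing_max``; both boundaries are kept. Marker order is preserved.
    """
    stats = compute_marker_stats(genotypes)
    keep_maf = stats.maf.to_numpy() >= maf_min
    keep_miss = stats.missing_rate.to_numpy() <= missing_max
    keep = keep_maf & keep_miss
    if not keep.any():
        warnings.warn("all markers removed by QC filters", stacklevel=2)
    return FilterResult(
        genotypes=genotypes.subset_markers(keep),
        retained_mask=keep,
        n_input=genotypes.n_markers,
        n_retained=int(keep.sum()),
        n_removed_maf=int((~keep_maf).sum()),
        n_removed_missing=int((keep_maf & ~keep_miss).sum()),
    )


def impute_naive(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing calls with the per-marker modal code.

    Ties between modal codes are resolved by the per-marker mean of observed
    codes rounded toward zero (so a +1/-1 tie imputes the heterozygous 0).
    A deliberately simple stand-in for haplotype-aware imputation.
    """
    codes = genotypes.codes.copy()
    missing = np.isnan(codes)
    if not missing.any():
        return genotypes
    n_obs = (~missing).sum(axis=0)
    if (n_obs == 0).any():
        bad = [m for m, n in zip(genotypes.markers, n_obs) if n == 0]
        raise ValueError(f"cannot impute all-missing marker(s): {bad[:5]}")
    for j in np.where(missing.any(axis=0))[0]:
        col = codes[:, j]
        obs = col[~np.isnan(col)]
        values, counts = np.unique(obs, return_counts=True)
        top = values[counts == counts.max()]
        if len(top) == 1:
            fill = top[0]
        else:
            fill = float(np.trunc(obs.mean()))
        col[np.isnan(col)] = fill
    return GenotypeMatrix(
        lines=list(genotypes.lines),
        markers=list(genotypes.markers),
        codes=codes,
        marker_map=genotypes.marker_map.copy(),
    )


def chromosome_density(
    stats: MarkerStats | Mapping[str, int] | pd.Series,
) -> pd.Series:
    """Per-chromosome marker counts plus total and integer-truncated mean.

    Accepts either full :class:`MarkerStats` or a plain chromosome->count
    mapping.  The mean density is truncated (not rounded) toward zero.
    """
    if isinstance(stats, MarkerStats):
        counts = stats.chrom_counts
    else:
        counts = pd.Series(stats)
    counts = counts.astype(int)
    total = int(counts.sum())
    mean_truncated = total // len(counts)
    out = counts.copy()
    out.loc["total"] = total
    out.loc["mean_per_chromosome"] = mean_truncated
    return out
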