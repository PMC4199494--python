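"""Phased haplotype samples and analysis windows.

The :class:`HaplotypeSample` is the in-memory currency of the whole package:
a binary haplotype-by-site matrix (0 = ancestral allele, 1 = derived allele)
with base-pair positions, one population label per haplotype row and an
optional focal-site index. Both the simulator and the VCF reader produce it;
every summary statistic consumes it.

Coordinates are 0-based and half-open internally; the VCF reader is the only
place where 1-based coordinates appear.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import SweepABCError


@dataclass
class HaplotypeSample:
    """Phased binary haplotypes at segregating sites for one or two populations.

    Parameters
    ----------
    matrix
        ``(n_haplotypes, n_sites)`` array with entries in {0, 1};
        0 is the ancestral allele, 1 the derived allele.
    positions
        Base-pair position of each site inside the region, strictly
        increasing. Positions may be fractional (the simulator places
        mutations continuously).
    pop_labels
        One label per haplotype row. At most two distinct populations.
    focal_index
        Column index of the focal variant, or ``None``.
    region_length
        Length of the surveyed region in bp.
    """

    matrix: np.ndarray
    positions: np.ndarray
    pop_labels: np.ndarray
    focal_index: int | None = None
    region_length: float | None = None

    def __post_init__(self):
        self.matrix = np.ascontiguousarray(np.asarray(self.matrix, dtype=np.uint8))
        if self.matrix.ndim != 2:
            raise SweepABCError("haplotype matrix must be 2-D")
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.pop_labels = np.asarray(self.pop_labels)
        n, s = self.matrix.shape
        if self.positions.shape != (s,):
            raise SweepABCError(
                f"positions length {self.positions.shape} does not match "
                f"{s} sites"
            )
        if self.pop_labels.shape != (n,):
            raise SweepABCError("one population label per haplotype required")
        if s and not (self.matrix <= 1).all():
            raise SweepABCError("haplotype matrix entries must be 0/1")
        if s > 1 and not (np.diff(self.positions) > 0).all():
            raise SweepABCError("positions must be strictly increasing")
        if len(self.pops()) > 2:
            raise SweepABCError("at most two populations are supported")
        if self.focal_index is not None:
            if not (0 <= self.focal_index < s):
                raise SweepABCError("focal_index out of range")
            col = self.matrix[:, self.focal_index]
            if col.min() == col.max():
                raise SweepABCError("focal site must be biallelic in the pooled sample")
        if self.region_length is None and s:
            self.region_length = float(np.ceil(self.positions[-1]) + 1)

    # -- basic views ---------------------------------------------------
    def pops(self) -> list:
        """Population labels in order of first appearance."""
        seen: dict = {}
        for lab in self.pop_labels:
            seen.setdefault(lab, None)
        return list(seen)

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def pop_mask(self, pop) -> np.ndarray:
        mask = self.pop_labels == pop
        if not mask.any():
            raise SweepABCError(f"population {pop!r} not present in sample")
        return mask

    def haplotypes_of(self, pop) -> np.ndarray:
        """Rows belonging to ``pop`` (view when possible)."""
        return self.matrix[self.pop_mask(pop)]

    def derived_counts(self, pop=None) -> np.ndarray:
        """Per-site derived-allele counts, optionally within one population."""
        m = self.matrix if pop is None else self.haplotypes_of(pop)
        return m.sum(axis=0, dtype=np.int64)

    def derived_freq(self, pop=None, site: int | None = None) -> float:
        """Derived-allele frequency at ``site`` (default: the focal site)."""
        if site is None:
            if self.focal_index is None:
                raise SweepABCError("sample has no focal site")
            site = self.focal_index
        m = self.matrix if pop is None else self.haplotypes_of(pop)
        return float(m[:, site].mean())

    @property
    def focal_position(self) -> float:
        if self.focal_index is None:
            raise SweepABCError("sample has no focal site")
        return float(self.positions[self.focal_index])

    def restrict_sites(self, site_mask: np.ndarray) -> "HaplotypeSample":
        """A copy limited to the sites selected by a boolean mask."""
        site_mask = np.asarray(site_mask, dtype=bool)
        focal = None
        if self.focal_index is not None and site_mask[self.focal_index]:
            focal = int(site_mask[: self.focal_index].sum())
        return replace(
            self,
            matrix=self.matrix[:, site_mask],
            positions=self.positions[site_mask],
            focal_index=focal,
        )


@dataclass(frozen=True)
class WindowSpec:
    """A window around the focal site over which statistics are computed.

    ``up_bp`` extends toward lower coordinates (upstream of the focal site in
    the internal orientation), ``down_bp`` toward higher coordinates. The two
    shipped defaults follow the 4 kb symmetric / 8 kb asymmetric (6 kb
    upstream + 2 kb downstream) windows used throughout the analysis.
    """

    kind: str = "symmetric"
    up_bp: float = 2000.0
    down_bp: float = 2000.0

    def __post_init__(self):
        if self.kind not in ("symmetric", "asymmetric", "whole_region"):
            raise SweepABCError(f"unknown window kind {self.kind!r}")
        if self.up_bp < 0 or self.down_bp < 0:
            raise SweepABCError("window extents must be non-negative")

    @classmethod
    def symmetric_4kb(cls) -> "WindowSpec":
        return cls("symmetric", 2000.0, 2000.0)

    @classmethod
    def asymmetric_8kb(cls) -> "WindowSpec":
        return cls("asymmetric", 6000.0, 2000.0)

    @classmethod
    def whole_region(cls) -> "WindowSpec":
        return cls("whole_region", 0.0, 0.0)

    def site_mask(self, sample: HaplotypeSample) -> np.ndarray:
        """Boolean mask of sites inside the window (clipped to the region)."""
        if self.kind == "whole_region":
            return np.ones(sample.n_sites, dtype=bool)
        centre = sample.focal_position
        lo, hi = centre - self.up_bp, centre + self.down_bp
        return (sample.positions >= lo) & (sample.positions <= hi)
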