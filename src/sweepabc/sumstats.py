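"""Within- and between-population summary statistics.

Implements the statistics used to characterise the focal region: nucleotide
diversity π, Watterson's θ, Tajima's D, Fay & Wu's H (unnormalised θ_π −
θ_H form), Weir-Cockerham and Reynolds F_ST estimators, extended haplotype
homozygosity (EHH), its integral iHH, raw iHS and XP-EHH, frequency-binned
standardisation and empirical p-values, plus the named summary vector the
ABC machinery consumes.

Statistics that are mathematically undefined for an input (Tajima's D with
no segregating site, F_ST at a site monomorphic in both populations, EHH
with fewer than two core-allele carriers) raise
:class:`~sweepabc.errors.UndefinedStatisticError` rather than returning 0;
the summary-vector builder converts those into NaN sentinels and flags the
vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import ehh_curve
from .errors import SweepABCError, UndefinedStatisticError
from .haplotypes import HaplotypeSample, WindowSpec
from .io_formats import GeneticMap

__all__ = [
    "FstComponents", "SummaryVector", "ScoreDistribution", "IhhResult",
    "pairwise_diversity", "watterson_theta", "tajimas_d", "fay_wu_h",
    "wc_fst_site", "wc_fst_components", "region_fst", "reynolds_fst_site",
    "ehh", "ihh", "ihs", "xpehh", "standardize_binned", "empirical_pvalue",
    "compute_summary_vector", "default_registry",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FstComponents:
    """Weir-Cockerham (1984) per-site variance components.

    ``a`` among populations, ``b`` among individuals within populations,
    ``c`` within individuals; the estimator is θ̂ = a/(a+b+c).
    """

    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if denom == 0:
            raise UndefinedStatisticError(
                "F_ST undefined: zero total variance (monomorphic site)")
        return self.a / denom


@dataclass
class SummaryVector:
    """Named, deterministically ordered map statistic-id -> value.

    Undefined entries hold NaN and are listed in ``flags``.
    """

    values: dict
    flags: set = field(default_factory=set)

    def as_array(self, keys=None) -> np.ndarray:
        keys = list(self.values) if keys is None else keys
        return np.array([self.values[k] for k in keys], dtype=float)

    @property
    def is_complete(self) -> bool:
        return not self.flags


@dataclass
class ScoreDistribution:
    """Sorted empirical score distribution with a designated tail."""

    values: np.ndarray
    tail: str = "upper"

    def __post_init__(self):
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if self.values.size < 2:
            raise SweepABCError("score distribution needs at least 2 values")
        if self.tail not in ("upper", "lower"):
            raise SweepABCError("tail must be 'upper' or 'lower'")


@dataclass(frozen=True)
class IhhResult:
    """Integrated EHH (cM) with an edge-truncation flag."""

    value: float
    edge_truncated: bool


@dataclass(frozen=True)
class EmpiricalPValue:
    """Empirical p-value; ``is_floor`` marks the zero-exceedance bound 1/N."""

    p: float
    is_floor: bool = False

    def __float__(self):
        return self.p


# ---------------------------------------------------------------------------
# SFS statistics
# ---------------------------------------------------------------------------

def _window_counts(sample: HaplotypeSample, window: WindowSpec, pop):
    """Derived counts per in-window site and the population haplotype count."""
    hap = sample.haplotypes_of(pop)
    n = hap.shape[0]
    mask = window.site_mask(sample)
    counts = hap[:, mask].sum(axis=0, dtype=np.int64)
    return counts, n


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float((1.0 / i ** power).sum())


def pairwise_diversity(sample, window, pop) -> float:
    """π: mean number of pairwise differences between haplotypes in the
    window, Σ 2i(n−i)/(n(n−1)) over sites with derived count i."""
    counts, n = _window_counts(sample, window, pop)
    if n < 2:
        raise UndefinedStatisticError("pairwise diversity needs >= 2 haplotypes")
    return float((2.0 * counts * (n - counts)).sum() / (n * (n - 1)))


def watterson_theta(sample, window, pop) -> float:
    """Watterson's θ_W = S / a_n with a_n = Σ_{i<n} 1/i."""
    counts, n = _window_counts(sample, window, pop)
    if n < 2:
        raise UndefinedStatisticError("Watterson's theta needs >= 2 haplotypes")
    S = int(((counts > 0) & (counts < n)).sum())
    return S / _harmonic(n)


def tajimas_d(sample, window, pop) -> float:
    """Tajima's D with the 1989 normalising constants.

    Raises :class:`UndefinedStatisticError` when the window has no
    segregating site (the statistic is 0/0, not 0).
    """
    counts, n = _window_counts(sample, window, pop)
    if n < 2:
        raise UndefinedStatisticError("Tajima's D needs >= 2 haplotypes")
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        raise UndefinedStatisticError("Tajima's D undefined for S = 0")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    pi = (2.0 * counts * (n - counts)).sum() / (n * (n - 1))
    var = e1 * S + e2 * S * (S - 1)
    return float((pi - S / a1) / np.sqrt(var))


def fay_wu_h(sample, window, pop) -> float:
    """Fay & Wu's H = θ_π − θ_H (unnormalised 2000 form).

    θ_H = Σ 2i²/(n(n−1)) weights high-frequency derived alleles; a negative
    H signals their excess, the footprint of a recent sweep. Requires
    derived/ancestral polarisation, which HaplotypeSample carries by
    construction.
    """
    counts, n = _window_counts(sample, window, pop)
    if n < 2:
        raise UndefinedStatisticError("Fay & Wu's H needs >= 2 haplotypes")
    seg = (counts > 0) & (counts < n)
    i = counts[seg].astype(float)
    theta_pi = (2.0 * i * (n - i)).sum() / (n * (n - 1))
    theta_h = (2.0 * i * i).sum() / (n * (n - 1))
    return float(theta_pi - theta_h)


# ---------------------------------------------------------------------------
# F_ST estimators
# ---------------------------------------------------------------------------

def wc_fst_components(genotype_counts) -> FstComponents:
    """Weir-Cockerham (1984) a, b, c from per-population diploid genotype
    counts ``[(n_AA, n_Aa, n_aa), ...]`` (a = derived allele) for r = 2
    populations, using the observed heterozygote frequencies."""
    gc = np.asarray(genotype_counts, dtype=float)
    if gc.shape != (2, 3):
        raise SweepABCError("need genotype counts for exactly two populations")
    n_i = gc.sum(axis=1)
    if (n_i < 1).any():
        raise UndefinedStatisticError("each population needs >= 1 genotype")
    r = 2.0
    p_i = (gc[:, 1] + 2 * gc[:, 2]) / (2 * n_i)
    h_i = gc[:, 1] / n_i
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    if nbar <= 1 or nc <= 0:
        raise UndefinedStatisticError("sample sizes too small for W&C F_ST")
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return FstComponents(float(a), float(b), float(c))


def wc_fst_site(genotype_counts) -> tuple[FstComponents, float]:
    """Per-site Weir-Cockerham θ̂ (may be negative; 1 for a fixed
    difference; undefined when monomorphic in both populations)."""
    comp = wc_fst_components(genotype_counts)
    return comp, comp.theta


def genotype_counts_at(sample: HaplotypeSample, site: int):
    """Diploid genotype counts per population, pairing consecutive
    haplotypes (phased GT order defines the individuals)."""
    out = []
    for pop in sample.pops():
        hap = sample.haplotypes_of(pop)[:, site]
        if hap.size % 2:
            raise SweepABCError(f"odd haplotype count in {pop!r}")
        g = hap[0::2] + hap[1::2]
        out.append([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()])
    if len(out) != 2:
        raise SweepABCError("two populations required for F_ST")
    return out


def region_fst(sample: HaplotypeSample, window: WindowSpec) -> float:
    """Multi-site Weir-Cockerham θ̂ as a ratio of sums Σa / Σ(a+b+c) over
    in-window sites (not a mean of per-site ratios)."""
    mask = window.site_mask(sample)
    sites = np.flatnonzero(mask)
    num = den = 0.0
    usable = 0
    for s in sites:
        try:
            comp = wc_fst_components(genotype_counts_at(sample, s))
        except UndefinedStatisticError:
            continue
        tot = comp.a + comp.b + comp.c
        if tot == 0:
            continue
        num += comp.a
        den += tot
        usable += 1
    if usable == 0 or den == 0:
        raise UndefinedStatisticError("no usable polymorphic site in window")
    return num / den


def reynolds_fst_site(allele_counts) -> float:
    """Reynolds-Weir-Cockerham (1983) per-site θ̂ from haploid allele
    counts ``[(n_haplotypes, n_derived), (n_haplotypes, n_derived)]``.

    The allele-count analogue of the 1984 estimator (no within-individual
    term); 1 for a fixed difference, ≤ 0 for identical frequencies.
    """
    (n1, d1), (n2, d2) = allele_counts
    if n1 < 2 or n2 < 2:
        raise UndefinedStatisticError("each population needs >= 2 haplotypes")
    r = 2.0
    n_i = np.array([n1, n2], dtype=float)
    p_i = np.array([d1 / n1, d2 / n2])
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    if a + b == 0:
        raise UndefinedStatisticError(
            "Reynolds F_ST undefined: site monomorphic in both populations")
    return float(a / (a + b))


# ---------------------------------------------------------------------------
# haplotype homozygosity
# ---------------------------------------------------------------------------

def _carriers(sample, pop, core_site, core_allele):
    """Rows carrying ``core_allele`` at the core; ``None`` pools all rows."""
    hap = sample.haplotypes_of(pop)
    if core_allele is None:
        return hap
    return hap[hap[:, core_site] == core_allele]


def ehh(sample, pop, core_site, core_allele, target_site) -> float:
    """Extended haplotype homozygosity: fraction of core-allele-carrier
    pairs identical at every site between core and target inclusive."""
    car = _carriers(sample, pop, core_site, core_allele)
    k = car.shape[0]
    if k < 2:
        raise UndefinedStatisticError("EHH needs >= 2 core-allele carriers")
    lo, hi = sorted((core_site, target_site))
    seg = car[:, lo:hi + 1]
    _, counts = np.unique(seg, axis=0, return_counts=True)
    return float((counts * (counts - 1)).sum() / (k * (k - 1)))


def _ihh_one_side(car, sample, core_site, gmap, truncation, direction):
    """Trapezoid integral of the EHH decay on one side of the core.

    Integrates EHH against genetic distance outward until the first site
    where EHH < truncation (that closing trapezoid included); if EHH never
    falls below the threshold the integral runs to the region edge with the
    last EHH value and is flagged edge-truncated.
    """
    if direction > 0:
        cols = np.arange(core_site, sample.n_sites)
        edge_bp = sample.region_length
    else:
        cols = np.arange(core_site, -1, -1)
        edge_bp = 0.0
    # the scan includes the core column, so EHH at distance 0 is the core
    # homozygosity (1 for allele-specific carrier sets, p^2+q^2 pooled)
    curve = ehh_curve(np.ascontiguousarray(car[:, cols]))
    g = gmap.genetic_position(sample.positions)
    total = 0.0
    e_prev, g_prev = curve[0], g[core_site]
    if e_prev < truncation:
        return 0.0, False
    for j in range(1, len(cols)):
        e_cur = curve[j]
        g_cur = g[cols[j]]
        total += 0.5 * (e_prev + e_cur) * abs(g_cur - g_prev)
        if e_cur < truncation:
            return total, False
        e_prev, g_prev = e_cur, g_cur
    g_edge = gmap.genetic_position(edge_bp)
    total += e_prev * abs(float(g_edge) - g_prev)
    return total, True


def ihh(sample, pop, core_site, core_allele, gmap: GeneticMap,
        truncation: float = 0.05) -> IhhResult:
    """Integrated EHH (cM) of ``core_allele`` at ``core_site``, both
    directions summed; see :func:`_ihh_one_side` for the truncation rule."""
    car = _carriers(sample, pop, core_site, core_allele)
    if car.shape[0] < 2:
        raise UndefinedStatisticError("iHH needs >= 2 core-allele carriers")
    right, edge_r = _ihh_one_side(car, sample, core_site, gmap, truncation, +1)
    left, edge_l = _ihh_one_side(car, sample, core_site, gmap, truncation, -1)
    return IhhResult(left + right, edge_l or edge_r)


def ihs(sample, pop, core_site, gmap, truncation: float = 0.05,
        min_maf: float = 0.05) -> float:
    """Raw (unstandardised) iHS = ln(iHH_ancestral / iHH_derived).

    Cores below the minor-allele-frequency filter are rejected; a zero iHH
    in either allelic class makes the score undefined.
    """
    freq = sample.derived_freq(pop, core_site)
    if min(freq, 1 - freq) < min_maf:
        raise UndefinedStatisticError(
            f"core site below the {min_maf:.0%} MAF filter")
    ihh_anc = ihh(sample, pop, core_site, 0, gmap, truncation).value
    ihh_der = ihh(sample, pop, core_site, 1, gmap, truncation).value
    if ihh_anc <= 0 or ihh_der <= 0:
        raise UndefinedStatisticError("zero iHH in one allelic class")
    return float(np.log(ihh_anc / ihh_der))


def xpehh(sample_a: HaplotypeSample, sample_b: HaplotypeSample, core_site,
          gmap, truncation: float = 0.05,
          core_allele: int | None = None) -> float:
    """Raw XP-EHH = ln(iHH_A / iHH_B) at the core site.

    By default the site-wise pooled definition is used: EHH is computed
    over all haplotypes of each population from the core site outward (the
    statistic's original cross-population form). Passing ``core_allele=1``
    (or 0) restricts to carriers of that allele instead. Positive values
    mean longer haplotypes around the core in population A (the
    candidate-selected population); swapping A and B negates the score.
    """
    vals = []
    for smp in (sample_a, sample_b):
        pop = smp.pops()
        if len(pop) != 1:
            raise SweepABCError("xpehh expects single-population samples")
        v = ihh(smp, pop[0], core_site, core_allele, gmap, truncation).value
        if v <= 0:
            raise UndefinedStatisticError("zero iHH in one population")
        vals.append(v)
    return float(np.log(vals[0] / vals[1]))


def single_pop_view(sample: HaplotypeSample, pop) -> HaplotypeSample:
    """One population's rows as a standalone sample (the focal index is
    carried over even if the focal site is monomorphic within the subset)."""
    mask = sample.pop_mask(pop)
    sub = HaplotypeSample(
        matrix=sample.matrix[mask],
        positions=sample.positions,
        pop_labels=sample.pop_labels[mask],
        focal_index=None,
        region_length=sample.region_length,
    )
    sub.focal_index = sample.focal_index
    return sub


# ---------------------------------------------------------------------------
# standardisation and empirical p-values
# ---------------------------------------------------------------------------

def standardize_binned(scores, freqs, bin_width: float = 0.01):
    """Z-score raw scores within derived-allele-frequency bins.

    Scores are binned by frequency (default 1% bins) and standardised to
    mean 0 / sd 1 within each bin; bins holding fewer than 2 scores are
    merged with the nearest populated bin (returned in ``merged_bins``).

    Returns ``(standardised scores, merged_bins)``.
    """
    scores = np.asarray(scores, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if scores.shape != freqs.shape:
        raise SweepABCError("scores and freqs must align")
    nb = max(1, int(round(1.0 / bin_width)))
    idx = np.minimum((freqs / bin_width).astype(int), nb - 1)
    counts = np.bincount(idx, minlength=nb)
    # merge under-filled bins into the nearest bin with >= 2 scores
    merged: list = []
    target = np.arange(nb)
    ok = counts >= 2
    if not ok.any():
        raise SweepABCError("no frequency bin holds >= 2 scores")
    ok_bins = np.flatnonzero(ok)
    for b in np.flatnonzero(~ok):
        if counts[b] == 0:
            continue
        nearest = ok_bins[np.argmin(np.abs(ok_bins - b))]
        target[b] = nearest
        merged.append((int(b), int(nearest)))
    eff = target[idx]
    out = np.empty_like(scores)
    for b in np.unique(eff):
        sel = eff == b
        mu = scores[sel].mean()
        sd = scores[sel].std()
        if sd == 0:
            raise SweepABCError(f"zero score variance in frequency bin {b}")
        out[sel] = (scores[sel] - mu) / sd
    return out, merged


def empirical_pvalue(score, dist: ScoreDistribution) -> EmpiricalPValue:
    """Empirical p-value of ``score`` against a reference distribution.

    Upper tail: p = #{x >= score}/N (the focal score is not re-added); ties
    count as exceedances. With zero exceedances the floor bound 1/N is
    reported and flagged rather than p = 0.
    """
    vals = dist.values
    N = vals.size
    if dist.tail == "upper":
        k = N - np.searchsorted(vals, score, side="left")
    else:
        k = np.searchsorted(vals, score, side="right")
    if k == 0:
        return EmpiricalPValue(1.0 / N, is_floor=True)
    return EmpiricalPValue(float(k) / N, is_floor=False)


# ---------------------------------------------------------------------------
# summary vectors
# ---------------------------------------------------------------------------

_SFS_STATS = {
    "pi": pairwise_diversity,
    "thetaW": watterson_theta,
    "tajD": tajimas_d,
    "fwH": fay_wu_h,
}
_WINDOWS = {
    "w4kb": WindowSpec.symmetric_4kb,
    "w8kb": WindowSpec.asymmetric_8kb,
    "region": WindowSpec.whole_region,
}


def default_registry() -> list:
    """The default statistic registry: {π, θ_W, D, H} × {4 kb, 8 kb} ×
    both populations, Reynolds F_ST at the focal site, Weir-Cockerham F_ST
    in 4 kb and over the whole region, raw XP-EHH at the focal site, and
    the derived focal-allele frequency in each population (22 entries)."""
    reg = []
    for p in ("p1", "p2"):
        for w in ("w4kb", "w8kb"):
            for s in ("pi", "thetaW", "tajD", "fwH"):
                reg.append(f"{s}_{w}_{p}")
    reg += ["fst_site", "fst_w4kb", "fst_region", "xpehh_site",
            "daf_p1", "daf_p2"]
    return reg


def _tajima_constants(n: int):
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def _wc_components_vec(hap0: np.ndarray, hap1: np.ndarray):
    """Vectorised per-site Weir-Cockerham a, b, c over all sites at once
    (same formulas as :func:`wc_fst_components`, consecutive-haplotype
    genotype pairing)."""
    g0 = hap0[0::2].astype(np.int16) + hap0[1::2]
    g1 = hap1[0::2].astype(np.int16) + hap1[1::2]
    n_i = np.array([g0.shape[0], g1.shape[0]], float)
    r = 2.0
    p = np.stack([g0.mean(axis=0) / 2.0, g1.mean(axis=0) / 2.0])
    hh = np.stack([(g0 == 1).mean(axis=0), (g1 == 1).mean(axis=0)])
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * hh).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def compute_summary_vector(sample: HaplotypeSample, gmap: GeneticMap,
                           registry: list | None = None,
                           truncation: float = 0.05) -> SummaryVector:
    """Evaluate every registry statistic on a two-population sample.

    ``p1``/``p2`` refer to the first/second population by order of first
    appearance (the convention throughout: p1 is the reference/African-like
    population, p2 the candidate-selected one); XP-EHH is signed so that
    positive means longer haplotypes in p2 and uses the pooled (all-
    haplotype) core. Undefined entries become NaN and are flagged.

    SFS statistics and the multi-site F_ST are computed from shared
    vectorised per-site quantities; each entry agrees with its standalone
    operation applied to the same window.
    """
    if registry is None:
        registry = default_registry()
    pops = sample.pops()
    if len(pops) != 2:
        raise SweepABCError("summary vectors require two populations")
    popof = {"p1": pops[0], "p2": pops[1]}
    if sample.focal_index is None:
        raise SweepABCError("summary vectors require a focal site")
    focal = sample.focal_index
    values: dict = {}
    flags: set = set()

    hap = {p: sample.haplotypes_of(popof[p]) for p in ("p1", "p2")}
    counts = {p: hap[p].sum(axis=0, dtype=np.int64) for p in ("p1", "p2")}
    nhap = {p: hap[p].shape[0] for p in ("p1", "p2")}
    masks = {w: _WINDOWS[w]().site_mask(sample) for w in ("w4kb", "w8kb")}
    need_wc = any(k in registry for k in ("fst_w4kb", "fst_region"))
    if need_wc:
        wc_a, wc_b, wc_c = _wc_components_vec(hap["p1"], hap["p2"])
        wc_tot = wc_a + wc_b + wc_c

    def sfs_stat(stat, win, p):
        n = nhap[p]
        if n < 2:
            raise UndefinedStatisticError("needs >= 2 haplotypes")
        i = counts[p][masks[win]].astype(float)
        seg = (i > 0) & (i < n)
        S = int(seg.sum())
        pi = (2.0 * i * (n - i)).sum() / (n * (n - 1))
        if stat == "pi":
            return pi
        a1, e1, e2 = _tajima_constants(n)
        if stat == "thetaW":
            return S / a1
        if stat == "tajD":
            if S == 0:
                raise UndefinedStatisticError("Tajima's D undefined for S = 0")
            return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        th = (2.0 * i[seg] ** 2).sum() / (n * (n - 1))
        pi_seg = (2.0 * i[seg] * (n - i[seg])).sum() / (n * (n - 1))
        return pi_seg - th

    def wc_ratio(mask):
        sel = mask & (wc_tot != 0)
        if not sel.any() or wc_tot[sel].sum() == 0:
            raise UndefinedStatisticError("no usable polymorphic site in window")
        return wc_a[sel].sum() / wc_tot[sel].sum()

    def put(key, fn):
        try:
            values[key] = float(fn())
        except UndefinedStatisticError:
            values[key] = np.nan
            flags.add(key)

    for key in registry:
        parts = key.split("_")
        if parts[0] in _SFS_STATS and len(parts) == 3:
            stat, win, p = parts
            put(key, lambda s=stat, w=win, p=p: sfs_stat(s, w, p))
        elif key == "fst_site":
            put(key, lambda: reynolds_fst_site(
                [(nhap[p], int(counts[p][focal])) for p in ("p1", "p2")]))
        elif key == "fst_w4kb":
            put(key, lambda: wc_ratio(masks["w4kb"]))
        elif key == "fst_region":
            put(key, lambda: wc_ratio(np.ones(sample.n_sites, bool)))
        elif key == "xpehh_site":
            def _xp():
                vals = []
                for p in ("p2", "p1"):
                    sub = single_pop_view(sample, popof[p])
                    v = ihh(sub, popof[p], focal, None, gmap, truncation).value
                    if v <= 0:
                        raise UndefinedStatisticError("zero iHH")
                    vals.append(v)
                return np.log(vals[0] / vals[1])
            put(key, _xp)
        elif key == "daf_p1":
            values[key] = counts["p1"][focal] / nhap["p1"]
        elif key == "daf_p2":
            values[key] = counts["p2"][focal] / nhap["p2"]
        else:
            raise SweepABCError(f"unknown registry entry {key!r}")
    return SummaryVector(values=values, flags=flags)
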