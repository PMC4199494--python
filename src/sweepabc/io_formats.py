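"""Readers and writers for the standard formats the pipeline touches.

Covers phased-VCF subsets (via cyvcf2), ms-format haplotype blocks, HapMap
style genetic-map text, and the YAML run configuration. Internal coordinates
are 0-based half-open; the VCF boundary is the only 1-based surface, and
haplotypes are polarised here (0 = ancestral, 1 = derived) using the
ancestral-allele INFO annotation. Sites without a high-confidence ancestral
call, indels and multiallelic records are dropped and counted.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigError, FormatError
from .haplotypes import HaplotypeSample


# ---------------------------------------------------------------------------
# genetic maps
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Piecewise-linear physical-to-genetic map.

    ``positions`` are physical bp (strictly increasing), ``rates`` local
    recombination rates in cM/Mb, ``cum_map`` cumulative genetic position in
    cM with ``cum_map[0] == 0``. Interpolation between map points is linear
    on ``cum_map``; queries beyond either end extrapolate with the edge rate.
    """

    positions: np.ndarray
    rates: np.ndarray
    cum_map: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.cum_map = np.asarray(self.cum_map, dtype=np.float64)
        if not (self.positions.shape == self.rates.shape == self.cum_map.shape):
            raise FormatError("genetic map columns must have equal length")
        if self.positions.size == 0:
            raise FormatError("empty genetic map")
        if self.positions.size > 1 and not (np.diff(self.positions) > 0).all():
            raise FormatError("genetic-map positions must be strictly increasing")
        if (self.rates < 0).any():
            raise FormatError("negative recombination rate in genetic map")
        if self.positions.size > 1 and (np.diff(self.cum_map) < -1e-12).any():
            raise FormatError("cumulative map must be non-decreasing")
        if abs(self.cum_map[0]) > 1e-12:
            # re-anchor so that the first map point is the origin
            self.cum_map = self.cum_map - self.cum_map[0]

    @classmethod
    def constant(cls, rate_cM_per_Mb: float, length_bp: float) -> "GeneticMap":
        """A uniform-rate map covering ``[0, length_bp]``."""
        return cls(
            positions=np.array([0.0, float(length_bp)]),
            rates=np.array([rate_cM_per_Mb, rate_cM_per_Mb]),
            cum_map=np.array([0.0, rate_cM_per_Mb * length_bp / 1e6]),
        )

    def genetic_position(self, bp) -> np.ndarray:
        """Genetic position (cM) of physical position(s) ``bp``."""
        bp = np.asarray(bp, dtype=np.float64)
        if self.positions.size == 1:
            # single-point map: constant-rate extrapolation from its rate
            out = self.cum_map[0] + (bp - self.positions[0]) * self.rates[0] / 1e6
            return out if out.shape else float(out)
        out = np.interp(bp, self.positions, self.cum_map)
        lo = bp < self.positions[0]
        hi = bp > self.positions[-1]
        if np.any(lo):
            out = np.where(
                lo,
                self.cum_map[0] - (self.positions[0] - bp) * self.rates[0] / 1e6,
                out)
        if np.any(hi):
            out = np.where(
                hi,
                self.cum_map[-1] + (bp - self.positions[-1]) * self.rates[-1] / 1e6,
                out)
        return out if out.shape else float(out)


def read_genetic_map(path) -> GeneticMap:
    """Read a HapMap-style 3-column (position, cM/Mb rate, cumulative cM)
    whitespace-delimited genetic map; a header line is tolerated."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            parts = line.split()
            if not parts or line.startswith("#"):
                continue
            try:
                vals = [float(p) for p in parts[-3:]]
            except ValueError:
                if lineno == 0 or not rows:
                    continue  # header
                raise FormatError(f"unparseable map line {lineno + 1}: {line!r}")
            rows.append(vals)
    if not rows:
        raise FormatError(f"no usable rows in genetic map {path}")
    arr = np.array(rows)
    return GeneticMap(positions=arr[:, 0], rates=arr[:, 1], cum_map=arr[:, 2])


# ---------------------------------------------------------------------------
# VCF haplotypes
# ---------------------------------------------------------------------------

@dataclass
class VcfReadReport:
    """Per-filter exclusion counts from :func:`read_vcf_haplotypes`."""

    n_kept: int = 0
    n_no_ancestral: int = 0
    n_indel: int = 0
    n_multiallelic: int = 0
    n_ancestral_mismatch: int = 0


_BASES = frozenset("ACGT")


def read_vcf_haplotypes(
    path,
    region: str,
    sample_ids: dict,
    ancestral_field: str = "AA",
    accept_lowercase: bool = False,
    focal_position: int | None = None,
) -> tuple[HaplotypeSample, VcfReadReport]:
    """Read phased diploid genotypes into a polarised HaplotypeSample.

    Parameters
    ----------
    region
        ``"contig:start-end"`` with 1-based inclusive coordinates.
    sample_ids
        Mapping population label -> list of sample names (order preserved;
        two haplotype rows per sample, in GT order). At most two populations.
    ancestral_field
        INFO key carrying the ancestral allele. By default only upper-case
        (high-confidence) calls are accepted.
    focal_position
        Optional 1-based position of the focal variant; its site index is
        recorded on the returned sample.

    Only biallelic SNPs with a resolvable ancestral allele are kept; the
    report counts every exclusion. Unphased genotypes are a hard error.
    """
    from cyvcf2 import VCF

    labels = list(sample_ids)
    if len(labels) > 2:
        raise FormatError("at most two populations are supported")
    all_samples = [s for lab in labels for s in sample_ids[lab]]
    vcf = VCF(str(path))
    missing = set(all_samples) - set(vcf.samples)
    if missing:
        raise FormatError(f"samples absent from VCF: {sorted(missing)}")
    vcf.set_samples(all_samples)
    order = vcf.samples  # cyvcf2 returns them in file order
    row_of = {s: i for i, s in enumerate(order)}

    try:
        contig, _, span = region.partition(":")
        start, _, end = span.partition("-")
        start_i, end_i = int(start), int(end)
    except ValueError:
        raise FormatError(f"region must be 'contig:start-end', got {region!r}")

    def _records():
        # tabix-indexed files support direct region queries; plain-text
        # VCFs are scanned and filtered
        try:
            yield from vcf(region)
        except (AssertionError, OSError):
            fallback = VCF(str(path))
            fallback.set_samples(all_samples)
            for v in fallback:
                if v.CHROM == contig and start_i <= v.POS <= end_i:
                    yield v

    report = VcfReadReport()
    columns, positions = [], []
    focal_index = None
    for v in _records():
        if len(v.ALT) != 1:
            report.n_multiallelic += 1
            warnings.warn(f"multiallelic site at {v.CHROM}:{v.POS} dropped")
            continue
        if not v.is_snp:
            report.n_indel += 1
            continue
        aa = v.INFO.get(ancestral_field)
        if aa is None:
            report.n_no_ancestral += 1
            continue
        aa = str(aa).split("|")[0].strip()
        if accept_lowercase:
            aa = aa.upper()
        if aa not in _BASES:
            report.n_no_ancestral += 1
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if aa == ref:
            flip = False
        elif aa == alt:
            flip = True
        else:
            report.n_ancestral_mismatch += 1
            continue
        col = np.empty(2 * len(all_samples), dtype=np.uint8)
        gts = v.genotypes
        for s in all_samples:
            g = gts[row_of[s]]
            if len(g) < 3 or not g[2]:
                raise FormatError(
                    f"unphased genotype for sample {s} at {v.CHROM}:{v.POS}")
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                raise FormatError(
                    f"missing genotype for sample {s} at {v.CHROM}:{v.POS}")
            idx = all_samples.index(s)
            col[2 * idx] = a0
            col[2 * idx + 1] = a1
        if flip:
            col = 1 - col
        pos0 = v.POS - 1  # internal 0-based
        if focal_position is not None and v.POS == focal_position:
            focal_index = len(positions)
        columns.append(col)
        positions.append(pos0)
    if not columns:
        raise FormatError(f"no usable sites in region {region}")
    report.n_kept = len(columns)
    matrix = np.stack(columns, axis=1)
    pop_labels = np.array(
        [lab for lab in labels for _ in range(2 * len(sample_ids[lab]))])
    sample = HaplotypeSample(
        matrix=matrix,
        positions=np.array(positions, dtype=float),
        pop_labels=pop_labels,
        focal_index=focal_index,
    )
    return sample, report


def write_vcf_haplotypes(sample: HaplotypeSample, path, contig="1",
                         ancestral_field="AA", position_offset=0) -> None:
    """Write a HaplotypeSample as a minimal phased VCF (one diploid sample
    per consecutive haplotype pair), with derived coded as the ALT allele
    and the ancestral allele annotated in INFO."""
    n = sample.n_haplotypes
    if n % 2:
        raise FormatError("need an even haplotype count to form diploids")
    names = []
    counts: dict = {}
    for i in range(0, n, 2):
        lab = sample.pop_labels[i]
        counts[lab] = counts.get(lab, 0) + 1
        names.append(f"{lab}_{counts[lab]}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={ancestral_field},Number=1,Type=String,'
                 'Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j in range(sample.n_sites):
            pos1 = int(round(sample.positions[j])) + 1 + position_offset
            gts = "\t".join(
                f"{sample.matrix[i, j]}|{sample.matrix[i + 1, j]}"
                for i in range(0, n, 2))
            fh.write(f"{contig}\t{pos1}\t.\tA\tG\t.\tPASS\t"
                     f"{ancestral_field}=A\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# ms-format blocks
# ---------------------------------------------------------------------------

def write_ms_block(sample: HaplotypeSample, stream) -> None:
    """Write one ms-style block (``//``, ``segsites:``, ``positions:`` with
    positions rescaled to [0,1) by the region length, then 0/1 rows).

    Population labels and the focal index are carried as key=value tokens on
    the ``//`` line so that a round trip preserves them.
    """
    L = sample.region_length
    meta = "pops=" + ",".join(str(lab) for lab in sample.pop_labels)
    meta += f" L={L:g}"
    if sample.focal_index is not None:
        meta += f" focal={sample.focal_index}"
    stream.write(f"// {meta}\n")
    stream.write(f"segsites: {sample.n_sites}\n")
    if sample.n_sites:
        pos = sample.positions / L
        stream.write("positions: " + " ".join(f"{p:.8f}" for p in pos) + "\n")
        for row in sample.matrix:
            stream.write("".join(str(int(x)) for x in row) + "\n")
    stream.write("\n")


def read_ms_block(stream, region_length: float | None = None,
                  n_haplotypes: int | None = None) -> HaplotypeSample:
    """Read one ms-style block written by :func:`write_ms_block` (or by any
    standard coalescent simulator; labels then default to ``pop1``)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    meta: dict = {}
    line = ""
    for line in stream:
        if line.startswith("//"):
            for tok in line[2:].split():
                if "=" in tok:
                    k, _, v = tok.partition("=")
                    meta[k] = v
            break
    else:
        raise FormatError("no '//' block found in ms stream")
    L = region_length if region_length is not None else float(meta.get("L", 1.0))
    seg_line = stream.readline()
    if not seg_line.startswith("segsites:"):
        raise FormatError(f"expected 'segsites:' line, got {seg_line!r}")
    segsites = int(seg_line.split(":")[1])
    labels = meta.get("pops", "").split(",") if meta.get("pops") else None
    if segsites == 0:
        n = len(labels) if labels else (n_haplotypes or 0)
        return HaplotypeSample(
            matrix=np.zeros((n, 0), np.uint8),
            positions=np.zeros(0),
            pop_labels=np.array(labels if labels else ["pop1"] * n),
            region_length=L,
        )
    pos_line = stream.readline()
    if not pos_line.startswith("positions:"):
        raise FormatError(f"expected 'positions:' line, got {pos_line!r}")
    rel = np.array([float(p) for p in pos_line.split()[1:]])
    if rel.size != segsites:
        raise FormatError(
            f"positions line has {rel.size} entries for segsites {segsites}")
    rows = []
    for line in stream:
        line = line.strip()
        if not line:
            break
        if len(line) != segsites:
            raise FormatError(
                f"haplotype row length {len(line)} != segsites {segsites}")
        rows.append([int(c) for c in line])
    matrix = np.array(rows, np.uint8)
    if labels is not None and len(labels) != matrix.shape[0]:
        raise FormatError("pops metadata does not match haplotype count")
    focal = int(meta["focal"]) if "focal" in meta else None
    return HaplotypeSample(
        matrix=matrix,
        positions=rel * L,
        pop_labels=np.array(labels if labels else ["pop1"] * matrix.shape[0]),
        focal_index=focal,
        region_length=L,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: priors exactly as printed for the three competing models:
#: selection coefficients as fractions, onset/appearance times in kya.
DEFAULT_PRIORS = {
    "SDN": {"s_A": (0.0, 0.015), "s_NA": (0.005, 0.05), "t_mut": (40.0, 70.0)},
    "SSV": {"s_NA": (0.0, 0.05), "f0": (0.0, 0.20), "t_mut": (21.0, 51.0)},
    "NTR": {"t_mut": (40.0, 70.0)},
}

_CONFIG_DEFAULTS = {
    "demography": "afr_eas",
    "models": ["NTR", "SDN", "SSV"],
    "dominance": 0.5,
    "n_sims": 1000,
    "retain_fraction": 0.01,
    "n_components": 7,
    "registry": None,
    "region_length": 12000.0,
    "focal_position": 8000.0,
    "mutation_rate": None,      # default: the demography's rate
    "rec_rate_cM_per_Mb": 1.76,
    "n_haplotypes": [100, 100],
    "rescaling": 10.0,
    "priors": None,             # default: DEFAULT_PRIORS
    "out_dir": "sweepabc_out",
}


@dataclass
class RunConfig:
    """Validated, fully-defaulted configuration of a pipeline run."""

    seed: int
    demography: str = "afr_eas"
    models: list = field(default_factory=lambda: ["NTR", "SDN", "SSV"])
    dominance: float = 0.5
    n_sims: int = 1000
    retain_fraction: float = 0.01
    n_components: int = 7
    registry: list | None = None
    region_length: float = 12000.0
    focal_position: float = 8000.0
    mutation_rate: float | None = None
    rec_rate_cM_per_Mb: float = 1.76
    n_haplotypes: list = field(default_factory=lambda: [100, 100])
    rescaling: float = 10.0
    priors: dict | None = None
    out_dir: str = "sweepabc_out"

    def __post_init__(self):
        if not isinstance(self.seed, int):
            raise ConfigError("seed: an integer seed is mandatory")
        if not 0 < self.retain_fraction <= 1:
            raise ConfigError("retain_fraction: must be in (0, 1]")
        if self.n_sims < 1:
            raise ConfigError("n_sims: must be >= 1")
        if self.n_components < 1:
            raise ConfigError("n_components: must be >= 1")
        if self.dominance < 0 or self.dominance > 1:
            raise ConfigError("dominance: h must be in [0, 1]")
        if self.rescaling <= 0:
            raise ConfigError("rescaling: must be > 0")
        if self.region_length <= 0:
            raise ConfigError("region_length: must be > 0")
        if not 0 <= self.focal_position <= self.region_length:
            raise ConfigError("focal_position: outside the region")
        if self.mutation_rate is not None and self.mutation_rate < 0:
            raise ConfigError("mutation_rate: must be >= 0")
        if self.rec_rate_cM_per_Mb < 0:
            raise ConfigError("rec_rate_cM_per_Mb: must be >= 0")
        for model in self.models:
            if model not in ("NTR", "SDN", "SSV"):
                raise ConfigError(f"models: unknown model {model!r}")
        if len(self.n_haplotypes) != 2 or min(self.n_haplotypes) < 2:
            raise ConfigError("n_haplotypes: need two entries >= 2")
        priors = self.priors if self.priors is not None else DEFAULT_PRIORS
        for model, pr in priors.items():
            for key, (lo, hi) in pr.items():
                if hi < lo:
                    raise ConfigError(
                        f"priors.{model}.{key}: upper bound {hi} < lower {lo}")

    def effective_priors(self) -> dict:
        return self.priors if self.priors is not None else DEFAULT_PRIORS

    def to_dict(self) -> dict:
        d = {"seed": self.seed}
        for k in _CONFIG_DEFAULTS:
            d[k] = getattr(self, k)
        return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected (with the offending key path in the message);
    omitted keys take the documented defaults. ``load_config`` of a dumped
    effective config reproduces it.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_CONFIG_DEFAULTS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("seed: an integer seed is mandatory")
    kwargs = dict(_CONFIG_DEFAULTS)
    kwargs.update(raw)
    if isinstance(kwargs.get("priors"), dict):
        kwargs["priors"] = {
            m: {k: tuple(v) for k, v in pr.items()}
            for m, pr in kwargs["priors"].items()}
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
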