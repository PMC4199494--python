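"""Config-driven orchestration of simulation, statistics and inference.

Each stage is a plain function taking a validated :class:`RunConfig`;
the CLI wraps these 1:1. A single top-level seed is split into per-stage
child seeds with :class:`numpy.random.SeedSequence` (documented scheme:
``SeedSequence([seed, stage_index])``), so stages can be rerun
independently yet reproducibly. Every run writes a manifest recording the
config hash, seed, package version, per-stage outputs with checksums, and
the acceptance rates that define the effective priors.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abc import cross_validate_power, infer
from .demography import load_demography, single_deme
from .errors import ConfigError, SweepABCError
from .haplotypes import WindowSpec
from .io_formats import (RunConfig, read_genetic_map,
                         read_vcf_haplotypes)
from .simulate import SimulatorSpec, neutral_null_sims, simulate_batch
from .sumstats import (compute_summary_vector, default_registry,
                       empirical_pvalue, fay_wu_h)

_STAGES = {"simulate": 0, "observed": 1, "abc": 2, "power": 3, "fwtest": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Derived child seed for a pipeline stage (< 2**31)."""
    ss = np.random.SeedSequence([seed, _STAGES[stage]])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int
    version: str = __version__
    outputs: dict = field(default_factory=dict)   # path -> checksum
    log: dict = field(default_factory=dict)       # timings, acceptance rates

    def add_output(self, path):
        self.outputs[str(path)] = _checksum(path)

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _simulator_spec(config: RunConfig) -> SimulatorSpec:
    return SimulatorSpec(
        region_length=config.region_length,
        focal_position=config.focal_position,
        mutation_rate=config.mutation_rate,
        rec_rate_cM_per_Mb=config.rec_rate_cM_per_Mb,
        n_haplotypes=tuple(config.n_haplotypes),
        rescaling=config.rescaling,
    )


def _tsv_header(config: RunConfig) -> str:
    return (f"# sweepabc {__version__} config={config_hash(config)} "
            f"seed={config.seed}\n")


def write_table(table: pd.DataFrame, path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header(config))
        table.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig, n_sims: int | None = None,
                 models: list | None = None, dominance=None,
                 progress: bool = False) -> dict:
    """Simulate reference tables for every requested model (and dominance
    value) and write them under the output directory with a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dem = load_demography(config.demography)
    spec = _simulator_spec(config)
    seed = stage_seed(config.seed, "simulate")
    n_sims = n_sims or config.n_sims
    models = models or config.models
    hs = [config.dominance] if dominance is None else list(dominance)
    manifest = RunManifest(config_hash=config_hash(config), seed=config.seed)
    paths = {}
    for h in hs:
        for k, model in enumerate(models):
            t0 = time.time()
            table = simulate_batch(
                model, n_sims, dem, spec,
                seed=seed + 1000 * k + int(round(h * 100)),
                registry=config.registry, h=h,
                priors=config.priors, progress=progress)
            tag = f"{model}_h{h:g}" if len(hs) > 1 else model
            path = out / f"sims_{config.demography}_{tag}.tsv"
            write_table(table, path, config)
            manifest.add_output(path)
            manifest.log[tag] = {
                "n_sims": len(table),
                "acceptance_rate": len(table) / int(table["attempts"].sum()),
                "seconds": round(time.time() - t0, 1),
            }
            paths[tag] = path
    manifest.write(out / "manifest_simulate.json")
    return paths


def run_observed_stats(config: RunConfig, vcf_path, samples: dict,
                       region: str, focal_position: int,
                       map_path=None) -> pd.DataFrame:
    """Observed summary vector for a focal variant from a phased VCF.

    ``samples`` maps the two population labels (reference first, candidate
    second) to sample-name lists; ``focal_position`` is 1-based. Without a
    genetic map, pass ``map_path=None`` only if a constant-rate fallback is
    acceptable — an explicit error suggests the flag otherwise.
    """
    if map_path is None:
        raise ConfigError(
            "no genetic map given; pass --constant-map to use the "
            f"configured constant rate of {config.rec_rate_cM_per_Mb} cM/Mb")
    sample, report = read_vcf_haplotypes(
        str(vcf_path), region, samples, focal_position=focal_position)
    if sample.focal_index is None:
        raise SweepABCError(
            f"focal variant at {focal_position} absent or filtered")
    if map_path == "constant":
        gmap = _simulator_spec(config).genetic_map()
    else:
        gmap = read_genetic_map(map_path)
    registry = config.registry or default_registry()
    sv = compute_summary_vector(sample, gmap, registry)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame([sv.values])
    path = out / "observed_stats.tsv"
    with open(path, "w") as fh:
        fh.write(_tsv_header(config))
        fh.write(f"# dropped: no_ancestral={report.n_no_ancestral} "
                 f"indel={report.n_indel} "
                 f"multiallelic={report.n_multiallelic}\n")
        if sv.flags:
            fh.write(f"# undefined: {sorted(sv.flags)}\n")
        table.to_csv(fh, sep="\t", index=False)
    return table


def run_abc(config: RunConfig, sim_tables: dict, observed) -> dict:
    """Full ABC report (model posteriors, Bayes factors, parameters with
    mode and 95% CI under the winning model) from reference tables and one
    observed summary vector."""
    tables = {m: (read_table(p) if not isinstance(p, pd.DataFrame) else p)
              for m, p in sim_tables.items()}
    if isinstance(observed, (str, Path)):
        observed = read_table(observed).iloc[0]
    elif isinstance(observed, pd.DataFrame):
        observed = observed.iloc[0]
    registry = config.registry or default_registry()
    priors = config.effective_priors()
    bounds = {}
    for m, pr in priors.items():
        for k, v in pr.items():
            bounds.setdefault(k, v)
    post = infer(tables, observed, registry,
                 retain_fraction=config.retain_fraction,
                 n_components=config.n_components,
                 seed=stage_seed(config.seed, "abc"),
                 prior_bounds=bounds)
    report = post.to_report()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "abc_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    rows = [{"parameter": k, "mode": p.mode,
             "ci_2.5%": p.ci_low, "ci_97.5%": p.ci_high}
            for k, p in post.parameters.items()]
    with open(out / "abc_parameters.tsv", "w") as fh:
        fh.write(_tsv_header(config))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    return report


def run_power(config: RunConfig, sim_tables: dict,
              n_pseudo: int = 200) -> "pd.DataFrame":
    """Cross-validated model-choice power; writes the confusion matrix."""
    tables = {m: (read_table(p) if not isinstance(p, pd.DataFrame) else p)
              for m, p in sim_tables.items()}
    cm = cross_validate_power(
        tables, n_pseudo=n_pseudo,
        retain_fraction=config.retain_fraction,
        n_components=config.n_components,
        seed=stage_seed(config.seed, "power"))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "confusion_matrix.tsv"
    with open(path, "w") as fh:
        fh.write(_tsv_header(config))
        cm.counts.to_csv(fh, sep="\t")
        for m, r in cm.rates.items():
            fh.write(f"# {m}: {100 * r:.1f}% +- "
                     f"{100 * cm.standard_errors[m]:.1f}%\n")
    return cm


def run_fwtest(config: RunConfig, observed_sample, deme: int = 1,
               n_sims: int = 10_000) -> dict:
    """Fay & Wu's H on the observed region with a demographic-null
    empirical p-value from neutral coalescent simulations."""
    dem = load_demography(config.demography)
    null_dem = single_deme(dem, deme)
    spec = _simulator_spec(config)
    pop = observed_sample.pops()[min(deme, len(observed_sample.pops()) - 1)]
    h_obs = fay_wu_h(observed_sample, WindowSpec.whole_region(), pop)
    dist = neutral_null_sims(null_dem, spec, n=n_sims,
                             seed=stage_seed(config.seed, "fwtest"))
    p = empirical_pvalue(h_obs, dist)
    return {"H": h_obs, "p": p.p, "p_is_floor_bound": p.is_floor,
            "population": str(pop), "n_null_sims": n_sims}
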