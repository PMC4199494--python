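"""The synthetic-data generator and simulation engine.

Generates the focal variant's allele-frequency trajectory forward in time
under one of three competing histories — NTR (neutral), SDN (selection on a
de novo mutation, immediately beneficial with strength s_A in Africa and
s_NA outside) and SSV (a standing neutral variant at frequency f0 becomes
beneficial in the non-African deme at t_mut) — in a two-deme out-of-Africa
demography, conditioning by rejection on the variant segregating in both
demes at present. Linked neutral variation over the surveyed region is then
generated by a structured coalescent conditioned on that trajectory
(infinite-sites mutation, uniform crossover), yielding two-population
haplotype samples with the focal column set by the trajectory.

Trajectories run at full per-generation resolution (their cost is
dominated by short-lived rejected draws); the coalescent runs in rescaled
units (sizes N/λ, rates ×λ, generations /λ, default λ = 10), the standard
speed/accuracy trade, reading frequencies off the trajectory's λ-grid.
λ = 1 recovers the fully unrescaled model.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import (COAL_OK, conditioned_coalescent, wf_trajectory,
                       wf_trajectory_batch, wf_update)
from .demography import DemographicModel
from .errors import ConditioningError, ConfigError, SweepABCError
from .haplotypes import HaplotypeSample
from .io_formats import DEFAULT_PRIORS, GeneticMap
from .sumstats import ScoreDistribution, compute_summary_vector, default_registry
from .sumstats import fay_wu_h
from .haplotypes import WindowSpec

__all__ = [
    "SelectionScenario", "SimulatorSpec", "Trajectory", "SimulationEngine",
    "sample_prior", "simulate_trajectory", "simulate_haplotypes",
    "simulate_batch", "neutral_null_sims", "deterministic_selection_update",
]

_MODEL_CODE = {"NTR": _kernels.NTR, "SDN": _kernels.SDN, "SSV": _kernels.SSV}


def deterministic_selection_update(p: float, s: float, h: float) -> float:
    """One generation of deterministic selection with fitnesses
    1 : 1+hs : 1+s (the drift-free limit of the WF update)."""
    return float(wf_update(p, s, h))


@dataclass(frozen=True)
class SelectionScenario:
    """One draw of the parameter vector the ABC infers.

    ``s_A``/``s_NA`` are selection coefficients (fractions) in the African
    and non-African demes, ``t_mut_kya`` the time (kya) at which the
    mutation appears (NTR/SDN) or selection starts (SSV), ``f0`` the
    standing frequency at onset (SSV only), ``h`` the dominance
    coefficient.
    """

    model: str
    t_mut_kya: float
    s_A: float = 0.0
    s_NA: float = 0.0
    f0: float | None = None
    h: float = 0.5

    def __post_init__(self):
        if self.model not in _MODEL_CODE:
            raise ConfigError(f"unknown model {self.model!r}")
        if self.model == "SSV":
            if self.f0 is None or not (0 <= self.f0 <= 1):
                raise ConfigError("SSV requires a standing frequency f0 in [0,1]")
        elif self.f0 is not None:
            raise ConfigError(f"f0 is only meaningful for SSV, not {self.model}")
        if self.model == "NTR" and (self.s_A or self.s_NA):
            raise ConfigError("NTR must have zero selection coefficients")
        if self.model == "SSV" and self.s_A:
            raise ConfigError("SSV is neutral in the African deme (s_A = 0)")
        if self.t_mut_kya <= 0:
            raise ConfigError("t_mut must be positive")
        if not (0 <= self.h <= 1):
            raise ConfigError("dominance h must be in [0, 1]")


@dataclass(frozen=True)
class SimulatorSpec:
    """Region geometry, rates and sampling configuration.

    Defaults: a 12 kb region with the focal site at 8 kb (room for the
    6 kb-upstream + 2 kb-downstream window), constant recombination
    1.76 cM/Mb, 100 sampled haplotypes per deme, rescaling λ = 10.
    The mutation rate defaults to the demography's rate.
    """

    region_length: float = 12000.0
    focal_position: float = 8000.0
    mutation_rate: float | None = None
    rec_rate_cM_per_Mb: float = 1.76
    n_haplotypes: tuple = (100, 100)
    rescaling: float = 10.0
    n_loci: int = 48
    max_sites: int = 8192
    max_attempts: int = 1_000_000
    origin_cap_gens: float = 200_000.0  # cap on SSV backward pre-path

    def __post_init__(self):
        if self.rescaling <= 0:
            raise ConfigError("rescaling factor must be > 0")
        if not (0 <= self.focal_position <= self.region_length):
            raise ConfigError("focal position outside the region")
        if not (1 <= self.n_loci <= 64):
            raise ConfigError("n_loci must be in [1, 64]")
        if min(self.n_haplotypes) < 1:
            raise ConfigError("need at least one haplotype per deme")

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.constant(self.rec_rate_cM_per_Mb, self.region_length)

    @property
    def rec_rate_per_bp(self) -> float:
        return self.rec_rate_cM_per_Mb * 0.01 / 1e6


@dataclass
class Trajectory:
    """Per-generation derived-allele frequency path of the focal variant.

    ``x0``/``x1`` are indexed by rescaled generation before present (index
    0 = present) up to the allele origin ``origin_gen``; before the split
    both demes carry the shared ancestral path in ``x0``. Conditioning
    guarantees the present-day frequencies are strictly inside (0, 1).
    """

    x0: np.ndarray
    x1: np.ndarray
    origin_gen: int
    rescaling: float
    attempts: int = 1

    @property
    def final_freqs(self) -> tuple:
        return float(self.x0[0]), float(self.x1[0])


class SimulationEngine:
    """Precomputed, reusable simulator for one (demography, spec) pair."""

    def __init__(self, demography: DemographicModel, spec: SimulatorSpec):
        self.demography = demography
        self.spec = spec
        lam = spec.rescaling
        if abs(lam - round(lam)) > 1e-9 or lam < 1:
            raise ConfigError("rescaling factor must be a positive integer")
        self.lam = float(lam)
        self.lam_i = int(round(lam))
        self.Tsp = demography.split_gen_rescaled(lam)
        # trajectories run unrescaled; the coalescent runs on the lam-grid
        self.G_cap_u = int(max(spec.origin_cap_gens,
                               (self.Tsp + 10) * self.lam_i))
        self.G_cap = self.G_cap_u // self.lam_i
        self.N0u, self.N1u, self.Mu = demography.rescaled_arrays(
            1.0, self.G_cap_u + self.lam_i)
        self.N0, self.N1, self.M = demography.rescaled_arrays(lam, self.G_cap + 1)
        self.ep_start, self.ep_N = demography.rescaled_anc_epochs(lam)
        mu = spec.mutation_rate
        if mu is None:
            mu = demography.mutation_rate
        self.mu_r = mu * lam
        self.rec_r = spec.rec_rate_per_bp * lam
        self.gmap = spec.genetic_map()

    # -- conversions ---------------------------------------------------
    def kya_to_gen(self, kya: float) -> int:
        """Unrescaled generations before present."""
        g = int(round(kya * 1000.0 / self.demography.generation_time))
        return max(g, 1)

    def kya_to_rescaled_gen(self, kya: float) -> int:
        g = int(round(kya * 1000.0 / self.demography.generation_time / self.lam))
        return max(g, 1)

    # -- trajectory ----------------------------------------------------
    def _attempt_trajectory(self, scenario: SelectionScenario, seed: int):
        model = _MODEL_CODE[scenario.model]
        g_t = self.kya_to_gen(scenario.t_mut_kya)
        g_a = g_t if scenario.model in ("NTR", "SDN") else 0
        g_m = g_t if scenario.model == "SSV" else 0
        X0 = np.zeros(self.G_cap + 2)
        X1 = np.zeros(self.G_cap + 2)
        ok, origin = wf_trajectory(
            seed, model, g_a, g_m,
            float(scenario.f0 or 0.0),
            scenario.s_A, scenario.s_NA, scenario.h,
            self.Tsp * self.lam_i, self.N0u, self.N1u, self.Mu,
            self.G_cap_u, self.lam_i, X0, X1)
        if not ok:
            return None
        return Trajectory(x0=X0[: origin + 2], x1=X1[: origin + 2],
                          origin_gen=int(origin), rescaling=self.lam)

    def sample_conditioned(self, model: str, rng: np.random.Generator,
                           priors: dict | None = None, h: float = 0.5,
                           chunk: int = 256):
        """Draw (scenario, trajectory) from the conditioned prior.

        Parameters are redrawn from the prior on every rejection, so the
        accepted draw realises the post-conditioning effective prior.
        Prior draws happen in vectorised blocks of ``chunk`` attempts with
        the rejection loop inside the compiled kernel. Returns
        ``(scenario, trajectory, attempts)``.
        """
        priors = priors or DEFAULT_PRIORS
        pr = priors[model]
        code = _MODEL_CODE[model]
        gen_kya = 1000.0 / self.demography.generation_time
        X0 = np.zeros(self.G_cap + 2)
        X1 = np.zeros(self.G_cap + 2)
        attempts = 0
        models = np.full(chunk, code, np.int64)
        zeros = np.zeros(chunk)
        while attempts < self.spec.max_attempts:
            seeds = rng.integers(0, 2 ** 31, size=chunk)
            t_mut = rng.uniform(*pr["t_mut"], size=chunk)
            g_t = np.maximum(np.rint(t_mut * gen_kya), 1).astype(np.int64)
            if model == "SDN":
                sA = rng.uniform(*pr["s_A"], size=chunk)
                sNA = rng.uniform(*pr["s_NA"], size=chunk)
                f0 = zeros
                g_a, g_m = g_t, np.zeros(chunk, np.int64)
            elif model == "SSV":
                sA = zeros
                sNA = rng.uniform(*pr["s_NA"], size=chunk)
                f0 = rng.uniform(*pr["f0"], size=chunk)
                g_a, g_m = np.zeros(chunk, np.int64), g_t
            else:
                sA = sNA = f0 = zeros
                g_a, g_m = g_t, np.zeros(chunk, np.int64)
            idx, origin = wf_trajectory_batch(
                seeds, models, g_a, g_m, f0, sA, sNA, h,
                self.Tsp * self.lam_i, self.N0u, self.N1u, self.Mu,
                self.G_cap_u, self.lam_i, X0, X1)
            if idx >= 0:
                attempts += idx + 1
                scen = SelectionScenario(
                    model,
                    t_mut_kya=float(t_mut[idx]),
                    s_A=float(sA[idx]) if model == "SDN" else 0.0,
                    s_NA=float(sNA[idx]) if model != "NTR" else 0.0,
                    f0=float(f0[idx]) if model == "SSV" else None,
                    h=h)
                traj = Trajectory(
                    x0=X0[: origin + 2].copy(), x1=X1[: origin + 2].copy(),
                    origin_gen=int(origin), rescaling=self.lam,
                    attempts=attempts)
                return scen, traj, attempts
            attempts += chunk
        raise ConditioningError(
            f"{model}: conditioning failed in {attempts} prior draws",
            attempts=attempts)

    def simulate_trajectory(self, scenario: SelectionScenario,
                            rng: np.random.Generator) -> Trajectory:
        """Rejection-sample a trajectory for a fixed scenario, conditioned
        on present-day segregation in both demes."""
        for attempt in range(1, self.spec.max_attempts + 1):
            traj = self._attempt_trajectory(
                scenario, int(rng.integers(0, 2 ** 31)))
            if traj is not None:
                traj.attempts = attempt
                return traj
        raise ConditioningError(
            f"no conditioned trajectory for {scenario} in "
            f"{self.spec.max_attempts} attempts "
            f"(acceptance < {1 / self.spec.max_attempts:g})",
            attempts=self.spec.max_attempts)

    # -- haplotypes ----------------------------------------------------
    def simulate_haplotypes(self, traj: Trajectory,
                            rng: np.random.Generator) -> HaplotypeSample:
        """Structured-coalescent haplotypes conditioned on ``traj``."""
        spec = self.spec
        n0, n1 = spec.n_haplotypes
        p0, p1 = traj.final_freqs
        for _ in range(10_000):
            d0 = int(rng.binomial(n0, p0))
            d1 = int(rng.binomial(n1, p1))
            if 0 < d0 + d1 < n0 + n1:
                break
        else:  # pragma: no cover - requires pathological frequencies
            raise ConditioningError("could not draw a polymorphic focal sample")
        return self._coalesce(d0, d1, traj, rng)

    def _coalesce(self, d0, d1, traj, rng,
                  neutral_single_deme: bool = False) -> HaplotypeSample:
        spec = self.spec
        n0, n1 = spec.n_haplotypes
        if neutral_single_deme:
            n1 = 0
            Tsp = 0
            origin = -1
            G_step = self.Tsp  # step through any growth/split-side epochs
            X0 = np.zeros(2)
            X1 = np.zeros(2)
        else:
            Tsp = self.Tsp
            origin = traj.origin_gen
            G_step = max(origin + 1, self.Tsp)
            X0, X1 = traj.x0, traj.x1
        n = n0 + n1
        W = (n + 63) // 64
        out_pos = np.zeros(spec.max_sites)
        out_desc = np.zeros((spec.max_sites, W), np.uint64)
        status, ns = conditioned_coalescent(
            int(rng.integers(0, 2 ** 31)),
            n0, d0, n1, d1,
            Tsp, origin, G_step,
            self.N0, self.N1, self.M, X0, X1,
            self.ep_start, self.ep_N,
            spec.region_length, spec.focal_position, spec.n_loci,
            self.mu_r, self.rec_r,
            out_pos, out_desc)
        if status != COAL_OK:
            raise SweepABCError(
                f"coalescent capacity exceeded (status {status}); "
                "increase max_sites")
        pos = out_pos[:ns]
        bits = np.unpackbits(
            out_desc[:ns].view(np.uint8).reshape(ns, -1) if ns else
            np.zeros((0, 8 * W), np.uint8),
            axis=1, bitorder="little")[:, :n] if ns else np.zeros((0, n), np.uint8)
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        bits = bits[order]
        keep = np.ones(ns, bool)
        if ns > 1:
            keep[1:] = np.diff(pos) > 0  # drop exact position collisions
        pos = pos[keep]
        matrix = bits[keep].T  # (n, S)
        focal_index = None
        if not neutral_single_deme:
            fi = int(np.searchsorted(pos, spec.focal_position))
            focal_col = np.zeros((n, 1), np.uint8)
            focal_col[:d0, 0] = 1
            focal_col[n0:n0 + d1, 0] = 1
            matrix = np.concatenate(
                [matrix[:, :fi], focal_col, matrix[:, fi:]], axis=1)
            pos = np.concatenate([pos[:fi], [spec.focal_position], pos[fi:]])
            focal_index = fi
        names = self.demography.pop_names
        labels = [names[0]] * n0 + [names[1]] * n1
        return HaplotypeSample(
            matrix=matrix, positions=pos,
            pop_labels=np.array(labels),
            focal_index=focal_index,
            region_length=spec.region_length)

    def simulate_neutral_sample(self, rng) -> HaplotypeSample:
        """A neutral single-deme sample (no focal site), for null tests."""
        return self._coalesce(0, 0, None, rng, neutral_single_deme=True)


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def single_deme_fixation_fraction(N: int, s: float, h: float,
                                  n_reps: int, rng: np.random.Generator,
                                  max_gens: int = 10 ** 7) -> float:
    """Fraction of new single-copy mutations that reach fixation in one
    Wright-Fisher deme of constant diploid size ``N`` (same
    selection-then-drift update as the trajectory simulator; the classic
    closed forms are 1/(2N) neutrally and ≈2hs for beneficial mutations).
    """
    p = np.full(n_reps, 1.0 / (2 * N))
    active = np.ones(n_reps, bool)
    fixed = np.zeros(n_reps, bool)
    for _ in range(max_gens):
        if not active.any():
            break
        pa = p[active]
        pp = np.asarray([wf_update(x, s, h) for x in pa])
        pa = rng.binomial(2 * N, pp) / (2 * N)
        p[active] = pa
        newly_fixed = pa >= 1.0
        done = (pa <= 0.0) | newly_fixed
        idx = np.flatnonzero(active)
        fixed[idx[newly_fixed]] = True
        active[idx[done]] = False
    return float(fixed.mean())


def sample_prior(model: str, rng: np.random.Generator,
                 priors: dict | None = None, h: float = 0.5) -> SelectionScenario:
    """Draw one scenario from the uniform priors of ``model``.

    Defaults: SDN s_A~U(0, 1.5%), s_NA~U(0.5%, 5%), t_mut~U(40, 70) kya;
    SSV s_NA~U(0, 5%), f0~U(0, 20%), t_mut~U(21, 51) kya; NTR appearance
    time ~U(40, 70) kya. The realised post-conditioning prior is whatever
    survives rejection and is recorded empirically by the batch driver.
    """
    priors = priors or DEFAULT_PRIORS
    if model not in priors:
        raise ConfigError(f"unknown model {model!r}")
    pr = priors[model]

    def u(key):
        lo, hi = pr[key]
        return float(rng.uniform(lo, hi))

    if model == "SDN":
        return SelectionScenario("SDN", t_mut_kya=u("t_mut"),
                                 s_A=u("s_A"), s_NA=u("s_NA"), h=h)
    if model == "SSV":
        return SelectionScenario("SSV", t_mut_kya=u("t_mut"),
                                 s_NA=u("s_NA"), f0=u("f0"), h=h)
    return SelectionScenario("NTR", t_mut_kya=u("t_mut"), h=h)


def simulate_trajectory(scenario, demography, spec, rng) -> Trajectory:
    return SimulationEngine(demography, spec).simulate_trajectory(scenario, rng)


def simulate_haplotypes(trajectory, scenario, demography, spec,
                        rng) -> HaplotypeSample:
    return SimulationEngine(demography, spec).simulate_haplotypes(
        trajectory, rng)


def simulate_batch(model: str, n_sims: int, demography: DemographicModel,
                   spec: SimulatorSpec, seed: int,
                   registry: list | None = None, h: float = 0.5,
                   priors: dict | None = None,
                   checkpoint_path=None, checkpoint_every: int = 2000,
                   progress: bool = False) -> pd.DataFrame:
    """Simulate ``n_sims`` accepted (conditioned) draws under ``model`` and
    summarise each into the statistic registry.

    Every rejection redraws the parameters from the prior, so the accepted
    rows realise the post-conditioning (non-uniform) effective prior; the
    per-row rejection count is recorded in ``attempts`` (the batch
    acceptance rate is ``n_sims / attempts.sum()``). Per-row seeds derive
    from ``(seed, row)``, so runs are deterministic, order-independent and
    resumable from a checkpoint TSV.
    """
    if n_sims < 1:
        raise ConfigError("n_sims must be >= 1")
    registry = registry or default_registry()
    engine = SimulationEngine(demography, spec)
    rows: list = []
    start_at = 0
    if checkpoint_path is not None:
        try:
            prev = pd.read_csv(checkpoint_path, sep="\t", comment="#")
            rows = prev.to_dict("records")
            start_at = len(rows)
        except (FileNotFoundError, pd.errors.EmptyDataError):
            start_at = 0
    t0 = time.time()
    for i in range(start_at, n_sims):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        scen, traj, attempts = engine.sample_conditioned(
            model, rng, priors=priors, h=h)
        sample = engine.simulate_haplotypes(traj, rng)
        sv = compute_summary_vector(sample, engine.gmap, registry)
        row = {"model": model, "s_A": scen.s_A, "s_NA": scen.s_NA,
               "t_mut": scen.t_mut_kya,
               "f0": scen.f0 if scen.f0 is not None else np.nan,
               "h": scen.h, "origin_gen": traj.origin_gen,
               "attempts": attempts}
        row.update(sv.values)
        rows.append(row)
        if checkpoint_path is not None and (i + 1) % checkpoint_every == 0:
            pd.DataFrame(rows).to_csv(checkpoint_path, sep="\t", index=False)
        if progress and (i + 1) % 1000 == 0:
            el = time.time() - t0
            print(f"  {model}: {i + 1}/{n_sims} sims "
                  f"({el:.0f}s, {(i + 1 - start_at) / max(el, 1e-9):.0f}/s)")
    table = pd.DataFrame(rows)
    if checkpoint_path is not None:
        table.to_csv(checkpoint_path, sep="\t", index=False)
    return table


def batch_acceptance_rate(table: pd.DataFrame) -> float:
    """Fraction of prior draws that satisfied the segregation conditioning
    (defines the effective prior mass kept per model)."""
    return float(len(table) / table["attempts"].sum())


def neutral_null_sims(demography: DemographicModel, spec: SimulatorSpec,
                      n: int = 10_000, seed: int = 0,
                      statistic=None) -> ScoreDistribution:
    """Distribution of Fay & Wu's H (by default) over ``n`` neutral
    replicates of the focal region under a single-population demographic
    null — the reference for lower-tail empirical p-values of observed H.
    """
    if statistic is None:
        def statistic(s):
            return fay_wu_h(s, WindowSpec.whole_region(), s.pops()[0])
    engine = SimulationEngine(demography, spec)
    vals = np.empty(n)
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        sample = engine.simulate_neutral_sample(rng)
        vals[i] = statistic(sample)
    return ScoreDistribution(values=vals, tail="lower")
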