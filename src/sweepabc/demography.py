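"""Two-deme piecewise demographic histories.

The shipped defaults transcribe the two-population out-of-Africa histories
used throughout the package: an ancestral population that grows at 148 kya,
splits at the out-of-Africa event (51 kya; 25-year generations) into an
African deme of constant size and a non-African deme that passes through a
bottleneck and then grows exponentially (East Asian-like or European-like
parameterisation), with symmetric migration between the demes. Sizes are
diploid; times are generations before present unless a method says years.

Single-deme variants of the same histories back the demographic-null
neutrality tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class GrowthEpoch:
    """One deme epoch on ``[start, end)`` generations before present.

    The size at the old edge is ``N_end``; going forward in time the deme
    grows exponentially at ``growth`` per generation, so at generation g
    (``start <= g < end``) the size is ``N_end * exp(growth * (end - g))``.
    """

    start: float
    end: float
    N_end: float
    growth: float = 0.0

    def size_at(self, g: float) -> float:
        return self.N_end * math.exp(self.growth * (self.end - g))


@dataclass
class DemographicModel:
    """Piecewise two-deme (or single-deme) history.

    ``deme0`` (African / ancestral line) and ``deme1`` (non-African) tile
    ``[0, T_split)``; ``anc_epochs`` is the piecewise-constant single
    ancestral population beyond the split, as ``(start_gen, N)`` pairs with
    ascending starts beginning at ``T_split``. ``migration`` lists
    symmetric per-generation migration rates as ``(start, end, m)``.
    For a single-deme model ``deme1`` is ``None`` and ``T_split`` marks the
    horizon behind which sizes are constant.
    """

    name: str
    T_split: float
    deme0: list
    anc_epochs: list
    deme1: list | None = None
    migration: list = field(default_factory=list)
    mutation_rate: float = 2.36e-8
    generation_time: float = 25.0
    pop_names: tuple = ("AFR", "NONAFR")

    def __post_init__(self):
        if self.T_split < 0:
            raise ConfigError("T_split must be >= 0")
        for (s, N) in self.anc_epochs:
            if N <= 0:
                raise ConfigError("ancestral sizes must be > 0")
        starts = [s for s, _ in self.anc_epochs]
        if starts != sorted(starts):
            raise ConfigError("ancestral epoch starts must be ascending")
        for ep in self.deme0 + (self.deme1 or []):
            if ep.N_end <= 0:
                raise ConfigError("deme sizes must be > 0")
        for (_, _, m) in self.migration:
            if m < 0:
                raise ConfigError("migration rate must be >= 0")

    # -- evaluation ----------------------------------------------------
    @property
    def two_demes(self) -> bool:
        return self.deme1 is not None

    def _deme_size(self, epochs, g: float) -> float:
        for ep in epochs:
            if ep.start <= g < ep.end:
                return ep.size_at(g)
        return epochs[-1].N_end

    def anc_size(self, g: float) -> float:
        N = self.anc_epochs[0][1]
        for (s, n) in self.anc_epochs:
            if g >= s:
                N = n
        return N

    def size(self, deme: int, g: float) -> float:
        if g >= self.T_split or (deme == 1 and not self.two_demes):
            return self.anc_size(g)
        epochs = self.deme0 if deme == 0 else self.deme1
        return self._deme_size(epochs, g)

    def migration_rate(self, g: float) -> float:
        for (s, e, m) in self.migration:
            if s <= g < e:
                return m
        return 0.0

    def years_to_gens(self, years: float) -> float:
        return years / self.generation_time

    # -- rescaled arrays for the kernels -------------------------------
    def _sizes_vec(self, deme: int, g: np.ndarray) -> np.ndarray:
        out = np.empty(g.shape)
        anc_starts = np.array([s for s, _ in self.anc_epochs])
        anc_sizes = np.array([N for _, N in self.anc_epochs])
        idx = np.clip(np.searchsorted(anc_starts, g, side="right") - 1,
                      0, len(anc_sizes) - 1)
        out[:] = anc_sizes[idx]
        if self.two_demes or deme == 0:
            epochs = self.deme0 if deme == 0 else self.deme1
            for ep in epochs:
                sel = (g >= ep.start) & (g < ep.end) & (g < self.T_split)
                out[sel] = ep.N_end * np.exp(ep.growth * (ep.end - g[sel]))
        return out

    def rescaled_arrays(self, lam: float, G_len: int):
        """Per-rescaled-generation size and migration arrays of length
        ``G_len + 1`` (sizes N/λ, migration m·λ, one entry per λ original
        generations); ``lam = 1`` gives the unrescaled arrays."""
        g = np.arange(G_len + 1) * lam
        N0 = self._sizes_vec(0, g) / lam
        N1 = self._sizes_vec(1, g) / lam
        M = np.zeros(g.shape)
        for (s, e, m) in self.migration:
            M[(g >= s) & (g < e)] = m
        return N0, N1, M * lam

    def rescaled_anc_epochs(self, lam: float):
        starts = np.array([s / lam for s, _ in self.anc_epochs])
        sizes = np.array([N / lam for _, N in self.anc_epochs])
        return starts, sizes

    def split_gen_rescaled(self, lam: float) -> int:
        return int(round(self.T_split / lam))

    # -- construction --------------------------------------------------
    @classmethod
    def constant(cls, N: float, name: str = "constant",
                 mutation_rate: float = 2.36e-8,
                 generation_time: float = 25.0) -> "DemographicModel":
        """A single constant-size population (calibration null)."""
        return cls(name=name, T_split=0.0, deme0=[],
                   anc_epochs=[(0.0, N)], deme1=None,
                   mutation_rate=mutation_rate,
                   generation_time=generation_time,
                   pop_names=("pop1", "pop1"))

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        def _epochs(lst):
            return [GrowthEpoch(float(e["start"]), float(e["end"]),
                                float(e["N_end"]), float(e.get("growth", 0.0)))
                    for e in lst]
        return cls(
            name=d["name"],
            T_split=float(d["T_split"]),
            deme0=_epochs(d["deme0"]),
            deme1=_epochs(d["deme1"]) if d.get("deme1") else None,
            anc_epochs=[(float(s), float(N)) for s, N in d["anc_epochs"]],
            migration=[(float(s), float(e), float(m))
                       for s, e, m in d.get("migration", [])],
            mutation_rate=float(d.get("mutation_rate", 2.36e-8)),
            generation_time=float(d.get("generation_time", 25.0)),
            pop_names=tuple(d.get("pop_names", ("AFR", "NONAFR"))),
        )

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_BUILTIN = {"afr_eas": "gravel_afr_eas.yaml", "afr_eur": "gravel_afr_eur.yaml"}


def load_demography(name: str) -> DemographicModel:
    """Load a shipped two-deme configuration (``afr_eas`` or ``afr_eur``)."""
    if name not in _BUILTIN:
        raise ConfigError(
            f"unknown demography {name!r}; shipped: {sorted(_BUILTIN)}")
    ref = resources.files("sweepabc").joinpath("data", _BUILTIN[name])
    with ref.open() as fh:
        return DemographicModel.from_dict(yaml.safe_load(fh))


def single_deme(model: DemographicModel, deme: int) -> DemographicModel:
    """Collapse a two-deme model to the single-population history of one
    deme (used by the demographic-null neutrality tests)."""
    if not model.two_demes:
        return model
    epochs = model.deme0 if deme == 0 else model.deme1
    return DemographicModel(
        name=f"{model.name}_{model.pop_names[deme]}",
        T_split=model.T_split,
        deme0=list(epochs),
        deme1=None,
        anc_epochs=list(model.anc_epochs),
        migration=[],
        mutation_rate=model.mutation_rate,
        generation_time=model.generation_time,
        pop_names=(model.pop_names[deme], model.pop_names[deme]),
    )
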