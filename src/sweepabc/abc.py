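"""Rejection-ABC model choice and parameter estimation with PLS reduction.

The pipeline is the classic simulation-based one: z-score every summary
statistic across the simulated reference table, reduce the statistic space
to a small number of partial-least-squares components (discriminant PLS
with dummy-coded model labels for model choice, ordinary PLS on the
parameters for estimation; 7 components by default), retain the simulations
closest to the observed vector in component space (pure rejection,
Euclidean distance, 1% by default), and read model posteriors, Bayes
factors and parameter posteriors (KDE mode + 2.5-97.5% credible interval)
off the retained set.

Simulations with undefined summary entries are dropped (and counted)
before any fit; if the observed vector itself has an undefined entry the
statistic is removed from the registry for that run, with a warning.
Model-choice training sets are balanced by downsampling to the smallest
model's count so posterior proportions are not driven by unequal
simulation budgets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cross_decomposition import PLSRegression

from .errors import SweepABCError

__all__ = [
    "PLSModel", "RejectionResult", "ModelPosterior", "ParameterEstimate",
    "ABCPosterior", "ConfusionMatrix",
    "zscore_table", "fit_pls", "project", "abc_reject", "model_posterior",
    "estimate_parameters", "cross_validate_power", "dominance_model_choice",
    "drop_incomplete_rows", "model_param_columns", "infer",
    "epanechnikov_weights",
]

#: parameters inferred under each model (prior support read from the priors)
_MODEL_PARAMS = {
    "SDN": ["s_A", "s_NA", "t_mut"],
    "SSV": ["s_NA", "f0", "t_mut"],
    "NTR": ["t_mut"],
}


def model_param_columns(model: str) -> list:
    return list(_MODEL_PARAMS[model])


# ---------------------------------------------------------------------------
# table preparation
# ---------------------------------------------------------------------------

def drop_incomplete_rows(table: pd.DataFrame, stat_cols) -> tuple:
    """Remove simulations with undefined (NaN) statistic entries.

    Returns ``(clean table, number dropped)``. Distances over
    mixed-defined vectors are ill-posed, so such rows cannot enter the
    reference table.
    """
    ok = ~table[list(stat_cols)].isna().any(axis=1)
    return table[ok].reset_index(drop=True), int((~ok).sum())


def zscore_table(sim_stats: pd.DataFrame, observed) -> tuple:
    """Standardise each statistic to mean 0 / sd 1 across simulations and
    transform the observed vector with the same constants.

    Constant columns (zero variance) are dropped with a warning; a
    statistic missing from the observed vector is an error. Returns
    ``(Z, z_obs, transform)`` where ``transform`` holds the means/sds for
    de-standardising.
    """
    obs = pd.Series(observed, dtype=float)
    missing = [c for c in sim_stats.columns if c not in obs.index]
    if missing:
        raise SweepABCError(f"observed vector lacks statistics: {missing}")
    means = sim_stats.mean(axis=0)
    sds = sim_stats.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.all():
        warnings.warn(
            f"dropping constant statistic columns: {list(sds.index[~keep])}")
    cols = list(sim_stats.columns[keep])
    Z = (sim_stats[cols] - means[cols]) / sds[cols]
    z_obs = (obs[cols] - means[cols]) / sds[cols]
    transform = {"means": means[cols], "sds": sds[cols], "columns": cols}
    return Z, z_obs, transform


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """A fitted PLS reduction (discriminant or regression mode)."""

    mode: str
    columns: list
    n_components: int
    classes: list | None
    _pls: PLSRegression

    @property
    def x_scores_(self):
        return self._pls.x_scores_


def fit_pls(table: pd.DataFrame, response, mode: str,
            n_components: int = 7) -> PLSModel:
    """Fit the PLS summary-statistic reduction.

    ``mode="discriminant"``: ``response`` is a label sequence, dummy-coded
    into indicator columns (PLS-DA). ``mode="regression"``: ``response``
    is a DataFrame/array of parameter values. Components maximise
    covariance with the response; the fit is deterministic given the data
    order.
    """
    X = np.asarray(table, dtype=float)
    rank_cap = min(X.shape[1], X.shape[0] - 1)
    if n_components > rank_cap:
        raise SweepABCError(
            f"n_components={n_components} exceeds usable rank {rank_cap}")
    classes = None
    if mode == "discriminant":
        labels = pd.Series(list(response))
        classes = sorted(labels.unique())
        Y = np.column_stack([(labels == c).to_numpy(float) for c in classes])
    elif mode == "regression":
        Y = np.asarray(response, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
    else:
        raise SweepABCError(f"unknown PLS mode {mode!r}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, Y)
    return PLSModel(mode=mode, columns=list(table.columns),
                    n_components=n_components, classes=classes, _pls=pls)


def project(model: PLSModel, rows) -> np.ndarray:
    """Component scores of new (already z-scored) statistic rows."""
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return model._pls.transform(X)


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

@dataclass
class RejectionResult:
    indices: np.ndarray
    distances: np.ndarray
    cutoff: float


def abc_reject(observed_scores, sim_scores,
               retain_fraction: float = 0.01) -> RejectionResult:
    """Retain the ``ceil(retain_fraction * n)`` simulations closest to the
    observed point in component space (Euclidean), plus any ties at the
    cutoff distance."""
    sims = np.asarray(sim_scores, dtype=float)
    if sims.size == 0:
        raise SweepABCError("empty simulation table")
    if not 0 < retain_fraction <= 1:
        raise SweepABCError("retain_fraction must be in (0, 1]")
    obs = np.asarray(observed_scores, dtype=float).ravel()
    d = np.sqrt(((sims - obs) ** 2).sum(axis=1))
    k = math.ceil(retain_fraction * sims.shape[0])
    cutoff = np.partition(d, k - 1)[k - 1]
    idx = np.flatnonzero(d <= cutoff)
    return RejectionResult(indices=idx, distances=d[idx], cutoff=float(cutoff))


@dataclass
class ModelPosterior:
    """Posterior model probabilities and pairwise Bayes factors.

    Zero retained counts are reported as the bound 1/n_retained and
    flagged in ``floor_models`` (the corresponding Bayes factors are
    floor bounds too).
    """

    probabilities: dict
    bayes_factors: dict
    n_retained: int
    floor_models: set = field(default_factory=set)

    def best_model(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)


def epanechnikov_weights(distances) -> np.ndarray:
    """Epanechnikov kernel weights over the retained distances,
    w_i ∝ 1 − (d_i/d_max)², with the cutoff just beyond the largest
    retained distance so every retained simulation keeps positive weight."""
    d = np.asarray(distances, dtype=float)
    dmax = d.max() * (1 + 1e-9) if d.max() > 0 else 1.0
    return 1.0 - (d / dmax) ** 2


def model_posterior(retained_labels, training_counts: dict,
                    priors: dict | None = None,
                    weights=None) -> ModelPosterior:
    """Posterior model probabilities from the retained simulations.

    Retained counts are weighted inversely by each model's training count
    (so unequal simulation budgets do not masquerade as evidence) and by
    the model priors (equal by default); Bayes factors are posterior
    ratios under those priors. ``weights`` (e.g. from
    :func:`epanechnikov_weights`) replace the default uniform retention
    weighting with distance-kernel weighting.
    """
    labels = pd.Series(list(retained_labels))
    if labels.empty:
        raise SweepABCError("empty retained set")
    models = [m for m, c in training_counts.items() if c > 0]
    absent = set(training_counts) - set(models)
    if absent:
        warnings.warn(f"models absent from training, excluded: {sorted(absent)}")
    if priors is None:
        priors = {m: 1.0 / len(models) for m in models}
    n_ret = len(labels)
    if weights is None:
        w = np.ones(n_ret)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_ret,):
            raise SweepABCError("one weight per retained simulation required")
    raw = {m: priors[m] * w[(labels == m).to_numpy()].sum()
           / training_counts[m] for m in models}
    tot = sum(raw.values())
    probs = {m: raw[m] / tot for m in models}
    floor = {m for m in models if probs[m] == 0.0}
    bounded = dict(probs)
    for m in floor:
        bounded[m] = 1.0 / n_ret  # reported as "< 1/n_retained"
    bf = {}
    for i in models:
        for j in models:
            if i != j:
                bf[(i, j)] = bounded[i] / bounded[j]
    return ModelPosterior(probabilities=probs, bayes_factors=bf,
                          n_retained=n_ret, floor_models=floor)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class ParameterEstimate:
    mode: float
    ci_low: float
    ci_high: float
    sample: np.ndarray
    unstable: bool = False

    def __str__(self):
        return f"{self.mode:.3g} ({self.ci_low:.3g}-{self.ci_high:.3g})"


def _kde_mode(values: np.ndarray, support=None) -> float:
    """Posterior mode via Gaussian KDE (Silverman bandwidth) on a grid."""
    if np.ptp(values) == 0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    if support is not None:
        lo = max(lo, support[0])
        hi = min(hi, support[1])
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def estimate_parameters(retained_params: pd.DataFrame, distances,
                        adjustment: str = "none",
                        retained_scores=None, observed_scores=None,
                        prior_bounds: dict | None = None) -> dict:
    """Per-parameter posterior sample, KDE mode and 95% credible interval.

    ``adjustment="local-linear"`` applies the standard regression
    correction (each parameter regressed on the component scores among the
    retained simulations, residuals shifted to the observed point);
    adjusted values are clamped to the prior support. Fewer than 50
    retained rows flags every interval as unstable.
    """
    params = retained_params.reset_index(drop=True)
    n = len(params)
    if n == 0:
        raise SweepABCError("no retained simulations for parameter estimation")
    unstable = n < 50
    if unstable:
        warnings.warn(f"only {n} retained rows; credible intervals unstable")
    out = {}
    for col in params.columns:
        vals = params[col].to_numpy(float)
        if adjustment == "local-linear":
            if retained_scores is None or observed_scores is None:
                raise SweepABCError(
                    "local-linear adjustment needs retained and observed scores")
            X = np.asarray(retained_scores, float)
            X = np.column_stack([np.ones(len(X)), X])
            obs = np.concatenate(
                [[1.0], np.asarray(observed_scores, float).ravel()])
            beta, *_ = np.linalg.lstsq(X, vals, rcond=None)
            vals = vals + (obs - X).dot(beta)
        elif adjustment != "none":
            raise SweepABCError(f"unknown adjustment {adjustment!r}")
        support = None
        if prior_bounds and col in prior_bounds:
            support = prior_bounds[col]
            vals = np.clip(vals, support[0], support[1])
        lo, hi = np.quantile(vals, [0.025, 0.975])
        out[col] = ParameterEstimate(
            mode=_kde_mode(vals, support), ci_low=float(lo),
            ci_high=float(hi), sample=vals, unstable=unstable)
    return out


@dataclass
class ABCPosterior:
    """Full ABC report: model posteriors, Bayes factors, retained set and
    per-parameter mode + 95% credible interval under the winning model."""

    model_posterior: ModelPosterior
    retained: RejectionResult
    parameters: dict
    chosen_model: str

    def to_report(self) -> dict:
        return {
            "posterior_probabilities": self.model_posterior.probabilities,
            "bayes_factors": {f"{i}/{j}": v for (i, j), v
                              in self.model_posterior.bayes_factors.items()},
            "chosen_model": self.chosen_model,
            "n_retained": self.model_posterior.n_retained,
            "parameters": {k: {"mode": p.mode, "ci95": [p.ci_low, p.ci_high]}
                           for k, p in self.parameters.items()},
        }


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def _balance(tables: dict, rng: np.random.Generator) -> dict:
    """Downsample every model's table to the smallest model's count."""
    n_min = min(len(t) for t in tables.values())
    out = {}
    for m, t in tables.items():
        if len(t) > n_min:
            idx = rng.choice(len(t), size=n_min, replace=False)
            idx.sort()
            out[m] = t.iloc[idx].reset_index(drop=True)
        else:
            out[m] = t.reset_index(drop=True)
    return out


def _prepare_observed(observed, stat_cols) -> tuple:
    """Drop registry statistics that are undefined in the observed vector."""
    obs = pd.Series(observed, dtype=float)
    bad = [c for c in stat_cols if c in obs.index and np.isnan(obs[c])]
    if bad:
        warnings.warn(f"observed statistics undefined, removed from "
                      f"registry for this run: {bad}")
    return obs, [c for c in stat_cols if c not in bad]


def infer(tables: dict, observed, stat_cols,
          retain_fraction: float = 0.01, n_components: int = 7,
          seed: int = 0, adjustment: str = "none",
          prior_bounds: dict | None = None,
          estimate_for: str | None = None) -> ABCPosterior:
    """End-to-end ABC on one observed summary vector.

    ``tables`` maps model name to its simulated reference table (parameter
    columns + statistic columns). Stage 1 (PLS-DA + rejection) yields the
    model posterior; stage 2 refits an ordinary-PLS reduction on the
    winning model's own table (or ``estimate_for``) and estimates its
    parameters from the retained simulations.
    """
    rng = np.random.default_rng(seed)
    observed, stat_cols = _prepare_observed(observed, stat_cols)
    clean = {}
    for m, t in tables.items():
        ct, dropped = drop_incomplete_rows(t, stat_cols)
        if len(ct) == 0:
            raise SweepABCError(f"model {m}: no complete simulations")
        clean[m] = ct
    balanced = _balance(clean, rng)
    train = pd.concat(balanced.values(), ignore_index=True)
    labels = np.concatenate(
        [[m] * len(t) for m, t in balanced.items()])
    Z, z_obs, _ = zscore_table(train[stat_cols], observed[stat_cols])
    ncomp = min(n_components, Z.shape[1], len(Z) - 1)
    plsda = fit_pls(Z, labels, "discriminant", ncomp)
    scores = project(plsda, Z)
    obs_scores = project(plsda, z_obs.to_numpy())
    rej = abc_reject(obs_scores, scores, retain_fraction)
    counts = {m: len(t) for m, t in balanced.items()}
    post = model_posterior(labels[rej.indices], counts)
    chosen = estimate_for or post.best_model()

    # stage 2: parameter estimation within the chosen model
    tbl = clean[chosen]
    if chosen in _MODEL_PARAMS:
        pcols = [c for c in _MODEL_PARAMS[chosen] if c in tbl.columns]
    else:
        meta = {"model", "h", "origin_gen", "attempts"}
        pcols = [c for c in tbl.columns
                 if c not in stat_cols and c not in meta
                 and not tbl[c].isna().all()]
    Zm, z_obs_m, _ = zscore_table(tbl[stat_cols], observed[stat_cols])
    ncomp_m = min(n_components, Zm.shape[1], len(Zm) - 1, len(pcols) * 3)
    ncomp_m = max(ncomp_m, 1)
    pls_r = fit_pls(Zm, tbl[pcols], "regression", ncomp_m)
    sc_m = project(pls_r, Zm)
    obs_sc_m = project(pls_r, z_obs_m.to_numpy())
    rej_m = abc_reject(obs_sc_m, sc_m, retain_fraction)
    params = estimate_parameters(
        tbl.iloc[rej_m.indices][pcols], rej_m.distances,
        adjustment=adjustment,
        retained_scores=sc_m[rej_m.indices], observed_scores=obs_sc_m,
        prior_bounds=prior_bounds)
    return ABCPosterior(model_posterior=post, retained=rej,
                        parameters=params, chosen_model=chosen)


@dataclass
class ConfusionMatrix:
    """Cross-validation assignment counts and per-model correct rates."""

    counts: pd.DataFrame           # true model x assigned model
    rates: dict                    # true model -> correct fraction
    standard_errors: dict          # binomial SE of each rate
    n_dropped: dict                # sentinel rows removed per model

    def __str__(self):
        lines = [self.counts.to_string()]
        for m, r in self.rates.items():
            lines.append(f"{m}: {100 * r:.1f}% +- "
                         f"{100 * self.standard_errors[m]:.1f}%")
        return "\n".join(lines)


def cross_validate_power(tables: dict, n_pseudo: int,
                         retain_fraction: float = 0.01,
                         n_components: int = 7,
                         seed: int = 0) -> ConfusionMatrix:
    """Leave-out cross-validation of the model-choice procedure.

    ``n_pseudo`` simulations per model are held out as pseudo-observed
    datasets (excluded from training); the remaining training sets are
    balanced, reduced with one PLS-DA fit and each pseudo-observed vector
    is assigned to the argmax-posterior model after rejection. Returns the
    confusion matrix with per-model correct-assignment rates and binomial
    standard errors.
    """
    rng = np.random.default_rng(seed)
    models = list(tables)
    stat_cols = None
    clean, dropped = {}, {}
    for m in models:
        t = tables[m]
        if stat_cols is None:
            stat_cols = [c for c in t.columns if c not in
                         ("model", "s_A", "s_NA", "t_mut", "f0", "h",
                          "origin_gen", "attempts")]
        clean[m], dropped[m] = drop_incomplete_rows(t, stat_cols)
        if len(clean[m]) <= n_pseudo:
            raise SweepABCError(
                f"model {m}: {len(clean[m])} usable rows cannot supply "
                f"{n_pseudo} pseudo-observed datasets plus training")
    holdout, training = {}, {}
    for m in models:
        idx = rng.permutation(len(clean[m]))
        holdout[m] = clean[m].iloc[idx[:n_pseudo]].reset_index(drop=True)
        training[m] = clean[m].iloc[idx[n_pseudo:]].reset_index(drop=True)
    training = _balance(training, rng)
    train = pd.concat(training.values(), ignore_index=True)
    labels = np.concatenate([[m] * len(t) for m, t in training.items()])
    means = train[stat_cols].mean(axis=0)
    sds = train[stat_cols].std(axis=0, ddof=0)
    keep = [c for c in stat_cols if sds[c] > 0]
    Z = (train[keep] - means[keep]) / sds[keep]
    ncomp = min(n_components, len(keep), len(Z) - 1)
    plsda = fit_pls(Z, labels, "discriminant", ncomp)
    scores = project(plsda, Z)
    counts = {m: len(t) for m, t in training.items()}
    assigned = {m: {m2: 0 for m2 in models} for m in models}
    for m in models:
        Zh = ((holdout[m][keep] - means[keep]) / sds[keep]).to_numpy()
        h_scores = project(plsda, Zh)
        for row in h_scores:
            rej = abc_reject(row, scores, retain_fraction)
            post = model_posterior(labels[rej.indices], counts)
            assigned[m][post.best_model()] += 1
    cm = pd.DataFrame(assigned).T[models]
    rates, ses = {}, {}
    for m in models:
        r = cm.loc[m, m] / n_pseudo
        rates[m] = float(r)
        ses[m] = float(np.sqrt(r * (1 - r) / n_pseudo))
    return ConfusionMatrix(counts=cm, rates=rates, standard_errors=ses,
                           n_dropped=dropped)


@dataclass
class DominanceResult:
    """Joint and marginal posteriors of the dominance comparison."""

    joint: dict                    # category -> probability
    dominance_marginal: dict       # h value (or "NTR") -> probability
    selection_marginal: dict       # h value -> {model -> probability}
    n_retained: int


def dominance_model_choice(tables: dict, observed, stat_cols,
                           retain_fraction: float = 0.01,
                           n_components: int = 7,
                           seed: int = 0) -> DominanceResult:
    """Joint ABC over selection-model x dominance-model categories.

    ``tables`` maps ``(model, h)`` for model in {SDN, SSV} and h in
    {0, 0.38, 0.5}, plus ``"NTR"``, to reference tables. One rejection run
    over all categories gives the joint posterior; the dominance marginal
    sums SDN and SSV within each h (NTR kept as its own category), and the
    selection marginal renormalises SDN/SSV within each dominance model.
    """
    expected_h = (0.0, 0.38, 0.5)
    cats = {}
    for h in expected_h:
        for model in ("SDN", "SSV"):
            key = (model, h)
            if key not in tables:
                raise SweepABCError(f"missing dominance category {key}")
            cats[f"{model}@h={h:g}"] = tables[key]
    if "NTR" not in tables:
        raise SweepABCError("missing NTR table")
    cats["NTR"] = tables["NTR"]
    rng = np.random.default_rng(seed)
    observed, stat_cols = _prepare_observed(observed, stat_cols)
    clean = {k: drop_incomplete_rows(t, stat_cols)[0] for k, t in cats.items()}
    balanced = _balance(clean, rng)
    train = pd.concat(balanced.values(), ignore_index=True)
    labels = np.concatenate([[k] * len(t) for k, t in balanced.items()])
    Z, z_obs, _ = zscore_table(train[stat_cols], observed[stat_cols])
    ncomp = min(n_components, Z.shape[1], len(Z) - 1)
    plsda = fit_pls(Z, labels, "discriminant", ncomp)
    scores = project(plsda, Z)
    obs_scores = project(plsda, z_obs.to_numpy())
    rej = abc_reject(obs_scores, scores, retain_fraction)
    counts = {k: len(t) for k, t in balanced.items()}
    post = model_posterior(labels[rej.indices], counts)
    joint = post.probabilities
    dom = {}
    sel = {}
    for h in expected_h:
        ph = joint[f"SDN@h={h:g}"] + joint[f"SSV@h={h:g}"]
        dom[h] = ph
        sel[h] = ({m: joint[f"{m}@h={h:g}"] / ph for m in ("SDN", "SSV")}
                  if ph > 0 else {m: np.nan for m in ("SDN", "SSV")})
    dom["NTR"] = joint["NTR"]
    return DominanceResult(joint=joint, dominance_marginal=dom,
                           selection_marginal=sel,
                           n_retained=post.n_retained)
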