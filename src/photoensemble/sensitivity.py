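"""Variance-based sensitivity analysis over the 12-model ensemble.

Two complementary analyses are provided:

* **Parameter SA** — first-order Sobol indices of the 14 parameters via the
  Saltelli two-matrix estimator, computed per model and per environmental
  scenario, then pooled across models and integrated across scenarios by
  variance weighting.  This captures within-model variance only.

* **Process SA** — first-order indices of four *processes* (carboxylation,
  electron transport, TPU, limiting-rate selection), where a factor is the
  pair (hypothesis choice, member parameters) of that process.  The
  conditional mean of the output given a process's factor is estimated by
  stratifying over the process's hypotheses and enumerating all complementary
  hypothesis combinations, so the indices capture both between-model
  (hypothesis) and within-model (parameter) variance.

Outputs are tidy DataFrames with one row per scenario (plus an integrated
row), columns ``mean``, ``variance`` and one ``S_<factor>`` per factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    ETRANS_HYPOTHESES,
    SELECTION_HYPOTHESES,
    ModelConfig,
    all_models,
)
from .params import SA_CENTRAL, Environment, PhotoParams, StomatalParams
from .stomata import solve_coupled_batch

__all__ = [
    "ParamRange",
    "PARAM_RANGES",
    "ScenarioGrid",
    "ProcessSpec",
    "PROCESSES",
    "SAResult",
    "sample_parameters",
    "parameter_sa",
    "process_sa",
    "stratified_process_indices",
    "saltelli_first_order",
    "delta_a",
    "integrate_indexes",
    "bootstrap_convergence",
]


@dataclass(frozen=True)
class ParamRange:
    """Uniform sampling range of one parameter (±10% of its central value)."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"invalid range for {self.name}: [{self.low}, {self.high}]")

    @property
    def central(self) -> float:
        return 0.5 * (self.low + self.high)


# The 14 varied parameters with their printed ±10% ranges.
PARAM_RANGES: dict[str, ParamRange] = {
    r.name: r
    for r in [
        ParamRange("vcmax25", 45.0, 55.0),
        ParamRange("kc_half", 36.4, 44.5),
        ParamRange("ko_half", 25.1, 30.6),
        ParamRange("ko_kc_ratio", 0.19, 0.23),
        ParamRange("absorptance_a", 0.72, 0.88),
        ParamRange("f_loss", 0.207, 0.253),
        ParamRange("theta_j", 0.81, 0.99),
        ParamRange("a_jv", 26.2, 32.0),
        ParamRange("b_jv", 1.467, 1.804),
        ParamRange("b_tv", 0.15, 0.183),
        ParamRange("alpha_tpu", 0.45, 0.55),
        ParamRange("b_rv", 0.0135, 0.0165),
        ParamRange("theta_cj", 0.81, 0.99),
        ParamRange("theta_cjp", 0.81, 0.99),
    ]
}

PARAM_NAMES = tuple(PARAM_RANGES)


@dataclass(frozen=True)
class ScenarioGrid:
    """Factorial Ca × I scenario grid plus the ΔA (CO2-step) scenarios."""

    ca_levels: tuple = (280.0, 400.0, 600.0)
    i_levels: tuple = (200.0, 500.0, 1000.0)
    ca_pairs: tuple = ((280.0, 400.0), (400.0, 600.0))

    def scenarios(self) -> list[tuple[float, float]]:
        """The 9 (Ca, I) combinations, I-major to match the reported tables."""
        return [(ca, i) for i in self.i_levels for ca in self.ca_levels]

    def delta_scenarios(self) -> list[tuple[tuple[float, float], float]]:
        """The 6 (Ca_low→Ca_high, I) combinations."""
        return [(pair, i) for i in self.i_levels for pair in self.ca_pairs]


@dataclass(frozen=True)
class ProcessSpec:
    """A process: its alternative hypotheses and the parameters it owns."""

    process: str
    hypotheses: tuple
    member_params: tuple


# R_d scales with V_cmax, so b_rv is grouped with carboxylation.
PROCESSES: dict[str, ProcessSpec] = {
    "carboxylation": ProcessSpec(
        "carboxylation", (None,),
        ("vcmax25", "kc_half", "ko_half", "ko_kc_ratio", "b_rv"),
    ),
    "electron_transport": ProcessSpec(
        "electron_transport", ETRANS_HYPOTHESES,
        ("absorptance_a", "f_loss", "theta_j", "a_jv", "b_jv"),
    ),
    "tpu": ProcessSpec("tpu", (False, True), ("b_tv", "alpha_tpu")),
    "limiting_rate_selection": ProcessSpec(
        "limiting_rate_selection", SELECTION_HYPOTHESES,
        ("theta_cj", "theta_cjp"),
    ),
}

# sanity: the four member sets partition all 14 parameters
assert sorted(sum((p.member_params for p in PROCESSES.values()), ())) == sorted(PARAM_NAMES)


@dataclass
class SAResult:
    """Tidy per-scenario table, integrated summary, and optional raw samples."""

    output: str
    factors: tuple
    per_scenario: pd.DataFrame
    integrated: dict
    samples: Optional[dict] = None
    n: int = 0

    def index(self, factor: str) -> float:
        return self.integrated[f"S_{factor}"]


def sample_parameters(n: int, ranges: dict[str, ParamRange] | None = None,
                      rng=None, names: Sequence[str] | None = None) -> dict[str, np.ndarray]:
    """n independent uniform draws of each named parameter."""
    if n <= 0:
        raise ValueError("n must be > 0")
    ranges = ranges or PARAM_RANGES
    names = tuple(names) if names is not None else tuple(ranges)
    rng = np.random.default_rng(rng)
    return {name: rng.uniform(ranges[name].low, ranges[name].high, n) for name in names}


def _evaluate(sample: dict, config: ModelConfig, scenario, output: str,
              stomatal: StomatalParams, base: PhotoParams, env0: Environment):
    """Output (A or ΔA) for a dict of parameter arrays under one scenario."""
    params = base.replace(**sample)
    if output == "A":
        ca, irr = scenario
        env = env0.replace(ca=ca, irradiance=irr)
        return solve_coupled_batch(env, params, config, stomatal)
    if output == "deltaA":
        (ca_lo, ca_hi), irr = scenario
        a_hi = solve_coupled_batch(env0.replace(ca=ca_hi, irradiance=irr), params, config, stomatal)
        a_lo = solve_coupled_batch(env0.replace(ca=ca_lo, irradiance=irr), params, config, stomatal)
        return a_hi - a_lo
    raise ValueError(f"unknown output: {output!r}")


def delta_a(config: ModelConfig, params: PhotoParams, i_level: float,
            ca_pair: tuple[float, float],
            stomatal: StomatalParams | None = None,
            env: Environment | None = None):
    """Assimilation response A(Ca_high) - A(Ca_low) at identical parameters."""
    stomatal = stomatal or StomatalParams()
    env = env or Environment()
    ca_lo, ca_hi = ca_pair
    a_hi = solve_coupled_batch(env.replace(ca=ca_hi, irradiance=i_level), params, config, stomatal)
    a_lo = solve_coupled_batch(env.replace(ca=ca_lo, irradiance=i_level), params, config, stomatal)
    return a_hi - a_lo


def _scenario_label(scenario, output):
    if output == "A":
        return {"ca": scenario[0], "i": scenario[1]}
    (lo, hi), irr = scenario
    return {"ca": f"{lo:g}-{hi:g}", "i": irr}


# ---------------------------------------------------------------------------
# Parameter SA (Saltelli first-order estimator)
# ---------------------------------------------------------------------------

def saltelli_first_order(func: Callable[[np.ndarray], np.ndarray],
                         a_mat: np.ndarray, b_mat: np.ndarray):
    """First-order Sobol indices of ``func`` by the Saltelli scheme.

    ``a_mat``/``b_mat`` are (n, k) sample matrices.  Returns
    ``(indices, mean, variance, samples)`` where samples holds the raw
    evaluations (f_A, f_B, f_AB of shape (k, n)) for bootstrapping.
    S_i = E[f_B (f_AB_i - f_A)] / Var(Y), the Saltelli/Jansen-style
    correlation form, which is exact in expectation for independent inputs.
    """
    n, k = a_mat.shape
    blocks = [a_mat, b_mat]
    for i in range(k):
        ab = a_mat.copy()
        ab[:, i] = b_mat[:, i]
        blocks.append(ab)
    y = func(np.vstack(blocks))
    f_a, f_b = y[:n], y[n:2 * n]
    f_ab = y[2 * n:].reshape(k, n)
    pooled = np.concatenate([f_a, f_b])
    mean = pooled.mean()
    var = pooled.var()
    if var <= 0:
        raise ZeroDivisionError("degenerate output variance; indices undefined")
    # centring f_B does not change the expectation (E[f_AB_i - f_A] = 0) but
    # removes the mean-level noise term, which dominates when |E Y| >> sd(Y)
    s = ((f_b - mean) * (f_ab - f_a)).mean(axis=1) / var
    return s, mean, var, {"f_a": f_a, "f_b": f_b, "f_ab": f_ab}


def parameter_sa(n: int, scenarios=None, output: str = "A",
                 configs: Sequence[ModelConfig] | None = None,
                 ranges: dict[str, ParamRange] | None = None,
                 stomatal: StomatalParams | None = None,
                 base_params: PhotoParams | None = None,
                 env: Environment | None = None,
                 seed=0, keep_samples: bool = False) -> SAResult:
    """First-order Sobol indices of the 14 parameters, per model/scenario.

    Per-scenario pooling across models weights each model's indices by its
    output variance (models enter with equal probability); integration across
    scenarios also weights indices by scenario variance, while means and
    variances integrate as unweighted scenario averages.
    """
    grid = ScenarioGrid() if scenarios is None else scenarios
    if isinstance(grid, ScenarioGrid):
        scen_list = grid.scenarios() if output == "A" else grid.delta_scenarios()
    else:
        scen_list = list(grid)
    configs = list(configs) if configs is not None else all_models()
    ranges = ranges or PARAM_RANGES
    stomatal = stomatal or StomatalParams()
    base = base_params or SA_CENTRAL
    env0 = env or Environment()
    names = tuple(ranges)
    k = len(names)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows = []
    samples = {} if keep_samples else None
    for scenario in scen_list:
        lo = np.array([ranges[nm].low for nm in names])
        span = np.array([ranges[nm].high - ranges[nm].low for nm in names])
        a_mat = lo + span * rng.random((n, k))
        b_mat = lo + span * rng.random((n, k))
        for config in configs:
            def func(mat, _c=config, _s=scenario):
                sample = {nm: mat[:, i] for i, nm in enumerate(names)}
                return _evaluate(sample, _c, _s, output, stomatal, base, env0)

            s, mean, var, raw = saltelli_first_order(func, a_mat, b_mat)
            row = {**_scenario_label(scenario, output), "model_id": config.model_id,
                   "mean": mean, "variance": var}
            row.update({f"S_{nm}": s[i] for i, nm in enumerate(names)})
            rows.append(row)
            if keep_samples:
                samples[(scenario, config.model_id)] = raw

    per_model = pd.DataFrame(rows)
    s_cols = [f"S_{nm}" for nm in names]

    # pool across models within each scenario (variance-weighted indices)
    pooled_rows = []
    for scenario in scen_list:
        lbl = _scenario_label(scenario, output)
        sub = per_model[(per_model["ca"] == lbl["ca"]) & (per_model["i"] == lbl["i"])]
        w = sub["variance"].to_numpy()
        row = {**lbl, "model_id": "int",
               "mean": sub["mean"].mean(), "variance": sub["variance"].mean()}
        for c in s_cols:
            row[c] = float((w * sub[c].to_numpy()).sum() / w.sum())
        pooled_rows.append(row)
    pooled = pd.DataFrame(pooled_rows)

    integrated = integrate_indexes(pooled, s_cols)
    # Table-4 style per-model integration across scenarios
    model_rows = []
    for config in configs:
        sub = per_model[per_model["model_id"] == config.model_id]
        r = integrate_indexes(sub, s_cols)
        r["model_id"] = config.model_id
        model_rows.append(r)
    per_scenario = pd.concat([pooled, per_model], ignore_index=True)
    result = SAResult(output=output, factors=names, per_scenario=per_scenario,
                      integrated=integrated, samples=samples, n=n)
    result.per_model_integrated = pd.DataFrame(model_rows)
    return result


# ---------------------------------------------------------------------------
# Process SA (stratified within- plus between-model decomposition)
# ---------------------------------------------------------------------------

def _combine_config(assign: dict) -> ModelConfig:
    return ModelConfig(tpu_included=assign["tpu"],
                       selection=assign["limiting_rate_selection"],
                       etrans_hypothesis=assign["electron_transport"])


def stratified_process_indices(evaluate: Callable, processes: dict,
                               ranges: dict, n: int, rng,
                               keep_samples: bool = False) -> dict:
    """Generic stratified estimator of first-order process indices.

    ``evaluate(assignment, sample)`` maps a hypothesis assignment (dict
    process name → hypothesis) and a dict of parameter arrays to an output
    array.  For each process the factor is (hypothesis, member parameters):
    n outer draws of the member parameters are crossed with each hypothesis
    stratum, the conditional mean enumerates every combination of the other
    processes' hypotheses with n shared draws of the remaining parameters
    (common random numbers across strata), and
    S_k = Var(E[Y | factor_k]) / Var(Y) with the total variance pooled over
    every execution.
    """
    proc_names = tuple(processes)
    if any(len(processes[p].hypotheses) == 0 for p in proc_names):
        raise ValueError("every process needs at least one hypothesis")
    all_names = tuple(sum((tuple(processes[p].member_params) for p in proc_names), ()))
    total_sum = total_sumsq = 0.0
    total_count = 0
    cond_means = {}
    samples = {} if keep_samples else None
    for pname in proc_names:
        spec = processes[pname]
        outer = sample_parameters(n, ranges, rng, names=spec.member_params)
        comp_names = [nm for nm in all_names if nm not in spec.member_params]
        inner = sample_parameters(n, ranges, rng, names=comp_names) if comp_names else {}
        other = {q: processes[q].hypotheses for q in proc_names if q != pname}
        combos = [dict(zip(other, vals)) for vals in product(*other.values())]
        m_k = len(spec.hypotheses)
        M = np.zeros((m_k, n))
        y_store = [] if keep_samples else None
        for hi_, hyp in enumerate(spec.hypotheses):
            acc = np.zeros(n)
            for combo in combos:
                assign = dict(combo)
                assign[pname] = hyp
                sample = {nm: outer[nm][:, None] for nm in spec.member_params}
                sample.update({nm: inner[nm][None, :] for nm in comp_names})
                y = np.broadcast_to(np.asarray(evaluate(assign, sample), dtype=float),
                                    (n, n))
                acc += y.mean(axis=1)
                total_sum += y.sum()
                total_sumsq += (y * y).sum()
                total_count += y.size
                if keep_samples:
                    y_store.append(np.array(y))
            M[hi_] = acc / len(combos)
        cond_means[pname] = M
        if keep_samples:
            samples[pname] = np.array(y_store).reshape(m_k, len(combos), n, n)
    mean = total_sum / total_count
    var = total_sumsq / total_count - mean * mean
    indices = {p: float((np.mean(M * M) - np.mean(M) ** 2) / var)
               for p, M in cond_means.items()}
    return {"mean": mean, "variance": var, "indices": indices,
            "cond_means": cond_means, "samples": samples}


def process_sa(n: int, scenarios=None, output: str = "A",
               ranges: dict[str, ParamRange] | None = None,
               stomatal: StomatalParams | None = None,
               base_params: PhotoParams | None = None,
               env: Environment | None = None,
               seed=0, keep_samples: bool = False) -> SAResult:
    """First-order process sensitivity indices over the 12-model ensemble.

    For process k with m_k hypotheses and member parameters x_k, the factor
    is (h_k, x_k).  n outer draws of x_k are paired with each hypothesis
    stratum (uniform weight 1/m_k); the conditional mean for each outer
    sample enumerates all 12/m_k complementary hypothesis combinations with
    n shared draws of the remaining parameters (common random numbers across
    strata).  S_k = Var(E[Y | h_k, x_k]) / Var(Y), with the total variance
    taken over every ensemble execution of the scenario.
    """
    grid = ScenarioGrid() if scenarios is None else scenarios
    if isinstance(grid, ScenarioGrid):
        scen_list = grid.scenarios() if output == "A" else grid.delta_scenarios()
    else:
        scen_list = list(grid)
    ranges = ranges or PARAM_RANGES
    stomatal = stomatal or StomatalParams()
    base = base_params or SA_CENTRAL
    env0 = env or Environment()
    proc_names = tuple(PROCESSES)
    ss = np.random.SeedSequence(seed)
    scen_rngs = [np.random.default_rng(child) for child in ss.spawn(len(scen_list))]

    rows = []
    samples = {} if keep_samples else None
    for scen_i, scenario in enumerate(scen_list):
        def evaluate(assign, sample, _s=scenario):
            config = _combine_config({k: v for k, v in assign.items()
                                      if k != "carboxylation"})
            return _evaluate(sample, config, _s, output, stomatal, base, env0)

        res = stratified_process_indices(evaluate, PROCESSES, ranges, n,
                                         scen_rngs[scen_i], keep_samples)
        row = {**_scenario_label(scenario, output),
               "mean": res["mean"], "variance": res["variance"]}
        row.update({f"S_{p}": res["indices"][p] for p in proc_names})
        rows.append(row)
        if keep_samples:
            for pname, y in res["samples"].items():
                samples[(scen_i, pname)] = y

    per_scenario = pd.DataFrame(rows)
    s_cols = [f"S_{p}" for p in proc_names]
    integrated = integrate_indexes(per_scenario, s_cols)
    return SAResult(output=output, factors=proc_names, per_scenario=per_scenario,
                    integrated=integrated, samples=samples, n=n)


# ---------------------------------------------------------------------------
# Integration and convergence
# ---------------------------------------------------------------------------

def integrate_indexes(per_scenario: pd.DataFrame, index_cols: Sequence[str]) -> dict:
    """Variance-weighted integration of indices across scenarios.

    Indices are weighted by scenario variance; the integrated mean and
    variance are unweighted scenario averages (this reproduces the reported
    integrated rows exactly from the per-scenario rows).
    """
    if len(per_scenario) == 0:
        raise ValueError("need at least one scenario")
    w = per_scenario["variance"].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ZeroDivisionError("zero total variance")
    out = {
        "mean": float(per_scenario["mean"].mean()),
        "variance": float(per_scenario["variance"].mean()),
    }
    for c in index_cols:
        out[c] = float((w * per_scenario[c].to_numpy(dtype=float)).sum() / w.sum())
    return out


def bootstrap_convergence(result: SAResult, n_boot: int = 200, seed=0) -> pd.DataFrame:
    """Bootstrap standard deviations of the per-scenario indices.

    Requires a result produced with ``keep_samples=True``.  Convergence is
    declared when every index SD is below 0.001.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if result.samples is None:
        raise ValueError("run the SA with keep_samples=True to bootstrap")
    rng = np.random.default_rng(seed)
    rows = []
    if result.factors == tuple(PROCESSES):
        # process SA: resample outer and inner draw indices jointly
        scen_ids = sorted({k[0] for k in result.samples})
        for scen_i in scen_ids:
            reps = {p: [] for p in result.factors}
            for _ in range(n_boot):
                stats = {}
                tot_s = tot_sq = tot_n = 0.0
                for pname in result.factors:
                    y = result.samples[(scen_i, pname)]
                    n = y.shape[2]
                    oi = rng.integers(0, n, n)
                    ji = rng.integers(0, y.shape[3], y.shape[3])
                    yb = y[:, :, oi][:, :, :, ji]
                    stats[pname] = yb.mean(axis=(1, 3))
                    tot_s += yb.sum()
                    tot_sq += (yb * yb).sum()
                    tot_n += yb.size
                mean = tot_s / tot_n
                var = tot_sq / tot_n - mean * mean
                for pname, M in stats.items():
                    reps[pname].append((np.mean(M * M) - np.mean(M) ** 2) / var)
            row = {"scenario": scen_i}
            row.update({f"S_{p}": float(np.std(reps[p])) for p in result.factors})
            rows.append(row)
    else:
        # parameter SA: resample sample rows
        for key, raw in result.samples.items():
            scenario, model_id = key
            f_a, f_b, f_ab = raw["f_a"], raw["f_b"], raw["f_ab"]
            n = len(f_a)
            reps = []
            for _ in range(n_boot):
                idx = rng.integers(0, n, n)
                fa, fb, fab = f_a[idx], f_b[idx], f_ab[:, idx]
                var = np.concatenate([fa, fb]).var()
                reps.append((fb * (fab - fa)).mean(axis=1) / var)
            sds = np.std(np.array(reps), axis=0)
            row = {"scenario": str(scenario), "model_id": model_id}
            row.update({f"S_{nm}": float(sds[i]) for i, nm in enumerate(result.factors)})
            rows.append(row)
    df = pd.DataFrame(rows)
    s_cols = [c for c in df.columns if c.startswith("S_")]
    df.attrs["converged"] = bool((df[s_cols].to_numpy() < 0.001).all())
    return df
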