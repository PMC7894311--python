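"""Coupled assimilation / stomatal-conductance / Ci solution.

The demand side (biochemistry, :mod:`photo_core`) fixes A as a function of
Ci; the supply side is CO2 diffusion through stomata whose conductance
follows the unified (Medlyn) model,

    g_s = g0 + 1.6 (1 + g1/sqrt(D)) max(A, 0) / C_a ,
    Ci  = C_a - 1.6 A / g_s            (mole-fraction form).

The solver finds the Ci where demand and supply agree.  Because the
minimum-selection models have derivative discontinuities, a safeguarded
bisection on the supply-demand residual is used rather than a Newton-type
method; it is fully vectorized over parameter/environment arrays.
Boundary-layer and mesophyll resistances are taken as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import ModelConfig
from .params import Environment, PhotoParams, StomatalParams
from .photo_core import PhotoResult, demand_a_net, electron_transport, gamma_star

__all__ = ["medlyn_gs", "solve_coupled_batch", "solve_coupled", "response_curve"]

DEFAULT_CA_GRID = np.arange(50.0, 1501.0, 50.0)      # µmol/mol at I = 960
DEFAULT_I_GRID = np.arange(10.0, 1961.0, 50.0)       # µmol m-2 s-1 at Ca = 400
N_BISECT = 52


def medlyn_gs(a_net, ca, vpd, stomatal: StomatalParams):
    """Stomatal conductance to water (mol m⁻² s⁻¹) from the unified model.

    ``ca`` in µmol/mol, ``vpd`` in kPa.  A is floored at zero so conductance
    never drops below the residual g0.
    """
    vpd = np.asarray(vpd, dtype=float)
    if np.any(vpd <= 0):
        raise ValueError("vpd must be > 0")
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca must be > 0")
    a_pos = np.maximum(np.asarray(a_net, dtype=float), 0.0)
    return stomatal.g0 + 1.6 * (1.0 + stomatal.g1 / np.sqrt(vpd)) * a_pos / ca


def _demand_fast(ci_pa, pre, config: ModelConfig):
    """Ci-dependent part of the demand chain, on precomputed invariants."""
    ac = pre["vcmax"] * ci_pa / (ci_pa + pre["km_eff"])
    aj = 0.25 * pre["j"] * ci_pa / (ci_pa + 2.0 * pre["gstar"])
    if config.selection == "minimum":
        ag = np.minimum(ac, aj)
    else:
        ag = smaller_root_fast(pre["theta_cj"], ac, aj)
    if config.tpu_included:
        denom = ci_pa - pre["tpu_cut"]
        applicable = denom > 0
        ap = 3.0 * pre["tpu"] * ci_pa / np.where(applicable, denom, 1.0)
        if config.selection == "minimum":
            ag = np.where(applicable & (ap < ag), ap, ag)
        else:
            ag = np.where(applicable,
                          smaller_root_fast(pre["theta_cjp"], ag, np.where(applicable, ap, 1.0)),
                          ag)
    return ag * (1.0 - pre["gstar"] / ci_pa) - pre["rd"]


def smaller_root_fast(theta, x1, x2):
    # same conjugate form as photo_core.smaller_root, minus domain checks
    s = x1 + x2
    disc = np.maximum(s * s - 4.0 * theta * x1 * x2, 0.0)
    return 2.0 * x1 * x2 / (s + np.sqrt(disc))


def solve_coupled_batch(env: Environment, params: PhotoParams,
                        config: ModelConfig, stomatal: StomatalParams,
                        n_bisect: int = N_BISECT, full: bool = False):
    """Vectorized coupled solve; returns A or a dict of intermediates.

    ``env`` fields and ``params`` fields may be arrays of a common broadcast
    shape.  The residual r(Ci) = Ci_supply(A(Ci)) - Ci is positive at Ci→0
    (negative A inflates supply above C_a) and negative at the upper bracket,
    so bisection always converges; the default iteration count leaves the
    bracket width at machine level.
    """
    ca = np.asarray(env.ca, dtype=float)
    to_pa = np.asarray(env.pressure, dtype=float) * 1e-3
    gstar = gamma_star(params, env)
    km_eff = params.kc_half * (1.0 + np.asarray(env.oi) / params.ko_half)
    pre = {
        "vcmax": np.asarray(params.vcmax25, dtype=float),
        "km_eff": km_eff,
        "gstar": gstar,
        "j": np.asarray(
            electron_transport(env.irradiance, params, config.etrans_hypothesis),
            dtype=float),
        "rd": np.asarray(params.rd, dtype=float),
        "theta_cj": np.asarray(params.theta_cj, dtype=float),
        "theta_cjp": np.asarray(params.theta_cjp, dtype=float),
        "tpu": np.asarray(params.tpu25, dtype=float),
        "tpu_cut": (1.0 + 3.0 * np.asarray(params.alpha_tpu)) * gstar,
    }
    gs_slope = 1.6 * (1.0 + stomatal.g1 / np.sqrt(np.asarray(env.vpd, dtype=float)))
    # Upper bracket: Ca plus the largest possible supply inflation from
    # negative A (bounded by R_d + V_cmax·Γ*/K_m) through g0.
    a_floor = pre["rd"] + pre["vcmax"] * gstar / km_eff
    lo = np.zeros(np.broadcast_shapes(ca.shape, np.shape(a_floor), np.shape(pre["j"]))) + 1e-9
    hi = np.broadcast_to(ca + 1.6 * a_floor / stomatal.g0 + 10.0, lo.shape).copy()

    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        a = _demand_fast(mid * to_pa, pre, config)
        gs = stomatal.g0 + gs_slope * np.maximum(a, 0.0) / ca
        pos = (ca - 1.6 * a / gs - mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)

    ci_mf = 0.5 * (lo + hi)
    ci_pa = ci_mf * to_pa
    if not full:
        return demand_a_net(ci_pa, params, env, config)
    out = demand_a_net(ci_pa, params, env, config, full=True)
    out["gs"] = medlyn_gs(out["a_net"], ca, env.vpd, stomatal)
    out["ci_pa"] = ci_pa
    out["ci_umol_mol"] = ci_mf
    out["residual"] = ca - 1.6 * out["a_net"] / out["gs"] - ci_mf
    out["converged"] = np.abs(out["residual"]) < 1e-6 * ca
    return out


def solve_coupled(env: Environment, params: PhotoParams, config: ModelConfig,
                  stomatal: StomatalParams | None = None) -> PhotoResult:
    """Scalar coupled solve returning a full :class:`PhotoResult`."""
    stomatal = stomatal or StomatalParams()
    out = solve_coupled_batch(env, params, config, stomatal, full=True)
    ap = out["ap_g"]
    return PhotoResult(
        a_net=float(out["a_net"]), a_gross=float(out["a_gross"]),
        ac_g=float(out["ac_g"]), aj_g=float(out["aj_g"]),
        ap_g=None if ap is None else float(np.asarray(ap)),
        acj_g=float(out["acj_g"]), j=float(np.asarray(out["j"])),
        ci=float(np.asarray(out["ci_pa"])), gs=float(np.asarray(out["gs"])),
        gamma_star=float(np.asarray(out["gamma_star"])),
        rd=float(np.asarray(out["rd"])),
        limiting_state=str(np.asarray(out["limiting_state"]).item()),
        converged=bool(np.asarray(out["converged"]).all()),
        residual=float(np.asarray(out["residual"])),
        model_id=config.model_id,
    )


def response_curve(params: PhotoParams, config: ModelConfig,
                   stomatal: StomatalParams | None = None,
                   axis: str = "ca", grid=None,
                   env: Environment | None = None) -> pd.DataFrame:
    """A-Ca or A-I response curve with the potential-rate decomposition.

    Default grids: Ca 50-1,500 µmol/mol in steps of 50 at I = 960; I 10-1,960
    µmol m⁻² s⁻¹ in steps of 50 at Ca = 400.
    """
    stomatal = stomatal or StomatalParams()
    env = env or Environment()
    if axis == "ca":
        grid = DEFAULT_CA_GRID if grid is None else np.asarray(grid, dtype=float)
        env = env.replace(ca=grid, irradiance=960.0)
    elif axis == "irradiance":
        grid = DEFAULT_I_GRID if grid is None else np.asarray(grid, dtype=float)
        env = env.replace(ca=400.0, irradiance=grid)
    else:
        raise ValueError("axis must be 'ca' or 'irradiance'")
    if len(grid) == 0:
        raise ValueError("empty grid")
    out = solve_coupled_batch(env, params, config, stomatal, full=True)
    ap = out["ap_g"]
    return pd.DataFrame({
        "model_id": config.model_id,
        "ca_umol_mol": np.broadcast_to(env.ca, grid.shape),
        "i_umol_m2_s": np.broadcast_to(env.irradiance, grid.shape),
        "ci_pa": out["ci_pa"],
        "a_net": out["a_net"],
        "ac_g": out["ac_g"],
        "aj_g": out["aj_g"],
        "ap_g": np.full(grid.shape, np.nan) if ap is None else ap,
        "j": np.broadcast_to(out["j"], grid.shape),
        "gs": out["gs"],
        "limiting_state": out["limiting_state"],
    })
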