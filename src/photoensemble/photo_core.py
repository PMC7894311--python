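"""Biochemical (demand-side) C3 photosynthesis at prescribed Ci.

Net assimilation is

    A = A_g (1 - Γ*/Ci) - R_d

with the gross rate A_g taken from up to three potentially limiting rates:
RuBisCO-limited carboxylation A_c,g, electron-transport-limited RuBP
regeneration A_j,g, and triose-phosphate-use-limited A_p,g.  The rates are
combined either by the strict minimum or by two-stage quadratic
(non-rectangular hyperbola) smoothing with curvatures θ_cj and θ_cjp.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import ModelConfig
from .params import Environment, PhotoParams

__all__ = [
    "gamma_star",
    "derive_dependent",
    "ac_gross",
    "electron_transport",
    "aj_gross",
    "ap_gross",
    "smaller_root",
    "select_rate",
    "net_assimilation",
    "demand_a_net",
    "assimilation_at_ci",
    "PhotoResult",
]

# A_p,g values at or above this sentinel mark "TPU not applicable": the rate
# is excluded from selection instead of raising, so low-Ci points still
# evaluate.
TPU_NOT_LIMITING = np.inf


def gamma_star(params: PhotoParams, env: Environment):
    """Photorespiratory CO2 compensation point Γ* (Pa).

    Γ* = (k_o:k_c) · K_c · O_i / (2 K_o), with K_c in Pa and O_i, K_o in kPa
    (the kPa units cancel).
    """
    ko = np.asarray(params.ko_half, dtype=float)
    if np.any(ko <= 0):
        raise ValueError("ko_half must be > 0")
    return params.ko_kc_ratio * params.kc_half * np.asarray(env.oi) / (2.0 * ko)


def derive_dependent(params: PhotoParams):
    """(J_max,25, TPU25, R_d) derived from V_cmax,25 by linear scaling."""
    return params.jmax25, params.tpu25, params.rd


def ac_gross(ci, params: PhotoParams, env: Environment):
    """RuBisCO-limited gross rate, V_cmax·Ci / (Ci + K_c(1 + O_i/K_o))."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci < 0):
        raise ValueError("ci must be >= 0")
    km_eff = params.kc_half * (1.0 + np.asarray(env.oi) / params.ko_half)
    return params.vcmax25 * ci / (ci + km_eff)


def electron_transport(irradiance, params: PhotoParams, hypothesis: str):
    """Electron transport rate J (µmol e m⁻² s⁻¹) under one of three hypotheses.

    linear_cbgb:       J = a·α_i·I  (no maximum)
    hyperbola_harley:  J = a·α_i·I / sqrt(1 + (a·α_i·I/J_max)²)
    nonrect_fw:        smaller root of θ_j J² - (a·α_i·I + J_max) J
                       + a·α_i·I·J_max = 0
    """
    i_abs = params.absorptance_a * params.alpha_i * np.asarray(irradiance, dtype=float)
    if np.any(np.asarray(irradiance) < 0):
        raise ValueError("irradiance must be >= 0")
    if hypothesis == "linear_cbgb":
        return i_abs
    jmax = np.asarray(params.jmax25, dtype=float)
    if np.any(jmax <= 0):
        raise ValueError("J_max must be > 0 for saturating electron transport")
    if hypothesis == "hyperbola_harley":
        return i_abs / np.sqrt(1.0 + (i_abs / jmax) ** 2)
    if hypothesis == "nonrect_fw":
        return smaller_root(params.theta_j, i_abs, jmax)
    raise ValueError(f"unknown electron transport hypothesis: {hypothesis!r}")


def aj_gross(ci, j, gstar):
    """RuBP-regeneration-limited gross rate, (J/4)·Ci/(Ci + 2Γ*)."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci < 0):
        raise ValueError("ci must be >= 0")
    return 0.25 * np.asarray(j) * ci / (ci + 2.0 * np.asarray(gstar))


def ap_gross(ci, tpu, alpha_tpu, gstar):
    """TPU-limited gross rate, 3·TPU·Ci / (Ci - (1 + 3α_tpu)Γ*).

    The expression is singular at Ci = (1+3α_tpu)Γ*; at or below that point
    TPU cannot limit and the returned rate is +inf (``TPU_NOT_LIMITING``).
    With α_tpu = 0, multiplying the result by the photorespiration factor
    (1 - Γ*/Ci) gives exactly 3·TPU.
    """
    ci = np.asarray(ci, dtype=float)
    denom = ci - (1.0 + 3.0 * np.asarray(alpha_tpu)) * np.asarray(gstar)
    with np.errstate(divide="ignore", invalid="ignore"):
        ap = np.where(denom > 0, 3.0 * np.asarray(tpu) * ci / np.where(denom > 0, denom, 1.0), TPU_NOT_LIMITING)
    return ap


def smaller_root(theta, x1, x2):
    """Smaller root of θz² - (x1+x2)z + x1·x2 = 0.

    Evaluated in the cancellation-free conjugate form
    2·x1·x2 / (x1 + x2 + sqrt((x1+x2)² - 4θ·x1·x2)) so that θ → 0 smoothly
    yields the rectangular hyperbola x1·x2/(x1+x2).  The result never exceeds
    min(x1, x2), with equality iff θ = 1 or x1·x2 = 0.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta must lie in [0, 1]")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    s = x1 + x2
    disc = s * s - 4.0 * theta * x1 * x2
    # disc >= (x1-x2)^2 >= 0 analytically; clip rounding noise
    disc = np.maximum(disc, 0.0)
    denom = s + np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, 2.0 * x1 * x2 / np.where(denom > 0, denom, 1.0), 0.0)
    return out


_STATE_LABELS = np.array(["Ac", "Aj", "Ap"])


def select_rate(ac_g, aj_g, ap_g, config: ModelConfig, params: PhotoParams):
    """Combine the potential rates into A_g.

    Returns ``(a_gross, acj_g, limiting_state)`` where ``acj_g`` is the latent
    first-stage smoothing rate (equal to min(A_c,g, A_j,g) under the minimum
    rule) and ``limiting_state`` labels the smallest potential rate.

    ``ap_g`` is ``None`` when TPU is excluded; +inf entries mark points where
    TPU is not applicable and are excluded from both selection rules.
    """
    ac_g = np.asarray(ac_g, dtype=float)
    aj_g = np.asarray(aj_g, dtype=float)
    have_ap = ap_g is not None
    if have_ap:
        ap_g = np.asarray(ap_g, dtype=float)
        ap_ok = np.isfinite(ap_g)
    if config.selection == "minimum":
        acj = np.minimum(ac_g, aj_g)
        ag = np.minimum(acj, np.where(ap_ok, ap_g, np.inf)) if have_ap else acj
    else:
        acj = smaller_root(params.theta_cj, ac_g, aj_g)
        if have_ap:
            ag = np.where(
                ap_ok,
                smaller_root(params.theta_cjp, acj, np.where(ap_ok, ap_g, 1.0)),
                acj,
            )
        else:
            ag = acj
    state_idx = np.where(ac_g <= aj_g, 0, 1)
    if have_ap:
        amin = np.minimum(ac_g, aj_g)
        state_idx = np.where(ap_ok & (ap_g < amin), 2, state_idx)
    return ag, acj, _STATE_LABELS[state_idx]


def net_assimilation(a_gross, ci, gstar, rd):
    """Net assimilation A = A_g(1 - Γ*/Ci) - R_d."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise ValueError("ci must be > 0")
    return np.asarray(a_gross) * (1.0 - np.asarray(gstar) / ci) - np.asarray(rd)


def demand_a_net(ci, params: PhotoParams, env: Environment, config: ModelConfig,
                 full: bool = False):
    """Vectorized demand-side evaluation chain at prescribed Ci (Pa).

    Returns A (net) by default, or a dict with all intermediates when
    ``full=True``.  This is the hot path shared by the coupled solver, the
    sensitivity samplers and the curve fitters.
    """
    gstar = gamma_star(params, env)
    ac = ac_gross(ci, params, env)
    j = electron_transport(env.irradiance, params, config.etrans_hypothesis)
    aj = aj_gross(ci, j, gstar)
    ap = ap_gross(ci, params.tpu25, params.alpha_tpu, gstar) if config.tpu_included else None
    ag, acj, state = select_rate(ac, aj, ap, config, params)
    a = net_assimilation(ag, ci, gstar, params.rd)
    if not full:
        return a
    return {
        "a_net": a, "a_gross": ag, "ac_g": ac, "aj_g": aj, "ap_g": ap,
        "acj_g": acj, "j": j, "gamma_star": gstar, "rd": params.rd,
        "limiting_state": state,
    }


@dataclass
class PhotoResult:
    """Realized assimilation with its potential-rate decomposition."""

    a_net: float
    a_gross: float
    ac_g: float
    aj_g: float
    ap_g: Optional[float]   # None when TPU excluded; inf when not applicable
    acj_g: float
    j: float
    ci: float               # Pa
    gs: Optional[float]     # mol m-2 s-1; None for prescribed-Ci evaluation
    gamma_star: float
    rd: float
    limiting_state: str
    converged: bool = True
    residual: float = 0.0
    model_id: str = ""


def assimilation_at_ci(ci, env: Environment, params: PhotoParams,
                       config: ModelConfig) -> PhotoResult:
    """Full scalar evaluation at a prescribed intercellular CO2 (Pa)."""
    out = demand_a_net(ci, params, env, config, full=True)
    ap = out["ap_g"]
    return PhotoResult(
        a_net=float(out["a_net"]), a_gross=float(out["a_gross"]),
        ac_g=float(out["ac_g"]), aj_g=float(out["aj_g"]),
        ap_g=None if ap is None else float(ap),
        acj_g=float(out["acj_g"]), j=float(out["j"]), ci=float(ci),
        gs=None, gamma_star=float(out["gamma_star"]), rd=float(np.asarray(out["rd"])),
        limiting_state=str(np.asarray(out["limiting_state"]).item()),
        model_id=config.model_id,
    )
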