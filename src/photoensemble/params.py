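"""Parameter sets, environments and presets for the C3 photosynthesis ensemble.

All kinetic parameters are 25°C reference values.  Units follow the unified
convention: rates in µmol m⁻² s⁻¹, K_c and Γ* in Pa, K_o and O_i in kPa,
CO2 mole fractions in µmol/mol, pressures in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Any

import numpy as np
import yaml

__all__ = [
    "PhotoParams",
    "Environment",
    "StomatalParams",
    "SA_CENTRAL",
    "FVCB_ORIGINAL",
    "CBGB_ORIGINAL",
    "read_params",
    "write_params",
]


@dataclass
class PhotoParams:
    """The 14 varied parameters plus optional fixed overrides.

    Fields may hold scalars or numpy arrays of a common shape; all model
    arithmetic broadcasts.  J_max,25, TPU25 and R_d are derived from V_cmax,25
    (linear scaling) unless explicitly overridden via ``jmax25_fixed`` etc.
    """

    vcmax25: Any = 50.0          # maximum carboxylation rate, µmol CO2 m-2 s-1
    kc_half: Any = 40.45         # Michaelis constant of RuBisCO for CO2, Pa
    ko_half: Any = 27.85         # Michaelis constant of RuBisCO for O2, kPa
    ko_kc_ratio: Any = 0.21      # ratio of oxygenase:carboxylase turnover numbers
    absorptance_a: Any = 0.80    # leaf absorptance of visible light (a)
    f_loss: Any = 0.23           # fraction of absorbed photons lost before the photosystems (f)
    theta_j: Any = 0.90          # curvature of the light response of J
    a_jv: Any = 29.1             # intercept of J_max,25 ~ V_cmax,25, µmol e m-2 s-1
    b_jv: Any = 1.6355           # slope of J_max,25 ~ V_cmax,25, e CO2-1
    b_tv: Any = 0.1665           # TPU25 = b_tv * V_cmax,25
    alpha_tpu: Any = 0.5         # glycolate carbon exported and not returned
    b_rv: Any = 0.015            # R_d = b_rv * V_cmax,25
    theta_cj: Any = 0.90         # co-limitation curvature, stage 1 (A_c vs A_j)
    theta_cjp: Any = 0.90        # co-limitation curvature, stage 2 (vs A_p)
    # Optional fixed overrides used by the original-publication presets; None means
    # "derive from V_cmax".
    jmax25_fixed: Any = None
    tpu25_fixed: Any = None
    rd_fixed: Any = None

    @property
    def alpha_i(self):
        """Intrinsic quantum efficiency of electron transport, 0.5(1 - f)."""
        return 0.5 * (1.0 - np.asarray(self.f_loss))

    @property
    def jmax25(self):
        if self.jmax25_fixed is not None:
            return self.jmax25_fixed
        return self.a_jv + self.b_jv * np.asarray(self.vcmax25)

    @property
    def tpu25(self):
        if self.tpu25_fixed is not None:
            return self.tpu25_fixed
        return self.b_tv * np.asarray(self.vcmax25)

    @property
    def rd(self):
        if self.rd_fixed is not None:
            return self.rd_fixed
        return self.b_rv * np.asarray(self.vcmax25)

    def replace(self, **kwargs) -> "PhotoParams":
        return replace(self, **kwargs)

    def validate(self) -> None:
        """Raise ValueError on out-of-domain scalar parameters."""
        def bad(x, lo, hi, lo_open=False, hi_open=False):
            x = np.asarray(x, dtype=float)
            lo_bad = (x <= lo) if lo_open else (x < lo)
            hi_bad = (x >= hi) if hi_open else (x > hi)
            return bool(np.any(lo_bad | hi_bad))

        if bad(self.vcmax25, 0, np.inf, lo_open=True):
            raise ValueError("vcmax25 must be > 0")
        if bad(self.kc_half, 0, np.inf, lo_open=True):
            raise ValueError("kc_half must be > 0")
        if bad(self.ko_half, 0, np.inf, lo_open=True):
            raise ValueError("ko_half must be > 0")
        if bad(self.ko_kc_ratio, 0, np.inf, lo_open=True):
            raise ValueError("ko_kc_ratio must be > 0")
        for name in ("theta_j", "theta_cj", "theta_cjp"):
            if bad(getattr(self, name), 0.0, 1.0, lo_open=True):
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("absorptance_a", "f_loss", "alpha_tpu"):
            if bad(getattr(self, name), 0.0, 1.0, hi_open=True):
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass
class Environment:
    """Driving conditions for a leaf at 25°C."""

    ca: Any = 400.0          # atmospheric CO2, µmol/mol
    irradiance: Any = 1000.0  # incident PAR, µmol photons m-2 s-1
    oi: Any = 21.0           # internal O2 partial pressure, kPa
    vpd: Any = 1.0           # vapour pressure deficit, kPa
    pressure: Any = 101.325  # air pressure, kPa
    leaf_temp: Any = 25.0    # °C; all parameters are 25°C values, no scaling

    def ca_pa(self):
        """Atmospheric CO2 partial pressure in Pa."""
        return np.asarray(self.ca) * np.asarray(self.pressure) * 1e-3

    def ci_mole_fraction_to_pa(self, ci_umol_mol):
        return np.asarray(ci_umol_mol) * np.asarray(self.pressure) * 1e-3

    def ci_pa_to_mole_fraction(self, ci_pa):
        return np.asarray(ci_pa) / (np.asarray(self.pressure) * 1e-3)

    def replace(self, **kwargs) -> "Environment":
        return replace(self, **kwargs)


@dataclass
class StomatalParams:
    """Unified (Medlyn) stomatal model parameters."""

    g0: float = 0.01   # residual conductance, mol m-2 s-1
    g1: float = 4.3    # slope, kPa^0.5 (global C3 mean)

    def __post_init__(self):
        if self.g0 < 0:
            raise ValueError("g0 must be >= 0")
        if self.g1 <= 0:
            raise ValueError("g1 must be > 0")


# Central, commonly used parameterization used by the sensitivity analysis
# (midpoints of the ±10% ranges).
SA_CENTRAL = PhotoParams()

# Original Farquhar-style parameterization: fixed J_max and R_d, no TPU.
FVCB_ORIGINAL = PhotoParams(
    vcmax25=98.0, kc_half=46.0, ko_half=33.0, ko_kc_ratio=0.21,
    absorptance_a=0.80, f_loss=0.23, theta_j=0.67,
    jmax25_fixed=210.0, rd_fixed=1.1,
    theta_cj=1.0, theta_cjp=1.0,
)

# Original Collatz-style parameterization: linear electron transport, TPU with
# a closed photorespiratory cycle (alpha_tpu = 0), quadratic smoothing.
CBGB_ORIGINAL = PhotoParams(
    vcmax25=200.0, kc_half=30.0, ko_half=30.0, ko_kc_ratio=0.38,
    absorptance_a=0.86, f_loss=0.52,
    b_tv=0.167, alpha_tpu=0.0, b_rv=0.015,
    theta_cj=0.95, theta_cjp=0.98,
)

PRESETS = {
    "sa-central": SA_CENTRAL,
    "fvcb-original": FVCB_ORIGINAL,
    "cbgb-original": CBGB_ORIGINAL,
}

_PARAM_FIELDS = {f.name for f in fields(PhotoParams)}


def read_params(path) -> PhotoParams:
    """Read a parameter set from a YAML/key-value file.

    Unknown keys are rejected so silent typos cannot skew an analysis.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - _PARAM_FIELDS
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    p = PhotoParams(**data)
    p.validate()
    return p


def write_params(params: PhotoParams, path) -> None:
    data = {
        f.name: getattr(params, f.name)
        for f in fields(PhotoParams)
        if getattr(params, f.name) is not None
    }
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in data.items()}, fh, sort_keys=False)
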