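"""Synthetic high-resolution A-Ci curves.

Emulates a gas-exchange protocol designed to resolve the co-limitation
transition: a standard descending Ca leg (400 → 50 µmol/mol), a dense scan
from 305 to 1,000 µmol/mol in 5 µmol/mol steps (140 setpoints spanning the
transition zone), and a short high-Ca extension.  Observed assimilation is
the coupled forward model plus iid Gaussian measurement noise, which is
exactly the statistical structure the curve-fitting likelihood assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ModelConfig
from .params import Environment, PhotoParams, StomatalParams
from .stomata import solve_coupled_batch

__all__ = ["AciCurve", "protocol_ca_sequence", "generate_aci_curve",
           "read_aci_csv", "write_aci_csv"]

# Descending-leg and high-extension setpoints follow common A-Ci practice;
# only the 305->1000 transition scan is prescribed exactly.
DESCENDING_CA = (400.0, 300.0, 200.0, 150.0, 100.0, 75.0, 50.0)
HIGH_EXTENSION_CA = (1100.0, 1250.0, 1500.0, 1800.0)
DEFAULT_NOISE_SD = 0.3  # µmol m-2 s-1, typical instrument noise
PROTOCOL_IRRADIANCE = 2000.0  # saturating chamber light, µmol m-2 s-1

CSV_COLUMNS = ["obs", "phase", "ca_set_umol_mol", "ci_pa", "ci_umol_mol",
               "a_umol_m2_s", "a_true_umol_m2_s", "qin", "tleaf_c",
               "gsw_mol_m2_s"]


def protocol_ca_sequence() -> pd.DataFrame:
    """Ordered Ca setpoints (µmol/mol) with phase labels."""
    scan = np.arange(305.0, 1000.0 + 2.5, 5.0)
    phases = (["descending"] * len(DESCENDING_CA)
              + ["transition_scan"] * len(scan)
              + ["high_extension"] * len(HIGH_EXTENSION_CA))
    ca = np.concatenate([DESCENDING_CA, scan, HIGH_EXTENSION_CA])
    return pd.DataFrame({"ca_set_umol_mol": ca, "phase": phases})


@dataclass
class AciCurve:
    """Ordered gas-exchange records plus generation metadata."""

    data: pd.DataFrame
    true_params: PhotoParams | None = None
    config: ModelConfig | None = None
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int | None = None
    env: Environment = field(default_factory=Environment)

    def __len__(self):
        return len(self.data)

    def subset(self, mask) -> "AciCurve":
        return AciCurve(data=self.data[mask].reset_index(drop=True),
                        true_params=self.true_params, config=self.config,
                        noise_sd=self.noise_sd, seed=self.seed, env=self.env)


def generate_aci_curve(true_params: PhotoParams, config: ModelConfig,
                       stomatal: StomatalParams | None = None,
                       noise_sd: float = DEFAULT_NOISE_SD, seed=0,
                       env: Environment | None = None) -> AciCurve:
    """Drive the coupled forward model through the protocol and add noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    stomatal = stomatal or StomatalParams()
    env = env or Environment(irradiance=PROTOCOL_IRRADIANCE)
    seq = protocol_ca_sequence()
    run_env = env.replace(ca=seq["ca_set_umol_mol"].to_numpy())
    out = solve_coupled_batch(run_env, true_params, config, stomatal, full=True)
    rng = np.random.default_rng(seed)
    a_true = np.asarray(out["a_net"], dtype=float)
    a_obs = a_true + rng.normal(0.0, noise_sd, a_true.shape)
    data = pd.DataFrame({
        "obs": np.arange(1, len(seq) + 1),
        "phase": seq["phase"],
        "ca_set_umol_mol": seq["ca_set_umol_mol"],
        "ci_pa": out["ci_pa"],
        "ci_umol_mol": out["ci_umol_mol"],
        "a_umol_m2_s": a_obs,
        "a_true_umol_m2_s": a_true,
        "qin": np.broadcast_to(env.irradiance, a_true.shape),
        "tleaf_c": np.broadcast_to(env.leaf_temp, a_true.shape),
        "gsw_mol_m2_s": out["gs"],
        "solver_converged": np.broadcast_to(out["converged"], a_true.shape),
    })
    return AciCurve(data=data, true_params=true_params, config=config,
                    noise_sd=noise_sd, seed=seed, env=env)


def write_aci_csv(curve: AciCurve, path) -> None:
    curve.data[CSV_COLUMNS].to_csv(path, index=False)


def read_aci_csv(path, env: Environment | None = None) -> AciCurve:
    """Read an instrument-style curve CSV; extra columns are tolerated."""
    df = pd.read_csv(path)
    missing = {"ca_set_umol_mol", "ci_pa", "a_umol_m2_s"} - set(df.columns)
    if missing:
        raise ValueError(f"curve file lacks required columns: {sorted(missing)}")
    if "obs" not in df.columns:
        df.insert(0, "obs", np.arange(1, len(df) + 1))
    return AciCurve(data=df, env=env or Environment(irradiance=PROTOCOL_IRRADIANCE))
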