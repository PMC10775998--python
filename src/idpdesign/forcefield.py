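"""Coarse-grained residue-level energy model for intrinsically disordered proteins.

Each amino acid is a single bead carrying a hydropathy scaling factor
``lambda``, a van der Waals diameter ``sigma`` (A), a point charge ``q``
(elementary charges), and a mass (g/mol).  Beads interact through

* a harmonic bond between consecutive residues, ``k_b (r - b0)^2``;
* an Ashbaugh-Hatch van der Waals term that interpolates, via the pair
  hydropathy ``lambda_ij = (lambda_i + lambda_j)/2``, between a purely
  repulsive (lambda = 0) and a full Lennard-Jones (lambda = 1) potential;
* Debye-Hueckel screened electrostatics with screening length ``kappa``.

Energies are reported in kcal/mol with distances in Angstrom.  The Coulomb
prefactor e^2 N_A / (4 pi eps0) is folded into the single constant
:data:`COULOMB_KCAL` = 332.0637 kcal*A/(mol*e^2), so the screened pair energy
reads ``COULOMB_KCAL * q_i q_j / (D * r) * exp(-r / kappa)`` with relative
dielectric ``D``.  No cutoffs are applied: the functions below are analytic
pair energies, not a molecular-dynamics engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AMINO_ACIDS",
    "COULOMB_KCAL",
    "KB_KCAL",
    "ParamTable",
    "ParamTableError",
    "load_parameter_table",
    "bonded_energy",
    "vdw_pair_energy",
    "elec_pair_energy",
    "total_pair_potential",
    "mean_residue_mass",
    "debye_length",
]

#: Canonical one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Coulomb constant in kcal*A/(mol*e^2).
COULOMB_KCAL = 332.0637

#: Boltzmann constant in kcal/(mol*K).
KB_KCAL = 0.0019872041


class ParamTableError(ValueError):
    """Raised when a residue parameter table fails validation."""


@dataclass(frozen=True)
class ParamTable:
    """Per-residue force-field parameters plus global constants.

    Arrays are indexed alphabetically by one-letter code (see
    :data:`AMINO_ACIDS`); :meth:`index` maps codes to array positions.
    """

    lambda_scale: np.ndarray
    sigma: np.ndarray
    charge: np.ndarray
    mass: np.ndarray
    bond_k: float = 10.0
    bond_b0: float = 3.82
    epsilon: float = 0.2
    dielectric: float = 80.0
    debye_kappa: float = 10.0
    source: str = "hps_urry"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(AMINO_ACIDS)})
        for name in ("lambda_scale", "sigma", "charge", "mass"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (20,):
                raise ParamTableError(f"{name} must have exactly 20 entries, got {arr.shape}")
        if np.any(self.sigma <= 0):
            bad = AMINO_ACIDS[int(np.argmax(self.sigma <= 0))]
            raise ParamTableError(f"non-physical value: sigma <= 0 for residue {bad}")
        if np.any(self.mass <= 0):
            bad = AMINO_ACIDS[int(np.argmax(self.mass <= 0))]
            raise ParamTableError(f"non-physical value: mass <= 0 for residue {bad}")

    def index(self, residue: str) -> int:
        try:
            return self._index[residue]
        except KeyError:
            raise ParamTableError(f"unknown residue code {residue!r}") from None

    def pair_lambda(self, res_i: str, res_j: str) -> float:
        i, j = self.index(res_i), self.index(res_j)
        return 0.5 * (self.lambda_scale[i] + self.lambda_scale[j])

    def pair_sigma(self, res_i: str, res_j: str) -> float:
        i, j = self.index(res_i), self.index(res_j)
        return 0.5 * (self.sigma[i] + self.sigma[j])


def _default_path(name: str) -> Path:
    return Path(str(resources.files("idpdesign.data").joinpath(name)))


def load_parameter_table(
    source: str | Path = "hps_urry",
    globals_path: str | Path | None = None,
    his_charge: float | None = None,
) -> ParamTable:
    """Load and validate a residue parameter table.

    Parameters
    ----------
    source
        ``"hps_urry"`` for the packaged table, or a path to a TSV file with
        header ``residue lambda sigma charge mass``.
    globals_path
        Optional YAML file overriding the packaged global constants.
    his_charge
        Optional histidine charge override (the packaged default is neutral,
        appropriate at pH 7 for this model family).
    """
    if isinstance(source, str) and source == "hps_urry":
        path = _default_path("hps_urry.tsv")
    else:
        path = Path(source)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise ParamTableError(f"malformed parameter file {path}: {exc}") from exc
    required = {"residue", "lambda", "sigma", "charge", "mass"}
    if not required.issubset(df.columns):
        raise ParamTableError(
            f"malformed parameter file {path}: need columns {sorted(required)}"
        )
    df = df.set_index("residue")
    missing = [a for a in AMINO_ACIDS if a not in df.index]
    if missing:
        raise ParamTableError(f"missing residue {','.join(missing)} in {path}")
    extra = [r for r in df.index if r not in AMINO_ACIDS]
    if extra:
        raise ParamTableError(f"unknown residue {','.join(map(str, extra))} in {path}")

    gpath = Path(globals_path) if globals_path else _default_path("globals.yaml")
    with open(gpath) as fh:
        g = yaml.safe_load(fh)

    charge = df.loc[list(AMINO_ACIDS), "charge"].to_numpy(dtype=float)
    if his_charge is not None:
        charge = charge.copy()
        charge[AMINO_ACIDS.index("H")] = his_charge
    return ParamTable(
        lambda_scale=df.loc[list(AMINO_ACIDS), "lambda"].to_numpy(dtype=float),
        sigma=df.loc[list(AMINO_ACIDS), "sigma"].to_numpy(dtype=float),
        charge=charge,
        mass=df.loc[list(AMINO_ACIDS), "mass"].to_numpy(dtype=float),
        bond_k=float(g["bond_k"]),
        bond_b0=float(g["bond_b0"]),
        epsilon=float(g["epsilon"]),
        dielectric=float(g["dielectric"]),
        debye_kappa=float(g["debye_kappa"]),
        source=str(path),
    )


def bonded_energy(r, params: ParamTable):
    """Harmonic bond energy ``k_b (r - b0)^2`` in kcal/mol."""
    r = np.asarray(r, dtype=float)
    return params.bond_k * (r - params.bond_b0) ** 2


def _lj(r, sigma, epsilon):
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def vdw_pair_energy(r, res_i: str, res_j: str, params: ParamTable):
    """Ashbaugh-Hatch van der Waals pair energy in kcal/mol.

    For ``r <= 2^(1/6) sigma_ij`` the potential is the shifted repulsive LJ
    branch ``phi_LJ + (1 - lambda_ij) eps``; beyond the minimum it is the LJ
    tail scaled by ``lambda_ij``.  Continuous at the crossover by construction.
    """
    lam = params.pair_lambda(res_i, res_j)
    sig = params.pair_sigma(res_i, res_j)
    r = np.asarray(r, dtype=float)
    with np.errstate(over="ignore", divide="ignore"):
        lj = _lj(r, sig, params.epsilon)
        out = np.where(
            r <= 2.0 ** (1.0 / 6.0) * sig,
            lj + (1.0 - lam) * params.epsilon,
            lam * lj,
        )
    return out if out.ndim else float(out)


def elec_pair_energy(r, res_i: str, res_j: str, params: ParamTable):
    """Debye-Hueckel screened electrostatic pair energy in kcal/mol."""
    qi = params.charge[params.index(res_i)]
    qj = params.charge[params.index(res_j)]
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        out = COULOMB_KCAL * qi * qj / (params.dielectric * r) * np.exp(-r / params.debye_kappa)
    return out if out.ndim else float(out)


def total_pair_potential(r, res_i: str, res_j: str, params: ParamTable):
    """Sum of van der Waals and screened electrostatic pair energies."""
    return vdw_pair_energy(r, res_i, res_j, params) + elec_pair_energy(r, res_i, res_j, params)


def mean_residue_mass(params: ParamTable) -> float:
    """Mean of the 20 residue masses, g/mol."""
    return float(np.mean(params.mass))


def debye_length(ionic_strength_molar: float, dielectric: float = 80.0,
                 temperature: float = 300.0) -> float:
    """Debye screening length in meters for a 1:1 electrolyte.

    ``kappa^-1 = sqrt(eps0 * eps_r * kB * T / (2 * NA * e^2 * I))`` with the
    ionic strength ``I`` in mol/L (converted to mol/m^3 internally).
    """
    eps0 = 8.8541878128e-12  # F/m
    kb = 1.380649e-23  # J/K
    e = 1.602176634e-19  # C
    na = 6.02214076e23  # 1/mol
    ionic = ionic_strength_molar * 1000.0  # mol/m^3
    return math.sqrt(eps0 * dielectric * kb * temperature / (2.0 * na * e * e * ionic))
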