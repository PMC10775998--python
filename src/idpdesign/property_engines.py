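"""Desk-scale physical-property computations for coarse-grained IDP chains.

The three properties driving sequence design are

* the second virial coefficient ``B2 = 2 pi int r^2 [1 - exp(-beta u(r))] dr``
  obtained from a potential of mean force (PMF) between two chains' centers of
  mass (negative B2 = net attraction, the thermodynamic-stability proxy);
* a phase-separation call plus condensed-phase density ``rho_c`` from a
  pressure-density equation of state (a van der Waals loop in a finite system
  signals coexistence; ``rho_c`` is the highest density where the fitted
  pressure crosses zero, assuming a near-zero coexistence pressure);
* the condensed-phase self-diffusion coefficient ``D`` from the long-time
  slope of the chain center-of-mass mean-squared displacement, ``D = slope/6``.

Everything here runs at desk scale: PMFs come either from the analytic pair
potential (exact for single beads) or from a reduced Monte-Carlo sampler for
short flexible chains, and EOS / trajectory inputs may come from any oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy import stats

from .forcefield import KB_KCAL, ParamTable, total_pair_potential

__all__ = [
    "PMFCurve",
    "EOSCurve",
    "Trajectory",
    "PropertyRecord",
    "ReferenceScales",
    "MCConfig",
    "FitWindow",
    "PhaseResult",
    "DiffusionResult",
    "ScalingFit",
    "default_r_grid",
    "b2_from_pmf",
    "pair_pmf_exact",
    "two_chain_pmf_mc",
    "hard_sphere_pmf",
    "square_well_pmf",
    "eos_phase_analysis",
    "diffusion_from_msd",
    "reference_scales",
    "homopolymer_scaling",
]

KB_SI = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23


def default_r_grid(r_max: float = 100.0, dr: float = 0.2) -> np.ndarray:
    """Center-of-mass distance grid in Angstrom, matching the 0.2 A binning."""
    n = int(round(r_max / dr))
    return dr * np.arange(1, n + 1)


@dataclass
class PMFCurve:
    """Potential of mean force u(r) between two chains' centers of mass."""

    r: np.ndarray  # A, strictly increasing
    u: np.ndarray  # kcal/mol; +inf marks hard-core / unsampled-repulsive bins
    temperature: float = 300.0  # K
    u_se: np.ndarray | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.u.shape:
            raise ValueError("r and u must be 1-d arrays of equal length")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing")

    @property
    def beta(self) -> float:
        return 1.0 / (KB_KCAL * self.temperature)


@dataclass
class EOSCurve:
    """Pressure-density equation of state with per-point standard errors."""

    densities: np.ndarray  # g/ml, strictly increasing after sorting
    pressures: np.ndarray
    pressure_se: np.ndarray | None = None
    temperature: float = 300.0

    def __post_init__(self):
        order = np.argsort(np.asarray(self.densities, dtype=float))
        self.densities = np.asarray(self.densities, dtype=float)[order]
        self.pressures = np.asarray(self.pressures, dtype=float)[order]
        if self.pressure_se is not None:
            self.pressure_se = np.asarray(self.pressure_se, dtype=float)[order]
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("densities must be distinct")


@dataclass
class Trajectory:
    """Chain center-of-mass trajectory: times (ps) and positions (F, C, 3)."""

    times: np.ndarray
    com_positions: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.com_positions = np.asarray(self.com_positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least 2 frames")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("time step must be uniform")
        if self.com_positions.ndim != 3 or self.com_positions.shape[0] != len(self.times):
            raise ValueError("com_positions must be (frames, chains, 3)")


@dataclass
class PropertyRecord:
    """Measured or oracle-provided properties for one sequence."""

    sequence: str
    B2: float  # A^3
    B2_se: float = 0.0
    phase_separates: bool = False
    rho_c: float | None = None  # g/ml
    rho_c_se: float | None = None
    D: float | None = None  # m^2/s
    D_se: float | None = None
    provenance: str = "oracle"

    def __post_init__(self):
        if self.phase_separates and self.D is None:
            raise ValueError("phase-separating record must carry D")
        if not self.phase_separates and self.D is not None:
            raise ValueError("D is only defined for phase-separating records")


@dataclass(frozen=True)
class ReferenceScales:
    """Ideal-chain reference volume and Rouse reference diffusivity.

    ``V0 = (4 pi / 3) b0^3 (N/6)^(3/2)`` (pervaded volume of an ideal chain)
    and ``D0 = tau kB T / (N Mbar)`` for an ideal Rouse chain with damping
    time tau and mean residue mass Mbar.
    """

    V0: float  # A^3
    D0: float  # m^2/s
    tau_ps: float
    Mbar: float  # g/mol
    b0_ref: float  # A
    N: int
    temperature: float


# ---------------------------------------------------------------------------
# B2 quadrature


def b2_from_pmf(pmf: PMFCurve) -> float:
    """Second virial coefficient (A^3) by composite quadrature of the PMF.

    Non-finite u is treated as hard core (integrand exactly 1), with the
    hard wall located at the non-finite grid node.  Segments whose endpoints
    both sit on the unit plateau are integrated with the exact cubic
    antiderivative; a segment leaving a hard-core node uses the finite branch
    value across the whole segment (the wall is a step, not a ramp); smooth
    segments use the trapezoid rule.  Below the first grid point the
    integrand is extended by its first value; beyond the last it is zero
    (u -> 0 tail).
    """
    beta = pmf.beta
    finite = np.isfinite(pmf.u)
    with np.errstate(over="ignore", invalid="ignore"):
        expo = np.exp(-beta * np.where(finite, pmf.u, np.inf))
    integrand = 1.0 - expo
    r = pmf.r

    # core extension [0, r_0]: integrand assumed constant at its first value
    total = integrand[0] * r[0] ** 3 / 3.0
    left, right = integrand[:-1], integrand[1:]
    r0, r1 = r[:-1], r[1:]
    cubic = (r1**3 - r0**3) / 3.0
    plateau = (left == 1.0) & (right == 1.0)
    wall_exit = ~finite[:-1] & finite[1:]  # step out of the hard core
    seg = np.where(
        plateau,
        cubic,
        np.where(
            wall_exit,
            right * cubic,
            0.5 * (left * r0**2 + right * r1**2) * (r1 - r0),
        ),
    )
    total += float(np.sum(seg))
    return 2.0 * np.pi * total


def hard_sphere_pmf(sigma: float, grid: np.ndarray | None = None,
                    temperature: float = 300.0) -> PMFCurve:
    """Synthetic hard-sphere PMF (u = inf for r <= sigma) for validation."""
    r = default_r_grid() if grid is None else np.asarray(grid, dtype=float)
    u = np.where(r <= sigma, np.inf, 0.0)
    return PMFCurve(r=r, u=u, temperature=temperature)


def square_well_pmf(sigma: float, well_width_factor: float, depth: float,
                    grid: np.ndarray | None = None,
                    temperature: float = 300.0) -> PMFCurve:
    """Synthetic square-well PMF: hard core to sigma, depth out to lam*sigma.

    The closed-form virial coefficient is
    ``(2 pi / 3) [sigma^3 - (lam^3 - 1) sigma^3 (exp(beta depth) - 1)]``.
    """
    r = default_r_grid() if grid is None else np.asarray(grid, dtype=float)
    edge = well_width_factor * sigma
    u = np.where(r <= sigma, np.inf, np.where(r < edge, -depth, 0.0))
    return PMFCurve(r=r, u=u, temperature=temperature)


def pair_pmf_exact(res_i: str, res_j: str, params: ParamTable,
                   grid: np.ndarray | None = None,
                   temperature: float = 300.0) -> PMFCurve:
    """Exact PMF for two single beads: the center-of-mass PMF of two
    one-residue chains is the analytic pair potential itself."""
    r = default_r_grid() if grid is None else np.asarray(grid, dtype=float)
    u = np.asarray(total_pair_potential(r, res_i, res_j, params), dtype=float)
    return PMFCurve(r=r, u=u, temperature=temperature,
                    u_se=np.zeros_like(r))


# ---------------------------------------------------------------------------
# Reduced Monte-Carlo PMF for short flexible chains


@dataclass
class MCConfig:
    """Configuration for the reduced two-chain PMF sampler."""

    n_samples: int = 400
    max_chain_length: int = 10
    r_max: float = 100.0
    dr: float = 0.2


def _sample_chain(n: int, params: ParamTable, rng: np.random.Generator,
                  beta: float, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample chain conformations from the bonded-only reference ensemble.

    Bond lengths are Gaussian about b0 with variance kT/(2 k_b) (harmonic
    bond Boltzmann), directions isotropic.  Returns COM-centered positions
    (S, n, 3) and the intramolecular nonbonded energy per sample.
    """
    if n == 1:
        return np.zeros((n_samples, 1, 3)), np.zeros(n_samples)
    sd = np.sqrt(1.0 / (2.0 * beta * params.bond_k))
    lengths = rng.normal(params.bond_b0, sd, size=(n_samples, n - 1))
    # isotropic unit vectors
    v = rng.normal(size=(n_samples, n - 1, 3))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    steps = lengths[..., None] * v
    pos = np.concatenate(
        [np.zeros((n_samples, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    pos -= pos.mean(axis=1, keepdims=True)
    return pos, np.zeros(n_samples)  # intra energy filled by caller


def _pair_energy_matrix(params: ParamTable, seq_a: str, seq_b: str,
                        dists: np.ndarray) -> np.ndarray:
    """Total pair energy summed over residue pairs; dists is (..., Na, Nb)."""
    e = np.zeros(dists.shape[:-2])
    for i, ra in enumerate(seq_a):
        for j, rb in enumerate(seq_b):
            e = e + total_pair_potential(dists[..., i, j], ra, rb, params)
    return e


def _intra_energy(seq: str, pos: np.ndarray, params: ParamTable) -> np.ndarray:
    """Intramolecular nonbonded energy (pairs separated by >= 2 bonds)."""
    n = len(seq)
    e = np.zeros(pos.shape[0])
    for i in range(n):
        for j in range(i + 2, n):
            d = np.linalg.norm(pos[:, i] - pos[:, j], axis=-1)
            e = e + total_pair_potential(d, seq[i], seq[j], params)
    return e


def two_chain_pmf_mc(seq_a: str, seq_b: str, params: ParamTable,
                     mc: MCConfig | None = None, seed: int = 0,
                     temperature: float = 300.0) -> PMFCurve:
    """Estimate the two-chain center-of-mass PMF by reference-ensemble
    reweighting at fixed COM separation.

    Conformations of both chains are drawn from the bonded-only ensemble
    (common random numbers across all r bins); at each separation r the
    constrained free energy is ``u(r) = -kT ln < w exp(-beta U_inter) > /
    < w >`` with ``w = exp(-beta U_intra)``.  Exact (zero variance) for
    single beads, where the PMF is the pair potential itself.
    """
    mc = mc or MCConfig()
    if len(seq_a) > mc.max_chain_length or len(seq_b) > mc.max_chain_length:
        raise ValueError(
            f"chain length exceeds MC maximum {mc.max_chain_length}; "
            "use an external oracle for longer chains"
        )
    beta = 1.0 / (KB_KCAL * temperature)
    rng = np.random.default_rng(seed)
    pos_a, _ = _sample_chain(len(seq_a), params, rng, beta, mc.n_samples)
    pos_b, _ = _sample_chain(len(seq_b), params, rng, beta, mc.n_samples)
    w = np.exp(-beta * (_intra_energy(seq_a, pos_a, params)
                        + _intra_energy(seq_b, pos_b, params)))
    wsum = float(np.sum(w))

    r_grid = default_r_grid(mc.r_max, mc.dr)
    u = np.empty_like(r_grid)
    u_se = np.empty_like(r_grid)
    diff = pos_a[:, :, None, :] - pos_b[:, None, :, :]  # (S, Na, Nb, 3)
    for k, r in enumerate(r_grid):
        shifted = diff.copy()
        shifted[..., 2] -= r
        dists = np.linalg.norm(shifted, axis=-1)
        e_inter = _pair_energy_matrix(params, seq_a, seq_b, dists)
        with np.errstate(over="ignore"):
            boltz = np.exp(-np.clip(beta * e_inter, -700, 700))
        m = float(np.sum(w * boltz)) / wsum
        if m <= 0.0:
            u[k] = np.inf
            u_se[k] = np.inf
            continue
        u[k] = -np.log(m) / beta
        var = float(np.sum((w * (boltz - m)) ** 2)) / wsum**2
        u_se[k] = np.sqrt(var) / (beta * m)
    return PMFCurve(r=r_grid, u=u, temperature=temperature, u_se=u_se)


# ---------------------------------------------------------------------------
# EOS analysis


@dataclass
class PhaseResult:
    phase_separates: bool
    rho_c: float | None = None
    rho_c_se: float | None = None
    unresolved: bool = False  # all-negative pressures: condensed branch not bracketed


def _rho_c_of_spline(dens: np.ndarray, pres: np.ndarray) -> tuple[bool, float | None, bool]:
    spline = CubicSpline(dens, pres)
    grid = np.linspace(dens[0], dens[-1], 2048)
    vals = spline(grid)
    separates = bool(np.min(vals) < 0.0)
    if not separates:
        return False, None, False
    roots = spline.roots(extrapolate=False)
    roots = roots[np.isreal(roots)].real
    roots = roots[(roots >= dens[0]) & (roots <= dens[-1])]
    if roots.size == 0:
        return True, None, True
    return True, float(np.max(roots)), False


def eos_phase_analysis(eos: EOSCurve, n_boot: int = 50,
                       seed: int | None = 0) -> PhaseResult:
    """Cubic-spline EOS analysis: phase separation iff the fitted pressure
    dips below zero; rho_c is the highest zero crossing.  Standard errors by
    Gaussian resampling of the per-point pressures (n_boot replicates)."""
    if len(eos.densities) < 4:
        raise ValueError("need at least 4 density points for a cubic spline")
    separates, rho_c, unresolved = _rho_c_of_spline(eos.densities, eos.pressures)
    if not separates:
        return PhaseResult(False)
    if unresolved:
        warnings.warn("all fitted pressures negative: condensed branch not bracketed")
        return PhaseResult(True, None, None, unresolved=True)
    se = None
    if eos.pressure_se is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            p = rng.normal(eos.pressures, eos.pressure_se)
            sep_b, rc, unres = _rho_c_of_spline(eos.densities, p)
            if sep_b and rc is not None:
                boots.append(rc)
        se = float(np.std(boots)) if boots else None
    return PhaseResult(True, rho_c, se)


# ---------------------------------------------------------------------------
# Self-diffusion from the MSD


@dataclass
class FitWindow:
    """MSD fit window: lags used span [start_frac, end_frac] of the maximum
    lag, which itself is max_lag_frac of the trajectory length.

    The default caps lags at 10% of the trajectory and fits the upper half
    of that range: long enough to sit in the diffusive regime, short enough
    that time-origin averaging still has good statistics (MSD estimates at
    lags comparable to the trajectory length are dominated by noise)."""

    start_frac: float = 0.5
    end_frac: float = 1.0
    max_lag_frac: float = 0.1


@dataclass
class DiffusionResult:
    D: float
    D_se: float
    slope: float
    intercept: float
    msd_exponent: float | None
    anomalous: bool


def _msd_fft(pos: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD for one chain, (F, 3) -> (F,) via FFT."""
    f = pos.shape[0]
    nfft = 1 << (2 * f - 1).bit_length()
    sq = np.sum(pos**2, axis=1)
    acf = np.zeros(f)
    for d in range(3):
        fx = np.fft.rfft(pos[:, d], nfft)
        acf += np.fft.irfft(fx * np.conj(fx), nfft)[:f].real
    sumsq = 2.0 * np.sum(sq)
    s1 = np.empty(f)
    s1[0] = sumsq
    for m in range(1, f):
        sumsq -= sq[m - 1] + sq[f - m]
        s1[m] = sumsq
    counts = f - np.arange(f)
    return s1 / counts - 2.0 * acf / counts


def diffusion_from_msd(traj: Trajectory, fit: FitWindow | None = None) -> DiffusionResult:
    """Self-diffusion coefficient from the long-time MSD slope, D = slope/6.

    The MSD is averaged over chains and time origins; the slope comes from a
    least-squares fit over the configured long-time window.  A power-law
    diagnostic flags sub-linear (plateau) or super-linear (ballistic) MSD.
    Units follow the trajectory (positions^2 / time unit).
    """
    fit = fit or FitWindow()
    f, c, _ = traj.com_positions.shape
    msd = np.zeros(f)
    per_chain_d = []
    dt = traj.times[1] - traj.times[0]
    max_lag = max(int(round(fit.max_lag_frac * (f - 1))), 2)
    lo = max(int(round(fit.start_frac * max_lag)), 1)
    hi = max(int(round(fit.end_frac * max_lag)), lo + 2)
    lags = np.arange(lo, min(hi, f - 1) + 1)
    tau = lags * dt
    for ci in range(c):
        m = _msd_fft(traj.com_positions[:, ci, :])
        msd += m
        sl, _ = np.polyfit(tau, m[lags], 1)
        per_chain_d.append(sl / 6.0)
    msd /= c
    slope, intercept = np.polyfit(tau, msd[lags], 1)
    d = slope / 6.0
    d_se = float(np.std(per_chain_d, ddof=1) / np.sqrt(c)) if c > 1 else 0.0

    exponent = None
    anomalous = False
    vals = msd[lags]
    if np.all(vals > 0):
        exponent = float(np.polyfit(np.log(tau), np.log(vals), 1)[0])
        anomalous = exponent < 0.8 or exponent > 1.3
        if anomalous:
            warnings.warn(
                f"MSD power-law exponent {exponent:.2f} deviates from linear; "
                "diffusive fit may be unreliable"
            )
    return DiffusionResult(d, d_se, slope, intercept, exponent, anomalous)


# ---------------------------------------------------------------------------
# Reference scales and homopolymer scaling law


def reference_scales(N: int, temperature: float = 300.0,
                     params: ParamTable | None = None,
                     b0_ref: float = 3.8, tau_ps: float = 1.0,
                     Mbar: float | None = None) -> ReferenceScales:
    """Ideal-chain pervaded volume V0 and Rouse reference diffusivity D0.

    ``b0_ref`` defaults to 3.8 A (the reference bond length used for the
    pervaded-volume estimate, slightly rounded from the bonded-term b0).
    ``Mbar`` defaults to the mean residue mass of the parameter table.
    """
    if N < 1:
        raise ValueError("N >= 1 required")
    if Mbar is None:
        if params is None:
            from .forcefield import load_parameter_table
            params = load_parameter_table()
        Mbar = float(np.mean(params.mass))
    v0 = (4.0 * np.pi / 3.0) * b0_ref**3 * (N / 6.0) ** 1.5
    chain_mass_kg = N * Mbar * 1e-3 / AVOGADRO
    d0 = tau_ps * 1e-12 * KB_SI * temperature / chain_mass_kg
    return ReferenceScales(V0=v0, D0=d0, tau_ps=tau_ps, Mbar=Mbar,
                           b0_ref=b0_ref, N=N, temperature=temperature)


@dataclass
class ScalingFit:
    slope: float
    intercept: float
    correlation: float
    correlation_unscaled: float
    n_used: int


def homopolymer_scaling(records: list[tuple[int, float, float]],
                        temperature: float = 300.0) -> ScalingFit:
    """Log-log regression of D against the Rouse-motivated regressor
    ``-N^(1/2) B2``: for an unentangled melt the condensed-phase self-diffusion
    should scale as ``D ~ -N^(1/2) B2``.

    Records are (N, B2, D) for phase-separating chains; entries with
    B2 >= 0 are excluded with a warning.  Both D and the regressor are reduced
    by the N = 50 reference scales so the fit is dimensionless.  Also reports
    the correlation against the unscaled regressor ``-B2`` for comparison.
    """
    recs = [(n, b2, d) for (n, b2, d) in records if b2 < 0]
    dropped = len(records) - len(recs)
    if dropped:
        warnings.warn(f"excluded {dropped} records with B2 >= 0")
    if len(recs) < 3:
        raise ValueError("need at least 3 phase-separating records with B2 < 0")
    ref = reference_scales(50, temperature)
    n = np.array([r[0] for r in recs], dtype=float)
    b2 = np.array([r[1] for r in recs])
    d = np.array([r[2] for r in recs])
    x = np.log(np.sqrt(n) * (-b2) / ref.V0)
    x0 = np.log((-b2) / ref.V0)
    y = np.log(d / ref.D0)
    res = stats.linregress(x, y)
    res0 = stats.linregress(x0, y)
    return ScalingFit(slope=float(res.slope), intercept=float(res.intercept),
                      correlation=float(res.rvalue),
                      correlation_unscaled=float(res0.rvalue), n_used=len(recs))
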