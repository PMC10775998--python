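"""30-dimensional sequence featurization for IDP property models.

A sequence is represented by its 20 amino-acid composition fractions plus 10
sequence-level descriptors:

========  ==================================================================
N         chain length (residues)
lam_mean  mean hydropathy scaling factor, from the force-field table
SHD       sequence hydropathy decoration, (1/N) sum_{m>n} (lam_m+lam_n)(m-n)^-1
q_plus    fraction of positively charged residues
q_minus   fraction of negatively charged residues
q_abs     absolute net charge per residue
SCD       sequence charge decoration, (1/N) sum_{m>n} q_m q_n (m-n)^(1/2)
B2_MF     mean-field second virial coefficient (A^3): composition-weighted
          sum of single-bead pair virial integrals of the CG pair potential
S         Shannon entropy of the composition (nats)
M_mean    mean residue mass (g/mol)
========  ==================================================================

SHD and SCD are the literature-standard patterning sums; their kernel
exponents are exposed so alternative conventions can be configured.  B2_MF is
an orientation-free single-bead mean-field stand-in for the chain-level
virial coefficient, cheap enough to evaluate inside a genetic-algorithm inner
loop.  Descriptors are min-max scaled to [0, 1] with fixed physical bounds
(stored in a :class:`ScalerConfig`) so feature vectors remain comparable
across active-learning iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forcefield import AMINO_ACIDS, ParamTable
from .property_engines import PMFCurve, b2_from_pmf, default_r_grid
from .forcefield import total_pair_potential

__all__ = [
    "DESCRIPTOR_NAMES",
    "FEATURE_NAMES",
    "ScalerConfig",
    "validate_sequence",
    "composition_vector",
    "descriptors",
    "pair_virial_matrix",
    "feature_vector",
    "feature_matrix",
    "default_scaler",
    "cosine_similarity",
]

DESCRIPTOR_NAMES = (
    "N", "lam_mean", "SHD", "q_plus", "q_minus",
    "q_abs", "SCD", "B2_MF", "S", "M_mean",
)
FEATURE_NAMES = tuple(f"comp_{a}" for a in AMINO_ACIDS) + DESCRIPTOR_NAMES

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def validate_sequence(seq: str, min_len: int = 2, max_len: int | None = None) -> str:
    """Check alphabet and length; returns the sequence unchanged."""
    if not isinstance(seq, str) or len(seq) < min_len:
        raise ValueError(f"sequence must have length >= {min_len}: {seq!r}")
    if max_len is not None and len(seq) > max_len:
        raise ValueError(f"sequence longer than {max_len}: {len(seq)} residues")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid residue code(s) {sorted(bad)} in sequence {seq[:12]!r}...")
    return seq


_CODE_LUT = np.full(256, -1, dtype=np.intp)
for _a, _i in _AA_INDEX.items():
    _CODE_LUT[ord(_a)] = _i


def _indices(seq: str) -> np.ndarray:
    idx = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if idx.min(initial=0) < 0:
        bad = sorted(set(seq) - set(AMINO_ACIDS))
        raise ValueError(f"invalid residue code(s) {bad}")
    return idx


def composition_vector(seq: str) -> np.ndarray:
    """Fraction of each residue type, alphabetical order, sums to 1."""
    idx = _indices(validate_sequence(seq))
    return np.bincount(idx, minlength=20).astype(float) / len(seq)


_SHD_COEF_CACHE: dict[tuple, np.ndarray] = {}


def _shd_coefficients(n: int, beta: float) -> np.ndarray:
    """Per-position coefficients for the separable SHD sum.

    ``sum_{m>n} (lam_m + lam_n) (m-n)^-beta = sum_m lam_m c_m`` with
    ``c_m = H(m) + H(n-1-m)`` and ``H(k) = sum_{j<=k} j^-beta``; cached per
    (length, beta) since the sum runs inside tight design loops.
    """
    key = (n, beta)
    hit = _SHD_COEF_CACHE.get(key)
    if hit is None:
        h = np.concatenate([[0.0], np.cumsum(np.arange(1, n, dtype=float) ** (-beta))])
        m = np.arange(n)
        hit = h[m] + h[n - 1 - m]
        _SHD_COEF_CACHE[key] = hit
    return hit


_PAIR_VIRIAL_CACHE: dict[int, np.ndarray] = {}


def pair_virial_matrix(params: ParamTable, r_max: float = 100.0,
                       dr: float = 0.2, temperature: float = 300.0) -> np.ndarray:
    """20 x 20 matrix of single-bead pair virial integrals (A^3),
    ``2 pi int r^2 [1 - exp(-beta phi_ab(r))] dr``, cached per parameter table."""
    key = id(params)
    if key in _PAIR_VIRIAL_CACHE:
        return _PAIR_VIRIAL_CACHE[key]
    grid = default_r_grid(r_max, dr)
    m = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j in range(i, 20):
            b = AMINO_ACIDS[j]
            u = np.asarray(total_pair_potential(grid, a, b, params), dtype=float)
            m[i, j] = m[j, i] = b2_from_pmf(
                PMFCurve(r=grid, u=u, temperature=temperature))
    _PAIR_VIRIAL_CACHE[key] = m
    return m


def _descriptors_from_idx(idx: np.ndarray, comp: np.ndarray, params: ParamTable,
                          scd_exponent: float, shd_exponent: float) -> np.ndarray:
    n = len(idx)
    lam = params.lambda_scale[idx]
    q = params.charge[idx]

    shd = float(lam @ _shd_coefficients(n, shd_exponent)) / n

    charged = np.nonzero(q)[0]
    if len(charged) >= 2:
        qc = q[charged]
        sep = (charged[:, None] - charged[None, :]).astype(float)
        m_gt = sep > 0
        scd = float(np.sum((qc[:, None] * qc[None, :])[m_gt]
                           * sep[m_gt] ** scd_exponent)) / n
    else:
        scd = 0.0

    q_plus = float((q > 0).sum()) / n
    q_minus = float((q < 0).sum()) / n
    q_abs = abs(float(q.sum())) / n
    nz = comp[comp > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    b2_mf = float(comp @ pair_virial_matrix(params) @ comp)
    return np.array([
        float(n), float(lam.sum()) / n, shd, q_plus, q_minus,
        q_abs, scd, b2_mf, entropy, float(params.mass[idx].sum()) / n,
    ])


def descriptors(seq: str, params: ParamTable, scd_exponent: float = 0.5,
                shd_exponent: float = 1.0) -> np.ndarray:
    """The 10 sequence-level descriptors, in :data:`DESCRIPTOR_NAMES` order."""
    idx = _indices(validate_sequence(seq))
    comp = np.bincount(idx, minlength=20).astype(float) / len(idx)
    return _descriptors_from_idx(idx, comp, params, scd_exponent, shd_exponent)


@dataclass(frozen=True)
class ScalerConfig:
    """Fixed min-max bounds for unit-scaling the 10 descriptors."""

    lower: np.ndarray
    upper: np.ndarray
    clamp_warn: bool = True

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != (10,) or hi.shape != (10,) or np.any(hi <= lo):
            raise ValueError("scaler bounds must be 10 pairs with upper > lower")

    def scale(self, desc: np.ndarray) -> np.ndarray:
        z = (np.asarray(desc, dtype=float) - self.lower) / (self.upper - self.lower)
        clipped = np.clip(z, 0.0, 1.0)
        if self.clamp_warn and np.any(np.abs(z - clipped) > 1e-9):
            out = [DESCRIPTOR_NAMES[i] for i in
                   np.nonzero(np.abs(z - clipped) > 1e-9)[0]]
            warnings.warn(f"descriptor(s) outside configured bounds, clamped: {out}")
        return clipped

    def to_dict(self) -> dict:
        return {"lower": self.lower.tolist(), "upper": self.upper.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerConfig":
        return cls(lower=np.array(d["lower"]), upper=np.array(d["upper"]))


_DEFAULT_SCALER_CACHE: dict[int, ScalerConfig] = {}


def default_scaler(params: ParamTable, max_len: int = 50) -> ScalerConfig:
    """Bounds computed once from extremal sequences at N <= max_len.

    SHD/SCD/B2_MF bounds come from extremal constructions (all-W, all-E,
    charge diblock, alternating charges); composition-dependent quantities use
    their exact physical ranges.
    """
    key = (id(params), max_len)
    if key in _DEFAULT_SCALER_CACHE:
        return _DEFAULT_SCALER_CACHE[key]
    n = max_len
    extremal = [
        "W" * n,                     # max SHD, max lam_mean
        "E" * n,                     # max positive SCD (all like charges)
        "K" * n,
        "E" * (n // 2) + "K" * (n - n // 2),   # strongly negative SCD (diblock)
        "".join("EK"[i % 2] for i in range(n)),  # alternating charges
        "G" * n,
    ]
    shd_vals, scd_vals = [], []
    for s in extremal:
        d = descriptors(s, params)
        shd_vals.append(d[2])
        scd_vals.append(d[6])
    m = pair_virial_matrix(params)
    cfg = ScalerConfig(
        lower=np.array([
            20.0, float(params.lambda_scale.min()), 0.0, 0.0, 0.0,
            0.0, 1.1 * min(scd_vals), 1.1 * float(m.min()) if m.min() < 0 else 0.9 * float(m.min()),
            0.0, float(params.mass.min()),
        ]),
        upper=np.array([
            float(max_len), float(params.lambda_scale.max()), 1.1 * max(shd_vals),
            1.0, 1.0, 1.0, 1.1 * max(scd_vals), 1.1 * float(m.max()),
            np.log(20.0), float(params.mass.max()),
        ]),
    )
    _DEFAULT_SCALER_CACHE[key] = cfg
    return cfg


def feature_vector(seq: str, params: ParamTable,
                   scaler: ScalerConfig | None = None) -> np.ndarray:
    """Concatenated 30-dim feature vector: composition + unit-scaled descriptors."""
    scaler = scaler or default_scaler(params)
    idx = _indices(validate_sequence(seq))
    comp = np.bincount(idx, minlength=20).astype(float) / len(idx)
    desc = _descriptors_from_idx(idx, comp, params, 0.5, 1.0)
    return np.concatenate([comp, scaler.scale(desc)])


def feature_matrix(seqs: list[str], params: ParamTable,
                   scaler: ScalerConfig | None = None) -> np.ndarray:
    scaler = scaler or default_scaler(params)
    return np.vstack([feature_vector(s, params, scaler) for s in seqs])


_PARTS = {"full": slice(0, 30), "composition": slice(0, 20), "descriptors": slice(20, 30)}


def cosine_similarity(x: np.ndarray, y: np.ndarray, part: str = "full") -> float:
    """Cosine similarity on the selected sub-vector (full / composition /
    descriptors).  Raises on a zero-norm sub-vector."""
    sl = _PARTS[part]
    a = np.asarray(x, dtype=float)[sl]
    b = np.asarray(y, dtype=float)[sl]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError(f"zero-norm {part} sub-vector in cosine similarity")
    return float(np.dot(a, b) / (na * nb))
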