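"""The active-learning outer loop.

Each iteration (i) refits the surrogates on all data gathered so far,
(ii) proposes a batch of child sequences with the stage-appropriate fitness,
(iii) evaluates the children through the property oracle, and (iv) updates
the dataset, Pareto archive and convergence metrics.  The schedule is:

* iteration 0 — minimize B2 only (establishes phase-separating training data
  for the diffusion model);
* iterations 1 .. n_ehvi_rounds — expected-hypervolume-improvement rounds,
  gated by the phase classifier and the similarity penalty;
* one final exploitation round maximizing -B2~ + D~.

If an EHVI round is reached without enough phase-separating data to train
the diffusion model and classifier, the B2-only stage is repeated.

Convergence is tracked in a fixed raw objective plane (-B2/V0, D/D0) with a
fixed reference point, so the archive hypervolume trace is nondecreasing by
construction; the standardized plane (recomputed each iteration from the
current dataset) is used only inside the EHVI acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acquisition import FitnessContext, ParetoArchive, fitness, hypervolume, pareto_front
from .forcefield import ParamTable, load_parameter_table
from .ga_design import GAConfig, propose_children
from .property_engines import PropertyRecord, reference_scales
from .sequence_features import ScalerConfig, default_scaler, feature_vector
from .surrogates import (GPConfig, fit_b2_gpr, fit_d_gpr,
                         fit_phase_classifier, standardize)
from .synthetic_oracle import SyntheticOracle

__all__ = [
    "ALConfig",
    "IterationMetrics",
    "ALState",
    "seed_state",
    "run_iteration",
    "run_active_learning",
    "convergence_metrics",
]


@dataclass(frozen=True)
class ALConfig:
    n_ehvi_rounds: int = 7
    exploitation_round: bool = True
    ga: GAConfig = field(default_factory=GAConfig)
    gp: GPConfig = field(default_factory=GPConfig)
    rf_trees: int = 500
    min_separators: int = 3          # needed before entering EHVI rounds
    regime_split: float = 50.0       # -B2/V0 threshold for the weak regime
    ref_margin: float = 0.1          # EHVI reference-point margin
    raw_reference: tuple = (0.0, 0.0)  # fixed ref point in the (-B2/V0, D/D0) plane

    @property
    def n_iterations(self) -> int:
        return 1 + self.n_ehvi_rounds + (1 if self.exploitation_round else 0)


@dataclass
class IterationMetrics:
    k: int
    stage: int
    hypervolume: float
    fraction_new_pareto: float
    hypervolume_restricted: float
    fraction_new_restricted: float
    n_front: int
    n_new_front: int
    n_separators: int


@dataclass
class ALState:
    """Dataset, archive and bookkeeping for one active-learning run."""

    params: ParamTable
    scaler: ScalerConfig
    master_seed: int
    k: int = 0
    sequences: list = field(default_factory=list)
    records: dict = field(default_factory=dict)        # seq -> PropertyRecord
    features: dict = field(default_factory=dict)       # seq -> 30-dim vector
    iteration_of: dict = field(default_factory=dict)   # seq -> "seed" or k
    history: list = field(default_factory=list)        # feature vectors for alpha
    archive: ParetoArchive | None = None
    metrics: list = field(default_factory=list)
    models: dict = field(default_factory=dict)

    def raw_objectives(self, seq: str) -> tuple[float, float]:
        ref = reference_scales(50, params=self.params)
        rec = self.records[seq]
        return (-rec.B2 / ref.V0, rec.D / ref.D0)

    @property
    def separators(self) -> list:
        return [s for s in self.sequences if self.records[s].phase_separates]


def _evaluate(state: ALState, oracle, seqs: list[str], tag="seed") -> list[str]:
    """Oracle-evaluate sequences (cached; failures excluded with a warning)."""
    added = []
    for s in seqs:
        if s in state.records:
            continue
        try:
            rec = oracle(s)
        except Exception as exc:  # noqa: BLE001 - oracle contract: skip failures
            warnings.warn(f"oracle failed on {s[:12]}...: {exc}")
            continue
        state.records[s] = rec
        state.features[s] = feature_vector(s, state.params, state.scaler)
        state.sequences.append(s)
        state.history.append(state.features[s])
        state.iteration_of[s] = tag
        added.append(s)
    return added


def seed_state(seed_sequences: list[str], oracle, params: ParamTable | None = None,
               scaler: ScalerConfig | None = None, master_seed: int = 0,
               config: ALConfig | None = None) -> ALState:
    """Evaluate the seed set and initialize archive and state (k = 0)."""
    config = config or ALConfig()
    params = params or load_parameter_table()
    scaler = scaler or default_scaler(params)
    state = ALState(params=params, scaler=scaler, master_seed=master_seed)
    state.archive = ParetoArchive(reference_point=config.raw_reference)
    _evaluate(state, oracle, seed_sequences)
    seps = state.separators
    if seps:
        state.archive.add(seps, np.array([state.raw_objectives(s) for s in seps]))
    return state


def _fit_models(state: ALState, config: ALConfig, rng) -> dict:
    X = np.vstack([state.features[s] for s in state.sequences])
    b2 = np.array([state.records[s].B2 for s in state.sequences])
    zb2, scale_b2 = standardize(b2)
    models = {"gp_b2": fit_b2_gpr(X, zb2, config.gp), "scale_b2": scale_b2,
              "gp_d": None, "scale_d": None, "classifier": None}
    seps = state.separators
    dvals = np.array([state.records[s].D for s in seps])
    labels = np.array([int(state.records[s].phase_separates) for s in state.sequences])
    if len(seps) >= config.min_separators and len(np.unique(dvals)) >= 2:
        Xd = np.vstack([state.features[s] for s in seps])
        zd, scale_d = standardize(dvals)
        models["gp_d"] = fit_d_gpr(Xd, zd, config.gp,
                                   min_rows=config.min_separators)
        models["scale_d"] = scale_d
    if 0 < labels.sum() < len(labels):
        models["classifier"] = fit_phase_classifier(
            X, labels, n_trees=config.rf_trees,
            seed=int(rng.integers(0, 2**31 - 1)))
    return models


def _standardized_front(state: ALState, models: dict, config: ALConfig):
    """Front and reference point in the per-iteration standardized plane."""
    seps = state.separators
    o1 = -models["scale_b2"].transform([state.records[s].B2 for s in seps])
    o2 = models["scale_d"].transform([state.records[s].D for s in seps])
    pts = np.column_stack([o1, o2])
    front = pts[pareto_front(pts)]
    span = np.maximum(pts.max(axis=0) - pts.min(axis=0), 1e-9)
    ref = pts.min(axis=0) - config.ref_margin * span
    return front, tuple(ref)


def _select_parents(state: ALState, stage: int) -> list[str]:
    if stage > 0 and state.archive.ids:
        return list(state.archive.ids)
    negative = [s for s in state.sequences if state.records[s].B2 < 0]
    if negative:
        return negative
    b2 = np.array([state.records[s].B2 for s in state.sequences])
    order = np.argsort(b2)
    return [state.sequences[i] for i in order[: max(10, len(order) // 10)]]


def run_iteration(state: ALState, oracle, config: ALConfig | None = None) -> ALState:
    """Execute one active-learning iteration in place and return the state."""
    config = config or ALConfig()
    k = state.k
    rng = np.random.default_rng([state.master_seed, k])
    models = _fit_models(state, config, rng)
    k_final = config.n_iterations - 1 if config.exploitation_round else np.inf

    stage = k
    if 0 < k < config.n_iterations and models["gp_d"] is None:
        stage = 0  # not enough phase separators yet: repeat the B2-only stage
    if stage != 0 and (models["classifier"] is None) and k < k_final:
        stage = 0

    ctx = FitnessContext(k=stage, k_final=k_final, gp_b2=models["gp_b2"],
                         gp_d=models["gp_d"], classifier=models["classifier"],
                         history=list(state.history))
    if 0 < stage < k_final:
        ctx.front, ctx.reference_point = _standardized_front(state, models, config)

    cache: dict[str, np.ndarray] = {}

    def fitness_fn(seqs: list[str]) -> np.ndarray:
        rows = []
        for s in seqs:
            v = state.features.get(s)
            if v is None:
                v = cache.get(s)
                if v is None:
                    v = feature_vector(s, state.params, state.scaler)
                    cache[s] = v
            rows.append(v)
        return fitness(np.vstack(rows), ctx)

    parents = _select_parents(state, stage)
    children = propose_children(
        parents, fitness_fn, config.ga, rng,
        known=set(state.sequences),
        on_accept=lambda s: ctx.history.append(
            cache.get(s) if s in cache else feature_vector(s, state.params, state.scaler)),
    )
    added = _evaluate(state, oracle, children, tag=k)

    new_seps = [s for s in added if state.records[s].phase_separates]
    new_front_ids = []
    if new_seps:
        new_front_ids = state.archive.add(
            new_seps, np.array([state.raw_objectives(s) for s in new_seps]))
    state.models = models
    state.k = k + 1
    state.metrics.append(_metrics(state, config, k, stage, new_front_ids))
    return state


def _metrics(state: ALState, config: ALConfig, k: int, stage: int,
             new_front_ids: list) -> IterationMetrics:
    arch = state.archive
    hv = arch.hypervolume()
    n_front = len(arch.ids)
    frac = len(new_front_ids) / n_front if n_front else 0.0
    mask = arch.points[:, 0] <= config.regime_split if n_front else np.array([], bool)
    hv_r = hypervolume(arch.points[mask], arch.reference_point) if mask.any() else 0.0
    restricted_ids = [i for i, m in zip(arch.ids, mask) if m]
    new_r = [i for i in new_front_ids if i in restricted_ids]
    frac_r = len(new_r) / len(restricted_ids) if restricted_ids else 0.0
    return IterationMetrics(
        k=k, stage=stage, hypervolume=hv, fraction_new_pareto=frac,
        hypervolume_restricted=hv_r, fraction_new_restricted=frac_r,
        n_front=n_front, n_new_front=len(new_front_ids),
        n_separators=len(state.separators),
    )


def convergence_metrics(state: ALState) -> list[IterationMetrics]:
    """Full per-iteration convergence history (hypervolume, fraction-new)."""
    return list(state.metrics)


def desk_scale_config() -> ALConfig:
    """The reduced problem size used for desk-scale closed-loop studies:
    32 children per iteration, 8 greedy trials of 130 steps per child
    (optimized eight children per surrogate batch), a 50-tree classifier and
    the two-point composition-weight GP grid.  The full schedule (one
    B2-only round, seven EHVI rounds, one exploitation round) is retained;
    relative to the full-scale procedure only the per-iteration batch and
    search effort are reduced.
    """
    return ALConfig(
        ga=GAConfig(n_steps=130, n_trials=8, n_children=32, wave_size=8),
        gp=GPConfig(composition_weights=(1.0, 0.3)),
        rf_trees=50,
    )


def run_active_learning(seed_sequences: list[str], oracle=None,
                        params: ParamTable | None = None,
                        config: ALConfig | None = None,
                        master_seed: int = 0) -> ALState:
    """Run the full schedule: seed evaluation, the B2-only round, the EHVI
    rounds and the final exploitation round."""
    config = config or ALConfig()
    params = params or load_parameter_table()
    if oracle is None:
        oracle = SyntheticOracle(params, seed=master_seed + 7)
    state = seed_state(seed_sequences, oracle, params,
                       master_seed=master_seed, config=config)
    for _ in range(config.n_iterations):
        run_iteration(state, oracle, config)
    return state
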