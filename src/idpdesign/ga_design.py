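"""Genetic-algorithm sequence proposal.

Child sequences are generated from a parent pool by four moves applied
independently, in order, with fixed probabilities: crossover (0.5), point
mutation (0.8), segment deletion (0.2), and segment growth (0.5, duplicating
a contiguous piece of the sequence in place).  Each proposal trial runs a
fixed number of greedy keep-if-better steps; a batch of independent trials is
run per child and only the best-fitness sequence is kept.  Moves that cannot
respect the [min_len, max_len] length bounds fall back to the identity.

Fitness functions are batched: they accept a list of sequences and return an
array, which lets surrogate models evaluate all concurrent trials at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forcefield import AMINO_ACIDS

__all__ = [
    "GAConfig",
    "crossover",
    "mutate",
    "delete_segment",
    "grow_segment",
    "optimize_one",
    "propose_children",
]


@dataclass(frozen=True)
class GAConfig:
    p_crossover: float = 0.5
    p_mutation: float = 0.8
    p_deletion: float = 0.2
    p_growth: float = 0.5
    n_steps: int = 100
    n_trials: int = 96
    n_children: int = 96
    min_len: int = 20
    max_len: int = 50
    max_unique_retries: int = 20
    #: number of children optimized concurrently per fitness batch.  1 keeps
    #: the strictly sequential procedure (each child sees all earlier
    #: children in the similarity-penalty history); larger waves trade that
    #: within-iteration coupling for fewer, larger surrogate batches.
    wave_size: int = 1

    def __post_init__(self):
        for p in (self.p_crossover, self.p_mutation, self.p_deletion, self.p_growth):
            if not 0.0 <= p <= 1.0:
                raise ValueError("move probabilities must be in [0, 1]")
        if not 2 <= self.min_len <= self.max_len:
            raise ValueError("need 2 <= min_len <= max_len")


def crossover(parent_a: str, parent_b: str, rng: np.random.Generator,
              min_len: int = 20, max_len: int = 50, retries: int = 10) -> str:
    """Single random cut-and-swap at the same relative position in both
    parents (identical parents therefore reproduce themselves); resampled if
    the child violates the length bounds."""
    la, lb = len(parent_a), len(parent_b)
    for _ in range(retries):
        ca = int(rng.integers(1, la))
        cb = min(max(int(round(ca * lb / la)), 1), lb - 1)
        child = parent_a[:ca] + parent_b[cb:]
        if min_len <= len(child) <= max_len:
            return child
    return parent_a


def mutate(seq: str, rng: np.random.Generator) -> str:
    """Substitute one uniformly chosen site with a different residue."""
    i = int(rng.integers(len(seq)))
    choices = AMINO_ACIDS.replace(seq[i], "")
    return seq[:i] + choices[int(rng.integers(len(choices)))] + seq[i + 1:]


def delete_segment(seq: str, rng: np.random.Generator, min_len: int = 20) -> str:
    """Remove a random contiguous segment; identity if at the lower bound."""
    slack = len(seq) - min_len
    if slack <= 0:
        return seq
    length = int(rng.integers(1, slack + 1))
    start = int(rng.integers(0, len(seq) - length + 1))
    return seq[:start] + seq[start + length:]

def grow_segment(seq: str, rng: np.random.Generator, max_len: int = 50) -> str:
    """Duplicate a random contiguous segment in place; identity at max length."""
    slack = min(max_len - len(seq), len(seq))
    if slack <= 0:
        return seq
    length = int(rng.integers(1, slack + 1))
    start = int(rng.integers(0, len(seq) - length + 1))
    seg = seq[start:start + length]
    return seq[:start + length] + seg + seq[start + length:]


def _propose(seq: str, parents: list[str], cfg: GAConfig,
             rng: np.random.Generator) -> str:
    """Apply the four moves independently, in the fixed order."""
    if rng.random() < cfg.p_crossover:
        partner = parents[int(rng.integers(len(parents)))]
        seq = crossover(seq, partner, rng, cfg.min_len, cfg.max_len)
    if rng.random() < cfg.p_mutation:
        seq = mutate(seq, rng)
    if rng.random() < cfg.p_deletion:
        seq = delete_segment(seq, rng, cfg.min_len)
    if rng.random() < cfg.p_growth:
        seq = grow_segment(seq, rng, cfg.max_len)
    return seq


def optimize_one(parents: list[str], fitness_fn, cfg: GAConfig,
                 rng: np.random.Generator) -> tuple[str, float, list[float]]:
    """Greedy local search from a random parent: n_steps proposals, each
    accepted only if it improves the fitness.  Returns the best sequence,
    its fitness, and the (nondecreasing) best-so-far trace."""
    if not parents:
        raise ValueError("parent pool must be nonempty")
    cur = parents[int(rng.integers(len(parents)))]
    cur_fit = float(np.asarray(fitness_fn([cur]))[0])
    trace = [cur_fit]
    for _ in range(cfg.n_steps):
        cand = _propose(cur, parents, cfg, rng)
        f = float(np.asarray(fitness_fn([cand]))[0])
        if f > cur_fit:
            cur, cur_fit = cand, f
        trace.append(cur_fit)
    return cur, cur_fit, trace


def _optimize_batch(parents: list[str], fitness_fn, cfg: GAConfig,
                    rng: np.random.Generator, n_searches: int,
                    perturb_start: bool = False) -> tuple[list[str], np.ndarray]:
    """Run n_searches independent greedy searches in lockstep (one batched
    fitness call per step); returns final sequences and fitnesses.

    With perturb_start each search begins one move away from its parent
    rather than at the parent itself — used on uniqueness retries so that a
    flat (e.g. fully classifier-gated) fitness landscape still yields
    distinct children.
    """
    trial_rngs = [np.random.default_rng(s) for s in
                  rng.integers(0, 2**31 - 1, size=n_searches)]
    if perturb_start:
        cur = [_propose(parents[int(r.integers(len(parents)))], parents, cfg, r)
               for r in trial_rngs]
    else:
        cur = [parents[int(r.integers(len(parents)))] for r in trial_rngs]
    cur_fit = np.asarray(fitness_fn(cur), dtype=float)
    for _ in range(cfg.n_steps):
        cands = [_propose(cur[t], parents, cfg, trial_rngs[t])
                 for t in range(n_searches)]
        fits = np.asarray(fitness_fn(cands), dtype=float)
        better = fits > cur_fit
        for t in np.nonzero(better)[0]:
            cur[t] = cands[t]
        cur_fit = np.where(better, fits, cur_fit)
    return cur, cur_fit


def propose_children(parents: list[str], fitness_fn, cfg: GAConfig,
                     rng: np.random.Generator,
                     known: set[str] | None = None,
                     on_accept=None) -> list[str]:
    """Generate cfg.n_children unique child sequences.

    Each child is the best of cfg.n_trials independent greedy searches.
    cfg.wave_size children are optimized concurrently per fitness batch.
    Duplicates (within the batch or against `known`) are retried up to
    cfg.max_unique_retries times; a partial batch is returned with a warning
    if uniqueness is unreachable.  `on_accept(seq)` is invoked as children
    are accepted, so callers can grow the similarity-penalty history.
    """
    if not parents:
        raise ValueError("parent pool must be nonempty")
    known = set(known or ())
    children: list[str] = []
    retries = 0
    while len(children) < cfg.n_children and retries < cfg.max_unique_retries:
        n_wave = min(max(cfg.wave_size, 1), cfg.n_children - len(children))
        seqs, fits = _optimize_batch(parents, fitness_fn, cfg, rng,
                                     n_wave * cfg.n_trials,
                                     perturb_start=retries > 0)
        accepted_any = False
        for c in range(n_wave):
            block = slice(c * cfg.n_trials, (c + 1) * cfg.n_trials)
            best = c * cfg.n_trials + int(np.argmax(fits[block]))
            child = seqs[best]
            if child not in known and child not in children:
                children.append(child)
                accepted_any = True
                if on_accept is not None:
                    on_accept(child)
        retries = 0 if accepted_any else retries + 1
    if len(children) < cfg.n_children:
        warnings.warn(
            f"could not reach {cfg.n_children} unique children; "
            f"returning {len(children)}"
        )
    return children
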