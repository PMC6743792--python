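"""Ensemble Boolean network propagation.

Expression values are scaled per gene to [0, 1] and interpreted as the
probability that a gene is "on" in a given cell.  An ensemble of Boolean
trajectories is started from Bernoulli draws of those probabilities and
updated synchronously; the per-node activity is the mean bit over the last
``tail`` steps of all runs.  Defaults follow the reference protocol: 1000
runs, 100 synchronous steps, averaging over the last 10.

A brute-force oracle (:func:`exact_state_distribution`) computes the exact
expectation of the ensemble activity for networks of up to 12 nodes by
enumerating all initial states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rules import RuleSet

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble simulation settings."""

    runs: int = 1000
    steps: int = 100
    tail: int = 10
    mode: str = "synchronous"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.runs < 1 or self.steps < 1 or self.tail < 1:
            raise SimulationError("runs, steps and tail must be positive")
        if self.tail > self.steps:
            raise SimulationError("tail must not exceed steps")
        if self.mode not in ("synchronous", "asynchronous"):
            raise SimulationError(f"unknown update mode {self.mode!r}")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class ActivityMatrix:
    """Node x sample activities in [0, 1] plus provenance metadata."""

    data: pd.DataFrame
    provenance: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise SimulationError("activities must lie in [0, 1]")

    @property
    def nodes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def scale_to_unit(expr: pd.DataFrame) -> ActivityMatrix:
    """Scale each gene's row to [0, 1] by dividing by its own maximum.

    All-zero rows stay zero (with a warning); everything else spans up to 1.
    """
    vals = expr.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise SimulationError("expression matrix contains negative entries")
    rowmax = vals.max(axis=1)
    zero = rowmax == 0
    if zero.any():
        logger.warning("%d all-zero gene rows left at zero during scaling", zero.sum())
    denom = np.where(zero, 1.0, rowmax)
    scaled = vals / denom[:, None]
    return ActivityMatrix(
        data=pd.DataFrame(scaled, index=expr.index, columns=expr.columns),
        provenance="data-scaled",
    )


# ---------------------------------------------------------------------------
# Compiled model
# ---------------------------------------------------------------------------


# memoized rule truth tables keyed by (signs, term_mask)
_TT_CACHE: dict[tuple, tuple[int, ...]] = {}


def _rule_table(rule) -> tuple[int, ...]:
    key = (rule.signs, rule.term_mask)
    table = _TT_CACHE.get(key)
    if table is None:
        table = rule.truth_table()
        _TT_CACHE[key] = table
    return table


class CompiledModel:
    """Array form of a RuleSet for fast vectorized updates.

    Each node's rule is reduced to a truth table of length 8 indexed by the
    bit-pattern of (up to 3) regulator states.  Source nodes are compiled as
    self-copy rules, which realizes the hold-initial-value semantics without
    special-casing the kernel.
    """

    def __init__(self, rs: RuleSet):
        self.ruleset = rs
        self.nodes: list[str] = sorted(rs.graph.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.regs = np.zeros((3, n), dtype=np.intp)
        self.negs = np.zeros((3, n), dtype=np.uint8)
        self.weights = np.zeros((3, n), dtype=np.int32)
        tt = np.zeros((n, 8), dtype=np.uint8)
        for j, node in enumerate(self.nodes):
            rule = rs.rules[node]
            if rule.is_hold:
                # hold == copy own state
                self.regs[0, j] = j
                self.weights[0, j] = 1
                tt[j, :2] = (0, 1)
                continue
            k = len(rule.regulators)
            tt[j, : 1 << k] = _rule_table(rule)
            for r, reg in enumerate(rule.regulators):
                self.regs[r, j] = self.index[reg]
                self.weights[r, j] = 1 << r
        self.tt_flat = tt.reshape(-1)
        self.offsets = (np.arange(n, dtype=np.int32) * 8)[None, :]

    def with_rule(self, rule) -> "CompiledModel":
        """Copy of the model with one node's rule swapped (arrays patched in
        place of a full recompile; the hot path of the local search)."""
        import copy

        clone = copy.copy(self)
        j = self.index[rule.target]
        clone.regs = self.regs.copy()
        clone.weights = self.weights.copy()
        clone.tt_flat = self.tt_flat.copy()
        clone.regs[:, j] = 0
        clone.weights[:, j] = 0
        clone.tt_flat[8 * j: 8 * (j + 1)] = 0
        if rule.is_hold:
            clone.regs[0, j] = j
            clone.weights[0, j] = 1
            clone.tt_flat[8 * j + 1] = 1
        else:
            k = len(rule.regulators)
            clone.tt_flat[8 * j: 8 * j + (1 << k)] = _rule_table(rule)
            for r, reg in enumerate(rule.regulators):
                clone.regs[r, j] = self.index[reg]
                clone.weights[r, j] = 1 << r
        rules = dict(self.ruleset.rules)
        rules[rule.target] = rule
        clone.ruleset = RuleSet(graph=self.ruleset.graph, rules=rules)
        return clone

    def step(self, state: np.ndarray) -> np.ndarray:
        """One synchronous update of a (rows, nodes) uint8 state array."""
        idx = state[:, self.regs[0]] * self.weights[0]
        idx += state[:, self.regs[1]] * self.weights[1]
        idx += state[:, self.regs[2]] * self.weights[2]
        idx += self.offsets
        return self.tt_flat[idx]

    def step_async(self, state: np.ndarray, order: np.ndarray) -> np.ndarray:
        """One full asynchronous sweep in the given node order (in place)."""
        for j in order:
            idx = (
                state[:, self.regs[0, j]] * self.weights[0, j]
                + state[:, self.regs[1, j]] * self.weights[1, j]
                + state[:, self.regs[2, j]] * self.weights[2, j]
            )
            state[:, j] = self.tt_flat[8 * j + idx]
        return state


def _run_trajectories(
    model: CompiledModel,
    init: np.ndarray,
    cfg: SimulationConfig,
    clamp_idx: np.ndarray,
    clamp_val: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Propagate initial bit rows and return the summed tail states (rows, nodes)."""
    state = init
    if clamp_idx.size:
        state[:, clamp_idx] = clamp_val
    acc = np.zeros(state.shape, dtype=np.uint32)
    first_tail = cfg.steps - cfg.tail
    for t in range(cfg.steps):
        if cfg.mode == "synchronous":
            state = model.step(state)
        else:
            order = rng.permutation(len(model.nodes))
            state = model.step_async(state.copy(), order)
        if clamp_idx.size:
            state[:, clamp_idx] = clamp_val
        if t >= first_tail:
            acc += state
    return acc


def _clamp_arrays(model: CompiledModel, clamps: dict[str, int] | None):
    if not clamps:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.uint8)
    for node, v in clamps.items():
        if node not in model.index:
            raise SimulationError(f"unknown clamp node {node!r}")
        if v not in (0, 1):
            raise SimulationError(f"clamp value for {node!r} must be 0 or 1")
    idx = np.array([model.index[n] for n in clamps], dtype=np.intp)
    val = np.array([clamps[n] for n in clamps], dtype=np.uint8)
    return idx, val


def simulate_activities(
    rs: RuleSet | CompiledModel,
    initial_probs: pd.DataFrame,
    cfg: SimulationConfig,
    clamps: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> ActivityMatrix:
    """Ensemble activities for several samples at once.

    ``initial_probs`` is a node x sample frame of Bernoulli probabilities; it
    must cover every network node (apply defaults upstream).  Per run, each
    node's initial bit is drawn independently; clamped nodes are held at
    their clamp value at every step including t=0.
    """
    model = rs if isinstance(rs, CompiledModel) else CompiledModel(rs)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    missing = set(model.nodes) - set(initial_probs.index)
    if missing:
        raise SimulationError(f"initial probabilities missing for {sorted(missing)}")
    probs = initial_probs.reindex(model.nodes).to_numpy(dtype=float).T  # (d, n)
    if np.any(probs < 0) or np.any(probs > 1):
        raise SimulationError("initial probabilities must lie in [0, 1]")
    d, n = probs.shape
    rep = np.repeat(probs, cfg.runs, axis=0)  # (d*runs, n)
    init = (rng.random(rep.shape) < rep).astype(np.uint8)
    clamp_idx, clamp_val = _clamp_arrays(model, clamps)
    acc = _run_trajectories(model, init, cfg, clamp_idx, clamp_val, rng)
    tail_mean = acc.reshape(d, cfg.runs, n).sum(axis=1) / (cfg.runs * cfg.tail)
    return ActivityMatrix(
        data=pd.DataFrame(tail_mean.T, index=model.nodes, columns=initial_probs.columns),
        provenance="simulated",
        meta={"runs": cfg.runs, "steps": cfg.steps, "tail": cfg.tail,
              "mode": cfg.mode, "clamps": dict(clamps or {})},
    )


def simulate_ensemble(
    rs: RuleSet | CompiledModel,
    initial_probs: pd.Series | dict[str, float],
    cfg: SimulationConfig,
    clamps: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Single-sample convenience wrapper around :func:`simulate_activities`."""
    probs = pd.Series(initial_probs, dtype=float)
    out = simulate_activities(rs, probs.to_frame("s0"), cfg, clamps=clamps, rng=rng)
    return out.data["s0"]


def exact_state_distribution(
    rs: RuleSet | CompiledModel,
    initial_probs: pd.Series | dict[str, float],
    cfg: SimulationConfig,
    clamps: dict[str, int] | None = None,
) -> pd.Series:
    """Exact expected ensemble activity by enumerating all 2^m initial states.

    Deterministic; only valid for synchronous mode and m <= 12 nodes.
    """
    model = rs if isinstance(rs, CompiledModel) else CompiledModel(rs)
    if cfg.mode != "synchronous":
        raise SimulationError("exact distribution is defined for synchronous mode only")
    m = len(model.nodes)
    if m > 12:
        raise SimulationError(f"exact enumeration refused for {m} > 12 nodes")
    probs = pd.Series(initial_probs, dtype=float).reindex(model.nodes)
    if probs.isna().any():
        raise SimulationError("initial probabilities missing for some nodes")
    p = probs.to_numpy()
    states = ((np.arange(1 << m)[:, None] >> np.arange(m)) & 1).astype(np.uint8)
    clamp_idx, clamp_val = _clamp_arrays(model, clamps)
    # clamped nodes contribute no probability weight: force their bit
    eff_p = p.copy()
    if clamp_idx.size:
        eff_p[clamp_idx] = clamp_val
    weights = np.prod(np.where(states == 1, eff_p, 1.0 - eff_p), axis=1)
    acc = _run_trajectories(model, states.copy(), cfg, clamp_idx, clamp_val)
    tail_mean = acc / cfg.tail
    return pd.Series(weights @ tail_mean, index=model.nodes)
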