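"""Rule inference: global genetic-algorithm search plus node-wise local search.

The genetic algorithm evolves network-wide rule assignments (one OR-of-ANDs
rule per node) to minimize the global steady-state mismatch between scaled
expression and ensemble-propagated activities.  The best individual then
seeds an exhaustive per-node local search that scores every candidate rule
by its node-local error and keeps all rules within a tolerance of the
minimum — the equivalent rule set (ERS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .networks import SignedDiGraph
from .propagation import (
    ActivityMatrix,
    CompiledModel,
    SimulationConfig,
    _run_trajectories,
    scale_to_unit,
    simulate_activities,
)
from .rules import (
    EquivalentRuleSet,
    Rule,
    RuleError,
    RuleSet,
    enumerate_rule_space,
    hold_rule,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings; defaults follow the reference protocol
    (population 24, 120 generations, max in-degree 3)."""

    population: int = 24
    generations: int = 120
    crossover_prob: float = 0.6
    mutation_prob: float = 0.4
    tournament_size: int = 3
    elitism: bool = True
    seed: int | None = None
    ers_tolerance: float = 0.1
    ga_runs: int = 100  # reduced in-loop ensemble size during GA evaluations

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class FitnessTrace:
    """Best and mean global fitness per generation (index 0 = initial population)."""

    best: list[float] = field(default_factory=list)
    mean: list[float] = field(default_factory=list)

    def append(self, best: float, mean: float) -> None:
        self.best.append(best)
        self.mean.append(mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": range(len(self.best)), "best": self.best, "mean": self.mean}
        )


@dataclass
class InferenceResult:
    ers: EquivalentRuleSet
    best: RuleSet
    trace: FitnessTrace
    provenance: dict


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


def _aligned(D: pd.DataFrame | ActivityMatrix, O: pd.DataFrame | ActivityMatrix):
    d = D.data if isinstance(D, ActivityMatrix) else D
    o = O.data if isinstance(O, ActivityMatrix) else O
    if d.shape != o.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {o.shape}")
    return d, o.reindex(index=d.index, columns=d.columns)


def global_fitness(D, O) -> float:
    """Sum over samples of the mean-over-nodes squared error between data and
    simulated activities; zero iff the matrices are equal."""
    d, o = _aligned(D, O)
    n = d.shape[0]
    return float(((d.to_numpy() - o.to_numpy()) ** 2).sum() / n)


def node_error(D, O, node: str) -> float:
    """Sum over samples of the squared error at a single node."""
    d, o = _aligned(D, O)
    if node not in d.index:
        raise ValueError(f"unknown node {node!r}")
    return float(((d.loc[node].to_numpy() - o.loc[node].to_numpy()) ** 2).sum())


# ---------------------------------------------------------------------------
# Regulator sub-sampling for high in-degree nodes
# ---------------------------------------------------------------------------


def sample_upstream(
    node: str,
    in_neighbors: list[str],
    scaled_expr: pd.DataFrame,
    rng: np.random.Generator,
    k: int = 3,
    epsilon: float = 1e-6,
) -> list[str]:
    """Sample ``k`` regulators with probability proportional to the absolute
    Spearman correlation with the target across samples.

    Nodes with <= k in-neighbors are returned unchanged.  Regulators (or the
    target) absent from the data get the epsilon floor weight.
    """
    if len(in_neighbors) <= k:
        return list(in_neighbors)
    weights = np.full(len(in_neighbors), epsilon)
    if node in scaled_expr.index:
        target = scaled_expr.loc[node].to_numpy()
        for i, reg in enumerate(in_neighbors):
            if reg not in scaled_expr.index:
                continue
            vals = scaled_expr.loc[reg].to_numpy()
            if np.ptp(vals) == 0 or np.ptp(target) == 0:
                continue  # undefined correlation keeps the epsilon floor
            r = stats.spearmanr(vals, target).statistic
            if np.isfinite(r):
                weights[i] = max(abs(float(r)), epsilon)
    weights = weights / weights.sum()
    picked = rng.choice(len(in_neighbors), size=k, replace=False, p=weights)
    return [in_neighbors[int(i)] for i in sorted(picked)]


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

# GA genome: dict node -> (regulators tuple, term_mask) over non-source nodes.
Genome = dict[str, tuple[tuple[str, ...], int]]


class _Evaluator:
    """Caches fitness evaluations of genomes against the scaled data."""

    def __init__(self, graph, D: pd.DataFrame, init_probs: pd.DataFrame,
                 cfg: SimulationConfig, rng: np.random.Generator):
        self.graph = graph
        self.D = D
        self.init_probs = init_probs
        self.cfg = cfg
        self.rng = rng
        self.cache: dict[tuple, float] = {}

    def ruleset(self, genome: Genome) -> RuleSet:
        rules = {}
        for n in self.graph.nodes:
            if n in genome:
                regs, mask = genome[n]
                rules[n] = Rule(
                    target=n,
                    regulators=regs,
                    signs=tuple(self.graph.edge_sign(r, n) for r in regs),
                    term_mask=mask,
                )
            else:
                rules[n] = hold_rule(n)
        return RuleSet(graph=self.graph, rules=rules)

    def __call__(self, genome: Genome) -> float:
        key = tuple(sorted(genome.items()))
        if key in self.cache:
            return self.cache[key]
        sub = np.random.default_rng(self.rng.integers(2**63))
        O = simulate_activities(self.ruleset(genome), self.init_probs, self.cfg, rng=sub)
        fit = global_fitness(self.D, O.data.reindex(index=self.D.index))
        self.cache[key] = fit
        return fit


def _random_gene(graph, node, scaled, rng) -> tuple[tuple[str, ...], int]:
    preds = sorted(graph.predecessors(node))
    regs = tuple(sample_upstream(node, preds, scaled, rng))
    mask = int(rng.integers(1, 1 << ((1 << len(regs)) - 1)))
    return regs, mask


def run_genetic_algorithm(
    graph: SignedDiGraph,
    scaled_data: pd.DataFrame,
    cfg: GAConfig,
    sim_cfg: SimulationConfig | None = None,
    init_probs: pd.DataFrame | None = None,
) -> tuple[RuleSet, FitnessTrace]:
    """Evolve rule sets minimizing the global fitness; returns the best
    individual found and the per-generation fitness trace.

    ``scaled_data`` is a node x sample frame in [0, 1].  Offspring are
    produced by uniform-by-node crossover or by mutating one node's
    regulators and term mask; selection is by tournament with elitism.
    """
    if len(graph) == 0:
        raise ValueError("cannot infer rules on an empty graph")
    sim_cfg = (sim_cfg or SimulationConfig()).with_(runs=cfg.ga_runs)
    rng = np.random.default_rng(cfg.seed)
    if init_probs is None:
        init_probs = initial_probabilities(graph, scaled_data)
    non_source = sorted(n for n in graph.nodes if graph.in_degree(n) > 0)
    evaluate = _Evaluator(graph, scaled_data, init_probs, sim_cfg, rng)

    def random_genome() -> Genome:
        return {n: _random_gene(graph, n, scaled_data, rng) for n in non_source}

    def mutate(g: Genome) -> Genome:
        child = dict(g)
        if non_source:
            n = non_source[int(rng.integers(len(non_source)))]
            child[n] = _random_gene(graph, n, scaled_data, rng)
        return child

    def crossover(a: Genome, b: Genome) -> Genome:
        return {n: (a[n] if rng.random() < 0.5 else b[n]) for n in non_source}

    def tournament(pop, fits) -> int:
        picks = rng.integers(len(pop), size=min(cfg.tournament_size, len(pop)))
        return int(min(picks, key=lambda i: fits[i]))

    pop = [random_genome() for _ in range(cfg.population)]
    fits = [evaluate(g) for g in pop]
    best_i = int(np.argmin(fits))
    elite, elite_fit = pop[best_i], fits[best_i]
    trace = FitnessTrace()
    trace.append(elite_fit, float(np.mean(fits)))

    for _ in range(cfg.generations):
        offspring, off_fits = [], []
        for _ in range(cfg.population):
            if rng.random() < cfg.crossover_prob:
                child = crossover(pop[tournament(pop, fits)], pop[tournament(pop, fits)])
            else:
                child = mutate(pop[tournament(pop, fits)])
            offspring.append(child)
            off_fits.append(evaluate(child))
        pop, fits = offspring, off_fits
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < elite_fit:
            elite, elite_fit = pop[gen_best], fits[gen_best]
        if cfg.elitism:
            worst = int(np.argmax(fits))
            pop[worst], fits[worst] = elite, elite_fit
        trace.append(elite_fit, float(np.mean(fits)))

    return evaluate.ruleset(elite), trace


# ---------------------------------------------------------------------------
# Local search
# ---------------------------------------------------------------------------


def _node_order(graph: SignedDiGraph) -> list[str]:
    """Sources-first visit order: topological where possible, ids break ties."""
    try:
        return list(nx.lexicographical_topological_sort(graph))
    except nx.NetworkXUnfeasible:
        return sorted(graph.nodes, key=lambda n: (graph.in_degree(n), n))


def local_search(
    graph: SignedDiGraph,
    scaled_data: pd.DataFrame,
    ga_best: RuleSet,
    tolerance: float = 0.1,
    sim_cfg: SimulationConfig | None = None,
    init_probs: pd.DataFrame | None = None,
    seed: int | None = None,
    error_floor: float | None = None,
) -> EquivalentRuleSet:
    """Exhaustive per-node rule search holding all other rules fixed.

    For each node (sources first), every rule over the GA-chosen regulators
    is substituted into the current rule set and scored by its node-local
    error under a fresh propagation; the minimal-error rule replaces the
    node's rule before moving on.  The ERS keeps every rule with error
    <= min_error * (1 + tolerance) + floor.  Within one node, candidate
    evaluations share the ensemble's initial-state draws so candidate
    ranking is not blurred by Monte-Carlo noise.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    sim_cfg = sim_cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    if init_probs is None:
        init_probs = initial_probabilities(graph, scaled_data)
    d = scaled_data.shape[1]
    floor = 0.001 * d if error_floor is None else error_floor

    model = CompiledModel(ga_best)
    probs = init_probs.reindex(model.nodes).to_numpy(dtype=float).T  # (d, n)
    n_samples, n_nodes = probs.shape
    rep = np.repeat(probs, sim_cfg.runs, axis=0)
    denom = sim_cfg.runs * sim_cfg.tail
    no_clamp = (np.empty(0, dtype=np.intp), np.empty(0, dtype=np.uint8))
    sample_of_row = np.repeat(np.arange(n_samples), sim_cfg.runs)
    descendants = {n: nx.descendants(graph, n) for n in graph.nodes}

    best: dict[str, Rule] = {}
    members: dict[str, list[Rule]] = {}
    errors: dict[str, list[float]] = {}
    data_nodes = set(scaled_data.index)

    for node in _node_order(graph):
        ga_rule = model.ruleset.rules[node]
        if ga_rule.is_hold:
            best[node] = ga_rule
            members[node] = [ga_rule]
            errors[node] = [0.0]
            continue
        signed_regs = [(r, graph.edge_sign(r, node)) for r in ga_rule.regulators]
        candidates = enumerate_rule_space(node, signed_regs)
        if not candidates:
            raise RuleError(f"empty rule space at node {node!r}")
        # shared initial draws for all candidates at this node (common random
        # numbers: candidate ranking is not blurred by Monte-Carlo noise)
        node_rng = np.random.default_rng(rng.integers(2**63))
        init = (node_rng.random(rep.shape) < rep).astype(np.uint8)
        j = model.index[node]
        scorable = node in data_nodes
        if not scorable:
            errs = np.zeros(len(candidates))
        elif not (descendants[node] | {node}) & set(ga_rule.regulators):
            # feed-forward node: its regulators' trajectories do not depend on
            # its own rule, so one simulation scores every candidate exactly —
            # tally regulator bit patterns over the tail window and read each
            # candidate's activity off its truth table
            target = scaled_data.loc[node].to_numpy(dtype=float)
            errs = _feed_forward_errors(
                model, node, candidates, init, sim_cfg, target, sample_of_row)
        else:
            target = scaled_data.loc[node].to_numpy(dtype=float)
            errs = np.empty(len(candidates))
            for c, cand in enumerate(candidates):
                trial = model.with_rule(cand)
                acc = _run_trajectories(trial, init, sim_cfg, *no_clamp)
                act = acc.reshape(n_samples, sim_cfg.runs, n_nodes)[:, :, j].sum(1) / denom
                errs[c] = float(((target - act) ** 2).sum())
        i_min = int(np.argmin(errs))
        cutoff = errs[i_min] * (1.0 + tolerance) + floor
        keep = np.flatnonzero(errs <= cutoff)
        best[node] = candidates[i_min]
        members[node] = [candidates[i] for i in keep]
        errors[node] = [float(errs[i]) for i in keep]
        model = model.with_rule(candidates[i_min])

    return EquivalentRuleSet(
        best=best, members=members, errors=errors, tolerance=tolerance, graph=graph
    )


def _feed_forward_errors(
    model: CompiledModel,
    node: str,
    candidates: list[Rule],
    init: np.ndarray,
    sim_cfg: SimulationConfig,
    target: np.ndarray,
    sample_of_row: np.ndarray,
) -> np.ndarray:
    """Node errors for every candidate rule from one shared trajectory set.

    Only valid when no directed path leads from ``node`` back to any of its
    regulators; then the node's tail activity under rule f equals the
    truth-table average of f over the regulator bit patterns seen one step
    earlier, which a (sample x 8) histogram captures exactly.
    """
    j = model.index[node]
    regs = model.regs[:, j]
    w = model.weights[:, j]
    n_samples = int(sample_of_row[-1]) + 1
    hist = np.zeros(8 * n_samples, dtype=np.int64)
    first_tail = sim_cfg.steps - sim_cfg.tail
    state = init
    for t in range(sim_cfg.steps):
        if t >= first_tail:
            idx = (state[:, regs[0]] * w[0] + state[:, regs[1]] * w[1]
                   + state[:, regs[2]] * w[2])
            hist += np.bincount(sample_of_row * 8 + idx, minlength=8 * n_samples)
        state = model.step(state)
    hist = hist.reshape(n_samples, 8)
    tt = np.zeros((len(candidates), 8), dtype=float)
    for c, cand in enumerate(candidates):
        table = _rule_table_for(cand)
        tt[c, : len(table)] = table
    acts = hist @ tt.T / (sim_cfg.runs * sim_cfg.tail)  # (samples, candidates)
    return ((target[:, None] - acts) ** 2).sum(axis=0)


def _rule_table_for(rule: Rule) -> tuple[int, ...]:
    from .propagation import _rule_table

    return _rule_table(rule)


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------


def initial_probabilities(
    graph: SignedDiGraph, scaled_data: pd.DataFrame, default: float = 0.5
) -> pd.DataFrame:
    """Node x sample Bernoulli probabilities; network genes absent from the
    data default to 0.5 (logged)."""
    probs = scaled_data.reindex(sorted(graph.nodes))
    missing = probs.index[probs.isna().all(axis=1)]
    if len(missing):
        logger.info("%d network genes absent from data initialize at %.2f: %s",
                    len(missing), default, list(missing)[:10])
    return probs.fillna(default)


def match_expression(
    graph: SignedDiGraph, expr: pd.DataFrame
) -> pd.DataFrame:
    """Case-insensitively match network nodes to expression rows.

    Returns the expression sub-frame re-indexed by node id (matched rows
    only); unmatched nodes are reported at INFO level.
    """
    lower = {}
    for gene in expr.index:
        lower.setdefault(str(gene).lower(), gene)
    mapping = {n: lower[n.lower()] for n in graph.nodes if n.lower() in lower}
    unmatched = sorted(set(graph.nodes) - set(mapping))
    if unmatched:
        logger.info("%d network genes not in expression data: %s",
                    len(unmatched), unmatched[:10])
    sub = expr.loc[[mapping[n] for n in mapping]]
    sub.index = list(mapping)
    return sub


def infer_rules(
    graph: SignedDiGraph,
    expr: pd.DataFrame,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimulationConfig | None = None,
    prescaled: bool = False,
) -> InferenceResult:
    """Scale the data, run the genetic algorithm, then the local search.

    ``expr`` is a gene x sample frame of nonnegative values (or activities
    already in [0, 1] if ``prescaled``).  Raises when no network gene is
    present in the data or there are fewer than 2 samples.
    """
    ga_cfg = ga_cfg or GAConfig()
    sim_cfg = sim_cfg or SimulationConfig()
    if expr.shape[1] < 2:
        raise ValueError("at least 2 samples are required")
    matched = match_expression(graph, expr)
    if matched.empty:
        raise ValueError("no overlap between network genes and expression genes")
    scaled = matched if prescaled else scale_to_unit(matched).data
    init_probs = initial_probabilities(graph, scaled)
    rng = np.random.default_rng(ga_cfg.seed)
    ga_seed, ls_seed = (int(s) for s in rng.integers(2**63, size=2))
    best, trace = run_genetic_algorithm(
        graph, scaled, ga_cfg.__class__(**{**ga_cfg.__dict__, "seed": ga_seed}),
        sim_cfg=sim_cfg, init_probs=init_probs,
    )
    ers = local_search(
        graph, scaled, best,
        tolerance=ga_cfg.ers_tolerance, sim_cfg=sim_cfg,
        init_probs=init_probs, seed=ls_seed,
    )
    provenance = {
        "ga": {k: v for k, v in ga_cfg.__dict__.items()},
        "sim": {k: v for k, v in sim_cfg.__dict__.items()},
        "n_matched_genes": int(matched.shape[0]),
        "n_samples": int(expr.shape[1]),
    }
    return InferenceResult(ers=ers, best=ers.best_ruleset(), trace=trace,
                           provenance=provenance)
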