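"""Topology-aware pathway analysis via knockout/knock-in impact scores.

Each gene's impact score is the summed squared difference between ensemble
activities with the gene clamped off versus clamped on.  A pathway's
modulation score combines per-gene impact, absolute log fold difference
between two conditions, and the gene's standard deviation across samples;
its significance comes from re-sampling (fold difference, std) pairs from
the full expression matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .inference import GAConfig, infer_rules, initial_probabilities, match_expression
from .networks import SignedDiGraph
from .propagation import CompiledModel, SimulationConfig, scale_to_unit, simulate_activities
from .rules import RuleSet

logger = logging.getLogger(__name__)

MIN_GENES = 4  # pathways need >= 4 genes matched in the data


@dataclass(frozen=True)
class Contrast:
    """Two disjoint sample groups defining a comparison."""

    group1: tuple[str, ...]
    group2: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("both contrast groups must be nonempty")
        if set(self.group1) & set(self.group2):
            raise ValueError("contrast groups overlap")

    @classmethod
    def from_labels(cls, labels: pd.Series, a: str, b: str) -> "Contrast":
        return cls(
            tuple(labels.index[labels == a]), tuple(labels.index[labels == b])
        )


@dataclass
class PathwayResult:
    pathway: str
    n_genes: int
    modulation_score: float
    p_value: float
    gene_table: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Impact scores
# ---------------------------------------------------------------------------


def impact_score(
    rs: RuleSet | CompiledModel,
    init_probs: pd.DataFrame,
    sim_cfg: SimulationConfig,
    gene: str,
    rng: np.random.Generator | None = None,
    common_random_numbers: bool = True,
) -> float:
    """Summed squared activity difference between knockout and knock-in of ``gene``.

    The gene is clamped to 0 (knockout) and 1 (knock-in) in two ensemble
    simulations per sample; the score sums (O - Z)^2 over all nodes and
    samples.  With ``common_random_numbers`` (default) both simulations share
    the same initial-state draws, reducing Monte-Carlo variance.
    """
    model = rs if isinstance(rs, CompiledModel) else CompiledModel(rs)
    if gene not in model.index:
        raise ValueError(f"unknown gene {gene!r}")
    if rng is None:
        rng = np.random.default_rng(sim_cfg.seed)
    pair_seed = int(rng.integers(2**63))
    activities = []
    for value in (0, 1):
        sub_seed = pair_seed if common_random_numbers else int(rng.integers(2**63))
        out = simulate_activities(
            model, init_probs, sim_cfg, clamps={gene: value},
            rng=np.random.default_rng(sub_seed),
        )
        activities.append(out.data.to_numpy())
    O, Z = activities
    return float(((O - Z) ** 2).sum())


def impact_scores(
    rs: RuleSet | CompiledModel,
    init_probs: pd.DataFrame,
    sim_cfg: SimulationConfig,
    seed: int | None = None,
    common_random_numbers: bool = True,
) -> pd.Series:
    """Impact score for every network gene, in sorted node order."""
    model = rs if isinstance(rs, CompiledModel) else CompiledModel(rs)
    rng = np.random.default_rng(seed if seed is not None else sim_cfg.seed)
    return pd.Series(
        {
            g: impact_score(model, init_probs, sim_cfg, g, rng=rng,
                            common_random_numbers=common_random_numbers)
            for g in model.nodes
        }
    )


# ---------------------------------------------------------------------------
# Modulation score
# ---------------------------------------------------------------------------


def fold_difference(
    expr: pd.DataFrame, gene: str, contrast: Contrast, pseudocount: float = 1.0
) -> float:
    """Ratio of (group mean + pseudocount) on the raw expression scale."""
    if gene not in expr.index:
        raise ValueError(f"gene {gene!r} absent from expression matrix")
    m1 = float(expr.loc[gene, list(contrast.group1)].mean())
    m2 = float(expr.loc[gene, list(contrast.group2)].mean())
    return (m1 + pseudocount) / (m2 + pseudocount)


def fold_differences(expr: pd.DataFrame, contrast: Contrast,
                     pseudocount: float = 1.0) -> pd.Series:
    m1 = expr[list(contrast.group1)].mean(axis=1) + pseudocount
    m2 = expr[list(contrast.group2)].mean(axis=1) + pseudocount
    return m1 / m2


def modulation_score(
    impacts: pd.Series | np.ndarray,
    fold_diffs: pd.Series | np.ndarray,
    stds: pd.Series | np.ndarray,
) -> float:
    """Sum over genes of log2(1 + impact) * |log2 fold difference| * std.

    The +1 shift keeps zero-impact genes at zero contribution and the score
    finite for impacts below 1.
    """
    I = np.asarray(impacts, dtype=float)
    q = np.asarray(fold_diffs, dtype=float)
    s = np.asarray(stds, dtype=float)
    if not (I.shape == q.shape == s.shape):
        raise ValueError("impacts, fold differences and stds must align")
    if np.any(I < 0):
        raise ValueError("impact scores must be nonnegative")
    return float(np.sum(np.log2(1.0 + I) * np.abs(np.log2(q)) * s))


def pathway_pvalue(
    observed: float,
    impacts: pd.Series,
    pool: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """One-sided resampling p-value for a pathway modulation score.

    ``pool`` has one row per expression gene with columns ``fold`` and
    ``std``; each permutation assigns every pathway gene a (fold, std) pair
    drawn uniformly with replacement from the pool and recomputes the score
    with the observed (fixed) impact scores.  Add-one estimator, never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(pool) < 2 * len(impacts):
        logger.warning(
            "resampling pool (%d genes) is small relative to the pathway (%d)",
            len(pool), len(impacts),
        )
    rng = np.random.default_rng(seed)
    logI = np.log2(1.0 + impacts.to_numpy(dtype=float))
    weight = np.abs(np.log2(pool["fold"].to_numpy(dtype=float)))
    weight *= pool["std"].to_numpy(dtype=float)
    n_genes = len(logI)
    hits = 0
    chunk = max(1, 4_000_000 // max(n_genes, 1))  # bound memory for large n_perm
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        draws = rng.integers(len(pool), size=(m, n_genes))
        perm_scores = (logI[None, :] * weight[draws]).sum(axis=1)
        hits += int(np.sum(perm_scores >= observed))
        done += m
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------


def analyze_pathway(
    graph: SignedDiGraph,
    expr: pd.DataFrame,
    contrast: Contrast,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimulationConfig | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    ruleset: RuleSet | None = None,
) -> PathwayResult | None:
    """Full analysis of one pathway network; None when < 4 genes match.

    Rules are inferred on all samples pooled (unless a ``ruleset`` is
    supplied), impact scores use the minimal-error rule set, fold differences
    and stds come from the contrast, and the p-value from the resampled null.
    """
    sim_cfg = sim_cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    name = graph.graph.get("name") or graph.graph.get("pathway_id") or "pathway"
    matched = match_expression(graph, expr)
    if matched.shape[0] < MIN_GENES:
        logger.info("skipping %s: only %d genes in data", name, matched.shape[0])
        return None
    if ruleset is None:
        ga_cfg = ga_cfg or GAConfig()
        ga_cfg = GAConfig(**{**ga_cfg.__dict__, "seed": int(rng.integers(2**63))})
        result = infer_rules(graph, expr, ga_cfg=ga_cfg, sim_cfg=sim_cfg)
        ruleset = result.best
    scaled = scale_to_unit(matched).data
    init_probs = initial_probabilities(graph, scaled)
    impacts = impact_scores(ruleset, init_probs, sim_cfg,
                            seed=int(rng.integers(2**63)))
    genes = list(matched.index)
    q = fold_differences(matched, contrast).reindex(genes)
    stds = scaled.std(axis=1, ddof=0).reindex(genes)
    m_p = modulation_score(impacts.reindex(genes), q, stds)
    # resampling pool: (fold, std) pairs over the whole expression matrix
    scaled_all = scale_to_unit(expr).data
    pool = pd.DataFrame({
        "fold": fold_differences(expr, contrast),
        "std": scaled_all.std(axis=1, ddof=0),
    })
    p = pathway_pvalue(m_p, impacts.reindex(genes), pool, n_perm=n_perm,
                       seed=int(rng.integers(2**63)))
    gene_table = pd.DataFrame({
        "gene": genes,
        "impact": impacts.reindex(genes).to_numpy(),
        "fold_difference": q.to_numpy(),
        "std": stds.to_numpy(),
    })
    return PathwayResult(
        pathway=name, n_genes=len(genes), modulation_score=m_p, p_value=p,
        gene_table=gene_table,
    )


def run_pathway_analysis(
    networks: list[SignedDiGraph],
    expr: pd.DataFrame,
    contrast: Contrast,
    ga_cfg: GAConfig | None = None,
    sim_cfg: SimulationConfig | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    rulesets: list[RuleSet] | None = None,
) -> pd.DataFrame:
    """Analyze several pathway networks; returns a table sorted by p-value.

    Pathways with fewer than 4 matched genes are skipped with a log line; a
    Benjamini-Hochberg column is included for convenience.
    """
    if len(contrast.group1) < 2 or len(contrast.group2) < 2:
        raise ValueError("each contrast group needs >= 2 samples")
    rng = np.random.default_rng(seed)
    rows, tables = [], {}
    for i, g in enumerate(networks):
        res = analyze_pathway(
            g, expr, contrast, ga_cfg=ga_cfg, sim_cfg=sim_cfg, n_perm=n_perm,
            seed=int(rng.integers(2**63)),
            ruleset=None if rulesets is None else rulesets[i],
        )
        if res is None:
            continue
        rows.append({
            "pathway": res.pathway,
            "n_genes": res.n_genes,
            "modulation_score": res.modulation_score,
            "p_value": res.p_value,
        })
        tables[res.pathway] = res.gene_table
    if not rows:
        logger.warning("no pathway passed the >= %d matched-gene filter", MIN_GENES)
        return pd.DataFrame(
            columns=["pathway", "n_genes", "modulation_score", "p_value", "bh_fdr"]
        )
    out = pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    out["bh_fdr"] = _benjamini_hochberg(out["p_value"].to_numpy())
    out.attrs["gene_tables"] = tables
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Annotated export
# ---------------------------------------------------------------------------


def export_annotated_network(
    graph: SignedDiGraph,
    ruleset: RuleSet,
    impacts: pd.Series,
    fold_diffs: pd.Series,
    path,
) -> None:
    """Write a GraphML file with AND-terms expanded as connector nodes.

    A rule ``C = A or (B and D)`` yields a direct edge A->C plus an auxiliary
    AND node fed by B and D.  Gene nodes carry the impact score normalized by
    the pathway maximum, the fold difference, and the rule text.
    """
    out = nx.DiGraph(**graph.graph)
    max_impact = float(impacts.max()) if len(impacts) else 0.0
    for node in graph.nodes:
        out.add_node(
            node,
            kind="gene",
            impact=float(impacts.get(node, 0.0)) / max_impact if max_impact else 0.0,
            fold_difference=float(fold_diffs.get(node, 1.0)),
            rule=ruleset.rules[node].to_text(),
        )
    sign_attr = {1: "a", -1: "i"}
    for node, rule in ruleset.rules.items():
        if rule.is_hold:
            continue
        for t, term in enumerate(rule.terms()):
            if len(term) == 1:
                reg = term[0]
                sign = rule.signs[rule.regulators.index(reg)]
                out.add_edge(reg, node, signal=sign_attr[sign])
            else:
                aux = f"{node}_and_{t}"
                out.add_node(aux, kind="and", impact=0.0, fold_difference=1.0, rule="")
                for reg in term:
                    sign = rule.signs[rule.regulators.index(reg)]
                    out.add_edge(reg, aux, signal=sign_attr[sign])
                out.add_edge(aux, node, signal="a")
    nx.write_graphml(out, path)
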