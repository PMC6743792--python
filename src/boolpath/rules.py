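"""Boolean logic rules encoded as OR-of-ANDs over signed regulators.

A :class:`Rule` for a target node with k regulators (k <= 3) selects a
nonempty subset of the 2^k - 1 possible AND-terms; each AND-term is a
conjunction over a nonempty subset of regulators, with a regulator appearing
plain when its edge is activating and negated when inhibiting (unate /
sign-compatible functions).  Term subsets are indexed by bitmask ``s`` in
``1 .. 2^k - 1`` over regulator positions, and a rule's ``term_mask`` sets
bit ``s - 1`` when term ``s`` is included, so the rule space for k regulators
has ``2 ** (2**k - 1) - 1`` encodings: 1, 7, and 127 for k = 1, 2, 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .networks import SignedDiGraph


class RuleError(ValueError):
    """Raised for invalid rule structures or mismatched rule/network inputs."""


@dataclass(frozen=True)
class Rule:
    """An OR-of-ANDs update rule for one node.

    ``regulators`` is the ordered tuple of input node ids; ``signs`` the
    matching edge signs; ``term_mask`` the inclusion bitvector over the
    nonempty AND-terms.  A source node's hold rule has no regulators and
    ``term_mask == 0``.
    """

    target: str
    regulators: tuple[str, ...]
    signs: tuple[int, ...]
    term_mask: int

    def __post_init__(self) -> None:
        k = len(self.regulators)
        if k != len(self.signs):
            raise RuleError("regulators and signs must have equal length")
        if k > 3:
            raise RuleError("at most 3 regulators per rule")
        if len(set(self.regulators)) != k:
            raise RuleError("regulators must be distinct")
        if any(s not in (1, -1) for s in self.signs):
            raise RuleError("signs must be +1 or -1")
        n_terms = (1 << k) - 1
        if k == 0:
            if self.term_mask != 0:
                raise RuleError("hold rule must have term_mask 0")
        elif not 1 <= self.term_mask <= (1 << n_terms) - 1:
            raise RuleError(
                f"term_mask must be in 1..{(1 << n_terms) - 1} for {k} regulators"
            )

    @property
    def is_hold(self) -> bool:
        return not self.regulators

    def terms(self) -> list[tuple[str, ...]]:
        """Included AND-terms, each as a tuple of regulator ids."""
        k = len(self.regulators)
        out = []
        for s in range(1, 1 << k):
            if self.term_mask >> (s - 1) & 1:
                out.append(tuple(r for i, r in enumerate(self.regulators) if s >> i & 1))
        return out

    def evaluate(self, state: dict[str, int]) -> int:
        """Evaluate the rule on a binary assignment of its regulators."""
        if self.is_hold:
            raise RuleError("hold rule has no logic to evaluate")
        try:
            lits = [
                state[r] if s > 0 else 1 - state[r]
                for r, s in zip(self.regulators, self.signs)
            ]
        except KeyError as exc:
            raise RuleError(f"missing state bit for regulator {exc.args[0]!r}") from exc
        k = len(self.regulators)
        for s in range(1, 1 << k):
            if self.term_mask >> (s - 1) & 1:
                if all(lits[i] for i in range(k) if s >> i & 1):
                    return 1
        return 0

    def truth_table(self) -> tuple[int, ...]:
        """Outputs on all 2^k regulator assignments, LSB-first in regulator order."""
        k = len(self.regulators)
        return tuple(
            self.evaluate({r: x >> i & 1 for i, r in enumerate(self.regulators)})
            for x in range(1 << k)
        )

    def used_regulators(self) -> tuple[str, ...]:
        """Regulators appearing in at least one included AND-term."""
        k = len(self.regulators)
        used = 0
        for s in range(1, 1 << k):
            if self.term_mask >> (s - 1) & 1:
                used |= s
        return tuple(r for i, r in enumerate(self.regulators) if used >> i & 1)

    def to_text(self) -> str:
        """Serialize as e.g. ``C = A or (A and not B)``."""
        if self.is_hold:
            return f"{self.target} = {self.target}"
        parts = []
        for term in self.terms():
            lits = [
                r if self.signs[self.regulators.index(r)] > 0 else f"not {r}"
                for r in term
            ]
            parts.append(lits[0] if len(lits) == 1 else "(" + " and ".join(lits) + ")")
        return f"{self.target} = " + " or ".join(parts)


def hold_rule(target: str) -> Rule:
    """The source-node rule: state is held at its initial value."""
    return Rule(target=target, regulators=(), signs=(), term_mask=0)


def rule_from_text(text: str) -> Rule:
    """Parse the text form produced by :meth:`Rule.to_text`.

    ``"C = A or (A and not B)"`` round-trips; ``"A = A"`` parses as the hold
    rule.  Regulator order follows first appearance; signs are inferred from
    ``not``.
    """
    try:
        target, rhs = (part.strip() for part in text.split("=", 1))
    except ValueError as exc:
        raise RuleError(f"cannot parse rule text {text!r}") from exc
    if rhs == target:
        return hold_rule(target)
    regulators: list[str] = []
    signs: dict[str, int] = {}
    terms: list[tuple[str, ...]] = []
    for chunk in rhs.split(" or "):
        chunk = chunk.strip().strip("()")
        term = []
        for lit in chunk.split(" and "):
            lit = lit.strip()
            sign = 1
            if lit.startswith("not "):
                sign, lit = -1, lit[4:].strip()
            if not lit:
                raise RuleError(f"empty literal in rule text {text!r}")
            if lit not in regulators:
                regulators.append(lit)
            if signs.setdefault(lit, sign) != sign:
                raise RuleError(f"conflicting signs for {lit!r} in {text!r}")
            term.append(lit)
        terms.append(tuple(term))
    if len(regulators) > 3:
        raise RuleError(f"more than 3 regulators in {text!r}")
    mask = 0
    for term in terms:
        s = sum(1 << regulators.index(r) for r in set(term))
        mask |= 1 << (s - 1)
    return Rule(
        target=target,
        regulators=tuple(regulators),
        signs=tuple(signs[r] for r in regulators),
        term_mask=mask,
    )


def enumerate_rule_space(
    target: str, regulators: list[tuple[str, int]]
) -> list[Rule]:
    """Every rule encoding over the given signed regulators, in term_mask order.

    Counts: 1, 7, 127 encodings for 1, 2, 3 regulators.  With zero
    regulators returns the singleton hold rule.
    """
    k = len(regulators)
    if k == 0:
        return [hold_rule(target)]
    if k > 3:
        raise RuleError("rule spaces are only enumerated for <= 3 regulators")
    names = tuple(r for r, _ in regulators)
    signs = tuple(s for _, s in regulators)
    n_terms = (1 << k) - 1
    return [
        Rule(target=target, regulators=names, signs=signs, term_mask=mask)
        for mask in range(1, 1 << n_terms)
    ]


def functionally_equal(a: Rule, b: Rule) -> bool:
    """Truth-table equality over the union of the two rules' regulator sets."""
    if a.is_hold or b.is_hold:
        return a.is_hold and b.is_hold
    union = sorted(set(a.regulators) | set(b.regulators))
    if len(union) > 6:  # pragma: no cover - impossible with k <= 3 each
        raise RuleError("too many regulators for truth-table comparison")
    for x in range(1 << len(union)):
        state = {r: x >> i & 1 for i, r in enumerate(union)}
        if a.evaluate(state) != b.evaluate(state):
            return False
    return True


@dataclass
class RuleSet:
    """A network-wide rule assignment: exactly one rule per node.

    Source nodes (in-degree 0) carry the hold rule.  This is the unit the
    genetic algorithm evolves.
    """

    graph: SignedDiGraph
    rules: dict[str, Rule]

    def __post_init__(self) -> None:
        missing = set(self.graph.nodes) - set(self.rules)
        extra = set(self.rules) - set(self.graph.nodes)
        if missing or extra:
            raise RuleError(
                f"rule set does not cover the network exactly "
                f"(missing: {sorted(missing)}, extra: {sorted(extra)})"
            )
        for node, rule in self.rules.items():
            if rule.target != node:
                raise RuleError(f"rule for {node!r} targets {rule.target!r}")
            preds = set(self.graph.predecessors(node))
            if not set(rule.regulators) <= preds:
                raise RuleError(
                    f"rule for {node!r} uses non-regulator inputs "
                    f"{set(rule.regulators) - preds}"
                )

    def replace(self, rule: Rule) -> "RuleSet":
        rules = dict(self.rules)
        rules[rule.target] = rule
        return RuleSet(graph=self.graph, rules=rules)

    def non_source_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) > 0)

    def to_text(self) -> str:
        return "\n".join(self.rules[n].to_text() for n in sorted(self.rules))


@dataclass
class EquivalentRuleSet:
    """Per node, all rules whose local error is within tolerance of the minimum.

    ``best`` holds the minimal-error rule per node; ``members`` every rule
    within ``min_error * (1 + tolerance) + floor``; ``errors`` the matching
    local errors.
    """

    best: dict[str, Rule]
    members: dict[str, list[Rule]]
    errors: dict[str, list[float]]
    tolerance: float
    graph: SignedDiGraph = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for node, mem in self.members.items():
            if not mem:
                raise RuleError(f"empty ERS for node {node!r}")
            if not any(m is self.best[node] or m == self.best[node] for m in mem):
                raise RuleError(f"minimal-error rule missing from ERS of {node!r}")

    def size(self, node: str) -> int:
        return len(self.members[node])

    def best_ruleset(self) -> RuleSet:
        return RuleSet(graph=self.graph, rules=dict(self.best))


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


def effective_edges(rs: RuleSet) -> set[tuple[str, str, int]]:
    """Signed edges realized by the rules: regulators appearing in >= 1 AND-term."""
    edges = set()
    for node, rule in rs.rules.items():
        for reg in rule.used_regulators():
            sign = rule.signs[rule.regulators.index(reg)]
            edges.add((reg, node, sign))
    return edges


def structural_distance(rs: RuleSet, reference: SignedDiGraph) -> int:
    """Edge-edit distance between the rules' effective network and a reference.

    Symmetric difference over (source, target, sign) triples, so an edge
    recovered with the wrong sign costs 2 (one removal plus one addition).
    """
    if set(rs.graph.nodes) != set(reference.nodes):
        raise RuleError("rule set and reference graph have different node sets")
    return len(effective_edges(rs) ^ reference.signed_edges())


def min_structural_distance(ers: EquivalentRuleSet, reference: SignedDiGraph) -> int:
    """Minimum structural distance over per-node choices of ERS members.

    The symmetric difference decomposes over target nodes (each rule only
    contributes in-edges of its own target), so the per-node minimum is the
    global minimum.
    """
    if set(ers.graph.nodes) != set(reference.nodes):
        raise RuleError("rule set and reference graph have different node sets")
    ref = reference.signed_edges()
    total = 0
    for node in ers.graph.nodes:
        ref_in = {e for e in ref if e[1] == node}
        candidates = ers.members.get(node) or [ers.best[node]]
        best = None
        for rule in candidates:
            eff = {
                (reg, node, rule.signs[rule.regulators.index(reg)])
                for reg in rule.used_regulators()
            }
            d = len(eff ^ ref_in)
            best = d if best is None else min(best, d)
        total += best
    return total


def rule_accuracy(
    ers: EquivalentRuleSet, truth: RuleSet
) -> tuple[float, float]:
    """Percent of non-source nodes recovered exactly and within the ERS.

    A node counts as exact when its minimal-error rule is functionally equal
    (truth-table equality over the union of regulator sets) to the planted
    rule; it counts for ERS accuracy when any ERS member is.  Source nodes
    are excluded from the denominator.
    """
    nodes = truth.non_source_nodes()
    if not nodes:
        raise RuleError("no non-source nodes to score")
    exact = ers_hit = 0
    for node in nodes:
        true_rule = truth.rules[node]
        if node not in ers.members or not ers.members[node]:
            raise RuleError(f"empty ERS for node {node!r}")
        if functionally_equal(ers.best[node], true_rule):
            exact += 1
        if any(functionally_equal(m, true_rule) for m in ers.members[node]):
            ers_hit += 1
    return 100.0 * exact / len(nodes), 100.0 * ers_hit / len(nodes)


def random_ruleset(
    graph: SignedDiGraph,
    seed: int | np.random.Generator | None = None,
    max_indegree: int = 3,
) -> RuleSet:
    """Plant a uniformly random rule (over encodings) at every non-source node.

    Nodes with more than ``max_indegree`` regulators get a random regulator
    subset of that size.
    """
    rng = np.random.default_rng(seed)
    rules: dict[str, Rule] = {}
    for node in sorted(graph.nodes):
        preds = sorted(graph.predecessors(node))
        if not preds:
            rules[node] = hold_rule(node)
            continue
        if len(preds) > max_indegree:
            idx = rng.choice(len(preds), size=max_indegree, replace=False)
            preds = [preds[int(i)] for i in sorted(idx)]
        k = len(preds)
        mask = int(rng.integers(1, 1 << ((1 << k) - 1)))
        rules[node] = Rule(
            target=node,
            regulators=tuple(preds),
            signs=tuple(graph.edge_sign(p, node) for p in preds),
            term_mask=mask,
        )
    return RuleSet(graph=graph, rules=rules)
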