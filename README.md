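# boolpath

Ensemble Boolean network propagation, logic-rule inference, and
topology-aware pathway analysis for cross-sectional transcriptomics.

`boolpath` models bulk expression heterogeneity as a mixture of cells with
binary gene states. Expression is scaled per gene to [0, 1] and used as
Bernoulli probabilities for the initial states of an ensemble of synchronous
Boolean simulations (1000 runs × 100 steps by default, activities averaged
over the last 10 steps). On top of this propagation engine it provides:

- **Rule inference** — a genetic algorithm over network-wide rule sets
  (OR-of-ANDs logic over ≤3 signed regulators, population 24, 120
  generations) minimizing steady-state mismatch, followed by an exhaustive
  per-node local search that records the *equivalent rule set* (ERS): all
  rules whose node-local error is within a tolerance of the minimum.
- **Pathway analysis** — per-gene impact scores from in-silico
  knockout/knock-in (summed squared activity difference between clamping a
  gene to 0 and to 1), combined with fold differences and per-gene standard
  deviations into a pathway modulation score, with p-values from a
  resampled-fold-difference permutation null.
- **Network I/O** — KGML (KEGG XML), GraphML (edge attribute
  `signal` ∈ {a, i}), and SIF readers/writers for signed directed networks;
  synthetic network generators and corruption utilities.
- **Benchmarks** — planted-rule recovery (accuracy vs noise, sample count,
  and false-positive edges) and a negative-binomial source-attenuation ROC
  study, all generated internally and reproducible from a single seed.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which reruns the headline
simulation studies at desk scale (several minutes of compute). One property
test (`test_impact_rank_differs_from_degree`) is a known failure at this
synthetic scale; see the test's comment.

## Quick start (Python)

```python
import boolpath as bp

g = bp.generate_random_network(20, seed=1)          # or bp.parse_kgml(...)
data, truth = bp.benchmark.generate_planted_data(   # synthetic activities
    g, n_samples=5, sim_cfg=bp.SimulationConfig(runs=300, steps=25, tail=5),
    seed=2,
)
result = bp.infer_rules(g, data, ga_cfg=bp.GAConfig(seed=3), prescaled=True)
print(result.best.to_text())
print(bp.rule_accuracy(result.ers, truth))
```

## Command line

```bash
# infer rules for one network from an expression matrix (genes x samples)
boolpath infer --network pathway.graphml --expr counts.tsv --seed 7 --out out/

# pathway analysis across a directory of KGML/GraphML/SIF networks
boolpath analyze --networks nets/ --expr counts.tsv \
    --conditions conditions.csv --contrast treated,control --out out/

# benchmarks
boolpath simulate recovery --networks 5 --seed 1 --out out/
boolpath simulate attenuation --levels 0,0.5,1,1.5,2 --replicates 3 --out out/

# format conversion
boolpath convert pathway.xml pathway.graphml
```

Every run writes a `manifest.json` (resolved config, seeds, input digests)
into the output directory. The flags `--runs --steps --generations
--population --tolerance --permutations` default to the reference protocol
(1000, 100, 120, 24, 0.1, 1000).

## Layout

| module                  | contents                                                  |
| ----------------------- | --------------------------------------------------------- |
| `boolpath.networks`     | `SignedDiGraph`, KGML/GraphML/SIF I/O, topology statistics, random networks |
| `boolpath.rules`        | `Rule`/`RuleSet`/`EquivalentRuleSet`, rule-space enumeration, recovery metrics |
| `boolpath.propagation`  | unit scaling, vectorized ensemble simulation, exact brute-force oracle |
| `boolpath.inference`    | fitness functions, genetic algorithm, local search, `infer_rules` |
| `boolpath.pathway`      | impact scores, modulation score, permutation p-values, GraphML export |
| `boolpath.benchmark`    | NB count simulation, attenuation/recovery/false-edge experiment drivers |
| `boolpath.cli`          | `boolpath` console entry point                             |
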