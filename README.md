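# ethochain

First-order Markov chain analysis of agonistic (fighting) behavior
sequences in animals, built around the published nine-state ethogram of the
Pacific white shrimp *Litopenaeus vannamei*.

Agonistic behavior — threatening, attacking, retreating — limits survival
and growth in high-density crustacean aquaculture. A standard way to
quantify it is to score videos into a sequence of discrete behavior
patterns (an *ethogram*) and model the sequence as a first-order Markov
chain: the probability of the next behavior pattern depends only on the
current one,

    p_ij = P(X_{n+1} = E_j | X_n = E_i),   0 ≤ p_ij ≤ 1,  Σ_j p_ij = 1,

estimated by row-normalizing the table of observed transition counts.
Summing each row over the stage membership of the *target* behaviors gives
the probability that the next behavior falls in each fighting stage
(encounter → contact → withdrawal), which exposes the logic of the fight.

`ethochain` provides, for anyone analyzing behavioral event logs:

- **Ethogram handling** — the built-in nine-state *L. vannamei* agonistic
  ethogram (parade, demonstration, attack, fight, chase, impact, feint,
  temporary retreat, retreat; three stages), or your own via YAML/JSON.
- **Event-log ingestion** — CSV/TSV logs (`session_id, time_s, behavior`)
  to per-session state sequences, with run-collapse of repeated states.
- **Transition model** — counts, maximum-likelihood transition matrix
  (with optional smoothing and explicit undefined rows), stage
  aggregation, and the built-in published transition matrix.
- **Markov dynamics** — simulation, k-step probabilities, stationary
  distribution, sequence log-likelihood, a G-test of sequential dependence
  against an independent-draws null, and session-level bootstrap CIs.
- **Synthetic data** — a generator with known ground truth (configurable
  sessions, lengths, record dropout) plus parameter-recovery reports.
- **Diagrams** — the behavior-model graph as DOT or GraphML, with edge
  thickness proportional to transition probability and dashed stage
  clusters.
- **Expression arithmetic** — 2^−ΔΔCt relative expression from qPCR Ct
  tables and qPCR-vs-RNA-seq log2-fold-change sign concordance.

## Worked example

```python
from ethochain import (MarkovChain, aggregate_stages, count_transitions,
                       estimate_matrix, simulate, stationary, test_first_order,
                       vannamei_ethogram, vannamei_transition_matrix)

eth = vannamei_ethogram()
matrix = vannamei_transition_matrix()

print(f"P(retreat | fight) = {matrix.prob('fight', 'retreat'):.4f}")
stages = aggregate_stages(matrix, eth)
print(f"P(next in contact stage | temporary retreat) = "
      f"{stages.prob('temporary retreat', 'contact'):.4f}")

pi = stationary(matrix)
print(f"long-run occupancy of demonstration = {pi.pi[1]:.4f}")

chain = MarkovChain.uniform_start(matrix)
seqs = [simulate(chain, 2000, seed=s) for s in range(10)]
est = estimate_matrix(count_transitions(seqs, eth))
print(f"re-estimated P(retreat | impact) = {est.prob('impact', 'retreat'):.4f}")
res = test_first_order(seqs, eth)
print(f"G = {res.statistic:.1f}, df = {res.df}, p = {res.p_value:.3g}")
```

prints

```
P(retreat | fight) = 0.6718
P(next in contact stage | temporary retreat) = 0.5453
long-run occupancy of demonstration = 0.2376
re-estimated P(retreat | impact) = 0.7693
G = 51794.5, df = 55, p = 0
```

Read: after a fight, the loser retreats 67% of the time; after a temporary
retreat, the animal re-engages in contact behavior slightly more often
than it backs off; demonstration is the most-occupied behavior in the long
run; simulating ~20,000 transitions and re-estimating recovers the
impact→retreat probability (true value 0.7601) to sampling error; and the
simulated sequences are, as expected, overwhelmingly sequentially
dependent rather than random draws.

The same pipeline is available from the shell:

```sh
ethochain estimate --log events.csv --percent       # fit a matrix from a log
ethochain stages --percent                          # stage table of the built-in matrix
ethochain simulate --steps 500 --seed 7             # simulate a bout sequence
ethochain diagram --format dot --out model.dot      # behavior-model diagram
ethochain synth --sessions 25 --seed 1 --out-dir d  # synthetic study + truth manifest
```

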