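# ctrlcascade

Structural controllability of directed networks under load-driven cascading
edge failures.

Many directed systems — neural wiring, food webs, peer-to-peer overlays,
power and transport networks — are both *controlled* through a small set of
driver nodes and *damaged* through overload cascades. This package follows
the two together: it measures how the minimum number of driver nodes evolves
while a betweenness-load cascade, triggered by random or targeted edge
removal, eats through a network.

## The model

**Controllability.** For linear time-invariant dynamics
$\dot{x} = Ax + Bu$ on a directed network, the minimum number of independent
inputs for full structural controllability is

$$N_D = \max\bigl(N - |M^*|,\; 1\bigr),$$

where $|M^*|$ is the size of a maximum matching of the network — a largest
edge set in which no two edges share a source or share a target. Nodes with
no inbound matched edge are the *driver nodes*; attaching one input to each
makes the system controllable for almost every weight assignment. Every edge
plays one of three roles: **critical** (its removal raises $N_D$),
**redundant** (it lies in no maximum matching), or **ordinary** (in some but
not all maximum matchings). An independent cross-check with concrete weights
is the exact count $N_D = \max_\lambda\,[N - \mathrm{rank}(\lambda I - A)]$
over the eigenvalues of $A$.

**Cascade.** Each edge's load $L_e$ is the number of shortest directed paths
(over all ordered node pairs) passing through it, and its capacity is frozen
at $C_e = (1+\alpha)L_e(0)$ with tolerance $\alpha \ge 0$. An attack removes
edges — uniformly at random (RA), in descending order of initial load (IA),
or just the single highest-load edge — after which loads reroute; every edge
with $L_e > C_e$ fails, all at once, and the process repeats until no edge
is overloaded. Per stage the simulation records the failed edges, $N_D$, and
the number of edges inside strongly connected components.

Synthetic ensembles stand in for real networks: directed Erdős–Rényi graphs
with mean degree $\langle k\rangle = M/N$ and directed scale-free graphs
(static model) with tail exponent $\gamma$. Any directed network can also be
supplied as a plain-text edge list.

## Worked example

```python
from ctrlcascade import ExperimentConfig, GeneratorSpec, single_trigger_experiment

cfg = ExperimentConfig(
    generator=GeneratorSpec("er", 500, 3.0),  # ER, N=500, <k>=3
    alpha=0.3,
    n_realizations=20,
    master_seed=1,
)
res = single_trigger_experiment(cfg)
print(res.trace.head(4).to_string(index=False))
```

```
 stage  n_drivers_mean  n_drivers_se  scc_edges_mean  scc_edges_se
     0           38.80      1.696126         1320.75     16.750943
     1           39.70      1.800731         1302.95     18.367516
     2           41.35      1.764079         1285.00     18.279554
     3           42.35      1.780412         1274.75     19.686206
```

Removing one highest-load edge per realization starts a cascade that, at
this moderate mean degree, grows the averaged driver count from 38.6 on the
intact graphs to 65.1 at termination (a mean increment of 26.5 drivers)
while failing on average 143 of ~1491 edges — the SCC edge count dropping in
step with the driver-count rise.

The same pipeline is scriptable from the shell:

```
$ ctrlcascade gen --model er --n 500 --k 6 --seed 7 --out er.txt
wrote er.txt: N=500 M=2932
$ ctrlcascade ctrl --in er.txt --classify
N       M       N_D     n_D     n_critical      n_ordinary      n_redundant
500     2932    2       0.004   13      2852    67
$ ctrlcascade cascade --in er.txt --alpha 0.3 --attack highest --seed 1 --trace trace.tsv
attacked 1 edge(s); 2 failed in 1 cascade stage(s); trace -> trace.tsv
```

`ctrlcascade sweep --config cfg.yaml --out DIR` runs the full RA/IA
removal-fraction factorial (with the failed-edge category census) and writes
tidy TSV tables plus a manifest; `ctrlcascade trigger` does the same for the
highest-load-edge experiment.

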