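# dtwalk

Drug–target interaction prediction by **random walk with restart (RWR) on a
heterogeneous drug/target network**.

Knowing which proteins a drug binds is central both to finding new uses for
existing drugs and to anticipating side effects, but experimental target
panels cover only a small slice of chemistry × proteome space.  `dtwalk`
ranks candidate protein targets for a query drug by diffusing probability
over a three-layer network:

* a **drug–drug layer** `S_d` blending chemical fingerprint similarity
  (Tanimoto coefficient `C/(A + B − C)` on binary fingerprints, `C_s`) with
  a shared-target Jaccard similarity computed from the known interaction
  matrix (`C_s^n`): `S_d = w_d C_s + (1 − w_d) C_s^n`;
* a **target–target layer** `S_t` blending normalized Smith–Waterman
  sequence similarity `T_s(g, g′) = SW(g, g′)/(√SW(g, g) · √SW(g′, g′))`
  with a shared-drug Jaccard similarity `T_s^n`:
  `S_t = w_t T_s + (1 − w_t) T_s^n`;
* the **bipartite interaction layer** `A`, with `A(i, j) = 1` when drug `i`
  is known to bind target `j`.

Nodes with at least one interaction are *bridge nodes*: a walker there
crosses layers with jumping probability `λ` and stays within its layer with
`1 − λ`, giving a row-stochastic block transition matrix

```
W = [ W_TT  W_TD ]
    [ W_DT  W_DD ]
```

The walk iterates `p_{t+1} = (1 − c) Wᵀ p_t + c p_0` to its fixed point,
where the restart distribution splits mass between the query drug's known
targets (`u_0`) and the drug itself (`v_0`): `p_0 = [(1 − η) u_0; η v_0]`.
The steady-state target probabilities `u_∞` rank the candidate (non-seed)
targets; a drug with no known target is still queryable, entering the
network through chemical similarity alone.  Evaluation follows a
link-perturbation protocol (hide known links, measure the rank at which
they are re-found) with early-recognition metrics — recovered fraction at
top N, AUAC, AUC, partial AUC on the top decile, BEDROC(α) and the
enrichment factor — against a degree-preserving randomized baseline and a
pure sequence-similarity baseline.

## Worked example

A built-in generator produces planted-cluster benchmark worlds: drugs and
targets fall into matched clusters with correlated fingerprints, sequences
and interactions, and 20% of the generated links are withheld as ground
truth.

```python
import dtwalk as dw

world = dw.generate_world()              # 60 drugs x 60 targets, 4 clusters
net = dw.world_to_hetnet(world)          # full similarity pipeline
params = dw.WalkParams()                 # c=0.3, eta=0.01, lambda=0.5

pred = dw.predict_targets(net, "D000", params)
for i, (t, s) in enumerate(zip(pred.targets[:5], pred.scores[:5]), 1):
    print(i, t, f"{s:.6g}")
```

prints

```
1 T013 0.0164784
2 T012 0.0153478
3 T000 0.0140573
4 T002 0.0135452
5 T008 0.0129375
```

Drug `D000` belongs to cluster 0 and all five top-ranked candidates are
cluster-0 targets — the walk has identified the drug's neighborhood from
fingerprint, sequence and co-interaction signal.  The scores are
steady-state probabilities: their absolute size depends on network size,
only the ordering matters.  Ranking every withheld link the same way:

```python
records = dw.rank_held_out(net, world.held_out_links, params)
report = dw.compute_metrics(records, top_ns=(10, 50))
print(report.as_dict())
```

gives (56 held-out links) recovered fraction 0.732 at top 10 and 1.0 at
top 50, AUAC 0.852, AUC 0.868, BEDROC(20) 0.250 and EF(0.1) 3.57 — against
an AUC of ~0.5 for the degree-preserving randomized baseline.

The same pipeline is scriptable from a shell:

```bash
dtwalk simulate --outdir world --seed 7
dtwalk predict  --interactions world/interactions.tsv \
                --fingerprints world/fingerprints.tsv \
                --sequences world/sequences.fasta --top 10
dtwalk evaluate --interactions world/interactions.tsv \
                --fingerprints world/fingerprints.tsv \
                --sequences world/sequences.fasta --seed 1
```

`evaluate` runs the single-link-removal protocol (one hidden link per
drug, with the shared-neighbor similarities recomputed so the hidden link
cannot leak through topology) and prints the metric table alongside the
randomized baseline.

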