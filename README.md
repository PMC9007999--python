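# oncodag

Consensus Bayesian-network inference linking oncogene expression to the
cellular composition of tissue samples.

## The problem

Bulk-tissue transcriptomes can be deconvolved into cell-level features:
prevalence scores for immune and stromal cell types, cell-state metrics
(e.g. epithelial–mesenchymal), proliferation scores, oncogene expression, and
0/1 sample attributes such as whether the tissue is malignant.  Given such a
samples × features table, `oncodag` infers a directed acyclic graph (DAG)
describing how the oncogene and the malignant state reshape the heterocellular
network — which cell populations they promote, which they inhibit, and
through which intermediates — and turns that DAG into a generative model that
answers conditional-probability questions.

The package is aimed at computational biologists who already have a feature
table (deconvolution itself is out of scope) and want causal-structure
hypotheses with honest uncertainty rather than a correlation heat map.

## The method

Each feature is a node of a linear-Gaussian Bayesian network: every node is
Gaussian with mean linear in its parents, Y_j | pa(j) ~ N(b0_j + Σ b_jk·Y_k,
σ_j²), fitted per node by maximum likelihood.  The structure comes from a
four-step consensus workflow:

1. **Blacklist** — prior knowledge as node roles: the cancer attribute is a
   root (nothing in the table causes oncogenesis), the oncogene a quasi-root
   (child only of the cancer attribute), therapeutic endpoints and heavily
   zero-inflated cell features are leaves.  Roles compile to forbidden arcs.
2. **Ensemble** — ten structure-learning algorithms (hc, tabu, pc_stable,
   gs, iamb, iamb_fdr, mmpc, si_hiton_pc, mmhc, rsmax2), each run under
   bootstrap resampling (default n_boot = 10,000); per algorithm, a
   model-averaged network keeps edges whose inclusion frequency clears an
   automatically chosen threshold (the L1-optimal step-CDF fit, nominally
   0.5).
3. **Whitelist** — edges detected across algorithms with a consistent
   direction are swept over significance thresholds of their exact-t partial
   correlation p-value ("edge strength"); each node's parents at its minimum
   L1-BIC, BIC_j = n_arcs·log10(n_obs) + Σ|Ŷ−Y|, enter a consensus seed,
   admitting arcs in order of evidence and skipping any that would close a
   cycle.
4. **Final learning** — a hybrid learner (mmhc) under blacklist + consensus
   whitelist, bootstrap-averaged; edge width/annotation carries the inclusion
   probability, coefficient, and promote/inhibit sign.

Conditional queries use logic sampling (forward sampling, default 10⁵
samples, rejection-filtered on evidence such as `Cancer < 0.05`).

See `docs/methods.md` for assumptions, numerical choices, and limitations.

## Worked example

Everything below is runnable as-is; the data are generated by the package's
own benchmark generator (a 12-node network with a binary "Cancer" root, a
"CCN4"-like oncogene quasi-root, and two zero-inflated leaf cell types).

```python
from oncodag import ConsensusDAGModel
from oncodag.synthetic import make_ground_truth, sample_dataset, default_roles

truth = make_ground_truth(seed=3)                 # known generating DAG
table = sample_dataset(truth, 500, seed=4)        # 500 samples, features in [0,1]

model = ConsensusDAGModel(table, default_roles())
result = model.fit(algorithms=("hc", "tabu", "pc_stable", "mmhc"),
                   n_boot=200, seed=7)
print(result.summary())
```

```
Consensus Bayesian network (linear-Gaussian)
==========================================================
samples: 500    nodes: 12    arcs: 13
ensemble: hc, tabu, pc_stable, mmhc
n_boot: 200    seed: 7
blacklist: 39 arcs    consensus whitelist: 13 arcs
----------------------------------------------------------
arc                                    coef   effect P(incl)
CCN4 -> F6                           -0.825  inhibit    1.00
Cancer -> CCN4                        0.499  promote    1.00
Cancer -> F3                          0.253  promote    1.00
...
root Cancer: mean=0.448 sd=0.497 (bernoulli)
```

Reading it: each arc line is one inferred causal influence — the coefficient
is the linear effect on the [0,1]-normalized scale (`Cancer -> CCN4  0.499`
means malignant samples sit ≈0.5 higher in normalized oncogene expression),
`effect` is its sign, and `P(incl)` is the bootstrap inclusion probability
(1.00 for consensus-whitelisted arcs).  Query the fitted model:

```python
_, summary = result.query(evidence=["Cancer>0.5"], report=["CCN4"],
                          n_samples=100000, seed=1)
print(summary)          # conditional mean/sd of CCN4 in malignant tissue
delta = result.quantile_contrast("CCN4", 5)
print(delta)            # top-vs-bottom CCN4-quantile shift per feature
```

A command-line interface mirrors the library (`oncodag features`,
`blacklist`, `ensemble`, `run`, `learn`, `query`, `simulate`, `benchmark`);
`oncodag run --config cfg.yaml --outdir out/` writes the full artifact bundle
(normalized table, blacklist, strengths, edge evidence, BIC sweep, whitelist,
final DAG as GraphML, fitted network JSON, query summaries, manifest) and is
byte-reproducible for a fixed config.

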