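# neuromaxent

Maximum-entropy null models for neural connectomes and contactomes.

Cellular-scale brain reconstructions give two networks on the same
neurons: the **connectome** (an edge wherever at least one chemical
synapse exists) and the **contactome** (an edge wherever two neuron
surfaces approach within tens of nanometres — a strict superset of the
connectome). Understanding which features of connectome structure
follow from spatial and physical constraints, and which require
topological ones, calls for tunable null models. `neuromaxent`
implements the canonical maximum-entropy ensembles that answer this:
distributions over graphs that preserve chosen constraints on average
(or absolutely) while assuming nothing else.

All six ensembles factorise over node pairs into independent edge
probabilities p_ij, so they are fitted by fast fixed-point iteration
and sampled directly, with no Markov-chain Monte Carlo:

| model | constraints | edge probability |
|-------|-------------|------------------|
| `d`   | binned connection probability vs distance | p_b(d_ij) |
| `k`   | expected degrees (soft configuration model) | 1/(1 + x_i x_j) |
| `k+L` | expected degrees + total wiring length L | 1/(1 + x_i x_j e^{d_ij/d0}) |
| `c`   | expected edge count, contact pairs only | E*/E_cont |
| `d+c` | conditional p(d), contact pairs only | p_b(d_ij) |
| `k+c` | expected degrees, contact pairs only | 1/(1 + x_i x_j) |

Here x_i = e^{θ_i} are exponentiated Lagrange multipliers fitted so
that ⟨k_i⟩ = k_i*, and d0 is the decay scale that makes the expected
wiring length ⟨L⟩ = Σ p_ij d_ij match its target to within 0.01%.
Distances are measured between neuron "centers of mesh" and reported in
soma-size units.

The package also provides the surrounding toolchain: contactome
construction from per-neuron surface point clouds (exact minimum
inter-cloud distances, data-driven nanometre threshold selection at 99%
synaptic coverage), spatial statistics (binned p(d), exponential decay
scales, finite-size cutoffs, soma-radius estimation, directional decay
along principal axes), an evaluation suite (induced graphlet counts,
network measures, degree statistics, wiring-length shuffle test,
ROC/precision-recall edge prediction, probability–weight rank
correlation, ensemble z-score comparison), and seeded synthetic
multilayer scenarios with planted ground truth. See `docs/methods.md`
for the full model and parameter documentation.

## Worked example

```python
import neuromaxent as nm

# a seeded synthetic multilayer scenario: 300 neurons in a 100-unit cube,
# exponential contact kernel, heterogeneous synaptic subnetwork
scen = nm.generate_scenario(n=300, seed=7)
print("E_syn =", scen.connectome.n_edges, " E_cont =", scen.contactome.n_edges)

# fit the degree + wiring-length ensemble to the realized graph
d = nm.condensed_distances(scen.nodes)
k = scen.connectome.degrees()
L = scen.connectome.wiring_length()
model = nm.fit_degree_wiring_model(k, L, d, node_ids=scen.nodes.ids)
print(f"d0 = {model.d0:.2f} soma sizes")
print(f"wiring error = {100*abs(model.expected_wiring_length()-L)/L:.4f} %")

# does the ensemble reproduce a statistic it was not fitted to?
samples = nm.sample_ensemble(model, seed=7, n_realizations=100, distances=d)
tri = [nm.graphlet_counts(nm.SpatialNetwork(scen.nodes, e)).n_triangle
       for e in samples]
comp = nm.ensemble_compare(nm.graphlet_counts(scen.connectome).n_triangle,
                           tri, stat_name="triangle")
print(f"triangles: data {comp.data_value:.0f}, model {comp.model_mean:.1f} "
      f"+/- {comp.model_sd:.1f}, inverse fold change "
      f"{comp.inverse_fold_change:.2f} ({comp.significance})")

# are the node positions wiring-optimal given the topology?
ratio, p = nm.wiring_shuffle_test(scen.connectome, n_perm=999, seed=7)
print(f"shuffled/observed wiring = {ratio:.2f}, p = {p:.4f}")
```

Output:

```
E_syn = 277  E_cont = 1088
d0 = 10.91 soma sizes
wiring error = 0.0097 %
triangles: data 12, model 21.8 +/- 6.7, inverse fold change 1.82 (n.s.)
shuffled/observed wiring = 2.30, p = 0.0010
```

Reading the numbers: the fitted decay scale d0 ≈ 11 soma sizes is close
to the planted contact kernel's 12; the calibration holds the expected
wiring length to a ten-thousandth of the target; the triangle count of
the data sits inside the ensemble's spread (not significant at this
small size); and the observed wiring length is 2.3× shorter than
position-shuffled copies of the same topology — the planted positions
are wiring-optimal, as the permutation p-value confirms.

A thin CLI mirrors the library: `neuromaxent synth`, `fit`, `stats
distance|soma|directional`, `contactome`, `evaluate` (see `--help`).

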