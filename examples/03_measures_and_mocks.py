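"""Network measures, small-worldness, and mock-ensemble delta correction.

Estimates a network from simulated lists, measures it, then re-estimates
networks from within-list permutations of the same data (mock networks) and
prints the deltas: participant value minus mock mean.  Deltas isolate the
contribution of response ORDER, since mocks share the item frequencies and
list sizes but scramble the sequence.
"""

import networkx as nx
import numpy as np

from fluencynet import (
    FluencyCorpus,
    FluencyList,
    WalkSimulator,
    compute_measures,
    delta_measures,
    estimate_network,
    mock_ensemble,
    smallworld_coefficient,
)

truth = nx.relabel_nodes(
    nx.connected_watts_strogatz_graph(20, 4, 0.1, seed=3), lambda i: f"animal{i:02d}"
)
rng = np.random.default_rng(5)
sim = WalkSimulator(truth)
corpus = FluencyCorpus(
    "demo",
    tuple(
        FluencyList("demo", f"v{i}", tuple(sim.sample_emissions(0.1, 12, rng)))
        for i in range(6)
    ),
)

result = estimate_network(corpus, seed=9)
measures = compute_measures(result.network)
sw = smallworld_coefficient(result.network, n_random=50, rng=rng)

print("participant network:")
for name, value in measures.as_dict().items():
    print(f"  {name:>14}: {value:.3f}")
print(f"  {'smallworld':>14}: {sw:.3f}  (> 1 means small-world structure)")

ensemble = mock_ensemble(corpus, k=8, rng=rng)
print(f"\nmock ensemble: {len(ensemble.measures)} replicates "
      f"({ensemble.n_failed} failed)")
for name, delta in delta_measures(measures, ensemble).items():
    print(f"  delta_{name:>12}: {delta:+.3f}")

print()
print("Negative delta mean degree / positive delta aspl say the real response")
print("order supports a sparser, longer-path network than arbitrary orderings")
print("of the very same items would - the signature of structured retrieval.")
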