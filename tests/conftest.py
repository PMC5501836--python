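import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


def random_connected_weight_matrix(k, rng, low=0.05, high=0.5):
    """Random symmetric positive weight matrix whose graph is connected."""
    while True:
        w = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        present = rng.random(len(iu[0])) < 0.6
        vals = rng.uniform(low, high, len(iu[0])) * present
        w[iu] = vals
        w += w.T
        # connectivity check via reachability on the binary adjacency
        adj = w > 0
        seen = {0}
        frontier = [0]
        while frontier:
            node = frontier.pop()
            for nxt in np.flatnonzero(adj[node]):
                if nxt not in seen:
                    seen.add(int(nxt))
                    frontier.append(int(nxt))
        if len(seen) == k:
            return w
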