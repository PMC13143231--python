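import numpy as np
import pytest

import convscan as cs


@pytest.fixture(scope="session")
def lg():
    return cs.load_model("LG")


@pytest.fixture(scope="session")
def toy2():
    """Two-state reversible model with asymmetric stationary frequencies."""
    S = np.array([[0.0, 1.0], [1.0, 0.0]])
    return cs.SubstitutionModel(S, [0.3, 0.7], alphabet="AC", name="toy2")


@pytest.fixture
def quartet():
    return cs.parse_newick(
        "((A:0.12,B:0.3)0.9:0.08,(C:0.2,D:0.05)0.9:0.11);")


@pytest.fixture
def nine_taxon_tree():
    from convscan.synthetic_data import DEFAULT_TOPOLOGY
    return cs.parse_newick(DEFAULT_TOPOLOGY)


def random_rooted_tree(labels, rng, max_len=0.4):
    """Random binary topology over the given leaf labels (newick string)."""
    parts = [f"{x}:{rng.uniform(0.02, max_len):.4f}" for x in labels]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        support = rng.choice([0.5, 0.9, 0.96, 1.0])
        parts.append(f"({a},{b}){support:g}:{rng.uniform(0.02, max_len):.4f}")
    return parts[0] + ";"
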