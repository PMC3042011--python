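import numpy as np
import pytest

from mapfuse.core import A, B, MISSING, GenotypeMatrix, LinkageMap


def make_matrix(rows, population="pop0", lines=None, markers=None):
    """Build a GenotypeMatrix from a list of per-line symbol strings.

    ``rows`` like ["AB-", "BBA"]; columns are markers m0, m1, ...
    """
    code = {"A": A, "B": B, "-": MISSING}
    calls = np.array([[code[c] for c in row] for row in rows], dtype=np.int8)
    n_lines, n_markers = calls.shape
    lines = lines or [f"L{i}" for i in range(n_lines)]
    markers = markers or [f"m{j}" for j in range(n_markers)]
    return GenotypeMatrix(population, lines, markers, calls)


def make_map(positions, lg="LG1", map_name="test", names=None):
    names = names or [f"m{j}" for j in range(len(positions))]
    return LinkageMap(map_name, lg, list(zip(names, positions)))


@pytest.fixture
def simple_matrix():
    return make_matrix(["AAB", "ABB", "A-B", "BAA"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
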