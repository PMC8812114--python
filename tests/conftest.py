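import itertools

import pytest
from hypothesis import settings

from edascreen.annotate import annotate_table
from edascreen.features import group_replicates
from edascreen.synth import StudyConfig, generate_study

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent brute-force isotopologue oracle
# ---------------------------------------------------------------------------

from edascreen._isotopes import ISOTOPES  # noqa: E402


def brute_force_pattern(counts: dict, resolution_bin: float = 0.01, prune: float = 1e-4):
    """Enumerate every isotopologue atom-by-atom (itertools.product), merge
    within the resolution bin by abundance-weighted centroid, prune, and
    normalize to base 1. Independent of the convolution implementation.
    Only usable for molecules with a small total number of isotope
    combinations."""
    atoms = [sym for sym, n in counts.items() for _ in range(n)]
    choices = [ISOTOPES[sym] for sym in atoms]
    raw = {}
    for combo in itertools.product(*choices):
        m = sum(c[0] for c in combo)
        p = 1.0
        for c in combo:
            p *= c[1]
        raw[m] = raw.get(m, 0.0) + p
    peaks = sorted(raw.items())
    merged = []
    cluster = []
    for m, a in peaks:
        if cluster and m - cluster[0][0] > resolution_bin:
            tot = sum(x[1] for x in cluster)
            merged.append((sum(x[0] * x[1] for x in cluster) / tot, tot))
            cluster = []
        cluster.append((m, a))
    if cluster:
        tot = sum(x[1] for x in cluster)
        merged.append((sum(x[0] * x[1] for x in cluster) / tot, tot))
    base = max(a for _, a in merged)
    return [(m, a / base) for m, a in merged if a / base >= prune]


def n_isotope_combinations(counts: dict) -> int:
    n = 1
    for sym, c in counts.items():
        n *= len(ISOTOPES[sym]) ** c
    return n


# ---------------------------------------------------------------------------
# shared synthetic study
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def study():
    return generate_study(StudyConfig(seed=1))


@pytest.fixture(scope="session")
def merged_tables(study):
    return {mode: group_replicates(tabs) for mode, tabs in study.tables.items()}


@pytest.fixture(scope="session")
def annotations(study, merged_tables):
    out = []
    for table in merged_tables.values():
        out.extend(annotate_table(table, study.hierarchy))
    return out
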