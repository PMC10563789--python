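import numpy as np
import pytest

from ribostress.fixtures import generate_fixtures
from ribostress.reference import CompositeReference, generate_composite_reference, revcomp


@pytest.fixture(scope="session")
def small_ref() -> CompositeReference:
    return generate_composite_reference(
        n_parents=4, pseudos_per_parent=2, mrna_len=300, divergence_rate=0.05, seed=7
    )


@pytest.fixture(scope="session")
def fixtures():
    return generate_fixtures(seed=3)


def naive_locus_scan(seq: str, ref: CompositeReference) -> set[str]:
    """Brute-force both-strand substring scan over every locus (test oracle)."""
    hits = set()
    rc = revcomp(seq)
    for loc in ref.loci:
        s = ref.locus_seq(loc.locus_id)
        if seq in s or rc in s:
            hits.add(loc.locus_id)
    return hits


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """BH q-values straight from the definition: q(k) = min_{i>=k} m * p(i) / i."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q = np.empty(m)
    for pos, idx in enumerate(order):
        q[idx] = min(1.0, (m * p_sorted[pos:] / ranks[pos:]).min())
    return q
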