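import numpy as np
import pytest

from tenomech.simulate import CurveParams, simulate_curve


@pytest.fixture
def plain_curve():
    """Noise-free curve with no toe, no preconditioning: k=50, ultimate=100."""
    params = CurveParams(k_true=50.0, ultimate_load_true=100.0, toe_length=0.0,
                         noise_sd=0.0, precondition_cycles=0, seed=1)
    return simulate_curve(params)


@pytest.fixture
def toe_curve():
    """Noise-free curve with a 1 mm quadratic toe and preconditioning cycles."""
    params = CurveParams(k_true=40.0, toe_length=1.0, toe_exponent=2.0,
                         ultimate_load_true=100.0, noise_sd=0.0, seed=2)
    return simulate_curve(params)


@pytest.fixture
def noisy_curve():
    """Protocol-level noise (0.5 N), preconditioning included."""
    params = CurveParams(k_true=40.0, ultimate_load_true=150.0, noise_sd=0.5, seed=3)
    return simulate_curve(params)


def min_letters_bruteforce(labels, sig_pairs):
    """Smallest number of letters consistent with a significance pattern.

    Naive search over all families of label subsets: a subset is a valid
    letter column iff it contains no significant pair; a family is a valid
    assignment iff it covers every label and keeps every non-significant
    pair together in some column. Independent of the clique-based
    implementation.
    """
    import itertools

    labels = list(labels)
    sig = {frozenset(p) for p in sig_pairs}
    nonsig = [frozenset(p) for p in itertools.combinations(labels, 2)
              if frozenset(p) not in sig]
    columns = [frozenset(c) for r in range(1, len(labels) + 1)
               for c in itertools.combinations(labels, r)
               if not any(s <= frozenset(c) for s in sig)]
    for m in range(1, len(labels) + 1):
        for fam in itertools.combinations(columns, m):
            if set().union(*fam) != set(labels):
                continue
            if all(any(e <= c for c in fam) for e in nonsig):
                return m
    raise AssertionError("unreachable: singletons always form a valid family")


def count_strict_local_maxima(f: np.ndarray) -> int:
    interior = (f[1:-1] > f[:-2]) & (f[1:-1] >= f[2:])
    return int(interior.sum())
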