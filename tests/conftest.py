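import numpy as np
import pytest

from excitatory_perceptron import (
    AssociationStatistics,
    PatternSet,
    make_distribution,
    sample_patterns,
)


@pytest.fixture
def exp_dist():
    return make_distribution("exponential", 1.0)


@pytest.fixture
def exp_exp_patterns(exp_dist):
    """Small exponential/exponential association set (B = 1)."""
    return sample_patterns(exp_dist, exp_dist, 200, 0.3, seed=11)


def make_manual_patterns(inputs, targets, stats=None, alpha=None, seed=0):
    """Hand-built PatternSet for algebraic unit tests."""
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if stats is None:
        stats = AssociationStatistics(1.0, 1.0, 1.0, 1.0)
    if alpha is None:
        alpha = inputs.shape[0] / inputs.shape[1]
    return PatternSet(inputs=inputs, targets=targets, stats=stats, seed=seed, alpha=alpha)
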