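import numpy as np
import pytest

from tfcobind.motifs import BASES, PWM, PromoterSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_random_pwm(rng, width=6, tf_id="TF"):
    """Non-degenerate random PWM (Dirichlet rows)."""
    probs = rng.dirichlet(np.ones(4), size=width)
    probs = np.clip(probs, 1e-6, None)
    probs /= probs.sum(axis=1, keepdims=True)
    return PWM(tf_id, probs, pseudocount=0.0)


def make_consensus_pwm(word, tf_id="TF", dominance=0.91, rng=None):
    """Concentrated PWM with slightly varying per-position dominance so score
    distributions have no heavy ties."""
    idx = {b: i for i, b in enumerate(BASES)}
    width = len(word)
    probs = np.empty((width, 4))
    for i, b in enumerate(word):
        p = dominance if rng is None else rng.uniform(0.85, 0.96)
        probs[i, :] = (1 - p) / 3
        probs[i, idx[b]] = p
    return PWM(tf_id, probs, pseudocount=0.0)


def random_sequence(rng, length, gc=0.5, n_prob=0.0):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = [BASES[c] for c in codes]
    if n_prob > 0:
        for i in range(length):
            if rng.random() < n_prob:
                seq[i] = "N"
    return "".join(seq)


@pytest.fixture
def small_promoters(rng):
    return PromoterSet.from_sequences(
        {f"g{i}": random_sequence(rng, 80) for i in range(12)}
    )
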