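import numpy as np
import pytest

from beadbench.io_bead import BeadSummaryMatrix, ClassLabels, NegControlSummary


def make_matrix(signal, probe_ids=None, sample_ids=None, bead_se=None,
                neg_values=None, **kw):
    """Small BeadSummaryMatrix builder for tests."""
    signal = np.asarray(signal, dtype=float)
    p, s = signal.shape
    probe_ids = probe_ids or [f"P{i}" for i in range(p)]
    sample_ids = sample_ids or [f"S{j}" for j in range(s)]
    neg = {}
    if neg_values is not None:
        for j, sid in enumerate(sample_ids):
            vals = np.asarray(neg_values[j] if np.ndim(neg_values) > 1 else neg_values,
                              dtype=float)
            neg[sid] = NegControlSummary(
                count=vals.size, mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0, values=vals,
            )
    return BeadSummaryMatrix(probe_ids=probe_ids, sample_ids=sample_ids,
                             signal=signal, bead_se=bead_se, neg_control=neg, **kw)


def make_labels(sample_ids, n_control):
    """First n_control samples are controls, the rest tests."""
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-replicate warning
            return ClassLabels({
                s: ("control" if i < n_control else "test")
                for i, s in enumerate(sample_ids)
            })


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_group_matrix(rng):
    """20 probes x 6 samples with controls, 3 per group."""
    signal = rng.lognormal(7, 0.5, (20, 6))
    neg = rng.normal(100, 20, (6, 50))
    m = make_matrix(signal, neg_values=neg)
    labels = make_labels(m.sample_ids, 3)
    return m, labels
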