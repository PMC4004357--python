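from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import tifind as tf

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_te() -> tf.SeqRecord:
    """A 400 bp random element with unambiguous 17-bp termini."""
    return tf.random_te(length=400, seed=42)


@pytest.fixture(scope="session")
def toy_sig(toy_te) -> tf.TESignature:
    return tf.signature_from_te(toy_te)


@pytest.fixture(scope="session")
def small_sim(toy_te, toy_sig):
    """60 kb genome, 4 planted insertions (mixed orientation), 30x reads."""
    genome = tf.make_genome(2, [30_000, 30_000], seed=7)
    mutant, truth = tf.plant_insertions(
        genome, toy_te, n=4, tsd_len=5, frac_reverse=0.5, seed=9)
    reads = tf.generate_reads(mutant, coverage=30.0, seed=10)
    return dict(genome=genome, te=toy_te, sig=toy_sig, mutant=mutant,
                truth=truth, reads=reads)


@pytest.fixture(scope="session")
def recovery_sim(toy_te, toy_sig):
    """The headline parameter-recovery setting: 200 kb genome, 12 planted
    insertions of a 400 bp element with 5-bp TSDs in mixed orientations,
    error-free 100 bp paired reads at 30x coverage."""
    genome = tf.make_genome(2, [100_000, 100_000], seed=101)
    mutant, truth = tf.plant_insertions(
        genome, toy_te, n=12, tsd_len=5, frac_reverse=0.5, seed=103)
    reads = tf.generate_reads(mutant, read_len=100, coverage=30.0,
                              paired=True, error_rate=0.0, seed=104)
    calls = tf.run_extended(iter(reads), toy_sig, genome)
    groups = tf.run_basic(iter(reads), toy_sig, tsd_len=5)
    return dict(genome=genome, te=toy_te, sig=toy_sig, mutant=mutant,
                truth=truth, reads=reads, calls=calls, groups=groups)
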