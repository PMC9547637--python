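import numpy as np
import pytest

from seclink import default_config
from seclink.mpc import CountingBundle, Dealer, PartyRuntime, run_pair


@pytest.fixture(scope="session")
def cfg():
    return default_config()


def mpc_run(builder, seed=1):
    """Execute ``builder(rt) -> result`` as a two-party protocol.

    Performs the setup-phase tally pass (counting dealer stub), materialises
    exactly the tallied correlated randomness, runs the online pass and
    returns both parties' results.
    """

    def mk(party, bundle):
        def prog(ch):
            rt = PartyRuntime(party, ch, bundle,
                              np.random.default_rng([seed, party]))
            out = builder(rt)
            bundle.assert_exhausted()
            return out

        return prog

    tally0, tally1 = CountingBundle(), CountingBundle()
    run_pair(mk(0, tally0), mk(1, tally1))
    assert tally0.counts == tally1.counts
    b0, b1 = Dealer(seed + 9999).generate(tally0.counts)
    r0, r1, _ = run_pair(mk(0, b0), mk(1, b1))
    return r0, r1


@pytest.fixture
def two_party():
    return mpc_run
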