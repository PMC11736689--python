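import numpy as np
import pytest

from abfekit.core import KB_KCAL_MOL_K, ThermoContext, WorkRecord, WorkSet


@pytest.fixture
def ctx300() -> ThermoContext:
    return ThermoContext(300.0)


@pytest.fixture
def ctx_kt1() -> ThermoContext:
    """Thermodynamic context with kT exactly 1 kcal/mol."""
    return ThermoContext(1.0 / KB_KCAL_MOL_K)


def make_workset(wf, wr, replica_fwd=None, replica_rev=None, **kw) -> WorkSet:
    """Build a WorkSet from forward/reverse work arrays (default replica 1)."""
    wf = np.atleast_1d(np.asarray(wf, float))
    wr = np.atleast_1d(np.asarray(wr, float))
    rf = replica_fwd if replica_fwd is not None else [1] * wf.size
    rr = replica_rev if replica_rev is not None else [1] * wr.size
    records = tuple(
        [WorkRecord("forward", int(r), float(w)) for w, r in zip(wf, rf)]
        + [WorkRecord("reverse", int(r), float(w)) for w, r in zip(wr, rr)]
    )
    return WorkSet(records=records, **kw)
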