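import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import linprog

from fermenet import ToyProducerParams, figure1_net, make_toy_producer, table1_model


@pytest.fixture
def table1():
    return table1_model()


@pytest.fixture
def fig1():
    return figure1_net()


@pytest.fixture
def toy():
    """(params, cell model, chemostat spec) of the default toy producer."""
    params = ToyProducerParams()
    model, spec = make_toy_producer(params)
    return params, model, spec


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def direct_fba(model, rid, sense="max"):
    """Independent FBA oracle: plain LP over {S.v=0, L<=v<=U}, no FN, no unfolding."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    j = rxn_ids.index(rid)
    c = np.zeros(len(rxn_ids))
    c[j] = -1.0 if sense == "max" else 1.0
    bounds = [(r.lb, r.ub) for r in model.reactions]
    res = linprog(c, A_eq=sp.csr_matrix(S), b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    if res.status == 2:
        return None, "infeasible"
    if res.status == 3:
        return None, "unbounded"
    assert res.status == 0, res.message
    sign = -1.0 if sense == "max" else 1.0
    return sign * res.fun, "optimal"
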