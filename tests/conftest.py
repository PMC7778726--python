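"""Shared fixtures: published parameter sets, ODE and quadrature oracles,
and small study fixtures."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cortipk import (BET_POPULATION, DEX_POPULATION, Depot, build_design,
                     generate_study)
from cortipk.model import StructuralParams

_DEPOT_ORDER = (Depot.IM_PHOSPHATE, Depot.ORAL, Depot.IM_ACETATE)


def ode_concentration(params: StructuralParams, doses, times,
                      rtol=1e-11, atol=1e-13):
    """Independent oracle: adaptive integration of the structural ODEs
    (central and peripheral concentration plus three depot amounts, ug),
    with dose events applied as state jumps."""
    times = np.asarray(times, dtype=float)
    kas = [params.ka_im, params.ka_po,
           params.ka_ima if params.ka_ima is not None else 0.0]

    def rhs(t, y):
        cp, ct = y[0], y[1]
        inp = sum(ka * a for ka, a in zip(kas, y[2:]))
        dcp = (inp - (params.cl_f + params.cld_f) * cp
               + params.cld_f * ct) / params.vp_f
        dct = params.cld_f * (cp - ct) / params.vt_f
        return [dcp, dct] + [-ka * a for ka, a in zip(kas, y[2:])]

    events = sorted(doses, key=lambda d: d.time)
    y = np.zeros(5)
    t_now = 0.0
    out = np.zeros((times.size, 5))
    done = np.zeros(times.size, dtype=bool)
    boundaries = [d.time for d in events] + [float(times[-1]) + 1.0]
    ei = 0
    while ei <= len(events):
        t_next = boundaries[ei] if ei < len(events) else boundaries[-1]
        sel = (~done) & (times >= t_now) & (times < t_next)
        t_eval = times[sel]
        if t_next > t_now:
            sol = solve_ivp(rhs, (t_now, t_next), y, t_eval=t_eval,
                            rtol=rtol, atol=atol, method="LSODA")
            if t_eval.size:
                out[sel] = sol.y.T
                done[sel] = True
            y = solve_ivp(rhs, (t_now, t_next), y, rtol=rtol, atol=atol,
                          method="LSODA").y[:, -1]
        if ei < len(events):
            d = events[ei]
            frac = (d.bioavail_scale if d.bioavail_scale is not None
                    else params.depot_fraction(d.depot))
            y[2 + _DEPOT_ORDER.index(d.depot)] += d.amount * 1000.0 * frac
        t_now = t_next
        ei += 1
    # samples exactly at a dose time take the pre-dose state (closed form
    # contributes zero at tau = 0, so the two conventions agree)
    return out[:, 0], out[:, 1], out[:, 2:]


@pytest.fixture(scope="session")
def dex_params():
    return DEX_POPULATION.theta


@pytest.fixture(scope="session")
def bet_params():
    return BET_POPULATION.theta


@pytest.fixture(scope="session")
def dex_pop():
    return DEX_POPULATION


@pytest.fixture(scope="session")
def bet_pop():
    return BET_POPULATION


@pytest.fixture(scope="session")
def mini_design():
    return build_design(n_per_sequence=1)


@pytest.fixture(scope="session")
def mini_study(mini_design):
    return generate_study(design=mini_design, seed=42)


@pytest.fixture(scope="session")
def full_study():
    return generate_study(seed=7)


def random_structural(rng, with_acetate=False) -> StructuralParams:
    """A random physiologically plausible parameter draw (log-uniform)."""

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    kwargs = dict(
        cl_f=lu(1.0, 20.0), vp_f=lu(10.0, 200.0), cld_f=lu(0.05, 5.0),
        vt_f=lu(1.0, 50.0), ka_im=lu(0.05, 5.0), ka_po=lu(0.05, 5.0),
        fr=lu(0.3, 2.0))
    if with_acetate:
        kwargs.update(ka_ima=lu(0.002, 0.5), fra=lu(0.3, 1.5))
    return StructuralParams(**kwargs)
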