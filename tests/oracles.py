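"""Independent reference implementations used as test oracles.

Everything here is deliberately written without cablekit's solver or
channel machinery: plain textbook formulas integrated naively, plus a
brute-force tag-query evaluator. These stay independent of the code paths
they check.
"""

from __future__ import annotations

import math
import random

import numpy as np


def passive_step_response(t_ms, E_mV, G_uS, C_nF, I_nA, t_on_ms=0.0):
    """Closed-form RC charging: V(t) = E + (I/G)(1 - exp(-(t-t_on)/tau))."""
    t = np.asarray(t_ms, dtype=float)
    tau = C_nF / G_uS
    rel = np.maximum(t - t_on_ms, 0.0)
    return E_mV + (I_nA / G_uS) * (1.0 - np.exp(-rel / tau))


def hh_forward_euler_spike_count(
    i_density_uA_cm2: float,
    stim_dur_ms: float = 100.0,
    stim_delay_ms: float = 10.0,
    total_ms: float = 120.0,
    dt_ms: float = 0.0005,
    v0_mV: float = -65.0,
    threshold_mV: float = 0.0,
) -> int:
    """Forward-Euler integration of the textbook squid-axon equations."""

    def am(v):
        return 0.1 * (v + 40) / (1 - math.exp(-(v + 40) / 10)) \
            if abs(v + 40) > 1e-9 else 1.0

    def bm(v):
        return 4.0 * math.exp(-(v + 65) / 18)

    def ah(v):
        return 0.07 * math.exp(-(v + 65) / 20)

    def bh(v):
        return 1.0 / (1 + math.exp(-(v + 35) / 10))

    def an(v):
        return 0.01 * (v + 55) / (1 - math.exp(-(v + 55) / 10)) \
            if abs(v + 55) > 1e-9 else 0.1

    def bn(v):
        return 0.125 * math.exp(-(v + 65) / 80)

    cm, gna, gk, gl = 1.0, 120.0, 36.0, 0.3
    ena, ek, el = 50.0, -77.0, -54.3
    v = v0_mV
    m = am(v) / (am(v) + bm(v))
    h = ah(v) / (ah(v) + bh(v))
    n = an(v) / (an(v) + bn(v))
    spikes = 0
    nsteps = int(round(total_ms / dt_ms))
    for k in range(nsteps):
        t = k * dt_ms
        i_inj = (i_density_uA_cm2
                 if stim_delay_ms <= t < stim_delay_ms + stim_dur_ms else 0.0)
        ina = gna * m ** 3 * h * (v - ena)
        ik = gk * n ** 4 * (v - ek)
        il = gl * (v - el)
        dv = (-ina - ik - il + i_inj) / cm
        m += dt_ms * (am(v) * (1 - m) - bm(v) * m)
        h += dt_ms * (ah(v) * (1 - h) - bh(v) * h)
        n += dt_ms * (an(v) * (1 - n) - bn(v) * n)
        prev = v
        v += dt_ms * dv
        if prev < threshold_mV <= v:
            spikes += 1
    return spikes


# -- brute-force tag query oracle ------------------------------------------
# Queries are plain nested tuples:
#   ("ALL", [tags]) | ("ANY", [tags]) | ("NOT", q) | ("AND", a, b) | ("OR", a, b)

def eval_query_tuple(q, tags) -> bool:
    folded = {t.lower() for t in tags}
    op = q[0]
    if op == "ALL":
        return all(t.lower() in folded for t in q[1])
    if op == "ANY":
        return any(t.lower() in folded for t in q[1])
    if op == "NOT":
        return not eval_query_tuple(q[1], tags)
    if op == "AND":
        return eval_query_tuple(q[1], tags) and eval_query_tuple(q[2], tags)
    if op == "OR":
        return eval_query_tuple(q[1], tags) or eval_query_tuple(q[2], tags)
    raise ValueError(op)


def query_tuple_to_text(q) -> str:
    op = q[0]
    if op in ("ALL", "ANY"):
        return f"{op}{{{','.join(q[1])}}}"
    if op == "NOT":
        return f"NOT ({query_tuple_to_text(q[1])})"
    return (f"({query_tuple_to_text(q[1])} {op} "
            f"{query_tuple_to_text(q[2])})")


_TAG_POOL = ["Voltage", "Current", "cell1", "cell2", "NMDA", "AMPA",
             "SYNAPTIC", "loc:soma", "PRE:cell1", "POST:cell2", "x_1"]


def random_query_tuple(rng: random.Random, depth: int = 0):
    if depth >= 4 or rng.random() < 0.4:
        kind = rng.choice(["ALL", "ANY"])
        k = rng.randint(1, 3)
        return (kind, rng.sample(_TAG_POOL, k))
    op = rng.choice(["NOT", "AND", "OR"])
    if op == "NOT":
        return ("NOT", random_query_tuple(rng, depth + 1))
    return (op, random_query_tuple(rng, depth + 1),
            random_query_tuple(rng, depth + 1))


def random_tag_set(rng: random.Random) -> set[str]:
    k = rng.randint(0, 5)
    tags = set(rng.sample(_TAG_POOL, k))
    if rng.random() < 0.5:
        tags = {t.upper() if rng.random() < 0.5 else t for t in tags}
    return tags
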