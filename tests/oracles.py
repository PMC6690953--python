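"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the partial correlation
comes from the inverse of the joint correlation matrix, and the path search
from exhaustive enumeration of alternating metabolite-reaction sequences.
"""

from __future__ import annotations

import numpy as np


def partial_corr_inverse_matrix(x, y, covars) -> float:
    """r_xy.z = -Omega_xy / sqrt(Omega_xx * Omega_yy), Omega = inv(corr)."""
    M = np.column_stack([x, y, covars])
    C = np.corrcoef(M, rowvar=False)
    omega = np.linalg.inv(C)
    return float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))


def enumerate_paths(net, a: str, b: str, max_steps: int):
    """All alternating paths a -> ... -> b with <= max_steps reactions.

    Same semantics as the implementation is supposed to honour: direction
    respected unless the reaction is reversible, hubs never traversed as
    intermediates, the target matched against substrates-and-products of any
    reaction reached, no metabolite revisited.  Returns a list of step counts
    (one per distinct path found).
    """
    if a == b:
        return [0]
    found: list[int] = []

    def entries(met):
        out = []
        for rid in sorted(net.reactions):
            rxn = net.reactions[rid]
            if met in rxn.substrates or (rxn.reversible and met in rxn.products):
                out.append(rid)
        return out

    def outputs(rid, met):
        rxn = net.reactions[rid]
        if met in rxn.substrates:
            out = set(rxn.products)
            if rxn.reversible:
                out |= rxn.substrates
        else:
            out = set(rxn.substrates)
        out.discard(met)
        return out

    def walk(met, steps, visited):
        if steps >= max_steps:
            return
        for rid in entries(met):
            if b in net.reactions[rid].participants:
                found.append(steps + 1)
            for nxt in outputs(rid, met):
                if nxt in visited or nxt in net.hubs:
                    continue
                walk(nxt, steps + 1, visited | {nxt})

    walk(a, 0, {a})
    return found
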