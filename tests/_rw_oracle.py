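"""Independent plain Rescorla-Wagner oracle used to cross-check the engine.

Deliberately written in a different style from the package (dict state,
per-unit Python floats, no arrays, no sign-dependent weighting) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations


def plain_rw_trajectory(trial_units, reinforced_flags, alpha_of, lam=1.0):
    """Run the symmetric delta rule over a whole schedule.

    Parameters
    ----------
    trial_units : list of tuple of str
        Active units per trial, in order.
    reinforced_flags : list of bool
    alpha_of : callable unit -> effective learning rate (alpha*beta)
    lam : asymptote

    Returns (predictions_before_update, final_V_dict).
    """
    V: dict[str, float] = {}
    preds = []
    for units, r in zip(trial_units, reinforced_flags):
        v_sum = 0.0
        for u in units:
            v_sum += V.get(u, 0.0)
        preds.append(v_sum)
        delta = (lam if r else 0.0) - v_sum
        for u in units:
            V[u] = V.get(u, 0.0) + alpha_of(u) * delta
    return preds, V
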