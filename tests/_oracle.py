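"""Independent naive oracles used across the test suite.

The likelihood oracle composes the public single-step update
functions in a plain Python loop with ``math.log`` — no shared code
with the vectorised likelihood engine beyond the update rules
themselves being the published equations.
"""

import math

from prlflex.models import apply_update, choice_prob, init_state


def loop_loglik(data, model_id, params: dict) -> float:
    """Trial-by-trial log-likelihood via the scalar update functions."""
    state = init_state(model_id)
    total = 0.0
    for t in range(data.n_trials):
        p_a = choice_prob(state, params["beta"], params["alpha"])
        p = p_a if data.choices[t] == 0 else 1.0 - p_a
        total += math.log(max(p, 1e-12))
        state = apply_update(model_id, state, int(data.choices[t]), float(data.outcomes[t]), params)
    return total


def binomial_tail_ge(k: int, n: int) -> float:
    """P(X >= k) for X ~ Binomial(n, 1/2), by direct summation."""
    return sum(math.comb(n, i) for i in range(k, n + 1)) / 2**n
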