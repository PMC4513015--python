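"""Generic accept-reject sampling.

A proposal X* and U ~ Uniform(0, 1) are drawn repeatedly until
U <= accept_prob(X*); the accepted value is then a draw from the density
proportional to proposal-density x accept_prob.  Proposal and uniform draws
consume the same seeded stream in a fixed order (proposal first), so runs are
exactly reproducible given (seed, data, configuration).

When ``max_attempts`` is exhausted the configured fallback applies:
``"strict"`` raises; ``"best-candidate"`` (default) returns the proposal with
the highest acceptance probability seen and logs a warning, so a single
pathological subject does not abort a long multiple-imputation run.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["RejectionError", "rejection_sample", "rejection_sample_batch"]

logger = logging.getLogger(__name__)

DEFAULT_MAX_ATTEMPTS = 10_000


class RejectionError(RuntimeError):
    """Raised in strict mode when max_attempts is exhausted."""


def rejection_sample(propose, accept_prob, rng, max_attempts: int = DEFAULT_MAX_ATTEMPTS,
                     fallback: str = "best-candidate", label: str = ""):
    """Draw one value; returns ``(value, attempts_used)``.

    ``propose(rng)`` generates a candidate and ``accept_prob(candidate)`` maps
    it to [0, 1].
    """
    best_p, best_x = -np.inf, None
    for attempt in range(1, max_attempts + 1):
        x = propose(rng)
        p = accept_prob(x)
        u = rng.random()
        if p > best_p:
            best_p, best_x = p, x
        if u <= p:
            return x, attempt
    if fallback == "strict":
        raise RejectionError(f"no acceptance within {max_attempts} attempts {label}")
    logger.warning(
        "rejection sampler fell back to best candidate (p=%.3g) after %d attempts %s",
        best_p, max_attempts, label,
    )
    return best_x, max_attempts


def rejection_sample_batch(propose, accept_prob, n: int, rng,
                           max_attempts: int = DEFAULT_MAX_ATTEMPTS,
                           fallback: str = "best-candidate", label: str = ""):
    """Vectorised accept-reject over ``n`` independent targets.

    ``propose(idx, rng)`` returns one candidate per entry of ``idx`` (indices
    into 0..n-1, possibly with repeats); ``accept_prob(idx, candidates)``
    their acceptance probabilities.  Returns ``(values, attempts,
    n_fallback)`` where ``attempts[i]`` is the number of proposals consumed
    for target ``i``.

    Proposals are drawn in geometrically growing blocks per still-active
    target and scanned in order for the first acceptance, which is
    sequentially equivalent to one-at-a-time rejection sampling but keeps the
    loop count logarithmic in ``max_attempts``.
    """
    values = np.empty(n)
    attempts = np.zeros(n, dtype=np.int64)
    best_p = np.full(n, -np.inf)
    best_x = np.full(n, np.nan)
    active = np.arange(n)
    used = 0
    block = 1
    while active.size and used < max_attempts:
        k = min(block, max_attempts - used)
        a = active.size
        rep_idx = np.repeat(active, k)
        cand = np.asarray(propose(rep_idx, rng), dtype=float).reshape(a, k)
        p = np.asarray(accept_prob(rep_idx, cand.ravel()), dtype=float).reshape(a, k)
        u = rng.random((a, k))
        acc = u <= p
        rows = np.arange(a)
        pmax_col = p.argmax(axis=1)
        pmax = p[rows, pmax_col]
        better = pmax > best_p[active]
        best_p[active[better]] = pmax[better]
        best_x[active[better]] = cand[rows, pmax_col][better]
        any_acc = acc.any(axis=1)
        first = acc.argmax(axis=1)
        hit = active[any_acc]
        values[hit] = cand[any_acc, first[any_acc]]
        attempts[hit] = used + first[any_acc] + 1
        active = active[~any_acc]
        used += k
        block = min(block * 2, 1024)
    if active.size == 0:
        return values, attempts, 0
    if fallback == "strict":
        raise RejectionError(
            f"{active.size} target(s) not accepted within {max_attempts} attempts {label}"
        )
    logger.warning(
        "rejection sampler fell back to best candidate for %d target(s) %s",
        active.size, label,
    )
    values[active] = best_x[active]
    attempts[active] = max_attempts
    return values, attempts, int(active.size)
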