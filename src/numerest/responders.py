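"""Simulated responders that fill in the ``response`` column of a session.

Four responders cover the modelling spectrum used as test baselines:

* ``ideal_observer`` — the CRP-mixture Bayes estimator (particle filter),
  plus Gaussian response noise;
* ``exemplar`` — the all-singletons (alpha -> infinity) limit of the same
  machinery;
* ``color_prototype`` — running mean of previous true counts *of the same
  color* within the block (a Huttenlocher-style color-prototype heuristic);
* ``global_mean`` — running mean of all previous true counts in the block.

Responses are generated block-sequentially with feedback equal to the true
count, rounded to the nearest integer, and (by default) clamped to the
two-digit keyboard range [10, 99].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .crp import Hyperparameters
from .inference import run_session

__all__ = ["ResponderSpec", "simulate_responses", "EXEMPLAR_ALPHA"]

#: concentration used to realize the exemplar (all-singletons) limit
EXEMPLAR_ALPHA = 1e8

_RESPONDERS = ("ideal_observer", "exemplar", "color_prototype", "global_mean")


@dataclass(frozen=True)
class ResponderSpec:
    """Which responder to simulate, and with what parameters."""

    kind: str = "ideal_observer"
    hp: Hyperparameters = field(default_factory=Hyperparameters)
    response_noise_sd: float = 2.0
    n_particles: int = 300
    clamp_range: Optional[tuple] = (10, 99)

    def __post_init__(self):
        if self.kind not in _RESPONDERS:
            raise ValueError(
                f"unknown responder {self.kind!r}; expected one of {_RESPONDERS}")
        if self.response_noise_sd < 0:
            raise ValueError("response_noise_sd must be >= 0")


def _heuristic_estimates(trials, kind: str, default: float) -> list:
    """Block-wise running-mean heuristics (global or per-color)."""
    est = []
    history: dict = {}
    current_block = None
    for t in trials:
        if t.block_index != current_block:
            history = {}
            current_block = t.block_index
        key = t.color if kind == "color_prototype" else "all"
        prev = history.get(key, [])
        est.append(float(np.mean(prev)) if prev else default)
        history.setdefault(key, []).append(t.true_count)
    return est


def simulate_responses(trials, responder: ResponderSpec, rng=None) -> list:
    """Return a copy of ``trials`` with integer responses on all valid trials.

    Deterministic given the seed.  Invalid trials (human timeouts) are left
    without a response; simulated responders never time out.
    """
    trials = [t for t in trials]
    rng = np.random.default_rng(rng)
    if responder.kind == "ideal_observer":
        preds, _ = run_session(trials, responder.hp,
                               n_particles=responder.n_particles, rng=rng)
        estimates = [p.estimate for p in preds]
    elif responder.kind == "exemplar":
        hp = responder.hp.replace(alpha=EXEMPLAR_ALPHA)
        preds, _ = run_session(trials, hp, n_particles=1, rng=rng,
                               force_singletons=True)
        estimates = [p.estimate for p in preds]
    else:
        # first trial of a block has no history: fall back to the prior mean
        estimates = _heuristic_estimates(trials, responder.kind,
                                         default=responder.hp.mu0)
    noise = rng.normal(0.0, responder.response_noise_sd, size=len(trials)) \
        if responder.response_noise_sd > 0 else np.zeros(len(trials))
    out = []
    for t, est, eps in zip(trials, estimates, noise):
        r = t
        if t.valid:
            resp = int(np.rint(est + eps))
            if responder.clamp_range is not None:
                lo, hi = responder.clamp_range
                resp = int(np.clip(resp, lo, hi))
            r = type(t)(**{**t.__dict__, "response": resp})
        out.append(r)
    return out
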