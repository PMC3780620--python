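"""Posterior inference over trial partitions and trial-wise count estimates.

Two inference routes are provided over the same conjugate kernel
(:mod:`numerest.crp`):

* :func:`enumerate_posterior` / :func:`enumerate_session` — exact summation
  over all set partitions (Bell-number bounded, ``t <= 12``), used as the
  in-package oracle;
* :class:`ParticleSet` / :func:`run_session` — a Rao-Blackwellized sequential
  importance resampling filter: each particle carries a partition hypothesis
  ``z_{1:t}`` with category parameters integrated out, proposes ``z_t`` from
  its conditional posterior after feedback, reweights by the marginal
  likelihood of the new ``(x_t, c_t)``, and resamples systematically when the
  effective sample size drops below half the particle count.

The trial-wise estimate (the Bayes-optimal posterior mean of the true count
given the noisy sensory signal ``y_t``) is computed *before* feedback.  Per
particle, each candidate category ``k`` (every occupied one plus a new one)
receives weight

    w_k  ∝  CRP(k) * P(c_t | k) * N(y_t; mu_hat_k, v_k + sigma_y^2)

and contributes the precision-weighted mean ``m_k = (v_k y_t +
sigma_y^2 mu_hat_k) / (v_k + sigma_y^2)``, where ``v_k`` is the variance of a
Gaussian moment-matched to the category's Student-t count predictive
(``v = beta * nu/(nu-2)`` for ``nu > 2``, falling back to ``beta`` otherwise).
This realizes the "mixture of Gaussians" estimator; the t->Gaussian moment
match makes the convolution with sensory noise closed-form and is applied
identically on the enumeration route, so particle-filter error can be
measured against enumeration directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from . import crp
from .crp import Hyperparameters, CategoryStats


def _row_logsumexp(a: np.ndarray) -> np.ndarray:
    """logsumexp along axis 1; rows must contain at least one finite entry."""
    m = np.max(a, axis=1, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=1, keepdims=True)))[:, 0]

__all__ = [
    "TrialPrediction",
    "ParticleSet",
    "particle_filter_step",
    "estimate_count",
    "run_session",
    "enumerate_posterior",
    "enumerate_session",
    "single_category_estimates",
    "BlockSummary",
]

_MAX_ENUM_TRIALS = 12


@dataclass
class TrialPrediction:
    """Pre-feedback estimate for one trial.

    ``category_post`` is the aggregated posterior over candidate categories
    (existing ones first, the would-be new category last).
    ``expected_n_categories`` is the posterior mean number of occupied
    categories among the *previous* trials of the block.
    """

    estimate: float
    category_post: np.ndarray
    expected_n_categories: float


@dataclass
class BlockSummary:
    """End-of-block posterior summaries of the category structure."""

    block_index: int
    expected_n_categories: float
    modal_n_categories: int


def _moment_matched_var(a: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Variance of a Gaussian moment-matched to a t with ``2a`` dof and squared
    scale ``beta``; falls back to ``beta`` when the variance is undefined."""
    nu = 2.0 * a
    return np.where(nu > 2.0, beta * nu / np.maximum(nu - 2.0, 1e-12), beta)


class ParticleSet:
    """Vectorized set of Rao-Blackwellized particles over one block's partition.

    All particles track the same trial stream, so sufficient statistics live
    in dense ``(n_particles, n_slots)`` arrays; slot ``n_cat[p]`` of particle
    ``p`` plays the role of the (empty) new category.
    """

    def __init__(self, hp: Hyperparameters, n_particles: int, max_trials: int,
                 force_singletons: bool = False):
        self.hp = hp
        P, K = int(n_particles), int(max_trials) + 1
        if P < 1:
            raise ValueError("n_particles must be >= 1")
        self.n_particles, self.n_slots = P, K
        self.M = np.zeros((P, K))
        self.Ncol = np.zeros((P, K, hp.n_colors))
        self.mean = np.zeros((P, K))
        self.sse = np.zeros((P, K))
        self.n_cat = np.zeros(P, dtype=int)
        self.log_w = np.zeros(P)
        self.t = 0  # trials observed
        self.force_singletons = force_singletons
        self._cache = None
        # per-M tables for the Student-t predictive (df = M + a0): the
        # normalization constant and the tail exponent, indexed by M
        Ms = np.arange(K + 1, dtype=float)
        df = Ms + hp.a0
        self._t_const = (gammaln((df + 1.0) / 2.0) - gammaln(df / 2.0)
                         - 0.5 * np.log(df * math.pi))
        self._t_expo = (df + 1.0) / 2.0
        self._t_df = df

    # -- internals ---------------------------------------------------------

    def _slot_scores(self, c: int):
        """Per-slot log CRP prior + log color predictive + posterior params."""
        if self._cache is not None and self._cache[0] == (self.t, c):
            return self._cache[1]
        hp = self.hp
        if not 1 <= c <= hp.n_colors:
            raise ValueError(f"color {c} out of range 1..{hp.n_colors}")
        slot = np.arange(self.n_slots)[None, :]
        is_new = slot == self.n_cat[:, None]
        valid = slot <= self.n_cat[:, None]
        if self.t == 0:
            log_prior = np.where(is_new, 0.0, -np.inf)
        else:
            num = np.where(is_new, hp.alpha, self.M)
            with np.errstate(divide="ignore"):
                log_prior = np.log(num) - math.log(self.t + hp.alpha)
        log_prior = np.where(valid, log_prior, -np.inf)
        colorp = (hp.lam + self.Ncol[:, :, c - 1]) / (hp.n_colors * hp.lam + self.M)
        pp = crp.posterior_params(self.M, self.mean, self.sse, hp)
        out = (log_prior, np.log(colorp), pp, valid)
        self._cache = ((self.t, c), out)
        return out

    def weights(self) -> np.ndarray:
        """Normalized particle weights."""
        w = np.exp(self.log_w - self.log_w.max())
        return w / w.sum()

    # -- prediction --------------------------------------------------------

    def predict(self, y: float, c: int) -> TrialPrediction:
        """Bayes estimate of the true count from sensory signal ``y`` and
        color ``c``, before feedback."""
        if not np.isfinite(y):
            raise ValueError("y must be finite")
        hp = self.hp
        log_prior, log_colorp, pp, valid = self._slot_scores(c)
        v = _moment_matched_var(pp.a, pp.beta)
        sy2 = hp.sigma_y ** 2
        tot = v + sy2
        log_like = -0.5 * (np.log(2.0 * math.pi * tot) + (y - pp.mu_hat) ** 2 / tot)
        scores = np.where(valid, log_prior + log_colorp + log_like, -np.inf)
        lse = _row_logsumexp(scores)[:, None]
        wk = np.exp(scores - lse)
        m = (v * y + sy2 * pp.mu_hat) / tot
        est_p = np.sum(wk * m, axis=1)
        W = self.weights()
        estimate = float(np.sum(W * est_p))
        # aggregate category posterior: existing slots first, "new" last
        kmax = int(self.n_cat.max())
        post = np.zeros(kmax + 1)
        rows = np.arange(self.n_particles)
        new_p = wk[rows, self.n_cat]
        old = wk[:, :kmax].copy()
        old[np.arange(kmax)[None, :] >= self.n_cat[:, None]] = 0.0
        post[:kmax] = W @ old
        post[-1] = float(np.sum(W * new_p))
        return TrialPrediction(
            estimate=estimate,
            category_post=post,
            expected_n_categories=float(np.sum(W * self.n_cat)),
        )

    # -- update ------------------------------------------------------------

    def observe(self, x: float, c: int, rng: np.random.Generator) -> None:
        """Incorporate feedback ``(x, c)``: sample ``z_t``, reweight, resample."""
        if not np.isfinite(x):
            raise ValueError("x must be finite")
        log_prior, log_colorp, pp, valid = self._slot_scores(c)
        # Student-t logpdf via the per-M tables (equivalent to
        # crp.student_t_logpdf with df = M + a0, squared scale beta)
        Mi = self.M.astype(np.intp)
        df = self._t_df[Mi]
        z2 = (x - pp.mu_hat) ** 2 / pp.beta
        log_like = (self._t_const[Mi] - 0.5 * np.log(pp.beta)
                    - self._t_expo[Mi] * np.log1p(z2 / df))
        scores = np.where(valid, log_prior + log_colorp + log_like, -np.inf)
        lse = _row_logsumexp(scores)
        if not np.all(np.isfinite(lse)):
            raise FloatingPointError(
                "all candidate weights underflowed for some particle; "
                "scores are already computed in log space — check hyperparameters")
        self.log_w += lse
        rows = np.arange(self.n_particles)
        if self.force_singletons:
            choice = self.n_cat.copy()
        else:
            gumb = rng.gumbel(size=scores.shape)
            choice = np.argmax(scores + gumb, axis=1)
        # Welford update of the chosen slot
        self.Ncol[rows, choice, c - 1] += 1
        self.M[rows, choice] += 1
        delta = x - self.mean[rows, choice]
        self.mean[rows, choice] += delta / self.M[rows, choice]
        self.sse[rows, choice] += delta * (x - self.mean[rows, choice])
        self.n_cat += (choice == self.n_cat)
        self.t += 1
        self._cache = None
        self._maybe_resample(rng)

    def _maybe_resample(self, rng: np.random.Generator) -> None:
        W = self.weights()
        ess = 1.0 / np.sum(W ** 2)
        if ess >= self.n_particles / 2.0 or self.n_particles == 1:
            return
        pos = (rng.random() + np.arange(self.n_particles)) / self.n_particles
        idx = np.searchsorted(np.cumsum(W), pos)
        idx = np.clip(idx, 0, self.n_particles - 1)
        for name in ("M", "Ncol", "mean", "sse", "n_cat"):
            setattr(self, name, getattr(self, name)[idx])
        self.log_w = np.zeros(self.n_particles)
        self._cache = None

    # -- summaries ---------------------------------------------------------

    def expected_n_categories(self) -> float:
        return float(np.sum(self.weights() * self.n_cat))

    def modal_n_categories(self) -> int:
        W = self.weights()
        counts = np.bincount(self.n_cat, weights=W)
        return int(np.argmax(counts))


def particle_filter_step(particles: ParticleSet, x, c: int, y: float,
                         rng) -> tuple:
    """One filter step: predict from ``(y, c)``, then (if ``x`` is given)
    assimilate the feedback.  Returns ``(particles, TrialPrediction)``."""
    rng = np.random.default_rng(rng)
    pred = particles.predict(y, c)
    if x is not None:
        particles.observe(x, c, rng)
    return particles, pred


def estimate_count(particles: ParticleSet, y: float, c: int,
                   hp: Hyperparameters | None = None) -> TrialPrediction:
    """Pre-feedback Bayes estimate from the current particle set."""
    if hp is not None and hp is not particles.hp:
        raise ValueError("hyperparameters do not match the particle set")
    return particles.predict(y, c)


def _check_sorted(trials) -> None:
    keys = [(t.block_index, t.trial_index_in_block) for t in trials]
    if keys != sorted(keys):
        raise ValueError("trials must be sorted by presentation order "
                         "(block_index, trial_index_in_block)")


def run_session(trials, hp: Hyperparameters, n_particles: int = 1000,
                rng=None, reset_per_block: bool = True,
                force_singletons: bool = False):
    """Run the filter over a full session with ``y_t = x_t``.

    Returns ``(predictions, block_summaries)``: one :class:`TrialPrediction`
    per trial (in order) and one :class:`BlockSummary` per block.  Particles
    are re-initialized at block boundaries when ``reset_per_block`` (prior
    beliefs are per-block), which also makes a block's predictions invariant
    to the ordering of earlier blocks.
    """
    trials = list(trials)
    if not trials:
        return [], []
    _check_sorted(trials)
    rng = np.random.default_rng(rng)
    # each block gets its own substream keyed by block index, so that (with
    # per-block resets) a block's predictions do not depend on which other
    # blocks were presented before it
    base_seed = int(rng.integers(0, 2 ** 31))
    blocks: dict[int, list] = {}
    for t in trials:
        blocks.setdefault(t.block_index, []).append(t)
    preds: list[TrialPrediction] = []
    summaries: list[BlockSummary] = []
    ps = None
    block_rng = rng
    if not reset_per_block:
        ps = ParticleSet(hp, n_particles, len(trials), force_singletons)
    for b in sorted(blocks):
        if reset_per_block:
            ps = ParticleSet(hp, n_particles, len(blocks[b]), force_singletons)
            block_rng = np.random.default_rng([base_seed, int(b)])
        for t in blocks[b]:
            x = float(t.true_count)
            _, pred = particle_filter_step(ps, x, t.color, x, block_rng)
            preds.append(pred)
        summaries.append(BlockSummary(
            block_index=b,
            expected_n_categories=ps.expected_n_categories(),
            modal_n_categories=ps.modal_n_categories()))
    return preds, summaries


# ---------------------------------------------------------------------------
# exact enumeration (oracle route)

def _partition_states(observations, hp: Hyperparameters, predict: bool):
    """Sequentially expand all partitions, optionally emitting predictions.

    States are ``(rgs, categories, logp)`` where ``rgs`` is the restricted
    growth string of the partition and ``logp`` the unnormalized log joint of
    (partition, data).  Written with the scalar :mod:`numerest.crp` API so it
    shares no array bookkeeping with the particle filter.
    """
    states = [((), [], 0.0)]
    preds = []
    sy2 = hp.sigma_y ** 2
    for (x, c) in observations:
        if predict:
            logw = np.array([s[2] for s in states])
            logw -= logsumexp(logw)
            est = 0.0
            for (rgs, cats, _), lw in zip(states, logw):
                prior = crp.crp_prior([s.M for s in cats], hp.alpha)
                num = 0.0
                den = 0.0
                for k, pk in enumerate(prior):
                    if pk == 0.0:
                        continue
                    st = cats[k] if k < len(cats) else CategoryStats(hp.n_colors)
                    pp = crp.posterior_params_stats(st, hp)
                    v = float(_moment_matched_var(np.asarray(pp.a),
                                                  np.asarray(pp.beta)))
                    tot = v + sy2
                    like = math.exp(-0.5 * (math.log(2 * math.pi * tot)
                                            + (x - pp.mu_hat) ** 2 / tot))
                    wk = pk * crp.color_predictive(st, c, hp) * like
                    m = (v * x + sy2 * pp.mu_hat) / tot
                    num += wk * m
                    den += wk
                est += math.exp(lw) * (num / den)
            exp_k = float(np.sum(np.exp(logw)
                                 * np.array([len(s[1]) for s in states])))
            preds.append((est, exp_k))
        new_states = []
        for (rgs, cats, logp) in states:
            prior = crp.crp_prior([s.M for s in cats], hp.alpha)
            for k, pk in enumerate(prior):
                if pk == 0.0:
                    continue
                st = cats[k] if k < len(cats) else CategoryStats(hp.n_colors)
                lp = (logp + math.log(pk)
                      + math.log(crp.color_predictive(st, c, hp))
                      + float(crp.count_predictive_logpdf(x, st, hp)))
                new_cats = [s for s in cats]
                if k < len(cats):
                    new_cats[k] = crp.update_stats(st, x, c)
                else:
                    new_cats.append(crp.update_stats(st, x, c))
                new_states.append((rgs + (k,), new_cats, lp))
        states = new_states
    return states, preds


def enumerate_posterior(observations, hp: Hyperparameters) -> dict:
    """Exact posterior over set partitions of ``observations = [(x, c), ...]``.

    Returns a dict mapping restricted-growth-string tuples to probabilities
    (summing to 1).  Guarded to ``t <= 12`` (Bell-number growth).
    """
    observations = list(observations)
    t = len(observations)
    if t == 0:
        raise ValueError("need at least one observation")
    if t > _MAX_ENUM_TRIALS:
        raise RuntimeError(
            f"exact enumeration limited to t <= {_MAX_ENUM_TRIALS} trials "
            f"(got {t}); use the particle filter")
    states, _ = _partition_states(observations, hp, predict=False)
    logps = np.array([s[2] for s in states])
    probs = np.exp(logps - logsumexp(logps))
    probs /= probs.sum()
    return {s[0]: float(p) for s, p in zip(states, probs)}


def enumerate_session(observations, hp: Hyperparameters):
    """Exact-filter counterpart of :func:`run_session` on one short block.

    Returns ``(estimates, expected_k_per_trial, expected_k_final)`` where the
    per-trial quantities mirror the particle filter's pre-feedback prediction
    (with ``y_t = x_t``) and ``expected_k_final`` is the posterior mean number
    of categories after the last trial.
    """
    observations = list(observations)
    if len(observations) > _MAX_ENUM_TRIALS:
        raise RuntimeError(f"exact enumeration limited to t <= {_MAX_ENUM_TRIALS}")
    states, preds = _partition_states(observations, hp, predict=True)
    logps = np.array([s[2] for s in states])
    w = np.exp(logps - logsumexp(logps))
    w /= w.sum()
    ks = np.array([len(s[1]) for s in states])
    estimates = [p[0] for p in preds]
    exp_k_per_trial = [p[1] for p in preds]
    return estimates, exp_k_per_trial, float(np.sum(w * ks))


def single_category_estimates(observations, hp: Hyperparameters):
    """Analytic estimator assuming a single category (the ``alpha -> 0``
    limit): all history pooled into one set of conjugate statistics."""
    st = CategoryStats(hp.n_colors)
    sy2 = hp.sigma_y ** 2
    out = []
    for (x, c) in observations:
        pp = crp.posterior_params_stats(st, hp)
        v = float(_moment_matched_var(np.asarray(pp.a), np.asarray(pp.beta)))
        out.append((v * x + sy2 * pp.mu_hat) / (v + sy2))
        st = crp.update_stats(st, x, c)
    return out
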