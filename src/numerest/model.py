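"""Per-subject model fitting: the rational CRP observer vs. the exemplar limit.

The modelling objects follow the Model / Results convention: an
:class:`ObserverModel` is built from one subject's trials and ``fit()``
returns an :class:`ObserverResults` carrying the estimates, fit diagnostics
and a ``summary()`` table.

Fitting conventions
-------------------
Responses and true counts are recentered by subtracting the subject's mean
true count over valid trials, so the prior mean is fixed at ``mu0 = 0``;
``lam = 1`` and ``b0 = 10`` are also held fixed.  The free parameters are
``(alpha, a0, eta0, sigma_y)`` for the rational model and ``(a0, eta0,
sigma_y)`` for the exemplar model (the exemplar is the same machinery with
assignments forced all-singletons and the concentration pinned to a huge
value, so the rational model nests it exactly).  The objective is the mean
squared error between the filter's pre-feedback predictions and the
subject's (recentered) estimates, minimized by bounded Nelder-Mead from
several quasi-random restarts; every evaluation reuses the same filter seed
(common random numbers), making the objective — and hence the whole fit —
deterministic given the seed.

Model comparison uses the Gaussian maximum-likelihood plug-in
``BIC = n ln(mse) + p ln(n)`` (shared additive constants dropped) and the
BIC approximation to the log Bayes factor, ``log BF = (BIC_exemplar −
BIC_rational)/2``; positive values favor the rational model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .crp import Hyperparameters
from .inference import run_session
from .responders import EXEMPLAR_ALPHA

__all__ = [
    "FitConfig", "ObserverModel", "ObserverResults",
    "recenter", "fit_subject", "compare_models", "count_categories",
    "FitFailure",
]

_N_PARAMS = {"rational": 4, "exemplar": 3}


class FitFailure(RuntimeError):
    """All optimizer restarts returned a non-finite objective."""


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and filter settings for a fit.

    Bounds are in optimizer coordinates: ``alpha`` and ``eta0`` are searched
    on a log10 scale, ``a0`` and ``sigma_y`` directly.
    """

    n_particles: int = 1000
    n_restarts: int = 5
    maxfev: int = 150
    b0: float = 10.0
    lam: float = 1.0
    mu0: float = 0.0
    reset_per_block: bool = True
    count_method: str = "modal"  # or "expected"
    log10_alpha_bounds: tuple = (-3.0, 3.0)
    a0_bounds: tuple = (0.5, 50.0)
    log10_eta0_bounds: tuple = (-2.0, 2.0)
    sigma_y_bounds: tuple = (0.5, 30.0)


def recenter(trials):
    """Shift a subject's counts and responses by minus the mean true count.

    Returns ``(recentered_trials, offset)``; the recentered stream is fitted
    with ``mu0 = 0``.  Applying the offset back (``+offset``) inverts the
    transform exactly.
    """
    trials = list(trials)
    valid = [t for t in trials if t.valid]
    if not valid:
        raise ValueError("subject has no valid trials")
    offset = float(np.mean([t.true_count for t in valid]))
    out = []
    for t in trials:
        d = dict(t.__dict__)
        d["true_count"] = t.true_count - offset
        if t.response is not None:
            d["response"] = t.response - offset
        out.append(type(t)(**d))
    return out, offset


class ObserverModel:
    """One subject's estimation model (``kind='rational'`` or ``'exemplar'``).

    Parameters
    ----------
    trials : sequence of TrialRecord
        One subject's session, sorted by presentation order.
    kind : str
        ``'rational'`` (CRP mixture, free concentration) or ``'exemplar'``
        (all-singletons limit, no concentration parameter).
    config : FitConfig
    n_colors : int
    """

    def __init__(self, trials, kind: str = "rational",
                 config: FitConfig = FitConfig(), n_colors: int = 3):
        if kind not in _N_PARAMS:
            raise ValueError(f"unknown model kind {kind!r}")
        self.kind = kind
        self.config = config
        self.n_colors = n_colors
        self.trials = list(trials)
        fitted = [t for t in self.trials if t.valid and t.response is not None]
        if not fitted:
            raise ValueError("need at least one valid responded trial")
        self.recentered, self.offset = recenter(self.trials)
        self._fit_mask = np.array(
            [t.valid and t.response is not None for t in self.trials])
        self._responses = np.array(
            [t.response if (t.valid and t.response is not None) else np.nan
             for t in self.recentered], dtype=float)
        self.n_trials_fit = int(self._fit_mask.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ObserverModel":
        """Build from one subject's rows of the standard trial table."""
        from .task import frame_to_trials
        if df["subject_id"].nunique() != 1:
            raise ValueError("expected trials of exactly one subject")
        df = df.sort_values(["block_index", "trial_index_in_block"])
        return cls(frame_to_trials(df), **kwargs)

    # -- parameter plumbing -------------------------------------------------

    def _bounds(self):
        c = self.config
        if self.kind == "rational":
            return [c.log10_alpha_bounds, c.a0_bounds,
                    c.log10_eta0_bounds, c.sigma_y_bounds]
        return [c.a0_bounds, c.log10_eta0_bounds, c.sigma_y_bounds]

    def _theta_to_hp(self, theta) -> Hyperparameters:
        c = self.config
        if self.kind == "rational":
            la, a0, le, sy = theta
            alpha = 10.0 ** la
        else:
            a0, le, sy = theta
            alpha = EXEMPLAR_ALPHA
        return Hyperparameters(alpha=alpha, a0=a0, b0=c.b0, eta0=10.0 ** le,
                               mu0=c.mu0, lam=c.lam, sigma_y=sy,
                               n_colors=self.n_colors)

    def _hp_to_theta(self, hp: Hyperparameters):
        if self.kind == "rational":
            return [math.log10(hp.alpha), hp.a0, math.log10(hp.eta0), hp.sigma_y]
        return [hp.a0, math.log10(hp.eta0), hp.sigma_y]

    # -- objective ----------------------------------------------------------

    def predict(self, hp: Hyperparameters, eval_seed: int = 0):
        """Filter predictions (recentered scale) and block summaries at ``hp``."""
        n_part = 1 if self.kind == "exemplar" else self.config.n_particles
        return run_session(self.recentered, hp, n_particles=n_part,
                           rng=eval_seed,
                           reset_per_block=self.config.reset_per_block,
                           force_singletons=(self.kind == "exemplar"))

    def mse(self, hp: Hyperparameters, eval_seed: int = 0) -> float:
        """Mean squared error of the model's predictions on responded trials."""
        preds, _ = self.predict(hp, eval_seed)
        est = np.array([p.estimate for p in preds])
        resid = est[self._fit_mask] - self._responses[self._fit_mask]
        return float(np.mean(resid ** 2))

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0, n_restarts: Optional[int] = None,
            start: Optional[Hyperparameters] = None) -> "ObserverResults":
        """Minimize the MSE objective from multiple restarts.

        Restart points are a Sobol sequence over the bounds, plus a mid-bounds
        default and a near-flat start (top of the ``eta0`` and ``sigma_y``
        ranges, whose predictions approximate the constant-zero baseline).
        """
        cfg = self.config
        n_restarts = cfg.n_restarts if n_restarts is None else n_restarts
        bounds = np.array(self._bounds())
        eval_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))

        def objective(theta):
            theta = np.clip(theta, bounds[:, 0], bounds[:, 1])
            try:
                return self.mse(self._theta_to_hp(theta), eval_seed)
            except FloatingPointError:
                return np.inf

        starts = []
        if start is not None:
            starts.append(np.asarray(self._hp_to_theta(start), dtype=float))
        mid = bounds.mean(axis=1)
        starts.append(mid)
        flat = mid.copy()
        flat[-2:] = bounds[-2:, 1]  # eta0, sigma_y at their upper bounds
        starts.append(flat)
        n_qmc = max(n_restarts - len(starts), 0)
        if n_qmc:
            sob = qmc.Sobol(d=bounds.shape[0], scramble=True, seed=seed)
            draw = 1 << (n_qmc - 1).bit_length()  # power of 2 for balance
            pts = qmc.scale(sob.random(draw), bounds[:, 0], bounds[:, 1])
            starts.extend(list(pts[:n_qmc]))
        starts = starts[:max(n_restarts, 1)]

        best = None
        for x0 in starts:
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                bounds=[tuple(b) for b in bounds],
                options={"maxfev": cfg.maxfev, "xatol": 1e-3, "fatol": 1e-4})
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise FitFailure("all optimizer restarts returned a non-finite MSE")
        theta = np.clip(best.x, bounds[:, 0], bounds[:, 1])
        hp = self._theta_to_hp(theta)
        preds, summaries = self.predict(hp, eval_seed)
        return ObserverResults(self, hp, float(best.fun), preds, summaries,
                               eval_seed)


class ObserverResults:
    """Fit results: parameters, per-trial predictions, MSE/BIC, category counts."""

    def __init__(self, model: ObserverModel, params: Hyperparameters,
                 mse: float, predictions, block_summaries, eval_seed: int):
        self.model = model
        self.kind = model.kind
        self.params = params
        self.mse = mse
        self.n_trials_fit = model.n_trials_fit
        self.eval_seed = eval_seed
        self._preds = predictions
        self._summaries = block_summaries

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.kind]

    @property
    def bic(self) -> float:
        n = self.n_trials_fit
        return n * math.log(self.mse) + self.n_params * math.log(n)

    @property
    def predictions(self) -> pd.DataFrame:
        """Per-trial predictions on the original (un-recentered) scale."""
        rows = []
        for t, p in zip(self.model.trials, self._preds):
            rows.append({
                "subject_id": t.subject_id, "block_index": t.block_index,
                "trial_index_in_block": t.trial_index_in_block,
                "trial_type": t.trial_type, "true_count": t.true_count,
                "response": t.response,
                "estimate": p.estimate + self.model.offset,
                "expected_n_categories": p.expected_n_categories,
            })
        return pd.DataFrame(rows)

    @property
    def n_categories_per_block(self) -> np.ndarray:
        """Inferred number of occupied categories per block (modal across
        particles at block end, or posterior-expected if configured)."""
        if self.model.config.count_method == "expected":
            return np.array([s.expected_n_categories for s in self._summaries])
        return np.array([s.modal_n_categories for s in self._summaries])

    @property
    def median_n_categories(self) -> float:
        return float(np.median(self.n_categories_per_block))

    def compare(self, other: "ObserverResults") -> float:
        return compare_models(self, other)

    def summary(self) -> str:
        hp = self.params
        lines = [
            f"{'Observer fit':<28}{self.kind}",
            f"{'No. trials fit':<28}{self.n_trials_fit}",
            f"{'MSE':<28}{self.mse:.4f}",
            f"{'BIC':<28}{self.bic:.2f}",
            f"{'Median categories/block':<28}{self.median_n_categories:.1f}",
            "Parameters (recentered scale; b0, lam, mu0 fixed):",
        ]
        free = (["alpha"] if self.kind == "rational" else []) + \
            ["a0", "eta0", "sigma_y"]
        for name in free:
            lines.append(f"  {name:<26}{getattr(hp, name):.4g}")
        for name in ("b0", "lam", "mu0"):
            lines.append(f"  {name:<26}{getattr(hp, name):.4g} (fixed)")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "model": self.kind,
            "params": json.loads(self.params.to_json()),
            "mse": self.mse,
            "n_trials_fit": self.n_trials_fit,
            "bic": self.bic,
            "offset": self.model.offset,
            "n_categories_per_block": [int(v) if float(v).is_integer() else float(v)
                                       for v in self.n_categories_per_block],
        })


def fit_subject(trials, model: str = "rational",
                config: FitConfig = FitConfig(), seed: int = 0) -> ObserverResults:
    """Functional wrapper: build an :class:`ObserverModel` and fit it."""
    return ObserverModel(trials, kind=model, config=config).fit(seed=seed)


def compare_models(fit_rational: ObserverResults,
                   fit_exemplar: ObserverResults) -> float:
    """BIC-approximated log Bayes factor, rational vs. exemplar (positive
    favors the rational model)."""
    if fit_rational.kind != "rational" or fit_exemplar.kind != "exemplar":
        raise ValueError("expected (rational, exemplar) results in that order")
    a = fit_rational.model.trials
    b = fit_exemplar.model.trials
    keys = lambda ts: [(t.subject_id, t.block_index, t.trial_index_in_block,
                        t.true_count, t.response) for t in ts]
    if keys(a) != keys(b):
        raise ValueError("the two fits are not based on the same trials")
    return (fit_exemplar.bic - fit_rational.bic) / 2.0


def count_categories(fit: ObserverResults):
    """Per-block inferred category counts and their subject-level median."""
    counts = fit.n_categories_per_block
    return counts, float(np.median(counts))
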