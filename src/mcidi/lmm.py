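"""Gaussian random-intercept model for the per-feature state-effect screen.

Each acoustic feature is screened with the repeated-measures model

    f_ik = (beta0 + b_i) + beta1 * s_ik + eps_ik,

where ``s`` indicates the recording state (1 = calculation task, 0 = reading
baseline), ``b_i ~ N(0, sigma_b^2)`` is a per-subject random intercept and
``eps ~ N(0, sigma_e^2)``. The screen needs this fit for hundreds to tens of
thousands of features, and again inside every cross-validation fold, so the
model is fitted by exact profiled maximum likelihood: for a fixed variance
ratio ``gamma = sigma_b^2 / sigma_e^2`` the GLS estimates and the residual
variance have closed forms via per-subject sums (the marginal covariance is
block-compound-symmetric), leaving a one-dimensional likelihood in ``gamma``
that is minimized numerically. The design structure (subject grouping and
state column) is shared by all features of a table and is precomputed once.

Inference on ``beta1`` is a two-sided Wald test from the ML fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["LmmDesign", "LmmFit", "fit_state_lmm"]

logger = logging.getLogger(__name__)

_GAMMA_LOG_BOUNDS = (-12.0, 12.0)


@dataclass(frozen=True)
class LmmFit:
    """Maximum-likelihood fit of the random-intercept state-effect model."""

    beta0: float
    beta1: float
    sigma_b2: float  # between-subject (random-intercept) variance
    sigma_e2: float  # residual variance
    se_beta1: float
    z_value: float
    p_value: float
    loglike: float
    boundary: bool  # True when sigma_b^2 was estimated at the zero boundary


class LmmDesign:
    """Precomputed grouping/state structure shared by every feature column.

    Parameters
    ----------
    subject_ids : array-like
        Subject identifier per utterance row.
    state : array-like
        Binary state indicator per row (1 = calculation, 0 = reading).
    """

    def __init__(self, subject_ids, state) -> None:
        state = np.asarray(state, dtype=float)
        if not np.isin(state, (0.0, 1.0)).all():
            raise ValueError("state must be binary (0 = reading, 1 = calculation)")
        _, codes = np.unique(np.asarray(subject_ids), return_inverse=True)
        self.codes = codes
        self.n_groups = int(codes.max()) + 1
        if self.n_groups < 2:
            raise ValueError("need at least 2 subjects for a random-intercept fit")
        self.n = state.size
        self.state = state
        self.counts = np.bincount(codes, minlength=self.n_groups).astype(float)
        self.state_sums = np.bincount(codes, weights=state, minlength=self.n_groups)
        self.sum_s = float(state.sum())
        self.sum_s2 = self.sum_s  # s is 0/1
        if not (state.min() == 0.0 and state.max() == 1.0):
            raise ValueError("both states must be present")

    def _profile(self, y: np.ndarray, gamma: float):
        """GLS estimates and -2 log-likelihood at a fixed variance ratio."""
        w = gamma / (1.0 + gamma * self.counts)  # per-group shrinkage weight
        ys = np.bincount(self.codes, weights=y, minlength=self.n_groups)
        a11 = self.n - float(w @ (self.counts**2))
        a12 = self.sum_s - float(w @ (self.counts * self.state_sums))
        a22 = self.sum_s2 - float(w @ (self.state_sums**2))
        c1 = float(y.sum()) - float(w @ (self.counts * ys))
        c2 = float(self.state @ y) - float(w @ (self.state_sums * ys))
        yvy = float(y @ y) - float(w @ (ys**2))
        det = a11 * a22 - a12 * a12
        if det <= 0:
            return None
        beta0 = (a22 * c1 - a12 * c2) / det
        beta1 = (a11 * c2 - a12 * c1) / det
        rss = max(yvy - (c1 * beta0 + c2 * beta1), 0.0)
        sigma_e2 = rss / self.n
        logdet_v = float(np.log1p(gamma * self.counts).sum())
        if sigma_e2 <= 0:
            nll2 = -np.inf  # perfect fit; caller handles the degenerate case
        else:
            nll2 = self.n * np.log(2.0 * np.pi * sigma_e2) + logdet_v + self.n
        var_beta1 = sigma_e2 * a11 / det
        return beta0, beta1, sigma_e2, var_beta1, nll2

    def fit(self, y) -> LmmFit:
        """Fit the model to one feature column by profiled ML."""
        y = np.asarray(y, dtype=float)
        if y.size != self.n:
            raise ValueError("response length does not match the design")

        def nll2_of(logg: float) -> float:
            out = self._profile(y, float(np.exp(logg)))
            return np.inf if out is None else out[4]

        res = optimize.minimize_scalar(
            nll2_of, bounds=_GAMMA_LOG_BOUNDS, method="bounded",
            options={"xatol": 1e-8},
        )
        gamma = float(np.exp(res.x))
        nll2_hat = res.fun
        # The zero-variance boundary is outside the log parameterization;
        # compare explicitly and fall back to the OLS limit when it wins.
        boundary = False
        out0 = self._profile(y, 0.0)
        if out0 is not None and out0[4] <= nll2_hat:
            gamma, nll2_hat, boundary = 0.0, out0[4], True
            logger.debug("random-intercept variance estimated at zero boundary")
        out = self._profile(y, gamma)
        if out is None:
            raise np.linalg.LinAlgError("singular design in random-intercept fit")
        beta0, beta1, sigma_e2, var_beta1, nll2 = out
        if sigma_e2 <= 0 or var_beta1 <= 0:
            # degenerate (e.g. constant response): no evidence either way
            se = 0.0
            z = 0.0 if beta1 == 0 else np.inf * np.sign(beta1)
            p = 1.0 if beta1 == 0 else 0.0
            ll = np.inf
        else:
            se = float(np.sqrt(var_beta1))
            z = beta1 / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            ll = -0.5 * nll2
        return LmmFit(
            beta0=float(beta0),
            beta1=float(beta1),
            sigma_b2=float(gamma * sigma_e2),
            sigma_e2=float(sigma_e2),
            se_beta1=se,
            z_value=float(z),
            p_value=float(p),
            loglike=float(ll),
            boundary=boundary,
        )


def fit_state_lmm(values, state, subject_ids) -> LmmFit:
    """Fit the random-intercept state-effect model for a single feature.

    Convenience wrapper around :class:`LmmDesign` for one response series;
    when screening many features of one table, build the design once and call
    :meth:`LmmDesign.fit` per column instead.
    """
    return LmmDesign(subject_ids, state).fit(values)
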