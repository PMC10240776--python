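"""Variance-preserving noise schedule.

The forward process q(z_t | x) = N_x(alpha_t x, sigma_t^2 I) is
parameterized through the log inverse signal-to-noise ratio

    gamma(t) = -log SNR(t),   SNR(t) = alpha_t^2 / sigma_t^2,

with alpha_t^2 = sigmoid(-gamma(t)) and sigma_t^2 = sigmoid(gamma(t)), so
alpha_t^2 + sigma_t^2 = 1 identically. gamma is strictly increasing on
[0, 1]; the default linear form interpolates between gamma_min at t=0 and
gamma_max at t=1. The endpoints are chosen so that sigma_0^2 < 1e-4
(z_0 is essentially the data) and alpha_1^2 < 1e-2 (z_1 is essentially the
standard subspace Gaussian prior).

All quantities are evaluated in log/sigmoid space; in particular the
transition variance sigma_{t|s}^2 = sigma_t^2 (1 - exp(gamma(s) - gamma(t)))
uses ``expm1`` to stay accurate when s is close to t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSchedule"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


@dataclass(frozen=True)
class NoiseSchedule:
    """gamma(t) and the derived signal/noise scales of the VP process.

    Parameters
    ----------
    gamma_min, gamma_max:
        Values of gamma at t=0 and t=1 (dimensionless log inverse SNR).
    form:
        Interpolation shape; only ``"linear"`` is implemented.
    """

    gamma_min: float = -13.3
    gamma_max: float = 5.0
    form: str = "linear"

    def __post_init__(self) -> None:
        if self.form != "linear":
            raise ValueError(f"unknown schedule form {self.form!r}")
        if not self.gamma_max > self.gamma_min:
            raise ValueError("gamma_max must exceed gamma_min")
        if _sigmoid(self.gamma_min) >= 1e-4:
            raise ValueError("endpoint contract violated: sigma_0^2 must be < 1e-4")
        if _sigmoid(-self.gamma_max) >= 1e-2:
            raise ValueError("endpoint contract violated: alpha_1^2 must be < 1e-2")

    # -- gamma and its derivative -----------------------------------------

    def _check_t(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        if np.any(t < 0.0) or np.any(t > 1.0):
            raise ValueError("diffusion time must lie in [0, 1]")
        return t

    def gamma(self, t):
        """Log inverse SNR at time ``t`` (scalar or array)."""
        t = self._check_t(t)
        return self.gamma_min + (self.gamma_max - self.gamma_min) * t

    def gamma_prime(self, t):
        """d gamma / dt; constant for the linear form."""
        self._check_t(t)
        return np.broadcast_to(
            np.float64(self.gamma_max - self.gamma_min), np.shape(t)
        ) if np.ndim(t) else float(self.gamma_max - self.gamma_min)

    # -- marginal scales ---------------------------------------------------

    def alpha_sigma(self, t):
        """(alpha_t, sigma_t) with alpha_t^2 + sigma_t^2 = 1."""
        g = self.gamma(t)
        return np.sqrt(_sigmoid(-g)), np.sqrt(_sigmoid(g))

    def snr(self, t):
        """Signal-to-noise ratio alpha_t^2 / sigma_t^2 = exp(-gamma(t))."""
        return np.exp(-self.gamma(t))

    # -- transition q(z_t | z_s), t > s ------------------------------------

    def transition_params(self, s, t):
        """(alpha_{t|s}, sigma_{t|s}^2) of the Markov transition.

        alpha_{t|s} = alpha_t / alpha_s and
        sigma_{t|s}^2 = sigma_t^2 - alpha_{t|s}^2 sigma_s^2
                      = sigma_t^2 (1 - exp(gamma(s) - gamma(t))) >= 0.
        """
        s = np.asarray(s, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64)
        if np.any(s > t):
            raise ValueError("transition requires s <= t")
        gs, gt = self.gamma(s), self.gamma(t)
        alpha_ts = np.sqrt(_sigmoid(-gt) / _sigmoid(-gs))
        sigma2_ts = _sigmoid(gt) * (-np.expm1(gs - gt))
        return alpha_ts, sigma2_ts

    # -- posterior q(z_s | z_t, x), s < t -----------------------------------

    def posterior_params(self, z_t: np.ndarray, x: np.ndarray, s, t):
        """(mu, sigma_post) of the Gaussian posterior over z_s.

        mu = (alpha_{t|s} sigma_s^2 / sigma_t^2) z_t
           + (alpha_s sigma_{t|s}^2 / sigma_t^2) x
        sigma_post = sigma_{t|s} sigma_s / sigma_t  (scalar stddev).
        """
        z_t = np.asarray(z_t, dtype=np.float64)
        x = np.asarray(x, dtype=np.float64)
        if z_t.shape != x.shape:
            raise ValueError(f"shape mismatch: z_t {z_t.shape} vs x {x.shape}")
        if not np.all(np.asarray(s) < np.asarray(t)):
            raise ValueError("posterior requires s < t")
        alpha_s, sigma_s = self.alpha_sigma(s)
        _, sigma_t = self.alpha_sigma(t)
        alpha_ts, sigma2_ts = self.transition_params(s, t)
        sigma_t2 = sigma_t**2
        mu = (alpha_ts * sigma_s**2 / sigma_t2) * z_t + (alpha_s * sigma2_ts / sigma_t2) * x
        sigma_post = np.sqrt(sigma2_ts) * sigma_s / sigma_t
        return mu, float(sigma_post)
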