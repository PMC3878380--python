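"""Subject-side models of the asset's up-probability.

Two trackers are provided for the belief ``q_t`` that the asset goes up:

* a Bayesian volatility filter in the tradition of hierarchical
  reward-probability learners: the up-probability ``r`` is assumed to drift
  with a volatility ``v`` that itself drifts at a (static) rate ``k``, and
  the joint posterior over a discretized ``(r, v, k)`` grid is propagated
  through the drift kernels and conditioned on each binary outcome;
* a delta-rule (Rescorla–Wagner) tracker with a single learning rate
  ``lambda_s``, the reinforcement-learning alternative.

``q_t`` is always the marginal posterior mean of ``r`` (or the delta-rule
scalar) *before* trial ``t``'s outcome is seen.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = [
    "VolatilityFilter",
    "update_volatility_filter",
    "asset_point_estimate",
    "asset_belief_series",
    "RLAssetState",
    "rl_asset_update",
    "rl_asset_belief_series",
]

_NORM_TOL = 1e-10


def _beta_kernel(r_grid: np.ndarray, sd: float) -> np.ndarray:
    """Row-stochastic transition matrix K[i,j] = P(r'=r_j | r=r_i) for one sd."""
    R = r_grid.size
    if sd < 1e-8:  # static limit: probability does not move
        return np.eye(R)
    m = r_grid
    # moment-matched beta centered on the current probability; near the grid
    # edges the nominal sd is capped so the parameterization stays proper
    sd_eff = np.minimum(sd, 0.9 * np.sqrt(m * (1 - m)))
    nu = m * (1 - m) / sd_eff**2 - 1.0
    a = (m * nu)[:, None]
    b = ((1 - m) * nu)[:, None]
    dens = stats.beta.pdf(r_grid[None, :], a, b)
    dens /= dens.sum(axis=1, keepdims=True)
    return dens


def _logv_kernel(v_grid: np.ndarray, k: float) -> np.ndarray:
    """Row-stochastic Gaussian-in-log-volatility transition matrix for one k."""
    V = v_grid.size
    if V == 1 or k < 1e-8:
        return np.eye(V)
    lv = np.log(v_grid)
    d = lv[None, :] - lv[:, None]
    dens = np.exp(-0.5 * (d / k) ** 2)
    dens /= dens.sum(axis=1, keepdims=True)
    return dens


@dataclasses.dataclass
class VolatilityFilter:
    """Grid posterior over (reward probability r, volatility v, meta-volatility k).

    Parameters
    ----------
    n_r, n_v, n_k
        Grid sizes. ``r`` lies on cell midpoints of (0,1); ``v`` (the SD of
        the per-trial beta drift of ``r``) and ``k`` (the SD of the log-v
        random walk) are log-spaced.
    v_range, k_range
        Grid end points for ``v`` and ``k``.
    """

    n_r: int = 30
    n_v: int = 30
    n_k: int = 15
    v_range: tuple[float, float] = (0.01, 0.25)
    k_range: tuple[float, float] = (0.05, 2.0)
    v_fixed: float | None = None  # collapse the v grid to one value (static limit)

    def __post_init__(self) -> None:
        self.r_grid = (np.arange(self.n_r) + 0.5) / self.n_r
        if self.v_fixed is not None:
            self.v_grid = np.array([self.v_fixed])
            self.k_grid = np.array([0.0])
        else:
            self.v_grid = np.geomspace(*self.v_range, self.n_v)
            self.k_grid = np.geomspace(*self.k_range, self.n_k)
        # transition tensors: Tr[i,j,v] over r, Tv[i,j,k] over v
        self._Tr = np.stack(
            [_beta_kernel(self.r_grid, v) for v in self.v_grid], axis=-1
        )
        self._Tv = np.stack([_logv_kernel(self.v_grid, k) for k in self.k_grid], axis=-1)
        self.posterior = np.full(
            (self.r_grid.size, self.v_grid.size, self.k_grid.size),
            1.0 / (self.r_grid.size * self.v_grid.size * self.k_grid.size),
        )

    def _check(self) -> None:
        s = self.posterior.sum()
        if not np.isfinite(s) or s <= 0:
            raise FloatingPointError("volatility filter posterior degenerated")
        if abs(s - 1.0) > _NORM_TOL:
            self.posterior /= s

    def update(self, outcome: int) -> None:
        """Propagate one step through the drift kernels, then condition on the outcome."""
        self._check()
        P = self.posterior
        # v drifts under its k-specific kernel, then r drifts under its v-specific kernel
        P = np.einsum("vwk,rvk->rwk", self._Tv, P)
        P = np.einsum("rsv,rvk->svk", self._Tr, P)
        lik = self.r_grid if outcome == 1 else 1.0 - self.r_grid
        P = P * lik[:, None, None]
        s = P.sum()
        if s <= 0 or not np.isfinite(s):
            raise FloatingPointError("volatility filter update underflowed")
        self.posterior = P / s

    @property
    def q(self) -> float:
        """Marginal posterior mean of the up-probability r."""
        marg_r = self.posterior.sum(axis=(1, 2))
        return float(np.dot(marg_r, self.r_grid))

    def r_marginal(self) -> np.ndarray:
        return self.posterior.sum(axis=(1, 2))


def update_volatility_filter(state: VolatilityFilter, outcome: int) -> VolatilityFilter:
    """Functional wrapper: return an updated copy of the filter state."""
    new = dataclasses.replace(state)
    new.posterior = state.posterior.copy()
    new.update(outcome)
    return new


def asset_point_estimate(state: "VolatilityFilter | RLAssetState") -> float:
    """Current belief q that the asset goes up."""
    if isinstance(state, RLAssetState):
        return float(state.q_hat)
    return state.q


def asset_belief_series(
    outcomes: np.ndarray, filt: VolatilityFilter | None = None, **filter_kwargs
) -> np.ndarray:
    """Per-trial prior beliefs q_t from the volatility filter.

    ``q[t]`` is the filter's estimate before outcome ``t`` is observed
    (``q[0]`` is the uniform-prior mean, 0.5).
    """
    filt = filt if filt is not None else VolatilityFilter(**filter_kwargs)
    q = np.empty(len(outcomes))
    for t, o in enumerate(np.asarray(outcomes, dtype=int)):
        q[t] = filt.q
        filt.update(int(o))
    return q


@dataclasses.dataclass
class RLAssetState:
    """Delta-rule asset tracker with learning rate ``lambda_s``."""

    q_hat: float = 0.5
    lambda_s: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_s <= 1.0:
            raise ValueError("lambda_s must lie in [0,1]")
        if not 0.0 <= self.q_hat <= 1.0:
            raise ValueError("q_hat must lie in [0,1]")


def rl_asset_update(state: RLAssetState, outcome: int) -> RLAssetState:
    """q_hat <- q_hat + lambda_s * (outcome - q_hat)."""
    return RLAssetState(
        q_hat=state.q_hat + state.lambda_s * (outcome - state.q_hat),
        lambda_s=state.lambda_s,
    )


def rl_asset_belief_series(outcomes: np.ndarray, lambda_s: float, q0: float = 0.5) -> np.ndarray:
    """Per-trial prior beliefs q_t from the delta-rule tracker."""
    o = np.asarray(outcomes, dtype=float)
    q = np.empty(o.size)
    cur = q0
    for t in range(o.size):
        q[t] = cur
        cur = cur + lambda_s * (o[t] - cur)
    return q
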