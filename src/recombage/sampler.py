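"""No-U-Turn Hamiltonian Monte Carlo sampler.

A self-contained NUTS implementation (slice variant with dual-averaging
step-size adaptation and diagonal mass-matrix estimation during warmup)
operating on an unconstrained parameter vector with a user-supplied
log-density-and-gradient callable. Warmup follows the usual three-phase
schedule: an initial step-size-only buffer, doubling covariance-estimation
windows, and a terminal step-size buffer. Draws returned are post-warmup
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

_MAX_DELTA = 1000.0  # divergence threshold on the log joint


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split potential-scale-reduction statistic per parameter.

    ``draws`` has shape (chains, draws, dim); each chain is split in half,
    and R-hat is the usual between- versus within-chain variance ratio
    sqrt((W*(m-1)/m + B/m) / W) over the resulting 2*chains sequences.
    """
    n_c, n_d, dim = draws.shape
    half = n_d // 2
    if half < 2:
        return np.full(dim, np.nan)
    seq = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, n = seq.shape[0], half
    means = seq.mean(axis=1)                       # (m, dim)
    w = seq.var(axis=1, ddof=1).mean(axis=0)       # within
    b = n * means.var(axis=0, ddof=1)              # between
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = w * (n - 1) / n + b / n
        out = np.sqrt(var_plus / w)
    out = np.where(w <= 1e-300, 1.0, out)
    return out


@dataclass
class ChainResult:
    draws: np.ndarray        # (n_draws, dim)
    logp: np.ndarray         # (n_draws,)
    step_size: float
    inv_mass: np.ndarray
    n_divergent: int
    mean_accept: float


class _Tree:
    __slots__ = (
        "theta_minus", "r_minus", "grad_minus", "theta_plus", "r_plus",
        "grad_plus", "theta_prop", "logp_prop", "grad_prop", "n", "s",
        "alpha", "n_alpha", "div",
    )


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_mass * r1
    logp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, grad1, logp1


def _joint(logp, r, inv_mass):
    return logp - 0.5 * float(np.dot(r, inv_mass * r))


class NutsSampler:
    def __init__(
        self,
        logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
        dim: int,
        target_accept: float = 0.8,
        max_treedepth: int = 10,
    ):
        self.logp_grad = logp_grad
        self.dim = dim
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth

    # -- one NUTS transition --------------------------------------------------

    def _build_tree(self, theta, r, grad, logu, direction, depth, eps, inv_mass, rng):
        out = _Tree()
        if depth == 0:
            theta1, r1, grad1, logp1 = _leapfrog(
                self.logp_grad, theta, r, grad, direction * eps, inv_mass
            )
            joint = _joint(logp1, r1, inv_mass)
            if not np.isfinite(joint):
                joint = -np.inf
            out.theta_minus = out.theta_plus = out.theta_prop = theta1
            out.r_minus = out.r_plus = r1
            out.grad_minus = out.grad_plus = out.grad_prop = grad1
            out.logp_prop = logp1
            out.n = 1 if logu <= joint else 0
            out.s = 1 if logu < joint + _MAX_DELTA else 0
            out.div = 1 - out.s
            out.alpha = min(1.0, float(np.exp(min(joint - self._joint0, 0.0))))
            out.n_alpha = 1
            return out

        left = self._build_tree(theta, r, grad, logu, direction, depth - 1, eps, inv_mass, rng)
        out.theta_minus, out.r_minus, out.grad_minus = (
            left.theta_minus, left.r_minus, left.grad_minus)
        out.theta_plus, out.r_plus, out.grad_plus = (
            left.theta_plus, left.r_plus, left.grad_plus)
        out.theta_prop, out.logp_prop, out.grad_prop = (
            left.theta_prop, left.logp_prop, left.grad_prop)
        out.n, out.s, out.alpha, out.n_alpha = left.n, left.s, left.alpha, left.n_alpha
        out.div = left.div
        if left.s == 1:
            if direction == -1:
                right = self._build_tree(
                    left.theta_minus, left.r_minus, left.grad_minus,
                    logu, direction, depth - 1, eps, inv_mass, rng)
                out.theta_minus, out.r_minus, out.grad_minus = (
                    right.theta_minus, right.r_minus, right.grad_minus)
            else:
                right = self._build_tree(
                    left.theta_plus, left.r_plus, left.grad_plus,
                    logu, direction, depth - 1, eps, inv_mass, rng)
                out.theta_plus, out.r_plus, out.grad_plus = (
                    right.theta_plus, right.r_plus, right.grad_plus)
            total = left.n + right.n
            if total > 0 and rng.random() < right.n / total:
                out.theta_prop, out.logp_prop, out.grad_prop = (
                    right.theta_prop, right.logp_prop, right.grad_prop)
            out.n = total
            out.div = left.div or right.div
            out.alpha = left.alpha + right.alpha
            out.n_alpha = left.n_alpha + right.n_alpha
            out.s = right.s * self._no_uturn(
                out.theta_minus, out.theta_plus, out.r_minus, out.r_plus, inv_mass)
        return out

    @staticmethod
    def _no_uturn(theta_minus, theta_plus, r_minus, r_plus, inv_mass) -> int:
        dtheta = theta_plus - theta_minus
        return int(
            np.dot(dtheta, inv_mass * r_minus) >= 0
            and np.dot(dtheta, inv_mass * r_plus) >= 0
        )

    def _transition(self, theta, logp, grad, eps, inv_mass, rng):
        r0 = rng.standard_normal(self.dim) / np.sqrt(inv_mass)
        joint0 = _joint(logp, r0, inv_mass)
        self._joint0 = joint0
        logu = joint0 + np.log(rng.random())
        theta_minus = theta_plus = theta
        r_minus = r_plus = r0
        grad_minus = grad_plus = grad
        theta_prop, logp_prop, grad_prop = theta, logp, grad
        n, s, depth = 1, 1, 0
        alpha_sum, n_alpha = 0.0, 0
        divergent = False
        while s == 1 and depth < self.max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                tree = self._build_tree(
                    theta_minus, r_minus, grad_minus, logu, -1, depth, eps, inv_mass, rng)
                theta_minus, r_minus, grad_minus = (
                    tree.theta_minus, tree.r_minus, tree.grad_minus)
            else:
                tree = self._build_tree(
                    theta_plus, r_plus, grad_plus, logu, 1, depth, eps, inv_mass, rng)
                theta_plus, r_plus, grad_plus = (
                    tree.theta_plus, tree.r_plus, tree.grad_plus)
            if tree.s == 1 and rng.random() < min(1.0, tree.n / n):
                theta_prop, logp_prop, grad_prop = (
                    tree.theta_prop, tree.logp_prop, tree.grad_prop)
            n += tree.n
            alpha_sum += tree.alpha
            n_alpha += tree.n_alpha
            if tree.div:
                divergent = True
            s = tree.s * self._no_uturn(theta_minus, theta_plus, r_minus, r_plus, inv_mass)
            depth += 1
        accept_stat = alpha_sum / max(n_alpha, 1)
        return theta_prop, logp_prop, grad_prop, accept_stat, divergent

    # -- step-size heuristics ---------------------------------------------------

    def _find_reasonable_eps(self, theta, logp, grad, inv_mass, rng) -> float:
        eps = 1.0
        r0 = rng.standard_normal(self.dim) / np.sqrt(inv_mass)
        joint0 = _joint(logp, r0, inv_mass)
        _, r1, _, logp1 = _leapfrog(self.logp_grad, theta, r0, grad, eps, inv_mass)
        joint1 = _joint(logp1, r1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        direction = 1.0 if joint1 - joint0 > np.log(0.5) else -1.0
        for _ in range(50):
            eps *= 2.0**direction
            _, r1, _, logp1 = _leapfrog(self.logp_grad, theta, r0, grad, eps, inv_mass)
            joint1 = _joint(logp1, r1, inv_mass)
            if not np.isfinite(joint1):
                joint1 = -np.inf
            if direction * (joint1 - joint0) <= direction * np.log(0.5):
                break
        return max(eps, 1e-10)

    # -- main loop --------------------------------------------------------------

    def run(
        self,
        theta0: np.ndarray,
        n_draws: int,
        n_warmup: int,
        rng: np.random.Generator,
    ) -> ChainResult:
        """Run one chain; returns the ``n_draws`` post-warmup draws."""
        theta = np.asarray(theta0, dtype=float).copy()
        logp, grad = self.logp_grad(theta)
        if not np.isfinite(logp):
            raise ValueError("initial position has non-finite log density")
        inv_mass = np.ones(self.dim)

        # Warmup windows (Stan-like schedule, scaled to short warmups).
        init_buf = min(75, max(5, n_warmup // 6))
        term_buf = min(50, max(5, n_warmup // 8))
        window_start = init_buf
        window_size = min(25, max(5, n_warmup // 10))
        window_end = min(window_start + window_size, n_warmup - term_buf)

        eps = self._find_reasonable_eps(theta, logp, grad, inv_mass, rng)
        mu_da = np.log(10.0 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        da_count = 0

        window_buf: list[np.ndarray] = []
        divergences = 0
        accept_hist: list[float] = []

        draws = np.empty((n_draws, self.dim))
        lps = np.empty(n_draws)

        total = n_warmup + n_draws
        for it in range(total):
            theta, logp, grad, accept, div = self._transition(
                theta, logp, grad, eps, inv_mass, rng)
            if it < n_warmup:
                # Dual averaging.
                da_count += 1
                frac = 1.0 / (da_count + t0)
                h_bar = (1.0 - frac) * h_bar + frac * (self.target_accept - accept)
                log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
                weight = da_count ** -kappa
                log_eps_bar = weight * log_eps + (1.0 - weight) * log_eps_bar
                eps = float(np.exp(log_eps))
                if init_buf <= it < n_warmup - term_buf:
                    window_buf.append(theta.copy())
                    if it + 1 == window_end:
                        pos = np.asarray(window_buf)
                        n_w = len(pos)
                        var = pos.var(axis=0, ddof=1) if n_w > 1 else np.ones(self.dim)
                        inv_mass = (n_w / (n_w + 5.0)) * var + 1e-3 * (5.0 / (n_w + 5.0))
                        inv_mass = np.maximum(inv_mass, 1e-10)
                        window_buf = []
                        window_size *= 2
                        window_start = window_end
                        window_end = window_start + window_size
                        if window_end + window_size > n_warmup - term_buf:
                            window_end = n_warmup - term_buf
                        eps = self._find_reasonable_eps(theta, logp, grad, inv_mass, rng)
                        mu_da = np.log(10.0 * eps)
                        h_bar, log_eps_bar, da_count = 0.0, 0.0, 0
                if it + 1 == n_warmup:
                    eps = float(np.exp(log_eps_bar)) if da_count > 0 else eps
            else:
                k = it - n_warmup
                draws[k] = theta
                lps[k] = logp
                accept_hist.append(accept)
                if div:
                    divergences += 1
        return ChainResult(
            draws=draws, logp=lps, step_size=eps, inv_mass=inv_mass,
            n_divergent=divergences,
            mean_accept=float(np.mean(accept_hist)) if accept_hist else float("nan"),
        )

    def run_fixed(
        self,
        theta0: np.ndarray,
        n_draws: int,
        eps: float,
        inv_mass: np.ndarray,
        rng: np.random.Generator,
    ) -> ChainResult:
        """Continue sampling with a frozen step size and mass matrix.

        Used to extend converged-adaptation chains when the R-hat rule asks
        for more draws.
        """
        theta = np.asarray(theta0, dtype=float).copy()
        logp, grad = self.logp_grad(theta)
        draws = np.empty((n_draws, self.dim))
        lps = np.empty(n_draws)
        divergences = 0
        accepts = np.empty(n_draws)
        for it in range(n_draws):
            theta, logp, grad, accept, div = self._transition(
                theta, logp, grad, eps, inv_mass, rng)
            draws[it] = theta
            lps[it] = logp
            accepts[it] = accept
            if div:
                divergences += 1
        return ChainResult(
            draws=draws, logp=lps, step_size=eps, inv_mass=inv_mass,
            n_divergent=divergences, mean_accept=float(accepts.mean()),
        )
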