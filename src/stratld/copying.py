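"""Genetic-map-aware Li & Stephens haplotype-copying HMM.

A query haplotype is modelled as an imperfect mosaic of ``K`` reference
haplotypes.  The hidden state ``X_l`` is the panel haplotype being copied at
site ``l``; between adjacent sites separated by ``g_l`` Morgans the chain
stays put with probability ``exp(-lam*g_l) + (1-exp(-lam*g_l))/K`` and moves
to any given other state with probability ``(1-exp(-lam*g_l))/K``, where
``lam`` is the jump rate per Morgan.  Emissions match the copied allele with
probability ``1-eps``.  The jump rate is estimated by maximising the forward
log-likelihood, either jointly with ``eps`` (2-D quasi-Newton in
``(log lam, logit eps)`` coordinates from a small deterministic multistart)
or as a 1-D profile with ``eps`` fixed (Brent-style bounded search), with
standard errors from a central finite-difference Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

__all__ = [
    "CopyingParams",
    "CopyingPanel",
    "CopyingFit",
    "transition_prob",
    "forward_loglik",
    "fit_joint",
    "fit_profile_lambda",
    "fit_standard_errors",
    "sample_generative",
    "LAMBDA_FLOOR",
    "LAMBDA_CEIL",
    "EPS_FLOOR",
    "EPS_CEIL",
]

# optimisation box: the nominal jump-rate range [0, 1e6] is searched in log
# coordinates with a floor at 1e-3 per Morgan standing in for the 0 bound
LAMBDA_FLOOR = 1e-3
LAMBDA_CEIL = 1e6
EPS_FLOOR = 1e-6
EPS_CEIL = 0.5 - 1e-6


@dataclass(frozen=True)
class CopyingParams:
    """Jump rate ``lam`` (per Morgan) and copying-error probability ``eps``."""

    lam: float
    eps: float

    def __post_init__(self):
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"lam must be finite and >= 0, got {self.lam}")
        if not (0 <= self.eps < 0.5):
            raise ValueError(f"eps must be in [0, 0.5), got {self.eps}")


@dataclass
class CopyingPanel:
    """Reference panel, query haplotype and genetic-map positions.

    ``panel`` is K x S with alleles in {0, 1}; ``query`` is length S with -1
    marking missing calls (marginalised in the likelihood).  ``map_pos`` is
    non-decreasing, in Morgans; inter-site distances ``g`` are its first
    differences.
    """

    panel: np.ndarray
    query: np.ndarray
    map_pos: np.ndarray

    def __post_init__(self):
        self.panel = np.asarray(self.panel, dtype=np.int8)
        self.query = np.asarray(self.query, dtype=np.int8)
        self.map_pos = np.asarray(self.map_pos, dtype=float)
        if self.panel.ndim != 2 or self.panel.shape[0] < 1 or self.panel.shape[1] < 1:
            raise ValueError("panel must be a K x S matrix with K, S >= 1")
        k, s = self.panel.shape
        if self.query.shape != (s,) or self.map_pos.shape != (s,):
            raise ValueError("query and map_pos must have length S")
        if np.any(np.diff(self.map_pos) < 0):
            raise ValueError("map_pos must be non-decreasing")
        if np.any((self.panel != 0) & (self.panel != 1)):
            raise ValueError("panel alleles must be 0/1 (drop sites missing in the panel)")

    @property
    def n_haplotypes(self) -> int:
        return self.panel.shape[0]

    @property
    def n_sites(self) -> int:
        return self.panel.shape[1]

    @property
    def g(self) -> np.ndarray:
        return np.diff(self.map_pos)

    def restrict_maf(self, maf_min: float = 0.05) -> "CopyingPanel":
        """Keep sites with panel minor-allele frequency strictly above ``maf_min``.

        Inter-site distances are re-differenced from the retained map
        positions, so they stay non-negative.
        """
        freq = self.panel.mean(axis=0)
        keep = np.minimum(freq, 1.0 - freq) > maf_min
        if not np.any(keep):
            raise ValueError("no sites pass the panel MAF filter")
        return CopyingPanel(self.panel[:, keep], self.query[keep], self.map_pos[keep])


@dataclass(frozen=True)
class CopyingFit:
    """Maximum-likelihood copying-model fit."""

    lam_hat: float
    eps_hat: float
    loglik: float
    mode: str
    converged: bool
    n_sites: int
    se_lam: float | None = None
    se_eps: float | None = None
    at_bound: bool = False
    se_ok: bool | None = None


def transition_prob(params: CopyingParams, g_l: float, K: int, same_state: bool) -> float:
    """Single-step transition probability between copying states.

    Rows sum to 1: the stay term includes the ``1/K`` share of the jump mass.
    """
    if g_l < 0:
        raise ValueError("g_l must be >= 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    stay = np.exp(-params.lam * g_l)
    move = (1.0 - stay) / K
    return float(stay + move) if same_state else float(move)


def _emissions(data: CopyingPanel, eps: float) -> np.ndarray:
    """(S, K) emission matrix; missing query sites emit 1 for every state."""
    h = data.query
    match = data.panel.T == h[:, None]
    em = np.where(match, 1.0 - eps, eps)
    em[h < 0, :] = 1.0
    return em


def forward_loglik(data: CopyingPanel, params: CopyingParams) -> float:
    """Scaled forward-algorithm log-likelihood of the query given the panel.

    Initial distribution uniform over the K states.  Returns ``-inf`` (not an
    exception) if the data are impossible, e.g. ``eps = 0`` with a mismatch.
    """
    k = data.n_haplotypes
    em = _emissions(data, params.eps)
    g = data.g
    stay = np.exp(-params.lam * g)
    alpha = em[0] / k
    c = alpha.sum()
    if c == 0.0:
        return -np.inf
    ll = np.log(c)
    alpha /= c
    for l in range(1, data.n_sites):
        s = stay[l - 1]
        alpha = s * alpha + (1.0 - s) / k  # alpha sums to 1 entering the step
        alpha *= em[l]
        c = alpha.sum()
        if c == 0.0:
            return -np.inf
        ll += np.log(c)
        alpha /= c
    return float(ll)


def _informative(data: CopyingPanel) -> bool:
    return bool(np.any(data.query >= 0))


_DEFAULT_STARTS = ((100.0, 0.01), (10.0, 0.05), (1000.0, 0.005))


def fit_joint(data: CopyingPanel, starts=_DEFAULT_STARTS) -> CopyingFit:
    """Joint 2-D maximum-likelihood fit of (lam, eps).

    Optimises in ``(log lam, logit eps)`` coordinates with L-BFGS-B from a
    small deterministic multistart; the natural-scale box spans
    ``lam in [1e-3, 1e6]``, ``eps in [1e-6, 0.5 - 1e-6]``.
    """
    if not _informative(data):
        return CopyingFit(
            lam_hat=np.nan, eps_hat=np.nan, loglik=0.0, mode="joint",
            converged=False, n_sites=data.n_sites,
        )

    def nll(x):
        lam = float(np.exp(x[0]))
        eps = float(expit(x[1]))
        return -forward_loglik(data, CopyingParams(lam, eps))

    bounds = [
        (np.log(LAMBDA_FLOOR), np.log(LAMBDA_CEIL)),
        (logit(EPS_FLOOR), logit(EPS_CEIL)),
    ]
    best = None
    any_ok = False
    for lam0, eps0 in starts:
        res = optimize.minimize(
            nll, x0=[np.log(lam0), logit(eps0)], method="L-BFGS-B", bounds=bounds
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    lam_hat = float(np.exp(best.x[0]))
    eps_hat = float(expit(best.x[1]))
    at_bound = (
        lam_hat <= LAMBDA_FLOOR * 1.01
        or lam_hat >= LAMBDA_CEIL * 0.99
        or eps_hat <= EPS_FLOOR * 1.01
        or eps_hat >= EPS_CEIL * 0.999
    )
    return CopyingFit(
        lam_hat=lam_hat, eps_hat=eps_hat, loglik=float(-best.fun), mode="joint",
        converged=any_ok, n_sites=data.n_sites, at_bound=at_bound,
    )


def fit_profile_lambda(data: CopyingPanel, eps_fixed: float = 1e-2) -> CopyingFit:
    """Profile maximum-likelihood fit of lam with eps held fixed.

    Brent-style bounded scalar search over ``log lam`` across [1e-3, 1e6]
    per Morgan.
    """
    if not (0.0 < eps_fixed < 0.5):
        raise ValueError("eps_fixed must be in (0, 0.5)")
    if not _informative(data):
        return CopyingFit(
            lam_hat=np.nan, eps_hat=eps_fixed, loglik=0.0, mode="profile",
            converged=False, n_sites=data.n_sites,
        )

    def nll(x):
        return -forward_loglik(data, CopyingParams(float(np.exp(x)), eps_fixed))

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(LAMBDA_FLOOR), np.log(LAMBDA_CEIL)), method="bounded"
    )
    lam_hat = float(np.exp(res.x))
    at_bound = lam_hat <= LAMBDA_FLOOR * 1.01 or lam_hat >= LAMBDA_CEIL * 0.99
    return CopyingFit(
        lam_hat=lam_hat, eps_hat=float(eps_fixed), loglik=float(-res.fun),
        mode="profile", converged=bool(res.success), n_sites=data.n_sites,
        at_bound=at_bound,
    )


def fit_standard_errors(
    data: CopyingPanel, fit: CopyingFit, loglik_fn=None, rel_step: float = 1e-4
) -> CopyingFit:
    """Finite-difference standard errors at the MLE.

    Central second differences of the log-likelihood in the transformed
    coordinates ``(log lam, logit eps)``; SEs are the square roots of the
    diagonal of the inverse negative Hessian, delta-method mapped back to the
    natural scale.  Estimates on an optimisation bound, or a Hessian that is
    not positive definite after negation, yield missing SEs with
    ``se_ok=False`` rather than an exception.
    """
    if not fit.converged or fit.at_bound:
        return replace(fit, se_lam=None, se_eps=None, se_ok=False)
    if loglik_fn is None:
        def loglik_fn(lam, eps):
            return forward_loglik(data, CopyingParams(lam, eps))

    if fit.mode == "profile":
        x0 = np.log(fit.lam_hat)
        h = rel_step * max(1.0, abs(x0))
        def f(x):
            return loglik_fn(float(np.exp(x)), fit.eps_hat)
        d2 = (f(x0 + h) - 2.0 * f(x0) + f(x0 - h)) / h**2
        if d2 >= 0 or not np.isfinite(d2):
            return replace(fit, se_lam=None, se_eps=None, se_ok=False)
        se_x = float(np.sqrt(-1.0 / d2))
        return replace(fit, se_lam=se_x * fit.lam_hat, se_eps=None, se_ok=True)

    x0 = np.array([np.log(fit.lam_hat), logit(fit.eps_hat)])
    h = rel_step * np.maximum(1.0, np.abs(x0))

    def f(x):
        return loglik_fn(float(np.exp(x[0])), float(expit(x[1])))

    hess = np.empty((2, 2))
    f0 = f(x0)
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = h[i]
        hess[i, i] = (f(x0 + ei) - 2.0 * f0 + f(x0 - ei)) / h[i] ** 2
    e0 = np.array([h[0], 0.0])
    e1 = np.array([0.0, h[1]])
    hess[0, 1] = hess[1, 0] = (
        f(x0 + e0 + e1) - f(x0 + e0 - e1) - f(x0 - e0 + e1) + f(x0 - e0 - e1)
    ) / (4.0 * h[0] * h[1])
    neg = -hess
    try:
        cov = np.linalg.inv(neg)
    except np.linalg.LinAlgError:
        return replace(fit, se_lam=None, se_eps=None, se_ok=False)
    if np.any(np.diag(cov) <= 0) or np.any(np.linalg.eigvalsh(neg) <= 0):
        return replace(fit, se_lam=None, se_eps=None, se_ok=False)
    se_lam = float(np.sqrt(cov[0, 0]) * fit.lam_hat)
    se_eps = float(np.sqrt(cov[1, 1]) * fit.eps_hat * (1.0 - fit.eps_hat))
    return replace(fit, se_lam=se_lam, se_eps=se_eps, se_ok=True)


def sample_generative(panel: np.ndarray, map_pos: np.ndarray, params: CopyingParams, rng_seed):
    """Sample a query haplotype from the copying model; returns (query, hidden path).

    ``X_1`` is uniform on the K panel haplotypes; transitions follow the
    map-aware kernel and emissions flip the copied allele with probability
    ``eps``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    panel = np.asarray(panel, dtype=np.int8)
    map_pos = np.asarray(map_pos, dtype=float)
    k, s = panel.shape
    if map_pos.shape != (s,):
        raise ValueError("map_pos must have length S")
    if np.any(np.diff(map_pos) < 0):
        raise ValueError("map_pos must be non-decreasing")
    g = np.diff(map_pos)
    stay = np.exp(-params.lam * g)
    path = np.empty(s, dtype=np.int64)
    path[0] = rng.integers(k)
    jump = rng.random(s - 1) >= stay  # leave-state events (may land back on the same state)
    dest = rng.integers(0, k, size=s - 1)
    for l in range(1, s):
        path[l] = dest[l - 1] if jump[l - 1] else path[l - 1]
    query = panel[path, np.arange(s)].astype(np.int8)
    flips = rng.random(s) < params.eps
    query[flips] = 1 - query[flips]
    return query, path
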