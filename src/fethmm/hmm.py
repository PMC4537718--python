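"""Two-state hidden Markov model numerics.

Scaled forward-backward recursions (Rabiner scaling), posterior decoding,
and Baum-Welch EM with two emission families:

* :class:`BernoulliEmission` — a single symmetric correctness probability
  ``p``: an observed binary call matches the hidden state with probability
  ``p`` and flips with probability ``1 - p``. Re-estimated each M-step and
  projected onto [0.5, 1 - 1e-6] so that state 1 always means "differential
  methylation".
* :class:`FixedEmissionMatrix` — a per-bin N x 2 likelihood matrix (row n =
  likelihood of the observation under state 0 and state 1) that is never
  re-estimated; EM then updates only the initial distribution and the
  transition matrix.

The decoded quantity is the posterior ``gamma_n(i) = P(s_n = i | O)``; no
Viterbi path is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, ValidationError

#: floor/ceiling applied to fixed emission likelihoods
EMISSION_CLIP = 1e-10

#: projection bounds of the Bernoulli correctness probability
P_CORRECT_MIN = 0.5
P_CORRECT_MAX = 1.0 - 1e-6

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _fb_core(pi, A, E):
    """Scaled forward-backward for a 2-state chain.

    Returns (gamma, xi_sum, loglik) where gamma is (N, 2), xi_sum is the
    (2, 2) sum over n < N of xi_n(i, j), and loglik = sum(log c_n).
    """
    N = E.shape[0]
    alpha = np.empty((N, 2))
    c = np.empty(N)

    a0 = pi[0] * E[0, 0]
    a1 = pi[1] * E[0, 1]
    c0 = a0 + a1
    if c0 <= 0.0:
        return np.empty((0, 2)), np.zeros((2, 2)), np.nan
    alpha[0, 0] = a0 / c0
    alpha[0, 1] = a1 / c0
    c[0] = c0

    for t in range(1, N):
        a0 = (alpha[t - 1, 0] * A[0, 0] + alpha[t - 1, 1] * A[1, 0]) * E[t, 0]
        a1 = (alpha[t - 1, 0] * A[0, 1] + alpha[t - 1, 1] * A[1, 1]) * E[t, 1]
        ct = a0 + a1
        if ct <= 0.0:
            return np.empty((0, 2)), np.zeros((2, 2)), np.nan
        alpha[t, 0] = a0 / ct
        alpha[t, 1] = a1 / ct
        c[t] = ct

    gamma = np.empty((N, 2))
    xi_sum = np.zeros((2, 2))
    b0 = 1.0
    b1 = 1.0
    gamma[N - 1, 0] = alpha[N - 1, 0]
    gamma[N - 1, 1] = alpha[N - 1, 1]
    for t in range(N - 2, -1, -1):
        # beta hat at t, scaled by c[t+1]
        e0 = E[t + 1, 0] * b0
        e1 = E[t + 1, 1] * b1
        nb0 = (A[0, 0] * e0 + A[0, 1] * e1) / c[t + 1]
        nb1 = (A[1, 0] * e0 + A[1, 1] * e1) / c[t + 1]
        # xi_t(i, j) = alpha_t(i) A_ij E[t+1, j] betahat_{t+1}(j) / c[t+1]
        xi_sum[0, 0] += alpha[t, 0] * A[0, 0] * e0 / c[t + 1]
        xi_sum[0, 1] += alpha[t, 0] * A[0, 1] * e1 / c[t + 1]
        xi_sum[1, 0] += alpha[t, 1] * A[1, 0] * e0 / c[t + 1]
        xi_sum[1, 1] += alpha[t, 1] * A[1, 1] * e1 / c[t + 1]
        g0 = alpha[t, 0] * nb0
        g1 = alpha[t, 1] * nb1
        s = g0 + g1
        gamma[t, 0] = g0 / s
        gamma[t, 1] = g1 / s
        b0 = nb0
        b1 = nb1

    loglik = 0.0
    for t in range(N):
        loglik += np.log(c[t])
    return gamma, xi_sum, loglik


@dataclass(frozen=True)
class BernoulliEmission:
    """Symmetric binary emission: P(observation matches state) = p_correct."""

    p_correct: float

    def __post_init__(self) -> None:
        if not (0.5 <= self.p_correct <= 1.0):
            raise ValidationError(
                f"p_correct must lie in [0.5, 1], got {self.p_correct}"
            )

    def likelihoods(self, obs: np.ndarray) -> np.ndarray:
        """(N, 2) matrix with entry [n, i] = P(o_n | s_n = i)."""
        obs = np.asarray(obs)
        if obs.ndim != 1 or not np.all((obs == 0) | (obs == 1)):
            raise ValidationError("Bernoulli emission requires a binary 1-D sequence")
        p = min(self.p_correct, P_CORRECT_MAX)
        E = np.empty((obs.shape[0], 2))
        E[:, 0] = np.where(obs == 0, p, 1.0 - p)
        E[:, 1] = np.where(obs == 1, p, 1.0 - p)
        return E


@dataclass(frozen=True)
class FixedEmissionMatrix:
    """Per-bin likelihood rows (state 0, state 1); never re-estimated."""

    rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != 2:
            raise ValidationError("emission matrix must have shape (N, 2)")
        object.__setattr__(
            self, "rows", np.clip(rows, EMISSION_CLIP, 1.0 - EMISSION_CLIP)
        )

    def likelihoods(self, obs: np.ndarray | None = None) -> np.ndarray:
        return self.rows


@dataclass(frozen=True)
class HmmParams:
    """Initial distribution pi, row-stochastic 2x2 transition matrix A, emission."""

    pi: np.ndarray
    A: np.ndarray
    emission: BernoulliEmission | FixedEmissionMatrix

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if pi.shape != (2,) or A.shape != (2, 2):
            raise ValidationError("HmmParams requires pi of shape (2,) and A of shape (2, 2)")
        if np.any(pi < -1e-12) or np.any(A < -1e-12):
            raise ValidationError("pi and A entries must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-9 or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("pi and rows of A must each sum to 1")
        # renormalise away float dust so downstream sums hold to 1e-12
        object.__setattr__(self, "pi", np.clip(pi, 0.0, 1.0) / pi.sum())
        object.__setattr__(self, "A", np.clip(A, 0.0, 1.0) / A.sum(axis=1, keepdims=True))

    def to_dict(self) -> dict:
        d: dict = {"pi": self.pi.tolist(), "A": self.A.tolist()}
        if isinstance(self.emission, BernoulliEmission):
            d["emission"] = {"kind": "bernoulli", "p_correct": self.emission.p_correct}
        else:
            d["emission"] = {"kind": "fixed", "n_rows": int(self.emission.rows.shape[0])}
        return d


@dataclass
class PosteriorTrack:
    """Posterior state probabilities for one chain.

    ``gamma`` holds P(s_n = i | O) per bin; ``gamma1`` is the differential
    methylation column; ``xi_sum`` the summed two-slice marginals;
    ``log_likelihood`` the scaled-forward log P(O).
    """

    gamma: np.ndarray
    xi_sum: np.ndarray
    log_likelihood: float

    @property
    def gamma1(self) -> np.ndarray:
        return self.gamma[:, 1]


@dataclass
class BaumWelchResult:
    params: HmmParams
    track: PosteriorTrack
    log_likelihoods: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _emission_matrix(params: HmmParams, obs: np.ndarray | None) -> np.ndarray:
    if isinstance(params.emission, BernoulliEmission):
        if obs is None:
            raise ValidationError("Bernoulli emission requires an observation sequence")
        return params.emission.likelihoods(obs)
    return params.emission.likelihoods()


def forward_backward(params: HmmParams, obs: np.ndarray | None = None) -> PosteriorTrack:
    """Posterior decode one chain under fixed parameters.

    For Bernoulli emissions pass the binary observation sequence ``obs``;
    for a fixed emission matrix the likelihood rows are taken from the
    parameters directly.
    """
    E = np.ascontiguousarray(_emission_matrix(params, obs), dtype=float)
    if E.shape[0] < 1:
        raise ValidationError("chain length must be >= 1")
    gamma, xi_sum, ll = _fb_core(
        np.ascontiguousarray(params.pi, dtype=float),
        np.ascontiguousarray(params.A, dtype=float),
        E,
    )
    if not np.isfinite(ll):
        raise NumericalError(
            "zero total probability in forward pass; emission likelihoods "
            "vanished for every state at some bin"
        )
    return PosteriorTrack(gamma=gamma, xi_sum=xi_sum, log_likelihood=float(ll))


estep_only = forward_backward  # the E-step of FastFHC is exactly one decode


def _m_step(params: HmmParams, track: PosteriorTrack, obs: np.ndarray | None) -> HmmParams:
    gamma, xi = track.gamma, track.xi_sum
    pi_new = gamma[0].copy()
    denom = xi.sum(axis=1)
    A_new = params.A.copy()
    for i in range(2):
        if denom[i] > 0:
            A_new[i] = xi[i] / denom[i]
    if isinstance(params.emission, BernoulliEmission):
        # posterior-weighted agreement rate, projected to keep state 1 = DMS
        agree = np.where(obs == 0, gamma[:, 0], gamma[:, 1]).sum() / gamma.shape[0]
        p_new = float(np.clip(agree, P_CORRECT_MIN, P_CORRECT_MAX))
        emission = BernoulliEmission(p_new)
    else:
        emission = params.emission
    return HmmParams(pi=pi_new, A=A_new, emission=emission)


def baum_welch(
    init: HmmParams,
    obs: np.ndarray | None = None,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> BaumWelchResult:
    """Fit a 2-state HMM by EM from ``init``.

    With a :class:`BernoulliEmission` all of (pi, A, p) are re-estimated;
    with a :class:`FixedEmissionMatrix` the emission stays fixed and only
    pi and A are updated. Iteration stops when the relative log-likelihood
    change drops below ``tol`` or after ``max_iter`` sweeps; ``max_iter=0``
    (or an infinite ``tol``) returns the initial parameters and their
    posterior untouched.
    """
    if isinstance(init.emission, BernoulliEmission):
        if obs is None:
            raise ValidationError("Baum-Welch with Bernoulli emission requires obs")
        obs = np.asarray(obs)
        n_bins = obs.shape[0]
    else:
        n_bins = init.emission.rows.shape[0]
    if n_bins < 2 and max_iter > 0 and np.isfinite(tol):
        raise ValidationError(
            f"chain of length {n_bins} is too short for transition estimation"
        )

    params = init
    track = forward_backward(params, obs)
    lls = [track.log_likelihood]
    if max_iter == 0 or not np.isfinite(tol):
        return BaumWelchResult(params, track, lls, n_iter=0, converged=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        params = _m_step(params, track, obs)
        new_track = forward_backward(params, obs)
        prev_ll = track.log_likelihood
        track = new_track
        lls.append(track.log_likelihood)
        if abs(track.log_likelihood - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
    return BaumWelchResult(params, track, lls, n_iter=it, converged=converged)


def random_init(
    rng: np.random.Generator,
    emission: BernoulliEmission | FixedEmissionMatrix | None = None,
) -> HmmParams:
    """Seeded random starting point for EM.

    pi = (0.5, 0.5); the diagonal of A is drawn uniformly from [0.6, 0.95];
    a Bernoulli correctness probability, when no emission is supplied, from
    [0.7, 0.95].
    """
    d = rng.uniform(0.6, 0.95, size=2)
    A = np.array([[d[0], 1.0 - d[0]], [1.0 - d[1], d[1]]])
    if emission is None:
        emission = BernoulliEmission(float(rng.uniform(0.7, 0.95)))
    return HmmParams(pi=np.array([0.5, 0.5]), A=A, emission=emission)
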