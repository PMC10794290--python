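"""Multinomial likelihoods, LFDR and the Bayes decision rule, in log space.

The model: a site covered by K reads yields counts X = (R, M, X1, X2) for
the reference, dominant-alternative and two minor-alternative alleles,

    X | theta ~ Multinomial(K; p_R, p_M, e/3, e/3),
    p_R = theta*e/3 + (1-theta)*(1-e),
    p_M = theta*(1-e) + (1-theta)*e/3,

where theta is the alternative allele frequency (0 under the null) and e
the per-read error probability.  The alternative marginal likelihood
averages the multinomial over an equal-weight atom set {theta_l} (the
empirical distribution of allele frequencies at suspected mutant sites).

The LFDR is the posterior null probability

    psi = pi0 * P(X | theta=0) / (pi0 * P(X|theta=0) + (1-pi0) * P(X|theta>0)).

Everything is computed in natural-log space and surfaced as log10: call
thresholds in practice reach 10^-300 and beyond, far outside the linear
double-precision range once weighted by pi0, so log space is not an
optimisation but a correctness requirement.  The convention 0*log(0) = 0
applies to zero-count classes throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

LN10 = math.log(10.0)


@dataclass
class ModelParams:
    """Fitted mixture parameters: null proportion pi0 and the equal-weight
    allele-frequency atoms defining the empirical alternative distribution."""

    pi0: float
    theta_atoms: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError(f"pi0 must be in [0, 1], got {self.pi0}")
        atoms = np.asarray(self.theta_atoms, dtype=float)
        if atoms.size < 1:
            raise ValueError("theta_atoms must contain at least one atom")
        if np.any(atoms <= 0.0) or np.any(atoms > 1.0):
            raise ValueError("all atoms must lie in (0, 1]")
        self.theta_atoms = atoms

    @property
    def s(self) -> int:
        return int(self.theta_atoms.size)


@dataclass
class LfdrResult:
    """Per-site LFDR: log10 psi (authoritative), psi clamped to the linear
    double range, and the binary decision delta (1 = call variant)."""

    site: object
    log10_psi: float
    psi: float
    delta: int = 0
    flagged: bool = False


@dataclass(frozen=True)
class LossSpec:
    """Type-I/type-II loss pair, or a directly supplied LFDR threshold.

    With loss l_I for a false call (type I) and l_II for a missed variant
    (type II), calling is optimal exactly when l_I*psi <= l_II*(1-psi),
    i.e. psi <= tau with tau = l_II / (l_I + l_II): a costlier type-I error
    lowers the threshold and makes calling harder.  A ``tau`` given
    explicitly wins over the loss pair.
    """

    l_I: float = 1.0
    l_II: float = 1.0
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.l_I < 0 or self.l_II < 0 or self.l_I + self.l_II <= 0:
            raise ValueError("losses must be nonnegative with l_I + l_II > 0")
        if self.tau is not None and not (0.0 <= self.tau <= 1.0):
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")

    @property
    def threshold(self) -> float:
        if self.tau is not None:
            return self.tau
        return self.l_II / (self.l_I + self.l_II)


def log_multinomial_coef(K: int, R: int, M: int, X1: int, X2: int) -> float:
    """ln of the multinomial coefficient K! / (R! M! X1! X2!), via log-gamma."""
    if K != R + M + X1 + X2:
        raise ValueError(f"K={K} != R+M+X1+X2={R + M + X1 + X2}")
    if min(R, M, X1, X2) < 0:
        raise ValueError("counts must be nonnegative")
    return float(gammaln(K + 1) - gammaln(R + 1) - gammaln(M + 1) - gammaln(X1 + 1) - gammaln(X2 + 1))


def _xlogy(x: float, y: float) -> float:
    """x*log(y) with the 0*log(0)=0 convention; -inf for x>0, y=0."""
    if x == 0:
        return 0.0
    return x * (math.log(y) if y > 0 else -math.inf)


def log_null_likelihood(site, e: float) -> float:
    """ln P(X | theta=0): all non-reference reads are errors.

    Equals log-multinomial-coefficient + R ln(1-e) + (K-R) ln(e/3).
    At e=0 the value is 0 for an all-reference site and -inf otherwise.
    """
    coef = log_multinomial_coef(site.K, site.R, site.M, site.X1, site.X2)
    return coef + _xlogy(site.R, 1.0 - e) + _xlogy(site.K - site.R, e / 3.0)


def category_probs(theta: float, e: float) -> tuple[float, float, float, float]:
    """(p_R, p_M, p_X1, p_X2) of the four-allele multinomial at (theta, e)."""
    p_r = theta * e / 3.0 + (1.0 - theta) * (1.0 - e)
    p_m = theta * (1.0 - e) + (1.0 - theta) * e / 3.0
    return p_r, p_m, e / 3.0, e / 3.0


def log_alt_likelihood_at_theta(site, e: float, theta: float) -> float:
    """ln P(X | theta) for a fixed alternative allele frequency theta."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    p_r, p_m, p_x, _ = category_probs(theta, e)
    coef = log_multinomial_coef(site.K, site.R, site.M, site.X1, site.X2)
    return coef + _xlogy(site.R, p_r) + _xlogy(site.M, p_m) + _xlogy(site.X1 + site.X2, p_x)


def log_alt_likelihood_empirical(site, e: float, atoms) -> float:
    """ln P(X | theta>0) under the equal-weight atom set: the log of the
    plain average of the per-atom likelihoods, via log-sum-exp."""
    atoms = np.asarray(atoms, dtype=float)
    if atoms.size == 0:
        raise ValueError("empty atom set")
    logs = np.array([log_alt_likelihood_at_theta(site, e, t) for t in atoms])
    return float(logsumexp(logs) - math.log(atoms.size))


def lfdr(log_p0: float, log_p1: float, pi0: float, site=None) -> LfdrResult:
    """Posterior null probability psi from the two log-likelihoods and pi0.

    Computed entirely in log space: log psi = a - logaddexp(a, b) with
    a = ln pi0 + log_p0 and b = ln(1-pi0) + log_p1, exact at pi0 in {0, 1}.
    If both likelihoods are zero the result is undefined and flagged.
    """
    if not (0.0 <= pi0 <= 1.0):
        raise ValueError(f"pi0 must be in [0, 1], got {pi0}")
    if pi0 == 0.0:
        return LfdrResult(site=site, log10_psi=-math.inf, psi=0.0)
    if pi0 == 1.0:
        return LfdrResult(site=site, log10_psi=0.0, psi=1.0)
    a = math.log(pi0) + log_p0
    b = math.log1p(-pi0) + log_p1
    if a == -math.inf and b == -math.inf:
        return LfdrResult(site=site, log10_psi=math.nan, psi=math.nan, flagged=True)
    log_psi = a - np.logaddexp(a, b)
    log10_psi = float(log_psi / LN10)
    return LfdrResult(site=site, log10_psi=log10_psi, psi=float(math.exp(log_psi)))


def decide(result: LfdrResult, loss: LossSpec) -> int:
    """Bayes rule: delta = 1 (call a variant) iff psi <= tau, boundary
    inclusive.  The comparison is performed on the log10 scale so that
    thresholds below the linear double range still discriminate."""
    tau = loss.threshold
    if math.isnan(result.log10_psi):
        return 0
    if tau == 0.0:
        return int(result.log10_psi == -math.inf)
    log10_tau = math.log10(tau)
    return int(result.log10_psi <= log10_tau)


def lfdr_from_bayes_factor(log_bf: float, pi0: float) -> LfdrResult:
    """psi from the null/alternative Bayes factor: with prior odds
    PO = pi0/(1-pi0), psi = PO*BF / (PO*BF + 1), computed in log space.

    Algebraically identical to :func:`lfdr` with log_bf = log_p0 - log_p1.
    """
    return lfdr(log_p0=log_bf, log_p1=0.0, pi0=pi0)


# ---------------------------------------------------------------------------
# Vectorised forms used for genome-scale passes.


def log_null_likelihood_arrays(K, R, M, X1, X2, e) -> np.ndarray:
    """Vectorised ln P(X | theta=0) for arrays of sites (shared shapes)."""
    K = np.asarray(K, float)
    R = np.asarray(R, float)
    coef = (gammaln(K + 1) - gammaln(R + 1) - gammaln(np.asarray(M, float) + 1)
            - gammaln(np.asarray(X1, float) + 1) - gammaln(np.asarray(X2, float) + 1))
    e = np.asarray(e, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ref = np.where(R > 0, R * np.log(1.0 - e), 0.0)
        t_err = np.where(K - R > 0, (K - R) * np.log(e / 3.0), 0.0)
    return coef + t_ref + t_err


def log_alt_likelihood_empirical_arrays(K, R, M, X1, X2, e, atoms,
                                        block_size: int = 512) -> np.ndarray:
    """Vectorised ln P(X | theta>0) under an atom set, blocked over sites.

    Evaluates the (sites x atoms) per-atom log-likelihood matrix in blocks
    of ``block_size`` sites to bound memory, then log-sum-exps over atoms.
    """
    K = np.asarray(K, float)
    R = np.asarray(R, float)
    M = np.asarray(M, float)
    X = np.asarray(X1, float) + np.asarray(X2, float)
    e = np.broadcast_to(np.asarray(e, float), K.shape)
    atoms = np.asarray(atoms, float)
    if atoms.size == 0:
        raise ValueError("empty atom set")
    coef = (gammaln(K + 1) - gammaln(R + 1) - gammaln(M + 1)
            - gammaln(np.asarray(X1, float) + 1) - gammaln(np.asarray(X2, float) + 1))
    n = K.size
    out = np.empty(n)
    log_s = math.log(atoms.size)
    th = atoms[None, :]
    for start in range(0, n, block_size):
        sl = slice(start, min(start + block_size, n))
        eb = e[sl, None]
        p_r = th * eb / 3.0 + (1.0 - th) * (1.0 - eb)
        p_m = th * (1.0 - eb) + (1.0 - th) * eb / 3.0
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(R[sl, None] > 0, R[sl, None] * np.log(p_r), 0.0)
            ll += np.where(M[sl, None] > 0, M[sl, None] * np.log(p_m), 0.0)
            ll += np.where(X[sl, None] > 0, X[sl, None] * np.log(eb / 3.0), 0.0)
        out[sl] = logsumexp(ll, axis=1) - log_s
    return coef + out


def lfdr_arrays(log_p0: np.ndarray, log_p1: np.ndarray, pi0: float) -> np.ndarray:
    """Vectorised log10 psi; same boundary handling as :func:`lfdr`."""
    if not (0.0 <= pi0 <= 1.0):
        raise ValueError(f"pi0 must be in [0, 1], got {pi0}")
    log_p0 = np.asarray(log_p0, float)
    log_p1 = np.asarray(log_p1, float)
    if pi0 == 0.0:
        return np.full(log_p0.shape, -np.inf)
    if pi0 == 1.0:
        return np.zeros(log_p0.shape)
    a = math.log(pi0) + log_p0
    b = math.log1p(-pi0) + log_p1
    with np.errstate(invalid="ignore"):
        log_psi = a - np.logaddexp(a, b)
    log_psi = np.where((a == -np.inf) & (b == -np.inf), np.nan, log_psi)
    return log_psi / LN10
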