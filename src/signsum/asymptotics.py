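"""Asymptotic confidence intervals for the subsampling statistics.

Both the subsample t-statistic U^T and the sign-sum statistic U^S are
two-sample U-statistics and hence asymptotically normal, so each admits
an interval E[U] +/- Z_{alpha/2} * sigma_U / sqrt(n).  For U^T the
interval is available in closed form and depends on the two group
distributions only through their first two moments; for U^S the mean
and asymptotic variance involve the full distribution functions:

    E[U^S]        = E[G1(V1)],
    sigma_tilde^2 = (a^2/pi1) Var[G1(V1)] + (b^2/pi0) Var[G0(V0)],

where G_y(v) = Pr(W_y <= v) and, with X_1* ~ F1 and X_0* ~ F0 all
independent,

    V1 = (1/a) X_11,   W1 = -(1/a) sum_{i=2}^{a} X_1i + (1/b) sum_j X_0j,
    V0 = -(1/b) X_01,  W0 = -(1/a) sum_i X_1i + (1/b) sum_{j=2}^{b} X_0j.

Because U^S depends on F1 and F0 beyond their moments, its upper
confidence limit separates a homogeneous disease group from a
mixture-contaminated one even when the two are calibrated to identical
asymptotic t — the basis for preferring small a and larger b.

For normal and two-component normal-mixture groups every W_y is itself a
finite normal mixture (the number of second-component draws among k iid
mixture draws is Binomial(k, tau2), giving an exact (k+1)-component
expansion), so G_y is a closed-form mixture CDF and the outer
expectations reduce to one-dimensional quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "NormalMixture",
    "TwoGroupModel",
    "ConfidenceInterval",
    "mixture_moments",
    "t_ci",
    "signsum_moments",
    "signsum_ci",
    "ucl_difference",
]

_QUAD_SD_RANGE = 10.0  # integrate over +/- 10 sd of each component
_QUAD_EPSABS = 1e-10


class QuadratureError(RuntimeError):
    """Adaptive quadrature failed to reach the requested tolerance."""


@dataclass(frozen=True)
class NormalMixture:
    """Finite normal mixture sum_c w_c N(mu_c, var_c).

    A single-component instance represents a plain normal; components
    with ``var == 0`` are point masses (only valid as intermediate
    convolution terms).
    """

    w: tuple[float, ...]
    mu: tuple[float, ...]
    var: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.w) == len(self.mu) == len(self.var)):
            raise ValueError("component arrays must have equal length")
        if abs(sum(self.w) - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if any(v < 0 for v in self.var):
            raise ValueError("variances must be non-negative")

    @classmethod
    def normal(cls, mu: float, var: float) -> "NormalMixture":
        return cls((1.0,), (float(mu),), (float(var),))

    @classmethod
    def two_component(cls, tau1: float, m1: float, v1_sq: float,
                      m2: float, v2_sq: float) -> "NormalMixture":
        if not 0.0 < tau1 < 1.0:
            raise ValueError("mixing proportion tau1 must lie in (0, 1)")
        if v1_sq <= 0 or v2_sq <= 0:
            raise ValueError("component variances must be positive")
        return cls((float(tau1), 1.0 - float(tau1)),
                   (float(m1), float(m2)), (float(v1_sq), float(v2_sq)))

    # -- moments -------------------------------------------------------
    def mean(self) -> float:
        return float(np.dot(self.w, self.mu))

    def variance(self) -> float:
        w, mu, var = map(np.asarray, (self.w, self.mu, self.var))
        return float(np.dot(w, var + mu**2) - self.mean() ** 2)

    # -- algebra -------------------------------------------------------
    def scale(self, c: float) -> "NormalMixture":
        """Distribution of c * X."""
        return NormalMixture(self.w, tuple(c * m for m in self.mu),
                             tuple(c * c * v for v in self.var))

    def iid_sum(self, k: int) -> "NormalMixture":
        """Distribution of the sum of ``k`` iid draws.

        For a two-component mixture the number of second-component draws
        is Binomial(k, w2), so the sum is an exact (k+1)-component
        mixture; for a plain normal it is a single component.  ``k = 0``
        is the point mass at zero.
        """
        if k == 0:
            return NormalMixture((1.0,), (0.0,), (0.0,))
        if len(self.w) == 1:
            return NormalMixture((1.0,), (k * self.mu[0],), (k * self.var[0],))
        if len(self.w) != 2:
            raise ValueError("iid_sum supports at most two components")
        j = np.arange(k + 1)
        weights = stats.binom.pmf(j, k, self.w[1])
        mus = (k - j) * self.mu[0] + j * self.mu[1]
        vars_ = (k - j) * self.var[0] + j * self.var[1]
        return NormalMixture(tuple(weights), tuple(mus), tuple(vars_))

    def convolve(self, other: "NormalMixture") -> "NormalMixture":
        """Distribution of X + Y for independent X ~ self, Y ~ other."""
        w = np.outer(self.w, other.w).ravel()
        mu = np.add.outer(self.mu, other.mu).ravel()
        var = np.add.outer(self.var, other.var).ravel()
        return NormalMixture(tuple(w), tuple(mu), tuple(var))

    # -- evaluation ----------------------------------------------------
    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros(x.shape)
        for w, m, v in zip(self.w, self.mu, self.var):
            if v == 0.0:
                out += w * (x >= m)
            else:
                out += w * stats.norm.cdf(x, loc=m, scale=np.sqrt(v))
        return out

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.w), size=size, p=self.w)
        sd = np.sqrt(np.asarray(self.var))[comp]
        return np.asarray(self.mu)[comp] + sd * rng.standard_normal(size)

    def expect(self, fn) -> float:
        """E[fn(X)] by adaptive quadrature, component by component."""
        total = 0.0
        for w, m, v in zip(self.w, self.mu, self.var):
            if v == 0.0:
                total += w * float(fn(np.array(m)))
                continue
            sd = np.sqrt(v)
            val, err = integrate.quad(
                lambda x: fn(x) * stats.norm.pdf(x, loc=m, scale=sd),
                m - _QUAD_SD_RANGE * sd, m + _QUAD_SD_RANGE * sd,
                epsabs=_QUAD_EPSABS, limit=200,
            )
            if err > 1e-6:
                raise QuadratureError(
                    f"quadrature error estimate {err:.2e} for component "
                    f"N({m:.3g}, {v:.3g})"
                )
            total += w * val
        return total


@dataclass(frozen=True)
class TwoGroupModel:
    """Parametric two-group expression model.

    ``f0`` is the normal-group distribution (a plain normal); ``f1`` the
    disease-group distribution, either a plain normal (homo gene) or a
    two-component normal mixture (hetero gene, with proportion ``tau1``
    indistinguishable from the normal group).  ``pi1`` is the asymptotic
    disease sampling ratio; ``pi0 = 1 - pi1``.
    """

    f1: NormalMixture
    f0: NormalMixture
    pi1: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.pi1 < 1.0:
            raise ValueError("pi1 must lie in (0, 1)")
        if any(v <= 0 for v in self.f1.var) or any(v <= 0 for v in self.f0.var):
            raise ValueError("group variances must be positive")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    @classmethod
    def homo(cls, mu1: float = 1.0, sigma1_sq: float = 1.0,
             mu0: float = 0.0, sigma0_sq: float = 1.0,
             pi1: float = 0.5) -> "TwoGroupModel":
        return cls(NormalMixture.normal(mu1, sigma1_sq),
                   NormalMixture.normal(mu0, sigma0_sq), pi1)

    @classmethod
    def hetero(cls, tau1: float, m2: float, m1: float = 0.0,
               v1_sq: float = 1.0, v2_sq: float = 1.0,
               mu0: float = 0.0, sigma0_sq: float = 1.0,
               pi1: float = 0.5) -> "TwoGroupModel":
        return cls(NormalMixture.two_component(tau1, m1, v1_sq, m2, v2_sq),
                   NormalMixture.normal(mu0, sigma0_sq), pi1)


@dataclass(frozen=True)
class ConfidenceInterval:
    center: float
    half_width: float
    alpha: float
    n: int
    statistic: str

    @property
    def lower(self) -> float:
        return self.center - self.half_width

    @property
    def upper(self) -> float:
        return self.center + self.half_width


def mixture_moments(f1: NormalMixture) -> tuple[float, float]:
    """Mean and variance (mu1*, sigma1*^2) of a disease-group mixture."""
    return f1.mean(), f1.variance()


def _z(alpha: float) -> float:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


def t_ci(model: TwoGroupModel, a: int, b: int, n: int,
         alpha: float = 0.05) -> ConfidenceInterval:
    """Asymptotic CI for the subsample t-statistic U^T.

    Center sqrt(a+b)(mu1 - mu0)/sqrt(sigma1^2/pi1 + sigma0^2/pi0); for a
    mixture disease group, mu1 and sigma1^2 are the mixture moments.
    The half-width Z_{alpha/2} sqrt((a+b)/n) does not depend on the
    model at all — which is why two calibrated genes are
    indistinguishable to the t-statistic.
    """
    if n < 1:
        raise ValueError("n must be positive")
    mu1, s1_sq = mixture_moments(model.f1)
    mu0, s0_sq = mixture_moments(model.f0)
    center = (np.sqrt(a + b) * (mu1 - mu0)
              / np.sqrt(s1_sq / model.pi1 + s0_sq / model.pi0))
    half = _z(alpha) * np.sqrt((a + b) / n)
    return ConfidenceInterval(float(center), float(half), alpha, n,
                              "subsample_t")


def _w_distributions(model: TwoGroupModel, a: int, b: int
                     ) -> tuple[NormalMixture, NormalMixture]:
    """Distributions of W1 and W0 as finite normal mixtures."""
    neg_f1 = model.f1.scale(-1.0 / a)
    pos_f0 = model.f0.scale(1.0 / b)
    w1 = neg_f1.iid_sum(a - 1).convolve(pos_f0.iid_sum(b))
    w0 = neg_f1.iid_sum(a).convolve(pos_f0.iid_sum(b - 1))
    return w1, w0


def signsum_moments(model: TwoGroupModel, a: int, b: int
                    ) -> tuple[float, float]:
    """(E[U^S], sigma_tilde^2) for the sign-sum statistic.

    G_y(v) = Pr(W_y <= v) is a closed-form normal-mixture CDF; the outer
    expectations over V1 = (1/a) X_11 and V0 = -(1/b) X_01 are evaluated
    by adaptive quadrature (absolute tolerance well below 1e-8).
    """
    if a < 1 or b < 1:
        raise ValueError("subset sizes must be positive")
    w1, w0 = _w_distributions(model, a, b)
    v1 = model.f1.scale(1.0 / a)
    v0 = model.f0.scale(-1.0 / b)

    e1 = v1.expect(w1.cdf)
    e1_sq = v1.expect(lambda x: w1.cdf(x) ** 2)
    var1 = max(e1_sq - e1 * e1, 0.0)
    e0 = v0.expect(w0.cdf)
    e0_sq = v0.expect(lambda x: w0.cdf(x) ** 2)
    var0 = max(e0_sq - e0 * e0, 0.0)

    sigma_tilde_sq = a * a / model.pi1 * var1 + b * b / model.pi0 * var0
    return float(e1), float(sigma_tilde_sq)


def signsum_ci(model: TwoGroupModel, a: int, b: int, n: int,
               alpha: float = 0.05) -> ConfidenceInterval:
    """Asymptotic CI for U^S: E[U^S] +/- Z_{alpha/2} sigma_tilde/sqrt(n)."""
    if n < 1:
        raise ValueError("n must be positive")
    e_us, sig_sq = signsum_moments(model, a, b)
    half = _z(alpha) * np.sqrt(sig_sq / n)
    return ConfidenceInterval(e_us, float(half), alpha, n, "sign_sum")


def ucl_difference(homo: TwoGroupModel, hetero: TwoGroupModel,
                   a: int, b: int, n: int,
                   alpha: float = 0.05) -> float:
    """Homo minus hetero upper confidence limit of the sign-sum statistic.

    When the two models are calibrated to equal asymptotic t, a positive
    value means the sign-sum statistic separates the homo gene from the
    hetero gene even though the t-statistic cannot.
    """
    return (signsum_ci(homo, a, b, n, alpha).upper
            - signsum_ci(hetero, a, b, n, alpha).upper)


def ucl_difference_grid(homo: TwoGroupModel, hetero: TwoGroupModel,
                        a_values, b_values, n: int,
                        alpha: float = 0.05):
    """UCL differences over a grid of (a, b); returns a tidy DataFrame."""
    import pandas as pd

    rows = [
        {"a": a, "b": b,
         "ucl_difference": ucl_difference(homo, hetero, a, b, n, alpha)}
        for a in a_values for b in b_values
    ]
    return pd.DataFrame(rows)


def plot_ucl_difference(grid, ax=None):
    """Line plot of UCL difference vs b, one line per a."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for a, sub in grid.groupby("a"):
        ax.plot(sub["b"], sub["ucl_difference"], marker="o", label=f"a={a}")
    ax.set_xlabel("b (normal-group subset size)")
    ax.set_ylabel("UCL(homo) - UCL(hetero)")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.legend()
    return ax
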