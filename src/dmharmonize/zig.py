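"""The zero-inflated gamma (ZIG) distribution.

A sparse non-negative connectivity value is modeled as a mixture of a point
mass at zero with weight ``lam`` and a gamma density ``g(c; shape, scale)`` on
the positive reals:

    f(c) = lam * delta_+(c) + (1 - lam) * g(c; gamma_shape, beta)

The CDF uses a step ``u`` with ``u(0) = 0``, so the mixture CDF is exactly 0
at c = 0 and the closed-form inverse CDF maps any probability p <= lam to 0.
This zero-preserving convention is what makes quantile mapping between two
ZIG distributions send zeros to zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = ["ZIGParams", "fit_zig", "zig_pdf", "zig_cdf", "zig_invcdf"]

# upper clip for probabilities entering the gamma quantile, keeps outputs finite
P_CLIP = 1.0 - 1e-12

#: below this many positive observations a gamma MLE is flagged unreliable
DEFAULT_MIN_NONZERO = 10


@dataclass(frozen=True)
class ZIGParams:
    """Fitted parameters of one connection's zero-inflated gamma model.

    ``beta`` is the gamma scale and ``gamma_shape`` the gamma shape; both are
    None when the sample had no positive values (``lam == 1``), in which case
    the continuous component must not be evaluated.  ``reliable`` is False
    when the positive sample was smaller than the configured minimum.
    """

    lam: float
    beta: float | None
    gamma_shape: float | None
    n_obs: int
    n_nonzero: int
    reliable: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.n_nonzero > self.n_obs:
            raise ValueError("n_nonzero cannot exceed n_obs")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta (scale) must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    @property
    def degenerate(self) -> bool:
        """True when the distribution is a pure point mass at zero."""
        return self.beta is None or self.gamma_shape is None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ZIGParams":
        return cls(**d)


def _check_params(params: ZIGParams) -> None:
    if params.degenerate and params.lam < 1.0:
        raise ValueError("gamma parameters undefined but lam < 1")


def fit_zig(
    values: np.ndarray, min_nonzero: int = DEFAULT_MIN_NONZERO
) -> ZIGParams:
    """Fit the ZIG model to a non-negative sample.

    ``lam`` is the empirical fraction of exact zeros (no epsilon threshold);
    the gamma scale and shape are the maximum-likelihood estimates over the
    strictly positive values, with location fixed at zero.  A fit with fewer
    than ``min_nonzero`` positive values is flagged unreliable; a fit whose
    estimated shape falls below 1 triggers a warning (the model expects a
    density that vanishes at the origin).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    if np.isnan(values).any():
        raise ValueError("sample contains NaN")
    if (values < 0).any():
        raise ValueError("sample contains negative values")
    n_obs = values.size
    positive = values[values > 0]
    n_nonzero = positive.size
    lam = 1.0 - n_nonzero / n_obs
    if n_nonzero == 0:
        return ZIGParams(
            lam=1.0, beta=None, gamma_shape=None, n_obs=n_obs, n_nonzero=0,
            reliable=False,
        )
    if n_nonzero == 1:
        # MLE is undefined for a single point; record a degenerate-width fit
        shape, scale = 1.0, float(positive[0])
    else:
        shape, _, scale = stats.gamma.fit(positive, floc=0)
    if shape < 1.0:
        warnings.warn(
            f"estimated gamma shape {shape:.3g} < 1; density diverges at 0",
            stacklevel=2,
        )
    return ZIGParams(
        lam=lam,
        beta=float(scale),
        gamma_shape=float(shape),
        n_obs=n_obs,
        n_nonzero=n_nonzero,
        reliable=n_nonzero >= min_nonzero,
    )


def zig_pdf(c, params: ZIGParams):
    """Continuous part of the mixture density, (1 - lam) * g(c).

    The point mass at zero is *not* folded in here; its weight is
    ``params.lam`` and should be reported separately (a density and a point
    mass live on different scales).
    """
    _check_params(params)
    c = np.asarray(c, dtype=float)
    if (c < 0).any():
        raise ValueError("connectivity values must be non-negative")
    out = (1.0 - params.lam) * stats.gamma.pdf(
        c, params.gamma_shape, scale=params.beta
    )
    return out if out.ndim else float(out)


def zig_cdf(c, params: ZIGParams):
    """Mixture CDF  F(c) = lam * u(c) + (1 - lam) * G(c),  with u(0) = 0."""
    c = np.asarray(c, dtype=float)
    step = (c > 0).astype(float)
    if params.degenerate:
        out = params.lam * step
    else:
        out = params.lam * step + (1.0 - params.lam) * stats.gamma.cdf(
            np.maximum(c, 0.0), params.gamma_shape, scale=params.beta
        )
    return out if out.ndim else float(out)


def zig_invcdf(p, params: ZIGParams):
    """Closed-form inverse CDF: 0 for p <= lam, else the gamma quantile of
    (p - lam) / (1 - lam).

    Probabilities are clipped just below 1 before the gamma quantile so the
    output is always finite.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.minimum(p, P_CLIP)
    at_zero = p <= params.lam
    if params.degenerate:
        if not at_zero.all():
            raise ValueError("p > lam requested from a pure point-mass distribution")
        out = np.zeros_like(p)
        return out if out.ndim else float(out)
    inner = (p - params.lam) / (1.0 - params.lam)
    out = np.where(
        at_zero,
        0.0,
        stats.gamma.ppf(np.where(at_zero, 0.0, inner), params.gamma_shape,
                        scale=params.beta),
    )
    return out if out.ndim else float(out)
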