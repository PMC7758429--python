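"""Exchange-correlation functionals: LDA (Slater exchange) and PBE
(exchange + correlation with a PW92 local part), restricted spin.

Gradient dependence is carried through sigma = |grad rho|^2 (the gradient
invariant), with derivative channels

    v_rho   = d(rho * eps)/d(rho)
    v_sigma = d(rho * eps)/d(sigma)

which together with Z_mu = 1/2 v_rho phi_mu + 2 v_sigma (grad rho . grad
phi_mu) reproduce the standard GGA potential.  All derivative channels are
analytic and validated against finite differences in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Negative densities larger in magnitude than this are treated as errors;
#: anything in (-CLAMP_TOL, 0) is quadrature noise and clamped to zero.
CLAMP_TOL = 1e-14

#: Floor applied inside correlation logarithms/powers at grid tails.
RHO_FLOOR = 1e-32

# Slater exchange: eps_x = -Cx rho^(1/3)
_CX = 0.75 * (3.0 / np.pi) ** (1.0 / 3.0)

# PBE exchange
PBE_KAPPA = 0.804
PBE_MU = 0.2195149727645171

# PW92 unpolarized correlation parameters
_PW_A = 0.0310907
_PW_A1 = 0.21370
_PW_B1 = 7.5957
_PW_B2 = 3.5876
_PW_B3 = 1.6382
_PW_B4 = 0.49294

# PBE correlation gradient term
_PBE_GAMMA = (1.0 - np.log(2.0)) / np.pi ** 2
_PBE_BETA = 0.06672455060314922


@dataclass
class XCEval:
    """Per-point energy density and derivative channels.

    When produced by :func:`eval_functional` with quadrature weights, all
    three arrays are elementwise weight-folded.
    """

    eps: np.ndarray
    vrho: np.ndarray
    vsigma: np.ndarray

    def __post_init__(self):
        if not (self.eps.shape == self.vrho.shape == self.vsigma.shape):
            raise ValueError("XCEval channels must be congruent")


def u_variables(rho: np.ndarray,
                grad_rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reference-frame-independent functional inputs (rho, sigma).

    Tiny negative densities from quadrature noise are clamped to zero;
    anything below -CLAMP_TOL is an error.
    """
    rho = np.asarray(rho, dtype=float)
    grad_rho = np.asarray(grad_rho, dtype=float)
    if grad_rho.shape != rho.shape + (3,):
        raise ValueError(
            f"gradient shape {grad_rho.shape} does not match density "
            f"shape {rho.shape}")
    if np.any(rho < -CLAMP_TOL):
        raise ValueError(
            f"density has entries below -{CLAMP_TOL:g}; not quadrature "
            f"noise")
    rho = np.where(rho < 0.0, 0.0, rho)
    sigma = np.einsum("...i,...i->...", grad_rho, grad_rho)
    return rho, sigma


def lda_exchange(rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slater exchange energy density per particle and v_rho."""
    rho = np.asarray(rho, dtype=float)
    eps = -_CX * np.cbrt(rho)
    return eps, (4.0 / 3.0) * eps


def pbe_exchange(rho: np.ndarray, sigma: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PBE exchange: LDA exchange times the enhancement factor
    F(s) = 1 + kappa - kappa / (1 + mu s^2 / kappa)."""
    rho = np.asarray(rho, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    eps = np.zeros_like(rho)
    vrho = np.zeros_like(rho)
    vsigma = np.zeros_like(rho)
    pos = rho > 0.0
    if not np.any(pos):
        return eps, vrho, vsigma
    r = rho[pos]
    sg = sigma[pos]
    eps_lda = -_CX * np.cbrt(r)
    kf2 = (3.0 * np.pi ** 2) ** (2.0 / 3.0) * r ** (2.0 / 3.0)
    s2 = sg / (4.0 * kf2 * r * r)
    denom = 1.0 + PBE_MU * s2 / PBE_KAPPA
    F = 1.0 + PBE_KAPPA - PBE_KAPPA / denom
    dF_ds2 = PBE_MU / denom ** 2
    eps[pos] = eps_lda * F
    # d(rho eps)/drho at fixed sigma: s2 ~ rho^(-8/3)
    vrho[pos] = (4.0 / 3.0) * eps_lda * F \
        + r * eps_lda * dF_ds2 * (-8.0 / 3.0) * s2 / r
    vsigma[pos] = r * eps_lda * dF_ds2 / (4.0 * kf2 * r * r)
    return eps, vrho, vsigma


def _pw92_ec(rs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PW92 unpolarized correlation energy per particle and d/d(rs)."""
    sqrt_rs = np.sqrt(rs)
    den = 2.0 * _PW_A * (_PW_B1 * sqrt_rs + _PW_B2 * rs
                         + _PW_B3 * rs * sqrt_rs + _PW_B4 * rs * rs)
    dden = 2.0 * _PW_A * (0.5 * _PW_B1 / sqrt_rs + _PW_B2
                          + 1.5 * _PW_B3 * sqrt_rs + 2.0 * _PW_B4 * rs)
    log_arg = np.log1p(1.0 / den)
    ec = -2.0 * _PW_A * (1.0 + _PW_A1 * rs) * log_arg
    dec = (-2.0 * _PW_A * _PW_A1 * log_arg
           + 2.0 * _PW_A * (1.0 + _PW_A1 * rs) * dden / (den * den + den))
    return ec, dec


def pbe_correlation(rho: np.ndarray, sigma: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PBE correlation: PW92 local part plus the gradient term H."""
    rho = np.asarray(rho, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    eps = np.zeros_like(rho)
    vrho = np.zeros_like(rho)
    vsigma = np.zeros_like(rho)
    pos = rho > RHO_FLOOR
    if not np.any(pos):
        return eps, vrho, vsigma
    r = rho[pos]
    sg = sigma[pos]

    rs = (3.0 / (4.0 * np.pi * r)) ** (1.0 / 3.0)
    ec_loc, dec_drs = _pw92_ec(rs)
    drs_drho = -rs / (3.0 * r)
    dec_drho = dec_drs * drs_drho

    # t^2 = sigma / (4 ks^2 rho^2), ks^2 = 4 kF / pi
    kf = (3.0 * np.pi ** 2) ** (1.0 / 3.0) * np.cbrt(r)
    t2 = sg * np.pi / (16.0 * kf * r * r)
    bg = _PBE_BETA / _PBE_GAMMA
    expm = np.exp(-ec_loc / _PBE_GAMMA)
    Ah = bg / np.maximum(expm - 1.0, RHO_FLOOR)
    u = Ah * t2
    D = 1.0 + u + u * u
    Q = t2 * (1.0 + u) / D
    H = _PBE_GAMMA * np.log1p(bg * Q)

    dH_dQ = _PBE_BETA / (1.0 + bg * Q)
    dQ_dt2 = (1.0 + 2.0 * u) / (D * D)
    dQ_dA = -t2 * t2 * u * (2.0 + u) / (D * D)
    dA_dec = (bg / _PBE_GAMMA) * expm / np.maximum(expm - 1.0,
                                                   RHO_FLOOR) ** 2
    dt2_drho = -(7.0 / 3.0) * t2 / r
    dt2_dsigma = np.pi / (16.0 * kf * r * r)

    dH_drho = dH_dQ * (dQ_dt2 * dt2_drho + dQ_dA * dA_dec * dec_drho)
    # H -> -ec_loc at gradient saturation; roundoff can leave the sum a
    # few ulp positive, which would violate eps_c <= 0
    eps[pos] = np.minimum(ec_loc + H, 0.0)
    vrho[pos] = (ec_loc + H) + r * (dec_drho + dH_drho)
    vsigma[pos] = r * dH_dQ * dQ_dt2 * dt2_dsigma
    return eps, vrho, vsigma


_FUNCTIONALS = ("LDA", "PBE")


def eval_functional(name: str, rho: np.ndarray, sigma: np.ndarray,
                    weights: np.ndarray | None = None) -> XCEval:
    """Evaluate a named functional, folding quadrature weights into all
    channels (eps_i <- w_i eps_i, likewise the derivatives)."""
    key = name.upper()
    if key == "LDA":
        # Slater exchange only; correlation enters through the PBE branch
        eps, vrho = lda_exchange(rho)
        vsigma = np.zeros_like(eps)
    elif key == "PBE":
        ex, vxr, vxs = pbe_exchange(rho, sigma)
        ec, vcr, vcs = pbe_correlation(rho, sigma)
        eps, vrho, vsigma = ex + ec, vxr + vcr, vxs + vcs
    else:
        raise ValueError(
            f"unknown functional {name!r}; supported: {_FUNCTIONALS}")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        eps = eps * weights
        vrho = vrho * weights
        vsigma = vsigma * weights
    return XCEval(eps=eps, vrho=vrho, vsigma=vsigma)


def _lda_correlation(rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PW92 local correlation (the sigma -> 0 limit of PBE correlation)."""
    rho = np.asarray(rho, dtype=float)
    eps = np.zeros_like(rho)
    vrho = np.zeros_like(rho)
    pos = rho > RHO_FLOOR
    if not np.any(pos):
        return eps, vrho
    r = rho[pos]
    rs = (3.0 / (4.0 * np.pi * r)) ** (1.0 / 3.0)
    ec, dec_drs = _pw92_ec(rs)
    eps[pos] = ec
    vrho[pos] = ec + r * dec_drs * (-rs / (3.0 * r))
    return eps, vrho
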