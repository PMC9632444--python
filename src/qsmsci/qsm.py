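"""Susceptibility mapping: dipole physics, background-field removal and inversion.

The field perturbation produced by a susceptibility distribution is the
convolution of chi with the unit magnetic dipole response, which in k-space
is the multiplication by

    D(k) = 1/3 - (k . b0)^2 / |k|^2,        D(0) = 0.

The D(0) = 0 convention makes the simulated/fitted field zero-mean and the
reconstructed chi map referenced to its mask mean (chi maps are intrinsically
referenced; here the reference is the brain-mask mean, recorded on the result).

Background fields from sources outside the brain are removed by projection
onto dipole fields (PDF): the field is explained as well as possible by
exterior sources and the explained part subtracted. The inversion solves the
Tikhonov-regularized least-squares problem

    chi_hat = argmin_chi || W (D * chi - f) ||^2 + alpha ||chi||^2

by conjugate gradients on the normal equations, with alpha = 0.013 by
default, selected by the L-curve criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate
from scipy.sparse.linalg import LinearOperator, cg, lsmr

from .core import hz_per_ppm

DEFAULT_ALPHA = 0.013


def dipole_kernel(shape, voxel_size, b0_direction) -> np.ndarray:
    """k-space dipole kernel D(k) on an fft-ordered grid; D(0) = 0."""
    vs = np.asarray(voxel_size, dtype=float)
    if np.any(vs <= 0):
        raise ValueError("voxel sizes must be positive")
    b0 = np.asarray(b0_direction, dtype=float)
    if not np.isclose(np.linalg.norm(b0), 1.0, atol=1e-6):
        raise ValueError("b0_direction must be a unit vector")
    ks = [np.fft.fftfreq(int(n), d=d) for n, d in zip(shape, vs)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij", sparse=True)
    k_par = kx * b0[0] + ky * b0[1] + kz * b0[2]
    k2 = kx ** 2 + ky ** 2 + kz ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - (k_par ** 2) / k2
    d[~np.isfinite(d)] = 0.0
    return d


def field_from_chi(chi: np.ndarray, voxel_size, b0_direction, pad: bool = True) -> np.ndarray:
    """Forward dipole convolution chi -> field (same units as chi, i.e. ppm -> ppm).

    With ``pad=True`` the grid is zero-padded to twice the FOV before the
    FFT convolution to suppress wrap-around, then cropped back.
    """
    chi = np.asarray(chi, dtype=float)
    if not np.all(np.isfinite(chi)):
        raise ValueError("chi must be finite")
    shape = chi.shape
    if pad:
        work = np.zeros(tuple(2 * n for n in shape))
        work[: shape[0], : shape[1], : shape[2]] = chi
    else:
        work = chi
    d = dipole_kernel(work.shape, voxel_size, b0_direction)
    out = np.fft.ifftn(d * np.fft.fftn(work)).real
    if pad:
        out = out[: shape[0], : shape[1], : shape[2]]
    return out


def hz_to_ppm(field_hz: np.ndarray, b0_tesla: float) -> np.ndarray:
    """Convert a field map from Hz to ppm of B0."""
    return np.asarray(field_hz, dtype=float) / hz_per_ppm(b0_tesla)


@dataclass
class LocalFieldMap:
    local_field_ppm: np.ndarray
    mask: np.ndarray
    b0_direction: tuple[float, float, float]
    voxel_size: tuple[float, float, float]
    converged: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        f = np.asarray(self.local_field_ppm, dtype=float)
        if not np.all(np.isfinite(f[self.mask])):
            raise ValueError("local field must be finite inside the mask")
        f = np.where(self.mask, f, 0.0)
        self.local_field_ppm = f


@dataclass
class SusceptibilityMap:
    chi_ppm: np.ndarray
    mask: np.ndarray
    alpha_used: float
    reference: str = "mean-mask"
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    correction_factor: float = 1.0
    chi_raw: np.ndarray | None = field(default=None, repr=False)
    """The unmasked, unreferenced, uncorrected minimizer (norm diagnostics)."""


@dataclass
class RegularizationScan:
    alphas: np.ndarray
    residual_norms: np.ndarray
    solution_norms: np.ndarray
    selected_alpha: float
    curvature: np.ndarray = field(default=None, repr=False)


def _conv_op(shape, voxel_size, b0_direction):
    d = dipole_kernel(shape, voxel_size, b0_direction)

    def conv(x3d):
        return np.fft.ifftn(d * np.fft.fftn(x3d)).real

    return conv


def remove_background_pdf(
    total_field_ppm: np.ndarray,
    mask: np.ndarray,
    b0_direction,
    voxel_size,
    tol: float = 1e-4,
    maxiter: int = 100,
) -> LocalFieldMap:
    """Background-field removal by projection onto dipole fields.

    Fits exterior-supported sources chi_ext minimizing
    ``|| M (f - D * chi_ext) ||`` (M = brain mask) with LSMR, then returns
    the masked residual field, demeaned over the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    f = np.asarray(total_field_ppm, dtype=float)
    shape = f.shape
    # the mask must leave room for exterior sources
    edge = np.zeros(shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for idx in (0, 1, -2, -1):
            sl[ax] = idx
            edge[tuple(sl)] = True
    if np.any(mask & edge):
        raise ValueError("mask must lie strictly inside the grid (>= 2-voxel margin)")

    exterior = ~mask
    n_ext = int(exterior.sum())
    n_in = int(mask.sum())
    conv = _conv_op(shape, voxel_size, b0_direction)

    def matvec(x):
        g = np.zeros(shape)
        g[exterior] = x
        return conv(g)[mask]

    def rmatvec(y):
        g = np.zeros(shape)
        g[mask] = y
        return conv(g)[exterior]  # D is real and even in k-space: self-adjoint

    op = LinearOperator((n_in, n_ext), matvec=matvec, rmatvec=rmatvec)
    res = lsmr(op, f[mask], atol=tol, btol=tol, maxiter=maxiter)
    x, istop = res[0], res[1]
    converged = istop in (0, 1, 2, 4, 5)
    bg = np.zeros(shape)
    bg[exterior] = x
    background = conv(bg)
    local = np.where(mask, f - background, 0.0)
    local[mask] -= local[mask].mean()
    return LocalFieldMap(
        local_field_ppm=local,
        mask=mask,
        b0_direction=tuple(np.asarray(b0_direction, dtype=float)),
        voxel_size=tuple(np.asarray(voxel_size, dtype=float)),
        converged=converged,
    )


def invert_tikhonov(
    local_field: LocalFieldMap,
    alpha: float = DEFAULT_ALPHA,
    weight: np.ndarray | None = None,
    tol: float = 1e-6,
    maxiter: int = 300,
    bias_correction: bool = True,
) -> SusceptibilityMap:
    """Tikhonov-regularized dipole inversion by CG on the normal equations.

    With ``bias_correction`` the result is rescaled by the inverse mean
    k-space response 1 / <D^2 / (D^2 + alpha)>, compensating the global
    susceptibility underestimation the quadratic penalty introduces (the
    standard correction applied with iterative Tikhonov inversion). Set it
    to False to obtain the raw penalized solution, whose norm vanishes as
    alpha grows.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    mask = local_field.mask
    f = local_field.local_field_ppm
    shape = f.shape
    if weight is None:
        w2 = mask.astype(float)
    else:
        w2 = (np.asarray(weight, dtype=float) * mask) ** 2
    conv = _conv_op(shape, local_field.voxel_size, local_field.b0_direction)
    n = f.size

    def normal_op(x):
        x3 = x.reshape(shape)
        ax = conv(w2 * conv(x3)) + alpha * x3
        return ax.ravel()

    op = LinearOperator((n, n), matvec=normal_op)
    rhs = conv(w2 * f).ravel()
    x, info = cg(op, rhs, rtol=tol, maxiter=maxiter)
    if info < 0:
        raise RuntimeError(f"CG breakdown in Tikhonov inversion (info={info})")
    chi = x.reshape(shape)
    raw = chi.copy()
    factor = 1.0
    if bias_correction:
        d = dipole_kernel(shape, local_field.voxel_size, local_field.b0_direction)
        factor = float(1.0 / np.mean(d ** 2 / (d ** 2 + alpha)))
        chi = chi * factor
    chi = np.where(mask, chi, 0.0)
    chi[mask] -= chi[mask].mean()
    return SusceptibilityMap(
        chi_ppm=chi,
        mask=mask,
        alpha_used=float(alpha),
        reference="mean-mask",
        voxel_size=local_field.voxel_size,
        b0_direction=local_field.b0_direction,
        correction_factor=factor,
        chi_raw=raw,
    )


def residual_and_solution_norms(local_field: LocalFieldMap, chi_map: SusceptibilityMap):
    """Data-fit norm ||W(D*chi - f)|| and solution norm ||chi||.

    Evaluated on the raw minimizer (before masking/referencing/correction)
    when available — monotonicity in alpha is a property of the minimizer,
    not of the post-processed map.
    """
    chi = chi_map.chi_raw if chi_map.chi_raw is not None else chi_map.chi_ppm
    conv = _conv_op(local_field.local_field_ppm.shape, local_field.voxel_size,
                    local_field.b0_direction)
    r = (conv(chi) - local_field.local_field_ppm)[local_field.mask]
    return float(np.linalg.norm(r)), float(np.linalg.norm(chi))


def lcurve_select_alpha(
    local_field: LocalFieldMap,
    alphas,
    weight: np.ndarray | None = None,
    monotone_rtol: float = 1e-6,
) -> RegularizationScan:
    """Scan regularization weights and select alpha at the L-curve corner.

    The corner is the point of maximum curvature of the cubic-spline-smoothed
    log residual-norm vs log solution-norm curve; ties break to smaller alpha.
    """
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size < 5:
        raise ValueError("need at least 5 alphas")
    if not np.all(np.diff(alphas) > 0):
        raise ValueError("alphas must be strictly increasing")
    if np.log10(alphas[-1] / alphas[0]) < 3 - 1e-9:
        raise ValueError("alpha grid must span at least 3 decades")

    res_norms = np.empty_like(alphas)
    sol_norms = np.empty_like(alphas)
    for i, a in enumerate(alphas):
        # the raw penalized solution: its norms are provably monotone in alpha
        chi = invert_tikhonov(local_field, alpha=a, weight=weight, bias_correction=False)
        res_norms[i], sol_norms[i] = residual_and_solution_norms(local_field, chi)

    if np.any(np.diff(res_norms) < -monotone_rtol * np.abs(res_norms[:-1])):
        raise RuntimeError("residual norms are not nondecreasing in alpha (solver failure)")
    if np.any(np.diff(sol_norms) > monotone_rtol * np.abs(sol_norms[:-1])):
        raise RuntimeError("solution norms are not nonincreasing in alpha (solver failure)")

    t = np.log10(alphas)
    floor = np.finfo(float).tiny
    x = interpolate.CubicSpline(t, np.log10(np.maximum(res_norms, floor)))
    y = interpolate.CubicSpline(t, np.log10(np.maximum(sol_norms, floor)))
    xp, xpp = x(t, 1), x(t, 2)
    yp, ypp = y(t, 1), y(t, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        # traversing from small to large alpha, log-residual increases and
        # log-solution decreases; the L-corner then has negative signed
        # curvature, so negate to make the corner the maximum
        kappa = -(xp * ypp - yp * xpp) / np.power(xp ** 2 + yp ** 2, 1.5)
    kappa[~np.isfinite(kappa)] = -np.inf
    # spline endpoints carry artificial curvature: search interior points only
    interior = kappa.copy()
    interior[0] = interior[-1] = -np.inf
    best = int(np.argmax(interior))  # first (smallest-alpha) maximum on ties
    return RegularizationScan(
        alphas=alphas,
        residual_norms=res_norms,
        solution_norms=sol_norms,
        selected_alpha=float(alphas[best]),
        curvature=kappa,
    )
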