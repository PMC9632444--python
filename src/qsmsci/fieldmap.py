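"""From the complex multi-echo series to an unwrapped total field map.

The per-voxel signal model is

    S(TE) = A exp(-R2* TE) exp(i (phi0 + 2 pi f TE))

with f the total field in Hz. The field is estimated by Gauss-Newton on the
complex data (initialized from magnitude-weighted least squares on the
phase increments between adjacent echoes), residual wraps are removed with
a Laplacian/DCT unwrapper with congruence restoration, and volumes can be
rotated so the grid z-axis is parallel to the main field before inversion.

With uniform echo spacing dTE the field is only identifiable modulo the
alias period 1/dTE (250 Hz at dTE = 4 ms); fitted fields are reported in
(-1/(2 dTE), +1/(2 dTE)] before unwrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import MultiEchoSeries


@dataclass
class FieldMapResult:
    total_field_hz: np.ndarray
    phi0_rad: np.ndarray
    residual: np.ndarray          # per-voxel RMS of the complex model residual
    mask: np.ndarray
    flags: np.ndarray             # nonzero where the fit fell back / failed
    amplitude: np.ndarray | None = None
    r2star_s_inv: np.ndarray | None = None
    residual_history: np.ndarray | None = field(default=None, repr=False)


def derive_brain_mask(first_echo_magnitude: np.ndarray) -> np.ndarray:
    """Otsu threshold + largest connected component + morphological closing."""
    mag = np.asarray(first_echo_magnitude, dtype=float)
    thr = threshold_otsu(mag)
    m = mag > thr
    lab, n = ndimage.label(m)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        m = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_closing(m, structure=np.ones((3, 3, 3)))


def combine_coils(series: MultiEchoSeries) -> MultiEchoSeries:
    """Phase-difference coil combination.

    Per-coil constant phase offsets are estimated by extrapolating the
    coil-offset-free phase difference between the first two echoes back to
    TE1 and comparing with each coil's observed first-echo phase. The
    combined volume has sum-of-squares magnitude and magnitude-weighted
    phase. Single-coil input is returned unchanged.
    """
    if not series.per_coil:
        return series
    data = series.data
    if data.shape[0] == 1:
        return MultiEchoSeries(data[0], series.echo_times_ms, series.affine,
                               series.voxel_size, series.b0_direction, series.b0_tesla)
    if series.n_echoes < 2:
        raise ValueError("phase-difference combination needs at least two echoes")
    te = series.echo_times_s
    # coil-offset-free inter-echo phase difference (Hermitian product over coils)
    herm = np.sum(data[..., 1] * np.conj(data[..., 0]), axis=0)
    dphi = np.angle(herm)
    phi1 = dphi * te[0] / (te[1] - te[0])  # extrapolated true phase at TE1
    offsets = np.empty(data.shape[0])
    for c in range(data.shape[0]):
        z = np.sum(np.abs(data[c, ..., 0]) * data[c, ..., 0] * np.exp(-1j * phi1))
        offsets[c] = np.angle(z)
    aligned = data * np.exp(-1j * offsets)[:, None, None, None, None]
    sos_mag = np.sqrt(np.sum(np.abs(data) ** 2, axis=0))
    w_sum = np.sum(np.abs(aligned) * aligned, axis=0)
    phase = np.angle(w_sum)
    combined = sos_mag * np.exp(1j * phase)
    return MultiEchoSeries(combined, series.echo_times_ms, series.affine,
                           series.voxel_size, series.b0_direction, series.b0_tesla)


def _phase_difference_field(s: np.ndarray, te: np.ndarray):
    """Weighted LS on phase increments; weights are squared magnitudes."""
    dte = np.diff(te)
    pd = np.angle(s[:, 1:] * np.conj(s[:, :-1]))
    w = (np.abs(s[:, 1:]) * np.abs(s[:, :-1])) ** 2
    denom = np.sum(w * dte ** 2, axis=1)
    denom = np.where(denom > 0, denom, 1.0)
    f = np.sum(w * pd * dte, axis=1) / (2 * np.pi * denom)
    return f


def _loglinear_mag(s: np.ndarray, te: np.ndarray):
    mag = np.abs(s)
    floor = 1e-12 * max(mag.max(), 1e-300)
    ln = np.log(np.maximum(mag, floor))
    t = te - te.mean()
    slope = ln @ t / (t @ t)
    intercept = ln.mean(axis=1) - slope * te.mean()
    return intercept, -slope  # lnA, R2*


def fit_field_nonlinear(
    series: MultiEchoSeries,
    mask: np.ndarray | None = None,
    max_iter: int = 50,
    rtol: float = 1e-8,
) -> FieldMapResult:
    """Voxelwise Gauss-Newton fit of the 4-parameter complex decay model.

    Per-voxel backtracking keeps the residual non-increasing at every
    iteration; voxels whose 4x4 normal system is singular fall back to the
    weighted phase-difference initializer and are flagged.
    """
    if series.per_coil:
        series = combine_coils(series)
    if series.n_echoes < 3:
        raise ValueError("need at least 3 echoes for the nonlinear field fit")
    te = series.echo_times_s
    shape = series.data.shape[:3]
    if mask is None:
        mask = derive_brain_mask(np.abs(series.data[..., 0]))
    mask = np.asarray(mask, dtype=bool)

    s_all = series.data.reshape(-1, series.n_echoes)
    midx = np.flatnonzero(mask.ravel())
    s = s_all[midx]
    nonzero = np.abs(s).sum(axis=1) > 0
    flags_vox = np.zeros(midx.size, dtype=np.int8)
    flags_vox[~nonzero] = 2  # all-zero voxel

    sv = s[nonzero]
    f0 = _phase_difference_field(sv, te)
    lnA, r2 = _loglinear_mag(sv, te)
    phi0 = np.angle(np.sum(np.abs(sv) * sv * np.exp(-2j * np.pi * f0[:, None] * te), axis=1))
    params = np.stack([lnA, r2, phi0, f0], axis=1)  # (V,4)
    init_params = params.copy()

    def model(p):
        return np.exp(p[:, 0, None] - p[:, 1, None] * te
                      + 1j * (p[:, 2, None] + 2 * np.pi * p[:, 3, None] * te))

    def cost(p, data=None):
        data = sv if data is None else data
        return np.sum(np.abs(data - model(p)) ** 2, axis=1)

    c = cost(params)
    history = [float(c.sum())]
    # absolute convergence floor: residual energy negligible vs data energy
    energy = np.maximum(np.sum(np.abs(sv) ** 2, axis=1), 1e-300)
    singular = np.zeros(params.shape[0], dtype=bool)
    for _ in range(max_iter):
        m = model(params)
        r = sv - m
        # Jacobian columns: d m / d(lnA, R2*, phi0, f)
        j = np.stack([m, -te * m, 1j * m, 2j * np.pi * te * m], axis=2)  # (V,E,4)
        jh = np.conj(j)
        h = np.real(np.einsum("vea,veb->vab", jh, j))
        g = np.real(np.einsum("vea,ve->va", jh, r))
        h = h + 1e-12 * np.eye(4) * np.maximum(
            np.trace(h, axis1=1, axis2=2), 1e-30)[:, None, None]
        try:
            step = np.linalg.solve(h, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            ok = np.linalg.matrix_rank(h) == 4
            singular |= ~ok
            step = np.zeros_like(g)
            step[ok] = np.linalg.solve(h[ok], g[ok, :, None])[..., 0]
        new = params + step
        cn = cost(new)
        scale = np.ones(params.shape[0])
        for _bt in range(10):
            worse = cn > c
            if not worse.any():
                break
            scale[worse] *= 0.5
            new[worse] = params[worse] + scale[worse, None] * step[worse]
            cn[worse] = cost(new[worse], data=sv[worse])
        stuck = cn > c
        new[stuck] = params[stuck]
        cn[stuck] = c[stuck]
        rel = np.abs(c - cn) / np.maximum(c, 1e-300)
        params, c = new, cn
        history.append(float(c.sum()))
        if np.all((rel < rtol) | (c <= 1e-24 * energy)):
            break

    params[singular] = init_params[singular]
    nz_idx = np.flatnonzero(nonzero)
    flags_vox[nz_idx[singular]] = 1  # fell back to the phase-difference estimate

    # report the field within the alias band of the echo spacing
    period = 1.0 / np.min(np.diff(te))
    fvals = params[:, 3] % period
    fvals = np.where(fvals > period / 2, fvals - period, fvals)
    params[:, 3] = fvals

    def scatter(vals, fill=0.0):
        out = np.full(s_all.shape[0], fill)
        tmp = np.full(midx.size, fill)
        tmp[nonzero] = vals
        out[midx] = tmp
        return out.reshape(shape)

    res_vox = np.sqrt(c / series.n_echoes)
    flags = np.zeros(s_all.shape[0], dtype=np.int8)
    flags[midx] = flags_vox
    return FieldMapResult(
        total_field_hz=scatter(params[:, 3]),
        phi0_rad=scatter(params[:, 2]),
        residual=scatter(res_vox),
        mask=mask,
        flags=flags.reshape(shape),
        amplitude=scatter(np.exp(params[:, 0])),
        r2star_s_inv=scatter(params[:, 1]),
        residual_history=np.asarray(history),
    )


def _dct_laplacian_solve(rho: np.ndarray) -> np.ndarray:
    """Solve the Poisson equation with Neumann BC via DCT-II."""
    shape = rho.shape
    r = sfft.dctn(rho, type=2, norm="ortho")
    eig = np.zeros(shape)
    for ax, n in enumerate(shape):
        k = np.arange(n)
        lam = 2.0 * np.cos(np.pi * k / n) - 2.0
        sh = [1, 1, 1]
        sh[ax] = n
        eig = eig + lam.reshape(sh)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = r / eig
    r[tuple(0 for _ in shape)] = 0.0
    return sfft.idctn(r, type=2, norm="ortho")


def _laplacian(u: np.ndarray) -> np.ndarray:
    """Second-difference Laplacian with reflecting (Neumann) boundaries.

    The half-sample-symmetric 'reflect' boundary is exactly the operator the
    DCT-II basis diagonalizes, so :func:`_dct_laplacian_solve` inverts it.
    """
    out = np.zeros_like(u, dtype=float)
    for ax in range(u.ndim):
        out += ndimage.correlate1d(u.astype(float), np.array([1.0, -2.0, 1.0]),
                                   axis=ax, mode="reflect")
    return out


def unwrap_field(
    volume: np.ndarray,
    mask: np.ndarray | None = None,
    period: float = 2 * np.pi,
) -> tuple[np.ndarray, int]:
    """Laplacian-based unwrapping with congruence restoration.

    ``period`` is 2 pi for phase in radians or the alias period for a field
    map in Hz. The output equals the input plus an integer number of
    periods at every masked voxel. Disconnected mask components are
    unwrapped independently; their count is returned.
    """
    vol = np.asarray(volume, dtype=float)
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not np.all(np.isfinite(vol[mask])):
        raise ValueError("input must be finite inside the mask")
    x = vol * (2 * np.pi / period)
    sx, cx = np.sin(x), np.cos(x)
    rho = cx * _laplacian(sx) - sx * _laplacian(cx)
    est = _dct_laplacian_solve(rho)

    lab, n_comp = ndimage.label(mask)
    out = x.copy()
    for ci in range(1, n_comp + 1):
        sel = lab == ci
        k = np.round((est[sel] - x[sel]) / (2 * np.pi))
        # remove the arbitrary global multiple per component (keep k integer)
        k -= np.round(np.median(k))
        out[sel] = x[sel] + 2 * np.pi * k
    return out * (period / (2 * np.pi)), n_comp


def rotation_to_b0(b0_direction) -> np.ndarray:
    """Rotation matrix R with R @ b0 = z_hat (identity when already aligned)."""
    b0 = np.asarray(b0_direction, dtype=float)
    b0 = b0 / np.linalg.norm(b0)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(b0, z)
    s = np.linalg.norm(v)
    c = float(b0 @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def align_to_b0(
    volume: np.ndarray,
    b0_direction,
    affine: np.ndarray | None = None,
    interpolation: str = "trilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a volume so its grid z-axis is parallel to B0.

    Masks should use ``interpolation='nearest'`` (exact for axis-aligned
    rotations), continuous maps ``'trilinear'``. Returns the rotated volume
    and the updated grid-to-world affine.
    """
    b0 = np.asarray(b0_direction, dtype=float)
    if not np.isclose(np.linalg.norm(b0), 1.0, atol=1e-6):
        raise ValueError("b0_direction must be a unit vector")
    if affine is None:
        affine = np.eye(4)
    vol = np.asarray(volume)
    r = rotation_to_b0(b0)
    if np.allclose(r, np.eye(3)):
        return vol.copy(), np.asarray(affine, dtype=float).copy()
    c = (np.array(vol.shape, dtype=float) - 1) / 2.0
    m = r.T
    offset = c - m @ c
    order = 0 if interpolation == "nearest" else 1
    is_bool = vol.dtype == bool
    out = ndimage.affine_transform(vol.astype(float), m, offset=offset,
                                   order=order, mode="constant", cval=0.0,
                                   prefilter=False)
    t = np.eye(4)
    t[:3, :3] = m
    t[:3, 3] = offset
    new_affine = np.asarray(affine, dtype=float) @ t
    if is_bool:
        return out > 0.5, new_affine
    return out, new_affine
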