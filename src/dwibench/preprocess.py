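"""Processing steps: MPPCA denoising, Gibbs-ringing removal by subvoxel
shifts, simplified motion/eddy correction with b-vector rotation, Gaussian
smoothing, and the enumerator of the eight step combinations.

Steps are always chained in the fixed order MPPCA -> Gibbs -> Eddy (then
smoothing immediately before model fitting); only the eddy/motion correction
may alter encoding directions, and no step touches b-values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, optimize

from .core import AcquisitionScheme, DWIDataset
from .geometry import angles_zyx, apply_affine, eddy_matrix, rotation_zyx

log = logging.getLogger(__name__)

STEP_ORDER = ("MPPCA", "Gibbs", "Eddy")


@dataclass(frozen=True)
class PipelineConfig:
    """One processing pipeline: an ordered subset of the three steps plus a
    smoothing kernel SD (voxel units; 0 disables smoothing)."""

    steps: tuple[str, ...] = ()
    smoothing_sigma: float = 0.0

    def __post_init__(self):
        unknown = set(self.steps) - set(STEP_ORDER)
        if unknown:
            raise ValueError(f"unknown step(s): {sorted(unknown)}")
        ordered = tuple(s for s in STEP_ORDER if s in self.steps)
        object.__setattr__(self, "steps", ordered)
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")

    @property
    def name(self) -> str:
        return "+".join(self.steps) if self.steps else "none"


def enumerate_pipelines(smoothing_sigma: float = 0.0) -> list[PipelineConfig]:
    """All 8 pipelines: 'none' plus the 7 non-empty subsets of
    {MPPCA, Gibbs, Eddy}, each applied in the fixed step order."""
    configs = []
    for r in range(len(STEP_ORDER) + 1):
        for combo in itertools.combinations(STEP_ORDER, r):
            configs.append(PipelineConfig(steps=combo, smoothing_sigma=smoothing_sigma))
    return configs


# --------------------------------------------------------------------------
# MPPCA

def mppca_denoise(data: DWIDataset, patch_radius: int = 2) -> tuple[DWIDataset, np.ndarray]:
    """Marchenko-Pastur PCA denoising.

    For every sliding patch (edge 2*patch_radius+1, default 5^3 = 125 voxels,
    which keeps M >= N for all three study protocols) the volume-by-volume
    second-moment matrix X X^T / M is eigendecomposed. With eigenvalues
    lam_1 <= ... <= lam_N, the q smallest are classified as noise when their
    spread is consistent with the Marchenko-Pastur support width for their
    mean:

        lam_q - lam_1  <  4 * sqrt(q / M) * mean(lam_1..lam_q)

    (the largest such q is used; mean(lam_1..lam_q) estimates sigma^2).
    The patch is reconstructed with those eigencomponents suppressed, and
    overlapping patch estimates are aggregated by averaging. Returns the
    denoised dataset and the per-voxel noise-SD estimate.
    """
    if patch_radius < 1:
        raise ValueError("patch must be at least 3 voxels wide (radius >= 1)")
    sig = data.signal
    N = sig.shape[3]
    p = 2 * patch_radius + 1
    if any(s < p for s in sig.shape[:3]):
        raise ValueError("volume smaller than the patch")
    M = p**3
    win = sliding_window_view(sig, (p, p, p), axis=(0, 1, 2))  # (nx',ny',nz',N,p,p,p)
    nx, ny, nz = win.shape[:3]
    npatch = nx * ny * nz
    flat = win.reshape(npatch, N, M)
    shape3 = sig.shape[:3]
    out = np.zeros(sig.shape)
    cnt = np.zeros(shape3)
    sig_acc = np.zeros(shape3)
    # voxel linear offsets of one patch
    ox, oy, oz = np.meshgrid(np.arange(p), np.arange(p), np.arange(p), indexing="ij")
    off_lin = (ox * shape3[1] + oy) * shape3[2] + oz  # (p,p,p)
    off_lin = off_lin.ravel()
    out_flat = out.reshape(-1, N)
    cnt_flat = cnt.reshape(-1)
    sig_flat = sig_acc.reshape(-1)
    q_arr = np.arange(1, N + 1, dtype=float)
    chunk = 2048
    for s in range(0, npatch, chunk):
        X = np.ascontiguousarray(flat[s:s + chunk])  # (c, N, M)
        c = X.shape[0]
        C = X @ X.transpose(0, 2, 1) / M
        lam, vecs = np.linalg.eigh(C)  # ascending
        csum = np.cumsum(lam, axis=1)
        mean_lam = csum / q_arr[None, :]
        ok = (lam - lam[:, :1]) < 4.0 * np.sqrt(q_arr[None, :] / M) * mean_lam
        qn = np.where(ok, q_arr[None, :], 0).max(axis=1).astype(int)
        sigma2 = np.where(qn > 0, csum[np.arange(c), np.maximum(qn - 1, 0)] / np.maximum(qn, 1), 0.0)
        keep = np.arange(N)[None, :] >= qn[:, None]
        V = vecs * keep[:, None, :]
        Xd = V @ (V.transpose(0, 2, 1) @ X)  # (c, N, M)
        ci = np.stack(np.unravel_index(np.arange(s, s + c), (nx, ny, nz)), 1)
        corner_lin = (ci[:, 0] * shape3[1] + ci[:, 1]) * shape3[2] + ci[:, 2]
        idx = corner_lin[:, None] + off_lin[None, :]  # (c, M)
        np.add.at(out_flat, idx.ravel(), Xd.transpose(0, 2, 1).reshape(-1, N))
        np.add.at(cnt_flat, idx.ravel(), 1.0)
        np.add.at(sig_flat, idx.ravel(), np.repeat(np.sqrt(np.maximum(sigma2, 0.0)), M))
    out_flat /= np.maximum(cnt_flat, 1.0)[:, None]
    sigma_map = sig_acc / np.maximum(cnt, 1.0)
    return data.with_signal(np.maximum(out, 0.0)), sigma_map


# --------------------------------------------------------------------------
# Gibbs unringing

def _unring_lines(lines: np.ndarray, nsh: int, minw: int, maxw: int) -> np.ndarray:
    """Subvoxel-shift unringing of 1D profiles (last axis).

    Shifted copies at s = k/(2*nsh), k = -nsh..nsh, are generated with the
    Fourier shift theorem; per sample the shift minimizing a one-sided
    oscillation measure (sum of |first differences| over a window of
    minw..maxw neighbours, the smaller of the left/right side) is chosen, and
    the value is linearly interpolated back onto the integer grid.
    """
    n_lines, n = lines.shape
    freqs = np.fft.fftfreq(n)
    F = np.fft.fft(lines, axis=-1)
    best_meas = np.full(lines.shape, np.inf)
    best_val = lines.copy()
    for k in range(-nsh, nsh + 1):
        s = k / (2.0 * nsh)
        Is = np.real(np.fft.ifft(F * np.exp(2j * np.pi * freqs * s), axis=-1))
        d = np.abs(np.diff(Is, axis=-1))
        dpad = np.pad(d, ((0, 0), (maxw, maxw)), mode="edge")
        left = np.zeros_like(Is)
        right = np.zeros_like(Is)
        for w in range(minw, maxw + 1):
            left += dpad[:, maxw - w:maxw - w + n]
            right += dpad[:, maxw + w - 1:maxw + w - 1 + n]
        meas = np.minimum(left, right)
        if s > 0:
            val = (1 - s) * Is + s * np.roll(Is, 1, axis=-1)
        elif s < 0:
            val = (1 + s) * Is - s * np.roll(Is, -1, axis=-1)
        else:
            val = Is
        upd = meas < best_meas
        best_meas[upd] = meas[upd]
        best_val[upd] = val[upd]
    return best_val


def gibbs_unring(data: DWIDataset, max_shift_steps: int = 20, window: int = 3) -> DWIDataset:
    """Remove Gibbs ringing slice-wise by optimal subvoxel shifts.

    Each axial slice is split into two k-space-weighted images, one per
    in-plane axis — the weights (1 + cos k_other) / ((1 + cos k_x) +
    (1 + cos k_y)) assign each axis the frequencies it dominates — and each
    part is unrung along its own axis; the parts are then summed.
    """
    if max_shift_steps < 1 or window < 1:
        raise ValueError("max_shift_steps and window must be >= 1")
    sig = data.signal
    nx, ny = sig.shape[:2]
    kx = 2 * np.pi * np.fft.fftfreq(nx)[:, None]
    ky = 2 * np.pi * np.fft.fftfreq(ny)[None, :]
    denom = (1 + np.cos(kx)) + (1 + np.cos(ky))
    safe = denom > 1e-12
    gx = np.where(safe, (1 + np.cos(ky)) / np.where(safe, denom, 1.0), 0.5)
    gy = np.where(safe, (1 + np.cos(kx)) / np.where(safe, denom, 1.0), 0.5)
    K = np.fft.fft2(sig, axes=(0, 1))
    ix = np.real(np.fft.ifft2(K * gx[:, :, None, None], axes=(0, 1)))
    iy = np.real(np.fft.ifft2(K * gy[:, :, None, None], axes=(0, 1)))
    # unring ix along x: lines are the x-profiles for every (y, z, vol)
    lx = np.moveaxis(ix, 0, -1).reshape(-1, nx)
    cx = _unring_lines(lx, max_shift_steps, 1, window)
    cx = np.moveaxis(cx.reshape(ix.shape[1], ix.shape[2], ix.shape[3], nx), -1, 0)
    ly = np.moveaxis(iy, 1, -1).reshape(-1, ny)
    cy = _unring_lines(ly, max_shift_steps, 1, window)
    cy = np.moveaxis(cy.reshape(iy.shape[0], iy.shape[2], iy.shape[3], ny), -1, 1)
    return data.with_signal(np.maximum(cx + cy, 0.0))


# --------------------------------------------------------------------------
# motion / eddy correction

def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask]
    bv = b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    den = np.sqrt((av * av).sum() * (bv * bv).sum())
    return float((av * bv).sum() / den) if den > 0 else 0.0


def _params_to_matrix(p: np.ndarray, with_eddy: bool) -> tuple[np.ndarray, np.ndarray]:
    R = rotation_zyx(np.deg2rad(p[:3]))
    t = p[3:6]
    if with_eddy:
        M = R @ eddy_matrix(p[6], p[7], p[8])
    else:
        M = R
    return M, t


def _register_volume(moving, ref, mask, *, with_eddy, x0=None, xtol=1e-3, order=1,
                     max_rot_deg=15.0, max_trans_vox=None, maxfev=None):
    # bounded search: subject motion between volumes is small, and the bounds
    # keep the optimizer away from spurious optima of near-symmetric images
    nparam = 9 if with_eddy else 6
    x0 = np.zeros(nparam) if x0 is None else np.asarray(x0, float)[:nparam]
    if max_trans_vox is None:
        max_trans_vox = 0.25 * min(moving.shape)
    bounds = [(-max_rot_deg, max_rot_deg)] * 3 + [(-max_trans_vox, max_trans_vox)] * 3
    if with_eddy:
        bounds += [(-0.15, 0.15)] * 3
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])

    def cost(p):
        M, t = _params_to_matrix(p, with_eddy)
        return -_masked_ncc(apply_affine(moving, M, t, order=order), ref, mask)

    options = {"xtol": xtol, "ftol": 1e-9, "maxiter": 3000}
    if maxfev:
        options["maxfev"] = maxfev
    res = optimize.minimize(cost, x0, method="Powell", bounds=bounds, options=options)
    return res.x, -res.fun, -cost(x0)


def correct_motion_eddy(
    data: DWIDataset,
    *,
    model: str = "rigid+eddy",
    n_refine: int = 2,
    presmooth: float = 0.5,
    xtol: float = 1e-3,
    margin: int | None = None,
    min_gain: float = 0.0,
    maxfev: int | None = None,
) -> tuple[DWIDataset, list[dict], AcquisitionScheme]:
    """Model-driven motion/eddy correction with b-vector rotation.

    b0 volumes are registered rigidly to the first b0 (the reference frame).
    Diffusion-weighted volumes are then aligned in ``n_refine`` model-based
    rounds: the current estimate of the corrected data is fitted by WLLS, each
    raw volume is registered against its own model-predicted signal (which has
    the *same* diffusion contrast, unlike a b0 reference), and the fit is
    refreshed. The per-volume transform is rigid plus phase-encode-axis
    shear/scale (``model="rigid"`` drops the eddy terms; b0 volumes are always
    rigid-only).

    The similarity is normalized cross-correlation over an interior mask
    (excluding a border of ``margin`` voxels so out-of-field voxels cannot
    bias the optimum), optimized with bounded Powell on lightly presmoothed
    volumes. A volume whose registration worsens the similarity keeps its
    previous transform and a warning is logged. Volumes are resampled exactly
    once, from the raw data, with the final transform (cubic spline).

    ``min_gain`` is a parsimony threshold: a volume's transform is only
    adopted when it improves the similarity by more than this amount, so
    artifact-free data pass through (exactly) unchanged instead of picking up
    spurious sub-voxel warps. Default 0 (always adopt improvements).

    Returns (corrected dataset, per-volume transform estimates, rotated scheme).
    """
    from .modelfit import fit_wlls

    if model not in ("rigid", "rigid+eddy"):
        raise ValueError("model must be 'rigid' or 'rigid+eddy'")
    scheme = data.scheme
    b0_idx = np.flatnonzero(scheme.b0_mask)
    if len(b0_idx) == 0:
        raise ValueError("motion/eddy correction requires at least one b0 volume")
    sig = data.signal
    shape = sig.shape[:3]
    if margin is None:
        margin = int(np.clip(min(shape) // 6, 2, 4))
    mask = np.zeros(shape, bool)
    mask[margin:-margin, margin:-margin, margin:-margin] = True

    def smooth(v):
        return ndimage.gaussian_filter(v, presmooth) if presmooth > 0 else v

    ref = smooth(sig[..., b0_idx[0]])
    params = [np.zeros(9) for _ in range(len(scheme))]
    b0_stack = [sig[..., b0_idx[0]]]
    for v in b0_idx[1:]:
        x, after, before = _register_volume(smooth(sig[..., v]), ref, mask,
                                            with_eddy=False, xtol=xtol, maxfev=maxfev)
        if after < before + min_gain:
            if after < before:
                log.warning("b0 registration diverged for volume %d; keeping identity", v)
            x = np.zeros(6)
        params[v][:6] = x
        M, t = _params_to_matrix(x, False)
        b0_stack.append(apply_affine(sig[..., v], M, t, order=1))

    with_eddy = model == "rigid+eddy"
    fit_model = "dki" if (scheme.dki_capable and len(scheme) >= 22) else "dti"
    dw_idx = [v for v in range(len(scheme)) if v not in b0_idx]
    # initialization: every DW volume against the averaged-b0 reference. The
    # diffusion contrast differs from b0, but the shared anatomical intensity
    # pattern dominates enough for a rough alignment.
    ref0 = smooth(np.mean(b0_stack, axis=0))
    for v in dw_idx:
        x, after, before = _register_volume(
            smooth(sig[..., v]), ref0, mask, with_eddy=with_eddy, xtol=xtol, maxfev=maxfev
        )
        if after >= before + min_gain:
            params[v] = np.concatenate([x, np.zeros(9 - len(x))])
    for _ in range(max(n_refine, 0)):
        corrected = np.maximum(_resample_all(sig, params, with_eddy, order=1), 1e-12)
        # Gauge fix: per-volume registration against model predictions cannot
        # observe a rotation/shift common to all DW volumes (the fitted model
        # follows it). The mean corrected DW volume has direction-averaged
        # contrast with the same sign as b0 (tracts darker), so one rigid
        # registration of it against the b0 reference pins that mode.
        b0ref = corrected[..., b0_idx].mean(axis=-1)
        mean_dw = corrected[..., dw_idx].mean(axis=-1)
        g, g_after, g_before = _register_volume(
            smooth(mean_dw), smooth(b0ref), mask, with_eddy=False, xtol=xtol,
            max_rot_deg=5.0, max_trans_vox=3.0,
        )
        if g_after >= g_before + min_gain and np.any(g):
            Rg = rotation_zyx(np.deg2rad(g[:3]))
            for v in dw_idx:
                Rv = rotation_zyx(np.deg2rad(params[v][:3]))
                params[v][:3] = np.rad2deg(angles_zyx(Rg @ Rv))
                params[v][3:6] = Rg @ params[v][3:6] + g[3:6]
            corrected = np.maximum(_resample_all(sig, params, with_eddy, order=1), 1e-12)
        # fit with the b-vectors as currently estimated (rotated per volume):
        # predictions with stale directions would bias the next registration
        dirs = scheme.directions.copy()
        for v in dw_idx:
            dirs[v] = rotation_zyx(np.deg2rad(params[v][:3])) @ dirs[v]
        for v in dw_idx:
            # leave-one-out prediction: a prediction that includes the volume
            # itself partially matches its current (wrong) pose and creates a
            # biased fixed point
            keep = np.array([i for i in range(len(scheme)) if i != v])
            scheme_wo = AcquisitionScheme(
                name=scheme.name, bvalues=scheme.bvalues[keep], directions=dirs[keep],
                voxel_size=scheme.voxel_size, te_ms=scheme.te_ms, tr_ms=scheme.tr_ms,
            )
            fit = fit_wlls(
                DWIDataset(signal=corrected[..., keep], scheme=scheme_wo,
                           affine=data.affine, subject_id=data.subject_id, group=data.group),
                model=fit_model, iterations=1,
            )
            pred_v = fit.predict(AcquisitionScheme(
                name="loo", bvalues=np.array([0.0, scheme.bvalues[v]]),
                directions=np.vstack([np.zeros(3), dirs[v]]),
                voxel_size=scheme.voxel_size,
            ))[..., 1]
            # out-of-field voxels fitted from zero-filled samples can predict
            # absurd values that would hijack the similarity metric
            np.clip(pred_v, 0.0, 2.0 * sig.max(), out=pred_v)
            x, after, before = _register_volume(
                smooth(sig[..., v]), smooth(pred_v), mask,
                with_eddy=with_eddy, x0=params[v], xtol=xtol, maxfev=maxfev,
            )
            if after >= before + min_gain:
                params[v] = np.concatenate([x, np.zeros(9 - len(x))])
            elif after < before:
                log.warning("registration diverged for volume %d; keeping previous", v)

    out = _resample_all(sig, params, True, order=3)
    records = []
    new_dirs = scheme.directions.copy()
    for v, p in enumerate(params):
        M, t = _params_to_matrix(p, True)
        R = rotation_zyx(np.deg2rad(p[:3]))
        if not scheme.b0_mask[v]:
            new_dirs[v] = R @ scheme.directions[v]
        records.append({
            "volume": v,
            "rotation_deg": p[:3].copy(),
            "translation_vox": p[3:6].copy(),
            "eddy": p[6:9].copy(),
            "matrix": M,
        })
    rotated = AcquisitionScheme(
        name=scheme.name, bvalues=scheme.bvalues.copy(), directions=new_dirs,
        voxel_size=scheme.voxel_size, te_ms=scheme.te_ms, tr_ms=scheme.tr_ms,
    )
    return data.with_signal(np.maximum(out, 0.0), scheme=rotated), records, rotated


def _resample_all(sig, params, with_eddy, order):
    out = np.empty_like(sig)
    for v in range(sig.shape[3]):
        p = params[v]
        if p is None or not np.any(p):
            out[..., v] = sig[..., v]
        else:
            M, t = _params_to_matrix(p, with_eddy)
            out[..., v] = apply_affine(sig[..., v], M, t, order=order)
    return out


# --------------------------------------------------------------------------
# smoothing and pipeline application

def smooth_gaussian(data: DWIDataset, sigma: float) -> DWIDataset:
    """Per-volume 3D Gaussian smoothing, SD ``sigma`` in voxel units.

    sigma = 0 is the identity. Reflecting boundary handling conserves the
    total signal sum (symmetric kernel tails fold back into the volume).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return data.with_signal(data.signal.copy())
    out = ndimage.gaussian_filter(data.signal, sigma=(sigma, sigma, sigma, 0), mode="reflect")
    return data.with_signal(out)


def apply_pipeline(
    data: DWIDataset,
    config: PipelineConfig,
    *,
    cache: dict | None = None,
    mppca_kwargs: dict | None = None,
    gibbs_kwargs: dict | None = None,
    eddy_kwargs: dict | None = None,
) -> DWIDataset:
    """Apply a pipeline's steps in the fixed order MPPCA -> Gibbs -> Eddy.

    ``cache`` (optional, per subject) memoizes step-prefix results so that the
    8-pipeline enumeration reuses shared prefixes. Smoothing is *not* applied
    here: it belongs immediately before model fitting and never touches
    segmentation masks.
    """
    cache = cache if cache is not None else {}
    prefix: tuple[str, ...] = ()
    current = data
    for step in config.steps:
        prefix = prefix + (step,)
        if prefix in cache:
            current = cache[prefix]
            continue
        if step == "MPPCA":
            current, _ = mppca_denoise(current, **(mppca_kwargs or {}))
        elif step == "Gibbs":
            current = gibbs_unring(current, **(gibbs_kwargs or {}))
        elif step == "Eddy":
            current, _, _ = correct_motion_eddy(current, **(eddy_kwargs or {}))
        cache[prefix] = current
    return current
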