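"""Weighted linear least-squares fitting of the diffusion tensor (DTI) and
diffusion kurtosis (DKI) signal models, and derivation of scalar maps.

Signal model
------------
For encoding direction n and weighting b the log-signal is modelled as

    ln S(b, n) = ln S0 - b * D_app(n) + (b^2 / 6) * MD^2 * W_app(n)

with D_app(n) = n^T D n and W_app(n) = sum_ijkl n_i n_j n_k n_l W_ijkl.
The kurtosis term is linearized through the substitution V = MD^2 * W, which
keeps the estimator a genuine (weighted) *linear* least-squares problem; W is
recovered afterwards by dividing by the fitted MD^2.

Internally b is expressed in ms/um^2 and diffusivities in um^2/ms so that all
design-matrix columns are O(1); the public API uses mm^2/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import AcquisitionScheme, DWIDataset, fibonacci_sphere

log = logging.getLogger(__name__)

# unique index sets of the symmetric rank-2 and rank-4 tensors, with the
# multinomial multiplicity of each in the fully expanded contraction
TENSOR_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
TENSOR_MULT = np.array([1, 1, 1, 2, 2, 2], dtype=float)
KURTOSIS_IDX = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
KURTOSIS_MULT = np.array([1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float)

DTI_PARAMS = ("FA", "MD", "AD", "RD")
DKI_PARAMS = DTI_PARAMS + ("MK", "AK", "RK")


def tensor_monomials(directions: np.ndarray) -> np.ndarray:
    """(n, 6) array of mult * n_i n_j for the unique tensor components."""
    d = np.asarray(directions, float)
    cols = [TENSOR_MULT[a] * d[:, i] * d[:, j] for a, (i, j) in enumerate(TENSOR_IDX)]
    return np.stack(cols, axis=1)


def kurtosis_monomials(directions: np.ndarray) -> np.ndarray:
    """(n, 15) array of mult * n_i n_j n_k n_l for the unique rank-4 components."""
    d = np.asarray(directions, float)
    cols = [
        KURTOSIS_MULT[a] * d[:, i] * d[:, j] * d[:, k] * d[:, l]
        for a, (i, j, k, l) in enumerate(KURTOSIS_IDX)
    ]
    return np.stack(cols, axis=1)


def tensor_from_unique(unique: np.ndarray) -> np.ndarray:
    """(..., 6) unique components -> (..., 3, 3) symmetric matrices."""
    u = np.asarray(unique, float)
    out = np.zeros(u.shape[:-1] + (3, 3), dtype=float)
    for a, (i, j) in enumerate(TENSOR_IDX):
        out[..., i, j] = u[..., a]
        out[..., j, i] = u[..., a]
    return out


def unique_from_tensor(full: np.ndarray) -> np.ndarray:
    full = np.asarray(full, float)
    return np.stack([full[..., i, j] for (i, j) in TENSOR_IDX], axis=-1)


def unique_from_tensor4(full: np.ndarray) -> np.ndarray:
    """(..., 3, 3, 3, 3) -> (..., 15) unique components."""
    full = np.asarray(full, float)
    return np.stack([full[..., i, j, k, l] for (i, j, k, l) in KURTOSIS_IDX], axis=-1)


def design_matrix(scheme: AcquisitionScheme, model: str) -> np.ndarray:
    """Design matrix mapping [ln S0, D(6), V(15)] to log-signals.

    Rows are volumes. DTI columns: 1 and -b * mult * n_i n_j (6 terms, b in
    ms/um^2). DKI appends (b^2/6) * mult * n_i n_j n_k n_l (15 terms). Raises
    when the scheme cannot identify the model (DTI needs >= 7 measurements,
    DKI needs >= 22 and at least two distinct non-zero shells).
    """
    model = model.lower()
    if model not in ("dti", "dki"):
        raise ValueError(f"unknown model '{model}'")
    n = len(scheme)
    if model == "dti" and n < 7:
        raise ValueError(f"DTI requires >= 7 measurements, scheme has {n}")
    if model == "dki":
        if n < 22:
            raise ValueError(f"DKI requires >= 22 measurements, scheme has {n}")
        if not scheme.dki_capable:
            raise ValueError("DKI requires >= 2 distinct non-zero b-values")
    return _design_columns(scheme, model)


def _design_columns(scheme: AcquisitionScheme, model: str) -> np.ndarray:
    """Design rows without the fit-side measurement-count validation (used
    when predicting arbitrary volume subsets from an existing fit)."""
    n = len(scheme)
    b = scheme.bvalues / 1000.0  # ms/um^2
    d = np.where(scheme.b0_mask[:, None], 0.0, scheme.directions)
    cols = [np.ones(n), -b[:, None] * tensor_monomials(d)]
    if model == "dki":
        cols.append((b[:, None] ** 2 / 6.0) * kurtosis_monomials(d))
    return np.concatenate([c if c.ndim == 2 else c[:, None] for c in cols], axis=1)


@dataclass
class DiffusionFit:
    """Voxelwise result of a WLLS diffusion fit.

    ``tensor`` holds the 6 unique components of D in mm^2/s; ``kurtosis_scaled``
    the 15 unique components of V = MD^2 W (internal um^4/ms^2 scale, None for
    DTI fits). ``fit_ok`` is False where input signals were non-positive or the
    solve failed; such voxels carry zeros.
    """

    s0: np.ndarray
    tensor: np.ndarray
    kurtosis_scaled: np.ndarray | None
    fit_ok: np.ndarray
    scheme: AcquisitionScheme
    model: str

    @property
    def tensor_internal(self) -> np.ndarray:
        """D in um^2/ms (the unit the design matrix works in)."""
        return self.tensor * 1e3

    def predict(self, scheme: AcquisitionScheme | None = None) -> np.ndarray:
        """Noise-free model signals on ``scheme`` (default: the fitted scheme)."""
        scheme = scheme or self.scheme
        A = _design_columns(scheme, self.model)
        coeffs = self._coefficients()
        flat = coeffs.reshape(-1, coeffs.shape[-1])
        sig = np.exp(np.clip(flat @ A.T, -700, 700)).reshape(self.s0.shape + (len(scheme),))
        return sig * self.fit_ok[..., None]

    def _coefficients(self) -> np.ndarray:
        parts = [np.log(np.maximum(self.s0, 1e-300))[..., None], self.tensor_internal]
        if self.kurtosis_scaled is not None:
            parts.append(self.kurtosis_scaled)
        return np.concatenate(parts, axis=-1)


def fit_wlls(
    data: DWIDataset,
    model: str = "dti",
    iterations: int = 2,
    mask: np.ndarray | None = None,
) -> DiffusionFit:
    """Weighted linear least-squares fit of the DTI or DKI model.

    An ordinary LLS pass on the log-signals is followed by ``iterations``
    reweighted passes with per-measurement weights equal to the squared
    predicted signals (the standard WLLS weighting, under which log-domain
    noise variance ~ sigma^2 / S^2).

    Signals are clamped to 1e-6 * max(S) before the log; voxels containing
    non-positive signals are flagged in ``fit_ok`` but still fitted from the
    clamped values, leaving their neighbours unaffected.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    A = design_matrix(data.scheme, model)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("design matrix is rank-deficient for this scheme")
    shape = data.shape
    sig = data.signal.reshape(-1, len(data.scheme))
    if mask is not None:
        sel = np.flatnonzero(mask.ravel())
    else:
        sel = np.arange(sig.shape[0])
    S = sig[sel]
    ok = np.all(S > 0, axis=1)
    eps = 1e-6 * max(S.max(), 1e-300)
    y = np.log(np.maximum(S, eps))
    # OLS start: one shared pseudo-inverse
    x = (np.linalg.pinv(A) @ y.T).T  # (V, P)
    for _ in range(iterations):
        w = np.exp(2.0 * np.clip(x @ A.T, -350, 350))  # predicted S^2
        Aw = np.einsum("vn,ni,nj->vij", w, A, A)
        bw = np.einsum("vn,ni->vi", w * y, A)
        try:
            x = np.linalg.solve(Aw, bw[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for v in range(len(x)):
                try:
                    x[v] = np.linalg.solve(Aw[v], bw[v])
                except np.linalg.LinAlgError:
                    ok[v] = False
                    x[v] = 0.0
    n_vox = sig.shape[0]
    P = A.shape[1]
    coeffs = np.zeros((n_vox, P))
    coeffs[sel] = x
    fit_ok = np.zeros(n_vox, dtype=bool)
    fit_ok[sel] = ok
    s0 = np.exp(np.clip(coeffs[:, 0], -700, 700)) * (coeffs[:, 0] != 0)
    tensor = coeffs[:, 1:7] * 1e-3  # um^2/ms -> mm^2/s
    kurt = coeffs[:, 7:22] if model.lower() == "dki" else None
    return DiffusionFit(
        s0=s0.reshape(shape),
        tensor=tensor.reshape(shape + (6,)),
        kurtosis_scaled=None if kurt is None else kurt.reshape(shape + (15,)),
        fit_ok=fit_ok.reshape(shape),
        scheme=data.scheme,
        model=model.lower(),
    )


class DiffusionModel:
    """dipy-style front end: ``DiffusionModel(scheme, "dki").fit(dataset)``."""

    def __init__(self, scheme: AcquisitionScheme, model: str = "dti", iterations: int = 2):
        self.scheme = scheme
        self.model = model
        self.iterations = iterations
        self.design_ = design_matrix(scheme, model)  # validates the scheme

    def fit(self, data: DWIDataset, mask: np.ndarray | None = None) -> DiffusionFit:
        if data.scheme is not self.scheme and len(data.scheme) != len(self.scheme):
            raise ValueError("dataset scheme does not match model scheme")
        return fit_wlls(data, model=self.model, iterations=self.iterations, mask=mask)


@dataclass
class ScalarMaps:
    """Voxelwise scalar parameter maps derived from a diffusion fit.

    Diffusivities (MD, AD, RD) are in mm^2/s; FA and the kurtosis metrics are
    dimensionless. Kurtosis maps are None for DTI fits.
    """

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    mk: np.ndarray | None = None
    ak: np.ndarray | None = None
    rk: np.ndarray | None = None
    fit_ok: np.ndarray | None = None
    clip_fraction: float = 0.0

    @property
    def parameters(self) -> tuple[str, ...]:
        return DTI_PARAMS if self.mk is None else DKI_PARAMS

    def __getitem__(self, name: str) -> np.ndarray:
        out = getattr(self, name.lower(), None)
        if out is None:
            raise KeyError(name)
        return out


def scalar_metrics(
    fit: DiffusionFit,
    direction_set: np.ndarray | None = None,
    n_radial: int = 36,
    clip_range: tuple[float, float] = (-2.0, 10.0),
) -> ScalarMaps:
    """Derive FA/MD/AD/RD (and MK/AK/RK for DKI fits) from a fit.

    FA = sqrt(3/2) * sqrt(sum (lam_i - mean)^2 / sum lam_i^2); MD, AD, RD are
    the mean, largest, and mean-of-two-smallest eigenvalues. Apparent kurtosis
    along n is K_app(n) = V_app(n) / D_app(n)^2 with V = MD^2 W, so MK is the
    average of K_app over ``direction_set`` (>= 60 quasi-uniform vectors,
    default 120), AK is K_app along the principal eigenvector, and RK averages
    K_app over ``n_radial`` directions orthogonal to it.

    Negative eigenvalues (noise) are clamped to zero; kurtosis values are
    clipped to ``clip_range`` and the clipped fraction recorded.
    """
    D = tensor_from_unique(fit.tensor_internal)  # um^2/ms
    vals, vecs = np.linalg.eigh(D)
    vals = vals[..., ::-1]  # descending
    vecs = vecs[..., ::-1]
    n_neg = int((vals < 0).sum())
    if n_neg:
        log.info("clamped %d negative eigenvalue(s) to zero (%.2g%%)",
                 n_neg, 100.0 * n_neg / vals.size)
    vals = np.maximum(vals, 0.0)
    md = vals.mean(axis=-1)
    ad = vals[..., 0]
    rd = 0.5 * (vals[..., 1] + vals[..., 2])
    ssq = (vals**2).sum(axis=-1)
    dev = ((vals - md[..., None]) ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev / np.where(ssq > 0, ssq, 1.0))
    fa = np.where(ssq > 0, fa, 0.0)
    ok = fit.fit_ok
    fa, md, ad, rd = (np.where(ok, m, 0.0) for m in (fa, md, ad, rd))
    maps = ScalarMaps(fa=np.clip(fa, 0, 1), md=md * 1e-3, ad=ad * 1e-3, rd=rd * 1e-3, fit_ok=ok)
    if fit.kurtosis_scaled is None:
        return maps

    if direction_set is None:
        direction_set = fibonacci_sphere(120)
    direction_set = np.asarray(direction_set, float)
    if len(direction_set) < 60:
        raise ValueError("direction_set must contain at least 60 vectors")
    V15 = fit.kurtosis_scaled.reshape(-1, 15)
    D6 = fit.tensor_internal.reshape(-1, 6)

    def k_app(dirs):
        v_app = V15 @ kurtosis_monomials(dirs).T  # (vox, ndir)
        d_app = D6 @ tensor_monomials(dirs).T
        with np.errstate(invalid="ignore", divide="ignore"):
            k = v_app / np.where(d_app > 1e-12, d_app, 1.0) ** 2
        return np.where(d_app > 1e-12, k, 0.0)

    mk = k_app(direction_set).mean(axis=1)
    # axial: per-voxel principal axis -> evaluate directly
    e1 = vecs[..., :, 0].reshape(-1, 3)
    v_ax = (kurtosis_monomials(e1) * V15).sum(axis=1)
    d_ax = (tensor_monomials(e1) * D6).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ak = np.where(d_ax > 1e-12, v_ax / np.where(d_ax > 1e-12, d_ax, 1.0) ** 2, 0.0)
    # radial: average over a circle orthogonal to e1
    e2 = vecs[..., :, 1].reshape(-1, 3)
    e3 = vecs[..., :, 2].reshape(-1, 3)
    angles = np.linspace(0, np.pi, n_radial, endpoint=False)
    rk = np.zeros(len(V15))
    for t in angles:
        n_r = np.cos(t) * e2 + np.sin(t) * e3
        v_r = (kurtosis_monomials(n_r) * V15).sum(axis=1)
        d_r = (tensor_monomials(n_r) * D6).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rk += np.where(d_r > 1e-12, v_r / np.where(d_r > 1e-12, d_r, 1.0) ** 2, 0.0)
    rk /= n_radial

    shape = fit.s0.shape
    lo, hi = clip_range
    stack = np.stack([mk, ak, rk])
    n_clip = int(((stack < lo) | (stack > hi)).sum())
    maps.clip_fraction = n_clip / stack.size
    if n_clip:
        log.info("clipped %.3g%% of kurtosis values to [%g, %g]", 100 * maps.clip_fraction, lo, hi)
    okf = ok.ravel()
    maps.mk = (np.clip(mk, lo, hi) * okf).reshape(shape)
    maps.ak = (np.clip(ak, lo, hi) * okf).reshape(shape)
    maps.rk = (np.clip(rk, lo, hi) * okf).reshape(shape)
    return maps
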