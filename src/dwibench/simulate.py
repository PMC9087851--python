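"""Synthetic two-group dMRI cohorts with known ground truth.

The generator emulates the statistical structure of a tract-wise group study:
tube-shaped white-matter bundles in a 3D grid (with mirrored left/right pairs
and midline tracts), per-tract tensor + kurtosis tissue parameters with
between-subject variability, a designed group effect concentrated in chosen
tracts, Rician noise, and optional Gibbs-ringing, motion and eddy-current
corruption whose ground-truth transforms are recorded for recovery tests.

Tissue realism is deliberately piecewise-smooth (tract plateau blended into a
background compartment by the tract probability), not anatomical: the
machinery under test is the effect-size benchmarking, not anatomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AcquisitionScheme, AtlasError, DWIDataset, TractAtlas, fibonacci_sphere, subject_seeds
from .geometry import apply_affine, eddy_matrix, rotation_zyx, rotation_to_axis
from .modelfit import _design_columns, unique_from_tensor, unique_from_tensor4

log = logging.getLogger(__name__)

PHASE_ENCODE_AXIS = 1  # y


# --------------------------------------------------------------------------
# specs

@dataclass
class PopulationSpec:
    """Statistical structure of the two groups.

    The group effect shifts the affected parameter's tract mean by
    ``designed_d * between_subject_sd[param]`` in the patient group, so the
    population Cohen's d equals ``designed_d`` exactly by construction.

    Between-subject variation decomposes into a global per-subject component
    shared by all tracts and an independent per-tract component;
    ``tract_corr`` is the shared-variance fraction (diffusion parameters are
    strongly correlated across tracts within a subject).
    """

    n_hc: int = 20
    n_sle: int = 56
    affected_tracts: tuple[str, ...] = ()
    affected_param: str = "FA"
    effect_direction: float = -1.0  # pathology lowers FA
    designed_d: float = 0.8
    between_subject_sd: dict = field(default_factory=lambda: {
        "FA": 0.02, "MD": 0.03e-3, "MK": 0.06, "AK": 0.05, "RK": 0.08,
    })
    tract_corr: float = 0.8
    baseline_seed: int = 12345
    s0: float = 100.0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_sle < 2:
            raise ValueError("group sizes must be >= 2")
        if not 0.0 <= self.tract_corr <= 1.0:
            raise ValueError("tract_corr must lie in [0, 1]")


@dataclass
class ArtifactSpec:
    """Acquisition artifact model.

    ``snr_b0`` sets the Rician noise level (sigma = mean in-mask b0 signal /
    snr_b0; ``inf`` disables noise). Motion is a per-volume rigid perturbation
    (uniform in the given ranges); eddy shear/scale along the phase-encode
    axis scales with the volume's diffusion-gradient amplitude along that
    axis. ``gibbs_truncation`` is the retained central k-space fraction per
    in-plane axis (1.0 = off). ``bias_field`` adds a smooth multiplicative
    field of the given relative amplitude (0 = off).
    """

    snr_b0: float = np.inf
    motion_rot_deg: float = 0.0
    motion_trans_vox: float = 0.0
    eddy_scale: float = 0.0
    eddy_shear: float = 0.0
    gibbs_truncation: float = 1.0
    bias_field: float = 0.0
    #: motion is expressed relative to the initial head position, so the
    #: first b0 volume keeps the identity transform
    anchor_first_b0: bool = True

    def __post_init__(self) -> None:
        if not self.snr_b0 > 0:
            raise ValueError("snr_b0 must be positive")
        if not 0.0 < self.gibbs_truncation <= 1.0:
            raise ValueError("gibbs_truncation must lie in (0, 1]")


BACKGROUND = {"FA": 0.12, "MD": 0.85e-3, "MK": 0.7, "AK": 0.7, "RK": 0.7}
BACKGROUND_SD = {"FA": 0.015, "MD": 0.025e-3, "MK": 0.05, "AK": 0.05, "RK": 0.05}


# --------------------------------------------------------------------------
# atlas generation

def build_atlas(grid_shape, n_tracts: int, seed: int, *, radius_range=(1.2, 1.7)) -> TractAtlas:
    """Generate a synthetic tract atlas of soft-edged tubes.

    Tracts come as mirrored left/right pairs plus midline tubes
    (``n_tracts // 3`` pairs, the rest midline). Probability maps have a
    plateau near 1 inside the tube and a smooth sigmoid falloff. Deterministic
    given ``seed``.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if min(grid_shape) < 16:
        raise ValueError("grid must be at least 16 voxels along each axis")
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    nx, ny, nz = grid_shape
    rng = np.random.default_rng(seed)
    n_pairs = n_tracts // 3
    n_mid = n_tracts - 2 * n_pairs
    coords = np.indices(grid_shape, dtype=float)

    def tube(center, direction, radius):
        rel = coords - np.asarray(center)[:, None, None, None]
        par = np.tensordot(direction, rel, axes=1)
        perp2 = np.maximum((rel**2).sum(axis=0) - par**2, 0.0)
        return 1.0 / (1.0 + np.exp((np.sqrt(perp2) - radius) / 0.6))

    probs, names, orients = [], [], []
    occupancy = np.zeros(grid_shape)

    # Tube centers sit on jittered lattice slots: x-columns alternate between
    # anterior-posterior (y) and inferior-superior (z) tube axes, emulating
    # the orientation diversity of real white matter while keeping tubes from
    # crossing (tubes in one column are parallel; different columns are
    # separated in x). Pairs occupy a left-hemisphere band (mirrored to the
    # right); midline tubes a narrow central band.
    def slots(x_lo, x_hi, count, alternate_axis=True):
        n_cols = max(1, int((x_hi - x_lo) / 4.0) + 1) if x_hi > x_lo else 1
        n_per = int(np.ceil(count / n_cols))
        xs = np.linspace(x_lo, x_hi, n_cols + 2)[1:-1] if n_cols > 1 else [(x_lo + x_hi) / 2]
        us = np.linspace(0.15 * nz, 0.85 * nz, n_per + 2)[1:-1]
        out = []
        for j, u in enumerate(us):
            for i, x in enumerate(xs):
                axis = "y" if (not alternate_axis or i % 2 == 0) else "z"
                out.append((x, u, axis))
        du = (us[1] - us[0]) if len(us) > 1 else 0.7 * nz
        dx = (xs[1] - xs[0]) if len(xs) > 1 else (x_hi - x_lo) or du
        return out[:count], min(dx if dx > 0 else du, du)

    def place(center, radius, midline):
        x0, u0, axis = center
        for attempt in range(60):
            j1, j2 = rng.uniform(-0.8, 0.8, 2)
            if axis == "y":
                c = np.array([x0 + (0.0 if midline else j1), rng.uniform(0.3 * ny, 0.7 * ny), u0 + j2])
            else:
                c = np.array([x0 + (0.0 if midline else j1), u0 + j2, rng.uniform(0.3 * nz, 0.7 * nz)])
            d = _tube_direction(rng, axis=axis, midline=midline)
            r = max(radius * 0.95 ** (attempt // 5), 1.0)
            p = tube(c, d, r)
            if (occupancy * p).max() < 0.4:
                return c, d, p
        raise AtlasError("n_tracts exceeds packable volume for this grid")

    idx = 0
    if n_pairs:
        pair_slots, spacing = slots(0.10 * nx, 0.40 * nx, n_pairs)
        for center in pair_slots:
            radius = min(rng.uniform(*radius_range), max(1.0, 0.35 * spacing))
            c, d, p = place(center, radius, midline=False)
            cm = np.array([nx - 1 - c[0], c[1], c[2]])
            dm = np.array([-d[0], d[1], d[2]])
            pm = tube(cm, dm, radius)
            occupancy += p + pm
            idx += 1
            probs += [p, pm]
            names += [f"bundle_{idx:02d}_left", f"bundle_{idx:02d}_right"]
            orients += [d, dm]
    if n_mid:
        mid_slots, spacing = slots((nx - 1) / 2.0, (nx - 1) / 2.0, n_mid)
        for center in mid_slots:
            radius = min(rng.uniform(*radius_range), max(1.0, 0.35 * spacing))
            c, d, p = place(center, radius, midline=True)
            occupancy += p
            idx += 1
            probs.append(p)
            names.append(f"bundle_{idx:02d}_mid")
            orients.append(d)
    return TractAtlas(
        probabilities=np.stack(probs, axis=-1),
        tract_names=names,
        orientations=np.asarray(orients),
    )


def _unit(v):
    return v / np.linalg.norm(v)


def _s0_texture(shape, rng, sd: float = 0.12, corr_len: float = 2.0, n_blobs: int = 6,
                avoid: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative anatomy texture for the baseline (T2-like) signal.

    A smooth random field (mean 1, SD ~``sd``) plus a handful of bright
    sharp-edged inclusions emulating CSF spaces — placed outside the tracts
    (``avoid`` mask), where the diffusion attenuation is isotropic, so the
    landmarks keep the same shape in every volume. Real brains are edge-rich
    at every scale; without such landmarks, sub-degree registration is
    ill-posed on a small grid. The texture multiplies every volume
    identically, so it cancels out of all diffusion parameter estimates.
    """
    from scipy import ndimage
    f = ndimage.gaussian_filter(rng.standard_normal(shape), corr_len, mode="wrap")
    f *= sd / max(f.std(), 1e-12)
    tex = 1.0 + np.clip(f, -0.3, 0.3)
    coords = np.indices(shape, dtype=float)
    placed = 0
    for _ in range(20 * n_blobs):
        if placed >= n_blobs:
            break
        c = np.array([rng.uniform(0.15 * s, 0.85 * s) for s in shape])
        if avoid is not None and avoid[tuple(np.round(c).astype(int))] > 0.15:
            continue
        r = rng.uniform(1.2, 2.2)
        amp = rng.uniform(0.35, 0.7)
        d2 = ((coords - c[:, None, None, None]) ** 2).sum(axis=0)
        tex += amp / (1.0 + np.exp((np.sqrt(d2) - r) / 0.35))
        placed += 1
    return tex


def _tube_direction(rng, axis: str = "y", midline: bool = False) -> np.ndarray:
    """Tube axis: the column's dominant axis (y or z) with a random tilt;
    midline tubes keep a zero left-right component."""
    tilt_x = 0.0 if midline else rng.uniform(-0.15, 0.15)
    tilt_u = rng.uniform(-0.15, 0.15)
    if axis == "y":
        return _unit(np.array([tilt_x, 1.0, tilt_u]))
    return _unit(np.array([tilt_x, tilt_u, 1.0]))


# --------------------------------------------------------------------------
# tissue model

@dataclass
class TissueModel:
    """Voxelwise ground-truth tissue parameters for one subject.

    ``tensor`` is the symmetric diffusion tensor per voxel in mm^2/s;
    ``kurtosis`` the 15 unique components of the dimensionless rank-4 tensor W
    (None for DTI-only tissue). ``tract_params`` records the per-tract scalar
    ground truth this realization was built from.
    """

    s0: np.ndarray
    tensor: np.ndarray  # (..., 3, 3) mm^2/s
    kurtosis: np.ndarray | None  # (..., 15)
    tract_params: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = np.linalg.eigvalsh(self.tensor)
        if vals.min() < -1e-12:
            raise ValueError("tensor has negative eigenvalues")


def axisymmetric_eigenvalues(fa, md):
    """Eigenvalues (ad, rd, rd) of an axially symmetric tensor with given FA, MD.

    For lam = MD*(1+2a, 1-a, 1-a) one has FA = 3a / sqrt(3 + 6a^2), inverted
    here in closed form. FA must lie in [0, 1).
    """
    fa = np.asarray(fa, float)
    md = np.asarray(md, float)
    if np.any((fa < 0) | (fa >= 1)):
        raise ValueError("FA must lie in [0, 1)")
    a = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    return md * (1 + 2 * a), md * (1 - a)


_MK_DIRS = fibonacci_sphere(120)
_MK_C2 = None  # lazy cos^2 table


def _mk_cos2():
    global _MK_C2
    if _MK_C2 is None:
        _MK_C2 = _MK_DIRS[:, 2] ** 2  # fiber frame = z axis
    return _MK_C2


def axisymmetric_kurtosis(ad, rd, ak, rk, mk_target):
    """Per-voxel unique components (fiber frame, axis = z) of W hitting the
    given axial/radial kurtosis exactly and the direction-averaged mean
    kurtosis via the remaining cross term W_xxzz.

    Returns (w_rrrr, w_zzzz, w_xxzz) arrays.
    """
    ad = np.asarray(ad, float)
    rd = np.asarray(rd, float)
    md = (ad + 2 * rd) / 3.0
    w_zzzz = np.asarray(ak) * ad**2 / md**2
    w_rrrr = np.asarray(rk) * rd**2 / md**2
    c2 = _mk_cos2()[None, :]
    s2 = 1.0 - c2
    d_app = rd[..., None] + (ad - rd)[..., None] * c2
    base = md[..., None] ** 2 * (w_rrrr[..., None] * s2**2 + w_zzzz[..., None] * c2**2) / d_app**2
    slope = md[..., None] ** 2 * (6.0 * s2 * c2) / d_app**2
    w_xxzz = (np.asarray(mk_target) - base.mean(axis=-1)) / slope.mean(axis=-1)
    return w_rrrr, w_zzzz, w_xxzz


def _w15_fiber_frame(w_rrrr, w_zzzz, w_xxzz):
    """Stack the 15 unique components (fiber frame) from the 3 axisym values."""
    n = len(w_rrrr)
    w = np.zeros((n, 15))
    w[:, 0] = w_rrrr          # xxxx
    w[:, 1] = w_rrrr          # yyyy
    w[:, 2] = w_zzzz          # zzzz
    w[:, 9] = w_rrrr / 3.0    # xxyy
    w[:, 10] = w_xxzz         # xxzz
    w[:, 11] = w_xxzz         # yyzz
    return w


def _full_from_w15(w15):
    from .modelfit import KURTOSIS_IDX
    import itertools
    out = np.zeros(w15.shape[:-1] + (3, 3, 3, 3))
    for a, idx in enumerate(KURTOSIS_IDX):
        for perm in set(itertools.permutations(idx)):
            out[(...,) + perm] = w15[..., a]
    return out


def tract_baselines(atlas: TractAtlas, pop: PopulationSpec) -> pd.DataFrame:
    """Cohort-level per-tract baseline parameters (deterministic given
    ``pop.baseline_seed``); shared by every subject of both groups."""
    rows = []
    for t, name in enumerate(atlas.tract_names):
        rng = np.random.default_rng(np.random.SeedSequence([pop.baseline_seed, t]))
        # left/right partners share a baseline: derive from the merged name
        if name in atlas.pairs:
            pair_idx = min(t, atlas.tract_names.index(atlas.pairs[name]))
            rng = np.random.default_rng(np.random.SeedSequence([pop.baseline_seed, pair_idx]))
        rows.append({
            "tract": name,
            "FA": rng.uniform(0.35, 0.55),
            "MD": rng.uniform(0.70e-3, 0.90e-3),
            "MK": rng.uniform(0.9, 1.1),
            "AK": rng.uniform(0.6, 0.8),
            "RK": rng.uniform(1.2, 1.6),
        })
    return pd.DataFrame(rows).set_index("tract")


def sample_subject(
    pop: PopulationSpec,
    atlas: TractAtlas,
    group: str,
    seed: int,
    *,
    with_kurtosis: bool = True,
) -> TissueModel:
    """Draw one subject's tissue realization.

    Per-tract means are the cohort baselines plus correlated between-subject
    deviations; patients (group ``"SLE"``) get the designed shift in the
    affected tracts. Tensors are axially symmetric along each tract's
    orientation; the probability map blends tract and background parameters
    (partial volume). Ground truth is stored in ``tract_params``.
    """
    for t in pop.affected_tracts:
        if t not in atlas.tract_names:
            raise ValueError(f"affected tract '{t}' not in atlas")
    base = tract_baselines(atlas, pop)
    rng = np.random.default_rng(seed)
    params = list(pop.between_subject_sd)
    z_shared = {p: rng.standard_normal() for p in params}
    rho = pop.tract_corr
    values = base.copy()
    # left/right partners also share the independent deviation (one anatomical tract)
    indep: dict[str, dict[str, float]] = {}
    for name in atlas.tract_names:
        key = atlas.pairs.get(name)
        if key is not None and key in indep:
            indep[name] = indep[key]
        else:
            indep[name] = {p: rng.standard_normal() for p in params}
    for p in params:
        sd = pop.between_subject_sd[p]
        dev = np.array([
            sd * (np.sqrt(rho) * z_shared[p] + np.sqrt(1 - rho) * indep[n][p])
            for n in atlas.tract_names
        ])
        values[p] = base[p].to_numpy() + dev
    if group.upper() == "SLE" and pop.designed_d != 0:
        shift = pop.effect_direction * pop.designed_d * pop.between_subject_sd[pop.affected_param]
        for t in pop.affected_tracts:
            values.loc[t, pop.affected_param] += shift
    bg = {p: BACKGROUND[p] + BACKGROUND_SD[p] * rng.standard_normal() for p in BACKGROUND}
    values["FA"] = values["FA"].clip(0.0, 0.95)

    shape = atlas.probabilities.shape[:3]
    probs = atlas.probabilities
    owner = probs.argmax(axis=-1)
    pmax = probs.max(axis=-1)
    tensor = np.zeros(shape + (3, 3))
    w15 = np.zeros(shape + (15,)) if with_kurtosis else None

    def fill(mask, weights, fa_t, md_t, mk_t, ak_t, rk_t, R):
        w = weights[mask]
        fa = w * fa_t + (1 - w) * bg["FA"]
        md = w * md_t + (1 - w) * bg["MD"]
        ad, rd = axisymmetric_eigenvalues(fa, md)
        lam = np.stack([rd, rd, ad], axis=-1)  # fiber axis = z in local frame
        D = np.einsum("ai,vi,bi->vab", R, lam, R)
        tensor[mask] = D
        if w15 is not None:
            mk = w * mk_t + (1 - w) * bg["MK"]
            ak = w * ak_t + (1 - w) * bg["AK"]
            rk = w * rk_t + (1 - w) * bg["RK"]
            wr, wz, wx = axisymmetric_kurtosis(ad * 1e3, rd * 1e3, ak, rk, mk)
            wf = _full_from_w15(_w15_fiber_frame(wr, wz, wx))
            wrot = np.einsum("ai,bj,ck,dl,vijkl->vabcd", R, R, R, R, wf)
            w15[mask] = unique_from_tensor4(wrot)

    # background everywhere first (isotropic-leaning, axis z)
    all_mask = np.ones(shape, dtype=bool)
    fill(all_mask, np.zeros(shape), 0.0, bg["MD"], 0.0, 0.0, 0.0, np.eye(3))
    del all_mask
    for t, name in enumerate(atlas.tract_names):
        mask = (owner == t) & (pmax > 0.01)
        if not mask.any():
            continue
        row = values.loc[name]
        fill(mask, pmax, row["FA"], row["MD"], row["MK"], row["AK"], row["RK"],
             rotation_to_axis(np.asarray(atlas.orientations[t])) if atlas.orientations is not None
             else np.eye(3))

    values = values.reset_index()
    values.insert(1, "group", group)
    return TissueModel(
        # T2-like baseline contrast: tracts ~20% darker than background plus a
        # smooth per-subject texture field. The texture multiplies every
        # volume identically (it cancels in the model fit), but it gives b0
        # and diffusion-weighted volumes a strong shared intensity pattern --
        # the anatomical detail registration relies on in real brains.
        s0=pop.s0 * (1.0 - 0.2 * np.where(pmax > 0.01, pmax, 0.0)) * _s0_texture(shape, rng, avoid=pmax),
        tensor=tensor,
        kurtosis=w15,
        tract_params=values,
    )


# --------------------------------------------------------------------------
# forward model and artifacts

def forward_signal(tissue: TissueModel, scheme: AcquisitionScheme, *, subject_id="", group="") -> DWIDataset:
    """Noise-free signals for one subject under ``scheme``.

    Evaluates ln S = ln S0 - b D_app + (b^2/6) MD^2 W_app through the same
    design-matrix convention the fitting module uses, so a noise-free
    forward/fit roundtrip is exact. S(b=0) = S0 exactly.
    """
    model = "dki" if tissue.kurtosis is not None else "dti"
    A = _design_columns(scheme, model)
    d6 = unique_from_tensor(tissue.tensor).reshape(-1, 6) * 1e3  # um^2/ms
    md = (d6[:, 0] + d6[:, 1] + d6[:, 2]) / 3.0
    parts = [np.log(np.maximum(tissue.s0.reshape(-1), 1e-300))[:, None], d6]
    if tissue.kurtosis is not None:
        parts.append(tissue.kurtosis.reshape(-1, 15) * md[:, None] ** 2)  # V = MD^2 W
    coeffs = np.concatenate(parts, axis=1)
    sig = np.exp(coeffs @ A.T).reshape(tissue.s0.shape + (len(scheme),))
    # exp(log(s0)) costs one ulp; pin the unweighted volumes to S0 exactly
    sig[..., scheme.b0_mask] = tissue.s0[..., None]
    return DWIDataset(signal=sig, scheme=scheme, subject_id=subject_id, group=group)


def _forward_volume(tissue: TissueModel, bvalue: float, direction: np.ndarray) -> np.ndarray:
    """Noise-free signal volume for a single (b, n) measurement."""
    from .modelfit import kurtosis_monomials, tensor_monomials

    b_ms = bvalue / 1000.0
    d6 = unique_from_tensor(tissue.tensor).reshape(-1, 6) * 1e3
    n = np.asarray(direction, float).reshape(1, 3)
    n /= np.linalg.norm(n)
    lnS = np.log(np.maximum(tissue.s0.reshape(-1), 1e-300)) - b_ms * (d6 @ tensor_monomials(n).T)[:, 0]
    if tissue.kurtosis is not None:
        md = (d6[:, 0] + d6[:, 1] + d6[:, 2]) / 3.0
        v15 = tissue.kurtosis.reshape(-1, 15) * md[:, None] ** 2
        lnS = lnS + (b_ms**2 / 6.0) * (v15 @ kurtosis_monomials(n).T)[:, 0]
    return np.exp(lnS).reshape(tissue.s0.shape)


def add_rician_noise(data: DWIDataset, spec: ArtifactSpec, seed: int) -> DWIDataset:
    """Replace S by sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma^2) with
    sigma = mean in-mask b0 signal / snr_b0. The rectified floor makes the
    expectation of a zero signal sigma * sqrt(pi / 2)."""
    if not np.isfinite(spec.snr_b0):
        return data.with_signal(data.signal.copy())
    b0 = data.signal[..., data.scheme.b0_mask]
    mask = b0.mean(axis=-1) > 1e-12
    sigma = b0[mask].mean() / spec.snr_b0 if mask.any() else 0.0
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, data.signal.shape)
    e2 = rng.normal(0.0, sigma, data.signal.shape)
    noisy = np.sqrt((data.signal + e1) ** 2 + e2**2)
    return data.with_signal(noisy)


def apply_bias_field(data: DWIDataset, spec: ArtifactSpec, seed: int) -> DWIDataset:
    """Smooth multiplicative field 1 + amplitude * f(x), f a low-order
    polynomial ramp normalized to [-1, 1] (a stand-in for B1 heterogeneity)."""
    if spec.bias_field == 0:
        return data
    rng = np.random.default_rng(seed)
    g = [np.linspace(-1, 1, n) for n in data.shape]
    c = rng.normal(size=3)
    f = (c[0] * g[0][:, None, None] + c[1] * g[1][None, :, None] + c[2] * g[2][None, None, :]) / (
        np.abs(c).sum() + 1e-12
    )
    field = 1.0 + spec.bias_field * f
    return data.with_signal(data.signal * field[..., None])


def apply_gibbs(data: DWIDataset, spec: ArtifactSpec) -> DWIDataset:
    """Truncate each axial slice's 2D k-space to the central retained fraction
    and take the inverse-FFT magnitude, producing Gibbs ringing at edges."""
    frac = spec.gibbs_truncation
    if not 0.0 < frac <= 1.0:
        raise ValueError("gibbs_truncation must lie in (0, 1]")
    sig = data.signal
    nx, ny = sig.shape[:2]
    kx = np.fft.fftfreq(nx)
    ky = np.fft.fftfreq(ny)
    keep = (np.abs(kx)[:, None] <= frac / 2 + 1e-12) & (np.abs(ky)[None, :] <= frac / 2 + 1e-12)
    K = np.fft.fft2(sig, axes=(0, 1))
    out = np.abs(np.fft.ifft2(K * keep[:, :, None, None], axes=(0, 1)))
    return data.with_signal(out)


def apply_motion_eddy(
    data: DWIDataset, spec: ArtifactSpec, seed: int, *, tissue: TissueModel | None = None
) -> tuple[DWIDataset, list[dict]]:
    """Per-volume rigid motion plus eddy-current shear/scale along the
    phase-encode axis (y), the latter proportional to the volume's gradient
    amplitude along that axis (so b=0 volumes get motion only). Returns the
    corrupted dataset and the ground-truth transforms.

    When ``tissue`` is supplied the corruption is physically consistent: a
    rotated head experiences the scanner-frame gradient along a different
    tissue-frame direction, so the volume is re-simulated with the effective
    encoding direction R^T n before resampling. Without tissue the transform
    is image-space only (the encoding change from rotations <= a few degrees
    is second-order for most purposes, but motion/eddy *correction* assumes
    the physical convention when it rotates b-vectors back)."""
    rng = np.random.default_rng(seed)
    b = data.scheme.bvalues
    bmax = max(b.max(), 1.0)
    out = np.empty_like(data.signal)
    records = []
    first_b0 = int(np.flatnonzero(data.scheme.b0_mask)[0]) if data.scheme.b0_mask.any() else -1
    for v in range(len(data.scheme)):
        ang = rng.uniform(-spec.motion_rot_deg, spec.motion_rot_deg, 3)
        tr = rng.uniform(-spec.motion_trans_vox, spec.motion_trans_vox, 3)
        if spec.anchor_first_b0 and v == first_b0:
            ang = np.zeros(3)
            tr = np.zeros(3)
        g_pe = np.sqrt(b[v] / bmax) * abs(data.scheme.directions[v, PHASE_ENCODE_AXIS])
        scale = rng.uniform(-spec.eddy_scale, spec.eddy_scale) * g_pe
        shears = rng.uniform(-spec.eddy_shear, spec.eddy_shear, 2) * g_pe
        R = rotation_zyx(np.deg2rad(ang))
        E = eddy_matrix(scale, shears[0], shears[1], axis=PHASE_ENCODE_AXIS)
        M = R @ E
        vol = data.signal[..., v]
        if tissue is not None and b[v] > 0 and np.any(ang):
            vol = _forward_volume(tissue, b[v], R.T @ data.scheme.directions[v])
        if np.allclose(M, np.eye(3)) and not np.any(tr):
            out[..., v] = vol
        else:
            out[..., v] = apply_affine(vol, M, tr, order=3)
        records.append({
            "volume": v,
            "rotation_deg": ang,
            "translation_vox": tr,
            "eddy_scale": scale,
            "eddy_shears": shears,
            "matrix": M,
        })
    return data.with_signal(out), records


# --------------------------------------------------------------------------
# cohorts

def simulate_cohort(
    scheme: AcquisitionScheme,
    atlas: TractAtlas,
    pop: PopulationSpec,
    artifacts: ArtifactSpec | None = None,
    seed: int = 0,
    *,
    with_kurtosis: bool | None = None,
) -> tuple[list[DWIDataset], pd.DataFrame, list[pd.DataFrame]]:
    """Simulate a full two-group cohort on one protocol.

    Returns (datasets, design table, per-subject ground-truth tables). All
    randomness derives from ``seed`` via per-subject child seeds, so cohorts
    are reproducible and, for a fixed seed, identical across pipelines.
    """
    artifacts = artifacts or ArtifactSpec()
    if with_kurtosis is None:
        with_kurtosis = scheme.dki_capable
    n = pop.n_hc + pop.n_sle
    seeds = subject_seeds(seed, 4 * n)
    groups = ["HC"] * pop.n_hc + ["SLE"] * pop.n_sle
    datasets, rows, truths = [], [], []
    for i, group in enumerate(groups):
        sid = f"{group.lower()}{i:03d}"
        tissue = sample_subject(pop, atlas, group, seeds[4 * i], with_kurtosis=with_kurtosis)
        dwi = forward_signal(tissue, scheme, subject_id=sid, group=group)
        dwi = apply_bias_field(dwi, artifacts, seeds[4 * i + 1])
        if artifacts.gibbs_truncation < 1.0:
            dwi = apply_gibbs(dwi, artifacts)
        if artifacts.motion_rot_deg or artifacts.motion_trans_vox or artifacts.eddy_scale or artifacts.eddy_shear:
            dwi, _ = apply_motion_eddy(dwi, artifacts, seeds[4 * i + 2], tissue=tissue)
        dwi = add_rician_noise(dwi, artifacts, seeds[4 * i + 3])
        datasets.append(dwi)
        rows.append({"subject_id": sid, "group": group})
        truths.append(tissue.tract_params)
    return datasets, pd.DataFrame(rows), truths
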