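"""Core domain containers: acquisition schemes, DWI datasets, tract atlases, study config.

All tract statistics are computed in the native voxel space of each subject;
voxel indices are 0-based. Directions follow the FSL 3-row bvec dialect and are
interpreted in image axes. b-values at or below ``B0_TOLERANCE`` are treated as
unweighted (b0) volumes, accommodating scanner-reported small b-values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

#: b-values (s/mm^2) at or below this are treated as b=0.
B0_TOLERANCE = 50.0

#: Parameters whose effect-size sign is flipped so pathology-driven change is positive.
DIFFUSIVITY_PARAMS = ("MD", "RD", "AD")


def fibonacci_sphere(n: int, *, hemisphere: bool = True) -> np.ndarray:
    """Quasi-uniform unit vectors from the Fibonacci spiral.

    With ``hemisphere=True`` points are folded to z >= 0, which is the natural
    symmetry for diffusion encoding (antipodal directions are equivalent).
    """
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    if hemisphere:
        pts[pts[:, 2] < 0] *= -1.0
    return pts


class SchemeError(ValueError):
    """Raised when an acquisition scheme violates its invariants."""


@dataclass
class AcquisitionScheme:
    """One diffusion protocol: per-volume b-values and encoding directions.

    Parameters
    ----------
    name : str
        Protocol label, e.g. ``"3T-DTI"``.
    bvalues : array, shape (N,)
        Diffusion weighting per volume in s/mm^2.
    directions : array, shape (N, 3)
        Unit encoding vectors in image axes; the zero vector is allowed (and
        conventional) for b=0 volumes.
    voxel_size : float
        Isotropic voxel edge length in mm.
    te_ms, tr_ms : float
        Echo/repetition time metadata (not used in computation).
    """

    name: str
    bvalues: np.ndarray
    directions: np.ndarray
    voxel_size: float = 2.0
    te_ms: float = 0.0
    tr_ms: float = 0.0

    def __post_init__(self) -> None:
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise SchemeError("directions must have shape (N, 3)")
        if len(self.bvalues) != len(self.directions):
            raise SchemeError(
                f"scheme length {len(self.bvalues)} != direction count {len(self.directions)}"
            )
        norms = np.linalg.norm(self.directions, axis=1)
        weighted = self.bvalues > B0_TOLERANCE
        bad = weighted & (np.abs(norms - 1.0) > 1e-3)
        if np.any(bad):
            raise SchemeError(
                f"{int(bad.sum())} weighted direction(s) deviate from unit norm by > 1e-3"
            )
        fix = weighted & (np.abs(norms - 1.0) > 1e-6)
        if np.any(fix):
            self.directions = self.directions.copy()
            self.directions[fix] /= norms[fix, None]
        if not np.any(~weighted):
            raise SchemeError("scheme has no b=0 volume")

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues <= B0_TOLERANCE

    @property
    def shells(self) -> np.ndarray:
        """Distinct non-zero b-values, ascending."""
        return np.unique(np.round(self.bvalues[~self.b0_mask]))

    @property
    def dki_capable(self) -> bool:
        return len(self.shells) >= 2

    def subsample_directions(self, n_directions: int, seed: int = 0) -> "AcquisitionScheme":
        """Return a copy keeping all b0 volumes and ``n_directions`` weighted ones.

        Used for the angular-subsampling experiment (e.g. a 64-direction
        protocol reduced to 30 directions).
        """
        weighted = np.flatnonzero(~self.b0_mask)
        if n_directions > len(weighted):
            raise SchemeError("cannot subsample to more directions than available")
        rng = np.random.default_rng(seed)
        keep_w = np.sort(rng.choice(weighted, size=n_directions, replace=False))
        keep = np.sort(np.concatenate([np.flatnonzero(self.b0_mask), keep_w]))
        return AcquisitionScheme(
            name=f"{self.name}-{n_directions}dir",
            bvalues=self.bvalues[keep],
            directions=self.directions[keep],
            voxel_size=self.voxel_size,
            te_ms=self.te_ms,
            tr_ms=self.tr_ms,
        )


def _shelled_scheme(name, shells, voxel_size, te_ms, tr_ms):
    bvals, dirs = [], []
    for b, n in shells:
        bvals.extend([b] * n)
        if b <= B0_TOLERANCE:
            dirs.append(np.zeros((n, 3)))
        else:
            dirs.append(fibonacci_sphere(n))
    return AcquisitionScheme(
        name=name,
        bvalues=np.array(bvals, float),
        directions=np.concatenate(dirs, axis=0),
        voxel_size=voxel_size,
        te_ms=te_ms,
        tr_ms=tr_ms,
    )


def standard_schemes() -> dict[str, AcquisitionScheme]:
    """The three study protocols.

    ============  ===========  =======================================  =========
    protocol      voxel (mm)   b-values s/mm^2 (directions)             TR/TE ms
    ============  ===========  =======================================  =========
    3T-DTI        2.0          0 (8), 1000 (64)                         7300/73
    3T-DKI        2.3          0 (3), 250 (6), 500 (6), 1000 (20),      7500/103
                               2750 (30)
    7T-DTI        2.0          0 (3), 1000 (30)                         8816/62
    ============  ===========  =======================================  =========
    """
    return {
        "3T-DTI": _shelled_scheme("3T-DTI", [(0, 8), (1000, 64)], 2.0, 73, 7300),
        "3T-DKI": _shelled_scheme(
            "3T-DKI", [(0, 3), (250, 6), (500, 6), (1000, 20), (2750, 30)], 2.3, 103, 7500
        ),
        "7T-DTI": _shelled_scheme("7T-DTI", [(0, 3), (1000, 30)], 2.0, 62, 8816),
    }


#: Study cohort sizes per protocol as (n_hc, n_sle).
STUDY_GROUP_SIZES: dict[str, tuple[int, int]] = {
    "3T-DTI": (20, 63),
    "3T-DKI": (20, 56),
    "7T-DTI": (21, 54),
}


@dataclass
class DWIDataset:
    """One subject's 4D diffusion-weighted volume plus its scheme and geometry."""

    signal: np.ndarray
    scheme: AcquisitionScheme
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be a 4D (x, y, z, volume) array")
        if self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"scheme length {len(self.scheme)} != volume count {self.signal.shape[3]}"
            )
        n_bad = int(np.size(self.signal) - np.isfinite(self.signal).sum())
        if n_bad:
            raise ValueError(f"signal contains {n_bad} non-finite voxel value(s)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def with_signal(self, signal: np.ndarray, scheme: AcquisitionScheme | None = None) -> "DWIDataset":
        return DWIDataset(
            signal=signal,
            scheme=self.scheme if scheme is None else scheme,
            affine=self.affine,
            subject_id=self.subject_id,
            group=self.group,
        )


class AtlasError(ValueError):
    """Raised when a tract atlas violates its invariants."""


MAX_TRACTS = 72


@dataclass
class TractAtlas:
    """Per-tract probability maps with names and left/right pairing.

    ``laterality`` maps each tract name to ``"left"``, ``"right"`` or
    ``"midline"``; ``pairs`` maps each lateralized tract to its contralateral
    partner (an involution).
    """

    probabilities: np.ndarray
    tract_names: list[str]
    laterality: dict[str, str] = field(default_factory=dict)
    pairs: dict[str, str] = field(default_factory=dict)
    orientations: np.ndarray | None = None  # (n_tracts, 3) dominant fiber axis
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 4:
            raise AtlasError("probabilities must be 4D (x, y, z, tract)")
        if self.probabilities.shape[3] != len(self.tract_names):
            raise AtlasError("tract_names length must match 4th dimension")
        if len(self.tract_names) > MAX_TRACTS:
            raise AtlasError(f"atlas has more than {MAX_TRACTS} tracts")
        lo, hi = self.probabilities.min(), self.probabilities.max()
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise AtlasError(f"probability outside [0, 1]: range [{lo}, {hi}]")
        np.clip(self.probabilities, 0.0, 1.0, out=self.probabilities)
        if not self.laterality:
            self.laterality, self.pairs = infer_laterality(self.tract_names)
        for a, b in self.pairs.items():
            if b not in self.pairs or self.pairs[b] != a:
                raise AtlasError(f"dangling or asymmetric pair reference: {a} -> {b}")
            if a not in self.tract_names or b not in self.tract_names:
                raise AtlasError(f"pair references unknown tract: {a} or {b}")

    @property
    def n_tracts(self) -> int:
        return len(self.tract_names)

    def probability(self, name: str) -> np.ndarray:
        return self.probabilities[..., self.tract_names.index(name)]

    def empty_tracts(self) -> list[str]:
        """Tracts whose probability map is identically zero."""
        mass = self.probabilities.reshape(-1, self.n_tracts).sum(axis=0)
        return [n for n, m in zip(self.tract_names, mass) if m == 0]

    def merged_names(self) -> list[str]:
        """Names after left/right merging: one entry per pair plus midline tracts."""
        out, seen = [], set()
        for name in self.tract_names:
            if name in seen:
                continue
            if name in self.pairs:
                partner = self.pairs[name]
                seen.update({name, partner})
                out.append(merge_name(name))
            else:
                seen.add(name)
                out.append(name)
        return out


def merge_name(name: str) -> str:
    """Strip a _left/_right suffix to get the merged (bilateral) tract name."""
    for suf in ("_left", "_right"):
        if name.endswith(suf):
            return name[: -len(suf)]
    return name


def infer_laterality(names: Sequence[str]) -> tuple[dict[str, str], dict[str, str]]:
    """Resolve left/right pairing from ``_left``/``_right`` name suffixes."""
    laterality: dict[str, str] = {}
    pairs: dict[str, str] = {}
    names = list(names)
    for name in names:
        if name.endswith("_left"):
            laterality[name] = "left"
            partner = name[:-5] + "_right"
            if partner in names:
                pairs[name] = partner
        elif name.endswith("_right"):
            laterality[name] = "right"
            partner = name[:-6] + "_left"
            if partner in names:
                pairs[name] = partner
        else:
            laterality[name] = "midline"
    return laterality, pairs


DEFAULT_THRESHOLDS: dict[str, float] = {
    "mask_prob": 0.5,
    "cov_max": 0.25,
    "alpha": 0.05,
    "n_tracts_for_bonferroni": 72,
}


@dataclass
class StudyConfig:
    """Configuration of one full factorial experiment.

    ``pipelines`` is a list of step tuples (subsets of {"MPPCA", "Gibbs",
    "Eddy"}); ``group_sizes`` is (n_hc, n_sle). Thresholds carry the mask
    probability floor, the tract-volume CoV exclusion limit, the significance
    level, and the number of tests assumed by the Bonferroni correction.
    """

    protocols: list[str] = field(default_factory=lambda: ["3T-DTI", "3T-DKI", "7T-DTI"])
    pipelines: list[tuple[str, ...]] | None = None  # None -> all 8
    smoothing_sigmas: list[float] = field(default_factory=lambda: [round(0.1 * i, 1) for i in range(11)])
    seed: int = 0
    group_sizes: tuple[int, int] | None = None  # None -> per-protocol study sizes
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_tracts: int = 12
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    simulation: dict = field(default_factory=dict)  # PopulationSpec / ArtifactSpec overrides
    registration: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = dict(DEFAULT_THRESHOLDS)
        t.update(self.thresholds or {})
        self.thresholds = t
        if not 0 < t["mask_prob"] < 1:
            raise ValueError("mask_prob must lie in (0, 1)")
        if t["cov_max"] <= 0:
            raise ValueError("cov_max must be positive")
        if not 0 < t["alpha"] < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.pipelines is not None:
            self.pipelines = [tuple(p) for p in self.pipelines]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "group_sizes" in raw and raw["group_sizes"] is not None:
            raw["group_sizes"] = tuple(raw["group_sizes"])
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "protocols": list(self.protocols),
            "pipelines": None if self.pipelines is None else [list(p) for p in self.pipelines],
            "smoothing_sigmas": [float(s) for s in self.smoothing_sigmas],
            "seed": int(self.seed),
            "group_sizes": None if self.group_sizes is None else list(self.group_sizes),
            "grid_shape": list(self.grid_shape),
            "n_tracts": int(self.n_tracts),
            "thresholds": {k: float(v) for k, v in self.thresholds.items()},
            "simulation": self.simulation,
            "registration": self.registration,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def subject_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-subject seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
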