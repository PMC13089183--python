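"""Synthetic-data generators with known ground truth.

Three input families feed the downstream analyses and none of them can be
shipped with the package (they come from enzyme assays, annealing MD
sampling, and fragment-based quantum chemistry).  The generators here
emulate each family under a planted truth so that every stage — kinetic
fitting, conformational clustering, attack-geometry scoring — has a
recoverable target:

* initial-rate kinetic tables with additive Gaussian rate noise,
* pair-interaction-energy (PIE) matrices with planted conformation clusters,
* short trajectories of the four atoms that define the nucleophilic-attack
  geometry (SAM sulfur, SAM methyl carbon, nucleophile, substituent), built
  to realize exactly a sampled set of internal coordinates (d, theta, phi).

All randomness is driven by the integer seed on each spec; identical spec +
seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .kinetics import DualMMModel, KineticDataset, MMParams, predict_dual_mm, predict_mm

__all__ = [
    "DEFAULT_CONCENTRATIONS_UM",
    "KineticDesign",
    "PIEClusterSpec",
    "Fixed",
    "Uniform",
    "TruncNormal",
    "GeomSpec",
    "TrajectoryFrames",
    "gen_mm_rates",
    "gen_dual_mm_rates",
    "gen_pie_matrix",
    "gen_trajectory",
]

# assay design concentrations (uM) used for the sulfide substrates
DEFAULT_CONCENTRATIONS_UM = (0.0, 20.0, 200.0, 2000.0)

# fixed auxiliary bond lengths (A) used when realizing internal coordinates
_SSAM_CSAM_BOND_A = 1.81
_SUBSTITUENT_BOND_A = 2.05


@dataclass(frozen=True)
class KineticDesign:
    """Design of a simulated initial-rate experiment."""

    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS_UM
    n_rep: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0:
            raise ValueError("design needs at least one concentration")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if np.unique(c[c > 0]).size < 2:
            raise ValueError("at least 2 distinct positive concentrations required")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _noisy_dataset(s: np.ndarray, mean: np.ndarray, design: KineticDesign, condition: str) -> KineticDataset:
    rng = np.random.default_rng(design.seed)
    eps = rng.normal(0.0, design.noise_sd, size=mean.size) if design.noise_sd > 0 else 0.0
    reps = np.tile(np.arange(design.n_rep), len(design.concentrations))
    return KineticDataset.from_arrays(s, mean + eps, replicate=reps, condition=condition)


def gen_mm_rates(truth: MMParams, design: KineticDesign, condition: str = "mm") -> KineticDataset:
    """Simulate initial rates from a single Michaelis–Menten truth.

    rate(s, rep) = Vmax*s/(Km+s) + eps, eps ~ Normal(0, noise_sd^2); the
    mean rate at s = 0 is exactly 0.
    """
    s = np.repeat(np.asarray(design.concentrations, dtype=float), design.n_rep)
    mean = np.asarray(predict_mm(truth, s), dtype=float)
    return _noisy_dataset(s, mean, design, condition)


def gen_dual_mm_rates(
    gss: MMParams, h2s: MMParams, c1: float, design: KineticDesign, condition: str = "dual"
) -> KineticDataset:
    """Simulate initial rates from the piecewise dual-substrate model."""
    model = DualMMModel(gss=gss, h2s=h2s, c1=c1)  # validates c1 >= 0
    s = np.repeat(np.asarray(design.concentrations, dtype=float), design.n_rep)
    mean = np.asarray(predict_dual_mm(model, s), dtype=float)
    return _noisy_dataset(s, mean, design, condition)


@dataclass(frozen=True)
class PIEClusterSpec:
    """Planted-cluster specification for a synthetic PIE matrix.

    ``cluster_mean_profiles[c]`` is the per-fragment mean PIE (kJ/mol) of
    cluster c; each conformation in the cluster is that profile plus
    independent Normal(0, within_sd^2) noise per fragment.
    """

    n_fragments: int
    cluster_sizes: tuple[int, ...]
    cluster_mean_profiles: tuple[tuple[float, ...], ...]
    within_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) != len(self.cluster_mean_profiles):
            raise ValueError("one mean profile per cluster is required")
        if any(n < 1 for n in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 1")
        for p in self.cluster_mean_profiles:
            if len(p) != self.n_fragments:
                raise ValueError(
                    f"mean profile length {len(p)} != n_fragments {self.n_fragments}"
                )
        if self.within_sd < 0:
            raise ValueError("within_sd must be >= 0")


def gen_pie_matrix(spec: PIEClusterSpec, fragment_labels: Sequence[str] | None = None):
    """Generate a (conformations x fragments) PIE matrix with planted clusters.

    Returns ``(PIEMatrix, true_labels)`` where true_labels[i] is the planted
    cluster index of conformation i, for recovery scoring.
    """
    from .conformers import PIEMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    rows, labels = [], []
    for c, (size, profile) in enumerate(zip(spec.cluster_sizes, spec.cluster_mean_profiles)):
        mu = np.asarray(profile, dtype=float)
        noise = rng.normal(0.0, spec.within_sd, size=(size, spec.n_fragments)) if spec.within_sd > 0 else 0.0
        rows.append(np.broadcast_to(mu, (size, spec.n_fragments)) + noise)
        labels.extend([c] * size)
    values = np.vstack(rows)
    if fragment_labels is None:
        fragment_labels = [f"F{j:03d}" for j in range(spec.n_fragments)]
    table = pd.DataFrame(
        values,
        index=[f"conf_{i:04d}" for i in range(values.shape[0])],
        columns=list(fragment_labels),
    )
    return PIEMatrix(table), np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# distribution specs for trajectory internal coordinates


@dataclass(frozen=True)
class Fixed:
    value: float

    def sample(self, rng: np.random.Generator, n: int, domain=None) -> np.ndarray:
        _check_domain(np.full(1, self.value), domain)
        return np.full(n, float(self.value))


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def sample(self, rng: np.random.Generator, n: int, domain=None) -> np.ndarray:
        _check_domain(np.array([self.low, self.high]), domain)
        return rng.uniform(self.low, self.high, size=n)


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mean, sd) truncated to the sampling domain by resampling,
    which preserves the distribution's shape inside the domain."""

    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, n: int, domain=None) -> np.ndarray:
        lo, hi = domain if domain is not None else (-np.inf, np.inf)
        out = rng.normal(self.mean, self.sd, size=n)
        bad = (out < lo) | (out > hi)
        while np.any(bad):
            out[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
            bad = (out < lo) | (out > hi)
        return out


def _check_domain(values: np.ndarray, domain) -> None:
    if domain is None:
        return
    lo, hi = domain
    if np.any(values < lo) or np.any(values > hi):
        raise ValueError(f"distribution parameters outside domain [{lo}, {hi}]")


@dataclass(frozen=True)
class GeomSpec:
    """Sampling spec for per-frame attack geometry (d in A, angles in deg)."""

    n_frames: int
    d_dist: object
    theta_dist: object
    phi_dist: object
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")


@dataclass
class TrajectoryFrames:
    """Multi-frame coordinates for the four attack-geometry atoms.

    coords has shape (n_frames, 4, 3) in A, atom order matching
    ``atom_names``.  ``truth`` carries the internal coordinates each frame
    was built from (columns d_A, theta_deg, phi_deg), for recovery scoring.
    """

    atom_names: tuple[str, str, str, str]
    coords: np.ndarray
    truth: pd.DataFrame | None = None

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


REQUIRED_ATOM_ROLES = ("S_SAM", "C_SAM", "nucleophile", "substituent")


def gen_trajectory(
    spec: GeomSpec, atom_names: Sequence[str] = ("S_SAM", "C_SAM", "S1", "S2")
) -> TrajectoryFrames:
    """Build frames realizing exactly the sampled (d, theta, phi).

    Construction per frame: C_SAM at the origin, S_SAM on the -z axis; the
    nucleophile placed at distance d from C_SAM so the S_SAM–C_SAM–nucleophile
    angle is theta (random azimuth); the substituent bonded to the nucleophile
    so the substituent–nucleophile–C_SAM angle is phi (random azimuth about
    the nucleophile–C_SAM axis).  A random rigid-body rotation + translation
    is then applied, so recomputed internal coordinates are pose-independent.
    """
    if len(atom_names) != 4:
        raise ValueError("atom_names must name exactly 4 atoms (S_SAM, C_SAM, nucleophile, substituent)")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    d = np.asarray(spec.d_dist.sample(rng, n, domain=(1e-6, np.inf)), dtype=float)
    theta = np.asarray(spec.theta_dist.sample(rng, n, domain=(0.0, 180.0)), dtype=float)
    phi = np.asarray(spec.phi_dist.sample(rng, n, domain=(0.0, 180.0)), dtype=float)

    coords = np.empty((n, 4, 3))
    for i in range(n):
        coords[i] = _frame_from_internal(d[i], theta[i], phi[i], rng)
    truth = pd.DataFrame({"d_A": d, "theta_deg": theta, "phi_deg": phi})
    return TrajectoryFrames(atom_names=tuple(atom_names), coords=coords, truth=truth)


def _frame_from_internal(d: float, theta_deg: float, phi_deg: float, rng: np.random.Generator) -> np.ndarray:
    c_sam = np.zeros(3)
    s_sam = np.array([0.0, 0.0, -_SSAM_CSAM_BOND_A])
    u = np.array([0.0, 0.0, -1.0])  # unit C_SAM -> S_SAM

    th = np.deg2rad(theta_deg)
    az = rng.uniform(0.0, 2 * np.pi)
    # direction at angle theta from u, azimuth about the z axis
    dir_nuc = np.cos(th) * u + np.sin(th) * np.array([np.cos(az), np.sin(az), 0.0])
    nuc = d * dir_nuc

    w = -dir_nuc  # unit nucleophile -> C_SAM
    # orthonormal basis perpendicular to w, random in-plane azimuth
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, w)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    b1 = ref - np.dot(ref, w) * w
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(w, b1)
    ph = np.deg2rad(phi_deg)
    psi = rng.uniform(0.0, 2 * np.pi)
    v = np.cos(ph) * w + np.sin(ph) * (np.cos(psi) * b1 + np.sin(psi) * b2)
    sub = nuc + _SUBSTITUENT_BOND_A * v

    frame = np.stack([s_sam, c_sam, nuc, sub])
    quat = rng.normal(size=4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat))
    shift = rng.uniform(-10.0, 10.0, size=3)
    return rot.apply(frame) + shift
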