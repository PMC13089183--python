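"""Nucleophilic-attack geometry from trajectory frames.

An SN2-like methyl transfer from SAM requires the nucleophile (the anionic
sulfur of a persulfide, or a selenide Se-) to approach the SAM methyl carbon
(C_SAM) roughly in line with the breaking S_SAM–C_SAM bond, with its own
substituent out of the way.  Two internal coordinates capture this:

* theta — the angle S_SAM / C_SAM / nucleophile, near 180 deg for in-line
  attack alignment;
* phi — the angle substituent / nucleophile / C_SAM, where values in
  100–180 deg leave the lone-pair face of the nucleophile unhindered.

Frames with nucleophile–C_SAM distance within 4 A and theta in 150–180 deg
(inclusive cutoffs) are considered attack-competent; among those, the
fraction with phi in the optimal 100–180 deg range scores how often the
ligand's own substituent sterically blocks the transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AtomMap",
    "GeometrySummary",
    "frame_geometry",
    "trajectory_geometry",
    "extract_reactive_frames",
    "phi_histogram",
    "optimal_phi_fraction",
]

D_MAX_DEFAULT_A = 4.0
THETA_RANGE_DEFAULT = (150.0, 180.0)
PHI_RANGE_DEFAULT = (100.0, 180.0)

GEOMETRY_COLUMNS = ("frame", "d1_A", "d2_A", "theta_deg", "theta2_deg", "phi_deg", "d_diff_A")


@dataclass(frozen=True)
class AtomMap:
    """Atom indices of the four attack-geometry atoms within each frame."""

    s_sam: int
    c_sam: int
    nucleophile: int
    substituent: int
    ligand_kind: str = "other"

    def __post_init__(self) -> None:
        idx = (self.s_sam, self.c_sam, self.nucleophile, self.substituent)
        if len(set(idx)) != 4:
            raise ValueError("the four mapped atoms must be distinct")
        if any(i < 0 for i in idx):
            raise ValueError("atom indices must be >= 0")

    @classmethod
    def from_names(cls, atom_names, s_sam="S_SAM", c_sam="C_SAM",
                   nucleophile="S1", substituent="S2", ligand_kind="other") -> "AtomMap":
        names = list(atom_names)
        return cls(
            s_sam=names.index(s_sam),
            c_sam=names.index(c_sam),
            nucleophile=names.index(nucleophile),
            substituent=names.index(substituent),
            ligand_kind=ligand_kind,
        )


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle a-vertex-b in degrees, vectorized over leading axes."""
    va = a - vertex
    vb = b - vertex
    na = np.linalg.norm(va, axis=-1)
    nb = np.linalg.norm(vb, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("coincident atoms at an angle vertex: angle undefined")
    cos = np.sum(va * vb, axis=-1) / (na * nb)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def trajectory_geometry(coords: np.ndarray, atom_map: AtomMap, units: str = "angstrom") -> pd.DataFrame:
    """Per-frame attack geometry from coordinates of shape (n_frames, n_atoms, 3).

    Columns: d1_A (nucleophile–C_SAM), d2_A (substituent–C_SAM), theta_deg
    (S_SAM/C_SAM/nucleophile), theta2_deg (S_SAM/C_SAM/substituent, reported
    but not used for filtering), phi_deg (substituent/nucleophile/C_SAM),
    d_diff_A = d1 - d2.  Pass ``units='nm'`` for nanometre inputs.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if units == "nm":
        coords = coords * 10.0
    elif units != "angstrom":
        raise ValueError(f"unknown units: {units!r}")
    n_atoms = coords.shape[1]
    for i in (atom_map.s_sam, atom_map.c_sam, atom_map.nucleophile, atom_map.substituent):
        if i >= n_atoms:
            raise ValueError(f"atom index {i} out of range for {n_atoms} atoms")

    s_sam = coords[:, atom_map.s_sam]
    c_sam = coords[:, atom_map.c_sam]
    nuc = coords[:, atom_map.nucleophile]
    sub = coords[:, atom_map.substituent]

    d1 = np.linalg.norm(nuc - c_sam, axis=-1)
    d2 = np.linalg.norm(sub - c_sam, axis=-1)
    theta = _angle_deg(s_sam, c_sam, nuc)
    theta2 = _angle_deg(s_sam, c_sam, sub)
    phi = _angle_deg(sub, nuc, c_sam)
    return pd.DataFrame(
        {
            "frame": np.arange(coords.shape[0]),
            "d1_A": d1,
            "d2_A": d2,
            "theta_deg": theta,
            "theta2_deg": theta2,
            "phi_deg": phi,
            "d_diff_A": d1 - d2,
        }
    )


def frame_geometry(coords: np.ndarray, atom_map: AtomMap, units: str = "angstrom") -> pd.Series:
    """Attack geometry of a single frame (coords shape (n_atoms, 3))."""
    return trajectory_geometry(np.asarray(coords)[None], atom_map, units=units).iloc[0]


def extract_reactive_frames(
    series: pd.DataFrame,
    d_max: float = D_MAX_DEFAULT_A,
    theta_range: tuple[float, float] = THETA_RANGE_DEFAULT,
) -> pd.DataFrame:
    """Frames geometrically competent for attack: d1 <= d_max and
    theta within theta_range, all bounds inclusive.  An empty result is valid."""
    lo, hi = theta_range
    keep = (
        (series["d1_A"] <= d_max)
        & (series["theta_deg"] >= lo)
        & (series["theta_deg"] <= hi)
    )
    return series.loc[keep]


def phi_histogram(subset: pd.DataFrame, bin_width: float = 10.0):
    """Histogram of phi over [0, 180] deg; bins are [lo, hi) except the last,
    which is closed at 180.  Returns (edges, counts)."""
    if bin_width <= 0 or not np.isclose(180.0 / bin_width, round(180.0 / bin_width)):
        raise ValueError(f"bin_width must evenly divide 180, got {bin_width}")
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    phi = subset["phi_deg"].to_numpy(dtype=float) if len(subset) else np.empty(0)
    counts, _ = np.histogram(phi, bins=edges)
    return edges, counts


@dataclass
class GeometrySummary:
    """Steric-accessibility score of a trajectory.

    ``optimal_fraction`` is the percentage of extracted (attack-competent)
    frames whose phi lies in the optimal range; None when no frame passed
    the extraction filter (undefined, not zero).
    """

    n_frames_total: int
    n_extracted: int
    phi_bin_edges: np.ndarray
    phi_counts: np.ndarray
    n_optimal: int
    optimal_fraction: float | None
    phi_range: tuple[float, float] = PHI_RANGE_DEFAULT


def optimal_phi_fraction(
    subset: pd.DataFrame,
    n_frames_total: int | None = None,
    phi_range: tuple[float, float] = PHI_RANGE_DEFAULT,
    bin_width: float = 10.0,
) -> GeometrySummary:
    """Percentage of attack-competent frames with phi in the optimal
    (inclusive) range, plus the phi histogram."""
    n_ext = int(len(subset))
    lo, hi = phi_range
    phi = subset["phi_deg"].to_numpy(dtype=float) if n_ext else np.empty(0)
    n_opt = int(np.sum((phi >= lo) & (phi <= hi)))
    edges, counts = phi_histogram(subset, bin_width=bin_width)
    frac = 100.0 * n_opt / n_ext if n_ext > 0 else None
    return GeometrySummary(
        n_frames_total=int(n_frames_total) if n_frames_total is not None else n_ext,
        n_extracted=n_ext,
        phi_bin_edges=edges,
        phi_counts=counts,
        n_optimal=n_opt,
        optimal_fraction=frac,
        phi_range=phi_range,
    )
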