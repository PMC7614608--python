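"""Symmetry-resolved pairwise pose geometry for C2-symmetric complexes.

Subtomogram averaging yields, for every particle, a rigid placement (a
*pose*: rotation plus center in Å) of a reference complex in the tomogram
frame.  When two copies of a C2-symmetric complex sit on the same mRNP
globule, their relative rotation is two-valued: composing either pose with
the complex's own two-fold operator gives an equally valid placement.  This
module canonicalizes that ambiguity with the marker-distance rule used in
the field — match the symmetry-mate markers (the two THOC1 copies, in the
TREX case) that end up closest in space — and reports per-pair descriptors:

* center-to-center distance between designated center markers (THOC5-K516
  stand-in), and the minimum inter-atom distance,
* the canonical relative rotation as intrinsic, right-handed X→Y→Z Euler
  angles in degrees,
* spherical angles (physics convention) of the A→B center vector expressed
  in A's model frame,
* a contact flag (closest-atom distance below a cutoff, default 10 Å).

Also here: duplicate-pose removal and pair enumeration, per-atom contact
frequencies, the 2-D t-SNE embedding of (rotX, rotY, rotZ, distance)
descriptors, and crosslink Cα–Cα distance validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "Pose",
    "RigidModel",
    "PairGeometry",
    "CrosslinkSet",
    "euler_from_matrix",
    "matrix_from_euler",
    "resolve_symmetry",
    "pair_geometry",
    "extract_pairs",
    "contact_frequency",
    "embed_pairs",
    "crosslink_distances",
]

_ORTHO_TOL = 1e-8


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got shape {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection (determinant -1), not a proper rotation")
    return R


@dataclass
class Pose:
    """Rigid placement of the reference complex in the tomogram frame.

    ``rotation`` maps model-frame coordinates to the tomogram frame:
    ``x_tomo = rotation @ x_model + center``.
    """

    rotation: np.ndarray
    center: np.ndarray
    tomogram_id: str = "tomo_0"
    particle_id: int | None = None

    def __post_init__(self) -> None:
        self.rotation = _check_rotation(self.rotation)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def place(self, coords: np.ndarray) -> np.ndarray:
        """Map model-frame coordinates (n, 3) into the tomogram frame."""
        return np.asarray(coords, float) @ self.rotation.T + self.center


@dataclass
class RigidModel:
    """Pseudo-atom model of a C2-symmetric complex with labeled markers.

    ``center_marker`` names the single reference atom used for
    center-to-center distances; ``symmetry_pair`` names the two atoms that
    the order-2 ``symmetry_op`` maps onto each other (the disambiguation
    markers).  Atom coordinates are Å in the model frame; the symmetry
    operator acts in that same frame.
    """

    labels: list[str]
    chains: list[str]
    residues: list[int]
    coords: np.ndarray                      # (n_atoms, 3) Å
    center_marker: str
    symmetry_pair: tuple[str, str]
    symmetry_op: np.ndarray                 # 3x3, proper, order 2
    marker_tol: float = 1.0                 # Å, symmetry self-consistency

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if not (len(self.labels) == len(self.chains) == len(self.residues) == n):
            raise ValueError("labels/chains/residues/coords lengths disagree")
        self.symmetry_op = _check_rotation(self.symmetry_op)
        if not np.allclose(self.symmetry_op @ self.symmetry_op, np.eye(3), atol=1e-6):
            raise ValueError("symmetry_op must have order 2 (C2)")
        for lbl in (self.center_marker, *self.symmetry_pair):
            if self.labels.count(lbl) != 1:
                raise ValueError(f"marker {lbl!r} must match exactly one atom")
        s1, s2 = (self.coords[self.labels.index(l)] for l in self.symmetry_pair)
        if np.linalg.norm(self.symmetry_op @ s1 - s2) > self.marker_tol:
            raise ValueError(
                "symmetry_op does not map the symmetry_pair markers onto "
                f"each other within {self.marker_tol} Å"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def atom(self, label: str) -> np.ndarray:
        return self.coords[self.labels.index(label)]

    @property
    def center_coord(self) -> np.ndarray:
        return self.atom(self.center_marker)

    @property
    def symmetry_coords(self) -> np.ndarray:
        return np.stack([self.atom(l) for l in self.symmetry_pair])


@dataclass
class PairGeometry:
    """Descriptors of one A/B pair after symmetry resolution."""

    distance_center: float          # Å between placed center markers
    distance_closest: float         # Å minimum inter-atom distance
    euler: tuple[float, float, float]   # intrinsic XYZ, degrees
    theta: float                    # polar angle of A->B in A's model frame, deg
    phi: float                      # azimuth, deg in (-180, 180]
    contact: bool
    swapped: bool = False           # True if the C2-composed representative won
    index_a: int | None = None
    index_b: int | None = None
    particle_id: int | None = None

    def as_dict(self) -> dict:
        rx, ry, rz = self.euler
        return {
            "index_a": self.index_a,
            "index_b": self.index_b,
            "particle_id": self.particle_id,
            "distance_center": self.distance_center,
            "distance_closest": self.distance_closest,
            "rotX": rx,
            "rotY": ry,
            "rotZ": rz,
            "theta": self.theta,
            "phi": self.phi,
            "contact": self.contact,
            "swapped": self.swapped,
        }


def pairs_to_frame(pairs: Sequence[PairGeometry]) -> pd.DataFrame:
    """Tabulate PairGeometry records (one row per pair)."""
    return pd.DataFrame([p.as_dict() for p in pairs])


# ---------------------------------------------------------------------------
# Euler angles

def euler_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    """Decompose a proper rotation into intrinsic, right-handed X→Y→Z
    Euler angles in degrees.

    Ranges: rotX, rotZ in (−180, 180], rotY in [−90, 90].  At gimbal lock
    (|rotY| = 90°) the decomposition is degenerate; rotX carries the full
    in-plane angle and rotZ is reported as 0.
    """
    R = _check_rotation(R)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        angles = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
    return tuple(float(a) for a in angles)


def matrix_from_euler(angles: Sequence[float]) -> np.ndarray:
    """Compose a rotation matrix from intrinsic XYZ Euler angles (degrees)."""
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (3,):
        raise ValueError("expected three Euler angles (rotX, rotY, rotZ)")
    return Rotation.from_euler("XYZ", angles, degrees=True).as_matrix()


# ---------------------------------------------------------------------------
# Symmetry resolution

def resolve_symmetry(
    pose_a: Pose, pose_b: Pose, model: RigidModel
) -> tuple[np.ndarray, bool]:
    """Canonical relative rotation of a pair of poses of a C2 complex.

    Because the complex is two-fold symmetric, either pose may be composed
    with the model's C2 operator without moving any atom, so the relative
    rotation ``R = R_A.T @ R_B`` has four equivalent representatives
    ``C2^α · R · C2^β`` (α, β ∈ {0, 1}).  The canonical one is picked by
    the marker rule: measure all four distances between the symmetry-mate
    markers as placed by the two poses and keep the assignment (α, β)
    whose matched markers are globally closest.  An exact tie resolves to
    the plain representative (α = β = 0).

    This choice is exactly invariant under replacing either pose by its
    C2-composed equivalent, and canonical(B, A) is the transpose of
    canonical(A, B).

    Returns ``(R_canonical, swapped)``; ``swapped`` records whether a
    non-trivial assignment was chosen.
    """
    sym_a = pose_a.place(model.symmetry_coords)    # (2, 3)
    sym_b = pose_b.place(model.symmetry_coords)
    d = cdist(sym_a, sym_b)
    alpha, beta = np.unravel_index(np.argmin(d), d.shape)
    if d[alpha, beta] == d[0, 0]:
        alpha = beta = 0                           # documented tie-break
    r_rel = pose_a.rotation.T @ pose_b.rotation
    c2 = model.symmetry_op
    if alpha:
        r_rel = c2 @ r_rel
    if beta:
        r_rel = r_rel @ c2
    return r_rel, bool(alpha or beta)


# ---------------------------------------------------------------------------
# Pair descriptors

def pair_geometry(
    pose_a: Pose,
    pose_b: Pose,
    model: RigidModel,
    contact_cutoff: float = 10.0,
) -> PairGeometry:
    """Measure the full descriptor set for one pose pair.

    All quantities are invariant under a common rigid motion of both poses.
    If the placed center markers coincide the A→B direction is undefined;
    θ and φ are reported as 0 with a warning.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    atoms_a = pose_a.place(model.coords)
    atoms_b = pose_b.place(model.coords)
    cen_a = pose_a.place(model.center_coord[None, :])[0]
    cen_b = pose_b.place(model.center_coord[None, :])[0]

    distance_center = float(np.linalg.norm(cen_b - cen_a))
    distance_closest = float(cdist(atoms_a, atoms_b).min())

    r_rel, swapped = resolve_symmetry(pose_a, pose_b, model)
    euler = euler_from_matrix(r_rel)

    v = pose_a.rotation.T @ (cen_b - cen_a)     # A->B in A's model frame
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        warnings.warn("degenerate pair: coincident center markers; theta/phi set to 0")
        theta = phi = 0.0
    else:
        theta = float(np.degrees(np.arccos(np.clip(v[2] / norm, -1.0, 1.0))))
        phi = float(np.degrees(np.arctan2(v[1], v[0])))
        if phi <= -180.0:
            phi += 360.0
    return PairGeometry(
        distance_center=distance_center,
        distance_closest=distance_closest,
        euler=euler,
        theta=theta,
        phi=phi,
        contact=distance_closest <= contact_cutoff,
        swapped=swapped,
        particle_id=pose_a.particle_id,
    )


def deduplicate_poses(
    poses: Sequence[Pose],
    assignment: Sequence[int],
    dedup_cutoff: float = 100.0,
) -> list[int]:
    """Indices of poses kept after duplicate removal.

    Two poses on the same particle with centers within ``dedup_cutoff`` Å
    are duplicates; the first by input order is kept.
    """
    kept: list[int] = []
    for i, pose in enumerate(poses):
        dup = False
        for j in kept:
            if assignment[j] == assignment[i] and (
                np.linalg.norm(pose.center - poses[j].center) <= dedup_cutoff
            ):
                dup = True
                break
        if not dup:
            kept.append(i)
    return kept


def extract_pairs(
    poses: Sequence[Pose],
    assignment: Sequence[int],
    model: RigidModel,
    dedup_cutoff: float = 100.0,
    contact_cutoff: float = 10.0,
) -> list[PairGeometry]:
    """All unordered within-particle pose pairs, after duplicate removal.

    ``assignment`` gives the particle id of each pose; cross-particle pairs
    are excluded.  Empty input yields an empty list.
    """
    if len(assignment) != len(poses):
        raise ValueError("assignment must cover all poses")
    kept = deduplicate_poses(poses, assignment, dedup_cutoff)
    out: list[PairGeometry] = []
    for ii, i in enumerate(kept):
        for j in kept[ii + 1:]:
            if assignment[i] != assignment[j]:
                continue
            pg = pair_geometry(poses[i], poses[j], model, contact_cutoff)
            pg.index_a, pg.index_b = i, j
            pg.particle_id = assignment[i]
            out.append(pg)
    return out


def contact_frequency(
    pose_pairs: Sequence[tuple[Pose, Pose]],
    model: RigidModel,
    cutoff: float = 10.0,
) -> tuple[np.ndarray, float]:
    """Per-atom contact frequency and overall contact fraction.

    For each (A, B) pair, an atom of A is "in contact" when it lies within
    ``cutoff`` Å of any atom of B.  Returns the per-atom fraction of pairs
    in which each A atom contacts B, and the fraction of pairs with any
    contact at all.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(pose_pairs) == 0:
        raise ValueError("need at least one pose pair")
    counts = np.zeros(model.n_atoms)
    n_contact_pairs = 0
    for pose_a, pose_b in pose_pairs:
        d = cdist(pose_a.place(model.coords), pose_b.place(model.coords))
        hit = (d <= cutoff).any(axis=1)
        counts += hit
        n_contact_pairs += bool(hit.any())
    return counts / len(pose_pairs), n_contact_pairs / len(pose_pairs)


# ---------------------------------------------------------------------------
# Embedding

def embed_pairs(
    pair_table: pd.DataFrame | np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE embedding of the 4-D (rotX, rotY, rotZ, distance) descriptors.

    Features are z-scored before embedding so the distance (Å, typically
    hundreds) does not dominate the angles (degrees).  Requires at least
    ``3 * perplexity`` rows.  Deterministic for a fixed seed.
    """
    from sklearn.manifold import TSNE

    if isinstance(pair_table, pd.DataFrame):
        X = pair_table[["rotX", "rotY", "rotZ", "distance_center"]].to_numpy(float)
    else:
        X = np.asarray(pair_table, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("pair_table must have four columns: rotX, rotY, rotZ, distance")
    n_min = int(np.ceil(3 * perplexity))
    if len(X) < n_min:
        raise ValueError(
            f"embedding needs at least {n_min} pairs for perplexity={perplexity}, got {len(X)}"
        )
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    tsne = TSNE(
        n_components=2, perplexity=perplexity, init="pca",
        random_state=seed, max_iter=1000,
    )
    return tsne.fit_transform(Z)


# ---------------------------------------------------------------------------
# Crosslink validation

@dataclass
class CrosslinkSet:
    """Crosslinked residue pairs, optionally evaluated against coordinates."""

    pairs: list[tuple[str, int, str, int]]      # (chainA, resA, chainB, resB)
    distances: np.ndarray | None = None         # Å, NaN where unmapped
    satisfied: np.ndarray | None = None
    cutoff: float | None = None
    n_unmapped: int = 0
    ground_truth_long: np.ndarray | None = None  # generator bookkeeping

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pairs, columns=["chainA", "resA", "chainB", "resB"])
        if self.distances is not None:
            df["distance_A"] = self.distances
            df["satisfied"] = self.satisfied
        return df


def crosslink_distances(
    links: CrosslinkSet,
    coords: Mapping[tuple[str, int], np.ndarray],
    cutoff: float = 30.0,
    bin_width: float = 5.0,
) -> tuple[CrosslinkSet, np.ndarray, np.ndarray]:
    """Evaluate Cα–Cα distances of crosslinked residue pairs on a model.

    ``coords`` maps (chain, residue) to a Cα position in Å.  Links whose
    residues are absent from the model (unmodelled regions are common) are
    tallied in ``n_unmapped`` and carry NaN distances — they are reported,
    never silently dropped.  Returns the evaluated set plus histogram
    counts and bin edges (``bin_width``-Å bins from 0).
    """
    dists = np.full(len(links.pairs), np.nan)
    n_unmapped = 0
    for k, (ca, ra, cb, rb) in enumerate(links.pairs):
        try:
            xa, xb = coords[(ca, ra)], coords[(cb, rb)]
        except KeyError:
            n_unmapped += 1
            continue
        dists[k] = np.linalg.norm(np.asarray(xa, float) - np.asarray(xb, float))
    mapped = dists[~np.isnan(dists)]
    hi = bin_width if mapped.size == 0 else bin_width * np.ceil(mapped.max() / bin_width + 1e-9)
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(mapped, bins=edges)
    evaluated = CrosslinkSet(
        pairs=list(links.pairs),
        distances=dists,
        satisfied=dists <= cutoff,
        cutoff=cutoff,
        n_unmapped=n_unmapped,
        ground_truth_long=links.ground_truth_long,
    )
    return evaluated, counts, edges
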