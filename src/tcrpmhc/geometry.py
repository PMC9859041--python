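"""Rigid-body coordinate frames and the 6-parameter docking geometry.

The relative orientation of a TCR over a peptide-MHC is summarized by the
rigid transform between two internal coordinate frames, one anchored in the
beta-sheet floor of the MHC peptide-binding groove and one in the paired
variable domains of the TCR.  Both frames exploit the approximate two-fold
(C2) internal symmetry of their domain: the symmetry rotation axis, oriented
toward the binding partner, is the frame x-axis; the vector between the
centers of mass of the two symmetric halves (orthogonalized against x) is the
z-axis; y completes a right-handed system.

The transform between the frames is charted locally by six real parameters:
the inter-origin distance d, a dihedral (torsion) about the line connecting
the origins, and two unit vectors -- the origin-to-origin direction expressed
in each frame -- each parameterized by a polar angle from the frame x-axis
and an azimuth in the frame's y-z plane.  A multivariate normal fit to these
6-vectors over a structure database gives a Mahalanobis "docking Z score"
measuring how far a binding mode sits from the consensus for its MHC class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "Frame",
    "DockingGeometry",
    "GeometryDistribution",
    "dihedral",
    "pseudo_symmetry_transform",
    "build_frame_from_halves",
    "build_mhc_frame",
    "build_tcr_frame",
    "compute_docking_geometry",
    "geometry_to_transform",
    "tcr_frame_from_geometry",
    "fit_geometry_distribution",
    "load_geometry_priors",
    "mahalanobis_z",
    "kabsch",
]

_ORTHO_TOL = 1e-8
# indices of the circular components of the 6-vector (torsion, two azimuths)
ANGULAR_COMPONENTS = (1, 3, 5)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a near-zero vector")
    return v / n


def kabsch(
    fixed: np.ndarray, mobile: np.ndarray, weights: np.ndarray | None = None
) -> "RigidTransform":
    """Least-squares rigid transform T minimizing sum w_i |fixed_i - T(mobile_i)|^2.

    Closed-form SVD solution with determinant correction, so the result is a
    proper rotation (no reflections).
    """
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = fixed.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    cf = (w[:, None] * fixed).sum(axis=0) / wsum
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    x = mobile - cm
    y = fixed - cf
    h = (w[:, None] * x).T @ y
    u, s, vt = np.linalg.svd(h)
    # guard against degenerate (e.g. collinear) geometry: at least two
    # singular values must be meaningfully non-zero to pin the rotation
    scale = max(s[0], 1e-12)
    if s[1] / scale < 1e-9:
        raise ValueError("degenerate (collinear or coincident) point geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return RigidTransform(rotation=rot, translation=cf - rot @ cm)


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral angle (radians) of four points, IUPAC sign convention.

    Rotating p4 about the p2->p3 axis by +phi (right-hand rule) decreases the
    returned angle by phi.
    """
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x = n1 @ n2
    y = m1 @ n2
    if abs(x) < 1e-14 and abs(y) < 1e-14:
        raise ValueError("dihedral undefined: collinear bond vectors")
    return float(np.arctan2(y, x))


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    axis = _unit(np.asarray(axis, float))
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        if rot.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -(self.rotation.T @ self.translation))

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians, in [0, pi]."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def rotation_axis(self) -> np.ndarray:
        """Unit rotation axis (sign convention of scipy's rotvec)."""
        from scipy.spatial.transform import Rotation

        vec = Rotation.from_matrix(self.rotation).as_rotvec()
        return _unit(vec)


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal coordinate frame embedded in global space."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, float).reshape(3)
        axes = [np.asarray(a, float).reshape(3) for a in (self.x_axis, self.y_axis, self.z_axis)]
        rot = np.column_stack(axes)
        if not np.allclose(rot.T @ rot, np.eye(3), atol=_ORTHO_TOL * 10):
            raise ValueError("frame axes are not orthonormal")
        if not np.isclose(np.cross(axes[0], axes[1]) @ axes[2], 1.0, atol=1e-6):
            raise ValueError("frame is not right-handed")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "x_axis", axes[0])
        object.__setattr__(self, "y_axis", axes[1])
        object.__setattr__(self, "z_axis", axes[2])

    @classmethod
    def identity(cls) -> "Frame":
        return cls(np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    @classmethod
    def from_rotation(cls, rotation: np.ndarray, origin: np.ndarray) -> "Frame":
        rotation = np.asarray(rotation, float)
        return cls(origin, rotation[:, 0], rotation[:, 1], rotation[:, 2])

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with the axes as columns (local -> global)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) @ self.rotation

    def from_local(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.origin

    def transformed(self, t: RigidTransform) -> "Frame":
        return Frame.from_rotation(t.rotation @ self.rotation, t.apply(self.origin))


def pseudo_symmetry_transform(half_a: np.ndarray, half_b: np.ndarray) -> RigidTransform:
    """Least-squares transform mapping (half_a, half_b) onto (half_b, half_a).

    For a domain with internal C2 pseudo-symmetry the two halves swap under an
    approximate 180-degree rotation; this returns the best-fit proper rigid
    motion implementing the swap.  A perfectly symmetric point set gives zero
    residual and an exactly 180-degree rotation.
    """
    a = np.asarray(half_a, float)
    b = np.asarray(half_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("halves must be matching (n>=3, 3) arrays")
    mobile = np.vstack([a, b])
    fixed = np.vstack([b, a])
    return kabsch(fixed, mobile)


def build_frame_from_halves(
    half_n: np.ndarray, half_c: np.ndarray, toward: np.ndarray
) -> Frame:
    """Frame from two pseudo-symmetric residue halves.

    x = symmetry rotation axis, sign chosen so it points toward `toward`
    (e.g. the peptide for the MHC, the CDR loops for the TCR); z = direction
    from the N-half COM to the C-half COM, orthogonalized against x;
    y = z cross x; origin = COM of all core points.
    """
    half_n = np.asarray(half_n, float)
    half_c = np.asarray(half_c, float)
    t = pseudo_symmetry_transform(half_n, half_c)
    x = t.rotation_axis()
    allpts = np.vstack([half_n, half_c])
    origin = allpts.mean(axis=0)
    if (np.asarray(toward, float) - origin) @ x < 0:
        x = -x
    z_raw = half_c.mean(axis=0) - half_n.mean(axis=0)
    z = z_raw - (z_raw @ x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        raise ValueError("z-axis degenerate: half-COM separation parallel to symmetry axis")
    z = z / nz
    y = np.cross(z, x)
    return Frame(origin, x, y, z)


def build_mhc_frame(complex, cores) -> Frame:
    """MHC coordinate frame from the 6+6 beta-sheet core residues.

    The symmetry axis of the transform swapping the N- and C-terminal
    half-sheets, signed toward the peptide, is x; see build_frame_from_halves.
    """
    mhc = complex.chain("mhc")
    half_n = np.array([mhc[i].ca_xyz for i in cores.mhc_n_half])
    half_c = np.array([mhc[i].ca_xyz for i in cores.mhc_c_half])
    pep = complex.chain("peptide")
    pep_com = np.array([r.ca_xyz for r in pep]).mean(axis=0)
    return build_frame_from_halves(half_n, half_c, pep_com)


def build_tcr_frame(complex, cores) -> Frame:
    """TCR coordinate frame from the 13 alpha + 13 beta conserved core residues.

    Same construction as the MHC frame with the halves replaced by the alpha-
    and beta-chain cores; the x-axis is signed toward the CDR3 loops, so z
    runs from the alpha-core COM to the beta-core COM.
    """
    tcra = complex.chain("tcra")
    tcrb = complex.chain("tcrb")
    half_a = np.array([tcra[i].ca_xyz for i in cores.tcra_core])
    half_b = np.array([tcrb[i].ca_xyz for i in cores.tcrb_core])
    cdr3_pts = []
    for chain, loop in ((tcra, "cdr3a"), (tcrb, "cdr3b")):
        lo, hi = complex.annotation.cdr_spans[loop]
        cdr3_pts.extend(chain[i].ca_xyz for i in range(lo, hi))
    if not cdr3_pts:
        raise ValueError("no CDR3 coordinates available to orient the TCR frame")
    return build_frame_from_halves(half_a, half_b, np.asarray(cdr3_pts).mean(axis=0))


def _unit_to_angles(u: np.ndarray) -> tuple[float, float]:
    """(polar from local x-axis, azimuth in the local y-z plane)."""
    polar = float(np.arccos(np.clip(u[0], -1.0, 1.0)))
    azimuth = float(np.arctan2(u[2], u[1]))
    return polar, azimuth


def _angles_to_unit(polar: float, azimuth: float) -> np.ndarray:
    sp = np.sin(polar)
    return np.array([np.cos(polar), sp * np.cos(azimuth), sp * np.sin(azimuth)])


@dataclass(frozen=True)
class DockingGeometry:
    """6-DOF relation between the MHC and TCR coordinate frames.

    d        -- inter-origin distance (Angstrom)
    torsion  -- dihedral of (MHC x-tip, MHC origin, TCR origin, TCR x-tip)
    mhc_unit -- MHC->TCR direction expressed in the MHC frame
    tcr_unit -- TCR->MHC direction expressed in the TCR frame
    """

    d: float
    torsion: float
    mhc_unit: np.ndarray
    tcr_unit: np.ndarray

    def __post_init__(self):
        if not self.d > 0:
            raise ValueError("inter-origin distance must be positive")
        mu = np.asarray(self.mhc_unit, float).reshape(3)
        tu = np.asarray(self.tcr_unit, float).reshape(3)
        for u in (mu, tu):
            if not np.isclose(np.linalg.norm(u), 1.0, atol=1e-8):
                raise ValueError("direction vectors must be unit length")
        object.__setattr__(self, "d", float(self.d))
        object.__setattr__(self, "torsion", float(self.torsion))
        object.__setattr__(self, "mhc_unit", mu)
        object.__setattr__(self, "tcr_unit", tu)

    def as_vector(self) -> np.ndarray:
        """(d, torsion, polar/azimuth of mhc_unit, polar/azimuth of tcr_unit)."""
        pm, am = _unit_to_angles(self.mhc_unit)
        pt, at = _unit_to_angles(self.tcr_unit)
        return np.array([self.d, self.torsion, pm, am, pt, at])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "DockingGeometry":
        v = np.asarray(v, float).reshape(6)
        return cls(
            d=float(v[0]),
            torsion=float(v[1]),
            mhc_unit=_angles_to_unit(v[2], v[3]),
            tcr_unit=_angles_to_unit(v[4], v[5]),
        )


def compute_docking_geometry(mhc_frame: Frame, tcr_frame: Frame) -> DockingGeometry:
    """Extract the 6 docking parameters relating two frames.

    Invariant under any global rigid motion applied to both frames.
    """
    delta = tcr_frame.origin - mhc_frame.origin
    d = float(np.linalg.norm(delta))
    if d < 1e-8:
        raise ValueError("frame origins coincide; docking geometry undefined")
    mhc_unit = mhc_frame.rotation.T @ (delta / d)
    tcr_unit = tcr_frame.rotation.T @ (-delta / d)
    try:
        torsion = dihedral(
            mhc_frame.origin + mhc_frame.x_axis,
            mhc_frame.origin,
            tcr_frame.origin,
            tcr_frame.origin + tcr_frame.x_axis,
        )
    except ValueError:
        # an x-axis parallel to the inter-origin line leaves the torsion
        # undefined; fix it at 0 by convention
        torsion = 0.0
    return DockingGeometry(d=d, torsion=torsion, mhc_unit=mhc_unit, tcr_unit=tcr_unit)


def geometry_to_transform(g: DockingGeometry) -> RigidTransform:
    """Pose of the TCR frame when the MHC frame is the identity frame.

    Inverse of compute_docking_geometry: with the MHC frame at the origin and
    axis-aligned, returns the rigid transform whose rotation columns are the
    TCR frame axes and whose translation is the TCR frame origin.
    """
    o_tcr = g.d * g.mhc_unit  # MHC frame is identity, so local == global
    # one rotational DOF remains after requiring R @ tcr_unit == -mhc_unit;
    # start from the minimal rotation and fix the residual spin via the torsion
    target = -g.mhc_unit
    source = g.tcr_unit
    c = float(source @ target)
    if c < -1.0 + 1e-12:
        # antiparallel: 180 degrees about any axis perpendicular to source
        perp = np.cross(source, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(source, [0.0, 1.0, 0.0])
        r0 = _rotation_about_axis(perp, np.pi)
    elif c > 1.0 - 1e-12:
        r0 = np.eye(3)
    else:
        axis = np.cross(source, target)
        r0 = _rotation_about_axis(axis, float(np.arccos(np.clip(c, -1, 1))))
    tau0 = dihedral(
        np.array([1.0, 0.0, 0.0]), np.zeros(3), o_tcr, o_tcr + r0 @ np.array([1.0, 0, 0])
    )
    # spinning the TCR frame about the connecting axis by +phi subtracts phi
    spin = _rotation_about_axis(g.mhc_unit, tau0 - g.torsion)
    return RigidTransform(spin @ r0, o_tcr)


def tcr_frame_from_geometry(g: DockingGeometry, mhc_frame: Frame | None = None) -> Frame:
    """Realize the TCR frame implied by a docking geometry.

    With no MHC frame given, the MHC frame is the identity.
    """
    t = geometry_to_transform(g)
    frame = Frame.from_rotation(t.rotation, t.translation)
    if mhc_frame is not None:
        glob = RigidTransform(mhc_frame.rotation, mhc_frame.origin)
        frame = frame.transformed(glob)
    return frame


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.arctan2(np.sin(angles).mean(), np.cos(angles).mean()))


def _unwrap_against(values: np.ndarray, center: float) -> np.ndarray:
    """Shift each angle by multiples of 2*pi into (center-pi, center+pi]."""
    return center + np.angle(np.exp(1j * (values - center)))


@dataclass(frozen=True)
class GeometryDistribution:
    """Multivariate normal fit to docking-geometry 6-vectors of one MHC class."""

    mean: np.ndarray
    covariance: np.ndarray
    mhc_class: int
    n_samples: int = 0

    def __post_init__(self):
        mean = np.asarray(self.mean, float).reshape(6)
        cov = np.asarray(self.covariance, float)
        if cov.shape != (6, 6) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric 6x6")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("covariance must be positive semidefinite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)


def load_geometry_priors() -> dict:
    """Shipped per-MHC-class docking-geometry distributions (synthetic priors)."""
    import json
    from importlib import resources

    text = resources.files("tcrpmhc.data").joinpath("geometry_priors.json").read_text()
    raw = json.loads(text)
    return {
        int(k): GeometryDistribution(
            mean=np.asarray(v["mean"]),
            covariance=np.asarray(v["covariance"]),
            mhc_class=int(k),
            n_samples=int(v["n_samples"]),
        )
        for k, v in raw.items()
        if not k.startswith("_")
    }


def fit_geometry_distribution(
    geoms: list[DockingGeometry], mhc_class: int, regularization: float = 1e-6
) -> GeometryDistribution:
    """Sample mean/covariance of the 6-vectors, circular components unwrapped.

    The torsion and the two azimuths live on a circle; each is unwrapped into
    the 2*pi window around its circular mean before moments are taken.  The
    covariance gets a +regularization*I ridge for small-sample stability.
    """
    if len(geoms) < 7:
        raise ValueError(
            f"need at least 7 geometries for a rank-6 covariance, got {len(geoms)}"
        )
    v = np.array([g.as_vector() for g in geoms])
    for idx in ANGULAR_COMPONENTS:
        center = _circular_mean(v[:, idx])
        v[:, idx] = _unwrap_against(v[:, idx], center)
    mean = v.mean(axis=0)
    cov = np.cov(v, rowvar=False, bias=False) + regularization * np.eye(6)
    return GeometryDistribution(mean=mean, covariance=cov, mhc_class=mhc_class, n_samples=len(geoms))


def mahalanobis_z(g: DockingGeometry, dist: GeometryDistribution) -> float:
    """Mahalanobis distance of a docking geometry from its class consensus.

    In-distribution geometries give Z^2 ~ chi-squared(6).
    """
    v = g.as_vector()
    for idx in ANGULAR_COMPONENTS:
        v[idx] = _unwrap_against(np.array([v[idx]]), dist.mean[idx])[0]
    delta = v - dist.mean
    try:
        sol = np.linalg.solve(dist.covariance, delta)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular covariance in geometry distribution") from e
    return float(np.sqrt(delta @ sol))
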