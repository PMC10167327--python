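"""Residual dipolar couplings and Saupe alignment-tensor analysis.

An N-H RDC is the difference of the one-bond scalar coupling measured in a
weakly aligned and an isotropic sample, D = J_aligned - J_iso. For a rigid
molecule the couplings are a linear function of the five independent
components of the symmetric, traceless alignment (Saupe) order matrix A:

    D_i = Dmax * v_i^T A v_i

with v_i the unit N-H bond vector. The five components are obtained by a
linear singular-value-decomposition fit; the physical constant Dmax is
folded into the tensor so that the axial magnitude Da and rhombicity R are
reported directly in Hz of N-H RDC.

The quality factor is Q = rms(D_obs - D_calc) / rms(D_obs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spxlab.io import InsufficientDataError, ValidationError

__all__ = [
    "RdcSet",
    "AlignmentTensor",
    "TensorFit",
    "SegmentComparison",
    "DegenerateGeometryError",
    "compute_rdc",
    "fit_tensor",
    "back_calculate",
    "q_factor",
    "compare_segment_orientation",
]

#: Sanity bound on |D| for one-bond N-H couplings in conventional media (Hz).
NH_RDC_SANITY_HZ = 60.0


class DegenerateGeometryError(ValidationError):
    """The N-H vector geometry cannot determine all five tensor components."""


@dataclass(frozen=True)
class RdcSet:
    """Per-residue couplings: isotropic, aligned, and their difference (Hz)."""

    residue_index: np.ndarray
    J_iso: np.ndarray
    J_aligned: np.ndarray
    error: np.ndarray | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.residue_index)
        if np.unique(idx).size != idx.size:
            raise ValidationError("duplicate residues in RDC set")
        if np.any(np.abs(self.D) >= NH_RDC_SANITY_HZ):
            raise ValidationError(
                f"|D| exceeds the {NH_RDC_SANITY_HZ} Hz N-H sanity bound"
            )

    @property
    def D(self) -> np.ndarray:
        return np.asarray(self.J_aligned, float) - np.asarray(self.J_iso, float)

    def as_dict(self) -> dict[int, float]:
        return dict(zip(np.asarray(self.residue_index).tolist(), self.D.tolist()))


def compute_rdc(
    iso_couplings: dict[int, float], aligned_couplings: dict[int, float]
) -> RdcSet:
    """Build an RDC set from per-residue J couplings of both samples.

    D = J_aligned - J_iso, per the measurement's subtraction order; only
    residues present in both samples are kept.
    """
    shared = sorted(set(iso_couplings) & set(aligned_couplings))
    if not shared:
        raise ValidationError("no residue has couplings in both samples")
    return RdcSet(
        np.asarray(shared, int),
        np.asarray([iso_couplings[i] for i in shared], float),
        np.asarray([aligned_couplings[i] for i in shared], float),
    )


@dataclass(frozen=True)
class AlignmentTensor:
    """Symmetric traceless order matrix with derived Da, R and orientation.

    ``saupe`` holds (Axx, Ayy, Axy, Axz, Ayz) in Hz (Dmax folded in);
    Azz = -(Axx + Ayy). Da = Azz'/2 over the principal values ordered
    |Azz'| >= |Ayy'| >= |Axx'|; R = (2/3)(Axx' - Ayy')/Azz' in [0, 2/3].
    """

    saupe: tuple[float, float, float, float, float]

    def matrix(self) -> np.ndarray:
        axx, ayy, axy, axz, ayz = self.saupe
        azz = -(axx + ayy)
        return np.array([[axx, axy, axz], [axy, ayy, ayz], [axz, ayz, azz]])

    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Principal values (ordered x, y, z by |value|) and axis matrix.

        The rotation matrix columns are the principal axes; signs are fixed
        deterministically (largest-magnitude component positive, right-handed
        frame) so identical tensors yield identical frames.
        """
        w, v = np.linalg.eigh(self.matrix())
        order = np.argsort(np.abs(w))  # |Axx'| <= |Ayy'| <= |Azz'|
        w = w[order]
        v = v[:, order]
        for k in range(3):
            col = v[:, k]
            if col[np.argmax(np.abs(col))] < 0:
                v[:, k] = -col
        if np.linalg.det(v) < 0:
            v[:, 0] = -v[:, 0]
        return w, v

    @property
    def Da(self) -> float:
        """Axial magnitude in Hz of N-H RDC (Azz'/2)."""
        w, _ = self.principal()
        return float(w[2] / 2.0)

    @property
    def R(self) -> float:
        """Rhombicity, in [0, 2/3]."""
        w, _ = self.principal()
        return float((2.0 / 3.0) * (w[0] - w[1]) / w[2])

    @property
    def euler_deg(self) -> tuple[float, float, float]:
        """z-y-z Euler angles (degrees) of the principal-axis frame."""
        _, v = self.principal()
        beta = float(np.degrees(np.arccos(np.clip(v[2, 2], -1.0, 1.0))))
        if abs(v[2, 2]) > 1 - 1e-12:
            alpha = float(np.degrees(np.arctan2(v[1, 0], v[0, 0])))
            gamma = 0.0
        else:
            alpha = float(np.degrees(np.arctan2(v[1, 2], v[0, 2])))
            gamma = float(np.degrees(np.arctan2(v[2, 1], -v[2, 0])))
        return alpha, beta, gamma


def _design_matrix(vectors: np.ndarray) -> np.ndarray:
    x, y, z = vectors[:, 0], vectors[:, 1], vectors[:, 2]
    return np.column_stack([x**2 - z**2, y**2 - z**2, 2 * x * y, 2 * x * z, 2 * y * z])


@dataclass(frozen=True)
class TensorFit:
    """Alignment-tensor fit with back-calculated couplings and Q factor."""

    tensor: AlignmentTensor
    residue_index: np.ndarray
    D_obs: np.ndarray
    D_calc: np.ndarray

    @property
    def Q(self) -> float:
        return q_factor(self.D_obs, self.D_calc)


def q_factor(d_obs: np.ndarray, d_calc: np.ndarray) -> float:
    """Normalized rms deviation between observed and calculated RDCs."""
    d_obs = np.asarray(d_obs, float)
    d_calc = np.asarray(d_calc, float)
    denom = np.sqrt(np.mean(d_obs**2))
    if denom == 0:
        return 0.0 if np.allclose(d_obs, d_calc) else np.inf
    return float(np.sqrt(np.mean((d_obs - d_calc) ** 2)) / denom)


def fit_tensor(
    rdcs: RdcSet,
    vectors: list[tuple[int, np.ndarray]] | dict[int, np.ndarray],
    dmax: float = 1.0,
) -> TensorFit:
    """Linear SVD fit of the five Saupe components to measured RDCs.

    Requires >= 5 residues carrying both a coupling and an N-H vector, with
    geometry of full rank; otherwise a :class:`DegenerateGeometryError`
    names the deficiency.
    """
    vec_map = dict(vectors) if not isinstance(vectors, dict) else vectors
    d_map = rdcs.as_dict()
    shared = sorted(set(d_map) & set(vec_map))
    if len(shared) < 5:
        raise DegenerateGeometryError(
            f"only {len(shared)} residues have both an RDC and an N-H vector (need >= 5)"
        )
    V = np.array([np.asarray(vec_map[i], float) for i in shared])
    V = V / np.linalg.norm(V, axis=1, keepdims=True)
    D = np.array([d_map[i] for i in shared])
    A = dmax * _design_matrix(V)
    rank = np.linalg.matrix_rank(A, tol=1e-8)
    if rank < 5:
        raise DegenerateGeometryError(
            f"design matrix rank {rank} < 5: N-H vectors are too coplanar/collinear "
            "to determine all tensor components"
        )
    s, *_ = np.linalg.lstsq(A, D, rcond=None)
    tensor = AlignmentTensor(tuple(float(x) for x in s))
    d_calc = A @ s
    return TensorFit(tensor, np.asarray(shared, int), D, d_calc)


def back_calculate(
    tensor: AlignmentTensor,
    vectors: dict[int, np.ndarray] | list[tuple[int, np.ndarray]],
    dmax: float = 1.0,
) -> dict[int, float]:
    """Couplings predicted by a tensor for the given N-H vectors."""
    vec_map = dict(vectors) if not isinstance(vectors, dict) else vectors
    M = tensor.matrix()
    out = {}
    for i, v in vec_map.items():
        v = np.asarray(v, float)
        v = v / np.linalg.norm(v)
        out[i] = float(dmax * v @ M @ v)
    return out


@dataclass(frozen=True)
class SegmentComparison:
    """Orientation change of one structural segment between two states."""

    start: int
    end: int
    mean_angle_deg: float | None
    status: str  # maintained / changed / insufficient_data
    q_cross: float | None = None


def compare_segment_orientation(
    tensor_a: AlignmentTensor,
    tensor_b: AlignmentTensor,
    segments: list[tuple[int, int]],
    vectors: dict[int, np.ndarray] | list[tuple[int, np.ndarray]],
    rdcs_a: RdcSet | None = None,
    rdcs_b: RdcSet | None = None,
    q_cutoff: float = 0.3,
    dmax: float = 1.0,
) -> list[SegmentComparison]:
    """Per-segment angular change between two alignment-tensor frames.

    Both tensors must have been fitted on the same structural model. For
    each segment the N-H vectors are projected into the two principal-axis
    frames; the mean angle between the projections quantifies reorientation.
    When RDC sets are supplied, a segment whose couplings are jointly
    consistent with both tensors (cross-state Q below ``q_cutoff``) is
    reported as "maintained". Segments with fewer than 3 couplings are
    reported as insufficient_data.
    """
    vec_map = dict(vectors) if not isinstance(vectors, dict) else vectors
    _, Ra = tensor_a.principal()
    _, Rb = tensor_b.principal()
    d_a = rdcs_a.as_dict() if rdcs_a is not None else None
    d_b = rdcs_b.as_dict() if rdcs_b is not None else None

    out = []
    for start, end in segments:
        members = [i for i in vec_map if start <= i <= end]
        with_rdc = [
            i
            for i in members
            if (d_a is None or i in d_a) and (d_b is None or i in d_b)
        ]
        if len(with_rdc) < 3:
            out.append(SegmentComparison(start, end, None, "insufficient_data"))
            continue
        angles = []
        for i in with_rdc:
            v = np.asarray(vec_map[i], float)
            v = v / np.linalg.norm(v)
            ua, ub = Ra.T @ v, Rb.T @ v
            cosang = abs(float(np.dot(ua, ub)))  # N-H axis has no polarity
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        mean_angle = float(np.mean(angles))

        q_cross = None
        status = "changed" if mean_angle > 10.0 else "maintained"
        if d_a is not None and d_b is not None:
            calc_b = back_calculate(tensor_b, {i: vec_map[i] for i in with_rdc}, dmax)
            calc_a = back_calculate(tensor_a, {i: vec_map[i] for i in with_rdc}, dmax)
            obs = np.array([d_a[i] for i in with_rdc] + [d_b[i] for i in with_rdc])
            calc = np.array(
                [calc_b[i] for i in with_rdc] + [calc_a[i] for i in with_rdc]
            )
            q_cross = q_factor(obs, calc)
            status = "maintained" if q_cross <= q_cutoff else "changed"
        out.append(SegmentComparison(start, end, mean_angle, status, q_cross))
    return out
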