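"""Trajectory geometry: superposition, RMSD/RMSF, covariance PCA,
cosine-content sampling diagnostics.

All operations remove overall translation/rotation by least-squares rigid
superposition (Kabsch, proper rotations only) before measuring internal
motion.  Coordinates are Å throughout; RMSD series can be reported in nm
for plotting conventions that prefer it.

The cosine content of a principal-component projection p(t) compares it to
the cosine of matching period,

    c_i = (2/T) · (∫ cos(iπt/T) p(t) dt)² / ∫ p(t)² dt ,

evaluated by trapezoid quadrature on the sampled, mean-centred series.
Values near 1 mean the component looks like random diffusion (the first
PCs of an unconverged trajectory); the conventional sampling criterion
flags components with content ≥ 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InsufficientFramesError,
    SelectionOverlapError,
    UndefinedContentError,
)
from .structure import Ensemble, Selection, require_nonempty

COSINE_CONTENT_CUTOFF = 0.5


@dataclass
class RigidTransform:
    """Proper rigid motion y = R·x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class SeriesResult:
    """A per-frame scalar series (e.g. RMSD) with its time axis."""

    times: np.ndarray  # ps
    values: np.ndarray
    units: str = "A"

    def to_units(self, units: str) -> "SeriesResult":
        if units == self.units:
            return self
        if {units, self.units} != {"A", "nm"}:
            raise ValueError(f"unsupported unit conversion {self.units}->{units}")
        factor = 0.1 if units == "nm" else 10.0
        return SeriesResult(self.times.copy(), self.values * factor, units)


@dataclass
class PCAResult:
    """Essential-dynamics decomposition of a coordinate covariance matrix."""

    eigenvalues: np.ndarray  # descending, Å²
    eigenvectors: np.ndarray  # (3N, K) orthonormal columns
    projections: np.ndarray  # (F, K) Å
    variance_fraction: np.ndarray  # per component, sums to 1 over all comps
    cosine_content: np.ndarray  # per reported component, in [0, 1]
    times: np.ndarray  # ps
    mean: np.ndarray  # (3N,) average structure coordinates


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper rotation + translation and the residual RMSD
    in Å.  Requires at least three non-collinear points; reflections are
    never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    mu_m = w @ mobile
    mu_r = w @ reference
    x = mobile - mu_m
    y = reference - mu_r
    if np.linalg.matrix_rank(y, tol=1e-9) < 2:
        raise DegenerateGeometryError("reference points are collinear")
    h = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = mu_r - rotation @ mu_m
    transform = RigidTransform(rotation, translation)
    delta = transform.apply(mobile) - reference
    rmsd = float(np.sqrt((w * (delta**2).sum(axis=1)).sum()))
    return transform, rmsd


def _check_disjoint(a: Selection, b: Selection) -> None:
    if np.intersect1d(a.indices, b.indices).size:
        raise SelectionOverlapError(
            f"selections {a.expression!r} and {b.expression!r} share atoms"
        )


def rmsd_series(
    ensemble: Ensemble,
    fit_sel: Selection,
    calc_sel: Selection | None = None,
    units: str = "A",
) -> SeriesResult:
    """Per-frame RMSD after superposing each frame on the reference.

    Each frame is fit to the reference over ``fit_sel``; the RMSD is then
    measured over ``calc_sel`` (defaults to ``fit_sel``).
    """
    require_nonempty(fit_sel, "fit selection")
    calc_sel = calc_sel if calc_sel is not None else fit_sel
    require_nonempty(calc_sel, "calc selection")
    ref = ensemble.reference.coords
    fit_ref = ref[fit_sel.indices]
    calc_ref = ref[calc_sel.indices]
    values = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        frame = ensemble.frames[f]
        transform, _ = kabsch_superpose(frame[fit_sel.indices], fit_ref)
        moved = transform.apply(frame[calc_sel.indices])
        values[f] = np.sqrt(((moved - calc_ref) ** 2).sum(axis=1).mean())
    return SeriesResult(ensemble.times.copy(), values, "A").to_units(units)


def split_rmsd(
    ensemble: Ensemble, sel_a: Selection, sel_b: Selection, units: str = "A"
) -> tuple[SeriesResult, SeriesResult]:
    """RMSD of each binding partner fit independently to its own reference.

    Because each component is superposed on itself, the complex RMSD is not
    the sum of the two split series — relative inter-partner motion is
    removed here but present in the whole-complex fit.
    """
    _check_disjoint(sel_a, sel_b)
    out = []
    for sel in (sel_a, sel_b):
        require_nonempty(sel, "component selection")
        out.append(rmsd_series(ensemble, sel, sel, units=units))
    return out[0], out[1]


def _superpose_frames(
    frames: np.ndarray, target: np.ndarray
) -> np.ndarray:
    fitted = np.empty_like(frames)
    for f in range(frames.shape[0]):
        transform, _ = kabsch_superpose(frames[f], target)
        fitted[f] = transform.apply(frames[f])
    return fitted


def rmsf(
    ensemble: Ensemble, sel: Selection, fit: bool = True
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation over the trajectory, in Å.

    With ``fit=True`` frames are superposed on the time-average structure
    (two passes: fit to the reference, average, refit to the average).
    Returns one value per selected atom, in selection order; callers that
    want per-residue values take the value at each residue's Cα.
    """
    require_nonempty(sel, "selection")
    if ensemble.n_frames < 2:
        raise InsufficientFramesError("RMSF needs >= 2 frames")
    frames = ensemble.frames[:, sel.indices, :]
    if fit:
        fitted = _superpose_frames(frames, ensemble.reference.coords[sel.indices])
        mean = fitted.mean(axis=0)
        fitted = _superpose_frames(fitted, mean)
        mean = fitted.mean(axis=0)
    else:
        fitted = frames
        mean = frames.mean(axis=0)
    delta = fitted - mean
    return np.sqrt((delta**2).sum(axis=2).mean(axis=0))


def residue_rmsf(
    ensemble: Ensemble, sel: Selection, fit: bool = True
) -> "list[tuple[str, int, str, float]]":
    """RMSF per residue: the value at each residue's α-carbon.

    Returns ``(chain, res_seq, res_name, rmsf_Å)`` tuples for every residue
    whose Cα is inside the selection.
    """
    values = rmsf(ensemble, sel, fit=fit)
    by_atom = dict(zip(sel.indices.tolist(), values))
    out = []
    for res in ensemble.reference.residues:
        ca = ensemble.reference.ca_index(res)
        if ca is not None and ca in by_atom:
            out.append((res.chain, res.res_seq, res.res_name, float(by_atom[ca])))
    return out


def pca(
    ensemble: Ensemble, sel: Selection, n_components: int | None = None
) -> PCAResult:
    """PCA of the coordinate covariance after superposition on the reference.

    Frames are rigid-fit to the reference over the selection, flattened to
    3N-vectors and mean-centred; the covariance eigendecomposition is done
    through the SVD of the centred frame matrix.  ``variance_fraction``
    always covers the full spectrum (it sums to 1); ``projections`` and
    ``cosine_content`` are reported for the leading ``n_components``
    (default: all).
    """
    require_nonempty(sel, "selection")
    if ensemble.n_frames < 2:
        raise InsufficientFramesError("PCA needs >= 2 frames")
    frames = _superpose_frames(
        ensemble.frames[:, sel.indices, :], ensemble.reference.coords[sel.indices]
    )
    f = frames.shape[0]
    x = frames.reshape(f, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / (f - 1)
    total = eigenvalues.sum()
    variance_fraction = (
        eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    )
    k = len(eigenvalues) if n_components is None else min(n_components, len(eigenvalues))
    eigenvectors = vt[:k].T
    projections = xc @ eigenvectors
    cc = np.empty(k)
    for i in range(k):
        p = projections[:, i]
        cc[i] = 0.0 if np.allclose(p, 0) else cosine_content(p, i + 1, ensemble.times)
    return PCAResult(
        eigenvalues=eigenvalues[:k],
        eigenvectors=eigenvectors,
        projections=projections,
        variance_fraction=variance_fraction,
        cosine_content=cc,
        times=ensemble.times.copy(),
        mean=mean,
    )


def cosine_content(
    projection: np.ndarray, order: int = 1, times: np.ndarray | None = None
) -> float:
    """Hess cosine content of order ``i`` of a projection time series.

    ``c_i`` is 1 when p(t) is exactly cos(iπt/T) and near 0 for genuinely
    oscillatory, well-sampled motion.  Needs at least 4 samples; an
    all-zero series has no defined content.
    """
    p = np.asarray(projection, dtype=float)
    if p.ndim != 1 or p.size < 4:
        raise InsufficientFramesError("cosine content needs >= 4 samples")
    if order < 1:
        raise ValueError("order must be >= 1")
    if times is None:
        t = np.arange(p.size, dtype=float)
    else:
        t = np.asarray(times, dtype=float)
        if t.shape != p.shape:
            raise ValueError("times must match projection length")
    p = p - p.mean()
    denom = np.trapezoid(p * p, t)
    if denom <= 0:
        raise UndefinedContentError("projection is constant; content undefined")
    span = t[-1] - t[0]
    cos_wave = np.cos(order * np.pi * (t - t[0]) / span)
    num = np.trapezoid(cos_wave * p, t)
    return float(2.0 / span * num**2 / denom)


def extreme_projection_frames(
    ensemble: Ensemble, sel: Selection, result: PCAResult, component: int = 0
) -> Ensemble:
    """2-frame ensemble at the extremes of one PC projection.

    A porcupine-style surrogate for animating a principal component: the
    frames with the most negative and most positive projection.
    """
    p = result.projections[:, component]
    lo, hi = int(np.argmin(p)), int(np.argmax(p))
    frames = ensemble.frames[[lo, hi]]
    times = np.array([0.0, 1.0])
    return Ensemble(ensemble.reference, frames, times)
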