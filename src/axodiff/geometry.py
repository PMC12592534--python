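"""Arc-length-parameterized axon profiles and their geometric statistics.

The cross-sectional area A(l) of an axon, sampled uniformly along its arc
length l, is the raw material for everything downstream: the tortuosity
<1/alpha> that fixes the long-time diffusivity, the log-area field
eta = ln alpha whose power spectral density controls the D(t) tail, the
sinuosity xi of the 3-D skeleton, and the volume weights that turn per-axon
curves into an ensemble (dMRI-like) measurement.

Units are micrometers throughout (areas in um^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "AxonProfile",
    "RelativeProfile",
    "resample_arclength",
    "relative_profile",
    "tortuosity",
    "sinuosity",
    "volume_weights",
    "read_profile_table",
    "write_profile_table",
    "read_swc",
    "profile_from_swc",
]

_MIN_SAMPLES = 16
_SPACING_RTOL = 1e-9


@dataclass
class AxonProfile:
    """Uniformly arc-length-sampled cross-sectional area of one axon.

    Attributes
    ----------
    arc_positions : ndarray
        Arc-length coordinate l in um, strictly increasing, uniform spacing.
    areas : ndarray
        Cross-sectional area A(l) in um^2, strictly positive.
    skeleton_points : ndarray or None
        Optional (n, 3) ordered 3-D skeleton coordinates in um.
    axon_id : str
        Identifier.
    """

    arc_positions: np.ndarray
    areas: np.ndarray
    skeleton_points: np.ndarray | None = None
    axon_id: str = ""

    def __post_init__(self) -> None:
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.arc_positions.ndim != 1 or self.areas.ndim != 1:
            raise ValueError("arc_positions and areas must be 1-D")
        if self.arc_positions.size != self.areas.size:
            raise ValueError("arc_positions and areas must have equal length")
        if self.arc_positions.size < _MIN_SAMPLES:
            raise ValueError(
                f"profile needs >= {_MIN_SAMPLES} samples, got {self.arc_positions.size}"
            )
        steps = np.diff(self.arc_positions)
        if np.any(steps <= 0):
            raise ValueError("arc_positions must be strictly increasing")
        dl = steps.mean()
        if np.max(np.abs(steps - dl)) > _SPACING_RTOL * max(dl, 1.0):
            raise ValueError("arc_positions must be uniformly spaced")
        if np.any(self.areas <= 0):
            bad = int(np.argmax(self.areas <= 0))
            raise ValueError(
                f"areas must be strictly positive; first offender at index {bad} "
                f"(l = {self.arc_positions[bad]:.4g} um)"
            )
        if self.skeleton_points is not None:
            self.skeleton_points = np.asarray(self.skeleton_points, dtype=float)

    @property
    def dl(self) -> float:
        """Sampling interval in um."""
        return float(np.diff(self.arc_positions).mean())

    @property
    def n_samples(self) -> int:
        return int(self.arc_positions.size)

    @property
    def record_length(self) -> float:
        """Record length L = N * dl in um (the Fourier normalization length)."""
        return self.n_samples * self.dl

    @property
    def mean_area(self) -> float:
        return float(self.areas.mean())

    @property
    def volume(self) -> float:
        """Axon volume int A dl = Abar * L in um^3."""
        return self.mean_area * self.record_length


@dataclass
class RelativeProfile:
    """Dimensionless relative cross-section alpha = A/Abar and eta = ln alpha."""

    alpha: np.ndarray
    eta: np.ndarray
    mean_area: float
    length: float
    dl: float
    axon_id: str = ""

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if abs(self.alpha.mean() - 1.0) > 1e-12:
            raise ValueError("mean of alpha must equal 1")


def _chord_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative chord-length arc coordinate of an ordered 3-D point set."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_arclength(
    skeleton_points: np.ndarray,
    areas_at_points: np.ndarray,
    dl: float = 0.1,
    axon_id: str = "",
) -> AxonProfile:
    """Resample areas onto a uniform arc-length grid of spacing dl.

    The arc coordinate is the cumulative chord length of the skeleton; areas
    are cubic-spline interpolated (natural end conditions) over arc length and
    sampled on the uniform grid covering [0, L] with floor(L/dl) + 1 points.

    Raises
    ------
    ValueError
        For duplicate (non-monotone) points, fewer than 4 points, nonpositive
        input areas, or any interpolated area <= 0 (reported with location).
    """
    points = np.asarray(skeleton_points, dtype=float)
    areas = np.asarray(areas_at_points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("skeleton_points must be (n, 3)")
    if points.shape[0] < 4:
        raise ValueError("need >= 4 skeleton points")
    if areas.shape != (points.shape[0],):
        raise ValueError("areas_at_points must match the number of points")
    if np.any(areas <= 0):
        raise ValueError("input areas must be positive")
    if dl <= 0:
        raise ValueError("dl must be positive")

    arc = _chord_arclength(points)
    if np.any(np.diff(arc) <= 0):
        bad = int(np.argmax(np.diff(arc) <= 0))
        raise ValueError(f"duplicate skeleton points at index {bad}: arc length not monotone")

    spline = CubicSpline(arc, areas, bc_type="natural")
    total = arc[-1]
    n = int(np.floor(total / dl)) + 1
    grid = np.arange(n) * dl
    a_grid = spline(grid)
    if np.any(a_grid <= 0):
        bad = int(np.argmax(a_grid <= 0))
        raise ValueError(
            f"interpolated area <= 0 at l = {grid[bad]:.4g} um (index {bad}); "
            "profile rejected"
        )
    skel_spline = CubicSpline(arc, points, bc_type="natural", axis=0)
    return AxonProfile(grid, a_grid, skeleton_points=skel_spline(grid), axon_id=axon_id)


def relative_profile(profile: AxonProfile) -> RelativeProfile:
    """alpha = A/<A> and eta = ln alpha for a valid profile."""
    alpha = profile.areas / profile.mean_area
    alpha = alpha / alpha.mean()  # exact unit mean in floating point
    return RelativeProfile(
        alpha=alpha,
        eta=np.log(alpha),
        mean_area=profile.mean_area,
        length=profile.record_length,
        dl=profile.dl,
        axon_id=profile.axon_id,
    )


def tortuosity(rel: RelativeProfile) -> float:
    """Geometric tortuosity <1/alpha> = D0/Dinf.

    Always >= 1 by Jensen's inequality since <alpha> = 1; equals 1 only for a
    uniform tube.
    """
    return float(np.mean(1.0 / rel.alpha))


def sinuosity(skeleton_points: np.ndarray) -> float:
    """Sinuosity xi = arc length / Euclidean end-to-end distance (>= 1)."""
    points = np.asarray(skeleton_points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need >= 2 skeleton points")
    euclid = float(np.linalg.norm(points[-1] - points[0]))
    if euclid == 0.0:
        raise ValueError("coincident endpoints: Euclidean length is zero")
    return float(_chord_arclength(points)[-1] / euclid)


def volume_weights(profiles: list[AxonProfile]) -> np.ndarray:
    """Normalized volume weights w_i proportional to Abar_i * L_i, sum = 1."""
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    vols = np.array([p.volume for p in profiles], dtype=float)
    return vols / vols.sum()


# ---------------------------------------------------------------------------
# File formats


def read_profile_table(path, dl: float | None = None, axon_id: str = "") -> AxonProfile:
    """Read a profile TSV/CSV with columns arc_um, area_um2 (+ optional x/y/z_um).

    A table already on a uniform grid is taken as-is; otherwise (or when a
    different ``dl`` is requested) it is re-gridded through cubic-spline
    interpolation over arc length.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    if not {"arc_um", "area_um2"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns arc_um, area_um2")
    arc = df["arc_um"].to_numpy(dtype=float)
    area = df["area_um2"].to_numpy(dtype=float)
    skel = None
    if {"x_um", "y_um", "z_um"}.issubset(df.columns):
        skel = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    steps = np.diff(arc)
    if np.any(steps <= 0):
        raise ValueError(f"{path}: arc_um must be strictly increasing")
    uniform = np.max(np.abs(steps - steps.mean())) <= _SPACING_RTOL * max(steps.mean(), 1.0)
    if uniform and (dl is None or np.isclose(steps.mean(), dl, rtol=1e-9)):
        return AxonProfile(arc, area, skeleton_points=skel, axon_id=axon_id)
    target = dl if dl is not None else 0.1
    spline = CubicSpline(arc, area, bc_type="natural")
    n = int(np.floor((arc[-1] - arc[0]) / target)) + 1
    grid = arc[0] + np.arange(n) * target
    a_grid = spline(grid)
    if np.any(a_grid <= 0):
        bad = int(np.argmax(a_grid <= 0))
        raise ValueError(f"{path}: interpolated area <= 0 at l = {grid[bad]:.4g} um")
    return AxonProfile(grid - grid[0], a_grid, skeleton_points=skel, axon_id=axon_id)


def write_profile_table(profile: AxonProfile, path) -> None:
    """Write a profile as TSV (arc_um, area_um2, optional skeleton columns)."""
    data = {"arc_um": profile.arc_positions, "area_um2": profile.areas}
    if profile.skeleton_points is not None:
        data["x_um"] = profile.skeleton_points[:, 0]
        data["y_um"] = profile.skeleton_points[:, 1]
        data["z_um"] = profile.skeleton_points[:, 2]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_swc(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an SWC skeleton; return (points (n,3) um, radii (n,) um).

    Only unbranched root-to-tip paths are accepted: every non-root node must
    have exactly one child. Branching morphologies are rejected.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}: malformed SWC record: {line!r}")
            rows.append(
                (int(parts[0]), float(parts[2]), float(parts[3]), float(parts[4]),
                 float(parts[5]), int(parts[6]))
            )
    if not rows:
        raise ValueError(f"{path}: empty SWC file")
    ids = [r[0] for r in rows]
    parents = [r[5] for r in rows]
    children: dict[int, list[int]] = {}
    for i, par in zip(ids, parents):
        children.setdefault(par, []).append(i)
    roots = children.get(-1, [])
    if len(roots) != 1:
        raise ValueError(f"{path}: expected exactly one root, found {len(roots)}")
    for par, kids in children.items():
        if par != -1 and len(kids) > 1:
            raise ValueError(f"{path}: bifurcation at node {par}; only unbranched paths accepted")
    by_id = {r[0]: r for r in rows}
    order = []
    node = roots[0]
    while True:
        order.append(node)
        kids = children.get(node, [])
        if not kids:
            break
        node = kids[0]
    if len(order) != len(rows):
        raise ValueError(f"{path}: disconnected nodes present")
    pts = np.array([[by_id[i][1], by_id[i][2], by_id[i][3]] for i in order])
    radii = np.array([by_id[i][4] for i in order])
    return pts, radii


def profile_from_swc(path, dl: float = 0.1, axon_id: str = "") -> AxonProfile:
    """Build an AxonProfile from an SWC skeleton using A = pi r^2 per node."""
    pts, radii = read_swc(path)
    if np.any(radii <= 0):
        raise ValueError(f"{path}: nonpositive radius")
    return resample_arclength(pts, np.pi * radii**2, dl=dl, axon_id=axon_id or str(path))
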