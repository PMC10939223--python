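"""Microelectrode-recording model and brain-shift estimation.

During DBS surgery, 2-5 parallel microelectrodes (a Ben-gun array) record
extracellular activity at 25-30 depths per trajectory.  Signal energy (RMS)
rises inside the STN; normalizing each trajectory by the mean RMS of its
first five (extranuclear) sites removes electrode-impedance and gain effects
(NRMS).  The model assumes log-normal NRMS emissions for the IN and OUT
states, blended by a sigmoid of the signed distance to the STN surface
(positive inside), and estimates the intra-operative brain shift as the
per-axis translation (+-2 mm) and scaling (0.9-1.2) of the segmented STN mesh
that maximizes the likelihood of the recorded NRMS series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import lognorm
from sklearn.base import BaseEstimator

from .mesh import SurfaceMesh, signed_distance

__all__ = [
    "MerTrajectorySet",
    "MerModelParams",
    "FitTransform",
    "compute_nrms",
    "extract_rms",
    "sigmoid_transition",
    "site_likelihood",
    "train_mer_model",
    "MerSignalModel",
    "BrainShiftEstimator",
    "fit_transform",
    "classify_sites",
    "evaluate_containment",
    "init_from_plan",
    "init_max_likely_exit",
    "apply_transform",
]

TRANSLATION_BOUND_MM = 2.0
SCALE_BOUNDS = (0.9, 1.2)
# double-oblique approach running roughly along the STN long axis, as in
# surgical practice where the electrode traverses 4-6 mm of nucleus
DEFAULT_DIRECTION = np.array([0.87, 0.30, -0.40]) / np.linalg.norm([0.87, 0.30, -0.40])
BEN_GUN_RADIUS_MM = 2.0
# 1.0 mm steps from 10 to 5 mm above the target, then 0.5 mm steps down to
# 7 mm below (negative = above target)
DEFAULT_DEPTHS_MM = np.concatenate([np.arange(-10.0, -5.0, 1.0), np.arange(-5.0, 7.01, 0.5)])
BEN_GUN_NAMES = ("central", "anterior", "posterior", "medial", "lateral")


@dataclass
class MerTrajectorySet:
    """Recording sites of one hemisphere, grouped by trajectory.

    ``sites`` columns: trajectory, depth_mm (negative above the planned
    target), x_mm, y_mm, z_mm, nrms, label (IN/OUT/unknown).
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"trajectory", "depth_mm", "x_mm", "y_mm", "z_mm"}
        missing = required - set(self.sites.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if "nrms" not in self.sites.columns:
            self.sites["nrms"] = np.nan
        if "label" not in self.sites.columns:
            self.sites["label"] = "unknown"
        self.sites = (
            self.sites.sort_values(["trajectory", "depth_mm"], kind="stable").reset_index(drop=True)
        )
        for traj, grp in self.sites.groupby("trajectory"):
            depths = grp["depth_mm"].to_numpy()
            if len(np.unique(depths)) != len(depths):
                raise ValueError(f"duplicate depth within trajectory {traj!r}")
        valid = self.sites["nrms"].dropna()
        if len(valid) and (valid <= 0).any():
            raise ValueError("nrms values must be positive")

    @property
    def positions(self) -> np.ndarray:
        return self.sites[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    @property
    def nrms(self) -> np.ndarray:
        return self.sites["nrms"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.sites["label"].to_numpy()

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def with_positions(self, positions: np.ndarray) -> "MerTrajectorySet":
        df = self.sites.copy()
        df[["x_mm", "y_mm", "z_mm"]] = np.asarray(positions, dtype=float)
        return MerTrajectorySet(df)


@dataclass
class MerModelParams:
    """Sigmoid border (beta0, beta1) and log-normal emission parameters."""

    beta0: float
    beta1: float
    mu_in: float
    sigma_in: float
    mu_out: float
    sigma_out: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma_in <= 0 or self.sigma_out <= 0:
            raise ValueError("log-scale sigmas must be positive")


@dataclass
class FitTransform:
    """Per-axis translation (mm) and scaling of the STN mesh about its centroid."""

    t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    s: np.ndarray = field(default_factory=lambda: np.ones(3))
    converged: bool = True

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.s = np.asarray(self.s, dtype=float)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.t, self.s])

    @classmethod
    def identity(cls) -> "FitTransform":
        return cls()


def apply_transform(mesh: SurfaceMesh, transform: FitTransform, center: np.ndarray | None = None) -> SurfaceMesh:
    """Translate and scale a mesh per axis about its (untransformed) centroid."""
    c = mesh.centroid if center is None else np.asarray(center, dtype=float)
    verts = c + transform.s * (mesh.vertices - c) + transform.t
    return mesh.with_vertices(verts)


def compute_nrms(rms: np.ndarray, n_reference: int = 5) -> np.ndarray:
    """NRMS: each RMS divided by the mean RMS of the first ``n_reference`` sites.

    The first recordings of a trajectory lie well above the STN, so their mean
    serves as the extranuclear reference; the ratio is invariant to electrode
    gain.
    """
    rms = np.asarray(rms, dtype=float)
    if len(rms) < n_reference:
        raise ValueError(f"need at least {n_reference} recording positions")
    if (rms <= 0).any():
        raise ValueError("rms values must be positive")
    return rms / rms[:n_reference].mean()


def extract_rms(signal: np.ndarray, fs: float, window_s: float = 1.0, k: float = 3.0) -> float:
    """RMS over stationary windows of a raw MER sweep.

    Splits the sweep into fixed windows and rejects windows whose variance
    exceeds ``k`` times the median window variance (a stand-in stationarity
    screen for transient artefacts).  Falls back to the full-signal RMS with
    a warning if every window is rejected.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    n_win = max(int(len(signal) / (fs * window_s)), 1)
    if n_win < 2:
        return float(np.sqrt(np.mean(signal**2)))
    windows = np.array_split(signal[: n_win * int(fs * window_s)], n_win)
    variances = np.array([w.var() for w in windows])
    med = np.median(variances)
    if med == 0:
        warnings.warn("signal has zero median window variance; RMS may be degenerate", stacklevel=2)
        return float(np.sqrt(np.mean(signal**2)))
    keep = variances <= k * med
    if not keep.any():
        warnings.warn("all windows rejected by stationarity screen; using full-signal RMS", stacklevel=2)
        return float(np.sqrt(np.mean(signal**2)))
    kept = np.concatenate([w for w, ok in zip(windows, keep) if ok])
    return float(np.sqrt(np.mean(kept**2)))


def sigmoid_transition(d: np.ndarray, beta0: float, beta1: float) -> np.ndarray:
    """P(IN) as a sigmoid of the signed distance to the STN surface (mm)."""
    with np.errstate(over="ignore"):  # exp overflow saturates correctly to 0
        return 1.0 / (1.0 + np.exp(-(beta0 + beta1 * np.asarray(d, dtype=float))))


def _lognorm_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return lognorm.pdf(x, s=sigma, scale=np.exp(mu))


def site_likelihood(nrms: np.ndarray, d: np.ndarray, params: MerModelParams) -> np.ndarray:
    """Mixture density p(x|IN) S(d) + p(x|OUT) (1 - S(d))."""
    s = sigmoid_transition(d, params.beta0, params.beta1)
    p_in = _lognorm_pdf(nrms, params.mu_in, params.sigma_in)
    p_out = _lognorm_pdf(nrms, params.mu_out, params.sigma_out)
    return p_in * s + p_out * (1.0 - s)


def train_mer_model(
    nrms: np.ndarray, labels: np.ndarray, distances: np.ndarray
) -> MerModelParams:
    """Fit emission and border parameters from labelled sites.

    Log-normal parameters are the closed-form MLE of log-NRMS per class;
    (beta0, beta1) come from an unpenalized logistic regression of the IN/OUT
    label on the signed distance, pooled over entries and exits (a single
    mean border trend).
    """
    nrms = np.asarray(nrms, dtype=float)
    labels = np.asarray(labels)
    distances = np.asarray(distances, dtype=float)
    is_in = labels == "IN"
    is_out = labels == "OUT"
    if not is_in.any() or not is_out.any():
        raise ValueError("both IN and OUT labels are required")

    log_in = np.log(nrms[is_in])
    log_out = np.log(nrms[is_out])
    mu_in, sigma_in = float(log_in.mean()), float(log_in.std())
    mu_out, sigma_out = float(log_out.mean()), float(log_out.std())
    degenerate = False
    if sigma_in < 1e-9 or sigma_out < 1e-9 or abs(mu_in - mu_out) < 1e-9:
        warnings.warn("IN and OUT emissions are (near-)identical; fit is degenerate", stacklevel=2)
        degenerate = True
        sigma_in = max(sigma_in, 1e-6)
        sigma_out = max(sigma_out, 1e-6)

    mask = is_in | is_out
    y = is_in[mask].astype(float)
    X = sm.add_constant(distances[mask])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0)
    beta0, beta1 = float(res.params[0]), float(res.params[1])
    return MerModelParams(beta0, beta1, mu_in, sigma_in, mu_out, sigma_out, degenerate=degenerate)


class MerSignalModel(BaseEstimator):
    """Estimator wrapper around :func:`train_mer_model`.

    ``fit`` takes per-site NRMS values, expert IN/OUT labels and signed
    distances to the (training) STN surface; ``predict_proba`` returns the
    sigmoid IN probability at given distances.
    """

    def fit(self, nrms: np.ndarray, labels: np.ndarray, distances: np.ndarray) -> "MerSignalModel":
        self.params_ = train_mer_model(nrms, labels, distances)
        return self

    def predict_proba(self, distances: np.ndarray) -> np.ndarray:
        return sigmoid_transition(distances, self.params_.beta0, self.params_.beta1)

    def log_likelihood(self, sites: MerTrajectorySet, mesh: SurfaceMesh) -> float:
        d = signed_distance(mesh, sites.positions)
        return float(np.log(site_likelihood(sites.nrms, d, self.params_) + 1e-300).sum())


def _colinear_groups(sites: MerTrajectorySet, tol: float = 1e-8) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] | None:
    """Per-trajectory (origin, direction, site parameters, site indices) if the
    sites of every trajectory are colinear; None otherwise."""
    pos = sites.positions
    groups = []
    for _, grp in sites.sites.groupby("trajectory"):
        idx = grp.index.to_numpy()
        p = pos[idx]
        if len(p) < 2:
            return None
        d = p[-1] - p[0]
        norm = np.linalg.norm(d)
        if norm < tol:
            return None
        d = d / norm
        t = (p - p[0]) @ d
        resid = p - (p[0] + t[:, None] * d[None, :])
        if np.abs(resid).max() > 1e-6:
            return None
        groups.append((p[0], d, t, idx))
    return groups


def _parallel_line_hits(
    origins: np.ndarray, direction: np.ndarray, vertices: np.ndarray, faces: np.ndarray
) -> list[np.ndarray]:
    """Line parameters of mesh hits for parallel lines (batched Moeller-Trumbore)."""
    tri = vertices[faces]
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    h = np.cross(direction[None, :], e2)  # shared across parallel lines
    det = np.einsum("mi,mi->m", e1, h)
    ok = np.abs(det) > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
        s = origins[:, None, :] - v0[None, :, :]  # (R, M, 3)
        u = np.einsum("rmi,mi->rm", s, h) * inv[None, :]
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("i,rmi->rm", direction, q) * inv[None, :]
        t = np.einsum("mi,rmi->rm", e2, q) * inv[None, :]
        hit = ok[None, :] & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
    return [np.sort(t[r][hit[r]]) for r in range(len(origins))]


def _signed_distances(
    vertices: np.ndarray,
    faces: np.ndarray,
    positions: np.ndarray,
    groups: list | None,
) -> np.ndarray:
    """Signed site distances; fast ray-parity sign when sites are colinear."""
    from . import geometry

    if groups is None:
        return geometry.signed_distance_points(positions, vertices, faces)
    d = geometry.pruned_point_mesh_distance(positions, vertices, faces)
    inside = np.zeros(len(positions), dtype=bool)
    directions = np.array([g[1] for g in groups])
    if np.allclose(directions, directions[0], atol=1e-12):
        origins = np.array([g[0] for g in groups])
        hits = _parallel_line_hits(origins, directions[0], vertices, faces)
        for (origin, direction, t, idx), t_hits in zip(groups, hits):
            if len(t_hits):
                inside[idx] = np.searchsorted(t_hits, t) % 2 == 1
    else:
        for origin, direction, t, idx in groups:
            t_hits, _, _ = geometry.ray_mesh_intersections(origin, direction, vertices, faces)
            if len(t_hits):
                inside[idx] = np.searchsorted(t_hits, t) % 2 == 1
    return np.where(inside, d, -d)


def _negative_log_likelihood(
    x: np.ndarray,
    sites_pos: np.ndarray,
    nrms: np.ndarray,
    mesh: SurfaceMesh,
    center: np.ndarray,
    params: MerModelParams,
    groups: list | None = None,
) -> float:
    tr = FitTransform(t=x[:3], s=x[3:])
    moved = apply_transform(mesh, tr, center=center)
    d = _signed_distances(moved.vertices, moved.faces, sites_pos, groups)
    lik = site_likelihood(nrms, d, params)
    return float(-np.log(lik + 1e-300).sum())


def fit_transform(
    sites: MerTrajectorySet,
    mesh: SurfaceMesh,
    params: MerModelParams,
    init: FitTransform | None = None,
    ftol: float = 1e-5,
    maxfev: int = 4000,
) -> FitTransform:
    """Constrained ML estimate of the STN translation and per-axis scaling.

    Minimizes the summed negative log site likelihood over (tx, ty, tz,
    sx, sy, sz), recomputing every site's signed distance from the
    transformed mesh at each evaluation.  Bounds: +-2 mm translation per
    axis, 0.9-1.2 scaling per axis; no rotation.
    """
    init = init or FitTransform.identity()
    x0 = np.clip(
        init.as_vector(),
        [-TRANSLATION_BOUND_MM] * 3 + [SCALE_BOUNDS[0]] * 3,
        [TRANSLATION_BOUND_MM] * 3 + [SCALE_BOUNDS[1]] * 3,
    )
    bounds = [(-TRANSLATION_BOUND_MM, TRANSLATION_BOUND_MM)] * 3 + [SCALE_BOUNDS] * 3
    center = mesh.centroid
    groups = _colinear_groups(sites)
    res = minimize(
        _negative_log_likelihood,
        x0,
        args=(sites.positions, sites.nrms, mesh, center, params, groups),
        method="Powell",
        bounds=bounds,
        options={"ftol": ftol, "xtol": 1e-3, "maxfev": maxfev},
    )
    if not res.success and not np.isfinite(res.fun):
        warnings.warn("transform optimization failed; returning initialization", stacklevel=2)
        return replace(init, converged=False)
    x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    # snap solver fuzz onto an active bound so railed axes report the bound exactly
    for i, (lo, hi) in enumerate(bounds):
        if x[i] - lo < 1e-3:
            x[i] = lo
        elif hi - x[i] < 1e-3:
            x[i] = hi
    return FitTransform(t=x[:3], s=x[3:], converged=bool(res.success))


class BrainShiftEstimator(BaseEstimator):
    """Estimator facade over :func:`fit_transform`.

    Parameters are the trained :class:`MerModelParams`; ``fit`` stores the ML
    transform of the given mesh to the recorded NRMS series as
    ``transform_`` and the shifted mesh as ``mesh_``.
    """

    def __init__(self, params: MerModelParams | None = None, ftol: float = 1e-5, maxfev: int = 4000):
        self.params = params
        self.ftol = ftol
        self.maxfev = maxfev

    def fit(
        self, sites: MerTrajectorySet, mesh: SurfaceMesh, init: FitTransform | None = None
    ) -> "BrainShiftEstimator":
        if self.params is None:
            raise ValueError("params (trained MerModelParams) are required")
        self.transform_ = fit_transform(sites, mesh, self.params, init=init, ftol=self.ftol, maxfev=self.maxfev)
        self.mesh_ = apply_transform(mesh, self.transform_)
        return self

    def predict(self, sites: MerTrajectorySet) -> np.ndarray:
        return classify_sites(self.mesh_, sites)


def classify_sites(mesh: SurfaceMesh, sites: MerTrajectorySet) -> np.ndarray:
    """IN iff the site lies strictly inside the mesh (signed distance > 0)."""
    d = signed_distance(mesh, sites.positions)
    return np.where(d > 0, "IN", "OUT")


def evaluate_containment(pred: np.ndarray, expert: np.ndarray) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and Youden's J vs expert labels."""
    pred = np.asarray(pred)
    expert = np.asarray(expert)
    if pred.shape != expert.shape:
        raise ValueError("label arrays must have the same length")
    known = (expert == "IN") | (expert == "OUT")
    pred, expert = pred[known], expert[known]
    p = pred == "IN"
    e = expert == "IN"
    tp = int((p & e).sum())
    tn = int((~p & ~e).sum())
    fp = int((p & ~e).sum())
    fn = int((~p & e).sum())
    out = {"accuracy": (tp + tn) / max(len(pred), 1)}
    out["sensitivity"] = tp / (tp + fn) if (tp + fn) else float("nan")
    out["specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")
    if np.isnan(out["sensitivity"]) or np.isnan(out["specificity"]):
        warnings.warn("sensitivity/specificity undefined: a class is absent in expert labels", stacklevel=2)
    out["youden_j"] = out["sensitivity"] + out["specificity"] - 1.0
    return out


def _ben_gun_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def init_from_plan(
    target: np.ndarray,
    direction: np.ndarray = DEFAULT_DIRECTION,
    n_trajectories: int = 5,
    ben_gun_radius: float = BEN_GUN_RADIUS_MM,
    depths: np.ndarray = DEFAULT_DEPTHS_MM,
) -> MerTrajectorySet:
    """Site positions from the surgical plan: Ben-gun array around the target.

    Depth 0 of the central trajectory is the planned target point; parallel
    trajectories are offset by ``ben_gun_radius`` perpendicular to the
    insertion direction.  The associated transform is the identity.
    """
    if not 1 <= n_trajectories <= 5:
        raise ValueError("n_trajectories must be in 1..5")
    target = np.asarray(target, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    u, v = _ben_gun_frame(d)
    offsets = [np.zeros(3), v * ben_gun_radius, -v * ben_gun_radius, u * ben_gun_radius, -u * ben_gun_radius]
    rows = []
    for name, off in list(zip(BEN_GUN_NAMES, offsets))[:n_trajectories]:
        for depth in depths:
            p = target + off + depth * d
            rows.append({"trajectory": name, "depth_mm": depth, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]})
    return MerTrajectorySet(pd.DataFrame(rows))


def init_max_likely_exit(
    vertex_density: np.ndarray, mesh: SurfaceMesh, sites: MerTrajectorySet
) -> MerTrajectorySet:
    """Shift the trajectory bundle so the central depth-0 site lands on the
    maximum-density entry vertex mapped to this subject's mesh.

    The density lives on the corresponded reference surface; by point
    correspondence its argmax vertex index addresses the same anatomical spot
    on the individual mesh.  Ties break to the first index (deterministic).
    """
    vertex_density = np.asarray(vertex_density, dtype=float)
    if len(vertex_density) != mesh.n_vertices:
        raise ValueError("density must be defined per vertex of the corresponded mesh")
    target_vertex = mesh.vertices[int(np.argmax(vertex_density))]
    central = sites.sites[sites.sites["trajectory"] == "central"]
    if len(central) == 0:
        raise ValueError("sites contain no central trajectory")
    idx = (central["depth_mm"].abs()).idxmin()
    depth0 = central.loc[idx, ["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    shift = target_vertex - depth0
    return sites.with_positions(sites.positions + shift)
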