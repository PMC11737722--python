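"""Two-axis piecewise-linear ("hinge") threshold dose-response model.

The mean change in response is zero below both thresholds and grows
linearly in the supra-threshold excess on each axis:

    dy = 0                                   if theta < theta0 and phi < phi0
    dy = c1*(theta - theta0)                 if theta >= theta0 and phi < phi0
    dy = c2*(phi - phi0)                     if theta < theta0 and phi >= phi0
    dy = c1*(theta - theta0) + c2*(phi - phi0)   otherwise

Candidate threshold pairs are postulated on a grid, each cell is fit by
least squares on the hinge regressors (no intercept; the sub-threshold
mean is fixed at zero), significance is assessed by inverting the F
distribution against the all-zero null, and the reported thresholds are
the lowest significant, adequately supported pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import ttest_ind

#: canonical grid bounds (degrees, degrees/s)
THETA_MAX = 45.0
PHI_MAX = 3500.0

#: hinge-column correlation above which the design is treated as
#: unidentifiable and collapsed onto the theta hinge alone
COLLINEARITY_R = 0.99

DEFAULT_ALPHAS = (0.05, 0.01, 0.001)
DEFAULT_SUPPORT_MIN = 3

_RSS_TOL = 1e-12


@dataclass
class DoseResponseRecord:
    """One eye/timepoint observation of dose and response change."""

    subject_id: str
    theta: float
    phi: float
    dy_amplitude: float = math.nan
    dy_latency: float = math.nan
    timepoint: str = "D0"
    eye: str = "OD"

    def __post_init__(self) -> None:
        if self.theta < 0 or self.phi < 0:
            raise ValueError("theta and phi must be >= 0")
        if not (np.isfinite(self.dy_amplitude) or np.isfinite(self.dy_latency)):
            raise ValueError("at least one dy field must be finite")


@dataclass
class DesignInfo:
    """Hinge design at one candidate threshold pair."""

    X: np.ndarray                 # (n, q) retained hinge columns
    columns: list[str]            # names of retained columns
    n_supra_theta: int
    n_supra_phi: int
    identifiable: bool
    collapsed: bool               # both hinges present but collinear


@dataclass
class ThresholdFit:
    theta0: float
    phi0: float
    c1: float
    c2: float
    rss: float
    df_model: int
    df_resid: int
    f_stat: float
    p_value: float
    n_supra_theta: int
    n_supra_phi: int
    identifiable: bool
    n: int

    def predict(self, theta, phi):
        return eq1_mean(theta, phi, theta0=self.theta0, phi0=self.phi0,
                        c1=0.0 if not np.isfinite(self.c1) else self.c1,
                        c2=0.0 if not np.isfinite(self.c2) else self.c2)


@dataclass
class GridScan:
    theta_grid: np.ndarray
    phi_grid: np.ndarray
    p_surface: np.ndarray         # (n_theta, n_phi)
    c1_surface: np.ndarray
    c2_surface: np.ndarray
    rss_surface: np.ndarray
    identifiable: np.ndarray      # bool (n_theta, n_phi)
    n_supra_theta: np.ndarray     # per theta0 value
    n_supra_phi: np.ndarray       # per phi0 value
    outcome: str
    timepoint: str
    n: int
    n_cells_tested: int
    selections: dict = field(default_factory=dict)

    def argmin_p(self) -> tuple[float, float]:
        """Grid coordinates of the lowest p (ties: lowest RSS, then first)."""
        flat = np.lexsort((self.rss_surface.ravel(), self.p_surface.ravel()))
        i, j = np.unravel_index(flat[0], self.p_surface.shape)
        return float(self.theta_grid[i]), float(self.phi_grid[j])


@dataclass
class GridSpec:
    """Candidate-threshold grid (defaults: 0.5 deg and 25 deg/s steps)."""

    theta_min: float = 0.0
    theta_max: float = THETA_MAX
    theta_step: float = 0.5
    phi_min: float = 0.0
    phi_max: float = PHI_MAX
    phi_step: float = 25.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_min < self.theta_max <= THETA_MAX):
            raise ValueError(f"theta grid must lie within [0, {THETA_MAX}]")
        if not (0.0 <= self.phi_min < self.phi_max <= PHI_MAX):
            raise ValueError(f"phi grid must lie within [0, {PHI_MAX}]")
        if self.theta_step <= 0 or self.phi_step <= 0:
            raise ValueError("grid steps must be > 0")

    def theta_values(self) -> np.ndarray:
        n = int(round((self.theta_max - self.theta_min) / self.theta_step))
        return self.theta_min + self.theta_step * np.arange(n + 1)

    def phi_values(self) -> np.ndarray:
        n = int(round((self.phi_max - self.phi_min) / self.phi_step))
        return self.phi_min + self.phi_step * np.arange(n + 1)


# ---------------------------------------------------------------------------
# model mean
# ---------------------------------------------------------------------------

def eq1_mean(theta, phi, *, theta0: float, phi0: float,
             c1: float, c2: float = 0.0):
    """Piecewise-linear two-threshold mean change.

    The boundary belongs to the supra-threshold branch (>= on both
    thresholds); the contribution there is zero, so the mean is continuous
    and identically zero on the sub-threshold quadrant.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    t_excess = np.where(theta >= theta0, theta - theta0, 0.0)
    p_excess = np.where(phi >= phi0, phi - phi0, 0.0)
    out = c1 * t_excess + c2 * p_excess
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# per-cell regression
# ---------------------------------------------------------------------------

def _records_xy(records: Sequence[DoseResponseRecord],
                outcome: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    attr = {"amplitude": "dy_amplitude", "latency": "dy_latency"}[outcome]
    theta = np.array([r.theta for r in records], dtype=float)
    phi = np.array([r.phi for r in records], dtype=float)
    y = np.array([getattr(r, attr) for r in records], dtype=float)
    keep = np.isfinite(y)
    return theta[keep], phi[keep], y[keep]


def build_design(theta: np.ndarray, phi: np.ndarray,
                 theta0: float, phi0: float,
                 collinearity_r: float = COLLINEARITY_R) -> DesignInfo:
    """Hinge design matrix with zero-column dropping and collinearity collapse.

    Columns are max(theta - theta0, 0) and max(phi - phi0, 0).  A column
    with no supra-threshold observations is dropped.  If both columns are
    retained but correlate above ``collinearity_r`` the design collapses
    to the theta hinge alone and is flagged unidentifiable.
    """
    x1 = np.clip(np.asarray(theta, float) - theta0, 0.0, None)
    x2 = np.clip(np.asarray(phi, float) - phi0, 0.0, None)
    n_sup_t = int(np.count_nonzero(x1 > 0))
    n_sup_p = int(np.count_nonzero(x2 > 0))
    cols, names = [], []
    if n_sup_t > 0:
        cols.append(x1)
        names.append("theta")
    if n_sup_p > 0:
        cols.append(x2)
        names.append("phi")
    collapsed = False
    identifiable = True
    if len(cols) == 2:
        s1, s2 = x1.std(), x2.std()
        r = 1.0 if s1 == 0 or s2 == 0 else float(np.corrcoef(x1, x2)[0, 1])
        if abs(r) > collinearity_r:
            cols, names = [x1], ["theta"]
            collapsed = True
            identifiable = False
    X = np.column_stack(cols) if cols else np.empty((x1.size, 0))
    return DesignInfo(X=X, columns=names, n_supra_theta=n_sup_t,
                      n_supra_phi=n_sup_p, identifiable=identifiable,
                      collapsed=collapsed)


def _f_test(rss0: float, rss1: float, q: int, n: int) -> tuple[float, float]:
    """F statistic and upper-tail p against the all-zero null mean."""
    if q == 0 or n - q < 1:
        return 0.0, 1.0
    scale = max(rss0, 1.0)
    if rss1 <= _RSS_TOL * scale:
        if rss0 <= _RSS_TOL:
            return 0.0, 1.0        # response identically zero
        return math.inf, 0.0       # exact fit of a non-zero response
    f = ((rss0 - rss1) / q) / (rss1 / (n - q))
    f = max(f, 0.0)
    return f, float(f_dist.sf(f, q, n - q))


def fit_cell(records: Sequence[DoseResponseRecord], theta0: float,
             phi0: float, outcome: str = "amplitude",
             collinearity_r: float = COLLINEARITY_R) -> ThresholdFit:
    """Least-squares hinge fit at one candidate threshold pair.

    The null model is the identically-zero mean (no intercept), so
    RSS0 = sum(dy^2) and F = ((RSS0-RSS1)/q) / (RSS1/(n-q)) with p from
    the upper tail of F(q, n-q).
    """
    theta, phi, y = _records_xy(records, outcome)
    n = y.size
    if n == 0:
        raise ValueError("no finite observations for outcome " + outcome)
    info = build_design(theta, phi, theta0, phi0, collinearity_r)
    q = info.X.shape[1]
    rss0 = float(y @ y)
    c1 = c2 = math.nan
    if q == 0:
        rss1 = rss0
        f, p = 0.0, 1.0
    else:
        beta, *_ = np.linalg.lstsq(info.X, y, rcond=None)
        resid = y - info.X @ beta
        rss1 = float(resid @ resid)
        f, p = _f_test(rss0, rss1, q, n)
        for name, b in zip(info.columns, beta):
            if name == "theta":
                c1 = float(b)
            else:
                c2 = float(b)
    return ThresholdFit(theta0=theta0, phi0=phi0, c1=c1, c2=c2, rss=rss1,
                        df_model=q, df_resid=n - q, f_stat=f, p_value=p,
                        n_supra_theta=info.n_supra_theta,
                        n_supra_phi=info.n_supra_phi,
                        identifiable=info.identifiable, n=n)


# ---------------------------------------------------------------------------
# grid scan (vectorised; must agree with fit_cell cell-by-cell)
# ---------------------------------------------------------------------------

def grid_scan(records: Sequence[DoseResponseRecord],
              grid: Optional[GridSpec] = None,
              outcome: str = "amplitude",
              timepoint: str = "",
              collinearity_r: float = COLLINEARITY_R) -> GridScan:
    """Hinge fit and F-test at every grid cell.

    Vectorised over the grid via per-cell 2x2 normal equations; agrees
    with :func:`fit_cell` at every cell (tested property).
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    grid = grid or GridSpec()
    theta, phi, y = _records_xy(records, outcome)
    n = y.size
    if n == 0:
        raise ValueError("no finite observations for outcome " + outcome)
    tg = grid.theta_values()
    pg = grid.phi_values()
    nt, npg = tg.size, pg.size

    # hinge columns for every grid value: (n, nt) and (n, npg)
    X1 = np.clip(theta[:, None] - tg[None, :], 0.0, None)
    X2 = np.clip(phi[:, None] - pg[None, :], 0.0, None)

    s11 = np.einsum("it,it->t", X1, X1)            # (nt,)
    s22 = np.einsum("ip,ip->p", X2, X2)            # (npg,)
    s12 = X1.T @ X2                                # (nt, npg)
    s1y = X1.T @ y                                 # (nt,)
    s2y = X2.T @ y                                 # (npg,)
    syy = float(y @ y)

    m1 = X1.mean(axis=0)
    m2 = X2.mean(axis=0)
    v1 = s11 / n - m1 ** 2
    v2 = s22 / n - m2 ** 2
    cov = s12 / n - np.outer(m1, m2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(np.outer(v1, v2))
    corr = np.where(np.isfinite(corr), corr, 1.0)

    has1 = (s11 > 0)[:, None] & np.ones(npg, bool)[None, :]
    has2 = np.ones(nt, bool)[:, None] & (s22 > 0)[None, :]
    both = has1 & has2
    collinear = both & (np.abs(corr) > collinearity_r)
    theta_only = (has1 & ~has2) | collinear
    phi_only = has2 & ~has1
    full = both & ~collinear
    none = ~has1 & ~has2

    c1s = np.full((nt, npg), np.nan)
    c2s = np.full((nt, npg), np.nan)
    rss = np.full((nt, npg), syy)
    qs = np.zeros((nt, npg), dtype=int)

    with np.errstate(invalid="ignore", divide="ignore"):
        # single theta hinge: regression through origin
        b_t = np.where(s11 > 0, s1y / np.where(s11 > 0, s11, 1.0), np.nan)
        rss_t = syy - np.where(s11 > 0, b_t * s1y, 0.0)
        c1s[theta_only] = np.broadcast_to(b_t[:, None], (nt, npg))[theta_only]
        rss[theta_only] = np.broadcast_to(rss_t[:, None], (nt, npg))[theta_only]
        qs[theta_only] = 1
        # single phi hinge
        b_p = np.where(s22 > 0, s2y / np.where(s22 > 0, s22, 1.0), np.nan)
        rss_p = syy - np.where(s22 > 0, b_p * s2y, 0.0)
        c2s[phi_only] = np.broadcast_to(b_p[None, :], (nt, npg))[phi_only]
        rss[phi_only] = np.broadcast_to(rss_p[None, :], (nt, npg))[phi_only]
        qs[phi_only] = 1
        # both hinges: 2x2 normal equations
        det = np.outer(s11, s22) - s12 ** 2
        safe = np.where(full & (det > 0), det, 1.0)
        b1 = (s22[None, :] * s1y[:, None] - s12 * s2y[None, :]) / safe
        b2 = (s11[:, None] * s2y[None, :] - s12 * s1y[:, None]) / safe
        rss_f = syy - b1 * s1y[:, None] - b2 * s2y[None, :]
        degenerate = full & (det <= 0)          # numerically rank deficient
        full = full & (det > 0)
        c1s[full] = b1[full]
        c2s[full] = b2[full]
        rss[full] = rss_f[full]
        qs[full] = 2
        if degenerate.any():                     # fall back to theta hinge
            c1s[degenerate] = np.broadcast_to(b_t[:, None],
                                              (nt, npg))[degenerate]
            rss[degenerate] = np.broadcast_to(rss_t[:, None],
                                              (nt, npg))[degenerate]
            qs[degenerate] = 1
            collinear = collinear | degenerate

    rss = np.clip(rss, 0.0, None)

    p = np.ones((nt, npg))
    fsurf = np.zeros((nt, npg))
    scale = max(syy, 1.0)
    exact = rss <= _RSS_TOL * scale
    for q in (1, 2):
        mask = (qs == q) & ~exact & (n - q >= 1)
        if mask.any():
            f = ((syy - rss[mask]) / q) / (rss[mask] / (n - q))
            f = np.clip(f, 0.0, None)
            fsurf[mask] = f
            p[mask] = f_dist.sf(f, q, n - q)
    if syy > _RSS_TOL:
        hit = exact & (qs > 0)
        p[hit] = 0.0
        fsurf[hit] = np.inf
    p[none] = 1.0

    identifiable = ~(collinear | none)
    return GridScan(theta_grid=tg, phi_grid=pg, p_surface=p,
                    c1_surface=c1s, c2_surface=c2s, rss_surface=rss,
                    identifiable=identifiable,
                    n_supra_theta=(X1 > 0).sum(axis=0).astype(int),
                    n_supra_phi=(X2 > 0).sum(axis=0).astype(int),
                    outcome=outcome, timepoint=timepoint, n=n,
                    n_cells_tested=nt * npg)


# ---------------------------------------------------------------------------
# threshold selection & contours
# ---------------------------------------------------------------------------

def select_thresholds(scan: GridScan, alpha: float,
                      support_min: int = DEFAULT_SUPPORT_MIN,
                      bonferroni: bool = False,
                      profile_region: bool = True
                      ) -> Optional[tuple[float, float]]:
    """Lowest significant, adequately supported threshold pair.

    "Lowest" is the scaled lexicographic order theta0/45 + phi0/3500 with
    ties broken by the smaller theta0.  ``bonferroni=True`` divides alpha
    by the number of tested grid cells.

    With ``profile_region=True`` (default) candidate cells must also lie
    inside the profile-RSS confidence region of the best-fitting cell,
    RSS <= RSS_min * (1 + q/(n-q) * F(q, n-q; alpha)).  Without this
    restriction any cell whose hinge fit captures part of a genuine trend
    is "significant", and the lowest significant pair collapses to the
    grid origin whenever an effect exists at all.
    """
    level = alpha / scan.n_cells_tested if bonferroni else alpha
    support = (scan.n_supra_theta[:, None] + scan.n_supra_phi[None, :])
    ok = (scan.p_surface <= level) & (support >= support_min)
    if profile_region and ok.any():
        q = np.where(np.isfinite(scan.c2_surface), 2, 1)
        rss_min = scan.rss_surface[ok].min()
        dfr = scan.n - q
        with np.errstate(invalid="ignore"):
            bound = rss_min * (1.0 + q / np.maximum(dfr, 1)
                               * f_dist.isf(alpha, q, np.maximum(dfr, 1)))
        ok &= scan.rss_surface <= np.maximum(bound, rss_min + _RSS_TOL)
    if not ok.any():
        return None
    ii, jj = np.nonzero(ok)
    score = scan.theta_grid[ii] / THETA_MAX + scan.phi_grid[jj] / PHI_MAX
    order = np.lexsort((scan.theta_grid[ii], score))
    k = order[0]
    return float(scan.theta_grid[ii[k]]), float(scan.phi_grid[jj[k]])


def apply_selections(scan: GridScan,
                     alphas: Sequence[float] = DEFAULT_ALPHAS,
                     support_min: int = DEFAULT_SUPPORT_MIN,
                     bonferroni: bool = False,
                     profile_region: bool = True) -> GridScan:
    """Populate ``scan.selections`` for each alpha; returns the scan."""
    scan.selections = {
        float(a): select_thresholds(scan, a, support_min, bonferroni,
                                    profile_region)
        for a in alphas
    }
    return scan


def contour_surface(scan: GridScan,
                    levels: Sequence[float] = DEFAULT_ALPHAS
                    ) -> dict[float, list[np.ndarray]]:
    """Iso-probability polylines over the (theta0, phi0) plane.

    Returns, per requested level, a list of (k, 2) arrays of
    (theta0, phi0) vertices; empty when the surface never crosses the
    level (e.g. a constant surface).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out: dict[float, list[np.ndarray]] = {}
    fig, ax = plt.subplots()
    try:
        for level in levels:
            lo, hi = scan.p_surface.min(), scan.p_surface.max()
            if not (lo < level < hi):
                out[float(level)] = []
                continue
            cs = ax.contour(scan.theta_grid, scan.phi_grid,
                            scan.p_surface.T, levels=[level])
            segs = cs.allsegs[0] if cs.allsegs else []
            out[float(level)] = [np.asarray(s) for s in segs if len(s) > 1]
    finally:
        plt.close(fig)
    return out


# ---------------------------------------------------------------------------
# supra-threshold variance comparison
# ---------------------------------------------------------------------------

def variance_change_test(sub, supra, method: str = "f") -> tuple[float, float]:
    """One-sided test of Var(supra) > Var(sub).

    ``method='f'`` is the variance-ratio test (statistic is the ratio of
    sample variances, p from the upper F tail).  ``method='bf'`` is a
    Brown-Forsythe-style one-sided Welch t-test on median-centred absolute
    deviations.
    """
    sub = np.asarray(sub, dtype=float)
    supra = np.asarray(supra, dtype=float)
    if sub.size < 2 or supra.size < 2:
        raise ValueError("need at least 2 observations per group")
    v_sub = float(np.var(sub, ddof=1))
    v_supra = float(np.var(supra, ddof=1))
    if method == "f":
        if v_sub == 0:
            raise ValueError("degenerate sub-threshold group (zero variance)")
        stat = v_supra / v_sub
        p = float(f_dist.sf(stat, supra.size - 1, sub.size - 1))
        return stat, p
    if method == "bf":
        d_sub = np.abs(sub - np.median(sub))
        d_supra = np.abs(supra - np.median(supra))
        if np.var(d_sub) == 0 and np.var(d_supra) == 0:
            raise ValueError("degenerate groups (zero spread)")
        res = ttest_ind(d_supra, d_sub, equal_var=False,
                        alternative="greater")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
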