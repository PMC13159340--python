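"""%GMT-vs-outcome heatmaps on PSI and PSI x {ICP, PRx, CPP} grids.

For each grid cell the percentage of each patient's good monitoring time
spent in the cell is correlated with the 6-month Glasgow Outcome Scale using
Spearman's rank correlation.  Cells with fewer than five patients
contributing at least 5 min of GMT are masked (rendered white).  Rendering
replicates each cell into a 6 x 6 block of subpixels and applies a Gaussian
blur of one pixel (six subpixels) standard deviation, with masked cells
excluded from the blur support and re-whitened afterwards; outcome maps are
clipped to |r| <= 0.3 (jet scale, blue = favourable, red = unfavourable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import spearmanr

__all__ = [
    "GridSpec",
    "HeatmapGrid",
    "patient_cell_gmt",
    "cell_spearman",
    "cohort_cell_stats",
    "cell_density",
    "render",
    "render_png",
]


@dataclass(frozen=True)
class GridSpec:
    """Binning grid: PSI on x, optionally a second variable on y.

    Edges are left-closed/right-open with the last bin closed above.
    """

    x_name: str
    x_edges: np.ndarray
    y_name: str | None = None
    y_edges: np.ndarray | None = None

    @property
    def n_x(self) -> int:
        return len(self.x_edges) - 1

    @property
    def n_y(self) -> int:
        return 1 if self.y_edges is None else len(self.y_edges) - 1

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def is_2d(self) -> bool:
        return self.y_name is not None

    # -- the four study grids ------------------------------------------------

    @staticmethod
    def psi() -> "GridSpec":
        """Univariable PSI grid: 6 cells of width 0.5 over [1, 4]."""
        return GridSpec("psi", np.arange(1.0, 4.01, 0.5))

    @staticmethod
    def psi_icp() -> "GridSpec":
        """PSI x ICP: 6 x 20 = 120 cells, ICP 0-40 mmHg in 2-mmHg steps."""
        return GridSpec("psi", np.arange(1.0, 4.01, 0.5), "icp", np.arange(0.0, 40.01, 2.0))

    @staticmethod
    def psi_prx() -> "GridSpec":
        """PSI x PRx: 6 x 20 = 120 cells, PRx -1..1 in 0.1 steps."""
        return GridSpec("psi", np.arange(1.0, 4.01, 0.5), "prx", np.round(np.arange(-1.0, 1.001, 0.1), 10))

    @staticmethod
    def psi_cpp() -> "GridSpec":
        """PSI x CPP: 6 x 30 = 180 cells, CPP 40-100 mmHg in 2-mmHg steps."""
        return GridSpec("psi", np.arange(1.0, 4.01, 0.5), "cpp", np.arange(40.0, 100.01, 2.0))


def patient_cell_gmt(minutes: pd.DataFrame, grid: GridSpec):
    """Per-cell %GMT and minutes-in-cell for one patient.

    Minutes where every grid variable is valid form the denominator.  Returns
    ``(pct, mins, out_of_range_pct)`` with ``pct``/``mins`` shaped
    ``(n_y, n_x)``, or ``None`` when the patient has zero jointly valid
    minutes (excluded from this grid).  In-range cell percentages plus the
    out-of-range remainder sum to 100.
    """
    x = minutes[grid.x_name].to_numpy(dtype=float)
    if grid.is_2d:
        y = minutes[grid.y_name].to_numpy(dtype=float)
        joint = np.isfinite(x) & np.isfinite(y)
    else:
        joint = np.isfinite(x)
    total = int(joint.sum())
    if total == 0:
        return None
    xv = x[joint]
    if grid.is_2d:
        yv = minutes[grid.y_name].to_numpy(dtype=float)[joint]
        counts, _, _ = np.histogram2d(yv, xv, bins=[grid.y_edges, grid.x_edges])
    else:
        c1, _ = np.histogram(xv, bins=grid.x_edges)
        counts = c1[None, :].astype(float)
    pct = counts / total * 100.0
    out_of_range = 100.0 - pct.sum()
    return pct, counts, float(out_of_range)


@dataclass
class HeatmapGrid:
    """Cell statistics for one grid over a cohort."""

    grid: GridSpec
    r: np.ndarray  # (n_y, n_x) Spearman r, NaN where masked
    n_contrib: np.ndarray  # patients with >= min_minutes in the cell
    eligible: np.ndarray  # bool mask (n_y, n_x)
    pct: np.ndarray  # (n_patients, n_y, n_x) per-patient %GMT
    minutes: np.ndarray  # (n_patients, n_y, n_x)
    patients: list = field(default_factory=list)
    gos: np.ndarray | None = None

    def cell_table(self) -> pd.DataFrame:
        rows = []
        for iy in range(self.grid.n_y):
            for ix in range(self.grid.n_x):
                rows.append(
                    {
                        "x_lo": self.grid.x_edges[ix],
                        "x_hi": self.grid.x_edges[ix + 1],
                        "y_lo": self.grid.y_edges[iy] if self.grid.is_2d else np.nan,
                        "y_hi": self.grid.y_edges[iy + 1] if self.grid.is_2d else np.nan,
                        "spearman_r": self.r[iy, ix],
                        "n_contributors": int(self.n_contrib[iy, ix]),
                        "eligible": bool(self.eligible[iy, ix]),
                    }
                )
        return pd.DataFrame(rows)


def cell_spearman(
    pct: np.ndarray,
    minutes: np.ndarray,
    gos: np.ndarray,
    min_minutes: float = 5.0,
    min_contributors: int = 5,
    include_zero_contributors: bool = True,
):
    """Spearman r of per-patient cell %GMT against GOS, with eligibility mask.

    ``pct`` and ``minutes`` are (n_patients, n_y, n_x).  A cell's
    contributors are the patients with at least ``min_minutes`` of GMT in it;
    the cell is eligible only with >= ``min_contributors`` of them.  By
    default every grid-valid patient enters the correlation, with %GMT set to
    0 for sub-threshold contributors (exposure logic); set
    ``include_zero_contributors=False`` to correlate over contributors only.
    Cells with zero variance in either variable are masked.  Ties get average
    ranks (Spearman default).
    """
    n_p, n_y, n_x = pct.shape
    r = np.full((n_y, n_x), np.nan)
    n_contrib = np.zeros((n_y, n_x), dtype=int)
    eligible = np.zeros((n_y, n_x), dtype=bool)
    gos = np.asarray(gos, dtype=float)
    for iy in range(n_y):
        for ix in range(n_x):
            contrib = minutes[:, iy, ix] >= min_minutes
            n_contrib[iy, ix] = int(contrib.sum())
            if n_contrib[iy, ix] < min_contributors:
                continue
            if include_zero_contributors:
                vals = np.where(contrib, pct[:, iy, ix], 0.0)
                g = gos
            else:
                vals = pct[contrib, iy, ix]
                g = gos[contrib]
            if np.ptp(vals) == 0 or np.ptp(g) == 0:
                continue
            rho = spearmanr(vals, g).statistic
            if np.isfinite(rho):
                r[iy, ix] = float(rho)
                eligible[iy, ix] = True
    return r, n_contrib, eligible


def cohort_cell_stats(
    minute_frames: dict,
    metadata: pd.DataFrame,
    grid: GridSpec,
    min_minutes: float = 5.0,
    min_contributors: int = 5,
    include_zero_contributors: bool = True,
) -> HeatmapGrid:
    """Assemble per-patient %GMT matrices and per-cell Spearman statistics.

    ``minute_frames`` maps patient id to its minute series; ``metadata`` must
    carry ``patient`` and ``gos``.  Patients with missing GOS or zero jointly
    valid minutes on the grid are excluded.
    """
    meta = metadata.dropna(subset=["gos"]).set_index("patient")
    pcts, mins, pats, gos = [], [], [], []
    for pid, df in minute_frames.items():
        if pid not in meta.index:
            continue
        res = patient_cell_gmt(df, grid)
        if res is None:
            continue
        pct, counts, _ = res
        pcts.append(pct)
        mins.append(counts)
        pats.append(pid)
        gos.append(float(meta.at[pid, "gos"]))
    if not pats:
        raise ValueError("no patient has valid data on this grid")
    pct3 = np.stack(pcts)
    min3 = np.stack(mins)
    gos_v = np.asarray(gos)
    r, n_contrib, eligible = cell_spearman(
        pct3, min3, gos_v, min_minutes, min_contributors, include_zero_contributors
    )
    return HeatmapGrid(
        grid=grid,
        r=r,
        n_contrib=n_contrib,
        eligible=eligible,
        pct=pct3,
        minutes=min3,
        patients=pats,
        gos=gos_v,
    )


def cell_density(hm: HeatmapGrid, norm: str = "per_patient") -> np.ndarray:
    """Observation density per cell, in [0, 1].

    ``per_patient``: each patient's cell counts are divided by that patient's
    highest cell count, then averaged across patients (default).  ``global``:
    pooled cell counts divided by the pooled maximum.
    """
    if norm == "per_patient":
        per_max = hm.minutes.reshape(len(hm.patients), -1).max(axis=1)
        scaled = hm.minutes / np.where(per_max > 0, per_max, 1.0)[:, None, None]
        return scaled.mean(axis=0)
    if norm == "global":
        tot = hm.minutes.sum(axis=0)
        mx = tot.max()
        return tot / (mx if mx > 0 else 1.0)
    raise ValueError(f"unknown density normalisation: {norm!r}")


def render(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    mode: str = "outcome",
    clip: float = 0.3,
    subpix: int = 6,
    sigma_px: float = 1.0,
) -> np.ndarray:
    """Subpixel-smoothed image of per-cell values; masked cells stay white.

    ``values`` is the (n_y, n_x) cell array (Spearman r for outcome mode,
    density in [0, 1] for density mode); ``mask`` is True where a cell is
    *masked* (ineligible).  Each cell becomes a ``subpix x subpix`` block and
    a Gaussian blur of ``sigma_px`` pixels (= ``sigma_px * subpix`` subpixels,
    truncated at 3 sigma, reflective boundaries) is applied by normalised
    convolution so masked cells contribute nothing; they are re-set to NaN
    (white) afterwards.  Outcome values are clipped to ``+-clip`` first.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    if mask is None:
        mask = ~np.isfinite(v)
    else:
        mask = np.asarray(mask, dtype=bool) | ~np.isfinite(v)
    if mode == "outcome":
        v = np.clip(v, -clip, clip)
    elif mode != "density":
        raise ValueError("mode must be 'outcome' or 'density'")
    big_v = np.repeat(np.repeat(np.where(mask, 0.0, v), subpix, axis=0), subpix, axis=1)
    big_w = np.repeat(np.repeat((~mask).astype(float), subpix, axis=0), subpix, axis=1)
    sigma = sigma_px * subpix
    num = ndimage.gaussian_filter(big_v * big_w, sigma=sigma, truncate=3.0, mode="reflect")
    den = ndimage.gaussian_filter(big_w, sigma=sigma, truncate=3.0, mode="reflect")
    out = np.where(den > 1e-12, num / np.where(den > 1e-12, den, 1.0), np.nan)
    out[big_w == 0.0] = np.nan  # masked cells rendered white
    return out


def render_png(
    image: np.ndarray,
    path: str,
    mode: str = "outcome",
    clip: float = 0.3,
    grid: GridSpec | None = None,
) -> None:
    """Write the smoothed image to ``path`` (jet scale, NaN cells white).

    Blue encodes a favourable association (positive r) or frequent
    observations; red the opposite.  The colour mapping is presentation
    metadata only -- the numeric arrays are the analysis surface.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap("jet_r").copy()
    cmap.set_bad("white")
    fig, ax = plt.subplots(figsize=(6, 4))
    if mode == "outcome":
        vmin, vmax = -clip, clip
        label = "Spearman r (%GMT vs GOS)"
    else:
        vmin, vmax = 0.0, 1.0
        label = "normalised density"
    extent = None
    if grid is not None:
        y_edges = grid.y_edges if grid.is_2d else np.array([0.0, 1.0])
        extent = [grid.x_edges[0], grid.x_edges[-1], y_edges[0], y_edges[-1]]
        ax.set_xlabel(grid.x_name.upper())
        if grid.is_2d:
            ax.set_ylabel(grid.y_name.upper())
    im = ax.imshow(
        np.ma.masked_invalid(image),
        origin="lower",
        aspect="auto",
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
        extent=extent,
    )
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
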