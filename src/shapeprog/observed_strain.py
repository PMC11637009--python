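"""Observed strain profiles from stage pairs of cell networks.

Cells are compared within topologically tracked bins: each ring k of the
earlier stage, identified by its cumulative cell count N, is matched to the
cells occupying the same count range at the later stage.  Three observed
strain components are extracted per bin:

* area strain      lambda_A* = sqrt( A(N, t+dt) / A(N, t) )   (local length)
* elongation strain lambda_Q* = L(N, t+dt) / L(N, t)  with the radial length
  scale L = exp( sign(Q_rr) |Q| ) ring-averaged with cell-area weights
* rearrangement strain lambda_R* = n(N, t+dt), the (fractional) number of
  later-stage rings containing the bin's cells — radially oriented
  rearrangements stretch the ring count (> 1), tangential ones shrink it

and the combined anisotropic strain lambda~* = lambda_Q* lambda_R*.
Bootstrap resampling of cells within bins (10,000 repeats) provides 95%
percentile confidence intervals.  Profiles indexed by the normalised
coordinate r (or rho) interpolate onto lattice vertices to program the
spring model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cell_network import CellNetwork, directional_component, network_elongation_tensors
from .strain_frames import (REGION_NAMES, RegionalFrame, SpontaneousStrainField,
                            assemble_strain_tensor)
from .topo_coords import TopoChart

__all__ = [
    "measure_stage",
    "strain_from_area",
    "strain_from_elongation",
    "strain_from_rearrangements",
    "combine_anisotropic",
    "strain_profiles",
    "bootstrap_profile",
    "map_profile_to_lattice",
]

BOOTSTRAP_REPEATS = 10_000
OFFDIAG_RING_WARN = 0.05


def _coeff_norm_rows(Q: np.ndarray) -> np.ndarray:
    return np.sqrt(0.5 * np.einsum("nij,nij->n", Q, Q))


def measure_stage(net: CellNetwork, chart: TopoChart,
                  origin_point: np.ndarray | None = None) -> pd.DataFrame:
    """Per-ring measurement table for one stage and region.

    Columns: k, delta_N, N, coord (mean r/rho), area_mean, L_mean
    (area-weighted), Qrr_mean, Qoff_mean.  ``origin_point`` overrides the
    radial-direction origin; by default the origin cells' mean centroid
    (outDVB single-cell origins) or the nearest origin cell (origin lines)
    provides the direction.
    """
    cen, area, nrm = net.geometry()
    Q = network_elongation_tensors(net)
    valid = chart.cell_mask & (chart.k >= 0)
    cells = np.flatnonzero(valid)
    origin_cen = cen[chart.origin_cells]
    qrr = np.full(net.n_cells, np.nan)
    qoff = np.full(net.n_cells, np.nan)
    for c in cells:
        if origin_point is not None:
            o = np.asarray(origin_point, float)
        elif len(chart.origin_cells) == 1:
            o = origin_cen[0]
        else:
            # origin line: nearest origin cell's centroid (Eq.-style averaged
            # position of the topologically nearest k = 0 cells)
            d = np.linalg.norm(origin_cen - cen[c], axis=1)
            near = d <= d.min() + 1e-9
            o = origin_cen[near].mean(axis=0)
        if int(c) in set(int(x) for x in chart.origin_cells) and np.allclose(o, cen[c]):
            qrr[c] = 0.0
            qoff[c] = 0.0
            continue
        r = cen[c] - o
        r_t = r - (r @ nrm[c]) * nrm[c]
        if np.linalg.norm(r_t) < 1e-12:
            continue
        qrr[c] = directional_component(Q[c], cen[c], o, nrm[c])
        r_hat = r_t / np.linalg.norm(r_t)
        p_hat = np.cross(nrm[c], r_hat)
        qoff[c] = float(r_hat @ Q[c] @ p_hat)
    qnorm = _coeff_norm_rows(Q)
    L = np.exp(np.sign(np.nan_to_num(qrr)) * qnorm)
    ks = chart.k
    kmax = int(ks[valid].max())
    rows = []
    for k in range(kmax + 1):
        sel = valid & (ks == k)
        if not np.any(sel):
            rows.append((k, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        w = area[sel]
        rows.append((
            k, int(sel.sum()),
            float(np.nanmean(chart.coord[sel])) if chart.coord is not None else np.nan,
            float(w.mean()),
            float(np.average(L[sel], weights=w)),
            float(np.average(np.nan_to_num(qrr[sel]), weights=w)),
            float(np.average(np.abs(np.nan_to_num(qoff[sel])), weights=w)),
        ))
    df = pd.DataFrame(rows, columns=["k", "delta_N", "coord", "area_mean",
                                     "L_mean", "Qrr_mean", "Qoff_mean"])
    df["N"] = df["delta_N"].cumsum()
    if np.nanmax(df["Qoff_mean"].to_numpy()) > OFFDIAG_RING_WARN:
        warnings.warn("ring-averaged |Q_r,phi| exceeds 0.05: elongation axes "
                      "do not align with the coordinate axes", RuntimeWarning,
                      stacklevel=2)
    return df


def _bin_mean(later: pd.DataFrame, col: str, N_lo: float, N_hi: float) -> float:
    """Mean of a piecewise-constant per-ring quantity over a count interval."""
    edges = np.concatenate([[0.0], later["N"].to_numpy(dtype=float)])
    vals = later[col].to_numpy(dtype=float)
    lo = np.clip(edges[:-1], N_lo, N_hi)
    hi = np.clip(edges[1:], N_lo, N_hi)
    w = hi - lo
    tot = w.sum()
    if tot <= 0:
        return np.nan
    return float(np.nansum(w * vals) / tot)


def _k_of_N(later: pd.DataFrame):
    # continuous ring index: ring j covers counts (N(j-1), N(j)], so the
    # interpolant passes through (N(j), j) and starts at -1 for N = 0
    # (making the identity transition give exactly n = 1 on every bin)
    xs = np.concatenate([[0.0], later["N"].to_numpy(dtype=float)])
    ys = np.concatenate([[-1.0], later["k"].to_numpy(dtype=float)])

    def f(n):
        return np.interp(n, xs, ys)

    return f


def strain_from_area(rings_t: pd.DataFrame, rings_later: pd.DataFrame) -> np.ndarray:
    """lambda_A*(N) = sqrt(A(N, t+dt) / A(N, t)) on the earlier stage's bins."""
    out = np.full(len(rings_t), np.nan)
    N = rings_t["N"].to_numpy(dtype=float)
    N_lo = np.concatenate([[0.0], N[:-1]])
    N_max = float(rings_later["N"].iloc[-1])
    for i in range(len(rings_t)):
        if N[i] > N_max:
            continue
        a_t = rings_t["area_mean"].iloc[i]
        a_l = _bin_mean(rings_later, "area_mean", N_lo[i], N[i])
        if a_t <= 0 or a_l <= 0 or not np.isfinite(a_t * a_l):
            raise ValueError("non-positive bin areas")
        out[i] = np.sqrt(a_l / a_t)
    _warn_dropped(out, N, N_max)
    return out


def strain_from_elongation(rings_t: pd.DataFrame, rings_later: pd.DataFrame) -> np.ndarray:
    """lambda_Q*(N) = L(N, t+dt) / L(N, t) with ring-averaged radial scales."""
    out = np.full(len(rings_t), np.nan)
    N = rings_t["N"].to_numpy(dtype=float)
    N_lo = np.concatenate([[0.0], N[:-1]])
    N_max = float(rings_later["N"].iloc[-1])
    for i in range(len(rings_t)):
        if N[i] > N_max:
            continue
        L_t = rings_t["L_mean"].iloc[i]
        L_l = _bin_mean(rings_later, "L_mean", N_lo[i], N[i])
        out[i] = L_l / L_t
    _warn_dropped(out, N, N_max)
    return out


def strain_from_rearrangements(rings_t: pd.DataFrame, rings_later: pd.DataFrame) -> np.ndarray:
    """lambda_R*(N) = n(N, t+dt): rings needed at the later stage for the
    cells of one earlier-stage ring (n(N, t) = 1 by construction)."""
    out = np.full(len(rings_t), np.nan)
    N = rings_t["N"].to_numpy(dtype=float)
    N_lo = np.concatenate([[0.0], N[:-1]])
    N_max = float(rings_later["N"].iloc[-1])
    kofn = _k_of_N(rings_later)
    inside = N <= N_max
    out[inside] = kofn(N[inside]) - kofn(N_lo[inside])
    _warn_dropped(out, N, N_max)
    return out


def _warn_dropped(values: np.ndarray, N: np.ndarray, N_max: float) -> None:
    dropped = int(np.sum(N > N_max))
    if dropped:
        warnings.warn(f"{dropped} terminal bins exceed the later stage's cell "
                      "count and were dropped", RuntimeWarning, stacklevel=3)


def combine_anisotropic(lam_Q: np.ndarray, lam_R: np.ndarray) -> np.ndarray:
    """Combined anisotropic strain: elementwise product per bin."""
    return np.asarray(lam_Q) * np.asarray(lam_R)


def strain_profiles(rings_t: pd.DataFrame, rings_later: pd.DataFrame,
                    region: str = "", stages: tuple[str, str] = ("t", "t+dt")
                    ) -> pd.DataFrame:
    """Full observed-strain profile on the earlier stage's bins."""
    lam_A = strain_from_area(rings_t, rings_later)
    lam_Q = strain_from_elongation(rings_t, rings_later)
    lam_R = strain_from_rearrangements(rings_t, rings_later)
    return pd.DataFrame({
        "region": region,
        "k": rings_t["k"],
        "N": rings_t["N"],
        "coordinate": rings_t["coord"],
        "lambda_A": lam_A,
        "lambda_Q": lam_Q,
        "lambda_R": lam_R,
        "lambda_total": combine_anisotropic(lam_Q, lam_R),
        "stage_from": stages[0],
        "stage_to": stages[1],
    })


def bootstrap_profile(values_by_bin: dict, seed: int,
                      repeats: int = BOOTSTRAP_REPEATS,
                      weights_by_bin: dict | None = None) -> pd.DataFrame:
    """Percentile bootstrap mean and 95% CI per bin.

    ``values_by_bin`` maps bin label -> per-cell values; optional
    ``weights_by_bin`` (e.g. cell areas for elongation) makes the statistic a
    weighted mean.  Resampling is over cells within each bin, seeded.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label in sorted(values_by_bin):
        v = np.asarray(values_by_bin[label], dtype=float)
        if len(v) == 0:
            raise ValueError(f"bin {label!r} is empty")
        w = None
        if weights_by_bin is not None:
            w = np.asarray(weights_by_bin[label], dtype=float)
        stat = np.average(v, weights=w)
        idx = rng.integers(0, len(v), size=(repeats, len(v)))
        if w is None:
            boots = v[idx].mean(axis=1)
        else:
            boots = np.sum(v[idx] * w[idx], axis=1) / np.sum(w[idx], axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((label, stat, float(np.mean(boots)), float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["bin", "stat", "boot_mean", "ci_low", "ci_high"])


def map_profile_to_lattice(profile: pd.DataFrame, frame: RegionalFrame,
                           iso_col: str | None = None,
                           aniso_col: str | None = None) -> SpontaneousStrainField:
    """Interpolate a binned profile onto lattice vertices as a strain field.

    ``iso_col`` / ``aniso_col`` select which profile columns feed the
    isotropic and anisotropic factors (missing -> 1).  Rows are matched to
    vertices through the region label and the normalised coordinate, linear
    with clamped ends; the anisotropic factor is oriented along the local e1.
    The single-behaviour scenario fields are {1, lambda_R*},
    {1, lambda_Q*}, {lambda_A*, 1}.
    """
    lam = np.ones(frame.n)
    lam_t = np.ones(frame.n)
    for code, name in REGION_NAMES.items():
        mask = frame.region == code
        if not np.any(mask):
            continue
        g = profile[profile["region"] == name]
        if len(g) == 0 and name.startswith("outDVB"):
            g = profile[profile["region"] == "outDVB"]
        if len(g) == 0:
            raise ValueError(f"profile has no rows for region {name!r}")
        g = g.dropna(subset=[c for c in (iso_col, aniso_col) if c]).sort_values("coordinate")
        xs = g["coordinate"].to_numpy(dtype=float)
        if iso_col is not None:
            lam[mask] = np.interp(frame.coord[mask], xs, g[iso_col].to_numpy(dtype=float))
        if aniso_col is not None:
            lam_t[mask] = np.interp(frame.coord[mask], xs, g[aniso_col].to_numpy(dtype=float))
    return assemble_strain_tensor(lam, lam_t, frame)
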