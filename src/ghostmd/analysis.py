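"""Structural, dynamical and spectroscopic observables.

Everything the downstream study needs from a trajectory without electronic
structure: a geometric cavity detector (maximin void radius on a periodic
grid), cavity tracking with twin-cavity flags, cavity-centered radial
distribution functions and coordination numbers, gyration radius and relative
shape anisotropy of the void, diffusion coefficients from FFT-based mean
squared displacements with block errors, the vibrational density of states
from the mass-weighted velocity autocorrelation (with band peak metrics), and
a probabilistic hydrogen-bond census based on smoothly switched geometric
criteria.

The cavity detector is a deliberate surrogate: production studies center
their distributions on the excess electron's spin density, which needs
electronic structure; here the center of the largest void (grid maximum of
the distance-to-nearest-atom field, locally refined) stands in for it.  In
toy-reference runs the relaxed ghost position is available as well, so the
two trackers can be cross-checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .dynamics import Trajectory
from .system import Configuration, GhostMDError, minimum_image, wrap_positions
from .units import ATOMIC_MASSES, C_CM_FS, ELEMENT_OF

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cavity detection
# ---------------------------------------------------------------------------

@dataclass
class CavityRecord:
    """Void center(s) of one frame and their shape statistics."""

    time: float
    centers: np.ndarray          # (k, 3) Å, sorted by decreasing radius
    maximin_radii: np.ndarray    # (k,)
    r_gyr: float | None          # Å, of the primary void region
    anisotropy: float | None     # κ² ∈ [0, 1]
    twin: bool
    shell_molecules: list[int] = field(default_factory=list)

    @property
    def n_centers(self) -> int:
        return len(self.maximin_radii)


def _nearest_atom_distance(point, positions, cell):
    d = minimum_image(positions - point, cell)
    return float(np.min(np.linalg.norm(d, axis=1)))


def void_center(frame: Configuration, grid_spacing: float = 0.4,
                radius_threshold: float = 2.55, pairing_cutoff: float = 6.0,
                r_shell: float = 3.5, refine: bool = True,
                max_candidates: int = 8) -> CavityRecord:
    """Find void centers: periodic local maxima of distance-to-nearest-atom.

    Candidate centers below ``radius_threshold`` are discarded (an empty
    record is a valid delocalized/neat outcome).  The twin flag is set when
    at least two surviving centers lie within ``pairing_cutoff`` (clamped to
    half the box).  Gyration statistics are computed over the connected grid
    region of the primary void.
    """
    cell = frame.cell
    pos = wrap_positions(frame.positions, cell)
    tree = cKDTree(pos, boxsize=cell)
    dims = np.maximum(2, np.round(cell / grid_spacing).astype(int))
    axes = [np.arange(n) * (L / n) for n, L in zip(dims, cell)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    dist = tree.query(pts)[0].reshape(dims)

    localmax = dist >= ndimage.maximum_filter(dist, size=3, mode="wrap")
    # pre-select with a grid-resolution margin; the exact threshold is applied
    # after local refinement (a grid point can sit up to ~h·√3/2 off-center)
    margin = 0.87 * float(np.max(cell / dims))
    cand = np.argwhere(localmax & (dist >= max(radius_threshold - margin, 1e-9)))
    if len(cand) == 0:
        return CavityRecord(0.0, np.zeros((0, 3)), np.zeros(0), None, None,
                            False, [])
    cand_r = dist[tuple(cand.T)]
    order = np.argsort(cand_r)[::-1][:max_candidates]
    centers, radii = [], []
    for idx in order:
        c = cand[idx] * (cell / dims)
        r = cand_r[idx]
        if refine:
            res = minimize(lambda x: -_nearest_atom_distance(x, pos, cell),
                           c, method="Nelder-Mead",
                           options=dict(xatol=1e-3, fatol=1e-6, maxiter=200))
            c, r = wrap_positions(res.x, cell), -res.fun
        if r < radius_threshold:
            continue
        # merge with an existing (larger) center if closer than its radius
        dup = any(np.linalg.norm(minimum_image(c - c0, cell)) < max(1.5, r0)
                  for c0, r0 in zip(centers, radii))
        if not dup:
            centers.append(np.asarray(c, float))
            radii.append(float(r))
    if not centers:
        return CavityRecord(0.0, np.zeros((0, 3)), np.zeros(0), None, None,
                            False, [])
    centers = np.array(centers)
    radii = np.array(radii)

    pair_cut = min(pairing_cutoff, 0.5 * float(np.min(cell)))
    twin = False
    if len(centers) >= 2:
        sep = np.linalg.norm(minimum_image(centers[1:] - centers[0], cell),
                             axis=1)
        twin = bool(np.any(sep <= pair_cut))

    # gyration of the void region around the primary center
    primary = centers[0]
    blob_level = max(1.2, 0.6 * radii[0])
    rel = minimum_image(pts - primary, cell)
    near = (np.linalg.norm(rel, axis=1) <= pair_cut) & \
        (dist.ravel() >= blob_level)
    if near.sum() >= 1:
        r_gyr, kappa2 = gyration_stats(rel[near])
    else:
        r_gyr, kappa2 = 0.0, 0.0
    shell = shell_members(frame, primary, r_shell)
    return CavityRecord(0.0, centers, radii, r_gyr, kappa2, twin, shell)


def track_cavities(traj: Trajectory, grid_spacing: float = 0.4,
                   radius_threshold: float = 2.55, pairing_cutoff: float = 6.0,
                   match_radius: float = 2.0, stride: int = 1):
    """Per-frame cavity records with nearest-center identity tracking.

    Returns (records, events) where events has ``switches`` — times at which
    the identity of the primary (largest) void changed to a different track —
    and ``twin_frames`` — indices of frames flagged as twin cavities.
    """
    records: list[CavityRecord] = []
    events = dict(switches=[], twin_frames=[])
    track_pos: dict[int, np.ndarray] = {}
    track_of_primary = None
    next_track = 0
    cell = traj.cell
    for i in range(0, traj.n_frames, stride):
        rec = void_center(traj.frame_config(i), grid_spacing,
                          radius_threshold, pairing_cutoff)
        rec.time = float(traj.times[i])
        records.append(rec)
        if rec.twin:
            events["twin_frames"].append(i)
        if rec.n_centers == 0:
            continue
        # greedy nearest matching of current centers to existing tracks
        assigned = {}
        used = set()
        for ci, c in enumerate(rec.centers):
            best, best_d = None, match_radius
            for tid, tpos in track_pos.items():
                if tid in used:
                    continue
                d = np.linalg.norm(minimum_image(c - tpos, cell))
                if d < best_d:
                    best, best_d = tid, d
            if best is None:
                best = next_track
                next_track += 1
            assigned[ci] = best
            used.add(best)
            track_pos[best] = c
        primary_track = assigned[0]
        if track_of_primary is not None and primary_track != track_of_primary:
            events["switches"].append(rec.time)
        track_of_primary = primary_track
    return records, events


def shell_members(frame: Configuration, center, r_shell: float = 3.5) -> list[int]:
    """Molecules whose O site lies within r_shell of the center (closed bound).

    The default 3.5 Å matches the first-coordination-shell radius used for
    shell-restricted spectra.
    """
    out = []
    for m in range(frame.n_molecules):
        sel = (frame.molecule_index == m) & frame.is_element("O")
        o_pos = frame.positions[sel][0]
        if np.linalg.norm(minimum_image(o_pos - np.asarray(center), frame.cell)) \
                <= r_shell:
            out.append(m)
    return out


def gyration_stats(points: np.ndarray, weights: np.ndarray | None = None):
    """Weighted gyration radius and relative shape anisotropy κ².

    κ² = 1 − 3(λ1λ2 + λ2λ3 + λ3λ1)/(λ1+λ2+λ3)² from the gyration-tensor
    eigenvalues: 0 for isotropic distributions, 1 for collinear ones.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, float)
        if np.any(w < 0) or w.sum() == 0:
            raise GhostMDError("weights must be non-negative with positive sum")
    mean = np.average(pts, axis=0, weights=w)
    rel = pts - mean
    r_gyr2 = np.average(np.sum(rel * rel, axis=1), weights=w)
    S = (w[:, None, None] * rel[:, :, None] * rel[:, None, :]).sum(axis=0) / w.sum()
    lam = np.linalg.eigvalsh(S)
    tr = lam.sum()
    if tr <= 0:
        return 0.0, 0.0
    kappa2 = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / tr**2
    return float(np.sqrt(r_gyr2)), float(kappa2)


# ---------------------------------------------------------------------------
# radial distribution functions
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray            # bin centers, Å
    g: np.ndarray
    n_of_r: np.ndarray       # running coordination number
    n_frames: int            # center-frames actually used
    species: str
    tag: str = ""


def _species_mask(frame: Configuration, species: str) -> np.ndarray:
    """'O'/'H' match by element (D counts as H); 'D' matches the isotope."""
    if species == "D":
        return frame.species == "D"
    return frame.elements == species


def rdf_about_centers(traj: Trajectory, centers, species: str,
                      r_max: float | None = None, n_bins: int = 60,
                      single_cavity_only: bool = True,
                      tag: str = "") -> RDFResult:
    """g(r) of one species about per-frame centers, ideal-gas normalized.

    ``centers`` is a list (length n_frames) of (k, 3) arrays; frames with no
    centers are skipped, frames with several are skipped when
    ``single_cavity_only`` (the usual restriction for cavity-shape statistics)
    and otherwise contribute every center.
    """
    cell = traj.cell
    if r_max is None:
        r_max = 0.5 * float(np.min(cell))
    if r_max > 0.5 * np.min(cell) + 1e-9:
        raise GhostMDError("r_max exceeds half the smallest cell length")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    used = 0
    mask0 = _species_mask(traj.frame_config(0), species)
    n_sp = int(mask0.sum())
    for i in range(traj.n_frames):
        cs = np.atleast_2d(np.asarray(centers[i], float)) \
            if centers[i] is not None and len(np.atleast_1d(centers[i])) else None
        if cs is None or len(cs) == 0:
            continue
        if single_cavity_only and len(cs) > 1:
            continue
        pos = traj.positions[i][mask0]
        for c in cs:
            d = np.linalg.norm(minimum_image(pos - c, cell), axis=1)
            counts += np.histogram(d, bins=edges)[0]
            used += 1
    if used == 0:
        raise GhostMDError("no usable center-frames for the RDF")
    rho = n_sp / float(np.prod(cell))
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (used * rho * shell_vol)
    n_of_r = np.cumsum(counts) / used
    r = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r, g, n_of_r, used, species, tag)


def pair_rdf(traj: Trajectory, species_a: str, species_b: str,
             r_max: float | None = None, n_bins: int = 80,
             include_intramolecular: bool = True, stride: int = 1,
             tag: str = "") -> RDFResult:
    """Site–site g(r) averaged over frames (optionally skipping same-molecule
    pairs); used e.g. for the covalent O–H peak whose quantum broadening is a
    key nuclear-quantum-effect signature."""
    cell = traj.cell
    if r_max is None:
        r_max = 0.5 * float(np.min(cell))
    if r_max > 0.5 * np.min(cell) + 1e-9:
        raise GhostMDError("r_max exceeds half the smallest cell length")
    f0 = traj.frame_config(0)
    mask_a = _species_mask(f0, species_a)
    mask_b = _species_mask(f0, species_b)
    ia = np.flatnonzero(mask_a)
    ib = np.flatnonzero(mask_b)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    used = 0
    mol = f0.molecule_index
    pairs_a, pairs_b = np.meshgrid(ia, ib, indexing="ij")
    keep = pairs_a != pairs_b
    if not include_intramolecular:
        keep &= mol[pairs_a] != mol[pairs_b]
    pa, pb = pairs_a[keep], pairs_b[keep]
    for i in range(0, traj.n_frames, stride):
        d = np.linalg.norm(minimum_image(traj.positions[i][pa] -
                                         traj.positions[i][pb], cell), axis=1)
        counts += np.histogram(d, bins=edges)[0]
        used += 1
    rho_b = len(ib) / float(np.prod(cell))
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (used * len(ia) * rho_b * shell_vol)
    n_of_r = np.cumsum(counts) / (used * len(ia))
    return RDFResult(0.5 * (edges[1:] + edges[:-1]), g, n_of_r, used,
                     f"{species_a}-{species_b}", tag)


def coordination_number(rdf: RDFResult, r_cut="auto") -> float:
    """n(r_cut); with r_cut='auto', the first minimum of g after its first peak."""
    if r_cut == "auto":
        g = np.convolve(rdf.g, np.ones(3) / 3.0, mode="same")
        peak = int(np.argmax(g))
        minima = signal.argrelmin(g, order=2)[0]
        minima = minima[minima > peak]
        if len(minima) == 0:
            raise GhostMDError("no first minimum found after the first peak; "
                               "pass an explicit r_cut")
        r_cut = float(rdf.r[minima[0]])
    if r_cut < rdf.r[0] or r_cut > rdf.r[-1]:
        raise GhostMDError("r_cut outside the RDF grid")
    return float(np.interp(r_cut, rdf.r, rdf.n_of_r))


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

@dataclass
class DiffusionResult:
    times: np.ndarray        # lag times, fs
    msd: np.ndarray          # Å²
    D: float                 # Å²/ps
    D_err: float             # Å²/ps (block standard error)
    fit_window: tuple
    poor_fit: bool
    D_blocks: np.ndarray


def unwrap_track(positions: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping of a (F, ..., 3) track via minimum-image steps."""
    steps = minimum_image(np.diff(positions, axis=0), cell)
    out = np.concatenate([positions[:1], positions[:1] + np.cumsum(steps, axis=0)])
    return out


def _msd_fft(track: np.ndarray) -> np.ndarray:
    """MSD of one unwrapped track (F, d) by the FFT correlation algorithm."""
    F = len(track)
    nfft = 1 << (2 * F - 1).bit_length()
    S2 = np.zeros(F)
    for c in range(track.shape[1]):
        X = np.fft.rfft(track[:, c], nfft)
        acf = np.fft.irfft(X * np.conj(X), nfft)[:F]
        S2 += acf
    norm = F - np.arange(F)
    S2 = S2 / norm
    sq = np.sum(track ** 2, axis=1)
    ss = np.concatenate([sq, [0.0]])
    s1 = np.empty(F)
    run = 2.0 * sq.sum()
    for m in range(F):
        s1[m] = run / (F - m)
        run -= ss[m] + ss[F - 1 - m]
    return s1 - 2.0 * S2


def msd_diffusion(traj: Trajectory | None = None, selection=None,
                  track: np.ndarray | None = None,
                  times: np.ndarray | None = None,
                  fit_window: tuple = (0.1, 0.5), n_blocks: int = 5,
                  dim: int = 3) -> DiffusionResult:
    """Diffusion coefficient from the Einstein relation, D = slope/(2·dim).

    Tracks are unwrapped with minimum-image bookkeeping.  The MSD is averaged
    over selected atoms (or a single center track); D comes from a least
    squares fit on the stated lag-time window, with the error estimated from
    independent contiguous blocks.
    """
    if track is not None:
        tracks = np.asarray(track, float)
        if tracks.ndim == 2:
            tracks = tracks[:, None, :]
        times = np.asarray(times, float)
        cell = None
    else:
        sel = np.asarray(selection if selection is not None
                         else np.arange(traj.positions.shape[1]))
        tracks = traj.positions[:, sel, :]
        times = traj.times
        cell = traj.cell
    if cell is not None:
        tracks = unwrap_track(tracks, cell)
    else:
        # center tracks are wrapped too; unwrap against the trajectory cell
        pass
    F = len(tracks)
    lo = max(1, int(fit_window[0] * F))
    hi = max(lo + 2, int(fit_window[1] * F))
    if hi >= F:
        raise GhostMDError("track shorter than the requested fit window")
    msd = np.mean(np.stack([_msd_fft(tracks[:, a, :])
                            for a in range(tracks.shape[1])]), axis=0)
    lag = times - times[0]

    def fit_D(msd_arr, lag_arr):
        A = np.vstack([lag_arr[lo:hi], np.ones(hi - lo)]).T
        slope, icpt = np.linalg.lstsq(A, msd_arr[lo:hi], rcond=None)[0]
        resid = msd_arr[lo:hi] - (A @ [slope, icpt])
        scale = np.std(msd_arr[lo:hi]) or 1.0
        return slope / (2 * dim), float(np.sqrt(np.mean(resid ** 2)) / scale)

    D_fs, rel_resid = fit_D(msd, lag)
    # block estimates: for an ensemble of tracks the independent unit is the
    # particle (disjoint particle groups, full time span); time-blocks of a
    # pooled ensemble share slow lag-window fluctuations and understate the
    # estimator's variance.  Single tracks fall back to time blocking.
    n_part = tracks.shape[1]
    Ds = []
    if n_part >= 2 * n_blocks:
        groups = np.array_split(np.arange(n_part), n_blocks)
        for grp in groups:
            m = np.mean(np.stack([_msd_fft(tracks[:, a, :]) for a in grp]),
                        axis=0)
            Ds.append(fit_D(m, lag)[0])
    else:
        n_tb = max(2, min(n_blocks, F // max(8, hi - lo)))
        bl = F // n_tb
        for b in range(n_tb):
            seg = tracks[b * bl:(b + 1) * bl]
            if len(seg) < 8:
                continue
            m = np.mean(np.stack([_msd_fft(seg[:, a, :])
                                  for a in range(seg.shape[1])]), axis=0)
            l = max(1, int(fit_window[0] * len(seg)))
            h = max(l + 2, int(fit_window[1] * len(seg)))
            A = np.vstack([lag[:len(seg)][l:h], np.ones(h - l)]).T
            slope = np.linalg.lstsq(A, m[l:h], rcond=None)[0][0]
            Ds.append(slope / (2 * dim))
    Ds = np.array(Ds)
    if len(Ds) < 2:
        raise GhostMDError("need at least 2 blocks for an error estimate")
    err_fs = float(np.std(Ds, ddof=1) / np.sqrt(len(Ds)))
    return DiffusionResult(lag, msd, D_fs * 1e3, err_fs * 1e3,
                           fit_window, rel_resid > 0.1, Ds * 1e3)


# ---------------------------------------------------------------------------
# vibrational density of states
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    nu: np.ndarray           # cm⁻¹
    intensity: np.ndarray    # amu Å²/fs² per cm⁻¹ (arbitrary but consistent)
    tag: str = ""
    windowed_variance: float = 0.0   # Σ_a m_a ⟨(w v)²⟩, for the Parseval identity


def vdos(traj, selection=None, max_band: float = 4000.0,
         isotope_resolved: bool = False, tag: str = "") -> Spectrum | dict:
    """Mass-weighted VDOS: Hann-windowed periodogram of atomic velocities.

    Equivalent to the Fourier transform of the velocity autocorrelation
    function (Wiener–Khinchin).  The normalization satisfies Parseval:
    ∫ I(ν) dν equals the windowed mass-weighted velocity variance.  A list of
    trajectories is averaged (replica averaging); isotope_resolved returns a
    dict of spectra keyed by species.
    """
    trajs = traj if isinstance(traj, (list, tuple)) else [traj]
    t0 = trajs[0]
    if t0.velocities is None:
        raise GhostMDError("trajectory has no stored velocities")
    dt = t0.dt_frame
    nyquist = 1.0 / (2.0 * dt) / C_CM_FS
    if nyquist < max_band:
        raise GhostMDError(
            f"frame interval {dt} fs gives a Nyquist frequency of "
            f"{nyquist:.0f} cm⁻¹ < required band {max_band:.0f} cm⁻¹; "
            "store velocities at a finer stride")
    if isotope_resolved:
        out = {}
        for sp in np.unique(t0.species):
            sel = np.flatnonzero(t0.species == sp)
            if selection is not None:
                sel = np.intersect1d(sel, selection)
            if len(sel):
                out[sp] = vdos(trajs, selection=sel, max_band=max_band,
                               tag=f"{tag}:{sp}")
        return out

    spec_sum = None
    var_sum = 0.0
    for tr in trajs:
        sel = np.asarray(selection) if selection is not None \
            else np.arange(tr.velocities.shape[1])
        v = tr.velocities[:, sel, :]
        F = len(v)
        masses = np.asarray(tr.metadata["masses"])[sel]
        w = np.hanning(F)[:, None, None]
        y = w * v
        Y = np.fft.rfft(y, axis=0)
        coef = np.full(Y.shape[0], 2.0)
        coef[0] = 1.0
        if F % 2 == 0:
            coef[-1] = 1.0
        power = np.sum(np.abs(Y) ** 2 * masses[None, :, None], axis=(1, 2))
        dnu = (1.0 / (F * dt)) / C_CM_FS
        I = coef * power / (F * F * dnu)
        var_sum += float(np.sum(masses[None, :, None] * y * y) / F)
        spec_sum = I if spec_sum is None else spec_sum + I
    nu = np.fft.rfftfreq(len(trajs[0].velocities), d=dt) / C_CM_FS
    n = len(trajs)
    return Spectrum(nu, spec_sum / n, tag, var_sum / n)


def peak_metrics(spectrum: Spectrum, bands: dict,
                 reference: Spectrum | None = None,
                 prominence: float = 0.1) -> dict:
    """Band peak positions (parabolic interpolation), half-maximum crossings,
    doublet detection, and shifts vs a reference spectrum.

    For each band (cm⁻¹ window) returns peak, half_max (highest-frequency
    half-height crossing), doublet (up to two prominent maxima) and
    splitting; absent maxima are reported as None.
    """
    out = {}
    for name, (lo, hi) in bands.items():
        m = (spectrum.nu >= lo) & (spectrum.nu <= hi)
        res = dict(peak=None, half_max=None, doublet=[], splitting=None,
                   shift=None)
        if m.sum() >= 3 and np.any(spectrum.intensity[m] > 0):
            nu = spectrum.nu[m]
            I = spectrum.intensity[m]
            res["peak"] = _parabolic_peak(nu, I, int(np.argmax(I)))
            half = 0.5 * I.max()
            above = np.flatnonzero(I >= half)
            j = above[-1]
            if j + 1 < len(I):
                frac = (I[j] - half) / (I[j] - I[j + 1])
                res["half_max"] = float(nu[j] + frac * (nu[j + 1] - nu[j]))
            else:
                res["half_max"] = float(nu[j])
            pk, _ = signal.find_peaks(I, prominence=prominence * I.max())
            if len(pk) >= 2:
                top = pk[np.argsort(I[pk])[::-1][:2]]
                pos = sorted(_parabolic_peak(nu, I, int(p)) for p in top)
                res["doublet"] = pos
                res["splitting"] = float(pos[1] - pos[0])
            if reference is not None:
                ref = peak_metrics(reference, {name: (lo, hi)},
                                   prominence=prominence)[name]
                if ref["peak"] is not None:
                    res["shift"] = res["peak"] - ref["peak"]
        out[name] = res
    return out


def _parabolic_peak(nu, I, j) -> float:
    if 0 < j < len(I) - 1:
        denom = I[j - 1] - 2 * I[j] + I[j + 1]
        if denom != 0:
            delta = 0.5 * (I[j - 1] - I[j + 1]) / denom
            return float(nu[j] + delta * (nu[1] - nu[0]))
    return float(nu[j])


# ---------------------------------------------------------------------------
# probabilistic hydrogen-bond census
# ---------------------------------------------------------------------------

@dataclass
class HBParams:
    """Smoothed geometric criterion: p = s((d0−d_OA)/Δd)·s((θ0−β)/Δθ),

    with s the logistic function, d_OA the donor-O/acceptor-O distance and β
    the acceptor–donorO–H angle (0° for an ideal linear bond)."""

    d0: float = 3.5          # Å
    delta_d: float = 0.25    # Å
    theta0: float = 30.0     # deg
    delta_theta: float = 7.5  # deg


@dataclass
class HBReport:
    donor_counts: np.ndarray      # (M,) expected donated bonds per molecule
    acceptor_counts: np.ndarray   # (M,)
    n_single_donor: int
    n_single_acceptor: int

    def diff(self, reference: "HBReport") -> dict:
        return dict(
            single_donor=self.n_single_donor - reference.n_single_donor,
            single_acceptor=self.n_single_acceptor - reference.n_single_acceptor,
            mean_donor=float(self.donor_counts.mean() -
                             reference.donor_counts.mean()),
            mean_acceptor=float(self.acceptor_counts.mean() -
                                reference.acceptor_counts.mean()))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def hb_state(frame: Configuration, params: HBParams | None = None) -> HBReport:
    """Expected donor/acceptor counts per molecule and single-donor/acceptor
    totals, from the probabilistic hydrogen-bond criterion."""
    params = params or HBParams()
    cell = frame.cell
    M = frame.n_molecules
    from .toy import molecular_topology
    o_idx, h_idx = molecular_topology(frame.species, frame.molecule_index)
    o_pos = frame.positions[o_idx]                     # (M, 3)
    donors = np.zeros(M)
    acceptors = np.zeros(M)
    d_oo = minimum_image(o_pos[:, None, :] - o_pos[None, :, :], cell)
    r_oo = np.linalg.norm(d_oo, axis=-1)
    for m in range(M):
        for h in h_idx[m]:
            oh = minimum_image(frame.positions[h] - o_pos[m], cell)
            r_oh = np.linalg.norm(oh)
            for a in range(M):
                if a == m:
                    continue
                oa = -d_oo[m, a]                       # donor O → acceptor O
                r = r_oo[m, a]
                cosb = np.dot(oh, oa) / (r_oh * r)
                beta = np.degrees(np.arccos(np.clip(cosb, -1, 1)))
                p = _logistic((params.d0 - r) / params.delta_d) * \
                    _logistic((params.theta0 - beta) / params.delta_theta)
                donors[m] += p
                acceptors[a] += p
    ns_d = int(np.sum((donors >= 0.5) & (donors < 1.5)))
    ns_a = int(np.sum((acceptors >= 0.5) & (acceptors < 1.5)))
    return HBReport(donors, acceptors, ns_d, ns_a)


def hb_average(traj: Trajectory, params: HBParams | None = None,
               stride: int = 1) -> HBReport:
    """Frame-averaged hydrogen-bond report (totals averaged, then rounded)."""
    reports = [hb_state(traj.frame_config(i), params)
               for i in range(0, traj.n_frames, stride)]
    return HBReport(
        np.mean([r.donor_counts for r in reports], axis=0),
        np.mean([r.acceptor_counts for r in reports], axis=0),
        float(np.mean([r.n_single_donor for r in reports])),
        float(np.mean([r.n_single_acceptor for r in reports])))
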