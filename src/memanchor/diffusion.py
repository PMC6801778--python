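"""Lateral diffusion from single-particle tracks.

Jump-distance analysis (JDA): for 2D Brownian motion with diffusion
coefficient D, the distribution of displacement magnitudes r over a lag
time dt is

    p(r) = sum_i f_i * r / (2 D_i dt) * exp(-r^2 / (4 D_i dt)),

a (mixture of) Rayleigh densities. Fitting this density to the pooled jumps
of many particles resolves subpopulations that a mean-square-displacement
fit would average away. The squared jump r^2 is exponentially distributed
with mean 4 D dt, so the mixture is fitted by expectation-maximisation on
squared jumps, with closed-form M-steps; the single-component maximum
likelihood estimate is D = <r^2> / (4 dt).

Unit convention: positions nm, times ns, so D is nm^2/ns internally;
reported values use 1e-7 cm^2 s^-1 (1 nm^2/ns = 100 x 1e-7 cm^2 s^-1),
the customary scale for lipid diffusion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .traj_core import AtomSet, Trajectory, wrap_displacement

logger = logging.getLogger(__name__)

__all__ = [
    "TrackSet",
    "JdaFit",
    "NM2_PER_NS_TO_1E7_CM2_S",
    "unwrap_tracks",
    "jump_distances",
    "fit_jda",
    "jda_with_uncertainty",
    "msd_curve",
    "msd_diffusion",
    "diffusion_ratio",
    "round_sig",
]

#: multiply a diffusion coefficient in nm^2/ns by this to get 1e-7 cm^2/s
NM2_PER_NS_TO_1E7_CM2_S = 100.0


@dataclass
class TrackSet:
    """Unwrapped 2D positions: (n_particles, n_frames, 2) in nm."""

    positions: np.ndarray
    dt: float                       # frame interval, ns
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_particles, n_frames, 2)")
        if self.dt <= 0:
            raise ValueError("frame interval must be positive")
        if not self.labels:
            self.labels = ["particle"] * self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


@dataclass
class JdaFit:
    """Fitted jump-distance mixture: components are (D, fraction) pairs.

    D in 1e-7 cm^2 s^-1; fractions sum to 1 after pruning. ``d_uncertainty``
    holds the sd of each component D over contiguous trajectory segments
    (NaN when the fit was made from pooled jumps without segment structure).
    """

    lag: float
    components: list[tuple[float, float]]
    residual: float                 # mean negative log-likelihood per jump
    d_uncertainty: list[float]
    n_jumps: int
    log_likelihood: float

    def __post_init__(self) -> None:
        fr = np.array([f for _, f in self.components])
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must be non-negative and sum to 1")
        if any(d < 0 for d, _ in self.components):
            raise ValueError("diffusion coefficients must be non-negative")

    @property
    def d(self) -> float:
        """Fraction-weighted mean D (equals the component D for one component)."""
        return float(sum(d * f for d, f in self.components))


class FitError(RuntimeError):
    """Mixture fit failed to converge."""


# ---------------------------------------------------------------------------
# Track extraction
# ---------------------------------------------------------------------------

def unwrap_tracks(traj: Trajectory, atoms: AtomSet) -> TrackSet:
    """Undo periodic wrapping of lateral positions by minimum-image steps.

    Each consecutive-frame displacement is replaced by its minimum image
    before cumulative summation; the first frame anchors the track at its
    wrapped coordinates. Steps whose minimum image reaches box/2 are counted
    and reported as a warning — at that point the true displacement is
    ambiguous (undersampled trajectory).
    """
    idx = atoms.indices
    n_frames = traj.n_frames
    pos = np.empty((len(idx), n_frames, 2))
    pos[:, 0, :] = traj.frames[0].coordinates[idx, :2]
    suspect = 0
    for t in range(1, n_frames):
        prev = traj.frames[t - 1].coordinates[idx, :2]
        cur = traj.frames[t].coordinates[idx, :2]
        box = traj.frames[t].box[:2]
        raw = cur - prev
        step = np.column_stack([
            wrap_displacement(raw[:, 0], box[0]),
            wrap_displacement(raw[:, 1], box[1]),
        ])
        suspect += int(np.sum(np.abs(step) >= box / 2.0 * (1 - 1e-12)))
        pos[:, t, :] = pos[:, t - 1, :] + step
    if suspect:
        warnings.warn(
            f"unwrap_tracks: {suspect} steps at or beyond box/2; "
            "trajectory may be undersampled", stacklevel=2)
    times = traj.times
    dt = float(times[1] - times[0]) if n_frames > 1 else 1.0
    labels = [traj.topology.molecule_labels.get(int(m), "particle")
              for m in traj.topology.molecule_ids[idx]]
    return TrackSet(pos, dt, labels)


def jump_distances(tracks: TrackSet, lag: float) -> np.ndarray:
    """All lateral jump magnitudes |r(t+lag) - r(t)|, overlapping origins."""
    ratio = lag / tracks.dt
    lag_frames = int(round(ratio))
    if abs(ratio - lag_frames) > 1e-6 or lag_frames < 1:
        raise ValueError(f"lag {lag} ns is not a positive multiple of dt={tracks.dt} ns")
    if lag_frames >= tracks.n_frames:
        raise ValueError("lag exceeds track duration")
    disp = tracks.positions[:, lag_frames:, :] - tracks.positions[:, :-lag_frames, :]
    return np.hypot(disp[..., 0], disp[..., 1]).ravel()


# ---------------------------------------------------------------------------
# JDA mixture fitting
# ---------------------------------------------------------------------------

def _em_exponential_mixture(u: np.ndarray, mu0: np.ndarray, f0: np.ndarray,
                            max_iter: int = 600, tol: float = 1e-8):
    """EM for a mixture of exponentials; returns (mu, f, loglik)."""
    mu = mu0.copy()
    f = f0.copy()
    n = len(u)
    prev_ll = -np.inf
    for _ in range(max_iter):
        with np.errstate(over="ignore", under="ignore"):
            dens = f[None, :] / mu[None, :] * np.exp(-u[:, None] / mu[None, :])
        tot = dens.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.log(tot).sum())
        gamma = dens / tot[:, None]
        nk = gamma.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = (gamma * u[:, None]).sum(axis=0) / nk
        mu = np.maximum(mu, 1e-12)
        f = nk / n
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    else:
        raise FitError("EM did not converge within the iteration budget")
    return mu, f, prev_ll


def fit_jda(jumps: np.ndarray, lag: float, n_components: int = 1,
            seed: int = 0, min_fraction: float = 0.01) -> JdaFit:
    """Maximum-likelihood fit of the jump-distance mixture density.

    Deterministic given ``seed`` (a fixed multi-start schedule: quantile
    splits plus seeded perturbations). Components with fitted fraction below
    ``min_fraction`` are pruned with a warning and the remainder refitted.
    """
    r = np.asarray(jumps, dtype=float)
    if len(r) < 100:
        raise ValueError("JDA needs at least 100 jumps")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    u = r**2
    mean_u = u.mean()
    if mean_u == 0.0:
        return JdaFit(lag, [(0.0, 1.0)], 0.0, [float("nan")], len(r), 0.0)

    if n_components == 1:
        mu = np.array([mean_u])
        f = np.array([1.0])
        ll = float(np.sum(np.log(1.0 / mu[0]) - u / mu[0]))
    else:
        rng = np.random.default_rng(seed)
        starts = []
        qs = np.linspace(0.15, 0.85, n_components)
        starts.append(np.maximum(np.quantile(u, qs), 1e-12))
        starts.append(mean_u * np.geomspace(0.3, 3.0, n_components))
        starts.append(mean_u * rng.uniform(0.2, 3.0, n_components))
        best = None
        for mu0 in starts:
            try:
                mu_i, f_i, ll_i = _em_exponential_mixture(
                    u, np.sort(mu0), np.full(n_components, 1.0 / n_components))
            except FitError:
                continue
            if best is None or ll_i > best[2]:
                best = (mu_i, f_i, ll_i)
        if best is None:
            raise FitError("all EM starts failed to converge")
        mu, f, ll = best

    keep = f >= min_fraction
    if not keep.any():
        keep = f == f.max()  # never prune the dominant component
    if not keep.all():
        warnings.warn(
            f"fit_jda: pruned {int((~keep).sum())} degenerate component(s) "
            f"with fraction < {min_fraction}", stacklevel=2)
        mu, f, ll = _em_exponential_mixture(
            u, mu[keep], f[keep] / f[keep].sum())

    # r^2 ~ Exp(mean 4 D dt)  ->  D = mu / (4 dt), then to 1e-7 cm^2/s.
    d_nm = mu / (4.0 * lag)
    order = np.argsort(d_nm)
    comps = [(float(d_nm[i] * NM2_PER_NS_TO_1E7_CM2_S), float(f[i])) for i in order]
    # normalise away float drift so the invariant holds exactly
    tot_f = sum(fr for _, fr in comps)
    comps = [(d, fr / tot_f) for d, fr in comps]
    # log-likelihood in r includes the Jacobian r -> r^2 terms; report the
    # r-space value for diagnostics
    ll_r = ll + float(np.sum(np.log(np.maximum(2.0 * r, 1e-300))))
    return JdaFit(lag, comps, -ll_r / len(r), [float("nan")] * len(comps), len(r), ll_r)


def jda_with_uncertainty(tracks: TrackSet, lag: float, n_components="auto",
                         n_segments: int = 5, seed: int = 0,
                         bic_margin: float = 10.0) -> JdaFit:
    """JDA on pooled jumps with segment-wise D uncertainties and BIC selection.

    With ``n_components="auto"`` a one- and a two-component model are fitted
    and the two-component model is reported only if its BIC is better by
    more than ``bic_margin`` (species tables conventionally carry a single
    coefficient). Uncertainty per component D is the sd over ``n_segments``
    contiguous time segments, refitted independently.
    """
    jumps = jump_distances(tracks, lag)
    if n_components == "auto":
        fit1 = fit_jda(jumps, lag, 1, seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit2 = fit_jda(jumps, lag, 2, seed)
        except FitError:
            fit2 = None
        fit = fit1
        if fit2 is not None and len(fit2.components) == 2:
            bic1 = -2 * fit1.log_likelihood + 1 * np.log(fit1.n_jumps)
            bic2 = -2 * fit2.log_likelihood + 3 * np.log(fit2.n_jumps)
            if bic1 - bic2 > bic_margin:
                fit = fit2
                logger.info("JDA model selection: two components preferred "
                            "(dBIC=%.1f)", bic1 - bic2)
    else:
        fit = fit_jda(jumps, lag, int(n_components), seed)

    # segment-wise refits for uncertainties
    lag_frames = int(round(lag / tracks.dt))
    bounds = np.linspace(0, tracks.n_frames, n_segments + 1).astype(int)
    seg_ds = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a <= lag_frames:
            continue
        seg = TrackSet(tracks.positions[:, a:b, :], tracks.dt, tracks.labels)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                seg_fit = fit_jda(jump_distances(seg, lag), lag,
                                  len(fit.components), seed)
        except (ValueError, FitError):
            continue
        if len(seg_fit.components) == len(fit.components):
            seg_ds.append([d for d, _ in seg_fit.components])
    if len(seg_ds) > 1:
        sds = np.std(np.array(seg_ds), axis=0, ddof=1)
        fit.d_uncertainty = [float(s) for s in sds]
    return fit


# ---------------------------------------------------------------------------
# MSD cross-check
# ---------------------------------------------------------------------------

def msd_curve(tracks: TrackSet, max_lag_frames: int | None = None):
    """Ensemble- and time-origin-averaged MSD(t); MSD(0) = 0 by construction."""
    n_frames = tracks.n_frames
    if max_lag_frames is None:
        max_lag_frames = n_frames - 1
    max_lag_frames = min(max_lag_frames, n_frames - 1)
    lags = np.arange(max_lag_frames + 1)
    msd = np.zeros(len(lags))
    for i, k in enumerate(lags):
        if k == 0:
            continue
        disp = tracks.positions[:, k:, :] - tracks.positions[:, :-k, :]
        msd[i] = np.mean(np.sum(disp**2, axis=-1))
    return lags * tracks.dt, msd


def msd_diffusion(tracks: TrackSet, fit_window: tuple[float, float]) -> float:
    """D from the slope of MSD(t) over ``fit_window`` (2D: slope / 4).

    Returned in 1e-7 cm^2 s^-1. A negative fitted slope is reported as-is
    with a warning so that pathological inputs are visible, not masked.
    """
    t_min, t_max = fit_window
    duration = (tracks.n_frames - 1) * tracks.dt
    if not (0 <= t_min < t_max <= duration):
        raise ValueError("fit window must lie within the track duration")
    times, msd = msd_curve(tracks, max_lag_frames=int(np.ceil(t_max / tracks.dt)))
    sel = (times >= t_min) & (times <= t_max)
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than two MSD points")
    slope, _ = np.polyfit(times[sel], msd[sel], 1)
    if slope < 0:
        warnings.warn("msd_diffusion: negative fitted slope", stacklevel=2)
    return float(slope / 4.0 * NM2_PER_NS_TO_1E7_CM2_S)


# ---------------------------------------------------------------------------
# Ratios
# ---------------------------------------------------------------------------

def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return float(round(x, -int(floor(log10(abs(x)))) + (sig - 1)))


def diffusion_ratio(d_a: float, d_b: float) -> float:
    """d_a / d_b to 2 significant figures (the convention for mobility ratios)."""
    if d_b == 0:
        raise ZeroDivisionError("denominator diffusion coefficient is zero")
    return round_sig(d_a / d_b, 2)
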