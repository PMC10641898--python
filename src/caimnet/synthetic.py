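"""Ground-truth simulator for the whole pipeline.

Generates treadmill speed with planted run bouts, the two-sensor streams
that would have produced that speed, sparse GCaMP-like dF/F traces with
known event times, movement modulation and shared-source pair
correlations, and small translated video stacks for registration tests.

Default rates and bout statistics emulate CA1 recordings at 20 Hz:
roughly 2 events/min per cell at rest, ~2.8 events/min during running for
movement-modulated cells, and ~20 run bouts of ~13 s in a 10-minute
session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .behavior import SpeedTrace
from .imaging import FluorescenceTrace, RoiSet


@dataclass
class SimConfig:
    """Study conditions for one simulated session."""

    duration_s: float = 600.0
    fs: float = 20.0
    n_cells: int = 50
    rest_rate: float = 1.71  # events/min per cell at rest
    run_rate: float = 2.79  # events/min per cell while running (modulated cells)
    rise_s: float = 0.5  # event kernel linear-rise duration
    decay_s: float = 1.0  # event kernel exponential-decay time constant
    amp_mean: float = 0.5  # dF/F units before normalization
    amp_sd: float = 0.1
    noise_sd: float = 0.02
    bout_mean_s: float = 12.8
    n_bouts: int = 20
    run_speed: float = 10.0  # cm/s plateau during run bouts
    shared_fraction: float = 0.0  # P(group member copies a shared-source event)
    correlated_pair_fraction: float = 0.0  # fraction of disjoint cell groups sharing a source
    source_group_size: int = 2  # cells per shared source (2 = independent pairs)
    rest_only_source_fraction: float = 0.0  # fraction of shared sources active only at rest
    source_rate: float = 2.0  # events/min of each shared source train
    modulated_fraction: float = 0.257
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rest_rate < 0 or self.run_rate < 0 or self.source_rate < 0:
            raise ValueError("rates must be non-negative")
        for name in ("shared_fraction", "modulated_fraction",
                     "correlated_pair_fraction", "rest_only_source_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(self.duration_s * self.fs - round(self.duration_s * self.fs)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def rng(self, stream: int = 0) -> np.random.Generator:
        # fixed per-purpose substreams so adding a stage never perturbs others
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    true_event_onsets: list[np.ndarray]  # sample indices per cell
    true_bouts: list[tuple[int, int]]  # half-open run intervals
    true_modulated: np.ndarray  # boolean per cell
    true_correlated_pairs: list[tuple[int, int, float]] = field(default_factory=list)


def simulate_speed(cfg: SimConfig) -> tuple[SpeedTrace, list[tuple[int, int]]]:
    """Speed trace with ``cfg.n_bouts`` disjoint run bouts planted in rest.

    Rest is near-zero with small non-negative jitter; run bouts plateau
    around ``cfg.run_speed`` (never below 5 cm/s mean) with half-second
    cosine ramps, and are at least 3 s long so the 2-s segmentation rule
    recovers them.
    """
    rng = cfg.rng(stream=1)
    n = cfg.n_samples
    fs = cfg.fs
    v = np.abs(rng.normal(0.0, 0.3, size=n))  # rest jitter, >= 0
    bouts: list[tuple[int, int]] = []
    if cfg.n_bouts > 0:
        durs = np.clip(rng.exponential(cfg.bout_mean_s, size=cfg.n_bouts), 3.0, None)
        min_gap = 3.0
        total_needed = durs.sum() + min_gap * (cfg.n_bouts + 1)
        if total_needed > cfg.duration_s:
            durs *= (cfg.duration_s - min_gap * (cfg.n_bouts + 1)) / durs.sum()
            durs = np.clip(durs, 3.0, None)
        slack = max(cfg.duration_s - durs.sum() - min_gap * (cfg.n_bouts + 1), 0.0)
        extra = rng.dirichlet(np.ones(cfg.n_bouts + 1)) * slack
        cursor = min_gap + extra[0]
        ramp_n = max(int(round(0.5 * fs)), 1)
        for k in range(cfg.n_bouts):
            s = int(round(cursor * fs))
            e = min(int(round((cursor + durs[k]) * fs)), n)
            if e - s >= int(3 * fs):
                plateau = max(cfg.run_speed * rng.uniform(0.8, 1.2), 6.0)
                prof = np.full(e - s, plateau)
                m = min(ramp_n, (e - s) // 2)
                ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, m)))
                prof[:m] *= ramp
                prof[-m:] *= ramp[::-1]
                prof += rng.normal(0.0, 0.3, size=e - s)
                v[s:e] = np.maximum(prof, 0.0)
                bouts.append((s, e))
            cursor += durs[k] + min_gap + extra[k + 1]
    t = np.arange(n) / fs
    return SpeedTrace(t, v, fs=fs), bouts


def simulate_sensors(
    speed: SpeedTrace,
    theta: float,
    heading: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two sensor streams whose velocity decomposition reproduces ``speed``.

    The animal's heading splits speed into perpendicular components
    ``X = V cos(phi)``, ``Y = V sin(phi)``; the right sensor reads ``R = Y``
    and the left sensor ``L = X sin(theta) + R cos(theta)``, the exact
    inverse of :func:`caimnet.behavior.compute_velocity`.
    """
    if not 0.0 < theta < np.pi:
        raise ValueError("theta must lie strictly between 0 and pi")
    v = speed.v
    if heading is None:
        phi = np.full(v.size, 0.5)
    else:
        phi = np.broadcast_to(np.asarray(heading, dtype=float), v.shape)
    X = v * np.cos(phi)
    Y = v * np.sin(phi)
    R = Y
    L = X * np.sin(theta) + R * np.cos(theta)
    return L, R


def event_kernel(rise_s: float, decay_s: float, fs: float) -> np.ndarray:
    """Unit-amplitude kernel: linear rise over ``rise_s``, then exp decay."""
    nr = max(int(round(rise_s * fs)), 1)
    nd = max(int(round(5.0 * decay_s * fs)), 1)
    rise = np.linspace(0.0, 1.0, nr + 1)[1:]
    decay = np.exp(-np.arange(1, nd + 1) / (decay_s * fs))
    return np.concatenate([rise, decay])


def _thin_onsets(onsets: np.ndarray, min_sep: int) -> np.ndarray:
    kept: list[int] = []
    last = -min_sep - 1
    for o in onsets:
        if o - last >= min_sep:
            kept.append(int(o))
            last = o
    return np.asarray(kept, dtype=int)


def simulate_traces(
    cfg: SimConfig,
    true_bouts: list[tuple[int, int]],
) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Sparse-event dF/F traces with known onsets, modulation, and pairing.

    Modulated cells draw onsets from an inhomogeneous Bernoulli process at
    ``run_rate`` inside run bouts and ``rest_rate`` elsewhere;
    non-modulated cells use ``rest_rate`` throughout.  Correlated pairs
    additionally copy events, independently with probability
    ``shared_fraction``, from a latent Poisson source train shared by the
    pair.  Traces are min-max normalized to [0, 1].
    """
    rng = cfg.rng(stream=2)
    n = cfg.n_samples
    fs = cfg.fs
    run_mask = np.zeros(n, dtype=bool)
    for s, e in true_bouts:
        run_mask[s:e] = True

    n_mod = int(round(cfg.modulated_fraction * cfg.n_cells))
    modulated = np.zeros(cfg.n_cells, dtype=bool)
    modulated[rng.choice(cfg.n_cells, size=n_mod, replace=False)] = True
    if cfg.rest_rate == cfg.run_rate:
        modulated[:] = False  # no rate contrast: nothing is truly modulated

    # shared sources over disjoint consecutive cell groups (0..g-1), (g..2g-1), ...
    g = max(int(cfg.source_group_size), 2)
    group_ids = [tuple(range(g * k, g * (k + 1)))
                 for k in range(cfg.n_cells // g)]
    n_corr = int(round(cfg.correlated_pair_fraction * len(group_ids)))
    corr_groups = group_ids[:n_corr] if cfg.shared_fraction > 0 else []
    source_events: dict[tuple[int, ...], np.ndarray] = {}
    p_src = cfg.source_rate / 60.0 / fs
    min_sep = int(round((cfg.rise_s + 2.0 * cfg.decay_s) * fs))
    for idx, group in enumerate(corr_groups):
        draws = rng.random(n) < p_src
        if cfg.rest_only_source_fraction > 0 and (
            idx < cfg.rest_only_source_fraction * len(corr_groups)
        ):
            draws &= ~run_mask
        source_events[group] = _thin_onsets(np.flatnonzero(draws), min_sep)

    kernel = event_kernel(cfg.rise_s, cfg.decay_s, fs)
    nr = max(int(round(cfg.rise_s * fs)), 1)
    onsets_per_cell: list[np.ndarray] = []
    traces: list[FluorescenceTrace] = []
    side = int(np.ceil(np.sqrt(cfg.n_cells)))
    for i in range(cfg.n_cells):
        p = np.where(run_mask & modulated[i], cfg.run_rate, cfg.rest_rate) / 60.0 / fs
        own = np.flatnonzero(rng.random(n) < p)
        shared = []
        for group, src in source_events.items():
            if i in group and src.size:
                keep = rng.random(src.size) < cfg.shared_fraction
                shared.append(src[keep])
        onsets = np.unique(np.concatenate([own] + shared)) if shared else own
        onsets = _thin_onsets(onsets, min_sep)
        x = np.zeros(n)
        for o in onsets:
            amp = max(rng.normal(cfg.amp_mean, cfg.amp_sd), 0.05)
            seg = kernel[: n - o]
            x[o : o + seg.size] += amp * seg
        if cfg.noise_sd > 0:
            x += rng.normal(0.0, cfg.noise_sd, size=n)
        lo, hi = x.min(), x.max()
        if hi - lo > 1e-12:
            x = (x - lo) / (hi - lo)
        centroid = (60.0 + 40.0 * (i % side), 60.0 + 40.0 * (i // side))
        traces.append(FluorescenceTrace(cell_id=i, values=x, centroid=centroid, fs=fs))
        onsets_per_cell.append(onsets)

    corr_pairs = [
        (a, b, cfg.shared_fraction)
        for group in corr_groups
        for k, a in enumerate(group)
        for b in group[k + 1:]
    ]
    truth = GroundTruth(
        true_event_onsets=onsets_per_cell,
        true_bouts=list(true_bouts),
        true_modulated=modulated,
        true_correlated_pairs=corr_pairs,
    )
    return traces, truth


def simulate_session(cfg: SimConfig):
    """Convenience wrapper: speed, bouts, traces and ground truth together."""
    speed, bouts = simulate_speed(cfg)
    traces, truth = simulate_traces(cfg, bouts)
    return speed, traces, truth


def simulate_video(
    cfg: SimConfig,
    shifts: np.ndarray,
    frame_shape: tuple[int, int] = (128, 128),
    n_cells: int = 8,
    cell_sigma_px: float = 3.0,
    noise_sd: float = 0.01,
) -> tuple[np.ndarray, RoiSet]:
    """Translated copies of a Gaussian-blob scene with known per-frame shifts.

    Frame ``k`` is the reference scene rolled by ``shifts[k] = (dy, dx)``
    plus Gaussian noise.  Shifts must stay within a 16-px margin of the
    frame edge.  ROI truth (masks, centroids) is in reference coordinates.
    """
    shifts = np.asarray(shifts, dtype=int)
    h, w = frame_shape
    margin = 16
    if np.abs(shifts).max(initial=0) >= margin:
        raise ValueError(f"shifts must be smaller than the {margin}-px margin")
    rng = cfg.rng(stream=3)
    yy, xx = np.mgrid[0:h, 0:w]
    ref = np.zeros((h, w))
    masks, cents = [], []
    for _ in range(n_cells):
        cx = rng.uniform(margin + 10, w - margin - 10)
        cy = rng.uniform(margin + 10, h - margin - 10)
        blob = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * cell_sigma_px**2))
        ref += blob
        masks.append(blob > 0.3)
        cents.append((cx, cy))
    frames = np.empty((shifts.shape[0], h, w))
    for k, (dy, dx) in enumerate(shifts):
        frames[k] = np.roll(ref, (dy, dx), axis=(0, 1))
        if noise_sd > 0:
            frames[k] += rng.normal(0.0, noise_sd, size=(h, w))
    return frames, RoiSet(masks=masks, centroids=np.asarray(cents))
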