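"""Synthetic data emulating the batch and mother-machine experiments.

Two generators are provided:

* :func:`generate_batch_dataset` wraps :func:`viralshunt.dynamics.simulate`
  and draws replicate OD600 observations around the model curve with
  multiplicative lognormal noise, emulating four biological replicates
  sampled hourly from an OD 0.01 start.
* :func:`generate_track_cohort` emulates mother-machine time-lapse data:
  cells grow exponentially in length, divide at a fixed threshold, and are
  observed every 5 min over 6 h with multiplicative length noise; a
  configurable fraction of lineages drifts past the chamber-exit position to
  exercise the pipeline's exit filter.

Everything is seeded explicitly; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import DEFAULT_GLUCOSE_OD, InitialState, ModelParams, SolverConfig, simulate
from .inference import GrowthCurveDataset
from .single_cell import CellTrack

__all__ = [
    "MixDesign",
    "BatchNoiseModel",
    "TrackCohortSpec",
    "scenario_presets",
    "generate_batch_dataset",
    "generate_batch_suite",
    "generate_track_cohort",
]


@dataclass(frozen=True)
class MixDesign:
    """An inoculum design: WT/TS split of the initial optical density."""

    label: str
    wt_fraction: float
    ts_fraction: float
    initial_od: float

    def __post_init__(self):
        if not np.isclose(self.wt_fraction + self.ts_fraction, 1.0):
            raise ValueError("wt_fraction + ts_fraction must equal 1")
        if self.initial_od <= 0:
            raise ValueError("initial_od must be positive")


def scenario_presets() -> list[MixDesign]:
    """The six batch-culture designs of the study.

    Four mixes at total OD600 0.01 (100WT, 73WT-27TS, 19WT-81TS, 100TS) plus
    the two WT-only controls inoculated at the matching reduced OD (73WT at
    0.0073, 19WT at 0.0019) that serve as no-lysis references.
    """
    return [
        MixDesign("100WT", 1.0, 0.0, 0.01),
        MixDesign("73WT", 1.0, 0.0, 0.0073),
        MixDesign("19WT", 1.0, 0.0, 0.0019),
        MixDesign("73WT-27TS", 0.73, 0.27, 0.01),
        MixDesign("19WT-81TS", 0.19, 0.81, 0.01),
        MixDesign("100TS", 0.0, 1.0, 0.01),
    ]


@dataclass(frozen=True)
class BatchNoiseModel:
    """Replicate observation model for batch OD600 curves.

    ``od_cv`` is the multiplicative lognormal noise scale: replicate
    observations are ``od * exp(N(0, od_cv))``, so the replicate mean carries
    a small lognormal bias of ~od_cv**2/2 relative to the model curve.
    """

    od_cv: float = 0.05
    n_replicates: int = 4
    sampling_interval: float = 1.0  # h
    t_end: float = 10.0  # h
    od_floor: float = 1e-5  # positivity floor for fully lysed cultures, OD units

    def __post_init__(self):
        if self.od_cv < 0:
            raise ValueError("od_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.od_floor <= 0:
            raise ValueError("od_floor must be positive")


def generate_batch_dataset(
    params: ModelParams,
    design: MixDesign,
    noise: BatchNoiseModel | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    c_g0: float = DEFAULT_GLUCOSE_OD,
    solver_cfg: SolverConfig | None = None,
) -> GrowthCurveDataset:
    """Simulate one mix and draw noisy replicate OD observations."""
    noise = noise or BatchNoiseModel()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, noise.t_end + 1e-9, noise.sampling_interval)
    init = InitialState(
        B_WT0=design.wt_fraction * design.initial_od,
        TS0=design.ts_fraction * design.initial_od,
        C_g0=c_g0,
    )
    traj = simulate(params, init, t_end=times[-1], solver_cfg=solver_cfg, t_eval=times)
    # a fully lysed culture decays toward zero OD; the floor keeps
    # observations positive (log-scale residuals must stay defined) while
    # sitting below every time point the staged fits actually use
    od = np.maximum(traj.od, noise.od_floor)
    if noise.od_cv > 0:
        draws = od[:, None] * np.exp(
            rng.normal(0.0, noise.od_cv, size=(times.size, noise.n_replicates))
        )
    else:
        draws = np.repeat(od[:, None], noise.n_replicates, axis=1)
    return GrowthCurveDataset(
        mix_label=design.label,
        wt_fraction=design.wt_fraction,
        ts_fraction=design.ts_fraction,
        initial_od=design.initial_od,
        times=times,
        replicates=draws,
    )


def generate_batch_suite(
    params: ModelParams,
    noise: BatchNoiseModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    designs: list[MixDesign] | None = None,
    c_g0: float = DEFAULT_GLUCOSE_OD,
) -> dict[str, GrowthCurveDataset]:
    """Generate the full preset scenario suite (independent noise per mix)."""
    designs = designs if designs is not None else scenario_presets()
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = ss.spawn(len(designs))
    return {
        d.label: generate_batch_dataset(params, d, noise, child, c_g0=c_g0)
        for d, child in zip(designs, children)
    }


def _default_conditions() -> dict[str, tuple[float, float]]:
    # supernatant-exposure conditions: mean +/- between-cell SD, h^-1
    return {"WT-sn": (0.54, 0.09), "WT-TS-sn": (0.61, 0.09), "TS-sn": (0.62, 0.10)}


@dataclass(frozen=True)
class TrackCohortSpec:
    """Design of a synthetic mother-machine cohort.

    ``conditions`` maps a condition label to the (mean, between-cell SD) of
    single-cell elongation rates in h^-1; defaults mirror the three
    supernatant-exposure conditions of the study.  ``n_cells`` is the number
    of lineage slots per condition and replicate; each slot yields one track
    per cell generation (tracks split at division).  Rates are redrawn per
    generation, so between-cell dispersion includes between-generation
    variation.
    """

    conditions: dict[str, tuple[float, float]] = field(default_factory=_default_conditions)
    n_cells: int = 300
    n_replicates: int = 4
    frame_interval: float = 5.0  # min
    duration: float = 6.0  # h
    length_noise_cv: float = 0.02
    birth_length: float = 2.0  # um
    division_length: float = 4.0  # um
    exit_fraction: float = 0.05
    chamber_length: float = 25.0  # um

    def __post_init__(self):
        if any(m <= 0 for m, _ in self.conditions.values()):
            raise ValueError("condition mean rates must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.division_length <= self.birth_length:
            raise ValueError("division_length must exceed birth_length")


def generate_track_cohort(
    spec: TrackCohortSpec, seed: int | np.random.SeedSequence = 0
) -> list[CellTrack]:
    """Generate tracks for all conditions and replicates of ``spec``.

    Per lineage slot: an initial cell of length ``birth_length * 2**u``
    (u ~ U(0,1), i.e. uniform cell age) grows exponentially at a rate drawn
    from the condition's truncated-at-zero normal distribution, divides
    (length halves) on reaching ``division_length``, and the daughter — with
    a freshly drawn rate — continues under a new track id.  Observed lengths
    carry multiplicative lognormal noise.  A fraction ``exit_fraction`` of
    slots drifts toward the chamber exit, with late-frame x-positions beyond
    80% of the chamber length.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(spec.duration * 60.0 / spec.frame_interval)) + 1
    frame_times = np.arange(n_frames) * spec.frame_interval  # min
    x_exit = 0.8 * spec.chamber_length
    tracks: list[CellTrack] = []

    def draw_rate(mean: float, sd: float) -> float:
        if sd == 0:
            return mean
        r = rng.normal(mean, sd)
        while r <= 0:
            r = rng.normal(mean, sd)
        return r

    for cond, (mean, sd) in spec.conditions.items():
        for rep in range(1, spec.n_replicates + 1):
            for slot in range(spec.n_cells):
                exits = rng.random() < spec.exit_fraction
                if exits:
                    # drift past the exit threshold in the last third of frames
                    x_path = np.linspace(
                        0.5 * x_exit, 1.15 * x_exit + rng.uniform(0, 2), n_frames
                    )
                else:
                    x_path = np.full(n_frames, rng.uniform(0.1, 0.6) * x_exit)
                # start at a geometrically uniform point of a birth -> 2x
                # cycle (never at or beyond the division threshold)
                length0 = min(
                    spec.birth_length * 2 ** rng.random(),
                    0.999 * spec.division_length,
                )
                t_seg = 0.0  # min, birth time of the current generation
                seg = 0
                while t_seg <= frame_times[-1]:
                    rate = draw_rate(mean, sd)
                    t_div = t_seg + 60.0 * np.log(spec.division_length / length0) / rate
                    mask = (frame_times >= t_seg) & (frame_times < t_div)
                    if mask.any():
                        in_seg = frame_times[mask]
                        true_len = length0 * np.exp(rate * (in_seg - t_seg) / 60.0)
                        if spec.length_noise_cv > 0:
                            obs = true_len * np.exp(
                                rng.normal(0, spec.length_noise_cv, in_seg.size)
                            )
                        else:
                            obs = true_len
                        tracks.append(
                            CellTrack(
                                track_id=f"{cond}-r{rep}-c{slot}-g{seg}",
                                condition=cond,
                                replicate=f"r{rep}",
                                times_min=in_seg.copy(),
                                lengths_um=obs,
                                x_um=x_path[mask],
                            )
                        )
                    t_seg = t_div
                    length0 = spec.division_length / 2.0
                    seg += 1
    return tracks
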