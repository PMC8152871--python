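"""Synthetic BOLD cohort generator with full ground truth.

Emulates the study design the analysis consumes: 6 runs per
participant, 128 volumes per run at TR = 2 s, 32 trials per run (4 per
each of 8 sentence conditions, 6-s stimulus + 2-s blank), three groups
(16 control / 9 / 9 patients).  Region series are AR(1)-filtered
Gaussian innovations whose covariance is the inverse of a planted
precision matrix Omega — so the population partial correlations are
known exactly — plus an HRF-convolved task signal and white measurement
noise.  Two connectivity states are planted: the harder-load state adds
cross-frontal between-network edges (enhancement) and weakens two
within-network pathway edges (suppression), mirroring the qualitative
load-dependent reorganization the analysis is designed to detect.  All
edge magnitudes are illustrative package constants, not empirical
values.

Behavioral tables are drawn from truncated normals with planted
condition effects (harder > easier error rates and response times,
extra elevation for patient groups under the potential-sentence
conditions).

Every operation is reproducible from a single master seed via
fixed per-group/participant/run substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .catalog import RegionCatalog, default_catalog
from .connectivity import population_partial_corr
from .roi import RoiTimeSeriesSet, RoiError, sphere_mask

__all__ = [
    "CONDITIONS",
    "RunDesign",
    "Trial",
    "GenerativeSpec",
    "GroundTruth",
    "SimulateError",
    "build_run_design",
    "default_generative_spec",
    "simulate_participant",
    "render_volumes",
    "simulate_behavior",
    "canonical_hrf",
]

CONDITIONS = ("Act", "Act+", "Pas", "Pas+", "Pot", "Pot+", "One", "Cont")
_EASIER = frozenset({"Act", "Act+", "Pas"})
_HARDER = frozenset({"Pas+", "Pot", "Pot+"})

#: flag threshold the planted structure is designed around (r units)
_PLANT_THRESHOLD = 0.20


class SimulateError(ValueError):
    """Raised for invalid generative specifications."""


@dataclass(frozen=True)
class Trial:
    condition: str
    onset_s: float
    stimulus_s: float
    blank_s: float


@dataclass(frozen=True)
class RunDesign:
    """One run: ordered trials, sampling interval, and volume count."""

    trials: tuple[Trial, ...]
    tr_s: float
    n_volumes: int

    def __post_init__(self) -> None:
        total = sum(t.stimulus_s + t.blank_s for t in self.trials)
        if abs(self.n_volumes * self.tr_s - total) > 1e-9:
            raise SimulateError(
                f"volumes x TR = {self.n_volumes * self.tr_s} s but trials "
                f"total {total} s"
            )

    @property
    def total_duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s

    def condition_boxcar(self, condition: str) -> np.ndarray:
        """1 during the condition's stimulus windows, sampled at volume times."""
        t = self.volume_times()
        box = np.zeros_like(t)
        for trial in self.trials:
            if trial.condition == condition:
                box[(t >= trial.onset_s) & (t < trial.onset_s + trial.stimulus_s)] = 1.0
        return box

    def volume_states(self) -> np.ndarray:
        """Connectivity state per volume: 'easier', 'harder' or 'mixture'.

        A volume takes the load state of the trial (stimulus + blank)
        covering it; harder-load conditions are Pas+, Pot and Pot+; the
        one-argument and control conditions count as easier load.
        """
        t = self.volume_times()
        states = np.full(self.n_volumes, "mixture", dtype=object)
        for trial in self.trials:
            inside = (t >= trial.onset_s) & (
                t < trial.onset_s + trial.stimulus_s + trial.blank_s
            )
            states[inside] = "harder" if trial.condition in _HARDER else "easier"
        return states


def build_run_design(
    trials_per_condition: int = 4,
    stimulus_s: float = 6.0,
    blank_s: float = 2.0,
    tr_s: float = 2.0,
    seed: int = 0,
) -> RunDesign:
    """Pseudorandomized event-related run design.

    Conditions are block-randomized: each consecutive block of 8 trials
    contains every condition exactly once, so no condition clusters at
    either end of the run.  Defaults give the study design: 32 trials
    of 8 s (6-s stimulus + 2-s blank) = 256 s = 128 volumes at TR 2 s.
    """
    if tr_s <= 0:
        raise SimulateError("TR must be positive")
    trial_s = stimulus_s + blank_s
    total = trials_per_condition * len(CONDITIONS) * trial_s
    n_volumes = total / tr_s
    if abs(n_volumes - round(n_volumes)) > 1e-9:
        raise SimulateError(f"TR {tr_s} s does not divide the run duration {total} s")
    rng = np.random.default_rng(seed)
    order: list[str] = []
    for _ in range(trials_per_condition):
        block = list(CONDITIONS)
        rng.shuffle(block)
        order.extend(block)
    trials = tuple(
        Trial(cond, onset_s=k * trial_s, stimulus_s=stimulus_s, blank_s=blank_s)
        for k, cond in enumerate(order)
    )
    return RunDesign(trials=trials, tr_s=tr_s, n_volumes=int(round(n_volumes)))


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at TR.

    Peak gamma (shape 6, scale 1 s) minus a 1/6-weighted undershoot
    gamma (shape 16, scale 1 s), normalized to peak 1.
    """
    t = np.arange(0, duration_s + tr_s / 2, tr_s)
    peak = scipy.stats.gamma.pdf(t, a=6, scale=1.0)
    undershoot = scipy.stats.gamma.pdf(t, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure a recovery analysis is scored against."""

    precision_easier: np.ndarray
    precision_harder: np.ndarray
    region_names: tuple[str, ...]
    enhanced_pairs: tuple[tuple[str, str], ...]
    suppressed_pairs: tuple[tuple[str, str], ...]
    behavioral_error_effect: float
    behavioral_rt_effect: float

    def population_partial(self, state: str) -> np.ndarray:
        omega = {
            "easier": self.precision_easier,
            "harder": self.precision_harder,
            "combined": (self.precision_easier + self.precision_harder) / 2,
        }[state]
        return population_partial_corr(omega)


@dataclass(frozen=True)
class GenerativeSpec:
    """Everything needed to simulate a cohort, with planted ground truth.

    ``precision_easier``/``precision_harder`` are the state-wise
    innovation precision matrices (symmetric positive definite);
    ``ar_coef`` the per-region AR(1) coefficient; ``task_amplitude``
    per-region task signal scales (innovation-sd units);
    ``noise_sd`` the white measurement noise.  ``group_sizes`` gives
    participants per group, default 16 control / 9 / 9 patients.
    """

    catalog: RegionCatalog
    precision_easier: np.ndarray
    precision_harder: np.ndarray
    ar_coef: np.ndarray
    task_amplitude: np.ndarray
    condition_gain: Mapping[str, float]
    noise_sd: float = 0.3
    innovation_scale: float = 1.0
    hrf_duration_s: float = 32.0
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 16, "lpmc_f3": 9, "extra": 9}
    )
    runs_per_participant: int = 6
    trials_per_condition: int = 4
    stimulus_s: float = 6.0
    blank_s: float = 2.0
    tr_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.catalog)
        for label, omega in (
            ("easier", self.precision_easier),
            ("harder", self.precision_harder),
        ):
            omega = np.asarray(omega, dtype=float)
            if omega.shape != (p, p):
                raise SimulateError(f"{label} precision must be {p}x{p}")
            if not np.allclose(omega, omega.T, atol=1e-10):
                raise SimulateError(f"{label} precision must be symmetric")
            if np.linalg.eigvalsh(omega).min() <= 0:
                raise SimulateError(f"{label} precision is not positive definite")
            object.__setattr__(self, f"precision_{label}", omega)
        ar = np.broadcast_to(np.asarray(self.ar_coef, dtype=float), (p,)).copy()
        if np.any(np.abs(ar) >= 1):
            raise SimulateError("AR(1) coefficients must lie in (-1, 1)")
        object.__setattr__(self, "ar_coef", ar)
        amp = np.broadcast_to(np.asarray(self.task_amplitude, dtype=float), (p,)).copy()
        object.__setattr__(self, "task_amplitude", amp)

    def precision(self, state: str) -> np.ndarray:
        if state == "easier":
            return self.precision_easier
        if state == "harder":
            return self.precision_harder
        if state in ("combined", "mixture"):
            return (self.precision_easier + self.precision_harder) / 2
        raise SimulateError(f"unknown state {state!r}")

    def ground_truth(self) -> GroundTruth:
        names = self.catalog.names
        pe = population_partial_corr(self.precision_easier)
        ph = population_partial_corr(self.precision_harder)
        enhanced, suppressed = [], []
        p = len(names)
        for i in range(p):
            for j in range(i + 1, p):
                if ph[i, j] > _PLANT_THRESHOLD >= pe[i, j]:
                    enhanced.append((names[i], names[j]))
                if pe[i, j] > _PLANT_THRESHOLD >= ph[i, j]:
                    suppressed.append((names[i], names[j]))
        return GroundTruth(
            precision_easier=self.precision_easier,
            precision_harder=self.precision_harder,
            region_names=names,
            enhanced_pairs=tuple(enhanced),
            suppressed_pairs=tuple(suppressed),
            behavioral_error_effect=_ERROR_HARDER_MEAN - _ERROR_EASIER_MEAN,
            behavioral_rt_effect=_RT_HARDER_MEAN - _RT_EASIER_MEAN,
        )


def _chain_strengths() -> list[float]:
    # within-network edge strengths; values avoid the 0.16-0.24 window so
    # estimated edges stay clearly on one side of the 0.20 flag threshold
    return [0.30, 0.14, 0.32, 0.26, 0.10, 0.28, 0.12]


def _planted_partial_corr(
    catalog: RegionCatalog, state: Literal["easier", "harder"], structure_seed: int
) -> np.ndarray:
    """Target population partial-correlation pattern for one load state."""
    names = catalog.names
    idx = {n: k for k, n in enumerate(names)}
    p = len(names)
    P = np.zeros((p, p))

    def put(a: str, b: str, value: float) -> None:
        if a in idx and b in idx:
            P[idx[a], idx[b]] = P[idx[b], idx[a]] = value

    # within-network chains (same in both states): consecutive catalog
    # regions of each network, strengths cycling through a fixed spread
    strengths = _chain_strengths()
    k = 0
    by_network: dict[str, list[str]] = {}
    for region in catalog:
        by_network.setdefault(region.network, []).append(region.name)
    for network in sorted(by_network):
        members = by_network[network]
        for a, b in zip(members[:-1], members[1:]):
            put(a, b, strengths[k % len(strengths)])
            k += 1

    # load-suppressed pathway edges (within networks II and III):
    # strong under easier load, collapsed under harder load
    pathway = [("L_LPMC", "L_AG"), ("L_F3t", "L_pSTG/MTG")]
    for a, b in pathway:
        put(a, b, 0.34 if state == "easier" else 0.06)

    # load-enhanced cross-frontal edges (between networks): absent under
    # easier load, strong under harder load
    enhanced = [("L_F3t", "L_F3op/F3t"), ("L_F3op/F3t", "L_LPMC")]
    for a, b in enhanced:
        put(a, b, 0.0 if state == "easier" else 0.32)

    # weak structured "noise floor" on all remaining pairs, shared across
    # states: reproducible near-zero partial correlations
    rng = np.random.default_rng([structure_seed, 97])
    jitter = rng.uniform(-0.04, 0.04, size=(p, p))
    jitter = (jitter + jitter.T) / 2
    mask = (P == 0) & ~np.eye(p, dtype=bool)
    P[mask] = jitter[mask]
    return P


def default_generative_spec(
    catalog: RegionCatalog | None = None,
    seed: int = 0,
    structure_seed: int | None = None,
    **overrides,
) -> GenerativeSpec:
    """Study-condition generative spec over the packaged 25-region catalog.

    ``structure_seed`` fixes the weak noise-floor edges of the planted
    precision structure; drawing two specs with different structure
    seeds yields independently structured cohorts (the planted chains
    and load effects stay, the near-zero edge pattern differs).
    """
    if catalog is None:
        catalog = default_catalog()
    if structure_seed is None:
        structure_seed = seed
    p = len(catalog)
    precisions = {}
    for state in ("easier", "harder"):
        P = _planted_partial_corr(catalog, state, structure_seed)
        omega = np.eye(p) - P  # omega_ij = -p_ij, diag 1
        ev_min = np.linalg.eigvalsh(omega).min()
        if ev_min <= 0.05:
            raise SimulateError(
                f"planted {state} precision nearly singular (min eig {ev_min:.3f})"
            )
        precisions[state] = omega
    rng = np.random.default_rng([structure_seed, 131])
    amplitude = rng.uniform(0.2, 0.6, size=p)
    condition_gain = {c: (1.3 if c in _HARDER else 1.0) for c in CONDITIONS}
    condition_gain["One"] = 0.8
    condition_gain["Cont"] = 0.6
    defaults = dict(
        catalog=catalog,
        precision_easier=precisions["easier"],
        precision_harder=precisions["harder"],
        ar_coef=0.3,
        task_amplitude=amplitude,
        condition_gain=condition_gain,
        seed=seed,
    )
    defaults.update(overrides)
    return GenerativeSpec(**defaults)


def load_cohort_config(path) -> GenerativeSpec:
    """Build a generative spec from a YAML (or JSON) config file.

    Recognized keys mirror :func:`default_generative_spec`: ``seed``,
    ``structure_seed``, ``regions_table`` (path to a region TSV), and
    any :class:`GenerativeSpec` field override (``noise_sd``,
    ``ar_coef``, ``group_sizes``, ``runs_per_participant``, ...).
    """
    import yaml

    from .catalog import load_region_table

    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise SimulateError(f"{path}: config must be a mapping")
    catalog = None
    if "regions_table" in config:
        catalog = load_region_table(config.pop("regions_table"))
    seed = int(config.pop("seed", 0))
    structure_seed = config.pop("structure_seed", None)
    return default_generative_spec(
        catalog=catalog, seed=seed, structure_seed=structure_seed, **config
    )


def random_generative_spec(
    seed: int = 0, structure_seed: int | None = None, **overrides
) -> GenerativeSpec:
    """Spec with a fully random sparse precision structure (both states equal).

    For the no-shared-structure control: each pair gets an edge with
    probability 0.1 (strength 0.08-0.32, mostly positive) plus the weak
    noise floor; off-diagonals are shrunk geometrically if needed to
    keep the precision matrix well-conditioned.
    """
    if structure_seed is None:
        structure_seed = seed
    catalog = default_catalog()
    p = len(catalog)
    rng = np.random.default_rng([structure_seed, 211])
    P = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    edges = rng.random(len(iu[0])) < 0.1
    strength = rng.uniform(0.08, 0.32, size=len(iu[0]))
    sign = np.where(rng.random(len(iu[0])) < 0.8, 1.0, -1.0)
    vals = np.where(edges, strength * sign, rng.uniform(-0.04, 0.04, len(iu[0])))
    P[iu] = vals
    P = P + P.T
    omega = np.eye(p) - P
    while np.linalg.eigvalsh(omega).min() <= 0.05:
        P *= 0.9
        omega = np.eye(p) - P
    amp_rng = np.random.default_rng([structure_seed, 131])
    amplitude = amp_rng.uniform(0.2, 0.6, size=p)
    condition_gain = {c: (1.3 if c in _HARDER else 1.0) for c in CONDITIONS}
    condition_gain["One"] = 0.8
    condition_gain["Cont"] = 0.6
    defaults = dict(
        catalog=catalog,
        precision_easier=omega,
        precision_harder=omega,
        ar_coef=0.3,
        task_amplitude=amplitude,
        condition_gain=condition_gain,
        seed=seed,
    )
    defaults.update(overrides)
    return GenerativeSpec(**defaults)


def simulate_run(
    spec: GenerativeSpec,
    design: RunDesign,
    seed_entropy: Sequence[int],
    state: str = "combined",
    participant: str = "",
    run: str = "",
    state_switching: Literal["run", "trial"] = "run",
) -> RoiTimeSeriesSet:
    """One run of region series: AR(1) network innovations + task + noise.

    ``state_switching="run"`` simulates the whole run under ``state``
    (the mixture precision for "combined"); ``"trial"`` switches the
    innovation covariance volume-by-volume between the easier and
    harder precisions according to the trial covering each volume.
    """
    rng = np.random.default_rng(list(seed_entropy))
    p = len(spec.catalog)
    n_t = design.n_volumes

    if state_switching == "run":
        chol = np.linalg.cholesky(np.linalg.inv(spec.precision(state)))
        innovations = spec.innovation_scale * chol @ rng.standard_normal((p, n_t))
    elif state_switching == "trial":
        chols = {
            s: np.linalg.cholesky(np.linalg.inv(spec.precision(s)))
            for s in ("easier", "harder", "mixture")
        }
        states = design.volume_states()
        white = rng.standard_normal((p, n_t))
        innovations = np.empty((p, n_t))
        for t in range(n_t):
            innovations[:, t] = spec.innovation_scale * chols[states[t]] @ white[:, t]
    else:
        raise SimulateError(f"unknown state_switching {state_switching!r}")

    # AR(1) filter along time, per region
    signal = np.empty_like(innovations)
    for k in range(p):
        signal[k] = scipy.signal.lfilter([1.0], [1.0, -spec.ar_coef[k]], innovations[k])

    # task component: HRF-convolved condition boxcars, region amplitudes
    hrf = canonical_hrf(design.tr_s, spec.hrf_duration_s)
    task = np.zeros(n_t)
    for cond in CONDITIONS:
        box = design.condition_boxcar(cond)
        if box.any():
            task += spec.condition_gain.get(cond, 1.0) * np.convolve(box, hrf)[:n_t]
    signal = signal + spec.task_amplitude[:, None] * task[None, :]

    signal = signal + spec.noise_sd * rng.standard_normal((p, n_t))
    return RoiTimeSeriesSet(
        participant=participant,
        run=run,
        data=signal,
        tr_s=design.tr_s,
        region_names=spec.catalog.names,
    )


def simulate_participant(
    spec: GenerativeSpec,
    participant_seed: int,
    state: str = "combined",
    participant: str = "",
    state_switching: Literal["run", "trial"] = "run",
) -> tuple[list[RoiTimeSeriesSet], GroundTruth]:
    """All runs for one participant, plus the planted ground truth.

    Each run gets its own design randomization and innovation stream,
    both derived from (master seed, participant seed, run index); the
    same seeds reproduce the output bit for bit.
    """
    runs = []
    for r in range(spec.runs_per_participant):
        design_seed = int(
            np.random.default_rng([spec.seed, participant_seed, r, 7]).integers(2**31)
        )
        design = build_run_design(
            trials_per_condition=spec.trials_per_condition,
            stimulus_s=spec.stimulus_s,
            blank_s=spec.blank_s,
            tr_s=spec.tr_s,
            seed=design_seed,
        )
        runs.append(
            simulate_run(
                spec,
                design,
                seed_entropy=[spec.seed, participant_seed, r],
                state=state,
                participant=participant or f"sub{participant_seed:03d}",
                run=f"run{r + 1}",
                state_switching=state_switching,
            )
        )
    return runs, spec.ground_truth()


def render_volumes(
    ts: RoiTimeSeriesSet,
    catalog: RegionCatalog,
    affine: np.ndarray,
    shape: Sequence[int],
    noise_sd: float = 0.0,
    radius_mm: float = 6.0,
    seed: int = 0,
) -> np.ndarray:
    """Paint region series into a 4D volume as non-overlapping spheres.

    Each region's sphere voxels carry that region's series plus
    independent voxel noise; everywhere else is background noise.  The
    end-to-end test surface for sphere extraction.
    """
    if ts.region_names != catalog.names:
        raise SimulateError("time-series region order must match the catalog")
    masks = [
        sphere_mask(region.center_mm, radius_mm, affine, shape) for region in catalog
    ]
    seen: dict[tuple[int, int, int], str] = {}
    for region, mask in zip(catalog, masks):
        for voxel in map(tuple, mask.indices):
            if voxel in seen:
                raise SimulateError(
                    f"spheres overlap: {seen[voxel]!r} and {region.name!r} "
                    f"share voxel {voxel}"
                )
            seen[voxel] = region.name
    rng = np.random.default_rng(seed)
    n_t = ts.n_timepoints
    data = noise_sd * rng.standard_normal((*shape[:3], n_t))
    for k, mask in enumerate(masks):
        idx = mask.indices
        voxel_noise = noise_sd * rng.standard_normal((len(idx), n_t))
        data[idx[:, 0], idx[:, 1], idx[:, 2], :] = ts.data[k][None, :] + voxel_noise
    return data


# behavioral generator constants (percent error / ms; illustrative).
# harder-minus-easier means: +15 % errors, +500 ms RT.
_ERROR_MEANS = {
    "Act": 4.0, "Act+": 8.0, "Pas": 6.0,
    "Pas+": 15.0, "Pot": 22.0, "Pot+": 26.0,
    "One": 5.0, "Cont": 3.0,
}
_RT_MEANS = {
    "Act": 2000.0, "Act+": 2200.0, "Pas": 2100.0,
    "Pas+": 2450.0, "Pot": 2600.0, "Pot+": 2750.0,
    "One": 2050.0, "Cont": 1800.0,
}
_ERROR_EASIER_MEAN = float(np.mean([_ERROR_MEANS[c] for c in sorted(_EASIER)]))
_ERROR_HARDER_MEAN = float(np.mean([_ERROR_MEANS[c] for c in sorted(_HARDER)]))
_RT_EASIER_MEAN = float(np.mean([_RT_MEANS[c] for c in sorted(_EASIER)]))
_RT_HARDER_MEAN = float(np.mean([_RT_MEANS[c] for c in sorted(_HARDER)]))
#: extra error (%) for patient groups under the listed conditions
_GROUP_ERROR_SHIFTS = {
    "normal": {},
    "lpmc_f3": {"Pot": 12.0, "Pot+": 12.0},
    "extra": {"Act+": 8.0, "Pot": 14.0, "Pot+": 14.0},
}
_ERROR_SD = 8.0
_RT_SD = 250.0


def simulate_behavior(
    group_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
    error_sd: float = _ERROR_SD,
    rt_sd: float = _RT_SD,
    effect_scale: float = 1.0,
) -> pd.DataFrame:
    """Behavioral table: per participant x condition error rate (%) and RT (ms).

    Errors are truncated-normal in [0, 100]; RTs truncated below at
    200 ms.  ``effect_scale`` scales the harder-minus-easier condition
    contrast around the easier mean for both measures (0 gives a null
    generator).
    """
    if group_sizes is None:
        group_sizes = {"normal": 16, "lpmc_f3": 9, "extra": 9}
    rows = []
    for g_idx, (group, size) in enumerate(sorted(group_sizes.items())):
        shifts = _GROUP_ERROR_SHIFTS.get(group, {})
        for s in range(size):
            rng = np.random.default_rng([seed, 547, g_idx, s])
            pid = f"{group}_{s + 1:02d}"
            for cond in CONDITIONS:
                err_mu = _ERROR_MEANS[cond] + shifts.get(cond, 0.0)
                rt_mu = _RT_MEANS[cond]
                if cond in _HARDER:
                    err_mu = (
                        _ERROR_EASIER_MEAN
                        + (err_mu - _ERROR_EASIER_MEAN) * effect_scale
                    )
                    rt_mu = _RT_EASIER_MEAN + (rt_mu - _RT_EASIER_MEAN) * effect_scale
                err = scipy.stats.truncnorm.rvs(
                    (0 - err_mu) / error_sd,
                    (100 - err_mu) / error_sd,
                    loc=err_mu,
                    scale=error_sd,
                    random_state=rng,
                )
                rt = scipy.stats.truncnorm.rvs(
                    (200 - rt_mu) / rt_sd,
                    np.inf,
                    loc=rt_mu,
                    scale=rt_sd,
                    random_state=rng,
                )
                rows.append(
                    {
                        "participant": pid,
                        "group": group,
                        "condition": cond,
                        "error_rate": float(err),
                        "mean_rt": float(rt),
                    }
                )
    return pd.DataFrame(rows)
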