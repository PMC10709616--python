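"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Everything downstream (PCA, GLM, state-space coordinates, mixed models) can
be exercised against data with known ground truth:

* ``make_gradients`` builds k smooth parcel maps that are mutually
  rank-decorrelated (|Spearman| below a tolerance) with 7-network labels
  whose extremes are network-coherent -- a stand-in for reference
  connectivity gradients.
* ``simulate_mdes`` draws 13-item probe ratings from 3 latent thought
  components (ratings on a continuous 1-10 scale, clipped).
* ``simulate_brain_maps`` plants per-subject maps as linear mixtures of the
  standardized gradients plus parcel noise.
* ``simulate_task_run`` schedules a sustained-attention run (TR 3 s,
  267 volumes, 80/20 non-target/target trials, 8 probes placed in vigilance
  periods) and synthesizes parcel timeseries through the same design
  machinery the GLM uses.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import glm as _glm
from .statespace import YEO7_NETWORKS, GradientSet

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "default_truth",
    "make_gradients",
    "simulate_brain_maps",
    "simulate_mdes",
    "simulate_task_run",
    "simulate_rt",
    "write_with_sidecar",
]

N_ITEMS = 13
N_COMPONENTS = 3

#: Rating model: rating = RATING_CENTER + RATING_SCALE * (loadings @ latent + noise),
#: clipped to [1, 10].  The scale keeps clipping rare (<5%) at default noise.
RATING_CENTER = 5.5
RATING_SCALE = 1.5


class SchedulingError(RuntimeError):
    """Raised when the requested events cannot fit in the run."""


@dataclasses.dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the sustained-attention paradigm the pipeline targets:
    3 runs of 267 volumes at TR 3 s, trials fixed at 3 s with 1.5-2.5 s
    jittered ISIs, 20% target trials, and 8 experience-sampling probes per
    run placed in vigilance periods (no target inside the 6 s pre-probe
    window).  The trial count per run is a free design choice; the default
    of 48 lets the default schedule (8 probe blocks of 13 rating screens at
    4 s + 0.5 s fixation each) fit comfortably within a run.
    """

    n_participants: int = 62
    n_runs: int = 3
    probes_per_run: int = 8
    n_parcels: int = 400
    tr: float = 3.0
    n_volumes: int = 267
    target_fraction: float = 0.20
    isi_range: tuple[float, float] = (1.5, 2.5)
    trial_duration: float = 3.0
    probe_window: float = 6.0
    trials_per_run: int = 48
    item_time: float = 4.0
    item_fixation: float = 0.5
    noise_sd: float = 0.5
    trait_sd: float = 0.8
    n_missing_run: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_participants,
            self.n_runs,
            self.probes_per_run,
            self.n_parcels,
            self.n_volumes,
            self.trials_per_run,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if not 0 < self.target_fraction < 1:
            raise ValueError("target_fraction must lie in (0, 1)")
        if self.probe_window <= 0:
            raise ValueError("probe_window must be positive")
        if self.isi_range[0] > self.isi_range[1] or self.isi_range[0] < 0:
            raise ValueError("invalid isi_range")
        if self.n_missing_run > self.n_participants:
            raise ValueError("cannot drop runs for more participants than exist")

    @property
    def probe_block_duration(self) -> float:
        """Time one probe occupies on screen: 13 rating screens + fixations."""
        return N_ITEMS * (self.item_time + self.item_fixation)

    @property
    def run_duration(self) -> float:
        return self.n_volumes * self.tr

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth the simulators plant and recovery tests check.

    ``loading_matrix`` (13 x 3, unit-norm columns) generates probe ratings;
    ``planted_coordinates`` maps each condition to the 5-vector of gradient
    mixing weights of its brain map; ``rt_effects`` couples response time
    linearly to named per-participant quantities (coordinates or scores).
    """

    loading_matrix: np.ndarray
    planted_coordinates: dict[str, np.ndarray]
    rt_effects: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        L = np.asarray(self.loading_matrix, float)
        if L.shape != (N_ITEMS, N_COMPONENTS):
            raise ValueError(f"loading_matrix must be {N_ITEMS}x{N_COMPONENTS}")
        norms = np.linalg.norm(L, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("loading columns must have unit norm")
        self.loading_matrix = L
        self.planted_coordinates = {
            k: np.asarray(v, float) for k, v in self.planted_coordinates.items()
        }
        for k, v in self.planted_coordinates.items():
            if not np.isfinite(v).all():
                raise ValueError(f"planted coordinates for {k!r} not finite")

    def standardized_loadings(self, noise_sd: float = 0.0, latent_var: float = 1.0) -> np.ndarray:
        """Planted loadings in the standardized-item metric.

        Correlation-matrix PCA standardizes each item, so the recoverable
        loading pattern is the planted one divided by each item's implied
        standard deviation ``sqrt(latent_var * sum_j L_ij^2 + noise_sd^2)``.
        This is the right comparison target for recovery checks.
        """
        L = self.loading_matrix
        sd = np.sqrt(latent_var * (L**2).sum(axis=1) + noise_sd**2)
        return L * np.sqrt(latent_var) / sd[:, None]


def default_truth(k: int = 5, seed: int = 0) -> PlantedTruth:
    """A reference ground truth: simple-structure loadings, distinct map mixtures.

    The loading matrix gives each latent component a block of 4-5 dominant
    items (simple structure, as varimax assumes); condition mixtures place
    the two overt task states apart mainly on dimensions 1 and 3, echoing
    the vigilance/target separation the method is designed to resolve.
    """
    rng = np.random.default_rng(seed)
    L = np.zeros((N_ITEMS, N_COMPONENTS))
    blocks = [slice(0, 5), slice(5, 9), slice(9, 13)]
    for j, b in enumerate(blocks):
        L[b, j] = rng.uniform(0.6, 1.0, b.stop - b.start)
        L[b, j] *= rng.choice([-1.0, 1.0], b.stop - b.start, p=[0.25, 0.75])
    L /= np.linalg.norm(L, axis=0)
    coords = {
        "vigilance": np.array([0.40, 0.15, 0.35, 0.10, 0.00])[:k],
        "target": np.array([-0.20, -0.10, -0.35, -0.15, 0.05])[:k],
        "off_task": np.array([0.30, 0.00, 0.25, 0.00, -0.05])[:k],
        "deliberate": np.array([-0.10, 0.20, -0.30, 0.10, 0.00])[:k],
        "verbal_self": np.array([0.15, -0.25, 0.10, -0.05, 0.10])[:k],
    }
    return PlantedTruth(
        loading_matrix=L,
        planted_coordinates=coords,
        rt_effects={"deliberate_score": -0.3},
    )


# ---------------------------------------------------------------------------
# gradients


def _smooth_fields(n_parcels: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency random fields over the parcel index (smooth basis)."""
    t = np.linspace(0.0, 1.0, n_parcels)
    fields = np.zeros((n_parcels, k))
    for j in range(k):
        for freq in range(1, 9):
            a, b = rng.normal(size=2) / freq
            fields[:, j] += a * np.sin(2 * np.pi * freq * t) + b * np.cos(2 * np.pi * freq * t)
        fields[:, j] += rng.normal(0, 0.05, n_parcels)
    return fields


def _rank_orthogonalize(V: np.ndarray, tol: float, max_iter: int = 200) -> np.ndarray:
    """Iteratively Gram-Schmidt the columns' rank vectors until all pairwise
    Spearman correlations fall below ``tol``."""
    n, k = V.shape
    for _ in range(max_iter):
        R = np.apply_along_axis(stats.rankdata, 0, V)
        R = (R - R.mean(axis=0)) / R.std(axis=0)
        Q = np.linalg.qr(R)[0]
        V = Q * np.sqrt(n)  # keep a sensible scale
        rho = stats.spearmanr(V)[0] if k > 1 else np.array(1.0)
        if k == 1:
            return V
        off = np.abs(rho - np.eye(k)).max()
        if off < tol:
            return V
    raise RuntimeError("rank decorrelation did not converge; increase n_parcels")


#: Network owning each gradient pole (dim index, sign), patterned on how the
#: reference gradients' poles align with canonical networks: gradient 1
#: separates association (default-mode) from sensory-motor cortex, gradient 2
#: motor from visual, gradient 3 default-mode from fronto-parietal, gradient 4
#: dorsal from ventral attention, gradient 5 visual from ventral attention.
_POLE_NETWORKS = {
    (0, +1): "default_mode",
    (0, -1): "somatomotor",
    (1, +1): "visual",
    (1, -1): "somatomotor",
    (2, +1): "default_mode",
    (2, -1): "frontoparietal",
    (3, +1): "dorsal_attention",
    (3, -1): "ventral_attention",
    (4, +1): "visual",
    (4, -1): "ventral_attention",
}


def _assign_networks(values: np.ndarray) -> np.ndarray:
    """Label parcels with 7 networks so each gradient's extremes are coherent.

    For k >= 3, each parcel takes the network of the pole it sits closest to
    (the gradient on which it is most extreme, signed); parcels extreme on
    no gradient form the limbic network.  Poles share networks the way the
    reference gradients' do, so every gradient's extremes are dominated by
    one label.  For k < 3 there are too few poles for 7 labels and quantile
    bins of the first gradient are used instead.
    """
    n, k = values.shape
    z = (values - values.mean(axis=0)) / values.std(axis=0)
    if k >= 3:
        dim = np.abs(z).argmax(axis=1)
        extremity = np.abs(z)[np.arange(n), dim]
        signs = np.sign(z[np.arange(n), dim]).astype(int)
        labels = np.array(
            [
                _POLE_NETWORKS[(d % 5 if d >= 5 else d, s)]
                for d, s in zip(np.minimum(dim, 4), signs)
            ]
        )
        labels[extremity < np.quantile(extremity, 0.15)] = "limbic"
        return labels
    qs = np.quantile(z[:, 0], np.linspace(0, 1, 8))
    qs[0] -= 1e-9
    idx = np.clip(np.searchsorted(qs, z[:, 0], side="right") - 1, 0, 6)
    return np.array(YEO7_NETWORKS)[idx]


def make_gradients(
    n_parcels: int, k: int = 5, seed: int = 0, tol: float = 0.01
) -> GradientSet:
    """Synthesize k mutually rank-decorrelated gradient maps over parcels.

    Smooth random fields are drawn, then Gram-Schmidt is applied to their
    rank vectors (iterated to convergence) so every pairwise Spearman
    correlation is below ``tol`` in absolute value.  Each parcel receives
    one of the 7 canonical network labels with network-coherent gradient
    extremes.  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_parcels < 10 * k:
        raise ValueError(f"n_parcels must be >= 10*k (= {10 * k})")
    rng = np.random.default_rng(seed)
    # the rank iteration can cycle at small n; restart with fresh fields
    for attempt in range(5):
        try:
            V = _rank_orthogonalize(_smooth_fields(n_parcels, k, rng), tol=tol)
            break
        except RuntimeError:
            if attempt == 4:
                raise
    parcel_ids = pd.RangeIndex(1, n_parcels + 1, name="parcel_id")
    values = pd.DataFrame(
        V, index=parcel_ids, columns=[f"gradient_{j + 1}" for j in range(k)]
    )
    networks = pd.Series(_assign_networks(V), index=parcel_ids, name="network")
    return GradientSet(values=values, networks=networks, provenance=f"synthetic(seed={seed})")


# ---------------------------------------------------------------------------
# brain maps


def simulate_brain_maps(
    gradients: GradientSet,
    truth: PlantedTruth,
    n_subjects: int,
    noise_sd: float = 0.5,
    seed: int = 0,
    conditions: Sequence[str] | None = None,
    weight_jitter_sd: float = 0.0,
) -> pd.DataFrame:
    """Per-subject parcel maps as planted mixtures of standardized gradients.

    Each map is ``sum_i w_i * z(gradient_i) + noise`` with subject-level
    Gaussian parcel noise; ``weight_jitter_sd`` optionally perturbs the
    planted weights per subject (between-subject variability in true
    coordinates).  Returns a frame indexed by parcel with MultiIndex columns
    (condition, subject).
    """
    conditions = list(conditions or truth.planted_coordinates)
    missing = [c for c in conditions if c not in truth.planted_coordinates]
    if missing:
        raise ValueError(f"no planted coordinates for conditions {missing}")
    G = gradients.values.to_numpy(float)
    k = G.shape[1]
    for c in conditions:
        if truth.planted_coordinates[c].shape != (k,):
            raise ValueError(
                f"planted coordinates for {c!r} have wrong length (need {k})"
            )
    Z = (G - G.mean(axis=0)) / G.std(axis=0)
    rng = np.random.default_rng(seed)
    data = {}
    for cond in conditions:
        w = truth.planted_coordinates[cond]
        for s in range(1, n_subjects + 1):
            ws = w + (rng.normal(0, weight_jitter_sd, k) if weight_jitter_sd else 0.0)
            noise = rng.normal(0, noise_sd, Z.shape[0]) if noise_sd else 0.0
            data[(cond, f"sub-{s:03d}")] = Z @ ws + noise
    out = pd.DataFrame(data, index=gradients.parcel_ids)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["condition", "subject"])
    return out


# ---------------------------------------------------------------------------
# experience sampling


def _run_plan(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """(participant, run) pairs honoring the seeded missing-run pattern."""
    participants = [f"p{p:03d}" for p in range(1, config.n_participants + 1)]
    missing = set()
    if config.n_missing_run:
        lost = rng.choice(config.n_participants, size=config.n_missing_run, replace=False)
        dropped_runs = rng.integers(1, config.n_runs + 1, size=config.n_missing_run)
        missing = {(participants[i], int(r)) for i, r in zip(lost, dropped_runs)}
    return [
        (p, r)
        for p in participants
        for r in range(1, config.n_runs + 1)
        if (p, r) not in missing
    ]


def simulate_mdes(
    truth: PlantedTruth,
    config: SimulationConfig,
    clip: bool = True,
    return_latents: bool = False,
):
    """Probe-level mDES ratings from the planted 3-component model.

    For each probe a latent 3-vector is drawn as the participant's trait
    mean (sd ``trait_sd``, stable across that participant's probes) plus an
    i.i.d. standard-normal probe-level deviation; ratings are an affine map
    of ``loadings @ latent`` plus item noise, clipped to the 1-10 scale.
    The trait component is what gives run-wise ICCs their between-
    participant signal.  Returns a keyed ProbeMatrix (participant, run,
    probe columns + item_1..item_13); with ``return_latents`` also the
    latent component values per probe (ground truth for recovery tests).
    """
    rng = np.random.default_rng(config.seed)
    plan = _run_plan(config, rng)
    n_probes = len(plan) * config.probes_per_run
    if n_probes == 0:
        raise ValueError("configuration yields no probes")
    traits = {
        p: rng.normal(0, config.trait_sd, N_COMPONENTS)
        for p in dict.fromkeys(p for p, _ in plan)
    }
    trait_rows = np.vstack(
        [traits[p] for (p, _) in plan for _ in range(config.probes_per_run)]
    )
    latents = trait_rows + rng.standard_normal((n_probes, N_COMPONENTS))
    noise = rng.normal(0, config.noise_sd, (n_probes, N_ITEMS))
    raw = RATING_CENTER + RATING_SCALE * (latents @ truth.loading_matrix.T + noise)
    ratings = np.clip(raw, 1.0, 10.0) if clip else raw
    keys = pd.DataFrame(
        [
            (p, r, i)
            for (p, r) in plan
            for i in range(1, config.probes_per_run + 1)
        ],
        columns=["participant", "run", "probe_index"],
    )
    items = pd.DataFrame(ratings, columns=[f"item_{i}" for i in range(1, N_ITEMS + 1)])
    probes = pd.concat([keys, items], axis=1)
    probes.attrs["clipped_fraction"] = float((raw != ratings).mean()) if clip else 0.0
    if return_latents:
        lat = pd.concat(
            [keys, pd.DataFrame(latents, columns=[f"latent_{j + 1}" for j in range(3)])],
            axis=1,
        )
        return probes, lat
    return probes


# ---------------------------------------------------------------------------
# task runs


def _schedule_run(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One run's event table: trials + probe blocks, probes in vigilance."""
    n_trials = config.trials_per_run
    n_probes = config.probes_per_run
    # probes occur after these trial indices (1-based, distinct, ordered)
    if n_probes > n_trials - 1:
        raise SchedulingError("more probes than trial gaps available")
    # first probe only after trial 2, so its pre-probe window fits in the run
    after = np.sort(rng.choice(np.arange(2, n_trials + 1), size=n_probes, replace=False))
    rows = []
    t = 0.0
    probe_onsets = []
    pi = 0
    for trial in range(1, n_trials + 1):
        rows.append({"onset": t, "duration": config.trial_duration, "event_type": "trial"})
        t += config.trial_duration + rng.uniform(*config.isi_range)
        while pi < n_probes and after[pi] == trial:
            probe_onsets.append(t)
            rows.append(
                {"onset": t, "duration": config.probe_block_duration, "event_type": "probe"}
            )
            t += config.probe_block_duration + rng.uniform(*config.isi_range)
            pi += 1
    if t > config.run_duration:
        raise SchedulingError(
            f"schedule needs {t:.1f}s but run is {config.run_duration:.1f}s; "
            "reduce trials_per_run or probe length"
        )
    events = pd.DataFrame(rows)

    # Trials overlapping a pre-probe window must stay non-target (probes are
    # presented in vigilance periods); keep the overall target rate at
    # target_fraction in expectation by up-weighting eligible trials.
    trial_mask = events["event_type"] == "trial"
    onsets = events.loc[trial_mask, "onset"].to_numpy()
    ends = onsets + events.loc[trial_mask, "duration"].to_numpy()
    protected = np.zeros(trial_mask.sum(), bool)
    for p in probe_onsets:
        lo = p - config.probe_window
        protected |= (onsets < p) & (ends > lo)
    n_eligible = int((~protected).sum())
    if n_eligible == 0:
        raise SchedulingError("no trials eligible to be targets")
    p_adj = min(1.0, config.target_fraction * n_trials / n_eligible)
    is_target = np.zeros(n_trials, bool)
    is_target[~protected] = rng.random(n_eligible) < p_adj
    etype = np.where(is_target, "target", "non_target")
    events.loc[trial_mask, "event_type"] = etype
    events.loc[trial_mask & (events["event_type"] == "target"), "response_time"] = (
        rng.uniform(0.4, 1.0, int(is_target.sum()))
    )
    return events


def simulate_task_run(
    config: SimulationConfig,
    betas: pd.DataFrame,
    seed: int,
    scores: pd.DataFrame | None = None,
    noise_sd: float | None = None,
    drift_amplitude: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one run: event schedule + parcel timeseries.

    ``betas`` is a parcels x regressors frame whose columns name task EVs
    (``vigilance``, ``target``, ``probe_window``, ``thought_1..k``); the
    timeseries is the HRF-convolved design (built by the same code the GLM
    uses) times these effects, plus an optional linear drift and white
    Gaussian noise.  ``scores`` supplies per-probe component scores for the
    parametric EVs (drawn standard normal when omitted and thought columns
    are requested).
    """
    rng = np.random.default_rng(seed)
    events = _schedule_run(config, rng)
    thought_cols = [c for c in betas.columns if c.startswith("thought_")]
    if thought_cols and scores is None:
        scores = pd.DataFrame(
            rng.standard_normal((config.probes_per_run, len(thought_cols))),
            columns=[f"score_{i + 1}" for i in range(len(thought_cols))],
        )
    design = _glm.build_design(
        events,
        scores if thought_cols else None,
        tr=config.tr,
        n_volumes=config.n_volumes,
        probe_window=config.probe_window,
    )
    missing = set(betas.columns) - set(design.task_columns)
    if missing:
        raise ValueError(f"beta columns {sorted(missing)} are not design EVs")
    X = design.frame[list(betas.columns)].to_numpy()
    Y = X @ betas.to_numpy(float).T
    if drift_amplitude:
        t = np.linspace(-1, 1, config.n_volumes)[:, None]
        Y = Y + drift_amplitude * t * rng.uniform(0.5, 1.5, betas.shape[0])
    sd = config.noise_sd if noise_sd is None else noise_sd
    if sd:
        Y = Y + rng.normal(0, sd, Y.shape)
    timeseries = pd.DataFrame(Y, columns=betas.index)
    timeseries.attrs["scores"] = scores
    return events, timeseries


def simulate_rt(
    predictors: pd.DataFrame,
    effects: Mapping[str, float],
    noise_sd: float = 0.5,
    seed: int = 0,
    intercept: float = 0.0,
) -> pd.Series:
    """Per-participant response times linearly coupled to named predictors."""
    rng = np.random.default_rng(seed)
    rt = np.full(len(predictors), float(intercept))
    for name, coef in effects.items():
        rt += coef * predictors[name].to_numpy(float)
    rt += rng.normal(0, noise_sd, len(predictors))
    return pd.Series(rt, index=predictors.index, name="rt")


# ---------------------------------------------------------------------------
# provenance


def write_with_sidecar(frame: pd.DataFrame, path, config: SimulationConfig, **meta) -> None:
    """Write a table with a YAML sidecar recording config + seed."""
    path = str(path)
    sep = "\t" if path.endswith(".tsv") else ","
    frame.to_csv(path, sep=sep, index=isinstance(frame.index, pd.RangeIndex) is False)
    sidecar = {"config": config.to_dict(), **meta}
    with open(path.rsplit(".", 1)[0] + ".yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
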