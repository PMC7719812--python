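"""Synthetic behavioral, EEG, and BOLD data with known ground truth.

The generators emulate the statistical structure the downstream analyses
assume, for two diagnostic groups (``control`` / ``patient``):

* **Behavior** — a latent-threshold observer run through the ascending
  method of limits: a picture sequence steps through fragmentation levels
  6 → 3 and stops at the first "yes".  On every presentation the observer
  draws an effective threshold ``t_eff = threshold + u / slope`` with
  standard-logistic ``u`` and answers yes iff ``level <= t_eff``;
  repetition priming shifts the threshold toward more-fragmented levels
  by ``priming_shift``.  In the ``slope -> inf`` limit the observer is
  deterministic and identifies exactly at the integer threshold level.
* **EEG** — epochs are sums of Gaussian-bump components (P1 at 115 ms,
  N1 at 180 ms, Ncl at 320 ms) lateralized to parieto-occipital
  electrodes, plus white noise.  Each bump is scaled so that its mean
  over the component's own analysis window equals the configured
  amplitude in microvolts, making window-mean extraction an exact
  inverse of the injection when noise is zero.
* **BOLD** — a 4-node latent network (DS, LOC, PFC, HIPP) follows a
  VAR(p) driven by condition boxcars, one step per TR.  Coefficients are
  stored in the sign convention ``x[n] = -sum_i A[i] x[n-i] + u[n]``
  (so the effective regression matrices are ``-A[i]``).  Each ROI voxel
  is the (optionally HRF-convolved) node series times a local gain plus
  observation noise.  Ground truth is always returned alongside the
  data so recovery tests never reverse-engineer it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from closurenet.containers import EpochSet
from closurenet.design import ErpBlockDesign, SessionDesign
from closurenet.glm import HrfParams, canonical_hrf

__all__ = [
    "ObserverModel",
    "ComponentSpec",
    "EegSimConfig",
    "NetworkModel",
    "BoldSimConfig",
    "BoldSimResult",
    "GROUPS",
    "EEG_CONDITIONS",
    "NETWORK_NODES",
    "simulate_behavior",
    "fit_observer_threshold",
    "simulate_eeg_epochs",
    "simulate_network_bold",
    "make_group_network",
    "default_roi_masks",
    "bold_to_nifti",
    "roi_mean_series",
]

GROUPS = ("control", "patient")
EEG_CONDITIONS = ("ID", "ID-1", "Repeat")
NETWORK_NODES = ("DS", "LOC", "PFC", "HIPP")

#: Nominal Talairach centers carried as metadata only (x, y, z).
TALAIRACH_LABELS = {
    "DS": (26, -79, 23),
    "LOC": (27, -59, -8),
    "PFC": (33, 4, 40),
    "HIPP": (26, -20, -20),
}


# ---------------------------------------------------------------------------
# behavior

@dataclass(frozen=True)
class ObserverModel:
    """Latent-threshold observer for the AML identification task.

    threshold_level
        Fragmentation level identified with probability 1/2 (boundary
        resolved as "yes"; the deterministic limit identifies at exactly
        this level).
    slope
        Inverse width of the psychometric function in levels; ``np.inf``
        gives a deterministic observer.
    priming_shift
        Threshold shift (levels, toward more-fragmented) for repeats.
    lapse
        Probability of missing an identification regardless of level.
    """

    threshold_level: float = 4.0
    slope: float = 2.5
    priming_shift: float = 1.0
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0 <= self.lapse < 1:
            raise ValueError("lapse must be in [0, 1)")
        if self.priming_shift < 0:
            raise ValueError("priming_shift must be nonnegative")

    def p_yes(self, level: float, is_repeat: bool = False) -> float:
        thr = self.threshold_level + (self.priming_shift if is_repeat else 0.0)
        if np.isinf(self.slope):
            return (1.0 - self.lapse) * float(level <= thr)
        return (1.0 - self.lapse) * float(expit(self.slope * (thr - level)))


def simulate_behavior(observer: ObserverModel, blocks: list[ErpBlockDesign], seed: int) -> pd.DataFrame:
    """Run the observer through AML blocks; one row per presentation.

    Columns: block, sequence_slot, picture_id, is_repeat, level, response
    (0/1) and, per sequence, identification_level (NaN when the sequence
    ran out without a "yes").
    """
    rng = np.random.default_rng(seed)
    rows = []
    for b, block in enumerate(blocks):
        for pres in block.presentations:
            thr = observer.threshold_level + (observer.priming_shift if pres.is_repeat else 0.0)
            ident: float = np.nan
            start = len(rows)
            for level in pres.level_schedule:
                if np.isinf(observer.slope):
                    t_eff = thr
                else:
                    t_eff = thr + rng.logistic(0.0, 1.0) / observer.slope
                yes = level <= t_eff and rng.random() >= observer.lapse
                rows.append({
                    "block": b,
                    "sequence_slot": pres.sequence_slot,
                    "picture_id": pres.picture_id,
                    "is_repeat": int(pres.is_repeat),
                    "level": level,
                    "response": int(yes),
                })
                if yes:
                    ident = level
                    break
            for r in rows[start:]:
                r["identification_level"] = ident
    return pd.DataFrame(rows)


def fit_observer_threshold(responses: pd.DataFrame, lapse: float = 0.0) -> tuple[float, float]:
    """Maximum-likelihood (threshold, slope) from per-presentation yes/no.

    The likelihood matches the sampling model: P(yes | level) =
    (1 - lapse) * expit(slope * (threshold + shift - level)) with the
    repeat shift profiled out by fitting novel presentations only when
    both kinds are present; pass a pre-filtered table for other choices.
    """
    df = responses
    if "is_repeat" in df.columns and df["is_repeat"].nunique() > 1:
        df = df[df["is_repeat"] == 0]
    levels = df["level"].to_numpy(float)
    yes = df["response"].to_numpy(float)

    def nll(params):
        thr, log_slope = params
        p = (1.0 - lapse) * expit(np.exp(log_slope) * (thr - levels))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(yes * np.log(p) + (1 - yes) * np.log(1 - p))

    res = minimize(nll, x0=np.array([4.0, 1.0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    thr, log_slope = res.x
    return float(thr), float(np.exp(log_slope))


# ---------------------------------------------------------------------------
# EEG

@dataclass
class ComponentSpec:
    """One ERP component: Gaussian bump with per-group/condition amplitude."""

    peak_ms: float
    window_ms: tuple[float, float]
    electrodes: tuple[str, ...]
    amplitudes: dict[str, dict[str, float]]  # group -> condition -> microvolts
    sigma_ms: float = 8.5  # ~20 ms FWHM

    def __post_init__(self) -> None:
        lo, hi = self.window_ms
        if not lo <= self.peak_ms <= hi:
            raise ValueError("component peak must lie inside its window")


def _default_components() -> dict[str, ComponentSpec]:
    # Qualitative two-group pattern: closure negativity (Ncl) reduced in
    # patients; repetition enhances N1 similarly in both groups; P1 is
    # reduced by repetition in controls only.  Values are placeholders in
    # microvolts, not calibrated to any recorded data.
    return {
        "P1": ComponentSpec(
            peak_ms=115, window_ms=(100, 120), electrodes=("PO5", "PO6"),
            amplitudes={
                "control": {"ID": 3.0, "ID-1": 2.8, "Repeat": 2.0},
                "patient": {"ID": 2.0, "ID-1": 2.0, "Repeat": 2.0},
            },
        ),
        "N1": ComponentSpec(
            peak_ms=180, window_ms=(170, 200), electrodes=("PO7", "PO8"),
            amplitudes={
                "control": {"ID": -5.0, "ID-1": -4.0, "Repeat": -7.0},
                "patient": {"ID": -4.5, "ID-1": -3.6, "Repeat": -6.4},
            },
        ),
        "Ncl": ComponentSpec(
            peak_ms=320, window_ms=(300, 340), electrodes=("PO7", "PO8"),
            amplitudes={
                "control": {"ID": -4.0, "ID-1": -1.5, "Repeat": -3.5},
                "patient": {"ID": -2.0, "ID-1": -1.0, "Repeat": -2.8},
            },
        ),
    }


@dataclass
class EegSimConfig:
    sfreq: float = 512.0
    ch_names: tuple[str, ...] = ("PO5", "PO6", "PO7", "PO8", "POz", "O1", "O2", "Oz")
    tmin_ms: float = -100.0
    tmax_ms: float = 500.0
    components: dict[str, ComponentSpec] = field(default_factory=_default_components)
    noise_sd: float = 8.0   # single-trial broadband EEG noise, microvolts
    n_trials: int = 60      # per condition

    def __post_init__(self) -> None:
        if self.sfreq < 256:
            raise ValueError("sfreq must be at least 256 samples/s")
        required = {"PO5", "PO6", "PO7", "PO8"}
        if not required <= set(self.ch_names):
            raise ValueError(f"channel list must include {sorted(required)}")
        for name, comp in self.components.items():
            lo, hi = comp.window_ms
            if lo < self.tmin_ms or hi > self.tmax_ms:
                raise ValueError(f"component {name} window outside epoch extent")

    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        return np.arange(self.tmin_ms, self.tmax_ms + 0.5 * step, step)


def simulate_eeg_epochs(
    config: EegSimConfig,
    condition_labels: list[str],
    seed: int,
    group: str = "control",
    subject: str = "sim",
) -> EpochSet:
    """Generate epoched EEG: Gaussian-bump components plus white noise.

    Each epoch for condition ``c`` carries, on each component's
    electrodes, a bump ``a * g(t)`` where ``g`` is a unit Gaussian at the
    component's peak latency and ``a`` is chosen so the mean of the bump
    over the component's analysis window equals the configured amplitude
    for (group, c).  White Gaussian noise of ``config.noise_sd``
    microvolts is added to every channel and sample.
    """
    times = config.times_ms()
    n_ch, n_t = len(config.ch_names), len(times)
    ch_index = {c: i for i, c in enumerate(config.ch_names)}
    rng = np.random.default_rng(seed)

    # one noiseless template per condition
    templates: dict[str, np.ndarray] = {}
    for cond in set(condition_labels):
        tpl = np.zeros((n_ch, n_t))
        for comp in config.components.values():
            amp = comp.amplitudes.get(group, {}).get(cond, 0.0)
            if amp == 0.0:
                continue
            g = np.exp(-0.5 * ((times - comp.peak_ms) / comp.sigma_ms) ** 2)
            lo, hi = comp.window_ms
            win = (times >= lo) & (times <= hi)
            scale = amp / g[win].mean()
            for el in comp.electrodes:
                tpl[ch_index[el]] += scale * g
        templates[cond] = tpl

    data = np.empty((len(condition_labels), n_ch, n_t))
    for i, cond in enumerate(condition_labels):
        data[i] = templates[cond]
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
    return EpochSet(data=data, times=times, ch_names=list(config.ch_names),
                    conditions=list(condition_labels), sfreq=config.sfreq,
                    subject=subject, group=group)


# ---------------------------------------------------------------------------
# BOLD network

@dataclass
class NetworkModel:
    """Latent VAR(p) network over the four closure-processing nodes.

    Coefficient matrices ``a_minus[i]`` are stored in the minus-sign
    convention ``x[n] = -sum_i a_minus[i] x[n-i] + C s[n] + u[n]``; the
    effective regression matrices are ``-a_minus[i]`` with entry (row,
    col) = influence of node ``col`` on node ``row`` at that lag.
    """

    a_minus: list[np.ndarray]
    sigma_u: np.ndarray
    input_weights: dict[str, np.ndarray] = field(default_factory=dict)
    nodes: tuple[str, ...] = NETWORK_NODES
    group: str = ""

    def __post_init__(self) -> None:
        self.a_minus = [np.asarray(a, dtype=float) for a in self.a_minus]
        self.sigma_u = np.asarray(self.sigma_u, dtype=float)
        k = len(self.nodes)
        for a in self.a_minus:
            if a.shape != (k, k):
                raise ValueError("coefficient matrices must be node x node")
        if not np.allclose(self.sigma_u, self.sigma_u.T):
            raise ValueError("sigma_u must be symmetric")
        if np.any(np.linalg.eigvalsh(self.sigma_u) < -1e-12):
            raise ValueError("sigma_u must be positive semi-definite")

    @property
    def order(self) -> int:
        return len(self.a_minus)

    @property
    def a_effective(self) -> list[np.ndarray]:
        return [-a for a in self.a_minus]

    def spectral_radius(self) -> float:
        k, p = len(self.nodes), self.order
        comp = np.zeros((k * p, k * p))
        for i, a in enumerate(self.a_effective):
            comp[:k, i * k:(i + 1) * k] = a
        if p > 1:
            comp[k:, :-k] = np.eye(k * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


def make_group_network(group: str, coupling: float = 0.4, self_decay: float = 0.5,
                       input_gain: float = 1.0, noise_scale: float = 1.0) -> NetworkModel:
    """Directed couplings of the two diagnostic groups.

    Controls route closure through the prefrontal path (DS → PFC → LOC);
    patients use an alternate route with bidirectional DS ↔ LOC flow and
    hippocampal input to DS (HIPP → DS), bypassing PFC.  Stimulus input
    drives DS in both groups.
    """
    k = len(NETWORK_NODES)
    idx = {n: i for i, n in enumerate(NETWORK_NODES)}
    a_eff = self_decay * np.eye(k)
    if group == "control":
        edges = [("DS", "PFC"), ("PFC", "LOC")]
    elif group == "patient":
        edges = [("DS", "LOC"), ("LOC", "DS"), ("HIPP", "DS")]
    else:
        raise ValueError(f"unknown group {group!r}")
    for src, dst in edges:
        a_eff[idx[dst], idx[src]] = coupling
    drive = np.zeros(k)
    drive[idx["DS"]] = input_gain
    weights = {c: drive.copy() for c in ("primed", "unprimed", "scrambled")}
    return NetworkModel(a_minus=[-a_eff], sigma_u=noise_scale * np.eye(k),
                        input_weights=weights, group=group)


@dataclass
class BoldSimConfig:
    tr_ms: int = 2000
    hrf_params: HrfParams = field(default_factory=HrfParams)
    grid_shape: tuple[int, int, int] = (6, 6, 2)
    voxels_per_roi: int = 8
    noise_sd: float = 0.5
    gain_sd: float = 0.1
    talairach_labels: dict = field(default_factory=lambda: dict(TALAIRACH_LABELS))


def default_roi_masks(config: BoldSimConfig) -> dict[str, np.ndarray]:
    """Disjoint flat-index voxel sets, one block per network node."""
    n_vox = int(np.prod(config.grid_shape))
    need = config.voxels_per_roi * len(NETWORK_NODES)
    if need > n_vox:
        raise ValueError("grid too small for requested ROI sizes")
    masks = {}
    for i, node in enumerate(NETWORK_NODES):
        start = i * config.voxels_per_roi
        masks[node] = np.arange(start, start + config.voxels_per_roi)
    return masks


@dataclass
class BoldSimResult:
    volume: np.ndarray                  # (X, Y, Z, T)
    latents: np.ndarray                 # (T, n_nodes), pre-HRF node series
    roi_masks: dict[str, np.ndarray]    # node -> flat voxel indices
    nodes: tuple[str, ...]
    design: SessionDesign
    ground_truth: dict

    @property
    def series(self) -> np.ndarray:
        """Voxel time series as (T, n_voxels)."""
        X, Y, Z, T = self.volume.shape
        return self.volume.reshape(X * Y * Z, T).T


def simulate_network_bold(
    network: NetworkModel,
    config: BoldSimConfig,
    design: SessionDesign,
    seed: int,
    hrf: str = "canonical",
    latent_noise: bool = True,
    burn_in: int = 50,
) -> BoldSimResult:
    """Simulate 4-D BOLD from the latent VAR network, one step per TR.

    The latent node series follows the network's VAR driven by condition
    boxcars; each ROI voxel is the node series — convolved with the
    canonical double-gamma HRF unless ``hrf='identity'`` — times a local
    gain (N(1, gain_sd), truncated positive), plus white observation
    noise.  Non-ROI voxels contain observation noise only.  The returned
    ground-truth record holds everything a recovery test needs.
    """
    if hrf not in ("canonical", "identity"):
        raise ValueError("hrf must be 'canonical' or 'identity'")
    rho = network.spectral_radius()
    if rho >= 1.0:
        raise ValueError(f"network is not stationary: companion spectral radius {rho:.3f} >= 1")
    rng = np.random.default_rng(seed)
    nodes = network.nodes
    k, p = len(nodes), network.order
    T = design.total_tr
    a_eff = network.a_effective

    # condition input at each TR
    s = np.zeros((T, k))
    for t, cond in enumerate(design.schedule):
        w = network.input_weights.get(cond)
        if w is not None:
            s[t] = w

    n_tot = T + burn_in
    if latent_noise and np.any(network.sigma_u):
        try:
            chol = np.linalg.cholesky(network.sigma_u)
        except np.linalg.LinAlgError:  # PSD but singular
            w, V = np.linalg.eigh(network.sigma_u)
            chol = V * np.sqrt(np.clip(w, 0.0, None))
        u = rng.standard_normal((n_tot, k)) @ chol.T
    else:
        u = np.zeros((n_tot, k))
    x = np.zeros((n_tot, k))
    for t in range(n_tot):
        acc = u[t].copy()
        if t >= burn_in:
            acc += s[t - burn_in]
        for i, a in enumerate(a_eff):
            if t - i - 1 >= 0:
                acc += a @ x[t - i - 1]
        x[t] = acc
    latents = x[burn_in:]

    if hrf == "canonical":
        kernel = canonical_hrf(config.hrf_params, tr_s=config.tr_ms / 1000.0).kernel
        node_sig = np.column_stack(
            [np.convolve(latents[:, j], kernel)[:T] for j in range(k)]
        )
    else:
        node_sig = latents.copy()

    masks = default_roi_masks(config)
    n_vox = int(np.prod(config.grid_shape))
    gains = np.abs(rng.normal(1.0, config.gain_sd, size=n_vox))
    Yv = rng.normal(0.0, config.noise_sd, size=(T, n_vox)) if config.noise_sd > 0 else np.zeros((T, n_vox))
    for j, node in enumerate(nodes):
        for v in masks[node]:
            Yv[:, v] += gains[v] * node_sig[:, j]
    volume = Yv.T.reshape(*config.grid_shape, T)

    ground_truth = {
        "a_minus": [a.tolist() for a in network.a_minus],
        "a_effective": [a.tolist() for a in a_eff],
        "sigma_u": network.sigma_u.tolist(),
        "input_weights": {c: w.tolist() for c, w in network.input_weights.items()},
        "gains": gains.tolist(),
        "hrf": hrf,
        "group": network.group,
        "seed": int(seed),
        "edges": [
            (nodes[src], nodes[dst])
            for a in a_eff
            for dst in range(k)
            for src in range(k)
            if dst != src and abs(a[dst, src]) > 0
        ],
        "talairach_labels": {n: list(config.talairach_labels.get(n, ())) for n in nodes},
    }
    return BoldSimResult(volume=volume, latents=latents, roi_masks=masks,
                         nodes=nodes, design=design, ground_truth=ground_truth)


def roi_mean_series(result: BoldSimResult) -> pd.DataFrame:
    """Per-ROI mean voxel time course, columns named by node."""
    series = result.series
    return pd.DataFrame({n: series[:, idx].mean(axis=1) for n, idx in result.roi_masks.items()})


def bold_to_nifti(result: BoldSimResult, vol_path, mask_path=None) -> None:
    """Write the 4-D volume (and an ROI label volume) as NIfTI."""
    import nibabel as nib

    affine = np.eye(4)
    nib.save(nib.Nifti1Image(result.volume.astype(np.float32), affine), str(vol_path))
    if mask_path is not None:
        labels = np.zeros(int(np.prod(result.volume.shape[:3])), dtype=np.int16)
        for i, node in enumerate(result.nodes, start=1):
            labels[result.roi_masks[node]] = i
        nib.save(nib.Nifti1Image(labels.reshape(result.volume.shape[:3]), affine), str(mask_path))
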