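"""Ground-truth generator for trial-structured mixed spike/LFP data.

Draws per-bin latent bivariate standard normals with correlation ``rho``;
the continuous sample is ``mu_y + sigma * z_y`` and the spike indicator is
``z_x > -eta_x``, so simulated data follow exactly the generative process the
model module fits.  Supports an onset-locked parameter switch (coupling
turned on at stimulus onset), condition pairs differing only in post-onset
coupling strength, and additive spike-waveform contamination of the
continuous channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .copula_model import JointModel
from .io_preprocess import TrialSet

__all__ = [
    "SimConfig",
    "Contamination",
    "simulate_mixed",
    "inject_spike_artifacts",
    "make_condition_pair",
    "default_artifact_template",
    "ar_spectral_radius",
]


def default_artifact_template(fs: float = 1000.0) -> np.ndarray:
    """A 3 ms biphasic pulse (positive then negative lobe) at rate ``fs``."""
    n = max(2, int(round(0.003 * fs)))
    half = n // 2
    pos = np.hanning(2 * half + 2)[1 : half + 1]
    neg = -0.6 * np.hanning(2 * (n - half) + 2)[1 : n - half + 1]
    return np.concatenate([pos, neg])


@dataclass(frozen=True)
class Contamination:
    """Spike-waveform leakage added to the continuous channel."""

    template: np.ndarray
    gain: float = 1.0

    def __post_init__(self):
        object.__setattr__(
            self, "template", np.asarray(self.template, dtype=float)
        )
        if not np.all(np.isfinite(self.template)):
            raise ValueError("contamination template must be finite")


@dataclass
class SimConfig:
    """Full generative specification; ``seed`` determines output entirely."""

    model: JointModel
    n_trials: int
    n_bins: int
    fs: float = 1000.0
    onset_bin: int | None = None
    post_onset_model: JointModel | None = None
    contamination: Contamination | None = None
    seed: int = 0
    condition: str = "sim"

    def __post_init__(self):
        if self.n_trials < 1 or self.n_bins < 1:
            raise ValueError("n_trials and n_bins must be >= 1")
        if self.post_onset_model is not None and self.onset_bin is None:
            raise ValueError("post_onset_model given without onset_bin")
        if self.contamination is not None:
            if self.contamination.template.size >= self.n_bins:
                raise ValueError("contamination template must be much shorter than a trial")


def ar_spectral_radius(a: np.ndarray) -> float:
    """Spectral radius of the companion matrix of AR coefficients ``a``."""
    a = np.asarray(a, dtype=float)
    p = a.size
    if p == 1:
        return abs(a[0])
    C = np.zeros((p, p))
    C[0, :] = a
    C[1:, :-1] = np.eye(p - 1)
    return float(np.max(np.abs(np.linalg.eigvals(C))))


def _check_stable(model: JointModel, label: str):
    r = ar_spectral_radius(model.a)
    if r >= 1.0:
        raise ValueError(
            f"unstable continuous AR in {label} model: spectral radius {r:.4f} >= 1"
        )


def simulate_mixed(cfg: SimConfig) -> TrialSet:
    """Simulate a TrialSet from the generative joint model.

    Histories start at zero and a burn-in of ``10 p`` bins per trial is
    discarded so trial starts are near-stationary.  If ``onset_bin`` and
    ``post_onset_model`` are set, parameters switch at that bin and the time
    axis places 0 ms at the switch.
    """
    model = cfg.model
    _check_stable(model, "base")
    if cfg.post_onset_model is not None:
        if cfg.post_onset_model.p != model.p:
            raise ValueError("post_onset_model must share the base model order")
        _check_stable(cfg.post_onset_model, "post-onset")
    p = model.p
    burn = 10 * p
    rng = np.random.default_rng(cfg.seed)
    n_trials, n_bins = cfg.n_trials, cfg.n_bins

    Yh = np.zeros((n_trials, p))  # most-recent-first
    Xh = np.zeros((n_trials, p))
    lfp = np.empty((n_trials, n_bins))
    spikes = np.empty((n_trials, n_bins), dtype=np.int64)

    for t in range(-burn, n_bins):
        m = model
        if (
            cfg.post_onset_model is not None
            and cfg.onset_bin is not None
            and t >= cfg.onset_bin
        ):
            m = cfg.post_onset_model
        mu = m.c_y + Yh @ m.a + Xh @ m.b
        eta = m.c_x + Xh @ m.d + Yh @ m.e
        z_y = rng.standard_normal(n_trials)
        u = rng.standard_normal(n_trials)
        z_x = m.rho * z_y + math.sqrt(1.0 - m.rho * m.rho) * u
        y = mu + m.sigma * z_y
        x = (z_x > -eta).astype(np.int64)
        if t >= 0:
            lfp[:, t] = y
            spikes[:, t] = x
        if p > 1:
            Yh[:, 1:] = Yh[:, :-1]
            Xh[:, 1:] = Xh[:, :-1]
        Yh[:, 0] = y
        Xh[:, 0] = x

    onset = cfg.onset_bin if cfg.onset_bin is not None else 0
    t0 = -onset * 1000.0 / cfg.fs
    t_axis = t0 + np.arange(n_bins) * 1000.0 / cfg.fs
    ts = TrialSet(
        lfp=lfp, spikes=spikes, t=t_axis, fs=cfg.fs, condition=cfg.condition
    )
    if cfg.contamination is not None:
        ts = inject_spike_artifacts(
            ts, cfg.contamination.template, cfg.contamination.gain
        )
    return ts


def inject_spike_artifacts(ts: TrialSet, template, gain: float) -> TrialSet:
    """Add ``gain * (spikes * template)`` (convolution) to the LFP of each
    trial; spikes are unchanged."""
    template = np.asarray(template, dtype=float)
    if not np.all(np.isfinite(template)):
        raise ValueError("template must be finite")
    lfp = ts.lfp.copy()
    for i in range(ts.n_trials):
        lfp[i] += gain * np.convolve(ts.spikes[i].astype(float), template)[: ts.n_bins]
    return TrialSet(
        lfp=lfp, spikes=ts.spikes.copy(), t=ts.t.copy(), fs=ts.fs,
        condition=ts.condition,
    )


def _with_coupling(model: JointModel, coupling: float) -> JointModel:
    """Return ``model`` with its spike->LFP cross vector rescaled so its
    leading magnitude equals ``coupling`` (direction taken from the existing
    ``b`` pattern, or lag 1 if ``b`` is zero)."""
    b = np.asarray(model.b, dtype=float)
    norm = np.linalg.norm(b, ord=np.inf)
    if norm > 0:
        unit = b / norm
    else:
        unit = np.zeros(model.p)
        unit[0] = 1.0
    return replace(model, b=coupling * unit)


def make_condition_pair(
    base_cfg: SimConfig, coupling_weak: float, coupling_strong: float
):
    """Two TrialSets identical in every generator parameter except the
    post-onset spike->LFP coupling magnitude; labeled "1-bar" (weak) and
    "7-bar" (strong).  Seeds are ``seed`` and ``seed + 1``."""
    post = base_cfg.post_onset_model
    if post is None:
        post = base_cfg.model
        if base_cfg.onset_bin is None:
            raise ValueError("base_cfg must define onset_bin for a condition pair")
    out = []
    for coupling, label, seed_off in (
        (coupling_weak, "1-bar", 0),
        (coupling_strong, "7-bar", 1),
    ):
        cfg = replace(
            base_cfg,
            post_onset_model=_with_coupling(post, coupling),
            seed=base_cfg.seed + seed_off,
            condition=label,
        )
        out.append(simulate_mixed(cfg))
    return tuple(out)
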