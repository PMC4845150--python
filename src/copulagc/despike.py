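"""Removal of spike-waveform leakage from the LFP channel.

A single trial- and unit-invariant artifact template is estimated by least
squares: the LFP is regressed on shifted copies of the spike train over a
short post-spike window (plus an intercept).  This is a deconvolved
spike-triggered average — exact under linear superposition even when spike
windows overlap — and subtracting the convolution of spikes with the fitted
template is the exact inverse of template injection when the template
matches.  It deliberately stands in for more elaborate probabilistic
despiking schemes: the contamination control only requires that artifact
energy locked to spike times be removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_preprocess import TrialSet

__all__ = ["ArtifactModel", "estimate_artifact_template", "remove_spike_artifacts"]


@dataclass(frozen=True)
class ArtifactModel:
    """Per-bin artifact shape (LFP units) starting at the spike bin."""

    template: np.ndarray
    window_ms: float
    n_spikes_used: int

    def __post_init__(self):
        object.__setattr__(self, "template", np.asarray(self.template, dtype=float))
        if not np.all(np.isfinite(self.template)):
            raise ValueError("template must be finite")


def estimate_artifact_template(ts: TrialSet, window_ms: float = 5.0) -> ArtifactModel:
    """Least-squares artifact template over a ``window_ms`` post-spike window.

    Solves ``lfp ~ intercept + sum_k template[k] * spikes_{t-k}`` jointly over
    all trials, which handles overlapping spikes exactly.  Requires at least
    one spike; fewer than 20 produces a warning.
    """
    n_spikes = int(ts.spikes.sum())
    if n_spikes == 0:
        raise ValueError("cannot estimate an artifact template without spikes")
    if n_spikes < 20:
        warnings.warn(
            f"only {n_spikes} spikes available for template estimation; "
            "the template will be noisy",
            stacklevel=2,
        )
    L = max(1, int(round(window_ms * ts.fs / 1000.0)))
    n_bins = ts.n_bins
    spk = ts.spikes.astype(float)
    # columns: intercept then spike train delayed by k = 0..L-1
    X = np.zeros((ts.n_trials * n_bins, L + 1))
    X[:, 0] = 1.0
    for k in range(L):
        shifted = np.zeros_like(spk)
        shifted[:, k:] = spk[:, : n_bins - k]
        X[:, k + 1] = shifted.ravel()
    coef, *_ = np.linalg.lstsq(X, ts.lfp.ravel(), rcond=None)
    return ArtifactModel(
        template=coef[1:], window_ms=window_ms, n_spikes_used=n_spikes
    )


def remove_spike_artifacts(ts: TrialSet, am: ArtifactModel) -> TrialSet:
    """Subtract ``spikes * template`` (convolution) from the LFP per trial.

    Exact inverse of artifact injection when the template matches; spikes are
    unchanged.
    """
    lfp = ts.lfp.copy()
    for i in range(ts.n_trials):
        lfp[i] -= np.convolve(ts.spikes[i].astype(float), am.template)[: ts.n_bins]
    return TrialSet(
        lfp=lfp, spikes=ts.spikes.copy(), t=ts.t.copy(), fs=ts.fs,
        condition=ts.condition,
    )
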