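"""Trial-structured data containers, file formats, and signal conditioning.

The continuous channel (LFP) is stored as a ``n_trials x n_bins`` float
matrix, the discrete channel (spikes) as a same-shaped nonnegative-integer
matrix binned at the LFP sampling rate.  The time axis is in milliseconds
relative to stimulus onset (bin 0 of the axis need not be onset; the axis is
explicit so the alignment convention is visible in the files themselves).

Formats
-------
Delimited trial format (plain text)::

    #fs=1000.0
    #condition=1-bar
    #t0_ms=-300.0
    LFP
    <n_trials rows of n_bins tab-separated floats>
    ==
    SPIKES
    <n_trials rows of n_bins tab-separated integers>

Spike-time lists are two-column text (unit_id, time_s).  An ``.npz`` array
container with keys ``lfp, spikes, t, fs, condition`` is supported for both
reading and writing; MAT-files with the same variable names are supported
read-only for legacy data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as _sig

logger = logging.getLogger(__name__)

__all__ = [
    "RawTrace",
    "SpikeTimes",
    "TrialSet",
    "lowpass_downsample",
    "binarize_spikes",
    "align_trials",
    "read_trialset",
    "write_trialset",
    "read_spike_times",
    "write_spike_times",
]


@dataclass(frozen=True)
class RawTrace:
    """A regularly sampled continuous trace."""

    samples: np.ndarray
    fs: float
    channel_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a 1-D sequence of length >= 1")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class SpikeTimes:
    """Sorted spike event times in seconds for one unit."""

    times: np.ndarray
    unit_id: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("times must be 1-D")
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("spike times must be nondecreasing")
        if times.size and times[0] < 0:
            raise ValueError("spike times must be >= 0")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TrialSet:
    """Aligned trials of one continuous and one discrete channel.

    ``t`` is in milliseconds relative to stimulus onset and must be uniform
    at step ``1000/fs``.
    """

    lfp: np.ndarray
    spikes: np.ndarray
    t: np.ndarray
    fs: float
    condition: str = ""

    def __post_init__(self):
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.spikes = np.asarray(self.spikes)
        self.t = np.asarray(self.t, dtype=float)
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be 2-D (n_trials x n_bins)")
        if self.lfp.shape != self.spikes.shape:
            raise ValueError(
                f"lfp shape {self.lfp.shape} != spikes shape {self.spikes.shape}"
            )
        if self.t.shape != (self.lfp.shape[1],):
            raise ValueError(
                f"time axis length {self.t.shape} does not match "
                f"n_bins {self.lfp.shape[1]}"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.issubdtype(self.spikes.dtype, np.integer):
            spk = self.spikes
            if not np.allclose(spk, np.round(spk)):
                raise ValueError("spikes must be integers")
            self.spikes = np.round(spk).astype(np.int64)
        else:
            self.spikes = self.spikes.astype(np.int64)
        if np.any(self.spikes < 0):
            raise ValueError("spikes must be nonnegative")
        if self.t.size > 1:
            dt = np.diff(self.t)
            expected = 1000.0 / self.fs
            if np.any(dt <= 0) or not np.allclose(dt, expected, rtol=1e-6):
                raise ValueError(
                    f"time axis must be strictly increasing with uniform "
                    f"step {expected} ms"
                )

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_bins(self) -> int:
        return self.lfp.shape[1]

    @property
    def is_binary(self) -> bool:
        return bool(np.all(self.spikes <= 1))

    def select_bins(self, start: int, stop: int) -> "TrialSet":
        """Sub-TrialSet over a contiguous bin range [start, stop)."""
        return TrialSet(
            lfp=self.lfp[:, start:stop],
            spikes=self.spikes[:, start:stop],
            t=self.t[start:stop],
            fs=self.fs,
            condition=self.condition,
        )

    def select_trials(self, idx) -> "TrialSet":
        """Sub-TrialSet over a trial index array (resampling allowed)."""
        idx = np.asarray(idx, dtype=int)
        return TrialSet(
            lfp=self.lfp[idx],
            spikes=self.spikes[idx],
            t=self.t.copy(),
            fs=self.fs,
            condition=self.condition,
        )


def lowpass_downsample(raw: RawTrace, cutoff_hz: float, fs_out: float) -> RawTrace:
    """Zero-phase low-pass filter then downsample to ``fs_out``.

    A 4th-order Butterworth filter is applied forward-backward so event times
    stay aligned.  Integer rate ratios are decimated directly; non-integer
    ratios fall back to polyphase rational resampling of the filtered trace.
    Output length is ``floor(len(raw) * fs_out / raw.fs)``.
    """
    if fs_out > raw.fs:
        raise ValueError(f"fs_out {fs_out} exceeds input rate {raw.fs}")
    if not 0 < cutoff_hz < fs_out / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, output Nyquist {fs_out / 2} Hz)"
        )
    sos = _sig.butter(4, cutoff_hz, btype="low", fs=raw.fs, output="sos")
    filtered = _sig.sosfiltfilt(sos, raw.samples)
    n_out = int(math.floor(len(raw) * fs_out / raw.fs))
    ratio = Fraction(fs_out) / Fraction(raw.fs)
    if ratio.numerator == 1:
        out = filtered[:: ratio.denominator]
    else:
        out = _sig.resample_poly(filtered, ratio.numerator, ratio.denominator)
    out = out[:n_out]
    return RawTrace(samples=out, fs=fs_out, channel_id=raw.channel_id)


def binarize_spikes(
    spk: SpikeTimes,
    fs_out: float,
    t_start_s: float,
    t_end_s: float,
    mode: str = "binary",
) -> np.ndarray:
    """Bin spike times into half-open bins ``[t0 + b/fs, t0 + (b+1)/fs)``.

    ``binary`` mode clips multi-spike bins to 1 (with a logged warning);
    ``count`` mode keeps the per-bin event count.
    """
    if mode not in ("binary", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    if not t_end_s > t_start_s:
        raise ValueError("t_end_s must exceed t_start_s")
    if not fs_out > 0:
        raise ValueError("fs_out must be positive")
    n = int(round((t_end_s - t_start_s) * fs_out))
    times = spk.times
    inside = (times >= t_start_s) & (times < t_end_s)
    idx = np.floor((times[inside] - t_start_s) * fs_out).astype(int)
    idx = idx[idx < n]  # guard float edge at the right boundary
    counts = np.bincount(idx, minlength=n)
    if mode == "binary":
        n_clipped = int(np.sum(counts[counts > 1] - 1))
        if n_clipped:
            logger.warning(
                "binarize_spikes: clipped %d extra spike(s) in multi-spike bins "
                "(unit %r)", n_clipped, spk.unit_id,
            )
        counts = np.minimum(counts, 1)
    return counts.astype(np.int64)


def align_trials(
    lfp_trace: RawTrace,
    spk: SpikeTimes,
    onsets_s,
    window_ms,
    condition: str = "",
    spike_mode: str = "binary",
) -> TrialSet:
    """Cut trials around stimulus onsets; bin spikes at the LFP rate.

    ``window_ms`` is ``(pre, post)`` with ``pre < 0 <= post``; the time axis
    runs from ``pre`` (inclusive) toward ``post`` with one bin per LFP sample.
    Any onset whose window exceeds the trace bounds is rejected by index.
    """
    pre, post = window_ms
    if not (pre < 0 <= post):
        raise ValueError(f"window must satisfy pre < 0 <= post, got {window_ms}")
    onsets_s = np.asarray(onsets_s, dtype=float)
    fs = lfp_trace.fs
    n_bins = int(round((post - pre) * fs / 1000.0))
    lfp_rows = np.empty((len(onsets_s), n_bins))
    spk_rows = np.empty((len(onsets_s), n_bins), dtype=np.int64)
    for i, onset in enumerate(onsets_s):
        t0 = onset + pre / 1000.0
        start = int(round(t0 * fs))
        if start < 0 or start + n_bins > len(lfp_trace):
            raise ValueError(
                f"trial window out of trace bounds at onset index {i} "
                f"(onset {onset} s, samples [{start}, {start + n_bins}) of "
                f"{len(lfp_trace)})"
            )
        lfp_rows[i] = lfp_trace.samples[start : start + n_bins]
        spk_rows[i] = binarize_spikes(
            spk, fs, t0, t0 + n_bins / fs, mode=spike_mode
        )
    t = pre + np.arange(n_bins) * 1000.0 / fs
    return TrialSet(lfp=lfp_rows, spikes=spk_rows, t=t, fs=fs, condition=condition)


# ---------------------------------------------------------------------------
# file formats


def write_trialset(ts: TrialSet, path, format: str = "delimited"):
    """Write a TrialSet; ``format`` is ``delimited`` (text) or ``npz``."""
    path = Path(path)
    if format == "delimited":
        with open(path, "w") as fh:
            fh.write(f"#fs={float(ts.fs)!r}\n")
            fh.write(f"#condition={ts.condition}\n")
            fh.write(f"#t0_ms={float(ts.t[0])!r}\n")
            fh.write("LFP\n")
            for row in ts.lfp:
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")
            fh.write("==\n")
            fh.write("SPIKES\n")
            for row in ts.spikes:
                fh.write("\t".join(str(int(v)) for v in row) + "\n")
    elif format == "npz":
        np.savez(
            path,
            lfp=ts.lfp,
            spikes=ts.spikes,
            t=ts.t,
            fs=np.asarray(ts.fs),
            condition=np.asarray(ts.condition),
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_trialset(path, format: str | None = None) -> TrialSet:
    """Read a TrialSet written by :func:`write_trialset` (or a legacy MAT file
    with variables ``lfp, spikes, t, fs, condition``)."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"npz": "npz", ".npz": "npz", ".mat": "mat"}.get(suffix, "delimited")
    if format == "delimited":
        return _read_delimited(path)
    if format == "npz":
        with np.load(path, allow_pickle=False) as data:
            return TrialSet(
                lfp=data["lfp"],
                spikes=data["spikes"],
                t=data["t"],
                fs=float(data["fs"]),
                condition=str(data["condition"]),
            )
    if format == "mat":
        from scipy.io import loadmat

        data = loadmat(path, squeeze_me=True)
        return TrialSet(
            lfp=np.atleast_2d(data["lfp"]),
            spikes=np.atleast_2d(data["spikes"]),
            t=np.ravel(data["t"]),
            fs=float(data["fs"]),
            condition=str(data.get("condition", "")),
        )
    raise ValueError(f"unknown format {format!r}")


def _read_delimited(path: Path) -> TrialSet:
    header: dict[str, str] = {}
    lfp_rows: list[list[float]] = []
    spk_rows: list[list[int]] = []
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                header[key] = val
            elif line == "LFP":
                section = "lfp"
            elif line == "SPIKES":
                section = "spikes"
            elif line == "==":
                section = None
            elif section == "lfp":
                lfp_rows.append([float(v) for v in line.split("\t")])
            elif section == "spikes":
                spk_rows.append([int(v) for v in line.split("\t")])
            else:
                raise ValueError(f"unexpected line outside any block: {line!r}")
    if "fs" not in header:
        raise ValueError("missing #fs header")
    fs = float(header["fs"])
    lfp = np.asarray(lfp_rows, dtype=float)
    spikes = np.asarray(spk_rows, dtype=np.int64)
    if lfp.ndim != 2 or spikes.ndim != 2 or lfp.shape != spikes.shape:
        raise ValueError(
            f"LFP block shape {lfp.shape if lfp.ndim == 2 else 'ragged'} does not "
            f"match SPIKES block shape {spikes.shape if spikes.ndim == 2 else 'ragged'}"
        )
    if np.any(spikes < 0):
        raise ValueError("SPIKES block violates nonnegativity")
    t0 = float(header.get("t0_ms", "0"))
    t = t0 + np.arange(lfp.shape[1]) * 1000.0 / fs
    return TrialSet(
        lfp=lfp, spikes=spikes, t=t, fs=fs, condition=header.get("condition", "")
    )


def write_spike_times(spk_list, path):
    """Write spike-time lists as two-column text (unit_id, time_s)."""
    if isinstance(spk_list, SpikeTimes):
        spk_list = [spk_list]
    with open(path, "w") as fh:
        for spk in spk_list:
            for t in spk.times:
                fh.write(f"{spk.unit_id}\t{t:.9f}\n")
    return path


def read_spike_times(path) -> list[SpikeTimes]:
    """Read spike-time lists written by :func:`write_spike_times`."""
    by_unit: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            unit, _, t = line.partition("\t")
            by_unit.setdefault(unit, []).append(float(t))
    return [
        SpikeTimes(times=np.asarray(times), unit_id=unit)
        for unit, times in by_unit.items()
    ]
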