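"""Simulated local field potentials from synaptic currents.

The LFP proxy for one area is the electrode resistance times the mean over
excitatory neurons of the rectified synaptic currents,

    LFP(t) = R * sum_i (|I_E,i| + |I_I,i| + |I_bkg,i|) / N_E ,

with R = 1 MOhm, so nA sums give mV.  The raw signal (at the 10 kHz
simulation resolution) is mean-subtracted, zero-phase low-pass filtered and
decimated to 1 kHz before connectivity estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .network import CurrentTraces

__all__ = ["LFPRecord", "compute_lfp", "preprocess", "psd"]

DEFAULT_R_MOHM = 1.0


@dataclass(frozen=True)
class LFPRecord:
    """Preprocessed multi-area LFP: (n_samples, n_areas) in mV at ``fs`` Hz.
    ``transient_cut_s`` records how much initial signal was discarded."""

    signals: np.ndarray
    fs: float
    R_mohm: float = DEFAULT_R_MOHM
    transient_cut_s: float = 0.0
    area_labels: list[str] = field(default_factory=list)

    @property
    def n_areas(self) -> int:
        return self.signals.shape[1]


def compute_lfp(currents: CurrentTraces, R_mohm: float = DEFAULT_R_MOHM) -> np.ndarray:
    """Raw LFP (mV) per area at simulation resolution.

    ``currents`` already holds per-neuron-rectified sums over excitatory
    neurons; the absolute value here is idempotent on those sums.
    Returns (n_steps, n_areas).
    """
    comps = (currents.abs_I_E, currents.abs_I_I, currents.abs_I_bkg)
    n = {c.shape for c in comps}
    if len(n) != 1:
        raise ValueError("mismatched current trace lengths")
    total = sum(np.abs(np.asarray(c, dtype=float)) for c in comps)
    return R_mohm * total / currents.n_exc


def preprocess(
    raw: np.ndarray,
    fs_in: float,
    fs_out: float = 1000.0,
    cutoff: float | None = None,
    transient_s: float = 1.0,
    order: int = 8,
    R_mohm: float = DEFAULT_R_MOHM,
    area_labels=None,
) -> LFPRecord:
    """Anti-alias filter, decimate to ``fs_out``, mean-subtract.

    The transient is cut first; the mean is computed on the retained segment.
    Filtering is an ``order``-th order zero-phase (forward-backward)
    Butterworth low-pass at ``cutoff`` Hz (default 0.9 x the output Nyquist,
    which actually prevents aliasing at the target rate).  The decimation
    factor fs_in/fs_out must be an integer.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"non-integer decimation factor {factor}")
    factor = int(round(factor))
    cut = 0.45 * fs_out if cutoff is None else cutoff
    n_cut = int(round(transient_s * fs_in))
    x = x[n_cut:]
    x = x - x.mean(axis=0, keepdims=True)
    if factor > 1:
        sos = scipy.signal.butter(order, cut, btype="low", fs=fs_in, output="sos")
        x = scipy.signal.sosfiltfilt(sos, x, axis=0)
        x = x[::factor]
    x = x - x.mean(axis=0, keepdims=True)
    labels = list(area_labels) if area_labels is not None else []
    return LFPRecord(np.ascontiguousarray(x), fs_out, R_mohm, transient_s, labels)


def lfp_from_currents(
    currents: CurrentTraces,
    R_mohm: float = DEFAULT_R_MOHM,
    fs_out: float = 1000.0,
    transient_s: float = 1.0,
    cutoff: float | None = None,
) -> LFPRecord:
    """Convenience chain: compute_lfp then preprocess."""
    raw = compute_lfp(currents, R_mohm)
    return preprocess(
        raw,
        fs_in=currents.sampling_rate,
        fs_out=fs_out,
        cutoff=cutoff,
        transient_s=transient_s,
        R_mohm=R_mohm,
        area_labels=currents.area_labels,
    )


def psd(
    record: LFPRecord, segment_s: float = 1.0, overlap: float = 0.5
):
    """Averaged modified periodogram (Welch) PSD per area.

    Returns (frequencies_hz, psd) with psd of shape (n_freq, n_areas);
    density normalization, so the integral over frequency equals the signal
    variance.
    """
    nper = int(round(segment_s * record.fs))
    if nper > record.signals.shape[0] // 2:
        raise ValueError("segment longer than half the signal")
    f, p = scipy.signal.welch(
        record.signals,
        fs=record.fs,
        nperseg=nper,
        noverlap=int(nper * overlap),
        axis=0,
    )
    return f, p
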