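"""End-to-end drivers: simulate a network, synthesize the LFP, estimate GPDC,
and assemble edge tables.  The analysis scripts, the test suite and the
acceptance script all go through these functions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import analysis as an
from .connectome import FLNMatrix
from .lfp import LFPRecord, lfp_from_currents
from .mvar import edge_summary, gpdc, select_order
from .network import NetworkSpec, firing_rate, run_simulation

__all__ = ["SimulationResult", "simulate_lfp", "gpdc_summaries", "run_pipeline"]


@dataclass(frozen=True)
class SimulationResult:
    """One simulated run: spikes, LFP, and per-area excitatory rates (Hz)."""

    lfp: LFPRecord
    exc_rates: np.ndarray
    inh_rates: np.ndarray
    mean_exc_rate: float
    mean_inh_rate: float


def simulate_lfp(
    spec: NetworkSpec, transient_s: float = 1.0, progress: bool = False
) -> SimulationResult:
    """Run the spiking simulation and return the preprocessed 1 kHz LFP plus
    per-area mean firing rates (100 ms sliding window, transient excluded)."""
    raster, currents = run_simulation(spec, progress=progress)
    rec = lfp_from_currents(currents, transient_s=transient_s)
    n_areas = spec.n_areas
    exc = np.array(
        [
            firing_rate(raster, exc=True, area=a, transient=transient_s * 1000.0)[2]
            for a in range(n_areas)
        ]
    )
    inh = np.array(
        [
            firing_rate(raster, exc=False, area=a, transient=transient_s * 1000.0)[2]
            for a in range(n_areas)
        ]
    )
    _, _, mexc = firing_rate(raster, exc=True, transient=transient_s * 1000.0)
    _, _, minh = firing_rate(raster, exc=False, transient=transient_s * 1000.0)
    return SimulationResult(rec, exc, inh, mexc, minh)


def gpdc_summaries(record: LFPRecord, p_max: int = 50, n_freq: int = 512) -> dict:
    """Fit one full MVAR on all areas of a run, return GPDC edge summaries
    ('peak', 'mean', 'auc' matrices) plus the selected order under 'p'."""
    x = np.ascontiguousarray(record.signals.T)
    p_star, model = select_order(x, p_max)
    spec = gpdc(model, n_freq)
    return {
        "peak": edge_summary(spec, "peak"),
        "mean": edge_summary(spec, "mean"),
        "auc": edge_summary(spec, "auc"),
        "p": p_star,
    }


def run_pipeline(
    fln: FLNMatrix,
    distances,
    n_sims: int,
    duration: float,
    seed: int,
    p_max: int = 50,
    transient_s: float = 1.0,
    progress: bool = False,
    **spec_kw,
):
    """Simulate ``n_sims`` runs of the same connectome (fresh wiring noise and
    background per run) and return (edge_table, results, signals_by_sim).

    ``signals_by_sim`` maps run id -> (M, T) LFP arrays for the conditioning
    experiments; ``results`` are the per-run SimulationResult objects.
    """
    child = np.random.SeedSequence(seed).spawn(n_sims)
    results, summaries, signals = [], {}, {}
    for k in range(n_sims):
        run_seed = int(child[k].generate_state(1)[0] % (2**31))
        spec = NetworkSpec(
            fln=fln,
            distances=distances,
            duration=duration,
            seed=run_seed,
            **spec_kw,
        )
        res = simulate_lfp(spec, transient_s=transient_s, progress=progress)
        results.append(res)
        mats = gpdc_summaries(res.lfp, p_max=p_max)
        summaries[k] = {kk: vv for kk, vv in mats.items() if kk != "p"}
        signals[k] = np.ascontiguousarray(res.lfp.signals.T)
    table = an.build_edge_table(fln, summaries)
    return table, results, signals
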