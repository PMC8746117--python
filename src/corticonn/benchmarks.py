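"""Reference study configurations.

These functions pin down the exact problem sizes used for the package's
headline checks so that scripts and tests run the identical configuration:

* a reduced three-area network with full-size (2,000-neuron) populations and
  a normalized synthetic connectome, used to measure population firing rates;
* a full 19-area pipeline (simulation -> LFP -> GPDC -> edge table) at sizes
  chosen to run on a single CPU (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .connectome import DistanceMatrix
from .network import NetworkSpec, firing_rate, run_simulation
from .pipeline import run_pipeline
from .synthetic import SyntheticConnectomeParams, generate_distances, generate_fln

__all__ = ["three_area_rates", "full_scale_pipeline"]


def _delay_scaled_distances(n_areas: int, seed: int, speed: float = 3.5,
                            delay_range_ms=(1.0, 3.0)) -> DistanceMatrix:
    """Random area geometry rescaled so conduction delays span the given
    range (long-range delays of a few milliseconds at 3.5 m/s)."""
    d = generate_distances(n_areas, seed=seed).values
    off = ~np.eye(n_areas, dtype=bool)
    lo, hi = delay_range_ms[0] * speed, delay_range_ms[1] * speed  # mm
    dmin, dmax = d[off].min(), d[off].max()
    scaled = np.zeros_like(d)
    scaled[off] = lo + (d[off] - dmin) / (dmax - dmin) * (hi - lo)
    return DistanceMatrix((scaled + scaled.T) / 2)


def three_area_rates(seed: int = 1, duration: float = 10.0):
    """Mean excitatory/inhibitory population rates of a reduced three-area
    network with full-size populations.

    The connectome is synthetic with every row rescaled to sum 0.6 and
    delays spanning 1-3 ms; the simulation runs ``duration`` seconds at
    dt = 0.1 ms with the default model parameters, and rates are computed
    with a 100 ms sliding window after discarding a 1 s transient.
    Returns (exc_hz, inh_hz, n_neurons).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    conn_seed, dist_seed, sim_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss
    )
    fln = generate_fln(
        SyntheticConnectomeParams(
            n_areas=3, density=1.0, row_sum_range=(0.6, 0.6), seed=conn_seed
        )
    )
    dist = _delay_scaled_distances(3, dist_seed)
    spec = NetworkSpec(fln=fln, distances=dist, duration=duration, seed=sim_seed)
    raster, _ = run_simulation(spec)
    _, _, exc = firing_rate(raster, exc=True, transient=1000.0)
    _, _, inh = firing_rate(raster, exc=False, transient=1000.0)
    return exc, inh, 3 * spec.population.n


def full_scale_pipeline(
    seed: int = 1,
    n_sims: int = 2,
    duration: float = 8.0,
    p_max: int = 20,
):
    """Full 19-area pipeline at single-CPU problem sizes.

    Generates a synthetic 19-area connectome (default tract-tracing-like
    parameters), runs ``n_sims`` simulations of ``duration`` seconds with
    full 2,000-neuron populations, estimates the full GPDC per run and
    returns (fln, edge_table, results, signals_by_sim).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    conn_seed, dist_seed, pipe_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss
    )
    fln = generate_fln(SyntheticConnectomeParams(n_areas=19, seed=conn_seed))
    dist = _delay_scaled_distances(19, dist_seed)
    table, results, signals = run_pipeline(
        fln, dist, n_sims=n_sims, duration=duration, seed=pipe_seed, p_max=p_max
    )
    return fln, table, results, signals
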