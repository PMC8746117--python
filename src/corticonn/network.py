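"""Multi-area conductance-based spiking cortical network.

Each cortical area is a population of 2,000 Hodgkin-Huxley neurons (1,600
excitatory, 400 inhibitory) with random intra-areal wiring (p = 0.10),
conductance synapses (exponential decay, tau_E = 2 ms, tau_I = 8 ms), and a
7.3 kHz Poisson background drive per neuron.  Areas are coupled by excitatory
long-range projections wired with p = 0.05 whose weights are the structural
FLN values scaled by global gains (mu_E = 50 onto excitatory targets, mu_I =
25 onto inhibitory targets, in nS) and whose conduction delays are
distance / 3.5 m/s.  Integration is exponential Euler at dt = 0.1 ms.

Units: mV, ms, nF, uS (so currents come out in nA).  Synaptic weights are
specified in nS and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectome import DistanceMatrix, FLNMatrix
from ._engine import run_chunk

__all__ = [
    "NeuronParameters",
    "SynapseParams",
    "PopulationSpec",
    "LongRangeSpec",
    "NetworkSpec",
    "SpikeRaster",
    "CurrentTraces",
    "gate_rates",
    "steady_state_gates",
    "hh_step",
    "build_intra",
    "build_long_range",
    "run_simulation",
    "firing_rate",
]

EXC_POOL = 0  # excitatory conductance pool (local E + long-range), tau_exc, E = 0 mV
INH_POOL = 1  # inhibitory pool, tau_inh, E = -70 mV


@dataclass(frozen=True)
class NeuronParameters:
    """Single-compartment HH parameters (capacitance nF, conductance uS,
    potentials mV, current nA)."""

    C_m_exc: float = 0.50
    C_m_inh: float = 0.25
    g_Na: float = 12.5
    g_K: float = 4.74
    g_L: float = 0.025
    E_Na: float = 40.0
    E_K: float = -80.0
    E_L: float = -65.0
    I_ext: float = 0.0

    def __post_init__(self) -> None:
        if min(self.g_Na, self.g_K, self.g_L) <= 0:
            raise ValueError("conductances must be positive")
        if not (self.E_K < self.E_L < self.E_Na):
            raise ValueError("expected E_K < E_L < E_Na")


# (mean, sd) in nS per connection class
_DEFAULT_WEIGHTS = {
    "EE": (2.5, 1.0),
    "EI": (2.5, 1.0),
    "IE": (240.0, 10.0),
    "II": (240.0, 10.0),
    "bgE": (3.2, 1.0),
    "bgI": (3.2, 1.0),
}


@dataclass(frozen=True)
class SynapseParams:
    """Conductance-synapse parameters.  ``weight_table`` maps connection class
    ('EE' = E source onto E target, ..., 'bgE' = background onto E) to
    (mean, sd) of the Gaussian weight distribution in nS (truncated at 0)."""

    E_syn_exc: float = 0.0
    E_syn_inh: float = -70.0
    tau_exc: float = 2.0
    tau_inh: float = 8.0
    intra_delay: float = 1.0
    weight_table: dict = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        if self.tau_exc <= 0 or self.tau_inh <= 0:
            raise ValueError("synaptic time constants must be positive")
        for k, (mu, _sd) in self.weight_table.items():
            if mu <= 0:
                raise ValueError(f"mean weight for class {k} must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """One cortical area: N_E excitatory + N_I inhibitory neurons, random
    recurrent wiring with probability ``p_intra``, per-neuron Poisson
    background at ``background_rate`` (Hz)."""

    N_E: int = 1600
    N_I: int = 400
    p_intra: float = 0.10
    background_rate: float = 7300.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_intra < 1:
            raise ValueError("p_intra must be in [0, 1)")
        if self.N_E < 1 or self.N_I < 0:
            raise ValueError("population sizes invalid")

    @property
    def n(self) -> int:
        return self.N_E + self.N_I


@dataclass(frozen=True)
class LongRangeSpec:
    """Inter-areal projection parameters: wiring probability, FLN weight
    gains (nS per unit FLN), and axonal conduction speed (m/s)."""

    p_inter: float = 0.05
    mu_E: float = 50.0
    mu_I: float = 25.0
    conduction_speed: float = 3.5

    def __post_init__(self) -> None:
        if not 0 <= self.p_inter < 1:
            raise ValueError("p_inter must be in [0, 1)")
        if self.mu_E <= 0 or self.mu_I <= 0 or self.conduction_speed <= 0:
            raise ValueError("long-range parameters must be positive")


@dataclass(frozen=True)
class NetworkSpec:
    """Full parameterization of a multi-area simulation."""

    fln: FLNMatrix
    distances: DistanceMatrix
    duration: float = 30.0  # seconds
    dt: float = 0.1  # ms
    seed: int = 0
    population: PopulationSpec = field(default_factory=PopulationSpec)
    synapses: SynapseParams = field(default_factory=SynapseParams)
    neurons: NeuronParameters = field(default_factory=NeuronParameters)
    long_range: LongRangeSpec = field(default_factory=LongRangeSpec)
    spike_threshold: float = 0.0  # mV, upward crossing
    refractory_detect: float = 2.0  # ms, minimum inter-spike interval for detection

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.fln.n_areas != self.distances.n_areas:
            raise ValueError("FLN and distance matrices disagree on area count")

    @property
    def n_areas(self) -> int:
        return self.fln.n_areas

    def with_(self, **kw) -> "NetworkSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class SpikeRaster:
    """All spikes of a simulation as flat arrays plus neuron metadata.

    ``times`` (ms) and ``neuron_ids`` are sorted by time; ``area_of`` and
    ``is_exc`` index by global neuron id.
    """

    times: np.ndarray
    neuron_ids: np.ndarray
    area_of: np.ndarray
    is_exc: np.ndarray
    duration: float  # ms
    area_labels: list[str] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.area_of.shape[0]

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron]

    def area_spikes(self, area: int, exc_only: bool | None = None):
        sel = self.area_of[self.neuron_ids] == area
        if exc_only is not None:
            sel &= self.is_exc[self.neuron_ids] == exc_only
        return self.times[sel], self.neuron_ids[sel]


@dataclass(frozen=True)
class CurrentTraces:
    """Per-area sums over excitatory neurons of |I_E|, |I_I|, |I_bkg| (nA) at
    simulation resolution.  Rectification (absolute value) is applied per
    neuron and per current component before summing, as the LFP proxy
    requires."""

    abs_I_E: np.ndarray  # (n_steps, n_areas)
    abs_I_I: np.ndarray
    abs_I_bkg: np.ndarray
    dt: float  # ms
    n_exc: int
    area_labels: list[str] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return self.abs_I_E.shape[0]

    @property
    def sampling_rate(self) -> float:
        """Hz"""
        return 1000.0 / self.dt


# ---------------------------------------------------------------------------
# Hodgkin-Huxley kinetics (rates in 1/ms, V in mV)
# ---------------------------------------------------------------------------

def gate_rates(V):
    """Voltage-dependent transition rates (alpha_m, beta_m, alpha_h, beta_h,
    alpha_n, beta_n) in 1/ms.  Removable singularities of alpha_m (V = -16)
    and alpha_n (V = -20) are evaluated by their analytic limits."""
    V = np.asarray(V, dtype=float)
    xm = V + 16.0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        am = np.where(
            np.abs(xm) < 1e-7, 1.0, 0.1 * xm / (1.0 - np.exp(-xm / 10.0))
        )
        bm = 4.0 * np.exp(-(V + 41.0) / 18.0)
        ah = 0.07 * np.exp(-(V + 30.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-V / 10.0))
        xn = V + 20.0
        an = np.where(
            np.abs(xn) < 1e-7, 0.1, 0.01 * xn / (1.0 - np.exp(-xn / 10.0))
        )
        bn = 0.125 * np.exp(-(V + 30.0) / 80.0)
    return am, bm, ah, bh, an, bn


def steady_state_gates(V):
    """Gate steady states (m_inf, h_inf, n_inf) at fixed potential."""
    am, bm, ah, bh, an, bn = gate_rates(V)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def hh_step(state, I_syn, params: NeuronParameters, dt: float, C_m=None):
    """One exponential-Euler step of a single HH neuron.

    ``state`` is (V, m, h, n); gates are advanced exactly for frozen V
    (x <- x_inf + (x - x_inf) e^(-dt (a+b))), then V by exponential Euler on
    the conductance-linearized membrane equation.  ``I_syn`` in nA.
    Reference implementation used by the tests; the network engine applies
    the identical update vectorized.
    """
    V, m, h, n = state
    C = params.C_m_exc if C_m is None else C_m
    am, bm, ah, bh, an, bn = gate_rates(V)
    for idx, (a, b) in enumerate(((am, bm), (ah, bh), (an, bn))):
        r = a + b
        xinf = a / r
        x = (m, h, n)[idx]
        x = xinf + (x - xinf) * np.exp(-dt * r)
        if idx == 0:
            m = x
        elif idx == 1:
            h = x
        else:
            n = x
    gna = params.g_Na * m**3 * h
    gk = params.g_K * n**4
    G = gna + gk + params.g_L
    I_const = gna * params.E_Na + gk * params.E_K + params.g_L * params.E_L
    I_const += params.I_ext + I_syn
    Vinf = I_const / G
    V = Vinf + (V - Vinf) * np.exp(-dt * G / C)
    out = (float(V), float(m), float(h), float(n))
    if not all(np.isfinite(out)):
        raise FloatingPointError("HH integration blew up")
    return out


# ---------------------------------------------------------------------------
# Wiring
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, size):
    """Gaussian draws resampled until positive (conductances keep their sign)."""
    w = rng.normal(mean, sd, size)
    bad = w <= 0
    while np.any(bad):
        w[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = w <= 0
    return w


_EMPTY_BLOCK = (
    np.zeros(0, dtype=np.int32),
    np.zeros(0, dtype=np.int32),
    np.zeros(0, dtype=np.float32),
    np.zeros(0, dtype=np.int16),
    np.zeros(0, dtype=np.int8),
)


def build_intra(
    population: PopulationSpec,
    synapses: SynapseParams,
    rng,
    dt: float = 0.1,
    offset: int = 0,
):
    """Random recurrent wiring of one area: directed Bernoulli(p_intra) over
    ordered neuron pairs (no self-connections), class-dependent truncated-
    Gaussian weights (nS), fixed 1 ms delay.

    Returns (src, tgt, weight_nS, delay_steps, pool) arrays sorted by source,
    with neuron indices shifted by ``offset``.  The first N_E indices of the
    area are excitatory.
    """
    n, ne = population.n, population.N_E
    if population.p_intra == 0:
        return _EMPTY_BLOCK
    src_l, tgt_l = [], []
    for s in range(n):
        r = rng.random(n)
        r[s] = 1.0  # exclude self
        t = np.flatnonzero(r < population.p_intra)
        src_l.append(np.full(t.size, s, dtype=np.int32))
        tgt_l.append(t.astype(np.int32))
    src = np.concatenate(src_l)
    tgt = np.concatenate(tgt_l)
    src_exc = src < ne
    tgt_exc = tgt < ne
    w = np.empty(src.size, dtype=np.float32)
    for cls, s_mask, t_mask in (
        ("EE", src_exc, tgt_exc),
        ("EI", src_exc, ~tgt_exc),
        ("IE", ~src_exc, tgt_exc),
        ("II", ~src_exc, ~tgt_exc),
    ):
        sel = s_mask & t_mask
        mu, sd = synapses.weight_table[cls]
        w[sel] = _truncated_normal(rng, mu, sd, int(sel.sum()))
    delay_steps = max(1, int(np.floor(synapses.intra_delay / dt + 0.5)))
    delays = np.full(src.size, delay_steps, dtype=np.int16)
    pool = np.where(src_exc, EXC_POOL, INH_POOL).astype(np.int8)
    return src + offset, tgt + offset, w, delays, pool


def _iter_long_range_blocks(
    fln: FLNMatrix,
    distances: DistanceMatrix,
    spec: LongRangeSpec,
    population: PopulationSpec,
    rng,
    dt: float = 0.1,
):
    """Yield one compact connection block per ordered area pair (source
    sorted within each block).  Global neuron index of area a starts at
    a * population.n, excitatory first."""
    n_areas = fln.n_areas
    n, ne = population.n, population.N_E
    for i in range(n_areas):  # target
        for j in range(n_areas):  # source
            f = fln.values[i, j]
            if i == j or f == 0:
                continue
            dist = distances.values[i, j]
            if dist <= 0:
                raise ValueError(
                    f"zero distance between distinct areas {i} and {j}: "
                    "conduction delay undefined"
                )
            mask = rng.random((ne, n)) < spec.p_inter
            s_loc, t_loc = np.nonzero(mask)
            if s_loc.size == 0:
                continue
            w = np.where(t_loc < ne, spec.mu_E * f, spec.mu_I * f).astype(np.float32)
            delay_ms = dist / spec.conduction_speed
            d_steps = max(1, int(np.floor(delay_ms / dt + 0.5)))
            yield (
                (s_loc + j * n).astype(np.int32),
                (t_loc + i * n).astype(np.int32),
                w,
                np.full(s_loc.size, d_steps, dtype=np.int16),
                np.full(s_loc.size, EXC_POOL, dtype=np.int8),
            )


def build_long_range(
    fln: FLNMatrix,
    distances: DistanceMatrix,
    spec: LongRangeSpec,
    population: PopulationSpec,
    rng,
    dt: float = 0.1,
):
    """Excitatory inter-areal projections as flat connection arrays.

    For each ordered area pair (source j -> target i) with FLN_ij > 0,
    excitatory neurons of j connect to each neuron of i with probability
    ``p_inter``; the weight is mu_E * FLN_ij onto excitatory targets and
    mu_I * FLN_ij onto inhibitory targets (nS); the delay is
    distance_ij / conduction_speed rounded to the nearest integration step
    (ties up, minimum one step).
    """
    blocks = list(_iter_long_range_blocks(fln, distances, spec, population, rng, dt))
    if not blocks:
        return _EMPTY_BLOCK
    return tuple(np.concatenate([b[k] for b in blocks]) for k in range(5))


def _build_csr(blocks: list, n_neurons: int):
    """Assemble CSR-by-source connectivity from per-source-sorted blocks
    without a global sort (the full network has tens of millions of edges;
    this keeps peak memory at roughly the compact edge arrays themselves).
    Consumes ``blocks`` destructively.  Weights are converted nS -> uS."""
    degree = np.zeros(n_neurons, dtype=np.int64)
    for b in blocks:
        degree += np.bincount(b[0], minlength=n_neurons)
    indptr = np.zeros(n_neurons + 1, dtype=np.int64)
    np.cumsum(degree, out=indptr[1:])
    n_edges = int(indptr[-1])
    tgt = np.empty(n_edges, dtype=np.int32)
    w = np.empty(n_edges, dtype=np.float32)
    d = np.empty(n_edges, dtype=np.int16)
    pool = np.empty(n_edges, dtype=np.int8)
    next_pos = indptr[:-1].copy()
    while blocks:
        src_b, tgt_b, w_b, d_b, p_b = blocks.pop(0)
        if src_b.size == 0:
            continue
        uniq, start, counts = np.unique(src_b, return_index=True, return_counts=True)
        rank = np.arange(src_b.size, dtype=np.int64) - np.repeat(start, counts)
        pos = next_pos[src_b] + rank
        tgt[pos] = tgt_b
        w[pos] = w_b
        d[pos] = d_b
        pool[pos] = p_b
        next_pos[uniq] += counts
    w *= np.float32(1e-3)  # nS -> uS
    return indptr, tgt, w, d, pool


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def run_simulation(spec: NetworkSpec, progress: bool = False):
    """Integrate the full network and return (SpikeRaster, CurrentTraces).

    Deterministic given (spec, seed): the wiring realization, initial
    conditions, and background Poisson trains all derive from ``spec.seed``.
    Aborts with a diagnostic if any membrane potential becomes non-finite.
    """
    n_areas = spec.n_areas
    pop, syn, neu, lr = spec.population, spec.synapses, spec.neurons, spec.long_range
    n_per = pop.n
    n_total = n_areas * n_per
    dt = spec.dt
    n_steps = int(round(spec.duration * 1000.0 / dt))

    ss = np.random.SeedSequence(spec.seed)
    s_wire, s_init, s_bkg = ss.spawn(3)
    rng_w = np.random.default_rng(s_wire)

    blocks = [
        build_intra(pop, syn, rng_w, dt=dt, offset=a * n_per) for a in range(n_areas)
    ]
    if n_areas > 1:
        blocks.extend(
            _iter_long_range_blocks(spec.fln, spec.distances, lr, pop, rng_w, dt=dt)
        )
    indptr, tgt, w, d, pool = _build_csr(blocks, n_total)
    del blocks
    d_max = int(d.max()) if d.size else 1
    ring_len = d_max + 2

    area_of = np.repeat(np.arange(n_areas, dtype=np.int32), n_per)
    local = np.tile(np.arange(n_per), n_areas)
    is_exc = (local < pop.N_E).astype(np.bool_)

    rng_i = np.random.default_rng(s_init)
    V = rng_i.uniform(-70.0, -60.0, n_total)
    m, h, ngate = steady_state_gates(V)
    ge = np.zeros(n_total)
    gi = np.zeros(n_total)
    gb = np.zeros(n_total)
    C = np.where(is_exc, neu.C_m_exc, neu.C_m_inh)
    mu_bE, sd_bE = syn.weight_table["bgE"]
    mu_bI, sd_bI = syn.weight_table["bgI"]
    w_bkg = np.empty(n_total)
    w_bkg[is_exc] = _truncated_normal(rng_i, mu_bE, sd_bE, int(is_exc.sum()))
    w_bkg[~is_exc] = _truncated_normal(rng_i, mu_bI, sd_bI, int((~is_exc).sum()))
    w_bkg *= 1e-3  # nS -> uS

    ring_e = np.zeros((ring_len, n_total))
    ring_i = np.zeros((ring_len, n_total))
    last_spike = np.full(n_total, -10**9, dtype=np.int64)

    decay_e = float(np.exp(-dt / syn.tau_exc))
    decay_i = float(np.exp(-dt / syn.tau_inh))
    refr_steps = max(1, int(round(spec.refractory_detect / dt)))
    lam = pop.background_rate * dt / 1000.0  # expected events per step per neuron

    chunk = int(max(200, min(4000, 1.0e8 // max(1, 8 * n_total))))
    rng_b = np.random.default_rng(s_bkg)

    out_E = np.empty((n_steps, n_areas), dtype=np.float32)
    out_I = np.empty((n_steps, n_areas), dtype=np.float32)
    out_B = np.empty((n_steps, n_areas), dtype=np.float32)
    spk_t_all, spk_id_all = [], []

    head = 0
    step0 = 0
    while step0 < n_steps:
        cs = min(chunk, n_steps - step0)
        counts = rng_b.poisson(lam, size=(cs, n_total)).astype(np.uint8)
        cap = max(100_000, int(n_total * cs * dt / 1000.0 * 200.0))  # 200 Hz headroom
        spk_t = np.empty(cap)
        spk_id = np.empty(cap, dtype=np.int32)
        cE = np.zeros((cs, n_areas))
        cI = np.zeros((cs, n_areas))
        cB = np.zeros((cs, n_areas))
        nspk, head, status, bad_n, bad_s = run_chunk(
            cs, head, step0,
            V, m, h, ngate, ge, gi, gb,
            C, w_bkg, area_of, is_exc,
            indptr, tgt, w, d, pool,
            ring_e, ring_i, counts,
            dt, decay_e, decay_i, refr_steps,
            neu.I_ext, neu.g_Na, neu.g_K, neu.g_L,
            neu.E_Na, neu.E_K, neu.E_L,
            syn.E_syn_exc, syn.E_syn_inh,
            spec.spike_threshold,
            last_spike, cE, cI, cB, spk_t, spk_id,
        )
        if status == 1:
            t_bad = (step0 + bad_s) * dt
            raise FloatingPointError(
                f"non-finite membrane potential: area {area_of[bad_n]}, "
                f"neuron {bad_n}, t = {t_bad:.1f} ms"
            )
        if status == 2:  # spike buffer overflow: extremely high rates
            raise RuntimeError("spike buffer overflow (pathological firing rates)")
        spk_t_all.append(spk_t[:nspk].copy())
        spk_id_all.append(spk_id[:nspk].copy())
        out_E[step0 : step0 + cs] = cE
        out_I[step0 : step0 + cs] = cI
        out_B[step0 : step0 + cs] = cB
        step0 += cs
        if progress:
            print(f"  simulated {step0 * dt / 1000.0:.1f} / {spec.duration:.1f} s")

    times = np.concatenate(spk_t_all) if spk_t_all else np.zeros(0)
    ids = np.concatenate(spk_id_all) if spk_id_all else np.zeros(0, dtype=np.int32)
    labels = list(spec.fln.area_labels)
    raster = SpikeRaster(times, ids, area_of, is_exc, spec.duration * 1000.0, labels)
    traces = CurrentTraces(out_E, out_I, out_B, dt, pop.N_E, labels)
    return raster, traces


def firing_rate(
    raster: SpikeRaster,
    window: float = 100.0,
    exc: bool | None = None,
    transient: float = 1000.0,
    area: int | None = None,
):
    """Population firing rate with a sliding window.

    Returns (time_ms, rate_hz, mean_rate_hz): the rate time series (spike
    count in the window / (window x neuron count)) and its time average over
    t > ``transient``.  ``exc`` filters by neuron type, ``area`` by area.
    """
    if window > raster.duration:
        raise ValueError("window longer than simulation")
    sel = np.ones(raster.times.size, dtype=bool)
    nsel = np.ones(raster.n_neurons, dtype=bool)
    if exc is not None:
        nsel &= raster.is_exc == exc
    if area is not None:
        nsel &= raster.area_of == area
    if exc is not None or area is not None:
        sel = nsel[raster.neuron_ids]
    t = raster.times[sel]
    n_neurons = int(nsel.sum())
    if n_neurons == 0 or t.size == 0:
        edges = np.arange(0.0, raster.duration + 1.0, 1.0)
        mid = edges[:-1] + 0.5
        return mid, np.zeros(mid.size), 0.0
    bin_ms = 1.0
    nbins = int(np.ceil(raster.duration / bin_ms))
    counts, edges = np.histogram(t, bins=nbins, range=(0.0, nbins * bin_ms))
    k = int(round(window / bin_ms))
    kernel = np.ones(k) / k
    rate = np.convolve(counts, kernel, mode="same") / (bin_ms / 1000.0) / n_neurons
    mid = edges[:-1] + bin_ms / 2
    keep = mid > transient
    mean = float(rate[keep].mean()) if np.any(keep) else float(rate.mean())
    return mid, rate, mean
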