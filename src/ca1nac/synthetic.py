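"""Synthetic recording sessions with ground truth.

Generates complete sessions exhibiting every statistical structure the
downstream analyses assume: place- and theta-modulated pyramidal (PYR)
ensembles with embedded 25-ms-scale co-activation assemblies, striatal
MSN/FSI/TAN populations with class-distinct waveforms and firing rates,
millisecond-latency PYR->FSI spike transmission, FSI->MSN feedforward
inhibition, optogenetic suppression epochs, and two-enclosure
place-preference trajectories.

Reproducibility: a single master seed is split into counter-based
substreams (one per neuron, per assembly, and for the trajectory), so the
spike train of neuron *i* does not change when other neurons are added.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import PositionTrace, SpikeTrainSet, ThetaCycles

CLASS_NAMES = ("PYR", "MSN", "FSI", "TAN")

#: Default mean firing rates (Hz) per cell class during exploration.
#: FSIs discharge at substantially higher rates than MSNs and TANs;
#: MSNs have the lowest rate of the three striatal classes.
DEFAULT_RATES = {"PYR": 1.2, "MSN": 1.5, "FSI": 12.0, "TAN": 5.0}

#: Default theta-modulation depth per class (multiplicative ``1 + m*cos``);
#: a depth of 0.4 yields a spike-phase Rayleigh vector length near 0.2.
DEFAULT_THETA_DEPTH = {"PYR": 0.4, "MSN": 0.1, "FSI": 0.25, "TAN": 0.0}

#: Preferred theta phase per class (rad).  MSNs fire in phase opposition
#: to PYRs/FSIs, mirroring the anti-phased population rhythms of the two
#: regions.
DEFAULT_THETA_PHASE = {"PYR": 0.0, "MSN": math.pi, "FSI": 0.0, "TAN": 0.0}

ASSEMBLY_WINDOW_S = 0.025  # co-activation window of one 25-ms bin

WAVEFORM_FS_HZ = 40_000.0
#: Waveform-feature centroids per class:
#: (first-peak duration ms, second-peak duration ms, symmetry).
#: FSI templates are the narrowest.
WAVEFORM_CENTROIDS = {
    "FSI": (0.16, 0.22, 0.40),
    "MSN": (0.35, 0.55, 0.55),
    "TAN": (0.55, 0.85, 0.50),
    "PYR": (0.30, 0.50, 0.45),
}


# --------------------------------------------------------------------------
# configuration and ground truth
# --------------------------------------------------------------------------


@dataclass
class AssemblySpec:
    """One embedded co-activation assembly.

    members : neuron ids (PYR) taking part in the assembly
    rate : activation-event rate, events/s
    participation : probability that each member emits an extra spike
        within the 25-ms event window, per event
    """

    members: tuple
    rate: float
    participation: float

    def __post_init__(self):
        self.members = tuple(int(m) for m in self.members)
        if self.rate < 0:
            raise ValueError("assembly event rate must be >= 0")
        if not 0.0 <= self.participation <= 1.0:
            raise ValueError("participation probability must lie in [0, 1]")


@dataclass
class CouplingSpec:
    """Monosynaptic PYR->FSI coupling.

    latency_ms : synaptic latency in milliseconds (must be > 0)
    efficacy : spike-transmission probability per presynaptic spike
    """

    pyr: int
    fsi: int
    latency_ms: float
    efficacy: float

    def __post_init__(self):
        if self.latency_ms <= 0:
            raise ValueError("synaptic latency must be > 0")
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError("efficacy must lie in [0, 1]")


@dataclass
class FFISpec:
    """FSI->MSN feedforward inhibition (multiplicative rate dip)."""

    fsi: int
    msn: int
    strength: float

    def __post_init__(self):
        if self.strength < 0:
            raise ValueError("inhibition strength must be >= 0")


@dataclass
class LightEpoch:
    """Optogenetic epoch ``[start, stop)`` with per-neuron suppression.

    ``factors`` maps neuron id -> multiplicative rate factor in the epoch
    (0 silences the neuron completely, 1 leaves it untouched).
    """

    start: float
    stop: float
    factors: dict

    def __post_init__(self):
        if not self.stop > self.start:
            raise ValueError("light epoch must be non-empty")
        self.factors = {int(k): float(v) for k, v in self.factors.items()}
        for v in self.factors.values():
            if v < 0:
                raise ValueError("suppression factors must be >= 0")


@dataclass
class SessionConfig:
    """Full description of one synthetic session.

    Neuron ids are assigned contiguously: PYRs first, then MSNs, FSIs and
    TANs.  Defaults reproduce exploration-like statistics: ~8 Hz theta,
    place-tuned low-rate PYRs and the class-typical striatal rates.
    """

    duration: float = 600.0
    n_pyr: int = 50
    n_msn: int = 0
    n_fsi: int = 0
    n_tan: int = 0
    theta_freq: float = 8.0
    theta_freq_jitter: float = 0.0
    rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    theta_depth: dict = field(default_factory=lambda: dict(DEFAULT_THETA_DEPTH))
    place_depth: float = 0.5
    place_sigma_cm: float = 10.0
    assembly_spec: list = field(default_factory=list)
    coupling_spec: list = field(default_factory=list)
    coupling_jitter_ms: float = 0.3
    ffi_spec: list = field(default_factory=list)
    ffi_tau_ms: float = 10.0
    light_epochs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not 4.0 <= self.theta_freq <= 12.0:
            raise ValueError("theta frequency must lie in the 4-12 Hz band")
        for cls, r in self.rates.items():
            if r < 0:
                raise ValueError(f"negative rate for class {cls}")
        self.assembly_spec = [
            a if isinstance(a, AssemblySpec) else AssemblySpec(*a)
            for a in self.assembly_spec
        ]
        self.coupling_spec = [
            c if isinstance(c, CouplingSpec) else CouplingSpec(*c)
            for c in self.coupling_spec
        ]
        self.ffi_spec = [
            f if isinstance(f, FFISpec) else FFISpec(*f) for f in self.ffi_spec
        ]
        self.light_epochs = [
            e if isinstance(e, LightEpoch) else LightEpoch(*e)
            for e in self.light_epochs
        ]
        for e in self.light_epochs:
            if e.start < 0 or e.stop > self.duration:
                raise ValueError("light epochs must lie within [0, duration)")
        n = self.n_total
        pyr_ids = set(self.pyr_ids)
        fsi_ids = set(self.fsi_ids)
        msn_ids = set(self.msn_ids)
        for a in self.assembly_spec:
            if not set(a.members) <= pyr_ids:
                raise ValueError("assembly members must be PYR ids")
        for c in self.coupling_spec:
            if c.pyr not in pyr_ids or c.fsi not in fsi_ids:
                raise ValueError("coupling must link a PYR id to an FSI id")
        for f in self.ffi_spec:
            if f.fsi not in fsi_ids or f.msn not in msn_ids:
                raise ValueError("feedforward inhibition must link FSI to MSN")
        for e in self.light_epochs:
            if any(i >= n or i < 0 for i in e.factors):
                raise ValueError("light epoch references unknown neuron id")

    # -- id layout ---------------------------------------------------------
    @property
    def n_total(self) -> int:
        return self.n_pyr + self.n_msn + self.n_fsi + self.n_tan

    @property
    def pyr_ids(self) -> range:
        return range(0, self.n_pyr)

    @property
    def msn_ids(self) -> range:
        return range(self.n_pyr, self.n_pyr + self.n_msn)

    @property
    def fsi_ids(self) -> range:
        n0 = self.n_pyr + self.n_msn
        return range(n0, n0 + self.n_fsi)

    @property
    def tan_ids(self) -> range:
        n0 = self.n_pyr + self.n_msn + self.n_fsi
        return range(n0, n0 + self.n_tan)

    def class_of(self, nid: int) -> str:
        if nid in self.pyr_ids:
            return "PYR"
        if nid in self.msn_ids:
            return "MSN"
        if nid in self.fsi_ids:
            return "FSI"
        if nid in self.tan_ids:
            return "TAN"
        raise KeyError(nid)

    def expected_marginal_rate(self, nid: int) -> float:
        """Configured marginal rate (Hz) outside light epochs: base rate plus
        assembly-event and coupling contributions."""
        cls = self.class_of(nid)
        r = self.rates[cls]
        for a in self.assembly_spec:
            if nid in a.members:
                r += a.rate * a.participation
        for c in self.coupling_spec:
            if c.fsi == nid:
                r += self.rates["PYR"] * c.efficacy
        return r


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows and the analyses must recover."""

    assembly_memberships: list  # list of sets of neuron ids
    true_classes: dict  # neuron id -> class name
    coupling_graph: list  # list of CouplingSpec
    event_times: list  # per-assembly sorted activation times
    place_centers: dict = field(default_factory=dict)
    theta_phase_pref: dict = field(default_factory=dict)

    def __post_init__(self):
        self.assembly_memberships = [set(m) for m in self.assembly_memberships]
        for m in self.assembly_memberships:
            for nid in m:
                if nid not in self.true_classes:
                    raise ValueError(f"membership references unknown neuron {nid}")
        self.event_times = [np.sort(np.asarray(t, float)) for t in self.event_times]


# --------------------------------------------------------------------------
# substream helpers
# --------------------------------------------------------------------------

_STREAM_NEURON = 1
_STREAM_ASSEMBLY = 2
_STREAM_TRAJ = 3
_STREAM_LIGHT = 4
_STREAM_WAVEFORM = 5


def _rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(key)))


# --------------------------------------------------------------------------
# trajectory
# --------------------------------------------------------------------------


def default_geometry():
    """Two 46x46 cm enclosures joined by an 8x7 cm bridge (see behavior)."""
    from .behavior import EnclosureGeometry

    return EnclosureGeometry.two_box_bridge()


def generate_cpp_trajectory(
    duration: float,
    geometry=None,
    preference: float = 0.5,
    seed: int = 0,
    fs: float = 25.0,
    speed_cm_s: float = 8.0,
    mean_visit_s: float = 30.0,
) -> PositionTrace:
    """Smooth random walk over two enclosures with a set dwell preference.

    The animal alternates exponential-duration visits between enclosures A
    and B (bridge transits excluded from dwell), with mean visit lengths
    chosen so the fraction of enclosure time spent in A equals
    ``preference``.  Within a visit the walk is a reflected
    Ornstein-Uhlenbeck velocity process sampled at ``fs`` (camera) Hz.
    """
    if not 0.0 <= preference <= 1.0:
        raise ValueError("preference must lie in [0, 1]")
    if geometry is None:
        geometry = default_geometry()
    rng = _rng(seed, _STREAM_TRAJ)
    dt = 1.0 / fs
    n = int(round(duration * fs))
    t = np.arange(n) * dt

    box_a, box_b = geometry.box_a_bounds, geometry.box_b_bounds

    # visit schedule -------------------------------------------------------
    if preference >= 1.0:
        schedule = [("A", 0.0, duration)]
    elif preference <= 0.0:
        schedule = [("B", 0.0, duration)]
    else:
        tau_a = 2.0 * preference * mean_visit_s
        tau_b = 2.0 * (1.0 - preference) * mean_visit_s
        schedule = []
        cur = "A" if rng.random() < preference else "B"
        t0 = 0.0
        while t0 < duration:
            tau = tau_a if cur == "A" else tau_b
            dwell = rng.exponential(tau)
            schedule.append((cur, t0, min(t0 + dwell, duration)))
            t0 += dwell
            cur = "B" if cur == "A" else "A"

    # walk within boxes ----------------------------------------------------
    x = np.empty(n)
    y = np.empty(n)
    vx = vy = 0.0
    theta_v = rng.uniform(0, 2 * np.pi)
    vx, vy = speed_cm_s * np.cos(theta_v), speed_cm_s * np.sin(theta_v)
    sigma_v = speed_cm_s  # velocity-noise scale of the OU process
    tau_v = 1.0  # velocity correlation time (s)
    box0 = box_a if schedule[0][0] == "A" else box_b
    px = 0.5 * (box0[0] + box0[1])
    py = 0.5 * (box0[2] + box0[3])
    seg = 0
    a_ou = math.exp(-dt / tau_v)
    b_ou = sigma_v * math.sqrt(1.0 - a_ou**2)
    for i in range(n):
        while seg + 1 < len(schedule) and t[i] >= schedule[seg][2]:
            seg += 1
            box = box_a if schedule[seg][0] == "A" else box_b
            # teleport-free transit: re-enter the new box at the bridge side
            px = np.clip(px, box[0], box[1])
            py = np.clip(py, box[2], box[3])
        box = box_a if schedule[seg][0] == "A" else box_b
        vx = a_ou * vx + b_ou * rng.standard_normal()
        vy = a_ou * vy + b_ou * rng.standard_normal()
        px += vx * dt
        py += vy * dt
        # reflect at walls
        if px < box[0]:
            px = 2 * box[0] - px
            vx = -vx
        elif px > box[1]:
            px = 2 * box[1] - px
            vx = -vx
        if py < box[2]:
            py = 2 * box[2] - py
            vy = -vy
        elif py > box[3]:
            py = 2 * box[3] - py
            vy = -vy
        px = np.clip(px, box[0], box[1])
        py = np.clip(py, box[2], box[3])
        x[i] = px
        y[i] = py
    return PositionTrace(t, x, y)


# --------------------------------------------------------------------------
# waveforms
# --------------------------------------------------------------------------


def _waveform_template(
    d1_ms: float, d2_ms: float, symmetry: float, n_samples: int = 161
) -> np.ndarray:
    """Biphasic extracellular template with analytically placed features.

    Built from half-cosine lobes: a left positive peak closing at ``-d1``,
    a dominant trough at t = 0, a right positive peak closing at ``+d2``,
    and shallow negative tails beyond the peaks (so the waveform crosses
    zero exactly at -d1 and +d2).  Peak amplitudes are ``symmetry`` and
    ``1 - symmetry``; the trough amplitude is 1.5 so it stays the global
    minimum.  Sampled at 40 kHz over +-2 ms.
    """
    d1 = d1_ms * 1e-3
    d2 = d2_ms * 1e-3
    t = (np.arange(n_samples) - n_samples // 2) / WAVEFORM_FS_HZ
    w = np.zeros(n_samples)
    # trough lobe between the inner zero crossings at -d1/2 and +d2/2
    c1, c2 = d1 / 2.0, d2 / 2.0
    amp_l = max(symmetry, 1e-3)
    amp_r = max(1.0 - symmetry, 1e-3)
    tail = 0.08  # shallow negative tails beyond the peaks

    left_peak = (t >= -d1) & (t < -c1)
    w[left_peak] = amp_l * np.sin(np.pi * (t[left_peak] + d1) / (d1 - c1))
    # trough built from two quarter-cosine halves so its minimum sits at t=0
    lt_half = (t >= -c1) & (t < 0)
    w[lt_half] = -1.5 * np.cos(np.pi * t[lt_half] / (2 * c1))
    rt_half = (t >= 0) & (t <= c2)
    w[rt_half] = -1.5 * np.cos(np.pi * t[rt_half] / (2 * c2))
    right_peak = (t > c2) & (t <= d2)
    w[right_peak] = amp_r * np.sin(np.pi * (t[right_peak] - c2) / (d2 - c2))
    lt = t < -d1
    w[lt] = -tail * amp_l * (1 - np.exp(-(-t[lt] - d1) / 2e-4)) * np.exp(
        (t[lt] + d1) / 8e-4
    )
    rt = t > d2
    w[rt] = -tail * amp_r * (1 - np.exp(-(t[rt] - d2) / 2e-4)) * np.exp(
        -(t[rt] - d2) / 8e-4
    )
    return w


_FEATURE_SPREAD = np.array([0.05, 0.08, 0.05])  # per-feature jitter shape


def generate_waveforms(
    class_counts, separation: float = 5.0, seed: int = 0, n_samples: int = 161
):
    """Per-neuron mean waveforms from class-specific biphasic templates.

    Parameters
    ----------
    class_counts
        ``(n_fsi, n_msn, n_tan)`` or a mapping class name -> count.
    separation
        Distance between class centroids in feature-SD units.  Between-
        neuron jitter is scaled so the minimum pairwise centroid distance
        equals ``separation`` standard deviations; 0 collapses all classes
        onto one centroid (classifier chance level).

    Returns
    -------
    waveforms : (n, n_samples) array, labels : list of class names,
    features : (n, 3) array of the generating feature triplets.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if isinstance(class_counts, dict):
        counts = {k: int(v) for k, v in class_counts.items()}
    else:
        n_fsi, n_msn, n_tan = class_counts
        counts = {"FSI": int(n_fsi), "MSN": int(n_msn), "TAN": int(n_tan)}
    rng = _rng(seed, _STREAM_WAVEFORM)

    present = [c for c in ("FSI", "MSN", "TAN") if counts.get(c, 0) > 0]
    centroids = {c: np.asarray(WAVEFORM_CENTROIDS[c], float) for c in present}
    spread = _FEATURE_SPREAD.copy()
    if len(present) >= 2 and separation > 0:
        dmin = min(
            np.linalg.norm((centroids[a] - centroids[b]) / spread)
            for i, a in enumerate(present)
            for b in present[i + 1 :]
        )
        # scale jitter so the closest centroid pair sits `separation` SDs apart
        spread = spread * (dmin / separation)
    if separation == 0 and present:
        grand = np.mean([centroids[c] for c in present], axis=0)
        centroids = {c: grand for c in present}

    waveforms, labels, features = [], [], []
    for cls in present:
        for _ in range(counts[cls]):
            f = centroids[cls] + spread * rng.standard_normal(3)
            f[0] = max(f[0], 0.06)
            f[1] = max(f[1], 0.06)
            f[2] = float(np.clip(f[2], 0.05, 0.95))
            w = _waveform_template(f[0], f[1], f[2], n_samples)
            w = w + 0.01 * rng.standard_normal(n_samples)  # recording noise
            waveforms.append(w)
            labels.append(cls)
            features.append(f)
    if not waveforms:
        return np.zeros((0, n_samples)), [], np.zeros((0, 3))
    return np.asarray(waveforms), labels, np.asarray(features)


# --------------------------------------------------------------------------
# spike trains
# --------------------------------------------------------------------------


def _theta_phase_fn(config: SessionConfig, seed_jitter_rng=None):
    """Analytic theta phase: constant-frequency ramp (optional jitter)."""
    f = config.theta_freq
    if config.theta_freq_jitter <= 0:

        def phase(t):
            return (2.0 * np.pi * f * np.asarray(t)) % (2.0 * np.pi)

        boundaries = np.arange(0.0, config.duration + 0.5 / f, 1.0 / f)
        boundaries = boundaries[boundaries <= config.duration + 1e-9]
        return phase, boundaries
    # frequency jitter: per-cycle frequency drawn once, phase still piecewise
    rng = seed_jitter_rng if seed_jitter_rng is not None else _rng(config.seed, 99)
    bounds = [0.0]
    while bounds[-1] < config.duration:
        fc = f * (1.0 + config.theta_freq_jitter * rng.standard_normal())
        fc = float(np.clip(fc, 4.0, 12.0))
        bounds.append(bounds[-1] + 1.0 / fc)
    boundaries = np.asarray(bounds)
    cyc = ThetaCycles(boundaries)

    def phase(t):
        return cyc.phase(t)

    return phase, boundaries


def _inhomogeneous_poisson(rng, duration, rate_fn, rate_max):
    """Thinning sampler for an inhomogeneous Poisson process."""
    if rate_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    if cand.size == 0:
        return cand
    keep = rng.random(cand.size) < rate_fn(cand) / rate_max
    return cand[keep]


def generate_session(config: SessionConfig):
    """Generate a full synthetic session.

    Returns
    -------
    spikes : SpikeTrainSet
    cycles : ThetaCycles  (analytic generator cycles, exported as truth)
    position : PositionTrace
    waveforms : dict with keys ``bank`` (neuron id -> sample vector),
        ``fs_hz``, and ``matrix``/``ids`` views for the striatal units
    truth : SyntheticGroundTruth
    """
    cfg = config
    phase_fn, boundaries = _theta_phase_fn(cfg)
    cycles = ThetaCycles(boundaries)
    position = generate_cpp_trajectory(cfg.duration, preference=0.5, seed=cfg.seed)

    geometry = default_geometry()
    box_a, box_b = geometry.box_a_bounds, geometry.box_b_bounds

    trains: dict[int, np.ndarray] = {}
    region: dict[int, str] = {}
    classes: dict[int, str] = {}
    place_centers: dict[int, tuple] = {}
    phase_pref: dict[int, float] = {}

    # assembly events ------------------------------------------------------
    event_times = []
    extra_assembly: dict[int, list] = {nid: [] for nid in cfg.pyr_ids}
    for k, a in enumerate(cfg.assembly_spec):
        rng_a = _rng(cfg.seed, _STREAM_ASSEMBLY, k)
        n_ev = rng_a.poisson(a.rate * cfg.duration)
        ev = np.sort(rng_a.uniform(0.0, cfg.duration - ASSEMBLY_WINDOW_S, n_ev))
        event_times.append(ev)
        for m in a.members:
            take = rng_a.random(ev.size) < a.participation
            jit = rng_a.uniform(0.0, ASSEMBLY_WINDOW_S, int(take.sum()))
            extra_assembly[m].append(ev[take] + jit)

    # PYRs -----------------------------------------------------------------
    base_pyr = cfg.rates["PYR"]
    m_theta = cfg.theta_depth["PYR"]
    for nid in cfg.pyr_ids:
        rng_n = _rng(cfg.seed, _STREAM_NEURON, nid)
        # place field: center uniform over the two enclosures
        box = box_a if rng_n.random() < 0.5 else box_b
        cx = rng_n.uniform(box[0], box[1])
        cy = rng_n.uniform(box[2], box[3])
        place_centers[nid] = (cx, cy)
        pref = float(
            (DEFAULT_THETA_PHASE["PYR"] + 1.0 * rng_n.standard_normal())
            % (2 * np.pi)
        )
        phase_pref[nid] = pref
        # empirically normalized place factor (unit mean over the trajectory)
        d2 = (position.x - cx) ** 2 + (position.y - cy) ** 2
        g = 1.0 + cfg.place_depth * np.exp(-d2 / (2.0 * cfg.place_sigma_cm**2))
        g = g / g.mean()

        def rate_fn(t, pref=pref, g=g):
            gp = np.interp(t, position.t, g)
            return base_pyr * gp * (1.0 + m_theta * np.cos(phase_fn(t) - pref))

        rate_max = base_pyr * (1.0 + m_theta) * float(g.max()) * 1.01
        t_sp = _inhomogeneous_poisson(rng_n, cfg.duration, rate_fn, rate_max)
        if extra_assembly[nid]:
            t_sp = np.sort(np.concatenate([t_sp] + extra_assembly[nid]))
        trains[nid] = t_sp
        region[nid] = "dCA1"
        classes[nid] = "PYR"

    # striatal baseline (MSN/FSI/TAN) -------------------------------------
    for ids, cls in ((cfg.msn_ids, "MSN"), (cfg.fsi_ids, "FSI"), (cfg.tan_ids, "TAN")):
        base = cfg.rates[cls]
        m = cfg.theta_depth[cls]
        pref0 = DEFAULT_THETA_PHASE[cls]
        for nid in ids:
            rng_n = _rng(cfg.seed, _STREAM_NEURON, nid)
            pref = float((pref0 + 0.5 * rng_n.standard_normal()) % (2 * np.pi))
            phase_pref[nid] = pref

            def rate_fn(t, pref=pref, base=base, m=m):
                return base * (1.0 + m * np.cos(phase_fn(t) - pref))

            trains[nid] = _inhomogeneous_poisson(
                rng_n, cfg.duration, rate_fn, base * (1.0 + m)
            )
            region[nid] = "NAc"
            classes[nid] = cls

    # PYR -> FSI coupling --------------------------------------------------
    for c in cfg.coupling_spec:
        rng_c = _rng(cfg.seed, _STREAM_NEURON, c.fsi, c.pyr)
        pre = trains[c.pyr]
        fire = rng_c.random(pre.size) < c.efficacy
        lat = c.latency_ms * 1e-3 + np.abs(
            cfg.coupling_jitter_ms * 1e-3 * rng_c.standard_normal(int(fire.sum()))
        )
        evoked = pre[fire] + lat
        evoked = evoked[evoked < cfg.duration]
        trains[c.fsi] = np.sort(np.concatenate([trains[c.fsi], evoked]))

    # FSI -> MSN feedforward inhibition: thin MSN spikes after FSI spikes --
    tau = cfg.ffi_tau_ms * 1e-3
    by_msn: dict[int, list] = {}
    for f in cfg.ffi_spec:
        by_msn.setdefault(f.msn, []).append(f)
    for msn, links in by_msn.items():
        rng_i = _rng(cfg.seed, _STREAM_NEURON, msn, 777)
        t_sp = trains[msn]
        if t_sp.size == 0:
            continue
        drive = np.zeros(t_sp.size)
        for f in links:
            fs = trains[f.fsi]
            idx = np.searchsorted(fs, t_sp)  # FSI spikes strictly before
            # sum of exponential kernels from the last few FSI spikes
            for back in range(1, 6):
                j = idx - back
                ok = j >= 0
                dt_sp = np.where(ok, t_sp - fs[np.clip(j, 0, None)], np.inf)
                drive[ok] += f.strength * np.exp(-dt_sp[ok] / tau)
        keep = rng_i.random(t_sp.size) < np.exp(-drive)
        trains[msn] = t_sp[keep]

    # optogenetic suppression ---------------------------------------------
    for e_idx, e in enumerate(cfg.light_epochs):
        for nid, factor in e.factors.items():
            rng_l = _rng(cfg.seed, _STREAM_LIGHT, e_idx, nid)
            t_sp = trains[nid]
            inside = (t_sp >= e.start) & (t_sp < e.stop)
            keep = ~inside | (rng_l.random(t_sp.size) < factor)
            trains[nid] = t_sp[keep]

    spikes = SpikeTrainSet(trains, region, classes)

    # waveform bank for the striatal units ---------------------------------
    nac_ids = list(cfg.msn_ids) + list(cfg.fsi_ids) + list(cfg.tan_ids)
    counts = {"FSI": cfg.n_fsi, "MSN": cfg.n_msn, "TAN": cfg.n_tan}
    bank_mat, bank_labels, _feat = generate_waveforms(counts, seed=cfg.seed)
    # generate_waveforms emits FSI, MSN, TAN blocks in that order
    ordered_ids = list(cfg.fsi_ids) + list(cfg.msn_ids) + list(cfg.tan_ids)
    bank = {nid: bank_mat[i] for i, nid in enumerate(ordered_ids)}
    waveforms = {
        "bank": bank,
        "fs_hz": WAVEFORM_FS_HZ,
        "ids": nac_ids,
        "matrix": np.asarray([bank[nid] for nid in nac_ids])
        if nac_ids
        else np.zeros((0, 161)),
    }

    truth = SyntheticGroundTruth(
        assembly_memberships=[set(a.members) for a in cfg.assembly_spec],
        true_classes=classes,
        coupling_graph=list(cfg.coupling_spec),
        event_times=event_times,
        place_centers=place_centers,
        theta_phase_pref=phase_pref,
    )
    return spikes, cycles, position, waveforms, truth
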