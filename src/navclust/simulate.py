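"""Seeded synthetic-data generators with known ground truth.

Three families of inputs are emulated, one per downstream analysis stage:

* whole-cell voltage-clamp current families under the three standard
  protocols (steady-state activation, steady-state inactivation, two-pulse
  recovery from inactivation), driven by the m3h forward model;
* single-molecule localization patterns and raw blinking movies for the
  super-resolution cluster / nearest-neighbor analysis;
* three-channel (DAPI / GFP / PLA) 3D image stacks with ellipsoidal nuclei,
  cytoplasmic GFP volumes and Gaussian PLA puncta over Poisson noise.

Every generator takes an explicit integer seed and is bit-reproducible for a
fixed seed and configuration, and every generated object is accounted for in
the returned ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize_scalar

from .model import BoltzmannParams, HHState, Sense, boltzmann_curve, hh_m3h_timecourse, recovery_fraction
from .traces import Sweep, TraceSet

__all__ = [
    "ConfigError",
    "BellCurve",
    "DistSpec",
    "EphysSimConfig",
    "LocSimConfig",
    "PlaSimConfig",
    "simulate_activation_family",
    "simulate_inactivation_family",
    "simulate_recovery_family",
    "analytic_peak_conductance",
    "gmax_for_peak_density",
    "simulate_localization_pattern",
    "simulate_oligomer_pattern",
    "simulate_blinking_movie",
    "simulate_pla_stack",
    "ACTIVATION_VOLTAGES",
    "INACTIVATION_PREPULSES",
    "RECOVERY_INTERVALS",
]


class ConfigError(ValueError):
    """A simulation configuration field is invalid; the message names it."""


# Standard clamp protocols: 50 ms test pulses from a holding potential of
# -120 mV; activation steps -90..+35 mV in 5 mV increments (26 sweeps);
# inactivation uses 100 ms conditioning pre-pulses -140..-50 mV (19 sweeps)
# followed by a test pulse to -40 mV; recovery uses paired -40 mV pulses with
# the interval incremented by 3 ms up to 72 ms (24 intervals).
ACTIVATION_VOLTAGES = np.arange(-90.0, 35.0 + 2.5, 5.0)
INACTIVATION_PREPULSES = np.arange(-140.0, -50.0 + 2.5, 5.0)
RECOVERY_INTERVALS = np.arange(3.0, 72.0 + 1.5, 3.0)
HOLDING_MV = -120.0
INACT_TEST_MV = -40.0
PULSE_MS = 50.0
PREPULSE_MS = 100.0


@dataclass(frozen=True)
class BellCurve:
    """Bell-shaped voltage dependence, base + amp*exp(-((v-center)/width)^2).

    Used for the default tau_m(V) and tau_h(V) curves: strictly positive,
    peaked near the transition voltages, spanning roughly 0.2-5 ms.
    """

    base: float
    amp: float
    center: float
    width: float

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        out = self.base + self.amp * np.exp(-(((v - self.center) / self.width) ** 2))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class DistSpec:
    """A (mean, sd) spec for a positive quantity; sd = 0 means constant.

    Sampled from a gamma distribution with the matching first two moments,
    which keeps draws strictly positive.
    """

    mean: float
    sd: float = 0.0

    def sample(self, rng: np.random.Generator, size=None):
        if self.mean <= 0:
            raise ConfigError(f"DistSpec mean must be positive, got {self.mean}")
        if self.sd < 0:
            raise ConfigError(f"DistSpec sd must be non-negative, got {self.sd}")
        if self.sd == 0:
            return np.full(size, self.mean) if size is not None else self.mean
        shape = (self.mean / self.sd) ** 2
        scale = self.sd**2 / self.mean
        return rng.gamma(shape, scale, size=size)


# --------------------------------------------------------------------------
# Electrophysiology
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EphysSimConfig:
    """Ground-truth parameter set for simulated Na+ current families.

    The steady-state curves are Boltzmann functions (activation V1/2, k and
    inactivation V1/2, k); the kinetics are the m3h model with voltage-
    dependent tau_m and tau_h; ``offset`` is a residual leak conductance
    summand; ``noise_sd`` is additive Gaussian current noise in pA.
    """

    gmax: float = 100.0            # nS
    e_na: float = 19.58            # mV
    act_vhalf: float = -42.62      # mV
    act_k: float = 7.28            # mV
    inact_vhalf: float = -96.14    # mV
    inact_k: float = 7.17          # mV
    # bell-shaped kinetics, 0.2-1 ms (m) and 1-5 ms (h), peaked mid-protocol;
    # the two default curves are proportional (tau_h = 5 tau_m), which keeps
    # the peak-transient shape factor voltage-independent so the measured
    # peak-conductance curve reproduces the activation Boltzmann
    tau_m_of_v: Callable[[float], float] = BellCurve(0.2, 0.8, -60.0, 40.0)
    tau_h_of_v: Callable[[float], float] = BellCurve(1.0, 4.0, -60.0, 40.0)
    offset: float = 0.0            # nS
    c_m: float = 10.4              # pF
    noise_sd: float = 20.0         # pA
    seed: int = 0
    dt_ms: float = 0.05

    def __post_init__(self) -> None:
        if not self.gmax > 0:
            raise ConfigError(f"gmax must be positive, got {self.gmax}")
        if not self.act_k > 0:
            raise ConfigError(f"act_k must be positive, got {self.act_k}")
        if not self.inact_k > 0:
            raise ConfigError(f"inact_k must be positive, got {self.inact_k}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if not self.c_m > 0:
            raise ConfigError(f"c_m must be positive, got {self.c_m}")
        for name in ("tau_m_of_v", "tau_h_of_v"):
            curve = getattr(self, name)
            probe = np.asarray(curve(np.linspace(-140.0, 40.0, 19)))
            if not np.all(probe > 0):
                raise ConfigError(f"{name} must be strictly positive over the protocol range")

    @property
    def activation(self) -> BoltzmannParams:
        return BoltzmannParams(self.act_vhalf, self.act_k, Sense.ACTIVATION)

    @property
    def inactivation(self) -> BoltzmannParams:
        return BoltzmannParams(self.inact_vhalf, self.inact_k, Sense.INACTIVATION)


def _hh_state(cfg: EphysSimConfig, v_from: float, v_to: float) -> HHState:
    """m3h endpoints/taus for a step v_from -> v_to, matching the convention
    the fitting stage later uses: m = (activation Boltzmann)^(1/3), h = the
    inactivation Boltzmann, taus evaluated at the post-step voltage."""
    act, inact = cfg.activation, cfg.inactivation
    return HHState(
        m0=float(boltzmann_curve(v_from, act)) ** (1.0 / 3.0),
        m_inf=float(boltzmann_curve(v_to, act)) ** (1.0 / 3.0),
        h0=float(boltzmann_curve(v_from, inact)),
        h_inf=float(boltzmann_curve(v_to, inact)),
        tau_m=float(cfg.tau_m_of_v(v_to)),
        tau_h=float(cfg.tau_h_of_v(v_to)),
        gmax=cfg.gmax,
        offset=cfg.offset,
    )


def analytic_peak_conductance(state: HHState, t_max: float = PULSE_MS) -> float:
    """Noise-free maximum of the m3h transient on [0, t_max] ms."""
    res = minimize_scalar(
        lambda t: -hh_m3h_timecourse(t, state),
        bounds=(0.0, t_max),
        method="bounded",
        options={"xatol": 1e-7},
    )
    cand = [-res.fun, hh_m3h_timecourse(0.0, state), hh_m3h_timecourse(t_max, state)]
    return float(max(cand))


def gmax_for_peak_density(target_pa_per_pf: float, cfg: EphysSimConfig) -> float:
    """gmax (nS) giving a noise-free peak current density of the target.

    The peak current magnitude is linear in gmax (offset excluded), so the
    calibration is a single analytic solve over the activation protocol.
    """
    unit = replace(cfg, gmax=1.0, offset=0.0, noise_sd=0.0)
    dens = []
    for v in ACTIVATION_VOLTAGES:
        if v == cfg.e_na:
            continue
        g = analytic_peak_conductance(_hh_state(unit, HOLDING_MV, float(v)))
        dens.append(abs(g * (v - cfg.e_na)) / cfg.c_m)
    return float(target_pa_per_pf / max(dens))


def simulate_activation_family(cfg: EphysSimConfig) -> tuple[TraceSet, dict]:
    """Current family under the activation protocol, plus ground truth.

    One sweep per test voltage; I(t) = G(t) * (V - E_Na) with G(t) from the
    m3h forward model, plus Gaussian noise.  The ground truth records the
    generator parameters, the per-sweep gating state, and the analytic
    noise-free peak conductances (the quantity the peak-based activation
    curve actually estimates).
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, PULSE_MS + cfg.dt_ms / 2, cfg.dt_ms)
    sweeps, states, peaks = [], {}, {}
    for v in ACTIVATION_VOLTAGES:
        v = float(v)
        s = _hh_state(cfg, HOLDING_MV, v)
        g = hh_m3h_timecourse(t, s)
        i = g * (v - cfg.e_na)
        if cfg.noise_sd > 0:
            i = i + rng.normal(0.0, cfg.noise_sd, size=t.size)
        sweeps.append(Sweep(voltage=v, time_ms=t, current_pa=i))
        states[v] = s
        peaks[v] = analytic_peak_conductance(s)
    ts = TraceSet(sweeps, c_m=cfg.c_m, protocol="activation",
                  meta={"holding_mv": HOLDING_MV, "seed": cfg.seed, "e_na": cfg.e_na})
    pk = np.array([peaks[float(v)] for v in ACTIVATION_VOLTAGES])
    truth = {
        "config": cfg,
        "states": states,
        "peak_conductance_ns": peaks,
        "peak_g_over_gmax": {float(v): p / pk.max() for v, p in zip(ACTIVATION_VOLTAGES, pk)},
    }
    return ts, truth


def simulate_inactivation_family(cfg: EphysSimConfig) -> tuple[TraceSet, dict]:
    """Current family under the steady-state inactivation protocol.

    Each sweep is the -40 mV test-pulse response after a 100 ms conditioning
    pre-pulse; the test-pulse peak scales with the channel availability h at
    the end of the pre-pulse (the inactivation Boltzmann, fully settled to
    within exp(-100/tau_h)).
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, PULSE_MS + cfg.dt_ms / 2, cfg.dt_ms)
    act, inact = cfg.activation, cfg.inactivation
    sweeps, avail = [], {}
    for vp in INACTIVATION_PREPULSES:
        vp = float(vp)
        # gate state at the end of the conditioning pre-pulse
        h_pre = boltzmann_curve(vp, inact) - (
            boltzmann_curve(vp, inact) - boltzmann_curve(HOLDING_MV, inact)
        ) * math.exp(-PREPULSE_MS / float(cfg.tau_h_of_v(vp)))
        # the availability h carries the pre-pulse dependence; the activation
        # gate starts from its holding-potential value so that the test-pulse
        # peak scales with h alone (the quantity the protocol reads out)
        s = HHState(
            m0=float(boltzmann_curve(HOLDING_MV, act)) ** (1.0 / 3.0),
            m_inf=float(boltzmann_curve(INACT_TEST_MV, act)) ** (1.0 / 3.0),
            h0=float(h_pre),
            h_inf=float(boltzmann_curve(INACT_TEST_MV, inact)),
            tau_m=float(cfg.tau_m_of_v(INACT_TEST_MV)),
            tau_h=float(cfg.tau_h_of_v(INACT_TEST_MV)),
            gmax=cfg.gmax,
            offset=cfg.offset,
        )
        i = hh_m3h_timecourse(t, s) * (INACT_TEST_MV - cfg.e_na)
        if cfg.noise_sd > 0:
            i = i + rng.normal(0.0, cfg.noise_sd, size=t.size)
        sweeps.append(Sweep(voltage=vp, time_ms=t, current_pa=i))
        avail[vp] = float(h_pre)
    ts = TraceSet(sweeps, c_m=cfg.c_m, protocol="inactivation",
                  meta={"holding_mv": HOLDING_MV, "test_mv": INACT_TEST_MV,
                        "seed": cfg.seed, "e_na": cfg.e_na})
    hmax = max(avail.values())
    truth = {"config": cfg, "availability": avail,
             "availability_normalized": {v: h / hmax for v, h in avail.items()}}
    return ts, truth


def simulate_recovery_family(
    cfg: EphysSimConfig, tau_rec: float, intervals: Optional[np.ndarray] = None
) -> tuple[TraceSet, dict]:
    """Two-pulse recovery family: P2 responses at increasing P1-P2 intervals.

    Availability recovers as 1 - exp(-dt/tau_rec); the P2 trace is the P1
    response scaled by the recovered fraction (the inactivation gate is the
    only state that differs between the pulses), plus noise.
    """
    if not tau_rec > 0:
        raise ConfigError(f"tau_rec must be positive, got {tau_rec}")
    intervals = RECOVERY_INTERVALS if intervals is None else np.asarray(intervals, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, PULSE_MS + cfg.dt_ms / 2, cfg.dt_ms)
    p1_state = _hh_state(cfg, HOLDING_MV, INACT_TEST_MV)
    i_p1_clean = hh_m3h_timecourse(t, p1_state) * (INACT_TEST_MV - cfg.e_na)
    i_p1 = i_p1_clean + (rng.normal(0.0, cfg.noise_sd, t.size) if cfg.noise_sd > 0 else 0.0)
    sweeps, ratios = [], {}
    for dt in intervals:
        frac = recovery_fraction(float(dt), tau_rec)
        i2 = frac * i_p1_clean
        if cfg.noise_sd > 0:
            i2 = i2 + rng.normal(0.0, cfg.noise_sd, size=t.size)
        sweeps.append(Sweep(voltage=INACT_TEST_MV, time_ms=t, current_pa=i2,
                            interval_ms=float(dt)))
        ratios[float(dt)] = frac
    ts = TraceSet(sweeps, c_m=cfg.c_m, protocol="recovery",
                  meta={"holding_mv": HOLDING_MV, "seed": cfg.seed, "e_na": cfg.e_na,
                        "p1_time_ms": t, "p1_current_pa": i_p1})
    truth = {"config": cfg, "tau_rec": tau_rec, "t_half": tau_rec * math.log(2),
             "ratios": ratios}
    return ts, truth


# --------------------------------------------------------------------------
# Localization microscopy
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LocSimConfig:
    """Clustered 2D point pattern with blinking and localization error.

    ``clustered_fraction`` fixes the fraction of molecules that belong to
    clusters; the number of background monomers is derived from it (when it
    is None, ``background_density`` in monomers per um^2 is used instead).
    Each molecule emits >= 1 blink, geometrically distributed; every blink is
    displaced by isotropic Gaussian localization error.
    """

    field_size: tuple[float, float] = (5000.0, 5000.0)  # nm (x, y)
    n_clusters: int = 40
    molecules_per_cluster: DistSpec = DistSpec(8.0, 3.0)
    cluster_radius: DistSpec = DistSpec(10.0, 3.0)      # nm, RMS member distance
    clustered_fraction: Optional[float] = 0.4
    background_density: float = 10.0                    # monomers per um^2
    loc_error_sd: float = 3.0                           # nm
    blinks_per_molecule: DistSpec = DistSpec(3.0, 0.0)  # geometric mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clustered_fraction is not None and not 0.0 <= self.clustered_fraction <= 1.0:
            raise ConfigError(
                f"clustered_fraction must be in [0, 1], got {self.clustered_fraction}")
        if self.background_density < 0:
            raise ConfigError(f"background_density must be >= 0, got {self.background_density}")
        if self.loc_error_sd < 0:
            raise ConfigError(f"loc_error_sd must be >= 0, got {self.loc_error_sd}")
        if self.n_clusters < 0:
            raise ConfigError(f"n_clusters must be >= 0, got {self.n_clusters}")


def _blink_counts(rng: np.random.Generator, spec: DistSpec, n: int) -> np.ndarray:
    """Per-molecule blink counts >= 1, geometric with the given mean."""
    if n == 0:
        return np.zeros(0, dtype=int)
    mean = max(spec.mean, 1.0)
    p = 1.0 / mean
    return rng.geometric(p, size=n)


def simulate_localization_pattern(cfg: LocSimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a localization table with per-blink ground-truth labels.

    Returns a DataFrame with columns frame, x_nm, y_nm, intensity,
    precision_nm, plus ground truth carrying per-blink molecule and cluster
    ids (cluster_id = -1 for background monomers) and the per-cluster true
    centers and radii.
    """
    rng = np.random.default_rng(cfg.seed)
    fx, fy = cfg.field_size
    centers = rng.uniform([0, 0], [fx, fy], size=(cfg.n_clusters, 2))
    n_per = np.maximum(1, np.round(
        cfg.molecules_per_cluster.sample(rng, cfg.n_clusters)).astype(int)) \
        if cfg.n_clusters else np.zeros(0, dtype=int)
    radii = np.asarray(cfg.cluster_radius.sample(rng, cfg.n_clusters), dtype=float) \
        if cfg.n_clusters else np.zeros(0)

    mol_xy, mol_cluster = [], []
    for cid in range(cfg.n_clusters):
        # isotropic Gaussian with RMS member-to-center distance = radius
        sd = radii[cid] / math.sqrt(2.0)
        pts = centers[cid] + rng.normal(0.0, sd, size=(n_per[cid], 2))
        mol_xy.append(pts)
        mol_cluster.extend([cid] * n_per[cid])
    n_clustered = int(n_per.sum())

    if cfg.clustered_fraction is None:
        n_bg = rng.poisson(cfg.background_density * fx * fy / 1e6)
    elif cfg.clustered_fraction == 0:
        # no clusters rendered; background from density
        n_bg = max(1, rng.poisson(cfg.background_density * fx * fy / 1e6))
        mol_xy, mol_cluster, n_clustered = [], [], 0
    else:
        n_bg = int(round(n_clustered * (1.0 - cfg.clustered_fraction) / cfg.clustered_fraction))
    if n_bg:
        mol_xy.append(rng.uniform([0, 0], [fx, fy], size=(n_bg, 2)))
        mol_cluster.extend([-1] * n_bg)
    xy = np.vstack(mol_xy) if mol_xy else np.zeros((0, 2))
    mol_cluster = np.asarray(mol_cluster, dtype=int)
    n_mol = xy.shape[0]

    blinks = _blink_counts(rng, cfg.blinks_per_molecule, n_mol)
    mol_idx = np.repeat(np.arange(n_mol), blinks)
    bl_xy = xy[mol_idx] + rng.normal(0.0, cfg.loc_error_sd, size=(mol_idx.size, 2))
    frames = rng.integers(0, 10000, size=mol_idx.size)
    order = np.argsort(frames, kind="stable")
    table = pd.DataFrame({
        "frame": frames[order],
        "x_nm": bl_xy[order, 0],
        "y_nm": bl_xy[order, 1],
        "intensity": rng.gamma(5.0, 200.0, size=mol_idx.size),
        "precision_nm": np.full(mol_idx.size, max(cfg.loc_error_sd, 1e-3)),
    })
    truth = {
        "config": cfg,
        "molecule_xy": xy,
        "molecule_cluster": mol_cluster,
        "blink_molecule": mol_idx[order],
        "blink_cluster": mol_cluster[mol_idx][order],
        "cluster_centers": centers,
        "cluster_radii": radii,
        "n_clustered_molecules": n_clustered,
    }
    return table, truth


def simulate_oligomer_pattern(
    field_size: tuple[float, float] = (4000.0, 4000.0),
    n_dimers: int = 2000,
    n_tetramers: int = 0,
    dimer_spacing: float = 6.0,
    tetramer_spacing: float = 12.0,
    jitter_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Point pattern of dimers (and optionally square tetramers).

    Dimer partners sit ``dimer_spacing`` nm apart; tetramers are squares of
    side ``tetramer_spacing`` nm, so the nearest-neighbor distance
    distribution has modes at the two spacings.  Positions get isotropic
    Gaussian jitter of ``jitter_sd`` nm.
    """
    rng = np.random.default_rng(seed)
    fx, fy = field_size
    pts, kind = [], []
    for _ in range(n_dimers):
        c = rng.uniform([0, 0], [fx, fy])
        ang = rng.uniform(0, 2 * math.pi)
        off = 0.5 * dimer_spacing * np.array([math.cos(ang), math.sin(ang)])
        pts.extend([c + off, c - off])
        kind.extend(["dimer", "dimer"])
    half = tetramer_spacing / 2.0
    square = np.array([[-half, -half], [-half, half], [half, -half], [half, half]])
    for _ in range(n_tetramers):
        c = rng.uniform([0, 0], [fx, fy])
        ang = rng.uniform(0, 2 * math.pi)
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        for corner in square @ rot.T:
            pts.append(c + corner)
            kind.append("tetramer")
    xy = np.asarray(pts) + rng.normal(0.0, jitter_sd, size=(len(pts), 2))
    table = pd.DataFrame({
        "frame": np.arange(len(pts)),
        "x_nm": xy[:, 0],
        "y_nm": xy[:, 1],
        "intensity": np.full(len(pts), 1000.0),
        "precision_nm": np.full(len(pts), max(jitter_sd, 1e-3)),
    })
    truth = {"kind": np.asarray(kind), "modes_nm": (dimer_spacing, tetramer_spacing)}
    return table, truth


def simulate_blinking_movie(
    cfg: LocSimConfig,
    psf_sigma: float = 1.2,
    frames: int = 200,
    drift: tuple[float, float] = (0.0, 0.0),
    snr: float = 10.0,
    pixel_size_nm: float = 100.0,
    image_shape: tuple[int, int] = (64, 64),
    background: float = 100.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Raw blinking movie: sparse emitters rendered as 2D Gaussian spots.

    Each frame turns on a random subset of the molecules from the pattern
    generator (on-probability = mean blinks per molecule / frames, capped at
    1), renders each as a Gaussian of ``psf_sigma`` px with peak amplitude
    snr * sqrt(background) above a Poisson background, and applies a
    cumulative linear ``drift`` (nm per frame in x, y).  Returns the movie
    (frames, H, W) and the per-frame ground-truth emitter table.
    """
    if frames < 1:
        raise ConfigError(f"frames must be >= 1, got {frames}")
    if psf_sigma <= 0:
        raise ConfigError(f"psf_sigma must be positive, got {psf_sigma}")
    rng = np.random.default_rng(cfg.seed + 1)
    _, truth0 = simulate_localization_pattern(replace(cfg, seed=cfg.seed))
    xy = truth0["molecule_xy"]
    n_mol = xy.shape[0]
    h, w = image_shape
    on_p = min(1.0, cfg.blinks_per_molecule.mean / frames) if n_mol else 0.0
    amp = snr * math.sqrt(background)
    drift = np.asarray(drift, dtype=float)

    movie = np.empty((frames, h, w), dtype=np.uint16)
    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    for f in range(frames):
        clean = np.full((h, w), background, dtype=float)
        if n_mol:
            on = rng.random(n_mol) < on_p
            for mi in np.flatnonzero(on):
                x_nm = xy[mi, 0] + drift[0] * f
                y_nm = xy[mi, 1] + drift[1] * f
                xp, yp = x_nm / pixel_size_nm, y_nm / pixel_size_nm
                if not (-3 <= xp < w + 3 and -3 <= yp < h + 3):
                    continue
                clean += amp * np.exp(-((xx - xp) ** 2 + (yy - yp) ** 2) / (2 * psf_sigma**2))
                rows.append((f, mi, x_nm, y_nm))
        movie[f] = rng.poisson(clean).astype(np.uint16)
    truth = pd.DataFrame(rows, columns=["frame", "molecule", "x_nm", "y_nm"])
    return movie, truth


# --------------------------------------------------------------------------
# PLA stacks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaSimConfig:
    """Three-channel 3D stack: DAPI nuclei, cytoplasmic GFP, PLA puncta.

    Cells are ellipsoidal; nuclei are concentric smaller ellipsoids whose
    semi-axes are drawn from ``nucleus_spec`` (in voxels, y/x axes; the z
    semi-axis is scaled by the voxel anisotropy).  A ``gfp_fraction`` subset
    of cells is GFP-positive; PLA dots are placed inside GFP-positive cells,
    with probability ``membrane_weight`` within ``membrane_margin`` voxels of
    the cell-mask boundary (plasma-membrane-proximal placement), and rendered
    as 3D Gaussian puncta over a Poisson background.  Intensities are on an
    8-bit scale.
    """

    stack_shape: tuple[int, int, int] = (12, 160, 160)      # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1)  # um per axis
    n_cells: int = 6
    nucleus_spec: DistSpec = DistSpec(10.0, 1.0)            # semi-axis, voxels
    cell_scale: float = 2.0                                 # cell/nucleus semi-axis ratio
    gfp_fraction: float = 1.0
    dots_per_cell: DistSpec = DistSpec(8.0, 0.0)            # Poisson mean
    dot_amplitude: float = 100.0
    dot_sigma: tuple[float, float, float] = (0.8, 1.2, 1.2)  # voxels (z, y, x)
    background_level: float = 10.0
    membrane_weight: float = 0.7
    membrane_margin: int = 2                                # voxels
    placement_buffer: float = 6.0                           # voxels between cells
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dot_amplitude > 0:
            raise ConfigError(f"dot_amplitude must be positive, got {self.dot_amplitude}")
        if any(s <= 0 for s in self.stack_shape):
            raise ConfigError(f"stack_shape must be positive, got {self.stack_shape}")
        if not 0.0 <= self.gfp_fraction <= 1.0:
            raise ConfigError(f"gfp_fraction must be in [0, 1], got {self.gfp_fraction}")
        if not 0.0 <= self.membrane_weight <= 1.0:
            raise ConfigError(f"membrane_weight must be in [0, 1], got {self.membrane_weight}")


class GenerationError(RuntimeError):
    """Raised when non-overlapping cells cannot be placed within the retry budget."""


def _ellipsoid_mask(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    return ((zz - center[0]) / semi[0]) ** 2 + ((yy - center[1]) / semi[1]) ** 2 + (
        (xx - center[2]) / semi[2]) ** 2 <= 1.0


def simulate_pla_stack(cfg: PlaSimConfig) -> tuple[np.ndarray, dict]:
    """Render a (3, z, y, x) stack [DAPI, GFP, PLA] plus ground truth.

    Ground truth lists per-cell nucleus/cell geometry, GFP status, and the
    exact voxel coordinates of every planted PLA dot with its membrane flag.
    """
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.stack_shape
    aniso = cfg.voxel_size[1] / cfg.voxel_size[0]  # voxels in z per voxel in y

    cells, tries = [], 0
    while len(cells) < cfg.n_cells:
        tries += 1
        if tries > 200 * max(cfg.n_cells, 1):
            raise GenerationError(
                f"could not place {cfg.n_cells} non-overlapping cells in {cfg.stack_shape}")
        r_nuc = float(cfg.nucleus_spec.sample(rng))
        r_cell = cfg.cell_scale * r_nuc
        cz = nz / 2.0 + rng.normal(0, 0.5)
        cy = rng.uniform(r_cell, ny - r_cell) if ny > 2 * r_cell else ny / 2.0
        cx = rng.uniform(r_cell, nx - r_cell) if nx > 2 * r_cell else nx / 2.0
        # buffer keeps segmented GFP volumes from touching (they are
        # deliberately not split downstream)
        ok = all((cy - c["center"][1]) ** 2 + (cx - c["center"][2]) ** 2
                 > (r_cell + c["r_cell"] + cfg.placement_buffer) ** 2 for c in cells)
        if ok:
            cells.append({"center": (cz, cy, cx), "r_nuc": r_nuc, "r_cell": r_cell})

    gfp_pos = rng.random(cfg.n_cells) < cfg.gfp_fraction
    if cfg.gfp_fraction >= 1.0:
        gfp_pos[:] = True

    dapi = np.zeros(cfg.stack_shape, dtype=float)
    gfp = np.zeros(cfg.stack_shape, dtype=float)
    pla = np.zeros(cfg.stack_shape, dtype=float)
    dots = []
    for ci, cell in enumerate(cells):
        c = cell["center"]
        semi_nuc = (max(cell["r_nuc"] * aniso, 1.5), cell["r_nuc"], cell["r_nuc"])
        semi_cell = (max(cell["r_cell"] * aniso, 2.5), cell["r_cell"], cell["r_cell"])
        nuc_mask = _ellipsoid_mask(cfg.stack_shape, c, semi_nuc)
        cell_mask = _ellipsoid_mask(cfg.stack_shape, c, semi_cell)
        dapi[nuc_mask] = 150.0
        if gfp_pos[ci]:
            gfp[cell_mask & ~nuc_mask] = 120.0
            n_dots = int(round(float(cfg.dots_per_cell.sample(rng)))) \
                if cfg.dots_per_cell.sd > 0 else rng.poisson(cfg.dots_per_cell.mean)
            if n_dots == 0:
                continue
            cyto = cell_mask & ~nuc_mask
            # membrane shell by Euclidean distance (voxels) to the cell
            # boundary, the same metric the membrane-proximity readout uses
            boundary = cell_mask & ~ndimage.binary_erosion(cell_mask)
            dist = ndimage.distance_transform_edt(~boundary)
            shell = cyto & (dist <= cfg.membrane_margin)
            interior = cyto & (dist > cfg.membrane_margin)
            shell_idx = np.argwhere(shell)
            interior_idx = np.argwhere(interior if interior.any() else cyto)
            for _ in range(n_dots):
                at_membrane = rng.random() < cfg.membrane_weight and shell_idx.size
                pool = shell_idx if at_membrane else interior_idx
                z, y, x = pool[rng.integers(len(pool))]
                dots.append({"cell": ci, "z": int(z), "y": int(y), "x": int(x),
                             "membrane": bool(at_membrane)})

    sz, sy, sx = cfg.dot_sigma
    for d in dots:
        z0, y0, x0 = d["z"], d["y"], d["x"]
        zl, zh = max(0, z0 - 4), min(nz, z0 + 5)
        yl, yh = max(0, y0 - 6), min(ny, y0 + 7)
        xl, xh = max(0, x0 - 6), min(nx, x0 + 7)
        zz, yy, xx = np.mgrid[zl:zh, yl:yh, xl:xh]
        pla[zl:zh, yl:yh, xl:xh] += cfg.dot_amplitude * np.exp(
            -((zz - z0) ** 2 / (2 * sz**2) + (yy - y0) ** 2 / (2 * sy**2)
              + (xx - x0) ** 2 / (2 * sx**2)))

    stack = np.stack([
        rng.poisson(dapi + cfg.background_level),
        rng.poisson(gfp + cfg.background_level),
        rng.poisson(pla + cfg.background_level),
    ]).astype(np.float64)
    stack = np.clip(stack, 0, 255).astype(np.uint8)
    truth = {"config": cfg, "cells": cells, "gfp_positive": gfp_pos,
             "dots": pd.DataFrame(dots, columns=["cell", "z", "y", "x", "membrane"])}
    return stack, truth
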