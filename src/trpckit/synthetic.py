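"""Synthetic inputs with the statistical structure of the real assays.

Every downstream stage of the package — idealization, Hill surface
fitting, three-cube FRET, occupancy sorting, structure metrics — can be
exercised on data generated here with known ground truth:

* two-state (closed<->open) continuous-time Markov gating traces with
  low-pass-filtered recording noise;
* symmetry-expanded particle tables with prescribed occupancy-pattern
  frequencies and randomized rotational phases;
* Hill-form normalized-Po surfaces over a [PIP2] x [G-alpha] grid;
* three-cube intensity sets that invert the FRET measurement model
  exactly in the noiseless limit;
* toy coordinate sets under known rigid transforms and with controlled
  interface geometry.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .doseresponse import PoSurface, hill
from .fret import DEFAULT_EXTINCTION_RATIO, ThreeCubeSet
from .idealize import DwellSequence
from .occupancy import ParticleTable, classify_pattern, symmetry_expand
from .structure import StructureModel
from scipy.spatial.transform import Rotation

__all__ = [
    "GatingModel",
    "PatternFrequencies",
    "SurfaceTruth",
    "FretTruth",
    "gen_gating_trace",
    "gen_particle_table",
    "gen_hill_surface",
    "gen_three_cube",
    "gen_structure_fixture",
]


@dataclass(frozen=True)
class GatingModel:
    """Two-state Markov gating model plus recording parameters.

    Rates in s^-1; the unitary current is the open-minus-closed level in
    pA (negative for the inward currents typical of excised inside/out
    patches at negative potentials).  Defaults mirror a 10 kHz
    acquisition through a 1 kHz low-pass Bessel filter.
    """

    opening_rate: float
    closing_rate: float
    unitary_current: float = -2.0
    noise_sd: float = 0.2
    sampling_rate: float = 10_000.0
    filter_cutoff: float = 1_000.0
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.opening_rate <= 0 or self.closing_rate <= 0:
            raise ValueError("rates must be positive")
        if max(self.opening_rate, self.closing_rate) > self.sampling_rate / 2:
            raise ValueError("rates too fast for the sampling rate")
        if self.sampling_rate < 2 * self.filter_cutoff:
            raise ValueError("sampling_rate must be >= 2 * filter_cutoff")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def stationary_po(self) -> float:
        return self.opening_rate / (self.opening_rate + self.closing_rate)


def gen_gating_trace(model: GatingModel):
    """Simulate a single-channel current trace.

    The state path is a continuous-time Markov chain generated by
    exponential waiting times (no discretization of dwell times), then
    sampled at the model's sampling rate.  Additive white Gaussian
    noise, shaped by a 4-pole low-pass Bessel filter at the recording
    cutoff, emulates filtered amplifier noise.  The closed level is
    0 pA; the open level is the unitary current.

    Returns
    -------
    (RawTrace-compatible sample array wrapped as ``trpckit.idealize.RawTrace``,
    true DwellSequence of the underlying state path).
    """
    from .idealize import RawTrace

    rng = np.random.default_rng(model.seed)
    p_open = model.stationary_po
    state = bool(rng.random() < p_open)  # start at stationarity
    t = 0.0
    events: list[tuple[str, float]] = []
    while t < model.duration:
        rate = model.closing_rate if state else model.opening_rate
        dwell = rng.exponential(1.0 / rate)
        dwell = min(dwell, model.duration - t)
        events.append(("open" if state else "closed", dwell))
        t += dwell
        state = not state
    # coalesce is unnecessary: states alternate by construction
    truth = DwellSequence(events, T_m=model.duration)

    n = int(round(model.duration * model.sampling_rate))
    sample_t = np.arange(n) / model.sampling_rate
    # state at each sample time from the dwell boundaries
    bounds = np.cumsum([d for _, d in events])
    idx = np.searchsorted(bounds, sample_t, side="right")
    idx = np.minimum(idx, len(events) - 1)
    open_state = np.array([s == "open" for s, _ in events])[idx]
    clean = np.where(open_state, model.unitary_current, 0.0)

    if model.noise_sd > 0:
        white = rng.standard_normal(n)
        b, a = signal.bessel(4, model.filter_cutoff,
                             fs=model.sampling_rate, btype="low")
        shaped = signal.lfilter(b, a, white)
        # rescale so the delivered (post-filter) noise has the requested sd
        shaped *= model.noise_sd / shaped.std()
        samples = clean + shaped
    else:
        samples = clean
    trace = RawTrace(samples, sampling_rate=model.sampling_rate,
                     filter_cutoff=model.filter_cutoff)
    return trace, truth


@dataclass(frozen=True, init=False)
class PatternFrequencies:
    """Occupancy-pattern frequencies for a tetrameric ring.

    Keys from {"0", "1", "2-cis", "2-trans", "3", "4"}; values are
    non-negative and sum to 1.
    """

    freqs: tuple

    VALID = ("0", "1", "2-cis", "2-trans", "3", "4")

    def __init__(self, freqs: dict):
        object.__setattr__(self, "freqs", tuple(sorted(freqs.items())))
        d = dict(self.freqs)
        for label, f in d.items():
            if label not in self.VALID:
                raise ValueError(f"unknown pattern label {label!r}")
            if f < 0:
                raise ValueError("frequencies must be non-negative")
        if abs(sum(d.values()) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    def as_dict(self) -> dict:
        return dict(self.freqs)


#: a representative binary tuple per canonical tetramer pattern
_PATTERN_SEED_TUPLES = {
    "0": (0, 0, 0, 0),
    "1": (1, 0, 0, 0),
    "2-cis": (1, 1, 0, 0),
    "2-trans": (1, 0, 1, 0),
    "3": (1, 1, 1, 0),
    "4": (1, 1, 1, 1),
}


def gen_particle_table(n_particles: int, freqs: PatternFrequencies,
                       symmetry_order: int = 4, seed: int = 0,
                       bound_classes=(1, 2), unbound_classes=(3, 4)
                       ) -> ParticleTable:
    """Symmetry-expanded particle metadata with known pattern fractions.

    Each original particle draws a pattern from ``freqs``, a uniformly
    random rotational phase (so canonicalization is exercised), and a
    random in-plane base angle.  Expanded subunit rows carry focused
    class ids: a random bound class for occupied subunits, a random
    unbound class otherwise.
    """
    if symmetry_order != 4:
        raise NotImplementedError(
            "pattern frequencies are defined for tetramers (order 4)")
    rng = np.random.default_rng(seed)
    d = freqs.as_dict()
    labels = list(d)
    probs = np.array([d[l] for l in labels])
    draws = rng.choice(len(labels), size=n_particles, p=probs)

    originals = pd.DataFrame({
        "rlnImageName": [f"{i + 1:06d}@particles_{i // 1000:03d}.mrcs"
                         for i in range(n_particles)],
        "rlnMicrographName": [f"mic_{i // 1000:04d}.mrc"
                              for i in range(n_particles)],
        "rlnCoordinateX": np.round(rng.uniform(0, 4000, n_particles), 2),
        "rlnCoordinateY": np.round(rng.uniform(0, 4000, n_particles), 2),
        "rlnAngleRot": np.round(rng.uniform(0, 360.0 / symmetry_order,
                                            n_particles), 3),
    })
    table = symmetry_expand(originals, order=symmetry_order)
    df = table.df

    # per-particle bound flags with a random cyclic phase
    phases = rng.integers(0, symmetry_order, size=n_particles)
    class_ids = np.empty(len(df), dtype=int)
    bound_flags = np.empty(len(df), dtype=bool)
    # expanded table is blocks of the originals repeated per subunit copy;
    # recover (particle, copy) from position
    for row_pos in range(len(df)):
        copy_k, particle_i = divmod(row_pos, n_particles)
        pattern = _PATTERN_SEED_TUPLES[labels[draws[particle_i]]]
        ph = phases[particle_i]
        bound = bool(pattern[(copy_k + ph) % symmetry_order])
        bound_flags[row_pos] = bound
        pool = bound_classes if bound else unbound_classes
        class_ids[row_pos] = pool[rng.integers(0, len(pool))]
    df["rlnClassNumber"] = class_ids
    df["bound"] = bound_flags
    return ParticleTable(df, symmetry_order=symmetry_order)


@dataclass(frozen=True)
class SurfaceTruth:
    """Ground truth for a two-ligand Hill-form open-probability surface.

    Per co-ligand ([G-alpha]) column: apparent Kd for PIP2 (uM), Hill
    coefficient and amplitude (fraction of the global maximum).  The
    default grids follow the study conditions: G-alpha from 0.07 to
    14.6 uM, PIP2 doses spanning 1-100 uM, 6 replicate patches, 5%
    measurement noise.  Default Kd falls from 23.3 uM (lowest G-alpha)
    to 10.2 uM (highest).
    """

    gai3_concs: tuple = (0.07, 0.3, 0.91, 3.0, 14.6)
    pip2_concs: tuple = (1.0, 2.0, 5.0, 10.0, 16.0, 30.0, 50.0, 100.0)
    kd: tuple = (23.3, 19.8, 16.5, 13.2, 10.2)
    n: tuple = (2.0, 2.0, 2.0, 2.0, 2.0)
    amplitude: tuple = (0.5, 0.62, 0.75, 0.88, 1.0)
    noise_sd: float = 0.05
    replicates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.gai3_concs)
        for name in ("kd", "n", "amplitude"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per [G-alpha]")
        if not self.gai3_concs or not self.pip2_concs:
            raise ValueError("concentration grids must be non-empty")
        if any(v <= 0 for v in self.kd) or any(v <= 0 for v in self.n):
            raise ValueError("Kd and n must be positive")
        if any(not (0 < a <= 1) for a in self.amplitude):
            raise ValueError("amplitudes must lie in (0, 1]")
        if self.noise_sd < 0 or self.replicates < 1:
            raise ValueError("invalid noise_sd or replicates")


def gen_hill_surface(truth: SurfaceTruth) -> PoSurface:
    """Noisy Hill-form normalized-Po surface with known truth.

    Gaussian noise of sd ``noise_sd`` (on the normalized scale) is added
    per replicate and the result clipped to [0, 1]; noiseless when
    ``noise_sd`` is 0.
    """
    rng = np.random.default_rng(truth.seed)
    rows = []
    for j, g in enumerate(truth.gai3_concs):
        mean = hill(np.asarray(truth.pip2_concs), truth.kd[j], truth.n[j],
                    truth.amplitude[j])
        for rep in range(truth.replicates):
            vals = mean + (rng.normal(0.0, truth.noise_sd, mean.size)
                           if truth.noise_sd > 0 else 0.0)
            vals = np.clip(vals, 0.0, 1.0)
            for x, v in zip(truth.pip2_concs, vals):
                rows.append({"pip2_uM": x, "gai3_uM": g,
                             "replicate": rep, "po_norm": v})
    truth_dict = {
        "gai3_concs": truth.gai3_concs, "kd": truth.kd, "n": truth.n,
        "amplitude": truth.amplitude, "noise_sd": truth.noise_sd,
    }
    return PoSurface(pd.DataFrame(rows), truth=truth_dict)


@dataclass(frozen=True)
class FretTruth:
    """Ground truth for a three-cube FRET intensity set.

    ``efficiency`` is the intrinsic FRET efficiency E of a bound pair,
    ``bound_fraction`` the fraction A_b of acceptor-tagged molecules in
    complexes; the observable recovered by the analysis is
    E_EFF = E * A_b.
    """

    efficiency: float = 0.3
    bound_fraction: float = 1.0
    R_D1: float = 0.42
    R_D2: float = 0.06
    R_A1: float = 0.1
    extinction_ratio: float = DEFAULT_EXTINCTION_RATIO
    donor_brightness: float = 1000.0
    acceptor_brightness: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.efficiency <= 1.0):
            raise ValueError("efficiency must lie in [0, 1]")
        if not (0.0 <= self.bound_fraction <= 1.0):
            raise ValueError("bound_fraction must lie in [0, 1]")
        for name in ("R_D1", "R_D2", "R_A1", "extinction_ratio",
                     "donor_brightness", "acceptor_brightness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def e_eff(self) -> float:
        return self.efficiency * self.bound_fraction

    @property
    def fret_ratio(self) -> float:
        return 1.0 + self.e_eff / self.extinction_ratio


def gen_three_cube(truth: FretTruth) -> dict:
    """Three-cube intensity sets that invert the measurement model.

    Emits donor-only, acceptor-only and double-labelled sets such that
    the bleed-constant and FRET-ratio computations recover the truth
    exactly in the noiseless limit.  Multiplicative Gaussian noise of
    relative sd ``noise_sd`` is applied per intensity otherwise.

    Returns {"D": ThreeCubeSet, "A": ThreeCubeSet, "DA": ThreeCubeSet}.
    """
    rng = np.random.default_rng(truth.seed)
    Bd, Ba = truth.donor_brightness, truth.acceptor_brightness
    FR = truth.fret_ratio

    raw = {
        "D": {"CFP": Bd, "FRET": truth.R_D1 * Bd, "YFP": truth.R_D2 * Bd},
        "A": {"YFP": Ba, "FRET": truth.R_A1 * Ba, "CFP": 0.0},
        "DA": {
            "CFP": Bd,
            "YFP": truth.R_D2 * Bd + Ba,
            "FRET": truth.R_D1 * Bd + FR * truth.R_A1 * Ba,
        },
    }
    out = {}
    for spec, cubes in raw.items():
        S = {}
        for cube, val in cubes.items():
            if truth.noise_sd > 0 and val > 0:
                val = val * max(1.0 + rng.normal(0.0, truth.noise_sd), 0.0)
            S.setdefault(cube, {})[spec] = val
        out[spec] = ThreeCubeSet(S)
    return out


def _blob_coords(n: int, rng: np.random.Generator,
                 spread: float = 10.0) -> np.ndarray:
    pts = rng.normal(0.0, spread, size=(n, 3))
    # guard against (vanishingly unlikely) degenerate rank
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        raise ValueError("degenerate (collinear) point set generated")
    return pts


def _as_model(coords: np.ndarray, chain: str = "A",
              element: str = "C") -> StructureModel:
    n = coords.shape[0]
    return StructureModel(
        chain_id=[chain] * n,
        res_id=np.arange(1, n + 1),
        res_name=["ALA"] * n,
        atom_name=["CA"] * n,
        element=[element] * n,
        coord=coords,
    )


def gen_structure_fixture(kind: str, n_atoms: int = 60,
                          angle_deg: float = 0.0,
                          axis=(0.0, 0.0, 1.0),
                          translation=(0.0, 0.0, 0.0),
                          noise_sd: float = 0.0,
                          separation: float = 0.0,
                          radius: float = 2.0,
                          seed: int = 0):
    """Toy coordinate fixtures for the structure metrics.

    kind="rotated-copy": a random atom blob and its copy under the
    rigid transform (rotation ``angle_deg`` about ``axis`` through the
    blob centroid, then ``translation``), with optional coordinate
    noise.  Returns (model, moved_model, expected_rotation_matrix).

    kind="frame-domain": two-chain models (frame chain "F", domain
    chain "D") where the frame is identical in both and the domain of
    the second is rotated by ``angle_deg`` about ``axis`` through the
    origin and shifted by ``translation`` — the reference case for
    domain-rotation analysis.  Returns (modelA, modelB).

    kind="two-body-complex": two single-sphere "chains" of the given
    van der Waals radius at center separation ``separation`` along x —
    the analytic reference case for buried-area computations.  Returns
    a single two-chain StructureModel.
    """
    rng = np.random.default_rng(seed)
    if kind == "frame-domain":
        frame = _blob_coords(n_atoms, rng)
        domain = _blob_coords(n_atoms, rng, spread=6.0) + np.array([20.0, 0.0, -15.0])
        u = np.asarray(axis, float)
        u = u / np.linalg.norm(u)
        R = Rotation.from_rotvec(np.radians(angle_deg) * u).as_matrix()
        domain_b = domain @ R.T + np.asarray(translation, float)
        if noise_sd > 0:
            domain_b = domain_b + rng.normal(0.0, noise_sd, domain_b.shape)

        def combine(dom):
            both = np.vstack([frame, dom])
            n_f, n_d = len(frame), len(dom)
            return StructureModel(
                chain_id=["F"] * n_f + ["D"] * n_d,
                res_id=np.concatenate([np.arange(1, n_f + 1),
                                       np.arange(1, n_d + 1)]),
                res_name=["ALA"] * (n_f + n_d),
                atom_name=["CA"] * (n_f + n_d),
                element=["C"] * (n_f + n_d),
                coord=both,
            )

        return combine(domain), combine(domain_b)
    if kind == "rotated-copy":
        coords = _blob_coords(n_atoms, rng)
        u = np.asarray(axis, float)
        u = u / np.linalg.norm(u)
        R = Rotation.from_rotvec(np.radians(angle_deg) * u).as_matrix()
        center = coords.mean(axis=0)
        moved = (coords - center) @ R.T + center + np.asarray(translation, float)
        if noise_sd > 0:
            moved = moved + rng.normal(0.0, noise_sd, moved.shape)
        return _as_model(coords, "A"), _as_model(moved, "A"), R
    if kind == "two-body-complex":
        a = StructureModel(["A"], [1], ["SPH"], ["X1"], ["C"],
                           np.array([[0.0, 0.0, 0.0]]), radius=[radius])
        b = StructureModel(["B"], [1], ["SPH"], ["X1"], ["C"],
                           np.array([[separation, 0.0, 0.0]]), radius=[radius])
        return StructureModel(
            np.concatenate([a.chain_id, b.chain_id]),
            np.concatenate([a.res_id, b.res_id]),
            np.concatenate([a.res_name, b.res_name]),
            np.concatenate([a.atom_name, b.atom_name]),
            np.concatenate([a.element, b.element]),
            np.vstack([a.coord, b.coord]),
            radius=np.concatenate([a.radius, b.radius]),
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
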