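"""Parametric electron-track stand-in and absolute dosimetry.

Generates stochastic energy-deposition events inside the DNA scoring box
from isotropically incident, spectrum-sampled electrons.  The transport
model is deliberately simple and fully declared: each primary traverses the
bounding box on a straight mu-random chord, lays down interaction sites as
a Poisson process whose linear density is LET(E) / mean deposit energy, and
draws each site's deposit from a truncated exponential.  This preserves the
statistical structure the damage-scoring layer consumes (spatially
clustered, discrete eV-scale deposits along tracks) without any claim of
reproducing condensed-history or track-structure physics.

Primary counts are calibrated to absorbed dose (Gy = J/kg in the scoring
mass) by linear scaling from a pilot run.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .dna_geometry import DnaGeometry

__all__ = [
    "PhysicsParams",
    "DepositionEvent",
    "ExposureResult",
    "default_physics",
    "simulate_primary",
    "run_exposure",
    "calibrate_primaries",
    "save_events",
    "load_events",
]

EV_TO_J = 1.602176634e-19

# Chord entry points are drawn on a sphere just enclosing the box.
_BOUNDING_SPHERE_MARGIN = 1.01
_CANDIDATE_BATCH = 64


@dataclass(frozen=True)
class PhysicsParams:
    """Declared parameters of the parametric track model.

    ``stopping_table`` maps electron energy (MeV) to LET (keV/um,
    numerically equal to eV/nm), interpolated piecewise log-log.  Each
    interaction deposits a truncated-exponential energy with underlying
    scale ``mean_deposit_ev``, truncated to [deposit_min_ev,
    deposit_max_ev].  Values are illustrative model inputs, not measured
    cross-sections.
    """

    stopping_table: tuple[tuple[float, float], ...]
    mean_deposit_ev: float = 40.0
    deposit_min_ev: float = 5.0
    deposit_max_ev: float = 500.0

    def __post_init__(self) -> None:
        table = tuple((float(e), float(s)) for e, s in self.stopping_table)
        if len(table) < 2:
            raise ValueError("stopping_table needs >= 2 points")
        energies = [e for e, _ in table]
        if any(b <= a for a, b in zip(energies, energies[1:])):
            raise ValueError("stopping_table energies must ascend")
        if any(s <= 0 for _, s in table) or any(e <= 0 for e, _ in table):
            raise ValueError("stopping_table entries must be positive")
        if not 0 < self.deposit_min_ev < self.mean_deposit_ev < self.deposit_max_ev:
            raise ValueError(
                "need 0 < deposit_min_ev < mean_deposit_ev < deposit_max_ev"
            )
        object.__setattr__(self, "stopping_table", table)

    def let_ev_per_nm(self, energy_mev) -> np.ndarray:
        """LET at ``energy_mev`` (eV/nm), log-log interpolated and clamped
        to the table's range."""
        e = np.log(np.clip(np.asarray(energy_mev, dtype=float),
                           self.stopping_table[0][0],
                           self.stopping_table[-1][0]))
        xs = np.log([p[0] for p in self.stopping_table])
        ys = np.log([p[1] for p in self.stopping_table])
        return np.exp(np.interp(e, xs, ys))


@dataclass(frozen=True)
class DepositionEvent:
    """A single energy deposit: position (nm) and energy (eV)."""

    position: np.ndarray
    energy_ev: float
    primary_id: int
    within_volume: bool = True

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("event position must be a finite 3-vector")
        if self.energy_ev <= 0:
            raise ValueError("event energy must be positive")
        object.__setattr__(self, "position", pos)


@dataclass
class ExposureResult:
    """Aggregate of one seeded exposure: events, totals and absorbed dose."""

    events: list[DepositionEvent]
    n_primaries: int
    total_energy_ev: float
    dose_gy: float
    seed: int
    scoring_mass_kg: float = field(default=float("nan"))


def default_physics() -> PhysicsParams:
    """Load the editable packaged physics defaults (illustrative values)."""
    text = (
        importlib.resources.files("dsbkit.data")
        .joinpath("physics_default.yaml")
        .read_text()
    )
    return physics_from_dict(yaml.safe_load(text))


def physics_from_dict(cfg: dict) -> PhysicsParams:
    return PhysicsParams(
        stopping_table=tuple(
            (float(row[0]), float(row[1])) for row in cfg["stopping_table"]
        ),
        mean_deposit_ev=float(cfg.get("mean_deposit_ev", 40.0)),
        deposit_min_ev=float(cfg.get("deposit_min_ev", 5.0)),
        deposit_max_ev=float(cfg.get("deposit_max_ev", 500.0)),
    )


def _sample_box_chord(
    box_min: np.ndarray, box_max: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw a mu-random chord of the axis-aligned box.

    Entry points are uniform on a bounding sphere; directions follow the
    cosine (isotropic-fluence) law about the inward normal; candidates that
    miss the box are rejected.  This construction makes the chords
    mu-random, so the mean in-box chord length is exactly 4V/S.
    Returns (chord start point, unit direction, chord length in nm).
    """
    center = 0.5 * (box_min + box_max)
    radius = 0.5 * float(np.linalg.norm(box_max - box_min)) * _BOUNDING_SPHERE_MARGIN
    while True:
        m = _CANDIDATE_BATCH
        # uniform points on the sphere
        normal = rng.normal(size=(m, 3))
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        origin = center + radius * normal
        inward = -normal
        # cosine-law direction about the inward normal
        u1 = rng.random(m)
        u2 = rng.random(m)
        cos_t = np.sqrt(u1)
        sin_t = np.sqrt(1.0 - u1)
        phi = 2.0 * np.pi * u2
        # orthonormal frame around each inward normal
        helper = np.where(
            np.abs(inward[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
        )
        t1 = np.cross(inward, helper)
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        t2 = np.cross(inward, t1)
        direction = (
            cos_t[:, None] * inward
            + (sin_t * np.cos(phi))[:, None] * t1
            + (sin_t * np.sin(phi))[:, None] * t2
        )
        # slab intersection with the box
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (box_min - origin) / direction
            t_hi = (box_max - origin) / direction
        t_near = np.nanmax(np.minimum(t_lo, t_hi), axis=1)
        t_far = np.nanmin(np.maximum(t_lo, t_hi), axis=1)
        hits = np.flatnonzero((t_far > t_near) & (t_far > 0))
        if hits.size:
            i = int(hits[0])
            entry = origin[i] + t_near[i] * direction[i]
            return entry, direction[i], float(t_far[i] - t_near[i])


def _sample_deposit_energies(
    phys: PhysicsParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-exponential deposit energies (eV) by inverse CDF."""
    scale = phys.mean_deposit_ev
    f_lo = -np.expm1(-phys.deposit_min_ev / scale)
    f_hi = -np.expm1(-phys.deposit_max_ev / scale)
    u = f_lo + rng.random(n) * (f_hi - f_lo)
    return -scale * np.log1p(-u)


def simulate_primary(
    geometry: DnaGeometry,
    spec,
    phys: PhysicsParams,
    rng: np.random.Generator,
    primary_id: int = 0,
) -> list[DepositionEvent]:
    """Transport one spectrum-sampled electron through the scoring box.

    Samples the electron energy, a mu-random chord through the bounding
    box, a Poisson number of interaction sites with linear density
    LET(E)/mean_deposit_ev, uniform site positions along the chord and
    truncated-exponential site energies.  An empty list (no deposit) is a
    valid outcome.
    """
    from .spectrum import sample_energies

    energy_mev = float(sample_energies(spec, 1, rng)[0])
    entry, direction, length = _sample_box_chord(
        geometry.box_min, geometry.box_max, rng
    )
    density = float(phys.let_ev_per_nm(energy_mev)) / phys.mean_deposit_ev
    n_events = int(rng.poisson(density * length))
    if n_events == 0:
        return []
    offsets = np.sort(rng.random(n_events)) * length
    energies = _sample_deposit_energies(phys, n_events, rng)
    return [
        DepositionEvent(
            position=entry + t * direction,
            energy_ev=float(e),
            primary_id=primary_id,
            within_volume=True,
        )
        for t, e in zip(offsets, energies)
    ]


def run_exposure(
    geometry: DnaGeometry,
    spec,
    phys: PhysicsParams,
    n_primaries: int,
    seed: int,
) -> ExposureResult:
    """Aggregate ``n_primaries`` independent primaries under one seed.

    Absorbed dose is total in-volume energy (J) divided by the geometry's
    scoring mass (kg).  Bit-identical event streams for identical
    (seed, configuration).
    """
    if n_primaries < 1:
        raise ValueError("n_primaries must be >= 1")
    rng = np.random.default_rng(seed)
    events: list[DepositionEvent] = []
    for pid in range(n_primaries):
        events.extend(simulate_primary(geometry, spec, phys, rng, primary_id=pid))
    total_ev = float(sum(e.energy_ev for e in events if e.within_volume))
    mass = geometry.scoring_volume_mass
    return ExposureResult(
        events=events,
        n_primaries=n_primaries,
        total_energy_ev=total_ev,
        dose_gy=total_ev * EV_TO_J / mass,
        seed=seed,
        scoring_mass_kg=mass,
    )


def save_events(events: list[DepositionEvent], path) -> None:
    """Write events as CSV: primary_id, x_nm, y_nm, z_nm, energy_ev,
    within_volume."""
    import pandas as pd

    pd.DataFrame(
        [
            dict(
                primary_id=e.primary_id,
                x_nm=e.position[0],
                y_nm=e.position[1],
                z_nm=e.position[2],
                energy_ev=e.energy_ev,
                within_volume=e.within_volume,
            )
            for e in events
        ],
        columns=["primary_id", "x_nm", "y_nm", "z_nm", "energy_ev",
                 "within_volume"],
    ).to_csv(path, index=False)


def load_events(path) -> list[DepositionEvent]:
    """Read events from the CSV layout written by :func:`save_events`."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"primary_id", "x_nm", "y_nm", "z_nm", "energy_ev"}
    if not required.issubset(df.columns):
        raise ValueError(f"events CSV needs columns {sorted(required)}")
    if "within_volume" not in df.columns:
        df["within_volume"] = True
    return [
        DepositionEvent(
            position=np.array([r.x_nm, r.y_nm, r.z_nm]),
            energy_ev=float(r.energy_ev),
            primary_id=int(r.primary_id),
            within_volume=bool(r.within_volume),
        )
        for r in df.itertuples()
    ]


def calibrate_primaries(target_dose_gy: float, pilot: ExposureResult) -> int:
    """Primary count delivering ``target_dose_gy``, scaled linearly from a
    pilot exposure (absolute dosimetry)."""
    if pilot.dose_gy <= 0:
        raise ValueError("no energy deposited in pilot")
    return int(round(target_dose_gy * pilot.n_primaries / pilot.dose_gy))
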