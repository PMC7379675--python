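"""Replicate-driven exposures, threshold scans and dose-response analysis.

Mirrors the study protocol around the damage model: at each absorbed dose
the primary count is calibrated from a pilot run (absolute dosimetry), many
seed-replicated exposures are scored, and P(DSB) — the fraction of
replicate molecules carrying at least one DSB — is reported with its
standard error of the mean, SEM = SD/sqrt(N) with the sample (N-1)
standard deviation of the binary outcomes.  A full factorial scan over the
energy threshold (ET) and base-pair threshold (BPT) re-scores shared event
streams, and a quadratic least-squares fit P(DSB) = a D^2 + b D + c
summarizes any dose-response table, simulated or experimental.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .damage_scoring import DamageParams, assign_deposits, pair_dsb, score_ssb
from .dna_geometry import DnaGeometry
from .track_sim import PhysicsParams, calibrate_primaries, run_exposure

__all__ = [
    "DoseResponsePoint",
    "QuadraticFit",
    "ScanGrid",
    "ComparisonResult",
    "estimate_pdsb",
    "run_dose_series",
    "scan_thresholds",
    "fit_dose_response",
    "compare_to_experiment",
    "load_experimental_table",
    "save_experimental_table",
]

#: The study's threshold grids and dose list.
DEFAULT_ET_GRID_EV = (10.0, 12.5, 15.0, 17.5, 18.0, 19.0, 20.0, 22.5)
DEFAULT_BPT_GRID_BP = (6, 8, 10, 12, 14)
DEFAULT_DOSES_GY = (25.0, 50.0, 100.0, 150.0, 200.0)
DEFAULT_N_REPLICATES = 1000


@dataclass(frozen=True)
class DoseResponsePoint:
    """P(DSB) at one dose, with SEM, from experiment or simulation."""

    dose_gy: float
    p_dsb: float
    sem: float
    n_replicates: int = 1
    source: str = "simulation"
    sd: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_dsb <= 1.0:
            raise ValueError("p_dsb must lie in [0, 1]")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")
        if self.source == "simulation" and self.n_replicates < 1:
            raise ValueError("simulation points need n_replicates >= 1")


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic dose response p = a D^2 + b D + c."""

    a: float  # Gy^-2
    b: float  # Gy^-1
    c: float  # intercept
    residuals: tuple[float, ...]

    def predict(self, dose_gy) -> np.ndarray:
        d = np.asarray(dose_gy, dtype=float)
        return self.a * d * d + self.b * d + self.c


@dataclass
class ScanGrid:
    """Full-factorial P(DSB) over (ET, BPT, dose), shared event streams."""

    et_values: tuple[float, ...]
    bpt_values: tuple[int, ...]
    doses: tuple[float, ...]
    p_dsb: np.ndarray  # shape (n_et, n_bpt, n_dose)
    sem: np.ndarray
    n_replicates: int
    base_seed: int

    def __post_init__(self) -> None:
        shape = (len(self.et_values), len(self.bpt_values), len(self.doses))
        if self.p_dsb.shape != shape or self.sem.shape != shape:
            raise ValueError(f"scan tables must have shape {shape}")
        if np.any(self.p_dsb < 0) or np.any(self.p_dsb > 1):
            raise ValueError("p_dsb entries must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, et in enumerate(self.et_values):
            for j, bpt in enumerate(self.bpt_values):
                for k, dose in enumerate(self.doses):
                    rows.append(
                        dict(et_ev=et, bpt_bp=bpt, dose_gy=dose,
                             p_dsb=self.p_dsb[i, j, k],
                             sem=self.sem[i, j, k],
                             n=self.n_replicates)
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    """Per-dose simulated-vs-experimental differences."""

    table: pd.DataFrame  # dose_gy, p_sim, p_exp, abs_diff, rel_diff
    max_abs: float
    min_abs: float
    max_rel: float
    min_rel: float


def estimate_pdsb(
    broken_flags, dose_gy: float = float("nan"), source: str = "simulation"
) -> DoseResponsePoint:
    """P(DSB) and SEM from replicate binary outcomes.

    SEM = SD / sqrt(N) with SD the sample standard deviation (N-1
    denominator) of the 0/1 flags; at least two replicates are required
    for SD to exist.
    """
    flags = np.asarray(list(broken_flags), dtype=float)
    n = flags.size
    if n < 2:
        raise ValueError("need >= 2 replicates to estimate SEM")
    p = float(flags.mean())
    sd = float(flags.std(ddof=1))
    return DoseResponsePoint(
        dose_gy=dose_gy,
        p_dsb=p,
        sem=sd / math.sqrt(n),
        n_replicates=n,
        source=source,
        sd=sd,
    )


def _calibration_pilot(geometry, spec, phys, base_seed, pilot_primaries):
    """Pilot exposure for absolute dosimetry; grows until energy lands."""
    n = pilot_primaries
    for _ in range(10):
        pilot = run_exposure(geometry, spec, phys, n, seed=base_seed)
        if pilot.dose_gy > 0:
            return pilot
        n *= 4
    raise RuntimeError("pilot exposure deposited no energy; check physics")


def _replicate_seed(base_seed: int, dose_index: int, replicate: int,
                    n_replicates: int) -> int:
    # distinct stream per (dose, replicate); +1 keeps clear of the pilot
    return base_seed + 1 + dose_index * n_replicates + replicate


def run_dose_series(
    geometry: DnaGeometry,
    spec,
    phys: PhysicsParams,
    params: DamageParams,
    doses=DEFAULT_DOSES_GY,
    n_replicates: int = DEFAULT_N_REPLICATES,
    base_seed: int = 1,
    pilot_primaries: int = 2000,
) -> list[DoseResponsePoint]:
    """Seed-replicated P(DSB) at each dose with calibrated primary counts."""
    from .damage_scoring import score_molecule

    pilot = _calibration_pilot(geometry, spec, phys, base_seed, pilot_primaries)
    points = []
    for d_idx, dose in enumerate(doses):
        n_prim = max(1, calibrate_primaries(dose, pilot))
        flags = []
        for r in range(n_replicates):
            seed = _replicate_seed(base_seed, d_idx, r, n_replicates)
            exposure = run_exposure(geometry, spec, phys, n_prim, seed)
            flags.append(score_molecule(exposure.events, geometry, params).broken)
        points.append(estimate_pdsb(flags, dose_gy=dose))
    return points


def scan_thresholds(
    geometry: DnaGeometry,
    spec,
    phys: PhysicsParams,
    et_values=DEFAULT_ET_GRID_EV,
    bpt_values=DEFAULT_BPT_GRID_BP,
    doses=DEFAULT_DOSES_GY,
    n_replicates: int = DEFAULT_N_REPLICATES,
    base_seed: int = 1,
    capture_radius_nm: float = 0.35,
    pilot_primaries: int = 2000,
    per_deposit: bool = False,
) -> ScanGrid:
    """Full factorial P(DSB) over (ET, BPT, dose).

    Event streams are generated once per (dose, replicate) and re-scored
    for every (ET, BPT) cell, so threshold comparisons share events and
    the monotone orderings in ET and BPT hold exactly, not just in
    expectation.
    """
    et_values = tuple(float(v) for v in et_values)
    bpt_values = tuple(int(v) for v in bpt_values)
    doses = tuple(float(d) for d in doses)
    if not et_values or not bpt_values or not doses:
        raise ValueError("scan grids must be non-empty")

    pilot = _calibration_pilot(geometry, spec, phys, base_seed, pilot_primaries)
    broken = np.zeros(
        (len(et_values), len(bpt_values), len(doses), n_replicates), dtype=bool
    )
    reduce = "max" if per_deposit else "sum"
    for d_idx, dose in enumerate(doses):
        n_prim = max(1, calibrate_primaries(dose, pilot))
        for r in range(n_replicates):
            seed = _replicate_seed(base_seed, d_idx, r, n_replicates)
            exposure = run_exposure(geometry, spec, phys, n_prim, seed)
            tally = assign_deposits(
                exposure.events, geometry, capture_radius_nm, reduce=reduce
            )
            for e_idx, et in enumerate(et_values):
                ssbs = score_ssb(tally, et)
                for b_idx, bpt in enumerate(bpt_values):
                    broken[e_idx, b_idx, d_idx, r] = pair_dsb(ssbs, bpt) >= 1

    p = broken.mean(axis=3)
    sd = broken.std(axis=3, ddof=1)
    return ScanGrid(
        et_values=et_values,
        bpt_values=bpt_values,
        doses=doses,
        p_dsb=p,
        sem=sd / math.sqrt(n_replicates),
        n_replicates=n_replicates,
        base_seed=base_seed,
    )


def fit_dose_response(points: list[DoseResponsePoint]) -> QuadraticFit:
    """Unweighted least-squares fit of p on (D^2, D, 1)."""
    doses = np.array([pt.dose_gy for pt in points], dtype=float)
    p = np.array([pt.p_dsb for pt in points], dtype=float)
    if np.unique(doses).size < 3:
        raise ValueError("quadratic fit needs >= 3 distinct doses")
    design = np.column_stack([doses**2, doses, np.ones_like(doses)])
    coef, *_ = np.linalg.lstsq(design, p, rcond=None)
    resid = p - design @ coef
    return QuadraticFit(
        a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
        residuals=tuple(float(r) for r in resid),
    )


def compare_to_experiment(
    sim: list[DoseResponsePoint], exp: list[DoseResponsePoint]
) -> ComparisonResult:
    """Per-dose absolute and relative P(DSB) differences, with extremes."""
    sim_by_dose = {pt.dose_gy: pt for pt in sim}
    exp_by_dose = {pt.dose_gy: pt for pt in exp}
    if set(sim_by_dose) != set(exp_by_dose):
        raise ValueError(
            f"dose mismatch: simulated {sorted(sim_by_dose)} "
            f"vs experimental {sorted(exp_by_dose)}"
        )
    rows = []
    for dose in sorted(sim_by_dose):
        ps, pe = sim_by_dose[dose].p_dsb, exp_by_dose[dose].p_dsb
        rows.append(
            dict(
                dose_gy=dose,
                p_sim=ps,
                p_exp=pe,
                abs_diff=abs(ps - pe),
                rel_diff=abs(ps - pe) / pe if pe > 0 else float("inf"),
            )
        )
    table = pd.DataFrame(rows)
    return ComparisonResult(
        table=table,
        max_abs=float(table.abs_diff.max()),
        min_abs=float(table.abs_diff.min()),
        max_rel=float(table.rel_diff.max()),
        min_rel=float(table.rel_diff.min()),
    )


def load_experimental_table(path=None) -> list[DoseResponsePoint]:
    """Read a dose-response CSV (columns dose_gy, p_dsb, sem).

    Without ``path``, loads the packaged dosimeter measurements: P(DSB)
    4.3/8.1/14.9/19.6/24.2 % at 25/50/100/150/200 Gy.
    """
    if path is None:
        source = (
            importlib.resources.files("dsbkit.data").joinpath("table1.csv")
        )
        with source.open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"dose_gy", "p_dsb", "sem"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"dose-response table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df.empty:
        raise ValueError("dose-response table is empty")
    return [
        DoseResponsePoint(
            dose_gy=float(r.dose_gy), p_dsb=float(r.p_dsb), sem=float(r.sem),
            n_replicates=1, source="experiment",
        )
        for r in df.itertuples()
    ]


def save_experimental_table(points: list[DoseResponsePoint], path) -> None:
    pd.DataFrame(
        [dict(dose_gy=p.dose_gy, p_dsb=p.p_dsb, sem=p.sem) for p in points]
    ).to_csv(path, index=False)
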