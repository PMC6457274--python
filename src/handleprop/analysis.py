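"""Post-processing of simulation traces into propulsion summaries.

The crank revolution is partitioned into four zones (quadrants by
default, starting at crank angle 0 in the propulsion sense); zones 1 and
4 form the *pull* phase, zones 2 and 3 the *push* phase.  Per-muscle net
mechanical work, joint ranges of motion, normalized fiber mechanics, and
peak forces are computed from the steady-state evaluation cycle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arm import SimulationTrace
from .mechanism import net_power

__all__ = [
    "ZonePartition",
    "MuscleWorkReport",
    "muscle_work",
    "rom_summary",
    "fiber_mechanics",
    "peak_forces",
    "energy_balance",
    "report",
]

#: default ergonomic joint ranges for flagging (deg), planar coordinates
ERGONOMIC_RANGES_DEG = {"shoulder": (-120.0, 30.0), "elbow": (10.0, 120.0)}

ACTIVITY_THRESHOLD = 0.2  # activation level defining "active" regions


@dataclass(frozen=True)
class ZonePartition:
    """Four crank-angle intervals tiling [0, 2*pi).

    ``boundaries`` are the 5 monotone edge angles (rad), first 0 and last
    2*pi.  Zones 1 and 4 are the pull phase, 2 and 3 the push phase.
    """

    boundaries: tuple = (0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi, 2.0 * math.pi)
    pull: tuple = (1, 4)
    push: tuple = (2, 3)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size != 5 or np.any(np.diff(b) <= 0):
            raise ValueError("need 5 strictly increasing zone boundaries")
        if abs(b[0]) > 1e-12 or abs(b[-1] - 2.0 * math.pi) > 1e-9:
            raise ValueError("zones must tile [0, 2*pi)")
        if sorted(self.pull + self.push) != [1, 2, 3, 4]:
            raise ValueError("pull/push labels must partition zones 1-4")

    def zone_of(self, theta) -> np.ndarray:
        """1-based zone index per crank angle."""
        th = np.mod(np.asarray(theta, dtype=float), 2.0 * math.pi)
        return np.clip(
            np.searchsorted(np.asarray(self.boundaries), th, side="right"), 1, 4
        )


@dataclass(frozen=True)
class MuscleWorkReport:
    """Per-muscle, per-zone net musculotendon work (J) over one cycle."""

    muscle_names: tuple
    zone_work: np.ndarray  # (n_muscles, 4)
    positive_work: np.ndarray  # (n_muscles,)
    negative_work: np.ndarray  # (n_muscles,)

    @property
    def cycle_total(self) -> np.ndarray:
        return self.zone_work.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.zone_work,
            index=list(self.muscle_names),
            columns=[f"zone{z}_J" for z in (1, 2, 3, 4)],
        )
        df["total_J"] = self.cycle_total
        df["positive_J"] = self.positive_work
        df["negative_J"] = self.negative_work
        df.index.name = "muscle"
        return df


def _require_single_cycle(trace: SimulationTrace) -> SimulationTrace:
    if trace.n_cycles != 1:
        trace = trace.evaluation_cycle()
    span = trace.time[-1] - trace.time[0]
    if abs(span - trace.period) > 1e-3 * trace.period:
        raise ValueError("trace must cover exactly one crank cycle")
    return trace


def muscle_work(
    trace: SimulationTrace, zones: ZonePartition | None = None
) -> MuscleWorkReport:
    """Net musculotendon work per muscle and zone, W = int F * (-dL/dt) dt.

    Shortening under tension counts positive.  Per-interval trapezoid
    contributions are assigned to zones by the interval midpoint crank
    angle, so zone works sum exactly to the cycle total.
    """
    trace = _require_single_cycle(trace)
    zones = zones or ZonePartition()
    # power delivered by each muscle: F * (-dL_MT/dt) = F * (sum r qd)
    p = trace.forces * (-trace.v_mt)  # (n_t, n_m)
    dt = np.diff(trace.time)
    seg = 0.5 * (p[:-1] + p[1:]) * dt[:, None]  # (n_t-1, n_m)
    theta_mid = np.mod(
        trace.theta[:-1] + 0.5 * trace.omega * dt, 2.0 * math.pi
    )
    zone_idx = zones.zone_of(theta_mid)  # (n_t-1,)
    zone_work = np.zeros((p.shape[1], 4))
    for z in range(1, 5):
        mask = zone_idx == z
        zone_work[:, z - 1] = seg[mask].sum(axis=0)
    pos = np.clip(seg, 0.0, None).sum(axis=0)
    neg = np.clip(seg, None, 0.0).sum(axis=0)
    return MuscleWorkReport(
        muscle_names=trace.muscle_names,
        zone_work=zone_work,
        positive_work=pos,
        negative_work=neg,
    )


def rom_summary(
    trace: SimulationTrace, ergonomic_ranges_deg: dict | None = None
) -> pd.DataFrame:
    """Per-joint min/max angles (deg) over the evaluation cycle, with a
    flag when the excursion leaves the configured ergonomic range."""
    trace = _require_single_cycle(trace)
    ranges = ergonomic_ranges_deg or ERGONOMIC_RANGES_DEG
    rows = []
    for j, joint in enumerate(("shoulder", "elbow")):
        qdeg = np.degrees(trace.q[:, j])
        lo, hi = ranges.get(joint, (-math.inf, math.inf))
        rows.append(
            {
                "joint": joint,
                "min_deg": float(qdeg.min()),
                "max_deg": float(qdeg.max()),
                "rom_deg": float(qdeg.max() - qdeg.min()),
                "ergonomic_lo_deg": lo,
                "ergonomic_hi_deg": hi,
                "outside_ergonomic": bool(qdeg.min() < lo or qdeg.max() > hi),
            }
        )
    return pd.DataFrame(rows).set_index("joint")


@dataclass(frozen=True)
class FiberMechanics:
    """Normalized fiber length and velocity series with an activity mask
    (activation above the 20% threshold)."""

    muscle_names: tuple
    time: np.ndarray
    lm_norm: np.ndarray
    vm_over_vmax: np.ndarray
    active_mask: np.ndarray
    threshold: float = ACTIVITY_THRESHOLD


def fiber_mechanics(
    trace: SimulationTrace, threshold: float = ACTIVITY_THRESHOLD
) -> FiberMechanics:
    """Normalized fiber mechanics of the evaluation cycle.

    ``vm_over_vmax`` is fiber velocity normalized by each muscle's
    maximum shortening velocity (shortening negative); the mask marks
    samples with activation above ``threshold``.
    """
    trace = _require_single_cycle(trace)
    return FiberMechanics(
        muscle_names=trace.muscle_names,
        time=trace.time,
        lm_norm=trace.lm_norm,
        vm_over_vmax=trace.vm_norm,
        active_mask=trace.activations > threshold,
        threshold=threshold,
    )


def peak_forces(trace: SimulationTrace) -> dict:
    """Per-muscle maximum tendon force (N) over the evaluation cycle."""
    trace = _require_single_cycle(trace)
    peaks = trace.forces.max(axis=0)
    return {name: float(p) for name, p in zip(trace.muscle_names, peaks)}


def energy_balance(trace: SimulationTrace) -> dict:
    """Cycle energy audit: net crank work vs musculotendon + passive work.

    Over a periodic steady-state cycle the inverse-dynamics work
    (gravity + inertia) vanishes, so net crank work must equal the sum of
    musculotendon work and joint-limit (passive) work.
    """
    trace = _require_single_cycle(trace)
    t = trace.time
    w_crank = float(np.trapezoid(trace.power, t))
    w_muscle = float(np.trapezoid(np.sum(trace.forces * (-trace.v_mt), axis=1), t))
    w_limit = float(np.trapezoid(np.sum(trace.tau_limit * trace.qd, axis=1), t))
    w_id = float(np.trapezoid(np.sum(trace.tau_id * trace.qd, axis=1), t))
    return {
        "crank_work_J": w_crank,
        "muscle_work_J": w_muscle,
        "limit_work_J": w_limit,
        "inverse_dynamics_work_J": w_id,
        "residual_J": w_crank - (w_muscle + w_limit),
    }


def report(
    trace: SimulationTrace,
    out_dir,
    shape=None,
    circularity_value: float | None = None,
    zones: ZonePartition | None = None,
) -> dict:
    """Write the standard result bundle: summary JSON + CSV tables.

    Deterministic field ordering; returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ev = _require_single_cycle(trace)
    work = muscle_work(ev, zones)
    rom = rom_summary(ev)
    peaks = peak_forces(ev)
    summary = {
        "net_power_W": net_power(ev.time, ev.power, period=ev.period),
        "omega_rpm": ev.omega * 60.0 / (2.0 * math.pi),
        "circularity": circularity_value,
        "shape": None
        if shape is None
        else {
            "A_m": shape.A,
            "B_m": shape.B,
            "n": shape.n,
            "beta_deg": shape.beta_deg,
        },
        "peak_forces_N": {k: peaks[k] for k in sorted(peaks)},
        "energy_balance": energy_balance(ev),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=False)
        fh.write("\n")
    work.to_dataframe().to_csv(out / "muscle_work.csv", float_format="%.9g")
    rom.to_csv(out / "rom.csv", float_format="%.9g")
    ev.write_csv(out / "trace.csv")
    return summary
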