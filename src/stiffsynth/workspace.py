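"""Workspace-wide maps of stiffness controllability and energy headroom.

Each map sweeps a joint-angle grid (singular elbow angles excluded) and
records one value per posture:

* ``realizable_fraction_map`` — fraction of ellipse orientations achievable
  at a fixed ellipse shape (condition number);
* ``energy_reduction_map`` — the greatest percent energy reduction available
  at any realizable orientation (0 where the feasible set is a single point
  everywhere: no room to economize);
* ``synergy_fraction_map`` — orientation coverage of the two-synergy
  manifold, as a fraction of 180 degrees.

Maps are computed in joint space (no inverse-kinematics branch ambiguity)
and each record carries the endpoint coordinates for workspace rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .arm import ArmModel, Posture, forward_kinematics, posture_grid
from .feasibility import (
    assemble_constraints,
    auto_scale,
    energy_range,
    feasible_segment,
    realizable_fraction,
    scaled,
)
from .stiffness import desired_stiffness
from .synergy import SynergyBasis, orientation_range, ratio_sweep

__all__ = [
    "WorkspaceMap",
    "realizable_fraction_map",
    "energy_reduction_map",
    "synergy_fraction_map",
]

#: record status codes
OK = "ok"
NO_ORIENTATION = "no_realizable_orientation"
ISOTROPIC = "isotropic"


@dataclass(frozen=True)
class WorkspaceMap:
    """Tabular per-posture result with run metadata.

    ``records`` columns: theta1_deg, theta2_deg, endpoint_x, endpoint_y,
    value, status.
    """

    records: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, float_format="%.12g")

    def summary(self) -> dict[str, float]:
        ok = self.records[self.records.status == OK].value
        return {
            "n_postures": int(len(self.records)),
            "n_ok": int(len(ok)),
            "mean_value": float(ok.mean()) if len(ok) else float("nan"),
            "max_value": float(ok.max()) if len(ok) else float("nan"),
            "min_value": float(ok.min()) if len(ok) else float("nan"),
        }


def _base_record(arm: ArmModel, p: Posture) -> dict[str, float]:
    x, y = forward_kinematics(arm, p)
    t1, t2 = p.theta_deg
    return {
        "theta1_deg": t1,
        "theta2_deg": t2,
        "endpoint_x": float(x),
        "endpoint_y": float(y),
    }


def realizable_fraction_map(
    arm: ArmModel,
    shape: float,
    grid: tuple[int, int] = (25, 25),
    step_deg: float = 5.0,
    scale: float | str = "auto",
) -> WorkspaceMap:
    """Fraction of realizable ellipse orientations at each grid posture."""
    rows = []
    for p in posture_grid(arm, *grid):
        rec = _base_record(arm, p)
        rec["value"] = realizable_fraction(arm, p, shape, scale=scale, step_deg=step_deg)
        rec["status"] = OK
        rows.append(rec)
    meta = {
        "kind": "realizable_fraction",
        "shape": shape,
        "grid": list(grid),
        "orientation_step_deg": step_deg,
        "scale": scale,
    }
    return WorkspaceMap(records=pd.DataFrame(rows), metadata=meta)


def energy_reduction_map(
    arm: ArmModel,
    shape: float,
    grid: tuple[int, int] = (25, 25),
    step_deg: float = 5.0,
    scale: float | str = "auto",
) -> WorkspaceMap:
    """Best-case percent energy reduction per posture.

    For each posture, the maximum over realizable orientations of
    ``100 (e_max - e_min) / e_max``; postures with no realizable orientation
    are flagged rather than valued.
    """
    n_orient = int(round(180.0 / step_deg))
    rows = []
    for p in posture_grid(arm, *grid):
        rec = _base_record(arm, p)
        best = None
        for i in range(n_orient):
            task = assemble_constraints(arm, p, desired_stiffness(shape, i * step_deg, 1.0))
            s = auto_scale(task) if scale == "auto" else float(scale)
            seg = feasible_segment(scaled(task, s))
            if seg.empty:
                continue
            er = energy_range(scaled(task, s), seg)
            red = er.reduction_pct
            if red is not None and (best is None or red > best):
                best = red
        if best is None:
            rec["value"] = float("nan")
            rec["status"] = NO_ORIENTATION
        else:
            rec["value"] = best
            rec["status"] = OK
        rows.append(rec)
    meta = {
        "kind": "energy_reduction",
        "shape": shape,
        "grid": list(grid),
        "orientation_step_deg": step_deg,
        "scale": scale,
    }
    return WorkspaceMap(records=pd.DataFrame(rows), metadata=meta)


def synergy_fraction_map(
    arm: ArmModel,
    basis: SynergyBasis,
    grid: tuple[int, int] = (25, 25),
    ratios=None,
) -> WorkspaceMap:
    """Orientation coverage of the synergy manifold across the workspace."""
    rows = []
    for p in posture_grid(arm, *grid):
        rec = _base_record(arm, p)
        sweep = ratio_sweep(arm, p, basis, ratios=ratios)
        defined = [e for _, e in sweep if e.orientation_deg is not None]
        if len(defined) < 2:
            rec["value"] = float("nan")
            rec["status"] = ISOTROPIC
        else:
            _, frac = orientation_range(sweep)
            rec["value"] = frac
            rec["status"] = OK
        rows.append(rec)
    meta = {"kind": "synergy_fraction", "grid": list(grid), "n_ratios": len(ratios) if ratios is not None else 200}
    return WorkspaceMap(records=pd.DataFrame(rows), metadata=meta)
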