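"""Parameter serialization (JSON) and CSV dialects shared by all modules.

Parameters travel as a versioned :class:`ParameterBundle` whose sections
mirror the model parameter types; omitted sections fall back to the
shipped default coefficient tables, and unknown sections or fields are
rejected.  Numeric series use fixed-header CSV:

* force surfaces:   alpha_pps, L_norm, F_norm
* stretch stimuli:  t_s, L, Ldot, gamma
* afferent traces:  t_s, x, y, mode
* plant trajectories: t_s, theta_rad, omega, L1, L2, F1, F2,
  y_ia_1, y_ii_1, y_ia_2, y_ii_2

Values are written at full precision (repr round-trip); reads reject NaN
values, naming the first offending row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .control import RestLengthParams, StiffnessParams
from .evaluation import GaussianActiveParams, PassiveParams
from .oculomotor import EyePlantParams, SpindleCoupling
from .spindle import AfferentTrace, SpindleIaParams, SpindleIIParams, StimulusProfile

__all__ = [
    "SCHEMA_VERSION",
    "ParameterBundle",
    "SchemaError",
    "load_params",
    "save_params",
    "defaults_checksum",
    "read_surface_csv",
    "write_surface_csv",
    "read_profile_csv",
    "write_profile_csv",
    "write_trace_csv",
    "write_trajectory_csv",
]

SCHEMA_VERSION = 1

#: SHA-256 of the canonical JSON of the shipped default parameter tables;
#: pins "package defaults" as a fixed, testable artifact.
DEFAULTS_SHA256 = "d6bdbeb658b219bcc33efa7111699246d77a159b85585026e2905987ae1bbac3"


class SchemaError(ValueError):
    """A parameter file violates the bundle schema."""


_SIMPLE_SECTIONS = {
    "evaluation_passive": PassiveParams,
    "rest_length": RestLengthParams,
    "spindle_ia": SpindleIaParams,
    "spindle_ii": SpindleIIParams,
}


@dataclass(frozen=True)
class ParameterBundle:
    """Versioned container for every model parameter set.

    ``provenance`` records where the numbers came from: "paper-default"
    for the shipped tables, "fitted" for pipeline output, "user" otherwise.
    """

    evaluation_active: GaussianActiveParams = field(default_factory=GaussianActiveParams)
    evaluation_passive: PassiveParams = field(default_factory=PassiveParams)
    rest_length: RestLengthParams = field(default_factory=RestLengthParams)
    stiffness: StiffnessParams = field(default_factory=StiffnessParams)
    spindle_ia: SpindleIaParams = field(default_factory=SpindleIaParams)
    spindle_ii: SpindleIIParams = field(default_factory=SpindleIIParams)
    eye_plant: dict = field(
        default_factory=lambda: {
            "J": 1.0,
            "R": 1.0,
            "beta": 20.0,
            "L10": 0.5,
            "L20": 0.5,
            "coupling_scale": 4.0,
            "coupling_offset": 1.0,
        }
    )
    provenance: str = "paper-default"

    def eye_plant_params(self, muscle=None) -> EyePlantParams:
        ep = self.eye_plant
        kwargs = dict(
            J=ep["J"], R=ep["R"], beta=ep["beta"], L10=ep["L10"], L20=ep["L20"],
            coupling=SpindleCoupling(ep["coupling_scale"], ep["coupling_offset"]),
        )
        if muscle is not None:
            kwargs["muscle"] = muscle
        return EyePlantParams(**kwargs)

    def to_dict(self) -> dict:
        d: dict = {"schema_version": SCHEMA_VERSION, "provenance": self.provenance}
        d["evaluation_active"] = {
            "row1": list(self.evaluation_active.row1),
            "row2": list(self.evaluation_active.row2),
            "row3": list(self.evaluation_active.row3),
        }
        for name, cls in _SIMPLE_SECTIONS.items():
            obj = getattr(self, name)
            d[name] = {f.name: getattr(obj, f.name) for f in dataclasses.fields(cls)}
        d["stiffness"] = {"k": [list(row) for row in self.stiffness.k]}
        d["eye_plant"] = dict(self.eye_plant)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterBundle":
        if not isinstance(d, dict):
            raise SchemaError("parameter file must contain a JSON object")
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version {version}")
        provenance = d.pop("provenance", "paper-default")
        if provenance not in ("paper-default", "fitted", "user"):
            raise SchemaError(f"unknown provenance {provenance!r}")
        kwargs: dict = {"provenance": provenance}
        bad: list = []
        if "evaluation_active" in d:
            sec = d.pop("evaluation_active")
            extra = set(sec) - {"row1", "row2", "row3"}
            if extra:
                bad += [f"evaluation_active.{k}" for k in sorted(extra)]
            else:
                kwargs["evaluation_active"] = GaussianActiveParams(
                    tuple(sec.get("row1", GaussianActiveParams().row1)),
                    tuple(sec.get("row2", GaussianActiveParams().row2)),
                    tuple(sec.get("row3", GaussianActiveParams().row3)),
                )
        for name, klass in _SIMPLE_SECTIONS.items():
            if name in d:
                sec = d.pop(name)
                known = {f.name for f in dataclasses.fields(klass)}
                extra = set(sec) - known
                if extra:
                    bad += [f"{name}.{k}" for k in sorted(extra)]
                else:
                    defaults = klass()
                    kwargs[name] = klass(
                        **{k: sec.get(k, getattr(defaults, k)) for k in known}
                    )
        if "stiffness" in d:
            sec = d.pop("stiffness")
            extra = set(sec) - {"k"}
            if extra:
                bad += [f"stiffness.{k}" for k in sorted(extra)]
            else:
                kwargs["stiffness"] = StiffnessParams(tuple(map(tuple, sec["k"])))
        if "eye_plant" in d:
            sec = d.pop("eye_plant")
            known = set(ParameterBundle().eye_plant)
            extra = set(sec) - known
            if extra:
                bad += [f"eye_plant.{k}" for k in sorted(extra)]
            else:
                merged = dict(ParameterBundle().eye_plant)
                merged.update(sec)
                kwargs["eye_plant"] = merged
        bad += sorted(d)  # any leftover top-level section is unknown
        if bad:
            raise SchemaError(f"unknown parameter fields: {', '.join(bad)}")
        return cls(**kwargs)


def load_params(path) -> ParameterBundle:
    """Load a JSON parameter file; omitted sections take the shipped defaults."""
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    return ParameterBundle.from_dict(data)


def save_params(bundle: ParameterBundle, path) -> None:
    """Write a bundle as JSON; load(save(b)) round-trips exactly."""
    Path(path).write_text(json.dumps(bundle.to_dict(), indent=2) + "\n")


def defaults_checksum() -> str:
    """SHA-256 of the canonical JSON of the default bundle."""
    canon = json.dumps(ParameterBundle().to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _read_csv(path, columns: tuple) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    extra = [c for c in df.columns if c not in columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    if extra:
        raise ValueError(f"unexpected column(s): {', '.join(extra)}")
    numeric = [c for c in columns if c != "mode"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        nan_rows = np.nonzero(vals.isna().to_numpy())[0]
        if nan_rows.size:
            raise ValueError(f"non-numeric or NaN value in column {col}, row {nan_rows[0]}")
        df[col] = vals
    return df[list(columns)]


def read_surface_csv(path) -> pd.DataFrame:
    """Read a force-surface table (alpha_pps, L_norm, F_norm)."""
    return _read_csv(path, ("alpha_pps", "L_norm", "F_norm"))


def write_surface_csv(table: pd.DataFrame, path) -> None:
    """Write a force-surface table at full precision."""
    cols = ("alpha_pps", "L_norm", "F_norm")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    table[list(cols)].to_csv(path, index=False, float_format="%.17g")


def read_profile_csv(path, *, consistency_rtol: float | None = 0.05) -> StimulusProfile:
    """Read a stretch stimulus (t_s, L, Ldot, gamma) into a StimulusProfile."""
    df = _read_csv(path, ("t_s", "L", "Ldot", "gamma"))
    return StimulusProfile(
        t=df["t_s"].to_numpy(),
        L=df["L"].to_numpy(),
        Ldot=df["Ldot"].to_numpy(),
        gamma=df["gamma"].to_numpy(),
        consistency_rtol=consistency_rtol,
    )


def write_profile_csv(profile: StimulusProfile, path) -> None:
    pd.DataFrame(
        {"t_s": profile.t, "L": profile.L, "Ldot": profile.Ldot, "gamma": profile.gamma}
    ).to_csv(path, index=False, float_format="%.17g")


def write_trace_csv(trace: AfferentTrace, path) -> None:
    """Write an afferent trace (t_s, x, y, mode)."""
    pd.DataFrame(
        {"t_s": trace.t, "x": trace.x, "y": trace.y, "mode": list(trace.mode)}
    ).to_csv(path, index=False, float_format="%.17g")


def write_trajectory_csv(traj, path) -> None:
    """Write an eye-plant trajectory with afferent channels."""
    data = {
        "t_s": traj.t, "theta_rad": traj.theta, "omega": traj.omega,
        "L1": traj.L1, "L2": traj.L2, "F1": traj.F1, "F2": traj.F2,
    }
    for ch in ("y_ia_1", "y_ii_1", "y_ia_2", "y_ii_2"):
        v = getattr(traj, ch)
        if v is not None:
            data[ch] = v
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
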