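"""Trajectory, configuration and result I/O, fixtures and run manifests.

On-disk formats are plain delimited text throughout:

* trajectories: CSV with header ``t,x,y[,attached,motor_x]`` (units s and
  um), ``#``-prefixed metadata lines, 12-significant-digit round trip;
* configs: TOML (read via tomllib) or JSON, one section per concern
  (``simulation``, ``detachment``, ``geometry``);
* result tables: CSV with ``#`` metadata headers;
* manifests: JSON snapshots (config, version, seeds, outputs) sufficient
  to re-run a stage bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import tomllib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import Geometry, SimConfig, Trajectory, simulate
from .errors import FormatError
from .kinetics import (
    CooperativeModel,
    DiscreteMixture,
    GammaMixture,
    MarkovRate,
    NonMarkovRate,
)
from .noise import FgnSpec, displacement_increments, generate_fgn

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_config",
    "write_config",
    "config_to_dict",
    "make_fixture",
    "RunManifest",
    "write_table",
    "default_preset",
]

_FLOAT_FMT = "%.12g"
_CORE_COLUMNS = ("t", "x", "y")
_OPTIONAL_COLUMNS = ("attached", "motor_x")


def write_trajectory(traj: Trajectory, path, metadata: Optional[dict] = None) -> None:
    """Write a trajectory as delimited text (12 significant digits)."""
    path = Path(path)
    cols = {"t": traj.times, "x": traj.x, "y": traj.y}
    if traj.attached is not None:
        cols["attached"] = traj.attached.astype(int)
    if traj.motor_x is not None:
        cols["motor_x"] = traj.motor_x
    cols.update(traj.extras)
    frame = pd.DataFrame(cols)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> Trajectory:
    """Read a trajectory file; rejects missing columns and non-uniform time.

    Unknown extra columns are preserved in ``Trajectory.extras``.
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _CORE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    t = frame["t"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2 header/0-based offset -> human line number of the offending row
        raise FormatError(
            f"{path}: time not strictly increasing at data row {bad[0] + 1} "
            f"(t={t[bad[0] + 1]!r})"
        )
    if t.size > 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0):
            raise FormatError(f"{path}: non-uniform time grid")
    known = set(_CORE_COLUMNS) | set(_OPTIONAL_COLUMNS)
    extras = {
        c: frame[c].to_numpy() for c in frame.columns if c not in known
    }
    return Trajectory(
        times=t,
        x=frame["x"].to_numpy(dtype=float),
        y=frame["y"].to_numpy(dtype=float),
        attached=frame["attached"].to_numpy(dtype=bool) if "attached" in frame else None,
        motor_x=frame["motor_x"].to_numpy(dtype=float) if "motor_x" in frame else None,
        extras=extras,
    )


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_DETACHMENT_FAMILIES = {
    "markov": MarkovRate,
    "nonmarkov": NonMarkovRate,
    "discrete_mixture": DiscreteMixture,
    "gamma_mixture": GammaMixture,
    "cooperative": CooperativeModel,
}


def _detachment_to_dict(model) -> Optional[dict]:
    if model is None:
        return None
    for tag, cls in _DETACHMENT_FAMILIES.items():
        if isinstance(model, cls):
            d = dataclasses.asdict(model)
            d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
            return {"family": tag, **d}
    raise FormatError(f"unknown detachment family {type(model).__name__}")


def _detachment_from_dict(block: Optional[dict]):
    if block is None:
        return None
    block = dict(block)
    tag = block.pop("family", None)
    if tag not in _DETACHMENT_FAMILIES:
        raise FormatError(
            f"unknown detachment family {tag!r}; expected one of "
            f"{sorted(_DETACHMENT_FAMILIES)}"
        )
    cls = _DETACHMENT_FAMILIES[tag]
    try:
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in block.items()})
    except (TypeError, ValueError) as exc:
        raise FormatError(f"invalid {tag} detachment parameters: {exc}") from exc


def config_to_dict(config: SimConfig, geometry: Optional[Geometry] = None) -> dict:
    sim = dataclasses.asdict(config)
    sim.pop("detachment")
    doc = {"simulation": sim, "detachment": _detachment_to_dict(config.detachment)}
    if geometry is not None:
        doc["geometry"] = {
            k: v for k, v in dataclasses.asdict(geometry).items() if v is not None
        }
    return doc


def _config_from_dict(doc: dict) -> tuple[SimConfig, Geometry]:
    sim = dict(doc.get("simulation", {}))
    unknown = set(sim) - {f.name for f in dataclasses.fields(SimConfig)}
    if unknown:
        raise FormatError(f"unknown simulation key(s): {sorted(unknown)}")
    sim["detachment"] = _detachment_from_dict(doc.get("detachment"))
    geo_block = doc.get("geometry", {})
    unknown = set(geo_block) - {f.name for f in dataclasses.fields(Geometry)}
    if unknown:
        raise FormatError(f"unknown geometry key(s): {sorted(unknown)}")
    try:
        return SimConfig(**sim), Geometry(**geo_block)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"invalid configuration: {exc}") from exc


def read_config(path) -> tuple[SimConfig, Geometry]:
    """Read a simulation config (.toml or .json)."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    elif path.suffix == ".json":
        with open(path) as fh:
            doc = json.load(fh)
    else:
        raise FormatError(f"unsupported config format {path.suffix!r} (use .toml or .json)")
    return _config_from_dict(doc)


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(v) for v in value) + "]"
    return json.dumps(str(value))


def write_config(config: SimConfig, path, geometry: Optional[Geometry] = None) -> None:
    """Write a config as TOML (or JSON when the path ends in .json)."""
    path = Path(path)
    doc = config_to_dict(config, geometry)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return
    lines = []
    for section, block in doc.items():
        if block is None:
            continue
        lines.append(f"[{section}]")
        for key, val in block.items():
            if val is None:
                continue
            lines.append(f"{key} = {_toml_scalar(val)}")
        lines.append("")
    path.write_text("\n".join(lines))


def default_preset(model: str = "nonmarkov") -> SimConfig:
    """The dynein-like reference parameter set used throughout the docs.

    model: 'nonmarkov' (mu=1.4, tau_d=1 s) or 'markov' (epsilon=0.25/s).
    """
    if model == "nonmarkov":
        det = NonMarkovRate(mu=1.4, tau_d=1.0, F_d=3.0)
    elif model == "markov":
        det = MarkovRate(epsilon=0.25, F_d=3.0)
    else:
        raise ValueError("model must be 'nonmarkov' or 'markov'")
    return SimConfig(detachment=det)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, params: Optional[dict] = None, seed: int = 0) -> Trajectory:
    """Deterministic synthetic trajectories emulating the recordings.

    Stand-ins for experimental single-particle tracks: sampling interval
    1e-4 s, durations of a few seconds, optional 20-nm localization noise
    (``sigma_nm``).  Kinds: ballistic, brownian, fgn, run_rest, full_model.
    """
    from .dynamics import add_measurement_noise  # local to avoid cycle noise
    from .scenarios import EnsembleRunConfig, ensemble_trajectories

    p = dict(params or {})
    kind_l = kind.lower()
    dt = p.pop("dt", 1e-4)
    duration = p.pop("duration", 2.0)
    sigma = p.pop("sigma_nm", 0.0)

    if kind_l == "ballistic":
        v = p.pop("speed", 1.0)
        times = np.arange(int(round(duration / dt)) + 1) * dt
        traj = Trajectory(times=times, x=v * times, y=np.zeros_like(times))
    elif kind_l in ("brownian", "fgn"):
        H = 0.5 if kind_l == "brownian" else p.pop("hurst", 0.35)
        amp = p.pop("amplitude", 0.002)
        beta = p.pop("drag", 0.72)
        n = int(round(duration / dt))
        ss = np.random.SeedSequence(seed)
        inc = [
            displacement_increments(
                generate_fgn(FgnSpec(hurst=H, n_steps=n, dt=dt, amplitude=amp, seed=s)),
                amp, beta, dt,
            )
            for s in ss.spawn(2)
        ]
        times = np.arange(n + 1) * dt
        traj = Trajectory(
            times=times,
            x=np.concatenate([[0.0], np.cumsum(inc[0])]),
            y=np.concatenate([[0.0], np.cumsum(inc[1])]),
        )
    elif kind_l == "run_rest":
        cfg = EnsembleRunConfig(
            residence=p.pop("residence", GammaMixture(mu=1.4, tau_d=1.0)),
            speed=p.pop("speed", 1.0),
            rest_rate=p.pop("rest_rate", 1.0),
            n_traj=1, duration=duration, sample_dt=dt, seed=seed,
        )
        traj = ensemble_trajectories(cfg)[0]
    elif kind_l == "full_model":
        cfg = dataclasses.replace(
            default_preset(p.pop("model", "nonmarkov")),
            duration=duration, dt=dt, seed=seed, **p,
        )
        p = {}
        traj = simulate(cfg)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if p:
        raise ValueError(f"unused fixture parameter(s): {sorted(p)}")
    if sigma > 0:
        traj = add_measurement_noise(traj, sigma, seed=np.random.SeedSequence([seed, 1]))
    return traj


# ---------------------------------------------------------------------------
# result tables and manifests
# ---------------------------------------------------------------------------


def write_table(frame: pd.DataFrame, path, metadata: Optional[dict] = None) -> None:
    """Write a result table as CSV with ``#``-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-run one stage bit-identically."""

    stage: str
    config: dict
    base_seed: int
    outputs: list
    version: str = __version__
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.UTC).isoformat()
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
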