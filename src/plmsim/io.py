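"""Session file format and synthetic-session generation.

A session is a header-bearing comma-delimited table of per-time-step records
plus a YAML sidecar (same path with ``.yaml`` appended) carrying per-block
decoder settings, task settings, and -- for synthetic fixtures -- the
ground-truth user parameters.  Required columns::

    time_s, block_id, trial_id, target_<ax>..., target_radius,
    cursor_<ax>..., u_<ax>...

with axis suffixes x, y, z (then d3, d4, ... beyond three dimensions).
Velocity columns ``vel_<ax>`` are stored when available; if absent they are
reconstructed by finite differences of position with a logged notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decoder import DecoderParams, SpeedTransform
from .engine import simulate_session_chain
from .piecewise import PiecewiseLinearFn
from .task import CenterOutLayout, RandomTargetLayout, TaskSpec
from .user import ControlPolicy, NoiseModel, UserModel

log = logging.getLogger("plmsim")

__all__ = ["Session", "SchemaError", "read_session", "write_session",
           "make_synthetic_session", "user_to_dict", "user_from_dict",
           "decoder_to_dict", "decoder_from_dict", "task_to_dict", "task_from_dict"]

_FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """A session file violates the schema."""


def _axes(dims: int):
    names = ["x", "y", "z"]
    return [names[i] if i < 3 else f"d{i}" for i in range(dims)]


@dataclass
class Session:
    """In-memory session: per-step table + per-block configuration."""

    df: pd.DataFrame
    blocks: dict = field(default_factory=dict)  # block_id -> config dict
    dims: int = 2

    def block_ids(self):
        return list(pd.unique(self.df["block_id"]))

    def block_frame(self, block_id) -> pd.DataFrame:
        return self.df[self.df["block_id"] == block_id]

    def block_decoder(self, block_id) -> DecoderParams:
        return decoder_from_dict(self.blocks[block_id]["decoder"])

    def block_task(self, block_id) -> TaskSpec:
        return task_from_dict(self.blocks[block_id]["task"])

    def arrays(self, block_id):
        """(positions, velocities, u, targets, radii) for one block."""
        f = self.block_frame(block_id)
        ax = _axes(self.dims)
        p = f[[f"cursor_{a}" for a in ax]].to_numpy(float)
        v = f[[f"vel_{a}" for a in ax]].to_numpy(float)
        u = f[[f"u_{a}" for a in ax]].to_numpy(float)
        g = f[[f"target_{a}" for a in ax]].to_numpy(float)
        r = f["target_radius"].to_numpy(float)
        return p, v, u, g, r


# ---------------------------------------------------------------------------
# config serialization

def _plf_to_dict(fn: PiecewiseLinearFn) -> dict:
    return {"knots": [float(k) for k in fn.knots],
            "values": [float(v) for v in fn.values]}


def _plf_from_dict(d) -> PiecewiseLinearFn:
    return PiecewiseLinearFn(d["knots"], d["values"])


def decoder_to_dict(p: DecoderParams) -> dict:
    tr = p.speed_transform
    t = {"variant": tr.variant}
    if tr.variant == "exponent":
        t["exponent_p"] = float(tr.exponent_p)
    elif tr.variant == "piecewise":
        t["breakpoints"] = [[float(a), float(b)] for a, b in tr.breakpoints]
    return {"gain_beta": float(p.gain_beta), "smoothing_alpha": float(p.smoothing_alpha),
            "dt": float(p.dt), "dims": int(p.dims), "transform": t}


def decoder_from_dict(d) -> DecoderParams:
    t = d.get("transform", {"variant": "identity"})
    tr = SpeedTransform(
        variant=t.get("variant", "identity"),
        exponent_p=float(t.get("exponent_p", 1.0)),
        breakpoints=tuple(map(tuple, t.get("breakpoints", ()))) or (),
    )
    return DecoderParams(gain_beta=d["gain_beta"], smoothing_alpha=d["smoothing_alpha"],
                         dt=d.get("dt", 0.02), dims=int(d.get("dims", 2)),
                         speed_transform=tr)


def task_to_dict(t: TaskSpec) -> dict:
    g = t.target_generator
    if isinstance(g, CenterOutLayout):
        layout = {"kind": "center_out", "distance": g.distance,
                  "target_radius": g.target_radius, "n_directions": g.n_directions}
    elif isinstance(g, RandomTargetLayout):
        layout = {"kind": "random", "halfwidth": g.halfwidth,
                  "radii": [float(r) for r in g.radii], "min_distance": g.min_distance}
    else:
        layout = {"kind": type(g).__name__}
    return {"layout": layout, "cursor_radius": t.cursor_radius, "dwell_s": t.dwell_s,
            "max_trial_s": t.max_trial_s, "inter_trial_s": t.inter_trial_s}


def task_from_dict(d) -> TaskSpec:
    lay = d.get("layout", {})
    kind = lay.get("kind", "center_out")
    if kind == "center_out":
        gen = CenterOutLayout(distance=lay.get("distance", 1.0),
                              target_radius=lay.get("target_radius", 0.1),
                              n_directions=int(lay.get("n_directions", 8)))
    elif kind == "random":
        gen = RandomTargetLayout(halfwidth=lay.get("halfwidth", 1.0),
                                 radii=tuple(lay.get("radii", (0.1,))),
                                 min_distance=lay.get("min_distance", 0.2))
    else:
        raise SchemaError(f"unknown task layout kind {kind!r}")
    return TaskSpec(target_generator=gen, cursor_radius=d.get("cursor_radius", 0.0),
                    dwell_s=d.get("dwell_s", 0.5), max_trial_s=d.get("max_trial_s", 10.0),
                    inter_trial_s=d.get("inter_trial_s", 0.0))


def user_to_dict(u: UserModel) -> dict:
    return {
        "delay_tau": int(u.delay_tau),
        "policy": {"f_targ": _plf_to_dict(u.policy.f_targ),
                   "f_vel": _plf_to_dict(u.policy.f_vel)},
        "noise": {
            "ar_coeffs": [np.asarray(P).tolist() for P in u.noise.ar_coeffs],
            "innovation_cov": np.asarray(u.noise.innovation_cov).tolist(),
            "sdn_fn": _plf_to_dict(u.noise.sdn_fn),
        },
    }


def user_from_dict(d) -> UserModel:
    pol = ControlPolicy(f_targ=_plf_from_dict(d["policy"]["f_targ"]),
                        f_vel=_plf_from_dict(d["policy"]["f_vel"]))
    nz = d["noise"]
    noise = NoiseModel(ar_coeffs=tuple(np.asarray(P, float) for P in nz["ar_coeffs"]),
                       innovation_cov=np.asarray(nz["innovation_cov"], float),
                       sdn_fn=_plf_from_dict(nz["sdn_fn"]))
    return UserModel(policy=pol, noise=noise, delay_tau=int(d["delay_tau"]))


# ---------------------------------------------------------------------------
# read / write

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".yaml")


def write_session(session: Session, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    session.df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    side = {"dims": int(session.dims), "blocks": session.blocks}
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(side, fh, sort_keys=False)


def _validate(df: pd.DataFrame, dims: int) -> None:
    ax = _axes(dims)
    required = (["time_s", "block_id", "trial_id", "target_radius"]
                + [f"target_{a}" for a in ax] + [f"cursor_{a}" for a in ax]
                + [f"u_{a}" for a in ax])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    num_cols = [c for c in df.columns if c not in ("block_id",)]
    bad = df[num_cols].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise SchemaError(f"NaN value at row {row}, column {col!r}")
    if (df["target_radius"] <= 0).any():
        row = int((df["target_radius"] <= 0).idxmax())
        raise SchemaError(f"non-positive target_radius at row {row}")
    # time strictly increasing within each trial; constant dt within block
    for bid, bf in df.groupby("block_id", sort=False):
        dts = np.diff(bf["time_s"].to_numpy(float))
        for tid, tf in bf.groupby("trial_id", sort=False):
            t = tf["time_s"].to_numpy(float)
            d = np.diff(t)
            if np.any(d <= 0):
                row = int(tf.index[1:][d <= 0][0])
                raise SchemaError(
                    f"time_s not strictly increasing within trial {tid} "
                    f"of block {bid} at row {row}")
        if len(dts) and np.any(np.abs(dts - np.median(dts)) > 1e-9):
            # allow the larger gaps exactly at trial boundaries (inter-trial)
            within = np.ones(len(dts), bool)
            tid = bf["trial_id"].to_numpy()
            within &= tid[1:] == tid[:-1]
            if np.any(np.abs(dts[within] - np.median(dts)) > 1e-9):
                row = int(bf.index[1:][within][np.abs(dts[within] - np.median(dts)) > 1e-9][0])
                raise SchemaError(f"non-constant dt within block {bid} at row {row}")


def read_session(path) -> Session:
    """Read and validate a session file (and its YAML sidecar)."""
    path = Path(path)
    df = pd.read_csv(path)
    side_path = _sidecar_path(path)
    side = {}
    if side_path.exists():
        with open(side_path) as fh:
            side = yaml.safe_load(fh) or {}
    dims = int(side.get("dims", 2))
    _validate(df, dims)
    ax = _axes(dims)
    vel_cols = [f"vel_{a}" for a in ax]
    if not all(c in df.columns for c in vel_cols):
        log.info("velocity columns absent in %s; reconstructing by finite "
                 "differences of position", path)
        for bid, bf in df.groupby("block_id", sort=False):
            t = bf["time_s"].to_numpy(float)
            dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
            for a in ax:
                p = bf[f"cursor_{a}"].to_numpy(float)
                v = np.empty_like(p)
                v[0] = (p[1] - p[0]) / dt if len(p) > 1 else 0.0
                v[1:] = np.diff(p) / dt
                df.loc[bf.index, f"vel_{a}"] = v
    return Session(df=df, blocks=side.get("blocks", {}), dims=dims)


def make_synthetic_session(ground_truth: UserModel, decoder: DecoderParams,
                           task: TaskSpec, duration_s: float, seed: int,
                           block_id: str = "b0") -> Session:
    """Simulate one continuous closed-loop block and package it as a session.

    The ground-truth parameters are embedded in the sidecar under
    ``ground_truth`` so recovery tests can compare against them.
    """
    out, outcomes = simulate_session_chain(ground_truth, decoder, task,
                                           duration_s, seed)
    d = decoder.dims
    ax = _axes(d)
    cols = {"time_s": out["time_s"], "block_id": block_id, "trial_id": out["trial_id"]}
    for i, a in enumerate(ax):
        cols[f"target_{a}"] = out["target"][:, i]
    cols["target_radius"] = out["target_radius"]
    for i, a in enumerate(ax):
        cols[f"cursor_{a}"] = out["position"][:, i]
    for i, a in enumerate(ax):
        cols[f"vel_{a}"] = out["velocity"][:, i]
    for i, a in enumerate(ax):
        cols[f"u_{a}"] = out["u"][:, i]
    df = pd.DataFrame(cols)
    blocks = {block_id: {
        "decoder": decoder_to_dict(decoder),
        "task": task_to_dict(task),
        "seed": int(seed),
        "ground_truth": user_to_dict(ground_truth),
        "outcomes": outcomes,
    }}
    return Session(df=df, blocks=blocks, dims=d)
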