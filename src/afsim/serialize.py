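"""Serialization: substrates (JSON + run-length-encoded masks), flat
key-value config files, trace/snapshot export, and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np

from .dynamics import EpisodeTrace
from .substrate import (
    ModelConfig,
    PhysicalParams,
    Substrate,
    coarse_grain_nu,
    model_config_from_physical,
)

__all__ = [
    "SCHEMA_VERSION",
    "encode_mask",
    "decode_mask",
    "substrate_to_dict",
    "substrate_from_dict",
    "save_substrate",
    "load_substrate",
    "parse_config",
    "write_config",
    "trace_to_csv",
    "events_to_json",
    "snapshot_to_text",
    "snapshot_from_text",
    "RunManifest",
    "write_manifest",
]

SCHEMA_VERSION = 1


# -- run-length-encoded boolean masks ---------------------------------------

def encode_mask(mask: np.ndarray) -> str:
    """Row-major RLE: ``"<first bit>;n1,n2,..."`` with alternating runs."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return "0;"
    change = np.flatnonzero(np.diff(flat.view(np.int8))) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds)
    return f"{int(flat[0])};" + ",".join(str(int(r)) for r in runs)


def decode_mask(encoded: str, shape: tuple[int, int]) -> np.ndarray:
    head, _, body = encoded.partition(";")
    first = bool(int(head))
    runs = [int(r) for r in body.split(",")] if body else []
    total = sum(runs)
    if total != shape[0] * shape[1]:
        raise ValueError(
            f"RLE length {total} does not match shape {shape} ({shape[0] * shape[1]} cells)"
        )
    flat = np.empty(total, dtype=bool)
    pos, value = 0, first
    for r in runs:
        flat[pos : pos + r] = value
        pos += r
        value = not value
    return flat.reshape(shape)


def _checksum(mask: np.ndarray) -> str:
    return hashlib.sha256(np.packbits(np.asarray(mask, dtype=bool)).tobytes()).hexdigest()


# -- substrate container -----------------------------------------------------

def substrate_to_dict(substrate: Substrate) -> dict:
    cfg = substrate.config
    masks = {
        "vertical_edges": substrate.vertical_edges,
        "dysfunctional": substrate.dysfunctional,
        "ablated": substrate.ablated,
    }
    return {
        "schema_version": SCHEMA_VERSION,
        "L": cfg.L,
        "shape": list(substrate.shape),
        "nu": cfg.nu,
        "delta": cfg.delta,
        "epsilon": cfg.epsilon,
        "tau": cfg.tau,
        "T": cfg.T,
        "seed": cfg.seed,
        **{name: encode_mask(mask) for name, mask in masks.items()},
        "checksums": {name: _checksum(mask) for name, mask in masks.items()},
    }


def substrate_from_dict(data: dict) -> Substrate:
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {data.get('schema_version')!r}")
    shape = tuple(data.get("shape", (data["L"], data["L"])))
    masks = {}
    for name in ("vertical_edges", "dysfunctional", "ablated"):
        mask = decode_mask(data[name], shape)
        expected = data.get("checksums", {}).get(name)
        if expected is not None and _checksum(mask) != expected:
            raise ValueError(f"checksum mismatch for mask {name!r}")
        masks[name] = mask
    config = ModelConfig(
        L=data["L"],
        nu=data["nu"],
        delta=data["delta"],
        epsilon=data["epsilon"],
        tau=data["tau"],
        T=data["T"],
        seed=data["seed"],
    )
    return Substrate(config=config, **masks)


def save_substrate(substrate: Substrate, path: str | Path) -> None:
    Path(path).write_text(json.dumps(substrate_to_dict(substrate)) + "\n")


def load_substrate(path: str | Path) -> Substrate:
    return substrate_from_dict(json.loads(Path(path).read_text()))


# -- flat key-value config files ---------------------------------------------

_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}
_PHYS_KEYS = {f.name for f in dataclasses.fields(PhysicalParams)}
_INT_KEYS = {"L", "tau", "T", "seed", "b"}


def _parse_kv(text: str) -> dict:
    values: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    return values


def parse_config(
    path: Optional[str | Path] = None,
    overrides: Optional[dict] = None,
    mode: str = "dimensionless",
) -> ModelConfig:
    """Build a validated ModelConfig from a config file and/or overrides.

    ``mode="dimensionless"`` accepts ModelConfig keys; an empty config
    yields the defaults (L=200, tau=50, delta=epsilon=0.05, T=220).
    ``mode="physical"`` accepts PhysicalParams keys plus nu/delta/epsilon/
    seed (or ``nu_fine``, coarse-grained with b) and converts.  Overrides
    (e.g. CLI flags) take precedence over file values; unknown keys and
    out-of-range values raise errors naming the key.
    """
    values = _parse_kv(Path(path).read_text()) if path else {}
    for key, val in (overrides or {}).items():
        if val is not None:
            values[key] = val

    def pop_typed(key: str, raw):
        if isinstance(raw, str):
            try:
                return int(raw) if key in _INT_KEYS else float(raw)
            except ValueError:
                raise ValueError(f"config key {key!r}: cannot parse value {raw!r}") from None
        return raw

    if mode == "dimensionless":
        unknown = set(values) - _MODEL_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {k: pop_typed(k, v) for k, v in values.items()}
        return ModelConfig(**kwargs)
    if mode == "physical":
        allowed = _PHYS_KEYS | {"nu", "nu_fine", "delta", "epsilon", "seed"}
        unknown = set(values) - allowed
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        typed = {k: pop_typed(k, v) for k, v in values.items()}
        phys = PhysicalParams(**{k: v for k, v in typed.items() if k in _PHYS_KEYS})
        if "nu_fine" in typed and "nu" in typed:
            raise ValueError("give either 'nu' (coarse-grained) or 'nu_fine', not both")
        nu = typed.get("nu", coarse_grain_nu(typed["nu_fine"], phys.b) if "nu_fine" in typed else 0.18)
        return model_config_from_physical(
            phys,
            nu=nu,
            delta=typed.get("delta", 0.05),
            epsilon=typed.get("epsilon", 0.05),
            seed=int(typed.get("seed", 0)),
        )
    raise ValueError(f"mode must be 'dimensionless' or 'physical', got {mode!r}")


def write_config(config: ModelConfig, path: str | Path) -> None:
    lines = [f"{f.name} = {getattr(config, f.name)}" for f in dataclasses.fields(config)]
    Path(path).write_text("\n".join(lines) + "\n")


# -- trace / snapshot export --------------------------------------------------

def trace_to_csv(trace: EpisodeTrace, path: str | Path) -> None:
    """CSV of (t, n_excited); t counts steps from the start of the episode."""
    with open(path, "w") as fh:
        fh.write("t,n_excited\n")
        for i, n in enumerate(trace.n_excited, start=1):
            fh.write(f"{i},{int(n)}\n")


def events_to_json(trace: EpisodeTrace, path: str | Path) -> None:
    payload = [
        {"t": int(t), "kind": kind, "payload": payload_}
        for t, kind, payload_ in trace.events
    ]
    Path(path).write_text(json.dumps(payload, default=int) + "\n")


def snapshot_to_text(grid: np.ndarray, t: int, path: str | Path) -> None:
    """Dense counter grid: header ``rows cols t``, then one row per line."""
    R, C = grid.shape
    with open(path, "w") as fh:
        fh.write(f"{R} {C} {t}\n")
        for row in grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def snapshot_from_text(path: str | Path) -> tuple[np.ndarray, int]:
    lines = Path(path).read_text().splitlines()
    R, C, t = (int(v) for v in lines[0].split())
    grid = np.array([[int(v) for v in line.split()] for line in lines[1 : R + 1]])
    if grid.shape != (R, C):
        raise ValueError(f"snapshot body {grid.shape} does not match header ({R}, {C})")
    return grid, t


# -- run manifest --------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RunManifest:
    schema_version: int
    parameters: dict
    seed_schedule: str
    software_version: str
    timestamp: str
    outputs: list


def write_manifest(
    path: str | Path,
    parameters: dict,
    outputs: list,
    seed_schedule: str = "single seed",
) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        schema_version=SCHEMA_VERSION,
        parameters=parameters,
        seed_schedule=seed_schedule,
        software_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        outputs=[str(o) for o in outputs],
    )
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return manifest
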